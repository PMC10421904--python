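"""Time integration under piecewise-constant salt forcing.

Integration uses an adaptive Runge-Kutta pair (``RK45``) restarted at
every protocol breakpoint so forcing discontinuities are resolved
exactly; a stiff fallback (``LSODA``) kicks in if the explicit solver
fails.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.integrate import solve_ivp

from .model import (
    Genotype,
    ModelParameters,
    ModelState,
    SaltProtocol,
    WILD_TYPE,
    rhs_array,
)
from .steady import find_steady_state

__all__ = ["IntegrationError", "Trajectory", "simulate", "salt_step_experiment"]

#: Protocol constants of the published salt-step experiment.
SALT_STEP_VALUE = 0.5
SALT_STEP_T_END = 50.0


class IntegrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class Trajectory:
    """Sampled solution of the ODE system under a salt protocol."""

    times: np.ndarray  # (n,) strictly increasing, starting at 0
    states: np.ndarray  # (n, 3) columns CK, PHB, miR166
    protocol: SaltProtocol
    genotype: Genotype
    params: ModelParameters

    @property
    def CK(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def PHB(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def miR166(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def salt(self) -> np.ndarray:
        return np.array([self.protocol.salt_at(t) for t in self.times])

    def state_at(self, index: int) -> ModelState:
        return ModelState.from_array(self.states[index])

    @property
    def final_state(self) -> ModelState:
        return self.state_at(-1)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("time\tCK\tPHB\tmiR166\tsalt\n")
            for t, (ck, phb, mir), s in zip(self.times, self.states, self.salt):
                fh.write(f"{t:.10g}\t{ck:.12g}\t{phb:.12g}\t{mir:.12g}\t{s:.10g}\n")

    def manifest(self) -> dict:
        return {
            "command": "simulate",
            "parameters": self.params.to_dict(),
            "genotype": dataclasses.asdict(self.genotype),
            "protocol": [list(seg) for seg in self.protocol.segments],
            "t_end": float(self.times[-1]),
            "n_samples": int(len(self.times)),
        }

    def write_manifest(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _integrate_segment(
    params: ModelParameters,
    genotype: Genotype,
    salt: float,
    y0: np.ndarray,
    t0: float,
    t1: float,
    t_eval: np.ndarray,
    rtol: float,
    atol: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate one constant-salt interval; returns (samples, final state)."""

    def f(t: float, y: np.ndarray) -> np.ndarray:
        return rhs_array(y, params, salt, genotype)

    # always sample the segment end so the next segment starts exactly there
    pad_end = len(t_eval) == 0 or t_eval[-1] < t1
    grid = np.append(t_eval, t1) if pad_end else t_eval
    sol = None
    for method in ("RK45", "LSODA"):
        sol = solve_ivp(
            f, (t0, t1), y0, method=method, t_eval=grid,
            rtol=rtol, atol=atol, dense_output=False,
        )
        if sol.success:
            all_samples = sol.y.T
            y_end = all_samples[-1]
            samples = all_samples[:-1] if pad_end else all_samples
            return samples, y_end
    raise IntegrationError(
        f"integration failed on [{t0}, {t1}] at salt={salt} "
        f"(genotype={genotype.name}): {sol.message}"
    )


def simulate(
    params: ModelParameters,
    genotype: Genotype,
    protocol: SaltProtocol,
    t_end: float,
    init: ModelState,
    n_samples: int = 501,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate from ``init`` over ``[0, t_end]`` under ``protocol``.

    Samples are returned on a uniform grid of ``n_samples`` points
    including both endpoints.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    times = np.linspace(0.0, t_end, n_samples)
    states = np.empty((n_samples, 3))
    y = init.as_array()
    filled = np.zeros(n_samples, dtype=bool)
    for t0, t1, salt in protocol.intervals(t_end):
        # sample points inside (t0, t1]; t=0 is the initial condition
        mask = ((times > t0) if t0 > 0 else (times >= t0)) & (times <= t1)
        t_eval = times[mask]
        samples, y = _integrate_segment(
            params, genotype, salt, y, t0, t1, t_eval, rtol, atol
        )
        states[mask] = samples
        filled[mask] = True
    if not filled.all():  # pragma: no cover - defensive
        raise IntegrationError("sampling grid not fully covered by protocol")
    return Trajectory(
        times=times, states=states, protocol=protocol, genotype=genotype,
        params=params,
    )


def states_at(
    params: ModelParameters,
    genotype: Genotype,
    protocol: SaltProtocol,
    times: np.ndarray,
    init: ModelState,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """States sampled exactly at the requested (sorted, >= 0) times.

    Unlike :func:`simulate` the sample grid need not be uniform; used
    where solver-accurate values at arbitrary times are required.
    """
    times = np.asarray(times, dtype=float)
    if len(times) == 0:
        return np.empty((0, 3))
    if (times < 0).any() or (np.diff(times) < 0).any():
        raise ValueError("times must be sorted and >= 0")
    t_end = float(times[-1])
    states = np.empty((len(times), 3))
    y = init.as_array()
    states[times == 0.0] = y
    if t_end == 0.0:
        return states
    for t0, t1, salt in protocol.intervals(t_end):
        mask = (times > t0) & (times <= t1)
        samples, y = _integrate_segment(
            params, genotype, salt, y, t0, t1, times[mask], rtol, atol
        )
        states[mask] = samples
    return states


def salt_step_experiment(
    params: ModelParameters,
    genotype: Genotype = WILD_TYPE,
    salt_after: float = SALT_STEP_VALUE,
    t_end: float = SALT_STEP_T_END,
    n_samples: int = 501,
) -> Trajectory:
    """Published perturbation protocol: start at the salt=0 steady state,
    step salt to 0.5 at t=0, integrate to t=50."""
    init = find_steady_state(params, 0.0, genotype).state
    protocol = SaltProtocol.step(salt_after, at_time=0.0)
    return simulate(params, genotype, protocol, t_end, init, n_samples=n_samples)
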