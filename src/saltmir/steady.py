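"""Steady-state solver and salt-gradient sweeps.

``find_steady_state`` uses damped fixed-point iteration on the
steady-state relations (the system is nearly triangular at Hill
coefficient 1) followed by a Newton-type polish with ``scipy.optimize.root``.
``sweep_salt`` continues the solution along a salt grid.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import optimize

from .model import (
    Genotype,
    ModelParameters,
    ModelState,
    WILD_TYPE,
    production_terms,
    rhs,
)

__all__ = [
    "SteadyStateError",
    "SteadyStateResult",
    "SteadyStateSweep",
    "find_steady_state",
    "sweep_salt",
]


class SteadyStateError(RuntimeError):
    """Steady-state iteration failed to converge; carries the best residual."""

    def __init__(self, message: str, best_state: ModelState, residual: float):
        super().__init__(message)
        self.best_state = best_state
        self.residual = residual


@dataclass(frozen=True)
class SteadyStateResult:
    state: ModelState
    residual: float  # ||rhs||_inf at the returned state
    converged: bool
    iterations: int


@dataclass(frozen=True)
class SteadyStateSweep:
    """Steady states along an increasing salt grid."""

    salt_grid: np.ndarray
    states: tuple[ModelState, ...]
    residuals: np.ndarray
    converged: np.ndarray
    genotype: Genotype
    params: ModelParameters

    def column(self, name: str) -> np.ndarray:
        return np.array([getattr(s, name) for s in self.states])

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("salt\tCK\tPHB\tmiR166\tresidual\tconverged\n")
            for salt, st, res, ok in zip(
                self.salt_grid, self.states, self.residuals, self.converged
            ):
                fh.write(
                    f"{salt:.10g}\t{st.CK:.12g}\t{st.PHB:.12g}\t"
                    f"{st.miR166:.12g}\t{res:.3g}\t{bool(ok)}\n"
                )

    def manifest(self) -> dict:
        return {
            "command": "sweep_salt",
            "parameters": self.params.to_dict(),
            "genotype": dataclasses.asdict(self.genotype),
            "salt_min": float(self.salt_grid[0]),
            "salt_max": float(self.salt_grid[-1]),
            "n_points": int(len(self.salt_grid)),
        }

    def write_manifest(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _fixed_point_map(
    y: np.ndarray, params: ModelParameters, salt: float, genotype: Genotype
) -> np.ndarray:
    """One pass of the steady-state relations solved component-wise."""
    p = params
    state = ModelState(*(max(v, 0.0) for v in y))
    ck_prod, phb_prod, mir_prod = production_terms(state, p, salt)
    ck = ck_prod / p.dCK
    mir = mir_prod / p.dmiR
    denom = p.dPHB + p.dPHBmiR * genotype.dPHBmiR_multiplier * max(mir, 0.0)
    if denom <= 0:
        return np.array([ck, y[1], mir])
    return np.array([ck, phb_prod / denom, mir])


def find_steady_state(
    params: ModelParameters,
    salt: float,
    genotype: Genotype = WILD_TYPE,
    tol: float = 1e-10,
    initial_guess: ModelState | None = None,
    max_iter: int = 2000,
    damping: float = 0.5,
) -> SteadyStateResult:
    """Solve ``rhs(state) = 0`` for the given salt level and genotype.

    Deterministic for fixed inputs. Raises :class:`SteadyStateError` if
    the residual cannot be driven below ``tol``.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    y = (initial_guess or ModelState(1.0, 1.0, 1.0)).as_array()

    def residual_inf(vec: np.ndarray) -> float:
        return float(
            np.max(np.abs(rhs(ModelState(*vec), params, salt, genotype)))
        )

    # Damped fixed-point phase: cheap global contraction toward the basin.
    iterations = 0
    for iterations in range(1, max_iter + 1):
        y_new = (1.0 - damping) * y + damping * _fixed_point_map(
            y, params, salt, genotype
        )
        if np.max(np.abs(y_new - y)) < max(tol, 1e-13):
            y = y_new
            break
        y = y_new

    # Newton polish on the actual right-hand side.
    sol = optimize.root(
        lambda vec: rhs(
            ModelState(*(max(v, 0.0) for v in vec)), params, salt, genotype
        ),
        y,
        method="hybr",
        tol=1e-13,
    )
    # accept the polish on residual improvement alone: hybr can reach
    # machine precision yet still report failure on its progress test
    candidate = np.maximum(sol.x, 0.0)
    if np.all(np.isfinite(candidate)) and residual_inf(candidate) <= residual_inf(y):
        y = candidate

    res = residual_inf(y)
    state = ModelState(*y)
    if res >= tol:
        raise SteadyStateError(
            f"steady state did not converge (residual {res:.3g} >= tol {tol:.3g})"
            f" at salt={salt}, genotype={genotype.name}",
            state,
            res,
        )
    return SteadyStateResult(state=state, residual=res, converged=True,
                             iterations=iterations)


def sweep_salt(
    params: ModelParameters,
    genotype: Genotype = WILD_TYPE,
    salt_min: float = 0.0,
    salt_max: float = 10.0,
    n_points: int = 101,
    tol: float = 1e-10,
) -> SteadyStateSweep:
    """Steady states on an even salt grid, continued point-to-point.

    Each grid point is seeded from the previous solution so the sweep
    tracks a single branch.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if salt_max <= salt_min:
        raise ValueError("salt_max must exceed salt_min")
    grid = np.linspace(salt_min, salt_max, n_points)
    states: list[ModelState] = []
    residuals = np.empty(n_points)
    converged = np.zeros(n_points, dtype=bool)
    guess: ModelState | None = None
    for i, salt in enumerate(grid):
        try:
            result = find_steady_state(
                params, float(salt), genotype, tol=tol, initial_guess=guess
            )
        except SteadyStateError as err:
            raise SteadyStateError(
                f"sweep failed at grid point {i} (salt={salt}): {err}",
                err.best_state,
                err.residual,
            ) from err
        states.append(result.state)
        residuals[i] = result.residual
        converged[i] = result.converged
        guess = result.state
    return SteadyStateSweep(
        salt_grid=grid,
        states=tuple(states),
        residuals=residuals,
        converged=converged,
        genotype=genotype,
        params=params,
    )


def verify_uniqueness(
    params: ModelParameters,
    salt: float,
    genotype: Genotype = WILD_TYPE,
    tol: float = 1e-6,
) -> bool:
    """Multi-start check that 8 lattice starts in [0, 3]^3 agree on one state."""
    starts = [
        ModelState(a, b, c) for a in (0.5, 2.5) for b in (0.5, 2.5)
        for c in (0.5, 2.5)
    ]
    solutions = [
        find_steady_state(params, salt, genotype, initial_guess=s).state.as_array()
        for s in starts
    ]
    ref = solutions[0]
    return all(np.max(np.abs(s - ref)) < tol for s in solutions[1:])
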