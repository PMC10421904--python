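"""Shared fixtures and the independent long-time-integration oracle.

The oracle re-states the model equations from scratch (multiplicative
repression dialect, additive PHB degradation) and integrates them with
scipy directly, so steady-state results can be cross-checked against a
route that shares no code with the package solver.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from saltmir import ModelParameters, ModelState, PHB_1D, WILD_TYPE


@pytest.fixture
def params() -> ModelParameters:
    return ModelParameters()


@pytest.fixture
def wild_type():
    return WILD_TYPE


@pytest.fixture
def phb_1d():
    return PHB_1D


def oracle_rhs(y, p: ModelParameters, salt: float, mir_multiplier: float):
    """Literal multiplicative-dialect equations, written independently."""
    CK, PHB, miR = y

    def hill(x, K):
        return x ** p.n / (K ** p.n + x ** p.n)

    dCK = p.alphaCK + p.betaCK1 * hill(PHB, p.betaCK2) - p.dCK * CK
    dPHB = p.alphaPHB * (1.0 - hill(CK, p.betaPHB2)) - (
        p.dPHB + p.dPHBmiR * mir_multiplier * miR
    ) * PHB
    dmiR = (p.alphamiR / (1.0 + salt)) * (1.0 - hill(CK, p.betamiR2)) - p.dmiR * miR
    return [dCK, dPHB, dmiR]


def oracle_steady_state(
    p: ModelParameters,
    salt: float,
    mir_multiplier: float = 1.0,
    t_end: float = 500.0,
    y0=(1.0, 1.0, 1.0),
) -> np.ndarray:
    """Steady state by long-time integration from (1,1,1)."""
    sol = solve_ivp(
        lambda t, y: oracle_rhs(y, p, salt, mir_multiplier),
        (0.0, t_end),
        list(y0),
        rtol=1e-12,
        atol=1e-14,
    )
    assert sol.success
    return sol.y[:, -1]


def jittered_parameters(rng: np.random.Generator) -> ModelParameters:
    """Default parameters with every rate/constant jittered by +/-20%.

    The Hill coefficient and dialect are left at their defaults (n has a
    hard lower bound of 1, so a symmetric jitter is not admissible).
    """
    base = ModelParameters().to_dict()
    jittered = {
        k: v * (1.0 + rng.uniform(-0.2, 0.2))
        for k, v in base.items()
        if k not in ("n", "dialect")
    }
    return ModelParameters(**jittered)
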