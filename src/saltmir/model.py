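"""Core model: parameters, state, genotypes, salt forcing, and the ODE right-hand side.

The model couples three species — cytokinin (``CK``), the HD-ZIPIII
transcription factor PHABULOSA (``PHB``) and the pooled microRNA
``miR166`` (miR165/166) — in an incoherent feedforward loop. Salt enters
only through the basal miR transcription term, ``alphamiR / (1 + salt)``.

The repression terms can be resolved in three algebraically distinct ways
(the *dialect*); see :data:`DIALECTS`. The default, ``multiplicative``,
keeps all production terms nonnegative for any salt level.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import yaml

__all__ = [
    "DIALECTS",
    "ModelParameters",
    "ModelState",
    "Genotype",
    "WILD_TYPE",
    "PHB_1D",
    "genotype_from_name",
    "SaltProtocol",
    "hill_activation",
    "production_terms",
    "rhs",
]

#: Supported resolutions of the repression (Hill) terms.
DIALECTS = ("multiplicative", "subtractive_clamped", "literal_plus")

_POSITIVE_FIELDS = ("betaCK2", "betaPHB2", "betamiR2", "dCK", "dmiR")


class ConfigError(ValueError):
    """Raised on invalid parameter values or unknown configuration keys."""


@dataclass(frozen=True)
class ModelParameters:
    """All rate constants of the ODE system plus the repression dialect.

    Defaults reproduce the published parameter table: every value 1
    except the dissociation constants ``betaCK2`` (0.5), ``betaPHB2``
    and ``betamiR2`` (both 0.4). ``dmiR`` has no published value and
    defaults to 1 like every other unit-valued rate.
    """

    alphaCK: float = 1.0  # basal CK production
    betaCK1: float = 1.0  # max PHB-induced CK synthesis
    betaCK2: float = 0.5  # dissociation constant, PHB -> CK activation
    dCK: float = 1.0  # CK degradation
    alphaPHB: float = 1.0  # basal PHB transcription
    betaPHB1: float = 1.0  # max CK-inhibited PHB transcription
    betaPHB2: float = 0.4  # dissociation constant, CK -| PHB
    dPHB: float = 1.0  # baseline PHB degradation
    dPHBmiR: float = 1.0  # miR-induced PHB degradation rate constant
    alphamiR: float = 1.0  # basal miR transcription
    betamiR1: float = 1.0  # max CK-inhibited miR transcription
    betamiR2: float = 0.4  # dissociation constant, CK -| miR
    dmiR: float = 1.0  # miR degradation
    n: float = 1.0  # Hill coefficient
    dialect: str = "multiplicative"

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if f.name == "dialect":
                continue
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ConfigError(f"parameter {f.name} must be finite, got {v}")
            if v < 0:
                raise ConfigError(f"parameter {f.name} must be >= 0, got {v}")
        for name in _POSITIVE_FIELDS:
            if getattr(self, name) <= 0:
                raise ConfigError(f"parameter {name} must be > 0")
        if self.n < 1:
            raise ConfigError(f"Hill coefficient n must be >= 1, got {self.n}")
        if self.dialect not in DIALECTS:
            raise ConfigError(
                f"unknown dialect {self.dialect!r}; expected one of {DIALECTS}"
            )

    def replace(self, **changes: object) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelParameters":
        """Load parameters from a flat YAML key-value file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config {path} must be a flat key-value mapping")
        return cls.from_dict(raw)


@dataclass(frozen=True)
class ModelState:
    """Concentrations (arbitrary units) of the three model species."""

    CK: float
    PHB: float
    miR166: float

    def __post_init__(self) -> None:
        for name in ("CK", "PHB", "miR166"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"state component {name} must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.CK, self.PHB, self.miR166], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "ModelState":
        if len(y) != 3:
            raise ValueError("state vector must have exactly 3 components")
        return cls(float(y[0]), float(y[1]), float(y[2]))


@dataclass(frozen=True)
class Genotype:
    """A genotype is a multiplier on the miR-induced PHB degradation rate."""

    name: str
    dPHBmiR_multiplier: float

    def __post_init__(self) -> None:
        if self.dPHBmiR_multiplier < 0:
            raise ValueError("dPHBmiR_multiplier must be >= 0")


WILD_TYPE = Genotype("wild_type", 1.0)
PHB_1D = Genotype("phb_1d", 0.0)  # PHB transcript insensitive to miR165/166

_GENOTYPES = {g.name: g for g in (WILD_TYPE, PHB_1D)}


def genotype_from_name(name: str) -> Genotype:
    try:
        return _GENOTYPES[name]
    except KeyError:
        raise ConfigError(
            f"unknown genotype {name!r}; expected one of {sorted(_GENOTYPES)}"
        ) from None


@dataclass(frozen=True)
class SaltProtocol:
    """Piecewise-constant salt forcing.

    ``segments`` is an ordered tuple of ``(start_time, salt_value)``
    pairs; each segment holds from its start time until the next
    segment's start (the last segment holds forever).
    """

    segments: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        object.__setattr__(
            self,
            "segments",
            tuple((float(t), float(s)) for t, s in self.segments),
        )
        times = [t for t, _ in self.segments]
        if times[0] != 0.0:
            raise ValueError("first segment must start at time 0")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("segment start times must be strictly increasing")
        if any(s < 0 for _, s in self.segments):
            raise ValueError("salt values must be >= 0")

    @classmethod
    def constant(cls, salt: float) -> "SaltProtocol":
        return cls(((0.0, salt),))

    @classmethod
    def step(cls, salt_after: float, at_time: float = 0.0,
             salt_before: float = 0.0) -> "SaltProtocol":
        if at_time == 0.0:
            return cls(((0.0, salt_after),))
        return cls(((0.0, salt_before), (at_time, salt_after)))

    def salt_at(self, t: float) -> float:
        value = self.segments[0][1]
        for start, salt in self.segments:
            if t >= start:
                value = salt
            else:
                break
        return value

    def intervals(self, t_end: float) -> Iterator[tuple[float, float, float]]:
        """Yield ``(t0, t1, salt)`` covering ``[0, t_end]``."""
        starts = [t for t, _ in self.segments] + [t_end]
        for (t0, salt), t1 in zip(self.segments, starts[1:]):
            if t0 >= t_end:
                break
            yield t0, min(t1, t_end), salt


def hill_activation(x: float, K: float, n: float) -> float:
    """Saturating activation ``x**n / (K**n + x**n)``.

    Zero at ``x == 0``, half-maximal at ``x == K``, tends to 1 as x grows.
    """
    if x < 0:
        raise ValueError(f"hill_activation requires x >= 0, got {x}")
    if K <= 0:
        raise ValueError(f"hill_activation requires K > 0, got {K}")
    xn = x ** n
    return xn / (K ** n + xn)


def production_terms(
    state: ModelState, params: ModelParameters, salt: float
) -> tuple[float, float, float]:
    """Production rates (CK, PHB, miR166) under the configured dialect.

    CK production is the same in every dialect. The CK-repressed PHB and
    miR terms differ:

    - ``multiplicative``: ``alpha * (1 - hill(CK, K, n))``
    - ``subtractive_clamped``: ``max(0, alpha - beta1 * hill(CK, K, n))``
    - ``literal_plus``: ``alpha - beta1 / (1 + (CK/K)**n)`` (may go negative)
    """
    if salt < 0:
        raise ValueError(f"salt must be >= 0, got {salt}")
    p = params
    ck_prod = p.alphaCK + p.betaCK1 * hill_activation(state.PHB, p.betaCK2, p.n)
    alpha_mir = p.alphamiR / (1.0 + salt)
    if p.dialect == "multiplicative":
        phb_prod = p.alphaPHB * (1.0 - hill_activation(state.CK, p.betaPHB2, p.n))
        mir_prod = alpha_mir * (1.0 - hill_activation(state.CK, p.betamiR2, p.n))
    elif p.dialect == "subtractive_clamped":
        phb_prod = max(
            0.0, p.alphaPHB - p.betaPHB1 * hill_activation(state.CK, p.betaPHB2, p.n)
        )
        mir_prod = max(
            0.0, alpha_mir - p.betamiR1 * hill_activation(state.CK, p.betamiR2, p.n)
        )
    elif p.dialect == "literal_plus":
        phb_prod = p.alphaPHB - p.betaPHB1 / (1.0 + (state.CK / p.betaPHB2) ** p.n)
        mir_prod = alpha_mir - p.betamiR1 / (1.0 + (state.CK / p.betamiR2) ** p.n)
    else:  # pragma: no cover - guarded by ModelParameters validation
        raise ConfigError(f"unknown dialect {p.dialect!r}")
    return ck_prod, phb_prod, mir_prod


def rhs(
    state: ModelState,
    params: ModelParameters,
    salt: float,
    genotype: Genotype = WILD_TYPE,
) -> np.ndarray:
    """Time derivative ``(dCK/dt, dPHB/dt, dmiR166/dt)``.

    PHB degradation is additive in its baseline and miR-induced routes:
    ``(dPHB + dPHBmiR * multiplier * miR166) * PHB``, so PHB stays
    bounded in the phb-1d mutant (multiplier 0).
    """
    ck_prod, phb_prod, mir_prod = production_terms(state, params, salt)
    p = params
    d_ck = ck_prod - p.dCK * state.CK
    d_phb = phb_prod - (
        p.dPHB + p.dPHBmiR * genotype.dPHBmiR_multiplier * state.miR166
    ) * state.PHB
    d_mir = mir_prod - p.dmiR * state.miR166
    return np.array([d_ck, d_phb, d_mir], dtype=float)


def rhs_array(
    y: np.ndarray,
    params: ModelParameters,
    salt: float,
    genotype: Genotype = WILD_TYPE,
) -> np.ndarray:
    """Array-in/array-out variant of :func:`rhs` for ODE solvers.

    Negative excursions from solver overshoot are tolerated: Hill terms
    are evaluated at ``max(y, 0)``.
    """
    ck, phb, mir = (max(float(v), 0.0) for v in y)
    return rhs(ModelState(ck, phb, mir), params, salt, genotype)
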