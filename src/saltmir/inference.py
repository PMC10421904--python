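"""Parameter estimation from fold-change datasets.

Fits a small menu of structurally identifiable parameters (the dose
anchor ``s_ref``, the degradation rate ``dmiR``, the basal transcription
rate ``alphamiR``, and the model-time-per-hour ``time_scale``) by
least squares on log2 fold changes, via multi-start bounded local
optimisation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from .model import Genotype, ModelParameters, WILD_TYPE, genotype_from_name
from .steady import SteadyStateError
from .synth import DoseMap, SyntheticDataset, true_fold_changes
from .timecourse import IntegrationError

__all__ = ["FREE_PARAMETERS", "FitError", "FitResult", "loss", "fit"]

#: Parameters that may be freed during fitting (identifiability guard).
FREE_PARAMETERS = ("s_ref", "dmiR", "alphamiR", "time_scale")

#: Returned in place of the loss when the model cannot be evaluated.
EVALUATION_PENALTY = 1e6


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class FitResult:
    """Outcome of a multi-start fit; the best start is the reported one."""

    free_parameters: dict[str, float]
    loss: float
    n_starts: int
    start_losses: tuple[float, ...]
    converged: tuple[bool, ...]
    seed: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _apply_assignment(
    params: ModelParameters,
    metadata: Mapping,
    assignment: Mapping[str, float],
) -> tuple[ModelParameters, DoseMap, float]:
    unknown = set(assignment) - set(FREE_PARAMETERS)
    if unknown:
        raise ValueError(f"unknown free parameters: {sorted(unknown)}")
    updates = {k: float(v) for k, v in assignment.items() if k in ("dmiR", "alphamiR")}
    if updates:
        params = params.replace(**updates)
    s_ref = float(assignment.get("s_ref", metadata.get("s_ref", 0.5)))
    ref_dose = float(metadata.get("ref_dose_mM", 150.0))
    time_scale = float(assignment.get("time_scale", metadata.get("time_scale", 2.0)))
    return params, DoseMap(s_ref=s_ref, ref_dose_mM=ref_dose), time_scale


def loss(
    dataset: SyntheticDataset,
    params: ModelParameters,
    genotype: Genotype,
    free_assignment: Mapping[str, float],
) -> float:
    """Sum of squared log2 fold-change errors under the assignment.

    Solver failures inside the evaluation return a large finite penalty
    rather than raising, so optimisers can route around bad regions.
    """
    try:
        params, dose_map, time_scale = _apply_assignment(
            params, dataset.metadata, free_assignment
        )
    except (ValueError, TypeError):
        raise
    records = dataset.records
    total = 0.0
    try:
        for dose, group in records.groupby("dose_mM", sort=True):
            times = np.sort(group["time_h"].unique())
            fc = true_fold_changes(
                params, genotype, float(dose), times, dose_map, time_scale
            )
            model_fc = {
                gene: dict(zip(times, fc[gene])) for gene in ("miR166", "PHB")
            }
            for gene, t, observed in zip(
                group["gene"], group["time_h"], group["fold_change"]
            ):
                predicted = model_fc[gene][t]
                if predicted <= 0:
                    return EVALUATION_PENALTY
                total += (np.log2(observed) - np.log2(predicted)) ** 2
    except (SteadyStateError, IntegrationError):
        return EVALUATION_PENALTY
    return float(total)


def fit(
    dataset: SyntheticDataset,
    free_params: Sequence[str],
    bounds: Mapping[str, tuple[float, float]],
    params: ModelParameters | None = None,
    genotype: Genotype | None = None,
    n_starts: int = 8,
    seed: int = 0,
) -> FitResult:
    """Multi-start bounded least-squares fit of 1-3 free parameters.

    Starts are drawn uniformly within bounds from a seeded generator
    (the first start is the bounds midpoint), each refined with Powell's
    method. Deterministic given ``seed``.
    """
    free_params = list(free_params)
    if not 1 <= len(free_params) <= 3:
        raise ValueError("between 1 and 3 free parameters are supported")
    unknown = set(free_params) - set(FREE_PARAMETERS)
    if unknown:
        raise ValueError(f"unknown free parameters: {sorted(unknown)}")
    missing = set(free_params) - set(bounds)
    if missing:
        raise ValueError(f"missing bounds for: {sorted(missing)}")
    for name in free_params:
        lo, hi = bounds[name]
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError(f"bounds for {name} must be finite with lo < hi")
    if params is None:
        params = ModelParameters(**{
            k: v for k, v in dataset.metadata.get("parameters", {}).items()
        }) if dataset.metadata.get("parameters") else ModelParameters()
    if genotype is None:
        genotype = genotype_from_name(dataset.metadata.get("genotype", "wild_type"))

    lo = np.array([bounds[name][0] for name in free_params])
    hi = np.array([bounds[name][1] for name in free_params])
    rng = np.random.default_rng(seed)
    starts = [0.5 * (lo + hi)]
    starts += [lo + rng.uniform(size=len(free_params)) * (hi - lo)
               for _ in range(n_starts - 1)]

    def objective(x: np.ndarray) -> float:
        x = np.clip(x, lo, hi)
        return loss(dataset, params, genotype, dict(zip(free_params, x)))

    best_x: np.ndarray | None = None
    best_loss = np.inf
    start_losses: list[float] = []
    converged: list[bool] = []
    for x0 in starts:
        try:
            res = optimize.minimize(
                objective, x0, method="Powell",
                bounds=list(zip(lo, hi)),
                options={"xtol": 1e-8, "ftol": 1e-12, "maxiter": 200},
            )
        except Exception:
            start_losses.append(float("inf"))
            converged.append(False)
            continue
        value = float(res.fun)
        start_losses.append(value)
        converged.append(bool(res.success))
        if value < best_loss:
            best_loss = value
            best_x = np.clip(res.x, lo, hi)
    if best_x is None or not np.isfinite(best_loss):
        raise FitError("all optimisation starts failed")

    fitted = dict(zip(free_params, (float(v) for v in best_x)))
    # self-consistency: report the loss recomputed at the fitted values
    final_loss = loss(dataset, params, genotype, fitted)
    return FitResult(
        free_parameters=fitted,
        loss=final_loss,
        n_starts=n_starts,
        start_losses=tuple(start_losses),
        converged=tuple(converged),
        seed=seed,
    )


def grid_search_1d(
    dataset: SyntheticDataset,
    name: str,
    grid: np.ndarray,
    params: ModelParameters | None = None,
    genotype: Genotype | None = None,
) -> tuple[float, float]:
    """Exhaustive 1-D search; the independent check for 1-parameter fits.

    Returns ``(best_value, best_loss)``.
    """
    if params is None:
        params = ModelParameters(**dataset.metadata.get("parameters", {})) \
            if dataset.metadata.get("parameters") else ModelParameters()
    if genotype is None:
        genotype = genotype_from_name(dataset.metadata.get("genotype", "wild_type"))
    losses = [loss(dataset, params, genotype, {name: float(v)}) for v in grid]
    i = int(np.argmin(losses))
    return float(grid[i]), float(losses[i])
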