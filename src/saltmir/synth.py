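"""Synthetic qRT-PCR-like fold-change datasets.

Emulates 2^-ddCt readouts of miR166 and PHB relative to the untreated
control: the "true" fold change of a gene is its level on the treated
trajectory divided by its level at the untreated (salt = 0) steady
state, and measured replicates carry i.i.d. multiplicative lognormal
noise (normal on the log2 scale).

Doses in mM NaCl map linearly onto the model's dimensionless salt
variable through one anchor: 150 mM corresponds to salt = ``s_ref``
(default 0.5). Model time maps to hours through ``time_scale``
(model-time units per hour, default 2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    Genotype,
    ModelParameters,
    ModelState,
    SaltProtocol,
    WILD_TYPE,
)
from .steady import find_steady_state
from .timecourse import states_at

__all__ = [
    "DoseMap",
    "SyntheticDataset",
    "true_fold_change",
    "true_fold_changes",
    "generate_timecourse",
    "generate_dose_response",
]

DEFAULT_TIMEPOINTS_H = (0.5, 1.0, 1.5, 2.0, 3.0, 4.0)
DEFAULT_DOSES_MM = (0.0, 100.0, 150.0, 200.0)
DEFAULT_TIME_SCALE = 2.0  # model-time units per hour
DATASET_COLUMNS = ("gene", "dose_mM", "time_h", "replicate", "fold_change")


@dataclass(frozen=True)
class DoseMap:
    """Linear map from NaCl dose (mM) to the model's salt variable."""

    s_ref: float = 0.5  # salt value corresponding to ref_dose_mM
    ref_dose_mM: float = 150.0

    def __post_init__(self) -> None:
        if self.s_ref < 0:
            raise ValueError("s_ref must be >= 0")
        if self.ref_dose_mM <= 0:
            raise ValueError("ref_dose_mM must be > 0")

    def salt(self, dose_mM: float) -> float:
        if dose_mM < 0:
            raise ValueError("dose_mM must be >= 0")
        return self.s_ref * dose_mM / self.ref_dose_mM


@dataclass(frozen=True)
class SyntheticDataset:
    """Replicate fold-change measurements with generation metadata.

    ``records`` has columns gene, dose_mM, time_h, replicate,
    fold_change; regeneration with the same seed is bit-identical.
    """

    records: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(DATASET_COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"dataset missing columns: {sorted(missing)}")
        if (self.records["fold_change"] <= 0).any():
            raise ValueError("fold changes must be strictly positive")

    def write_tsv(self, path: str | Path, metadata_path: str | Path | None = None) -> None:
        path = Path(path)
        self.records.to_csv(path, sep="\t", index=False, float_format="%.12g")
        side = Path(metadata_path) if metadata_path else path.with_suffix(".meta.json")
        with open(side, "w") as fh:
            json.dump(self.metadata, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def read_tsv(cls, path: str | Path, metadata_path: str | Path | None = None) -> "SyntheticDataset":
        path = Path(path)
        records = pd.read_csv(path, sep="\t")
        side = Path(metadata_path) if metadata_path else path.with_suffix(".meta.json")
        metadata: dict = {}
        if side.exists():
            with open(side) as fh:
                metadata = json.load(fh)
        return cls(records=records, metadata=metadata)


def true_fold_changes(
    params: ModelParameters,
    genotype: Genotype,
    dose_mM: float,
    times_h: Sequence[float],
    dose_map: DoseMap | None = None,
    time_scale: float = DEFAULT_TIME_SCALE,
) -> dict[str, np.ndarray]:
    """Noise-free fold changes of miR166 and PHB at several timepoints.

    One integration serves all timepoints of a dose. Returns arrays
    aligned with ``times_h`` under keys ``"miR166"`` and ``"PHB"``.
    """
    if time_scale <= 0:
        raise ValueError("time_scale must be > 0")
    if any(t < 0 for t in times_h):
        raise ValueError("times_h must be >= 0")
    dose_map = dose_map or DoseMap()
    control = find_steady_state(params, 0.0, genotype).state
    salt = dose_map.salt(dose_mM)
    times_model = np.asarray([t * time_scale for t in times_h], dtype=float)
    if salt == 0.0:
        levels = {
            "miR166": np.full(len(times_model), control.miR166),
            "PHB": np.full(len(times_model), control.PHB),
        }
    else:
        order = np.argsort(times_model, kind="stable")
        sampled = states_at(
            params, genotype, SaltProtocol.constant(salt),
            times_model[order], init=control,
        )
        states = np.empty_like(sampled)
        states[order] = sampled
        levels = {"miR166": states[:, 2], "PHB": states[:, 1]}
    return {
        "miR166": levels["miR166"] / control.miR166,
        "PHB": levels["PHB"] / control.PHB,
    }


def true_fold_change(
    params: ModelParameters,
    genotype: Genotype,
    dose_mM: float,
    time_h: float,
    dose_map: DoseMap | None = None,
    time_scale: float = DEFAULT_TIME_SCALE,
) -> tuple[float, float]:
    """Noise-free ``(FC_miR166, FC_PHB)`` at a single dose and time."""
    fc = true_fold_changes(params, genotype, dose_mM, [time_h], dose_map, time_scale)
    return float(fc["miR166"][0]), float(fc["PHB"][0])


def _generate(
    params: ModelParameters,
    genotype: Genotype,
    doses_mM: Sequence[float],
    timepoints_h: Sequence[float],
    n_reps: int,
    noise_sd_log2: float,
    seed: int,
    dose_map: DoseMap,
    time_scale: float,
    design: str,
) -> SyntheticDataset:
    if noise_sd_log2 < 0:
        raise ValueError("noise_sd_log2 must be >= 0")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    rows: list[tuple] = []
    for dose in doses_mM:
        fc = true_fold_changes(params, genotype, dose, timepoints_h, dose_map, time_scale)
        for gene in ("miR166", "PHB"):
            for t, true_fc in zip(timepoints_h, fc[gene]):
                eps = rng.normal(0.0, noise_sd_log2, size=n_reps) if noise_sd_log2 > 0 else np.zeros(n_reps)
                for rep, e in enumerate(eps, start=1):
                    rows.append((gene, float(dose), float(t), rep, float(true_fc * 2.0 ** e)))
    records = pd.DataFrame(rows, columns=list(DATASET_COLUMNS))
    metadata = {
        "design": design,
        "parameters": params.to_dict(),
        "genotype": genotype.name,
        "doses_mM": [float(d) for d in doses_mM],
        "timepoints_h": [float(t) for t in timepoints_h],
        "s_ref": dose_map.s_ref,
        "ref_dose_mM": dose_map.ref_dose_mM,
        "time_scale": time_scale,
        "noise_sd_log2": noise_sd_log2,
        "n_reps": n_reps,
        "seed": seed,
    }
    return SyntheticDataset(records=records, metadata=metadata)


def generate_timecourse(
    params: ModelParameters,
    genotype: Genotype = WILD_TYPE,
    timepoints_h: Sequence[float] = DEFAULT_TIMEPOINTS_H,
    dose_mM: float = 150.0,
    n_reps: int = 3,
    noise_sd_log2: float = 0.15,
    seed: int = 0,
    dose_map: DoseMap | None = None,
    time_scale: float = DEFAULT_TIME_SCALE,
) -> SyntheticDataset:
    """Fold-change time course at one dose (default: 150 mM, 0.5-4 h)."""
    return _generate(
        params, genotype, [dose_mM], timepoints_h, n_reps, noise_sd_log2,
        seed, dose_map or DoseMap(), time_scale, design="timecourse",
    )


def generate_dose_response(
    params: ModelParameters,
    genotype: Genotype = WILD_TYPE,
    doses_mM: Sequence[float] = DEFAULT_DOSES_MM,
    time_h: float = 5.0,
    n_reps: int = 3,
    noise_sd_log2: float = 0.15,
    seed: int = 0,
    dose_map: DoseMap | None = None,
    time_scale: float = DEFAULT_TIME_SCALE,
) -> SyntheticDataset:
    """Fold changes across doses at one timepoint (default: 5 h)."""
    return _generate(
        params, genotype, doses_mM, [time_h], n_reps, noise_sd_log2,
        seed, dose_map or DoseMap(), time_scale, design="dose_response",
    )
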