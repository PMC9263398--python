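"""Cohort data model: subject phenotypes and ROI time series, with I/O.

Phenotypes live in a pandas DataFrame (one row per subject) holding the group
label, the GLM covariates (age, sex, education, mean frame displacement) and
the clinical rating-scale scores.  Time series are per-subject units x time
matrices; the default operating grain is one unit per ROI, but a finer
unit-to-ROI map (voxel-like units) is supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import ParcellationAtlas

#: Clinical rating scales carried on the phenotype table.
CLINICAL_SCORES = [
    "AD8", "MMSE", "MoCA", "DSC", "DST-forward", "DST-backward", "LNS",
    "CF-animal", "CF-fruit", "CF-color", "CF-city", "FMT", "HADS-A", "HADS-D",
]

#: Printed ranges of the rating scales (min, max); None = unbounded above.
SCORE_RANGES: dict[str, tuple[float, float | None]] = {
    "AD8": (0, 8), "MMSE": (0, 30), "MoCA": (0, 30), "DSC": (0, None),
    "DST-forward": (0, None), "DST-backward": (0, None), "LNS": (0, None),
    "CF-animal": (0, None), "CF-fruit": (0, None), "CF-color": (0, None),
    "CF-city": (0, None), "FMT": (0, None), "HADS-A": (0, 21), "HADS-D": (0, 21),
}

GROUPS = ("SCD", "NC")
PHENOTYPE_COLUMNS = ["subject_id", "group", "age", "sex", "education", "mean_fd"]


@dataclass
class RoiTimeSeries:
    """One subject's units x timepoints matrix with its sampling interval.

    ``unit_roi_ids`` maps each matrix row to a 1-based atlas roi_id; an id of
    0 marks a unit outside every ROI (dropped during aggregation).  At the
    default ROI grain there is exactly one unit per ROI.
    """

    subject_id: str
    data: np.ndarray
    tr: float
    unit_roi_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"{self.subject_id}: series must be 2-D (units x time)")
        if self.tr <= 0:
            raise ValueError(f"{self.subject_id}: tr must be positive")
        if self.unit_roi_ids is not None:
            self.unit_roi_ids = np.asarray(self.unit_roi_ids, dtype=int)
            if self.unit_roi_ids.shape != (self.data.shape[0],):
                raise ValueError(f"{self.subject_id}: unit_roi_ids length mismatch")

    @property
    def n_units(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    def validate(self) -> None:
        if not np.isfinite(self.data).all():
            raise ValueError(f"{self.subject_id}: series contains non-finite values")


@dataclass
class CohortDataset:
    """Atlas + phenotypes + one time series per subject."""

    atlas: ParcellationAtlas
    phenotypes: pd.DataFrame
    series: dict[str, RoiTimeSeries] = field(default_factory=dict)
    config_hash: str = ""

    def validate(self) -> None:
        pheno_ids = list(self.phenotypes["subject_id"])
        missing = [s for s in pheno_ids if s not in self.series]
        if missing:
            raise ValueError(f"missing time series for subject(s): {missing}")
        extra = [s for s in self.series if s not in set(pheno_ids)]
        if extra:
            raise ValueError(f"time series without phenotype row: {extra}")
        lengths = {s.n_timepoints for s in self.series.values()}
        if len(lengths) > 1:
            raise ValueError(f"timepoint count differs across subjects: {sorted(lengths)}")
        trs = {s.tr for s in self.series.values()}
        if len(trs) > 1:
            raise ValueError(f"tr differs across subjects: {sorted(trs)}")
        for s in self.series.values():
            s.validate()
        validate_phenotypes(self.phenotypes)

    @property
    def n_subjects(self) -> int:
        return len(self.phenotypes)

    def group_sizes(self) -> dict[str, int]:
        return self.phenotypes["group"].value_counts().to_dict()


def validate_phenotypes(pheno: pd.DataFrame) -> None:
    """Check required columns, group labels, and printed score ranges."""
    missing = [c for c in PHENOTYPE_COLUMNS if c not in pheno.columns]
    if missing:
        raise ValueError(f"phenotype table missing column(s): {missing}")
    if pheno["group"].isna().any():
        raise ValueError("phenotype table has missing group labels")
    bad = set(pheno["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown group label(s): {sorted(bad)}")
    if (pheno["mean_fd"] < 0).any():
        raise ValueError("mean_fd must be non-negative")
    for score, (lo, hi) in SCORE_RANGES.items():
        if score not in pheno.columns:
            continue
        vals = pheno[score].dropna()
        if (vals < lo).any() or (hi is not None and (vals > hi).any()):
            raise ValueError(f"clinical score {score} outside its printed range [{lo}, {hi}]")


def load_phenotypes(path) -> pd.DataFrame:
    pheno = pd.read_csv(path)
    validate_phenotypes(pheno)
    return pheno


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, index=False)


def _read_matrix(path: Path) -> np.ndarray:
    if path.suffix == ".npy":
        return np.load(path)
    delim = "," if path.suffix == ".csv" else None
    return np.loadtxt(path, delimiter=delim, ndmin=2)


def load_series(path, subject_id: str, tr: float,
                unit_roi_ids: np.ndarray | None = None) -> RoiTimeSeries:
    """Read one subject's units x time matrix (TSV/CSV/whitespace text or .npy)."""
    data = _read_matrix(Path(path))
    return RoiTimeSeries(subject_id=subject_id, data=data, tr=tr,
                         unit_roi_ids=unit_roi_ids)


def write_series(series: RoiTimeSeries, path) -> None:
    np.savetxt(path, series.data, delimiter="\t", fmt="%.10g")


def load_cohort(atlas_path, phenotype_path, series_dir, tr: float) -> CohortDataset:
    """Assemble and validate a cohort from files on disk.

    ``series_dir`` must hold one file per phenotype subject_id, named
    ``<subject_id>.tsv`` (or .csv/.txt/.npy).  Units are assumed to be in
    filtered-atlas ROI order unless a ``units.tsv`` map is present (columns:
    unit index, roi_id).
    """
    from .atlas import load_atlas

    atlas = load_atlas(atlas_path)
    pheno = load_phenotypes(phenotype_path)
    series_dir = Path(series_dir)
    unit_map_path = series_dir / "units.tsv"
    unit_roi_ids = None
    if unit_map_path.exists():
        unit_roi_ids = pd.read_csv(unit_map_path, sep="\t")["roi_id"].to_numpy(int)

    series: dict[str, RoiTimeSeries] = {}
    missing: list[str] = []
    for sid in pheno["subject_id"]:
        for ext in (".tsv", ".csv", ".txt", ".npy"):
            p = series_dir / f"{sid}{ext}"
            if p.exists():
                uids = unit_roi_ids if unit_roi_ids is not None else atlas.roi_ids
                series[sid] = load_series(p, sid, tr, unit_roi_ids=uids)
                break
        else:
            missing.append(sid)
    if missing:
        raise FileNotFoundError(f"no series file for subject(s): {missing}")

    dataset = CohortDataset(atlas=atlas, phenotypes=pheno, series=series)
    dataset.validate()
    return dataset


def apply_enrollment_exclusions(n_screened: int, exclusions: dict[str, int]) -> int:
    """Number of analyzable subjects after staged enrollment exclusions.

    ``exclusions`` maps reason -> count (e.g. psychiatric history, MCI,
    structural lesions, scanner motion).  Counts must not exceed the pool.
    """
    n = int(n_screened)
    for reason, count in exclusions.items():
        if count < 0:
            raise ValueError(f"negative exclusion count for {reason!r}")
        if count > n:
            raise ValueError(f"exclusion {reason!r} ({count}) exceeds remaining pool ({n})")
        n -= int(count)
    return n
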