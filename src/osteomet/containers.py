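"""Core in-memory containers shared across the pipeline.

The central object is :class:`IntensityMatrix`, a metabolites x samples table
of LC-MS peak intensities that carries a *stage* tag recording how far along
the preprocessing chain (raw -> imputed -> filtered -> normalized -> log) it
has travelled.  Stage transitions are enforced so that, e.g., total-intensity
normalization cannot run on a matrix that still contains missing cells.

Sample metadata travels as a plain :class:`pandas.DataFrame` with a small
validation helper; longitudinal baseline-ratio data as :class:`ResponseMatrix`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Preprocessing stages, in the only order transitions are allowed.
STAGES = ("raw", "imputed", "filtered", "normalized", "log")

#: Required columns of an RCT sample table.
RCT_SAMPLE_COLUMNS = ("sample", "subject", "arm", "time")

#: Required columns of a case-control cohort sample table.
COHORT_SAMPLE_COLUMNS = ("sample", "subject", "age", "height", "weight", "bmi",
                         "tibia_vbmd")

ARMS = ("treatment", "placebo")


class StageError(RuntimeError):
    """Raised when a preprocessing operation is applied out of order."""


class IntensityMatrix:
    """Metabolites x samples peak-intensity matrix with a processing stage tag.

    Parameters
    ----------
    data:
        DataFrame indexed by metabolite id with one column per sample id.
        Missing cells are NaN.  All finite values must be non-negative
        (intensities are peak areas).
    stage:
        One of :data:`STAGES`.
    """

    def __init__(self, data: pd.DataFrame, stage: str = "raw"):
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate metabolite ids: {dups[:5]}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        values = data.to_numpy(dtype=float)
        if stage != "log" and np.any(values[np.isfinite(values)] < 0):
            raise ValueError("negative intensities are not allowed before the "
                             "log stage")
        self.data = data.astype(float)
        self.stage = stage

    # ------------------------------------------------------------------
    @property
    def metabolites(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def missing_mask(self) -> pd.DataFrame:
        """Boolean mask of missing cells (True = missing)."""
        return self.data.isna()

    def require_stage(self, *allowed: str) -> None:
        if self.stage not in allowed:
            raise StageError(
                f"operation requires stage in {allowed}, matrix is at "
                f"{self.stage!r} (allowed order: {' -> '.join(STAGES)})")

    def advanced(self, data: pd.DataFrame, stage: str) -> "IntensityMatrix":
        """Return a new matrix at ``stage``, enforcing forward-only moves."""
        if STAGES.index(stage) <= STAGES.index(self.stage):
            raise StageError(f"cannot move from {self.stage!r} back/sideways "
                             f"to {stage!r}")
        return IntensityMatrix(data, stage)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        m, n = self.shape
        return f"IntensityMatrix({m} metabolites x {n} samples, stage={self.stage!r})"


def validate_rct_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Validate an RCT sample table (one row per serum sample)."""
    missing = [c for c in RCT_SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"sample table is missing columns {missing}")
    bad = set(samples["arm"]) - set(ARMS)
    if bad:
        raise ValueError(f"unknown arm labels {sorted(bad)}; expected {ARMS}")
    if samples["sample"].duplicated().any():
        dup = samples.loc[samples["sample"].duplicated(), "sample"].iloc[0]
        raise ValueError(f"duplicate sample id {dup!r}")
    if samples.duplicated(subset=["subject", "time"]).any():
        raise ValueError("more than one sample for some (subject, time)")
    return samples


def validate_cohort_samples(samples: pd.DataFrame) -> pd.DataFrame:
    """Validate a case-control cohort sample table (one row per woman)."""
    missing = [c for c in COHORT_SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns {missing}")
    if samples["sample"].duplicated().any():
        dup = samples.loc[samples["sample"].duplicated(), "sample"].iloc[0]
        raise ValueError(f"duplicate sample id {dup!r}")
    return samples


@dataclass
class ResponseMatrix:
    """Per-subject follow-up/baseline intensity ratios.

    ``ratios`` is indexed by metabolite id with a (subject, time) column
    MultiIndex covering follow-up times only; every ratio is positive.
    ``arms`` maps subject id -> arm label; ``excluded_subjects`` records
    subjects dropped for incomplete longitudinal series.
    """

    ratios: pd.DataFrame
    arms: pd.Series
    time_points: tuple[int, ...]
    excluded_subjects: list = field(default_factory=list)

    def subjects(self) -> pd.Index:
        return self.ratios.columns.get_level_values("subject").unique()

    def at_time(self, time: int) -> pd.DataFrame:
        """Metabolite x subject ratio slice for one follow-up time."""
        sub = self.ratios.xs(time, axis=1, level="time")
        return sub

    def arm_of(self, subjects) -> np.ndarray:
        return self.arms.loc[subjects].to_numpy()


@dataclass
class GroundTruth:
    """Planted signal bookkeeping for synthetic datasets."""

    responsive_ids: list = field(default_factory=list)
    group_marker_ids: list = field(default_factory=list)
    effects: dict = field(default_factory=dict)  # id -> signed log2 effect

    def to_dict(self) -> dict:
        return {
            "responsive_ids": list(self.responsive_ids),
            "group_marker_ids": list(self.group_marker_ids),
            "effects": {str(k): float(v) for k, v in self.effects.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            responsive_ids=list(d.get("responsive_ids", [])),
            group_marker_ids=list(d.get("group_marker_ids", [])),
            effects={k: float(v) for k, v in d.get("effects", {}).items()},
        )
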