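"""Preprocessing chain for untargeted LC-MS peak intensities.

Order is fixed and enforced by the stage tag on :class:`IntensityMatrix`:

1. :func:`impute` — replace missing cells with draws from a *downshifted*
   normal on the log scale: Normal(mu - shift_factor*sigma,
   (width_factor*sigma)^2) with mu, sigma the mean/SD of observed log
   intensities in the configured scope (default: per sample).  This models
   detection-limit (left-censored) missingness: signals too weak to be
   picked are simulated from the low tail of the observed distribution.
2. :func:`filter_missing` — keep metabolites whose *original* missing
   fraction is strictly below a threshold (default 25%).
3. :func:`normalize_total` — divide each sample by its total-intensity
   correction factor (total_i / min_j total_j), equalising sample totals to
   correct for serum-volume differences.
4. :func:`log_transform` — natural log, elementwise.

Imputation happens on log intensities and is exponentiated back, so imputed
peak areas are always positive; a configurable floor clips the extreme low
tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import IntensityMatrix, StageError

__all__ = ["ImputeParams", "FilterParams", "impute", "filter_missing",
           "normalize_total", "log_transform"]


@dataclass
class ImputeParams:
    """Downshifted-normal imputation parameters.

    width_factor
        Width of the imputation normal as a multiple of the observed SD.
    shift_factor
        Downshift of its centre as a multiple of the observed SD.
    scope
        Unit over which mu and sigma are estimated: ``per_sample`` (column,
        default — the standard practice for left-censored proteomics and
        metabolomics imputation), ``per_metabolite`` (row) or ``global``.
    log_scale
        Estimate moments (and draw) on log intensities, exponentiating back.
    floor_factor
        Imputed raw-scale values are clipped from below at
        ``min positive observed * floor_factor``.
    """

    width_factor: float = 0.5
    shift_factor: float = 2.5
    scope: str = "per_sample"
    log_scale: bool = True
    floor_factor: float = 1e-3
    seed: int = 0

    def validate(self) -> None:
        if self.width_factor <= 0:
            raise ValueError("width_factor must be > 0")
        if self.shift_factor < 0:
            raise ValueError("shift_factor must be >= 0")
        if self.scope not in ("per_sample", "per_metabolite", "global"):
            raise ValueError(f"unknown scope {self.scope!r}")


@dataclass
class FilterParams:
    """Missingness filter: keep metabolites with fraction < threshold."""

    max_missing_fraction: float = 0.25

    def validate(self) -> None:
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction must lie in [0, 1]")


def impute(matrix: IntensityMatrix, params: ImputeParams | None = None
           ) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Impute left-censored missing cells; returns (matrix, imputation mask).

    The mask is a boolean DataFrame aligned with the matrix, True where a
    cell was imputed.  Observed cells are never altered.  Deterministic under
    ``params.seed``.
    """
    params = params or ImputeParams()
    params.validate()
    matrix.require_stage("raw")
    data = matrix.data
    mask = data.isna()
    if not mask.to_numpy().any():
        return matrix.advanced(data.copy(), "imputed"), mask

    rng = np.random.default_rng(params.seed)
    observed = data.to_numpy()
    positive = observed[np.isfinite(observed) & (observed > 0)]
    if positive.size == 0:
        raise ValueError("matrix has no positive observed values to anchor "
                         "the imputation floor")
    floor = float(positive.min()) * params.floor_factor

    work = np.log(data.to_numpy()) if params.log_scale else data.to_numpy().copy()
    out = work.copy()

    def fill(unit_label: str, values: np.ndarray, sel: np.ndarray) -> np.ndarray:
        obs = values[~np.isnan(values)]
        if obs.size < 2:
            raise ValueError(
                f"cannot impute {unit_label}: fewer than 2 observed values")
        mu = obs.mean()
        sd = obs.std(ddof=1)
        n_missing = int(np.isnan(values).sum())
        return rng.normal(mu - params.shift_factor * sd,
                          params.width_factor * sd, size=n_missing)

    if params.scope == "per_sample":
        for j, col in enumerate(data.columns):
            col_missing = np.isnan(work[:, j])
            if col_missing.any():
                out[col_missing, j] = fill(f"sample {col!r}", work[:, j],
                                           col_missing)
    elif params.scope == "per_metabolite":
        for i, idx in enumerate(data.index):
            row_missing = np.isnan(work[i])
            if row_missing.any():
                out[i, row_missing] = fill(f"metabolite {idx!r}", work[i],
                                           row_missing)
    else:
        flat = work.ravel()
        flat_missing = np.isnan(flat)
        filled = fill("global scope", flat, flat_missing)
        flat = flat.copy()
        flat[flat_missing] = filled
        out = flat.reshape(work.shape)

    if params.log_scale:
        out = np.exp(out)
    np.maximum(out, floor, out=out, where=mask.to_numpy())
    # restore observed cells exactly (guards float round-trip through log)
    obs_sel = ~mask.to_numpy()
    out[obs_sel] = data.to_numpy()[obs_sel]

    imputed = pd.DataFrame(out, index=data.index, columns=data.columns)
    return matrix.advanced(imputed, "imputed"), mask


def filter_missing(matrix: IntensityMatrix, mask: pd.DataFrame,
                   params: FilterParams | None = None
                   ) -> tuple[IntensityMatrix, dict]:
    """Keep metabolites whose pre-imputation missing fraction < threshold.

    ``mask`` is the original missingness mask (from :func:`impute`); the
    comparison is strict, so a metabolite missing in exactly 25% of samples
    is dropped under the default threshold.  Returns the filtered matrix and
    a report dict with retained/dropped counts.
    """
    params = params or FilterParams()
    params.validate()
    matrix.require_stage("imputed")
    if not mask.index.equals(matrix.metabolites) or \
            not mask.columns.equals(matrix.samples):
        raise ValueError("missingness mask is not aligned with the matrix")
    frac = mask.mean(axis=1)
    keep = frac < params.max_missing_fraction
    if not keep.any():
        raise ValueError(
            "missingness filter removed every metabolite; review "
            f"max_missing_fraction={params.max_missing_fraction}")
    filtered = matrix.advanced(matrix.data.loc[keep], "filtered")
    report = {"retained": int(keep.sum()), "dropped": int((~keep).sum()),
              "threshold": params.max_missing_fraction}
    return filtered, report


def normalize_total(matrix: IntensityMatrix
                    ) -> tuple[IntensityMatrix, pd.Series]:
    """Total-intensity normalization; returns (matrix, correction factors).

    factor_i = total_i / min_j total_j; every cell of sample i is divided by
    factor_i, after which all sample totals equal the smallest original
    total.  Within-sample intensity ratios are preserved exactly.
    """
    matrix.require_stage("imputed", "filtered")
    data = matrix.data
    if data.isna().to_numpy().any():
        raise ValueError("normalize_total requires a fully imputed matrix")
    totals = data.sum(axis=0)
    bad = totals[totals <= 0]
    if len(bad):
        raise ValueError(f"non-positive total intensity in sample "
                         f"{bad.index[0]!r}")
    factors = totals / totals.min()
    normalized = data.div(factors, axis=1)
    return matrix.advanced(normalized, "normalized"), factors


def log_transform(matrix: IntensityMatrix) -> IntensityMatrix:
    """Natural-log transform of a normalized matrix."""
    matrix.require_stage("normalized")
    data = matrix.data
    values = data.to_numpy()
    nonpos = ~(values > 0)
    if nonpos.any():
        i, j = np.argwhere(nonpos)[0]
        raise ValueError(
            f"non-positive value at metabolite {data.index[i]!r}, sample "
            f"{data.columns[j]!r}; log transform requires positive input")
    return matrix.advanced(np.log(data), "log")
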