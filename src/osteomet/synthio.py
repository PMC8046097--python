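"""Synthetic LC-MS serum-metabolomics data with known ground truth.

Two generators are provided:

* :func:`simulate_rct` — a two-arm (probiotic treatment vs placebo),
  four-time-point longitudinal design with a planted subset of
  treatment-responsive metabolites;
* :func:`simulate_cohort` — a screening population of elderly women with
  clinical covariates and a latent tibia volumetric BMD, from which extreme
  low/high-BMD case and control groups are later selected and matched.

Intensities are generated on the natural-log scale and exponentiated, so the
observed peak areas are log-normal — the positive, right-skewed regime that
left-censored imputation presumes.  Missingness is driven by the *latent*
(pre-censoring) log intensity through a logistic detection model, so lower
abundance means a higher chance of a missing cell, exactly the assumption the
downshifted-normal imputer encodes.

All randomness flows through :class:`numpy.random.Generator` (PCG64) seeded
from the config, so identical configs give byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GroundTruth, IntensityMatrix

LN2 = float(np.log(2.0))

__all__ = [
    "SimConfig",
    "CaseControlConfig",
    "simulate_rct",
    "simulate_cohort",
    "write_fixture",
]


@dataclass
class SimConfig:
    """Configuration of the longitudinal two-arm simulator.

    Defaults mirror the shape of a one-year probiotic RCT in ~68 osteopenic
    women profiled on an untargeted LC-MS platform: ~1232 metabolites, four
    visits (months 0, 3, 6, 12), and a minority of metabolites that truly
    respond to treatment.
    """

    n_metabolites: int = 1232
    n_subjects_per_arm: int = 34
    time_points: tuple[int, ...] = (0, 3, 6, 12)
    n_responsive: int = 97
    effect_log2: float = 1.0          # planted follow-up log2 ratio, treatment arm
    base_mean: float = 15.0           # mean log intensity of metabolite baselines
    base_sd: float = 2.0              # spread of metabolite baselines (log)
    subject_sd: float = 0.8           # between-subject log-intensity SD
    noise_sd: float = 0.5             # residual log-intensity SD
    missing_steepness: float = 1.2    # logistic censoring slope (per log unit)
    missing_mid: float = 11.0         # log intensity at 50% censoring odds
    sample_scale_sd: float = 0.2      # SD of per-sample log scale factor
    seed: int = 0

    def validate(self) -> None:
        if self.n_metabolites <= 0 or self.n_subjects_per_arm <= 0:
            raise ValueError("n_metabolites and n_subjects_per_arm must be > 0")
        if not (0 <= self.n_responsive <= self.n_metabolites):
            raise ValueError("n_responsive must lie in [0, n_metabolites]")
        if any(s <= 0 for s in (self.base_sd, self.subject_sd, self.noise_sd,
                                self.sample_scale_sd)):
            raise ValueError("all SD parameters must be positive")
        tp = tuple(self.time_points)
        if len(tp) < 2 or tp[0] != 0 or any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("time_points must be strictly increasing and "
                             "start at 0")


@dataclass
class CaseControlConfig:
    """Configuration of the cross-sectional screening-cohort simulator.

    Clinical covariates use plausible defaults for 75- to 80-year-old women
    (age 78 +/- 1.7 y, BMI 24.4 +/- 3.6 kg/m^2); tibia total volumetric BMD is
    a latent trait correlated with the planted marker metabolites and,
    through ``age_bmd_slope``/``bmi_bmd_slope``, with age and BMI — this is
    the confounding that propensity matching and covariate-adjusted contrasts
    must remove.
    """

    n_population: int = 3028
    n_cases: int = 120
    n_controls: int = 120
    n_metabolites: int = 1232
    n_group_markers: int = 104
    group_effect_log2: float = 1.0    # planted low- vs high-BMD extreme contrast
    frac_down: float = 0.78           # fraction of markers lower in cases
    confounder_strength: float = 0.0  # log-intensity shift per covariate SD
    age_mean: float = 78.0
    age_sd: float = 1.7
    height_mean: float = 162.5       # cm
    height_sd: float = 6.1
    bmi_mean: float = 24.4
    bmi_sd: float = 3.6
    vbmd_mean: float = 212.0          # mg/cm^3, population mean
    vbmd_sd: float = 40.0
    age_bmd_slope: float = -5.0       # mg/cm^3 per year of age
    bmi_bmd_slope: float = 2.5        # mg/cm^3 per kg/m^2
    base_mean: float = 15.0
    base_sd: float = 2.0
    noise_sd: float = 0.5
    missing_steepness: float = 1.2
    missing_mid: float = 11.0
    sample_scale_sd: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_population, self.n_cases, self.n_controls,
               self.n_metabolites) <= 0:
            raise ValueError("all counts must be > 0")
        if self.n_cases + self.n_controls > self.n_population:
            raise ValueError("n_cases + n_controls exceeds the population")
        if not (0 <= self.n_group_markers <= self.n_metabolites):
            raise ValueError("n_group_markers must lie in [0, n_metabolites]")
        if not 0.0 <= self.frac_down <= 1.0:
            raise ValueError("frac_down must lie in [0, 1]")


def _metabolite_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"M{i + 1:0{width}d}" for i in range(n)]


def _censor(latent_log: np.ndarray, steepness: float, mid: float,
            rng: np.random.Generator) -> np.ndarray:
    """Bernoulli missingness, probability logistic-decreasing in log intensity."""
    p_missing = 1.0 / (1.0 + np.exp(steepness * (latent_log - mid)))
    return rng.random(latent_log.shape) < p_missing


def missing_probability(latent_log: np.ndarray, steepness: float,
                        mid: float) -> np.ndarray:
    """Censoring probability of the detection model, exposed for validation."""
    return 1.0 / (1.0 + np.exp(steepness * (np.asarray(latent_log) - mid)))


def simulate_rct(config: SimConfig) -> tuple[IntensityMatrix, pd.DataFrame, GroundTruth]:
    """Simulate the two-arm longitudinal serum-metabolome experiment.

    Returns a raw-stage :class:`IntensityMatrix` (metabolites x samples, NaN
    for censored cells), a sample table (sample, subject, arm, time), and the
    :class:`GroundTruth` of planted treatment-responsive metabolites.

    The generating model on the log scale is additive::

        log X[j, s(i, t)] = base_j + subject_i + effect_j * 1{arm=treatment,
                            t>0, j responsive} + scale_{s} + noise

    with censoring applied before the per-sample scale factor (the detection
    limit lives at the instrument, on latent abundance).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    m = config.n_metabolites
    tp = tuple(config.time_points)
    n_arm = config.n_subjects_per_arm
    mids = _metabolite_ids(m)

    subjects = [f"T{i + 1:03d}" for i in range(n_arm)] + \
               [f"P{i + 1:03d}" for i in range(n_arm)]
    arms = ["treatment"] * n_arm + ["placebo"] * n_arm

    base = rng.normal(config.base_mean, config.base_sd, size=m)
    subj_eff = rng.normal(0.0, config.subject_sd, size=(m, 2 * n_arm))

    responsive = sorted(rng.choice(m, size=config.n_responsive, replace=False))
    signs = rng.choice([-1.0, 1.0], size=config.n_responsive)
    effect_ln = np.zeros(m)
    effect_ln[responsive] = signs * config.effect_log2 * LN2

    rows = []
    cols = []
    data = np.empty((m, 2 * n_arm * len(tp)))
    missing = np.empty_like(data, dtype=bool)
    k = 0
    for i, (subj, arm) in enumerate(zip(subjects, arms)):
        for t in tp:
            latent = base + subj_eff[:, i] + rng.normal(0, config.noise_sd, m)
            if arm == "treatment" and t > 0:
                latent = latent + effect_ln
            miss = _censor(latent, config.missing_steepness, config.missing_mid,
                           rng)
            scale = rng.normal(0.0, config.sample_scale_sd)
            data[:, k] = np.exp(latent + scale)
            missing[:, k] = miss
            cols.append(f"{subj}_m{t:02d}")
            rows.append({"sample": cols[-1], "subject": subj, "arm": arm,
                         "time": t})
            k += 1

    data[missing] = np.nan
    matrix = IntensityMatrix(pd.DataFrame(data, index=mids, columns=cols),
                             stage="raw")
    samples = pd.DataFrame(rows)
    truth = GroundTruth(
        responsive_ids=[mids[j] for j in responsive],
        effects={mids[j]: float(s * config.effect_log2)
                 for j, s in zip(responsive, signs)},
    )
    return matrix, samples, truth


def _extreme_mean(frac: float) -> float:
    """E[Z | Z above the (1-frac) quantile] for a standard normal."""
    if frac <= 0 or frac >= 1:
        raise ValueError("tail fraction must lie in (0, 1)")
    q = stats.norm.ppf(1.0 - frac)
    return float(stats.norm.pdf(q) / frac)


def simulate_cohort(config: CaseControlConfig
                    ) -> tuple[IntensityMatrix, pd.DataFrame, GroundTruth]:
    """Simulate the screening population for the case-control comparison.

    One fasting serum sample per woman.  Tibia vBMD is::

        vbmd = vbmd_mean + age_bmd_slope*(age - age_mean)
                         + bmi_bmd_slope*(bmi - bmi_mean) + vbmd_sd * u

    with ``u`` standard normal.  Marker metabolites shift with the latent
    bone component ``u`` at a slope calibrated (via the truncated-normal mean
    of the selected tails) so that the *expected* contrast between the
    bottom-``n_cases`` and top-``n_controls`` extremes equals
    ``group_effect_log2`` on the log2 scale.  Null metabolites carry no bone
    signal but, when ``confounder_strength`` > 0, shift with age and BMI —
    which also drive selection, so unadjusted case/control contrasts on null
    metabolites are biased by design.

    Group labels are *not* assigned here; extreme selection and matching are
    downstream operations.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n = config.n_population
    m = config.n_metabolites
    mids = _metabolite_ids(m)
    subjects = [f"S{i + 1:04d}" for i in range(n)]

    age = rng.normal(config.age_mean, config.age_sd, n)
    height = rng.normal(config.height_mean, config.height_sd, n)
    bmi = rng.normal(config.bmi_mean, config.bmi_sd, n)
    weight = bmi * (height / 100.0) ** 2

    u = rng.standard_normal(n)
    vbmd = (config.vbmd_mean
            + config.age_bmd_slope * (age - config.age_mean)
            + config.bmi_bmd_slope * (bmi - config.bmi_mean)
            + config.vbmd_sd * u)

    # Slope of marker log levels per SD of u so the expected low-vs-high
    # extreme contrast is the planted effect.
    tail_lo = config.n_cases / n
    tail_hi = config.n_controls / n
    expected_gap = _extreme_mean(tail_hi) + _extreme_mean(tail_lo)
    slope_ln = config.group_effect_log2 * LN2 / expected_gap

    markers = sorted(rng.choice(m, size=config.n_group_markers, replace=False))
    n_down = int(round(config.frac_down * config.n_group_markers))
    # "down in cases" = lower at low vBMD = positive association with u
    signs = np.concatenate([np.ones(n_down),
                            -np.ones(config.n_group_markers - n_down)])
    rng.shuffle(signs)

    base = rng.normal(config.base_mean, config.base_sd, size=m)
    latent = base[:, None] + rng.normal(0, config.noise_sd, size=(m, n))
    marker_slopes = np.zeros(m)
    marker_slopes[markers] = signs * slope_ln
    latent += marker_slopes[:, None] * u[None, :]
    if config.confounder_strength:
        cov_z = ((age - config.age_mean) / config.age_sd
                 + (bmi - config.bmi_mean) / config.bmi_sd)
        latent += config.confounder_strength * cov_z[None, :]

    miss = _censor(latent, config.missing_steepness, config.missing_mid, rng)
    scale = rng.normal(0.0, config.sample_scale_sd, n)
    data = np.exp(latent + scale[None, :])
    data[miss] = np.nan

    matrix = IntensityMatrix(pd.DataFrame(data, index=mids, columns=subjects),
                             stage="raw")
    samples = pd.DataFrame({
        "sample": subjects,
        "subject": subjects,
        "age": age,
        "height": height,
        "weight": weight,
        "bmi": bmi,
        "tibia_vbmd": vbmd,
    })
    # effects recorded as case-vs-control log2: down in cases = negative
    truth = GroundTruth(
        group_marker_ids=[mids[j] for j in markers],
        effects={mids[j]: float(-s * config.group_effect_log2)
                 for j, s in zip(markers, signs)},
    )
    return matrix, samples, truth


def write_fixture(matrix: IntensityMatrix, samples: pd.DataFrame,
                  truth: GroundTruth, directory: str | Path,
                  annotations: pd.DataFrame | None = None) -> dict[str, Path]:
    """Write a dataset as the on-disk fixture layout.

    Produces ``intensities.tsv`` (first column metabolite id; missing cells
    empty), ``samples.tsv``, ``annotations.tsv`` and ``truth.json`` in
    ``directory``.  Round-trips losslessly through :mod:`osteomet.io`.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"cannot create fixture directory {directory}: {exc}")

    paths = {
        "intensities": directory / "intensities.tsv",
        "samples": directory / "samples.tsv",
        "annotations": directory / "annotations.tsv",
        "truth": directory / "truth.json",
    }
    out = matrix.data.copy()
    out.index.name = "metabolite"
    out.to_csv(paths["intensities"], sep="\t", na_rep="")
    samples.to_csv(paths["samples"], sep="\t", index=False)
    if annotations is None:
        annotations = default_annotations(matrix.metabolites, truth)
    annotations.to_csv(paths["annotations"], sep="\t", index=False)
    paths["truth"].write_text(json.dumps(truth.to_dict(), indent=1))
    return paths


_CLASSES = ("Amino acid", "Lipid", "Peptide", "Carbohydrate", "Nucleotide",
            "Cofactor", "Xenobiotic")


def default_annotations(metabolites, truth: GroundTruth) -> pd.DataFrame:
    """Deterministic placeholder annotation table (name, class, sub-pathway)."""
    flagged = set(truth.responsive_ids) | set(truth.group_marker_ids)
    rows = []
    for i, mid in enumerate(metabolites):
        cls = _CLASSES[i % len(_CLASSES)]
        rows.append({"metabolite": mid, "name": f"compound-{mid}",
                     "class": cls,
                     "sub_pathway": f"{cls} sub-pathway {(i // len(_CLASSES)) % 9 + 1}",
                     "planted": mid in flagged})
    return pd.DataFrame(rows)
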