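import numpy as np
import pandas as pd
import pytest

from osteomet import preprocess, synthio
from osteomet.containers import IntensityMatrix, ResponseMatrix


@pytest.fixture(scope="session")
def small_rct():
    """Small but realistic two-arm longitudinal simulation."""
    cfg = synthio.SimConfig(n_metabolites=250, n_subjects_per_arm=14,
                            n_responsive=15, effect_log2=1.2, seed=11)
    return synthio.simulate_rct(cfg)


@pytest.fixture(scope="session")
def small_rct_processed(small_rct):
    matrix, samples, truth = small_rct
    imputed, mask = preprocess.impute(matrix,
                                      preprocess.ImputeParams(seed=12))
    filtered, _ = preprocess.filter_missing(imputed, mask)
    normalized, _ = preprocess.normalize_total(filtered)
    logged = preprocess.log_transform(normalized)
    return normalized, logged, samples, truth


def make_matrix(values, stage="raw", prefix="M"):
    """Build an IntensityMatrix from a plain array."""
    values = np.asarray(values, dtype=float)
    idx = [f"{prefix}{i+1:03d}" for i in range(values.shape[0])]
    cols = [f"S{j+1:03d}" for j in range(values.shape[1])]
    return IntensityMatrix(pd.DataFrame(values, index=idx, columns=cols),
                           stage=stage)


@pytest.fixture
def rct_samples_frame():
    """Sample table for 4 subjects x 4 time points, two arms."""
    rows = []
    for subj, arm in [("T001", "treatment"), ("T002", "treatment"),
                      ("P001", "placebo"), ("P002", "placebo")]:
        for t in (0, 3, 6, 12):
            rows.append({"sample": f"{subj}_m{t:02d}", "subject": subj,
                         "arm": arm, "time": t})
    return pd.DataFrame(rows)


def response_matrix_from_profiles(profiles: dict, arms: dict, noise=0.0, seed=0,
                     times=(0, 3, 6, 12)):
    """Build a ResponseMatrix from per-metabolite (arm -> follow-up means).

    ``profiles`` maps metabolite id -> {arm: [ratio at each follow-up]}.
    One subject column per (arm, replicate).
    """
    rng = np.random.default_rng(seed)
    n_rep = arms.pop("_n", 8)
    cols = {}
    subjects = {}
    for arm in ("treatment", "placebo"):
        for r in range(n_rep):
            subj = f"{arm[0].upper()}{r:02d}"
            subjects[subj] = arm
            for ti, t in enumerate(times[1:]):
                vals = []
                for mid in profiles:
                    base = profiles[mid][arm][ti]
                    vals.append(base * np.exp(rng.normal(0, noise)))
                cols[(subj, t)] = vals
    ratios = pd.DataFrame(cols, index=list(profiles))
    ratios.columns = pd.MultiIndex.from_tuples(ratios.columns,
                                               names=["subject", "time"])
    return ResponseMatrix(ratios=ratios, arms=pd.Series(subjects),
                          time_points=times)
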