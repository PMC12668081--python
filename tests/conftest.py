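import logging
import warnings

import numpy as np
import pandas as pd
import pytest

from hatrial.synthetic_cohort import CohortSpec, generate_cohort

logging.getLogger("hatrial").setLevel(logging.ERROR)
warnings.filterwarnings("ignore", message="propensity truncation")
warnings.filterwarnings("ignore", message="only \\d+ rows under strategy")


@pytest.fixture(scope="session")
def default_spec():
    return CohortSpec(n_participants=2842, seed=42)


@pytest.fixture(scope="session")
def default_cohort(default_spec):
    """One full-size cohort with its truth record and pre-masking table."""
    df, truth, complete = generate_cohort(
        default_spec, return_complete=True, compute_truth=True
    )
    return df, truth, complete


@pytest.fixture(scope="session")
def small_cohort():
    spec = CohortSpec(n_participants=600, seed=7)
    df, truth, complete = generate_cohort(
        spec, return_complete=True, compute_truth=False
    )
    return spec, df, truth, complete


def make_confounded_dgp(n, seed, effect=2.0, spec_kwargs=None):
    """Complete-data survivor frame for estimator recovery tests.

    Returns the survivors of a pre-masking cohort with a `strategy`
    column; the generator's propensity is logistic-linear in
    (age, PTA, self-rated hearing, 3MS) and the outcome mean is linear in
    (baseline biomarker, age, treatment), so both nuisance GLMs can be
    correctly specified.
    """
    kwargs = dict(
        n_participants=n,
        seed=seed,
        true_mean_diff={"ptau181": effect},
        confounding_strength=1.0,
    )
    kwargs.update(spec_kwargs or {})
    spec = CohortSpec(**kwargs)
    _, _, complete = generate_cohort(
        spec, return_complete=True, compute_truth=False
    )
    surv = complete[complete["died_before_followup"] == 0].reset_index(drop=True)
    surv = surv.copy()
    surv["strategy"] = np.where(surv["ha_prescription"] == 1, "HA", "no_HA")
    return surv


CORRECT_PS_TERMS = [
    "age", "pta_better_ear", "hearing_problem_selfreport", "cognition_3ms"
]
CORRECT_OUTCOME_TERMS = ["ptau181", "age"]


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def brute_force_weighted_quantile(y, w, tau):
    """Independent oracle: smallest y whose weighted CDF reaches tau."""
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    total = w.sum()
    for val in sorted(set(y.tolist())):
        if w[y <= val].sum() / total >= tau - 1e-12:
            return float(val)
    return float(max(y))


def saturated_gcomp(df, strategy_label, strategy_col="strategy",
                    w_col="W", y_col="Y"):
    """Hand-enumerated plug-in: sum_w mean(Y | A=a, w) * Phat(w)."""
    out = 0.0
    n = len(df)
    for w, grp in df.groupby(w_col):
        cell = grp[grp[strategy_col] == strategy_label][y_col]
        out += cell.mean() * len(grp) / n
    return out
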