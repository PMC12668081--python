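"""Synthetic cohort generator with known ground truth.

Generates participant tables with the statistical structure the downstream
analysis assumes: confounded treatment assignment, death before follow-up,
MAR (optionally MNAR) outcome missingness driven by longitudinal
auxiliaries, heavy audiometry missingness, and a treatment effect injected
additively on the natural concentration scale so the true
survivor-conditional mean difference equals the configured value exactly.

Biomarkers are drawn on the log scale from a fixed 4x4 correlation
structure (pTau181/NfL/GFAP positively correlated, all negatively
correlated with the amyloid ratio) and exponentiated; follow-up values are
a linear drift from baseline plus skewed (lognormal-family, mean-zero)
noise, so the conditional outcome mean is exactly linear in
(baseline value, age, treatment).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

BIOMARKERS = ["ptau181", "nfl", "gfap", "abeta_ratio"]
FOLLOWUP_SUFFIX = "_fu"
FOLLOWUP_COLS = [b + FOLLOWUP_SUFFIX for b in BIOMARKERS]

#: biomarkers where "worse" is a *lower* value; their headline quantile is
#: the 10th percentile and their delta-adjustment sign is negative.
LOWER_TAIL_BIOMARKERS = {"abeta_ratio"}

FREQUENCY_LEVELS = ["never", "rare_sometimes", "often_always"]

# log-scale marginal parameters (median, sdlog) per biomarker
_LOG_PARAMS = {
    "ptau181": (35.0, 0.48),
    "nfl": (21.0, 0.38),
    "gfap": (130.0, 0.45),
    "abeta_ratio": (62.0, 0.18),
}

# follow-up drift: fu = d0 + d1 * baseline + d2*(age-75) + effect*A + noise
_DRIFT = {
    "ptau181": {"d1": 0.80, "d2": 0.30, "target": 36.0, "noise_scale": 8.0},
    "nfl": {"d1": 0.80, "d2": 0.45, "target": 31.0, "noise_scale": 6.0},
    "gfap": {"d1": 0.85, "d2": 1.50, "target": 175.0, "noise_scale": 35.0},
    "abeta_ratio": {"d1": 0.80, "d2": -0.10, "target": 61.0, "noise_scale": 6.0},
}

_LOG_CORR = np.array(
    [
        [1.00, 0.40, 0.45, -0.25],
        [0.40, 1.00, 0.50, -0.20],
        [0.45, 0.50, 1.00, -0.25],
        [-0.25, -0.20, -0.25, 1.00],
    ]
)


class CohortSpecError(ValueError):
    """Raised when a CohortSpec field is invalid."""


@dataclass(frozen=True)
class CohortSpec:
    """Configuration of the structural model behind one synthetic cohort."""

    n_participants: int = 2842
    seed: int = 0
    true_mean_diff: dict = field(
        default_factory=lambda: {b: 0.0 for b in BIOMARKERS}
    )
    treated_rate: float = 0.26
    confounding_strength: float = 0.5
    death_rate_untreated: float = 0.10
    death_treatment_logodds: float = 0.0
    outcome_missing_rate: float = 0.55
    exposure_missing_rate: float = 0.18
    audiometry_missing_rate: float = 0.91
    hearing_missing_rate: float = 0.05
    mnar_delta_sd: float = 0.0
    frequency_split: tuple = (0.10, 0.35, 0.55)
    # optional effect heterogeneity: effect_k(row) =
    #   true_mean_diff[k] + effect_mod_slope[k] * (modifier - its mean)
    effect_mod_col: str | None = None
    effect_mod_slope: dict = field(default_factory=dict)
    # planted healthcare-utilisation confounder of the negative control
    negctrl_confounding: float = 0.0

    def __post_init__(self):
        if int(self.n_participants) <= 0:
            raise CohortSpecError("n_participants must be positive")
        for name in (
            "treated_rate",
            "death_rate_untreated",
            "outcome_missing_rate",
            "exposure_missing_rate",
            "audiometry_missing_rate",
            "hearing_missing_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise CohortSpecError(f"{name} must lie in [0, 1], got {v}")
        if self.confounding_strength < 0:
            raise CohortSpecError("confounding_strength must be nonnegative")
        fs = np.asarray(self.frequency_split, dtype=float)
        if fs.shape != (3,) or np.any(fs < 0) or abs(fs.sum() - 1.0) > 1e-9:
            raise CohortSpecError(
                "frequency_split must be 3 nonnegative proportions summing to 1"
            )
        unknown = set(self.true_mean_diff) - set(BIOMARKERS)
        if unknown:
            raise CohortSpecError(f"true_mean_diff has unknown biomarkers {unknown}")

    def effect(self, biomarker: str) -> float:
        return float(self.true_mean_diff.get(biomarker, 0.0))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["frequency_split"] = list(self.frequency_split)
        return d


@dataclass
class TruthRecord:
    """Monte-Carlo ground truth for the contrasts the pipeline estimates."""

    mean_diff: dict
    quantile_diff: dict
    mean_diff_se: dict
    quantile_diff_se: dict
    n_oracle: int
    true_propensity: np.ndarray | None = None

    def to_dict(self) -> dict:
        d = {
            "mean_diff": self.mean_diff,
            "quantile_diff": self.quantile_diff,
            "mean_diff_se": self.mean_diff_se,
            "quantile_diff_se": self.quantile_diff_se,
            "n_oracle": self.n_oracle,
        }
        if self.true_propensity is not None:
            d["true_propensity"] = np.asarray(self.true_propensity).tolist()
        return d


def _calibrate_intercept(lp: np.ndarray, target: float) -> float:
    """Intercept c with mean(expit(c + lp)) == target, by bracketing."""
    target = min(max(target, 1e-6), 1 - 1e-6)

    def f(c):
        return expit(c + lp).mean() - target

    return brentq(f, -30.0, 30.0, xtol=1e-12)


def _simulate(spec: CohortSpec, n: int, rng: np.random.Generator,
              force_treatment: float | None = None) -> dict:
    """Draw the full structural model; returns latent and observed arrays.

    ``force_treatment`` overrides the treatment draw with a constant
    (used by the truth oracle); the rest of the model is unchanged.
    """
    age = 70.0 + rng.gamma(2.0, 2.5, size=n)
    sex = (rng.random(n) < 0.48).astype(int)
    education = rng.choice(
        6, size=n, p=[0.14, 0.31, 0.11, 0.16, 0.09, 0.19]
    )
    race_white = (rng.random(n) < 0.985).astype(int)
    cognition = np.clip(rng.normal(94.0, 4.0, size=n), 70.0, 100.0)
    bmi = np.clip(rng.normal(28.0, 4.5, size=n), 16.0, 55.0)
    diabetes = (rng.random(n) < 0.08).astype(int)
    antihyp = (rng.random(n) < 0.03).astype(int)
    smoking = rng.choice(3, size=n, p=[0.55, 0.42, 0.03])
    sbp = rng.normal(139.0, 16.0, size=n)
    apoe = (rng.random(n) < 0.255).astype(int)
    prior_ha = (rng.random(n) < 0.01).astype(int)
    dementia_t0 = (rng.random(n) < 0.01).astype(int)
    hearing_problem = (rng.random(n) < 0.97).astype(int)
    pta = np.clip(28.0 + 0.35 * (age - 75.0) + rng.normal(0, 8.0, size=n), 0, 90)

    # baseline biomarkers: correlated log-scale draws
    sdlog = np.array([_LOG_PARAMS[b][1] for b in BIOMARKERS])
    meanlog = np.array([np.log(_LOG_PARAMS[b][0]) for b in BIOMARKERS])
    chol = np.linalg.cholesky(_LOG_CORR)
    z = rng.standard_normal((n, 4)) @ chol.T
    logbio = meanlog + z * sdlog
    # mild age trend on NfL and GFAP (confounding via age)
    logbio[:, 1] += 0.020 * (age - 75.0)
    logbio[:, 2] += 0.015 * (age - 75.0)
    bio = np.exp(logbio)
    baseline = {b: bio[:, i] for i, b in enumerate(BIOMARKERS)}

    # treatment: logistic in standardized confounders, calibrated margin
    cs = spec.confounding_strength
    z_age = (age - 75.0) / 3.5
    z_pta = (pta - 28.0) / 8.0
    z_3ms = (cognition - 94.0) / 4.0
    lp_treat = cs * (
        0.5 * z_age + 0.5 * z_pta + 0.3 * (hearing_problem - 0.97) - 0.3 * z_3ms
    )
    c_treat = _calibrate_intercept(lp_treat, spec.treated_rate)
    propensity = expit(c_treat + lp_treat)
    if force_treatment is None:
        treated = (rng.random(n) < propensity).astype(int)
    else:
        treated = np.full(n, int(force_treatment))
        rng.random(n)  # keep the stream aligned with the observational draw

    freq = np.where(treated == 1, rng.choice(3, size=n, p=list(spec.frequency_split)), 0)

    # healthcare-utilisation latent; confounds the negative control when enabled
    z_health = rng.standard_normal(n)
    negctrl = (
        rng.random(n) < expit(-0.4 + spec.negctrl_confounding * z_health)
    ).astype(int)

    # death before follow-up: excludes treatment unless the stress flag is on
    lp_death = 0.07 * (age - 75.0) + 0.30 * (logbio[:, 1] - meanlog[1]) / sdlog[1]
    c_death = _calibrate_intercept(lp_death, spec.death_rate_untreated)
    p_death = expit(c_death + lp_death + spec.death_treatment_logodds * treated)
    died = (rng.random(n) < p_death).astype(int)

    # follow-up outcomes (generated for everyone; masked for the dead later)
    followup = {}
    modifier = None
    if spec.effect_mod_col is not None:
        modifier_map = {
            "age": age, "cognition_3ms": cognition, "apoe_e4": apoe,
            "pta_better_ear": pta, **baseline,
        }
        modifier = modifier_map[spec.effect_mod_col]
    for i, b in enumerate(BIOMARKERS):
        p = _DRIFT[b]
        noise = p["noise_scale"] * (np.exp(0.4 * rng.standard_normal(n)) - np.exp(0.08))
        eff = spec.effect(b)
        eff_vec = np.full(n, eff)
        if modifier is not None and b in spec.effect_mod_slope:
            eff_vec = eff + spec.effect_mod_slope[b] * (modifier - modifier.mean())
        d0 = p["target"] - p["d1"] * np.exp(
            meanlog[i] + sdlog[i] ** 2 / 2
        )
        y = (
            d0
            + p["d1"] * baseline[b]
            + p["d2"] * (age - 75.0)
            + eff_vec * treated
            + noise
        )
        if spec.negctrl_confounding:
            y = y + spec.negctrl_confounding * z_health * p["noise_scale"] / 4.0
        floor = 1.0 if b == "abeta_ratio" else 0.1
        followup[b] = np.maximum(y, floor)

    # longitudinal auxiliary 3MS: a latent decline drives outcome missingness
    decline = rng.gamma(2.0, 1.5, size=n) + 0.20 * (age - 75.0).clip(0)
    aux1 = np.clip(cognition - 0.4 * decline + rng.normal(0, 1.5, size=n), 40, 100)
    aux2 = np.clip(cognition - 1.0 * decline + rng.normal(0, 1.5, size=n), 40, 100)

    return dict(
        age=age, sex=sex, education=education, race_white=race_white,
        cognition_3ms=cognition, bmi=bmi, diabetes=diabetes,
        antihypertensive_use=antihyp, smoking=smoking, pta_better_ear=pta,
        hearing_problem_selfreport=hearing_problem, sbp=sbp, apoe_e4=apoe,
        prior_ha_use=prior_ha, dementia_at_t0=dementia_t0,
        baseline=baseline, treated=treated, freq=freq,
        skin_exam_negctrl=negctrl, died=died, followup=followup,
        aux1=aux1, aux2=aux2, decline=decline, propensity=propensity,
    )


def _assemble(sim: dict, n: int) -> pd.DataFrame:
    df = pd.DataFrame({"id": np.arange(n)})
    for col in (
        "age sex education race_white cognition_3ms bmi diabetes "
        "antihypertensive_use smoking pta_better_ear "
        "hearing_problem_selfreport sbp apoe_e4 prior_ha_use dementia_at_t0"
    ).split():
        df[col] = sim[col]
    for b in BIOMARKERS:
        df[b] = sim["baseline"][b]
    df["ha_prescription"] = sim["treated"].astype(float)
    df["ha_frequency"] = pd.array(
        [FREQUENCY_LEVELS[i] for i in sim["freq"]], dtype="object"
    )
    df["skin_exam_negctrl"] = sim["skin_exam_negctrl"]
    df["died_before_followup"] = sim["died"]
    for b in BIOMARKERS:
        df[b + FOLLOWUP_SUFFIX] = sim["followup"][b]
    df["aux_3ms_w1"] = sim["aux1"]
    df["aux_3ms_w2"] = sim["aux2"]
    return df


def generate_cohort(
    spec: CohortSpec, return_complete: bool = False, compute_truth: bool = True
):
    """Generate one cohort with missingness applied, plus its ground truth.

    Returns ``(cohort, truth)`` or ``(cohort, truth, complete)`` where
    ``complete`` is the pre-masking table (no missing cells, follow-up
    outcomes present even for the dead) used by imputation-recovery tests.

    With ``compute_truth=False`` the Monte-Carlo oracle is skipped and the
    truth record carries the analytic values implied by the additive-effect
    construction (valid whenever death does not depend on treatment);
    replicated simulation tests use this to avoid recomputing an unchanged
    truth hundreds of times.
    """
    n = int(spec.n_participants)
    rng = np.random.default_rng(spec.seed)
    sim = _simulate(spec, n, rng)
    complete = _assemble(sim, n)
    df = complete.copy()

    # structural zero: the dead have no follow-up outcomes
    dead = sim["died"] == 1
    df.loc[dead, FOLLOWUP_COLS] = np.nan

    # outcome missingness among survivors: MAR via the auxiliary decline,
    # plus an MNAR tilt on the latent outcome when mnar_delta_sd != 0
    surv = ~dead
    z_dec = (sim["decline"] - sim["decline"].mean()) / sim["decline"].std()
    lp_miss = 0.6 * z_dec + 0.05 * (sim["age"] - 75.0)
    if spec.mnar_delta_sd:
        z_out = np.zeros(n)
        for b in BIOMARKERS:
            zb = (sim["followup"][b] - sim["followup"][b].mean()) / sim[
                "followup"
            ][b].std()
            z_out += -zb if b in LOWER_TAIL_BIOMARKERS else zb
        lp_miss = lp_miss + spec.mnar_delta_sd * z_out / 4.0
    c_miss = _calibrate_intercept(lp_miss[surv], spec.outcome_missing_rate)
    miss_outcome = (rng.random(n) < expit(c_miss + lp_miss)) & surv
    df.loc[miss_outcome, FOLLOWUP_COLS] = np.nan

    # exposure missingness (MCAR): prescription and frequency together
    miss_exp = rng.random(n) < spec.exposure_missing_rate
    df.loc[miss_exp, "ha_prescription"] = np.nan
    df.loc[miss_exp, "ha_frequency"] = None

    # audiometry missing for most participants, independent of everything
    miss_pta = rng.random(n) < spec.audiometry_missing_rate
    df.loc[miss_pta, "pta_better_ear"] = np.nan

    # self-reported hearing eligibility variable (small MCAR fraction)
    miss_hear = rng.random(n) < spec.hearing_missing_rate
    df["hearing_problem_selfreport"] = df["hearing_problem_selfreport"].astype(float)
    df.loc[miss_hear, "hearing_problem_selfreport"] = np.nan

    # second auxiliary wave partially missing
    df.loc[rng.random(n) < 0.15, "aux_3ms_w2"] = np.nan

    if compute_truth:
        truth = truth_contrasts(spec, n_oracle=200_000)
    else:
        analytic = {b: spec.effect(b) for b in BIOMARKERS}
        truth = TruthRecord(
            mean_diff=dict(analytic),
            quantile_diff=dict(analytic),
            mean_diff_se={b: 0.0 for b in BIOMARKERS},
            quantile_diff_se={b: 0.0 for b in BIOMARKERS},
            n_oracle=0,
        )
    truth.true_propensity = sim["propensity"]

    if return_complete:
        return df, truth, complete
    return df, truth


def truth_contrasts(spec: CohortSpec, n_oracle: int = 200_000) -> TruthRecord:
    """Monte-Carlo truth for every contrast the pipeline estimates.

    Simulates ``n_oracle`` draws from the structural model with treatment
    forced to each strategy, conditions on survival within each arm, and
    reports survivor-conditional mean and tail-quantile differences with
    batch-mean Monte-Carlo standard errors.
    """
    if n_oracle < 100_000:
        raise ValueError("n_oracle must be at least 1e5")
    rng0 = np.random.default_rng((spec.seed, 202_406))
    sim0 = _simulate(spec, n_oracle, np.random.default_rng(rng0.integers(2**63)),
                     force_treatment=0)
    sim1 = _simulate(spec, n_oracle, np.random.default_rng(rng0.integers(2**63)),
                     force_treatment=1)
    s0 = sim0["died"] == 0
    s1 = sim1["died"] == 0

    mean_diff, q_diff, mean_se, q_se = {}, {}, {}, {}
    n_batch = 10
    for b in BIOMARKERS:
        tau = 0.1 if b in LOWER_TAIL_BIOMARKERS else 0.9
        y0 = sim0["followup"][b][s0]
        y1 = sim1["followup"][b][s1]
        mean_diff[b] = float(y1.mean() - y0.mean())
        q_diff[b] = float(
            np.quantile(y1, tau, method="inverted_cdf")
            - np.quantile(y0, tau, method="inverted_cdf")
        )
        md_b, qd_b = [], []
        for y0b, y1b in zip(np.array_split(y0, n_batch), np.array_split(y1, n_batch)):
            md_b.append(y1b.mean() - y0b.mean())
            qd_b.append(
                np.quantile(y1b, tau, method="inverted_cdf")
                - np.quantile(y0b, tau, method="inverted_cdf")
            )
        mean_se[b] = float(np.std(md_b, ddof=1) / np.sqrt(n_batch))
        q_se[b] = float(np.std(qd_b, ddof=1) / np.sqrt(n_batch))

    return TruthRecord(
        mean_diff=mean_diff,
        quantile_diff=q_diff,
        mean_diff_se=mean_se,
        quantile_diff_se=q_se,
        n_oracle=n_oracle,
    )


def write_cohort(df: pd.DataFrame, spec: CohortSpec, truth: TruthRecord,
                 csv_path, sidecar_path) -> None:
    """Write the cohort CSV (empty cell = missing) and a JSON sidecar."""
    df.to_csv(csv_path, index=False)
    sidecar = {"spec": spec.to_dict(), "truth": truth.to_dict()}
    with open(sidecar_path, "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_cohort(csv_path) -> pd.DataFrame:
    df = pd.read_csv(csv_path)
    if "ha_frequency" in df:
        df["ha_frequency"] = df["ha_frequency"].astype("object")
        df.loc[df["ha_frequency"].isna(), "ha_frequency"] = None
    return df


def generate_risk_training_cohort(n: int = 8329, seed: int = 7) -> pd.DataFrame:
    """Out-of-sample cohort with a 10-year dementia indicator.

    Dementia risk increases in log pTau181/NfL/GFAP and decreases in the
    amyloid ratio; used to train the dementia risk score on data disjoint
    from any analysis cohort.
    """
    rng = np.random.default_rng((seed, 881))
    sdlog = np.array([_LOG_PARAMS[b][1] for b in BIOMARKERS])
    meanlog = np.array([np.log(_LOG_PARAMS[b][0]) for b in BIOMARKERS])
    chol = np.linalg.cholesky(_LOG_CORR)
    z = rng.standard_normal((n, 4)) @ chol.T
    logbio = meanlog + z * sdlog
    zstd = (logbio - meanlog) / sdlog
    lp = -2.6 + 0.8 * zstd[:, 0] + 0.4 * zstd[:, 1] + 0.3 * zstd[:, 2] - 0.4 * zstd[:, 3]
    dementia = (rng.random(n) < expit(lp)).astype(int)
    df = pd.DataFrame(np.exp(logbio), columns=BIOMARKERS)
    df["dementia_10yr"] = dementia
    return df
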