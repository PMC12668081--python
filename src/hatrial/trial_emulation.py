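"""Eligibility screening, strategy assignment, and the dementia risk score.

Eligibility follows the emulated protocol: age >= 70, 3MS strictly above
77, self-reported hearing problems, no prior hearing-aid use, dementia-free
at time zero, and (sensitivity analyses only) an audiometric threshold.
Rows with a *missing* value for a criterion variable are retained and
flagged — eligibility is resolved after imputation, so each imputed
dataset can have its own eligible n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from hatrial.synthetic_cohort import BIOMARKERS, FREQUENCY_LEVELS


@dataclass(frozen=True)
class EligibilityCriteria:
    min_age: float = 70.0
    min_3ms: float = 77.0  # strict: score must exceed this
    require_hearing_problem: bool = True
    exclude_prior_ha: bool = True
    require_dementia_free_at_t0: bool = True
    pta_threshold_db: float | None = None  # sensitivity analysis only

    def __post_init__(self):
        for v in (self.min_age, self.min_3ms):
            if not np.isfinite(v):
                raise ValueError("eligibility thresholds must be finite")
        if self.pta_threshold_db is not None and not np.isfinite(
            self.pta_threshold_db
        ):
            raise ValueError("pta_threshold_db must be finite when set")


@dataclass(frozen=True)
class TrialDefinition:
    """One of the two emulated trials and its ordered strategy labels."""

    trial_id: int
    strategy_labels: tuple
    reference_strategy: str

    def __post_init__(self):
        if len(set(self.strategy_labels)) != len(self.strategy_labels):
            raise ValueError("strategy labels must be distinct")
        if self.strategy_labels[0] != self.reference_strategy:
            raise ValueError("the reference strategy must be the first label")


TRIAL_1 = TrialDefinition(1, ("no_HA", "HA"), "no_HA")
TRIAL_2 = TrialDefinition(
    2, ("never", "rare_sometimes", "often_always"), "never"
)


def _criterion_masks(cohort: pd.DataFrame, criteria: EligibilityCriteria):
    """Ordered (name, fail_mask, missing_mask) triples for active criteria."""
    out = []

    def add(name, col, fail):
        if col not in cohort.columns:
            raise KeyError(f"required eligibility column '{col}' is missing")
        v = cohort[col]
        miss = v.isna().to_numpy()
        out.append((name, fail(v).to_numpy() & ~miss, miss))

    add("age", "age", lambda v: v < criteria.min_age)
    add("3ms", "cognition_3ms", lambda v: v <= criteria.min_3ms)
    if criteria.require_hearing_problem:
        add("hearing", "hearing_problem_selfreport", lambda v: v != 1)
    if criteria.exclude_prior_ha:
        add("prior_ha", "prior_ha_use", lambda v: v == 1)
    if criteria.require_dementia_free_at_t0:
        add("dementia_t0", "dementia_at_t0", lambda v: v == 1)
    if criteria.pta_threshold_db is not None:
        add("pta", "pta_better_ear", lambda v: v < criteria.pta_threshold_db)
    return out


def apply_eligibility(cohort: pd.DataFrame, criteria: EligibilityCriteria):
    """Filter to eligible rows; returns ``(subcohort, tally)``.

    The tally counts exclusions per criterion in application order; a row
    failing several criteria is charged to the first. Rows whose criterion
    variable is missing are retained with ``eligibility_pending = True``.
    """
    masks = _criterion_masks(cohort, criteria)
    excluded = np.zeros(len(cohort), dtype=bool)
    pending = np.zeros(len(cohort), dtype=bool)
    tally = {}
    for name, fail, miss in masks:
        newly = fail & ~excluded
        tally[name] = int(newly.sum())
        excluded |= newly
        pending |= miss
    out = cohort.loc[~excluded].copy()
    out["eligibility_pending"] = pending[~excluded]
    return out, tally


def assign_strategies(cohort: pd.DataFrame, trial: TrialDefinition) -> pd.DataFrame:
    """Append a ``strategy`` column; total over (prescription, frequency)."""
    presc = cohort["ha_prescription"].to_numpy(dtype=float)
    if np.isnan(presc).any():
        raise ValueError(
            "ha_prescription contains missing values; impute before assignment"
        )
    out = cohort.copy()
    if trial.trial_id == 1:
        out["strategy"] = np.where(presc == 1, "HA", "no_HA")
        return out
    freq = cohort["ha_frequency"].to_numpy(dtype=object)
    bad = {
        f for f in freq
        if f is not None and not (isinstance(f, float) and np.isnan(f))
        and f not in FREQUENCY_LEVELS
    }
    if bad:
        raise ValueError(f"unknown ha_frequency level(s): {sorted(bad)}")
    strat = np.empty(len(cohort), dtype=object)
    for i in range(len(cohort)):
        if presc[i] == 0:
            strat[i] = "never"
        else:
            f = freq[i]
            if f is None or (isinstance(f, float) and np.isnan(f)):
                raise ValueError(
                    "ha_frequency missing for a prescribed participant; "
                    "impute before assignment"
                )
            strat[i] = f
    out["strategy"] = strat
    return out


@dataclass
class RiskScoreModel:
    """Logistic model for 10-year dementia risk on standardized log biomarkers."""

    coef: np.ndarray  # (intercept, then one slope per biomarker)
    means: np.ndarray  # log-scale standardization means
    sds: np.ndarray
    training_n: int
    biomarkers: tuple = field(default=tuple(BIOMARKERS))

    def predict(self, cohort: pd.DataFrame) -> np.ndarray:
        x = np.log(cohort[list(self.biomarkers)].to_numpy(dtype=float))
        z = (x - self.means) / self.sds
        lp = self.coef[0] + z @ self.coef[1:]
        return 1.0 / (1.0 + np.exp(-lp))


def fit_dementia_risk_score(
    training: pd.DataFrame, outcome_col: str = "dementia_10yr"
) -> RiskScoreModel:
    """Fit the out-of-sample risk score used as confounder / effect modifier."""
    y = training[outcome_col].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("dementia outcome is constant; risk score inestimable")
    x = np.log(training[BIOMARKERS].to_numpy(dtype=float))
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=0)
    z = (x - means) / sds
    design = sm.add_constant(z, has_constant="add")
    fit = sm.GLM(y, design, family=sm.families.Binomial()).fit()
    return RiskScoreModel(
        coef=np.asarray(fit.params),
        means=means,
        sds=sds,
        training_n=len(training),
    )


def add_risk_score(cohort: pd.DataFrame, model: RiskScoreModel) -> pd.DataFrame:
    out = cohort.copy()
    out["risk_score"] = model.predict(cohort)
    return out
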