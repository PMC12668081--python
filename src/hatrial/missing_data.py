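"""Multiple imputation by chained predictive mean matching.

The imputation engine mirrors the chained-equations/PMM approach of the
*mice* family: per incomplete variable, a Bayesian linear regression on the
currently completed data produces predicted means; each missing cell copies
the observed value of one of the ``pmm_donor_count`` nearest-predicted
donors (type-1 matching: donor predictions from the posterior-mean
coefficients, target predictions from a posterior draw). Passive terms are
recomputed after every variable update. MNAR sensitivity is a post-hoc
delta shift of imputed outcome cells for participants lost to follow-up.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

from hatrial.synthetic_cohort import (
    BIOMARKERS,
    FOLLOWUP_COLS,
    FOLLOWUP_SUFFIX,
    FREQUENCY_LEVELS,
    LOWER_TAIL_BIOMARKERS,
)

logger = logging.getLogger(__name__)

#: object-typed columns imputed through a fixed ordinal coding
CATEGORICAL_CODES = {"ha_frequency": list(FREQUENCY_LEVELS)}


@dataclass
class ImputationModelSpec:
    """Configuration of one chained-PMM run."""

    variables: list  # modelled columns (imputed and/or predictors)
    predictors: dict = field(default_factory=dict)  # var -> predictor columns
    pmm_donor_count: int = 5
    n_cycles: int = 10
    passive_terms: list = field(default_factory=list)  # (colname, fn(df)->values)
    forced_terms: list = field(default_factory=list)
    candidate_auxiliaries: list = field(default_factory=list)
    seed: int = 0

    def predictor_set(self, var: str) -> list:
        if var in self.predictors:
            return list(self.predictors[var])
        return [v for v in self.variables if v != var]

    def hash(self) -> str:
        key = repr(
            (
                sorted(self.variables),
                sorted((k, tuple(v)) for k, v in self.predictors.items()),
                self.pmm_donor_count,
                self.n_cycles,
                [t[0] for t in self.passive_terms],
                self.seed,
            )
        )
        return hashlib.sha256(key.encode()).hexdigest()[:16]


@dataclass
class ImputedDataset:
    data: pd.DataFrame
    bootstrap_index: int
    imputation_index: int
    spec_hash: str
    imputed_mask: pd.DataFrame  # True where a cell was filled in
    lost_to_followup: pd.Series  # survivors whose outcomes were missing


@dataclass(frozen=True)
class DeltaSpec:
    """MNAR shift in outcome-SD units, applied to imputed follow-up cells of
    participants lost to follow-up. Positive-tail biomarkers shift up,
    the amyloid ratio shifts down."""

    shift_sd: float
    sd: dict  # biomarker -> observed follow-up SD

    def signed_shift(self, biomarker: str) -> float:
        sign = -1.0 if biomarker in LOWER_TAIL_BIOMARKERS else 1.0
        return sign * self.shift_sd * self.sd[biomarker]


def delta_spec_from_cohort(cohort: pd.DataFrame, shift_sd: float) -> DeltaSpec:
    """Scale the delta by the observed-data follow-up SD per biomarker."""
    sd = {}
    for b in BIOMARKERS:
        col = cohort[b + FOLLOWUP_SUFFIX]
        sd[b] = float(col.dropna().std(ddof=1))
    return DeltaSpec(shift_sd=shift_sd, sd=sd)


# ---------------------------------------------------------------------------
# LASSO auxiliary selection
# ---------------------------------------------------------------------------

def expand_candidate_terms(
    cohort: pd.DataFrame, candidates: list
) -> pd.DataFrame:
    """Candidate design: main effects, squares, and pairwise products."""
    base = cohort[candidates].apply(pd.to_numeric, errors="coerce")
    base = base.fillna(base.mean())
    out = {c: base[c].to_numpy() for c in candidates}
    for c in candidates:
        out[f"{c}^2"] = base[c].to_numpy() ** 2
    for i, a in enumerate(candidates):
        for b in candidates[i + 1:]:
            out[f"{a}:{b}"] = base[a].to_numpy() * base[b].to_numpy()
    return pd.DataFrame(out, index=cohort.index)


def select_auxiliaries(
    cohort: pd.DataFrame,
    candidates: list,
    outcome: str,
    forced: list | None = None,
    seed: int = 0,
    n_folds: int = 5,
) -> list:
    """LASSO-select auxiliary/quadratic/product terms predictive of an outcome.

    Candidates are mean-imputed for selection only; the cross-validated
    penalty uses fixed shuffled folds so selection is deterministic given
    the seed. Forced terms (treatment x effect-modifier products) are
    always in the output regardless of their LASSO coefficient.
    """
    forced = list(forced or [])
    y = pd.to_numeric(cohort[outcome], errors="coerce")
    keep = y.notna()
    if int(keep.sum()) < 10:
        raise ValueError(
            f"fewer than 10 complete rows for outcome '{outcome}'"
        )
    X = expand_candidate_terms(cohort.loc[keep], candidates)
    yv = y[keep].to_numpy(dtype=float)
    sds = X.std(axis=0, ddof=0).replace(0.0, 1.0)
    Xs = (X - X.mean(axis=0)) / sds
    cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    lasso = LassoCV(cv=cv, alphas=60, max_iter=20_000, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lasso.fit(Xs.to_numpy(), yv)
    # one-standard-error rule: largest penalty whose CV error is within one
    # SE of the minimum (the CV-minimizing penalty notoriously over-selects)
    mse = lasso.mse_path_.mean(axis=1)
    se = lasso.mse_path_.std(axis=1, ddof=1) / np.sqrt(lasso.mse_path_.shape[1])
    i_min = int(np.argmin(mse))
    threshold = mse[i_min] + se[i_min]
    ok = np.where(mse <= threshold)[0]
    alpha_1se = float(lasso.alphas_[ok].max())
    refit = Lasso(alpha=alpha_1se, max_iter=20_000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        refit.fit(Xs.to_numpy(), yv)
    selected = [c for c, w in zip(X.columns, refit.coef_) if abs(w) > 1e-10]
    for term in forced:
        if term not in selected:
            selected.append(term)
    return selected


# ---------------------------------------------------------------------------
# chained PMM
# ---------------------------------------------------------------------------

def _encode(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col, levels in CATEGORICAL_CODES.items():
        if col in out.columns:
            mapping = {lv: i for i, lv in enumerate(levels)}
            out[col] = out[col].map(mapping).astype(float)
    return out


def _decode(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col, levels in CATEGORICAL_CODES.items():
        if col in out.columns:
            codes = out[col].round().clip(0, len(levels) - 1)
            out[col] = pd.array(
                [
                    None if pd.isna(c) else levels[int(c)]
                    for c in codes
                ],
                dtype="object",
            )
    return out


def _pmm_match(
    yhat_obs: np.ndarray,
    y_obs: np.ndarray,
    yhat_mis: np.ndarray,
    k: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """For each target prediction pick one of the k nearest donors' values."""
    order = np.argsort(yhat_obs, kind="stable")
    sorted_pred = yhat_obs[order]
    sorted_y = y_obs[order]
    n_obs = len(sorted_pred)
    k = min(k, n_obs)
    pos = np.searchsorted(sorted_pred, yhat_mis)
    out = np.empty(len(yhat_mis))
    for i, (p, yh) in enumerate(zip(pos, yhat_mis)):
        lo = max(0, p - k)
        hi = min(n_obs, p + k)
        window = np.arange(lo, hi)
        d = np.abs(sorted_pred[window] - yh)
        nearest = window[np.argsort(d, kind="stable")[:k]]
        out[i] = sorted_y[nearest[rng.integers(len(nearest))]]
    return out


def _bayes_regression(X, y, rng, warn_key=None, warned=None):
    """Posterior-mean and posterior-draw coefficients for a normal linear model.

    Rank-deficient designs are handled by pseudo-inverse (equivalent to
    dropping redundant predictors) with a logged warning (once per
    variable per run).
    """
    n, p = X.shape
    beta_hat, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p and (warned is None or warn_key not in warned):
        logger.warning(
            "collinear predictors for %s (rank %d < %d); redundant terms "
            "dropped", warn_key, rank, p,
        )
        if warned is not None:
            warned.add(warn_key)
    resid = y - X @ beta_hat
    dof = max(n - rank, 1)
    sse = float(resid @ resid)
    sigma2 = sse / stats.chi2.rvs(dof, random_state=rng)
    xtx = X.T @ X
    cov = np.linalg.pinv(xtx, hermitian=True) * sigma2
    # draw via eigen-decomposition (pinv cov may be singular)
    w, v = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    beta_draw = beta_hat + v @ (np.sqrt(w) * rng.standard_normal(p))
    return beta_hat, beta_draw


def chained_pmm_impute(
    cohort: pd.DataFrame,
    spec: ImputationModelSpec,
    m: int = 1,
    rng: np.random.Generator | None = None,
    bootstrap_index: int = 0,
) -> list[ImputedDataset]:
    """Produce ``m`` completed copies of the cohort by chained PMM.

    Variables are visited in ascending order of missingness fraction (ties
    alphabetical). Imputed values always lie in the observed support of
    their variable; observed cells are returned bit-identical.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    enc = _encode(cohort)
    modelled = [v for v in spec.variables if v in enc.columns]
    miss_frac = {v: float(enc[v].isna().mean()) for v in modelled}
    to_impute = sorted(
        (v for v in modelled if miss_frac[v] > 0),
        key=lambda v: (miss_frac[v], v),
    )
    for v in to_impute:
        if enc[v].notna().sum() == 0:
            raise ValueError(f"variable '{v}' has no observed values")
    if to_impute and not any(miss_frac[v] == 0 for v in modelled):
        raise ValueError("at least one modelled variable must be fully observed")

    obs_mask = {v: enc[v].notna().to_numpy() for v in to_impute}
    surv = cohort.get("died_before_followup")
    surv = (
        (surv == 0).to_numpy()
        if surv is not None
        else np.ones(len(cohort), dtype=bool)
    )
    outcome_missing = cohort[FOLLOWUP_COLS].isna().all(axis=1).to_numpy() if all(
        c in cohort.columns for c in FOLLOWUP_COLS
    ) else np.zeros(len(cohort), dtype=bool)
    lost = pd.Series(surv & outcome_missing, index=cohort.index, name="lost")

    results = []
    warned: set = set()
    for im in range(m):
        work = enc.copy()
        # initial fill: random draws from the observed margin
        for v in to_impute:
            obs_vals = work.loc[obs_mask[v], v].to_numpy()
            n_mis = int((~obs_mask[v]).sum())
            work.loc[~obs_mask[v], v] = obs_vals[
                rng.integers(len(obs_vals), size=n_mis)
            ]
        for name, fn in spec.passive_terms:
            work[name] = fn(work)

        n_cycles = spec.n_cycles if len(to_impute) > 1 else 1
        for _ in range(n_cycles):
            for v in to_impute:
                preds = [
                    p for p in spec.predictor_set(v) if p in work.columns and p != v
                ]
                X = work[preds].to_numpy(dtype=float)
                X = np.column_stack([np.ones(len(X)), X])
                y = work[v].to_numpy(dtype=float)
                ob = obs_mask[v]
                beta_hat, beta_draw = _bayes_regression(
                    X[ob], y[ob], rng, warn_key=v, warned=warned
                )
                yhat_obs = X[ob] @ beta_hat
                yhat_mis = X[~ob] @ beta_draw
                imputed = _pmm_match(
                    yhat_obs, y[ob], yhat_mis, spec.pmm_donor_count, rng
                )
                col = work[v].to_numpy(dtype=float)
                col[~ob] = imputed
                work[v] = col
                for name, fn in spec.passive_terms:
                    work[name] = fn(work)

        completed = _decode(work)
        # restore observed cells bit-identically (guards float round-trips)
        for v in to_impute:
            completed.loc[obs_mask[v], v] = cohort.loc[obs_mask[v], v]
        # structural coherence of the exposure pair
        if "ha_prescription" in completed and "ha_frequency" in completed:
            no_rx = completed["ha_prescription"] == 0
            completed.loc[no_rx, "ha_frequency"] = "never"

        mask = pd.DataFrame(
            {v: ~obs_mask[v] for v in to_impute}, index=cohort.index
        )
        results.append(
            ImputedDataset(
                data=completed,
                bootstrap_index=bootstrap_index,
                imputation_index=im,
                spec_hash=spec.hash(),
                imputed_mask=mask,
                lost_to_followup=lost,
            )
        )
    return results


def apply_delta_shift(imputed: ImputedDataset, delta: DeltaSpec) -> ImputedDataset:
    """Shift imputed follow-up outcome cells of the lost-to-follow-up.

    Observed cells and cells imputed for other reasons (e.g. covariates)
    are untouched; ``shift_sd = 0`` is an identity.
    """
    if imputed.imputed_mask is None or imputed.lost_to_followup is None:
        raise ValueError("delta adjustment requires imputation flags")
    data = imputed.data.copy()
    lost = imputed.lost_to_followup.to_numpy()
    for b in BIOMARKERS:
        col = b + FOLLOWUP_SUFFIX
        if col not in imputed.imputed_mask.columns:
            continue
        qualifies = imputed.imputed_mask[col].to_numpy() & lost
        data.loc[qualifies, col] = (
            data.loc[qualifies, col] + delta.signed_shift(b)
        )
    return ImputedDataset(
        data=data,
        bootstrap_index=imputed.bootstrap_index,
        imputation_index=imputed.imputation_index,
        spec_hash=imputed.spec_hash,
        imputed_mask=imputed.imputed_mask,
        lost_to_followup=imputed.lost_to_followup,
    )
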