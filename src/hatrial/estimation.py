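"""Causal estimators for the emulated trials.

TMLE for survivor-conditional mean contrasts (outcome scaled to [0,1],
logistic fluctuation with strategy-specific clever covariates), an
inverse-probability-weighted type-1 quantile estimator, restricted cubic
spline bases, MSM projection of targeted predictions for effect
modification, and a from-scratch MARS (degree-2 interactions) nuisance
fitter for the data-adaptive sensitivity analysis.

The weight-truncation rule bounds inverse-probability weights at
sqrt(n * ln(n)) / 5; equivalently, fitted propensities are floored at its
reciprocal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

__all__ = [
    "truncation_bound",
    "PropensityFit",
    "fit_propensity",
    "TMLEEstimate",
    "tmle_mean_contrast",
    "QuantileEstimate",
    "ipw_quantile_contrast",
    "weighted_quantile",
    "rcs_basis",
    "MSMEstimate",
    "tmle_msm_effect_modification",
    "MarsModel",
    "mars_nuisance_fit",
]


def truncation_bound(n: int) -> float:
    """Upper bound on inverse-probability weights: sqrt(n * ln(n)) / 5."""
    if n < 2:
        raise ValueError("n must be at least 2")
    return float(np.sqrt(n * np.log(n)) / 5.0)


# ---------------------------------------------------------------------------
# propensity
# ---------------------------------------------------------------------------

@dataclass
class PropensityFit:
    strategies: tuple
    proba: np.ndarray  # n x K, rows sum to 1
    proba_trunc: np.ndarray  # floored at 1/bound so weights <= bound
    bound: float
    n_truncated: int
    terms: tuple

    def g(self, label: str, truncated: bool = True) -> np.ndarray:
        k = self.strategies.index(label)
        return (self.proba_trunc if truncated else self.proba)[:, k]


def _design(df: pd.DataFrame, covariates: list) -> np.ndarray:
    X = df[list(covariates)].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(df)), X])


def fit_propensity(
    df: pd.DataFrame,
    strategy_col: str,
    covariates: list,
    strategies: tuple | None = None,
    method: str = "glm",
    mars_params: dict | None = None,
    min_rows_per_strategy: int = 10,
) -> PropensityFit:
    """Fit the strategy-assignment model and truncate the probabilities.

    Binary trials use a logistic GLM; three-level trials a multinomial
    logit. ``method='mars'`` fits MARS bases per non-reference strategy
    with a logistic link and renormalizes.
    """
    strat = df[strategy_col].to_numpy(dtype=object)
    if strategies is None:
        strategies = tuple(pd.unique(strat))
    counts = {s: int((strat == s).sum()) for s in strategies}
    low = [s for s, c in counts.items() if c < min_rows_per_strategy]
    if len(strategies) < 2 or low:
        raise ValueError(
            f"need >=2 strategies with >={min_rows_per_strategy} rows each; "
            f"low: {low}"
        )

    n = len(df)
    bound = truncation_bound(n)
    # constant columns (e.g. an eligibility variable fixed by screening)
    # duplicate the intercept; drop them
    covariates = [
        c for c in covariates if df[c].nunique(dropna=False) > 1
    ]
    X = _design(df, covariates)
    K = len(strategies)
    codes = np.array([strategies.index(s) for s in strat])

    if method == "mars":
        raw = _mars_propensity(df, codes, covariates, K, mars_params or {})
    elif K == 2:
        y = (codes == 1).astype(float)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", category=PerfectSeparationWarning)
                fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
        except Exception as exc:  # noqa: BLE001 - separation surfaces many ways
            raise ValueError(
                "propensity model failed to converge (possible perfect "
                "separation); consider removing product terms"
            ) from exc
        if not np.all(np.isfinite(fit.params)) or np.abs(fit.params).max() > 50:
            raise ValueError(
                "propensity coefficients diverged (possible perfect "
                "separation); consider removing product terms"
            )
        p1 = np.asarray(fit.predict(X))
        raw = np.column_stack([1 - p1, p1])
    else:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.MNLogit(codes, X).fit(disp=0, maxiter=200)
        except Exception as exc:  # noqa: BLE001
            raise ValueError(
                "multinomial propensity model failed; consider removing "
                "product terms"
            ) from exc
        raw = np.asarray(fit.predict(X))
        if not np.all(np.isfinite(raw)):
            raise ValueError("multinomial propensity produced non-finite values")

    floor = 1.0 / bound
    trunc = np.maximum(raw, floor)
    n_truncated = int((raw < floor).sum())
    return PropensityFit(
        strategies=tuple(strategies),
        proba=raw,
        proba_trunc=trunc,
        bound=bound,
        n_truncated=n_truncated,
        terms=tuple(covariates),
    )


def _mars_propensity(df, codes, covariates, K, mars_params):
    X = df[list(covariates)].to_numpy(dtype=float)
    cols = []
    for k in range(1, K):
        y = (codes == k).astype(float)
        model = MarsModel(**mars_params).fit(X, y)
        basis = model.transform(X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gfit = sm.GLM(y, basis, family=sm.families.Binomial()).fit(maxiter=100)
        cols.append(np.clip(np.asarray(gfit.predict(basis)), 1e-6, 1 - 1e-6))
    if K == 2:
        p1 = cols[0]
        return np.column_stack([1 - p1, p1])
    other = np.column_stack(cols)
    p0 = np.clip(1.0 - other.sum(axis=1), 1e-6, None)
    raw = np.column_stack([p0, other])
    return raw / raw.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# TMLE mean contrast
# ---------------------------------------------------------------------------

@dataclass
class TMLEEstimate:
    strategies: tuple
    means: dict  # strategy -> targeted mean, natural units
    contrasts: dict  # non-reference strategy -> mean difference vs reference
    epsilon: dict
    bounds: tuple
    score_residuals: dict  # strategy -> mean clever-covariate residual
    influence: dict = field(default_factory=dict)  # strategy -> IC values
    q_star: pd.DataFrame | None = None  # per-participant targeted predictions
    truncation_count: int = 0


def _solve_fluctuation(h, y, offset, tol=1e-12, max_iter=100):
    """1-D Newton for the logistic fluctuation score sum(h*(y-expit(off+h*e)))."""
    eps = 0.0
    for _ in range(max_iter):
        mu = expit(offset + h * eps)
        score = float(np.sum(h * (y - mu)))
        info = float(np.sum(h * h * mu * (1 - mu)))
        if info <= 0:
            break
        step = score / info
        eps += step
        if abs(step) < tol:
            break
    return eps


def _glm_outcome_fit(df, strategy_col, strategies, outcome_scaled, covariates,
                     interactions):
    """OLS initial fit; returns per-strategy prediction function."""
    codes = np.array([strategies.index(s) for s in df[strategy_col]])
    W = df[list(covariates)].to_numpy(dtype=float) if covariates else np.empty(
        (len(df), 0)
    )

    def build(code_vec):
        dummies = np.column_stack(
            [(code_vec == k).astype(float) for k in range(1, len(strategies))]
        ) if len(strategies) > 1 else np.empty((len(code_vec), 0))
        parts = [np.ones(len(code_vec)), dummies, W]
        if interactions:
            for k in range(dummies.shape[1]):
                parts.append(W * dummies[:, [k]])
        return np.column_stack(parts)

    Xobs = build(codes)
    beta, _, _, _ = np.linalg.lstsq(Xobs, outcome_scaled, rcond=None)

    def predict(strategy_label):
        k = strategies.index(strategy_label)
        return build(np.full(len(df), k)) @ beta

    return predict


def _mars_outcome_fit(df, strategy_col, strategies, outcome_scaled, covariates,
                      mars_params):
    codes = np.array([strategies.index(s) for s in df[strategy_col]])
    W = df[list(covariates)].to_numpy(dtype=float)
    dummies = np.column_stack(
        [(codes == k).astype(float) for k in range(1, len(strategies))]
    )
    X = np.column_stack([dummies, W])
    model = MarsModel(**mars_params).fit(X, outcome_scaled)

    def predict(strategy_label):
        k = strategies.index(strategy_label)
        dum = np.zeros((len(df), len(strategies) - 1))
        if k > 0:
            dum[:, k - 1] = 1.0
        return model.predict(np.column_stack([dum, W]))

    return predict


def tmle_mean_contrast(
    df: pd.DataFrame,
    strategy_col: str,
    outcome_col: str,
    covariates: list,
    propensity: PropensityFit,
    interactions: bool = False,
    nuisance: str = "glm",
    mars_params: dict | None = None,
) -> TMLEEstimate:
    """Targeted mean under each strategy and contrasts vs the reference.

    The outcome is scaled to [0,1] by its observed range, the initial fit
    is a linear model (or MARS) in strategy and covariates, and a logistic
    fluctuation with clever covariate I(A=a)/g_a per strategy solves the
    efficient-influence-curve score equation.
    """
    strategies = propensity.strategies
    y = df[outcome_col].to_numpy(dtype=float)
    a, b = float(y.min()), float(y.max())
    if b <= a:
        raise ValueError(f"outcome '{outcome_col}' is constant; cannot scale")
    ys = (y - a) / (b - a)

    if propensity.n_truncated > 0.2 * len(df):
        warnings.warn(
            f"propensity truncation affected {propensity.n_truncated} of "
            f"{len(df)} rows (> 20%)",
            stacklevel=2,
        )

    if nuisance == "mars":
        predict = _mars_outcome_fit(
            df, strategy_col, strategies, ys, covariates, mars_params or {}
        )
    else:
        predict = _glm_outcome_fit(
            df, strategy_col, strategies, ys, covariates, interactions
        )

    codes = np.array([strategies.index(s) for s in df[strategy_col]])
    Q = {s: np.clip(predict(s), 1e-4, 1 - 1e-4) for s in strategies}

    eps, q_star, means, score_res, influence = {}, {}, {}, {}, {}
    for k, s in enumerate(strategies):
        g = propensity.proba_trunc[:, k]
        ind = (codes == k).astype(float)
        h = ind / g
        off = logit(Q[s])
        e = _solve_fluctuation(h, ys, off)
        qs = expit(off + e / g)  # update evaluated at A=s for everyone
        eps[s] = e
        q_star[s] = qs
        means[s] = a + float(qs.mean()) * (b - a)
        score_res[s] = float(np.mean(h * (ys - qs)))
        influence[s] = (b - a) * (h * (ys - qs) + qs - qs.mean())

    ref = strategies[0]
    contrasts = {s: means[s] - means[ref] for s in strategies[1:]}
    return TMLEEstimate(
        strategies=strategies,
        means=means,
        contrasts=contrasts,
        epsilon=eps,
        bounds=(a, b),
        score_residuals=score_res,
        influence=influence,
        q_star=pd.DataFrame({s: a + q_star[s] * (b - a) for s in strategies},
                            index=df.index),
        truncation_count=propensity.n_truncated,
    )


# ---------------------------------------------------------------------------
# IPW quantiles
# ---------------------------------------------------------------------------

def weighted_quantile(y: np.ndarray, w: np.ndarray, tau: float) -> float:
    """Type-1 weighted quantile: smallest y with normalized cum-weight >= tau.

    Tied outcome values share cumulative weight.
    """
    if not 0 < tau < 1:
        raise ValueError("tau must lie in (0,1)")
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    order = np.argsort(y, kind="stable")
    ys, ws = y[order], w[order]
    cdf = np.cumsum(ws) / ws.sum()
    # push each tied block's cdf to the block's last element
    uniq, inverse = np.unique(ys, return_inverse=True)
    last_idx = np.searchsorted(inverse, np.arange(len(uniq)), side="right") - 1
    block_cdf = cdf[last_idx]
    j = int(np.searchsorted(block_cdf, tau - 1e-12))
    j = min(j, len(uniq) - 1)
    return float(uniq[j])


@dataclass
class QuantileEstimate:
    tau: float
    quantiles: dict  # strategy -> weighted quantile
    contrasts: dict  # non-reference -> difference vs reference


def ipw_quantile_contrast(
    df: pd.DataFrame,
    strategy_col: str,
    outcome_col: str,
    propensity: PropensityFit,
    tau: float,
) -> QuantileEstimate:
    """Weighted empirical quantile per strategy with weights 1/g (truncated)."""
    if not 0 < tau < 1:
        raise ValueError("tau must lie in (0,1)")
    strategies = propensity.strategies
    strat = df[strategy_col].to_numpy(dtype=object)
    y = df[outcome_col].to_numpy(dtype=float)
    quantiles = {}
    for k, s in enumerate(strategies):
        sel = strat == s
        n_s = int(sel.sum())
        if n_s == 0:
            raise ValueError(f"no rows under strategy '{s}'")
        if n_s < 20:
            warnings.warn(f"only {n_s} rows under strategy '{s}'", stacklevel=2)
        w = 1.0 / propensity.proba_trunc[sel, k]
        quantiles[s] = weighted_quantile(y[sel], w, tau)
    ref = strategies[0]
    contrasts = {s: quantiles[s] - quantiles[ref] for s in strategies[1:]}
    return QuantileEstimate(tau=tau, quantiles=quantiles, contrasts=contrasts)


# ---------------------------------------------------------------------------
# restricted cubic splines
# ---------------------------------------------------------------------------

def rcs_basis(x: np.ndarray, knots) -> np.ndarray:
    """Restricted (natural) cubic spline basis: k knots -> k-1 columns.

    Column 0 is x itself; the remaining columns are the standard
    normalized truncated-cubic combinations, linear beyond the boundary
    knots.
    """
    knots = np.asarray(knots, dtype=float)
    if knots.ndim != 1 or len(knots) < 3 or np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be >=3 strictly increasing values")
    x = np.asarray(x, dtype=float)
    k = len(knots)
    t1, tkm1, tk = knots[0], knots[-2], knots[-1]
    scale = (tk - t1) ** 2

    def cube(u):
        return np.clip(u, 0, None) ** 3

    cols = [x]
    for j in range(k - 2):
        tj = knots[j]
        term = (
            cube(x - tj)
            - cube(x - tkm1) * (tk - tj) / (tk - tkm1)
            + cube(x - tk) * (tkm1 - tj) / (tk - tkm1)
        ) / scale
        cols.append(term)
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# MSM effect modification
# ---------------------------------------------------------------------------

@dataclass
class MSMEstimate:
    coef: np.ndarray
    term_names: tuple
    knots: np.ndarray | None
    curve: pd.DataFrame  # columns: modifier, strategy, predicted_mean
    implied_means: dict  # strategy -> curve-free (strategy-only) mean


def _modifier_basis(values: np.ndarray, knots: np.ndarray | None):
    if knots is None:  # categorical / binary: identity coding
        return values.reshape(-1, 1), ("modifier",)
    basis = rcs_basis(values, knots)
    names = tuple(
        ["modifier"] + [f"modifier_rcs{j}" for j in range(1, basis.shape[1])]
    )
    return basis, names


def tmle_msm_effect_modification(
    df: pd.DataFrame,
    strategy_col: str,
    outcome_col: str,
    modifier_col: str | None,
    covariates: list,
    propensity: PropensityFit,
    grid_size: int = 50,
    tmle: TMLEEstimate | None = None,
) -> MSMEstimate:
    """Project targeted strategy-specific predictions onto an MSM.

    The MSM design is {intercept, strategy dummies, modifier basis,
    strategy x modifier products}; continuous modifiers use a restricted
    cubic spline with knots at the 10th/50th/90th sample percentiles, and
    the prediction grid spans the 2.5th-97.5th percentiles.
    ``modifier_col=None`` fits the strategy-saturated MSM whose implied
    means reproduce the TMLE means exactly.

    Unless a pre-computed ``tmle`` is supplied, the initial outcome fit
    includes strategy x covariate products (with the modifier forced into
    the covariate set): a main-effects-only fit cannot express effect
    modification, so projecting it would flatten every curve.
    """
    if tmle is None:
        covs = list(covariates)
        if modifier_col is not None and modifier_col not in covs:
            covs.append(modifier_col)
        tmle = tmle_mean_contrast(
            df, strategy_col, outcome_col, covs, propensity,
            interactions=True,
        )
    strategies = tmle.strategies
    K = len(strategies)
    n = len(df)
    preds = tmle.q_star  # natural units, per participant per strategy

    if modifier_col is not None:
        mod = df[modifier_col].to_numpy(dtype=float)
        if np.nanstd(mod) == 0:
            raise ValueError(f"modifier '{modifier_col}' is constant")
        continuous = len(np.unique(mod)) > 2
        knots = (
            np.quantile(mod, [0.1, 0.5, 0.9]) if continuous else None
        )
        if knots is not None and np.any(np.diff(knots) <= 0):
            knots = None  # degenerate percentiles: treat as categorical
        basis, basis_names = _modifier_basis(mod, knots)
    else:
        knots, basis, basis_names = None, np.empty((n, 0)), ()

    # stacked long design: one block per strategy
    rows_X, rows_y = [], []
    for k, s in enumerate(strategies):
        dummies = np.zeros((n, K - 1))
        if k > 0:
            dummies[:, k - 1] = 1.0
        parts = [np.ones(n), dummies, basis]
        for j in range(K - 1):
            parts.append(basis * dummies[:, [j]])
        rows_X.append(np.column_stack(parts))
        rows_y.append(preds[s].to_numpy())
    X = np.vstack(rows_X)
    yv = np.concatenate(rows_y)
    coef, _, _, _ = np.linalg.lstsq(X, yv, rcond=None)

    names = ["intercept"] + [f"strategy[{s}]" for s in strategies[1:]]
    names += list(basis_names)
    for s in strategies[1:]:
        names += [f"strategy[{s}]:{bn}" for bn in basis_names]

    # prediction curves over the modifier grid
    curves = []
    if modifier_col is not None:
        lo, hi = np.quantile(mod, [0.025, 0.975])
        if len(np.unique(mod)) > 2:
            grid = np.linspace(lo, hi, grid_size)
        else:
            grid = np.unique(mod)
        gbasis, _ = _modifier_basis(grid, knots)
        for k, s in enumerate(strategies):
            dummies = np.zeros((len(grid), K - 1))
            if k > 0:
                dummies[:, k - 1] = 1.0
            parts = [np.ones(len(grid)), dummies, gbasis]
            for j in range(K - 1):
                parts.append(gbasis * dummies[:, [j]])
            gx = np.column_stack(parts)
            curves.append(
                pd.DataFrame(
                    {
                        "modifier": grid,
                        "strategy": s,
                        "predicted_mean": gx @ coef,
                    }
                )
            )
        curve = pd.concat(curves, ignore_index=True)
    else:
        curve = pd.DataFrame(
            {
                "modifier": [np.nan] * K,
                "strategy": list(strategies),
                "predicted_mean": [
                    coef[0] + (coef[k] if k > 0 else 0.0) for k in range(K)
                ],
            }
        )

    implied = {}
    for k, s in enumerate(strategies):
        implied[s] = float(coef[0] + (coef[k] if 0 < k < K else 0.0))
    return MSMEstimate(
        coef=coef,
        term_names=tuple(names),
        knots=knots,
        curve=curve,
        implied_means=implied,
    )


# ---------------------------------------------------------------------------
# MARS (forward/backward, interactions of degree <= 2)
# ---------------------------------------------------------------------------

class _Hinge:
    __slots__ = ("var", "knot", "sign")

    def __init__(self, var, knot, sign):
        self.var, self.knot, self.sign = var, knot, sign

    def __call__(self, X):
        u = self.sign * (X[:, self.var] - self.knot)
        return np.clip(u, 0, None)


class _BasisTerm:
    """Product of up to ``max_degree`` hinge functions (1 = intercept)."""

    def __init__(self, hinges=()):
        self.hinges = tuple(hinges)

    @property
    def degree(self):
        return len(self.hinges)

    def variables(self):
        return {h.var for h in self.hinges}

    def evaluate(self, X):
        out = np.ones(len(X))
        for h in self.hinges:
            out = out * h(X)
        return out


class MarsModel:
    """Multivariate adaptive regression splines, interaction degree <= 2.

    Forward pass adds reflected hinge pairs greedily by SSE reduction
    (computed against the current orthonormalized basis); backward pass
    prunes terms by generalized cross-validation.
    """

    def __init__(self, max_terms: int = 15, max_degree: int = 2,
                 n_knot_candidates: int = 10, gcv_penalty: float = 3.0):
        self.max_terms = max_terms
        self.max_degree = max_degree
        self.n_knot_candidates = n_knot_candidates
        self.gcv_penalty = gcv_penalty
        self.terms_: list[_BasisTerm] = []
        self.coef_: np.ndarray | None = None

    # -- helpers ----------------------------------------------------------
    def _knots(self, x):
        qs = np.linspace(0.05, 0.95, self.n_knot_candidates)
        return np.unique(np.quantile(x, qs))

    def _gcv(self, sse, n, p):
        c = p + self.gcv_penalty * max(p - 1, 0) / 2.0
        denom = (1.0 - min(c / n, 0.99)) ** 2
        return (sse / n) / denom

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, d = X.shape
        terms = [_BasisTerm()]
        B = np.ones((n, 1))
        Q, _ = np.linalg.qr(B)
        resid = y - Q @ (Q.T @ y)

        knot_cache = [self._knots(X[:, v]) for v in range(d)]
        while len(terms) < self.max_terms:
            best = None
            for parent in terms:
                if parent.degree >= self.max_degree:
                    continue
                pcol = parent.evaluate(X)
                for v in range(d):
                    if v in parent.variables():
                        continue
                    for t in knot_cache[v]:
                        c1 = pcol * np.clip(X[:, v] - t, 0, None)
                        c2 = pcol * np.clip(t - X[:, v], 0, None)
                        C = np.column_stack([c1, c2])
                        Cp = C - Q @ (Q.T @ C)
                        norms = np.linalg.norm(Cp, axis=0)
                        keep = norms > 1e-8 * max(1.0, np.linalg.norm(C))
                        if not keep.any():
                            continue
                        Cp = Cp[:, keep] / norms[keep]
                        # orthogonalize the pair against each other
                        if Cp.shape[1] == 2:
                            Cp[:, 1] -= Cp[:, 0] * (Cp[:, 0] @ Cp[:, 1])
                            nrm = np.linalg.norm(Cp[:, 1])
                            if nrm > 1e-8:
                                Cp[:, 1] /= nrm
                            else:
                                Cp = Cp[:, :1]
                        gain = float(np.sum((Cp.T @ resid) ** 2))
                        if best is None or gain > best[0]:
                            best = (gain, parent, v, t)
            if best is None or best[0] <= 1e-10 * max(float(y @ y), 1.0):
                break
            _, parent, v, t = best
            for sign in (1.0, -1.0):
                terms.append(
                    _BasisTerm(parent.hinges + (_Hinge(v, t, sign),))
                )
            B = np.column_stack([tm.evaluate(X) for tm in terms])
            Q, _ = np.linalg.qr(B)
            resid = y - Q @ (Q.T @ y)

        # backward pruning by GCV
        def sse_of(subset):
            Bsub = np.column_stack([terms[i].evaluate(X) for i in subset])
            beta, _, _, _ = np.linalg.lstsq(Bsub, y, rcond=None)
            r = y - Bsub @ beta
            return float(r @ r), beta

        current = list(range(len(terms)))
        sse, beta = sse_of(current)
        best_gcv = self._gcv(sse, n, len(current))
        best_subset, best_beta = list(current), beta
        while len(current) > 1:
            trial_best = None
            for i in current[1:]:  # never drop the intercept
                subset = [j for j in current if j != i]
                sse_i, beta_i = sse_of(subset)
                g = self._gcv(sse_i, n, len(subset))
                if trial_best is None or g < trial_best[0]:
                    trial_best = (g, subset, beta_i)
            current = trial_best[1]
            if trial_best[0] < best_gcv:
                best_gcv, best_subset, best_beta = (
                    trial_best[0], list(current), trial_best[2]
                )
        self.terms_ = [terms[i] for i in best_subset]
        self.coef_ = best_beta
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return np.column_stack([tm.evaluate(X) for tm in self.terms_])

    def predict(self, X):
        return self.transform(X) @ self.coef_

    def max_interaction_order(self) -> int:
        return max((tm.degree for tm in self.terms_), default=0)


def mars_nuisance_fit(
    df: pd.DataFrame,
    target: str,
    strategy_col: str,
    outcome_col: str | None,
    covariates: list,
    strategies: tuple | None = None,
    mars_params: dict | None = None,
):
    """Fitted values from a MARS nuisance model.

    ``target='outcome'`` returns the fitted conditional outcome mean;
    ``target='propensity'`` returns probabilities through a logistic link
    on the selected MARS basis.
    """
    params = mars_params or {}
    if target == "propensity":
        fit = fit_propensity(
            df, strategy_col, covariates, strategies=strategies,
            method="mars", mars_params=params,
        )
        return fit.proba
    if target == "outcome":
        if outcome_col is None:
            raise ValueError("outcome_col required for target='outcome'")
        strat = df[strategy_col].to_numpy(dtype=object)
        if strategies is None:
            strategies = tuple(pd.unique(strat))
        codes = np.array([strategies.index(s) for s in strat])
        dummies = np.column_stack(
            [(codes == k).astype(float) for k in range(1, len(strategies))]
        )
        X = np.column_stack([dummies, df[list(covariates)].to_numpy(float)])
        y = df[outcome_col].to_numpy(dtype=float)
        model = MarsModel(**params).fit(X, y)
        return model.predict(X)
    raise ValueError("target must be 'propensity' or 'outcome'")
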