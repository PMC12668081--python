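"""Bootstrap-then-multiple-imputation confidence intervals.

Participants are resampled with replacement; within each resample the
cohort is imputed M times and the estimator applied to every completed
copy. The pooled point estimate is the grand mean of the B x M estimates
and the 95% interval is the 2.5th/97.5th percentile of the B
within-bootstrap means (percentile "MI Boot" pooling). Imputation is
nested inside resampling so imputation uncertainty propagates into the
bootstrap distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class BootstrapMIResult:
    estimates: np.ndarray  # B x M (nan where the replicate failed)
    point: float
    ci_lower: float
    ci_upper: float
    n_failed: int
    B: int
    M: int

    def replicate_means(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.estimates, axis=1)


class BootstrapFailureError(RuntimeError):
    pass


def _pool(estimates: np.ndarray, B: int, M: int, alpha: float = 0.05):
    rep_means = np.nanmean(estimates, axis=1)
    ok = np.isfinite(rep_means)
    point = float(np.nanmean(estimates[ok]))
    lo, hi = np.percentile(rep_means[ok], [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return point, float(lo), float(hi)


def bootstrap_mi(
    cohort: pd.DataFrame,
    imputer,
    estimator,
    B: int = 250,
    M: int = 2,
    seed: int = 0,
    alpha: float = 0.05,
    max_failure_rate: float = 0.05,
) -> dict:
    """Bootstrap-MI intervals for one or many estimands at once.

    Parameters
    ----------
    imputer : callable ``(resampled_cohort, m, rng) -> list of completed
        DataFrames`` (length ``m``); pass :func:`identity_imputer` when the
        cohort has no missing data.
    estimator : callable ``completed -> float`` or ``completed -> dict of
        name -> float``; a dict estimator lets one bootstrap loop serve
        every (trial, biomarker, contrast) cell.

    Returns a dict name -> :class:`BootstrapMIResult` (single-key ``"" ``
    for scalar estimators).
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    if M < 1:
        raise ValueError("M must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(cohort)

    arrays: dict[str, np.ndarray] = {}
    n_failed = 0
    failures = []
    for b in range(B):
        idx = rng.integers(n, size=n)
        resample = cohort.iloc[idx].reset_index(drop=True)
        for m_i in range(M):
            try:
                completed_list = imputer(resample, 1, rng)
                est = estimator(completed_list[0])
            except Exception as exc:  # noqa: BLE001 - counted, bounded below
                n_failed += 1
                failures.append((b, m_i, repr(exc)))
                est = None
            if est is None:
                est = {}
            elif np.isscalar(est):
                est = {"": float(est)}
            for name, value in est.items():
                if name not in arrays:
                    arrays[name] = np.full((B, M), np.nan)
                arrays[name][b, m_i] = value

    if n_failed > max_failure_rate * B * M:
        raise BootstrapFailureError(
            f"{n_failed}/{B * M} bootstrap-MI replicates failed; first "
            f"failures: {failures[:3]}"
        )

    out = {}
    for name, arr in arrays.items():
        point, lo, hi = _pool(arr, B, M, alpha)
        out[name] = BootstrapMIResult(
            estimates=arr, point=point, ci_lower=lo, ci_upper=hi,
            n_failed=n_failed, B=B, M=M,
        )
    return out


def identity_imputer(resample: pd.DataFrame, m: int, rng) -> list:
    """Imputer for complete data: returns the resample unchanged m times."""
    return [resample] * m


def pool_from_array(estimates: np.ndarray, alpha: float = 0.05) -> BootstrapMIResult:
    """Re-pool a persisted B x M estimate array."""
    estimates = np.asarray(estimates, dtype=float)
    B, M = estimates.shape
    point, lo, hi = _pool(estimates, B, M, alpha)
    return BootstrapMIResult(
        estimates=estimates, point=point, ci_lower=lo, ci_upper=hi,
        n_failed=int(np.isnan(estimates).sum()), B=B, M=M,
    )


def write_estimates(results: dict, path) -> None:
    """Persist estimate arrays as tidy CSV (name, b, m, estimate)."""
    rows = []
    for name, res in results.items():
        B, M = res.estimates.shape
        for b in range(B):
            for m in range(M):
                rows.append((name, b, m, res.estimates[b, m]))
    pd.DataFrame(rows, columns=["name", "b", "m", "estimate"]).to_csv(
        path, index=False
    )
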