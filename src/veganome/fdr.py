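"""Covariance-preserving permutation FDR (adapted Storey procedure).

The null distribution of the per-feature t-scores is built by permuting
the *residualized* diet vector: one permutation per draw, applied
identically to all features, so the observed covariance between
residualized feature abundances is retained in the joint null.  The
proportion of null features π0 is estimated by comparing the center
mass of the observed |t| distribution with the pooled permutation null,
and per-feature FDR values are Storey-style tail-ratio estimates scaled
by π̂0, with a +1 pseudo-count and step-up monotonicity enforcement.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import substream

logger = logging.getLogger(__name__)


@dataclass
class PermutationNull:
    """B × p matrix of t-scores under permutation of the diet vector."""

    null_ts: np.ndarray
    B: int
    seed: int

    def __post_init__(self) -> None:
        self.null_ts = np.asarray(self.null_ts, dtype=float)
        if self.null_ts.shape[0] != self.B:
            raise ValueError("null_ts row count must equal B")

    @property
    def pooled_abs(self) -> np.ndarray:
        return np.abs(self.null_ts).ravel()


def permutation_ts(
    residual_Y: np.ndarray, x_perm: np.ndarray, df: int
) -> np.ndarray:
    """t-scores of every feature for one or more residualized diet vectors.

    ``x_perm`` is (n,) or (B, n); each row is a (re-residualized)
    permutation of the diet vector.  Vectorized: for residual-on-residual
    regression, β_j = x̃ᵀỹ_j/s, RSS_j = ỹ_jᵀỹ_j − s β_j², t_j = β_j·√(s·df/RSS_j).
    """
    X = np.atleast_2d(np.asarray(x_perm, dtype=float))
    s = np.square(X).sum(axis=1, keepdims=True)  # B × 1
    yty = np.square(residual_Y).sum(axis=0)  # p
    C = X @ residual_Y  # B × p cross-products
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = C / s
        rss = np.maximum(yty[None, :] - s * beta**2, 0.0)
        ts = beta * np.sqrt(s * df / rss)
    out = np.where(rss > 0, ts, np.nan)
    return out[0] if np.asarray(x_perm).ndim == 1 else out


def permute_and_reresidualize(
    residual_X: np.ndarray,
    B: int,
    rng: np.random.Generator,
    nuisance: np.ndarray | None = None,
) -> np.ndarray:
    """B permutations of the residualized diet vector, each re-projected
    off the nuisance design.

    Re-residualizing keeps every null replicate orthogonal to the
    nuisance columns — exactly like the observed vector — so the null
    t-scores are neither under- nor over-dispersed.
    """
    n = len(residual_X)
    perms = np.stack([rng.permutation(n) for _ in range(B)])
    XP = np.asarray(residual_X, dtype=float)[perms]
    if nuisance is not None:
        Q = np.asarray(nuisance, dtype=float)
        coef = np.linalg.solve(Q.T @ Q, (XP @ Q).T)  # q × B
        XP = XP - coef.T @ Q.T
    return XP


def build_null(
    residual_Y: np.ndarray,
    residual_X: np.ndarray,
    B: int,
    seed: int = 0,
    df: int | None = None,
    nuisance: np.ndarray | None = None,
) -> PermutationNull:
    """Joint permutation null of the feature t-scores.

    One uniform permutation of the residualized diet vector per row,
    re-residualized on the nuisance design and applied across all
    features, retaining feature covariance.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if B < 20:
        warnings.warn(f"B={B} permutations give an unstable pi0 estimate",
                      stacklevel=2)
    n, p = residual_Y.shape
    if B * p > 500_000_000:
        raise MemoryError(f"null ensemble B*p = {B * p} too large")
    if df is None:
        df = n - 2
    rng = substream(seed, "perm", "metabolite")
    XP = permute_and_reresidualize(residual_X, B, rng, nuisance)
    ts = permutation_ts(residual_Y, XP, df)
    return PermutationNull(null_ts=ts, B=B, seed=seed)


def estimate_pi0(
    t_obs: np.ndarray, null: PermutationNull, lam: float | None = None
) -> float:
    """Estimate the proportion of null features.

    π̂0 = [#{|t_obs| ≤ λ}/p] / [#{|t_null| ≤ λ}/(Bp)], clipped to (0, 1].
    λ defaults to the median of the pooled null |t| — stable at small B.
    """
    t_obs = np.asarray(t_obs, dtype=float)
    pooled = null.pooled_abs
    if lam is None:
        lam = float(np.median(pooled))
    denom = np.mean(pooled <= lam)
    if denom <= 0:
        raise ValueError(
            f"no null mass at or below lambda={lam:.4g}; choose a smaller lambda"
        )
    num = np.mean(np.abs(t_obs) <= lam)
    pi0 = num / denom
    p = len(t_obs)
    return float(min(1.0, max(pi0, 1.0 / max(p, 1))))


@dataclass
class FdrResult:
    table: pd.DataFrame  # t_obs, rank, fdr per feature (input order)
    pi0: float
    B: int

    @property
    def fdr(self) -> np.ndarray:
        return self.table["fdr"].to_numpy()

    def n_significant(self, alpha: float = 0.05) -> int:
        return int((self.fdr < alpha).sum())


def assign_fdr(
    t_obs: np.ndarray,
    null: PermutationNull,
    pi0: float,
    feature_ids=None,
) -> FdrResult:
    """Per-feature FDR at the threshold |t| = |t_j|.

    FDR(j) = min(1, π̂0 · p · P̂_null(|T| ≥ |t_j|) / #{k: |t_obs_k| ≥ |t_j|})
    with the pooled-null tail probability using a +1 pseudo-count in
    numerator and denominator; monotone in |t| by cumulative minimum
    from the largest |t| down.  Ties share a threshold and therefore a
    value; feature order is stable.
    """
    t_obs = np.asarray(t_obs, dtype=float)
    p = len(t_obs)
    abs_t = np.abs(t_obs)
    finite = np.isfinite(abs_t)
    pooled = np.sort(null.pooled_abs[np.isfinite(null.pooled_abs)])
    n_null = len(pooled)

    # counts of null >= |t_j| and obs >= |t_j| via sorted search
    exceed_null = n_null - np.searchsorted(pooled, abs_t, side="left")
    order = np.argsort(-np.where(finite, abs_t, -np.inf), kind="stable")
    sorted_abs = np.sort(abs_t[finite])
    rank = len(sorted_abs) - np.searchsorted(sorted_abs, abs_t, side="left")

    tail = (exceed_null + 1) / (n_null + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.minimum(1.0, pi0 * p * tail / np.maximum(rank, 1))
    raw[~finite] = 1.0

    # step-up: each feature's FDR is the best attainable at any threshold
    # that still includes it (cumulative min from the least significant up)
    fdr = raw.copy()
    fdr[order] = np.minimum.accumulate(raw[order][::-1])[::-1]

    index = feature_ids if feature_ids is not None else pd.RangeIndex(p)
    table = pd.DataFrame(
        {"t_obs": t_obs, "rank": rank, "fdr": fdr}, index=index
    )
    return FdrResult(table=table, pi0=pi0, B=null.B)


def fdr_pipeline(
    residual_Y: np.ndarray,
    residual_X: np.ndarray,
    df: int,
    B: int = 1000,
    seed: int = 0,
    lam: float | None = None,
    feature_ids=None,
    t_obs: np.ndarray | None = None,
    nuisance: np.ndarray | None = None,
) -> FdrResult:
    """Observed t-scores → permutation null → π̂0 → per-feature FDR.

    ``t_obs`` may be supplied (e.g. cross-validation-shrunken scores);
    by default the observed scores are computed from the residual pair.
    """
    if t_obs is None:
        t_obs = permutation_ts(residual_Y, residual_X, df)
    null = build_null(residual_Y, residual_X, B=B, seed=seed, df=df,
                      nuisance=nuisance)
    pi0 = estimate_pi0(t_obs, null, lam=lam)
    return assign_fdr(t_obs, null, pi0, feature_ids=feature_ids)


def fdr_from_null(
    t_obs: np.ndarray,
    null: PermutationNull,
    lam: float | None = None,
    feature_ids=None,
) -> FdrResult:
    """π̂0 estimation plus FDR assignment against a prebuilt null."""
    pi0 = estimate_pi0(t_obs, null, lam=lam)
    return assign_fdr(t_obs, null, pi0, feature_ids=feature_ids)
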