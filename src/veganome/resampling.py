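"""Bootstrap stability of FDR calls and cross-validated shrunken t-scores.

``bootstrap_stability`` redraws subjects with replacement (stratified by
diet group by default), re-runs the whole inference stack — surrogate
variables, residualized regression, permutation FDR — inside every
resample, and reports per-feature significance fractions with stable
sets at the 50/90/100% thresholds.

``crossval_shrunken_ts`` computes K-fold out-of-sample residual
variances, Σ(y − ŷ)²/N per metabolite (always at least as large, on
average, as the in-sample estimate), converts them to deflated
("shrunken") t-scores via Var(β) = cv_variance/(N·var(x̃)), and re-runs
the permutation FDR on those scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .containers import AbundanceMatrix, Annotation, CohortMetadata
from .fdr import build_null, fdr_from_null, permutation_ts
from .regression import (
    DesignInfo,
    SurrogateModel,
    estimate_surrogates,
    fit_metabolite_models,
)
from .subclass import composite_null_ts, composite_subclass_test

logger = logging.getLogger(__name__)


@dataclass
class StabilityReport:
    fraction_significant: pd.Series  # per feature, fraction of resamples
    n_boot: int
    level: str

    def stable(self, threshold: float) -> list:
        """Features significant in at least ``threshold`` of resamples."""
        f = self.fraction_significant
        return list(f.index[f >= threshold])

    @property
    def stable_50(self) -> list:
        return self.stable(0.5)

    @property
    def stable_90(self) -> list:
        return self.stable(0.9)

    @property
    def stable_100(self) -> list:
        return self.stable(1.0)


def _stratified_resample(rng: np.random.Generator, diet: np.ndarray) -> np.ndarray:
    idx = []
    for level in (0.0, 1.0):
        pool = np.flatnonzero(diet == level)
        idx.append(rng.choice(pool, size=len(pool), replace=True))
    return np.concatenate(idx)


def _subset_log_matrix(Y: AbundanceMatrix, idx: np.ndarray) -> AbundanceMatrix:
    vals = Y.values.iloc[idx].reset_index(drop=True)
    vals.index = pd.Index([f"r{i}" for i in range(len(idx))], name="sample_id")
    return AbundanceMatrix(vals, state="log")


def _resolve_k(
    Y: AbundanceMatrix, design: DesignInfo, n_sv: int | str | None, seed: int
) -> int:
    if isinstance(n_sv, int):
        return n_sv
    sv = estimate_surrogates(Y, design, n_sv="auto", seed=seed)
    return sv.k


def bootstrap_stability(
    Y: AbundanceMatrix,
    metadata: CohortMetadata,
    annotation: Annotation | None = None,
    n_boot: int = 100,
    seed: int = 0,
    level: str = "metabolite",
    n_sv: int | str | None = "auto",
    inner_B: int = 200,
    alpha: float = 0.05,
    stratified: bool = True,
    resamples: Sequence[np.ndarray] | None = None,
) -> StabilityReport:
    """Fraction of bootstrap resamples in which each feature is significant.

    Surrogate variables and the permutation null are re-estimated inside
    every resample (the SV count is fixed at the parent cohort's
    data-driven choice so resamples differ only through the data).
    ``resamples`` overrides the random draws with explicit positional
    index arrays — passing ``[arange(n)]`` reproduces the parent
    analysis exactly.
    """
    Y.require_state("log")
    if level not in ("metabolite", "subclass"):
        raise ValueError("level must be 'metabolite' or 'subclass'")
    if level == "subclass" and annotation is None:
        raise ValueError("subclass-level stability requires an annotation")
    if resamples is None and n_boot < 2:
        raise ValueError("n_boot must be >= 2 (or pass explicit resamples)")
    n = Y.n_samples
    diet = metadata.diet_indicator
    design_parent = DesignInfo.from_metadata(metadata)
    k = _resolve_k(Y, design_parent, n_sv, seed)

    rng = substream(seed, "boot", "resample")
    draws = list(resamples) if resamples is not None else None
    n_total = len(draws) if draws is not None else n_boot

    counts: pd.Series | None = None
    for b in range(n_total):
        if draws is not None:
            idx = np.asarray(draws[b])
        else:
            for _ in range(100):
                idx = (
                    _stratified_resample(rng, diet)
                    if stratified
                    else rng.choice(n, size=n, replace=True)
                )
                if len(np.unique(diet[idx])) == 2:
                    break
                logger.info("resample %d had a single diet group; redrawn", b)
        Yb = _subset_log_matrix(Y, idx)
        meta_b = metadata.subset(idx)
        meta_b.table.index = Yb.sample_ids
        design_b = DesignInfo.from_metadata(meta_b)
        sv_b = (
            estimate_surrogates(Yb, design_b, n_sv=k, seed=seed + b)
            if k > 0
            else SurrogateModel.empty(len(idx))
        )
        fits = fit_metabolite_models(Yb, design_b, sv=sv_b)
        if level == "metabolite":
            null = build_null(fits.residual_y, fits.residual_x, B=inner_B,
                              seed=seed + 7919 * b, df=fits.df,
                              nuisance=fits.nuisance)
            res = fdr_from_null(fits.t, null, feature_ids=fits.metabolite_ids)
        else:
            sub = composite_subclass_test(fits, annotation)
            null_ts = composite_null_ts(fits, sub.membership, B=inner_B,
                                        seed=seed + 7919 * b)
            from .fdr import PermutationNull

            null = PermutationNull(null_ts=null_ts, B=inner_B, seed=seed)
            res = fdr_from_null(
                sub.table["composite_t"].to_numpy(), null,
                feature_ids=sub.table.index,
            )
        sig = pd.Series((res.fdr < alpha).astype(float), index=res.table.index)
        counts = sig if counts is None else counts.add(sig, fill_value=0.0)

    fractions = counts / n_total
    return StabilityReport(fraction_significant=fractions, n_boot=n_total, level=level)


@dataclass
class CvResult:
    table: pd.DataFrame  # t_full, shrunken_t, variances, fdr_full, fdr_cv
    K: int

    def n_lost(self, alpha: float = 0.05) -> int:
        """Features significant on the full sample but not under CV."""
        t = self.table
        return int(((t["fdr_full"] < alpha) & (t["fdr_cv"] >= alpha)).sum())


def _stratified_folds(
    rng: np.random.Generator, diet: np.ndarray, K: int
) -> list[np.ndarray]:
    folds: list[list[int]] = [[] for _ in range(K)]
    for level in (0.0, 1.0):
        pool = rng.permutation(np.flatnonzero(diet == level))
        for i, s in enumerate(pool):
            folds[i % K].append(int(s))
    return [np.asarray(sorted(f)) for f in folds if len(f)]


def crossval_shrunken_ts(
    Y: AbundanceMatrix,
    metadata: CohortMetadata,
    K: int = 10,
    seed: int = 0,
    n_sv: int | str | None = "auto",
    B: int = 1000,
    alpha: float = 0.05,
) -> CvResult:
    """K-fold cross-validated residual variances and shrunken t-scores.

    Each fold's model (nuisance covariates, surrogate variables and diet
    effect) is fitted on the other K−1 folds; held-out surrogate scores
    come from projecting held-out residuals onto the training factor
    loadings.  The out-of-sample residual variance Σ(y − ŷ)²/N replaces
    the in-sample one in Var(β) = variance/(N·var(x̃)), deflating each
    feature's t; the deflated scores are re-submitted to the
    permutation FDR against the full-sample null.
    """
    Y.require_state("log")
    n = Y.n_samples
    if K < 2:
        raise ValueError("K must be >= 2")
    if K > n:
        raise ValueError(f"K={K} exceeds sample count {n}")
    design = DesignInfo.from_metadata(metadata)
    k = _resolve_k(Y, design, n_sv, seed)
    sv_full = (
        estimate_surrogates(Y, design, n_sv=k, seed=seed)
        if k > 0
        else SurrogateModel.empty(n)
    )
    fits_full = fit_metabolite_models(Y, design, sv=sv_full)

    Ymat = Y.to_numpy()
    Qfull = design.full_matrix()  # SV-estimation design, incl. diet and BMI
    Znuis = design.nuisance_matrix()  # intercept, age, sex, race
    diet = design.diet

    rng = substream(seed, "cv", "folds")
    folds = _stratified_folds(rng, diet, K)
    # training sets must contain both diet groups
    for f in folds:
        tr = np.setdiff1d(np.arange(n), f)
        if len(np.unique(diet[tr])) < 2:
            raise ValueError("a training split lost a diet group; reduce K")

    Yp = np.empty_like(Ymat)
    for f in folds:
        tr = np.setdiff1d(np.arange(n), f)
        # surrogate variables on the training folds only
        coef_full = np.linalg.lstsq(Qfull[tr], Ymat[tr], rcond=None)[0]
        R_tr = Ymat[tr] - Qfull[tr] @ coef_full
        if k > 0:
            U, S, Vt = np.linalg.svd(R_tr, full_matrices=False)
            kk = min(k, (S > 1e-12).sum())
            u_tr = U[:, :kk]
            R_te = Ymat[f] - Qfull[f] @ coef_full
            u_te = (R_te @ Vt[:kk].T) / S[:kk]
            X_tr = np.column_stack([Znuis[tr], u_tr, diet[tr]])
            X_te = np.column_stack([Znuis[f], u_te, diet[f]])
        else:
            X_tr = np.column_stack([Znuis[tr], diet[tr]])
            X_te = np.column_stack([Znuis[f], diet[f]])
        coef = np.linalg.lstsq(X_tr, Ymat[tr], rcond=None)[0]
        Yp[f] = X_te @ coef

    cv_var = np.square(Ymat - Yp).mean(axis=0)  # Σ(y − ŷ)²/N
    insample_var = np.square(fits_full.residuals).sum(axis=0) / n
    # Var(β) = cv residual variance / (N · var(x̃)) = cv_var / sxx
    var_beta = cv_var / fits_full.sxx
    with np.errstate(divide="ignore", invalid="ignore"):
        shrunken_t = fits_full.beta / np.sqrt(var_beta)

    null = build_null(fits_full.residual_y, fits_full.residual_x, B=B,
                      seed=seed, df=fits_full.df, nuisance=fits_full.nuisance)
    res_full = fdr_from_null(fits_full.t, null, feature_ids=fits_full.metabolite_ids)
    res_cv = fdr_from_null(shrunken_t, null, feature_ids=fits_full.metabolite_ids)

    table = pd.DataFrame(
        {
            "t_full": fits_full.t,
            "shrunken_t": shrunken_t,
            "cv_residual_variance": cv_var,
            "insample_residual_variance": insample_var,
            "fdr_full": res_full.fdr,
            "fdr_cv": res_cv.fdr,
        },
        index=fits_full.metabolite_ids,
    )
    return CvResult(table=table, K=len(folds))
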