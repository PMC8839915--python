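"""Unsupervised and supervised multivariate views of the cohort.

PCA is performed on the covariance matrix of the log-abundance matrix
(centered, not variance-scaled), with an optional robust-Mahalanobis
outlier exclusion before decomposition.  Loadings for the high-loading
threshold are expressed as feature–component *correlations*
(eigenvector coordinate × √λ / feature SD), so a fixed 0.5 cutoff is
scale-free.  Retained components can be regressed on dietary variables
(adjusted for age, sex, race and BMI) and partial correlations with
diet group computed.

The random-forest classifier follows the classic recipe: every tree
learns from a stratified 50% subsample drawn *without* replacement,
out-of-bag votes give the misclassification error, and variable
importance is the mean decrease in OOB accuracy after permuting one
feature at a time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import MinCovDet
from sklearn.tree import DecisionTreeClassifier

from ._rng import substream
from .containers import AbundanceMatrix

logger = logging.getLogger(__name__)


@dataclass
class PcaResult:
    eigenvalues: np.ndarray  # descending, length = min(n-1, p) retained
    scores: pd.DataFrame  # samples × components
    loadings: pd.DataFrame  # metabolites × components (eigenvector coords)
    corr_loadings: pd.DataFrame  # metabolites × components (correlations)
    cum_var_explained: np.ndarray
    excluded_samples: list

    @property
    def n_nonzero(self) -> int:
        tol = self.eigenvalues[0] * 1e-9 if len(self.eigenvalues) else 0.0
        return int((self.eigenvalues > tol).sum())


def detect_outliers(Y: AbundanceMatrix, quantile: float = 0.999, seed: int = 0) -> list:
    """Samples flagged by robust Mahalanobis distance on the top-2 PC scores."""
    Y.require_state("log")
    X = Y.to_numpy()
    Xc = X - X.mean(axis=0)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    top2 = U[:, :2] * S[:2]
    mcd = MinCovDet(random_state=int(seed) % (2**31)).fit(top2)
    d2 = mcd.mahalanobis(top2)
    # MCD distances run high at small n; recalibrate so the median
    # matches its chi-square reference before applying the cut
    med = np.median(d2)
    if med > 0:
        d2 = d2 * stats.chi2.ppf(0.5, df=2) / med
    cut = stats.chi2.ppf(quantile, df=2)
    flagged = list(Y.sample_ids[d2 > cut])
    if flagged:
        logger.info("PCA outlier exclusion: %s (robust Mahalanobis > χ²₂(%g))",
                    flagged, quantile)
    return flagged


def run_pca(
    Y: AbundanceMatrix,
    exclude_outliers: bool = True,
    outlier_quantile: float = 0.999,
    seed: int = 0,
) -> PcaResult:
    """Covariance-matrix PCA of the log abundance matrix."""
    Y.require_state("log")
    if Y.n_samples < 3:
        raise ValueError("PCA requires at least 3 samples")
    excluded = (
        detect_outliers(Y, quantile=outlier_quantile, seed=seed)
        if exclude_outliers
        else []
    )
    keep = [s for s in Y.sample_ids if s not in set(excluded)]
    X = Y.values.loc[keep].to_numpy(dtype=float)
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    ncomp = min(n - 1, p)
    S = S[:ncomp]
    eig = S**2 / (n - 1)  # eigenvalues of the sample covariance
    scores = U[:, :ncomp] * S
    comp_names = [f"PC{i + 1}" for i in range(ncomp)]
    feat_sd = Xc.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = Vt[:ncomp].T * np.sqrt(eig)[None, :] / feat_sd[:, None]
    corr = np.where(feat_sd[:, None] > 0, corr, 0.0)
    return PcaResult(
        eigenvalues=eig,
        scores=pd.DataFrame(scores, index=pd.Index(keep, name="sample_id"),
                            columns=comp_names),
        loadings=pd.DataFrame(Vt[:ncomp].T, index=Y.metabolite_ids,
                              columns=comp_names),
        corr_loadings=pd.DataFrame(corr, index=Y.metabolite_ids,
                                   columns=comp_names),
        cum_var_explained=np.cumsum(eig) / eig.sum(),
        excluded_samples=excluded,
    )


def select_components(
    pca: PcaResult,
    eigen_threshold: float | None = None,
    n_components: int | None = None,
    cum_var: float | None = None,
) -> list[int]:
    """Indices (1-based) of retained components under the configured rule.

    Exactly one rule applies; the eigenvalue rule is strict (λ > threshold).
    An empty selection falls back to the top component with a warning.
    """
    rules = [eigen_threshold is not None, n_components is not None, cum_var is not None]
    if sum(rules) != 1:
        raise ValueError("specify exactly one of eigen_threshold, n_components, cum_var")
    if n_components is not None:
        return list(range(1, min(n_components, len(pca.eigenvalues)) + 1))
    if eigen_threshold is not None:
        sel = [i + 1 for i, lam in enumerate(pca.eigenvalues) if lam > eigen_threshold]
    else:
        k = int(np.searchsorted(pca.cum_var_explained, cum_var) + 1)
        sel = list(range(1, k + 1))
    if not sel:
        logger.warning("component selection empty; falling back to PC1")
        sel = [1]
    return sel


def high_loading_members(
    pca: PcaResult, threshold: float = 0.5, components: list[int] | None = None
) -> dict[str, pd.Series]:
    """Per component: metabolites whose |correlation loading| ≥ threshold, signed."""
    comps = components or list(range(1, len(pca.eigenvalues) + 1))
    out = {}
    for c in comps:
        col = pca.corr_loadings[f"PC{c}"]
        hits = col[col.abs() >= threshold]
        out[f"PC{c}"] = hits.sort_values(key=lambda s: -s.abs())
    return out


def regress_pc_on_variable(
    scores: pd.DataFrame,
    variable: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
    components: list[int] | None = None,
) -> pd.DataFrame:
    """Per retained PC: least-squares fit PC ~ variable + covariates.

    Missing covariate or variable values are mean-imputed.  Returns the
    variable's coefficient row (beta, se, t, p) per component.
    """
    v = pd.Series(np.asarray(variable, dtype=float), index=scores.index)
    if v.std(skipna=True) == 0 or v.isna().all():
        raise ValueError("variable is constant; regression undefined")
    v = v.fillna(v.mean())
    n = len(scores)
    blocks = [np.ones(n), v.to_numpy()]
    if covariates is not None:
        cov = covariates.loc[scores.index].astype(float)
        cov = cov.fillna(cov.mean())
        blocks.extend(cov.to_numpy().T)
    X = np.column_stack(blocks)
    df = n - X.shape[1]
    XtX_inv = np.linalg.pinv(X.T @ X)
    comps = components or list(range(1, scores.shape[1] + 1))
    rows = []
    for c in comps:
        y = scores[f"PC{c}"].to_numpy()
        coef = XtX_inv @ X.T @ y
        resid = y - X @ coef
        sigma2 = resid @ resid / df
        se = math.sqrt(sigma2 * XtX_inv[1, 1])
        beta = coef[1]
        t = beta / se
        rows.append({"component": f"PC{c}", "beta": beta, "se": se, "t": t,
                     "p": 2 * stats.t.sf(abs(t), df)})
    return pd.DataFrame(rows).set_index("component")


def partial_correlation(
    a, b, covariates: pd.DataFrame | np.ndarray | None = None
) -> tuple[float, float]:
    """Pearson correlation of a and b after removing the covariates.

    Both vectors are residualized on [1, covariates]; p-value from the t
    transform with df = n − 2 − #covariates.  With no covariates this is
    the plain Pearson correlation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValueError("a and b must have equal length")
    n = len(a)
    if covariates is None:
        Q = np.ones((n, 1))
        q = 0
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        Q = np.column_stack([np.ones(n), C])
        if np.linalg.matrix_rank(Q) < Q.shape[1]:
            raise np.linalg.LinAlgError("covariate design is rank deficient")
        q = C.shape[1]
    coef_a = np.linalg.lstsq(Q, a, rcond=None)[0]
    coef_b = np.linalg.lstsq(Q, b, rcond=None)[0]
    ra = a - Q @ coef_a
    rb = b - Q @ coef_b
    na = math.sqrt(ra @ ra)
    nb = math.sqrt(rb @ rb)
    tol_a = 1e-8 * max(math.sqrt(np.sum((a - a.mean()) ** 2)), 1e-30)
    tol_b = 1e-8 * max(math.sqrt(np.sum((b - b.mean()) ** 2)), 1e-30)
    if na <= tol_a or nb <= tol_b:
        raise ValueError("zero residual variance; partial correlation undefined")
    r = float(np.clip(ra @ rb / (na * nb), -1.0, 1.0))
    df = n - 2 - q
    if r**2 >= 1.0:
        return r, 0.0
    t = r * math.sqrt(df / (1 - r**2))
    return r, float(2 * stats.t.sf(abs(t), df))


@dataclass
class RfResult:
    oob_error: float
    importance: pd.DataFrame | None  # mean decrease accuracy, ranked
    n_trees: int
    subsample_fraction: float

    @property
    def accuracy(self) -> float:
        return 1.0 - self.oob_error


def rf_classify(
    Y: AbundanceMatrix,
    labels,
    n_trees: int = 50_000,
    subsample: float = 0.5,
    seed: int = 0,
    max_features: str | int = "sqrt",
    compute_importance: bool = True,
) -> RfResult:
    """Random-forest diet classification with OOB error and permutation MDA.

    Trees are CART classifiers on stratified ⌈subsample·n_class⌉-per-class
    draws without replacement; OOB votes define the misclassification
    error; importance is the average drop in a tree's OOB accuracy when
    one feature's OOB values are permuted.
    """
    Y.require_state("log")
    y = np.asarray(pd.factorize(np.asarray(labels))[0])
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("labels must contain exactly two classes")
    for c in classes:
        if (y == c).sum() < 2:
            raise ValueError("each class needs at least 2 samples")
    X = np.ascontiguousarray(Y.to_numpy(), dtype=np.float32)
    n, p = X.shape
    rng = substream(seed, "rf", "trees")
    pools = [np.flatnonzero(y == c) for c in classes]
    take = [max(1, math.ceil(subsample * len(pool))) for pool in pools]

    votes = np.zeros((n, 2))
    mda_sum = np.zeros(p)
    mda_sq = np.zeros(p)
    idx_all = np.arange(n)
    for t in range(n_trees):
        ib = np.concatenate(
            [rng.choice(pool, size=m, replace=False) for pool, m in zip(pools, take)]
        )
        oob = np.setdiff1d(idx_all, ib)
        tree = DecisionTreeClassifier(
            max_features=max_features,
            random_state=int(rng.integers(2**31 - 1)),
        ).fit(X[ib], y[ib])
        if len(oob) == 0:
            continue
        Xo = X[oob]
        pred = tree.predict(Xo)
        votes[oob, 0] += pred == 0
        votes[oob, 1] += pred == 1
        if compute_importance:
            acc0 = float(np.mean(pred == y[oob]))
            m = len(oob)
            # one predict call per chunk of features, each feature's copy
            # of the OOB block carrying its own permuted column
            chunk = max(1, 4_000_000 // max(m * p, 1))
            for j0 in range(0, p, chunk):
                js = range(j0, min(j0 + chunk, p))
                Xbig = np.tile(Xo, (len(js), 1))
                for i, j in enumerate(js):
                    Xbig[i * m:(i + 1) * m, j] = Xo[rng.permutation(m), j]
                preds = tree.predict(Xbig).reshape(len(js), m)
                accs = (preds == y[oob][None, :]).mean(axis=1)
                d = acc0 - accs
                mda_sum[list(js)] += d
                mda_sq[list(js)] += d * d

    voted = votes.sum(axis=1) > 0
    pred_class = (votes[:, 1] > votes[:, 0]).astype(int)
    oob_error = float(np.mean(pred_class[voted] != y[voted]))

    importance = None
    if compute_importance:
        mda = mda_sum / n_trees
        sd = np.sqrt(np.maximum(mda_sq / n_trees - mda**2, 0.0))
        importance = (
            pd.DataFrame(
                {
                    "mean_decrease_accuracy": mda,
                    "mda_se": sd / math.sqrt(n_trees),
                },
                index=Y.metabolite_ids,
            )
            .sort_values("mean_decrease_accuracy", ascending=False)
        )
    return RfResult(
        oob_error=oob_error,
        importance=importance,
        n_trees=n_trees,
        subsample_fraction=subsample,
    )
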