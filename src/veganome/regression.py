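"""Surrogate-variable estimation and residualized per-metabolite regression.

Unwanted (batch-like) variation is estimated from the residuals of the
log abundance matrix on the full covariate design (diet, age, sex,
race, BMI): the leading factors of that residual matrix are the
surrogate variables.  Inference then follows the Frisch–Waugh–Lovell
two-step: both the metabolite abundances and the diet indicator are
residualized on the nuisance design (intercept, age, sex, race and the
surrogate variables — BMI is excluded as a presumed mediator of diet),
and each metabolite's residual is regressed on the residualized diet
vector.  By the FWL identity the resulting beta, SE and t equal those
of the diet coefficient in the full multiple regression.

Adjusted group means are computed at covariate means, so their
difference is exactly beta and exp(beta) is the geometric-mean fold
change (vegan / non-vegetarian).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .containers import AbundanceMatrix, CohortMetadata

logger = logging.getLogger(__name__)

#: covariates used when estimating surrogate variables
SV_COVARIATES = ("age", "sex", "race", "bmi")
#: covariates kept as nuisance in the inference model (BMI excluded: mediator)
INFERENCE_COVARIATES = ("age", "sex", "race")


@dataclass
class DesignInfo:
    """Diet indicator plus covariate table for one cohort."""

    diet: np.ndarray  # 1 = vegan, 0 = non-vegetarian
    covariates: pd.DataFrame  # columns at least age, sex, race, bmi
    n_sv: int | str = "auto"

    def __post_init__(self) -> None:
        self.diet = np.asarray(self.diet, dtype=float)
        if set(np.unique(self.diet)) != {0.0, 1.0}:
            raise ValueError("diet indicator must contain both levels (0 and 1)")
        missing = [c for c in SV_COVARIATES if c not in self.covariates.columns]
        if missing:
            raise ValueError(f"covariates missing columns: {missing}")

    @classmethod
    def from_metadata(cls, metadata: CohortMetadata, n_sv: int | str = "auto") -> "DesignInfo":
        cov = metadata.table[list(SV_COVARIATES)].astype(float)
        # covariate missingness is mean-imputed before modelling
        cov = cov.fillna(cov.mean())
        return cls(diet=metadata.diet_indicator, covariates=cov, n_sv=n_sv)

    @property
    def n_samples(self) -> int:
        return len(self.diet)

    def nuisance_matrix(self, include_bmi: bool = False) -> np.ndarray:
        """[1, age, sex, race(, bmi)] design block."""
        cols = list(INFERENCE_COVARIATES) + (["bmi"] if include_bmi else [])
        Z = self.covariates[cols].to_numpy(dtype=float)
        return np.column_stack([np.ones(self.n_samples), Z])

    def full_matrix(self) -> np.ndarray:
        """[1, diet, age, sex, race, bmi] design used for SV estimation."""
        Z = self.covariates[list(SV_COVARIATES)].to_numpy(dtype=float)
        return np.column_stack([np.ones(self.n_samples), self.diet, Z])

    def covariate_matrix(self) -> np.ndarray:
        """[1, age, sex, race, bmi] design — the full design without diet."""
        Z = self.covariates[list(SV_COVARIATES)].to_numpy(dtype=float)
        return np.column_stack([np.ones(self.n_samples), Z])


def residualize(M: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Project out the column space of Q: returns M − Q(QᵀQ)⁻¹QᵀM.

    Q must have full column rank (rank-deficiency raises, naming the
    offending columns); the output is orthogonal to every column of Q.
    """
    M = np.asarray(M, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2:
        raise ValueError("Q must be 2-D")
    rank = np.linalg.matrix_rank(Q)
    if rank < Q.shape[1]:
        # identify columns involved in the collinearity for the message
        bad = []
        base_rank = 0
        kept: list[int] = []
        for j in range(Q.shape[1]):
            r = np.linalg.matrix_rank(Q[:, kept + [j]])
            if r == base_rank:
                bad.append(j)
            else:
                kept.append(j)
                base_rank = r
        raise np.linalg.LinAlgError(
            f"nuisance design is rank deficient (rank {rank} < {Q.shape[1]}); "
            f"collinear columns: {bad}"
        )
    coef, *_ = np.linalg.lstsq(Q, M, rcond=None)
    return M - Q @ coef


@dataclass
class SurrogateModel:
    """Estimated surrogate-variable scores (columns centered, orthogonal)."""

    sv_scores: np.ndarray  # n × k
    k: int
    method_tag: str = "reweighted-residual-svd"
    eigenvalues: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @classmethod
    def empty(cls, n: int) -> "SurrogateModel":
        return cls(sv_scores=np.zeros((n, 0)), k=0, method_tag="none")


def _parallel_analysis_k(
    R: np.ndarray,
    rng: np.random.Generator,
    n_perm: int,
    alpha: float,
    max_k: int,
    Q: np.ndarray | None = None,
) -> int:
    """Choose the factor count by permutation of residual entries.

    Each permutation scrambles every column of R independently,
    destroying cross-feature structure while keeping marginals; the
    permuted matrix is re-residualized on the design Q so observed and
    null spectra live in the same (n − rank Q)-dimensional row space.
    The retained count is the number of leading singular values
    exceeding the (1 − alpha) permutation quantile of the matching
    rank, counted until the first failure.
    """
    sv_obs = np.linalg.svd(R, compute_uv=False)
    n_keep = min(len(sv_obs), max_k + 1)
    null = np.empty((n_perm, n_keep))
    n = R.shape[0]
    # residual entries already lost a (n − q)/n share of variance to the
    # projection; re-projecting the permuted matrix would shrink them
    # again, so the second loss is compensated exactly
    scale = 1.0
    if Q is not None:
        q_rank = np.linalg.matrix_rank(Q)
        scale = math.sqrt(n / (n - q_rank))
    for b in range(n_perm):
        shuf = np.argsort(rng.random(R.shape), axis=0)
        Rp = np.take_along_axis(R, shuf, axis=0)
        if Q is not None:
            Rp = Rp - Q @ np.linalg.lstsq(Q, Rp, rcond=None)[0]
        null[b] = scale * np.linalg.svd(Rp, compute_uv=False)[:n_keep]
    thresh = np.quantile(null, 1.0 - alpha, axis=0)
    k = 0
    for i in range(min(max_k, n_keep)):
        if sv_obs[i] > thresh[i]:
            k += 1
        else:
            break
    return k


def estimate_surrogates(
    Y: AbundanceMatrix,
    design: DesignInfo,
    n_sv: int | str | None = None,
    seed: int = 0,
    n_perm: int = 19,
    alpha: float = 0.05,
    max_k: int = 10,
    reweight: bool = True,
) -> SurrogateModel:
    """Estimate surrogate variables from the full-design residual matrix.

    One iterative-reweighting pass is applied: metabolites are weighted
    by the share of their residual variance explained by the initial
    factors, concentrating the decomposition on features actually
    affected by the unwanted variation.
    """
    Y.require_state("log")
    if n_sv is None:
        n_sv = design.n_sv
    Ymat = Y.to_numpy()
    Q = design.full_matrix()
    R = residualize(Ymat, Q)
    avail = min(R.shape[0] - np.linalg.matrix_rank(Q), R.shape[1])
    if n_sv == "auto":
        k = _parallel_analysis_k(
            R, substream(seed, "sva", "parallel"), n_perm, alpha,
            min(max_k, avail), Q=Q,
        )
    else:
        k = int(n_sv)
        if k >= avail + 1:
            raise ValueError(f"n_sv={k} exceeds available residual rank {avail}")
    if k == 0:
        return SurrogateModel.empty(design.n_samples)

    # Factor directions are identified on the full-design residual
    # matrix, but the scores are rebuilt on the inference nuisance
    # residuals (intercept, age, sex, race — no diet, no BMI) so that a
    # factor's chance (or real) alignment with diet, or with the
    # BMI mediator, is carried by the surrogate variable and removed
    # from both sides of the FWL fit.  Scoring on R itself would force
    # the SVs orthogonal to diet and leave each factor's diet-aligned
    # component in the outcome, inflating the null t-scores.
    U, s, Vt = np.linalg.svd(R, full_matrices=False)
    if reweight:
        scores0 = U[:, :k]
        # per-metabolite share of residual variance carried by the factors
        fitted = scores0 @ (scores0.T @ R)
        tot = (R**2).sum(axis=0)
        tot[tot == 0] = 1.0
        w = (fitted**2).sum(axis=0) / tot
        tag = "reweighted-residual-svd"
    else:
        w = np.ones(R.shape[1])
        tag = "residual-svd"
    Y0 = residualize(Ymat, design.nuisance_matrix())
    U2, s2, _ = np.linalg.svd(Y0 * w[None, :], full_matrices=False)
    scores = U2[:, :k]
    logger.info("estimated %d surrogate variables (%s)", k, tag)
    return SurrogateModel(sv_scores=scores, k=k, method_tag=tag,
                          eigenvalues=s2[:k] ** 2)


@dataclass
class RegressionResult:
    """Per-metabolite diet-effect fits plus the residual machinery that
    the subclass statistic and the permutation FDR reuse."""

    table: pd.DataFrame  # beta, se, t, df, adj means, fold_change, ci
    residual_y: np.ndarray  # n × p, abundances residualized on nuisance
    residual_x: np.ndarray  # n, diet residualized on nuisance
    residuals: np.ndarray  # n × p, inference-model residuals
    df: int
    sxx: float  # x̃ᵀx̃
    nuisance: np.ndarray | None = None  # the nuisance design Q (incl. SVs)
    surrogate: SurrogateModel | None = None

    @property
    def beta(self) -> np.ndarray:
        return self.table["beta"].to_numpy()

    @property
    def t(self) -> np.ndarray:
        return self.table["t"].to_numpy()

    @property
    def metabolite_ids(self) -> pd.Index:
        return self.table.index


def fit_metabolite_models(
    Y: AbundanceMatrix,
    design: DesignInfo,
    sv: SurrogateModel | None = None,
    adjust_bmi_outcome: bool = False,
    ci: str = "normal",
) -> RegressionResult:
    """Fit the residualized diet-effect regression for every metabolite.

    Nuisance design: intercept, age, sex, race, surrogate variables
    (BMI excluded unless ``adjust_bmi_outcome``).  df = n − #nuisance − 1,
    matching the full multiple regression.  Fold-change CIs use
    exp(beta ± z·se) with z = 1.96 (``ci="t"`` switches to the
    t-quantile).
    """
    Y.require_state("log")
    Ymat = Y.to_numpy()
    n = design.n_samples
    if Ymat.shape[0] != n:
        raise ValueError("abundance matrix and design have different sample counts")
    Q = design.nuisance_matrix(include_bmi=adjust_bmi_outcome)
    if sv is not None and sv.k > 0:
        Q = np.column_stack([Q, sv.sv_scores])
    ytil = residualize(Ymat, Q)
    xtil = residualize(design.diet, Q)
    sxx = float(xtil @ xtil)
    if sxx <= 0:
        raise np.linalg.LinAlgError("diet indicator lies in the nuisance span")

    beta = (xtil @ ytil) / sxx
    resid = ytil - np.outer(xtil, beta)
    df = n - Q.shape[1] - 1
    if df <= 0:
        raise ValueError(f"non-positive residual df ({df})")
    sigma2 = (resid**2).sum(axis=0) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 / sxx)
        t = beta / se
    degenerate = sigma2 <= 0
    if degenerate.any():
        logger.warning(
            "%d metabolites with zero residual variance; t set to NA",
            int(degenerate.sum()),
        )
        t[degenerate] = np.nan
        se[degenerate] = np.nan

    ybar = Ymat.mean(axis=0)
    xbar = design.diet.mean()
    adj_vegan = ybar + beta * (1.0 - xbar)
    adj_nonveg = ybar - beta * xbar
    z = stats.t.ppf(0.975, df) if ci == "t" else 1.96
    fold = np.exp(beta)
    table = pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "t": t,
            "df": df,
            "adj_mean_vegan": adj_vegan,
            "adj_mean_nonveg": adj_nonveg,
            "fold_change": fold,
            "ci_lo": np.exp(beta - z * se),
            "ci_hi": np.exp(beta + z * se),
        },
        index=Y.metabolite_ids.rename("metabolite"),
    )
    return RegressionResult(
        table=table, residual_y=ytil, residual_x=xtil, residuals=resid,
        df=df, sxx=sxx, nuisance=Q, surrogate=sv,
    )


def fit_unadjusted_models(
    Y: AbundanceMatrix, design: DesignInfo, **kwargs
) -> RegressionResult:
    """Variant without surrogate variables: adjusts age, sex, race only."""
    return fit_metabolite_models(Y, design, sv=None, **kwargs)
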