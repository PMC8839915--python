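"""Composite subclass statistics for correlated metabolite sets.

For a subclass S with m members, the composite effect is the average of
the member regression betas, B̄ = (1/m) Σ_{j∈S} β_j.  Its variance uses
the full member covariance,

    Var(B̄) = (1/m²) Σ_{j,k∈S} Cov(β_j, β_k),
    Cov(β_j, β_k) = σ̂_jk / (x̃ᵀx̃),

where σ̂_jk is the cross-covariance of the inference-model residuals
(denominator df = n − #nuisance − 1, so diagonal terms reproduce the
per-metabolite se²) and x̃ is the residualized diet vector.  The
composite t is B̄ / √Var(B̄); the subclass fold change is exp(B̄), the
exponentiated mean of the member adjusted-log-mean differences.

Because residuals satisfy r_j = ỹ_j − β_j x̃, the covariance reduces to
σ̂_jk = (ỹ_jᵀỹ_k − sxx·β_j β_k)/df, which lets the permutation-null
composite t be computed from member beta sums alone (used by
``composite_null_ts``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import substream
from .containers import Annotation
from .regression import RegressionResult

logger = logging.getLogger(__name__)


@dataclass
class SubclassTestResult:
    table: pd.DataFrame  # per subclass: m_total, composite_t, composite_se, fold stats
    membership: dict[str, np.ndarray]  # subclass → member column indices


def beta_covariance(fits: RegressionResult, idx: np.ndarray) -> np.ndarray:
    """Covariance matrix of member betas by explicit residual assembly."""
    R = fits.residuals[:, idx]
    sigma = (R.T @ R) / fits.df
    return sigma / fits.sxx


def composite_subclass_test(
    fits: RegressionResult,
    annotation: Annotation,
    min_members: int = 2,
) -> SubclassTestResult:
    """Composite t, SE and fold change for every subclass.

    Subclasses with fewer than ``min_members`` measured metabolites are
    excluded (logged).  ``min_members=1`` is allowed for testing; the
    statistic then reduces exactly to the member's own t.
    """
    groups = annotation.subclass_members(fits.metabolite_ids)
    col_of = {m: i for i, m in enumerate(fits.metabolite_ids)}
    beta = fits.beta
    rows = []
    membership: dict[str, np.ndarray] = {}
    n_skipped = 0
    for name in sorted(groups):
        members = [m for m in groups[name] if m in col_of]
        if len(members) < min_members:
            n_skipped += 1
            continue
        idx = np.asarray([col_of[m] for m in members])
        m = len(idx)
        cov = beta_covariance(fits, idx)
        var_bar = float(cov.sum()) / m**2
        if var_bar <= 0:
            raise np.linalg.LinAlgError(
                f"singular member covariance for subclass {name!r}"
            )
        b_bar = float(beta[idx].mean())
        se = float(np.sqrt(var_bar))
        rows.append(
            {
                "subclass": name,
                "m_total": m,
                "composite_beta": b_bar,
                "composite_se": se,
                "composite_t": b_bar / se,
                "fold_change": float(np.exp(b_bar)),
                "ci_lo": float(np.exp(b_bar - 1.96 * se)),
                "ci_hi": float(np.exp(b_bar + 1.96 * se)),
            }
        )
        membership[name] = idx
    if n_skipped:
        logger.info("excluded %d subclasses with < %d members", n_skipped, min_members)
    table = pd.DataFrame(rows).set_index("subclass") if rows else pd.DataFrame(
        columns=["m_total", "composite_beta", "composite_se", "composite_t",
                 "fold_change", "ci_lo", "ci_hi"]
    )
    return SubclassTestResult(table=table, membership=membership)


def composite_null_ts(
    fits: RegressionResult,
    membership: dict[str, np.ndarray],
    B: int,
    seed: int = 0,
) -> np.ndarray:
    """Permutation-null composite t matrix (B × #subclasses).

    Each permutation scrambles the residualized diet vector once and is
    applied to every subclass, preserving the between-member residual
    covariance.  Uses the closed form

        t_S = S1 · √(df · sxx) / √(m·Gsum − sxx·S1²·m) · m ... (see module docstring)

    where S1 = Σ_{j∈S} β_j under the permutation and Gsum = Σ_{jk} ỹ_jᵀỹ_k.
    """
    from .fdr import permute_and_reresidualize

    if B < 1:
        raise ValueError("B must be >= 1")
    rng = substream(seed, "perm", "subclass")
    df = fits.df
    names = list(membership)
    # per-subclass Gram sums over residualized abundances
    gsum = np.array(
        [float(np.square(fits.residual_y[:, idx].sum(axis=1)).sum())
         for idx in (membership[nm] for nm in names)]
    )
    # row sums of residualized Y restricted to each subclass: n × S
    ysum = np.column_stack(
        [fits.residual_y[:, membership[nm]].sum(axis=1) for nm in names]
    )
    XP = permute_and_reresidualize(fits.residual_x, B, rng, fits.nuisance)
    s = np.square(XP).sum(axis=1, keepdims=True)  # B × 1
    with np.errstate(divide="ignore", invalid="ignore"):
        S1 = XP @ ysum / s  # B × S, sum of member betas per permutation
        var_bar = (gsum[None, :] - s * S1**2) / df / s
        # composite t = (S1/m) / sqrt(Σcov/m²) = S1 / sqrt(var_bar)
        ts = S1 / np.sqrt(var_bar)
    return ts


def member_direction_counts(
    fits: RegressionResult,
    fdr: pd.Series,
    annotation: Annotation,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per subclass: counts of FDR-significant members, split by sign of beta."""
    groups = annotation.subclass_members(fits.metabolite_ids)
    beta = pd.Series(fits.beta, index=fits.metabolite_ids)
    rows = []
    for name in sorted(groups):
        members = [m for m in groups[name] if m in beta.index]
        sig = [m for m in members if m in fdr.index and fdr[m] < alpha]
        n_down = sum(1 for m in sig if beta[m] < 0)
        n_up = sum(1 for m in sig if beta[m] > 0)
        rows.append(
            {"subclass": name, "n_sig_members": len(sig),
             "n_down": n_down, "n_up": n_up, "m_total": len(members)}
        )
    return pd.DataFrame(rows).set_index("subclass")
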