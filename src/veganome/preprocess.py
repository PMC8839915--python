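"""Abundance-matrix preprocessing: detection filter, median scaling,
minimum imputation, natural-log transform.

The stage order is filter → scale → impute → log.  Median scaling
divides each metabolite by its own median over *observed* values (the
observed median becomes exactly 1); missing (below-detection) entries
are then imputed with the metabolite's minimum observed scaled value,
mimicking a detection-limit floor; the log transform uses the natural
log so that downstream fold changes are plain exponentials of mean
differences.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix

logger = logging.getLogger(__name__)

FILTER_RULES = ("all", "any", "overall")


def filter_detection(
    matrix: AbundanceMatrix,
    groups,
    threshold: float = 0.5,
    rule: str = "all",
) -> AbundanceMatrix:
    """Drop metabolites with too much missingness.

    Under the default ``rule="all"`` a metabolite is removed when its
    missing fraction exceeds ``threshold`` in *both* diet groups (strict
    conjunction).  ``"any"`` removes when either group exceeds it;
    ``"overall"`` ignores groups and uses the pooled missing fraction.
    Survivor order is preserved.
    """
    matrix.require_state("raw")
    if rule not in FILTER_RULES:
        raise ValueError(f"rule must be one of {FILTER_RULES}")
    groups = np.asarray(groups)
    if len(groups) != matrix.n_samples:
        raise ValueError("groups length must match number of samples")
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"groups must have exactly two levels, got {list(levels)}")
    for lev in levels:
        if (groups == lev).sum() == 0:
            raise ValueError(f"group {lev!r} is empty")

    mask = matrix.mask.to_numpy()
    frac = {lev: mask[groups == lev].mean(axis=0) for lev in levels}
    a, b = (frac[lev] for lev in levels)
    if rule == "all":
        drop = (a > threshold) & (b > threshold)
    elif rule == "any":
        drop = (a > threshold) | (b > threshold)
    else:
        drop = mask.mean(axis=0) > threshold

    kept = matrix.values.loc[:, ~drop]
    logger.info(
        "detection filter (rule=%s, threshold=%g): removed %d of %d metabolites",
        rule, threshold, int(drop.sum()), matrix.n_metabolites,
    )
    return AbundanceMatrix(kept, state="raw")


def median_scale(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Divide each metabolite by its median over observed values.

    Uses the interpolated (midpoint) median for even counts; the
    observed median of every metabolite is exactly 1 afterwards.
    """
    matrix.require_state("raw")
    med = matrix.values.median(axis=0, skipna=True)
    bad = med.index[~(med > 0)]
    if len(bad):
        raise ValueError(
            f"median scaling undefined (median <= 0 or no observed values) for: "
            f"{list(bad[:5])}{'...' if len(bad) > 5 else ''}"
        )
    return AbundanceMatrix(matrix.values / med, state="scaled")


def impute_minimum(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Replace each missing entry with the metabolite's minimum observed value."""
    matrix.require_state("scaled")
    mins = matrix.values.min(axis=0, skipna=True)
    empty = mins.index[mins.isna()]
    if len(empty):
        raise ValueError(f"metabolites with no observed values: {list(empty[:5])}")
    return AbundanceMatrix(matrix.values.fillna(mins), state="imputed")


def log_transform(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Natural-log transform; requires strictly positive imputed values."""
    matrix.require_state("imputed")
    vals = matrix.values
    if (vals <= 0).any().any():
        raise ValueError("log transform requires strictly positive values")
    return AbundanceMatrix(np.log(vals), state="log")


def preprocess_pipeline(
    matrix: AbundanceMatrix,
    groups,
    threshold: float = 0.5,
    rule: str = "all",
) -> AbundanceMatrix:
    """filter → median scale → minimum impute → natural log."""
    return log_transform(
        impute_minimum(median_scale(filter_detection(matrix, groups, threshold, rule)))
    )
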