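"""Core in-memory containers shared across the pipeline.

The package works on three tables: a samples × metabolites abundance
matrix, a per-sample metadata table (diet group plus covariates) and a
metabolite annotation table (subclass / major class).  All three are
plain pandas objects wrapped just enough to track processing state and
to validate the contracts the downstream stages rely on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: allowed processing states, in pipeline order
STATES = ("raw", "scaled", "imputed", "log")

#: canonical diet labels
VEGAN = "vegan"
NONVEG = "non-vegetarian"


@dataclass
class AbundanceMatrix:
    """Samples × metabolites abundance matrix with a processing-state flag.

    Missing entries (below-detection values) are stored as NaN; the
    missingness mask is derived, never stored separately.  State moves
    monotonically raw → scaled → imputed → log; each preprocessing
    operation checks the state it requires and stamps the one it
    produces.
    """

    values: pd.DataFrame
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {STATES}")
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.state in ("imputed", "log") and self.values.isna().any().any():
            raise ValueError(f"state {self.state!r} forbids missing entries")

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missingness mask (True = missing / below detection)."""
        return self.values.isna()

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def metabolite_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def with_values(self, values: pd.DataFrame, state: str | None = None) -> "AbundanceMatrix":
        return AbundanceMatrix(values=values, state=state or self.state)

    def require_state(self, *states: str) -> None:
        if self.state not in states:
            raise ValueError(
                f"operation requires state in {states}, matrix is {self.state!r}"
            )


# required metadata columns and their roles
METADATA_COLUMNS = ("diet", "age", "sex", "race", "bmi")


@dataclass
class CohortMetadata:
    """Per-sample diet label and covariates.

    ``table`` is indexed by sample id and must contain at least the
    columns ``diet`` ('vegan' / 'non-vegetarian'), ``age`` (years),
    ``sex`` (0/1), ``race`` (0/1) and ``bmi`` (kg/m²).  Additional
    dietary or lifestyle columns (energy intake, exercise, ...) are
    carried along untouched.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in METADATA_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")
        labels = set(self.table["diet"].unique())
        if not labels <= {VEGAN, NONVEG}:
            raise ValueError(
                f"diet labels must be {{{VEGAN!r}, {NONVEG!r}}}, got {sorted(labels)}"
            )

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    @property
    def diet_indicator(self) -> np.ndarray:
        """1 for vegan, 0 for non-vegetarian."""
        return (self.table["diet"] == VEGAN).to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return len(self.table)

    def subset(self, idx) -> "CohortMetadata":
        """Row subset by positional indices (bootstrap / CV folds)."""
        sub = self.table.iloc[np.asarray(idx)]
        return CohortMetadata(sub)


@dataclass
class Annotation:
    """Metabolite → (subclass, major class) lookup."""

    table: pd.DataFrame  # indexed by metabolite id; columns subclass, major_class

    def __post_init__(self) -> None:
        for col in ("subclass", "major_class"):
            if col not in self.table.columns:
                raise ValueError(f"annotation missing column {col!r}")

    def subclass_members(self, metabolite_ids=None) -> dict[str, list[str]]:
        """Subclass name → member metabolite ids, restricted to given ids."""
        tab = self.table
        if metabolite_ids is not None:
            tab = tab.loc[tab.index.intersection(metabolite_ids)]
        groups: dict[str, list[str]] = {}
        for mid, sub in tab["subclass"].items():
            groups.setdefault(sub, []).append(mid)
        return groups
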