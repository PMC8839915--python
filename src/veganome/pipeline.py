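"""End-to-end orchestration: preprocessing → SVA regression → subclass
composites → permutation FDR → optional resampling and multivariate
stages → baseline table, with a reproducibility manifest.

All randomness flows from the single run seed through named
substreams; rerunning a configuration reproduces every output file
byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .baseline import baseline_table
from .containers import AbundanceMatrix, Annotation, CohortMetadata
from .fdr import PermutationNull, build_null, fdr_from_null
from .io import read_abundance, read_annotation, read_metadata
from .multivariate import rf_classify, run_pca, select_components
from .preprocess import preprocess_pipeline
from .regression import (
    DesignInfo,
    SurrogateModel,
    estimate_surrogates,
    fit_metabolite_models,
    fit_unadjusted_models,
)
from .resampling import bootstrap_stability, crossval_shrunken_ts
from .subclass import (
    composite_null_ts,
    composite_subclass_test,
    member_direction_counts,
)

logger = logging.getLogger(__name__)

TSV_FLOAT = "%.6g"


@dataclass
class RunConfig:
    abundance: str
    metadata: str
    annotation: str
    out_dir: str = "results"
    seed: int = 0
    n_sv: int | str = "auto"
    filter_rule: str = "all"
    filter_threshold: float = 0.5
    alpha: float = 0.05
    B: int = 1000
    run_unadjusted: bool = True
    n_boot: int = 0  # 0 disables bootstrap stability
    boot_inner_B: int = 200
    K: int = 0  # 0 disables cross-validation
    run_multivariate: bool = False
    pca_eigen_threshold: float | None = None
    rf_trees: int = 5000
    rf_importance: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, index_label: str) -> None:
    df.to_csv(path, sep="\t", float_format=TSV_FLOAT, index_label=index_label)


def analyze_cohort(
    Y: AbundanceMatrix,
    metadata: CohortMetadata,
    annotation: Annotation,
    seed: int = 0,
    n_sv: int | str = "auto",
    B: int = 1000,
    alpha: float = 0.05,
    with_sva: bool = True,
):
    """Core inference on a preprocessed (log-state) cohort.

    Returns (fits, metabolite FdrResult, subclass table with FDR and
    direction counts, surrogate model).
    """
    design = DesignInfo.from_metadata(metadata)
    sv = (
        estimate_surrogates(Y, design, n_sv=n_sv, seed=seed)
        if with_sva
        else SurrogateModel.empty(Y.n_samples)
    )
    fits = fit_metabolite_models(Y, design, sv=sv if sv.k else None)
    null = build_null(fits.residual_y, fits.residual_x, B=B, seed=seed,
                      df=fits.df, nuisance=fits.nuisance)
    met_fdr = fdr_from_null(fits.t, null, feature_ids=fits.metabolite_ids)

    sub = composite_subclass_test(fits, annotation)
    sub_null = PermutationNull(
        null_ts=composite_null_ts(fits, sub.membership, B=B, seed=seed),
        B=B, seed=seed,
    )
    sub_fdr = fdr_from_null(
        sub.table["composite_t"].to_numpy(), sub_null, feature_ids=sub.table.index
    )
    counts = member_direction_counts(
        fits, met_fdr.table["fdr"], annotation, alpha=alpha
    )
    sub_table = sub.table.join(sub_fdr.table["fdr"]).join(
        counts[["n_sig_members", "n_down", "n_up"]]
    )
    return fits, met_fdr, sub_table, sv


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and write result tables + manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "config_hash": config.digest(),
        "version": __version__,
        "seed": config.seed,
        "counts": {},
    }

    raw = read_abundance(config.abundance, state="raw")
    metadata = read_metadata(config.metadata)
    annotation = read_annotation(config.annotation)
    manifest["counts"]["metabolites_input"] = raw.n_metabolites

    Y = preprocess_pipeline(
        raw, metadata.table["diet"].to_numpy(),
        threshold=config.filter_threshold, rule=config.filter_rule,
    )
    manifest["counts"]["metabolites_analyzed"] = Y.n_metabolites
    manifest["counts"]["samples"] = Y.n_samples

    fits, met_fdr, sub_table, sv = analyze_cohort(
        Y, metadata, annotation, seed=config.seed, n_sv=config.n_sv,
        B=config.B, alpha=config.alpha,
    )
    manifest["counts"]["n_sv"] = sv.k
    manifest["pi0"] = met_fdr.pi0
    manifest["fdr_floor"] = 1.0 / (config.B * Y.n_metabolites + 1)

    met_table = fits.table.join(met_fdr.table["fdr"]).join(annotation.table)
    # fold change descending; ties broken by metabolite name for reproducibility
    met_table = met_table.sort_index().sort_values(
        "fold_change", ascending=False, kind="stable"
    )
    _write(met_table, out / "metabolites_sva.tsv", "metabolite")
    n_sig = met_fdr.n_significant(config.alpha)
    sig = met_table[met_table["fdr"] < config.alpha]
    manifest["counts"]["significant_metabolites_sva"] = n_sig
    manifest["counts"]["significant_decreased_sva"] = int((sig["beta"] < 0).sum())
    logger.info("SVA model: %d of %d metabolites significant at FDR<%g",
                n_sig, Y.n_metabolites, config.alpha)

    sub_sorted = sub_table.sort_index().sort_values(
        "fold_change", ascending=False, kind="stable"
    )
    _write(sub_sorted, out / "subclasses_sva.tsv", "subclass")
    manifest["counts"]["subclasses_tested"] = len(sub_table)
    manifest["counts"]["significant_subclasses_sva"] = int(
        (sub_table["fdr"] < config.alpha).sum()
    )

    if config.run_unadjusted:
        fits_u = fit_unadjusted_models(Y, DesignInfo.from_metadata(metadata))
        null_u = build_null(fits_u.residual_y, fits_u.residual_x, B=config.B,
                            seed=config.seed, df=fits_u.df,
                            nuisance=fits_u.nuisance)
        fdr_u = fdr_from_null(fits_u.t, null_u, feature_ids=fits_u.metabolite_ids)
        tab_u = fits_u.table.join(fdr_u.table["fdr"]).join(annotation.table)
        _write(
            tab_u.sort_index().sort_values("fold_change", ascending=False,
                                           kind="stable"),
            out / "metabolites_unadjusted.tsv", "metabolite",
        )
        manifest["counts"]["significant_metabolites_unadjusted"] = (
            fdr_u.n_significant(config.alpha)
        )

    if config.n_boot >= 2:
        rep = bootstrap_stability(
            Y, metadata, annotation, n_boot=config.n_boot, seed=config.seed,
            n_sv=sv.k, inner_B=config.boot_inner_B, alpha=config.alpha,
        )
        stab = pd.DataFrame(
            {
                "fraction_significant": rep.fraction_significant,
                "stable_50": rep.fraction_significant >= 0.5,
                "stable_90": rep.fraction_significant >= 0.9,
                "stable_100": rep.fraction_significant >= 1.0,
            }
        )
        _write(stab, out / "stability_metabolite.tsv", "metabolite")
        manifest["counts"]["stable_90_metabolites"] = len(rep.stable_90)
        manifest["counts"]["stable_100_metabolites"] = len(rep.stable_100)

    if config.K >= 2:
        cv = crossval_shrunken_ts(
            Y, metadata, K=config.K, seed=config.seed, n_sv=sv.k, B=config.B,
            alpha=config.alpha,
        )
        _write(cv.table, out / "crossval.tsv", "metabolite")
        manifest["counts"]["cv_lost_significance"] = cv.n_lost(config.alpha)

    if config.run_multivariate:
        pca = run_pca(Y, seed=config.seed)
        _write(
            pd.DataFrame(
                {
                    "eigenvalue": pca.eigenvalues,
                    "cum_var_explained": pca.cum_var_explained,
                },
                index=pd.Index(
                    [f"PC{i + 1}" for i in range(len(pca.eigenvalues))],
                    name="component",
                ),
            ),
            out / "pca_eigenvalues.tsv", "component",
        )
        _write(pca.scores, out / "pca_scores.tsv", "sample_id")
        _write(pca.corr_loadings, out / "pca_loadings.tsv", "metabolite")
        manifest["counts"]["pca_components"] = pca.n_nonzero
        manifest["counts"]["pca_excluded_samples"] = len(pca.excluded_samples)
        if config.pca_eigen_threshold is not None:
            manifest["counts"]["pca_retained"] = len(
                select_components(pca, eigen_threshold=config.pca_eigen_threshold)
            )
        rf = rf_classify(
            Y, metadata.table["diet"].to_numpy(), n_trees=config.rf_trees,
            seed=config.seed, compute_importance=config.rf_importance,
        )
        if rf.importance is not None:
            _write(rf.importance, out / "rf_importance.tsv", "metabolite")
        manifest["rf_oob_error"] = rf.oob_error

    base = baseline_table(metadata)
    _write(base, out / "baseline.tsv", "variable")

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True,
                                        default=str))
    logger.info("pipeline complete; manifest at %s", manifest_path)
    return manifest
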