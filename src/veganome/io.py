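"""Reading and writing the three standard input tables (TSV) and truth JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, Annotation, CohortMetadata
from .synthetic import SyntheticDataset

FLOAT_FMT = "%.10g"


def write_abundance(matrix: AbundanceMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", float_format=FLOAT_FMT,
                         index_label="sample_id")


def read_abundance(path, state: str = "raw") -> AbundanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return AbundanceMatrix(df, state=state)


def write_metadata(metadata: CohortMetadata, path) -> None:
    metadata.table.to_csv(path, sep="\t", float_format=FLOAT_FMT,
                          index_label="sample_id")


def read_metadata(path) -> CohortMetadata:
    return CohortMetadata(pd.read_csv(path, sep="\t", index_col=0))


def write_annotation(annotation: Annotation, path) -> None:
    annotation.table.to_csv(path, sep="\t", index_label="metabolite")


def read_annotation(path) -> Annotation:
    return Annotation(pd.read_csv(path, sep="\t", index_col=0))


def write_truth(dataset: SyntheticDataset, path) -> None:
    truth = dataset.truth
    payload = {
        "nonnull_set": [int(i) for i in truth.nonnull_set],
        "delta": [float(d) for d in truth.delta],
        "latent_scores": np.asarray(truth.latent_scores).tolist(),
        "latent_loadings": np.asarray(truth.latent_loadings).tolist(),
        "seed": dataset.config.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, str]:
    """Write abundance/metadata/annotation TSVs plus truth.json to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "abundance": str(outdir / "abundance.tsv"),
        "metadata": str(outdir / "metadata.tsv"),
        "annotation": str(outdir / "annotation.tsv"),
        "truth": str(outdir / "truth.json"),
    }
    write_abundance(dataset.raw, paths["abundance"])
    write_metadata(dataset.metadata, paths["metadata"])
    write_annotation(dataset.annotation, paths["annotation"])
    write_truth(dataset, paths["truth"])
    return paths
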