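"""TSV/JSON dialects shared across the pipeline stages."""

from __future__ import annotations

import json

import pandas as pd

from .counts import CountMatrix, NormFactors
from .ortho import OrthologMap

FLOAT_FMT = "%.10g"


def write_counts(cm: CountMatrix, counts_path, meta_path) -> None:
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    meta = cm.meta.copy()
    meta.index.name = "sample_id"
    meta.to_csv(meta_path, sep="\t", float_format=FLOAT_FMT)


def read_counts(counts_path, meta_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene_id")
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
    return CountMatrix(counts, meta)


def write_factors(factors: NormFactors, path) -> None:
    df = pd.DataFrame(
        {"tmm_factor": factors.factors, "lib_size": factors.lib_sizes}
    )
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_factors(path) -> NormFactors:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    return NormFactors(df["tmm_factor"], df["lib_size"])


def write_table(df: pd.DataFrame, path, index_label=None) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label=index_label,
              na_rep="NA")


def read_orthomap(path) -> OrthologMap:
    df = pd.read_csv(path, sep="\t")
    return OrthologMap(df[["gene_a", "gene_b"]])


def write_orthomap(omap: OrthologMap, path) -> None:
    omap.pairs.to_csv(path, sep="\t", index=False)


def read_targets(path, aliases: dict | None = None) -> pd.DataFrame:
    """Read a TargetScan-like target table; ``aliases`` maps file
    column names onto mirna_id/gene_id/context_score."""
    df = pd.read_csv(path, sep="\t")
    if aliases:
        df = df.rename(columns=aliases)
    return df[["mirna_id", "gene_id", "context_score"]]


def write_targets(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
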