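"""Cross-species comparison: ortholog mapping of term genes,
cross-condition concordance of significance calls, hierarchical
clustering of binary significance matrices, and the tumor stage-split
comparison."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr

from .counts import CountMatrix, tmm_factors, log_cpm
from .diffexp import paired_de
from .enrichment import GeneSetCollection, gage_paired

logger = logging.getLogger(__name__)


@dataclass
class OrthologMap:
    """Ordered (gene_a, gene_b) pairs; possibly many:many.

    Row order is meaningful: 'first'-mode mapping takes the earliest
    matching row, which is the determinism source for heatmaps.
    """

    pairs: pd.DataFrame  # columns gene_a, gene_b

    def __post_init__(self) -> None:
        if self.pairs.duplicated(subset=["gene_a", "gene_b"]).any():
            raise ValueError("duplicate ortholog pairs")
        if (self.pairs["gene_a"].astype(str) == "").any() or (
            self.pairs["gene_b"].astype(str) == ""
        ).any():
            raise ValueError("empty gene IDs in ortholog map")

    def reversed(self) -> "OrthologMap":
        rev = self.pairs.rename(columns={"gene_a": "gene_b", "gene_b": "gene_a"})
        return OrthologMap(rev[["gene_a", "gene_b"]].reset_index(drop=True))


def map_term_genes(genes, omap: OrthologMap, mode: str = "expand") -> set:
    """Map a gene set across species.

    mode='expand': union of all ortholog images (used for set-level
    tests, so a human gene with several fish orthologs contributes all
    of them).  mode='first': one image per source gene, the earliest
    map row (used for fold-change heatmaps).  Unmapped genes are
    dropped with a logged count.
    """
    if omap.pairs.empty:
        raise ValueError("empty ortholog map")
    genes = list(genes)
    sub = omap.pairs[omap.pairs["gene_a"].isin(genes)]
    unmapped = set(genes) - set(sub["gene_a"])
    if unmapped:
        logger.info("dropping %d unmapped genes", len(unmapped))
    if mode == "expand":
        return set(sub["gene_b"])
    if mode == "first":
        return set(sub.drop_duplicates(subset="gene_a", keep="first")["gene_b"])
    raise ValueError(f"unknown mode {mode!r}")


def concordance_counts(calls_a: pd.Series, calls_b: pd.Series) -> dict:
    """Agreement of two term-call vectors over their shared terms.

    Counts matched up/up and down/down calls, discordant calls (one or
    both called but not matching), and the agreement score
    matched / (# terms called in either).  Undefined (None score) when
    no term is called in either vector.
    """
    shared = calls_a.index.intersection(calls_b.index)
    a, b = calls_a.loc[shared], calls_b.loc[shared]
    called = (a != "ns") | (b != "ns")
    up_up = int(((a == "up") & (b == "up")).sum())
    down_down = int(((a == "down") & (b == "down")).sum())
    matched = up_up + down_down
    union = int(called.sum())
    return {
        "up_up": up_up,
        "down_down": down_down,
        "discordant": union - matched,
        "union_called": union,
        "score": (matched / union) if union else None,
    }


def concordance(sig: pd.DataFrame, cluster_calls: pd.DataFrame) -> pd.DataFrame:
    """Cluster x condition agreement scores between per-cluster term
    calls and a condition significance matrix (shared term namespace)."""
    out = pd.DataFrame(
        np.nan, index=cluster_calls.columns, columns=sig.columns, dtype=float
    )
    for cl in cluster_calls.columns:
        for cond in sig.columns:
            res = concordance_counts(cluster_calls[cl], sig[cond])
            out.loc[cl, cond] = np.nan if res["score"] is None else res["score"]
    return out


_CODE = {"up": 1.0, "down": -1.0, "ns": 0.0}


def encode_significance(sig: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame(
        np.vectorize(_CODE.get)(sig.to_numpy()), index=sig.index,
        columns=sig.columns, dtype=float,
    )


def hclust_binary(sig: pd.DataFrame, linkage: str = "complete") -> dict:
    """Agglomerative clustering of the +1/-1/0 encoded significance
    matrix on Euclidean distance, rows and columns; returns linkage
    matrices and leaf orders for heatmap rendering."""
    x = encode_significance(sig).to_numpy()
    out = {}
    for axis, labels, data in (("rows", sig.index, x), ("cols", sig.columns, x.T)):
        if data.shape[0] < 2:
            out[axis] = {"linkage": None, "order": list(labels)}
            continue
        lk = hierarchy.linkage(pdist(data, metric="euclidean"), method=linkage)
        order = [labels[i] for i in hierarchy.leaves_list(lk)]
        out[axis] = {"linkage": lk, "order": order}
    return out


def foldchange_heatmap(
    lfc_by_condition: dict[str, pd.Series],
    term_genes: set,
    linkage: str = "complete",
) -> dict:
    """Gene x condition log2FC matrix restricted to a term's genes, with
    hierarchical row/column orders; missing entries stay NaN."""
    cols = {}
    for cond, lfc in lfc_by_condition.items():
        cols[cond] = lfc.reindex(sorted(term_genes))
    mat = pd.DataFrame(cols)
    mat = mat.dropna(how="all")
    filled = mat.fillna(0.0)
    orders = {}
    for axis, data, labels in (("rows", filled.to_numpy(), mat.index),
                               ("cols", filled.to_numpy().T, mat.columns)):
        if data.shape[0] < 2:
            orders[axis] = list(labels)
        else:
            lk = hierarchy.linkage(pdist(data), method=linkage)
            orders[axis] = [labels[i] for i in hierarchy.leaves_list(lk)]
    return {"matrix": mat, "row_order": orders["rows"], "col_order": orders["cols"]}


def _minmax(v: pd.Series) -> pd.Series:
    lo, hi = v.min(), v.max()
    if hi == lo:
        return pd.Series(0.0, index=v.index)
    return (v - lo) / (hi - lo)


def stage_split_compare(
    cm: CountMatrix,
    sets: GeneSetCollection,
    early_stages=("I", "II"),
    late_stages=("III", "IV"),
    min_pairs: int = 3,
) -> dict:
    """Early- vs late-stage comparison for one tumor entity.

    Tumor samples are split by their ``stage`` metadata into early
    (I/II) and late (III/IV) groups; each group (with its paired
    normals) is run through paired DE and the paired set statistic;
    per stage the -log10 FDR of each term (best direction) is min-max
    scaled to [0, 1]; the result is the early/late scatter table and
    the Pearson r of the two scaled columns.
    """
    if "stage" not in cm.meta.columns:
        raise ValueError("stage metadata required")
    scaled = {}
    for label, stages in (("early", early_stages), ("late", late_stages)):
        tum = cm.meta[(cm.meta["condition"] == "tumor") & cm.meta["stage"].isin(stages)]
        pair_ids = set(tum["pair_id"].dropna())
        samples = cm.meta.index[cm.meta["pair_id"].isin(pair_ids)]
        if len(pair_ids) < min_pairs:
            logger.info("stage group %s skipped: %d pairs", label, len(pair_ids))
            continue
        sub = cm.subset_samples(samples)
        factors = tmm_factors(sub)
        expr = log_cpm(sub, factors)
        res = gage_paired(expr, sub.meta, sets)
        best = res.loc[res.groupby("term")["fdr"].idxmin()].set_index("term")
        scaled[label] = _minmax(-np.log10(best["fdr"].clip(lower=1e-300)))
    table = pd.DataFrame(scaled)
    r = np.nan
    if {"early", "late"} <= set(table.columns):
        ok = table.dropna()
        if len(ok) >= 3:
            r = float(pearsonr(ok["early"], ok["late"])[0])
    return {"table": table, "pearson_r": r}
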