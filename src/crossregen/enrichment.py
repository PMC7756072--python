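"""Gene-set enrichment: Fisher/hypergeometric over-representation for
gene lists and a paired fold-change set statistic for tumor-normal
cohorts, plus the categorical significance matrix that feeds all
cross-condition heatmaps.

The paired set statistic follows the gage idea: within each pair the
tumor-minus-normal log ratios of a set's genes are compared with the
ratios of all measured genes by an unequal-variance t test, one-sided
per direction, and the per-pair p-values are combined across pairs by
Stouffer's method.  Acceptance is planted-set recovery, not numeric
parity with any particular implementation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import bh_fdr

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets (GO:BP-like, hallmark-like)."""

    sets: dict[str, set]
    provenance: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"empty gene set {name!r}")
            self.sets[name] = set(genes)

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()

    def restrict(self, universe: set, min_size: int = 1) -> "GeneSetCollection":
        out = {
            n: g & universe for n, g in self.sets.items() if len(g & universe) >= min_size
        }
        return GeneSetCollection(out, provenance=self.provenance)


def read_gmt(path) -> GeneSetCollection:
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return GeneSetCollection(sets)


def write_gmt(coll: GeneSetCollection, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sorted(coll.sets):
            genes = "\t".join(sorted(coll.sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")


def ora_fisher(
    query, sets: GeneSetCollection, universe, direction: str = "n/a"
) -> pd.DataFrame:
    """One-sided Fisher exact (hypergeometric upper tail) enrichment of
    ``query`` in each set, over ``universe``; BH-FDR across terms.

    Returns a table with columns term, p, fdr, direction, overlap,
    set_size, gene_ratio (overlap / set size).
    """
    query, universe = set(query), set(universe)
    if not universe:
        raise ValueError("empty universe")
    stray = query - universe
    if stray:
        raise ValueError(f"query genes outside universe: {sorted(stray)[:5]}")
    rows = []
    for name, genes in sorted(sets.items()):
        s = genes & universe
        if not s:
            continue
        k = len(query & s)
        # P(X >= k), X ~ Hypergeom(N=|universe|, K=|set|, n=|query|)
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(s), len(query)))
        rows.append(
            {
                "term": name,
                "p": min(p, 1.0),
                "direction": direction,
                "overlap": k,
                "set_size": len(s),
                "gene_ratio": k / len(s),
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["fdr"] = bh_fdr(df["p"].to_numpy())
        df = df[["term", "p", "fdr", "direction", "overlap", "set_size", "gene_ratio"]]
    return df


def _stouffer(p: np.ndarray) -> float:
    """Combine one-sided p-values: z = sum(z_i)/sqrt(k)."""
    z = stats.norm.isf(np.clip(p, 1e-300, 1 - 1e-16))
    return float(stats.norm.sf(z.sum() / np.sqrt(len(z))))


def gage_paired(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    sets: GeneSetCollection,
    condition_pos: str = "tumor",
    condition_neg: str = "normal",
    min_set: int = 2,
) -> pd.DataFrame:
    """Paired per-set fold-change statistic.

    For each complete pair, per-gene log ratios (pos - neg) are formed;
    for each set, a Welch t of the set's ratios against all genes'
    ratios yields one-sided p-values per direction; Stouffer combines
    them across pairs; BH-FDR per direction.  Emits two rows per term
    (direction up / down).
    """
    pairs = []
    for pid, grp in meta.dropna(subset=["pair_id"]).groupby("pair_id"):
        pos = grp.index[grp["condition"] == condition_pos]
        neg = grp.index[grp["condition"] == condition_neg]
        if len(pos) == 1 and len(neg) == 1:
            pairs.append((pos[0], neg[0]))
    if len(pairs) < 2:
        raise ValueError("need at least 2 complete pairs")
    ratios = np.column_stack([expr[a].to_numpy() - expr[b].to_numpy() for a, b in pairs])
    gene_pos = {g: i for i, g in enumerate(expr.index)}
    rows = []
    for name, genes in sorted(sets.items()):
        idx = [gene_pos[g] for g in genes if g in gene_pos]
        if len(idx) < min_set:
            logger.info("term %s skipped: <%d measured genes", name, min_set)
            continue
        p_up, p_down = [], []
        for j in range(ratios.shape[1]):
            t, _ = stats.ttest_ind(
                ratios[idx, j], ratios[:, j], equal_var=False
            )
            df_w = _welch_df(ratios[idx, j], ratios[:, j])
            p_up.append(float(stats.t.sf(t, df_w)))
            p_down.append(float(stats.t.cdf(t, df_w)))
        for direction, ps in (("up", p_up), ("down", p_down)):
            rows.append(
                {
                    "term": name,
                    "p": _stouffer(np.array(ps)),
                    "direction": direction,
                    "overlap": len(idx),
                    "set_size": len(genes),
                    "gene_ratio": len(idx) / len(genes),
                }
            )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["fdr"] = np.nan
        for direction in ("up", "down"):
            mask = df["direction"] == direction
            df.loc[mask, "fdr"] = bh_fdr(df.loc[mask, "p"].to_numpy())
        df = df[["term", "p", "fdr", "direction", "overlap", "set_size", "gene_ratio"]]
    return df


def _welch_df(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    if va + vb == 0:
        return len(a) + len(b) - 2.0
    return (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))


def significance_matrix(
    results: dict[str, pd.DataFrame],
    cutoffs: dict[str, tuple[str, float]],
) -> pd.DataFrame:
    """Term x condition categorical matrix over {up, down, ns}.

    ``results`` maps condition name to an enrichment table;
    ``cutoffs`` maps condition name to (statistic, threshold), e.g.
    ("fdr", 0.1) for cluster ORA, ("fdr", 0.01) for cohorts, ("p", 0.01)
    for miRNA-target enrichment.  A term significant in both directions
    takes the smaller p; duplicate same-direction entries for one
    (term, condition) raise.
    """
    terms = sorted({t for df in results.values() if not df.empty for t in df["term"]})
    out = pd.DataFrame("ns", index=terms, columns=sorted(results))
    for cond, df in results.items():
        if df.empty:
            continue
        stat, cut = cutoffs[cond]
        if df.duplicated(subset=["term", "direction"]).any():
            raise ValueError(f"duplicate (term, direction) entries for {cond!r}")
        sig = df[df[stat] < cut]
        for term, grp in sig.groupby("term"):
            best = grp.sort_values("p").iloc[0]
            d = best["direction"]
            out.loc[term, cond] = d if d in ("up", "down") else "up"
    return out
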