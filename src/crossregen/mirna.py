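"""miRNA-mRNA regulation screen.

Predicted targets (TargetScan-like, context score below a cut) are
correlated with expression across shared samples, split by regulation
direction (miR up / mRNA down and vice versa); anticorrelated pairs
passing rho < -0.4 at FDR < 0.05 are "valid"; miRNAs sharing a
significant number of valid targets (hypergeometric FDR < 0.01) merge
into groups (connected components); groups rank by valid-target count
and the top 15 are kept; each group's union target set is tested for
gene-set over-representation at nominal p < 0.01.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import bh_fdr
from .enrichment import GeneSetCollection, ora_fisher

logger = logging.getLogger(__name__)

DIRECTIONS = ("miR-up/mRNA-down", "miR-down/mRNA-up")


def filter_targets(table: pd.DataFrame, score_cut: float = -0.2) -> pd.DataFrame:
    """Keep predicted interactions with context score strictly below
    ``score_cut``; duplicates of a (mirna, gene) pair collapse to the
    most negative score."""
    for col in ("mirna_id", "gene_id", "context_score"):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    out = table[table["context_score"] < score_cut]
    out = out.sort_values("context_score").drop_duplicates(
        subset=["mirna_id", "gene_id"], keep="first"
    )
    return out.reset_index(drop=True)


def correlate_pairs(
    mrna_expr: pd.DataFrame,
    mirna_expr: pd.DataFrame,
    candidates: pd.DataFrame,
    mrna_calls: pd.Series | None = None,
    mirna_calls: pd.Series | None = None,
    rho_cut: float = -0.4,
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation screen over candidate miRNA-mRNA pairs.

    Expression matrices must share sample columns (>= 5).  When DE
    calls are given, candidates are restricted to oppositely regulated
    molecules and tagged with their direction split; BH-FDR is computed
    within each split (global across that split's pairs).  A pair is
    valid when rho < ``rho_cut`` and FDR < ``fdr_cut``.
    """
    shared = [s for s in mrna_expr.columns if s in set(mirna_expr.columns)]
    if len(shared) < 5:
        raise ValueError("need at least 5 shared samples")
    mx = mrna_expr[shared]
    mix = mirna_expr[shared]
    cand = candidates[
        candidates["gene_id"].isin(mx.index) & candidates["mirna_id"].isin(mix.index)
    ].copy()
    if mrna_calls is not None and mirna_calls is not None:
        gcall = cand["gene_id"].map(mrna_calls)
        mcall = cand["mirna_id"].map(mirna_calls)
        dir1 = (mcall == "up") & (gcall == "down")
        dir2 = (mcall == "down") & (gcall == "up")
        cand["direction"] = np.where(dir1, DIRECTIONS[0], np.where(dir2, DIRECTIONS[1], ""))
        cand = cand[cand["direction"] != ""]
    else:
        cand["direction"] = "all"
    n = len(shared)
    rows = []
    for _, row in cand.iterrows():
        x = mix.loc[row["mirna_id"]].to_numpy(dtype=float)
        y = mx.loc[row["gene_id"]].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            logger.info("skipping zero-variance pair %s-%s", row["mirna_id"], row["gene_id"])
            continue
        rho, p = stats.pearsonr(x, y)
        rows.append(
            {
                "mirna": row["mirna_id"],
                "gene": row["gene_id"],
                "rho": float(rho),
                "p": float(p),
                "direction": row["direction"],
            }
        )
    res = pd.DataFrame(rows)
    if res.empty:
        return pd.DataFrame(
            columns=["mirna", "gene", "rho", "p", "fdr", "direction", "valid"]
        )
    res["fdr"] = np.nan
    for d, grp in res.groupby("direction"):
        res.loc[grp.index, "fdr"] = bh_fdr(grp["p"].to_numpy())
    res["valid"] = (res["rho"] < rho_cut) & (res["fdr"] < fdr_cut)
    return res


@dataclass
class MirnaGroup:
    """Merged miRNAs with the union of their valid targets."""

    members: list[str]
    targets: set
    member_targets: dict[str, set] = field(default_factory=dict)
    rank: int | None = None

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    @property
    def lead(self) -> str:
        return min(self.members)


def overlap_pvalue(n_a: int, n_b: int, overlap: int, universe: int) -> float:
    """Hypergeometric upper-tail probability of seeing >= ``overlap``
    shared targets between sets of sizes n_a and n_b in ``universe``."""
    return float(stats.hypergeom.sf(overlap - 1, universe, n_a, n_b))


def merge_mirnas(
    interactions: pd.DataFrame,
    universe_size: int | None = None,
    overlap_fdr: float = 0.01,
) -> list[MirnaGroup]:
    """Merge miRNAs that share significantly many valid targets.

    For each miRNA pair a hypergeometric test of their valid-target
    overlap (universe = mRNAs tested, i.e. unique genes in the
    interaction table unless given); BH-FDR over pairs; edges at
    FDR < ``overlap_fdr``; groups are connected components (singletons
    stay their own group).
    """
    valid = interactions[interactions["valid"]]
    targets = {m: set(g["gene"]) for m, g in valid.groupby("mirna")}
    if universe_size is None:
        universe_size = interactions["gene"].nunique()
    mirnas = sorted(targets)
    g = nx.Graph()
    g.add_nodes_from(mirnas)
    pairs, ps = [], []
    for a, b in combinations(mirnas, 2):
        ov = len(targets[a] & targets[b])
        pairs.append((a, b))
        ps.append(overlap_pvalue(len(targets[a]), len(targets[b]), ov, universe_size))
    if pairs:
        fdr = bh_fdr(np.array(ps))
        for (a, b), q in zip(pairs, fdr):
            if q < overlap_fdr:
                g.add_edge(a, b)
    groups = []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        union = set().union(*(targets[m] for m in members))
        groups.append(
            MirnaGroup(members, union, {m: targets[m] for m in members})
        )
    return groups


def top_k(groups: list[MirnaGroup], k: int = 15) -> list[MirnaGroup]:
    """Rank groups by union valid-target count (descending); ties by
    member count then lead miRNA; keep the top ``k``."""
    ranked = sorted(groups, key=lambda g: (-g.n_targets, -len(g.members), g.lead))
    out = ranked[:k]
    for i, g in enumerate(out):
        g.rank = i + 1
    return out


def enrich_targets(
    groups: list[MirnaGroup],
    sets: GeneSetCollection,
    universe,
    p_cut: float = 0.01,
) -> dict[str, pd.DataFrame]:
    """Fisher over-representation of each group's union target set;
    significance at nominal p < ``p_cut`` (column ``significant``)."""
    out = {}
    for g in groups:
        query = set(g.targets) & set(universe)
        if not query:
            logger.info("group %s skipped: empty target set", g.lead)
            continue
        res = ora_fisher(query, sets, universe)
        if not res.empty:
            res["significant"] = res["p"] < p_cut
        out[g.lead] = res
    return out
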