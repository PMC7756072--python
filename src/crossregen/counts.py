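"""Count-matrix hygiene: ID de-duplication, expression filtering, TMM
normalization and log-CPM transforms.

The central container is :class:`CountMatrix`, a nonnegative integer
gene-by-sample table with per-sample metadata (condition, timepoint,
pair ID).  All downstream stages consume it.  Normalization follows the
trimmed-mean-of-M-values (TMM) scheme of Robinson & Oshlack: per-sample
scaling factors are computed as a doubly trimmed, precision-weighted
mean of gene-wise log ratios against a reference sample, then centered
to geometric mean 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = {"injured", "sham", "healthy", "tumor", "normal"}


@dataclass
class CountMatrix:
    """Gene x sample raw counts plus per-sample metadata.

    Parameters
    ----------
    counts
        DataFrame with unique gene IDs as index, unique sample IDs as
        columns, finite nonnegative integer entries.
    meta
        DataFrame indexed by sample ID with columns ``condition`` and
        optionally ``timepoint`` (days) and ``pair_id``.  Every tumor
        sample carrying a pair_id must have a matching normal sample and
        vice versa.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene IDs")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample IDs")
        vals = self.counts.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError("counts must be finite")
        if (vals < 0).any():
            raise ValueError("counts must be nonnegative")
        if set(self.counts.columns) != set(self.meta.index):
            raise ValueError("metadata sample IDs do not match count columns")
        self.meta = self.meta.loc[self.counts.columns]
        bad = set(self.meta["condition"]) - CONDITIONS
        if bad:
            raise ValueError(f"unknown conditions: {sorted(bad)}")
        if "pair_id" in self.meta.columns:
            paired = self.meta.dropna(subset=["pair_id"])
            for pid, grp in paired.groupby("pair_id"):
                conds = set(grp["condition"])
                if conds & {"tumor", "normal"} and conds != {"tumor", "normal"}:
                    raise ValueError(f"pair {pid!r} lacks a tumor/normal partner")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def lib_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_samples(self, samples) -> "CountMatrix":
        samples = list(samples)
        return CountMatrix(self.counts[samples].copy(), self.meta.loc[samples].copy())

    def subset_genes(self, genes) -> "CountMatrix":
        genes = list(genes)
        return CountMatrix(self.counts.loc[genes].copy(), self.meta.copy())


@dataclass
class NormFactors:
    """Per-sample TMM factor and raw library size.

    The effective library size (the divisor of CPM) is the product of
    the two; TMM factors are centered so their geometric mean is 1.
    """

    factors: pd.Series
    lib_sizes: pd.Series

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("TMM factors must be positive")
        if (self.lib_sizes <= 0).any():
            raise ValueError("library sizes must be positive")

    @property
    def effective(self) -> pd.Series:
        return self.factors * self.lib_sizes


def _iqr(row: np.ndarray) -> float:
    q75, q25 = np.percentile(row, [75, 25])
    return float(q75 - q25)


def dedupe_ids(cm: CountMatrix, id_map: pd.DataFrame) -> CountMatrix:
    """Collapse rows that map to the same target ID.

    ``id_map`` has columns ``source_id`` and ``target_id`` (may be
    many:many, e.g. Ensembl -> Entrez).  When several source rows map to
    one target, the row with the largest inter-quartile range of counts
    across samples is kept; ties break by larger total count, then by
    lexicographically smaller source ID.  Source genes absent from the
    map are dropped.
    """
    if id_map.empty:
        raise ValueError("empty ID map")
    sub = id_map[id_map["source_id"].isin(cm.counts.index)]
    chosen: dict[str, str] = {}
    for target, grp in sub.groupby("target_id"):
        best = None
        for src in grp["source_id"].unique():
            row = cm.counts.loc[src].to_numpy()
            key = (_iqr(row), row.sum(), _NegStr(src))
            if best is None or key > best[0]:
                best = (key, src)
        chosen[target] = best[1]
    out = cm.counts.loc[list(chosen.values())].copy()
    out.index = pd.Index(list(chosen.keys()), name=cm.counts.index.name)
    # a single source row may win several targets; keep first occurrence
    out = out[~out.index.duplicated()]
    return CountMatrix(out.sort_index(), cm.meta.copy())


class _NegStr(str):
    """String with reversed ordering, so max() prefers the lexicographically smaller ID."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def cpm(cm: CountMatrix, lib_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million on raw (or supplied) library sizes."""
    libs = cm.lib_sizes() if lib_sizes is None else lib_sizes
    return cm.counts / libs * 1e6


def filter_low_expression(
    cm: CountMatrix, min_cpm: float = 1.0, min_samples: int = 3
) -> CountMatrix:
    """Keep genes with CPM >= ``min_cpm`` in at least ``min_samples`` samples.

    CPM is computed on raw library sizes because filtering precedes
    normalization.  Idempotent (library sizes are not recomputed within
    a call, and removing low genes barely changes them; the rule is
    re-evaluated on the surviving matrix's raw totals, so a second
    application at the same thresholds keeps the same genes).
    """
    if min_samples > cm.counts.shape[1]:
        raise ValueError("min_samples exceeds number of samples")
    keep = (cpm(cm) >= min_cpm).sum(axis=1) >= min_samples
    return CountMatrix(cm.counts.loc[keep].copy(), cm.meta.copy())


def tmm_factors(
    cm: CountMatrix,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
    ref: str | None = None,
) -> NormFactors:
    """Trimmed mean of M-values scaling factors.

    For each sample against a reference sample, gene-wise log2 ratios
    (M) and average log2 abundances (A) are computed over genes nonzero
    in both; the upper/lower ``logratio_trim`` fraction of M and
    ``sum_trim`` fraction of A are discarded; the factor is
    2**(weighted mean of the surviving M) with inverse asymptotic
    binomial variance weights.  With ``ref=None`` the reference is the
    sample whose CPM upper quartile is closest to the mean upper
    quartile.  Factors are centered to geometric mean 1.
    """
    counts = cm.counts.to_numpy(dtype=float)
    libs = counts.sum(axis=0)
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    if ref is None:
        uq = np.array([np.percentile(c[c > 0] / l, 75) for c, l in zip(counts.T, libs)])
        ref_i = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_i = cm.counts.columns.get_loc(ref)
    yr, nr = counts[:, ref_i], libs[ref_i]
    raw = np.ones(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref_i:
            continue
        yj, nj = counts[:, j], libs[j]
        ok = (yj > 0) & (yr > 0)
        if not ok.any():
            raise ValueError(
                f"sample {cm.counts.columns[j]!r} shares no nonzero genes with reference"
            )
        pj, pr = yj[ok] / nj, yr[ok] / nr
        m = np.log2(pj / pr)
        a = 0.5 * np.log2(pj * pr)
        w = (nj - yj[ok]) / (nj * yj[ok]) + (nr - yr[ok]) / (nr * yr[ok])
        if np.allclose(m, 0.0):
            raw[j] = 1.0
            continue
        lo_m, hi_m = np.quantile(m, [logratio_trim, 1 - logratio_trim])
        lo_a, hi_a = np.quantile(a, [sum_trim, 1 - sum_trim])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not keep.any():
            keep = np.ones_like(m, dtype=bool)
        raw[j] = 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))
    centered = raw / np.exp(np.mean(np.log(raw)))
    return NormFactors(
        pd.Series(centered, index=cm.counts.columns, name="tmm"),
        pd.Series(libs.astype(int), index=cm.counts.columns, name="lib_size"),
    )


def log_cpm(
    cm: CountMatrix, factors: NormFactors, prior_count: float = 0.5
) -> pd.DataFrame:
    """log2 counts per million on effective library sizes.

    The prior count is scaled per sample in proportion to effective
    library size per million (and the library size is inflated by twice
    the scaled prior), so the transform is finite everywhere and
    exactly invariant to doubling all counts and library sizes.
    """
    if set(factors.factors.index) != set(cm.counts.columns):
        raise ValueError("factors computed on different samples")
    eff = factors.effective.loc[cm.counts.columns].to_numpy(dtype=float)
    prior = prior_count * eff / 1e6
    return pd.DataFrame(
        np.log2((cm.counts.to_numpy(dtype=float) + prior) / (eff + 2 * prior) * 1e6),
        index=cm.counts.index,
        columns=cm.counts.columns,
    )


def pca_coords(expr: pd.DataFrame, n_components: int = 2):
    """Sample coordinates on the top principal components of log-expression.

    Samples are rows of the (transposed) expression matrix; they are
    gene-wise centered and projected on the leading right-singular
    directions.  Returns the coordinate table and per-component variance
    shares.
    """
    x = expr.to_numpy(dtype=float).T
    if x.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    if n_components > min(x.shape):
        raise ValueError("n_components exceeds matrix rank bound")
    xc = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    coords = u[:, :n_components] * s[:n_components]
    total = float(np.sum(s**2))
    shares = (s[:n_components] ** 2 / total) if total > 0 else np.zeros(n_components)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (
        pd.DataFrame(coords, index=expr.columns, columns=cols),
        pd.Series(shares, index=cols, name="variance_share"),
    )
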