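"""Paired differential expression with empirical-Bayes variance
moderation, NB dispersion estimation, BH-FDR and DEG calling rules.

The engine is a moderated paired-difference test on log-CPM: per pair
the tumor-minus-normal log2-CPM difference is formed, and a one-sample
location test with empirical-Bayes variance shrinkage (limma-style
moment-estimated variance prior) is applied per gene.  This keeps
the paired design's robustness to patient heterogeneity while staying
at the threshold/rank contract level.  A tagwise negative-binomial
dispersion fit is provided separately for generators, weighting and NB
extensions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .counts import CountMatrix, NormFactors, log_cpm


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("NaN p-values")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEResult:
    """Per-gene log2FC, raw p, BH-FDR and an up/down/ns call."""

    table: pd.DataFrame  # columns: log2FC, p, fdr, call
    fdr_cut: float = 0.01
    lfc_cut: float = 1.0
    relaxation_applied: bool = False

    def genes_called(self, call: str) -> pd.Index:
        return self.table.index[self.table["call"] == call]

    @property
    def n_up(self) -> int:
        return int((self.table["call"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.table["call"] == "down").sum())


@dataclass
class DispersionFit:
    """Raw, trended and shrunk (tagwise) NB dispersions per gene."""

    table: pd.DataFrame  # columns: mean, raw, trend, tagwise
    prior_df: float
    residual_df: float


def estimate_dispersion(
    cm: CountMatrix,
    factors: NormFactors,
    design: pd.Series | None = None,
    prior_df: float = 4.0,
) -> DispersionFit:
    """Tagwise NB dispersion: method-of-moments raw estimates shrunk
    toward a lowess mean-dispersion trend.

    Counts are put on a common scale (divided by relative effective
    library size); per gene the pooled within-group moment estimator
    phi = sum_k (n_k-1)(s2_k - m_k) / sum_k (n_k-1) m_k^2 solves
    var = mu + phi mu^2; negative estimates clip to 0.  The trend is a
    lowess fit of log dispersion on log mean, and the tagwise value is
    the prior-df weighted combination (d0*trend + df*raw)/(d0+df), which
    always lies between raw and trend.
    """
    if design is None:
        design = pd.Series("all", index=cm.samples)
    design = design.loc[cm.samples]
    eff = factors.effective.loc[cm.samples].to_numpy(dtype=float)
    z = cm.counts.to_numpy(dtype=float) / (eff / eff.mean())
    groups = [np.where((design == g).to_numpy())[0] for g in design.unique()]
    groups = [g for g in groups if len(g) >= 2]
    if not groups:
        raise ValueError("all groups are singletons; dispersion is inestimable")
    num = np.zeros(z.shape[0])
    den = np.zeros(z.shape[0])
    df = 0.0
    for idx in groups:
        sub = z[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        w = len(idx) - 1
        num += w * (v - m)
        den += w * m**2
        df += w
    mean_all = z.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(den > 0, num / den, 0.0)
    raw = np.clip(raw, 0.0, None)
    floor = 1e-4
    lx = np.log(np.maximum(mean_all, 1e-8))
    ly = np.log(raw + floor)
    fit = lowess(ly, lx, frac=0.5, return_sorted=False)
    trend = np.clip(np.exp(fit) - floor, 0.0, None)
    tagwise = (prior_df * trend + df * raw) / (prior_df + df)
    table = pd.DataFrame(
        {"mean": mean_all, "raw": raw, "trend": trend, "tagwise": tagwise},
        index=cm.genes,
    )
    return DispersionFit(table, prior_df=prior_df, residual_df=df)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (y > 0)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return y


def _moderate_var(
    s2: np.ndarray,
    df: float,
    prior_df: float | str = "auto",
    covariate: np.ndarray | None = None,
):
    """Empirical-Bayes variance shrinkage with an optional
    mean-expression trend.

    With ``prior_df='auto'`` the prior degrees of freedom d0 and prior
    variance s0^2 are estimated by moment matching on log s^2 (the
    scaled-F model behind moderated t statistics), so homogeneous
    variances get strong shrinkage and heterogeneous ones little; a
    numeric ``prior_df`` fixes d0.  When ``covariate`` (typically mean
    log-CPM) is given, the prior variance follows a lowess trend in it
    rather than a single constant, which absorbs the count-data
    mean-variance relationship.  Returns (posterior variances, total
    degrees of freedom).
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2 > 0
    if not pos.any():
        return np.zeros_like(s2), df
    z = np.log(s2[pos])
    # bias correction: E[log s^2] = log sigma^2 + digamma(df/2) - log(df/2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    if covariate is not None and e.size > 30:
        cov = np.asarray(covariate, dtype=float)[pos]
        trend = lowess(e, cov, frac=0.4, return_sorted=False)
        resid = e - trend
    else:
        trend = np.full_like(e, float(np.mean(e)))
        resid = e - trend
    if prior_df == "auto":
        var_e = float(np.var(resid, ddof=1)) if resid.size > 1 else 0.0
        gap = var_e - float(special.polygamma(1, df / 2.0))
        d0 = 2.0 * _trigamma_inverse(gap) if gap > 0 else np.inf
    else:
        d0 = float(prior_df)
    s0_log = np.full(s2.shape, float(np.mean(e)))
    s0_log[pos] = trend
    if np.isinf(d0):
        return np.exp(s0_log), 1e6
    s0 = np.exp(s0_log + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    post = (d0 * s0 + df * s2) / (d0 + df)
    return post, d0 + df


def paired_de(
    cm: CountMatrix,
    factors: NormFactors,
    prior_df: float | str = "auto",
    prior_count: float = 0.5,
    condition_pos: str = "tumor",
    condition_neg: str = "normal",
) -> DEResult:
    """Moderated paired test of ``condition_pos`` vs ``condition_neg``.

    log2FC is the mean per-pair log2-CPM difference; significance comes
    from a one-sample moderated t across pairs; the empirical-Bayes
    variance prior (d0, s0^2) is estimated from the data by default
    (``prior_df='auto'``) or fixed via ``prior_df``; BH-FDR over all
    tested genes.
    """
    meta = cm.meta
    if "pair_id" not in meta.columns or meta["pair_id"].isna().any():
        raise ValueError("every sample needs a pair_id for paired DE")
    expr = log_cpm(cm, factors, prior_count=prior_count)
    diffs = []
    for pid, grp in meta.groupby("pair_id"):
        pos = grp.index[grp["condition"] == condition_pos]
        neg = grp.index[grp["condition"] == condition_neg]
        if len(pos) != 1 or len(neg) != 1:
            raise ValueError(f"pair {pid!r} is incomplete")
        diffs.append(expr[pos[0]] - expr[neg[0]])
    if len(diffs) < 3:
        raise ValueError("paired DE needs at least 3 complete pairs")
    d = pd.concat(diffs, axis=1).to_numpy()
    n = d.shape[1]
    lfc = d.mean(axis=1)
    s2 = d.var(axis=1, ddof=1)
    post, dof = _moderate_var(s2, n - 1, prior_df, covariate=expr.mean(axis=1).to_numpy())
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / np.sqrt(post / n)
    t = np.where(np.isfinite(t), t, 0.0)
    p = 2 * stats.t.sf(np.abs(t), dof)
    table = pd.DataFrame(
        {"log2FC": lfc, "p": p, "fdr": bh_fdr(p), "call": "ns"}, index=cm.genes
    )
    return call_degs(DEResult(table))


def call_degs(
    de: DEResult,
    fdr_cut: float = 0.01,
    lfc_cut: float = 1.0,
    relax_fdr: float = 0.05,
    relax_min: int = 50,
) -> DEResult:
    """Apply the DEG rule FDR < fdr_cut and |log2FC| > lfc_cut.

    If fewer than ``relax_min`` genes come out up- or down-regulated,
    the FDR threshold is relaxed to ``relax_fdr`` and calls recomputed
    (the relaxation flag is set even when the relaxed set is empty).
    """
    t = de.table.copy()

    def _apply(cut: float) -> pd.Series:
        call = pd.Series("ns", index=t.index)
        sig = t["fdr"] < cut
        call[sig & (t["log2FC"] > lfc_cut)] = "up"
        call[sig & (t["log2FC"] < -lfc_cut)] = "down"
        return call

    call = _apply(fdr_cut)
    relaxed = False
    if relax_fdr is not None and (
        (call == "up").sum() < relax_min or (call == "down").sum() < relax_min
    ):
        call = _apply(relax_fdr)
        relaxed = True
    t["call"] = call
    active = relax_fdr if relaxed else fdr_cut
    return DEResult(t, fdr_cut=active, lfc_cut=lfc_cut, relaxation_applied=relaxed)
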