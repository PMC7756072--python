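"""Time-dependent modeled control for the injury time course.

Sham-operated fish control for surgery effects, but their influence
should fade as the wound heals; healthy fish are the long-run
reference.  The modeled control blends the two with an exponentially
decaying sham weight w(t) = exp(-t/tau): at t=0 the control is all
sham, for t >> tau it is all healthy.  Per-timepoint log2 fold changes
of injured fish against this control, with a weighted moderated test,
give the trajectory matrix that feeds soft clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .counts import CountMatrix, NormFactors, log_cpm
from .diffexp import _moderate_var, bh_fdr


@dataclass
class ControlModel:
    """Exponential-decay weighting of sham vs healthy controls."""

    tau: float  # days

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    def sham_weight(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if (t < 0).any():
            raise ValueError("negative timepoint")
        return np.exp(-t / self.tau)

    def weights(self, timepoints) -> pd.DataFrame:
        w = self.sham_weight(timepoints)
        return pd.DataFrame(
            {"sham": w, "healthy": 1.0 - w}, index=pd.Index(timepoints, name="timepoint")
        )


def control_weights(timepoints, tau: float) -> ControlModel:
    """Build the exponential-recovery control model; per-timepoint
    weights are available as ``model.weights(timepoints)``."""
    model = ControlModel(tau=tau)
    model.weights(timepoints)  # validates timepoints
    return model


@dataclass
class TrajectoryMatrix:
    """Gene x timepoint log2FC (injured vs modeled control) with
    companion p and FDR tables, all on the configured timepoint grid."""

    lfc: pd.DataFrame
    p: pd.DataFrame
    fdr: pd.DataFrame

    @property
    def timepoints(self) -> list:
        return list(self.lfc.columns)


def timecourse_de(
    cm: CountMatrix,
    factors: NormFactors,
    model: ControlModel,
    prior_df: float | str = "auto",
    prior_count: float = 0.5,
    sham_fallback: str = "error",
) -> TrajectoryMatrix:
    """Per-timepoint DE of injured fish against the modeled control.

    The control mean is w(t)*mean(sham at t) + (1-w(t))*mean(healthy);
    control replicates enter the test with observation weights spread
    evenly within each control group, so the weighted mean equals that
    blend.  Significance is a two-sample moderated t with the control
    side's effective sample size 1/sum(w_i^2); BH-FDR per timepoint.

    With ``sham_fallback='healthy'`` a timepoint lacking sham samples
    renormalizes the control onto healthy fish; the default raises when
    the sham weight is non-negligible there.
    """
    meta = cm.meta
    injured = meta[meta["condition"] == "injured"]
    healthy_idx = meta.index[meta["condition"] == "healthy"]
    if len(healthy_idx) < 2:
        raise ValueError("need at least 2 healthy samples")
    timepoints = sorted(injured["timepoint"].dropna().unique())
    if not timepoints:
        raise ValueError("no injured samples with timepoints")
    expr = log_cpm(cm, factors, prior_count=prior_count)
    x = expr.to_numpy()
    cols = {c: i for i, c in enumerate(expr.columns)}
    lfc, pmat = {}, {}
    for t in timepoints:
        inj = injured.index[injured["timepoint"] == t]
        if len(inj) == 0:
            continue
        sham = meta.index[(meta["condition"] == "sham") & (meta["timepoint"] == t)]
        w_sham = float(model.sham_weight(t))
        if len(sham) == 0:
            if w_sham > 1e-12 and sham_fallback != "healthy":
                raise ValueError(
                    f"timepoint {t}: no sham samples but sham weight {w_sham:.3g}; "
                    "set sham_fallback='healthy' to renormalize onto healthy"
                )
            w_sham = 0.0
        ctrl_samples = list(sham) + list(healthy_idx)
        w = np.concatenate(
            [
                np.full(len(sham), w_sham / max(len(sham), 1)),
                np.full(len(healthy_idx), (1 - w_sham) / len(healthy_idx)),
            ]
        )
        w = w / w.sum()
        xi = x[:, [cols[s] for s in inj]]
        xc = x[:, [cols[s] for s in ctrl_samples]]
        m1 = xi.mean(axis=1)
        m0 = xc @ w
        n1 = xi.shape[1]
        n_eff = 1.0 / np.sum(w**2)
        # weighted control variance with unbiased normalization
        resid2 = (xc - m0[:, None]) ** 2
        denom = 1.0 - np.sum(w**2)
        s0 = (resid2 @ w) / denom if denom > 1e-12 else np.zeros_like(m0)
        df1 = max(n1 - 1, 0)
        df0 = max(n_eff - 1.0, 0.0)
        if df1 + df0 <= 0:
            raise ValueError(f"timepoint {t}: no residual degrees of freedom")
        s1 = xi.var(axis=1, ddof=1) if n1 > 1 else np.zeros_like(m1)
        s2 = (df1 * s1 + df0 * s0) / (df1 + df0)
        post, dof = _moderate_var(s2, df1 + df0, prior_df, covariate=x.mean(axis=1))
        se = np.sqrt(post * (1.0 / n1 + 1.0 / n_eff))
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = (m1 - m0) / se
        tstat = np.where(np.isfinite(tstat), tstat, 0.0)
        lfc[t] = m1 - m0
        pmat[t] = 2 * stats.t.sf(np.abs(tstat), dof)
    lfc_df = pd.DataFrame(lfc, index=cm.genes)
    p_df = pd.DataFrame(pmat, index=cm.genes)
    fdr_df = p_df.apply(lambda col: bh_fdr(col.to_numpy()), axis=0, result_type="broadcast")
    return TrajectoryMatrix(lfc_df, p_df, fdr_df)


def union_degs(
    traj: TrajectoryMatrix, fdr_cut: float = 0.01, lfc_cut: float = 1.0
) -> pd.Index:
    """Genes significant (FDR < cut and |log2FC| > cut) at >= 1 timepoint."""
    if traj.lfc.empty:
        return pd.Index([])
    sig = (traj.fdr < fdr_cut) & (traj.lfc.abs() > lfc_cut)
    return traj.lfc.index[sig.any(axis=1)]
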