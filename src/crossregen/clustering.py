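"""Soft clustering of z-scored log2FC trajectories (fuzzy c-means) and
extraction of high-membership core genes."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamic import TrajectoryMatrix


def zscore_rows(traj: TrajectoryMatrix | pd.DataFrame) -> pd.DataFrame:
    """Standardize each gene's trajectory to mean 0, sd 1.

    Constant rows cannot be standardized and are excluded with a
    warning.  Idempotent up to floating-point error.
    """
    df = traj.lfc if isinstance(traj, TrajectoryMatrix) else traj
    vals = df.to_numpy(dtype=float)
    sd = vals.std(axis=1, ddof=0)
    keep = sd > 0
    if (~keep).any():
        warnings.warn(f"excluding {(~keep).sum()} constant trajectories from z-scoring")
    vals = vals[keep]
    z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, ddof=0, keepdims=True)
    return pd.DataFrame(z, index=df.index[keep], columns=df.columns)


@dataclass
class ClusterAssignment:
    """Fuzzy membership matrix (rows sum to 1), cluster centers, and
    the per-cluster core-gene sets above the membership cutoff."""

    membership: pd.DataFrame  # gene x cluster
    centers: pd.DataFrame  # cluster x timepoint
    objective: list[float]
    converged: bool
    c: int
    m: float

    def core_sets(self, threshold: float = 0.7) -> dict[str, list[str]]:
        return core_genes(self, threshold)


def _kmeanspp(x: np.ndarray, c: int, rng: np.random.Generator) -> np.ndarray:
    centers = [x[rng.integers(x.shape[0])]]
    for _ in range(1, c):
        d2 = np.min(
            ((x[:, None, :] - np.array(centers)[None, :, :]) ** 2).sum(-1), axis=1
        )
        total = d2.sum()
        if total <= 0:
            centers.append(x[rng.integers(x.shape[0])])
            continue
        centers.append(x[rng.choice(x.shape[0], p=d2 / total)])
    return np.array(centers)


def _fcm_once(x, c, m, rng, tol, max_iter):
    centers = _kmeanspp(x, c, rng)
    obj_seq = []
    converged = False
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
        zero = d2 <= 1e-300
        # u_gc = 1 / sum_k (d_gc/d_gk)^{2/(m-1)}  ==  d_gc^{-1/(m-1)} / sum_k d_gk^{-1/(m-1)}
        with np.errstate(divide="ignore", over="ignore"):
            inv = d2 ** (-1.0 / (m - 1.0))
        u = np.where(np.isfinite(inv), inv, 0.0)
        rows_zero = zero.any(axis=1)
        u[rows_zero] = zero[rows_zero].astype(float)
        u = u / u.sum(axis=1, keepdims=True)
        um = u**m
        obj_seq.append(float((um * d2).sum()))
        new_centers = (um.T @ x) / um.sum(axis=0)[:, None]
        shift = np.abs(new_centers - centers).max()
        centers = new_centers
        if shift < tol:
            converged = True
            break
    d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    with np.errstate(divide="ignore", over="ignore"):
        inv = d2 ** (-1.0 / (m - 1.0))
    u = np.where(np.isfinite(inv), inv, 0.0)
    zero = d2 <= 1e-300
    rows_zero = zero.any(axis=1)
    u[rows_zero] = zero[rows_zero].astype(float)
    u = u / u.sum(axis=1, keepdims=True)
    obj_seq.append(float((u**m * d2).sum()))
    return u, centers, obj_seq, converged


def fuzzy_cmeans(
    z: pd.DataFrame,
    c: int = 5,
    m: float = 1.25,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 1000,
    n_init: int = 10,
) -> ClusterAssignment:
    """Fuzzy c-means on row-standardized trajectories.

    Alternates the standard membership update
    u_gc = 1 / sum_k (d_gc/d_gk)^(2/(m-1)) (Euclidean d; a point
    coincident with a center takes full membership there) and the
    weighted center update until the largest center shift drops below
    ``tol``.  ``n_init`` k-means++-style restarts are run from streams
    of ``seed``; the solution with the lowest objective sum(u^m d^2) is
    kept.  The default fuzzifier m=1.25 suits standardized data, where
    m=2 pushes memberships toward uniform.
    """
    if c < 2:
        raise ValueError("c must be >= 2")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    if z.shape[0] < c:
        raise ValueError("need at least c genes")
    x = z.to_numpy(dtype=float)
    best = None
    for child in np.random.SeedSequence(seed).spawn(n_init):
        rng = np.random.default_rng(child)
        u, centers, obj, conv = _fcm_once(x, c, m, rng, tol, max_iter)
        if best is None or obj[-1] < best[2][-1]:
            best = (u, centers, obj, conv)
    u, centers, obj, conv = best
    if not conv:
        warnings.warn("fuzzy c-means did not converge within max_iter")
    cluster_ids = [f"cluster{i + 1}" for i in range(c)]
    return ClusterAssignment(
        membership=pd.DataFrame(u, index=z.index, columns=cluster_ids),
        centers=pd.DataFrame(centers, index=cluster_ids, columns=z.columns),
        objective=obj,
        converged=conv,
        c=c,
        m=m,
    )


def core_genes(assign: ClusterAssignment, threshold: float = 0.7) -> dict[str, list[str]]:
    """Per-cluster lists of genes whose maximum membership exceeds
    ``threshold`` (strict); ties on the maximum leave a gene unassigned."""
    u = assign.membership
    out: dict[str, list[str]] = {c: [] for c in u.columns}
    vals = u.to_numpy()
    mx = vals.max(axis=1)
    argmx = vals.argmax(axis=1)
    n_at_max = (vals == mx[:, None]).sum(axis=1)
    for i, gene in enumerate(u.index):
        if mx[i] > threshold and n_at_max[i] == 1:
            out[u.columns[argmx[i]]].append(gene)
    return out
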