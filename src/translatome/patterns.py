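"""Temporal expression clustering and correspondence analysis.

k-means runs on replicate-averaged log-expression trajectories of the DEG
union, one row per gene and one column per time point, z-scaled per gene so
clusters capture trajectory shape rather than expression level.  The number
of clusters defaults to 9; the full within-cluster sum-of-squares curve is
recorded so the elbow can be inspected (and an automatic max-curvature pick
is available).

Correspondence analysis decomposes the chi-square structure of the count
matrix: with P = X/N, row/column masses r, c, the standardised residuals
S = D_r^{-1/2}(P - r c^T)D_c^{-1/2} are SVD-factorised; squared singular
values are the principal inertias and sum to chi-square/N.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import kmeans_plusplus


@dataclasses.dataclass
class ClusterModel:
    k: int
    assignments: pd.Series           # gene -> cluster id (0-based)
    centroids: np.ndarray            # k x T
    wss: float
    wss_curve: dict[int, float]
    seed: int
    n_restarts: int
    elbow_k: int | None = None


@dataclasses.dataclass
class CoaResult:
    eigenvalues: np.ndarray          # principal inertias, non-increasing
    row_coords: pd.DataFrame         # gene principal coordinates
    col_coords: pd.DataFrame         # sample principal coordinates
    total_inertia: float


def _lloyd(x: np.ndarray, k: int, rng: np.random.Generator,
           max_iter: int = 300, tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray, float]:
    """One k-means run: k-means++ seeding then Lloyd iterations.

    WSS is checked to be non-increasing across iterations (a violated check
    would indicate a broken update step).
    """
    centers, _ = kmeans_plusplus(x, n_clusters=k,
                                 random_state=int(rng.integers(2**31 - 1)))
    prev = np.inf
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        wss = float(d2[np.arange(len(x)), labels].sum())
        if wss > prev + 1e-9:
            raise AssertionError("k-means WSS increased across a Lloyd iteration")
        if prev - wss < tol:
            prev = wss
            break
        prev = wss
        for j in range(k):
            sel = labels == j
            if sel.any():
                centers[j] = x[sel].mean(axis=0)
            else:  # re-seed an empty cluster at the worst-fitted point
                centers[j] = x[int(d2.min(axis=1).argmax())]
    return labels, centers, prev


def timepoint_means(mat: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Average replicate columns per time point (sheet order preserved)."""
    tps = list(dict.fromkeys(samples["timepoint"].astype(str)))
    return pd.DataFrame({tp: mat[samples.index[samples["timepoint"].astype(str) == tp]].mean(axis=1)
                         for tp in tps})


def elbow_k(wss_curve: dict[int, float]) -> int:
    """Max-curvature (discrete second difference) pick from a WSS curve."""
    ks = sorted(wss_curve)
    if len(ks) < 3:
        return ks[-1]
    w = np.array([wss_curve[k] for k in ks])
    curvature = w[:-2] - 2 * w[1:-1] + w[2:]
    return ks[1 + int(np.argmax(curvature))]


def kmeans_patterns(logcounts: pd.DataFrame, samples: pd.DataFrame,
                    deg_union: Sequence[str], k: int | None = 9,
                    k_range: Sequence[int] = tuple(range(2, 16)), seed: int = 0,
                    n_restarts: int = 25, scale: bool = True) -> ClusterModel:
    """Cluster replicate-averaged trajectories of the DEG union.

    Genes with zero trajectory variance are dropped (they carry no shape).
    ``k=None`` lets the elbow heuristic choose within ``k_range``.
    """
    traj = timepoint_means(logcounts, samples)
    genes = [g for g in deg_union if g in traj.index]
    traj = traj.loc[genes]
    x = traj.to_numpy(dtype=float)
    if scale:
        sd = x.std(axis=1, ddof=0)
        flat = sd == 0
        if flat.any():
            warnings.warn(f"dropping {int(flat.sum())} constant-expression genes")
            x, genes = x[~flat], [g for g, f in zip(genes, flat) if not f]
            sd = sd[~flat]
        x = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    if len(genes) == 0:
        raise ValueError("no genes left to cluster")

    rng = np.random.default_rng(seed)
    wss_curve: dict[int, float] = {}
    best_by_k: dict[int, tuple[np.ndarray, np.ndarray, float]] = {}
    ks = sorted(set(list(k_range) + ([k] if k else [])))
    for kk in ks:
        if kk > len(genes):
            continue
        best = None
        for _ in range(n_restarts):
            labels, centers, wss = _lloyd(x, kk, rng)
            if best is None or wss < best[2]:
                best = (labels, centers, wss)
        best_by_k[kk] = best
        wss_curve[kk] = best[2]

    auto = elbow_k(wss_curve)
    chosen = k if k is not None else auto
    if chosen not in best_by_k:
        raise ValueError(f"k={chosen} exceeds the {len(genes)} clusterable genes")
    labels, centers, wss = best_by_k[chosen]
    return ClusterModel(k=chosen, assignments=pd.Series(labels, index=genes),
                        centroids=centers, wss=wss, wss_curve=wss_curve,
                        seed=seed, n_restarts=n_restarts, elbow_k=auto)


def coa(counts: pd.DataFrame) -> CoaResult:
    """Correspondence analysis of a non-negative matrix (genes x samples)."""
    x = counts.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValueError("COA requires a non-negative matrix")
    rows_zero = counts.index[x.sum(axis=1) == 0]
    cols_zero = counts.columns[x.sum(axis=0) == 0]
    if len(rows_zero) or len(cols_zero):
        raise ValueError(f"zero margins: rows {list(rows_zero[:5])}, "
                         f"columns {list(cols_zero[:5])}")
    n = x.sum()
    p = x / n
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    s = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    u, sig, vt = np.linalg.svd(s, full_matrices=False)
    keep = sig > 1e-12
    u, sig, vt = u[:, keep], sig[keep], vt[keep]
    row_pc = (u * sig) / np.sqrt(r)[:, None]
    col_pc = (vt.T * sig) / np.sqrt(c)[:, None]
    axes = [f"axis{i+1}" for i in range(len(sig))]
    return CoaResult(
        eigenvalues=sig**2,
        row_coords=pd.DataFrame(row_pc, index=counts.index, columns=axes),
        col_coords=pd.DataFrame(col_pc, index=counts.columns, columns=axes),
        total_inertia=float((sig**2).sum()),
    )
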