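"""Negative-binomial differential expression for time-point contrasts.

The model for gene g in sample i of group j is
``Y_gi ~ NB(mu_gi, phi_g)`` with ``log mu_gi = log(N_i) + beta_g0 + beta_g1 x_i``
where N_i is the TMM-effective library size and x_i indicates the later time
point.  Dispersions are estimated by maximising the Cox-Reid adjusted profile
likelihood on a log-spaced grid (common = argmax of the summed APL; tagwise
shrinks each gene's APL toward the common curve with ``prior_df`` weight).
Each contrast is tested with a likelihood-ratio test of the group coefficient
against chi-square(1), and Benjamini-Hochberg FDR is applied across the genes
of the contrast.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from . import _nbglm
from .io_formats import CountMatrix
from .quantify import NormFactors, cpm, log_cpm

PHI_MIN, PHI_MAX = 1e-6, 10.0


@dataclasses.dataclass
class DispersionModel:
    common_dispersion: float
    tagwise: pd.Series                     # per-gene phi
    prior_df: float
    trended: pd.Series | None = None       # per-gene trended phi (optional)
    grid: np.ndarray | None = None
    apl_common_curve: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (PHI_MIN <= self.common_dispersion <= PHI_MAX):
            raise ValueError("common dispersion out of range")

    def per_gene(self, gene_ids: Sequence[str]) -> np.ndarray:
        """Tagwise phi aligned to gene_ids; common for genes not estimated."""
        return (self.tagwise.reindex(gene_ids)
                .fillna(self.common_dispersion).to_numpy())


@dataclasses.dataclass
class DegCalls:
    """Up/down DEG sets together with the tested gene universe."""

    up: set
    down: set
    universe: set
    contrast: str = ""
    fraction: str = ""


def filter_expressed(cm: CountMatrix, min_cpm: float = 1.0, min_samples: int = 3) -> CountMatrix:
    """Keep genes with CPM >= min_cpm in >= min_samples samples (order preserved)."""
    c = cpm(cm)
    keep = (c >= min_cpm).sum(axis=1) >= min_samples
    if keep.sum() == 0:
        warnings.warn("no genes pass the expression filter")
    return CountMatrix(cm.counts.loc[keep].copy(), cm.samples.copy())


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, mapped back to input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def _design_matrix(samples: pd.DataFrame, contrast: tuple[str, str]) -> np.ndarray:
    tp_a, tp_b = contrast
    x = (samples["timepoint"].astype(str) == tp_b).to_numpy(dtype=float)
    return np.column_stack([np.ones_like(x), x])


def _grid(n: int = 41) -> np.ndarray:
    return np.exp(np.linspace(np.log(PHI_MIN), np.log(PHI_MAX), n))


def _parabolic_argmax(logphi: np.ndarray, score: np.ndarray) -> float:
    """Refine a grid argmax with a 3-point parabola in log-phi."""
    i = int(np.argmax(score))
    if i == 0 or i == len(logphi) - 1:
        return float(logphi[i])
    x0, x1, x2 = logphi[i - 1], logphi[i], logphi[i + 1]
    y0, y1, y2 = score[i - 1], score[i], score[i + 1]
    denom = (y0 - 2 * y1 + y2)
    if denom >= 0 or abs(denom) < 1e-12:
        return float(x1)
    shift = 0.5 * (y0 - y2) / denom
    return float(np.clip(x1 + shift * (x1 - x0), x0, x2))


def estimate_dispersion(cm: CountMatrix, groups: Sequence[str] | None = None,
                        norm: NormFactors | None = None, prior_df: float = 10.0,
                        trended: bool = True, grid_size: int = 41,
                        min_genes_for_trend: int = 50) -> DispersionModel:
    """Common, trended and tagwise NB dispersion via Cox-Reid APL.

    The common value maximises the APL summed over genes; the trended value
    maximises the abundance-local APL (genes binned by average logCPM, bin
    argmaxes loess-smoothed); tagwise values maximise each gene's APL plus
    ``prior_df / residual_df`` times the shared (local, or common when
    ``trended=False`` or too few genes) curve.  ``groups`` defaults to the
    sample time points.  Requires positive residual degrees of freedom.
    """
    samples = cm.samples
    if groups is None:
        groups = samples["timepoint"].astype(str).tolist()
    groups = list(groups)
    levels = list(dict.fromkeys(groups))
    n, p = len(groups), len(levels)
    resid_df = n - p
    if resid_df <= 0:
        raise ValueError("no residual degrees of freedom to estimate dispersion")
    X = np.column_stack([(np.array(groups) == lv).astype(float) for lv in levels])

    nf = norm if norm is not None else NormFactors.unit(cm)
    offset = np.log(nf.effective_sizes.to_numpy(dtype=float))
    y = cm.counts.to_numpy(dtype=float)
    used = y.sum(axis=1) > 0
    y_used = y[used]

    grid = _grid(grid_size)
    logphi = np.log(grid)
    apl = np.empty((y_used.shape[0], grid.size))
    for k, phi in enumerate(grid):
        apl[:, k] = _nbglm.cox_reid_apl(y_used, X, offset, phi)

    common_curve = apl.mean(axis=0)
    common = float(np.exp(_parabolic_argmax(logphi, common_curve)))
    common = float(np.clip(common, PHI_MIN, PHI_MAX))

    trended_series = None
    shared = np.broadcast_to(common_curve, apl.shape)
    if trended and y_used.shape[0] >= min_genes_for_trend:
        from statsmodels.nonparametric.smoothers_lowess import lowess

        ave = log_cpm(cm, nf).mean(axis=1).to_numpy()[used]
        nbins = max(min(10, y_used.shape[0] // 50), 2)
        qs = np.quantile(ave, np.linspace(0, 1, nbins + 1))
        bin_idx = np.clip(np.searchsorted(qs[1:-1], ave, side="right"), 0, nbins - 1)
        bin_curves = np.empty((nbins, grid.size))
        bin_phi = np.empty(nbins)
        bin_ave = np.empty(nbins)
        for b in range(nbins):
            sel = bin_idx == b
            bin_curves[b] = apl[sel].mean(axis=0) if sel.any() else common_curve
            bin_phi[b] = np.exp(_parabolic_argmax(logphi, bin_curves[b]))
            bin_ave[b] = ave[sel].mean() if sel.any() else qs[b]
        sm = lowess(np.log(bin_phi), bin_ave, frac=2 / 3, return_sorted=True)
        phi_trend = np.exp(np.interp(ave, sm[:, 0], sm[:, 1]))
        phi_trend = np.clip(phi_trend, PHI_MIN, PHI_MAX)
        trended_series = pd.Series(np.full(y.shape[0], common), index=cm.gene_ids)
        trended_series[used] = phi_trend
        shared = bin_curves[bin_idx]      # abundance-local shrinkage target

    # tagwise: maximise APL_g + (prior_df / resid_df) * shared curve
    weight = prior_df / resid_df
    score = apl + weight * shared
    tag = np.empty(y_used.shape[0])
    for g in range(y_used.shape[0]):
        tag[g] = np.exp(_parabolic_argmax(logphi, score[g]))
    tag = np.clip(tag, PHI_MIN, PHI_MAX)

    tagwise = pd.Series(np.full(y.shape[0], common), index=cm.gene_ids)
    tagwise[used] = tag
    return DispersionModel(common_dispersion=common, tagwise=tagwise,
                           prior_df=prior_df, trended=trended_series,
                           grid=grid, apl_common_curve=common_curve)


def de_test(cm: CountMatrix, norm: NormFactors, disp: DispersionModel,
            contrast: tuple[str, str], fraction: str | None = None,
            dispersion: str = "tagwise") -> pd.DataFrame:
    """NB GLM likelihood-ratio test of one consecutive-time-point contrast.

    Returns one row per gene with log2FC (later vs earlier), average logCPM,
    LRT statistic, p and BH FDR.  Genes with zero counts in every sample of
    the contrast are reported with log2FC 0 and p 1 without fitting.
    """
    tp_a, tp_b = contrast
    sub = cm.contrast_samples(contrast, fraction)
    if fraction is None and len(set(sub.samples["fraction"])) > 1:
        raise ValueError("de_test mixes fractions; pass fraction explicitly")
    for tp in contrast:
        if not (sub.samples["timepoint"].astype(str) == tp).any():
            raise ValueError(f"time point {tp} absent in fraction {fraction}")

    eff = norm.effective_sizes.reindex(sub.samples.index)
    if eff.isna().any():
        raise ValueError("norm factors missing for contrast samples")
    offset = np.log(eff.to_numpy(dtype=float))
    X = _design_matrix(sub.samples, contrast)
    X_null = X[:, :1]

    y = sub.counts.to_numpy(dtype=float)
    nonzero = y.sum(axis=1) > 0
    phi_all = (disp.per_gene(sub.gene_ids) if dispersion == "tagwise"
               else np.full(y.shape[0], disp.common_dispersion))

    log2fc = np.zeros(y.shape[0])
    stat = np.zeros(y.shape[0])
    pvals = np.ones(y.shape[0])
    flag = np.array(["all_zero"] * y.shape[0], dtype=object)

    if nonzero.any():
        s, full, null = _nbglm.lrt(y[nonzero], X, X_null, offset, phi_all[nonzero])
        log2fc[nonzero] = full.beta[:, 1] / np.log(2)
        stat[nonzero] = s
        pvals[nonzero] = scipy.stats.chi2.sf(s, df=1)
        fl = np.where(full.converged & null.converged, "ok", "not_converged")
        flag[nonzero] = fl

    ave = log_cpm(sub, NormFactors(norm.factors.reindex(sub.samples.index),
                                   norm.library_sizes.reindex(sub.samples.index))
                  ).mean(axis=1).to_numpy()
    out = pd.DataFrame({
        "gene_id": sub.gene_ids,
        "fraction": fraction if fraction is not None else "all",
        "contrast": f"{tp_a}_vs_{tp_b}",
        "log2FC": log2fc,
        "avg_logCPM": ave,
        "lrt_stat": stat,
        "p": pvals,
        "fdr": bh_fdr(pvals),
        "flag": flag,
    })
    return out


def call_degs(results: pd.DataFrame, fdr_max: float = 0.05,
              abs_log2fc_min: float = 2.0) -> DegCalls:
    """Closed-threshold DEG sets: up = fdr <= fdr_max and log2FC >= cutoff."""
    sig = results["fdr"] <= fdr_max
    up = set(results.loc[sig & (results["log2FC"] >= abs_log2fc_min), "gene_id"])
    down = set(results.loc[sig & (results["log2FC"] <= -abs_log2fc_min), "gene_id"])
    contrast = results["contrast"].iloc[0] if len(results) else ""
    fraction = results["fraction"].iloc[0] if len(results) else ""
    return DegCalls(up=up, down=down, universe=set(results["gene_id"]),
                    contrast=contrast, fraction=fraction)
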