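"""Library-size normalisation (TMM) and CPM / RPKM / logCPM computation.

TMM (trimmed mean of M-values) rescales raw library sizes so that the bulk of
genes shows no fold change between samples: for each sample, per-gene log2
ratios (M) versus a reference sample are trimmed (30% each tail, plus 5% each
tail on average abundance A), averaged with inverse delta-method variance
weights, and the resulting factors are rescaled to geometric mean one.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .io_formats import CountMatrix


@dataclasses.dataclass
class NormFactors:
    """Per-sample TMM factors and raw library sizes (effective = product)."""

    factors: pd.Series
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("TMM factors must be positive")
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")

    @property
    def effective_sizes(self) -> pd.Series:
        return self.factors * self.library_sizes

    @classmethod
    def unit(cls, cm: CountMatrix) -> "NormFactors":
        lib = cm.library_sizes()
        return cls(pd.Series(1.0, index=lib.index), lib)


def cpm(cm: CountMatrix, norm: NormFactors | None = None) -> pd.DataFrame:
    """Counts per million; uses TMM-effective library sizes when given."""
    lib = norm.effective_sizes if norm is not None else cm.library_sizes().astype(float)
    if (lib <= 0).any():
        zero = list(lib.index[lib <= 0])
        raise ValueError(f"zero library size for samples: {zero}")
    return cm.counts / lib * 1e6


def rpkm(cm: CountMatrix, annot: pd.DataFrame, norm: NormFactors | None = None) -> pd.DataFrame:
    """Reads per kilobase of gene length per million mapped reads."""
    missing = set(cm.gene_ids) - set(annot.index)
    if missing:
        raise ValueError(f"genes missing from annotation: {sorted(missing)[:5]}")
    kb = annot.loc[cm.gene_ids, "length_bp"].astype(float) / 1000.0
    return cpm(cm, norm).div(kb, axis=0)


def log_cpm(cm: CountMatrix, norm: NormFactors | None = None, prior_count: float = 2.0) -> pd.DataFrame:
    """log2 CPM with a library-size-scaled prior count (finite at zero counts).

    Matches the usual aveLogCPM-style convention: the prior for sample j is
    ``prior_count * effective_j / mean(effective)`` added to the count, with
    the library size inflated by twice the scaled prior.
    """
    lib = (norm.effective_sizes if norm is not None else cm.library_sizes()).astype(float)
    scaled_prior = prior_count * lib / lib.mean()
    adj_lib = lib + 2.0 * scaled_prior
    shifted = cm.counts.add(scaled_prior, axis=1)
    return np.log2(shifted.div(adj_lib, axis=1) * 1e6)


def _upper_quartile_cpm(counts: np.ndarray, lib: np.ndarray) -> np.ndarray:
    c = counts / lib * 1e6
    return np.percentile(c, 75, axis=0)


def tmm_factors(cm: CountMatrix, ref_sample: str | None = None,
                trim_m: float = 0.30, trim_a: float = 0.05,
                min_genes: int = 10) -> NormFactors:
    """Trimmed-mean-of-M-values scaling factors.

    For sample s versus reference r with library sizes N_s, N_r:
    M_g = log2((x_gs/N_s)/(x_gr/N_r)), A_g = 0.5*log2((x_gs/N_s)(x_gr/N_r)),
    computed over genes with positive counts in both samples.  Genes in the
    top/bottom ``trim_m`` of M and ``trim_a`` of A are discarded; the factor
    is 2**(weighted mean of surviving M) with delta-method weights
    1/((N_s-x_s)/(N_s x_s) + (N_r-x_r)/(N_r x_r)).  Factors are rescaled to
    geometric mean one.  The reference is the sample whose upper-quartile CPM
    is closest to the mean upper quartile, unless given explicitly.
    """
    counts = cm.counts.to_numpy(dtype=float)
    lib = cm.library_sizes().to_numpy(dtype=float)
    sample_ids = list(cm.counts.columns)
    if len(sample_ids) < 2:
        raise ValueError("TMM needs at least 2 samples")
    if (lib <= 0).any():
        raise ValueError("every sample needs positive total counts")

    if ref_sample is None:
        uq = _upper_quartile_cpm(counts, lib)
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = sample_ids.index(ref_sample)

    xr = counts[:, ref_idx]
    nr = lib[ref_idx]
    factors = np.ones(len(sample_ids))
    for j, sid in enumerate(sample_ids):
        if j == ref_idx:
            continue
        xs = counts[:, j]
        ns = lib[j]
        ok = (xs > 0) & (xr > 0)
        if ok.sum() < min_genes:
            warnings.warn(f"TMM: <{min_genes} usable genes for {sid}; factor set to 1")
            continue
        ps, pr = xs[ok] / ns, xr[ok] / nr
        m = np.log2(ps / pr)
        a = 0.5 * np.log2(ps * pr)
        w = 1.0 / ((ns - xs[ok]) / (ns * xs[ok]) + (nr - xr[ok]) / (nr * xr[ok]))
        n_ok = ok.sum()
        lo_m, hi_m = np.floor(n_ok * trim_m) + 1, n_ok - np.floor(n_ok * trim_m)
        lo_a, hi_a = np.floor(n_ok * trim_a) + 1, n_ok - np.floor(n_ok * trim_a)
        rank_m = pd.Series(m).rank().to_numpy()
        rank_a = pd.Series(a).rank().to_numpy()
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if keep.sum() < min_genes:
            warnings.warn(f"TMM: <{min_genes} genes left after trimming for {sid}; factor set to 1")
            continue
        factors[j] = 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))

    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormFactors(pd.Series(factors, index=sample_ids),
                       pd.Series(lib, index=sample_ids))
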