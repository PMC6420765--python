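"""Polysome-occupancy analysis: polysome/free RPKM ratios and shift tests.

The descriptive ratio is mean polysome RPKM / mean free RPKM per time point
(replicate means).  The inferential shift between two time points is the
fraction x time interaction of a negative-binomial GLM on counts:

    log mu = log(N_i) + b0 + b1*poly_i + b2*late_i + b3*poly_i*late_i

Gene length cancels in the interaction, so offsets need only the effective
library size.  b3/ln2 estimates the change in log2 occupancy ratio;
``recruited`` means FDR <= 0.05 and delta >= 2, ``dissociated`` the mirror.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from . import _nbglm
from .diffexp import DispersionModel, bh_fdr
from .io_formats import CountMatrix
from .quantify import NormFactors


def occupancy_ratio(rpkm: pd.DataFrame, samples: pd.DataFrame,
                    free_floor: float = 0.1) -> pd.DataFrame:
    """Per-gene, per-time-point polysome/free ratio of replicate-mean RPKM.

    Time points whose free-fraction mean RPKM is below ``free_floor`` get NaN
    (the ratio is numerically meaningless there).
    """
    tps = list(dict.fromkeys(samples["timepoint"].astype(str)))
    out = {}
    for tp in tps:
        cols = {}
        for frac in ("free", "polysome"):
            sel = (samples["timepoint"].astype(str) == tp) & (samples["fraction"] == frac)
            if sel.sum() == 0:
                raise ValueError(f"fraction {frac} missing at time point {tp}")
            cols[frac] = rpkm[samples.index[sel]].mean(axis=1)
        ratio = cols["polysome"] / cols["free"]
        ratio[cols["free"] < free_floor] = np.nan
        out[tp] = ratio
    return pd.DataFrame(out)


def occupancy_shift_test(cm: CountMatrix, norm: NormFactors, disp: DispersionModel,
                         contrast: tuple[str, str], fdr_max: float = 0.05,
                         delta_min: float = 2.0, rpkm: pd.DataFrame | None = None,
                         free_floor: float = 0.1,
                         dispersion: str = "tagwise") -> pd.DataFrame:
    """Interaction LRT for occupancy shifts between two time points.

    When an ``rpkm`` matrix is supplied, genes whose free-fraction mean RPKM
    is below ``free_floor`` at either time point are flagged ``low_free`` and
    excluded from recruitment/dissociation calls.
    """
    tp_a, tp_b = contrast
    sub = cm.contrast_samples(contrast)
    fracs = set(sub.samples["fraction"])
    if fracs != {"free", "polysome"}:
        raise ValueError(f"both fractions required, found {sorted(fracs)}")

    poly = (sub.samples["fraction"] == "polysome").to_numpy(dtype=float)
    late = (sub.samples["timepoint"].astype(str) == tp_b).to_numpy(dtype=float)
    X_full = np.column_stack([np.ones_like(poly), poly, late, poly * late])
    X_null = X_full[:, :3]

    eff = norm.effective_sizes.reindex(sub.samples.index)
    offset = np.log(eff.to_numpy(dtype=float))
    y = sub.counts.to_numpy(dtype=float)
    nonzero = y.sum(axis=1) > 0
    phi = (disp.per_gene(sub.gene_ids) if dispersion == "tagwise"
           else np.full(y.shape[0], disp.common_dispersion))

    delta = np.zeros(y.shape[0])
    stat = np.zeros(y.shape[0])
    pvals = np.ones(y.shape[0])
    flag = np.array(["all_zero"] * y.shape[0], dtype=object)
    if nonzero.any():
        s, full, null = _nbglm.lrt(y[nonzero], X_full, X_null, offset, phi[nonzero])
        delta[nonzero] = full.beta[:, 3] / np.log(2)
        stat[nonzero] = s
        pvals[nonzero] = scipy.stats.chi2.sf(s, df=1)
        flag[nonzero] = np.where(full.converged & null.converged, "ok", "not_converged")

    fdr = bh_fdr(pvals)
    call = np.where((fdr <= fdr_max) & (delta >= delta_min), "recruited",
                    np.where((fdr <= fdr_max) & (delta <= -delta_min),
                             "dissociated", "unchanged"))
    call = np.asarray(call, dtype=object)
    call[flag == "not_converged"] = "unchanged"

    out = pd.DataFrame({
        "gene_id": sub.gene_ids,
        "contrast": f"{tp_a}_vs_{tp_b}",
        "delta_log2_ratio": delta,
        "lrt_stat": stat,
        "p": pvals,
        "fdr": fdr,
        "call": call,
        "flag": flag,
    })

    if rpkm is not None:
        ratios = occupancy_ratio(rpkm, sub.samples, free_floor=free_floor)
        out[f"ratio_{tp_a}"] = ratios[tp_a].reindex(out["gene_id"]).to_numpy()
        out[f"ratio_{tp_b}"] = ratios[tp_b].reindex(out["gene_id"]).to_numpy()
        low = out[f"ratio_{tp_a}"].isna() | out[f"ratio_{tp_b}"].isna()
        out.loc[low, "call"] = "unchanged"
        out.loc[low, "flag"] = "low_free"
    return out


def nondeg_occupancy(classes: pd.DataFrame, shifts: pd.DataFrame) -> pd.DataFrame:
    """Partition recruited/dissociated genes by their DEG status.

    Buckets mirror the Venn logic: ``free-only`` (buffered), ``polysome-only``
    (loaded), ``both`` (coordinated or discordant), ``neither`` (not DE).
    """
    if set(classes["contrast"]) != set(shifts["contrast"]):
        raise ValueError("classification and shift tests come from different contrasts")
    status_of = {
        "up_buffered": "free-only", "down_buffered": "free-only",
        "up_loaded": "polysome-only", "down_loaded": "polysome-only",
        "up_coordinated": "both", "down_coordinated": "both",
        "discordant": "both", "not_de": "neither",
    }
    cat = classes.set_index("gene_id")["category"]
    moved = shifts[shifts["call"].isin(["recruited", "dissociated"])]
    rows = []
    for call in ("recruited", "dissociated"):
        sub = moved[moved["call"] == call]
        buckets = sub["gene_id"].map(lambda g: status_of.get(cat.get(g, "not_de")))
        for bucket in ("free-only", "polysome-only", "both", "neither"):
            genes = sorted(sub.loc[buckets == bucket, "gene_id"])
            rows.append((call, bucket, len(genes), ";".join(genes)))
    return pd.DataFrame(rows, columns=["call", "deg_status", "count", "genes"])
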