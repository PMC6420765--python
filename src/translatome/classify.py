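"""Translatome classification: compare free- and polysome-fraction DEG calls.

For one contrast, each gene tested in both fractions falls into exactly one
category:

========================  =========================
free call / polysome call category
========================  =========================
up / up                   up_coordinated
down / down               down_coordinated
up / none                 up_buffered
down / none               down_buffered
none / up                 up_loaded
none / down               down_loaded
up / down or down / up    discordant
none / none               not_de
========================  =========================

Categories map onto regulation modes: coordinated (both coordinated
categories), post-transcriptional negative (up_buffered, down_loaded),
post-transcriptional positive (down_buffered, up_loaded).  A gene must also
show mean RPKM > 1 at one of the contrast's time points in the fraction(s)
driving its call; failures are demoted to ``not_de``.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .diffexp import DegCalls

CATEGORIES = [
    "up_coordinated", "down_coordinated",
    "up_buffered", "down_buffered",
    "up_loaded", "down_loaded",
    "discordant", "not_de",
]

MODE_OF_CATEGORY = {
    "up_coordinated": "coordinated",
    "down_coordinated": "coordinated",
    "up_buffered": "pt_negative",
    "down_loaded": "pt_negative",
    "down_buffered": "pt_positive",
    "up_loaded": "pt_positive",
    "discordant": "discordant",
    "not_de": "none",
}

_CATEGORY_TABLE = {
    ("up", "up"): "up_coordinated",
    ("down", "down"): "down_coordinated",
    ("up", "none"): "up_buffered",
    ("down", "none"): "down_buffered",
    ("none", "up"): "up_loaded",
    ("none", "down"): "down_loaded",
    ("up", "down"): "discordant",
    ("down", "up"): "discordant",
    ("none", "none"): "not_de",
}


def categorize(free_call: str, poly_call: str) -> str:
    """Category for one gene from its per-fraction calls in {up, down, none}."""
    return _CATEGORY_TABLE[(free_call, poly_call)]


def _mean_rpkm_by_cell(rpkm: pd.DataFrame, samples: pd.DataFrame,
                       timepoints: tuple[str, str]) -> dict[tuple[str, str], pd.Series]:
    out = {}
    for tp in timepoints:
        for frac in ("free", "polysome"):
            sel = (samples["timepoint"].astype(str) == tp) & (samples["fraction"] == frac)
            ids = samples.index[sel]
            if len(ids):
                out[(tp, frac)] = rpkm[ids].mean(axis=1)
    return out


def classify(free_de: DegCalls, poly_de: DegCalls, rpkm: pd.DataFrame,
             samples: pd.DataFrame, contrast: tuple[str, str],
             min_rpkm: float = 1.0, rpkm_semantics: str = "or") -> pd.DataFrame:
    """Assign every gene of the shared universe a category and regulation mode.

    ``rpkm_semantics`` controls coordinated/discordant genes: "or" (default)
    requires the RPKM floor in either fraction, "and" in both.
    """
    if free_de.universe != poly_de.universe:
        diff = sorted(free_de.universe ^ poly_de.universe)
        raise ValueError(f"gene universes differ between fractions: {diff[:10]}")

    cell_means = _mean_rpkm_by_cell(rpkm, samples, contrast)

    def passes(gene: str, fractions: Sequence[str]) -> bool:
        per_frac = []
        for frac in fractions:
            vals = [cell_means[(tp, frac)].get(gene, 0.0)
                    for tp in contrast if (tp, frac) in cell_means]
            per_frac.append(any(v > min_rpkm for v in vals))
        if rpkm_semantics == "and":
            return all(per_frac)
        return any(per_frac)

    rows = []
    for gene in sorted(free_de.universe):
        f = "up" if gene in free_de.up else ("down" if gene in free_de.down else "none")
        p = "up" if gene in poly_de.up else ("down" if gene in poly_de.down else "none")
        cat = categorize(f, p)
        ok = True
        if cat in ("up_coordinated", "down_coordinated", "discordant"):
            ok = passes(gene, ["free", "polysome"])
        elif cat in ("up_buffered", "down_buffered"):
            ok = passes(gene, ["free"])
        elif cat in ("up_loaded", "down_loaded"):
            ok = passes(gene, ["polysome"])
        if not ok:
            cat = "not_de"
        rows.append((gene, f"{contrast[0]}_vs_{contrast[1]}", cat,
                     MODE_OF_CATEGORY[cat], ok))
    return pd.DataFrame(rows, columns=["gene_id", "contrast", "category",
                                       "mode", "passed_rpkm_filter"])


def summarize_classification(classes: pd.DataFrame,
                             subset: Iterable[str] | None = None) -> pd.DataFrame:
    """Counts, raw fractions and one-decimal percentages per category and mode.

    Percentages are 100 * count / size of the summarised gene set (the subset
    if given), rounded half-even to one decimal; the raw fraction is reported
    alongside since printed one-decimal values are rounding-convention
    sensitive.
    """
    df = classes
    if subset is not None:
        subset = list(subset)
        known = set(df["gene_id"])
        missing = [g for g in subset if g not in known]
        if missing:
            warnings.warn(f"{len(missing)} subset genes absent from classification; ignored")
        df = df[df["gene_id"].isin(set(subset) & known)]
    denom = len(df)
    rows = []
    for kind, labels, col in (("category", CATEGORIES, "category"),
                              ("mode", ["coordinated", "pt_positive", "pt_negative",
                                        "discordant", "none"], "mode")):
        for label in labels:
            n = int((df[col] == label).sum())
            frac = n / denom if denom else np.nan
            rows.append((kind, label, n, denom, frac,
                         np.round(100 * frac, 1) if denom else np.nan))
    return pd.DataFrame(rows, columns=["kind", "label", "count", "denominator",
                                       "fraction", "percent"])


def biotype_tally(genes: Iterable[str], annot: pd.DataFrame) -> pd.DataFrame:
    """Per-biotype counts/percentages plus a coding vs non-coding rollup.

    Genes absent from the annotation are counted under ``unknown``; every
    biotype other than ``protein_coding`` counts as non-coding.
    """
    genes = list(genes)
    biotypes = [annot["biotype"].get(g, "unknown") for g in genes]
    ser = pd.Series(biotypes, dtype=object)
    denom = len(ser)
    rows = []
    for biot, n in ser.value_counts().items():
        rows.append(("biotype", biot, int(n), denom, 100 * n / denom))
    non_coding = int((ser != "protein_coding").sum())
    coding = denom - non_coding
    rows.append(("rollup", "protein_coding", coding, denom,
                 100 * coding / denom if denom else np.nan))
    rows.append(("rollup", "non_coding", non_coding, denom,
                 100 * non_coding / denom if denom else np.nan))
    return pd.DataFrame(rows, columns=["kind", "label", "count", "denominator", "percent"])
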