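"""Recovery metrics against the synthetic generator's planted truth.

These are the end-to-end checks the synthetic design exists for: how often a
planted regulatory class is recovered as its own category at the planted
transition, how often planted nulls escape ``not_de``, and how often planted
fraction-specific shifts are called recruited/dissociated.
"""

from __future__ import annotations

import pandas as pd

# planted class -> expected classifier category
CATEGORY_OF_CLASS = {
    "coordinated_up": "up_coordinated",
    "coordinated_down": "down_coordinated",
    "buffered_up": "up_buffered",
    "buffered_down": "down_buffered",
    "loaded_up": "up_loaded",
    "loaded_down": "down_loaded",
    "discordant": "discordant",
}

# planted class -> expected occupancy call at the planted transition; a
# free-only change moves the ratio opposite to a polysome-only change
OCC_CALL_OF_CLASS = {
    "loaded_up": "recruited",
    "loaded_down": "dissociated",
    "buffered_up": "dissociated",
    "buffered_down": "recruited",
}


def class_recovery(classes: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Per-class recovery at the planted transition.

    Returns one row per planted class with ``n`` (planted genes whose
    transition was classified) and ``recovered_pct``.
    """
    merged = classes.merge(truth, on="gene_id")
    at_transition = merged[(merged["class"] != "null")
                           & (merged["contrast"] == merged["transition"])]
    rows = []
    for cls, grp in at_transition.groupby("class"):
        expect = CATEGORY_OF_CLASS[cls]
        rows.append((cls, len(grp), 100.0 * (grp["category"] == expect).mean()))
    return pd.DataFrame(rows, columns=["class", "n", "recovered_pct"])


def null_escape_pct(classes: pd.DataFrame, truth: pd.DataFrame) -> float:
    """Percentage of planted-null classifications that are not ``not_de``."""
    merged = classes.merge(truth, on="gene_id")
    nulls = merged[merged["class"] == "null"]
    if len(nulls) == 0:
        return 0.0
    return float(100.0 * (nulls["category"] != "not_de").mean())


def occupancy_recovery(shifts: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Recruited/dissociated recovery for planted fraction-specific classes."""
    merged = shifts.merge(truth, on="gene_id")
    planted = merged[merged["class"].isin(OCC_CALL_OF_CLASS)
                     & (merged["contrast"] == merged["transition"])]
    rows = []
    for cls, grp in planted.groupby("class"):
        expect = OCC_CALL_OF_CLASS[cls]
        rows.append((cls, len(grp), 100.0 * (grp["call"] == expect).mean()))
    return pd.DataFrame(rows, columns=["class", "n", "recovered_pct"])


def occupancy_null_call_pct(shifts: pd.DataFrame, truth: pd.DataFrame) -> float:
    """Percentage of planted-null genes with a recruited/dissociated call."""
    merged = shifts.merge(truth, on="gene_id")
    nulls = merged[merged["class"] == "null"]
    if len(nulls) == 0:
        return 0.0
    return float(100.0 * (nulls["call"] != "unchanged").mean())
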