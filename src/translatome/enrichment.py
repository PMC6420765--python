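"""Local gene-set over-representation analysis (hypergeometric test).

For a query of n genes drawn from a universe of N, a term with K members in
the universe and k members in the query gets the upper-tail probability
P(X >= k) with X ~ Hypergeometric(N, K, n), followed by Benjamini-Hochberg
FDR across the terms of the collection.  This is a plain ORA; no EnrichR-style
combined score or background rank tables are involved.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd
import scipy.stats

from .diffexp import bh_fdr
from .io_formats import GeneSetCollection


def enrich(query: Iterable[str], collection: GeneSetCollection,
           universe: Iterable[str]) -> pd.DataFrame:
    """Hypergeometric ORA of ``query`` against every term of ``collection``.

    ``query`` must be a subset of ``universe``; term members outside the
    universe are dropped (the count is recorded in ``DataFrame.attrs``).
    Rows are sorted by p ascending, ties broken by term name.
    """
    universe = set(universe)
    query = set(query)
    if not query:
        raise ValueError("empty query gene list")
    stray = query - universe
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:5]}")

    n = len(query)
    N = len(universe)
    rows = []
    n_dropped = 0
    for term, members in collection.sets.items():
        in_universe = set(members) & universe
        n_dropped += len(members) - len(in_universe)
        K = len(in_universe)
        if K == 0:
            continue
        overlap = sorted(query & in_universe)
        k = len(overlap)
        p = float(scipy.stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, collection.name, k, n, K, N, min(p, 1.0), ";".join(overlap)))

    out = pd.DataFrame(rows, columns=["term", "collection", "k", "n", "K", "N",
                                      "p", "overlap_genes"])
    out["fdr"] = bh_fdr(out["p"].to_numpy()) if len(out) else []
    out = out.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
    out.attrs["n_members_dropped"] = n_dropped
    return out[["term", "collection", "k", "n", "K", "N", "p", "fdr", "overlap_genes"]]
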