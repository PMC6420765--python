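#!/usr/bin/env python
"""Temporal clustering of polysome-bound DEG trajectories.

Replicate-averaged log-CPM trajectories of the polysome DEG union are
z-scaled per gene and clustered with k-means (k = 9, best of 25 restarts);
the full within-cluster sum-of-squares curve is recorded alongside the
automatic elbow pick so the choice of k stays inspectable.
"""

from pathlib import Path

import pandas as pd

from translatome import diffexp, quantify
from translatome.io_formats import read_counts, write_table
from translatome.patterns import kmeans_patterns

DATA = Path("scratch/analysis/data")
OUT = Path("scratch/analysis")
RESULTS = Path("results/analysis")
SEED = 1
K = 9


def main() -> None:
    cm = read_counts(DATA / "counts.tsv", DATA / "samples.tsv")
    de = pd.read_csv(OUT / "de.tsv", sep="\t", comment="#")
    trans = de[(de["fraction"] == "polysome") & (de["contrast"] != "D0_vs_D15")]
    union = set(diffexp.call_degs(trans, 0.05, 2.0).up
                | diffexp.call_degs(trans, 0.05, 2.0).down)

    poly = cm.subset_samples(cm.samples["fraction"] == "polysome")
    norm = quantify.tmm_factors(cm)
    nf = quantify.NormFactors(norm.factors.reindex(poly.samples.index),
                              norm.library_sizes.reindex(poly.samples.index))
    logcpm = quantify.log_cpm(poly, nf)

    model = kmeans_patterns(logcpm, poly.samples, sorted(union), k=K, seed=SEED)
    write_table(pd.DataFrame({"gene_id": model.assignments.index,
                              "cluster": model.assignments.to_numpy()}),
                OUT / "clusters.tsv")
    write_table(pd.DataFrame({"k": list(model.wss_curve),
                              "wss": [round(v, 3) for v in model.wss_curve.values()]}),
                RESULTS / "wss_curve.tsv")
    sizes = model.assignments.value_counts().sort_index()
    print(f"clustered {len(model.assignments)} DEG trajectories into k={model.k} "
          f"(elbow heuristic suggests k={model.elbow_k})")
    print("cluster sizes:", sizes.to_dict())


if __name__ == "__main__":
    main()
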