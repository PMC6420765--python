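#!/usr/bin/env python
"""Classify every gene by comparing the two fractions' DEG calls.

For each transition, genes are up/down-coordinated (both fractions),
up/down-buffered (free only), or up/down-loaded (polysome only), with the
RPKM > 1 floor; categories map onto coordinated / post-transcriptional
positive / negative regulation.  Recovery is scored against the planted
truth, and biotypes of the polysome DEG union are tallied.
"""

from pathlib import Path

import pandas as pd

from translatome import diffexp, validation
from translatome.classify import biotype_tally, classify, summarize_classification
from translatome.io_formats import read_annotation, read_counts, write_table
from translatome.pipeline import contrast_plan

DATA = Path("scratch/analysis/data")
OUT = Path("scratch/analysis")
RESULTS = Path("results/analysis")


def main() -> None:
    cm = read_counts(DATA / "counts.tsv", DATA / "samples.tsv")
    annot = read_annotation(DATA / "annotation.tsv")
    truth = pd.read_csv(DATA / "truth.tsv", sep="\t", comment="#")
    de = pd.read_csv(OUT / "de.tsv", sep="\t", comment="#")
    rpkm = pd.read_csv(OUT / "rpkm.tsv", sep="\t", comment="#", index_col=0)

    plan = contrast_plan(cm.timepoints)
    all_classes, summaries = [], []
    deg_union: set[str] = set()
    for contrast in plan:
        label = f"{contrast[0]}_vs_{contrast[1]}"
        lfc = 1.0 if contrast == plan[-1] else 2.0
        calls = {}
        for fraction in ("free", "polysome"):
            sel = (de["contrast"] == label) & (de["fraction"] == fraction)
            calls[fraction] = diffexp.call_degs(de[sel], 0.05, lfc)
        classes = classify(calls["free"], calls["polysome"], rpkm, cm.samples,
                           contrast)
        all_classes.append(classes)
        s = summarize_classification(classes)
        s.insert(0, "contrast", label)
        summaries.append(s)
        if contrast != plan[-1]:
            deg_union |= calls["polysome"].up | calls["polysome"].down

    classes = pd.concat(all_classes, ignore_index=True)
    write_table(classes, OUT / "classes.tsv")
    write_table(pd.concat(summaries, ignore_index=True),
                RESULTS / "classification_summary.tsv")

    rec = validation.class_recovery(classes, truth)
    write_table(rec, RESULTS / "class_recovery.tsv")
    print(rec.to_string(index=False))
    print(f"planted nulls escaping not_de: "
          f"{validation.null_escape_pct(classes, truth):.2f} %")

    de_cats = classes[~classes["category"].isin(["not_de", "discordant"])]
    pt = de_cats["mode"].isin(["pt_positive", "pt_negative"]).mean()
    print(f"{100 * pt:.1f} % of classified DEGs show post-transcriptional "
          f"regulation (buffered or loaded)")

    tally = biotype_tally(sorted(deg_union), annot)
    write_table(tally, RESULTS / "biotype_tally.tsv")
    nc = tally[(tally["kind"] == "rollup") & (tally["label"] == "non_coding")]
    print(f"non-coding share of the polysome DEG union: "
          f"{nc['percent'].iloc[0]:.1f} %")


if __name__ == "__main__":
    main()
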