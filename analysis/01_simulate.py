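#!/usr/bin/env python
"""Generate the study-design dataset every later step analyses.

Five time points (D0, D1, D4, D9, D15) x two fractions (ribosome-free,
polysome-bound) x three replicates, 2000 genes, |log2FC| = 3 effects planted
in coordinated / buffered / loaded classes (50% nulls).  Counts, sample
sheet, annotation and the truth table land in scratch/analysis/data.
"""

from pathlib import Path

from translatome.io_formats import write_annotation, write_counts, write_table
from translatome.simulate import SimConfig, simulate

SEED = 1
DATA = Path("scratch/analysis/data")


def main() -> None:
    cfg = SimConfig(n_genes=2000, seed=SEED)
    cm, annot, truth = simulate(cfg)
    DATA.mkdir(parents=True, exist_ok=True)
    write_counts(cm, DATA / "counts.tsv", DATA / "samples.tsv", seed=SEED)
    write_annotation(annot, DATA / "annotation.tsv", seed=SEED)
    write_table(truth, DATA / "truth.tsv", seed=SEED)
    share = truth["class"].value_counts(normalize=True)
    print(f"simulated {cfg.n_genes} genes x {cm.counts.shape[1]} samples "
          f"(median library {int(cm.library_sizes().median()):,} reads)")
    print(f"planted classes: {dict((k, round(v, 3)) for k, v in share.items())}")


if __name__ == "__main__":
    main()
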