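# translatome

Analysis of paired **ribosome-free** and **polysome-bound** RNA-seq across a
differentiation time course — the "polysome profiling" design in which each
sample is split on a sucrose gradient into mRNA that is not ribosome-associated
(free) and mRNA engaged by polysomes (the translatome). Comparing differential
expression between the two fractions separates transcriptional from
post-transcriptional regulation:

| free fraction | polysome fraction | category | regulation mode |
|---|---|---|---|
| up | up | up-coordinated | coordinated |
| down | down | down-coordinated | coordinated |
| up | — | up-buffered | post-transcriptional negative |
| down | — | down-buffered | post-transcriptional positive |
| — | up | up-loaded | post-transcriptional positive |
| — | down | down-loaded | post-transcriptional negative |

The package provides, as importable modules with a thin CLI
(`translatome --help`):

- **quantify** — TMM normalisation factors, CPM / RPKM / logCPM
  (counts x_gj with effective library N_j: CPM = x/N·10⁶,
  RPKM = CPM/(length/1000)).
- **diffexp** — negative-binomial GLM per gene,
  log μ = log N + β₀ + β₁·[later time point], Var(Y) = μ + φμ²; dispersion by
  Cox-Reid adjusted profile likelihood (common → abundance-trended → tagwise
  shrinkage), likelihood-ratio test against χ²₁, Benjamini-Hochberg FDR, DEG
  calling at FDR ≤ 0.05 and |log₂FC| ≥ 2 (≥ 1 for the endpoint contrast).
- **classify** — the fraction-comparison table above plus an RPKM > 1 floor
  in the fraction(s) driving the call.
- **occupancy** — polysome/free RPKM ratios per time point, and shift tests
  via the fraction x time interaction of an NB GLM
  (Δlog₂ ratio = interaction coefficient / ln 2; recruited/dissociated at
  FDR ≤ 0.05 and |Δ| ≥ 2).
- **patterns** — k-means clustering of z-scaled replicate-averaged logCPM
  trajectories (k = 9 by default, WSS curve recorded), and correspondence
  analysis (principal inertias of the χ²-standardised count matrix;
  Σ inertias = χ²/N).
- **enrichment** — hypergeometric over-representation of query genes against
  GMT gene sets with BH FDR.
- **simulate** — a synthetic-data generator planting known coordinated /
  buffered / loaded effects (5 time points × 2 fractions × 3 replicates) so
  every stage can be validated against ground truth.

## Worked example

The numbered drivers under `analysis/` run the whole study on simulated data
(each step writes its tables under `results/analysis/`):

```
python analysis/01_simulate.py
python analysis/02_quantify.py
python analysis/03_differential_expression.py
python analysis/04_classification.py
```

`04_classification.py` prints, for the default design (2000 genes, planted
|log₂FC| = 3, three replicates):

```
           class   n  recovered_pct
   buffered_down 149      99.328859
     buffered_up 150     100.000000
coordinated_down 199      97.487437
  coordinated_up 200     100.000000
     loaded_down 150      98.000000
       loaded_up 150     100.000000
planted nulls escaping not_de: 0.00 %
60.2 % of classified DEGs show post-transcriptional regulation (buffered or loaded)
non-coding share of the polysome DEG union: 19.1 %
```

i.e. every planted regulatory class is recovered in its own category ≥ 97% of
the time, essentially no null gene is mis-called, and the planted 60%
post-transcriptional share and ~20% non-coding share are reproduced.
`05_occupancy.py`–`07_enrichment.py` continue with recruitment/dissociation
calls, trajectory clustering and a positive-control enrichment run.

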