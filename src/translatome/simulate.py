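"""Synthetic paired-fraction count data with planted regulatory classes.

The generator emulates the study design downstream stages expect: 5 ordered
time points (D0, D1, D4, D9, D15) x 2 fractions (free, polysome) x 3
replicates, overdispersed negative-binomial counts with a mean-dependent
dispersion trend phi(mu) = a + b/mu, log-normal baseline expression with a
long right tail, gene lengths uniform in [300, 10000] bp so RPKM is coherent,
and log-uniform library-size multipliers.

Each non-null gene carries one planted effect: at one randomly chosen
consecutive transition its mean steps by ``2**effect_log2fc`` (persistently,
from the later time point onward) in the fraction(s) its class dictates —
both fractions (coordinated), free only (buffered), polysome only (loaded),
or opposite signs (discordant).  The returned truth table makes every
downstream call checkable against ground truth.

Draw order under the single seed (stable across versions): gene lengths,
baseline expression, biotypes, class labels (permutation), planted
transitions, library multipliers, then the gamma-Poisson counts
sample-by-sample in sheet order.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CountMatrix

CLASSES = [
    "coordinated_up", "coordinated_down",
    "buffered_up", "buffered_down",
    "loaded_up", "loaded_down",
    "discordant", "null",
]

# (sign in free fraction, sign in polysome fraction), units of effect_log2fc
_CLASS_SIGNS = {
    "coordinated_up": (+1, +1),
    "coordinated_down": (-1, -1),
    "buffered_up": (+1, 0),
    "buffered_down": (-1, 0),
    "loaded_up": (0, +1),
    "loaded_down": (0, -1),
    "discordant": (+1, -1),
    "null": (0, 0),
}

DEFAULT_PROPORTIONS: dict[str, float] = {
    "coordinated_up": 0.10, "coordinated_down": 0.10,
    "buffered_up": 0.075, "buffered_down": 0.075,
    "loaded_up": 0.075, "loaded_down": 0.075,
    "discordant": 0.0, "null": 0.50,
}

_BIOTYPE_PROBS = {
    # ~20% non-coding, split 39/22/18/21 lincRNA/antisense/pseudogene/misc
    "protein_coding": 0.80,
    "lincRNA": 0.078,
    "antisense": 0.044,
    "processed_pseudogene": 0.036,
    "misc_RNA": 0.042,
}


@dataclasses.dataclass
class SimConfig:
    n_genes: int = 2000
    timepoints: Sequence[str] = ("D0", "D1", "D4", "D9", "D15")
    n_reps: int = 3
    class_proportions: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    effect_log2fc: float = 3.0
    dispersion_a: float = 0.05
    dispersion_b: float = 2.0
    libsize_range: tuple[float, float] = (0.5, 2.0)
    depth_millions: float = 30.0        # nominal sequencing depth (the design's ~30M reads)
    baseline_median: float = 6.0        # per-kb-per-million median of the log-normal baseline
    baseline_sdlog: float = 1.5
    length_range: tuple[int, int] = (300, 10000)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.get(c, 0.0) for c in CLASSES)
        extra = set(self.class_proportions) - set(CLASSES)
        if extra:
            raise ValueError(f"unknown classes in proportions: {sorted(extra)}")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, not 1")
        if self.effect_log2fc <= 0:
            raise ValueError("effect_log2fc must be positive")
        if self.n_reps < 2:
            raise ValueError("need at least 2 replicates")
        if len(self.timepoints) < 2:
            raise ValueError("need at least 2 time points")


def _class_counts(config: SimConfig) -> dict[str, int]:
    """Largest-remainder apportionment so class counts sum to n_genes exactly."""
    raw = {c: config.class_proportions.get(c, 0.0) * config.n_genes for c in CLASSES}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    deficit = config.n_genes - sum(counts.values())
    remainders = sorted(raw, key=lambda c: raw[c] - counts[c], reverse=True)
    for c in remainders[:deficit]:
        counts[c] += 1
    return counts


def simulate(config: SimConfig) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Generate (CountMatrix, gene annotation, truth table) for a SimConfig."""
    rng = np.random.default_rng(config.seed)
    g = config.n_genes
    gene_ids = [f"G{i:05d}" for i in range(g)]

    lengths = rng.integers(config.length_range[0], config.length_range[1] + 1, size=g)
    baseline = rng.lognormal(mean=np.log(config.baseline_median),
                             sigma=config.baseline_sdlog, size=g)
    biotypes = rng.choice(list(_BIOTYPE_PROBS), size=g, p=list(_BIOTYPE_PROBS.values()))

    counts_per_class = _class_counts(config)
    labels = np.array([c for c in CLASSES for _ in range(counts_per_class[c])])
    labels = labels[rng.permutation(g)]

    tps = list(config.timepoints)
    transitions = [(tps[i], tps[i + 1]) for i in range(len(tps) - 1)]
    planted_idx = rng.integers(0, len(transitions), size=g)

    sheet_rows = []
    for tp in tps:
        for frac in ("free", "polysome"):
            for rep in range(1, config.n_reps + 1):
                sheet_rows.append((f"{tp}_{frac}_r{rep}", tp, frac, rep))
    samples = pd.DataFrame(sheet_rows, columns=["sample_id", "timepoint",
                                                "fraction", "replicate"]).set_index("sample_id")
    samples["timepoint"] = pd.Categorical(samples["timepoint"], categories=tps, ordered=True)

    lo, hi = config.libsize_range
    libmult = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(samples)))

    # planted per-gene, per-fraction log2 effects, active from the later
    # time point of the planted transition onward (single persistent step)
    sign_free = np.array([_CLASS_SIGNS[c][0] for c in labels], dtype=float)
    sign_poly = np.array([_CLASS_SIGNS[c][1] for c in labels], dtype=float)
    onset = np.array([tps.index(transitions[i][1]) for i in planted_idx])

    # expected counts at the nominal depth; length scaling keeps RPKM coherent
    base_mu = baseline * (lengths / 1000.0) * config.depth_millions
    counts = np.empty((g, len(samples)), dtype=np.int64)
    for j, (sid, row) in enumerate(samples.iterrows()):
        tp_idx = tps.index(str(row["timepoint"]))
        sign = sign_free if row["fraction"] == "free" else sign_poly
        active = (tp_idx >= onset).astype(float)
        mu = base_mu * (2.0 ** (config.effect_log2fc * sign * active)) * libmult[j]
        mu = np.maximum(mu, 1e-8)
        phi = config.dispersion_a + config.dispersion_b / mu
        lam = rng.gamma(shape=1.0 / phi, scale=phi * mu)
        counts[:, j] = rng.poisson(lam)

    cm = CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=samples.index), samples)
    annot = pd.DataFrame({"length_bp": lengths, "biotype": biotypes},
                         index=pd.Index(gene_ids, name="gene_id"))
    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "class": labels,
        "transition": [f"{transitions[i][0]}_vs_{transitions[i][1]}" for i in planted_idx],
        "log2fc_free": config.effect_log2fc * sign_free,
        "log2fc_polysome": config.effect_log2fc * sign_poly,
    })
    truth.loc[truth["class"] == "null", "transition"] = "none"
    return cm, annot, truth
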