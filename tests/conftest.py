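import numpy as np
import pandas as pd
import pytest

from translatome.io_formats import CountMatrix


def make_count_matrix(counts: np.ndarray, timepoints, fractions, replicates=None,
                      gene_ids=None) -> CountMatrix:
    """Assemble a CountMatrix from an array and per-sample metadata lists."""
    counts = np.asarray(counts)
    n = counts.shape[1]
    if replicates is None:
        replicates = []
        seen: dict[tuple, int] = {}
        for tp, fr in zip(timepoints, fractions):
            seen[(tp, fr)] = seen.get((tp, fr), 0) + 1
            replicates.append(seen[(tp, fr)])
    ids = [f"{tp}_{fr}_r{rep}" for tp, fr, rep in zip(timepoints, fractions, replicates)]
    samples = pd.DataFrame({"timepoint": timepoints, "fraction": fractions,
                            "replicate": replicates}, index=pd.Index(ids, name="sample_id"))
    order = list(dict.fromkeys(timepoints))
    samples["timepoint"] = pd.Categorical(samples["timepoint"], categories=order, ordered=True)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(counts.shape[0])]
    return CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=ids), samples)


def two_group_matrix(rng, n_genes=200, reps=3, mu_median=150.0, phi=0.08,
                     lfc=None, n_affected=0, lib_factors=None) -> CountMatrix:
    """NB counts for a simple two-time-point, one-fraction design."""
    mu = rng.lognormal(np.log(mu_median), 1.0, n_genes)
    if lib_factors is None:
        lib_factors = np.ones(2 * reps)
    fc = np.ones((n_genes, 2 * reps))
    if lfc is not None and n_affected:
        fc[:n_affected, reps:] = 2.0 ** lfc
    m = mu[:, None] * fc * np.asarray(lib_factors)[None, :]
    if phi > 0:
        lam = rng.gamma(1.0 / phi, phi * m)
    else:
        lam = m
    counts = rng.poisson(lam)
    return make_count_matrix(counts, ["T1"] * reps + ["T2"] * reps,
                             ["free"] * 2 * reps)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
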