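import numpy as np
import pandas as pd
import pytest

from translatome.diffexp import DispersionModel
from translatome.occupancy import (nondeg_occupancy, occupancy_ratio,
                                   occupancy_shift_test)
from translatome.quantify import NormFactors

from conftest import make_count_matrix


def _paired_design(reps=3):
    tps, fracs = [], []
    for tp in ("T1", "T2"):
        for frac in ("free", "polysome"):
            tps += [tp] * reps
            fracs += [frac] * reps
    return tps, fracs


def _samples(reps=3):
    tps, fracs = _paired_design(reps)
    cm = make_count_matrix(np.ones((1, len(tps)), dtype=int), tps, fracs)
    return cm.samples


class TestRatio:
    def test_equal_means_give_unit_ratio(self):
        samples = _samples(reps=1)
        rpkm = pd.DataFrame([[4.0, 4.0, 6.0, 6.0]], index=["g0"], columns=samples.index)
        r = occupancy_ratio(rpkm, samples)
        np.testing.assert_allclose(r.loc["g0"], [1.0, 1.0])

    def test_four_fold_ratio(self):
        samples = _samples(reps=1)
        rpkm = pd.DataFrame([[2.0, 8.0, 2.0, 8.0]], index=["g0"], columns=samples.index)
        r = occupancy_ratio(rpkm, samples)
        assert r.loc["g0", "T1"] == pytest.approx(4.0)
        assert np.log2(r.loc["g0", "T1"]) == pytest.approx(2.0)

    def test_matches_hand_computation(self, rng):
        samples = _samples(reps=3)
        rpkm = pd.DataFrame(rng.uniform(1, 20, (20, 12)),
                            index=[f"g{i}" for i in range(20)], columns=samples.index)
        r = occupancy_ratio(rpkm, samples)
        for tp in ("T1", "T2"):
            free_cols = samples.index[(samples["timepoint"] == tp)
                                      & (samples["fraction"] == "free")]
            poly_cols = samples.index[(samples["timepoint"] == tp)
                                      & (samples["fraction"] == "polysome")]
            expect = rpkm[poly_cols].mean(axis=1) / rpkm[free_cols].mean(axis=1)
            np.testing.assert_allclose(r[tp], expect)

    def test_low_free_floor_yields_nan(self):
        samples = _samples(reps=1)
        rpkm = pd.DataFrame([[0.01, 8.0, 2.0, 8.0]], index=["g0"], columns=samples.index)
        r = occupancy_ratio(rpkm, samples)
        assert np.isnan(r.loc["g0", "T1"]) and np.isfinite(r.loc["g0", "T2"])

    def test_missing_fraction_is_error(self):
        cm = make_count_matrix(np.ones((1, 2), dtype=int), ["T1", "T2"],
                               ["free", "free"])
        rpkm = pd.DataFrame([[1.0, 1.0]], index=["g0"], columns=cm.samples.index)
        with pytest.raises(ValueError, match="polysome"):
            occupancy_ratio(rpkm, cm.samples)


def _shift_fixture(rng, n_genes=300, reps=3, phi=0.02, mu_median=300,
                   poly_fc=1.0, free_fc=1.0, n_affected=60):
    """Counts with a planted T2 fold change applied per fraction."""
    tps, fracs = _paired_design(reps)
    mu = rng.lognormal(np.log(mu_median), 0.8, n_genes)
    cols = []
    for tp, frac in zip(tps, fracs):
        m = mu.copy()
        if tp == "T2":
            fc = poly_fc if frac == "polysome" else free_fc
            m[:n_affected] = m[:n_affected] * fc
        lam = rng.gamma(1 / phi, phi * m)
        cols.append(rng.poisson(lam))
    cm = make_count_matrix(np.column_stack(cols), tps, fracs)
    from translatome.quantify import tmm_factors

    nf = tmm_factors(cm)      # corrects the composition bias of planted shifts
    disp = DispersionModel(common_dispersion=phi,
                           tagwise=pd.Series(phi, index=cm.gene_ids), prior_df=10)
    return cm, nf, disp


class TestShiftTest:
    def test_polysome_only_increase_is_recruited(self, rng):
        cm, nf, disp = _shift_fixture(rng, poly_fc=16.0)
        res = occupancy_shift_test(cm, nf, disp, ("T1", "T2"))
        assert (res["call"].iloc[:60] == "recruited").mean() >= 0.9
        assert (res["call"].iloc[60:] == "unchanged").mean() >= 0.95

    def test_coordinated_increase_cancels(self, rng):
        cm, nf, disp = _shift_fixture(rng, poly_fc=16.0, free_fc=16.0)
        res = occupancy_shift_test(cm, nf, disp, ("T1", "T2"))
        assert (res["call"].iloc[:60] == "unchanged").all()
        assert abs(res["delta_log2_ratio"].iloc[:60].median()) < 0.2

    def test_interaction_equals_difference_of_separate_fits(self, rng):
        """The interaction coefficient reproduces (polysome log2FC) minus
        (free log2FC) from independent two-group fits."""
        from translatome.diffexp import de_test

        cm, nf, disp = _shift_fixture(rng, n_genes=100, poly_fc=6.0, free_fc=2.0)
        res = occupancy_shift_test(cm, nf, disp, ("T1", "T2"))
        parts = {}
        for frac in ("free", "polysome"):
            sub = cm.subset_samples(cm.samples["fraction"] == frac)
            nf_sub = NormFactors(nf.factors.reindex(sub.samples.index),
                                 nf.library_sizes.reindex(sub.samples.index))
            parts[frac] = de_test(sub, nf_sub, disp, ("T1", "T2"),
                                  fraction=frac).set_index("gene_id")["log2FC"]
        expect = parts["polysome"] - parts["free"]
        got = res.set_index("gene_id")["delta_log2_ratio"]
        np.testing.assert_allclose(got, expect.reindex(got.index), atol=1e-3)

    def test_two_step_gene_recruited_then_dissociated(self, rng):
        """A planted recruit-then-release trajectory yields both calls across
        consecutive contrasts (Notch/Wnt-style pattern)."""
        reps, phi = 3, 0.02
        tps, fracs = [], []
        for tp in ("T1", "T2", "T3"):
            for frac in ("free", "polysome"):
                tps += [tp] * reps
                fracs += [frac] * reps
        mu = rng.lognormal(np.log(300), 0.5, 50)
        cols = []
        for tp, frac in zip(tps, fracs):
            m = mu.copy()
            if tp == "T2" and frac == "polysome":
                m[:10] *= 16.0
            lam = rng.gamma(1 / phi, phi * m)
            cols.append(rng.poisson(lam))
        cm = make_count_matrix(np.column_stack(cols), tps, fracs)
        from translatome.quantify import tmm_factors

        nf = tmm_factors(cm)
        disp = DispersionModel(common_dispersion=phi,
                               tagwise=pd.Series(phi, index=cm.gene_ids), prior_df=10)
        first = occupancy_shift_test(cm.contrast_samples(("T1", "T2")), _sub(nf, cm, ("T1", "T2")),
                                     disp, ("T1", "T2"))
        second = occupancy_shift_test(cm.contrast_samples(("T2", "T3")), _sub(nf, cm, ("T2", "T3")),
                                      disp, ("T2", "T3"))
        assert (first["call"].iloc[:10] == "recruited").mean() >= 0.9
        assert (second["call"].iloc[:10] == "dissociated").mean() >= 0.9

    def test_length_free_ratio(self, rng):
        """Occupancy calls do not depend on gene length (length cancels)."""
        cm, nf, disp = _shift_fixture(rng, n_genes=50, poly_fc=8.0, n_affected=10)
        res1 = occupancy_shift_test(cm, nf, disp, ("T1", "T2"))
        rpkm_a = pd.DataFrame(5.0, index=cm.gene_ids, columns=cm.samples.index)
        res2 = occupancy_shift_test(cm, nf, disp, ("T1", "T2"), rpkm=rpkm_a)
        np.testing.assert_allclose(res1["delta_log2_ratio"], res2["delta_log2_ratio"])


def _sub(nf, cm, contrast):
    sub = cm.contrast_samples(contrast)
    return NormFactors(nf.factors.reindex(sub.samples.index),
                       nf.library_sizes.reindex(sub.samples.index))


class TestNondegBuckets:
    def _classes(self, mapping):
        rows = [(g, "T1_vs_T2", cat, "none", True) for g, cat in mapping.items()]
        return pd.DataFrame(rows, columns=["gene_id", "contrast", "category",
                                           "mode", "passed_rpkm_filter"])

    def _shifts(self, calls):
        rows = [(g, "T1_vs_T2", 3.0, 10.0, 1e-4, 1e-3, call, "ok")
                for g, call in calls.items()]
        return pd.DataFrame(rows, columns=["gene_id", "contrast", "delta_log2_ratio",
                                           "lrt_stat", "p", "fdr", "call", "flag"])

    def test_buckets(self):
        classes = self._classes({"a": "not_de", "b": "up_loaded",
                                 "c": "up_buffered", "d": "up_coordinated"})
        shifts = self._shifts({"a": "recruited", "b": "recruited",
                               "c": "dissociated", "d": "unchanged"})
        table = nondeg_occupancy(classes, shifts).set_index(["call", "deg_status"])
        assert table.loc[("recruited", "neither"), "count"] == 1
        assert table.loc[("recruited", "polysome-only"), "count"] == 1
        assert table.loc[("dissociated", "free-only"), "count"] == 1
        assert table["count"].sum() == 3

    def test_matches_set_algebra(self, rng):
        genes = [f"g{i}" for i in range(80)]
        cats = rng.choice(["not_de", "up_loaded", "down_buffered",
                           "up_coordinated", "discordant"], size=80)
        calls = rng.choice(["recruited", "dissociated", "unchanged"], size=80)
        classes = self._classes(dict(zip(genes, cats)))
        shifts = self._shifts(dict(zip(genes, calls)))
        table = nondeg_occupancy(classes, shifts)
        status = {"not_de": "neither", "up_loaded": "polysome-only",
                  "down_buffered": "free-only", "up_coordinated": "both",
                  "discordant": "both"}
        for call in ("recruited", "dissociated"):
            for bucket in ("free-only", "polysome-only", "both", "neither"):
                expect = sum(1 for g, c, k in zip(genes, cats, calls)
                             if k == call and status[c] == bucket)
                got = table[(table["call"] == call)
                            & (table["deg_status"] == bucket)]["count"].iloc[0]
                assert got == expect

    def test_contrast_mismatch_is_error(self):
        classes = self._classes({"a": "not_de"})
        shifts = self._shifts({"a": "recruited"})
        shifts["contrast"] = "T9_vs_T10"
        with pytest.raises(ValueError, match="contrast"):
            nondeg_occupancy(classes, shifts)
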