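import itertools

import numpy as np
import pandas as pd
import pytest

from translatome.classify import (CATEGORIES, MODE_OF_CATEGORY, biotype_tally,
                                  categorize, classify, summarize_classification)
from translatome.diffexp import DegCalls

from conftest import make_count_matrix


def _rpkm_frame(genes, samples, value=5.0):
    return pd.DataFrame(value, index=genes, columns=samples.index)


def _setup(free_up=(), free_down=(), poly_up=(), poly_down=(), universe=("a", "b", "c")):
    free = DegCalls(set(free_up), set(free_down), set(universe))
    poly = DegCalls(set(poly_up), set(poly_down), set(universe))
    cm = make_count_matrix(np.ones((len(universe), 4), dtype=int),
                           ["D4", "D4", "D9", "D9"],
                           ["free", "polysome", "free", "polysome"],
                           gene_ids=list(universe))
    return free, poly, cm.samples


class TestTruthTable:
    def test_all_eight_call_combinations(self):
        """Exhaustive map of (free, polysome) call pairs onto categories."""
        expected = {
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
        for combo, cat in expected.items():
            assert categorize(*combo) == cat
        assert len(list(itertools.product(["up", "down", "none"], repeat=2))) == 9

    def test_mode_mapping_is_total(self):
        assert set(MODE_OF_CATEGORY) == set(CATEGORIES)
        assert MODE_OF_CATEGORY["up_buffered"] == "pt_negative"
        assert MODE_OF_CATEGORY["down_loaded"] == "pt_negative"
        assert MODE_OF_CATEGORY["down_buffered"] == "pt_positive"
        assert MODE_OF_CATEGORY["up_loaded"] == "pt_positive"
        assert MODE_OF_CATEGORY["up_coordinated"] == "coordinated"
        assert MODE_OF_CATEGORY["down_coordinated"] == "coordinated"

    def test_classify_end_to_end_categories(self):
        free, poly, samples = _setup(free_up={"a"}, poly_up={"b"})
        rpkm = _rpkm_frame(["a", "b", "c"], samples)
        out = classify(free, poly, rpkm, samples, ("D4", "D9"))
        got = out.set_index("gene_id")["category"]
        assert got["a"] == "up_buffered"       # free-only up (NKX2-5-like)
        assert got["b"] == "up_loaded"         # polysome-only up (MEF2A/TBX5-like)
        assert got["c"] == "not_de"


class TestRpkmFilter:
    def test_low_rpkm_demotes_to_not_de(self):
        free, poly, samples = _setup(free_up={"a"}, poly_up={"a"})
        rpkm = _rpkm_frame(["a", "b", "c"], samples, value=0.5)
        out = classify(free, poly, rpkm, samples, ("D4", "D9"))
        row = out.set_index("gene_id").loc["a"]
        assert row["category"] == "not_de" and not row["passed_rpkm_filter"]

    def test_or_semantics_for_coordinated(self):
        free, poly, samples = _setup(free_up={"a"}, poly_up={"a"})
        rpkm = _rpkm_frame(["a", "b", "c"], samples, value=0.5)
        free_cols = samples.index[samples["fraction"] == "free"]
        rpkm.loc["a", free_cols] = 9.0
        out = classify(free, poly, rpkm, samples, ("D4", "D9"))
        assert out.set_index("gene_id").loc["a", "category"] == "up_coordinated"
        strict = classify(free, poly, rpkm, samples, ("D4", "D9"),
                          rpkm_semantics="and")
        assert strict.set_index("gene_id").loc["a", "category"] == "not_de"

    def test_driving_fraction_decides_for_loaded(self):
        free, poly, samples = _setup(poly_up={"a"})
        rpkm = _rpkm_frame(["a", "b", "c"], samples, value=0.5)
        poly_cols = samples.index[samples["fraction"] == "polysome"]
        rpkm.loc["a", poly_cols] = 9.0
        out = classify(free, poly, rpkm, samples, ("D4", "D9"))
        assert out.set_index("gene_id").loc["a", "category"] == "up_loaded"


def test_universe_mismatch_reports_difference():
    free = DegCalls(set(), set(), {"a", "b"})
    poly = DegCalls(set(), set(), {"a", "c"})
    _, _, samples = _setup()
    with pytest.raises(ValueError, match="b"):
        classify(free, poly, _rpkm_frame(["a"], samples), samples, ("D4", "D9"))


def test_swapping_fractions_swaps_buffered_and_loaded():
    free, poly, samples = _setup(free_up={"a"}, free_down={"b"}, poly_up={"c"},
                                 universe=("a", "b", "c", "d"))
    rpkm = _rpkm_frame(["a", "b", "c", "d"], samples)
    fwd = classify(free, poly, rpkm, samples, ("D4", "D9")).set_index("gene_id")
    rev = classify(poly, free, rpkm, samples, ("D4", "D9")).set_index("gene_id")
    swap = {"up_buffered": "up_loaded", "up_loaded": "up_buffered",
            "down_buffered": "down_loaded", "down_loaded": "down_buffered"}
    for g in ["a", "b", "c", "d"]:
        assert rev.loc[g, "category"] == swap.get(fwd.loc[g, "category"],
                                                  fwd.loc[g, "category"])


class TestSummarize:
    def _classes(self, spec):
        rows = []
        i = 0
        for cat, n in spec.items():
            for _ in range(n):
                rows.append((f"g{i}", "D0_vs_D15", cat, MODE_OF_CATEGORY[cat], True))
                i += 1
        return pd.DataFrame(rows, columns=["gene_id", "contrast", "category",
                                           "mode", "passed_rpkm_filter"])

    def test_counts_partition_universe(self):
        classes = self._classes({"down_coordinated": 44, "down_loaded": 72,
                                 "down_buffered": 27})
        s = summarize_classification(classes)
        cat = s[s["kind"] == "category"]
        assert cat["count"].sum() == 143

    def test_printed_share_arithmetic(self):
        classes = self._classes({"down_coordinated": 44, "down_loaded": 72,
                                 "down_buffered": 27})
        s = summarize_classification(classes).set_index("label")
        assert s.loc["down_coordinated", "percent"] == pytest.approx(100 * 44 / 143, abs=0.05)
        assert s.loc["down_loaded", "percent"] == pytest.approx(100 * 72 / 143, abs=0.05)

    def test_empty_subset_gives_empty_counts(self):
        classes = self._classes({"up_loaded": 3})
        s = summarize_classification(classes, subset=[])
        assert (s["count"] == 0).all()

    def test_unknown_subset_gene_warned_and_ignored(self):
        classes = self._classes({"up_loaded": 3})
        with pytest.warns(UserWarning, match="absent"):
            s = summarize_classification(classes, subset=["g0", "nope"])
        assert s[s["label"] == "up_loaded"]["count"].iloc[0] == 1


class TestBiotypeTally:
    def _annot(self, biotypes):
        return pd.DataFrame({"length_bp": 1000, "biotype": biotypes},
                            index=[f"g{i}" for i in range(len(biotypes))])

    def test_non_coding_share(self):
        annot = self._annot(["protein_coding"] * 8 + ["lincRNA"] * 2)
        t = biotype_tally([f"g{i}" for i in range(10)], annot).set_index("label")
        assert t.loc["non_coding", "percent"] == pytest.approx(20.0)

    def test_all_coding(self):
        annot = self._annot(["protein_coding"] * 4)
        t = biotype_tally([f"g{i}" for i in range(4)], annot)
        assert t[t["label"] == "non_coding"]["percent"].iloc[0] == 0

    def test_matches_hand_count_and_unknowns(self):
        annot = self._annot(["protein_coding", "lincRNA", "antisense",
                             "processed_pseudogene", "misc_RNA"])
        t = biotype_tally(["g0", "g1", "g2", "g3", "g4", "gX"], annot)
        by = t[t["kind"] == "biotype"].set_index("label")["count"]
        assert by["unknown"] == 1 and by["lincRNA"] == 1
        roll = t[t["kind"] == "rollup"].set_index("label")["count"]
        assert roll["non_coding"] == 5 and roll["protein_coding"] == 1
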