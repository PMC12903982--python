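"""Window tiling, methylation pooling, exact testing, DMR/AMR/DML calling."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from svcascade import (GenomeLayout, GenomicInterval, SVRecord, call_amrs,
                       call_dmls, call_dmrs, fisher_window_test, metagene_profile,
                       pool_window_methylation, tile_windows)
from svcascade.genome import GeneModel


def enumeration_fisher(ma, ta, mb, tb):
    """Independent oracle: sum exact-rational hypergeometric masses <= observed."""
    m = ma + mb
    n = ta + tb

    def mass(k):
        return Fraction(comb(ta, k) * comb(tb, m - k), comb(n, m))

    observed = mass(ma)
    total = Fraction(0)
    for k in range(max(0, m - tb), min(ta, m) + 1):
        if mass(k) <= observed:
            total += mass(k)
    return float(total)


class TestTileWindows:
    def test_partial_terminal_window_retained(self):
        layout = GenomeLayout({"c": 2500})
        assert [(w.start, w.end) for w in tile_windows(layout, 1000)] == \
               [(0, 1000), (1000, 2000), (2000, 2500)]

    def test_stepped_windows(self):
        layout = GenomeLayout({"c": 2000})
        wins = tile_windows(layout, 1000, step=500)
        assert [w.start for w in wins] == [0, 500, 1000, 1500]

    def test_tiling_is_a_partition(self, layout):
        wins = tile_windows(layout, 317)
        for chrom in layout.names:
            chrom_wins = sorted(w for w in wins if w.chrom == chrom)
            assert chrom_wins[0].start == 0
            assert chrom_wins[-1].end == layout.length(chrom)
            for a, b in zip(chrom_wins, chrom_wins[1:]):
                assert a.end == b.start

    def test_nonpositive_size_rejected(self, layout):
        with pytest.raises(ValueError):
            tile_windows(layout, 0)


class TestPooling:
    def _calls(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "meth",
                                           "unmeth", "context"])

    def test_counts_pooled_within_window(self):
        calls = self._calls([("c", 10, "+", 3, 7, "CG"), ("c", 20, "-", 27, 63, "CG")])
        [win] = [GenomicInterval("c", 0, 100)]
        pooled = pool_window_methylation(calls, [win], "CG")
        assert pooled.loc[0, "meth"] == 30
        assert pooled.loc[0, "total"] == 100
        assert pooled.loc[0, "freqc"] == pytest.approx(0.30)

    def test_empty_window_flagged_no_data(self):
        calls = self._calls([("c", 500, "+", 1, 9, "CG")])
        pooled = pool_window_methylation(calls, [GenomicInterval("c", 0, 100)], "CG")
        assert pooled.loc[0, "total"] == 0 and np.isnan(pooled.loc[0, "freqc"])

    def test_pooling_is_order_invariant(self):
        rows = [("c", p, "+", p % 5, 10, "CG") for p in range(0, 1000, 37)]
        wins = [GenomicInterval("c", 0, 500), GenomicInterval("c", 500, 1000)]
        a = pool_window_methylation(self._calls(rows), wins, "CG")
        b = pool_window_methylation(self._calls(rows[::-1]), wins, "CG")
        pd.testing.assert_frame_equal(a, b)


class TestFisher:
    @pytest.mark.parametrize("table,expected", [
        ((3, 3, 0, 3), 0.10),
        ((8, 10, 2, 10), 0.023014137565221155),
    ])
    def test_worked_examples(self, table, expected):
        assert fisher_window_test(*table) == pytest.approx(expected, abs=1e-12)

    def test_identical_tables_give_p_one(self):
        assert fisher_window_test(5, 10, 5, 10) == 1.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fisher_window_test(0, 0, 0, 0)
        with pytest.raises(ValueError):
            fisher_window_test(5, 3, 0, 3)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.integers(0, 60), st.integers(0, 60), st.integers(1, 60), st.integers(1, 60))
    def test_matches_enumeration_and_is_symmetric(self, ma, mb, ta, tb):
        ma, mb = min(ma, ta), min(mb, tb)
        p = fisher_window_test(ma, ta, mb, tb)
        assert 0.0 < p <= 1.0
        assert p == pytest.approx(enumeration_fisher(ma, ta, mb, tb), abs=1e-12)
        assert p == fisher_window_test(mb, tb, ma, ta)


def _window_frames(tables, context="CG"):
    """Build paired window frames from (meth_a, total_a, meth_b, total_b) rows."""
    a = pd.DataFrame({"chrom": "c", "start": np.arange(len(tables)) * 1000,
                      "end": (np.arange(len(tables)) + 1) * 1000,
                      "meth": [t[0] for t in tables], "total": [t[1] for t in tables]})
    b = a.copy()
    b["meth"] = [t[2] for t in tables]
    b["total"] = [t[3] for t in tables]
    for df in (a, b):
        df["freqc"] = df["meth"] / df["total"].replace(0, np.nan)
        df["context"] = context
    return a, b


class TestCallDmrs:
    def test_effect_size_threshold_is_context_specific(self):
        # strong counts, delta 0.19: fails the CG >=20% rule no matter the q
        tables = [(190, 1000, 0, 1000)] * 5 + [(0, 1000, 190, 1000)] * 5
        a, b = _window_frames(tables, "CG")
        assert len(call_dmrs(a, b, "CG")) == 0
        # delta 0.12 passes the CHH >=10% rule when q < 0.01
        a, b = _window_frames([(0, 500, 60, 500)] * 4, "CHH")
        dmrs = call_dmrs(a, b, "CHH")
        assert len(dmrs) == 4 and (dmrs["q"] < 0.01).all()

    def test_identical_conditions_give_zero_dmrs(self):
        tables = [(k, 50, k, 50) for k in range(5, 45, 5)]
        a, b = _window_frames(tables)
        assert len(call_dmrs(a, b, "CG")) == 0

    def test_zero_coverage_windows_excluded_from_multiplicity(self):
        tables = [(0, 0, 10, 20), (40, 50, 5, 50)]
        a, b = _window_frames(tables)
        out = call_dmrs(a, b, "CG", return_all=True)
        assert len(out) == 1 and out.loc[0, "start"] == 1000

    def test_mismatched_window_sets_rejected(self):
        a, b = _window_frames([(5, 10, 5, 10)])
        b["start"] += 1
        with pytest.raises(ValueError, match="not identical"):
            call_dmrs(a, b, "CG")


class TestCallAmrs:
    def _windows(self, rows):
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "freqc"])
        return df

    def test_containment_overlap_and_freqc_rules(self):
        deletion = SVRecord("d1", "DEL", GenomicInterval("c", 10_000, 11_000), 1000)
        windows = self._windows([
            ("c", 10_200, 10_300, 0.55),   # fully inside, methylated -> AMR
            ("c", 10_950, 11_050, 0.55),   # 50% overlap -> no
            ("c", 10_400, 10_500, 0.15),   # freqC below threshold -> no
        ])
        amrs = call_amrs(windows, [deletion])
        assert list(amrs["start"]) == [10_200]
        assert amrs.loc[0, "sv_id"] == "d1"

    def test_insertion_span_supports_amrs(self):
        ins = SVRecord("i1", "INS", GenomicInterval("c", 5_000, 5_001), 1200)
        windows = self._windows([("c", 5_100, 5_200, 0.8)])
        amrs = call_amrs(windows, [ins])
        assert len(amrs) == 1 and amrs.loc[0, "sv_id"] == "i1"

    def test_inversions_rejected(self):
        inv = SVRecord("v1", "INV", GenomicInterval("c", 0, 5000), 5000)
        with pytest.raises(ValueError, match="InDels only"):
            call_amrs(self._windows([("c", 0, 100, 0.5)]), [inv])

    def test_monotone_in_both_thresholds(self):
        rng = np.random.default_rng(11)
        svs = [SVRecord(f"d{i}", "DEL",
                        GenomicInterval("c", int(s), int(s) + 500), 500)
               for i, s in enumerate(rng.choice(100_000, 40, replace=False) * 10)]
        starts = np.arange(0, 1_000_000, 100)
        windows = self._windows([("c", int(s), int(s) + 100, float(f))
                                 for s, f in zip(starts, rng.uniform(0, 1, len(starts)))])
        base = call_amrs(windows, svs, freqc_min=0.2, overlap_min=0.9)
        keys = set(map(tuple, base[["chrom", "start"]].itertuples(index=False)))
        for fc, ov in [(0.3, 0.9), (0.2, 0.95), (0.5, 1.0)]:
            sub = call_amrs(windows, svs, freqc_min=fc, overlap_min=ov)
            assert set(map(tuple, sub[["chrom", "start"]].itertuples(index=False))) <= keys


class TestCallDmls:
    def _sites(self, rows):
        return pd.DataFrame(rows, columns=["transcript", "position", "type",
                                           "modified", "coverage", "fraction"])

    def test_large_difference_called_small_delta_not(self):
        a = self._sites([("t1", 5, "m6A", 45, 50, 0.9), ("t2", 9, "m6A", 55, 100, 0.55)])
        b = self._sites([("t1", 5, "m6A", 5, 50, 0.1), ("t2", 9, "m6A", 40, 100, 0.40)])
        dmls = call_dmls(a, b)
        assert list(dmls["transcript"]) == ["t1"]     # t2 delta 0.15 < 0.20

    def test_identical_sites_give_zero_dmls(self):
        a = self._sites([("t1", 5, "m6A", 25, 50, 0.5)])
        assert len(call_dmls(a, a.copy())) == 0

    def test_unmatched_sites_skipped(self):
        a = self._sites([("t1", 5, "m6A", 45, 50, 0.9), ("tX", 1, "m5C", 10, 20, 0.5)])
        b = self._sites([("t1", 5, "m6A", 5, 50, 0.1)])
        assert len(call_dmls(a, b, return_all=True)) == 1


class TestMetagene:
    def _uniform_calls(self, level=0.5, spacing=50, span=30_000):
        pos = np.arange(0, span, spacing)
        return pd.DataFrame({"chrom": "c", "pos": pos, "strand": "+",
                             "meth": int(level * 20), "unmeth": 20 - int(level * 20),
                             "context": "CG"})

    def test_uniform_methylation_gives_flat_profile(self):
        genes = [GeneModel("g", GenomicInterval("c", 10_000, 16_000), "+")]
        prof = metagene_profile(self._uniform_calls(), genes)
        assert np.allclose(prof["level"].dropna(), 0.5)

    def test_minus_strand_reverses_orientation(self):
        # methylation rises with coordinate; on the minus strand the profile
        # must fall 5'->3'
        pos = np.arange(0, 30_000, 50)
        calls = pd.DataFrame({"chrom": "c", "pos": pos, "strand": "+",
                              "meth": (pos > 13_000).astype(int) * 10,
                              "unmeth": 10, "context": "CG"})
        gene_plus = [GeneModel("g", GenomicInterval("c", 10_000, 16_000), "+")]
        gene_minus = [GeneModel("g", GenomicInterval("c", 10_000, 16_000), "-")]
        up = metagene_profile(calls, gene_plus)["level"].to_numpy()
        down = metagene_profile(calls, gene_minus)["level"].to_numpy()
        assert np.allclose(up, down[::-1], equal_nan=True)

    def test_hand_placed_sites_give_hand_computed_means(self):
        # two features, one site each in the first body bin of the first
        # feature (level 1.0) and the last body bin of the second (level 0.0)
        calls = pd.DataFrame({
            "chrom": "c", "pos": [1000 + 5, 9000 - 5], "strand": "+",
            "meth": [10, 0], "unmeth": [0, 10], "context": "CG"})
        genes = [GeneModel("g1", GenomicInterval("c", 1000, 1300), "+"),
                 GeneModel("g2", GenomicInterval("c", 8700, 9000), "+")]
        prof = metagene_profile(calls, genes, flank=300, flank_bin=100, body_bins=3)
        body = prof[prof["segment"] == "body"]
        assert body["level"].iloc[0] == 1.0 and body["n_features"].iloc[0] == 1
        assert body["level"].iloc[-1] == 0.0 and body["n_features"].iloc[-1] == 1

    def test_short_features_skipped(self):
        genes = [GeneModel("tiny", GenomicInterval("c", 100, 110), "+")]
        prof = metagene_profile(self._uniform_calls(), genes, body_bins=30)
        assert prof["n_features"].sum() == 0
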