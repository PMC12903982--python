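"""Compartment labelling/switching, TAD matching, SV co-occurrence statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from svcascade import (GenomeLayout, GenomicInterval, SVRecord, TadDomain,
                       assign_compartments, boundary_sv_window_stats,
                       detect_switch_segments, differential_regions,
                       fraction_svs_in_regions, match_tads, sv_counts_per_tad,
                       sv_density_profile)


def bins_frame(values, chrom="c", size=40_000):
    return pd.DataFrame({"chrom": chrom,
                         "start": np.arange(len(values)) * size,
                         "end": (np.arange(len(values)) + 1) * size,
                         "pc1": values})


class TestCompartments:
    def test_positive_oriented_pc1_with_high_density_is_A(self):
        pc1 = bins_frame([1.2, -0.8, 0.5, -1.0])
        density = np.array([900.0, 100.0, 700.0, 50.0])
        out = assign_compartments(pc1, density)
        assert list(out["label"]) == ["A", "B", "A", "B"]

    def test_orientation_invariance_under_global_sign_flip(self):
        rng = np.random.default_rng(5)
        density = rng.uniform(0, 1000, 50)
        values = (density - density.mean()) / density.std() + rng.normal(0, 0.2, 50)
        a = assign_compartments(bins_frame(values), density)
        b = assign_compartments(bins_frame(-values), density)
        assert list(a["label"]) == list(b["label"])

    def test_zero_pc1_is_NA(self):
        out = assign_compartments(bins_frame([0.0, 1.0, -1.0]),
                                  np.array([10.0, 500.0, 1.0]))
        assert out.loc[0, "label"] == "NA"


class TestSwitchSegments:
    def _labelled(self, labels):
        df = bins_frame([1.0 if l == "A" else (-1.0 if l == "B" else 0.0)
                         for l in labels])
        df["label"] = labels
        return df

    def test_two_bin_flip_is_one_switch_segment(self):
        segs = detect_switch_segments(self._labelled(["A", "A", "A", "A"]),
                                      self._labelled(["A", "B", "B", "A"]))
        switches = segs[segs["class"] == "A2B"]
        assert len(switches) == 1
        assert switches.iloc[0]["n_bins"] == 2

    def test_single_bin_flip_is_not_a_switch(self):
        segs = detect_switch_segments(self._labelled(["A", "A", "A"]),
                                      self._labelled(["A", "B", "A"]))
        assert not segs["class"].isin(["A2B", "B2A"]).any()

    def test_identical_tracks_give_no_switches(self):
        track = self._labelled(["A", "B", "A", "B"])
        segs = detect_switch_segments(track, track.copy())
        assert not segs["class"].isin(["A2B", "B2A"]).any()

    def test_segments_partition_non_na_bins(self):
        rng = np.random.default_rng(9)
        la = rng.choice(["A", "B", "NA"], 200, p=[0.45, 0.45, 0.1])
        lb = rng.choice(["A", "B", "NA"], 200, p=[0.45, 0.45, 0.1])
        segs = detect_switch_segments(self._labelled(list(la)), self._labelled(list(lb)))
        covered = segs["n_bins"].sum()
        non_na = int(((la != "NA") & (lb != "NA")).sum())
        assert covered == non_na
        assert (segs[segs["class"].isin(["A2B", "B2A"])]["n_bins"] >= 2).all()

    def test_binning_mismatch_rejected(self):
        a = self._labelled(["A", "B"])
        b = self._labelled(["A", "B"])
        b["start"] += 1
        with pytest.raises(ValueError):
            detect_switch_segments(a, b)


def doms(spans, condition="x"):
    return [TadDomain(GenomicInterval("c", s, e), condition=condition) for s, e in spans]


class TestMatchTads:
    def test_identical_sets_all_conserved(self):
        a = doms([(0, 300_000), (300_000, 500_000)], "A")
        out = match_tads(a, doms([(0, 300_000), (300_000, 500_000)], "B"))
        assert (out["label"] == "conserved").all()

    def test_split_domain_is_differential(self):
        a = doms([(0, 500_000)], "A")
        b = doms([(0, 300_000), (300_000, 500_000)], "B")
        out = match_tads(a, b)
        big = out[(out["condition"] == "A")]
        assert big.iloc[0]["label"] == "differential"

    def test_small_boundary_shift_within_tolerance_conserved(self):
        a = doms([(0, 300_000)], "A")
        b = doms([(10_000, 310_000)], "B")
        assert (match_tads(a, b, tolerance=20_000)["label"] == "conserved").all()

    def test_symmetric_and_exhaustive(self):
        rng = np.random.default_rng(21)
        def random_doms(cond):
            edges = np.sort(rng.choice(np.arange(1, 50), 8, replace=False)) * 20_000
            return doms(list(zip(np.r_[0, edges], np.r_[edges, 1_000_000])), cond)
        a, b = random_doms("A"), random_doms("B")
        ab = match_tads(a, b)
        ba = match_tads(b, a)
        assert len(ab) == len(a) + len(b)
        key = ["condition", "chrom", "start", "end"]
        pd.testing.assert_frame_equal(
            ab.sort_values(key).reset_index(drop=True)[key + ["label"]],
            ba.sort_values(key).reset_index(drop=True)[key + ["label"]])


class TestSvTadStats:
    def _comparisons(self, spans_labels):
        return pd.DataFrame([{"condition": "A", "stage": "", "chrom": "c",
                              "start": s, "end": e, "label": lab, "partner": ""}
                             for s, e, lab in spans_labels])

    def _svs(self, positions, length=100):
        return [SVRecord(f"s{i}", "DEL", GenomicInterval("c", p, p + length), length)
                for i, p in enumerate(positions)]

    def test_equal_counts_give_t_zero_p_one(self):
        comp = self._comparisons([(0, 10_000, "conserved"),
                                  (10_000, 20_000, "conserved"),
                                  (20_000, 30_000, "differential"),
                                  (30_000, 40_000, "differential")])
        out, stats = sv_counts_per_tad(self._svs([100, 10_100, 20_100, 30_100]), comp)
        assert stats["t"] == 0.0 and stats["p"] == 1.0

    def test_welch_statistic_matches_closed_form(self):
        comp = self._comparisons(
            [(k * 1000, (k + 1) * 1000, "conserved") for k in range(4)]
            + [(k * 1000, (k + 1) * 1000, "differential") for k in range(4, 8)])
        svs = self._svs([50, 1050, 1060, 2050, 4050, 4060, 4070, 5050, 5060, 6050], length=10)
        out, stats = sv_counts_per_tad(svs, comp)
        cons = out[out["label"] == "conserved"]["sv_count"].to_numpy()
        diff = out[out["label"] == "differential"]["sv_count"].to_numpy()
        t_ref, p_ref = sps.ttest_ind(diff, cons, equal_var=False)
        assert stats["t"] == pytest.approx(float(t_ref))
        assert stats["p"] == pytest.approx(float(p_ref))

    def test_planted_enrichment_detected(self):
        rng = np.random.default_rng(31)
        spans = [(k * 10_000, (k + 1) * 10_000,
                  "differential" if k % 2 else "conserved") for k in range(60)]
        comp = self._comparisons(spans)
        positions = []
        for s, e, lab in spans:
            n = rng.poisson(9 if lab == "differential" else 3)
            positions.extend(rng.integers(s, e - 100, n).tolist())
        _, stats = sv_counts_per_tad(self._svs(sorted(positions)), comp)
        assert stats["mean_differential"] > stats["mean_conserved"]
        assert stats["p"] < 0.01

    def test_empty_group_reports_counts_only(self):
        comp = self._comparisons([(0, 10_000, "conserved")])
        _, stats = sv_counts_per_tad(self._svs([5]), comp)
        assert np.isnan(stats["t"]) and np.isnan(stats["p"])

    def test_density_profile_peaks_where_svs_are(self):
        comp = self._comparisons([(100_000, 200_000, "differential"),
                                  (300_000, 400_000, "differential")])
        svs = self._svs([149_990, 349_990, 349_995], length=20)  # domain centres
        prof = sv_density_profile(svs, comp, body_bins=51, flank_frac=0.5)
        centre = prof.loc[prof["differential"].idxmax()]
        assert 0.45 < centre["rel_position"] < 0.55
        assert prof["conserved"].sum() == 0

    def test_density_hand_count(self):
        comp = self._comparisons([(1000, 2000, "conserved")])
        # flank 500 each side, 2 body bins of 500: window 500..2500, bins of 500
        svs = self._svs([700, 1200, 2300], length=10)  # midpoints 705, 1205, 2305
        prof = sv_density_profile(svs, comp, body_bins=2, flank_frac=0.5)
        per_mb = 1.0 / (500 / 1e6)
        assert list(prof["conserved"]) == [per_mb, per_mb, 0.0, per_mb]


class TestFractionAndBoundaries:
    def test_fraction_extremes_and_hand_count(self):
        regions = [GenomicInterval("c", 0, 1000)]
        inside = [SVRecord(f"i{k}", "INS", GenomicInterval("c", k, k + 1), 10)
                  for k in range(13)]
        outside = [SVRecord(f"o{k}", "INS", GenomicInterval("c", 5000 + k, 5001 + k), 10)
                   for k in range(2)]
        assert fraction_svs_in_regions(inside, regions) == 1.0
        assert fraction_svs_in_regions(outside, regions) == 0.0
        assert fraction_svs_in_regions(inside + outside, regions) == pytest.approx(13 / 15)
        with pytest.raises(ValueError):
            fraction_svs_in_regions([], regions)

    def test_window_tiling_and_mean_proportion(self):
        layout = GenomeLayout({"c": 30_000_000})
        comp = pd.DataFrame([
            {"condition": "A", "stage": "", "chrom": "c", "start": s, "end": e,
             "label": "conserved", "partner": ""}
            for s, e in [(1_000_000, 2_000_000),       # window 0: 2 boundaries
                         (12_000_000, 14_000_000),     # window 1: 2 boundaries
                         (22_000_000, 24_000_000)]])   # window 2: 2 boundaries
        # SVs: both boundaries of domain 1 hit, one of domain 2, none of domain 3
        svs = [SVRecord("a", "DEL", GenomicInterval("c", 999_000, 1_001_000), 2000),
               SVRecord("b", "DEL", GenomicInterval("c", 1_999_000, 2_001_000), 2000),
               SVRecord("d", "DEL", GenomicInterval("c", 11_999_000, 12_001_000), 2000)]
        df, mean = boundary_sv_window_stats(comp, svs, layout)
        assert len(df) == 3
        assert list(df["proportion"]) == [1.0, 0.5, 0.0]
        assert mean == pytest.approx(0.5)

    def test_no_svs_gives_zero_mean(self):
        layout = GenomeLayout({"c": 10_000_000})
        comp = pd.DataFrame([{"condition": "A", "stage": "", "chrom": "c",
                              "start": 1_000_000, "end": 2_000_000,
                              "label": "conserved", "partner": ""}])
        _, mean = boundary_sv_window_stats(comp, [], layout)
        assert mean == 0.0

    def test_differential_regions_are_merged_union(self):
        comp = pd.DataFrame([
            {"condition": "A", "stage": "", "chrom": "c", "start": 0, "end": 100,
             "label": "differential", "partner": ""},
            {"condition": "B", "stage": "", "chrom": "c", "start": 50, "end": 150,
             "label": "differential", "partner": ""},
            {"condition": "A", "stage": "", "chrom": "c", "start": 500, "end": 600,
             "label": "conserved", "partner": ""}])
        assert differential_regions(comp) == [GenomicInterval("c", 0, 150)]
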