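"""Coordinate conventions, interval algebra, and format round trips."""

import numpy as np
import pandas as pd
import pytest

from svcascade import GeneModel, GenomeLayout, GenomicInterval, merge_intervals
from svcascade.genome import IntervalIndex, to_one_based, to_zero_based
from svcascade import io as gio


class TestIntervals:
    def test_invalid_intervals_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)

    def test_overlap_and_containment(self):
        a = GenomicInterval("chr1", 0, 1000)
        b = GenomicInterval("chr1", 999, 2000)
        assert a.overlaps(b) and a.overlap_len(b) == 1
        assert not a.overlaps(GenomicInterval("chr2", 0, 1000))
        assert a.contains(GenomicInterval("chr1", 0, 1000))

    def test_coordinate_conversions_are_inverse(self):
        for pos in (1, 17, 10**9):
            assert to_one_based(to_zero_based(pos)) == pos

    def test_merge_intervals_union(self):
        merged = merge_intervals([
            GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 5, 20),
            GenomicInterval("chr1", 30, 40), GenomicInterval("chr2", 0, 5),
        ])
        assert merged == [GenomicInterval("chr1", 0, 20),
                          GenomicInterval("chr1", 30, 40),
                          GenomicInterval("chr2", 0, 5)]

    def test_layout_validation(self, layout):
        with pytest.raises(ValueError):
            layout.validate(GenomicInterval("chrX", 0, 10))
        with pytest.raises(ValueError):
            layout.validate(GenomicInterval("chr2", 0, 500_001))
        with pytest.raises(ValueError):
            GenomeLayout({"chr1": 0})

    def test_interval_index_matches_bruteforce(self):
        rng = np.random.default_rng(42)
        stored = [GenomicInterval("chr1", int(s), int(s + l))
                  for s, l in zip(rng.integers(0, 10_000, 300),
                                  rng.integers(1, 500, 300))]
        index = IntervalIndex((iv, i) for i, iv in enumerate(stored))
        for _ in range(100):
            q = GenomicInterval("chr1", int(rng.integers(0, 10_000)),
                                int(rng.integers(10_000, 10_500)))
            expected = {i for i, iv in enumerate(stored) if iv.overlaps(q)}
            assert set(index.query(q)) == expected


class TestGeneModel:
    def test_tss_and_upstream_are_strand_aware(self):
        plus = GeneModel("p", GenomicInterval("chr1", 5000, 8000), "+")
        minus = GeneModel("m", GenomicInterval("chr1", 5000, 8000), "-")
        assert plus.tss == 5000 and minus.tss == 7999
        assert plus.upstream(2000) == GenomicInterval("chr1", 3000, 5000)
        assert minus.upstream(2000) == GenomicInterval("chr1", 8000, 10_000)

    def test_exon_invariants_enforced(self):
        with pytest.raises(ValueError):
            GeneModel("g", GenomicInterval("chr1", 0, 100), "+",
                      [GenomicInterval("chr1", 50, 150)])
        with pytest.raises(ValueError):
            GeneModel("g", GenomicInterval("chr1", 0, 100), "+",
                      [GenomicInterval("chr1", 0, 60), GenomicInterval("chr1", 50, 100)])


class TestCytosineReport:
    def _write(self, path, rows):
        path.write_text("".join("\t".join(map(str, r)) + "\n" for r in rows))

    def test_position_becomes_zero_based_and_filter_is_strict(self, tmp_path):
        path = tmp_path / "r.tsv"
        self._write(path, [
            ("chr1", 1, "+", 3, 2, "CG", "CGG"),    # coverage 5 -> dropped
            ("chr1", 10, "+", 4, 2, "CG", "CGA"),   # coverage 6 -> kept, pos 9
        ])
        df = gio.read_cytosine_report(path, min_coverage=5)
        assert len(df) == 1
        assert df.loc[0, "pos"] == 9

    def test_round_trip_preserves_counts(self, tmp_path):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "chrom": "chr1", "pos": np.sort(rng.choice(10_000, 50, replace=False)),
            "strand": "+", "meth": rng.integers(0, 10, 50),
            "unmeth": rng.integers(6, 15, 50), "context": "CHG", "trinuc": "CHG",
        })
        path = tmp_path / "w.tsv"
        gio.write_cytosine_report(df, path)
        back = gio.read_cytosine_report(path, min_coverage=0)
        pd.testing.assert_frame_equal(back[["pos", "meth", "unmeth"]],
                                      df[["pos", "meth", "unmeth"]].astype(int))

    def test_malformed_and_unknown_context_raise_with_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        self._write(path, [("chr1", "x", "+", 3, 9, "CG", "CGG")])
        with pytest.raises(ValueError, match="line 1"):
            gio.read_cytosine_report(path)
        self._write(path, [("chr1", 1, "+", 3, 9, "CZZ", "CZZ")])
        with pytest.raises(ValueError, match="context"):
            gio.read_cytosine_report(path)


class TestBedFamily:
    def test_bed_and_bedgraph(self, tmp_path, layout):
        bed = tmp_path / "a.bed"
        bed.write_text("chr1\t0\t1000\n")
        assert gio.read_intervals(bed, "BED", layout) == [GenomicInterval("chr1", 0, 1000)]
        bg = tmp_path / "a.bedgraph"
        bg.write_text("chr1\t0\t40000\t-1.25\n")
        [(iv, value)] = gio.read_intervals(bg, "bedGraph")
        assert value == -1.25 and iv.length == 40_000

    def test_empty_file_gives_empty_collection(self, tmp_path):
        empty = tmp_path / "e.bed"
        empty.write_text("")
        assert gio.read_intervals(empty, "BED") == []

    def test_bad_interval_or_chrom_raise(self, tmp_path, layout):
        bad = tmp_path / "b.bed"
        bad.write_text("chr1\t1000\t1000\n")
        with pytest.raises(ValueError):
            gio.read_intervals(bad, "BED")
        bad.write_text("chrZ\t0\t10\n")
        with pytest.raises(ValueError):
            gio.read_intervals(bad, "BED", layout)


class TestGff3:
    def test_one_based_conversion_and_round_trip(self, tmp_path, toy_genes):
        path = tmp_path / "g.gff3"
        path.write_text("##gff-version 3\n"
                        "chr1\tsrc\tgene\t1\t100\t.\t+\t.\tID=g1\n"
                        "chr1\tsrc\texon\t1\t100\t.\t+\t.\tID=g1.e1;Parent=g1\n")
        [gene] = gio.read_gff3_genes(path)
        assert gene.interval == GenomicInterval("chr1", 0, 100)

        rt = tmp_path / "rt.gff3"
        gio.write_gff3_genes(toy_genes, rt)
        back = gio.read_gff3_genes(rt)
        assert {(g.gene_id, g.interval, g.strand, tuple(g.exons)) for g in back} == \
               {(g.gene_id, g.interval, g.strand, tuple(g.exons)) for g in toy_genes}

    def test_duplicate_gene_id_rejected(self, tmp_path):
        path = tmp_path / "dup.gff3"
        path.write_text("chr1\ts\tgene\t1\t10\t.\t+\t.\tID=g1\n"
                        "chr1\ts\tgene\t20\t30\t.\t+\t.\tID=g1\n")
        with pytest.raises(ValueError, match="duplicate"):
            gio.read_gff3_genes(path)


class TestRnaModTable:
    def _frame(self, **overrides):
        data = {"transcript": ["t1"], "position": [5], "type": ["m6A"],
                "modified": [5], "coverage": [10], "fraction": [0.5]}
        data.update(overrides)
        return pd.DataFrame(data)

    def test_consistent_fraction_accepted(self, tmp_path):
        path = tmp_path / "m.tsv"
        self._frame().to_csv(path, sep="\t", index=False)
        df = gio.read_rnamod_table(path)
        assert df.loc[0, "fraction"] == 0.5

    def test_inconsistent_fraction_rejected(self, tmp_path):
        path = tmp_path / "m.tsv"
        self._frame(fraction=[0.9]).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="inconsistent"):
            gio.read_rnamod_table(path)

    def test_fraction_out_of_range_rejected(self, tmp_path):
        path = tmp_path / "m.tsv"
        self._frame(fraction=[1.5]).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="fraction"):
            gio.read_rnamod_table(path)
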