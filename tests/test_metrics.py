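"""GC statistics, splice census and length summaries."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from intronarch import (
    gc_by_codon_position,
    gc_content,
    intron_length_bins,
    length_summary,
    splice_site_census,
    splice_site_records,
)
from intronarch.datasets import _gene_with_intron_sites
from intronarch.models import GeneModel


class TestGCContent:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ATGC", 50.0), ("GGCC", 100.0), ("AATT", 0.0), ("AANN", 0.0), ("atgc", 50.0)],
    )
    def test_examples(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_ambiguity_excluded_from_denominator(self):
        # 2 of 4 counted bases are GC; the 4 Ns are ignored entirely
        assert gc_content("GCATNNNN") == pytest.approx(50.0)

    def test_all_ambiguous_is_nan_not_zero(self):
        assert math.isnan(gc_content("NNNN"))
        assert math.isnan(gc_content(""))


class TestGCByCodonPosition:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("ATGGCC", (50.0, 50.0, 100.0)),
            ("AAATTT", (0.0, 0.0, 0.0)),
            ("GCGGCG", (100.0, 100.0, 100.0)),  # codons GCG,GCG: C at every 2nd position
        ],
    )
    def test_hand_counts(self, seq, expected):
        assert gc_by_codon_position(seq) == pytest.approx(expected)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            gc_by_codon_position("AT")

    def test_trailing_partial_codon_dropped(self):
        with pytest.warns(UserWarning):
            assert gc_by_codon_position("ATGGCCGG") == pytest.approx((50.0, 50.0, 100.0))

    @settings(deadline=None, max_examples=200)
    @given(st.text(alphabet="ACGTN", min_size=3, max_size=90))
    def test_matches_bruteforce_tally(self, seq):
        seq = seq[: len(seq) - len(seq) % 3]
        if len(seq) < 3:
            return
        got = gc_by_codon_position(seq)
        for pos in range(3):
            bases = [seq[i] for i in range(pos, len(seq), 3)]
            counted = [b for b in bases if b in "ACGT"]
            if not counted:
                assert math.isnan(got[pos])
            else:
                gc = sum(b in "GC" for b in counted)
                assert got[pos] == pytest.approx(100.0 * gc / len(counted))


class TestSpliceCensus:
    def test_canonical_and_noncanonical_typing(self):
        m = _gene_with_intron_sites("tx", "g", [("GT", "AG"), ("GG", "CA")])
        recs = splice_site_records([m])
        assert [r.site_type for r in recs] == ["GT-AG", "GG-CA"]
        assert [r.canonical for r in recs] == [True, False]
        assert [r.intron_index for r in recs] == [1, 2]

    def test_census_conservation(self):
        models = [
            _gene_with_intron_sites("a", "g1", [("GT", "AG")] * 5 + [("GG", "CA")]),
            _gene_with_intron_sites("b", "g2", [("GC", "AG")] * 2),
        ]
        df = splice_site_census(models).set_index("site_type")
        total = int(df.loc["total", "count"])
        assert int(df.loc["canonical", "count"]) + int(df.loc["non_canonical", "count"]) == total
        type_rows = df.drop(["canonical", "non_canonical", "total"])
        assert int(type_rows["count"].sum()) == total
        assert type_rows["percent"].sum() == pytest.approx(100.0)

    def test_short_intron_excluded(self):
        # a 3 nt intron cannot have distinct donor and acceptor dinucleotides
        exon = "ATGGCAGTCAAG"
        gene_seq = exon + "GTG" + exon
        m = GeneModel(
            taxon="t", gene_id="g", scaffold="s", span=(0, len(gene_seq)), strand="+",
            exons=[(0, 12), (15, 27)], gene_seq=gene_seq,
        )
        recs = splice_site_records([m])
        assert len(recs) == 1 and not recs[0].valid
        census = splice_site_census([m]).set_index("site_type")
        assert int(census.loc["total", "count"]) == 0

    def test_intronless_contribute_nothing(self):
        m = _gene_with_intron_sites("t", "g", [])
        assert splice_site_records([m]) == []


class TestIntronLengthBins:
    def _model_with_intron_lengths(self, lengths):
        exon = "ATGGCAGTCAAG"
        pieces, exons, pos = [exon], [(0, len(exon))], len(exon)
        for L in lengths:
            intron = "GT" + "A" * (L - 4) + "AG"
            pieces.append(intron)
            pos += L
            pieces.append(exon)
            exons.append((pos, pos + len(exon)))
            pos += len(exon)
        seq = "".join(pieces)
        return GeneModel(
            taxon="t", gene_id="g", scaffold="s", span=(0, len(seq)), strand="+",
            exons=exons, gene_seq=seq,
        )

    def test_strict_bin_edges(self):
        m = self._model_with_intron_lengths([100, 6000, 12000])
        row = intron_length_bins([m]).iloc[0]
        assert (row["<=5000"], row["5001-10000"], row[">10000"]) == (1, 1, 1)

    def test_exactly_5000_in_first_bin(self):
        row = intron_length_bins([self._model_with_intron_lengths([5000])]).iloc[0]
        assert row["<=5000"] == 1 and row["5001-10000"] == 0

    def test_shortest_real_intron(self):
        row = intron_length_bins([self._model_with_intron_lengths([43, 43])]).iloc[0]
        assert row["<=5000"] == 2

    def test_intronless_zero_vector(self):
        row = intron_length_bins([self._model_with_intron_lengths([])]).iloc[0]
        assert row["<=5000"] == 0 and row[">10000"] == 0

    def test_non_monotone_edges_rejected(self):
        with pytest.raises(ValueError):
            intron_length_bins([self._model_with_intron_lengths([100])], edges=(10000, 5000))


class TestLengthSummary:
    def test_intron_fraction(self):
        m = _gene_with_intron_sites("t", "g", [("GT", "AG")] * 4)
        df = length_summary([m])
        row = df.iloc[0]
        assert row["gene_length"] == len(m.gene_seq)
        assert row["cds_length"] == len(m.cds_seq)
        expected = 1 - len(m.cds_seq) / len(m.gene_seq)
        assert row["intron_fraction"] == pytest.approx(expected)
        assert 0 <= row["intron_fraction"] < 1

    def test_intronless_fraction_zero(self):
        m = _gene_with_intron_sites("t", "g", [])
        assert length_summary([m]).iloc[0]["intron_fraction"] == 0.0

    def test_genome_size_join(self):
        m = _gene_with_intron_sites("t", "g", [])
        df = length_summary([m], {"t": 1.5e9})
        assert df.iloc[0]["genome_size"] == pytest.approx(1.5e9)
        missing = length_summary([m], {"other": 1.0})
        assert math.isnan(missing.iloc[0]["genome_size"])
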