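"""Seeded local search, hit chaining and block classification.

The oracle here is an independent, unbanded affine-gap Smith-Waterman
(plain dict DP, no windowing or seeding) under the same scoring scheme.
"""

import numpy as np
import pytest

from intronarch import (
    chain_hits_to_blocks,
    classify_block_location,
    scan_gene,
    seeded_local_search,
    smith_waterman,
)
from intronarch.dupscan import ExonHit, GAP_EXTEND, GAP_OPEN, MATCH, MISMATCH
from intronarch.simulate import DuplicationSpec, SimConfig, simulate_family


def oracle_sw_score(query, subject):
    """Full affine Smith-Waterman best score, written independently."""
    n, m = len(query), len(subject)
    NEG = float("-inf")
    best = 0
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] + GAP_EXTEND, H[i][j - 1] + GAP_OPEN + GAP_EXTEND)
            F[i][j] = max(F[i - 1][j] + GAP_EXTEND, H[i - 1][j] + GAP_OPEN + GAP_EXTEND)
            sub = MATCH if query[i - 1] == subject[j - 1] else MISMATCH
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return int(best)


def _rand_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestSmithWaterman:
    def test_exact_copy_scores_perfect(self):
        q = "ACGTACGTAACCGGTT"
        res = smith_waterman(q, "TTTT" + q + "GGGG")
        score, q0, q1, s0, s1, matches, columns = res
        assert score == MATCH * len(q)
        assert (q0, q1) == (0, len(q))
        assert matches == columns == len(q)

    def test_no_similarity_returns_none(self):
        assert smith_waterman("AAAA", "CCCC") is None

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            q = _rand_dna(rng, int(rng.integers(8, 30)))
            s = _rand_dna(rng, int(rng.integers(10, 60)))
            res = smith_waterman(q, s)
            got = res[0] if res else 0
            assert got == oracle_sw_score(q, s)

    def test_banded_never_exceeds_full(self):
        rng = np.random.default_rng(8)
        for _ in range(40):
            q = _rand_dna(rng, 25)
            s = _rand_dna(rng, 60)
            full = oracle_sw_score(q, s)
            res = smith_waterman(q, s, band=(-3, 3))
            banded = res[0] if res else 0
            assert banded <= full


class TestSeededSearch:
    def test_verbatim_copy_found(self):
        rng = np.random.default_rng(1)
        exon = _rand_dna(rng, 120)
        subject = _rand_dna(rng, 500) + exon + _rand_dna(rng, 500)
        (hit,) = seeded_local_search(exon, subject, exon_index=3)
        assert hit.identity == 1.0
        assert hit.coverage == 1.0
        assert (hit.start, hit.end) == (500, 620)
        assert hit.strand == "+"

    def test_inverted_copy_found_on_minus_strand(self):
        rng = np.random.default_rng(2)
        exon = _rand_dna(rng, 100)
        rc = exon.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        subject = _rand_dna(rng, 300) + rc + _rand_dna(rng, 300)
        hits = seeded_local_search(exon, subject)
        assert any(h.strand == "-" and h.identity == 1.0 for h in hits)

    def test_no_seed_no_hits(self):
        assert seeded_local_search("ATATATATATATAT", "GCGCGCGCGCGCGCGC" * 10) == []

    def test_query_shorter_than_k_skipped(self, caplog):
        with caplog.at_level("WARNING", logger="intronarch"):
            assert seeded_local_search("ACGTAC", "ACGTAC" * 50) == []
        assert "skipped" in caplog.text

    def test_self_hit_excluded(self):
        rng = np.random.default_rng(3)
        exon = _rand_dna(rng, 150)
        subject = _rand_dna(rng, 200) + exon + _rand_dna(rng, 200)
        hits = seeded_local_search(exon, subject, exclude=(200, 350))
        assert hits == []

    def test_mutated_copy_identity_near_divergence(self):
        rng = np.random.default_rng(4)
        exon = _rand_dna(rng, 200)
        mutated = list(exon)
        for i in rng.choice(len(exon), size=20, replace=False):
            mutated[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[i]]
        subject = _rand_dna(rng, 400) + "".join(mutated) + _rand_dna(rng, 400)
        hits = seeded_local_search(exon, subject)
        assert hits, "10% diverged copy must still be found"
        assert hits[0].identity == pytest.approx(0.90, abs=0.03)


def _hit(exon, start, end, strand="+"):
    return ExonHit(exon, start, end, strand, 1.0, 1.0, 2 * (end - start))


class TestChaining:
    def test_colinear_run_chains_to_one_block(self):
        hits = [_hit(i, 1000 * i, 1000 * i + 200) for i in range(4, 17)]
        (block,) = chain_hits_to_blocks(hits)
        assert (block.exon_first, block.exon_last) == (4, 16)
        assert block.exon_span == "exon 4 to exon 16"

    def test_distant_hits_split(self):
        hits = [_hit(1, 0, 200), _hit(2, 100200, 100400)]
        blocks = chain_hits_to_blocks(hits, max_gap=20000)
        assert len(blocks) == 2

    def test_inverted_block_decreasing_indices(self):
        hits = [_hit(5, 0, 200, "-"), _hit(4, 300, 500, "-"), _hit(3, 600, 800, "-")]
        (block,) = chain_hits_to_blocks(hits)
        assert (block.exon_first, block.exon_last, block.strand) == (3, 5, "-")


class TestClassification:
    @pytest.fixture
    def model(self):
        cfg = SimConfig(seed=6, n_leaves=2, gain_rate=0, loss_rate=0, subst_rate=0)
        models, _ = simulate_family(cfg)
        return models[0]

    def test_block_inside_intron(self, model):
        off = model.region_gene_start
        s, e = model.introns[13]  # intron 14, 1-based
        block = chain_hits_to_blocks([_hit(4, off + s + 2, off + e - 2)])[0]
        block = classify_block_location(block, model)
        assert block.location == "internal"
        assert block.intron_index == 14

    def test_upstream_distance(self, model):
        gene_start = model.region_gene_start
        block = chain_hits_to_blocks([_hit(2, gene_start - 2500, gene_start - 2000)])[0]
        block = classify_block_location(block, model)
        assert block.location == "upstream"
        assert block.distance == 2000

    def test_downstream_boundary(self, model):
        gene_end = model.region_gene_start + len(model.gene_seq)
        block = chain_hits_to_blocks([_hit(2, gene_end + 1, gene_end + 300)])[0]
        block = classify_block_location(block, model)
        assert block.location == "downstream"
        assert block.distance == 1

    def test_self_overlap_rejected(self, model):
        off = model.region_gene_start
        s, e = model.exons[3]
        block = chain_hits_to_blocks([_hit(4, off + s, off + e)])[0]
        with pytest.raises(AssertionError, match="self-hit"):
            classify_block_location(block, model)


class TestPlantedDuplicationRecovery:
    def test_exact_recovery_at_zero_divergence(self):
        cfg = SimConfig(
            seed=9, n_leaves=4, gain_rate=0, loss_rate=0, subst_rate=0,
            duplications=[
                DuplicationSpec("t1", 4, 8, "intron", 10, 0.0),
                DuplicationSpec("t2", 1, 5, "upstream", 15000, 0.0),
                DuplicationSpec("t3", 18, 22, "downstream", 8000, 0.0),
            ],
            flank=20000,
        )
        models, truth = simulate_family(cfg)
        by_taxon = {m.taxon: m for m in models}
        for planted in truth.duplications:
            assert planted["status"] == "planted"
            blocks = scan_gene(by_taxon[planted["taxon"]])
            match = [
                b for b in blocks
                if (b.exon_first, b.exon_last) == (planted["exon_first"], planted["exon_last"])
            ]
            assert match, f"planted {planted} not recovered"
            b = match[0]
            if planted["target"] == "intron":
                assert b.location == "internal" and b.intron_index == planted["position"]
            else:
                assert b.location == planted["target"]
                assert b.distance == pytest.approx(planted["position"], abs=5)
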