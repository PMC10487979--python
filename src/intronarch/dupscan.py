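"""Partial gene duplication detection.

Each exon is searched against the gene plus its flanking sequence with an
exact k-mer seed scan followed by Smith-Waterman refinement restricted to
the seeded window (affine gaps: match +2, mismatch -3, gap open -5, gap
extend -2 per residue). Colinear exon hits are chained into duplication
blocks and each block is classified by where it sits relative to the gene:
inside an intron (internal), or upstream/downstream at a distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .models import GeneModel

logger = logging.getLogger("intronarch")

MATCH = 2
MISMATCH = -3
GAP_OPEN = -5  # charged once per gap, in addition to the per-residue extend
GAP_EXTEND = -2

_NEG = -(10**9)


@dataclass
class ExonHit:
    """A local-alignment hit of one exon elsewhere in the scanned sequence."""

    exon_index: int  # 1-based
    start: int  # subject (region) frame, 0-based half-open
    end: int
    strand: str  # '+' or '-' relative to the gene
    identity: float  # matches / aligned columns
    coverage: float  # aligned query span / query length
    score: int


@dataclass
class DuplicationBlock:
    """A chained run of colinear exon hits."""

    exon_first: int
    exon_last: int
    start: int
    end: int
    strand: str
    mean_identity: float
    completeness: str = "partial"  # 'partial' or 'full'
    location: str = ""  # 'internal' / 'upstream' / 'downstream'
    intron_index: int | None = None  # 1-based, when internal
    distance: int | None = None  # nt from gene boundary, when flanking
    straddle: bool = False
    hits: list[ExonHit] = field(default_factory=list)

    @property
    def exon_span(self) -> str:
        return f"exon {self.exon_first} to exon {self.exon_last}"


# ---------------------------------------------------------------------------
# Smith-Waterman (Gotoh affine), optionally band-restricted
# ---------------------------------------------------------------------------

def smith_waterman(query: str, subject: str, band: tuple[int, int] | None = None):
    """Local affine-gap alignment.

    ``band`` restricts DP cells to diagonals ``lo <= j - i <= hi`` (i = query
    index, j = subject index). Returns ``(score, q0, q1, s0, s1, matches,
    columns)`` for the best local alignment, or None if no positive score.
    """
    n, m = len(query), len(subject)
    lo, hi = band if band is not None else (-n, m)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[_NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (consume subject)
    F = [[_NEG] * (m + 1) for _ in range(n + 1)]  # gap in subject (consume query)
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        qi = query[i - 1]
        j0 = max(1, i + lo)
        j1 = min(m, i + hi)
        Hi, Hp = H[i], H[i - 1]
        Ei, Fi, Fp = E[i], F[i], F[i - 1]
        for j in range(j0, j1 + 1):
            e = max(Ei[j - 1] + GAP_EXTEND, Hi[j - 1] + GAP_OPEN + GAP_EXTEND)
            f = max(Fp[j] + GAP_EXTEND, Hp[j] + GAP_OPEN + GAP_EXTEND)
            d = Hp[j - 1] + (MATCH if qi == subject[j - 1] else MISMATCH)
            h = max(0, d, e, f)
            Ei[j], Fi[j], Hi[j] = e, f, h
            if h > best:
                best, bi, bj = h, i, j
    if best <= 0:
        return None
    # traceback from (bi, bj)
    i, j = bi, bj
    matches = columns = 0
    while i > 0 and j > 0 and H[i][j] > 0:
        h = H[i][j]
        d = H[i - 1][j - 1] + (MATCH if query[i - 1] == subject[j - 1] else MISMATCH)
        if h == d:
            matches += query[i - 1] == subject[j - 1]
            columns += 1
            i, j = i - 1, j - 1
        elif h == E[i][j]:
            # walk the whole subject gap
            while j > 0 and E[i][j] != H[i][j - 1] + GAP_OPEN + GAP_EXTEND:
                columns += 1
                j -= 1
            columns += 1
            j -= 1
        elif h == F[i][j]:
            while i > 0 and F[i][j] != H[i - 1][j] + GAP_OPEN + GAP_EXTEND:
                columns += 1
                i -= 1
            columns += 1
            i -= 1
        else:  # local start
            break
    return best, i, bi, j, bj, matches, columns


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _seed_windows(query: str, subject: str, k: int, diag_slack: int = 24):
    """Cluster exact k-mer seed matches into candidate subject windows.

    Returns ``(s_window_start, s_window_end, diag_lo, diag_hi)`` tuples.
    """
    index: dict[str, list[int]] = {}
    for j in range(len(subject) - k + 1):
        index.setdefault(subject[j : j + k], []).append(j)
    seeds = []  # (diag, spos, qpos)
    step = max(1, k // 2)
    for q in range(0, len(query) - k + 1, step):
        for s in index.get(query[q : q + k], ()):
            seeds.append((s - q, s, q))
    if not seeds:
        return []
    seeds.sort()
    clusters: list[list[tuple[int, int, int]]] = [[seeds[0]]]
    for seed in seeds[1:]:
        last = clusters[-1][-1]
        if seed[0] - last[0] <= diag_slack and abs(seed[1] - last[1]) <= len(query) + diag_slack:
            clusters[-1].append(seed)
        else:
            clusters.append([seed])
    windows = []
    margin = diag_slack + k
    for cl in clusters:
        diags = [c[0] for c in cl]
        s_min = min(c[1] - c[2] for c in cl)
        s_max = max(c[1] + (len(query) - c[2]) for c in cl)
        windows.append(
            (
                max(0, s_min - margin),
                min(len(subject), s_max + margin),
                min(diags) - margin,
                max(diags) + margin,
            )
        )
    # merge overlapping windows
    windows.sort()
    merged = [list(windows[0])]
    for w in windows[1:]:
        if w[0] <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], w[1])
            merged[-1][2] = min(merged[-1][2], w[2])
            merged[-1][3] = max(merged[-1][3], w[3])
        else:
            merged.append(list(w))
    return [tuple(w) for w in merged]


def _overlaps(a0: int, a1: int, b0: int, b1: int) -> bool:
    return a0 < b1 and b0 < a1


def seeded_local_search(
    query: str,
    subject: str,
    exon_index: int = 0,
    exclude: tuple[int, int] | None = None,
    k: int = 11,
    min_identity: float = 0.70,
    min_coverage: float = 0.50,
) -> list[ExonHit]:
    """Find local-alignment hits of ``query`` (one exon) in ``subject``.

    Both strands are scanned. ``exclude`` is the exon's own location in the
    subject frame; hits overlapping it are the trivial self-match and are
    dropped. Queries shorter than ``k`` are skipped with a warning.
    """
    if len(query) < k:
        logger.warning("exon %d shorter than seed size %d; skipped", exon_index, k)
        return []
    hits: list[ExonHit] = []
    for strand, q in (("+", query), ("-", _revcomp(query))):
        for ws, we, dlo, dhi in _seed_windows(q, subject, k):
            sub = subject[ws:we]
            band = (dlo - ws, dhi - ws)
            res = smith_waterman(q, sub, band=band)
            if res is None:
                continue
            score, q0, q1, s0, s1, matches, columns = res
            if columns == 0:
                continue
            identity = matches / columns
            coverage = (q1 - q0) / len(q)
            start, end = ws + s0, ws + s1
            if exclude and _overlaps(start, end, *exclude):
                continue
            if identity >= min_identity and coverage >= min_coverage:
                hits.append(
                    ExonHit(
                        exon_index=exon_index,
                        start=start,
                        end=end,
                        strand=strand,
                        identity=identity,
                        coverage=coverage,
                        score=score,
                    )
                )
    # deduplicate overlapping hits, keep best-scoring
    hits.sort(key=lambda h: -h.score)
    kept: list[ExonHit] = []
    for h in hits:
        if not any(
            k2.strand == h.strand and _overlaps(h.start, h.end, k2.start, k2.end)
            for k2 in kept
        ):
            kept.append(h)
    kept.sort(key=lambda h: h.start)
    return kept


def chain_hits_to_blocks(
    hits: list[ExonHit],
    max_gap: int = 20000,
    forbidden: list[tuple[int, int]] | None = None,
) -> list[DuplicationBlock]:
    """Chain colinear exon hits into duplication blocks.

    Hits are sorted by position; a run of strictly increasing (plus strand)
    or strictly decreasing (inverted copies) exon indices with inter-hit
    gaps below ``max_gap`` forms one block. A chain never extends across a
    ``forbidden`` interval (the gene's own exons): a contiguous duplicate
    copy cannot contain the source exons, so hits on opposite sides of them
    are distinct blocks.
    """
    blocks: list[DuplicationBlock] = []
    for strand in ("+", "-"):
        shits = sorted(
            (h for h in hits if h.strand == strand), key=lambda h: (h.start, h.end)
        )
        run: list[ExonHit] = []
        direction = 0

        def flush():
            nonlocal run, direction
            if run:
                idx = [h.exon_index for h in run]
                blocks.append(
                    DuplicationBlock(
                        exon_first=min(idx),
                        exon_last=max(idx),
                        start=min(h.start for h in run),
                        end=max(h.end for h in run),
                        strand=strand,
                        mean_identity=sum(h.identity for h in run) / len(run),
                        hits=list(run),
                    )
                )
            run, direction = [], 0

        for h in shits:
            if not run:
                run.append(h)
                continue
            prev = run[-1]
            gap = h.start - prev.end
            step = h.exon_index - prev.exon_index
            ok_dir = (direction == 0 and step != 0) or (direction != 0 and step * direction > 0)
            crosses = any(
                _overlaps(prev.end, h.start, fs, fe) for fs, fe in (forbidden or ())
            )
            if gap <= max_gap and ok_dir and not crosses:
                direction = direction or (1 if step > 0 else -1)
                run.append(h)
            else:
                flush()
                run.append(h)
        flush()
    blocks.sort(key=lambda b: (b.start, b.end))
    return blocks


def classify_block_location(block: DuplicationBlock, model: GeneModel) -> DuplicationBlock:
    """Assign the location class of a block relative to its gene.

    The block and the model share the region coordinate frame. Fully inside
    intron *i* of the gene -> internal(i); beyond the gene boundaries ->
    upstream/downstream with the distance to the boundary; straddling an
    exon boundary -> internal by midpoint with a straddle flag.
    """
    off = model.region_gene_start
    gene_start, gene_end = off, off + len(model.gene_seq)
    src_exons = [(off + s, off + e) for s, e in model.exons]
    span_exons = src_exons[block.exon_first - 1 : block.exon_last]
    if any(_overlaps(block.start, block.end, s, e) for s, e in span_exons):
        raise AssertionError(
            f"block {block.exon_span} overlaps its own source exons (self-hit leak)"
        )
    block.completeness = "full" if (block.exon_first == 1 and block.exon_last == len(model.exons)) else "partial"
    if block.end <= gene_start:
        block.location = "upstream"
        block.distance = gene_start - block.end
        return block
    if block.start >= gene_end:
        block.location = "downstream"
        block.distance = block.start - gene_end
        return block
    introns = [(off + s, off + e) for s, e in model.introns]
    for i, (s, e) in enumerate(introns, start=1):
        if s <= block.start and block.end <= e:
            block.location = "internal"
            block.intron_index = i
            return block
    # straddles a boundary: assign by midpoint
    mid = (block.start + block.end) // 2
    block.location = "internal"
    block.straddle = True
    best_i, best_d = 1, None
    for i, (s, e) in enumerate(introns, start=1):
        d = 0 if s <= mid < e else min(abs(mid - s), abs(mid - e))
        if best_d is None or d < best_d:
            best_i, best_d = i, d
    if mid < gene_start:
        block.location, block.distance = "upstream", max(0, gene_start - block.end)
    elif mid >= gene_end:
        block.location, block.distance = "downstream", max(0, block.start - gene_end)
    else:
        block.intron_index = best_i
    return block


def scan_gene(
    model: GeneModel,
    k: int = 11,
    min_identity: float = 0.70,
    min_coverage: float = 0.50,
    max_gap: int = 20000,
) -> list[DuplicationBlock]:
    """Per-exon search over the gene's region sequence, chained and classified."""
    subject = model.region_seq or model.gene_seq
    off = model.region_gene_start
    all_hits: list[ExonHit] = []
    for i, (s, e) in enumerate(model.exons, start=1):
        query = model.gene_seq[s:e]
        all_hits.extend(
            seeded_local_search(
                query,
                subject,
                exon_index=i,
                exclude=(off + s, off + e),
                k=k,
                min_identity=min_identity,
                min_coverage=min_coverage,
            )
        )
    src_exons = [(off + s, off + e) for s, e in model.exons]
    blocks = chain_hits_to_blocks(all_hits, max_gap=max_gap, forbidden=src_exons)
    return [classify_block_location(b, model) for b in blocks]
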