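"""Alternative-splicing event classification and uORF detection.

Events are called pairwise from the intron chains of two transcripts of the
same gene restricted to their shared span: a donor shift, an acceptor
shift, exon skipping, mutually exclusive exons, intron retention, and a
catch-all "other" (which includes alternative first-exon usage). Identical
events found in several pairs are reported once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .models import Interval, Transcript

EVENT_TYPES = (
    "alt_acceptor",
    "alt_donor",
    "exon_skipping",
    "mutually_exclusive",
    "intron_retention",
    "other",
)


@dataclass(frozen=True)
class ASEvent:
    gene_id: str
    transcript_a: str
    transcript_b: str
    event_type: str
    intervals: tuple[Interval, ...]


@dataclass(frozen=True)
class UORF:
    transcript_id: str
    start: int  # transcript coordinates, 0-based
    stop_end: int  # end of the stop codon (half-open)
    length_aa: int  # includes the initiator Met, excludes the stop


def _contained_in_exon(intron: Interval, exons: list[Interval]) -> bool:
    return any(s <= intron[0] and intron[1] <= e for s, e in exons)


def _cluster_diffs(only_a: list[Interval], only_b: list[Interval]):
    """Group differing introns of the two chains into overlap clusters."""
    tagged = [(iv, "a") for iv in only_a] + [(iv, "b") for iv in only_b]
    tagged.sort(key=lambda x: x[0])
    clusters = []
    for iv, who in tagged:
        if clusters and iv[0] < max(e for (s, e), _ in clusters[-1]):
            clusters[-1].append((iv, who))
        else:
            clusters.append([(iv, who)])
    return clusters


def _type_cluster(a_ivs: list[Interval], b_ivs: list[Interval],
                  a_exons: list[Interval], b_exons: list[Interval]) -> str:
    if not a_ivs or not b_ivs:
        # introns unique to one chain: retained in the other if inside its exon
        ivs, other_exons = (a_ivs, b_exons) if a_ivs else (b_ivs, a_exons)
        if all(_contained_in_exon(iv, other_exons) for iv in ivs):
            return "intron_retention"
        return "other"
    if len(a_ivs) == 1 and len(b_ivs) == 1:
        (a0, a1), (b0, b1) = a_ivs[0], b_ivs[0]
        if a0 == b0 and a1 != b1:
            return "alt_acceptor"
        if a1 == b1 and a0 != b0:
            return "alt_donor"
        return "other"
    # one fused intron vs several: exon skipping
    for many, one in ((a_ivs, b_ivs), (b_ivs, a_ivs)):
        if len(one) == 1 and len(many) >= 2:
            if one[0][0] == many[0][0] and one[0][1] == many[-1][1]:
                return "exon_skipping"
    if len(a_ivs) == 2 and len(b_ivs) == 2:
        if a_ivs[0][0] == b_ivs[0][0] and a_ivs[1][1] == b_ivs[1][1]:
            ax = (a_ivs[0][1], a_ivs[1][0])
            bx = (b_ivs[0][1], b_ivs[1][0])
            if ax[1] <= bx[0] or bx[1] <= ax[0]:
                return "mutually_exclusive"
    return "other"


def classify_pair(
    gene_id: str, t1: Transcript, t2: Transcript
) -> list[ASEvent]:
    """Events between two transcripts of one gene (shared coordinate frame)."""
    span1 = (t1.exons[0][0], t1.exons[-1][1])
    span2 = (t2.exons[0][0], t2.exons[-1][1])
    lo, hi = max(span1[0], span2[0]), min(span1[1], span2[1])
    events: list[ASEvent] = []
    if hi <= lo:
        return events
    in1 = [iv for iv in t1.introns if lo <= iv[0] and iv[1] <= hi]
    in2 = [iv for iv in t2.introns if lo <= iv[0] and iv[1] <= hi]
    only1 = [iv for iv in in1 if iv not in in2]
    only2 = [iv for iv in in2 if iv not in in1]
    for cluster in _cluster_diffs(only1, only2):
        a_ivs = sorted(iv for iv, who in cluster if who == "a")
        b_ivs = sorted(iv for iv, who in cluster if who == "b")
        etype = _type_cluster(a_ivs, b_ivs, t1.exons, t2.exons)
        events.append(
            ASEvent(gene_id, t1.transcript_id, t2.transcript_id, etype,
                    tuple(sorted(set(a_ivs + b_ivs))))
        )
    # alternative first/last-exon usage: one transcript starts (or ends)
    # past whole introns of the other -> filed as "other"
    head = [iv for iv in t1.introns + t2.introns if iv[1] <= lo]
    tail = [iv for iv in t1.introns + t2.introns if iv[0] >= hi]
    if head:
        events.append(
            ASEvent(gene_id, t1.transcript_id, t2.transcript_id, "other",
                    ((min(span1[0], span2[0]), lo),))
        )
    if tail:
        events.append(
            ASEvent(gene_id, t1.transcript_id, t2.transcript_id, "other",
                    ((hi, max(span1[1], span2[1])),))
        )
    return events


def classify_as_events(
    gene_id: str,
    transcripts: list[Transcript],
    strands: dict[str, str] | None = None,
) -> list[ASEvent]:
    """Pairwise event calls over all transcripts, deduplicated.

    Two events are the same when their type and affected intervals agree,
    regardless of which transcript pair exposed them.
    """
    if strands and len(set(strands.values())) > 1:
        raise ValueError(f"gene {gene_id!r}: transcripts on different strands")
    if len(transcripts) < 2:
        return []
    seen: dict[tuple, ASEvent] = {}
    ordered = sorted(transcripts, key=lambda t: t.transcript_id)
    for i, t1 in enumerate(ordered):
        for t2 in ordered[i + 1 :]:
            for ev in classify_pair(gene_id, t1, t2):
                key = (ev.event_type, ev.intervals)
                seen.setdefault(key, ev)
    return list(seen.values())


_STOPS = {"TAA", "TAG", "TGA"}


def find_uorfs(
    transcript_seq: str, main_start_offset: int, transcript_id: str = "", min_aa: int = 2
) -> list[UORF]:
    """All upstream ORFs in a transcript's 5' leader.

    An ORF starts with ATG, ends at the first in-frame stop, lies entirely
    upstream of ``main_start_offset`` (stop codon included), may sit in any
    frame, and must encode at least ``min_aa`` residues (initiator Met
    counted, stop excluded). Overlapping uORFs are all reported.
    """
    if not (0 <= main_start_offset <= len(transcript_seq)):
        raise ValueError("main_start_offset outside transcript")
    seq = transcript_seq.upper()
    uorfs: list[UORF] = []
    for i in range(0, max(0, main_start_offset - 2)):
        if seq[i : i + 3] != "ATG":
            continue
        for j in range(i + 3, main_start_offset - 2, 3):
            codon = seq[j : j + 3]
            if codon in _STOPS:
                if j + 3 <= main_start_offset:
                    length_aa = (j - i) // 3
                    if length_aa >= min_aa:
                        uorfs.append(UORF(transcript_id, i, j + 3, length_aa))
                break
    return uorfs
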