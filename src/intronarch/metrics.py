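"""Per-gene descriptive statistics.

Lengths, GC content overall and by codon position (GC1/GC2/GC3), the
splice-site dinucleotide census, and intron-length bins. Percentages are
kept at full precision internally; rendering to 2 decimals happens only in
the report writer.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from .models import GeneModel

_GC = frozenset("GC")
_UNAMBIG = frozenset("ACGT")


def gc_content(seq: str) -> float:
    """GC percentage of a nucleotide string.

    IUPAC ambiguity codes are excluded from both numerator and denominator,
    so N-rich draft sequence does not deflate the estimate. A sequence with
    zero unambiguous bases yields NaN rather than 0.
    """
    seq = seq.upper()
    denom = sum(1 for b in seq if b in _UNAMBIG)
    if denom == 0:
        return math.nan
    gc = sum(1 for b in seq if b in _GC)
    return 100.0 * gc / denom


def gc_by_codon_position(cds_seq: str) -> tuple[float, float, float]:
    """GC percentage over positions 1, 2 and 3 of each complete codon.

    A trailing partial codon is dropped with a warning; sequences shorter
    than one codon are an error.
    """
    if len(cds_seq) < 3:
        raise ValueError("coding sequence shorter than one codon")
    if len(cds_seq) % 3:
        warnings.warn("coding sequence length not a multiple of 3; trailing bases dropped")
        cds_seq = cds_seq[: len(cds_seq) - len(cds_seq) % 3]
    return tuple(gc_content(cds_seq[i::3]) for i in range(3))  # type: ignore[return-value]


@dataclass
class SpliceSiteRecord:
    """Terminal dinucleotides of one intron (strand-normalized)."""

    taxon: str
    gene_id: str
    intron_index: int  # 1-based, transcription order
    donor: str
    acceptor: str
    valid: bool = True

    @property
    def site_type(self) -> str:
        return f"{self.donor}-{self.acceptor}"

    @property
    def canonical(self) -> bool:
        return self.site_type == "GT-AG"


def splice_site_records(models: list[GeneModel]) -> list[SpliceSiteRecord]:
    """One record per intron; introns shorter than 4 nt are flagged invalid."""
    records = []
    for m in models:
        for i, seq in enumerate(m.intron_seqs, start=1):
            seq = seq.upper()
            records.append(
                SpliceSiteRecord(
                    taxon=m.taxon,
                    gene_id=m.gene_id,
                    intron_index=i,
                    donor=seq[:2],
                    acceptor=seq[-2:],
                    valid=len(seq) >= 4,
                )
            )
    return records


def splice_site_census(models: list[GeneModel]) -> pd.DataFrame:
    """Census of splice-site types over all introns of all models.

    Returns one row per site type with count and percentage of valid sites,
    plus summary rows ``canonical``, ``non_canonical`` and ``total``.
    Invalid records (introns < 4 nt) are excluded from all totals.
    """
    records = [r for r in splice_site_records(models) if r.valid]
    total = len(records)
    counts: dict[str, int] = {}
    for r in records:
        counts[r.site_type] = counts.get(r.site_type, 0) + 1
    canonical = counts.get("GT-AG", 0)
    rows = [
        {"site_type": st, "count": n, "percent": 100.0 * n / total if total else math.nan}
        for st, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    for name, n in (
        ("canonical", canonical),
        ("non_canonical", total - canonical),
        ("total", total),
    ):
        rows.append(
            {"site_type": name, "count": n,
             "percent": 100.0 * n / total if total else math.nan}
        )
    return pd.DataFrame(rows, columns=["site_type", "count", "percent"])


DEFAULT_LENGTH_EDGES = (5000, 10000)


def intron_length_bins(
    models: list[GeneModel], edges: tuple[int, ...] = DEFAULT_LENGTH_EDGES
) -> pd.DataFrame:
    """Per-taxon counts of introns per length bin.

    ``edges=(5000, 10000)`` gives bins <=5000, 5001-10000, >10000 — "larger
    than 5 kb" is interpreted strictly (> 5000).
    """
    if list(edges) != sorted(set(edges)):
        raise ValueError(f"bin edges must be strictly increasing, got {edges}")
    labels = (
        [f"<={edges[0]}"]
        + [f"{lo + 1}-{hi}" for lo, hi in zip(edges, edges[1:])]
        + [f">{edges[-1]}"]
    )
    rows = []
    for m in models:
        counts = [0] * len(labels)
        for s, e in m.introns:
            length = e - s
            idx = sum(length > edge for edge in edges)
            counts[idx] += 1
        rows.append({"taxon": m.taxon, "gene_id": m.gene_id,
                     **dict(zip(labels, counts))})
    return pd.DataFrame(rows, columns=["taxon", "gene_id", *labels])


def gc_profile(model: GeneModel) -> dict:
    cds = model.cds_seq
    gc1, gc2, gc3 = gc_by_codon_position(cds)
    return {
        "gc_gene": gc_content(model.gene_seq),
        "gc_cds": gc_content(cds),
        "gc1": gc1,
        "gc2": gc2,
        "gc3": gc3,
        "gc_introns": [gc_content(s) for s in model.intron_seqs],
    }


def length_summary(
    models: list[GeneModel], genome_sizes: dict[str, float] | None = None
) -> pd.DataFrame:
    """Per-gene table of length metrics, GC profile and intron count.

    ``genome_sizes`` maps taxon -> genome size (any consistent unit); sizes
    are joined where available. The intron fraction is 1 − CDS/gene length.
    """
    if genome_sizes is not None and len(genome_sizes) != len(set(genome_sizes)):
        raise ValueError("duplicate taxon keys in genome size table")
    rows = []
    for m in models:
        cds_len = len(m.cds_seq)
        gene_len = m.gene_length
        prof = gc_profile(m)
        rows.append(
            {
                "taxon": m.taxon,
                "gene_id": m.gene_id,
                "gene_length": gene_len,
                "cds_length": cds_len,
                "n_introns": m.n_introns,
                "intron_fraction": 1.0 - cds_len / gene_len,
                "gc_gene": prof["gc_gene"],
                "gc_cds": prof["gc_cds"],
                "gc1": prof["gc1"],
                "gc2": prof["gc2"],
                "gc3": prof["gc3"],
                "genome_size": (genome_sizes or {}).get(m.taxon, math.nan),
            }
        )
    return pd.DataFrame(rows)
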