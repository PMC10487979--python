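"""Core domain types for gene-architecture analysis.

All internal coordinates are 0-based half-open. A :class:`GeneModel` is
strand-normalized: position 0 of the gene-local frame is the transcription
start, so exon/intron order equals transcription order regardless of the
genomic strand the gene was annotated on.
"""

from __future__ import annotations

from dataclasses import dataclass, field


Interval = tuple[int, int]


class ValidationError(ValueError):
    """An input violates a structural invariant of a domain type."""


@dataclass
class Transcript:
    """One transcript's exon chain in the gene-local (strand-normalized) frame."""

    transcript_id: str
    exons: list[Interval]

    @property
    def introns(self) -> list[Interval]:
        return [(self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class GeneModel:
    """One taxon's gene: ordered exons/introns with sequences.

    ``exons`` and ``introns`` live in the gene-local frame ``[0, len(gene_seq))``
    where 0 is the transcription start. ``region_seq`` is the gene plus its
    flanks (for the duplication scan), with the gene starting at
    ``region_gene_start`` of that frame.
    """

    taxon: str
    gene_id: str
    scaffold: str
    span: Interval  # genomic, 0-based half-open
    strand: str  # '+' or '-'
    exons: list[Interval]  # gene-local, transcription order
    gene_seq: str  # unspliced, strand-normalized
    region_seq: str = ""  # flanks + gene + flanks, strand-normalized
    region_gene_start: int = 0  # offset of gene start within region_seq
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def introns(self) -> list[Interval]:
        """Gaps between consecutive exons, transcription order."""
        return [(self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)]

    @property
    def cds_seq(self) -> str:
        """Spliced coding sequence (exons concatenated in transcription order)."""
        return "".join(self.gene_seq[s:e] for s, e in self.exons)

    @property
    def intron_seqs(self) -> list[str]:
        return [self.gene_seq[s:e] for s, e in self.introns]

    @property
    def gene_length(self) -> int:
        return self.span[1] - self.span[0]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    def intron_cds_offsets(self) -> list[int]:
        """CDS offset (nt 5' of each intron), transcription order."""
        offsets = []
        acc = 0
        for s, e in self.exons[:-1]:
            acc += e - s
            offsets.append(acc)
        return offsets

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValidationError(f"{self.gene_id}: no exons")
        if len(self.gene_seq) != self.span[1] - self.span[0]:
            raise ValidationError(
                f"{self.gene_id}: gene_seq length {len(self.gene_seq)} != span length "
                f"{self.span[1] - self.span[0]}"
            )
        prev_end = None
        for s, e in self.exons:
            if not (0 <= s < e <= len(self.gene_seq)):
                raise ValidationError(f"{self.gene_id}: exon ({s},{e}) outside gene")
            if prev_end is not None and s < prev_end:
                raise ValidationError(f"{self.gene_id}: overlapping/unsorted exons")
            prev_end = e
        if self.exons[0][0] != 0 or self.exons[-1][1] != len(self.gene_seq):
            raise ValidationError(f"{self.gene_id}: gene must start and end with an exon")
        if self.region_seq:
            g = self.region_seq[self.region_gene_start : self.region_gene_start + len(self.gene_seq)]
            if g != self.gene_seq:
                raise ValidationError(f"{self.gene_id}: region_seq does not embed gene_seq at offset")


TE_CLASSES = ("retrotransposon", "DNA_transposon", "helitron", "unclassified")


@dataclass
class TEAnnotation:
    """One repeat annotation on a gene-local coordinate frame."""

    target: str
    start: int
    end: int
    te_class: str  # one of TE_CLASSES
    superfamily: str = ""
    divergence: float = 0.0

    def __post_init__(self) -> None:
        if self.te_class not in TE_CLASSES:
            raise ValidationError(f"unknown te_class {self.te_class!r}")
        if self.end <= self.start:
            raise ValidationError(f"empty TE interval ({self.start},{self.end})")
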