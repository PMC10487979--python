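"""Homologize intron positions across taxa via protein-alignment coordinates.

Each intron is projected to a (codon index, phase) pair in its own protein,
the codon index is mapped through the taxon's gap pattern to a multiple-
alignment column, and positions sharing phase and column (within an optional
tolerance) are clustered into homologous intron sites. The result is the
binary taxa × sites presence/absence matrix consumed by the parsimony
reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .models import GeneModel, ValidationError


@dataclass(frozen=True)
class IntronPosition:
    """One intron located in protein and alignment coordinates."""

    taxon: str
    gene_id: str
    intron_index: int  # 1-based, transcription order
    codon_index: int  # 0-based, taxon's own protein
    phase: int  # 0, 1 or 2
    alignment_column: int  # 0-based MSA column


@dataclass
class IntronSiteMatrix:
    """Taxa × homologized intron sites, binary presence with NaN = missing gene."""

    presence: pd.DataFrame  # index taxa, columns site labels, values 1/0/NaN
    phases: dict[str, int] = field(default_factory=dict)  # site -> phase
    columns: dict[str, int] = field(default_factory=dict)  # site -> MSA column

    @property
    def sites(self) -> list[str]:
        return [str(c) for c in self.presence.columns]

    @property
    def taxa(self) -> list[str]:
        return [str(t) for t in self.presence.index]

    @classmethod
    def from_dict(cls, site_sets: dict[str, set[str] | list[str]],
                  site_order: list[str] | None = None,
                  missing_taxa: set[str] | None = None) -> "IntronSiteMatrix":
        """Build directly from per-taxon site inventories (for worked examples)."""
        missing_taxa = missing_taxa or set()
        if site_order is None:
            seen: list[str] = []
            for sites in site_sets.values():
                for s in sites:
                    if s not in seen:
                        seen.append(s)
            site_order = seen
        data = {}
        for taxon, sites in site_sets.items():
            sset = set(sites)
            data[taxon] = [
                float("nan") if taxon in missing_taxa else float(s in sset)
                for s in site_order
            ]
        df = pd.DataFrame.from_dict(data, orient="index", columns=site_order)
        return cls(presence=df)

    def total_present(self) -> int:
        return int(self.presence.fillna(0).to_numpy().sum())


# ---------------------------------------------------------------------------
# Protein star alignment
# ---------------------------------------------------------------------------

def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


def _pairwise_gapped(aligner, center: str, other: str) -> tuple[str, str]:
    aln = aligner.align(center, other)[0]
    a, b = str(aln[0]), str(aln[1])
    return a, b


def _insertion_profile(gapped_center: str, gapped_other: str):
    """Per-center-position insertion runs: ins[i] = other residues aligned
    into the gap immediately before center residue i (i = len(center) at end),
    and res[i] = the other-row character aligned to center residue i."""
    ins: list[str] = [""]
    res: list[str] = []
    for c, o in zip(gapped_center, gapped_other):
        if c == "-":
            ins[-1] += o
        else:
            res.append(o)
            ins.append("")
    return ins, res


def align_proteins(proteins: dict[str, str]) -> dict[str, str]:
    """Deterministic star multiple alignment of protein sequences.

    The longest sequence (ties broken by name) is the center; every other
    sequence is globally aligned to it (BLOSUM62, gap open 10, extend 1) and
    the pairwise alignments are merged with the once-a-gap-always-a-gap rule.
    Adequate for well-conserved coding regions; supply a real MSA for
    divergent data.
    """
    if len(proteins) < 2:
        raise ValueError("need at least 2 sequences to align")
    for name, seq in proteins.items():
        if not seq:
            raise ValueError(f"empty protein sequence for {name!r}")
    center_name = max(proteins, key=lambda n: (len(proteins[n]), n))
    center = proteins[center_name]
    aligner = _make_aligner()
    profiles = {}
    for name, seq in proteins.items():
        if name == center_name:
            continue
        a, b = _pairwise_gapped(aligner, center, seq)
        profiles[name] = _insertion_profile(a, b)
    n = len(center)
    master_ins = [0] * (n + 1)
    for ins, _ in profiles.values():
        for i, run in enumerate(ins):
            master_ins[i] = max(master_ins[i], len(run))
    msa: dict[str, str] = {}
    row = []
    for i in range(n + 1):
        row.append("-" * master_ins[i])
        if i < n:
            row.append(center[i])
    msa[center_name] = "".join(row)
    for name in proteins:
        if name == center_name:
            continue
        ins, res = profiles[name]
        row = []
        for i in range(n + 1):
            row.append(ins[i].ljust(master_ins[i], "-"))
            if i < n:
                row.append(res[i])
        msa[name] = "".join(row)
    return {name: msa[name] for name in proteins}


def check_msa(msa: dict[str, str], taxa: list[str] | None = None) -> None:
    lengths = {len(s) for s in msa.values()}
    if len(lengths) != 1:
        raise ValidationError("ragged MSA: rows differ in length")
    if taxa is not None and set(taxa) - set(msa):
        missing = sorted(set(taxa) - set(msa))
        raise ValidationError(f"MSA lacks rows for taxa: {missing}")


# ---------------------------------------------------------------------------
# Intron projection and site clustering
# ---------------------------------------------------------------------------

def translate_cds(cds_seq: str) -> str:
    prot = str(Seq(cds_seq[: len(cds_seq) - len(cds_seq) % 3]).translate())
    return prot[:-1] if prot.endswith("*") else prot


def map_introns_to_alignment(model: GeneModel, msa: dict[str, str]) -> list[IntronPosition]:
    """Project a model's introns into the MSA coordinate frame.

    Each intron at CDS offset *o* gets ``codon_index = o // 3`` and
    ``phase = o % 3``; the codon index is then mapped through the taxon's
    gap pattern to an alignment column.
    """
    if model.taxon not in msa:
        raise ValidationError(f"MSA has no row for taxon {model.taxon!r}")
    row = msa[model.taxon]
    ungapped = row.replace("-", "")
    protein = translate_cds(model.cds_seq)
    if ungapped != protein:
        raise ValidationError(
            f"taxon {model.taxon!r}: MSA row does not match the protein "
            f"translated from the CDS"
        )
    # column of each residue index
    residue_col = [i for i, c in enumerate(row) if c != "-"]
    positions = []
    for idx, offset in enumerate(model.intron_cds_offsets(), start=1):
        codon_index = offset // 3
        phase = offset % 3
        if codon_index >= len(protein):
            raise ValidationError(
                f"taxon {model.taxon!r}: intron {idx} lies beyond the last codon"
            )
        positions.append(
            IntronPosition(
                taxon=model.taxon,
                gene_id=model.gene_id,
                intron_index=idx,
                codon_index=codon_index,
                phase=phase,
                alignment_column=residue_col[codon_index],
            )
        )
    return positions


def build_presence_matrix(
    positions: list[IntronPosition],
    column_tolerance: int = 0,
    phase_strict: bool = True,
    reference_taxon: str | None = None,
    all_taxa: list[str] | None = None,
    missing_taxa: set[str] | None = None,
) -> IntronSiteMatrix:
    """Cluster projected intron positions into homologous sites.

    Single-linkage clustering of positions with identical phase (when
    ``phase_strict``) and alignment columns within ``column_tolerance``.
    Site labels are consecutive integers in column order; when a
    ``reference_taxon`` is designated, sites absent from it are suffixed
    with a prime on the nearest preceding reference label (e.g. ``21'``).
    """
    if len({p.taxon for p in positions}) < 2:
        raise ValueError("need intron positions from at least 2 taxa")
    keyed = sorted(positions, key=lambda p: (p.phase if phase_strict else 0,
                                             p.alignment_column, p.taxon, p.intron_index))
    clusters: list[list[IntronPosition]] = []
    for p in keyed:
        if clusters:
            last = clusters[-1][-1]
            same_phase = (not phase_strict) or last.phase == p.phase
            if same_phase and p.alignment_column - last.alignment_column <= column_tolerance:
                clusters[-1].append(p)
                continue
        clusters.append([p])
    for cl in clusters:
        taxa_in = [p.taxon for p in cl]
        dupes = sorted({t for t in taxa_in if taxa_in.count(t) > 1})
        if dupes:
            raise ValidationError(
                f"two introns of one taxon fell into one site cluster "
                f"(taxa {dupes}); reduce column_tolerance"
            )
    clusters.sort(key=lambda cl: (min(p.alignment_column for p in cl),
                                  cl[0].phase))
    # labels
    labels: list[str] = []
    if reference_taxon is None:
        labels = [str(i + 1) for i in range(len(clusters))]
    else:
        ref_number = 0
        for cl in clusters:
            if any(p.taxon == reference_taxon for p in cl):
                ref_number += 1
                labels.append(str(ref_number))
            else:
                labels.append(None)  # type: ignore[arg-type]
        seen: set[str] = set()
        cnt = 0
        for i, lab in enumerate(labels):
            if lab is not None:
                cnt = int(lab)
            else:
                candidate = f"{cnt}'"
                while candidate in seen:
                    candidate += "'"
                labels[i] = candidate
            seen.add(labels[i])
    taxa = sorted(all_taxa) if all_taxa else sorted({p.taxon for p in positions})
    missing_taxa = missing_taxa or set()
    data = {t: [float("nan")] * len(clusters) if t in missing_taxa else [0.0] * len(clusters)
            for t in taxa}
    for j, cl in enumerate(clusters):
        for p in cl:
            data[p.taxon][j] = 1.0
    df = pd.DataFrame.from_dict(data, orient="index", columns=labels)
    phases = {lab: cl[0].phase for lab, cl in zip(labels, clusters)}
    cols = {lab: min(p.alignment_column for p in cl) for lab, cl in zip(labels, clusters)}
    return IntronSiteMatrix(presence=df, phases=phases, columns=cols)
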