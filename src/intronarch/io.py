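"""Readers and writers for all external formats.

GFF3/GTF are ingested as 1-based inclusive and converted to the internal
0-based half-open convention at the parser boundary; minus-strand genes are
reverse-complemented so that exon order equals transcription order
everywhere downstream.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

from .models import GeneModel, TEAnnotation, Transcript, ValidationError
from .trees import SpeciesTree

logger = logging.getLogger("intronarch")

DEFAULT_FLANK = 500_000


class FormatError(ValueError):
    """A file does not conform to its declared format."""


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# GFF3 / GTF
# ---------------------------------------------------------------------------

def _feature_intervals(db, parent, featuretype) -> list[tuple[int, int]]:
    feats = list(db.children(parent, featuretype=featuretype))
    ivs = sorted((f.start - 1, f.end) for f in feats)
    return ivs


def _check_disjoint(ivs, transcript_id: str) -> None:
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        if s2 < e1:
            raise ValidationError(
                f"transcript {transcript_id!r}: overlapping exons "
                f"({s1},{e1}) and ({s2},{e2})"
            )


def _to_local(ivs, span, strand):
    gs, ge = span
    if strand == "+":
        out = [(s - gs, e - gs) for s, e in ivs]
    else:
        out = [(ge - e, ge - s) for s, e in reversed(ivs)]
    return out


def parse_gff3(
    gff_path,
    fasta_path,
    taxon: str | None = None,
    flank: int = DEFAULT_FLANK,
) -> list[GeneModel]:
    """Read gene models from a GFF3 (or GTF) file plus its genome FASTA.

    When a transcript has both CDS and exon children, the CDS features define
    the model (the analyses concern the coding gene). With several
    transcripts, the one with the longest spliced length is the constitutive
    model; all transcripts are retained for isoform analysis.
    """
    gff_path = Path(gff_path)
    if taxon is None:
        taxon = gff_path.stem
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    dialect = "gtf" if gff_path.suffix.lower() == ".gtf" else "gff3"
    db = gffutils.create_db(
        str(gff_path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=(dialect == "gtf"),
        disable_infer_transcripts=(dialect == "gtf"),
    )

    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        scaffold = gene.seqid
        if scaffold not in seqs:
            raise FormatError(
                f"gene {gene.id!r} references scaffold {scaffold!r} absent from FASTA"
            )
        parents = list(db.children(gene, featuretype=("mRNA", "transcript"))) or [gene]
        chains: dict[str, list[tuple[int, int]]] = {}
        for tr in parents:
            ivs = _feature_intervals(db, tr, "CDS") or _feature_intervals(db, tr, "exon")
            if not ivs:
                continue
            _check_disjoint(ivs, tr.id)
            chains[tr.id] = ivs
        if not chains:
            logger.warning("gene %s has no exon/CDS features; skipped", gene.id)
            continue
        constitutive_id = max(
            chains, key=lambda t: (sum(e - s for s, e in chains[t]), t)
        )
        ivs = chains[constitutive_id]
        span = (ivs[0][0], ivs[-1][1])
        strand = gene.strand if gene.strand in "+-" else "+"
        chrom = seqs[scaffold]
        gene_seq = chrom[span[0] : span[1]]
        rstart = max(0, span[0] - flank)
        rend = min(len(chrom), span[1] + flank)
        region_seq = chrom[rstart:rend]
        if strand == "-":
            gene_seq = _revcomp(gene_seq)
            region_seq = _revcomp(region_seq)
            region_gene_start = rend - span[1]
        else:
            region_gene_start = span[0] - rstart
        transcripts = [
            Transcript(tid, _to_local(chain, span, strand))
            for tid, chain in sorted(chains.items())
        ]
        model = GeneModel(
            taxon=taxon,
            gene_id=gene.id,
            scaffold=scaffold,
            span=span,
            strand=strand,
            exons=_to_local(ivs, span, strand),
            gene_seq=gene_seq,
            region_seq=region_seq,
            region_gene_start=region_gene_start,
            transcripts=transcripts,
        )
        model.validate()
        models.append(model)
    return models


def write_gff3(models: list[GeneModel], path) -> None:
    """Write gene models back to GFF3 (gene/mRNA/exon rows, genomic coords)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            gs, ge = m.span
            fh.write(
                f"{m.scaffold}\t.\tgene\t{gs + 1}\t{ge}\t.\t{m.strand}\t.\tID={m.gene_id}\n"
            )
            mrna_id = f"{m.gene_id}.t1"
            fh.write(
                f"{m.scaffold}\t.\tmRNA\t{gs + 1}\t{ge}\t.\t{m.strand}\t.\t"
                f"ID={mrna_id};Parent={m.gene_id}\n"
            )
            genomic = (
                [(gs + s, gs + e) for s, e in m.exons]
                if m.strand == "+"
                else [(ge - e, ge - s) for s, e in m.exons]
            )
            for s, e in sorted(genomic):
                fh.write(
                    f"{m.scaffold}\t.\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                    f"Parent={mrna_id}\n"
                )


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def parse_newick(path, taxa: list[str] | None = None) -> SpeciesTree:
    """Read a rooted Newick species tree.

    Unlabeled internal nodes receive deterministic post-order labels. If
    ``taxa`` is given, any asymmetric difference between tree leaves and
    gene-model taxa is logged as a warning.
    """
    tree = SpeciesTree.from_file(path)
    if taxa is not None:
        leaves = set(tree.leaf_labels)
        missing = sorted(set(taxa) - leaves)
        extra = sorted(leaves - set(taxa))
        if missing or extra:
            logger.warning(
                "tree/taxa mismatch: taxa without leaf %s; leaves without gene %s",
                missing, extra,
            )
    return tree


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

def _map_te_class(class_family: str) -> tuple[str, str]:
    cls, _, fam = class_family.partition("/")
    cl = cls.lower()
    if cl.startswith(("ltr", "line", "sine", "retro")):
        te_class = "retrotransposon"
    elif cl.startswith("dna") or cl == "tir":
        te_class = "DNA_transposon"
    elif cl.startswith("rc") or "helitron" in class_family.lower():
        te_class = "helitron"
    else:
        te_class = "unclassified"
    return te_class, fam


def parse_repeatmasker_out(path) -> list[TEAnnotation]:
    """Parse a RepeatMasker ``.out`` file into TE annotations.

    Query coordinates (1-based inclusive) are converted to 0-based
    half-open. The repeat class/family column is collapsed onto the four-way
    vocabulary retrotransposon / DNA_transposon / helitron / unclassified,
    keeping the superfamily (e.g. Gypsy, Copia). Malformed records are
    skipped with a logged count.
    """
    annotations: list[TEAnnotation] = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0] in ("SW", "score") or parts[0].startswith("-"):
                continue
            try:
                divergence = float(parts[1])
                target = parts[4]
                start, end = int(parts[5]) - 1, int(parts[6])
                te_class, fam = _map_te_class(parts[10])
                if end <= start:
                    raise ValueError("empty interval")
            except (ValueError, IndexError):
                skipped += 1
                continue
            annotations.append(
                TEAnnotation(
                    target=target,
                    start=start,
                    end=end,
                    te_class=te_class,
                    superfamily=fam,
                    divergence=divergence,
                )
            )
    if skipped:
        logger.warning("parse_repeatmasker_out: skipped %d malformed records", skipped)
    return annotations


def write_repeatmasker_out(annotations: list[TEAnnotation], path) -> None:
    """Write annotations in RepeatMasker ``.out`` column layout."""
    with open(path, "w") as fh:
        fh.write(
            "   SW  perc perc perc  query     position in query    matching"
            "  repeat          position in repeat\n"
            "score  div. del. ins.  sequence  begin end   (left)   repeat"
            "  class/family      begin  end (left)   ID\n\n"
        )
        rm_class = {
            "retrotransposon": "LTR",
            "DNA_transposon": "DNA",
            "helitron": "RC",
            "unclassified": "Unknown",
        }
        for i, a in enumerate(annotations, 1):
            cf = rm_class[a.te_class]
            if a.superfamily:
                cf = f"{cf}/{a.superfamily}"
            length = a.end - a.start
            fh.write(
                f"{1000:>5} {a.divergence:5.1f}  0.0  0.0  {a.target}  "
                f"{a.start + 1} {a.end} (0) + {a.superfamily or 'rep'}  {cf}  "
                f"1 {length} (0) {i}\n"
            )


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def fmt_pct(x: float) -> str:
    """Render a percentage with 2 decimals, e.g. ``94.05``."""
    return f"{x:.2f}"


def write_report_tables(results: dict, out_dir, manifest: dict | None = None) -> list[str]:
    """Write every DataFrame in ``results`` as a TSV plus a JSON run manifest.

    Keys become file names (``<key>.tsv``). Returns the list of files written.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = tempfile.TemporaryFile(dir=out_dir)
        probe.close()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc
    written = []
    for key, df in results.items():
        path = out_dir / f"{key}.tsv"
        keep_index = key == "presence_matrix"
        df.to_csv(path, sep="\t", index=keep_index, float_format="%.2f")
        written.append(str(path))
    if manifest is not None:
        manifest = dict(manifest)
        manifest["tables"] = [os.path.basename(w) for w in written]
        mpath = out_dir / "manifest.json"
        with open(mpath, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        written.append(str(mpath))
    return written
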