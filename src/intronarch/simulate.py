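"""Ortholog-family simulator with full ground truth.

An ancestral multi-exon gene is evolved down a rooted species tree:
per-branch Poisson intron losses and gains (gains at uniformly chosen CDS
offsets, so phases 0/1/2 arise naturally), intron length expansion through
insertions of labelled transposable-element copies (Gypsy/Copia LTR
retrotransposons, a DNA transposon, a helitron, plus an unclassified
repeat), synonymous-biased CDS substitution, species-specific partial gene
duplications (into an intron or into a flank at a set distance), and
alternative transcripts built by named splicing operations. Every event is
logged, so recovery of gains/losses, duplications and TE content can be
scored against the truth.

Defaults mirror the seed-plant regime the analyses target: a 23-exon
(22-intron) ancestral gene with a ~3.5 kb coding region, GT-AG splice sites
with a ~6% non-canonical admixture dominated by GG-CA, and loss outweighing
gain on each branch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .homology import IntronSiteMatrix
from .models import GeneModel, TEAnnotation, Transcript
from .trees import SpeciesTree
from . import io as io_mod

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}

# weights of non-canonical terminal dinucleotide pairs (GG-CA dominant)
NONCANONICAL_TYPES = [("GG", "CA"), ("GC", "AG"), ("AT", "AC"), ("CT", "AC")]
NONCANONICAL_WEIGHTS = [0.35, 0.30, 0.20, 0.15]


@dataclass
class TEElement:
    name: str
    te_class: str
    superfamily: str
    seq: str


def default_te_library() -> list[TEElement]:
    """Small synthetic consensus library, one element per class (two LTR
    superfamilies). Fixed internal seed: the library is a constant."""
    rng = np.random.default_rng(977231)

    def rand_seq(n, at=0.55):
        p = [(1 - at) / 2, at / 2, (1 - at) / 2, at / 2]  # C A G T? keep simple
        return "".join(rng.choice(list("CAGT"), size=n, p=p))

    return [
        TEElement("synGypsy1", "retrotransposon", "Gypsy", rand_seq(4000)),
        TEElement("synCopia1", "retrotransposon", "Copia", rand_seq(2800)),
        TEElement("synDNA1", "DNA_transposon", "hAT", rand_seq(1100)),
        TEElement("synHelitron1", "helitron", "Helitron", rand_seq(1700)),
        TEElement("synUnknown1", "unclassified", "", rand_seq(650)),
    ]


@dataclass
class DuplicationSpec:
    taxon: str
    exon_first: int  # 1-based
    exon_last: int
    target: str  # 'intron' | 'upstream' | 'downstream'
    position: int  # intron index (1-based) or flank distance in nt
    divergence: float = 0.0
    inverted: bool = False


@dataclass
class IsoformSpec:
    taxon: str
    op: str  # skip_exon | alt_donor | alt_acceptor | retain_intron |
    #          mutually_exclusive | alt_first_exon
    index: int  # exon or intron index, 1-based
    shift: int = 12  # donor/acceptor shift or offset into the exon 3' end


@dataclass
class SimConfig:
    seed: int = 0
    newick: str | None = None  # else a balanced tree of n_leaves
    n_leaves: int = 16
    root_exons: int = 23
    cds_codons: int = 1150
    intron_len_range: tuple[int, int] = (80, 500)
    min_exon_len: int = 60  # minimum spacing between ancestral intron offsets
    gain_rate: float = 0.1  # events per branch
    loss_rate: float = 0.3
    subst_rate: float = 0.005  # per CDS site per branch, 3:1 third-position bias
    te_rate: float = 0.0  # TE insertions per branch
    te_rate_max: float | None = None  # if set, per-branch rate ~ U(0, max)
    noncanonical_prob: float = 0.06
    flank: int = 3000
    duplications: list[DuplicationSpec] = field(default_factory=list)
    isoforms: list[IsoformSpec] = field(default_factory=list)

    def validate(self) -> None:
        if self.root_exons < 2:
            raise ValueError("root exon count must be >= 2")
        for r in (self.gain_rate, self.loss_rate, self.subst_rate, self.te_rate):
            if r < 0:
                raise ValueError("rates must be non-negative")
        lo, hi = self.intron_len_range
        if not (4 <= lo <= hi):
            raise ValueError("intron lengths must be >= 4 and ordered")


@dataclass
class _SimIntron:
    site: str
    offset: int  # nt offset into the CDS (fixed: the CDS never indels)
    seq: str
    tes: list[tuple[int, int, str, str, str, float]] = field(default_factory=list)
    # (start, end, name, te_class, superfamily, divergence) within the intron

    def clone(self) -> "_SimIntron":
        return _SimIntron(self.site, self.offset, self.seq, list(self.tes))


@dataclass
class _SimGene:
    cds: str
    introns: dict[str, _SimIntron]

    def clone(self) -> "_SimGene":
        return _SimGene(self.cds, {k: v.clone() for k, v in self.introns.items()})


@dataclass
class SimTruth:
    """Ground-truth log of a simulated family."""

    tree_newick: str
    events: list[dict] = field(default_factory=list)  # branch, site, kind
    site_offsets: dict[str, int] = field(default_factory=dict)
    leaf_sites: dict[str, list[str]] = field(default_factory=dict)
    te_registry: dict[str, list[dict]] = field(default_factory=dict)  # gene-local
    duplications: list[dict] = field(default_factory=list)
    isoforms: list[dict] = field(default_factory=list)
    msa: dict[str, str] = field(default_factory=dict)  # true protein alignment

    def matrix(self) -> IntronSiteMatrix:
        order = sorted(self.site_offsets, key=lambda s: (self.site_offsets[s], s))
        return IntronSiteMatrix.from_dict(
            {t: set(sites) for t, sites in self.leaf_sites.items()}, site_order=order
        )

    def event_set(self) -> set[tuple[str, str, str]]:
        return {(e["site"], e["branch"], e["kind"]) for e in self.events}


def _rand_seq(rng, n: int, at_bias: float = 0.6) -> str:
    p_at = at_bias / 2
    p_gc = (1 - at_bias) / 2
    return "".join(rng.choice(list("ACGT"), size=n, p=[p_at, p_gc, p_gc, p_at]))


def _mutate(rng, seq: str, divergence: float) -> str:
    if divergence <= 0:
        return seq
    arr = list(seq)
    hits = np.flatnonzero(rng.random(len(arr)) < divergence)
    for i in hits:
        choices = [b for b in _BASES if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def _revcomp(seq: str) -> str:
    comp = str.maketrans("ACGT", "TGCA")
    return seq.translate(comp)[::-1]


def _random_cds(rng, n_codons: int) -> str:
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(list(_BASES), size=3))
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _new_intron_seq(rng, cfg: SimConfig) -> str:
    length = int(rng.integers(cfg.intron_len_range[0], cfg.intron_len_range[1] + 1))
    if rng.random() < cfg.noncanonical_prob:
        idx = rng.choice(len(NONCANONICAL_TYPES), p=NONCANONICAL_WEIGHTS)
        donor, acceptor = NONCANONICAL_TYPES[idx]
    else:
        donor, acceptor = "GT", "AG"
    return donor + _rand_seq(rng, length - 4) + acceptor


def _substitute_cds(rng, cds: str, rate: float) -> str:
    if rate <= 0:
        return cds
    n = rng.poisson(rate * len(cds))
    if n == 0:
        return cds
    arr = list(cds)
    n_codons = len(cds) // 3
    for _ in range(n):
        for _attempt in range(20):
            # 3:1 weight toward third codon positions
            codon = int(rng.integers(1, n_codons - 1))  # keep start & stop intact
            pos_in = 2 if rng.random() < 0.6 else int(rng.integers(2))
            pos = codon * 3 + pos_in
            old = arr[pos]
            new = _BASES[rng.integers(4)]
            if new == old:
                continue
            arr[pos] = new
            cod = "".join(arr[codon * 3 : codon * 3 + 3])
            if cod in _STOPS:
                arr[pos] = old  # reject nonsense changes
                continue
            break
    return "".join(arr)



def _shift_te_intervals(tes, pos: int, length: int):
    """Adjust intra-intron TE intervals for an insertion of ``length`` at
    ``pos``: intervals right of the insertion shift, an interval containing
    it is split into its two surviving parts."""
    out = []
    for s0, e0, name, cls, fam, d in tes:
        if e0 <= pos:
            out.append((s0, e0, name, cls, fam, d))
        elif s0 >= pos:
            out.append((s0 + length, e0 + length, name, cls, fam, d))
        else:
            out.append((s0, pos, name, cls, fam, d))
            out.append((pos + length, e0 + length, name, cls, fam, d))
    return out


_TE_LIBRARY: list[TEElement] | None = None


def _te_library() -> list[TEElement]:
    global _TE_LIBRARY
    if _TE_LIBRARY is None:
        _TE_LIBRARY = default_te_library()
    return _TE_LIBRARY


def _evolve_branch(gene: _SimGene, rng, cfg: SimConfig, branch: str,
                   truth: SimTruth, gain_counter: list[int]) -> None:
    # losses first: a gain on this branch cannot be erased on the same branch
    for _ in range(rng.poisson(cfg.loss_rate)):
        if not gene.introns:
            truth.events.append({"branch": branch, "site": None, "kind": "loss_skipped"})
            continue
        sites = sorted(gene.introns)
        site = sites[rng.integers(len(sites))]
        del gene.introns[site]
        truth.events.append({"branch": branch, "site": site, "kind": "loss"})
    for _ in range(rng.poisson(cfg.gain_rate)):
        taken = {iv.offset for iv in gene.introns.values()}
        candidates = [o for o in range(3, len(gene.cds) - 3) if o not in taken]
        if not candidates:
            continue
        offset = candidates[rng.integers(len(candidates))]
        gain_counter[0] += 1
        site = f"g{gain_counter[0]}"
        gene.introns[site] = _SimIntron(site, offset, _new_intron_seq(rng, cfg))
        truth.site_offsets[site] = offset
        truth.events.append({"branch": branch, "site": site, "kind": "gain"})
    # TE insertions
    rate = cfg.te_rate
    if cfg.te_rate_max is not None:
        rate = float(rng.uniform(0, cfg.te_rate_max))
    library = _te_library()
    lib_weights = np.array([0.40, 0.25, 0.18, 0.05, 0.12])
    for _ in range(rng.poisson(rate)):
        if not gene.introns:
            continue
        sites = sorted(gene.introns)
        intron = gene.introns[sites[rng.integers(len(sites))]]
        elem = library[rng.choice(len(library), p=lib_weights)]
        div = float(rng.uniform(0.02, 0.20))
        insert = _mutate(rng, elem.seq, div)
        pos = int(rng.integers(2, len(intron.seq) - 2))
        intron.seq = intron.seq[:pos] + insert + intron.seq[pos:]
        moved = _shift_te_intervals(intron.tes, pos, len(insert))
        moved.append((pos, pos + len(insert), elem.name, elem.te_class, elem.superfamily, div))
        intron.tes = sorted(moved)
    gene.cds = _substitute_cds(rng, gene.cds, cfg.subst_rate)


def _assemble(gene: _SimGene):
    """Return (gene_seq, exon intervals, intron gene-local intervals by site)."""
    introns = sorted(gene.introns.values(), key=lambda iv: iv.offset)
    pieces = []
    exons = []
    intron_locs = {}
    cursor_cds = 0
    cursor_gene = 0
    for iv in introns:
        exon_len = iv.offset - cursor_cds
        pieces.append(gene.cds[cursor_cds : iv.offset])
        exons.append((cursor_gene, cursor_gene + exon_len))
        cursor_gene += exon_len
        pieces.append(iv.seq)
        intron_locs[iv.site] = (cursor_gene, cursor_gene + len(iv.seq))
        cursor_gene += len(iv.seq)
        cursor_cds = iv.offset
    pieces.append(gene.cds[cursor_cds:])
    exons.append((cursor_gene, cursor_gene + len(gene.cds) - cursor_cds))
    return "".join(pieces), exons, intron_locs


def _translate(cds: str) -> str:
    from Bio.Seq import Seq

    prot = str(Seq(cds).translate())
    return prot[:-1] if prot.endswith("*") else prot


def _make_isoform(constitutive: Transcript, spec: IsoformSpec) -> Transcript:
    """Apply one named splicing operation to the constitutive exon chain."""
    ex = list(constitutive.exons)
    op, i, shift = spec.op, spec.index, spec.shift
    tid = f"{constitutive.transcript_id}_alt_{op}{i}"
    if op == "skip_exon":
        if not (1 < i < len(ex)):
            raise ValueError("can only skip an internal exon")
        ex = ex[: i - 1] + ex[i:]
    elif op == "retain_intron":
        if not (1 <= i <= len(ex) - 1):
            raise ValueError("no such intron")
        ex = ex[: i - 1] + [(ex[i - 1][0], ex[i][1])] + ex[i + 1 :]
    elif op == "alt_donor":
        s, e = ex[i - 1]
        if e - shift <= s:
            raise ValueError("donor shift exceeds exon length")
        ex[i - 1] = (s, e - shift)
    elif op == "alt_acceptor":
        s, e = ex[i]
        if s + shift >= e:
            raise ValueError("acceptor shift exceeds exon length")
        ex[i] = (s + shift, e)
    elif op == "mutually_exclusive":
        if not (1 < i < len(ex)):
            raise ValueError("needs an internal exon")
        # alternative exon carved from the middle of the intron after exon i
        gap_s, gap_e = ex[i - 1][1], ex[i][0]
        width = max(10, min(120, (gap_e - gap_s) // 3))
        mid = (gap_s + gap_e) // 2
        alt = (mid, min(mid + width, gap_e - 2))
        ex = ex[: i - 1] + [alt] + ex[i:]
    elif op == "alt_first_exon":
        s, e = ex[i - 1]
        ex = [(e - shift, e)] + ex[i:]
    else:
        raise ValueError(f"unknown isoform operation {op!r}")
    return Transcript(tid, ex)


def _plant_duplication(rng, gene_seq: str, exons, spec: DuplicationSpec):
    """Return the mutated duplicate segment for a spec (gene-local source)."""
    s = exons[spec.exon_first - 1][0]
    e = exons[spec.exon_last - 1][1]
    segment = _mutate(rng, gene_seq[s:e], spec.divergence)
    if spec.inverted:
        segment = _revcomp(segment)
    return segment


def simulate_family(cfg: SimConfig) -> tuple[list[GeneModel], SimTruth]:
    """Evolve one gene family along the tree; fully deterministic given seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    tree = (
        SpeciesTree.from_newick(cfg.newick)
        if cfg.newick
        else SpeciesTree.balanced(cfg.n_leaves)
    )
    truth = SimTruth(tree_newick=tree.to_newick())

    # ancestral gene
    cds = _random_cds(rng, cfg.cds_codons)
    # ancestral intron offsets with a minimum exon spacing (stick-breaking)
    n_introns = cfg.root_exons - 1
    m = cfg.min_exon_len
    span = len(cds) - 2 * m - (n_introns - 1) * m
    if span < n_introns:
        raise ValueError("CDS too short for root_exons at min_exon_len spacing")
    ys = sorted(int(y) for y in rng.choice(np.arange(span), size=n_introns, replace=False))
    offsets = [m + y + i * m for i, y in enumerate(ys)]
    root_gene = _SimGene(cds=cds, introns={})
    for idx, off in enumerate(offsets, start=1):
        site = str(idx)
        root_gene.introns[site] = _SimIntron(site, off, _new_intron_seq(rng, cfg))
        truth.site_offsets[site] = off
        truth.events.append({"branch": tree.root_label, "site": site, "kind": "gain"})

    # evolve down the tree in preorder
    gain_counter = [0]
    genes: dict[str, _SimGene] = {tree.root_label: root_gene}
    for label in tree.preorder_labels():
        if label == tree.root_label:
            continue
        parent = tree.parent_label(label)
        gene = genes[parent].clone()
        _evolve_branch(gene, rng, cfg, label, truth, gain_counter)
        genes[label] = gene

    dup_by_taxon: dict[str, list[DuplicationSpec]] = {}
    for spec in cfg.duplications:
        dup_by_taxon.setdefault(spec.taxon, []).append(spec)
    iso_by_taxon: dict[str, list[IsoformSpec]] = {}
    for ispec in cfg.isoforms:
        iso_by_taxon.setdefault(ispec.taxon, []).append(ispec)

    models: list[GeneModel] = []
    for taxon in sorted(tree.leaf_labels):
        gene = genes[taxon]
        sites_sorted = sorted(gene.introns.values(), key=lambda iv: iv.offset)
        truth.leaf_sites[taxon] = [iv.site for iv in sites_sorted]
        truth.msa[taxon] = _translate(gene.cds)

        # every duplicate segment is copied from the pristine gene (before
        # any insertion), so planted copies never nest inside each other
        pristine_seq, pristine_exons, _ = _assemble(gene)

        # internal duplications go into an intron before final assembly
        for spec in dup_by_taxon.get(taxon, ()):
            if spec.target != "intron":
                continue
            if spec.position > len(pristine_exons) - 1:
                truth.duplications.append(
                    {"taxon": taxon, "status": "skipped_missing_intron",
                     **asdict(spec)}
                )
                continue
            segment = _plant_duplication(rng, pristine_seq, pristine_exons, spec)
            target_intron = sorted(gene.introns.values(), key=lambda iv: iv.offset)[
                spec.position - 1
            ]
            pos = len(target_intron.seq) // 2
            target_intron.seq = (
                target_intron.seq[:pos] + segment + target_intron.seq[pos:]
            )
            target_intron.tes = sorted(
                _shift_te_intervals(target_intron.tes, pos, len(segment))
            )
            truth.duplications.append(
                {"taxon": taxon, "status": "planted", "length": len(segment),
                 **asdict(spec)}
            )

        gene_seq, exons, intron_locs = _assemble(gene)

        # flanks, with room for any flank-targeted duplication
        up_need = cfg.flank
        down_need = cfg.flank
        flank_specs = [
            s for s in dup_by_taxon.get(taxon, ()) if s.target in ("upstream", "downstream")
        ]
        seg_cache = {}
        for spec in flank_specs:
            seg = _plant_duplication(rng, pristine_seq, pristine_exons, spec)
            seg_cache[id(spec)] = seg
            need = spec.position + len(seg) + 500
            if spec.target == "upstream":
                up_need = max(up_need, need)
            else:
                down_need = max(down_need, need)
        up = _rand_seq(rng, up_need)
        down = _rand_seq(rng, down_need)
        for spec in flank_specs:
            seg = seg_cache[id(spec)]
            if spec.target == "upstream":
                end = len(up) - spec.position
                up = up[: end - len(seg)] + seg + up[end:]
            else:
                start = spec.position
                down = down[:start] + seg + down[start + 0 :]
            truth.duplications.append(
                {"taxon": taxon, "status": "planted", "length": len(seg),
                 **asdict(spec)}
            )
        region = up + gene_seq + down
        gene_start = len(up)

        constitutive = Transcript(f"{taxon}_g1.t1", exons)
        transcripts = [constitutive]
        for ispec in iso_by_taxon.get(taxon, ()):
            transcripts.append(_make_isoform(constitutive, ispec))
            truth.isoforms.append({"taxon": taxon, **asdict(ispec)})

        model = GeneModel(
            taxon=taxon,
            gene_id=f"{taxon}_g1",
            scaffold=f"{taxon}_scaf",
            span=(gene_start, gene_start + len(gene_seq)),
            strand="+",
            exons=exons,
            gene_seq=gene_seq,
            region_seq=region,
            region_gene_start=gene_start,
            transcripts=transcripts,
        )
        model.validate()
        models.append(model)

        # gene-local TE registry
        registry = []
        for iv in sites_sorted:
            g0 = intron_locs[iv.site][0]
            for s, e, name, cls, fam, d in iv.tes:
                registry.append(
                    {"start": g0 + s, "end": g0 + e, "name": name,
                     "te_class": cls, "superfamily": fam, "divergence": d}
                )
        truth.te_registry[taxon] = registry
    return models, truth



# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def _flip_interval(iv, length):
    s, e = iv
    return (length - e, length - s)


def emit_files(models: list[GeneModel], truth: SimTruth, out_dir) -> dict[str, str]:
    """Write every pipeline input format plus the truth log.

    Per taxon: a FASTA scaffold (gene + flanks), a GFF3 with the
    constitutive transcript, a RepeatMasker-style ``.out`` (gene-local
    coordinates) when TEs were inserted, and a multi-transcript GTF when
    isoforms were planted. Alternate taxa are written on the minus strand to
    exercise strand normalization in the parsers. Shared files: the species
    tree, the protein FASTA, the true protein MSA, a genome-size proxy
    table, and ``truth.json``. Deterministic: two runs from the same seed
    produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    with open(out / "tree.nwk", "w") as fh:
        fh.write(truth.tree_newick + "\n")
    paths["tree"] = str(out / "tree.nwk")

    with open(out / "proteins.fasta", "w") as fh:
        for taxon in sorted(truth.msa):
            fh.write(f">{taxon}\n{truth.msa[taxon]}\n")
    paths["proteins"] = str(out / "proteins.fasta")
    with open(out / "msa.fasta", "w") as fh:
        for taxon in sorted(truth.msa):
            fh.write(f">{taxon}\n{truth.msa[taxon]}\n")
    paths["msa"] = str(out / "msa.fasta")

    with open(out / "genome_sizes.tsv", "w") as fh:
        fh.write("taxon\tgenome_size\n")
        for m in sorted(models, key=lambda m: m.taxon):
            fh.write(f"{m.taxon}\t{len(m.region_seq) * 50}\n")
    paths["genome_sizes"] = str(out / "genome_sizes.tsv")

    for idx, m in enumerate(sorted(models, key=lambda m: m.taxon)):
        minus = idx % 2 == 1
        L = len(m.region_seq)
        scaf_seq = _revcomp(m.region_seq) if minus else m.region_seq
        strand = "-" if minus else "+"
        with open(out / f"{m.taxon}.fasta", "w") as fh:
            fh.write(f">{m.scaffold}\n")
            for i in range(0, L, 80):
                fh.write(scaf_seq[i : i + 80] + "\n")

        def to_genomic(iv):
            giv = (m.region_gene_start + iv[0], m.region_gene_start + iv[1])
            return _flip_interval(giv, L) if minus else giv

        gspan = to_genomic((0, len(m.gene_seq)))
        with open(out / f"{m.taxon}.gff3", "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write(
                f"{m.scaffold}\t.\tgene\t{gspan[0] + 1}\t{gspan[1]}\t.\t{strand}\t.\t"
                f"ID={m.gene_id}\n"
            )
            tid = f"{m.gene_id}.t1"
            fh.write(
                f"{m.scaffold}\t.\tmRNA\t{gspan[0] + 1}\t{gspan[1]}\t.\t{strand}\t.\t"
                f"ID={tid};Parent={m.gene_id}\n"
            )
            for iv in sorted(to_genomic(e) for e in m.exons):
                fh.write(
                    f"{m.scaffold}\t.\texon\t{iv[0] + 1}\t{iv[1]}\t.\t{strand}\t.\t"
                    f"Parent={tid}\n"
                )
        paths[f"gff3:{m.taxon}"] = str(out / f"{m.taxon}.gff3")

        registry = truth.te_registry.get(m.taxon, [])
        if registry:
            annos = [
                TEAnnotation(
                    target=m.gene_id,
                    start=r["start"],
                    end=r["end"],
                    te_class=r["te_class"],
                    superfamily=r["superfamily"],
                    divergence=round(100 * r["divergence"], 1),
                )
                for r in sorted(registry, key=lambda r: r["start"])
            ]
            io_mod.write_repeatmasker_out(annos, out / f"{m.taxon}.rm.out")
            paths[f"rmout:{m.taxon}"] = str(out / f"{m.taxon}.rm.out")

        if len(m.transcripts) > 1:
            with open(out / f"{m.taxon}.gtf", "w") as fh:
                gs, ge = gspan
                fh.write(
                    f'{m.scaffold}\tsim\tgene\t{gs + 1}\t{ge}\t.\t{strand}\t.\t'
                    f'gene_id "{m.gene_id}";\n'
                )
                for tr in m.transcripts:
                    tspan = sorted(to_genomic(e) for e in tr.exons)
                    ts, te_ = tspan[0][0], tspan[-1][1]
                    fh.write(
                        f'{m.scaffold}\tsim\ttranscript\t{ts + 1}\t{te_}\t.\t{strand}\t.\t'
                        f'gene_id "{m.gene_id}"; transcript_id "{tr.transcript_id}";\n'
                    )
                    for iv in tspan:
                        fh.write(
                            f'{m.scaffold}\tsim\texon\t{iv[0] + 1}\t{iv[1]}\t.\t{strand}\t.\t'
                            f'gene_id "{m.gene_id}"; transcript_id "{tr.transcript_id}";\n'
                        )
            paths[f"gtf:{m.taxon}"] = str(out / f"{m.taxon}.gtf")

    with open(out / "truth.json", "w") as fh:
        json.dump(
            {
                "tree_newick": truth.tree_newick,
                "events": truth.events,
                "site_offsets": truth.site_offsets,
                "leaf_sites": truth.leaf_sites,
                "te_registry": truth.te_registry,
                "duplications": truth.duplications,
                "isoforms": truth.isoforms,
                "msa": truth.msa,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    paths["truth"] = str(out / "truth.json")
    return paths
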