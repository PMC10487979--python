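"""End-to-end orchestration: metrics -> homology -> parsimony -> duplication
scan -> TE content -> isoforms -> report tables + JSON manifest.

Inputs follow a per-taxon directory layout (the simulator emits exactly
this): ``<taxon>.gff3`` + ``<taxon>.fasta`` per taxon, ``tree.nwk``,
optional ``msa.fasta``, ``<taxon>.rm.out``, ``<taxon>.gtf`` and
``genome_sizes.tsv``. Stages lacking their inputs are skipped with a
notice; a stage failure halts the run with a stage-named error.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import dupscan as dup_mod
from . import homology, isoforms, metrics, parsimony, te
from .io import (
    parse_gff3,
    parse_newick,
    parse_repeatmasker_out,
    write_report_tables,
)
from .models import GeneModel

logger = logging.getLogger("intronarch")

ALL_STAGES = ("metrics", "homology", "parsimony", "dupscan", "te", "isoforms")


@dataclass
class PipelineConfig:
    input_dir: str
    out_dir: str
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    method: str = "dollo"  # or 'fitch'
    tiebreak: str = "ACCTRAN"
    column_tolerance: int = 0
    reference_taxon: str | None = None
    te_denominator: str = "gene"
    dup_min_identity: float = 0.70
    dup_min_coverage: float = 0.50
    dup_k: int = 11
    dup_max_gap: int = 20000
    flank: int = 500_000


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    input_digests: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)
    timestamp: str = ""

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "version": self.version,
            "input_digests": self.input_digests,
            "stage_counts": self.stage_counts,
            "warnings": self.warnings,
            "skipped": self.skipped,
            "timestamp": self.timestamp,
        }


class StageError(RuntimeError):
    pass


class _WarningCollector(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record):
        self.messages.append(self.format(record))


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _discover(input_dir: Path):
    gffs = sorted(input_dir.glob("*.gff3"))
    pairs = []
    for gff in gffs:
        fasta = gff.with_suffix(".fasta")
        if fasta.exists():
            pairs.append((gff.stem, gff, fasta))
        else:
            logger.warning("no FASTA for %s; skipped", gff.name)
    return pairs


def read_genome_sizes(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    if df["taxon"].duplicated().any():
        dupes = sorted(df.loc[df["taxon"].duplicated(), "taxon"])
        raise ValueError(f"duplicate taxon keys in genome size table: {dupes}")
    return dict(zip(df["taxon"], df["genome_size"].astype(float)))


def run_pipeline(config: PipelineConfig) -> tuple[RunManifest, dict[str, pd.DataFrame]]:
    """Execute the configured stages and write all report tables."""
    collector = _WarningCollector()
    logger.addHandler(collector)
    try:
        return _run(config, collector)
    finally:
        logger.removeHandler(collector)


def _run(config, collector):
    input_dir = Path(config.input_dir)
    manifest = RunManifest(config=vars(config).copy())
    manifest.config["stages"] = list(config.stages)
    results: dict[str, pd.DataFrame] = {}

    pairs = _discover(input_dir)
    if not pairs:
        raise StageError(f"input: no <taxon>.gff3/<taxon>.fasta pairs in {input_dir}")
    models: list[GeneModel] = []
    for taxon, gff, fasta in pairs:
        manifest.input_digests[gff.name] = _digest(gff)
        manifest.input_digests[fasta.name] = _digest(fasta)
        try:
            models.extend(parse_gff3(gff, fasta, taxon=taxon, flank=config.flank))
        except Exception as exc:
            raise StageError(f"input: parsing {gff.name} failed: {exc}") from exc
    taxa = sorted({m.taxon for m in models})
    manifest.stage_counts["models"] = len(models)
    # homology/parsimony work on one gene per taxon: the longest CDS
    primary = {}
    for m in models:
        cur = primary.get(m.taxon)
        if cur is None or len(m.cds_seq) > len(cur.cds_seq):
            primary[m.taxon] = m

    tree = None
    tree_path = input_dir / "tree.nwk"
    if tree_path.exists():
        manifest.input_digests[tree_path.name] = _digest(tree_path)
        tree = parse_newick(tree_path, taxa=taxa)

    sizes = None
    sizes_path = input_dir / "genome_sizes.tsv"
    if sizes_path.exists():
        manifest.input_digests[sizes_path.name] = _digest(sizes_path)
        sizes = read_genome_sizes(sizes_path)

    if "metrics" in config.stages:
        try:
            results["per_gene_metrics"] = metrics.length_summary(models, sizes)
            results["census_summary"] = metrics.splice_site_census(models)
            recs = metrics.splice_site_records(models)
            results["splice_records"] = pd.DataFrame(
                [
                    {
                        "taxon": r.taxon, "gene_id": r.gene_id,
                        "intron_index": r.intron_index, "site_type": r.site_type,
                        "canonical": r.canonical, "valid": r.valid,
                    }
                    for r in recs
                ]
            )
            results["intron_length_bins"] = metrics.intron_length_bins(
                [m for m in models if m.n_introns]
            )
            manifest.stage_counts["splice_sites"] = sum(r.valid for r in recs)
        except Exception as exc:
            raise StageError(f"metrics: {exc}") from exc

    matrix = None
    if "homology" in config.stages:
        if len(primary) < 2:
            manifest.skipped.append("homology: fewer than 2 taxa")
        else:
            try:
                msa_path = input_dir / "msa.fasta"
                proteins = {
                    t: homology.translate_cds(m.cds_seq) for t, m in primary.items()
                }
                if msa_path.exists():
                    manifest.input_digests[msa_path.name] = _digest(msa_path)
                    from Bio import SeqIO

                    msa = {
                        r.id: str(r.seq)
                        for r in SeqIO.parse(str(msa_path), "fasta")
                    }
                    homology.check_msa(msa, taxa=list(primary))
                else:
                    msa = homology.align_proteins(proteins)
                positions = []
                for t in sorted(primary):
                    positions.extend(
                        homology.map_introns_to_alignment(primary[t], msa)
                    )
                matrix = homology.build_presence_matrix(
                    positions,
                    column_tolerance=config.column_tolerance,
                    reference_taxon=config.reference_taxon,
                    all_taxa=list(primary),
                )
                results["presence_matrix"] = matrix.presence
                results["intron_positions"] = pd.DataFrame(
                    [vars(p) for p in positions]
                )
                manifest.stage_counts["intron_sites"] = len(matrix.sites)
            except Exception as exc:
                raise StageError(f"homology: {exc}") from exc

    if "parsimony" in config.stages:
        if matrix is None or tree is None:
            manifest.skipped.append("parsimony: needs presence matrix and tree.nwk")
        else:
            try:
                if config.method == "dollo":
                    history = parsimony.dollo_reconstruct(matrix, tree)
                else:
                    history = parsimony.fitch_reconstruct(
                        matrix, tree, tiebreak=config.tiebreak
                    )
                results["branch_events"] = history.events_table()
                results["branch_summary"] = history.branch_summary()
                (Path(config.out_dir)).mkdir(parents=True, exist_ok=True)
                with open(Path(config.out_dir) / "annotated_tree.nwk", "w") as fh:
                    fh.write(history.annotated_newick() + "\n")
                manifest.stage_counts["events"] = len(history.events)
            except Exception as exc:
                raise StageError(f"parsimony: {exc}") from exc

    if "dupscan" in config.stages:
        try:
            rows = []
            for m in models:
                for b in dup_mod.scan_gene(
                    m,
                    k=config.dup_k,
                    min_identity=config.dup_min_identity,
                    min_coverage=config.dup_min_coverage,
                    max_gap=config.dup_max_gap,
                ):
                    rows.append(
                        {
                            "taxon": m.taxon, "gene_id": m.gene_id,
                            "exon_first": b.exon_first, "exon_last": b.exon_last,
                            "start": b.start, "end": b.end, "strand": b.strand,
                            "mean_identity": b.mean_identity,
                            "completeness": b.completeness,
                            "location": b.location,
                            "intron_index": b.intron_index,
                            "distance": b.distance, "straddle": b.straddle,
                        }
                    )
            results["duplication_blocks"] = pd.DataFrame(
                rows,
                columns=[
                    "taxon", "gene_id", "exon_first", "exon_last", "start", "end",
                    "strand", "mean_identity", "completeness", "location",
                    "intron_index", "distance", "straddle",
                ],
            )
            manifest.stage_counts["duplication_blocks"] = len(rows)
        except Exception as exc:
            raise StageError(f"dupscan: {exc}") from exc

    if "te" in config.stages:
        rm_paths = {p.name[: -len(".rm.out")]: p for p in input_dir.glob("*.rm.out")}
        if not rm_paths:
            manifest.skipped.append("te: no .rm.out files")
        else:
            try:
                profiles = []
                for m in models:
                    annos = []
                    if m.taxon in rm_paths:
                        manifest.input_digests[rm_paths[m.taxon].name] = _digest(
                            rm_paths[m.taxon]
                        )
                        annos = [
                            a
                            for a in parse_repeatmasker_out(rm_paths[m.taxon])
                            if a.target == m.gene_id
                        ]
                    profiles.append(
                        te.te_profile(m, annos, denominator=config.te_denominator)
                    )
                results["te_profiles"] = te.te_profile_table(profiles)
                if "per_gene_metrics" in results:
                    results["correlations"] = pd.concat(
                        [
                            te.correlation_report(
                                profiles, results["per_gene_metrics"], sizes
                            ),
                            te.correlation_report(
                                profiles, results["per_gene_metrics"], None,
                                exclude_zero_te=True,
                            ),
                        ],
                        ignore_index=True,
                    )
                manifest.stage_counts["te_profiles"] = len(profiles)
            except Exception as exc:
                raise StageError(f"te: {exc}") from exc

    if "isoforms" in config.stages:
        gtfs = sorted(input_dir.glob("*.gtf"))
        if not gtfs:
            manifest.skipped.append("isoforms: no .gtf files")
        else:
            try:
                ev_rows, uorf_rows = [], []
                for gtf in gtfs:
                    manifest.input_digests[gtf.name] = _digest(gtf)
                    fasta = gtf.with_suffix(".fasta")
                    gmodels = parse_gff3(gtf, fasta, taxon=gtf.stem, flank=0)
                    for gm in gmodels:
                        events = isoforms.classify_as_events(gm.gene_id, gm.transcripts)
                        for ev in events:
                            ev_rows.append(
                                {
                                    "taxon": gm.taxon, "gene_id": ev.gene_id,
                                    "transcript_a": ev.transcript_a,
                                    "transcript_b": ev.transcript_b,
                                    "event_type": ev.event_type,
                                    "intervals": ";".join(
                                        f"{s}-{e}" for s, e in ev.intervals
                                    ),
                                }
                            )
                        for tr in gm.transcripts:
                            seq = "".join(
                                gm.gene_seq[max(s, 0) : e] for s, e in tr.exons
                            )
                            main = _main_orf_start(seq)
                            for u in isoforms.find_uorfs(
                                seq, main, transcript_id=tr.transcript_id
                            ):
                                uorf_rows.append(
                                    {
                                        "taxon": gm.taxon,
                                        "transcript_id": u.transcript_id,
                                        "start": u.start, "stop_end": u.stop_end,
                                        "length_aa": u.length_aa,
                                    }
                                )
                results["as_events"] = pd.DataFrame(
                    ev_rows,
                    columns=["taxon", "gene_id", "transcript_a", "transcript_b",
                             "event_type", "intervals"],
                )
                results["uorfs"] = pd.DataFrame(
                    uorf_rows,
                    columns=["taxon", "transcript_id", "start", "stop_end",
                             "length_aa"],
                )
                manifest.stage_counts["as_events"] = len(ev_rows)
            except Exception as exc:
                raise StageError(f"isoforms: {exc}") from exc

    manifest.warnings = list(collector.messages)
    manifest.stage_counts["tables"] = len(results)
    manifest.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S")
    write_report_tables(results, config.out_dir, manifest=manifest.to_dict())
    return manifest, results


def _main_orf_start(seq: str) -> int:
    """Offset of the start codon of the longest ORF (the main ORF proxy)."""
    best_start, best_len = 0, -1
    seq = seq.upper()
    stops = {"TAA", "TAG", "TGA"}
    for frame in range(3):
        i = frame
        while i + 3 <= len(seq):
            if seq[i : i + 3] == "ATG":
                j = i + 3
                while j + 3 <= len(seq) and seq[j : j + 3] not in stops:
                    j += 3
                if j - i > best_len:
                    best_start, best_len = i, j - i
                i = j + 3
            else:
                i += 3
    return best_start
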