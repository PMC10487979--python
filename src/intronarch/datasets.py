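"""Small worked-example datasets built programmatically.

These encode published seed-plant intron complements and the splice-site
census composition as in-memory objects, so the worked examples and the
reproduction script can run without any external downloads.
"""

from __future__ import annotations

from .homology import IntronSiteMatrix
from .models import GeneModel
from .trees import SpeciesTree

# Taxa representing the seed-plant clades
GYMNOSPERMS = ["Cycas", "Ginkgo", "Picea", "Gnetum", "Welwitschia"]
GNETALES = ["Gnetum", "Welwitschia"]
ANA_GRADE = ["Amborella", "Nymphaea", "Euryale"]
MESANGIOSPERMAE = ["Chloranthus", "Oryza", "Vitis", "Arabidopsis"]

SEED_PLANT_NEWICK = (
    "(((Cycas,Ginkgo),(Picea,(Gnetum,Welwitschia)))gymnosperms,"
    "((Amborella,(Nymphaea,Euryale))ana_grade,"
    "(Chloranthus,(Oryza,(Vitis,Arabidopsis)))mesangiospermae)angiosperms"
    ")seed_plants;"
)


def seed_plant_example() -> tuple[SpeciesTree, IntronSiteMatrix]:
    """Seed-plant intron presence/absence matrix and species tree.

    Clade intron complements: gymnosperms carry sites 1-22; Gnetum and
    Welwitschia additionally carry the derived site 21'; the ANA grade
    carries sites 1-22; Mesangiospermae carry sites 1-20 and 22 (site 21
    lost on their stem). Internal nodes of interest are labeled
    ``seed_plants``, ``mesangiospermae``, and the Gnetum+Welwitschia stem
    is the MRCA of those two leaves.
    """
    base = [str(i) for i in range(1, 23)]
    site_order = base[:21] + ["21'"] + base[21:]  # 21' sits after 21, before 22
    complements: dict[str, set[str]] = {}
    for taxon in GYMNOSPERMS:
        complements[taxon] = set(base)
    for taxon in GNETALES:
        complements[taxon] = set(base) | {"21'"}
    for taxon in ANA_GRADE:
        complements[taxon] = set(base)
    for taxon in MESANGIOSPERMAE:
        complements[taxon] = set(base) - {"21"}
    tree = SpeciesTree.from_newick(SEED_PLANT_NEWICK)
    matrix = IntronSiteMatrix.from_dict(complements, site_order=site_order)
    return tree, matrix


def _gene_with_intron_sites(taxon: str, gene_id: str, site_types: list[tuple[str, str]]) -> GeneModel:
    """Synthetic gene whose n introns carry the given terminal dinucleotides."""
    exon = "ATGGCAGTCAAG"  # 12 nt exon unit
    pieces = [exon]
    exons = [(0, len(exon))]
    pos = len(exon)
    for donor, acceptor in site_types:
        intron = donor + "TTTTAAAATTTT" + acceptor
        pieces.append(intron)
        pos += len(intron)
        pieces.append(exon)
        exons.append((pos, pos + len(exon)))
        pos += len(exon)
    gene_seq = "".join(pieces)
    return GeneModel(
        taxon=taxon,
        gene_id=gene_id,
        scaffold=f"{taxon}_scaf",
        span=(0, len(gene_seq)),
        strand="+",
        exons=exons,
        gene_seq=gene_seq,
    )


def census_example(
    n_total: int = 1479,
    n_canonical: int = 1391,
    n_ggca: int = 23,
    introns_per_gene: int = 29,
) -> list[GeneModel]:
    """Gene models whose pooled introns realize a prescribed splice census.

    Defaults give ``n_total`` splice sites of which ``n_canonical`` are
    GT-AG and, among the non-canonical remainder, ``n_ggca`` are GG-CA;
    other non-canonical sites are split over GC-AG and AT-AC.
    """
    n_noncanon = n_total - n_canonical
    n_rest = n_noncanon - n_ggca
    if min(n_canonical, n_ggca, n_rest) < 0:
        raise ValueError("inconsistent census composition")
    sites = (
        [("GT", "AG")] * n_canonical
        + [("GG", "CA")] * n_ggca
        + [("GC", "AG")] * (n_rest // 2)
        + [("AT", "AC")] * (n_rest - n_rest // 2)
    )
    models = []
    for i in range(0, len(sites), introns_per_gene):
        chunk = sites[i : i + introns_per_gene]
        idx = i // introns_per_gene
        models.append(_gene_with_intron_sites(f"taxon{idx}", f"g{idx}", chunk))
    return models
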