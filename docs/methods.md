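# Methods

## Coordinates and gene models

All internal coordinates are 0-based half-open; GFF3/GTF input (1-based
inclusive) is converted at the parser boundary and nowhere else. Gene
models are strand-normalized on ingestion: minus-strand genes are
reverse-complemented so that position 0 is the transcription start and
exon/intron indices (1-based, as in "intron 14") always count in
transcription order. Every model satisfies, by construction and by
validation: exons are disjoint and sorted; intron *i* is the gap between
exons *i* and *i+1*; the concatenated exons equal the spliced CDS; exons
plus introns tile the unspliced gene exactly.

When a transcript carries both CDS and exon features, the CDS features
define the model — the analyses concern the coding gene, and UTR exons
would shift intron phases. With several annotated transcripts the longest
spliced chain is the constitutive model; all transcripts are kept for the
isoform stage. Curation of third-party annotations is out of scope: models
are taken as provided.

## Architecture metrics

GC content excludes IUPAC ambiguity codes from both numerator and
denominator, so N-rich draft regions do not deflate the estimate; a window
with no unambiguous base yields NaN, never 0. GC1/GC2/GC3 are computed
over complete codons only, with a trailing partial codon dropped under a
warning.

The splice-site census records the first and last two bases of each
strand-normalized intron; "canonical" means exactly GT-AG. Introns shorter
than 4 nt cannot carry two distinct dinucleotides and are flagged invalid
and excluded from totals, so canonical + non-canonical always equals the
valid-site total. Percentages are held at full precision internally and
rendered to 2 decimals only in report tables.

Intron-length bins use strict lower bounds ("larger than 5 kb" means
> 5000 nt); the bin edges (5 kb, 10 kb) are configurable and validated for
monotonicity.

## Intron homology

An intron at CDS offset *o* has codon index ⌊o/3⌋ and phase o mod 3. The
codon index is mapped through the taxon's row of a protein multiple
alignment to an alignment column; introns sharing phase and column (within
a configurable tolerance, default 0) are single-linkage clustered into one
homologous site. Strict matching is deliberate: for deeply conserved
coding regions it is sufficient, and a tolerance loose enough to merge two
introns of one taxon into one site is reported as an error naming the
taxon rather than silently resolved.

The built-in aligner is a deterministic star alignment: the longest
sequence is the center, every other sequence is globally aligned to it
(BLOSUM62, gap open 10, extend 1), and the pairwise alignments are merged
under once-a-gap-always-a-gap. This is adequate for well-conserved
proteins and keeps the pipeline dependency-free; for divergent data a real
MSA (e.g. from MAFFT) can be supplied and is validated for shape and taxon
coverage. Site labels are integers in column order; with a designated
reference taxon, sites it lacks get a prime suffix on the nearest
preceding reference label (21′), matching the field's naming convention.
Intron sliding is not modeled: a shifted intron becomes a distinct site.

## Gain/loss parsimony

The character is binary site presence on a rooted species tree, with the
ancestral (above-root) state fixed to absent — for a gene family whose
outgroups are predominantly intronless this is the natural rooting. Two
reconstructions are provided:

* **Dollo** (default): the site's one gain sits on the branch entering the
  MRCA of all carriers; losses sit on the maximal carrier-free subtrees
  below it. This is the unique minimum-event history under the single-gain
  constraint.
* **Fitch** (unit-cost Sankoff) with the same root constraint expressed as
  a virtual edge above the root: a root reconstructed present costs one
  event, reported as "gained at or before the root". Ties between keeping
  the parent state and changing are broken by ACCTRAN (change rootward,
  default) or DELTRAN (delay leafward). Both variants are verified against
  exhaustive enumeration of all labelings on every rooted tree shape with
  up to 6 leaves.

Taxa whose gene is missing or incomplete are excluded per site (coded
missing, not absent): absence of evidence is not intron loss. Sites with
no carriers are dropped with a warning. Sites whose event placement
differs between the two methods can be flagged as low-confidence.

Identifiability: a gain followed by a loss that prunes one flank of the
gain clade is indistinguishable from a single later gain, and a site lost
in every lineage leaves no trace. Simulated-recovery statistics therefore
measure exact recovery of the logged history and enumerate the mismatches;
they are expected to approach, not reach, 100%.

## Duplication scan

Each exon is searched against the gene plus flanks (default up to 500 kb
each side when slicing genomes; the simulator sizes flanks to fit planted
copies). Exact k-mer seeds (k = 11, every ⌊k/2⌋ positions of the query)
are clustered by diagonal into candidate windows, each refined by affine
Smith–Waterman (match +2, mismatch −3, gap open −5 plus −2 per gap
residue) restricted to the window's diagonal band — the banded score can
never exceed the full-matrix optimum, which the tests check against an
independent unbanded implementation. Hits need ≥70% identity and ≥50%
query coverage; these thresholds mirror permissive nucleotide-BLAST
practice, are not derived from any published analysis, and are exposed in
configuration. Both strands are scanned; inverted copies chain by strictly
decreasing exon index and are flagged by strand.

Chaining joins colinear hits within 20 kb, and a chain never crosses the
gene's own exons — a contiguous duplicate cannot contain its source exons,
so hits on opposite sides of them belong to different blocks. Blocks are
classified as internal (fully inside intron *i*), upstream, or downstream
with the distance to the gene boundary; a block straddling an exon
boundary is assigned by midpoint and flagged. A block that covers all
exons is "full", otherwise "partial" (the analogue of a duplicate lacking
its terminal domain-coding exons). Exons shorter than k are skipped with a
warning and cannot contribute to recall.

## TE content

Coverage fractions are computed on interval unions, making them invariant
to split or duplicated annotations and monotone in added TE bases. The
denominator is the full gene length by default (intron-only is available
by flag — published "proportion of TEs" figures are ambiguous between the
two, so both are one switch apart). Class attribution resolves inter-class
overlaps by the fixed priority retrotransposon > DNA transposon >
helitron > unclassified; RepeatMasker output is normally non-overlapping,
so this guards only pathological input. The Pearson test uses the closed
form t = r·√((n−2)/(1−r²)) with n−2 df, validated to 1e-10 against
scipy's reference implementation; raw p-values are reported (two planned
tests, no multiplicity correction). The length~TE-fraction correlation is
computed both over all profiled genes and restricted to genes with any TE,
since published figures do not state which convention they used.

## Alternative splicing and uORFs

Events are typed purely from the two intron chains within the transcripts'
shared span: donor-only difference → alt_donor; acceptor-only →
alt_acceptor; one fused intron spanning several → exon_skipping; two
intron pairs sharing outer boundaries with non-overlapping middle exons →
mutually_exclusive; an intron of one inside an exon of the other →
intron_retention; anything else → other. Alternative first-exon usage is
deliberately "other": an isoform that starts mid-exon and skips upstream
introns is structurally ambiguous between first-exon choice and skipping,
and the classifier stays literal. Calls are pairwise with deduplication of
identical (type, intervals) events across pairs, and symmetric in the pair
order.

uORFs are ATG…stop ORFs in any frame lying entirely (stop included) 5′ of
the main start; length in aa counts the initiator Met and excludes the
stop; overlapping uORFs are all reported. In the pipeline, where a GTF
gives no CDS, the main start is proxied by the start of the longest ORF.

## Simulator

The simulator is the package's source of ground truth. An ancestral gene —
by default 23 exons / 22 introns around a ~3.45 kb CDS, the stable
seed-plant architecture — is built from random non-stop codons with intron
offsets spaced at least 60 nt apart (so every exon is seedable by the
duplication scan), then evolved in preorder down the tree. Per branch, in
fixed order: Poisson losses (a gain made on a branch cannot be erased on
that same branch), Poisson gains at unoccupied CDS offsets (phases arise
naturally), TE insertions (a mutated copy of a fixed 5-element synthetic
library — Gypsy/Copia retrotransposons, a DNA transposon, a helitron, an
unclassified repeat — at 2–20% divergence into a random intron), and CDS
substitution at the configured per-site rate with a 3:1 bias to third
codon positions, rejecting changes that create or destroy stops. Splice
sites are GT-AG except with probability 0.06 (the observed non-canonical
share), when a labelled non-canonical type is drawn with GG-CA most
likely. Default gain 0.1 and loss 0.3 events/branch make loss dominate,
as in the seed-plant data.

The CDS never indels, so the true protein alignment is the ungapped stack
of leaf proteins, and alignment columns equal codon indices — this is what
makes exact recovery checks possible. TE interval bookkeeping splits an
existing element's interval when a new insertion lands inside it, so
registry-derived coverage stays exact under nesting. Planted duplications
copy the pristine gene (before other insertions) so planted copies never
nest; flank-targeted copies replace flank sequence, preserving the
specified distance exactly. Isoforms are built by named operations
(skip_exon, alt_donor, alt_acceptor, retain_intron, mutually_exclusive,
alt_first_exon) on the constitutive chain.

Everything derives from one seeded PCG64 stream with fixed iteration
order; two runs from the same seed emit byte-identical files. Emission
writes alternate taxa on the minus strand to exercise parser
normalization. The multi-transcript GTF is separate from the GFF3 so the
constitutive model is unambiguous.

What the simulator does not emulate: non-TE intron indels, intron sliding,
nucleotide-level intron homology, rate variation across sites, gene
conversion between duplicate copies, and assembly/annotation error.
Passing recovery tests therefore demonstrates correctness of the
inference machinery under the stated generative model, not robustness to
every pathology of real genome data.

## Problem sizes and defaults in the test suite

The checks run at desk scale: oracle equivalence enumerates all rooted
shapes with ≤6 leaves; event recovery uses 16-leaf families over 20
replicate seeds (gain 0.1 / loss 0.3 per branch) and requires ≥95%
aggregate exact recovery; duplication recall plants 10 copies (spans of
3–14 exons; internal, upstream — one at 341 kb — and downstream targets)
at 0% and 10% divergence; the TE correlation uses 30 taxa with per-branch
insertion rates drawn from U(0, 4). Genome-scale published figures that
require the original multi-genome download (overall census sizes,
real-data correlation coefficients) are represented by the in-package
worked examples and property suites, not re-estimated.

## Known limitations

* The star aligner is not a substitute for a proper progressive aligner on
  divergent proteins; supply an MSA for such data.
* Dollo assumes sites are never regained; genuinely homoplastic intron
  positions (e.g. Introner-like bursts) would be merged into one site and
  misdated.
* Duplication recall degrades for exons shorter than the seed size and for
  copies below the identity threshold (~30% divergence).
* The AS classifier types pairwise structural differences; it does not
  build a splice graph and will file complex multi-event regions as
  "other".
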