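# intronarch

Comparative analysis of exon–intron architecture evolution in a gene
family sampled across a species phylogeny.

Single-copy genes sampled densely across a deep phylogeny — the green-plant
organelle-recombination gene family is the motivating case — show enormous
variation in length (kilobases to hundreds of kilobases), intron number
(0 to ~27), GC composition, splice-site usage, transposable-element (TE)
load, partial duplications, and splicing isoforms. `intronarch` provides a
tested, reproducible pipeline for the full set of analyses such a study
needs, plus a ground-truthed simulator to validate every step.

## What it computes

* **Architecture metrics** — gene/CDS lengths, intron fraction, GC content
  overall and by codon position (GC1/GC2/GC3), the splice-site
  dinucleotide census (canonical GT-AG vs non-canonical types such as
  GG-CA), and intron-length bins (≤5 kb / 5–10 kb / >10 kb).
* **Intron homology** — each intron is projected to a (codon index, phase)
  pair in its own protein and through a protein multiple alignment to an
  alignment column; positions sharing phase and column are clustered into
  homologous intron sites, giving the taxa × sites presence/absence
  matrix.
* **Gain/loss reconstruction** — ancestral intron complements and
  per-branch events on a rooted species tree under **Dollo parsimony**
  (each site gained once, lost freely, intronless ancestral state) or
  unit-cost **Fitch/Sankoff** with the same root constraint
  (ACCTRAN/DELTRAN tie-breaking).
* **Partial gene duplications** — per-exon seed-and-extend local alignment
  (exact k-mer seeds + banded affine Smith–Waterman) over the gene and its
  flanks; colinear hits are chained into blocks and classified as internal
  (in intron *i*) or upstream/downstream at a distance.
* **TE content** — RepeatMasker `.out` ingestion, union-based coverage
  fractions by the four TE classes (retrotransposon / DNA transposon /
  helitron / unclassified, with the Gypsy/Copia LTR split), and Pearson
  tests of gene length against TE fraction and genome size.
* **Alternative splicing** — intron-chain comparison of transcript pairs
  typed as alternative donor/acceptor, exon skipping, mutually exclusive
  exons, intron retention, or other (including alternative first-exon
  usage), plus uORF detection in 5′ leaders.
* **Simulation** — an ancestral multi-exon gene evolved along a tree with
  Poisson intron gains/losses, labelled TE insertions, synonymous-biased
  CDS substitution, planted duplications and isoforms, emitting every
  pipeline input format (FASTA/GFF3/GTF/Newick/RepeatMasker `.out`) plus a
  complete truth log.

The reconstruction model, in the field's notation: a binary character
(intron site presence) on a rooted tree with leaf states fixed by the
matrix. Dollo places the single allowed 0→1 change on the branch entering
the MRCA of all carriers and one 1→0 change on each maximal carrier-free
subtree below it; the Fitch variant minimizes total changes with the state
above the root fixed to 0, so a site present at the root costs one "gained
at or before the root" event.

## Worked example

```python
from intronarch import dollo_reconstruct
from intronarch.datasets import seed_plant_example

tree, matrix = seed_plant_example()   # 12 seed-plant taxa x 23 intron sites
history = dollo_reconstruct(matrix, tree)
print(history.intron_count("seed_plants"),
      history.intron_count("mesangiospermae"),
      history.intron_count(tree.mrca_label(["Gnetum", "Welwitschia"])))
```

prints `22 21 23`: the seed-plant ancestor carries 22 introns, the
Mesangiospermae ancestor 21 (site 21 is lost on its stem), and the
Gnetum+Welwitschia ancestor 23 (the derived site 21′ is gained on its
stem). Running `python examples/02_intron_gain_loss.py` shows the same
reconstruction with the per-branch `+gains/−losses` summary:

```
reconstructed intron counts:
  seed-plant ancestor:         22
  Mesangiospermae ancestor:    21
  Gnetum+Welwitschia ancestor: 23

per-branch events (+gains/-losses):
                  N1: +1/-0  (site 21')
     mesangiospermae: +0/-1  (site 21)
```

The other scripts under `examples/` each demonstrate one capability
(census arithmetic, simulation + event recovery, duplication scanning, TE
correlations, splicing classification) and print what the numbers mean.

## Command line

```bash
intronarch simulate --seed 5 --leaves 8 --out simdir
intronarch run --inputs simdir --out results/
```

`run` discovers `<taxon>.gff3`/`<taxon>.fasta` pairs, `tree.nwk`, and the
optional `msa.fasta`, `<taxon>.rm.out`, `<taxon>.gtf`,
`genome_sizes.tsv`; it writes TSV report tables and a JSON manifest with
input digests, stage counts and collected warnings. Per-stage subcommands
(`metrics`, `homology`, `parsimony`, `dupscan`, `te`, `isoforms`) run a
single stage.

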