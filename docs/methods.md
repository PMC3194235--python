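# Methods

## Model and assumptions

`markerphyler` classifies metagenomic reads by translated homology search
against protein-coding phylogenetic marker genes and estimates clade
abundances from marker depth of coverage. The method rests on three
assumptions:

1. **Markers track organisms.** The marker families are universal,
   single-copy and rarely horizontally transferred, so marker coverage is
   proportional to organism abundance (unlike 16S copy number or whole-
   genome read counts, which vary with copy number and genome size).
2. **Similarity decays with taxonomic distance.** Bit scores against a
   reference gene are higher for reads from close relatives than from
   distant ones. This is what makes a rank-specific score threshold
   meaningful. It holds on average, not gene by gene: the taxonomy is not
   perfectly congruent with sequence divergence, which is why thresholds
   are *learned* per gene rather than assumed.
3. **Bit score is linear in matching length.** The raw local-alignment
   score of a gene fragment is, in expectation, proportional to the
   fragment's aligned length, so the bit score of fragments of one gene is
   an affine function of HSP length. This justifies summarising per-length
   cutoffs by a linear regression; the package verifies it empirically
   (R² ≥ 0.999 for self-aligned prefixes of a synthetic 200 aa gene).

## Threshold learning

For gene *G*, rank *r* and simulated read length *L*, the score vectors are
**B_level** — all hits against *G* of reads simulated from the same rank-*r*
clade as *G* — and **B_else** — hits of every other read, including a
negative set of random non-marker reads (1:1 with the positive set by
default). Reads simulated from *G* itself are excluded from *both* vectors:
placing these maximal-scoring, same-clade-at-every-rank hits in B_else
would count them as errors above any threshold and force every cutoff
above the same-clade score range.

The cutoff minimises `err(b) = |{s ∈ B_level : s < b}| + |{s ∈ B_else :
s ≥ b}|`. Since `err` is a step function changing only at observed scores,
candidates are the observed scores plus a sentinel one unit above the
maximum; this makes an exhaustive scan exact and cheap, and the brute-force
scan is kept as a test oracle. Among minimisers the **largest** candidate
is returned: the stringent choice, which prefers refusing a specific label
over assigning one without support, and is what makes novel-taxon
detection possible. Degenerate cases are defined, not special-cased:
empty B_level yields `max(B_else)+1` (nothing passes); empty B_else yields
`min(B_level)`.

All frame-segment hits of a read against *G* enter the vectors (a read
whose translation is split by a stop codon contributes each stop-free
segment separately), mirroring how a translated search reports HSPs.

Cutoffs are regressed on length by ordinary least squares with length in
**amino acids** (`L_aa = L_nt / 3`), the unit in which translated searches
report HSP lengths, so training and classification share one unit. A
single available length falls back to a proportional fit through the
origin. Predictions are clamped at zero. HSP lengths outside the trained
support still classify via the clamped line but are flagged
`extrapolated`.

### Training simulation parameters

* **Read length grid**: 60 bp to the gene length in 60 bp steps.
* **Tiling stride**: 30 nt by default — deterministic tiling gives
  reproducible training and uniform positional coverage; random-start
  sampling exists for community simulation only.
* **Training read error rate**: 0.01 substitutions/nt, the same error
  model applied to query reads. Train/test consistency matters here: with
  error-free training reads the stringent cutoff sits at the minimum of
  clean same-clade scores and systematically rejects error-carrying reads
  of the same clade.
* **Negative set**: i.i.d. random DNA at GC 0.5, one negative per positive
  read. Random DNA guarantees no marker homology; a user-supplied
  non-marker FASTA can stand in for it when realistic background
  composition matters.

## Alignment

Queries are translated in all six frames; frames are split at stop codons
and segments shorter than 8 aa are dropped (they cannot form a meaningful
HSP). Scoring is Smith–Waterman with affine gaps: BLOSUM62, gap open −11,
extend −1 (a length-*k* gap costs 11 + *k*), bit scores via λ = 0.267,
K = 0.041 — the standard constants for this scoring system. Bulk scoring
runs in a numba kernel that processes all reference proteins in lockstep
against each query segment (the gene axis is contiguous and branch-free,
so it vectorises); full alignments with coordinates and identities are
computed only for reported hits, through Biopython's `PairwiseAligner`
under the identical scheme. The two implementations are cross-checked in
the tests, and both are checked against a pure-Python textbook DP oracle.
Externally computed BLAST tabular files can replace the built-in search;
their bit scores are used as-is, and E-values are carried through but
never used for decisions.

Best-hit selection is deterministic: maximal bit score, ties to the longer
HSP, then the lexicographically smallest gene id.

## Classification and novelty

Each read is classified from its best hit only (no lowest-common-ancestor
voting), trying genus → family → order → class → phylum and accepting the
first rank with `b ≥ b_cut(L)`. The comparison is `≥`: exact ties pass.
Reads stopping above genus appear at lower ranks as `Name{rank}` novelty
bins. The discrepancy report counts, per taxon, reads assigned exactly at
it versus below it; a non-genus taxon with at least `min_reads` (default 5)
reads stopped at it is flagged as a novel-clade candidate, with member
read ids listed for downstream assembly.

## Abundance estimation

Coverage of marker family *f* in a clade bin is the summed aligned
nucleotide bases (3 × HSP aa length) of the bin's reads whose best hit is
an *f* gene, divided by the mean nucleotide length of the *f* genes in the
bin's clade (family-wide mean when the clade has no reference gene, as for
novelty bins). A bin's depth of coverage is the **median** over the
configured marker set, with families lacking reads counted as zero — the
literal reading of a median over all markers; an `exclude-zero-markers`
mode is available because taxa covered on a minority of markers otherwise
collapse to zero. Relative abundance is coverage normalised over the bins
of the profiled rank. Profiles aggregate upward: a read assigned at genus
contributes to its family at the family-level profile; reads assigned
above the profiled rank form `Name{rank}` bins, which participate in the
normalisation, so each rank's profile sums to one.

## Synthetic data

The generator evolves one protein per marker family down a balanced,
rank-labelled taxonomy: each branch at rank *r* substitutes residues with
probability p(*r*) (defaults 0.30 phylum, 0.20 class, 0.15 order, 0.10
family, 0.06 genus, 0.02 species, 0.005 strain; monotonicity is enforced),
so expected identity is strictly ordered same-genus > same-family >
same-order — the property assumption 2 requires. Nucleotide sequences are
back-coded with a fixed codon per amino acid plus synonymous wobble
(rate 0.5), keeping the translation invariant exact while letting
nucleotide identity drift below protein identity. Communities embed each
planned taxon's markers, evenly spaced, in random background DNA; reads
are drawn uniformly from both strands with `round(coverage × genome length
/ read length)` reads per genome, and truth tables record every read's
origin. All generators are pure functions of (parameters, seed).

What the generator does **not** emulate: indels and realistic sequencing
chemistry (substitution errors only), rate heterogeneity across sites and
lineages, horizontal transfer, compositional bias, paralogy, and the
incomplete/inconsistent lineages of real taxonomies. Passing tests on this
data therefore demonstrate the correctness and internal consistency of the
machinery under the model's assumptions, not classifier performance on
real metagenomes.

## Evaluation protocols and problem sizes

Two experiments exercise the full pipeline at desk scale (each a few
minutes on one core).

**Community recovery.** Taxonomy (1,1,2,3,2,2,2) — one phylum down to two
strains per species — with 4 marker families of 100 aa; five *strains* in
distinct families form the community (coverages 25/10/5/5/5, 100 bp reads,
2400 nt genomes). The five genomes are removed from the reference before
training, mirroring a removed-genome benchmark: each genus keeps a
near-identical sister strain (~1% diverged) and each family a second
genus, so reads can recover their genus and the genus and family ranks
stay trainable after the deletion.
The estimate for a genus is its genus row plus its family's novelty bin
(unambiguous here because each community organism sits in its own family).
Across seeds this recovers the 50/20/10/10/10 % truth with max absolute
error ≤ ~4 points and Pearson r > 0.99.

**Held-out genus.** Taxonomy (2,1,2,1,4,2) with 3 families of 120 aa; all
genes of one genus are deleted from training and 300 bp reads simulated
from them are classified. The held-out genus is chosen deterministically
as the one whose nearest other-genus marker identity is the *median*
across genera: per-branch divergences are random, so an arbitrary fixed
genus is occasionally quasi-identical to a reference genus (a mislabelled-
taxonomy situation rather than a novel-taxon test) or atypically distant.
Training uses stride 15 nt, queries stride 5 nt (78 reads). Expected
outcome, verified across seeds: ≥ 90 % of classified reads correct at the
family level, < 5 % receiving any genus label, and the parent family
flagged in the discrepancy report.

The taxonomy shapes are structural requirements, not tuning: training
reads are simulated from the post-deletion reference, so a rank is only
trainable for a gene if a same-rank relative *survives* the deletion —
genera need a surviving species/strain, families a surviving second genus.
The count-based error of the cutoff search also needs the same-clade score
tier sampled on a comparable footing to the competing tier, which sets the
relative branching factors.

## Numerical choices and degenerate inputs

* Bit scores use double precision; cutoff candidates compare exactly
  (no tolerance) since candidates are drawn from the observed scores.
* The alignment kernel works in int32 with a −10⁶ sentinel; padding
  residues score −10⁶ so they can never extend an alignment.
* `relative_abundance` of an all-zero coverage vector returns zeros with a
  warning flag rather than dividing by zero; profiles of empty
  classification sets are empty and flagged.
* Taxon ids are opaque strings; ranks outside the five classification
  ranks plus root/no_rank/species/strain are read as `no_rank`.
* `same_clade` on a lineage lacking the rank is false, never an error;
  genes whose lineage lacks a rank are skipped (and counted) for that
  rank during training.
* CLI runs are byte-reproducible under a fixed seed; the JSON manifest
  deliberately records no wall-clock time (timestamps go to the stderr
  log) so that identical runs produce identical files.

## Known limitations

* Substitution-only error and evolution models; no indels, so no
  frameshift handling beyond six-frame search.
* The negative training set is random DNA, which is easier to reject than
  real intergenic sequence; learned cutoffs may be slightly permissive at
  the phylum end on real data.
* Cutoff learning needs relatives at each rank: taxa that are sole members
  of their clade get degenerate (maximally stringent) cutoffs at that
  rank, by design.
* No confidence scores: classification is binary per rank, and the
  stringent tie-break means borderline reads fall back to higher ranks.
* Abundance estimates ignore marker-length edge effects (reads overlapping
  gene ends align partially, deflating coverage uniformly; normalisation
  cancels most of it).
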