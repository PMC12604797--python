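# Methods

This note documents the models, decision rules, and numerical choices
behind `verifid`, and what the synthetic-data generator does and does not
emulate.

## The read model

The tetraplex PCR produces, per barcode, a double-stranded amplicon whose
top strand is `tail + F + insert + rc(R) + rc(tail)`, where `tail` is a
barcode-specific 13-bp unit repeated twice (CYTB `AGTGTCCTGCTAG`, COI
`CTGAGGTGATCAG`, 16S `AACATGTGGTAAG`, 12S `TTATTCGCACACT`) and the default
insert lengths are CYTB 307, COI 214, 12S 111, 16S 103 bp. The 26-nt tail
exists to give the transposase complex a landing zone.

Rapid-kit library preparation ("tagmentation") introduces one
double-strand break per molecule, modelled as uniform over internal
positions, and ligates the sample index to both newly created internal 5′
ends. Sequencing then proceeds 5′→3′ from each index, so each molecule
yields two reads:

- right fragment: `index + top_strand[k:]` — distal end carries
  `rc(R) + rc(tail)` → the *forward* strand consensus;
- left fragment: `index + rc(top_strand[:k])` — distal end carries
  `rc(F) + rc(tail)` → the *reverse* strand consensus.

Consequences the pipeline is built around: (i) a read is only
interpretable if a primer is found at its distal end; (ii) read coverage
of the amplicon thins towards the proximal (breakpoint) side, so each
strand consensus is reliable from its distal end inward; (iii) one
consensus per barcode is impossible — the unit of evidence is
(barcode, strand).

Reads that span the full amplicon also retain the *other* primer and a
partial tail at their proximal start. These are trimmed as well; leaving
them would let barcode-constant sequence inflate between-read identity
during clustering and merge species in mixtures.

## Read preparation

- Mean read quality is `Q = −10·log10(mean per-base error probability)`
  (the convention of common long-read filters, dominated by the worst
  bases). The value is rounded at the ninth decimal so a read of constant
  Phred q scores exactly q and the inclusive ≥ 11 threshold behaves as
  stated. Defaults: Q ≥ 11, length 100–500 bp inclusive, length checked
  first.
- Index demultiplexing: best edit distance within the leading 60 bases;
  default max edit 3 (indices are ~24 bp); ties or distances above the cap
  leave the read unassigned. The index region is trimmed through the end
  of the match.
- Primer search: the distal window is 1.5 × (primer + tail length); each
  of the eight primers is sought as its reverse complement, with IUPAC
  degeneracy codes matching their base sets at zero cost (implemented as
  edlib equality pairs and property-tested against a brute-force matcher).
  Default max edit is ⌈0.25 × primer length⌉, tolerant of ~10–15% nanopore
  error while keeping the four tails/primers mutually distinguishable.
  Tie-break: lowest distance, longest primer, fixed panel order
  (CYTB, COI, 16S, 12S), forward before reverse — fully deterministic.

## Clustering and consensus

Within each (sample, barcode, strand) bin, reads share a distal anchor, so
identity is computed over the shared distal span (suffix-clipped global
alignment). Greedy star clustering visits reads longest-first (ties by
read id, making the result input-order invariant); a read joins the first
cluster whose representative it matches at ≥ 0.80 identity, a default
that tolerates ~2× per-read nanopore error while separating species
diverged by ≥ ~15%.

Retained clusters must satisfy both the abundance ratio (default 0.1% of
the bin after filtering — the denominator is a package choice, stated
because upstream tools leave it implicit) and the supporting-read floor:
100 for single-source samples, 21 (i.e. "> 20") for mixtures. The mixture
floor can be derived from a negative control as
`max(floor, 3 × max control cluster support)`.

The consensus aligns up to the 500 longest members to the cluster
representative with the distal ends pinned (edlib `SHW` mode on reversed
sequences), then takes a per-column majority over {A, C, G, T, gap} with
ties resolved to the representative's base. Insertions relative to the
representative are voted on as junction fragments and restored when a
majority of the covering reads agree — this matters because a
representative carrying two adjacent errors produces tied alignment paths
that systematically vote a spurious deletion otherwise. Proximal columns
with coverage below `max(3, 30% of members)` are trimmed, mirroring the
thinning coverage of the tagmentation model. A partial-order aligner
would be the heavier alternative; at amplicon lengths ≤ 353 bp the star
consensus is exact in practice (the suite verifies exact recovery at 5%
substitution noise with 50 reads) and fully deterministic.

## Classification

Every consensus is aligned to every reference record under affine-gap
local alignment (match +2, mismatch −3, gap open −5, gap extend −2),
in both orientations — reverse-strand consensuses are reverse complements
of the deposited reference orientation. The E-value column is the
Karlin–Altschul form `E = K·m·n·e^(−λS)` with BLASTN-like constants
(λ = 0.625, K = 0.41). Because the database is desk-scale and E is used
only for ranking, the constants are a surrogate, not a calibration, and
no k-mer seeding layer is used — the full dynamic program is fast at
these sizes. Externally produced hit tables in the same eight-column
dialect can be ingested in place of the built-in aligner.

Hit filtering per query: rows sort by (E-value, −pident, −qcovs,
accession); the best row per taxid is kept; rows not labelled at species
rank and non-coding-RNA subjects are dropped, letting the next row become
top; if the surviving top row's identity is below 90% the query yields
nothing (a weak best match discards the consensus rather than promoting a
worse one); all rows tied with the top on (E-value, pident) are retained.
"Species level" is the taxonomy rank, not a name-string heuristic; the
ncRNA exclusion targets miscellaneous non-coding annotations — the 12S/16S
barcode loci are themselves rRNA and are never excluded.

## Species calling

A barcode identifies only when both strand consensuses survive
classification; its candidate set is the intersection of the strands'
top-tied taxids (on disjoint strands the union is kept and the call marked
discordant, letting the cross-barcode majority adjudicate — a whole
barcode is never discarded for strand disagreement alone). Numt flagging:
a barcode whose top hit is a nuclear-flagged record is a numt (this
applies to one-strand barcodes too, for reporting); so is an identifying
barcode whose candidates exclude the unique majority species of the other
identifying barcodes (ties → no flagging, conservative). If every barcode
is flagged the sample reports level `none` with diagnostics.

The final single-source call is species-level when exactly one species is
a candidate of every identifying barcode (a strict-majority variant is
configurable); otherwise it is the lowest common ancestor of the pooled
candidates, reported at the LCA's rank (genus, tribe, …). The LCA rule
makes the call monotone: removing a barcode's evidence can only coarsen
the level, never switch a species call to a different species
(property-tested).

Mixture calls are qualitative by design: a species is present iff at
least two barcodes each have both-strand consensuses whose retained hits
include it. Supporting-read totals are reported for transparency but no
proportions are inferred.

## Panel discrimination

K2P distances use pairwise deletion (sites with non-ACGT bases are
skipped per pair) and raise a saturation error when a log argument is
non-positive. Neighbour joining is the standard Saitou–Nei agglomeration
with deterministic tie-breaking (lexicographically smallest label pair at
equal Q); negative branch lengths are clamped to zero for reporting with
the raw value preserved on the node. Bootstrap supports resample
alignment columns with replacement (default 100 replicates), skip and
count saturated replicates, and report the fraction of successful
replicates containing each original bipartition.

A species is *resolved* by a barcode when its sequences form an exclusive
clade — separable from all other sequences by a single positive-length
edge of the unrooted tree. The positive-length requirement means
sequences identical to heterospecifics (zero-length, arbitrary topology)
never count as resolved. A species is *incorrectly placed* when one of
its sequences is strictly nearer a heterospecific than any conspecific.
Resolution is structural; bootstrap values are reported but not gating,
consistent with how such trees are read in practice. Combined rule: a
species is resolved overall iff at least one barcode resolves it and no
barcode places it incorrectly. Species represented by a single sequence
cannot satisfy either definition cleanly; they are scored by distinctness
(resolved iff no heterospecific sits at distance zero) and flagged
`single_sequence`. Species absent from every barcode are data-deficient,
not unresolved.

## The synthetic-data generator

The generator defines the study conditions for all tests. Species barcode
inserts descend from one random ancestor per barcode, each mutated at half
the between-species divergence (default pairwise 0.15 — mid-range for
vertebrate mitochondrial barcodes); intraspecific copies add 0.005.
Substitutions are Jukes–Cantor-style and there is no indel divergence
between species at barcode loci, so discrimination inputs are natively
aligned. Sequencing noise defaults to 3% substitutions, 1% insertions,
1% deletions (~5% combined, nanopore-realistic); qualities are per-base
Normal(18, 4) clipped to [2, 40], chosen so default reads clear Q ≥ 11
with realistic spread. The synthetic taxonomy nests species two-per-genus,
two genera per tribe, two tribes per family, giving the LCA rule real
levels to escalate through. Panel tails and insert lengths are the
published values; the primer sequences themselves are synthetic 22-mers
(flagged as such in the source) since real panels supply primers as
configuration.

Numts: with probability `numt_rate` a species carries a nuclear copy of
one barcode at `numt_divergence` (default 8%) from its mitochondrial
counterpart. Amplification is modelled as binary preferential
amplification: per (sample, barcode) the numt either replaces the
mitochondrial template (probability `numt_amplification_bias`, default
0.5) or is absent. A mixed pool at 8% divergence would merge with the
mitochondrial reads at the 0.80 clustering threshold and yield a chimeric
consensus that corresponds to no documented observation; the binary model
keeps the top-hit flagging rule testable and matches the
co-amplification/preferential-amplification framing of the phenomenon.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: homopolymer-biased and quality-correlated
nanopore errors, chimeric reads and middle adapters, PCR primer bias
between barcodes and species (a known cause of mixture dropout,
particularly for fish), incomplete or mislabelled reference databases,
degraded-DNA length profiles, and carry-over contamination. The
negative-control-derived mixture threshold exists precisely for the last
of these and is exercised only with synthetic support counts.

## Problem sizes and runtime

The bundled analyses use desk-scale sizes: single-source samples of 2,000
reads, mixtures of 5,000, reference sets of 5–20 species, 100-replicate
simulation batches, and 50-case NJ suites. The full test suite runs in
about two minutes and the acceptance script in about two minutes on one
CPU; all randomness flows from single integer seeds and every pipeline
output is byte-reproducible.

## Known limitations

- The star consensus depends on a decent representative; at error rates
  well above ~15% per read, or cluster sizes below ~10, column votes
  thin out and accuracy degrades before the supporting-read floors would
  reject the cluster.
- E-values are rank-only surrogates; do not compare them to BLAST output
  numerically.
- The numt discordance rule needs at least three identifying barcodes to
  form a strict majority; with two barcodes split 1–1 nothing is flagged
  and the call escalates to the LCA instead.
- Mixture calling reports presence only; relative read counts reflect
  amplification dynamics, not input proportions.
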