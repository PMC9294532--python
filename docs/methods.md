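# Methods

This note records what the package computes, the assumptions behind each
step, and the choices made where the underlying methodology was open.

## Data model

A variant is a protein-level nonsynonymous substitution: gene symbol,
1-based residue index, one-letter reference and alternate residues, and an
allele frequency (AF) in the population the record came from.  Synonymous
records (ref = alt) are invalid by construction.  All coordinates are
1-based inclusive everywhere (HGVS / PfamScan convention); domain intervals
include both endpoints.  Exactly one reference sequence per gene symbol is
required, mirroring the single-transcript-per-gene convention of curated
RefSeq matching; duplicate FASTA headers are an error rather than a silent
overwrite.  Ambiguity codes and selenocysteine (X, U, B, Z, J, O, `*`) are
excluded from residue counts with a warning.  Records at the same position
with different alternate residues are kept as distinct variants.

## Exchange spectrum and mutability

The exchange matrix is a 20×20 count of ref→alt substitutions.  The
normalized matrix divides each row by the reference-proteome count of the
row residue and multiplies by 100, so a cell is the percentage of that
residue's reference pool observed substituted to the column residue.  A
frequency-scale view (÷100) is exposed as well, since both axes appear in
published figures of this kind.

Mutability of residue `a` is `n_a / f_a`, where `n_a` is the number of
variants with reference residue `a` (after the common-variant AF filter,
default AF ≥ 10%) and `f_a` is the fraction of `a` among all residues of
the analyzed reference sequences.  The denominator is dimensionally a
fraction, which makes the score a count scaled by enrichment; only the
ranking is interpreted.  The AF comparator (≥ vs >) is a flag because both
conventions appear in practice; the default is inclusive (≥).

## Chemical-class shifts

Two built-in schemes classify residues by side-chain chemistry.  The
12-class scheme is overlapping (Arg is both Basic and Hydrophilic); the
class-conversion matrix therefore increments every (ref-class, alt-class)
cell whose classes contain the respective residues, so one variant
contributes |classes(ref)| × |classes(alt)| counts.  This multi-counting is
recorded in the output metadata; deduplicating per variant would be the
other defensible convention.  The 6-class scheme (Aliphatic, Hydroxyl,
Cyclic, Aromatic, Basic, Acidic) is disjoint; N, Q, C and M belong to no
class and are tallied in explicit unclassified margins — dropping them
silently would break the conservation identity Σdelta = classified(alt) −
classified(ref).  The cluster ordering of the 12-class matrix uses
average-linkage hierarchical clustering on Euclidean row distance and is
emitted as an ordering only.

## Population comparison

For each exchange pair the focal proportion is tested against a comparison
proportion with a one-proportion z-test,
`z = (k/n − p0) / sqrt(p0(1−p0)/n)`, two-sided normal p-value, no
continuity correction.  The default proportion denominator is the cohort's
total variant count; `condition_on_ref=True` conditions on exchanges
leaving the pair's reference residue instead (both readings of "exchange
frequency per pair" are defensible, so the choice is surfaced).  Pairs
absent from both cohorts are not tested; pairs whose comparison proportion
is 0 or 1 are skipped with a reason (the statistic is undefined there).
BH-FDR is applied jointly across the tested pairs of one comparison (not
pooled across comparisons), and significance means adjusted value < alpha
(default 0.05).

**When to use the pooled two-sample option.**  The one-sample form treats
`p0` as fixed, which is appropriate when the comparison cohort is much
larger than the focal one.  When both cohorts are the same size — as in the
package's own simulated studies — the estimated `p0` carries as much
sampling noise as the focal proportion, the statistic's true null variance
is ~2, and the raw rejection rate at nominal 0.05 is ~0.17.  The
`two_sample=True` pooled test is calibrated in that design (measured ~0.05
under null simulation) and is what the analysis drivers and calibration
checks use.  The one-sample default is kept because it matches the method
as usually stated for a fixed reference panel.

UpSet-style exclusive intersections partition the union of the
per-comparison significant sets by exact membership signature; rows are
sorted by size descending with lexicographic tie-break on the member-set
label.

## Domain position

A variant is `within` if its position falls inside any interval of its
gene (distance 0), `pre` if it precedes the first interval (distance to
that start), otherwise `post` with distance to the nearest interval
boundary.  Positions between two domains are classified `post`: the
three-way scheme has no "between" category, and reserving `pre` for
positions before the first domain matches the observed scarcity of
pre-domain variants in kinases (whose N-termini are short relative to the
catalytic domain).  Genes without domain annotation are reported as
`no_domain` and excluded from the three-way totals.

## Structure-dataset cascade and classifiers

The five-filter cascade retains a variant iff: (1) its gene has a crystal
structure; (2) a drug exists against the protein — soft by default, since
the structural set legitimately keeps drug-less genes while the docking set
does not; (3) the variant position is crystallized; (4) structure/sequence
coverage ≥ 70%, with a general exception for variants whose position is
crystallized despite lower coverage (togglable, since the historical
precedent applied it to three specific structures); (5) AF ≥ 10%.  Each
excluded variant carries the first failing filter number, which makes the
cascade idempotent and monotone under relaxation of any single filter.

Threshold classifiers (fixed conventions, boundary behaviour stated
because the sources are silent at the boundary):

* exposure: exposed iff relative solvent accessibility ≥ 5% (boundary →
  exposed);
* stability: destabilizing iff ΔΔG < 0 kcal/mol (0 → non-destabilizing);
  flexibility increased iff vibrational ΔΔS > 0 kcal/mol/K;
* conservation: highly conserved below −1, highly variable above +1 on the
  ConSurf-style relative scale (negative = conserved), else intermediate;
* hydrophobicity: Δ = π(ref) − π(alt) on the Fauchère–Pliska octanol/water
  scale (hard-coded, Gly = 0, Trp = 2.25, Arg = −1.01); positive Δ means
  the mutant is less hydrophobic.  |Δ| ≥ 2 is a significant change; a
  sign-only direction view supports simple tallies;
* hydrogen bonds: Δ = after − before (loss negative);
* binding energy: Δ = E_native − E_mutant in kcal/mol (more negative E =
  stronger binding), so negative Δ means the mutant binds the drug more
  weakly ("decrease");
* DSSP codes pass through verbatim and collapse to helix (H/G/I), strand
  (E/B), loop (everything else).

## Drug similarity

Chemical similarity is the Tanimoto coefficient of binary fingerprints
(|AND| / |OR|); the both-empty case returns 0 with a warning.
Dissimilarity is 1 − similarity.  The package consumes precomputed
bitstrings (166-bit MACCS-style or any uniform length) — bit definitions
are toolkit-specific, so generation is left to the producer.  Phenotypic
similarity is the Pearson correlation of binary drug–target indicator
vectors over a shared gene panel (equal to the phi coefficient; Spearman
behind a flag).  Constant profiles yield NaN, reported as missing rather
than coerced to 0.

## Synthetic-data generator

The generator emulates the statistical structure of multi-population
nsSNV tables, not their biology:

* reference sequences are i.i.d. uniform over the 20 residues by default
  (optionally a user composition), lengths uniform in 300–800 residues
  over 40 genes — enough to make every normalization denominator nontrivial
  and known;
* exchange pairs are drawn from a weight table.  The default puts weight 1
  on all 380 ordered pairs plus elevated weights (4–8) on ~17 exchanges
  frequent in human missense data (R→W, C→Y, L→F, K→E, N→D, A→T, …), so
  common pairs reach expected counts ≥ 20 at the default cohort size of
  5000 and the spectrum is realistically non-uniform;
* spikes multiply a pair's weight in one population before
  renormalization — the planted signal for recovery tests.  Note that
  spiking renormalizes all other pair probabilities downward, so heavy
  spikes on already-heavy pairs perturb the whole spectrum;
* each variant is placed uniformly among proteome positions carrying its
  reference residue, so emitted tables are internally consistent;
* allele frequencies are Beta(0.5, 5) per variant (low-frequency-heavy);
* domains are one or two non-overlapping intervals per protein, placed
  uniformly subject to a 45% per-protein coverage fraction (a kinase
  domain of ~250–300 residues in a ~600-residue protein);
* synthetic structure metadata/annotations draw coverage, accessibility,
  conservation, energy and H-bond values from plausible marginal
  distributions.  They exist to exercise the cascade and classifiers
  end-to-end and carry no biological meaning (files are suffixed
  `_synthetic`).

What the generator does not emulate: nucleotide-level mutation processes
(CpG context, transition/transversion structure), linkage between sites,
codon-degeneracy effects on exchange accessibility, realistic residue
composition, or correlations between AF and exchange type.  Passing tests
therefore demonstrate correctness of the computations and calibration of
the statistics under known conditions — not that real cohorts would show
any particular spectrum.

## Problem sizes and numerical choices

The package's own studies use 5000 variants per population over 12–40
genes; null calibration uses 100–200 replicate cohort pairs and
spike-recovery 50 seeds, sizes at which the binomial noise on a 5%
rejection rate is a fraction of the acceptance band.  All randomness flows
through `numpy.random.default_rng` from a single integer seed; identical
seeds give byte-identical output files.  BH adjustment delegates to
statsmodels (`fdr_bh`), the normal tail to scipy; both are cross-checked in
the test suite against independently coded oracles (hand-coded step-up,
`erfc`-based tail).  Ties and boundaries: matrix residue order is fixed
alphabetical one-letter; intersection rows tie-break lexicographically;
classifier boundaries are stated above.

## Known limitations

* The structural and docking measurements are inputs, not computations:
  the package classifies third-party tool exports and cannot validate
  them.
* The one-sample z-test default is anti-conservative whenever the
  comparison cohort is not much larger than the focal cohort (see above);
  users comparing equal-size cohorts should pass `two_sample=True`.
* The 12-class conversion matrix multi-counts by design; its totals are
  not variant counts.
* Mutability and normalized-exchange values depend on the gene set used
  for the reference composition; comparing scores across different gene
  universes is not meaningful.
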