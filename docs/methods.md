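# Methods

## The screen model

A fold screen compares, for each RNA fold, a fold-bait pull-down against a
generic control bait in differentially SILAC-labeled yeast extract, repeated
with the labels exchanged (forward and reverse experiments). The package
consumes MaxQuant-style `proteinGroups` tables — protein id, normalized H/L
ratio, ratio count, contaminant and decoy flags — and performs all analysis
downstream of the database search. Search-engine internals, peptide-level
quantification and ratio normalization are out of scope; ratios are trusted
as given.

Orientation is the load-bearing convention: every stored log2 ratio means
"fold bait over control bait", so the reverse experiment's raw ratio is
negated at parse time. This makes the two filters symmetric in their inputs:

* **stringent** — called iff `fwd > c` and `rev > c` with `c = 1` (strict
  inequalities; `c = 1` is exactly a two-fold enrichment). Proteins
  quantified in only one orientation are never called and are reported
  separately rather than imputed: the filter's definition demands both
  experiments.
* **flexible** — called iff `fwd > 0`, `rev > 0` and
  `hypot(fwd, rev) > hypot(puf3_fwd, puf3_rev)`, where the Puf3 anchor point
  is taken from the same experiment pair. The quadrant condition is required
  because distance is unsigned; without it a strongly control-side protein
  would pass. The Puf3 anchor is per experiment; a global override can be
  passed by the caller.

The per-call enrichment value is `log2 sqrt(fwd² + rev²)`, undefined (NaN)
at the origin.

Ratio-count ≥ 2, contaminant and decoy filters are applied before pairing.
Row-level parse failures drop the row and are counted in a warning rather
than aborting a whole table.

## Structure scoring

Per-region DMS reactivity vectors from three conditions are processed in the
order: normalize each condition to its most reactive base (max → 1), then
subtract the normalized denatured signal from the in vivo and in vitro
signals, clipping negative residuals at zero (reactivities are non-negative
by meaning). An all-zero region is flagged "unreactive" and passed through
unchanged.

The Gini coefficient uses the population mean-absolute-difference form
`G = Σᵢⱼ|xᵢ−xⱼ| / (2 n² x̄)`, computed via the O(n log n) sorted identity and
verified in tests against the double-loop definition to 1e-12. Bounds are
[0, (n−1)/n]; a constant vector scores 0; a zero-mean vector is undefined
(NaN). No small-sample correction is applied. Whether Gini is taken on the
raw-normalized or the denatured-subtracted signal is a flag
(`score_profile(..., subtract=...)`); both are meaningful, and subtraction
can zero out a region entirely (then NaN).

In vivo / in vitro agreement is a Spearman correlation with average ranks;
constant vectors yield NaN rather than an arbitrary value.

The background comparison samples `n_random` regions (default 200, split
evenly over intergenic/5′UTR/3′UTR/CDS, i.e. 50 per category) of fixed
length equal to the fold set's mean length, computes their Gini from a
supplied per-base signal track, and reports a two-sided Mann–Whitney
rank-sum p between fold and background Gini distributions.

## Interactome analytics

The call matrix is binary with enrichment values kept alongside; conflicting
duplicate calls are an error, not a silent overwrite. Venn categories are
the non-empty subsets of {5′UTR, CDS, 3′UTR} covered by an interactor's
bound folds and partition the interactor set; proteins with zero calls are
excluded with a warning. Promiscuity classes use counts: selective ≤ 1
fold, promiscuous ≥ 20, intermediate otherwise (both bounds configurable).
Region classes come from maximal base overlap with the transcript
annotation; exact ties break by the fixed precedence CDS > 5′UTR > 3′UTR,
or emit MIXED when `allow_mixed=True` — the default gives every fold exactly
one class.

The motif scanner reports all exact canonical UGUAAAUA occurrences and, of
the "similar" variants (default: the contiguous sub-words UGUAAAU, GUAAAUA,
UGUAAA, GUAAAU — truncations only, no mismatches), only occurrences that do
not overlap a canonical hit. It is tested for equality with a naive
sliding-window search.

## Feature analysis

Property comparisons are two-sided Welch t-tests of the interactor set
against the measured-proteome and predicted-proteome backgrounds, with
Benjamini–Hochberg q-values computed jointly over all (property, background)
tests of a run. Groups with < 3 finite values or zero pooled variance are
reported as missing. Annotation enrichment is a two-sided Fisher exact test;
the reported odds ratio is the sample cross-product `ad/bc` with a Haldane
0.5 correction on any zero cell (the choice is stated here because
conditional-MLE conventions differ). Disorder content is the fraction of
residues with predicted disorder probability strictly above 0.5. The tiered
classification checks, in order: any molecular-function GO term containing
the case-insensitive substring "RNA binding" (or a curated Pfam RNA-binding
domain), a curated RNA-related GO list, the same two criteria on the human
ortholog, else unknown; the curated lists are data inputs, not hard-coded.

## Genetic networks

Pair annotation keeps RBP–mRNA pairs with |ε| strictly above 0.08, signed.
Profile correlations are pairwise-complete Pearson coefficients over each
gene's ε row; pairs with fewer than `min_overlap = 3` shared observed
positions, or a constant shared profile, are missing rather than zero-filled.
Edges require PCC strictly above 0.2. Communities come from asynchronous
label propagation: unique initial labels, a seeded random vertex order per
sweep, majority-vote adoption with uniform random tie-breaks from the same
generator, termination when every vertex holds a neighborhood-majority label
(isolates keep their own) or after `max_iter` sweeps (flagged
non-converged). Labels are renumbered to consecutive integers over the
sorted vertex list, making results bitwise reproducible for a fixed
(graph, seed). Because initial labels are unique and only travel along
edges, communities can never span disconnected components. The
implementation is cross-checked in tests against networkx's independent
asynchronous label-propagation routine on well-separated graphs.

## Validation quantification

Percent input handles the input dilution on the Ct scale: a fraction *f* of
the material corresponds to `log2(1/f)` extra cycles, so
`%input = 100 · 2^(ct_input − log2(1/f) − ct_ip)`; the quantity is invariant
to a common Ct shift. +RT signal is divided by −RT signal; a zero −RT value
is an error directing the caller to set an explicit detection-limit floor
rather than a silent pseudo-count. SEMs combine in quadrature. GFP reporter
ratios divide each knock-out replicate by the wild-type replicate mean;
significance across constructs is a one-way ANOVA with per-construct
one-sample t-tests against a flat ratio of 1.

Pulsed-SILAC upregulation uses the Tukey boxplot convention: values strictly
above Q3 + 1.5·IQR (linear-interpolation quartiles) are flagged. For a
standard normal distribution this one-sided fence captures ≈0.35% of
observations, which is what the simulation test asserts.

## The synthetic-data generators

All generators are pure functions of their configuration and seed.

* **Screen** (`SimConfig` defaults: 200 proteins, 20 folds, 5 planted
  binders per fold, oriented log2 effect 2.0, background SD 0.3, 10%
  per-entry dropout, Puf3-like control at −2.0): planted binders draw their
  oriented ratio independently per orientation from N(effect, SD), the
  background from N(0, SD), and the control binder from N(−effect_ctrl, SD)
  in every experiment. Tables are written in MaxQuant shape with linear
  ratios (the reverse table inverted) plus contaminant/decoy/low-count decoy
  rows so the parser's filters are exercised. Effects are planted
  independently in the two orientations to exercise label-swap symmetry.
  Recovery metrics define sensitivity over planted pairs quantified in both
  orientations: the caller never calls single-orientation proteins by
  contract, so dropout is an ascertainment limit, not a caller error, and is
  reported separately.
* **DMS**: structured regions put ~20% of bases (loops) at reactivity
  0.5–1.0 and the rest near zero; unstructured regions draw a shared latent
  0.3–0.7 per base; in vivo and in vitro multiply the same latent by
  independent ±10% noise; denatured is uniformly high (0.8–1.2). This
  reproduces the qualitative signatures the scoring targets — high Gini and
  high vivo/vitro correlation for structured regions — but not read-count
  noise, coverage gaps or A/C-only reactivity of real DMS data, so passing
  tests demonstrate the scoring logic, not performance on real tracks.
* **GI**: genes in a planted block share a latent N(0,1) profile over all
  genes plus N(0, noise) — within-block profile correlations ≈
  1/(1+noise²), between-block ≈ 0 within sampling error of the profile
  length. End-to-end block recovery is demonstrated at 3 blocks of 30 genes
  (90-position profiles); shorter profiles make the null PCC spread
  (≈1/√n) cross the 0.2 edge threshold often enough to blur the blocks,
  which is a property of the thresholded-PCC construction itself.
* **Transcripts**: 5′UTR/CDS/3′UTR regions of realistic yeast-like lengths
  (50–150 / 300–900 / 100–250 nt) from a uniform base model, each region
  planting one canonical motif with the configured probability at a recorded
  offset.

## Problem sizes and numerical choices

The test suite and the acceptance script run the screen recovery at 20
seeds × the default configuration, the Gini oracle at 1000 random vectors,
primer-design oracle equivalence at 200 templates, the motif oracle at 500
sequences, and community recovery on a 60-vertex planted partition with 50
propagation seeds — sizes chosen so each statistical check is stable across
seeds while the whole suite runs in well under a minute. Strict inequalities
are used at every printed cutoff (log2 ratio > 1, |ε| > 0.08, PCC > 0.2,
disorder > 0.5, Tm > 58). Degenerate inputs (constant vectors, zero means,
all-zero profiles, origin points) return NaN or warn rather than raising,
except where the contract is unsatisfiable (empty inputs, unreachable Tm,
zero −RT signal).

## Known limitations

The published screen's headline counts (162 interactors of 186 folds, the
positional class sizes, the specific Fisher odds ratios) depend on the raw
mass-spectrometry data and external annotation resources and are therefore
covered structurally — the operations that produce such numbers are
implemented and tested on planted-truth inputs — not numerically. The
flexible filter's Puf3 anchor is per-experiment; a study-wide constant can
be supplied but is not the default. ΔΔCt reference-gene arrangements beyond
the input-dilution correction are left to the caller via the generic
functions.
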