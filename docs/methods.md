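# Methods

## Data model

The pipeline operates on a rectangular alignment of DNA sequences (IUPAC
codes plus `-`) keyed by specimen id, and a specimen table with collection,
region and host-category labels (`C_Host` for corn/sorghum/cotton sites,
`R_Host` for pasture-grass/millet/alfalfa sites).  All statistics use
*complete deletion*: any column containing a gap or ambiguity code in any
sequence of the sample under analysis is removed first, so S, π, D, F* and
the distance matrix always refer to the same site set.  Pairwise deletion is
available for distances only.

## Strain markers

Two diagnostic SNPs type the specimens: mCOI1164D (mitochondrial *COI*;
A or G → C_COI, T → R_COI, anything else unknown) and gTpi183Y (*Tpi* exon
4; C/T polymorphism).  *Tpi* is Z-linked, so ZZ males can be heterozygous;
direct sequencing of a heterozygote yields the IUPAC code `Y`, which calls
as *ambiguous* and — under the default `exclude` policy — removes the
specimen from every downstream computation.  Which of C/T denotes the
C-strain at gTpi183Y is not fixed by the marker's name alone; the default
map (C → C_Tpi, T → R_Tpi) follows the naming convention and is a config
option (`tpi_c_allele`), not a hidden assumption.  Marker positions are
given as 1-based aligned-column coordinates (gap columns count), because
locus names do not determine alignment offsets.

## Distances and trees

Distance models: p-distance; JC69, d = −(3/4)·ln(1 − 4p/3); K2P,
d = −(1/2)·ln(1 − 2P − Q) − (1/4)·ln(1 − 2Q) with transition/transversion
proportions P, Q; and `MCL`, a Tamura–Nei-form distance in which the base
frequencies are pooled over the whole sample (the composite-likelihood idea
of estimating shared substitution parameters jointly) while each pair
contributes its own purine-transition, pyrimidine-transition and
transversion proportions.  Saturation (a non-positive logarithm argument)
raises an error naming the pair rather than returning infinity.

Neighbor-Joining follows Saitou–Nei with the Q-criterion.  Two conventions
make trees bit-reproducible: ties in Q are resolved to the first (i, j) pair
in node-creation order, and a negative branch length is clamped to zero with
the deficit moved to its sister edge (preserving the path length through the
new node).  On additive matrices the output path-length matrix reproduces
the input to 1e-9 (tested).  Bootstrap support of an internal edge is the
percentage of column-resampled replicate trees containing the same
bipartition of the point-estimate tree (supports of the point tree, not a
consensus tree).  Rooting is midpoint by default; outgroup rooting places
the root mid-edge on the bipartition separating the outgroup and requires
the outgroup to be monophyletic in the unrooted tree.

## Clan delimitation

The two host-strain clusters are delimited on the rooted tree as the
largest clade whose C_Tpi frequency reaches `purity_threshold` (default
0.95; ties broken by higher purity, then lowest leftmost leaf id); the
complement is ClanR.  The purity achieved is reported so a user can judge
the call.  Note the size-first rule deliberately tolerates discordant leaves
nested inside an otherwise pure clade; with a clan-fixed marker, a sister
R_Tpi leaf is absorbed whenever its inclusion keeps purity above threshold.
Raising the threshold (e.g. to 0.98) makes the partition stricter and, on
the default synthetic data, recovers the planted partition exactly.

## Population statistics

For n sequences over L used sites: S segregating sites (multi-allelic sites
count once), singleton sites η_s (rarest allele in exactly one sequence —
orientation is unknowable without an outgroup), mean pairwise differences
k̄ (any mismatch counts 1), π = k̄/L, and Nei's sample-corrected haplotype
diversity Hd = n/(n−1)(1 − Σp_h²), with haplotypes grouped on the
deletion-filtered sequences for consistency with the site statistics.

Tajima's D = (k̄ − S/a₁)/√(e₁S + e₂S(S−1)) with the standard constant set.
Fu & Li's F* (no outgroup) = (k̄ − η_s(n−1)/n)/√(u_F\*S + v_F\*S²).  The
variance constants as first printed contain a known misprint; the default
`corrected` variant uses the widely adopted corrected u_F* (the convention
of standard sequence-analysis software), and the `original` variant is kept
for cross-checking — the two differ substantially (u_F* 1.07 vs 0.20 at
n = 4).  A Monte-Carlo null check (neutral coalescent, n = 20, θ = 5,
3000 replicates) gave mean ≈ −0.09 and variance ≈ 0.85 for the corrected
form, against variance ≈ 1.05 for the original.  Both statistics report
`undefined_S0` (value NaN) on monomorphic samples, and such values are
excluded from aggregates.

F_ST uses the Hudson/Slatkin/Maddison sequence form 1 − H_w/H_b, where H_w
is the unweighted average of the two within-population mean pairwise
difference counts and H_b the mean over between-population pairs.  It can be
slightly negative in finite samples (reported raw) and is defined as 0, with
a degeneracy flag, when H_b = 0.  A per-site Weir–Cockerham variant was
considered and not included: the sequence form is the one whose
within/between contrast the comparisons consume, and the report names the
estimator used.

Group comparisons: two-tailed pooled-variance t-tests (df = n_A + n_B − 2);
Pearson chi-square (no continuity correction) on the 2×K table of
trait-positive *counts* per collection, df = K − 1 — built from counts, not
percentages, which is the standard construction even though percent-based
inputs would produce the same df; ordinary one-way ANOVA with
r² = SS_between/SS_total and a Tukey HSD post-test summarised as compact
letters at α = 0.05 (groups sharing a letter are not significantly
different).  For two groups, ANOVA F equals t² of the pooled t-test
(tested to 1e-9).

## Synthetic data generator

The generator produces the statistical structure the analysis assumes, with
all randomness from one seed:

* **Sampling design.** Four collections (FLT, FLL, BrL, ArL) with per-clan
  cell sizes (33, 19), (5, 4), (4, 4), (5, 4) — roughly a ten-fold
  scale-down of the sequencing effort behind the original collections,
  adjusted so every clan×region cell has ≥ 4 sequences and the neutrality
  statistics are defined per cell.  These sizes keep the default test suite
  and the acceptance script fast while preserving the contrast structure.
* **Between-clan divergence.** The two clan ancestors differ at 6 fixed
  columns plus the diagnostic *Tpi* column (ClanC ancestor carries C, ClanR
  T).  These columns are excluded from mutation placement so the divergence
  and the marker stay fixed.
* **Within-clan genealogies.** Sequences evolve on Kingman coalescent
  genealogies (waiting times Exp with rate C(k,2)); mutations fall on
  branches as a Poisson process at θ/2 per lineage per coalescent time unit
  and hit distinct uniformly chosen columns (infinite sites on a finite
  locus, re-drawing on collision — keeps E[S] = θ·a₁ exact for the constant
  mode at the cost of no recurrent mutation).  ClanC uses θ_C = 0.8 with a
  *structured* genealogy: the sample splits into two sub-lineages whose
  MRCAs merge 1.5 (+Exp(0.375) jitter) coalescent units deeper than the
  later of the two, enriching intermediate-frequency variants and pushing
  D and F* positive.  ClanR uses θ_R = 8.0 with an *exponential-growth*
  genealogy: the cumulative standard time T maps to t = ln(1 + βT)/β
  (β = 20), compressing deep coalescences into a star-like shape with a
  singleton excess and negative D and F*.  Growth genealogies are then
  rescaled so the mean pairwise coalescence time is 1 — the E[k̄] = θ
  convention — because without the rescale strong growth shrinks the whole
  genealogy and a large θ would paradoxically yield *less* diversity,
  inverting the intended π contrast between the clans.  With these choices
  the generator delivers, across replicates: mean D and F* positive in
  ClanC and negative in ClanR, π(ClanR) > π(ClanC) in ~100% of replicates
  (mean ratio ≈ 4), and between-clan F_ST above the within-clan values in
  every replicate.
* **Marker and label noise.** Each specimen's mitochondrial haplogroup
  matches its clan with probability 0.85 (the mitochondrial marker is
  informative but imperfect); host category is C_Host with probability 0.97
  given ClanC and 0.33 given ClanR (the observed discordance rates of field
  collections); the *Tpi* diagnostic allele is clan-fixed by default, with
  an optional leakage probability.  The mitochondrial marker is a binary
  haplogroup label unless a two-haplotype *COI* alignment is requested
  (`emit_coi_sequences`), in which case the diagnostic base (A vs T) sits
  at a configurable column.

**What passing tests do and do not show.**  The generator reproduces the
contrast structure of real two-strain collections — diversity asymmetry,
site-frequency-spectrum asymmetry, fixed marker linkage, noisy host labels —
but not recombination, migration beyond the two-clan split, selection,
recurrent mutation, sequencing error, or alignment uncertainty.  Passing the
recovery suites demonstrates that the pipeline's inference chain is correct
and calibrated under its own assumptions, not that those assumptions hold
for any particular field dataset.

## Numerical and degenerate-input conventions

* Haplotype ids are deterministic: descending count, then first appearance.
* Percentages in summaries are reported rounded to integers (presentation
  parity); the unrounded fractions are retained alongside.
* Zero pooled variance in the t-test: t = 0 (p = 1) for equal means, ±inf
  (p = 0) otherwise.  All-identical ANOVA input is flagged degenerate.
* Chi-square: collections with no positives for either trait are dropped;
  a trait with zero positives everywhere leaves the test undefined (NaN)
  with a low-expected-count warning.
* The pipeline builds the tree on one representative per haplotype (the
  first-seen member), which keeps the bootstrap affordable and mirrors
  haplotype-level tree building; clan labels propagate from representatives
  to all haplotype members.
* All exclusions are accounted in the run manifest (in = out + excluded at
  every stage), and a fixed seed makes the whole report bundle
  byte-reproducible.

## Known limitations

* The MCL distance is a Tamura–Nei composite with pooled base frequencies,
  not a re-implementation of any particular desktop package's iteration;
  JC69/K2P/p are provided so conclusions need not hinge on its internals.
* Maximum-Likelihood tree search is out of scope; NJ covers clan
  delimitation, and robustness across distance models stands in for
  robustness across reconstruction methods.
* No coalescent-based significance intervals for D/F*; the statistics are
  reported with their undefined/degenerate status only.
* `classify_new_sequence` is a nearest-haplotype rule with an explicit
  unresolved outcome on ties; it is not a probabilistic or admixture-aware
  assignment.
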