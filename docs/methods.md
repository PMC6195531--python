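# Methods

## Data model

The unit of analysis is a *comparing dataset*: N homologous CDS pairs, one
extremophile member and one counterpart member per pair. Every CDS is
cleaned (whitespace removed, uppercased, U→T), framed from its first base,
and chunked into codons; 1–2 trailing bases are dropped with a warning and
codons containing non-ACGT characters are excluded from both numerator and
denominator by default (a strict mode rejects the record instead — the
default avoids fabricating fractional counts). Each CDS becomes a vector of
64 codon percentages in a fixed alphabetical order (AAA … TTT), giving two
N × 64 matrices per dataset.

Stop codons are ordinary features. Reported significant-codon lists and
harmony analyses in this field include stop codons, so the percentage
denominator counts all valid codons, stops included. Whether published
percentage tables include stops in the denominator is usually unstated; the
choice here is recorded, not inferred.

## Significance screen

Per codon, the N extremophile percentages are tested against the N
counterpart percentages with the two-sided two-sample Kolmogorov–Smirnov
test; codons with p < 0.05 form the significant set. Choices:

* **Asymptotic p-values by default** (`method="exact"` is available and
  sensible for N ≤ 25). The statistic D is the exact ECDF supremum either
  way and is verified in the tests against a brute-force double-loop oracle.
* **The samples are treated as unpaired** even though data arrive as pairs:
  KS is a two-sample test and no paired variant is defined for it.
* **No multiple-testing correction by default** — the raw per-codon
  p < 0.05 screen is the field's convention; Benjamini–Hochberg is
  available behind `bh_correct=True`.
* Codons constant and equal in both samples get (D, p) = (0, 1), not an
  error. `alpha >= 1` disables the filter (all 64 codons flagged).

**Calibration caveat.** Under the zero-bias synthetic generator the
fraction of codons flagged at α = 0.05 is **well below** 0.05 — about
0.005 at 300-codon genes and 0.02 at 10,000-codon genes (N = 100 pairs).
Two causes, both verified by control experiments: (i) codon percentages
are count-derived and heavily tied, and the KS null distribution assumes
continuity, making the test conservative on discrete data; (ii) homologous
pair members share their amino-acid sequence, so per-gene amino-acid
counts induce positive correlation between the two samples (≈ 0.24 for a
4-fold family at uniform amino-acid usage), shrinking ECDF differences
below the independent-samples null. The screen is therefore conservative —
it under-flags, never over-flags — and a two-sided calibration band around
the nominal level is not attainable for this data type. Power for real
effects remains high (see the recovery results below).

## Relative abundance

Per significant codon, class means are plain arithmetic means over the N
pairs (the printed formulas are Σ/N, whatever the surrounding prose calls
them), and

    beta_rel = (mean_e − mean_ne) / alpha_max .

`alpha_max` is, by default, the maximum **absolute** mean difference over
the significant set, which bounds beta_rel in [−1, 1] and preserves its
sign. A literal signed maximum (available via `alpha_max_mode="signed"`)
leaves beta_rel unbounded below whenever the largest difference is positive
while others are negative; the absolute convention is the interpretable
one and is the default. If every difference is zero, beta_rel is defined
as 0 with a warning. Codons with beta_rel > 0 strictly are the "positive
contributors" used by the composition and harmony stages.

## 1–9 ranking

Ratio weights ξ = mean_e / mean_ne are scaled by

    W = ((ξ − min ξ) / (max ξ − min ξ)) × 8 + 1 ,

so the largest ratio always receives W = 9 and the smallest W = 1. Integer
ranks are round-half-up of W (figures in this field show discrete 1–9
ranks while the scale itself is continuous). A zero denominator gets a
pseudocount of half the smallest nonzero mean percentage in the table and
is flagged; if every ξ is equal the scale is degenerate and all ranks are
set to 5 with a warning. Ties for the extreme codons are broken
lexicographically so results are deterministic.

## Composition and harmony

A codon is AT-rich iff at least two of its three bases are A or T (32 of
the 64 codons; the complement is GC-rich), and A/T-ending by its wobble
base alone. Composition summaries are percentages over the positive-
contributor set of one dataset. The harmony table crosses those sets over
the six extremophile classes (thermophile, psychrophile, acidophile,
alkaliphile, halophile, barophile — unknown labels are an error);
membership is abundance-positivity per class, with no additional rank
requirement (the rank analysis orders the same codons and adds no further
membership information).

## Machine learning

The feature table pools both classes: one row per CDS, one percentage
column per significant codon, plus the pair id as a group marker.

**Pair-grouped splitting.** Train/test splits keep both members of a
homologous pair on the same side (group shuffle split on pair id, 70/30 by
default, explicit seed). This matters: pooled paired rows contain
homologous twins with opposite labels and near-identical amino-acid
composition, and with row-level splits a test row's twin votes against the
true label from inside the training set — measured here as zero-bias k-NN
accuracy of ~44%, systematically below chance. Pair-grouped splits restore
null accuracy to ~50% and are exactly class-balanced by construction
(each pair contributes one row per class). Row-stratified splitting
remains the fallback for tables without group information.

**Attribute weighting.** Seven algorithms: chi-squared statistic,
information gain, gain ratio, Gini index, absolute Pearson correlation,
symmetric uncertainty, and classic relief (all-instance, single nearest
hit/miss, distances on min-max-scaled features so weights are invariant
under affine rescaling of a column). Continuous features are discretized
into 5 equal-frequency bins for the contingency-based measures. Weights
are min-max normalized to [0, 1] per algorithm; constant features are
pinned to 0 (they carry no information, and relief's negative scores for
noise features would otherwise shift the minimum). The support count of a
codon is the number of algorithms weighting it ≥ 0.5. Additional weighters
can be plugged in as `f(x, y) -> float`.

**Classifiers.** k-NN (k = 10 default), Gaussian naive Bayes, logistic
regression, decision tree, random forest, plus optional SVC and MLP
backends. Tree criterion names accepted on the surface — infogain,
gainratio, gini, accuracy — map onto the backend's impurity measures
(entropy, entropy, gini, gini respectively); scikit-learn implements no
gain-ratio or accuracy-based split criterion. The decision-tree default is
`max_depth=5`: the tree's deliverable is a short printed discrimination
rule (published rules in this field have 1–4 conditions), and unlimited
depth overfits noisy percentage features. Accuracy is always reported on
held-out rows, in percent.

**Rule extraction.** A fitted tree is unrolled into one root-to-leaf rule
per leaf, conditions as (codon, ≤/>, threshold-%) with half-open
semantics, rendered as `If % CAA (≤1.866] and % AGG (>1.441] → Label`.
In the pipeline the rule tree is refit on all rows — the split serves
accuracy estimation, and the final interpretable model uses all data.
A single-leaf tree yields an empty rule list with a warning.

## Synthetic generator

The generator emulates homologous pairs in the operative sense: both
members of a pair encode the same amino-acid sequence (sampled uniformly
over the 20 amino acids by default), and each class encodes each position
independently from its own per-family synonymous-codon distribution
(uniform within each family by default). Biases shift a chosen within-
family probability mass toward or away from a target codon, renormalizing
the rest of the family proportionally; a shift that would leave the
simplex is an error, never a silent clip. One stop codon (uniform over the
three stops) is appended by default, mirroring full-length CDS. The seed
fully determines the output, and the expected percentage of every codon is
available in closed form: `100 · p_aa(aa) · p_class(codon | family) ·
L/(L+1)` for sense codons at gene length L with an appended stop.

Defaults mirror the package's study conditions: 100 pairs of 300-codon
genes; the canonical strong-bias condition is AGG +0.3 / CAA −0.3
within-family mass (thermophile-like); single-codon-shift experiments use
GCG +0.3 — a 4-fold family keeps one dominant shifted codon, whereas
shifting a 2-fold codon (e.g. GAC) necessarily shifts its partner (GAT)
equally and makes "the" informative codon ill-defined.

What the generator does **not** emulate: dinucleotide autocorrelation,
amino-acid divergence between pair members, genome-scale GC gradients,
length variation, and phylogenetic structure. Passing tests therefore
demonstrate correctness of the statistics and recovery of within-family
synonymous shifts, not performance on real genomes.

## Measured behaviour at the default study conditions

All of the following are computed by the test suite / acceptance script,
not asserted from the literature:

* Bias recovery (AGG +0.3 / CAA −0.3, N = 100, L = 300): AGG and CAA both
  significant and ranked (9, 1) in 20/20 seeded runs.
* Classification (200 CDS/class): k-NN (k = 10) ≈ 96% and information-gain
  tree ≈ 93% mean held-out accuracy over 10 replicate seeds; ≈ 48–49%
  (chance) on zero-bias data. Stochastic accuracy claims are evaluated as
  means over 10 replicates because a single 120-row held-out split carries
  ~2.5% binomial noise.
* Rule extraction (GCG +0.3): the root rule names GCG in 10/10 replicates
  with mean threshold within 0.1% (absolute percentage points) of the
  generative midpoint.

## Known limitations

* The KS screen's nominal level is conservative for this data type (see
  above); reported significant sets err on the small side.
* Gain-ratio/accuracy tree criteria are impurity-mapped, not reimplemented.
* The chi-squared weighter's 5-bin equal-frequency discretization is a
  convention; original attribute-weighting toolchains do not document
  theirs.
* Percentages are used as produced per CDS; no additional normalization is
  applied before testing.
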