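# Methods

This note documents the models, defaults and numerical choices behind
`misig`, what the synthetic generators do and do not emulate, and the known
limitations of the estimators.

## Pairwise ANI/AF model

Genomes are compared as sets of protein-coding nucleotide genes; rRNA/tRNA
records (tagged `[class=...]` in the FASTA header) must be filtered out
first so conserved structural RNAs cannot inflate either index.

**Alignment.** Gene pairs are aligned locally with affine gaps
(Smith–Waterman/Gotoh). Default scoring: match +1, mismatch −1, gap open −5,
gap extend −2, with a gap of length L costing `5 + 2(L−1)`. Both
orientations of the target gene are tried (gene callers emit either strand)
and the better-scoring one kept. IUPAC ambiguity codes never match anything,
including themselves — a conservative identity convention. Because several
alignments can share the optimal score while differing in identity, the
aligner optimises a *lexicographic* objective — maximal score, then maximal
matches, then fewest alignment columns — packed into a single 64-bit integer
DP (weights `K₁·score + K₂·matches − columns` with `K₂` larger than any
column count and `K₁` larger than the secondary range). Reported identity
(matches / alignment columns, gaps counting as non-matches) is therefore
canonical and deterministic, which the test suite verifies against a
pure-Python tuple DP and, for scores, against Biopython's `PairwiseAligner`.

**Hit qualification and BBHs.** A hit qualifies with identity ≥ 0.70 and
aligned fraction of the shorter gene ≥ 0.70 (`identity_threshold`,
`coverage_threshold`). Per query gene the best qualifying hit is kept
(score, then identity, then alignment length, then lexicographically
smaller target id); BBHs are reciprocal best hits. An optional k-mer
prescreen (`prescreen_k`, default off; the pipeline uses k = 12) skips gene
pairs sharing no k-mer in the tested orientation. At the 70% identity floor
a shared 12-mer exists with overwhelming probability for genes of a few
hundred nt, and a dedicated test asserts prescreen and exhaustive paths
agree; the prescreen stays off by default so brute-force comparisons are
exact by construction.

**Scores.** ANI is the length-weighted mean BBH identity
(`Σ id·L / Σ L`, weights = alignment columns); an unweighted mean is
available via `ani_weighting` since the averaging convention is a known
point of variation between ANI tools. Directional AF divides the summed
length of a genome's BBH genes by its total protein-coding length; AF's
denominator includes genes that individually failed the 70/70 filter. With
fewer than `min_bbh` BBHs (default 5) the ANI fields are undefined rather
than a noisy average over a handful of genes; AF is still reported. In this
implementation the two directional ANI values are identical by construction
(the same canonical alignment serves both directions); directional AF
values differ whenever gene content does.

## Boundary, classification, rank-sum test

The boundary takes per-axis maxima over type-species scores (averaged AF
and ANI), so different species may set the two axes; a `joint` flag records
when one species sets both. Equality classifies as `at_or_below` (the
boundary-setting species itself is therefore at-or-below), strict
exceedance in both axes as `within_genus`, and the two mixed quadrants as an
explicit `borderline` zone rather than being forced into either side.
Scores with undefined ANI contribute their AF to the AF boundary but cannot
be classified.

The Wilcoxon rank-sum (Mann–Whitney U) test is exact — a count recursion
over the tie-free U null distribution, verified against full permutation
enumeration — when n₁+n₂ ≤ 20 and no value is shared across groups, and a
tie-corrected normal approximation with continuity correction otherwise.
Two-sided p sums both tails at least as extreme as the observed U. No
multiple-testing correction is applied across genera; per-genus p-values
are reported unadjusted.

## Inflection estimation

The quartic is fit by OLS in numpy's scaled-domain polynomial basis (exact
recovery of noiseless quartic data to ~1e−8 is tested) with the anchor
(1, 100) appended exactly once; R² is computed on the fitted point set and
clamped at 0. The second derivative's smaller real root inside the observed
AF range is the genus inflection point; its ANI is the quartic evaluated at
the root. Sigmoid cross-checks fit `y0 + A·exp(−B·exp(−C·AF))` (Gompertz)
and `y0 + A/(1+exp(−K(AF−x0)))` (logistic) by damped least squares from six
deterministic quantile-derived starts; Gompertz fits with non-positive B or
C are discarded (their inflection `ln B / C` is undefined). An estimate is
`accepted` when quartic R² ≥ `r2_min` (default 0.90) *and* both sigmoid
closed-form inflections agree with the quartic estimate within
`agreement_tol_af` = 0.05 and `agreement_tol_ani` = 1.0.

CIs are nonparametric percentile bootstrap (default `n_boot` = 1000; the
acceptance suite uses 200): non-anchor points are resampled with
replacement, the anchor is always retained, the quartic is re-fit and its
first root re-extracted; resamples without a real in-range root are dropped,
and CIs are reported only when at least half the resamples succeed. The 99%
interval nests the 95% one by construction. Identical seeds give identical
CIs.

**Known limitation — ANI at the inflection.** ANI being modelled as a
function of AF, the AF coordinate of the inflection is recovered almost
without bias (synthetic scatters: bias ~0.001, sd ~0.005). The ANI
coordinate, however, inherits a model-mismatch bias whenever the true trend
is a sigmoid: a quartic cannot follow an asymmetric knee exactly, and its
value at the inflection root sits ~+0.5 ANI above a Gompertz truth (and
~−3 below a logistic truth) even for dense noiseless data, independent of
steepness and sampling. Treat the inflection's ANI as indicative and its AF
as the quantitative output. Relatedly, Gompertz and logistic closed-form
inflection ANIs differ systematically by `(1/2 − 1/e)·A` of the fitted
amplitude, so for scatters spanning tens of ANI points the ±1.0 ANI
agreement gate rarely passes and `accepted` is typically driven to false by
the logistic term; widen `agreement_tol_ani` to compare families on AF
location alone.

## Cohort statistics

Mean, median, linear-interpolation quartiles (the common spreadsheet
convention — documented so comparisons against other tabulations can
diagnose convention mismatches) and a Student-t 95% CI of the mean
(undefined at n = 1). Only accepted inflection estimates are aggregated.

## Synthetic generators

`make_reference_genome` draws i.i.d. genes at a given GC; `evolve_genome`
applies Jukes–Cantor-like substitutions (uniform over the three alternative
bases, no transition bias), drops genes to a retention fraction, and
appends novel random genes, so expected ANI is `100(1−p)` and expected
directional AF is the retained length fraction. Indels default off because
the alignment oracles assume gap-free truth; an indel mode exists for
stress tests. `make_genus_scatter` draws role-labelled (AF, ANI) points
from a Gompertz/logistic trend plus Gaussian ANI noise and records the true
inflection so tests never re-derive it.

Defaults were chosen once to mirror study-like conditions: scatter Gompertz
y0 = 60, A = 40, C = 12 and inflection AF 0.35 (inflection ANI ≈ 74.7, curve
reaching ≈100 at the anchor, quartic R² ≈ 0.99); type cloud AF ∈
(0.02, 0.32) and non-type AF ∈ (0.38, 0.98) — disjoint, as the boundary
logic requires, but abutting the inflection region as published quadrant
scatters do; noise sd 0.5 ANI. Gene-level cohorts give type species high
divergence (p ≈ 0.20–0.26) with low retention plus novel genes (ANI ≈
74–80, AF ≈ 0.3–0.5) and non-type species low divergence with high
retention (ANI ≈ 92–97, AF ≈ 0.8–1.0). Test and acceptance runs use genomes
of 20–80 genes of 150–800 nt so the quadratic-time alignment stays cheap;
statistical conclusions scale with total aligned length via the binomial
error bands the tests assert.

What the generators do **not** emulate: recombination and HGT, codon
structure, rate variation across genes, assembly/gene-calling artefacts,
the 70%-identity censoring floor that keeps real ANI values above ~70, and
real phylogenetic correlation structure among cohort members. Passing tests
therefore demonstrate correctness of the computations and estimators under
controlled truth, not that any particular biological cohort satisfies the
separated-clouds assumption.

## Degenerate inputs and tie-breaks

Duplicate gene ids, empty gene sets, all-RNA genomes, zero or multiple
primary references, unknown roles, non-IUPAC characters, underdetermined or
AF-degenerate fits, zero-variance sigmoid targets and empty summaries all
raise `MisigError` with a stable message prefix. Best-hit ties resolve by
score, identity, alignment length, then lexicographic target id; equal-W
alignments are resolved row-major in the DP, which cannot change identity
or coverage because tied cells share the full lexicographic objective.
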