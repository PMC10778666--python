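# Methods

This note documents the models and procedures implemented in grapemet,
the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical choices that
matter for reproducing results.

## Mass scale and ion chemistry

All m/z arithmetic derives from one frozen table of monoisotopic
atomic masses (CODATA/IUPAC values for ¹H, ¹²C, ¹⁴N, ¹⁶O, ³²S, ³⁵Cl;
¹²C exactly 12) plus the electron rest mass, in
`grapemet/constants.py`. No other module defines mass constants.

A singly charged anion's m/z is M + Δ(adduct) + mₑ: the acquired
electron's mass is included by default because it is what reproduces
printed ultra-high-resolution peak positions (the glucose chloride
adduct computes to 215.03279 Da with the electron and 215.03224
without — a 2.5 ppm discrepancy, five times the assignment window).
`include_electron=False` is available as an explicit toggle.

Supported adducts are the three negative-mode species relevant to
grape juice: [M−H]⁻, [M−H−H₂O]⁻ (applied to the neutral as −H₂O then
−H) and [M+Cl]⁻. Annotations always report the **neutral** formula
plus an adduct tag, never the bare ion stoichiometry — ion
stoichiometries are ambiguous across adducts and have historically
caused published formula typos. ppm error is (m/z₁ − m/z₂)/m/z₁ × 10⁶,
signed, with the first argument the observed/reference mass.

## Formula assignment

`enumerate_formulas` scans the bounded C/H/N/O/S lattice per adduct:
the neutral target mass implied by the observed m/z is swept over the
(S, N, O, C) sub-lattice (numpy-vectorised) and the hydrogen count is
solved from the mass remainder — at sub-ppm tolerance at most a couple
of H values can match, so H never needs explicit enumeration. Default
bounds C 1–70, H 1–130, N 0–10, O 0–45, S 0–4 with plausibility
filters 0 ≤ RDBE ≤ 40, 0.2 ≤ H/C ≤ 3.1, O/C ≤ 1.5 cover the 92–1000 Da
range of small plant metabolites with headroom; all configurable.
Candidates sort by |ppm error|, then heteroatom count, then formula
string, so output order is fully specified. "Unambiguous" means
exactly one surviving candidate; multi-candidate peaks are returned
flagged `ambiguous`, never forced. The enumerator is held equal, in
the test suite, to an independent nested-loop brute force written
before it.

`assign_by_network` reproduces how ultra-high-resolution peak lists
are annotated in practice: compositions propagate from a handful of
trusted seed ions (glucose, fructose, tartaric and malic acid,
tryptophan as [M−H]⁻) along a ~30-entry library of exact biochemical
mass differences (H₂, CH₂, O, CO, CO₂, H₂O, NH, NH₃, S, SO₃, C₂H₂O,
glycosyl C₆H₁₀O₅, and the proteinogenic amino-acid residues). An edge
matches when the observed mass difference agrees with the library
delta within the tolerance expressed in ppm **of the heavier peak** (a
convention choice; the alternative — ppm of the lighter — differs only
in the last decimal at these mass ratios). Propagation is
breadth-first in m/z order, deterministic, and every inherited
composition must independently reproduce its own peak's m/z within
tolerance, which bounds drift across long paths. Peaks reached by
conflicting paths are flagged `conflict` rather than silently
resolved. The network assigner is validated against the enumeration
oracle (subset property), not against any proprietary tool.

## Feature alignment

Within-platform alignment pools all samples' peaks, sorts by m/z and
sweeps once: a peak joins the open feature while it is within the
window of the feature's running intensity-weighted centroid, otherwise
a new feature opens. After the sort the result is independent of
sample order and within-sample peak order. The centroid rule prevents
single-linkage chaining across well-spaced ladders (0.4-ppm spacing is
split correctly at a 0.5-ppm window); it does not impose a hard cap on
in-feature spread, which is deliberate — a hard cap versus the lowest
member would split legitimate features, because the range of ~50
Gaussian mass errors at 0.1 ppm sd routinely exceeds 0.5 ppm while the
centroid stays central. When a sample contributes several peaks to one
feature the maximum intensity is kept. Direct-infusion consensus m/z
is the intensity-weighted mean; LC isobar groups use the unweighted
mean of member features.

When peak lists carry retention times, m/z clusters are additionally
split at RT gaps larger than the tolerance (10 s default), so isomers
become distinct features.

Presence filtering is inclusive ("at least"): a count threshold (4 by
default) or a fraction with ceiling semantics (33% of 10 samples
requires ≥ 4). Isobar grouping merges LC features agreeing within
2 ppm; the group's multiplicity is its number of distinct RTs.
Cross-platform matching (LC group mean vs direct-infusion feature,
5 ppm) resolves multiple candidates by smallest |ppm| → smallest RT
delta → lower m/z; LC-vs-LC matching (mass window AND |ΔRT| ≤ 10 s)
puts the RT delta first. ppm for a cross-platform candidate is taken
relative to the LC group mean, so symmetric ±x ppm candidates tie
exactly and fall through to the documented cascade. Matching is
greedily one-to-at-most-one in both directions.

Venn-style coverage counts a feature as present in a sample group when
detected in at least 4 samples of that group (configurable); per
pairwise comparison the shared/unique percentages are taken over the
union and sum to 100.

## Preprocessing

Pipeline order: presence filter → zero imputation → batch correction →
log₁₀ → Pareto scaling → models. Correcting batches on the imputed raw
scale keeps undetected cells from dominating location estimates;
whether correction belongs before or after the log is genuinely open,
so the stages are exposed as separate functions and the order is an
assembly choice in the CLI. The matrix object tracks its state
("raw"/"imputed"/"scaled") and refuses double scaling.

Imputation replaces zeros with 2/3 of the feature's minimum nonzero
value. Batch correction is a two-stage per-feature least-squares
adjustment: batch means moved to the grand mean, then each batch's
spread around the grand mean rescaled to the pooled within-batch
value. It is idempotent to ~1e−11 and removes a planted additive
offset to ~1e−11; because the scale stage estimates per-batch
standard deviations, its sampling noise perturbs fold changes by
O(1/√n_batch) — under 2% at 100 samples per batch, up to ~9% at 20 —
so small-batch studies may prefer location-only correction (skip the
scale stage by passing singleton batches, or accept the perturbation).
When applied on the raw intensity scale the affine map can cross zero
for weak cells; such cells are floored at 2/3 of the feature's
smallest positive corrected value so the downstream log stays defined.

Pareto scaling divides the centered log₁₀ intensities by the square
root of the per-feature standard deviation (ddof = 1): a feature with
log-scale sd 4 ends with sd 2. Features constant up to float rounding
(sd ≤ 1e−12 relative) are zeroed instead of amplifying representation
noise.

The univariate screen uses Kruskal–Wallis plus Dunn's post-hoc z tests
(pooled mid-ranks, tie-corrected variance N(N+1)/12 − Σ(t³−t)/12(N−1))
for ≥ 3 groups; for 2 groups, Student's t when Shapiro–Wilk does not
reject normality in either group at α = 0.05, otherwise Mann–Whitney U
(the rule is documented here precisely because "either/or" choices are
a reproducibility hazard). Primary p-values are Benjamini–Hochberg
adjusted across features; fold change is the ratio of group means of
the imputed, unlogged intensities, with log₂ alongside. Constant
features get p = 1 and a flag. Dunn's implementation is hand-rolled
(no maintained Python implementation among the dependencies) and was
checked against the textbook rank-sum formula on frozen examples.

## Chemometrics

**OPLS-DA.** y is the centered ±1 class indicator. Each orthogonal
round computes the PLS weight w ∝ Xᵀy, the score t = Xw, the loading
p, removes from p its projection on w, and deflates X by the resulting
orthogonal component; the single predictive component is then
extracted from the filtered matrix. Defaults: 1 orthogonal component
(selectable by cross-validation: grow while Q² gains ≥ 0.01), 7-fold
class-stratified CV for Q², 500 label permutations with the add-one
correction p = (#{Q²_perm ≥ Q²} + 1)/(n + 1). All fold assignments and
permutations flow from a mandatory seed — no hidden global state. With
zero orthogonal components the predictive scores equal one-component
PLS (held against scikit-learn in a test).

VIP is the combined predictive + orthogonal variant: the predictive
component is weighted by the fractions of Y- and X-variance it
explains, each orthogonal component by its X-variance fraction
(orthogonal components explain no Y by construction). With unit-norm
weight vectors this keeps mean(VIP²) = 1 exactly. VIP variants differ
materially between implementations, which is why the formula is
spelled out here; weighting orthogonal components by raw X-variance
instead would let high-variance non-discriminant features crowd out
true markers.

**RDA / variance partitioning.** Factors are treatment-coded
(drop-first), centered, rank-checked (collinear columns dropped with a
warning). RDA is the eigenanalysis of the fitted values of the
multivariate least-squares regression of the centered response on the
design; canonical eigenvalues sum to the constrained variance.
Adjusted R² uses the Ezekiel correction 1 − (1−R²)(n−1)/(n−m−1) with m
the design rank. The partition over 2–3 factors is the all-subsets
inclusion–exclusion of adjusted R² (unique, pairwise-shared, triple-
shared, unexplained; the seven fractions sum to 1 by construction and
may individually be slightly negative). The global test permutes rows
of Y against the pseudo-F; marginal factor tests permute residuals of
the reduced model (Freedman–Lane). The implementation is cross-checked
against vegan's `rda`/`RsquareAdj` in the test suite on a small fixed
matrix.

## Synthetic data: what it emulates, what it does not

The generator emulates the statistical structure of a two-platform
grape-juice study: a CHNOS library spanning the van Krevelen envelope
(default class mix 70/15/10/5% CHO/CHNO/CHOS/CHNOS), homologous series
(CH₂ steps and glycosyl C₆H₁₀O₅ steps from glucose), a glucose
chloride "pollutant" emitted at 13 distinct retention times, the three
adducts, log-normal intensities (CV 30%), class-marker fold changes,
multiplicative batch offsets, mass error at 0.1 ppm sd (direct
infusion) vs 1.0 ppm (LC), 2-s RT jitter, and logistic-in-log-intensity
dropout as a statistical proxy for ionization competition. Noise
defaults were chosen once so the standard windows (0.5/2/5 ppm, 10 s)
are neither trivially loose nor unachievable. Library ions are
rejection-sampled to sit > 3 ppm apart so alignment has an unambiguous
truth.

It does **not** simulate chromatographic peak shapes, isotopologue
envelopes, multiply charged ions, positive mode, RT drift between
batches, or real ion-suppression physics. Passing recovery tests
therefore demonstrates correctness of the algorithms under the stated
noise model, not instrument-grade performance on real spectra — real
data add correlated mass errors, RT warping and abundance-dependent
resolution that this generator deliberately omits.

Default problem sizes used by the test suite and CLI presets — a
150-metabolite library, 40–50 samples per class, 50 planted markers at
3× fold change, 100 samples for the variance-partition design, 199
permutations where a p < 0.01 must be resolvable — are the package's
validation conditions: large enough for the planted effects to be
identifiable, small enough to run interactively.

## Known limitations

* The sweep clustering guarantees no chaining for ladders at the
  tested 0.4-ppm spacing but has no hard in-feature spread cap (see
  above); pathological adversarial ladders near the window width can
  exceed it.
* The network assigner propagates a single adduct hypothesis along each
  component; peaks observable only as a different adduct than their
  neighbours are left to enumeration.
* The batch model is location/scale per feature; nonlinear or
  intensity-dependent batch distortions are out of scope.
* OPLS-DA is strictly two-class; multi-class questions go through PCA,
  the univariate screen, or pairwise models.
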