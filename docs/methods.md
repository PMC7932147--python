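# Methods

This note documents the statistical procedures the package implements, the
modelling choices that were genuinely open, the synthetic-data model, and
the numerical conventions. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Exact permutation screen

For two groups of sizes n₁ (control) and n₂ (treated) the test enumerates
all C(n₁+n₂, n₂) assignments of the pooled values to the treated label.
Both supported statistics — difference of group means and Wilcoxon rank sum
(midranks) — are strictly monotone in the treated-group subset sum, so
extremeness is evaluated on subset sums; this keeps the enumeration exact
and allows vectorized chunked evaluation. Two-sided extremeness is defined
symmetrically around the statistic's exact null expectation (0 for the mean
difference, n₂(N+1)/2 for the rank sum). The observed assignment is always
counted, so p ≥ 1/C and p = k/C is returned as an exact rational.
Enumeration is refused above a configurable cap (default 10⁷ assignments);
Monte-Carlo approximation is deliberately out of scope because the method's
point is exactness at small n.

**The attainable floor.** One-sided tests can reach 1/C. Two-sided tests
with equal group sizes reach 2/C, because the mirror assignment (labels
swapped) has exactly the opposite mean difference. With unequal sizes the
two statistics differ: the rank-sum null is symmetric about its expectation
for *any* sizes, so the mirror always ties and the floor stays 2/C, whereas
the mean-difference mirror generically differs in magnitude and a single
assignment can be uniquely extreme, giving 1/C. `min_attainable_p` is
therefore statistic-aware.

**Separation ⇔ floor.** Complete separation (no overlap between groups,
cross-group ties break it) is equivalent to attaining the two-sided floor
for the rank-sum statistic at any sizes, and for the mean-difference
statistic at equal sizes; both equivalences are checked exhaustively for
all size pairs up to 6+6 in the test suite. For the mean difference with
unequal sizes the equivalence can fail on special configurations (e.g.
evenly spaced values, where the mirror assignment ties), which is why the
screen uses the separation flag itself — not a p-value comparison — as the
primary-hit criterion. At the study's design (5 vs 5, two-sided) the floor
is 2/252, rendered 0.008, and the two criteria coincide.

**Default statistic and sidedness.** The screen defaults to the mean
difference on normalized MFI, two-sided, with both choices configurable.
A 5v5 two-sided screen and a 4v5 one-sided screen share the same printed
floor (2/252 ≈ 1/126 ≈ 0.008); the equal-n two-sided reading is the default
and the `direction` field lets an increase-only selection be reproduced.

## Secondary screen

Exact Mann–Whitney U per analyte: tie-free samples with combined n ≤ 20 use
the exact U null distribution (scipy); tied samples small enough to
enumerate use the exact midrank permutation distribution (scipy's exact
method is not tie-corrected); larger samples fall back to the normal
approximation with tie correction. The method used is recorded on every
result. Benjamini–Hochberg step-up control is applied across the m = panel
size analytes *within* one tissue (the screens are reported per tissue),
at target FDR q = 0.1. Secondary hits are BH-significant analytes not
already in the separation set — "additional" molecules.

## Preprocessing

Duplicate wells (at most two per sample) are averaged arithmetically,
analytes and control beads alike, before normalization — matching deposited
duplicate-averaged tables. "Normalization against Chex #4" is implemented
as division by the sample's (duplicate-averaged) Chex #4 relative to the
plate median Chex #4: a per-well multiplicative drift that scales analyte
and control beads identically cancels exactly (the duplicate average is the
same linear combination in numerator and denominator), while the median
rescaling keeps values on the original MFI scale. The residual degree of
freedom is a single plate-wide factor (the median of the realized well
scales), which is immaterial to ratios, tests and clustering; the raw
(unscaled) division is available by normalizing with a different reference.
Ratio-to-control is the ratio of arithmetic group means of normalized MFI —
the simplest reading of a "ratio to control" column; medians or log-means
are deliberately not used.

## Clustering and segregation

Default preprocessing for clustering is log-transform then per-analyte
z-score; distance is Euclidean, linkage average. None of these choices is
dictated by the data — they are the common heatmap convention — so the full
descriptor (scaling, metric, linkage, axis, dimensions) is embedded in
every `ClusterResult`, and all are configurable. Constant analytes cannot
be z-scored and are dropped with a logged warning.

The segregation score formalizes "group X clusters away from the rest": cut
the sample dendrogram into two clusters; the score is (targets in the
cluster holding the majority of targets + non-targets in the other
cluster) / n, in [0, 1]. A single-group input scores 1.0 by convention and
a majority tie resolves to the higher score. Under label randomization the
score's null law is the hypergeometric placement of targets across the cut,
which the test suite uses as an enumerated oracle. A two-cluster cut is
used because the claim being quantified is binary (one group vs the rest).
When only a few panel analytes carry a group effect, segregation is
evaluated on the hit subset (as done for a 4-hit tissue), since the
39-analyte distance is then dominated by inert analytes.

## Structure statistics

The statistical unit is the eye for OCT and the animal for histology; the
unit is an explicit column, never inferred. INL-to-RPE is derived as
TRT − GCC (valid only for 0 < GCC < TRT, enforced), so
GCC + INL-to-RPE = TRT holds exactly row by row. Group summaries report
mean ± SEM with the n−1 sample SD. Paired t-tests are classical (df =
n − 1, post − pre sign convention); zero-variance nonzero differences are
reported as degenerate with direction rather than as a fabricated
statistic. One-way ANOVA is classical (not Welch — matching the defaults of
the commercial software such studies typically use; configurable), with
Tukey HSD post-hoc p-values from the studentized range distribution and the
Tukey–Kramer standard error for unequal n. `anova_tukey_from_summary`
reconstructs group SDs from printed SEM/n triples and is algebraically
identical to the raw-data path (the test suite asserts this); applied to
published rounded summaries it supports directional checks only, because
the printed means are rounded and the exact group membership of such
comparisons is typically under-documented. Two-way ANOVA (layer × group for
per-layer cell counts) uses OLS with type-II sums of squares; undefined F
ratios (e.g. all-zero counts) are flagged degenerate. Pearson correlation
uses the t-based two-sided p.

## Synthetic-data model

The generators emulate the study design: 39 analytes, three groups
(control, 1h and 18h posthypoxia), 5 samples per group (4 selectable) × two
duplicate wells. Per well and analyte,

MFI = baseline × group-fold × sample-noise(CV = `noise_cv`) ×
well-scale(log-SD = `well_scale_sd`) × well-noise(CV = `duplicate_cv`),

with all noise factors log-normal with median 1 (multiplicative error is
the natural model for positive-valued fluorescence). Chex beads carry the
same well-scale and well-noise but no biological term — this is the
mechanism that makes control-bead normalization testable, and with
technical noise at zero the normalization inverts the drift exactly.
Defaults: baseline 1000 MFI, noise CV 0.1, well-scale log-SD 0.2, duplicate
CV 0.05. Group sizes of 5 are used because the screen's printed floor
(0.008) is consistent with a 5v5 two-sided design and the study's histology
groups have n = 4–5. Fold effects are configurable per (analyte, group);
fold 2.0 at these defaults gives near-saturated separation power, so the
power curve is strictly increasing only below saturation (the test suite
checks strict increase where power < 1 plus monotonicity everywhere).

OCT tables draw baseline TRT and GCC jointly with correlation
`oct_coupling` (default 0.85) and apply additive per-layer group effects
plus measurement noise (default 1 μm) to each eye's own baseline; defaults
for the effects are the printed group-mean shifts (−4.3/+5.8 μm TRT,
−2.13/+2.6 μm GCC at 1h/18h). Effect sets that would force GCC ≥ TRT at
the mean level are rejected. Histology tables draw intensities and process
counts normally around the printed group means (CV 0.1) and apoptosis
counts as per-layer Poisson; the per-layer Poisson means are not printed in
the source bar graphs and are fixed here as small rates confined to the
outer nuclear layer (0 / 2 / 1 for control / 1h / 18h), consistent with
"rare" outer-retina positivity.

What the generators do **not** model: bead counts and saturation, standard
curves or absolute concentrations, plate-to-plate bridging, eye-within-
animal correlation, or any real biological covariance between analytes.
Passing tests therefore demonstrate correctness of the *procedures* under a
known multiplicative-noise model, not robustness to every artefact of real
bead assays.

`synthetic_reference_tables()` is a deterministic stand-in for deposited
duplicate-averaged supplementary tables that are not redistributed with the
package. It reconstructs a published hit *structure* — ten separated plasma
analytes and four retinal ones with the published ratio-to-control values
as fold inputs, seven further plasma analytes carrying a single-rank-
overlap pattern (exact rank-test p = 4/252, detectable by BH at q = 0.1 but
not separated), inert remainder, and an 18h group interleaved with controls
so it yields no hits. The seven rank-test-only analytes are a fixed
arbitrary choice because the publication does not name them.

## Numerical conventions and problem sizes

Exact p-values are `fractions.Fraction`s (automatically reduced; 2/252
prints as 1/126) and are rendered to three decimals in tables. Subset-sum
comparisons carry an absolute guard of 10⁻⁹ × scale against floating-point
roundoff. Thickness deltas are reported to 1 decimal, percentages to 1
decimal, p-values to 4 decimals. Monte-Carlo checks in the test suite use
2000 null panels (type-I error), 500 seeds (ratio recovery and power), 1000
panels (segregation null) and 120–200 seeds for the smaller recovery
oracles; these sizes give Monte-Carlo standard errors comfortably inside
the asserted 3-SE bands. All simulation seeds are explicit and every
pipeline bundle embeds the configuration fingerprint that produced it.

## Known limitations

* The enumeration cap rules out groups much larger than ~15 vs 15; this is
  by design (the exact test is the point).
* Mixed-effects models for paired eyes within animals are not provided;
  the paired t-test treats eyes as independent pairs.
* The Chex-normalization formula (relative to the plate median) is one of
  several defensible readings of "normalized against Chex #4"; it is
  configurable and its residual plate-wide factor cancels in every
  downstream statistic.
* Clustering results depend on the (configurable) preprocessing
  convention; only the segregation statement is treated as a testable
  claim, not any particular dendrogram topology.
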