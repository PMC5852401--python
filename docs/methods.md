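# Methods

This note records the modeling choices behind `mapdist`: the histogram and
distance conventions, the statistical procedures, the automated artifact
screen, and the design of the synthetic data that stands in for clinical
volumes. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Map histograms

A metric map enters the analysis as a 3-D volume with a boolean validity
mask. Cleaning masks out — in both maps of an FA/MD pair — every voxel whose
FA value exceeds 1.0; such values are non-physical by-products of tensor
fitting in noisy voxels, and removing the companion MD voxel keeps the two
histograms describing the same voxel population. Values are never rewritten,
only masked.

Histograms use a fixed specification so every map in a cohort is binned
identically: 100 bins over (0.0, 1.0] for FA and (0.0, 0.004] mm²/s for MD.
Bins are left-open/right-closed, so an exact 0.0 — the background outside
the head, and the bulk of what brain extraction removes — falls outside the
range, and FA exactly 1.0 lands in the last bin. Values outside the range
are tallied separately (`n_excluded_low`, `n_excluded_high`) so that voxel
counts are conserved. The probability normalization (counts divided by the
number of binned voxels) produces the vector every distance metric consumes;
distance-value histograms, by contrast, are density-normalized (heights ×
bin width sum to one) for plotting and cumulative curves.

No brain extraction is implemented: maps are assumed skull-stripped or
synthetic, and the open lower bin edge subsumes background-zero removal.

## The distance-metric registry

Thirteen metrics cover seven families:

| Family | Metrics |
| --- | --- |
| Minkowski | city_block, euclidean, chebyshev |
| Intersection | canberra, intersection |
| Inner Product | cosine |
| Squared L2 | squared_euclidean, squared_chi2 |
| Fidelity | hellinger, bhattacharyya |
| Shannon Entropy | jeffreys, jensen_shannon |
| Earth Mover's | emd_1d |

Conventions that matter:

* **Hellinger** is √(1 − BC) with BC = Σ√(pᵢqᵢ), bounded by 1. It is
  evaluated in the algebraically equivalent form √(½ Σ(√pᵢ − √qᵢ)²), which
  is exactly zero at P = Q instead of accumulating √-amplified round-off.
  The √2-scaled variant used by some authors is exposed as
  `hellinger_scaled`.
* **Bhattacharyya** (−ln BC) is unbounded; zero histogram overlap returns
  +∞ as a sentinel, not an exception.
* **Jeffreys** (symmetrized Kullback–Leibler) is computed on
  eps-smoothed (ε = 1e-10), renormalized inputs so empty bins cannot
  produce infinities. **Jensen–Shannon** needs no smoothing — the mixture
  M = (P+Q)/2 is positive wherever either input is — and is reported as the
  square root of the divergence in log base 2, a true metric bounded by 1.
* **canberra** and **squared_chi2** treat 0/0 terms as zero.
* **emd_1d** is the first Wasserstein distance between histograms on a
  shared grid, computed as bin_width × Σ|CPᵢ − CQᵢ| on the cumulative sums.
  For 1-D histograms this equals the exact minimum-cost transport, which the
  tests verify against a linear-programming oracle on small instances.

Six of the thirteen (city_block, euclidean, chebyshev, hellinger,
jensen_shannon, emd_1d) are flagged as true metrics and property-tested for
the triangle inequality. Distances are computed in double precision on
validated probability vectors (non-negative, sum within 1e-9 of one);
comparisons in tests use absolute tolerance 1e-9.

## Group comparison statistics

Within-group pairwise distance distributions are right-skewed and
non-Gaussian, so groups are compared nonparametrically.

* **Quartiles** use linear interpolation at positions (n−1)·q on the sorted
  sample (numpy's default). The box-whisker summary places the upper whisker
  at Q3 + 1.5·IQR; the *spread* is the upper whisker limit minus the
  median. Values beyond the whisker are reported as outliers but are never
  excluded from any test.
* **Mann–Whitney U** is reported for the first group with the tie-0.5
  convention: U = #{xᵢ > yⱼ} + ½·#ties. The two-sided p-value is exact for
  n_a·n_b ≤ 200, computed from the full tie-aware null distribution by a
  dynamic program over tie blocks (counting assignments by accumulated 2U);
  larger samples use the tie-corrected normal approximation with continuity
  correction. The exact path is validated against exhaustive enumeration of
  all assignments at small n.
* **Kolmogorov–Smirnov** defaults to samples mode — the exact maximum ECDF
  difference over pooled sample points, with the asymptotic p-value — and
  offers a binned mode that compares cumulative histograms at the bin edges
  of a shared specification, matching how cumulative-curve figures are read.
* No multiple-testing correction is applied across a comparison suite by
  default; raw p-values are reported and a Bonferroni adjustment is the
  reader's one-line division.

## The comparison suite

`run_comparison_suite` executes a YAML list of named two-group comparisons;
each group is selected from the cohort manifest by partial acquisition
metadata (vendor case-insensitive; field strength within 0.05 T; *b*-value
within 5 s/mm²; unspecified keys unconstrained). The packaged default suite
has nine entries walking from the least to the most restricted comparison:
all-vendor, vendor at 1.5 T, vendor at b = 1000, within-Siemens *b*-value
and field-strength contrasts, fully controlled vendor and field-strength
contrasts, and the 6-vs-25-direction contrast. The first two entries carry
the two customary names of the same all-Siemens-vs-all-GE comparison (the
within-vendor distance sets and their between-vendor comparison); they are
kept as separate rows so the suite mirrors the conventional nine-item
enumeration.

The manifest is the source of truth for grouping; acquisition metadata is
never re-derived from NIfTI headers, which do not carry vendor or diffusion
fields.

## Automated artifact discovery

The published procedure identified outlier modes in distance histograms
visually; `detect_artifacts` automates it with two rules per iteration:

1. the *tail* is every pairwise distance above the upper whisker
   (Q3 + 1.5·IQR) of the current distance set;
2. data set k is flagged iff its tail-pair count c_k exceeds `count_min`
   (default 2 — an ordinary data set should not appear in the tail more than
   twice) **and** c_k ≥ γ·(n−1) with γ = 0.1 (a flagged data set must be
   distant from a non-trivial fraction of the cohort).

Flagged data sets are removed — both modalities, via `remove_companions`,
regardless of which modality drove the flag — and the distances are
recomputed, iterating (default max 5) until an iteration flags nothing.
Both thresholds are configurable.

`evaluate_metrics` ranks the registry for this task: per metric, the
dynamic range (max − min of normal-normal distances) and a separation score
— (median artifact-vs-normal distance − median normal-normal distance)
divided by the normal spread — where a score above 1 means a typical
artifact distance lies beyond the normal upper whisker.

## Synthetic data: what it emulates and what it does not

The generator produces map-value *distributions*, not anatomy: every
downstream computation consumes only histograms, so a three-component
truncated-normal mixture (WM: FA 0.45 ± 0.12, MD 0.75 ± 0.15 ×10⁻³; GM:
FA 0.15 ± 0.05, MD 0.90 ± 0.18 ×10⁻³; CSF: FA 0.08 ± 0.03, MD 3.0 ± 0.4
×10⁻³ mm²/s; 15 % background zeros) reproduces the qualitative shapes that
matter — a bimodal FA histogram and a right-tailed MD histogram — at a
fraction of the cost of simulating diffusion physics. FA and MD are coupled
voxelwise through a shared component assignment.

Within-group variability is layered:

* **Protocol variants.** Each group contains three *deterministic* variant
  offsets along four global axes — FA shift (±0.03 × 0.67), FA log
  peak-width (±0.12 × 0.67), MD shift (±6×10⁻⁵ mm²/s × 0.67), MD log
  peak-width (±0.10 × 0.67) — emulating the discrete protocol revisions,
  coil and software differences that a parameter-matched clinical group
  still contains. Subjects are assigned to variants round-robin.
* **Subject scatter.** Each subject receives continuous uniform scatter at
  0.33 of the axis half-widths around its variant.

This structure was chosen over simple i.i.d. continuous jitter for a
substantive reason: curated clinical cohorts show compact, right-skewed
pairwise-distance distributions in which no clean data set is
over-represented in the upper tail. Purely continuous jitter cannot
reproduce that — in any finite draw one subject occasionally lands isolated
from the rest and becomes indistinguishable from a mild artifact — whereas
discrete variants with bounded scatter make the between-variant IQR large
relative to the largest natural distance, so the upper whisker sits beyond
it. Making the variants deterministic (a property of the acquisition group,
not a random draw) additionally guarantees that two groups generated from
the same tissue model are structurally identical, so their comparison shows
no false structure. The `jitter_scale` knob multiplies both layers,
turning a homogeneous group into a heterogeneous, mixed-protocol-like one.

Cohort volumes default to 32³ voxels, at which histogram sampling noise
contributes roughly 0.03 in Hellinger units — well below the
variant-driven separations — while keeping a 100-cohort test battery under
two minutes. The single-volume generator defaults to 16³ for cheap
illustration.

**Injected artifacts** (the `SEVERE_ARTIFACTS` presets) model gross,
visually obvious corruption:

* *intensity_offset* (+0.2 FA on tissue voxels) — a calibration/bias
  failure; deliberately pushes some FA above 1.0 to exercise the cleaning
  threshold;
* *noise_inflation* (×4 deviations from the tissue mean) — a severe SNR
  failure;
* *slice_corruption* (50 % of axial slices) — corrupted slices carry the
  signature of tensor fits run on scrambled data: spuriously high FA
  (uniform on 0.65–1.0) and implausibly low MD (uniform on
  0.05–0.45 ×10⁻³). Plain uniform-on-(0,1) slice values were rejected
  during design: a flat histogram has a high Bhattacharyya overlap with
  any map histogram and is therefore nearly invisible to fidelity-family
  distances, which does not match how corrupted volumes present;
* *extra_anatomy* (60 % of voxels, MD centered at 2.0×10⁻³ mm²/s, FA
  0.3–0.7) — a shifted field of view replacing part of the volume with
  non-brain anatomy (the head-and-neck-coil scenario), filling the
  otherwise sparse MD band between tissue and CSF.

Magnitudes are calibrated to "clearly separable": each preset's
artifact-to-normal distances clear the cohort's contaminated upper whisker
with margin, which is what "severe artifact" means operationally here.

What the generator does **not** emulate: spatial structure (anatomy,
partial-volume gradients, smoothing correlations between neighboring
voxels), k-space or physiological noise physics, eddy-current or motion
effects, and any coupling between acquisition metadata and map
distributions (a synthetic "GE" group differs from a synthetic "Siemens"
group only if given different models or jitter scales). Passing tests
therefore demonstrate that the *pipeline* — cleaning, binning, distances,
statistics, screening — behaves correctly on data with realistic
distributional structure; they do not validate claims about real scanner
differences.

**Synthetic reports** are assembled from templates whose keep/reject labels
follow from construction (surgical-history sentence, unnegated pathology
finding, negated finding, neutral text), giving the report filter an exact
ground truth independent of the filter's own logic.

## Curation filters

Report filtering is two-step: any surgical term anywhere rejects; otherwise
a pathology term rejects only if no negation cue occurs in the same
sentence. Matching is case-insensitive on word boundaries (multi-word terms
as phrases) — substring matching would fire "no" inside "normal", which is
itself a listed negation cue. Sentences split on `.`, `!`, `?` followed by
whitespace or end of text; abbreviations are not specially handled, and the
segmenter is deliberately the simplest reproducible rule. Series-tag
filtering is raw case-insensitive substring matching — including the
extremely permissive include string "b" — kept verbatim because that is the
documented archive practice; both vocabularies live in a packaged YAML and
are overridable per run. Gradient tables are checked in a fixed order:
length mismatch, negative *b*-value, fewer than six non-zero *b*-values,
all-zero direction with non-zero *b*-value; verdicts are returned, never
raised, since a bad table is an expected input.

## Numerical and degenerate-input choices

* Bin membership uses `searchsorted` on the shared edge grid (left-open,
  right-closed); a map with no in-range voxels raises `EmptyHistogramError`
  rather than producing an undefined probability vector.
* A distance histogram over identical values widens its range to one unit
  so the density (1/width in the single occupied bin) stays defined.
* `detect_artifacts` on all-identical histograms sees IQR = 0, an empty
  tail, and converges immediately with no flags; fewer than four histograms
  is rejected because pair-distance quartiles are meaningless.
* `evaluate_metrics` on a degenerate (all-identical) normal set reports
  dynamic range 0 and a +∞ separation sentinel when artifacts are separated
  at all.
* Exact Mann–Whitney state tables are sized by the global intermediate
  bound 2·⌊n/2⌋·⌈n/2⌉, not the final 2·n_a·n_b, because partial assignments
  can exceed the final maximum.
* Seeds derived inside generators stay below 2³¹.

## Known limitations

* The nine-comparison suite reproduces the *design* of the clinical
  analysis; the printed clinical statistics themselves require the original
  patient data, which is not publicly available, and are not reproduced.
* The Hellinger convention (√(1−BC) vs the √2-scaled variant) differs
  across the literature; both are provided, and cross-study comparisons of
  absolute distances must confirm the convention.
* The exact-U p-value is exact for the tie pattern observed, but the
  normal-approximation branch shares the usual asymptotic caveats at
  moderate samples with heavy ties.
* Within-group pairwise distances are not independent samples (each subject
  contributes to n−1 pairs); the U and K–S p-values inherit the standard
  caveat that effective sample sizes are smaller than pair counts, which is
  one reason the artifact screen uses counts and whiskers rather than
  p-values.
* The report filter is a vocabulary rule, not clinical NLP; its guarantees
  are relative to the configured term lists.
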