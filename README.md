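# mapdist

Histogram-distance similarity analysis and quality control for quantitative
MRI metric maps (fractional anisotropy and mean diffusivity).

## The problem

Clinical imaging archives hold diffusion MRI acquired under many different
protocols — vendors, field strengths, *b*-values, gradient-direction counts.
Before such data can be pooled or reused as control data, two questions must
be answered: *which acquisition parameters must match for the maps to be
comparable*, and *which individual volumes carry artifacts severe enough to
exclude*. `mapdist` answers both with one primitive: the distance between
probability-normalized histograms of map values.

Each FA or MD map is reduced to a 100-bin histogram — FA over (0.0, 1.0],
MD over (0.0, 0.004] mm²/s, left-open so background zeros are excluded —
normalized to a probability vector *P* = (p₁, …, p₁₀₀). For two maps the
package computes distances from a registry of 13 metrics spanning seven
families (Minkowski, Fidelity, Intersection, Inner Product, Squared L2,
Shannon Entropy, Earth Mover's). The presentation metric is the Hellinger
distance

&nbsp;&nbsp;&nbsp;&nbsp;H(P, Q) = √(1 − Σᵢ √(pᵢ qᵢ)) ∈ [0, 1],

a true metric on probability histograms. Within a group of comparably
acquired data sets, all n(n−1)/2 pairwise distances form a distance
distribution; groups are then compared nonparametrically (Mann–Whitney U and
two-sample Kolmogorov–Smirnov), summarized by box-whisker statistics with
the upper whisker at Q3 + 1.5·IQR, and by the *spread* — upper whisker limit
minus median — as the variability measure.

The same distance distribution drives artifact screening: a volume involved
in many more upper-tail pairs than its peers is dissimilar to most of the
cohort; it is flagged, removed together with its companion map in the other
modality, and the procedure iterates until nothing stands out.

Cohort curation from a clinical archive is covered by three upstream
filters: a two-step negation-aware radiology-report screen, DICOM tag-string
identification of diffusion series, and gradient-table validity rules
(at least six non-zero *b*-values, matching direction counts, no all-zero
direction vectors, no negative *b*-values).

No patient data ships with the package; a seeded synthetic-fixture module
generates FA/MD-like volumes (tissue mixture over background zeros, with
protocol-variant and subject-level variability) and injectable artifacts,
so every stage is testable end to end.

## Worked example

Compare a homogeneous group against a group with 3× the protocol
variability, using the library API:

```python
from mapdist import (simulate_group, clean_fa_md, build_histogram,
                     HistogramSpec, pairwise_distances, compare_groups)

def histograms(pairs, modality="FA"):
    out = []
    for fa, md in pairs:
        fa, md, _ = clean_fa_md(fa, md)
        out.append(build_histogram(fa, HistogramSpec.for_modality(modality)))
    return out

homo = simulate_group(12, seed=11, jitter_scale=1.0)
hetero = simulate_group(12, seed=99, jitter_scale=3.0)
ds_a = pairwise_distances(histograms(homo), "hellinger", group_label="homogeneous")
ds_b = pairwise_distances(histograms(hetero), "hellinger", group_label="heterogeneous")
r = compare_groups(ds_a, ds_b)
print(f"median_a={r.box_a.median:.4f} spread_a={r.box_a.spread:.4f}")
print(f"median_b={r.box_b.median:.4f} spread_b={r.box_b.spread:.4f}")
print(f"U={r.U:.1f} p_U={r.p_U:.3g} ks_D={r.ks_D:.4f} p_ks={r.p_ks:.3g}")
```

Output:

```
median_a=0.0976 spread_a=0.2253
median_b=0.2219 spread_b=0.6235
U=1007.0 p_U=9.98e-08 ks_D=0.4848 p_ks=1.15e-07
```

Each group contributes 66 pairwise Hellinger distances. The heterogeneous
group's distance distribution sits higher (median 0.22 vs 0.10) and is much
wider (spread 0.62 vs 0.23); both tests reject equality decisively — the
mixed-protocol group's maps are measurably less mutually similar.

Artifact screening on a group with one corrupted volume:

```python
from mapdist import detect_artifacts, inject_artifact
from mapdist.synthetic_fixtures import SEVERE_ARTIFACTS

pairs = simulate_group(10, seed=5)
pairs[9] = inject_artifact(*pairs[9], SEVERE_ARTIFACTS["slice_corruption"], seed=2)
report = detect_artifacts(histograms(pairs))
print(report.flagged_ids, report.converged)   # ['sub009'] True
```

The same operations are available from the shell via the `mapdist` CLI:
`mapdist simulate`, `mapdist histogram`, `mapdist pairwise`,
`mapdist compare` (ships with the default nine-comparison suite),
`mapdist detect-artifacts`, `mapdist evaluate-metrics`,
`mapdist filter-reports`, `mapdist filter-series`,
`mapdist validate-gradients`, `mapdist tabulate`, `mapdist list-metrics`.

## Layout

| Module | Role |
| --- | --- |
| `mapdist.core_io` | NIfTI map reading, cohort manifests, metadata grouping, composition tables |
| `mapdist.cohort_filters` | report, DICOM-tag and gradient-table curation filters |
| `mapdist.map_histograms` | FA/MD cleaning and fixed-specification histograms |
| `mapdist.distance_metrics` | the 13-metric registry and pairwise distance sets |
| `mapdist.similarity_analysis` | box-whisker/spread summaries, Mann–Whitney U, K–S, artifact discovery, metric evaluation, comparison suites |
| `mapdist.synthetic_fixtures` | seeded volume/cohort/report generators with ground truth |
| `mapdist.plotting` | box-whisker and cumulative-curve plots |
| `mapdist.cli` | the `mapdist` command-line interface |

See `docs/methods.md` for the modeling assumptions, parameter choices and
known limitations.
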