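"""Distance-distribution summaries, two-group nonparametric comparison,
iterative artifact discovery, and metric evaluation.

Within-group pairwise distance distributions are right-skewed and
non-Gaussian, so groups are compared nonparametrically: the Mann-Whitney
U-test (global stochastic ordering, rank based) and the two-sample
Kolmogorov-Smirnov test (maximum cumulative-distribution difference,
sensitive to range, location and shape). Distributions are summarized by
box-whisker statistics with the upper whisker at Q3 + 1.5*IQR; the
"spread" — upper whisker limit minus median — is the variability summary.
Outliers beyond the whisker are never dropped from the tests.

Artifact discovery iterates on the upper tail of the pairwise-distance
distribution: a data set implicated in many more tail pairs than its peers
is dissimilar to most of the cohort, is flagged and removed (together with
its companion map in the other modality), and the distances are recomputed
until no data set stands out.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import AcquisitionMetadata, CohortTable, Modality, read_metric_map, select_group
from .distance_metrics import (
    DistanceSet,
    MetricDescriptor,
    get_metric,
    list_metrics,
    pairwise_distances,
)
from .errors import ValidationError
from .map_histograms import HistogramSpec, MapHistogram, build_histogram, clean_fa_md

logger = logging.getLogger(__name__)

#: exact Mann-Whitney null up to this many (x, y) pair comparisons
EXACT_U_LIMIT = 200


@dataclass
class BoxStats:
    """Box-whisker summary with the 1.5*IQR upper-whisker convention."""

    median: float
    q1: float
    q3: float
    iqr: float
    upper_limit: float
    spread: float
    n: int
    outlier_values: np.ndarray


@dataclass
class DistanceHistogram:
    """Density-normalized histogram of distance values plus cumulative curve."""

    edges: np.ndarray
    density: np.ndarray
    cumulative: np.ndarray  # evaluated at the right edge of each bin; ends at 1
    n: int

    @property
    def bin_width(self) -> float:
        return float(self.edges[1] - self.edges[0])


@dataclass
class GroupComparisonResult:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    U: float
    p_U: float
    ks_D: float
    p_ks: float
    box_a: BoxStats
    box_b: BoxStats
    cumulative_a: np.ndarray
    cumulative_b: np.ndarray


@dataclass
class ArtifactReport:
    iterations: list[dict]
    converged: bool
    removed_total: int

    @property
    def flagged_ids(self) -> list[str]:
        out: list[str] = []
        for it in self.iterations:
            out.extend(it["flagged_ids"])
        return out


def box_whisker_summary(values: Sequence[float]) -> BoxStats:
    """Quartiles by linear interpolation at (n-1)*q on the sorted sample."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValidationError("box_whisker_summary needs at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    upper = q3 + 1.5 * iqr
    return BoxStats(
        median=float(med), q1=float(q1), q3=float(q3), iqr=float(iqr),
        upper_limit=float(upper), spread=float(upper - med), n=int(v.size),
        outlier_values=np.sort(v[v > upper]),
    )


def _exact_u_distribution(pooled_sorted: np.ndarray, n_x: int
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Exact tie-aware null distribution of 2U over all assignments of n_x of
    the pooled values to group x. Returns (support of 2U, counts)."""
    # tie blocks of the pooled multiset
    blocks: list[int] = []
    i = 0
    while i < len(pooled_sorted):
        j = i
        while j < len(pooled_sorted) and pooled_sorted[j] == pooled_sorted[i]:
            j += 1
        blocks.append(j - i)
        i = j
    n = len(pooled_sorted)
    # intermediate states with fewer than n_x placed can exceed the final
    # bound 2*n_x*(n - n_x); size by the global maximum over all splits
    max2u = 2 * (n // 2) * (n - n // 2)
    # dp[a] = vector over 2U of counts with a x's placed so far
    dp = [np.zeros(max2u + 1, dtype=object) for _ in range(n_x + 1)]
    dp[0][0] = 1
    processed = 0
    for m in blocks:
        new = [np.zeros(max2u + 1, dtype=object) for _ in range(n_x + 1)]
        choose = [math.comb(m, k) for k in range(m + 1)]
        for a in range(min(processed, n_x) + 1):
            col = dp[a]
            nz = np.nonzero(col)[0]
            if nz.size == 0:
                continue
            y_before = processed - a
            for k in range(0, min(m, n_x - a) + 1):
                du = 2 * k * y_before + k * (m - k)
                tgt = new[a + k]
                for u in nz:
                    tgt[u + du] += col[u] * choose[k]
        dp = new
        processed += m
    counts = dp[n_x]
    support = np.nonzero(counts)[0]
    return support, counts[support]


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> dict:
    """Mann-Whitney U for group x with the tie-0.5 convention.

    U = #{(x_i, y_j): x_i > y_j} + 0.5 * #ties. The two-sided p-value is
    exact (full tie-aware enumeration over assignments) when n_x*n_y <= 200,
    otherwise a tie-corrected normal approximation with continuity
    correction.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValidationError("mann_whitney_u needs two non-empty samples")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r_x = ranks[:nx].sum()
    u = r_x - nx * (nx + 1) / 2.0

    if nx * ny <= EXACT_U_LIMIT:
        support, counts = _exact_u_distribution(np.sort(pooled), nx)
        total = sum(int(c) for c in counts)
        two_u = int(round(2 * u))
        lo = sum(int(c) for s, c in zip(support, counts) if s <= two_u)
        hi = sum(int(c) for s, c in zip(support, counts) if s >= two_u)
        p = min(1.0, 2.0 * min(lo, hi) / total)
    else:
        n = nx + ny
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
        mu = nx * ny / 2.0
        sigma2 = nx * ny / 12.0 * ((n + 1) - tie_term)
        if sigma2 <= 0:
            p = 1.0
        else:
            z = (abs(u - mu) - 0.5) / math.sqrt(sigma2)
            p = min(1.0, 2.0 * sps.norm.sf(max(z, 0.0)))
    return {"U": float(u), "p_two_sided": float(p)}


def ks_two_sample(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "samples",
    spec: HistogramSpec | None = None,
) -> dict:
    """Two-sample Kolmogorov-Smirnov statistic and asymptotic p-value.

    samples mode evaluates the exact empirical CDFs at all pooled sample
    points; binned mode compares cumulative histograms at the bin edges of a
    shared HistogramSpec (the form used for cumulative-histogram plots).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValidationError("ks_two_sample needs two non-empty samples")
    if mode == "samples":
        res = sps.ks_2samp(x, y, method="asymp")
        return {"D": float(res.statistic), "p": float(res.pvalue)}
    if mode == "binned":
        if spec is None:
            raise ValidationError("binned mode requires a shared HistogramSpec")
        edges = spec.edges
        fx = np.searchsorted(np.sort(x), edges, side="right") / x.size
        fy = np.searchsorted(np.sort(y), edges, side="right") / y.size
        d = float(np.abs(fx - fy).max())
        en = x.size * y.size / (x.size + y.size)
        p = float(sps.kstwobign.sf(math.sqrt(en) * d))
        return {"D": d, "p": min(p, 1.0)}
    raise ValidationError(f"unknown K-S mode {mode!r}")


def distance_histogram(ds: DistanceSet | Sequence[float], n_bins: int = 100
                       ) -> DistanceHistogram:
    """Density-normalized histogram of a distance set with its cumulative
    curve (integral of the density equals one)."""
    values = ds.values if isinstance(ds, DistanceSet) else np.asarray(ds, float)
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValidationError("distance_histogram needs at least one value")
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        hi = lo + 1.0  # degenerate sample: one unit-wide support
    density, edges = np.histogram(values, bins=n_bins, range=(lo, hi),
                                  density=True)
    width = edges[1] - edges[0]
    cumulative = np.cumsum(density) * width
    cumulative[-1] = 1.0  # pin round-off
    return DistanceHistogram(edges=edges, density=density,
                             cumulative=cumulative, n=int(values.size))


def compare_groups(ds_a: DistanceSet, ds_b: DistanceSet, n_bins: int = 100
                   ) -> GroupComparisonResult:
    """Full nonparametric comparison of two within-group distance sets."""
    if ds_a.metric.name != ds_b.metric.name:
        raise ValidationError(
            f"metric mismatch: {ds_a.metric.name} vs {ds_b.metric.name}"
        )
    if len(ds_a) == 0 or len(ds_b) == 0:
        raise ValidationError("both distance sets must be non-empty")
    mw = mann_whitney_u(ds_a.values, ds_b.values)
    ks = ks_two_sample(ds_a.values, ds_b.values, mode="samples")
    # shared-range cumulative curves for plotting / binned K-S
    lo = float(min(ds_a.values.min(), ds_b.values.min()))
    hi = float(max(ds_a.values.max(), ds_b.values.max()))
    if hi == lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    cum_a = np.searchsorted(np.sort(ds_a.values), edges[1:], side="right") / len(ds_a)
    cum_b = np.searchsorted(np.sort(ds_b.values), edges[1:], side="right") / len(ds_b)
    return GroupComparisonResult(
        label_a=ds_a.group_label, label_b=ds_b.group_label,
        n_a=len(ds_a), n_b=len(ds_b),
        U=mw["U"], p_U=mw["p_two_sided"],
        ks_D=ks["D"], p_ks=ks["p"],
        box_a=box_whisker_summary(ds_a.values),
        box_b=box_whisker_summary(ds_b.values),
        cumulative_a=cum_a, cumulative_b=cum_b,
    )


def detect_artifacts(
    histograms: Sequence[MapHistogram],
    metric: str | MetricDescriptor = "hellinger",
    count_fraction: float = 0.1,
    count_min: int = 2,
    max_iter: int = 5,
) -> ArtifactReport:
    """Iteratively flag data sets over-represented in the upper tail of the
    pairwise-distance distribution.

    Per iteration: compute all pairwise distances, take the tail as distances
    above the upper whisker (Q3 + 1.5*IQR), count tail pairs per data set,
    and flag k when its count c_k exceeds ``count_min`` AND c_k >=
    ``count_fraction``*(n-1). Flagged data sets are removed and the loop
    repeats until an iteration flags nothing or ``max_iter`` is reached.
    """
    if len(histograms) < 4:
        raise ValidationError("artifact detection needs at least 4 histograms")
    desc = get_metric(metric)
    remaining = list(histograms)
    iterations: list[dict] = []
    converged = False
    for _ in range(max_iter):
        ds = pairwise_distances(remaining, desc)
        box = box_whisker_summary(ds.values)
        tail = ds.values > box.upper_limit
        counts: dict[str, int] = {h.subject_id: 0 for h in remaining}
        for (a, b), in_tail in zip(ds.pairs, tail):
            if in_tail:
                counts[a] += 1
                counts[b] += 1
        n = len(remaining)
        flagged = sorted(
            k for k, c in counts.items()
            if c > count_min and c >= count_fraction * (n - 1)
        )
        iterations.append({
            "flagged_ids": flagged,
            "tail_threshold": box.upper_limit,
            "counts": counts,
        })
        if not flagged:
            converged = True
            break
        remaining = [h for h in remaining if h.subject_id not in set(flagged)]
        if len(remaining) < 4:
            break
    removed = sum(len(it["flagged_ids"]) for it in iterations)
    return ArtifactReport(iterations=iterations, converged=converged,
                          removed_total=removed)


def remove_companions(flagged_ids: Sequence[str], cohort: CohortTable
                      ) -> CohortTable:
    """Drop flagged subjects from the cohort: removing a subject removes both
    its FA and MD maps, regardless of which modality drove the flag."""
    flagged = set(flagged_ids)
    unknown = flagged - set(cohort.subject_ids)
    if unknown:
        raise ValidationError(f"unknown subject ids: {sorted(unknown)}")
    keep = ~cohort.frame["subject_id"].isin(flagged)
    return CohortTable(frame=cohort.frame[keep].copy())


def evaluate_metrics(
    normal: Sequence[MapHistogram],
    artifact: Sequence[MapHistogram],
    metrics: Sequence[str | MetricDescriptor] | None = None,
) -> pd.DataFrame:
    """Rank distance metrics by how far artifact maps sit from the normal
    distance distribution.

    dynamic_range: max - min over normal-normal pairwise distances.
    separation_score: (median of artifact-vs-normal distances - median of
    normal-normal distances) / (upper whisker limit - median of
    normal-normal distances); > 1 means a typical artifact distance lies
    beyond the normal upper whisker. Degenerate normal sets (zero spread)
    report +inf when artifacts are separated at all, else 0.
    """
    if len(normal) < 2 or len(artifact) < 1:
        raise ValidationError(
            "need >= 2 normal and >= 1 artifact histograms"
        )
    rows = []
    for m in (metrics if metrics is not None else list_metrics()):
        desc = get_metric(m)
        nn = pairwise_distances(normal, desc).values
        w = normal[0].spec.bin_width
        an = np.asarray([
            desc.func(a.probs, h.probs, w, 1e-10)
            for a in artifact for h in normal
        ])
        box = box_whisker_summary(nn)
        dyn = float(nn.max() - nn.min())
        num = float(np.median(an) - box.median)
        den = box.spread
        if den > 0:
            sep = num / den
        else:
            sep = math.inf if num > 0 else 0.0
        rows.append({"metric": desc.name, "family": desc.family.value,
                     "dynamic_range": dyn, "separation_score": sep})
    out = pd.DataFrame(rows).sort_values(
        "separation_score", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
    return out


def _group_histograms(group: CohortTable, modality: Modality
                      ) -> list[MapHistogram]:
    col = "fa_path" if modality is Modality.FA else "md_path"
    hists = []
    for row in group.iter_rows():
        fa = read_metric_map(row["fa_path"], Modality.FA)
        md = read_metric_map(row["md_path"], Modality.MD)
        fa, md, _ = clean_fa_md(fa, md)
        m = fa if modality is Modality.FA else md
        h = build_histogram(m, HistogramSpec.for_modality(modality))
        h.subject_id = str(row["subject_id"])
        hists.append(h)
    return hists


def run_comparison_suite(
    cohort: CohortTable,
    suite: Sequence[Mapping],
    metric: str | MetricDescriptor = "hellinger",
    modalities: Sequence[Modality | str] = (Modality.FA, Modality.MD),
) -> pd.DataFrame:
    """Run a list of two-group comparisons over a cohort.

    Each suite entry is {name, criteria_a, criteria_b} where the criteria are
    partial acquisition-metadata dicts. For each entry and each modality the
    two groups are selected, maps are read and cleaned, per-map histograms
    built, within-group pairwise distances computed, and the two distance
    distributions compared. Entries whose groups resolve to fewer than two
    data sets are skipped with a logged reason.
    """
    desc = get_metric(metric)
    rows = []
    for entry in suite:
        name = entry["name"]
        ga = select_group(cohort, AcquisitionMetadata(**dict(entry["criteria_a"])))
        gb = select_group(cohort, AcquisitionMetadata(**dict(entry["criteria_b"])))
        if len(ga) < 2 or len(gb) < 2:
            logger.warning(
                "skipping comparison %r: group sizes %d and %d (< 2)",
                name, len(ga), len(gb),
            )
            continue
        for modality in modalities:
            modality = Modality(modality)
            ds_a = pairwise_distances(_group_histograms(ga, modality), desc,
                                      group_label=f"{name}:a")
            ds_b = pairwise_distances(_group_histograms(gb, modality), desc,
                                      group_label=f"{name}:b")
            r = compare_groups(ds_a, ds_b)
            rows.append({
                "name": name, "modality": modality.value,
                "n_a": r.n_a, "n_b": r.n_b,
                "U": r.U, "p_U": r.p_U, "ks_D": r.ks_D, "p_ks": r.p_ks,
                "median_a": r.box_a.median, "median_b": r.box_b.median,
                "spread_a": r.box_a.spread, "spread_b": r.box_b.spread,
            })
    return pd.DataFrame(rows)
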