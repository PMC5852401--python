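"""Registry of 13 histogram distance metrics across seven families.

Distances are computed on probability-normalized histograms P = (p_i),
Q = (q_i) of identical binning; all metrics are symmetric, non-negative and
zero at identity. The seven families are Minkowski, Fidelity, Intersection,
Inner Product, Squared L2 Norm, Shannon Entropy, and Earth Mover's.

Conventions:

* hellinger is sqrt(1 - BC) with BC = sum(sqrt(p_i q_i)), so it lives in
  [0, 1]; ``hellinger_scaled`` applies the alternative sqrt(2) scaling.
* bhattacharyya = -ln(BC) is unbounded; zero histogram overlap yields +inf
  (a sentinel, not an exception).
* jeffreys (symmetrized Kullback-Leibler) is evaluated on eps-smoothed,
  renormalized histograms so empty bins do not produce infinities.
* jensen_shannon is the square root of the JS divergence in log base 2,
  bounded by 1; no smoothing is needed because the mixture M = (P+Q)/2 is
  positive wherever either input is.
* emd_1d is the earth mover's (first Wasserstein) distance between 1-D
  histograms, bin_width * sum(|cumsum(P) - cumsum(Q)|); for histograms on a
  shared grid this equals the exact minimum-cost transport.

squared_chi2 and canberra treat 0/0 terms as contributing zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Sequence

import numpy as np

from .errors import ValidationError
from .map_histograms import MapHistogram

NORMALIZATION_TOL = 1e-9
DEFAULT_EPS = 1e-10


class Family(str, Enum):
    MINKOWSKI = "Minkowski"
    FIDELITY = "Fidelity"
    INTERSECTION = "Intersection"
    INNER_PRODUCT = "InnerProduct"
    SQUARED_L2 = "SquaredL2"
    SHANNON_ENTROPY = "ShannonEntropy"
    EARTH_MOVERS = "EarthMovers"


@dataclass(frozen=True)
class MetricDescriptor:
    name: str
    family: Family
    is_true_metric: bool
    upper_bound: float  # math.inf when unbounded
    func: Callable[[np.ndarray, np.ndarray, float, float], float] = field(
        repr=False, compare=False, default=None  # type: ignore[assignment]
    )


def _city_block(p, q, w, eps):
    return float(np.abs(p - q).sum())


def _euclidean(p, q, w, eps):
    return float(np.sqrt(((p - q) ** 2).sum()))


def _chebyshev(p, q, w, eps):
    return float(np.abs(p - q).max())


def _canberra(p, q, w, eps):
    s = p + q
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(s > 0, np.abs(p - q) / np.where(s > 0, s, 1.0), 0.0)
    return float(terms.sum())


def _intersection(p, q, w, eps):
    return float(1.0 - np.minimum(p, q).sum())


def _cosine(p, q, w, eps):
    denom = np.linalg.norm(p) * np.linalg.norm(q)
    if denom == 0:
        return 0.0
    # clip to kill tiny negative round-off at identity
    return float(max(1.0 - float(p @ q) / denom, 0.0))


def _squared_euclidean(p, q, w, eps):
    return float(((p - q) ** 2).sum())


def _squared_chi2(p, q, w, eps):
    s = p + q
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(s > 0, (p - q) ** 2 / np.where(s > 0, s, 1.0), 0.0)
    return float(terms.sum())


def _bhattacharyya_coefficient(p, q):
    return float(np.sqrt(p * q).sum())


def _hellinger(p, q, w, eps):
    # sqrt(1 - BC) in the numerically stable form 0.5*sum((sqrt p - sqrt q)^2),
    # which is exactly zero at p == q
    h2 = 0.5 * ((np.sqrt(p) - np.sqrt(q)) ** 2).sum()
    return float(math.sqrt(min(max(h2, 0.0), 1.0)))


def _hellinger_scaled(p, q, w, eps):
    return math.sqrt(2.0) * _hellinger(p, q, w, eps)


def _bhattacharyya(p, q, w, eps):
    bc = _bhattacharyya_coefficient(p, q)
    if bc <= 0:
        return math.inf
    return float(-math.log(min(bc, 1.0)))


def _jeffreys(p, q, w, eps):
    ps = p + eps
    ps = ps / ps.sum()
    qs = q + eps
    qs = qs / qs.sum()
    return float(((ps - qs) * np.log(ps / qs)).sum())


def _jensen_shannon(p, q, w, eps):
    m = 0.5 * (p + q)
    with np.errstate(invalid="ignore", divide="ignore"):
        kl_p = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0) / m), 0.0)
        kl_q = np.where(q > 0, q * np.log2(np.where(q > 0, q, 1.0) / m), 0.0)
    js = 0.5 * kl_p.sum() + 0.5 * kl_q.sum()
    return float(math.sqrt(max(js, 0.0)))


def _emd_1d(p, q, w, eps):
    return float(w * np.abs(np.cumsum(p) - np.cumsum(q)).sum())


_REGISTRY: dict[str, MetricDescriptor] = {}


def _register(name, family, is_true_metric, upper_bound, func):
    _REGISTRY[name] = MetricDescriptor(name, family, is_true_metric,
                                       upper_bound, func)


_register("city_block", Family.MINKOWSKI, True, 2.0, _city_block)
_register("euclidean", Family.MINKOWSKI, True, math.sqrt(2.0), _euclidean)
_register("chebyshev", Family.MINKOWSKI, True, 1.0, _chebyshev)
_register("canberra", Family.INTERSECTION, False, math.inf, _canberra)
_register("intersection", Family.INTERSECTION, False, 1.0, _intersection)
_register("cosine", Family.INNER_PRODUCT, False, 1.0, _cosine)
_register("squared_euclidean", Family.SQUARED_L2, False, 2.0, _squared_euclidean)
_register("squared_chi2", Family.SQUARED_L2, False, 2.0, _squared_chi2)
_register("hellinger", Family.FIDELITY, True, 1.0, _hellinger)
_register("bhattacharyya", Family.FIDELITY, False, math.inf, _bhattacharyya)
_register("jeffreys", Family.SHANNON_ENTROPY, False, math.inf, _jeffreys)
_register("jensen_shannon", Family.SHANNON_ENTROPY, True, 1.0, _jensen_shannon)
_register("emd_1d", Family.EARTH_MOVERS, True, math.inf, _emd_1d)

#: sqrt(2)-scaled Hellinger variant, exposed but not part of the 13-roster.
HELLINGER_SCALED = MetricDescriptor(
    "hellinger_scaled", Family.FIDELITY, True, math.sqrt(2.0), _hellinger_scaled
)

TRUE_METRICS = tuple(n for n, d in _REGISTRY.items() if d.is_true_metric)


def list_metrics() -> list[MetricDescriptor]:
    """The 13 registered distance metrics, covering all seven families."""
    return list(_REGISTRY.values())


def get_metric(name: str | MetricDescriptor) -> MetricDescriptor:
    if isinstance(name, MetricDescriptor):
        return name
    if name == "hellinger_scaled":
        return HELLINGER_SCALED
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ValidationError(
            f"unknown metric {name!r}; available: {sorted(_REGISTRY)}"
        ) from None


def _check_prob_vector(v: np.ndarray, label: str) -> np.ndarray:
    v = np.asarray(v, dtype=float).ravel()
    if np.any(v < 0):
        raise ValidationError(f"{label} has negative entries")
    if abs(v.sum() - 1.0) > NORMALIZATION_TOL:
        raise ValidationError(
            f"{label} is not probability-normalized (sum={v.sum():.12g})"
        )
    return v


def compute_distance(
    p: Sequence[float],
    q: Sequence[float],
    metric: str | MetricDescriptor = "hellinger",
    eps: float = DEFAULT_EPS,
    bin_width: float = 1.0,
) -> float:
    """Distance between two probability-normalized histograms.

    ``bin_width`` only affects emd_1d, which reports transport cost in value
    units (bin units when bin_width=1). ``eps`` is the smoothing constant of
    the entropy-family metrics that need it (jeffreys).
    """
    desc = get_metric(metric)
    p = _check_prob_vector(p, "p")
    q = _check_prob_vector(q, "q")
    if p.shape != q.shape:
        raise ValidationError(f"length mismatch: {p.size} vs {q.size}")
    if eps <= 0:
        raise ValidationError("eps must be > 0")
    return desc.func(p, q, bin_width, eps)


@dataclass
class DistanceSet:
    """All within-group pairwise distances plus the contributing pairs."""

    metric: MetricDescriptor
    values: np.ndarray
    pairs: list[tuple[str, str]]
    group_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.pairs):
            raise ValidationError("values and pairs lengths differ")

    def __len__(self) -> int:
        return len(self.values)


def pairwise_distances(
    histograms: Sequence[MapHistogram],
    metric: str | MetricDescriptor = "hellinger",
    group_label: str = "",
    eps: float = DEFAULT_EPS,
) -> DistanceSet:
    """Distances between all n(n-1)/2 unordered pairs of histograms.

    All histograms must share a binning specification; the spec's bin width
    feeds emd_1d so its output is in map-value units.
    """
    if len(histograms) < 2:
        raise ValidationError("pairwise distances need at least two histograms")
    specs = {h.spec for h in histograms}
    if len(specs) != 1:
        raise ValidationError("histograms have mixed binning specifications")
    desc = get_metric(metric)
    w = histograms[0].spec.bin_width
    probs = [h.probs for h in histograms]
    ids = [h.subject_id for h in histograms]
    values, pairs = [], []
    n = len(histograms)
    for i in range(n):
        for j in range(i + 1, n):
            values.append(desc.func(probs[i], probs[j], w, eps))
            pairs.append((ids[i], ids[j]))
    return DistanceSet(metric=desc, values=np.asarray(values), pairs=pairs,
                       group_label=group_label)
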