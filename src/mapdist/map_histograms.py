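"""Cleaning FA/MD map pairs and binning maps into fixed-specification histograms.

FA maps occasionally carry non-physical values above 1.0 (a by-product of the
tensor fit in noisy voxels); those voxels are masked out of BOTH the FA map
and its companion MD map so the two histograms always describe the same voxel
population.

Histograms use a fixed specification so that every map in a cohort is binned
identically: 100 bins over (0.0, 1.0] for FA and (0.0, 0.004] mm^2/s for MD.
Bins are left-open/right-closed, so a value exactly 0.0 (background outside
the brain) is excluded and FA exactly 1.0 falls in the last bin. The
probability-normalized bin vector (counts / total binned) is the p_i every
distance metric consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import MetricMap, Modality
from .errors import EmptyHistogramError, ValidationError

N_BINS_DEFAULT = 100
FA_RANGE = (0.0, 1.0)
MD_RANGE = (0.0, 0.004)


@dataclass(frozen=True)
class HistogramSpec:
    """Binning specification: n_bins bins over the left-open interval
    (range_min, range_max]."""

    n_bins: int = N_BINS_DEFAULT
    range_min: float = 0.0
    range_max: float = 1.0
    modality: str = "FA"

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValidationError("n_bins must be >= 1")
        if not self.range_min < self.range_max:
            raise ValidationError("range_min must be < range_max")

    @classmethod
    def for_modality(cls, modality: Modality | str, n_bins: int = N_BINS_DEFAULT
                     ) -> "HistogramSpec":
        modality = Modality(modality)
        lo, hi = FA_RANGE if modality is Modality.FA else MD_RANGE
        return cls(n_bins=n_bins, range_min=lo, range_max=hi,
                   modality=modality.value)

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(self.range_min, self.range_max, self.n_bins + 1)

    @property
    def bin_width(self) -> float:
        return (self.range_max - self.range_min) / self.n_bins


@dataclass
class MapHistogram:
    """Binned, probability-normalized representation of one metric map."""

    spec: HistogramSpec
    counts: np.ndarray
    n_binned: int
    n_excluded_low: int
    n_excluded_high: int
    subject_id: str = ""

    @property
    def probs(self) -> np.ndarray:
        """counts / n_binned — the probability vector the distances consume."""
        return self.counts / self.n_binned


def clean_fa_md(fa: MetricMap, md: MetricMap) -> tuple[MetricMap, MetricMap, int]:
    """Mask out every voxel with FA > 1.0 in both the FA and MD map.

    Returns cleaned copies plus the number of voxels removed. Voxel values are
    never altered, only masks.
    """
    if fa.voxels.shape != md.voxels.shape:
        raise ValidationError(
            f"FA shape {fa.voxels.shape} != MD shape {md.voxels.shape}"
        )
    bad = (fa.voxels > 1.0) & fa.mask
    removed = int(bad.sum())
    fa_clean = MetricMap(fa.voxels.copy(), fa.modality, fa.subject_id,
                         mask=fa.mask & ~bad)
    md_clean = MetricMap(md.voxels.copy(), md.modality, md.subject_id,
                         mask=md.mask & ~bad)
    return fa_clean, md_clean, removed


def _bin_values(values: np.ndarray, spec: HistogramSpec
                ) -> tuple[np.ndarray, int, int]:
    """Bin values into (min + i*w, min + (i+1)*w]; returns (counts, low, high)."""
    values = np.asarray(values, dtype=float).ravel()
    low = int(np.sum(values <= spec.range_min))
    high = int(np.sum(values > spec.range_max))
    inside = values[(values > spec.range_min) & (values <= spec.range_max)]
    # left-open/right-closed: first edge index with edge >= v, minus one
    idx = np.searchsorted(spec.edges, inside, side="left") - 1
    counts = np.bincount(idx, minlength=spec.n_bins)
    return counts.astype(np.int64), low, high


def build_histogram(m: MetricMap, spec: HistogramSpec | None = None
                    ) -> MapHistogram:
    """Bin a map's masked-in voxels under its modality's specification.

    Values at or below range_min (background zeros included) and above
    range_max are excluded and tallied separately. Raises
    EmptyHistogramError when no voxel lands inside the range — such a map
    cannot participate in distance comparisons.
    """
    if spec is None:
        spec = HistogramSpec.for_modality(m.modality)
    elif spec.modality not in ("DISTANCE", m.modality.value):
        raise ValidationError(
            f"spec modality {spec.modality} does not match map {m.modality.value}"
        )
    counts, low, high = _bin_values(m.masked_values, spec)
    n_binned = int(counts.sum())
    if n_binned == 0:
        raise EmptyHistogramError(
            f"map {m.subject_id!r}: no voxels inside "
            f"({spec.range_min}, {spec.range_max}]"
        )
    return MapHistogram(spec=spec, counts=counts, n_binned=n_binned,
                        n_excluded_low=low, n_excluded_high=high,
                        subject_id=m.subject_id)


def normalize_histogram(h: MapHistogram, mode: str = "probability") -> np.ndarray:
    """Return normalized bin heights.

    probability: heights sum to 1 (map histograms).
    density: heights * bin_width sum to 1 (distance-metric histograms).
    """
    if h.n_binned == 0:
        raise EmptyHistogramError("cannot normalize an empty histogram")
    if mode == "probability":
        return h.probs
    if mode == "density":
        return h.probs / h.spec.bin_width
    raise ValidationError(f"unknown normalization mode {mode!r}")
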