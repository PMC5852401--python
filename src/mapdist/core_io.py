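"""Reading metric-map volumes and cohort manifests, and grouping by acquisition metadata.

The cohort manifest (CSV) is the source of truth for acquisition metadata:
vendor, static field strength, diffusion *b*-value, and number of
diffusion-sensitizing gradient directions are the keys used to assemble
groups of comparably acquired data sets. NIfTI headers carry none of these
fields, so metadata is never re-derived from the volumes themselves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ConfigError, MapFormatError, ValidationError

logger = logging.getLogger(__name__)

#: Matching tolerance for nominal vs scanner-reported field strength, tesla.
FIELD_STRENGTH_TOL = 0.05
#: Matching tolerance for nominal vs scanner-reported b-value, s/mm^2.
B_VALUE_TOL = 5.0

MANIFEST_COLUMNS = (
    "subject_id",
    "fa_path",
    "md_path",
    "vendor",
    "field_strength",
    "b_value",
    "n_directions",
)


class Modality(str, Enum):
    """Which diffusion metric a map encodes."""

    FA = "FA"
    MD = "MD"


@dataclass
class MetricMap:
    """One 3-D quantitative map volume with a voxel validity mask.

    ``voxels`` holds FA (dimensionless) or MD (mm^2/s) values; ``mask`` marks
    the voxels that participate in histogram binning. Cleaning (the FA > 1.0
    threshold with companion removal) only ever clears mask bits, never
    rewrites voxel values.
    """

    voxels: np.ndarray
    modality: Modality
    subject_id: str
    mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValidationError(
                f"MetricMap voxels must be 3-D, got shape {self.voxels.shape}"
            )
        if self.mask is None:
            self.mask = np.ones(self.voxels.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.voxels.shape:
            raise ValidationError(
                f"mask shape {self.mask.shape} != voxel shape {self.voxels.shape}"
            )
        self.modality = Modality(self.modality)

    @property
    def masked_values(self) -> np.ndarray:
        """Values of the masked-in voxels, flattened."""
        return self.voxels[self.mask]


@dataclass(frozen=True)
class AcquisitionMetadata:
    """Acquisition parameters of one data set; the grouping keys.

    Any field may be None when used as a *selection criterion*, meaning
    "no restriction on this parameter".
    """

    vendor: str | None = None
    field_strength: float | None = None
    b_value: float | None = None
    n_directions: int | None = None

    def normalized(self) -> "AcquisitionMetadata":
        v = self.vendor.strip().upper() if self.vendor is not None else None
        return replace(self, vendor=v)

    def matches(self, other: "AcquisitionMetadata") -> bool:
        """True if ``other`` satisfies every constraint set on self."""
        a, b = self.normalized(), other.normalized()
        if a.vendor is not None and a.vendor != b.vendor:
            return False
        if a.field_strength is not None and (
            b.field_strength is None
            or abs(a.field_strength - b.field_strength) > FIELD_STRENGTH_TOL
        ):
            return False
        if a.b_value is not None and (
            b.b_value is None or abs(a.b_value - b.b_value) > B_VALUE_TOL
        ):
            return False
        if a.n_directions is not None and a.n_directions != b.n_directions:
            return False
        return True


@dataclass
class CohortTable:
    """Rows of (subject_id, fa_path, md_path, metadata); subject_id unique."""

    frame: pd.DataFrame
    dropped_incomplete: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ConfigError(f"cohort table missing columns: {missing}")
        dupes = self.frame["subject_id"][self.frame["subject_id"].duplicated()]
        if len(dupes):
            raise ValidationError(
                f"duplicate subject_ids in cohort: {sorted(set(dupes))}"
            )
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.frame["subject_id"])

    def metadata_for(self, subject_id: str) -> AcquisitionMetadata:
        row = self.frame[self.frame["subject_id"] == subject_id]
        if row.empty:
            raise ValidationError(f"unknown subject_id {subject_id!r}")
        r = row.iloc[0]
        return AcquisitionMetadata(
            vendor=str(r["vendor"]),
            field_strength=float(r["field_strength"]),
            b_value=float(r["b_value"]),
            n_directions=int(r["n_directions"]),
        )

    def iter_rows(self) -> Iterable[pd.Series]:
        for _, row in self.frame.iterrows():
            yield row


def read_metric_map(path: str | Path, modality: Modality | str) -> MetricMap:
    """Read a 3-D NIfTI metric map; 4-D with a singleton last axis is squeezed.

    The subject id defaults to the file stem (``.nii``/``.nii.gz`` stripped).
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj, dtype=float)
    except Exception as exc:  # nibabel raises several types for bad files
        raise MapFormatError(f"could not read NIfTI volume {path}: {exc}") from exc
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise MapFormatError(
            f"{path} has shape {data.shape}; a metric map must be a single 3-D volume"
        )
    stem = path.name
    for suffix in (".gz", ".nii"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
    return MetricMap(voxels=data, modality=Modality(modality), subject_id=stem)


def write_metric_map(m: MetricMap, path: str | Path) -> None:
    """Write a metric map as NIfTI with an identity affine."""
    img = nib.Nifti1Image(m.voxels.astype(np.float64), affine=np.eye(4))
    nib.save(img, str(path))


def load_cohort(manifest_path: str | Path) -> CohortTable:
    """Load a cohort manifest CSV.

    Rows lacking an FA or MD path are dropped (both metrics are required for
    companion cleaning) and the drop count is logged and recorded on the table.
    """
    frame = pd.read_csv(manifest_path, dtype={"subject_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in frame.columns]
    if missing:
        raise ConfigError(
            f"manifest {manifest_path} missing required columns: {missing}"
        )
    ok = frame["fa_path"].notna() & (frame["fa_path"].astype(str).str.len() > 0)
    ok &= frame["md_path"].notna() & (frame["md_path"].astype(str).str.len() > 0)
    dropped = int((~ok).sum())
    if dropped:
        logger.info(
            "dropped %d manifest rows lacking an FA or MD path", dropped
        )
    return CohortTable(frame=frame[ok].copy(), dropped_incomplete=dropped)


def select_group(
    cohort: CohortTable, criteria: AcquisitionMetadata | Mapping[str, object]
) -> CohortTable:
    """Subset a cohort to the rows matching every specified criterion.

    Unspecified (None) criteria are unconstrained. Vendor matching is
    case-insensitive; field strength and b-value match within tolerance
    (0.05 T, 5 s/mm^2) to absorb scanner-reported nominal-vs-actual jitter.
    """
    if not isinstance(criteria, AcquisitionMetadata):
        criteria = AcquisitionMetadata(**dict(criteria))
    keep = [
        criteria.matches(cohort.metadata_for(sid)) for sid in cohort.subject_ids
    ]
    sub = cohort.frame[np.asarray(keep, dtype=bool)].copy()
    return CohortTable(frame=sub)


def tabulate_composition(cohort: CohortTable) -> pd.DataFrame:
    """Cohort composition: (vendor, field_strength, b_value) rows by
    n_directions columns, integer counts. Cell counts sum to the cohort size."""
    if len(cohort) == 0:
        raise ValidationError("cannot tabulate an empty cohort")
    f = cohort.frame.copy()
    f["vendor"] = f["vendor"].astype(str).str.strip().str.upper()
    table = pd.pivot_table(
        f,
        index=["vendor", "field_strength", "b_value"],
        columns="n_directions",
        values="subject_id",
        aggfunc="count",
        fill_value=0,
    )
    table = table.astype(int)
    table.columns = [int(c) for c in table.columns]
    return table[sorted(table.columns)]
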