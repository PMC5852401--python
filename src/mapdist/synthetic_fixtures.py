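"""Seeded generators for FA/MD-like volumes, artifact injection, cohorts, and
radiology-report corpora.

Real diffusion metric maps are not required anywhere in the package: the
generators emulate the *distributional* shape of FA and MD maps — a bimodal
FA histogram (gray- and white-matter peaks) and a right-tailed MD histogram
(CSF component near 3e-3 mm^2/s) over a background of exact zeros — rather
than anatomy. A three-component truncated-normal tissue mixture is enough
because every downstream computation consumes only the map-value histogram.

Within-group variability is modeled at two levels, mirroring what a
selected acquisition-parameter group in a clinical archive actually
contains:

* three deterministic *protocol variants* (minor protocol revisions, coil or
  software differences) offset along four axes — a global FA shift, a global
  FA peak-width factor, a global MD shift, and a global MD width factor;
* continuous per-subject scatter around the subject's variant on the same
  axes, drawn uniformly.

This layered structure reproduces two properties of curated clinical
cohorts: the pairwise-distance distribution is right-skewed but compact
(its upper whisker exceeds the largest natural distance, so no clean data
set looks like an outlier), and between-group contrasts scale with the
``jitter_scale`` knob that turns a homogeneous group into a
heterogeneous (mixed-protocol-like) one.

Artifact injection covers four failure modes seen in clinical archives:
a global intensity offset, inflated noise, corrupted slices (whose broken
tensor fits show the classic spuriously-high-FA / implausibly-low-MD
signature), and a shifted field of view replacing part of the volume with
non-brain, high-MD anatomy.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .cohort_filters import ReportRecord, default_terms
from .core_io import (
    AcquisitionMetadata,
    CohortTable,
    MetricMap,
    Modality,
    write_metric_map,
)
from .errors import ValidationError

MD_MAX = 0.004  # mm^2/s, upper histogram limit for MD

#: Half-widths of the four protocol/subject variability axes at
#: jitter_scale 1: FA global shift (dimensionless), FA log peak-width,
#: MD global shift (mm^2/s), MD log peak-width.
JITTER_HALFWIDTH = (0.03, 0.12, 6e-5, 0.10)

#: Deterministic protocol-variant offsets, as fractions of the axis
#: half-widths. Fixed per group (a protocol revision is a property of the
#: acquisition setup, not a random draw per cohort).
VARIANT_PATTERN = (
    (0.0, 0.0, 0.0, 0.0),
    (0.67, -0.67, 0.67, -0.67),
    (-0.67, 0.67, -0.67, 0.67),
)

#: Subject-level scatter, as a fraction of the axis half-widths.
SUBJECT_SCATTER = 0.33


@dataclass(frozen=True)
class TissueComponent:
    label: str
    fraction: float
    fa_mean: float
    fa_sd: float
    md_mean: float  # mm^2/s
    md_sd: float


@dataclass(frozen=True)
class TissueModel:
    """Mixture of tissue components plus a background of exact zeros."""

    components: tuple[TissueComponent, ...]
    background_fraction: float

    def __post_init__(self) -> None:
        total = sum(c.fraction for c in self.components) + self.background_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"component fractions + background must sum to 1, got {total}"
            )

    @staticmethod
    def default() -> "TissueModel":
        return TissueModel(
            components=(
                TissueComponent("WM", 0.40, fa_mean=0.45, fa_sd=0.12,
                                md_mean=0.75e-3, md_sd=0.15e-3),
                TissueComponent("GM", 0.35, fa_mean=0.15, fa_sd=0.05,
                                md_mean=0.90e-3, md_sd=0.18e-3),
                TissueComponent("CSF", 0.10, fa_mean=0.08, fa_sd=0.03,
                                md_mean=3.0e-3, md_sd=0.40e-3),
            ),
            background_fraction=0.15,
        )


@dataclass(frozen=True)
class ArtifactSpec:
    """One injected failure mode.

    kind:
      intensity_offset — add ``magnitude`` to every tissue FA voxel (may push
        FA above 1.0, exercising the cleaning threshold);
      noise_inflation — scale each tissue voxel's deviation from the tissue
        mean by ``magnitude`` in both maps;
      slice_corruption — replace ``affected_fraction`` of axial slices with
        broken-tensor-fit values (FA uniform on (0.65, 1.0), MD uniform on
        (0.05e-3, 0.45e-3) — the high-anisotropy, low-diffusivity signature
        of fits run on scrambled diffusion volumes);
      extra_anatomy — a shifted field of view: ``affected_fraction`` of
        voxels are replaced by non-brain anatomy with MD centered at
        ``magnitude`` mm^2/s and cord-like FA on (0.3, 0.7).
    """

    kind: str
    magnitude: float
    affected_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.magnitude <= 0:
            raise ValidationError("artifact magnitude must be > 0")
        if not (0 < self.affected_fraction <= 1):
            raise ValidationError("affected_fraction must be in (0, 1]")


#: Severe, clearly visible instances of each failure mode — the kind of gross
#: corruption the iterative tail procedure is meant to catch.
SEVERE_ARTIFACTS: dict[str, ArtifactSpec] = {
    "intensity_offset": ArtifactSpec("intensity_offset", magnitude=0.2),
    "noise_inflation": ArtifactSpec("noise_inflation", magnitude=4.0),
    "slice_corruption": ArtifactSpec("slice_corruption", magnitude=1.0,
                                     affected_fraction=0.5),
    "extra_anatomy": ArtifactSpec("extra_anatomy", magnitude=2.0e-3,
                                  affected_fraction=0.6),
}


def _trunc_draw(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _apply_axis_offsets(model: TissueModel, fa_shift: float, fa_log_width: float,
                        md_shift: float, md_log_width: float) -> TissueModel:
    comps = tuple(
        replace(
            c,
            fa_mean=float(np.clip(c.fa_mean + fa_shift, 0.02, 0.95)),
            fa_sd=float(c.fa_sd * np.exp(fa_log_width)),
            md_mean=float(np.clip(c.md_mean + md_shift, 1e-4, MD_MAX - 1e-4)),
            md_sd=float(c.md_sd * np.exp(md_log_width)),
        )
        for c in model.components
    )
    return TissueModel(components=comps,
                       background_fraction=model.background_fraction)


def perturb_model(model: TissueModel, rng: np.random.Generator,
                  jitter_scale: float = 1.0) -> TissueModel:
    """Continuous random variant of a tissue model: uniform draws on the four
    variability axes, each within ``jitter_scale`` times its half-width."""
    offsets = [rng.uniform(-h, h) * jitter_scale for h in JITTER_HALFWIDTH]
    return _apply_axis_offsets(model, *offsets)


def protocol_variants(model: TissueModel, jitter_scale: float = 1.0
                      ) -> list[TissueModel]:
    """The deterministic protocol-variant models of a group."""
    out = []
    for pattern in VARIANT_PATTERN:
        offsets = [f * h * jitter_scale
                   for f, h in zip(pattern, JITTER_HALFWIDTH)]
        out.append(_apply_axis_offsets(model, *offsets))
    return out


def generate_fa_md_volume(
    model: TissueModel | None = None,
    shape: tuple[int, int, int] = (16, 16, 16),
    seed: int = 0,
    subject_id: str = "synthetic",
) -> tuple[MetricMap, MetricMap]:
    """One coupled FA/MD volume pair drawn from a tissue mixture.

    Voxels are assigned to components in exact proportion to the model
    fractions (positions randomized); FA is drawn from a per-component
    truncated normal on [0, 1] and MD on (0, 0.004], with the component
    assignment shared voxelwise between the two maps. Background voxels are
    exactly zero in both.
    """
    model = model or TissueModel.default()
    if any(s < 4 for s in shape):
        raise ValidationError("each volume dimension must be >= 4")
    rng = np.random.default_rng(seed)
    n = int(np.prod(shape))
    counts = [int(round(c.fraction * n)) for c in model.components]
    while sum(counts) > n:
        counts[int(np.argmax(counts))] -= 1
    labels = np.full(n, -1, dtype=int)  # -1 = background
    order = rng.permutation(n)
    start = 0
    for idx, c in enumerate(counts):
        labels[order[start:start + c]] = idx
        start += c
    fa = np.zeros(n)
    md = np.zeros(n)
    for idx, comp in enumerate(model.components):
        sel = labels == idx
        k = int(sel.sum())
        if k == 0:
            continue
        fa[sel] = _trunc_draw(rng, comp.fa_mean, comp.fa_sd, 0.0, 1.0, k)
        md[sel] = _trunc_draw(rng, comp.md_mean, comp.md_sd,
                              np.finfo(float).tiny, MD_MAX, k)
    fa_map = MetricMap(fa.reshape(shape), Modality.FA, subject_id)
    md_map = MetricMap(md.reshape(shape), Modality.MD, subject_id)
    return fa_map, md_map


def inject_artifact(
    fa: MetricMap,
    md: MetricMap,
    spec: ArtifactSpec,
    seed: int = 0,
) -> tuple[MetricMap, MetricMap]:
    """Return copies of the map pair with one artifact injected."""
    rng = np.random.default_rng(seed)
    fa_v = fa.voxels.copy()
    md_v = md.voxels.copy()
    tissue = fa_v > 0
    if spec.kind == "intensity_offset":
        fa_v[tissue] += spec.magnitude
    elif spec.kind == "noise_inflation":
        for v in (fa_v, md_v):
            m = v[tissue].mean()
            v[tissue] = m + spec.magnitude * (v[tissue] - m)
        np.clip(fa_v, 0.0, None, out=fa_v)
        np.clip(md_v, 0.0, None, out=md_v)
    elif spec.kind == "slice_corruption":
        nz = fa_v.shape[2]
        k = max(1, int(round(spec.affected_fraction * nz)))
        slices = rng.choice(nz, size=k, replace=False)
        for s in slices:
            fa_v[:, :, s] = rng.uniform(0.65, 1.0, fa_v.shape[:2])
            md_v[:, :, s] = rng.uniform(0.05e-3, 0.45e-3, md_v.shape[:2])
    elif spec.kind == "extra_anatomy":
        n = fa_v.size
        k = max(1, int(round(spec.affected_fraction * n)))
        sel = rng.choice(n, size=k, replace=False)
        md_flat, fa_flat = md_v.ravel(), fa_v.ravel()
        md_flat[sel] = _trunc_draw(rng, spec.magnitude, 0.3e-3,
                                   np.finfo(float).tiny, MD_MAX, k)
        fa_flat[sel] = rng.uniform(0.3, 0.7, k)
        md_v = md_flat.reshape(md_v.shape)
        fa_v = fa_flat.reshape(fa_v.shape)
    else:
        raise ValidationError(f"unknown artifact kind {spec.kind!r}")
    return (
        MetricMap(fa_v, Modality.FA, fa.subject_id, mask=fa.mask.copy()),
        MetricMap(md_v, Modality.MD, md.subject_id, mask=md.mask.copy()),
    )


def simulate_group(
    n: int,
    model: TissueModel | None = None,
    shape: tuple[int, int, int] = (32, 32, 32),
    seed: int = 0,
    jitter_scale: float = 1.0,
    id_prefix: str = "sub",
    start_index: int = 0,
) -> list[tuple[MetricMap, MetricMap]]:
    """In-memory cohort group: n coupled FA/MD pairs.

    Subjects are assigned round-robin to the group's deterministic protocol
    variants and receive continuous per-subject scatter
    (``SUBJECT_SCATTER`` times the axis half-widths) around their variant.
    """
    model = model or TissueModel.default()
    rng = np.random.default_rng(seed)
    variants = protocol_variants(model, jitter_scale)
    out = []
    for i in range(n):
        base = variants[i % len(variants)]
        subj = perturb_model(base, rng, jitter_scale * SUBJECT_SCATTER)
        subj_seed = int(rng.integers(0, 2**31 - 1))
        out.append(generate_fa_md_volume(
            subj, shape, subj_seed,
            subject_id=f"{id_prefix}{start_index + i:03d}"))
    return out


def generate_cohort(
    group_specs: Sequence[Mapping],
    out_dir: str | Path,
    artifact_ids: Mapping[str, ArtifactSpec] | None = None,
    seed: int = 0,
    shape: tuple[int, int, int] = (32, 32, 32),
) -> tuple[CohortTable, Path, Path]:
    """Write a synthetic cohort to disk: NIfTI volumes, manifest CSV, and a
    ground-truth sidecar JSON.

    Each group spec is {"metadata": AcquisitionMetadata or dict, "n": int,
    optional "model": TissueModel, optional "jitter_scale": float}.
    ``artifact_ids`` maps subject ids (assigned as sub000, sub001, ... across
    groups in order) to the ArtifactSpec injected into that subject's maps.
    Returns (cohort table, manifest path, truth path).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifact_ids = dict(artifact_ids or {})
    rng = np.random.default_rng(seed)
    rows = []
    truth: dict = {"groups": {}, "artifacts": {}}
    counter = 0
    total = sum(int(g["n"]) for g in group_specs)
    if total < 2:
        raise ValidationError("cohort needs at least 2 data sets")
    for gi, g in enumerate(group_specs):
        meta = g["metadata"]
        if not isinstance(meta, AcquisitionMetadata):
            meta = AcquisitionMetadata(**dict(meta))
        model = g.get("model") or TissueModel.default()
        jitter = float(g.get("jitter_scale", 1.0))
        group_seed = int(rng.integers(0, 2**31 - 1))
        pairs = simulate_group(int(g["n"]), model, shape, group_seed, jitter,
                               start_index=counter)
        for fa, md in pairs:
            sid = fa.subject_id
            counter += 1
            if sid in artifact_ids:
                spec = artifact_ids[sid]
                fa, md = inject_artifact(fa, md, spec,
                                         int(rng.integers(0, 2**31 - 1)))
                truth["artifacts"][sid] = {
                    "kind": spec.kind, "magnitude": spec.magnitude,
                    "affected_fraction": spec.affected_fraction,
                }
            fa_path = out_dir / f"{sid}_fa.nii.gz"
            md_path = out_dir / f"{sid}_md.nii.gz"
            write_metric_map(fa, fa_path)
            write_metric_map(md, md_path)
            truth["groups"][sid] = gi
            rows.append({
                "subject_id": sid, "fa_path": str(fa_path),
                "md_path": str(md_path), "vendor": meta.vendor,
                "field_strength": meta.field_strength,
                "b_value": meta.b_value, "n_directions": meta.n_directions,
            })
    unknown = set(artifact_ids) - set(truth["groups"])
    if unknown:
        raise ValidationError(f"artifact_ids not in cohort: {sorted(unknown)}")
    manifest = pd.DataFrame(rows)
    manifest_path = out_dir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    truth_path = out_dir / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=2))
    return CohortTable(frame=manifest), manifest_path, truth_path


_NEUTRAL_SENTENCES = (
    "The ventricles are of expected size and configuration.",
    "Gray-white differentiation is preserved.",
    "The examination was performed with standard technique.",
    "Diffusion weighted images were obtained.",
    "The study is of good diagnostic quality.",
)

_NEGATED_TEMPLATES = (
    "No {term} was identified.",
    "There is no evidence of {term}.",
    "Negative for {term}.",
    "Study without {term} or other acute finding.",
)

_UNNEGATED_TEMPLATES = (
    "There is {term} in the left frontal lobe.",
    "Findings suggestive of {term}.",
    "A region of {term} is seen adjacent to the ventricle.",
)

_SURGICAL_TEMPLATES = (
    "Patient is status post {term}.",
    "Changes of prior {term} are seen.",
)


def generate_reports(
    n: int, pathology_fraction: float = 0.3, seed: int = 0
) -> list[tuple[ReportRecord, bool]]:
    """Templated synthetic radiology reports with ground-truth keep labels.

    With probability ``pathology_fraction`` a report carries a rejecting
    sentence (a surgical-history mention or an unnegated pathology finding);
    otherwise it is keepable (neutral sentences, possibly with an in-sentence
    negated pathology mention). Labels follow from the templates by
    construction, independently of the filter implementation.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    if not (0 <= pathology_fraction <= 1):
        raise ValidationError("pathology_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    terms = default_terms()
    out: list[tuple[ReportRecord, bool]] = []
    for i in range(n):
        sentences = list(rng.choice(_NEUTRAL_SENTENCES,
                                    size=rng.integers(1, 3), replace=False))
        reject = rng.random() < pathology_fraction
        if reject:
            if rng.random() < 0.4:
                term = str(rng.choice(terms["surgical_terms"]))
                sentences.append(
                    str(rng.choice(_SURGICAL_TEMPLATES)).format(term=term))
            else:
                term = str(rng.choice(terms["pathology_terms"]))
                sentences.append(
                    str(rng.choice(_UNNEGATED_TEMPLATES)).format(term=term))
        elif rng.random() < 0.5:
            term = str(rng.choice(terms["pathology_terms"]))
            sentences.append(
                str(rng.choice(_NEGATED_TEMPLATES)).format(term=term))
        rng.shuffle(sentences)
        text = " ".join(sentences)
        out.append((ReportRecord(report_id=f"rep{i:04d}", text=text),
                    not reject))
    return out
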