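"""Cohort curation filters for clinical diffusion data.

Three gates stand between a raw clinical archive and a usable cohort:

1. ``filter_report`` — a two-step, negation-aware screen of free-text
   radiology reports. Step one rejects any report naming a surgical
   intervention. Step two rejects reports where a pathology term appears in a
   sentence containing no negation cue; a negated mention ("No tumor was
   identified") is allowed to pass.
2. ``filter_series_tags`` — identifies diffusion-weighted series from DICOM
   tag value strings by exclude/include substring lists.
3. ``validate_gradient_table`` — rejects gradient tables that cannot support
   a tensor fit: fewer than six non-zero b-values, b-value/direction count
   mismatch, an all-zero direction paired with a non-zero b-value, or a
   negative b-value.

All matching is case-insensitive. Report terms match on word boundaries
(multi-word terms as phrases) so that, e.g., the negation cue "no" never
fires inside "normal". Series-tag matching is plain substring matching —
deliberately permissive, mirroring archive practice of casting a wide net
for diffusion series and pruning later.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .errors import ConfigError, ValidationError

_SENTENCE_SPLIT = re.compile(r"[.!?](?:\s+|$)")


def default_terms() -> dict[str, list[str]]:
    """The packaged default curation vocabulary (deep copy, safe to edit)."""
    text = resources.files("mapdist.data").joinpath("filter_terms.yaml").read_text()
    return yaml.safe_load(text)


@dataclass(frozen=True)
class ReportRecord:
    report_id: str
    text: str


@dataclass(frozen=True)
class SeriesTagRecord:
    series_id: str
    tag_values: tuple[str, ...]


@dataclass
class GradientTable:
    """FSL-style gradient table: one b-value per diffusion volume plus the
    matching unit (or zero, for b=0) direction vectors."""

    b_values: list[float]
    directions: list[tuple[float, float, float]]


@dataclass(frozen=True)
class FilterVerdict:
    kept: bool
    reason: str = ""
    matched_term: str = ""

    def __post_init__(self) -> None:
        if not self.kept and not self.reason:
            raise ValidationError("a rejecting verdict must carry a reason")


def _term_pattern(term: str) -> re.Pattern[str]:
    # Whole-word / whole-phrase match; internal whitespace matches any run.
    escaped = r"\s+".join(re.escape(w) for w in term.split())
    return re.compile(rf"(?<!\w){escaped}(?!\w)", re.IGNORECASE)


def split_sentences(text: str) -> list[str]:
    """Split on '.', '!' or '?' followed by whitespace or end of text."""
    parts = [s.strip() for s in _SENTENCE_SPLIT.split(text)]
    return [s for s in parts if s]


def filter_report(
    report: ReportRecord,
    surgical_terms: Sequence[str] | None = None,
    pathology_terms: Sequence[str] | None = None,
    negation_terms: Sequence[str] | None = None,
) -> FilterVerdict:
    """Two-step negation-aware report screen; see module docstring.

    Defaults come from the packaged vocabulary. An empty report is kept
    (nothing to object to).
    """
    terms = default_terms()
    surgical = list(surgical_terms or terms["surgical_terms"])
    pathology = list(pathology_terms or terms["pathology_terms"])
    negation = list(negation_terms or terms["negation_terms"])
    if not (surgical and pathology and negation):
        raise ConfigError("term lists must be non-empty")

    # Step 1: any surgical term anywhere rejects outright.
    for term in surgical:
        if _term_pattern(term).search(report.text):
            return FilterVerdict(False, "surgical_term", term)

    # Step 2: a pathology term with no negation cue in the same sentence.
    negation_pats = [_term_pattern(t) for t in negation]
    for sentence in split_sentences(report.text):
        for term in pathology:
            if _term_pattern(term).search(sentence):
                if not any(p.search(sentence) for p in negation_pats):
                    return FilterVerdict(False, "pathology_unnegated", term)
    return FilterVerdict(True)


def filter_series_tags(
    record: SeriesTagRecord,
    exclude_strings: Sequence[str] | None = None,
    include_strings: Sequence[str] | None = None,
) -> FilterVerdict:
    """Keep a series iff no tag value contains an exclude string and at least
    one tag value contains an include string (case-insensitive substrings)."""
    terms = default_terms()
    exclude = list(exclude_strings if exclude_strings is not None
                   else terms["series_exclude_strings"])
    include = list(include_strings if include_strings is not None
                   else terms["series_include_strings"])
    if any(not s for s in include):
        raise ConfigError("include strings must be non-empty")
    values = [v.lower() for v in record.tag_values]
    for ex in exclude:
        exl = ex.lower()
        if any(exl in v for v in values):
            return FilterVerdict(False, "excluded_string", ex)
    for inc in include:
        incl = inc.lower()
        if any(incl in v for v in values):
            return FilterVerdict(True, matched_term=inc)
    return FilterVerdict(False, "no_include_match")


def validate_gradient_table(gt: GradientTable) -> FilterVerdict:
    """Apply the gradient-table validity rules; returns a verdict, never raises
    for bad tables (absence of the files is an upstream rejection)."""
    b = list(gt.b_values)
    dirs = list(gt.directions)
    if len(b) != len(dirs):
        return FilterVerdict(False, "count_mismatch")
    if any(x < 0 for x in b):
        return FilterVerdict(False, "negative_bvalue")
    n_nonzero = sum(1 for x in b if x != 0)
    if n_nonzero < 6:
        return FilterVerdict(False, "too_few_directions")
    for x, d in zip(b, dirs):
        if x > 0 and all(c == 0 for c in d):
            return FilterVerdict(False, "zero_vector")
    return FilterVerdict(True)


def read_gradient_table(bval_path: str | Path, bvec_path: str | Path) -> GradientTable:
    """Read FSL bval/bvec text files (one row of b-values; three rows of
    x/y/z direction components)."""
    b = np.loadtxt(bval_path, ndmin=1).ravel().tolist()
    vec = np.loadtxt(bvec_path, ndmin=2)
    if vec.shape[0] != 3:
        if vec.shape[1] == 3:  # tolerate transposed layout
            vec = vec.T
        else:
            raise ConfigError(
                f"bvec file {bvec_path} must have three rows (x, y, z)"
            )
    directions = [tuple(float(c) for c in col) for col in vec.T]
    return GradientTable(b_values=[float(x) for x in b], directions=directions)
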