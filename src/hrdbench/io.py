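"""Reading, validation and writing of cohort tables.

Two tab-separated inputs drive the pipeline:

``cohort.tsv``
    One row per tumor with columns ``sample_id``, ``cancer_type``,
    ``chord_score``, ``hrdetect_score``. Scores are HRD probabilities
    in [0, 1] emitted by the published classifiers; cancer-type labels
    are free text (lower-cased on ingest) so cohorts beyond breast /
    ovary / pancreas are accepted.

``alterations.tsv``
    One row per gene hit per tumor with columns ``sample_id``, ``gene``,
    ``hit_class``. A sample may carry several hits in one gene (e.g. a
    germline pathogenic variant plus LOH); every row is kept — hits are
    collapsed to per-gene multisets only at labeling time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

COHORT_COLUMNS = ("sample_id", "cancer_type", "chord_score", "hrdetect_score")
ALTERATION_COLUMNS = ("sample_id", "gene", "hit_class")

CLASSIFIERS = ("chord", "hrdetect")


class HitClass(str, Enum):
    """The five recognised kinds of gene hits."""

    GERMLINE_PV = "germline_pv"
    SOMATIC_MUTATION = "somatic_mutation"
    LOH = "loh"
    PROMOTER_METHYLATION = "promoter_methylation"
    DEEP_DELETION = "deep_deletion"


_HIT_TOKENS = {m.value: m for m in HitClass}


class CohortFormatError(ValueError):
    """Structural problem with an input table (missing columns etc.)."""


class CohortValidationError(ValueError):
    """A row violates an invariant (score range, unknown enum token)."""


@dataclass(frozen=True)
class SampleRecord:
    """One tumor: identifier, cancer type, and both classifier scores."""

    sample_id: str
    cancer_type: str
    chord_score: float
    hrdetect_score: float

    def score(self, classifier: str) -> float:
        if classifier == "chord":
            return self.chord_score
        if classifier == "hrdetect":
            return self.hrdetect_score
        raise KeyError(f"unknown classifier {classifier!r}")


@dataclass(frozen=True)
class AlterationRecord:
    """One gene hit in one tumor."""

    sample_id: str
    gene: str
    hit_class: HitClass


@dataclass
class ValidationReport:
    """Cohort-level diagnostics; empty iff the paired tables are clean."""

    duplicate_sample_ids: list[str] = field(default_factory=list)
    orphan_alterations: list[str] = field(default_factory=list)
    score_violations: list[str] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not (
            self.duplicate_sample_ids
            or self.orphan_alterations
            or self.score_violations
        )

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [("duplicate_sample_id", s) for s in self.duplicate_sample_ids]
            + [("orphan_alteration", s) for s in self.orphan_alterations]
            + [("score_violation", s) for s in self.score_violations]
        )
        return pd.DataFrame(rows, columns=["issue", "detail"])


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortFormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )


def read_cohort(path: str | Path) -> list[SampleRecord]:
    """Read ``cohort.tsv`` into sample records, preserving row order.

    Raises :class:`CohortFormatError` for a missing column and
    :class:`CohortValidationError` (with the 1-based data-row number)
    for a non-numeric or out-of-range score.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    _require_columns(df, COHORT_COLUMNS, path)
    records: list[SampleRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        scores = {}
        for col in ("chord_score", "hrdetect_score"):
            raw = getattr(row, col)
            try:
                val = float(raw)
            except (TypeError, ValueError):
                raise CohortValidationError(
                    f"{path}: row {i}: {col} {raw!r} is not a number"
                ) from None
            if not (0.0 <= val <= 1.0):
                raise CohortValidationError(
                    f"{path}: row {i}: {col} {val} outside [0, 1]"
                )
            scores[col] = val
        records.append(
            SampleRecord(
                sample_id=str(row.sample_id),
                cancer_type=str(row.cancer_type).strip().lower(),
                chord_score=scores["chord_score"],
                hrdetect_score=scores["hrdetect_score"],
            )
        )
    return records


def read_alterations(path: str | Path) -> list[AlterationRecord]:
    """Read ``alterations.tsv``; hit_class tokens match case-insensitively."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ALTERATION_COLUMNS, path)
    records: list[AlterationRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        token = str(row.hit_class).strip().lower()
        if token not in _HIT_TOKENS:
            raise CohortValidationError(
                f"{path}: row {i}: unknown hit_class {row.hit_class!r}; "
                f"allowed: {', '.join(sorted(_HIT_TOKENS))}"
            )
        records.append(
            AlterationRecord(
                sample_id=str(row.sample_id),
                gene=str(row.gene).strip(),
                hit_class=_HIT_TOKENS[token],
            )
        )
    return records


def validate_cohort(
    samples: Iterable[SampleRecord], alterations: Iterable[AlterationRecord]
) -> ValidationReport:
    """Cross-check the paired tables; never raises — issues go in the report."""
    report = ValidationReport()
    seen: set[str] = set()
    for s in samples:
        if s.sample_id in seen:
            report.duplicate_sample_ids.append(s.sample_id)
        seen.add(s.sample_id)
        for col in ("chord_score", "hrdetect_score"):
            val = getattr(s, col)
            if not (0.0 <= val <= 1.0):
                report.score_violations.append(f"{s.sample_id}:{col}={val}")
    for a in alterations:
        if a.sample_id not in seen:
            report.orphan_alterations.append(f"{a.sample_id}:{a.gene}")
    return report


def samples_to_frame(samples: Iterable[SampleRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.sample_id, s.cancer_type, s.chord_score, s.hrdetect_score) for s in samples],
        columns=list(COHORT_COLUMNS),
    )


def alterations_to_frame(alterations: Iterable[AlterationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(a.sample_id, a.gene, a.hit_class.value) for a in alterations],
        columns=list(ALTERATION_COLUMNS),
    )


def write_cohort(samples: Iterable[SampleRecord], path: str | Path) -> None:
    samples_to_frame(samples).to_csv(path, sep="\t", index=False)


def write_alterations(alterations: Iterable[AlterationRecord], path: str | Path) -> None:
    alterations_to_frame(alterations).to_csv(path, sep="\t", index=False)
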