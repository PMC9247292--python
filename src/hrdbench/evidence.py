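"""Biallelic/monoallelic inactivation calls from per-gene hit sets.

A tumor is treated as truly HR-deficient when at least one HR-related
gene carries biallelic inactivation, i.e. both copies are disabled:

* germline pathogenic variant plus a second hit (LOH or somatic mutation),
* a somatic mutation plus a second hit (LOH or another somatic mutation),
* promoter hypermethylation plus a second hit (somatic mutation or LOH),
* a somatic homozygous (deep) deletion, which is intrinsically biallelic.

A single hit that is a mutation (germline or somatic) is monoallelic;
LOH alone, or promoter methylation alone, is no call. When several rules
match the same gene the status is resolved by a fixed precedence:
deep deletion > germline > methylation > somatic > monoallelic > none.

Methylation evidence is switchable: every sample carries both an
``hrd_truth`` flag (all evidence) and an ``hrd_truth_no_meth`` flag
(promoter-methylation hits discarded before classification), emulating
cohorts in which promoter methylation was never assayed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import AlterationRecord, HitClass


class GeneStatus(str, Enum):
    BIALLELIC_DEEP_DELETION = "biallelic_deep_deletion"
    BIALLELIC_GERMLINE = "biallelic_germline"
    BIALLELIC_METHYLATION = "biallelic_methylation"
    BIALLELIC_SOMATIC = "biallelic_somatic"
    MONOALLELIC = "monoallelic"
    NONE = "none"

    @property
    def is_biallelic(self) -> bool:
        return self in _BIALLELIC


_BIALLELIC = {
    GeneStatus.BIALLELIC_DEEP_DELETION,
    GeneStatus.BIALLELIC_GERMLINE,
    GeneStatus.BIALLELIC_METHYLATION,
    GeneStatus.BIALLELIC_SOMATIC,
}

# Precedence order used when several rules match one gene.
STATUS_PRECEDENCE = (
    GeneStatus.BIALLELIC_DEEP_DELETION,
    GeneStatus.BIALLELIC_GERMLINE,
    GeneStatus.BIALLELIC_METHYLATION,
    GeneStatus.BIALLELIC_SOMATIC,
    GeneStatus.MONOALLELIC,
    GeneStatus.NONE,
)


@dataclass(frozen=True)
class SampleEvidence:
    """Per-tumor HRD-truth labels derived from its gene hits."""

    sample_id: str
    gene_evidence: Mapping[str, GeneStatus]
    hrd_truth: bool
    hrd_truth_no_meth: bool


def classify_gene(hits: Iterable[HitClass]) -> GeneStatus:
    """Resolve the hit multiset of one gene in one sample to a status.

    ``hits`` may contain repeats: two somatic-mutation rows count as two
    hits on that gene and therefore biallelic somatic inactivation.
    Total function — any combination of the five hit classes resolves.
    """
    counts = Counter(HitClass(h) for h in hits)
    n_germline = counts[HitClass.GERMLINE_PV]
    n_somatic = counts[HitClass.SOMATIC_MUTATION]
    n_loh = counts[HitClass.LOH]
    n_meth = counts[HitClass.PROMOTER_METHYLATION]

    if counts[HitClass.DEEP_DELETION]:
        return GeneStatus.BIALLELIC_DEEP_DELETION
    if n_germline and (n_loh or n_somatic):
        return GeneStatus.BIALLELIC_GERMLINE
    if n_meth and (n_somatic or n_loh):
        return GeneStatus.BIALLELIC_METHYLATION
    if n_somatic >= 2 or (n_somatic and n_loh):
        return GeneStatus.BIALLELIC_SOMATIC
    if n_germline or n_somatic:
        # a lone mutation other than LOH; methylation alone is no call
        return GeneStatus.MONOALLELIC
    return GeneStatus.NONE


def _classify_sample(
    hits_by_gene: Mapping[str, Sequence[HitClass]],
    include_methylation: bool,
) -> dict[str, GeneStatus]:
    out: dict[str, GeneStatus] = {}
    for gene, hits in hits_by_gene.items():
        if not include_methylation:
            hits = [h for h in hits if h is not HitClass.PROMOTER_METHYLATION]
        out[gene] = classify_gene(hits)
    return out


def label_sample(
    sample_id: str, alterations: Iterable[AlterationRecord]
) -> SampleEvidence:
    """Label one tumor from its alteration rows.

    Genes are classified independently; ``hrd_truth`` is true when any
    gene reaches a biallelic status, and ``hrd_truth_no_meth`` repeats
    the call with promoter-methylation hits removed first.
    """
    hits_by_gene: dict[str, list[HitClass]] = {}
    for rec in alterations:
        if rec.sample_id != sample_id:
            raise ValueError(
                f"alteration for {rec.sample_id!r} passed to label_sample({sample_id!r})"
            )
        hits_by_gene.setdefault(rec.gene, []).append(rec.hit_class)

    with_meth = _classify_sample(hits_by_gene, include_methylation=True)
    without_meth = _classify_sample(hits_by_gene, include_methylation=False)
    return SampleEvidence(
        sample_id=sample_id,
        gene_evidence=with_meth,
        hrd_truth=any(s.is_biallelic for s in with_meth.values()),
        hrd_truth_no_meth=any(s.is_biallelic for s in without_meth.values()),
    )


def label_cohort(
    sample_ids: Iterable[str], alterations: Iterable[AlterationRecord]
) -> dict[str, SampleEvidence]:
    """Label every sample in the cohort (samples without hits get all-false)."""
    by_sample: dict[str, list[AlterationRecord]] = {}
    for rec in alterations:
        by_sample.setdefault(rec.sample_id, []).append(rec)
    return {
        sid: label_sample(sid, by_sample.get(sid, []))
        for sid in sample_ids
    }


def summarize_evidence(
    evidence: Mapping[str, SampleEvidence],
    cancer_type_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Contingency counts of gene status per gene (and cancer type).

    Returns a tidy frame with columns cancer_type, gene, status, count;
    the ``none`` status is omitted (it carries no evidence).
    """
    rows: list[tuple[str, str, str]] = []
    for sid, ev in evidence.items():
        ct = cancer_type_of.get(sid, "all") if cancer_type_of else "all"
        for gene, status in ev.gene_evidence.items():
            if status is not GeneStatus.NONE:
                rows.append((ct, gene, status.value))
    df = pd.DataFrame(rows, columns=["cancer_type", "gene", "status"])
    if df.empty:
        return pd.DataFrame(columns=["cancer_type", "gene", "status", "count"])
    return (
        df.value_counts(["cancer_type", "gene", "status"])
        .rename("count")
        .reset_index()
        .sort_values(["cancer_type", "gene", "status"], ignore_index=True)
    )


def evidence_to_frame(evidence: Mapping[str, SampleEvidence]) -> pd.DataFrame:
    """Long-format evidence table: sample_id, gene, status, hrd flags."""
    rows = []
    for sid, ev in evidence.items():
        if ev.gene_evidence:
            for gene, status in ev.gene_evidence.items():
                rows.append((sid, gene, status.value, ev.hrd_truth, ev.hrd_truth_no_meth))
        else:
            rows.append((sid, "", GeneStatus.NONE.value, ev.hrd_truth, ev.hrd_truth_no_meth))
    return pd.DataFrame(
        rows, columns=["sample_id", "gene", "status", "hrd_truth", "hrd_truth_no_meth"]
    )
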