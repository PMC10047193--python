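"""Gene-disease association filtering by channel confidence score.

Evidence records (gene, DOID, disease name, channel, score) are kept
when their confidence score is strictly greater than the threshold
(default 2). A gene passing in any channel counts towards the distinct
gene total; the per-channel and per-disease breakdowns are always
reported. An optional DOID restriction filters records to one disease
identifier literally (no ontology traversal).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .datamodel import DiseaseAssociation


@dataclass
class DiseaseSummary:
    """Records passing the confidence filter, with summary counts."""

    min_score: float
    passing: list[DiseaseAssociation]
    genes: list[str] = field(default_factory=list)
    per_channel: dict[str, int] = field(default_factory=dict)
    per_disease: dict[str, int] = field(default_factory=dict)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def to_dict(self) -> dict:
        return {
            "min_score": self.min_score,
            "n_passing_records": len(self.passing),
            "n_distinct_genes": self.n_genes,
            "genes": self.genes,
            "per_channel": self.per_channel,
            "per_disease": self.per_disease,
        }


def filter_associations(
    records: list[DiseaseAssociation],
    min_score: float = 2.0,
    doid: str | None = None,
) -> DiseaseSummary:
    """Keep records with score > min_score (strict), summarize genes.

    Passing records are ordered by (score descending, gene ascending),
    so the summary is invariant to input order.
    """
    pool = records if doid is None else [r for r in records if r.disease_id == doid]
    passing = sorted(
        (r for r in pool if r.score > min_score),
        key=lambda r: (-r.score, r.gene),
    )
    genes = sorted({r.gene for r in passing})
    per_channel = Counter(r.channel for r in passing)
    per_channel.setdefault("knowledge", 0)
    per_channel.setdefault("experimental", 0)
    per_channel.setdefault("textmining", 0)
    per_disease = Counter(r.disease_id for r in passing)
    return DiseaseSummary(
        min_score=min_score,
        passing=passing,
        genes=genes,
        per_channel=dict(per_channel),
        per_disease=dict(per_disease),
    )
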