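"""Cut-off based selection of candidate proteins.

A predicted domain hit becomes a candidate when (a) its domain belongs to
the keyword-selected reference set and (b) it clears every enabled
statistical threshold. The default rule is the optimized pair of cut-offs
``coverage >= 39%`` AND ``similarity >= 24%``; residue identity, E-value and
gap-fraction thresholds are available but opt-in. Boundary values pass
(these are minimum/maximum cut-offs, compared with >= / <=).

Hits from dialects that report no residue counts carry only coverage and
E-value; they are gated on those and flagged ``partial_stats`` so the
output table records that similarity was never checked.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

from .ingest import DomainHit

__all__ = ["FilterParams", "filter_hits", "select_proteins",
           "merge_method_candidates", "MergeReport"]


@dataclass
class FilterParams:
    """The cut-off bundle gating hits into candidates.

    ``None`` disables a threshold. Defaults implement the optimized
    coverage/similarity rule (39% / 24%); identity (15%) and E-value (0.01)
    are the documented optional cut-offs.
    """

    min_coverage_pct: float | None = 39.0
    min_similarity_pct: float | None = 24.0
    min_identity_pct: float | None = None
    max_evalue: float | None = None
    max_gap_pct: float | None = None

    def __post_init__(self) -> None:
        for name in ("min_coverage_pct", "min_similarity_pct", "min_identity_pct",
                     "max_gap_pct"):
            v = getattr(self, name)
            if v is not None and not (0 <= v <= 100):
                raise ValueError(f"{name} must be within [0, 100], got {v}")
        if self.max_evalue is not None and self.max_evalue < 0:
            raise ValueError("max_evalue must be non-negative")


def _passes(hit: DomainHit, params: FilterParams) -> bool | None:
    """True/False, or None when the hit lacks the stats but clears what it has.

    Returning None signals a partial-stats pass: coverage and E-value were
    satisfied, similarity/identity could not be checked.
    """
    partial = False
    if params.min_coverage_pct is not None:
        if hit.coverage_pct is None:
            return False  # cannot vouch for coverage -> reject conservatively
        if hit.coverage_pct < params.min_coverage_pct:
            return False
    if params.max_evalue is not None:
        if hit.evalue is None or hit.evalue > params.max_evalue:
            return False
    if params.min_similarity_pct is not None:
        if hit.similarity_pct is None:
            partial = True
        elif hit.similarity_pct < params.min_similarity_pct:
            return False
    if params.min_identity_pct is not None:
        if hit.identity_pct is None:
            partial = True
        elif hit.identity_pct < params.min_identity_pct:
            return False
    if params.max_gap_pct is not None and hit.gap_pct is not None:
        if hit.gap_pct > params.max_gap_pct:
            return False
    return None if partial else True


def filter_hits(
    hits: Iterable[DomainHit],
    params: FilterParams,
    reference_set: set[str],
) -> list[DomainHit]:
    """Keep hits on reference domains that clear every enabled threshold.

    Order is preserved. Hits passing on partial statistics are flagged
    ``partial_stats`` in the returned records.
    """
    kept: list[DomainHit] = []
    for hit in hits:
        if hit.domain_id not in reference_set:
            continue
        verdict = _passes(hit, params)
        if verdict is False:
            continue
        kept.append(replace(hit, partial_stats=(verdict is None) or hit.partial_stats))
    return kept


def select_proteins(passing_hits: Iterable[DomainHit]) -> dict[str, list[DomainHit]]:
    """Group passing hits by query protein.

    Candidate proteins are those with at least one passing hit; per protein
    the hits are sorted by ascending E-value (missing E-values last), then
    descending coverage.
    """
    grouped: dict[str, list[DomainHit]] = {}
    for hit in passing_hits:
        grouped.setdefault(hit.query_id, []).append(hit)
    for hits in grouped.values():
        hits.sort(key=lambda h: (
            h.evalue if h.evalue is not None else float("inf"),
            -(h.coverage_pct if h.coverage_pct is not None else 0.0),
        ))
    return grouped


@dataclass
class MergeReport:
    """Union/intersection report for candidates from two prediction methods."""

    union: set[str]
    intersection: set[str]
    only_a: set[str]
    only_b: set[str]
    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def n_union(self) -> int:
        return len(self.union)

    @property
    def n_intersection(self) -> int:
        return len(self.intersection)


def merge_method_candidates(set_a: set[str], set_b: set[str]) -> MergeReport:
    """Merge candidate protein sets identified by two search methods.

    Combining methods raises sensitivity: proteins found by either method
    are candidates, and the intersection measures cross-method agreement.
    """
    set_a, set_b = set(set_a), set(set_b)
    inter = set_a & set_b
    provenance = {q: "both" for q in inter}
    provenance.update({q: "a" for q in set_a - inter})
    provenance.update({q: "b" for q in set_b - inter})
    return MergeReport(
        union=set_a | set_b,
        intersection=inter,
        only_a=set_a - set_b,
        only_b=set_b - set_a,
        provenance=provenance,
    )
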