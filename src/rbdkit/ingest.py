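"""Ingestion of domain-search outputs into unified hit records.

Two external dialects are supported: BLAST tabular output (extended outfmt
with ``positives`` and ``gaps`` columns, as produced by RPS-BLAST style
searches) and the standard InterProScan TSV layout. The internal profile
scanner emits hits directly as :class:`DomainHit`.

All coordinates are 1-based inclusive. The per-hit statistics used for
candidate filtering are expressed against the REFERENCE domain length:

* ``coverage_pct``  = 100 x matched reference span / reference length
* ``similarity_pct`` = 100 x positive-scoring residues / reference length
* ``identity_pct``  = 100 x identical residues / reference length
* ``gap_pct``       = 100 x gap positions / alignment length

Low coverage signals a fragmentary, likely spurious match; near-100%
coverage means the whole reference domain was found in the query.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

from .errors import CoordinateError, InputError, MalformedRecordError
from .refdomains import DomainEntry

logger = logging.getLogger(__name__)

__all__ = [
    "DomainHit",
    "parse_rpsblast_table",
    "parse_interproscan_tsv",
    "compute_hit_stats",
    "write_hits_tsv",
    "read_hits_tsv",
]

HIT_COLUMNS = [
    "query_id", "method", "domain_id", "q_start", "q_end", "s_start", "s_end",
    "aligned_length", "identical", "positive", "gaps", "evalue", "bitscore",
    "coverage_pct", "similarity_pct", "identity_pct", "gap_pct",
    "synthetic_subject_span", "partial_stats",
]


@dataclass
class DomainHit:
    """One predicted domain occurrence on a query protein.

    ``identical``/``positive``/``gaps`` may be ``None`` for dialects that do
    not report them (HMM-based searches report no positives); the derived
    percentages are then ``None`` too and the hit is flagged
    ``partial_stats`` downstream. ``synthetic_subject_span`` marks hits whose
    subject coordinates were reconstructed from the query span rather than
    reported by the search engine.
    """

    query_id: str
    method: str
    domain_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    aligned_length: int
    identical: int | None = None
    positive: int | None = None
    gaps: int | None = None
    evalue: float | None = None
    bitscore: float | None = None
    coverage_pct: float | None = None
    similarity_pct: float | None = None
    identity_pct: float | None = None
    gap_pct: float | None = None
    synthetic_subject_span: bool = False
    partial_stats: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.q_start <= self.q_end):
            raise ValueError(f"bad query span {self.q_start}..{self.q_end}")
        if not (1 <= self.s_start <= self.s_end):
            raise ValueError(f"bad subject span {self.s_start}..{self.s_end}")
        if self.aligned_length < 1:
            raise ValueError("aligned_length must be >= 1")
        if self.identical is not None and self.positive is not None:
            if not (0 <= self.identical <= self.positive <= self.aligned_length):
                raise ValueError(
                    f"counts must satisfy identical <= positive <= aligned_length "
                    f"({self.identical}, {self.positive}, {self.aligned_length})"
                )
        if self.gaps is not None and not (0 <= self.gaps <= self.aligned_length):
            raise ValueError("gaps out of range")
        if self.evalue is not None and self.evalue < 0:
            raise ValueError("evalue must be non-negative")


_RPSBLAST_COLS = 14  # qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore positives gaps


def parse_rpsblast_table(path: str | Path) -> list[DomainHit]:
    """Parse BLAST tabular output (extended outfmt 6).

    Expected columns: ``qseqid sseqid pident length mismatch gapopen qstart
    qend sstart send evalue bitscore positives gaps``. The identical-residue
    count is recovered as round(pident x length / 100).
    """
    p = Path(path)
    if not p.is_file():
        raise InputError(f"hit table not found: {p}")
    hits: list[DomainHit] = []
    for lineno, raw in enumerate(p.read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        cells = raw.rstrip("\n").split("\t")
        if len(cells) != _RPSBLAST_COLS:
            raise MalformedRecordError(
                f"expected {_RPSBLAST_COLS} columns, got {len(cells)}", line=lineno
            )
        try:
            pident = float(cells[2])
            length = int(cells[3])
            qstart, qend = int(cells[6]), int(cells[7])
            sstart, send = int(cells[8]), int(cells[9])
            evalue = float(cells[10])
            bitscore = float(cells[11])
            positives = int(cells[12])
            gaps = int(cells[13])
        except ValueError as exc:
            raise MalformedRecordError(f"non-numeric field: {exc}", line=lineno) from None
        identical = int(pident * length / 100 + 0.5)
        try:
            hit = DomainHit(
                query_id=cells[0], method="rpsblast-like", domain_id=cells[1],
                q_start=qstart, q_end=qend, s_start=sstart, s_end=send,
                aligned_length=length, identical=identical, positive=positives,
                gaps=gaps, evalue=evalue, bitscore=bitscore,
            )
        except ValueError as exc:
            raise MalformedRecordError(str(exc), line=lineno) from None
        hits.append(hit)
    return hits


def parse_interproscan_tsv(path: str | Path) -> list[DomainHit]:
    """Parse the standard 11+ column InterProScan TSV layout.

    Columns used: protein accession (1), signature accession (5), start (7),
    stop (8), score (9, an E-value when numeric). This dialect reports no
    subject coordinates and no residue counts, so the subject span is
    reconstructed as 1..matched_length (flagged ``synthetic_subject_span``)
    and similarity/identity are left unavailable.
    """
    p = Path(path)
    if not p.is_file():
        raise InputError(f"hit table not found: {p}")
    hits: list[DomainHit] = []
    for lineno, raw in enumerate(p.read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        cells = raw.rstrip("\n").split("\t")
        if len(cells) < 11:
            raise MalformedRecordError(
                f"expected >=11 columns, got {len(cells)}", line=lineno
            )
        try:
            start, stop = int(cells[6]), int(cells[7])
        except ValueError as exc:
            raise MalformedRecordError(f"non-numeric field: {exc}", line=lineno) from None
        score = cells[8].strip()
        try:
            evalue: float | None = float(score)
        except ValueError:
            evalue = None
        span = stop - start + 1
        if span < 1:
            raise MalformedRecordError(f"stop < start ({start}..{stop})", line=lineno)
        try:
            hit = DomainHit(
                query_id=cells[0], method="interproscan-like", domain_id=cells[4],
                q_start=start, q_end=stop, s_start=1, s_end=span,
                aligned_length=span, evalue=evalue,
                synthetic_subject_span=True, partial_stats=True,
            )
        except ValueError as exc:
            raise MalformedRecordError(str(exc), line=lineno) from None
        hits.append(hit)
    return hits


def compute_hit_stats(hit: DomainHit, ref: DomainEntry) -> DomainHit:
    """Return a copy of ``hit`` with the filtering statistics populated.

    All percentages are against the reference domain length except gap_pct,
    which is a property of the alignment itself.
    """
    if hit.domain_id != ref.domain_id:
        raise CoordinateError(
            f"hit references {hit.domain_id!r} but entry is {ref.domain_id!r}"
        )
    if hit.s_end > ref.length and not hit.synthetic_subject_span:
        raise CoordinateError(
            f"subject end {hit.s_end} exceeds reference length {ref.length} "
            f"for {hit.domain_id}"
        )
    span = hit.s_end - hit.s_start + 1
    coverage = 100.0 * span / ref.length
    similarity = 100.0 * hit.positive / ref.length if hit.positive is not None else None
    identity = 100.0 * hit.identical / ref.length if hit.identical is not None else None
    gap_pct = 100.0 * hit.gaps / hit.aligned_length if hit.gaps is not None else None
    return replace(
        hit,
        coverage_pct=coverage,
        similarity_pct=similarity,
        identity_pct=identity,
        gap_pct=gap_pct,
        partial_stats=similarity is None,
    )


def attach_stats(
    hits: Iterable[DomainHit], entries_by_id: dict[str, DomainEntry]
) -> list[DomainHit]:
    """Populate statistics for every hit whose reference entry is known.

    Hits on unknown signatures are retained with coverage unavailable and a
    logged warning, so that downstream steps can still report them.
    """
    out = []
    for hit in hits:
        ref = entries_by_id.get(hit.domain_id)
        if ref is None:
            logger.warning(
                "hit on %s: signature %s not in domain table; coverage unavailable",
                hit.query_id, hit.domain_id,
            )
            out.append(replace(hit, partial_stats=True))
        else:
            out.append(compute_hit_stats(hit, ref))
    return out


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_hits_tsv(hits: Iterable[DomainHit], path: str | Path, header_note: str = "") -> None:
    """Write the unified hit table. Coordinates are 1-based inclusive."""
    lines = []
    if header_note:
        lines.append(f"# {header_note}")
    lines.append("# coordinates: 1-based inclusive")
    lines.append("#" + "\t".join(HIT_COLUMNS))
    for h in hits:
        lines.append("\t".join(_fmt(getattr(h, c)) for c in HIT_COLUMNS))
    Path(path).write_text("\n".join(lines) + "\n")


def read_hits_tsv(path: str | Path) -> list[DomainHit]:
    """Re-read a unified hit table written by :func:`write_hits_tsv`."""
    p = Path(path)
    if not p.is_file():
        raise InputError(f"hit table not found: {p}")
    hits = []
    ints = {"q_start", "q_end", "s_start", "s_end", "aligned_length",
            "identical", "positive", "gaps"}
    floats = {"evalue", "bitscore", "coverage_pct", "similarity_pct",
              "identity_pct", "gap_pct"}
    bools = {"synthetic_subject_span", "partial_stats"}
    for lineno, raw in enumerate(p.read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        cells = raw.split("\t")
        if len(cells) != len(HIT_COLUMNS):
            raise MalformedRecordError(
                f"expected {len(HIT_COLUMNS)} columns, got {len(cells)}", line=lineno
            )
        kwargs = {}
        try:
            for col, cell in zip(HIT_COLUMNS, cells):
                if cell == "NA":
                    kwargs[col] = None
                elif col in ints:
                    kwargs[col] = int(cell)
                elif col in floats:
                    kwargs[col] = float(cell)
                elif col in bools:
                    kwargs[col] = cell == "1"
                else:
                    kwargs[col] = cell
            hits.append(DomainHit(**kwargs))
        except (ValueError, TypeError) as exc:
            raise MalformedRecordError(str(exc), line=lineno) from None
    return hits
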