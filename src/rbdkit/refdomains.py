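"""Reference domain sets: loading domain-annotation tables and selecting
entries by keyword.

The functional class of interest (e.g. RNA-binding domains) is defined by a
set of *domain selection keywords*. An entry belongs to the reference set if
at least one keyword matches its annotation text. A multi-word keyword only
matches when all of its words occur within the same annotation field
(short name, description, or a single GO term name) — co-occurrence across
fields does not count. Matching is case-insensitive substring matching, so
the keyword ``RNA-bind`` selects entries annotated "RNA-binding".
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from .errors import InputError, MalformedRecordError, PatternError

__all__ = ["DomainEntry", "KeywordSpec", "load_domain_table", "select_domains"]


@dataclass
class DomainEntry:
    """One reference domain/motif record.

    ``length`` is the reference domain length in residues; ``consensus``,
    when present, is the family's representative sequence and must have
    exactly ``length`` residues. Entries without a consensus can still be
    selected and filtered against, but feature scoring is unavailable for
    them.
    """

    source_db: str
    domain_id: str
    accession: str
    short_name: str
    description: str
    length: int
    consensus: str | None = None
    go_terms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"domain {self.domain_id}: length must be >= 1")
        if self.consensus is not None and len(self.consensus) != self.length:
            raise ValueError(
                f"domain {self.domain_id}: consensus has {len(self.consensus)} "
                f"residues but length is {self.length}"
            )


@dataclass
class KeywordSpec:
    """An ordered, deduplicated list of selection terms.

    With ``regex_mode`` each term is a regular expression applied to each
    annotation field; otherwise terms are plain (possibly multi-word)
    case-insensitive substrings.
    """

    terms: list[str]
    regex_mode: bool = False

    def __post_init__(self) -> None:
        seen: set[str] = set()
        unique = []
        for t in self.terms:
            if t and t not in seen:
                seen.add(t)
                unique.append(t)
        self.terms = unique

    @classmethod
    def from_file(cls, path: str | Path, regex_mode: bool = False) -> "KeywordSpec":
        """Read one term per line; blank lines and ``#`` comments skipped.

        Lines may carry an ``re:`` prefix (stripped here); whether terms are
        interpreted as patterns is governed solely by ``regex_mode``.
        """
        p = Path(path)
        if not p.is_file():
            raise InputError(f"keyword file not found: {p}")
        terms = []
        for raw in p.read_text().splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("re:"):
                line = line[3:].strip()
            terms.append(line)
        return cls(terms=terms, regex_mode=regex_mode)


def _go_name(go_entry: str) -> str:
    """The human-readable part of a GO annotation string.

    GO entries are stored as ``GO:NNNNNNN name of term``; plain keywords
    match only the name part so that numeric identifiers are never hit by
    accident. Entries with no name part yield an empty string.
    """
    if go_entry.upper().startswith("GO:"):
        parts = go_entry.split(None, 1)
        return parts[1] if len(parts) > 1 else ""
    return go_entry


def load_domain_table(path: str | Path, source_db: str = "CDD-style") -> list[DomainEntry]:
    """Parse a tab-separated domain-annotation table.

    Columns: ``domain_id  accession  short_name  description  length
    [consensus]  [go_terms]`` where go_terms are ``;``-joined. Lines starting
    with ``#`` are headers/comments. A ``-`` or empty consensus cell means
    the entry has none.
    """
    p = Path(path)
    if not p.is_file():
        raise InputError(f"domain table not found: {p}")
    entries: list[DomainEntry] = []
    seen_ids: set[str] = set()
    for lineno, raw in enumerate(p.read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        cells = raw.rstrip("\n").split("\t")
        if len(cells) < 5:
            raise MalformedRecordError(
                f"expected >=5 tab-separated columns, got {len(cells)}", line=lineno
            )
        domain_id, accession, short_name, description = (c.strip() for c in cells[:4])
        try:
            length = int(cells[4])
        except ValueError:
            raise MalformedRecordError(
                f"length column is not an integer: {cells[4]!r}", line=lineno
            ) from None
        consensus: str | None = None
        if len(cells) >= 6 and cells[5].strip() not in ("", "-"):
            consensus = cells[5].strip().upper()
        go_terms: list[str] = []
        if len(cells) >= 7 and cells[6].strip():
            go_terms = [g.strip() for g in cells[6].split(";") if g.strip()]
        if domain_id in seen_ids:
            raise MalformedRecordError(
                f"duplicate domain_id {domain_id!r}", line=lineno
            )
        seen_ids.add(domain_id)
        try:
            entry = DomainEntry(
                source_db=source_db,
                domain_id=domain_id,
                accession=accession,
                short_name=short_name,
                description=description,
                length=length,
                consensus=consensus,
                go_terms=go_terms,
            )
        except ValueError as exc:
            raise MalformedRecordError(str(exc), line=lineno) from None
        entries.append(entry)
    return entries


def _plain_fields(entry: DomainEntry) -> list[str]:
    return [entry.short_name, entry.description] + [_go_name(g) for g in entry.go_terms]


def _regex_fields(entry: DomainEntry) -> list[str]:
    return [entry.short_name, entry.description] + list(entry.go_terms)


def _term_matches_field(term_words: list[str], text: str) -> bool:
    low = text.casefold()
    return all(w in low for w in term_words)


def entry_matches(entry: DomainEntry, keywords: KeywordSpec) -> bool:
    """True if any keyword matches this entry's annotation text."""
    if keywords.regex_mode:
        for term in keywords.terms:
            try:
                pattern = re.compile(term, re.IGNORECASE)
            except re.error as exc:
                raise PatternError(f"invalid pattern {term!r}: {exc}") from None
            if any(pattern.search(f) for f in _regex_fields(entry)):
                return True
        return False
    for term in keywords.terms:
        words = [w.casefold() for w in term.split()]
        if not words:
            continue
        if any(_term_matches_field(words, f) for f in _plain_fields(entry)):
            return True
    return False


def select_domains(entries: list[DomainEntry], keywords: KeywordSpec) -> list[DomainEntry]:
    """Select the reference domain set by keyword.

    Returns the entries whose annotation matches at least one term, in input
    order, deduplicated by ``domain_id``.
    """
    if not keywords.terms:
        raise ValueError("keyword list is empty")
    selected: list[DomainEntry] = []
    seen: set[str] = set()
    for entry in entries:
        if entry.domain_id in seen:
            continue
        if entry_matches(entry, keywords):
            selected.append(entry)
            seen.add(entry.domain_id)
    return selected
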