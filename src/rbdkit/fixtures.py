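"""Synthetic labeled protein sets with planted domains.

The generator emulates the benchmark layout used throughout the package:
positive proteins carry exactly one mutated copy of a reference domain
consensus at a recorded position, negative proteins are plain background
sequence. Substitutions and (optional) single-residue indels are applied at
controlled rates, and the exact edit trace is retained so that emitted hit
tables carry statistics that agree with the sequence actually written.

Defaults are the package's standard study conditions: 50 positives, 50
negatives, substitution rate 0.1, no indels, protein lengths 80-200,
uniform residue background.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .chemdata import AA20
from .errors import ConfigError, InputError
from .refdomains import DomainEntry
from .scanner import _positive_pair

__all__ = ["FixtureConfig", "SyntheticProtein", "LabeledSet",
           "generate_labeled_set", "emit_hit_tables", "read_truth_table"]


@dataclass
class FixtureConfig:
    n_positive: int = 50
    n_negative: int = 50
    length_range: tuple[int, int] = (80, 200)
    substitution_rate: float = 0.1
    indel_rate: float = 0.0
    seed: int = 0
    background: Sequence[float] | None = None  # uniform 1/20 when None

    def __post_init__(self) -> None:
        if not (0 <= self.substitution_rate <= 1 and 0 <= self.indel_rate <= 1):
            raise ConfigError("rates must lie in [0, 1]")
        if self.length_range[0] > self.length_range[1] or self.length_range[0] < 1:
            raise ConfigError(f"bad length range {self.length_range}")
        if self.n_positive < 0 or self.n_negative < 0:
            raise ConfigError("set sizes must be non-negative")


@dataclass
class SyntheticProtein:
    """One generated protein plus, for positives, the plant's edit trace.

    ``edit_trace`` has one code per consensus position — ``M`` unchanged,
    ``S`` substituted, ``D`` deleted — and ``insertions`` counts inserted
    residues, so alignment statistics of the plant are exact by
    construction. ``subs`` maps consensus position (0-based) to the residue
    substituted in.
    """

    protein_id: str
    label: bool
    sequence: str
    domain_id: str | None = None
    plant_start: int | None = None  # 1-based inclusive
    plant_end: int | None = None
    edit_trace: str | None = None
    insertions: int = 0
    subs: dict[int, str] = field(default_factory=dict)


@dataclass
class LabeledSet:
    proteins: list[SyntheticProtein]
    config: FixtureConfig

    @property
    def positives(self) -> list[SyntheticProtein]:
        return [p for p in self.proteins if p.label]

    @property
    def negatives(self) -> list[SyntheticProtein]:
        return [p for p in self.proteins if not p.label]

    def write_fasta(self, path: str | Path) -> None:
        lines = []
        for p in self.proteins:
            lines.append(f">{p.protein_id}")
            for i in range(0, len(p.sequence), 60):
                lines.append(p.sequence[i : i + 60])
        Path(path).write_text("\n".join(lines) + "\n")

    def write_truth(self, path: str | Path) -> None:
        lines = ["#protein_id\tlabel\tdomain_id\tplant_start\tplant_end"]
        for p in self.proteins:
            lines.append("\t".join([
                p.protein_id, "1" if p.label else "0",
                p.domain_id or "NA",
                str(p.plant_start) if p.plant_start else "NA",
                str(p.plant_end) if p.plant_end else "NA",
            ]))
        Path(path).write_text("\n".join(lines) + "\n")


def read_truth_table(path: str | Path) -> dict[str, bool]:
    """protein_id -> label map from a truth table file."""
    p = Path(path)
    if not p.is_file():
        raise InputError(f"truth table not found: {p}")
    labels = {}
    for raw in p.read_text().splitlines():
        if not raw.strip() or raw.startswith("#"):
            continue
        cells = raw.split("\t")
        labels[cells[0]] = cells[1] == "1"
    return labels


def _sample_background(rng: np.random.Generator, n: int,
                       background: np.ndarray) -> str:
    idx = rng.choice(20, size=n, p=background)
    return "".join(AA20[i] for i in idx)


def _mutate(consensus: str, cfg: FixtureConfig,
            rng: np.random.Generator) -> tuple[str, str, int, dict[int, str]]:
    """Apply substitutions/indels; return (region, trace, n_insertions, subs)."""
    out: list[str] = []
    trace: list[str] = []
    subs: dict[int, str] = {}
    insertions = 0
    bg = (np.full(20, 1.0 / 20) if cfg.background is None
          else np.asarray(cfg.background, dtype=float))
    for i, res in enumerate(consensus):
        if cfg.indel_rate and rng.random() < cfg.indel_rate:
            trace.append("D")
            continue
        if rng.random() < cfg.substitution_rate:
            choices = [a for a in AA20 if a != res]
            new = choices[int(rng.integers(len(choices)))]
            out.append(new)
            trace.append("S")
            subs[i] = new
        else:
            out.append(res)
            trace.append("M")
        if cfg.indel_rate and rng.random() < cfg.indel_rate:
            out.append(_sample_background(rng, 1, bg))
            insertions += 1
    return "".join(out), "".join(trace), insertions, subs


def generate_labeled_set(cfg: FixtureConfig,
                         domains: Sequence[DomainEntry]) -> LabeledSet:
    """Generate positives with one planted domain each, plus negatives.

    Every domain must carry a consensus. Fully deterministic for a fixed
    ``cfg.seed``; each positive plants a randomly chosen domain's mutated
    consensus at a recorded 1-based position.
    """
    if not domains:
        raise ConfigError("at least one domain is required")
    for d in domains:
        if d.consensus is None:
            raise ConfigError(f"domain {d.domain_id} has no consensus")
        if d.length > cfg.length_range[1]:
            raise ConfigError(
                f"domain {d.domain_id} ({d.length} aa) longer than the "
                f"maximum protein length {cfg.length_range[1]}"
            )
    rng = np.random.default_rng(cfg.seed)
    bg = (np.full(20, 1.0 / 20) if cfg.background is None
          else np.asarray(cfg.background, dtype=float))
    if abs(float(bg.sum()) - 1.0) > 1e-9:
        raise ConfigError("background must sum to 1")
    proteins: list[SyntheticProtein] = []
    lo, hi = cfg.length_range
    for i in range(cfg.n_positive):
        domain = domains[int(rng.integers(len(domains)))]
        region, trace, n_ins, subs = _mutate(domain.consensus, cfg, rng)
        low = max(lo, len(region))
        length = int(rng.integers(low, hi + 1)) if low <= hi else len(region)
        flank_total = length - len(region)
        left = int(rng.integers(flank_total + 1))
        seq = (_sample_background(rng, left, bg) + region
               + _sample_background(rng, flank_total - left, bg))
        proteins.append(SyntheticProtein(
            protein_id=f"POS{i + 1:04d}", label=True, sequence=seq,
            domain_id=domain.domain_id,
            plant_start=left + 1, plant_end=left + len(region),
            edit_trace=trace, insertions=n_ins, subs=subs,
        ))
    for i in range(cfg.n_negative):
        length = int(rng.integers(lo, hi + 1))
        proteins.append(SyntheticProtein(
            protein_id=f"NEG{i + 1:04d}", label=False,
            sequence=_sample_background(rng, length, bg),
        ))
    return LabeledSet(proteins=proteins, config=cfg)


def plant_alignment_stats(protein: SyntheticProtein,
                          consensus: str) -> tuple[int, int, int, int]:
    """(aligned_length, identical, positive, gaps) of a plant, from its trace.

    Identical positions are the unchanged ones; positives add substitutions
    to a positively scoring residue (BLOSUM62 > 0); every deleted consensus
    position and inserted residue is one gap position.
    """
    trace = protein.edit_trace or ""
    identical = trace.count("M")
    deletions = trace.count("D")
    positive = identical
    for pos, new in protein.subs.items():
        if _positive_pair(consensus[pos], new):
            positive += 1
    gaps = deletions + protein.insertions
    aligned_length = len(consensus) + protein.insertions
    return aligned_length, identical, positive, gaps


def _plant_evalue(identical: int, aligned_length: int) -> float:
    # deterministic mock significance: more conserved plants get lower E
    return float(f"{10 ** -(5 + 30.0 * identical / aligned_length):.3e}")


def emit_hit_tables(
    labeled: LabeledSet,
    domains: Sequence[DomainEntry],
    dialect: str,
    path: str | Path,
    noise: float = 0.0,
    seed: int = 0,
) -> None:
    """Write a hit table for the planted domains in an external dialect.

    One true hit per positive, with alignment statistics recomputed from
    the plant's actual edit trace (so they agree with the FASTA), plus —
    at rate ``noise`` per protein — one spurious low-coverage hit on a
    random domain. ``dialect`` is ``rpsblast-like`` or ``interproscan-like``.
    """
    if dialect not in ("rpsblast-like", "interproscan-like"):
        raise ValueError(f"unknown dialect {dialect!r}")
    by_id = {d.domain_id: d for d in domains}
    rng = np.random.default_rng(seed)
    rows: list[str] = []

    def rps_row(p: SyntheticProtein, domain: DomainEntry, q_start: int, q_end: int,
                s_start: int, s_end: int, aligned: int, identical: int,
                positive: int, gaps: int, evalue: float) -> str:
        pident = 100.0 * identical / aligned
        mismatch = aligned - identical - gaps
        gapopen = 1 if gaps else 0
        bitscore = round(2.0 * identical + 0.5 * (positive - identical), 1)
        return "\t".join([
            p.protein_id, domain.domain_id, f"{pident:.2f}", str(aligned),
            str(mismatch), str(gapopen), str(q_start), str(q_end),
            str(s_start), str(s_end), f"{evalue:.3e}", f"{bitscore:.1f}",
            str(positive), str(gaps),
        ])

    def ipr_row(p: SyntheticProtein, domain: DomainEntry, q_start: int,
                q_end: int, evalue: float) -> str:
        md5 = hashlib.md5(p.sequence.encode()).hexdigest()
        return "\t".join([
            p.protein_id, md5, str(len(p.sequence)), domain.source_db,
            domain.domain_id, domain.description, str(q_start), str(q_end),
            f"{evalue:.3e}", "T", "01-01-2020",
        ])

    for p in labeled.proteins:
        if p.label:
            domain = by_id[p.domain_id]
            aligned, identical, positive, gaps = plant_alignment_stats(
                p, domain.consensus)
            evalue = _plant_evalue(identical, aligned)
            if dialect == "rpsblast-like":
                rows.append(rps_row(p, domain, p.plant_start, p.plant_end,
                                    1, domain.length, aligned, identical,
                                    positive, gaps, evalue))
            else:
                rows.append(ipr_row(p, domain, p.plant_start, p.plant_end, evalue))
        if noise and rng.random() < noise:
            domain = domains[int(rng.integers(len(domains)))]
            span = max(3, int(domain.length * float(rng.uniform(0.05, 0.30))))
            span = min(span, len(p.sequence))
            q_start = int(rng.integers(1, len(p.sequence) - span + 2))
            identical = max(1, int(span * float(rng.uniform(0.2, 0.5))))
            positive = min(span, identical + int(span * 0.1))
            evalue = float(rng.uniform(0.2, 5.0))
            if dialect == "rpsblast-like":
                s_start = 1
                rows.append(rps_row(p, domain, q_start, q_start + span - 1,
                                    s_start, s_start + span - 1, span,
                                    identical, positive, 0, evalue))
            else:
                rows.append(ipr_row(p, domain, q_start, q_start + span - 1, evalue))
    Path(path).write_text("\n".join(rows) + ("\n" if rows else ""))
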