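"""End-to-end pipeline runner and result classification.

Stages: build the reference domain set from keywords, obtain hits (internal
scanner over per-domain profiles, or ingestion of external hit tables),
attach statistics, filter into candidates, feature-score the candidates,
classify the results by keyword, and — when a truth table is supplied —
evaluate the selection. Every stage writes its table so any stage can be
re-entered on a previous run's output, and all randomness flows from the
single configured seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from . import __version__
from .assess import ConfusionCounts, Metrics, metrics
from .errors import ConfigError, ScoringUnavailableError
from .features import FeatureConfig, FeatureScores, score_hit
from .filtering import FilterParams, filter_hits, select_proteins
from .fixtures import read_truth_table
from .ingest import (DomainHit, attach_stats, parse_interproscan_tsv,
                     parse_rpsblast_table, write_hits_tsv)
from .refdomains import (DomainEntry, KeywordSpec, entry_matches,
                         load_domain_table, select_domains)
from .scanner import build_profile, scan

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunResult", "run_pipeline", "classify_results",
           "read_fasta"]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Query sequences as an ordered id -> sequence map."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


@dataclass
class RunConfig:
    fasta: str | Path
    domain_table: str | Path
    selection_keywords: KeywordSpec
    out_dir: str | Path
    classification_keywords: KeywordSpec | None = None
    hit_tables: list[tuple[str, str | Path]] = field(default_factory=list)
    use_scanner: bool = True
    filter_params: FilterParams = field(default_factory=FilterParams)
    feature_config: FeatureConfig = field(default_factory=FeatureConfig)
    truth_table: str | Path | None = None
    scanner_max_evalue: float = 0.01
    scanner_shuffles: int = 200
    seed: int = 0
    score_candidates: bool = True


@dataclass
class RunResult:
    reference: list[DomainEntry]
    hits: list[DomainHit]
    candidates: dict[str, list[DomainHit]]
    scores: dict[tuple[str, int], FeatureScores]
    classification: dict[str, set[str]]
    confusion: ConfusionCounts | None
    metrics: Metrics | None
    outputs: dict[str, Path]


def classify_results(
    selected: dict[str, list[DomainHit]],
    entries_by_id: dict[str, DomainEntry],
    keywords: KeywordSpec,
) -> dict[str, set[str]]:
    """Group candidate proteins under each result-classification keyword.

    A protein appears under every keyword matching the annotation of any of
    its passing hits' domains (same matching rules as reference selection);
    subsets may overlap, and proteins matching no keyword are collected
    under ``unclassified``.
    """
    groups: dict[str, set[str]] = {term: set() for term in keywords.terms}
    groups["unclassified"] = set()
    for query_id, hits in selected.items():
        matched_any = False
        for term in keywords.terms:
            single = KeywordSpec(terms=[term], regex_mode=keywords.regex_mode)
            for hit in hits:
                entry = entries_by_id.get(hit.domain_id)
                if entry is not None and entry_matches(entry, single):
                    groups[term].add(query_id)
                    matched_any = True
                    break
        if not matched_any:
            groups["unclassified"].add(query_id)
    return groups


def _provenance(cfg: RunConfig) -> str:
    return f"rbdkit {__version__} | seed={cfg.seed}"


def _write_table(path: Path, header_cols: list[str], rows: list[list[str]],
                 note: str) -> None:
    lines = [f"# {note}", "#" + "\t".join(header_cols)]
    lines += ["\t".join(r) for r in rows]
    path.write_text("\n".join(lines) + "\n")


def run_pipeline(cfg: RunConfig) -> RunResult:
    """Execute the full pipeline and write every stage's table.

    Raises the originating error (stage name in the log) on any stage
    failure; tables written before the failure are retained.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    note = _provenance(cfg)
    outputs: dict[str, Path] = {}

    logger.info("stage makeref: selecting reference domains")
    entries = load_domain_table(cfg.domain_table)
    reference = select_domains(entries, cfg.selection_keywords)
    if not reference:
        raise ConfigError("no domain matched the selection keywords")
    entries_by_id = {e.domain_id: e for e in entries}
    ref_ids = {e.domain_id for e in reference}
    ref_path = out / "reference_domains.tsv"
    _write_table(
        ref_path,
        ["domain_id", "accession", "short_name", "description", "length"],
        [[e.domain_id, e.accession, e.short_name, e.description, str(e.length)]
         for e in reference],
        note,
    )
    outputs["reference_domains"] = ref_path

    queries = read_fasta(cfg.fasta)
    if not queries:
        raise ConfigError(f"no sequences in {cfg.fasta}")

    logger.info("stage predict: collecting domain hits")
    hits: list[DomainHit] = []
    if cfg.use_scanner:
        profiles = [
            build_profile([e.consensus], domain_id=e.domain_id)
            for e in reference if e.consensus is not None
        ]
        if not profiles:
            raise ConfigError("scanner needs at least one consensus-bearing domain")
        for qid, seq in queries.items():
            for profile in profiles:
                hits.extend(scan(
                    profile, seq, query_id=qid,
                    n_shuffles=cfg.scanner_shuffles, seed=cfg.seed,
                    max_evalue=cfg.scanner_max_evalue,
                ))
    for dialect, path in cfg.hit_tables:
        if dialect == "rpsblast-like":
            hits.extend(parse_rpsblast_table(path))
        elif dialect == "interproscan-like":
            hits.extend(parse_interproscan_tsv(path))
        else:
            raise ConfigError(f"unknown hit-table dialect {dialect!r}")

    hits = attach_stats(hits, entries_by_id)
    hits_path = out / "hits.tsv"
    write_hits_tsv(hits, hits_path, header_note=note)
    outputs["hits"] = hits_path

    logger.info("stage filter: %d hits against %d reference domains",
                len(hits), len(ref_ids))
    passing = filter_hits(hits, cfg.filter_params, ref_ids)
    candidates = select_proteins(passing)
    cand_path = out / "candidates.tsv"
    write_hits_tsv(
        [h for q in sorted(candidates) for h in candidates[q]],
        cand_path, header_note=note + " | candidates",
    )
    outputs["candidates"] = cand_path

    scores: dict[tuple[str, int], FeatureScores] = {}
    if cfg.score_candidates:
        logger.info("stage score: feature scoring %d candidates", len(candidates))
        rows = []
        for qid in sorted(candidates):
            seq = queries.get(qid)
            for rank, hit in enumerate(candidates[qid]):
                entry = entries_by_id.get(hit.domain_id)
                if seq is None or entry is None or entry.consensus is None:
                    continue  # reported unscored
                try:
                    fs = score_hit(hit, seq, entry, config=cfg.feature_config)
                except ScoringUnavailableError:
                    continue
                scores[(qid, rank)] = fs
                row = [qid, hit.domain_id]
                for name in FeatureScores.FEATURE_NAMES:
                    v = getattr(fs, name)
                    row.append("NA" if v is None else f"{v:.4f}")
                row.append(f"{fs.combined:.4f}")
                row.append(";".join(f"{k}={v:.4g}" for k, v in fs.pvalues.items())
                           or "NA")
                rows.append(row)
        score_path = out / "scored.tsv"
        _write_table(
            score_path,
            ["query_id", "domain_id", *FeatureScores.FEATURE_NAMES,
             "combined", "pvalues"],
            rows, note,
        )
        outputs["scored"] = score_path

    classification: dict[str, set[str]] = {}
    if cfg.classification_keywords is not None:
        logger.info("stage classify")
        classification = classify_results(
            candidates, entries_by_id, cfg.classification_keywords)
        class_path = out / "classification.tsv"
        _write_table(
            class_path, ["keyword", "n_proteins", "proteins"],
            [[kw, str(len(prots)), ";".join(sorted(prots))]
             for kw, prots in classification.items()],
            note,
        )
        outputs["classification"] = class_path

    confusion = None
    result_metrics = None
    if cfg.truth_table is not None:
        logger.info("stage assess")
        labels = read_truth_table(cfg.truth_table)
        predicted = set(candidates)
        tp = sum(1 for q, lab in labels.items() if lab and q in predicted)
        fn = sum(1 for q, lab in labels.items() if lab and q not in predicted)
        fp = sum(1 for q, lab in labels.items() if not lab and q in predicted)
        tn = sum(1 for q, lab in labels.items() if not lab and q not in predicted)
        confusion = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
        result_metrics = metrics(confusion)
        r = result_metrics.rounded()
        metrics_path = out / "metrics.tsv"
        _write_table(
            metrics_path,
            ["tp", "fp", "tn", "fn", "sn", "sp", "acc", "mcc", "fmeasure"],
            [[str(tp), str(fp), str(tn), str(fn),
              f"{r.sn:.2f}", f"{r.sp:.2f}", f"{r.acc:.2f}",
              f"{r.mcc:.2f}", f"{r.fmeasure:.2f}"]],
            note,
        )
        outputs["metrics"] = metrics_path

    return RunResult(
        reference=reference, hits=hits, candidates=candidates, scores=scores,
        classification=classification, confusion=confusion,
        metrics=result_metrics, outputs=outputs,
    )
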