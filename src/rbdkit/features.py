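"""Feature-based scoring of predicted domain sites.

Each candidate hit is compared against the corresponding fragment of its
reference domain consensus across four feature categories:

1. chemical properties — average mass, mean ionizable side-chain pKa and
   isoelectric point of the two fragments, each turned into a relative
   agreement score ``1 - min(1, |q - r| / r)``;
2. global alignment — Needleman-Wunsch score of the fragments under
   BLOSUM62 with affine gaps (and, when 3-state strings are available, of
   their secondary-structure strings), normalized by the reference
   self-alignment score;
3. composition distance — Euclidean distance between di-peptide,
   tri-peptide and physico-chemical composition vectors, mapped to a score
   via ``1 / (1 + d)``;
4. site similarity — the residue-identity fraction of the hit itself.

The per-feature scores (each in [0, 1], 1 = complete match) are combined
into a single naive-Bayes posterior with a uniform prior. Empirical
P-values for the sequence-based features come from composition-preserving
shuffles of the query fragment; the chemical-property scores carry no
P-value because shuffling preserves composition and hence leaves them
unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product
from typing import Callable, Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from . import chemdata
from .errors import (AlphabetError, DimensionError, ScoringUnavailableError,
                     ShortSequenceError, UndefinedInputError)
from .ingest import DomainHit
from .refdomains import DomainEntry

__all__ = [
    "AlignScheme", "FeatureConfig", "FeatureScores", "nw_align", "ss_align",
    "composition_vector", "physchem_composition", "distance_score",
    "chemical_props", "ChemicalProps", "isoelectric_point",
    "combine_bayesian", "empirical_pvalue", "score_hit", "predict_secondary",
]

_VALID = set(chemdata.AA20) | {"X"}


def _check_alphabet(seq: str) -> None:
    bad = set(seq.upper()) - _VALID
    if bad:
        raise AlphabetError(f"illegal residue(s) {sorted(bad)} in sequence")


@dataclass(frozen=True)
class AlignScheme:
    """Substitution matrix + affine gap penalties for global alignment."""

    matrix: str = "BLOSUM62"
    gap_open: float = -10.0
    gap_extend: float = -0.5


@lru_cache(maxsize=8)
def _aligner(scheme: AlignScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(scheme.matrix)
    aligner.open_gap_score = scheme.gap_open
    aligner.extend_gap_score = scheme.gap_extend
    return aligner


def _gap_run_score(n: int, scheme: AlignScheme) -> float:
    return scheme.gap_open + (n - 1) * scheme.gap_extend if n else 0.0


def nw_align(seq_a: str, seq_b: str, scheme: AlignScheme = AlignScheme()) -> tuple[float, float]:
    """Needleman-Wunsch global alignment score and normalized similarity.

    Returns ``(raw, normalized)`` where ``normalized = max(0, raw /
    self_score(seq_b))`` so that a fragment identical to its reference
    scores exactly 1.0. End gaps are penalized (true global alignment).
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if not seq_a and not seq_b:
        raise UndefinedInputError("both sequences empty")
    _check_alphabet(seq_a)
    _check_alphabet(seq_b)
    if not seq_a or not seq_b:
        raw = _gap_run_score(max(len(seq_a), len(seq_b)), scheme)
        return raw, 0.0
    aligner = _aligner(scheme)
    raw = float(aligner.score(seq_a, seq_b))
    self_score = float(aligner.score(seq_b, seq_b))
    if self_score <= 0:
        return raw, 0.0
    return raw, max(0.0, raw / self_score)


_SS_STATES = set("HEC")


def ss_align(ss_a: str, ss_b: str) -> tuple[float, float]:
    """Global alignment of two 3-state secondary-structure strings.

    Scoring: +1 match, 0 mismatch, -1 per gap position; normalized by the
    reference self-score (its length).
    """
    ss_a, ss_b = ss_a.upper(), ss_b.upper()
    if not ss_a and not ss_b:
        raise UndefinedInputError("both structure strings empty")
    bad = (set(ss_a) | set(ss_b)) - _SS_STATES
    if bad:
        raise AlphabetError(f"illegal secondary-structure state(s) {sorted(bad)}")
    if not ss_a or not ss_b:
        return -float(max(len(ss_a), len(ss_b))), 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    raw = float(aligner.score(ss_a, ss_b))
    return raw, max(0.0, raw / len(ss_b))


def predict_secondary(seq: str) -> str:
    """Stand-in 3-state secondary-structure predictor.

    A simple per-residue propensity classifier (documented table in
    :mod:`rbdkit.chemdata`); it exists so the pipeline can exercise the
    structure-alignment feature without an external predictor and is NOT a
    realistic structure prediction. ``X`` maps to coil.
    """
    _check_alphabet(seq)
    return "".join(chemdata.SS_PROPENSITY.get(res, "C") for res in seq.upper())


@lru_cache(maxsize=4)
def _kmer_index(k: int) -> dict[str, int]:
    return {"".join(p): i for i, p in enumerate(product(chemdata.AA20, repeat=k))}


def composition_vector(seq: str, k: int) -> np.ndarray:
    """k-peptide composition: frequency of each of the 20^k k-mers.

    Frequencies are counts over the ``len(seq) - k + 1`` windows, so the
    vector sums to 1. Only the 20 standard residues are allowed.
    """
    if k not in (2, 3):
        raise ValueError("k must be 2 or 3")
    seq = seq.upper()
    bad = set(seq) - set(chemdata.AA20)
    if bad:
        raise AlphabetError(f"illegal residue(s) {sorted(bad)} for composition")
    n_windows = len(seq) - k + 1
    if n_windows < 1:
        raise ShortSequenceError(f"sequence of length {len(seq)} too short for k={k}")
    index = _kmer_index(k)
    vec = np.zeros(len(index))
    for i in range(n_windows):
        vec[index[seq[i : i + k]]] += 1.0
    return vec / n_windows


def physchem_composition(seq: str) -> np.ndarray:
    """Physico-chemical composition vector.

    Residues map to four property groups (hydrophobic AVLIMFWP, polar
    GSTCYNQ, acidic DE, basic KRH). The vector concatenates the 4 group
    frequencies (sum 1) and the 16 group-to-group transition frequencies of
    adjacent residue pairs (sum 1; all zero for single-residue input).
    """
    seq = seq.upper()
    if not seq:
        raise UndefinedInputError("empty sequence")
    bad = set(seq) - set(chemdata.AA20)
    if bad:
        raise AlphabetError(f"illegal residue(s) {sorted(bad)} for composition")
    order = chemdata.GROUP_ORDER
    gidx = {g: i for i, g in enumerate(order)}
    groups = [gidx[chemdata.RESIDUE_GROUP[res]] for res in seq]
    comp = np.zeros(4)
    for g in groups:
        comp[g] += 1.0
    comp /= len(groups)
    trans = np.zeros((4, 4))
    for a, b in zip(groups, groups[1:]):
        trans[a, b] += 1.0
    if len(groups) > 1:
        trans /= len(groups) - 1
    return np.concatenate([comp, trans.ravel()])


def distance_score(v_a: Sequence[float], v_b: Sequence[float]) -> tuple[float, float]:
    """Euclidean distance between two composition vectors and its score.

    The score ``1 / (1 + d)`` is 1 for identical vectors and decreases
    strictly with distance.
    """
    v_a, v_b = np.asarray(v_a, dtype=float), np.asarray(v_b, dtype=float)
    if v_a.shape != v_b.shape:
        raise DimensionError(f"vector shapes differ: {v_a.shape} vs {v_b.shape}")
    d = float(np.sqrt(np.sum((v_a - v_b) ** 2)))
    return d, 1.0 / (1.0 + d)


@dataclass(frozen=True)
class ChemicalProps:
    mass: float
    pi: float
    mean_pka: float


def _net_charge(counts: dict[str, int], ph: float) -> float:
    charge = 1.0 / (1.0 + 10 ** (ph - chemdata.NTERM_PKA))
    charge -= 1.0 / (1.0 + 10 ** (chemdata.CTERM_PKA - ph))
    for res in chemdata.BASIC_SIDECHAINS:
        if counts.get(res):
            charge += counts[res] / (1.0 + 10 ** (ph - chemdata.SIDECHAIN_PKA[res]))
    for res in chemdata.ACIDIC_SIDECHAINS:
        if counts.get(res):
            charge -= counts[res] / (1.0 + 10 ** (chemdata.SIDECHAIN_PKA[res] - ph))
    return charge


def isoelectric_point(seq: str, tol: float = 1e-4) -> float:
    """pH at which the peptide's Henderson-Hasselbalch net charge is zero.

    Solved by bisection on [0, 14] to ``|charge| < tol``.
    """
    seq = seq.upper()
    if not seq:
        raise UndefinedInputError("empty sequence")
    _check_alphabet(seq)
    counts: dict[str, int] = {}
    for res in seq:
        counts[res] = counts.get(res, 0) + 1
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        q = _net_charge(counts, mid)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def chemical_props(seq: str) -> ChemicalProps:
    """Average mass (Da), isoelectric point and mean ionizable side-chain pKa.

    ``X`` residues contribute the mean residue mass and are ignored for
    charge. Peptides with no ionizable side chain get mean_pka 7.0
    (neutral) by convention.
    """
    seq = seq.upper()
    if not seq:
        raise UndefinedInputError("empty sequence")
    _check_alphabet(seq)
    mean_res_mass = sum(chemdata.AVERAGE_MASS.values()) / 20.0
    mass = chemdata.WATER_MASS + sum(
        chemdata.AVERAGE_MASS.get(res, mean_res_mass) for res in seq
    )
    pkas = [chemdata.SIDECHAIN_PKA[res] for res in seq if res in chemdata.SIDECHAIN_PKA]
    mean_pka = sum(pkas) / len(pkas) if pkas else 7.0
    return ChemicalProps(mass=mass, pi=isoelectric_point(seq), mean_pka=mean_pka)


def relative_agreement(query_value: float, ref_value: float) -> float:
    """Chemical-property score: 1 - min(1, |q - r| / r)."""
    if ref_value == 0:
        return 1.0 if query_value == 0 else 0.0
    return 1.0 - min(1.0, abs(query_value - ref_value) / abs(ref_value))


_EPS = 1e-6


def combine_bayesian(scores: Iterable[float]) -> float:
    """Naive-Bayes combination of per-feature scores with a uniform prior.

    ``combined = prod(s) / (prod(s) + prod(1 - s))``; scores of exactly 0 or
    1 are clamped to [eps, 1-eps] first. Symmetric in its arguments and
    strictly increasing in each on (0, 1).
    """
    scores = list(scores)
    if not scores:
        raise UndefinedInputError("no feature scores to combine")
    for s in scores:
        if not (0.0 <= s <= 1.0):
            raise ValueError(f"feature score {s} outside [0, 1]")
    log_p = 0.0
    log_q = 0.0
    for s in scores:
        s = min(1.0 - _EPS, max(_EPS, s))
        log_p += math.log(s)
        log_q += math.log(1.0 - s)
    # stable evaluation of p / (p + q) in log space
    m = max(log_p, log_q)
    p = math.exp(log_p - m)
    q = math.exp(log_q - m)
    return p / (p + q)


def empirical_pvalue(
    observed: float,
    hit_region: str,
    ref_fragment: str,
    feature_fn: Callable[[str, str], float],
    n_shuffles: int = 100,
    seed: int = 0,
) -> float:
    """P-value of a feature score under composition-preserving shuffling.

    The null distribution is the feature recomputed on ``n_shuffles``
    random permutations of ``hit_region`` against the unchanged reference
    fragment; ``p = (1 + #{null >= observed}) / (1 + n)``, hence always in
    (0, 1] and deterministic for a fixed seed.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    region = np.array(list(hit_region))
    exceed = 0
    for _ in range(n_shuffles):
        shuffled = "".join(rng.permutation(region))
        if feature_fn(shuffled, ref_fragment) >= observed:
            exceed += 1
    return (1 + exceed) / (1 + n_shuffles)


@dataclass
class FeatureConfig:
    """Options for :func:`score_hit`."""

    scheme: AlignScheme = AlignScheme()
    n_shuffles: int = 100
    seed: int = 0
    predict_secondary: bool = False
    compute_pvalues: bool = True


@dataclass
class FeatureScores:
    """Per-feature 0-1 scores, combined score and empirical P-values.

    ``None`` marks a feature that could not be computed for this hit (e.g.
    secondary structure without 3-state strings, or site similarity when the
    search dialect reports no identities). P-values never include the three
    chemical properties.
    """

    chem_mass: float | None = None
    chem_pka: float | None = None
    chem_pi: float | None = None
    aln_primary: float | None = None
    aln_secondary: float | None = None
    dist_dipeptide: float | None = None
    dist_tripeptide: float | None = None
    dist_physchem: float | None = None
    site_similarity: float | None = None
    combined: float | None = None
    pvalues: dict[str, float] = field(default_factory=dict)

    FEATURE_NAMES = (
        "chem_mass", "chem_pka", "chem_pi", "aln_primary", "aln_secondary",
        "dist_dipeptide", "dist_tripeptide", "dist_physchem", "site_similarity",
    )

    def available(self) -> dict[str, float]:
        return {
            name: getattr(self, name)
            for name in self.FEATURE_NAMES
            if getattr(self, name) is not None
        }


def _strip_x(seq: str) -> str:
    return seq.replace("X", "").replace("x", "")


def score_hit(
    hit: DomainHit,
    query_seq: str,
    ref: DomainEntry,
    secondary_query: str | None = None,
    secondary_ref: str | None = None,
    config: FeatureConfig = FeatureConfig(),
) -> FeatureScores:
    """Score one candidate hit against its reference consensus.

    Extracts the predicted site ``query_seq[q_start..q_end]`` and the
    reference fragment ``consensus[s_start..s_end]``, computes every
    available feature, the combined naive-Bayes score, and (optionally)
    empirical P-values for the sequence-based features.

    ``secondary_query``/``secondary_ref`` are full-length 3-state strings
    aligned to ``query_seq`` and ``ref.consensus``; when absent the
    structure feature is skipped unless ``config.predict_secondary`` enables
    the built-in propensity stand-in.
    """
    if ref.consensus is None:
        raise ScoringUnavailableError(
            f"reference {ref.domain_id} has no consensus sequence"
        )
    if hit.q_end > len(query_seq):
        raise ScoringUnavailableError(
            f"hit {hit.query_id}: q_end {hit.q_end} beyond sequence "
            f"length {len(query_seq)}"
        )
    region = query_seq[hit.q_start - 1 : hit.q_end].upper()
    s_end = min(hit.s_end, ref.length)
    fragment = ref.consensus[hit.s_start - 1 : s_end].upper()

    scores = FeatureScores()

    props_q = chemical_props(region)
    props_r = chemical_props(fragment)
    scores.chem_mass = relative_agreement(props_q.mass, props_r.mass)
    scores.chem_pka = relative_agreement(props_q.mean_pka, props_r.mean_pka)
    scores.chem_pi = relative_agreement(props_q.pi, props_r.pi)

    _, scores.aln_primary = nw_align(region, fragment, config.scheme)

    ss_q, ss_r = secondary_query, secondary_ref
    if ss_q is None and config.predict_secondary:
        ss_region, ss_fragment = predict_secondary(region), predict_secondary(fragment)
    elif ss_q is not None and ss_r is not None:
        ss_region = ss_q[hit.q_start - 1 : hit.q_end]
        ss_fragment = ss_r[hit.s_start - 1 : s_end]
    else:
        ss_region = ss_fragment = None
    if ss_region and ss_fragment:
        _, scores.aln_secondary = ss_align(ss_region, ss_fragment)

    region_aa, fragment_aa = _strip_x(region), _strip_x(fragment)
    for name, k in (("dist_dipeptide", 2), ("dist_tripeptide", 3)):
        if len(region_aa) >= k and len(fragment_aa) >= k:
            _, s = distance_score(
                composition_vector(region_aa, k), composition_vector(fragment_aa, k)
            )
            setattr(scores, name, s)
    if region_aa and fragment_aa:
        _, scores.dist_physchem = distance_score(
            physchem_composition(region_aa), physchem_composition(fragment_aa)
        )

    if hit.identity_pct is not None:
        scores.site_similarity = min(1.0, hit.identity_pct / 100.0)

    available = scores.available()
    scores.combined = combine_bayesian(available.values())

    if config.compute_pvalues:
        pvalue_features: dict[str, Callable[[str, str], float]] = {
            "aln_primary": lambda a, b: nw_align(a, b, config.scheme)[1],
        }
        if scores.aln_secondary is not None and config.predict_secondary and ss_q is None:
            pvalue_features["aln_secondary"] = lambda a, b: ss_align(
                predict_secondary(a), predict_secondary(b)
            )[1]
        if scores.dist_dipeptide is not None:
            pvalue_features["dist_dipeptide"] = lambda a, b: distance_score(
                composition_vector(_strip_x(a), 2), composition_vector(_strip_x(b), 2)
            )[1]
        if scores.dist_tripeptide is not None:
            pvalue_features["dist_tripeptide"] = lambda a, b: distance_score(
                composition_vector(_strip_x(a), 3), composition_vector(_strip_x(b), 3)
            )[1]
        if scores.dist_physchem is not None:
            # group block is shuffle-invariant; the null varies through the
            # transition block only
            pvalue_features["dist_physchem"] = lambda a, b: distance_score(
                physchem_composition(_strip_x(a)), physchem_composition(_strip_x(b))
            )[1]
        for i, (name, fn) in enumerate(pvalue_features.items()):
            obs = getattr(scores, name)
            scores.pvalues[name] = empirical_pvalue(
                obs, region, fragment, fn,
                n_shuffles=config.n_shuffles, seed=config.seed + i,
            )
    return scores
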