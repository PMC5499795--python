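# Methods

This note documents the models and procedures implemented in `rbdkit`, the
parameters that matter, the numerical choices made where the design was
open, and what the synthetic benchmarks do and do not show.

## Reference domain selection

A domain entry is selected when at least one keyword matches its annotation
text. The searchable text for plain keywords is the short name, the
description, and the *name* part of each GO annotation; GO numeric
identifiers are reachable only in regex mode, so a keyword like `0003723`
cannot select entries by accident. A multi-word keyword matches only when
all of its words occur (as case-insensitive substrings, no stemming or word
boundaries) **within one field** — "cold" in the short name plus "shock" in
the description does not count. This is the strictest reading of
"co-occurrence in the same context" that still lets prefix terms such as
`RNA-bind` select "RNA-binding" annotations. Selection is monotone in the
keyword list and distributes over union; both properties are tested.

## Hit statistics

Coverage, similarity and identity are percentages of the **reference domain
length**, not of the alignment length: a fragmentary 20-residue hit on a
70-residue domain has 29% coverage however perfect its alignment is. Gap
fraction uses the alignment length, since gaps are not reference positions.
Coordinates are 1-based inclusive everywhere and converted once at parse
time.

The InterProScan-style dialect reports no subject coordinates and no
residue counts. Such hits get a reconstructed subject span (1..match
length, flagged `synthetic_subject_span`), coverage from that span over the
reference length when the signature is present in the domain table, and no
similarity/identity. They are gated on coverage and E-value only and
flagged `partial_stats` in every output; when a coverage threshold is
enabled but coverage is unknown (signature missing from the table) the hit
is rejected rather than waved through.

The BLAST-tabular dialect requires the extended column set including
`positives` and `gaps`; the identical-residue count is recovered from
`pident × length / 100` (rounded half-up), which is exact at the 2-decimal
precision the format carries for realistic alignment lengths.

## Filtering

The default combined rule is coverage ≥ 39% **and** similarity ≥ 24%; these
two cut-offs carry most of the discriminative signal between genuine and
spurious domain predictions, and identity (≥ 15%), E-value (≤ 0.01) and a
gap cap remain opt-in so the default keeps the hits that HMM-based searches
report without residue counts. All comparisons are inclusive ("minimum
cut-off" semantics: the boundary passes). Filtering is anti-monotone in
every threshold (tightening never adds a hit), which the suite checks
property-style.

## Feature scoring

All features compare the predicted query region with the corresponding
reference-consensus fragment and live in [0, 1] with 1 = complete match.

- **Chemical properties.** Average mass (residue average masses + one
  water), mean ionizable side-chain pKa (EMBOSS pKa set; 7.0 by convention
  when no side chain ionizes) and isoelectric point (bisection on the
  Henderson–Hasselbalch net charge to |q| < 1e-4, verified against a
  1e-3-pH grid scan). Per property the score is 1 − min(1, |q−r|/r).
- **Alignment.** Needleman–Wunsch global alignment, BLOSUM62, gap open −10,
  gap extend −0.5 (first gap residue costs the open penalty), end gaps
  penalized. The normalized score is max(0, raw / self-score of the
  reference fragment), hence exactly 1 on identity. Secondary structure
  uses the {H, E, C} alphabet with +1 match / 0 mismatch / −1 per gap
  position, normalized by the reference length; when no 3-state strings are
  supplied an optional per-residue propensity classifier (a documented
  majority table, explicitly a stand-in for a real structure predictor) can
  generate them.
- **Composition distances.** Di-/tri-peptide frequency vectors over the
  20^k k-mers (window counts normalized to sum 1) and a physico-chemical
  vector of 4 group frequencies (hydrophobic AVLIMFWP / polar GSTCYNQ /
  acidic DE / basic KRH) plus 16 group-transition frequencies. Euclidean
  distance d maps to the score 1/(1+d) — bounded, strictly decreasing, 1 at
  d = 0; the mapping itself is a design choice, as is the transition block.
- **Site similarity.** The hit's residue-identity fraction, the one
  per-site similarity measure available in every dialect that reports
  counts.

The combined score is the naive-Bayes posterior with uniform prior,
Πsᵢ/(Πsᵢ+Π(1−sᵢ)), evaluated in log space with inputs clamped to
[1e-6, 1−1e-6]. It is symmetric and strictly increasing in each feature on
(0, 1); features that cannot be computed for a hit are simply left out.

Empirical P-values: the null is the same feature recomputed on n
composition-preserving shuffles of the query region (default n = 100,
seeded), p = (1 + #{null ≥ observed})/(1 + n) ∈ (0, 1]. Chemical properties
are shuffle-invariant, so they carry no P-value; the site-similarity
statistic is a property of the search hit rather than of the two fragments,
so it carries none either.

## Assessment

The five metrics follow the definitions in the README; two conventions are
deliberate: **F = 2·SN·SP/(SN+SP)** uses specificity, not precision, and
any metric with a zero denominator is defined as 0. Reported tables round
half-up to 2 decimals; full precision is kept internally. ROC curves sweep
the distinct score values high→low with ties crossing together (verified
against exhaustive rank-sum pair counting); AUC is trapezoidal.

Cut-off optimization sweeps every distinct observed value as a threshold
(`min-threshold`: predict positive at value ≥ t; `max-threshold`: ≤ t) and
picks the accuracy-optimal one, breaking ties toward higher Youden's J and
then toward the less stringent threshold. Accuracy-with-Youden-tie-break is
a concrete rendering of "optimal TPR and FPR at high accuracy", which is
not by itself a single formula.

Residue overlap: a protein's overlap fraction is the share of its annotated
binding residues inside the union of its predicted site intervals; it is
*recovered* when the fraction is positive, cohort sensitivity is the
recovered share, and the count above 70% overlap is reported separately.
Proteins with no annotated residues are excluded with a warning.

## Internal profile scanner

Profiles are per-position natural-log odds with additive pseudocounts:
freq = (count + λ)/(n + 20λ) against a background (uniform 1/20 by
default), λ = 1. Scanning is **ungapped**: every window start is scored by
summing per-position log-odds. Significance is empirical: the query is
shuffled (composition-preserving) 200 times, all null window scores are
pooled, and a window's E-value is the add-one-smoothed expected count of
null windows scoring at least as high per shuffled sequence; windows with
E ≤ 0.01 are reported, greedily non-overlapping from the best down.
Reported counts (identical/positive vs. the profile consensus, BLOSUM62 > 0
for positives) feed the standard hit statistics; a full-window hit has
coverage 100%. The scanner exists to make the pipeline self-contained at
desk scale; it does not reproduce RPS-BLAST scores, gapped alignment or
analytic E-values, and gapped hits should enter through the parsers.

With single-sequence profiles the window score is a linear function of the
match count, so score ties between query and null windows are common; the
E-value handles ties conservatively (≥ counting). Random sequences produce
a hit in roughly 1% of scans per profile, which the scan property test
bounds.

## Synthetic benchmark generator

Positives carry exactly one mutated consensus copy at a recorded position;
negatives are background samples. Defaults define the standard study
conditions used by the acceptance checks: 50 positives / 50 negatives,
substitution rate 0.1, indel rate 0, lengths 80–200, uniform background.
Substitutions draw uniformly from the 19 other residues; indels are
single-residue events recorded in the edit trace, so emitted hit tables
carry alignment statistics that are exact by construction (and verified by
recomputation from the FASTA). Mock E-values in emitted tables are a
deterministic decreasing function of identity — plausible, not calibrated.

The built-in toy domain set pairs RBD-style annotations with **synthetic**
consensus sequences drawn once from a fixed seed; nothing in it derives
from real domain databases.

What passing these benchmarks shows: the machinery — selection, scanning,
statistics, filtering, scoring, evaluation — is internally consistent and
recovers planted signal at realistic divergence. What it does not show:
performance on real proteomes, where domain families are non-random,
backgrounds are compositionally biased, and hits are gapped; those require
real RPS-BLAST/InterProScan outputs, which the parsers accept.

## Problem sizes and determinism

Test and acceptance runs use the 50+50 benchmark with 200-shuffle scanner
nulls and ≤ 100-shuffle P-values — a few seconds end to end. Every random
choice flows from one seed; fixture files and all pipeline tables are
byte-identical across reruns with the same seed (no timestamps in
provenance headers, `repr`-precision floats in round-tripped tables).

## Known limitations

- The Bayesian combination treats features as independent; composition and
  alignment features are correlated, so the combined score is sharper than
  a calibrated posterior.
- The secondary-structure stand-in predictor is a per-residue propensity
  table, not a structure prediction; its feature mainly tracks sequence
  divergence.
- InterProScan-style hits cannot be scored for similarity/identity; their
  filtering is coverage/E-value only.
- The scanner's empirical E-values are resolution-limited by the shuffle
  count (minimum ≈ 1/(n_shuffles+1)); lowering `n_shuffles` below ~100
  makes the default threshold unreachable.
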