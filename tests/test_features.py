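"""Feature scoring: alignment, composition, chemistry, Bayesian combination."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbdkit.chemdata import AA20, AVERAGE_MASS, WATER_MASS
from rbdkit.errors import (AlphabetError, DimensionError,
                           ScoringUnavailableError, ShortSequenceError,
                           UndefinedInputError)
from rbdkit.features import (FeatureConfig, chemical_props, combine_bayesian,
                             composition_vector, distance_score,
                             empirical_pvalue, isoelectric_point, nw_align,
                             physchem_composition, score_hit)
from rbdkit.ingest import DomainHit
from rbdkit.refdomains import DomainEntry

from oracles import gotoh_score, grid_isoelectric_point

seqs = st.text(alphabet=AA20, min_size=1, max_size=12)


class TestNwAlign:
    def test_self_alignment_normalizes_to_one(self):
        for seq in ("A", "HEAGAWGHEE", "WWWW"):
            raw, norm = nw_align(seq, seq)
            assert norm == pytest.approx(1.0)

    def test_fixed_pair_matches_dp_oracle(self):
        raw, _ = nw_align("HEAGAWGHEE", "PAWHEAE")
        assert raw == pytest.approx(gotoh_score("HEAGAWGHEE", "PAWHEAE"))

    @settings(max_examples=60, deadline=None)
    @given(a=seqs, b=seqs)
    def test_random_pairs_match_dp_oracle(self, a, b):
        raw, norm = nw_align(a, b)
        assert raw == pytest.approx(gotoh_score(a, b))
        assert 0.0 <= norm <= 1.0 + 1e-12

    def test_empty_against_nonempty_is_one_terminal_gap(self):
        raw, norm = nw_align("", "AAAA")
        assert raw == pytest.approx(-10.0 + 3 * -0.5)
        assert norm == 0.0

    def test_both_empty_is_undefined(self):
        with pytest.raises(UndefinedInputError):
            nw_align("", "")

    def test_illegal_character(self):
        with pytest.raises(AlphabetError):
            nw_align("AC1E", "ACDE")


class TestCompositionVector:
    def test_single_repeated_dipeptide(self):
        vec = composition_vector("AA", 2)
        assert vec.sum() == pytest.approx(1.0)
        assert vec.max() == pytest.approx(1.0)  # all mass on AA

    def test_acdc_windows(self):
        vec = composition_vector("ACDC", 2)
        nonzero = vec[vec > 0]
        assert len(nonzero) == 3
        assert np.allclose(nonzero, 1 / 3)

    @settings(max_examples=50, deadline=None)
    @given(seq=st.text(alphabet=AA20, min_size=3, max_size=40),
           k=st.sampled_from([2, 3]))
    def test_normalization(self, seq, k):
        vec = composition_vector(seq, k)
        assert abs(vec.sum() - 1.0) < 1e-12
        assert (vec >= 0).all()

    def test_too_short(self):
        with pytest.raises(ShortSequenceError):
            composition_vector("AC", 3)


class TestPhyschemComposition:
    def test_pure_acidic(self):
        vec = physchem_composition("DDDD")
        assert vec[2] == pytest.approx(1.0)  # acidic group
        assert vec[:4].sum() == pytest.approx(1.0)
        assert vec[0] == vec[1] == vec[3] == 0.0

    def test_acid_base_transition(self):
        vec = physchem_composition("DK")
        groups, trans = vec[:4], vec[4:].reshape(4, 4)
        assert groups[2] == pytest.approx(0.5)   # acidic
        assert groups[3] == pytest.approx(0.5)   # basic
        assert trans[2, 3] == pytest.approx(1.0)  # acidic -> basic

    @settings(max_examples=30, deadline=None)
    @given(seq=st.text(alphabet=AA20, min_size=2, max_size=30),
           seed=st.integers(0, 1000))
    def test_group_block_is_permutation_invariant(self, seq, seed):
        rng = np.random.default_rng(seed)
        shuffled = "".join(rng.permutation(list(seq)))
        assert np.allclose(physchem_composition(seq)[:4],
                           physchem_composition(shuffled)[:4])


class TestDistanceScore:
    def test_identical_vectors(self):
        d, s = distance_score([0.2, 0.8], [0.2, 0.8])
        assert d == 0.0 and s == 1.0

    def test_unit_basis_vectors(self):
        d, s = distance_score([1.0, 0.0], [0.0, 1.0])
        assert d == pytest.approx(math.sqrt(2))
        assert s == pytest.approx(1 / (1 + math.sqrt(2)), abs=1e-4)

    def test_dimension_mismatch(self):
        with pytest.raises(DimensionError):
            distance_score([1.0], [1.0, 2.0])

    @settings(max_examples=30, deadline=None)
    @given(v=st.lists(st.floats(0, 1), min_size=2, max_size=8),
           w=st.lists(st.floats(0, 1), min_size=2, max_size=8))
    def test_score_bounded(self, v, w):
        n = min(len(v), len(w))
        d, s = distance_score(v[:n], w[:n])
        assert 0.0 < s <= 1.0 and d >= 0.0


class TestChemicalProps:
    def test_glycine_mass_is_residue_plus_water(self):
        assert chemical_props("G").mass == pytest.approx(
            AVERAGE_MASS["G"] + WATER_MASS)

    def test_acidic_residue_pi_below_basic(self):
        assert isoelectric_point("D") < isoelectric_point("K")

    @settings(max_examples=20, deadline=None)
    @given(seq=st.text(alphabet=AA20, min_size=1, max_size=15))
    def test_pi_matches_grid_scan_oracle(self, seq):
        assert isoelectric_point(seq) == pytest.approx(
            grid_isoelectric_point(seq), abs=0.01)

    def test_no_ionizable_side_chain_gets_neutral_pka(self):
        assert chemical_props("GGAA").mean_pka == 7.0


class TestCombineBayesian:
    def test_uninformative_features(self):
        assert combine_bayesian([0.5, 0.5, 0.5]) == pytest.approx(0.5)

    def test_near_certain_features(self):
        assert combine_bayesian([1.0, 1.0]) >= 1 - 1e-5

    def test_stated_formula_value(self):
        assert combine_bayesian([0.9, 0.8, 0.7]) == pytest.approx(
            0.504 / (0.504 + 0.006), abs=1e-6)

    @settings(max_examples=50, deadline=None)
    @given(scores=st.lists(st.floats(0.01, 0.99), min_size=2, max_size=6),
           seed=st.integers(0, 100))
    def test_symmetric_and_monotone(self, scores, seed):
        rng = np.random.default_rng(seed)
        permuted = list(rng.permutation(scores))
        assert combine_bayesian(scores) == pytest.approx(
            combine_bayesian(permuted))
        bumped = scores.copy()
        bumped[0] = min(0.999, bumped[0] + 0.05)
        assert combine_bayesian(bumped) >= combine_bayesian(scores)


class TestEmpiricalPvalue:
    feature = staticmethod(lambda a, b: nw_align(a, b)[1])

    def test_observed_above_all_nulls(self):
        p = empirical_pvalue(2.0, "ACDEFGHIKL", "ACDEFGHIKL", self.feature,
                             n_shuffles=19, seed=1)
        assert p == pytest.approx(1 / 20)

    def test_observed_below_all_nulls(self):
        p = empirical_pvalue(-1.0, "ACDEFGHIKL", "ACDEFGHIKL", self.feature,
                             n_shuffles=19, seed=1)
        assert p == 1.0

    def test_recount_against_stored_null_sample(self):
        region, frag = "MKVLAAGGYTRD", "MKVLSAGGWTRD"
        observed = self.feature(region, frag)
        n = 99
        rng = np.random.default_rng(5)
        chars = np.array(list(region))
        null = [self.feature("".join(rng.permutation(chars)), frag)
                for _ in range(n)]
        expected = (1 + sum(1 for v in null if v >= observed)) / (1 + n)
        assert empirical_pvalue(observed, region, frag, self.feature,
                                n_shuffles=n, seed=5) == pytest.approx(expected)

    def test_deterministic_for_fixed_seed(self):
        args = (0.4, "MKVLAAGGYTRD", "MKVLSAGGWTRD", self.feature)
        assert empirical_pvalue(*args, n_shuffles=50, seed=9) == \
            empirical_pvalue(*args, n_shuffles=50, seed=9)


def _domain(consensus):
    return DomainEntry(source_db="t", domain_id="dx", accession="a",
                       short_name="n", description="d",
                       length=len(consensus), consensus=consensus)


def _hit(n, identity_pct=100.0):
    return DomainHit(query_id="q", method="internal-scanner", domain_id="dx",
                     q_start=1, q_end=n, s_start=1, s_end=n,
                     aligned_length=n, identical=n, positive=n, gaps=0,
                     evalue=1e-10, identity_pct=identity_pct)


def _random_seq(rng, n):
    return "".join(AA20[i] for i in rng.integers(0, 20, n))


def _substitute(seq, rate, rng):
    out = []
    for res in seq:
        if rng.random() < rate:
            out.append(AA20[(AA20.index(res) + 1 + int(rng.integers(19))) % 20])
        else:
            out.append(res)
    return "".join(out)


class TestScoreHit:
    def test_identical_region_scores_one_everywhere(self):
        rng = np.random.default_rng(0)
        consensus = _random_seq(rng, 40)
        ref = _domain(consensus)
        fs = score_hit(_hit(40), consensus, ref,
                       config=FeatureConfig(n_shuffles=20, seed=0,
                                            predict_secondary=True))
        for name in ("aln_primary", "aln_secondary", "dist_dipeptide",
                     "dist_tripeptide", "dist_physchem", "site_similarity"):
            assert getattr(fs, name) == pytest.approx(1.0), name
        assert fs.combined > 0.99

    def test_substituted_region_scores_strictly_lower(self):
        rng = np.random.default_rng(1)
        consensus = _random_seq(rng, 40)
        ref = _domain(consensus)
        cfg = FeatureConfig(n_shuffles=10, seed=0, predict_secondary=True,
                            compute_pvalues=False)
        perfect = score_hit(_hit(40), consensus, ref, config=cfg)
        mutated = _substitute(consensus, 0.5, rng)
        identity = 100.0 * sum(a == b for a, b in zip(mutated, consensus)) / 40
        degraded = score_hit(_hit(40, identity_pct=identity), mutated, ref,
                             config=cfg)
        for name in ("aln_primary", "dist_dipeptide", "dist_tripeptide",
                     "dist_physchem", "site_similarity"):
            assert getattr(degraded, name) < getattr(perfect, name), name
        assert degraded.combined < perfect.combined

    def test_consensus_free_entry_is_unscorable(self):
        ref = DomainEntry(source_db="t", domain_id="dx", accession="a",
                          short_name="n", description="d", length=40)
        with pytest.raises(ScoringUnavailableError):
            score_hit(_hit(40), "A" * 40, ref)

    def test_pvalues_cover_sequence_features_only(self):
        rng = np.random.default_rng(2)
        consensus = _random_seq(rng, 30)
        fs = score_hit(_hit(30), _substitute(consensus, 0.2, rng),
                       _domain(consensus),
                       config=FeatureConfig(n_shuffles=30, seed=3))
        assert fs.pvalues  # non-empty
        for name, p in fs.pvalues.items():
            assert not name.startswith("chem_")
            assert 0.0 < p <= 1.0

    def test_median_combined_score_degrades_with_substitution_rate(self):
        rng = np.random.default_rng(3)
        cfg = FeatureConfig(compute_pvalues=False, predict_secondary=True)
        medians = []
        for rate in (0.0, 0.25, 0.6):
            combined = []
            for _ in range(5):
                consensus = _random_seq(rng, 35)
                mutated = _substitute(consensus, rate, rng)
                identity = 100.0 * sum(
                    a == b for a, b in zip(mutated, consensus)) / 35
                fs = score_hit(_hit(35, identity_pct=identity), mutated,
                               _domain(consensus), config=cfg)
                combined.append(fs.combined)
            medians.append(float(np.median(combined)))
        assert medians[0] >= medians[1] >= medians[2]
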