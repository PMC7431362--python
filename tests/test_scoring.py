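"""Score terms, their algebraic identities, whole-structure scores, profiles."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import igscore as ig
from igscore.scoring import TERM_FUNCTIONS
from igscore.training import BinGrid

from conftest import brute_force_pairs, make_model, random_rotation

positive_freq = st.floats(min_value=1e-12, max_value=1.0)


class TestTermFunctions:
    @pytest.mark.parametrize("term,f_obs,f_ref,expect", [
        ("PMF", 0.1, 0.1, 0.0),
        ("PMF", 0.0, 0.05, 10.0),     # undefined: log of zero
        ("PMF", 0.1, 0.0, 10.0),      # undefined: zero reference
        ("PMF", 0.2, 0.1, -math.log(2)),
        ("TIG", 0.1, 0.1, 0.0),
        ("TIG", 0.0, 0.05, 1.0),      # defined plateau, not a default
        ("TIG", 0.1, 0.0, 10.0),
        ("TIG", 0.2, 0.1, -1.0),
        ("MCK1", 0.1, 0.1, 0.0),
        ("MCK1", 0.0, 0.05, 2.0),
        ("MCK1", 0.0, 0.0, 10.0),     # the only undefined case: 0/0
        ("MCK1", 0.3, 0.1, -1.0),
        ("MCK2", 0.1, 0.1, 0.0),
        ("MCK2", 0.0, 0.05, 1.0),
        ("MCK2", 0.0, 0.0, 10.0),
        ("MCK2", 0.2, 0.1, -0.5),
    ])
    def test_term_values(self, term, f_obs, f_ref, expect):
        assert TERM_FUNCTIONS[term](f_obs, f_ref) == pytest.approx(expect, abs=1e-12)

    @given(f=positive_freq)
    def test_tig_plateau_exact(self, f):
        assert ig.tig_term(0.0, f) == 1.0

    @given(f=positive_freq)
    def test_zero_at_equal_frequencies(self, f):
        for fn in TERM_FUNCTIONS.values():
            assert fn(f, f) == 0.0

    @given(x=positive_freq, y=positive_freq)
    def test_log_mean_identity(self, x, y):
        # -ln(x/y) == -(x - y)/L(x, y) with L the logarithmic mean
        L = x if x == y else (x - y) / (math.log(x) - math.log(y))
        assert ig.pmf_term(x, y) == pytest.approx(-(x - y) / L, rel=1e-10)

    @given(x=positive_freq, y=positive_freq)
    def test_surprisal_difference_identity(self, x, y):
        # PMF term is a difference of surprisals
        assert ig.pmf_term(x, y) == pytest.approx((-math.log(x)) - (-math.log(y)),
                                                  abs=1e-12)

    @given(x=positive_freq, y=positive_freq)
    def test_pmf_dominates_tig(self, x, y):
        # from ln t <= t - 1: -ln(x/y) >= -(x - y)/y, equality iff x == y
        p, t = ig.pmf_term(x, y), ig.tig_term(x, y)
        if x == y:
            assert p == t == 0.0
        else:
            assert p > t


class TestBuildPotential:
    def test_pair_equal_to_reference_scores_zero(self):
        ref = np.full(30, 1 / 30)
        table = ig.FrequencyTable(BinGrid(), {ig.PairTypeKey(("ALA", "CA"), ("ALA", "CA")):
                                              ig.PairStats(ref.copy(), 10)}, ref.copy())
        for fm in ig.FORMALISMS:
            pot = ig.build_potential(table, fm)
            assert np.allclose(next(iter(pot.per_pair.values())), 0.0, atol=1e-12)

    def test_terms_bounded_and_finite(self, trained_table):
        # every stored term is finite; TIG is capped at the +10 default (its
        # defined values never exceed +1), MCK1/MCK2 at their +/-2 and +/-1
        # envelopes; PMF's log ratio is legitimately unbounded above
        bounds = {"TIG": 10.0, "MCK1": 10.0, "MCK2": 10.0}
        for fm in ig.FORMALISMS:
            pot = ig.build_potential(trained_table, fm)
            for terms in pot.per_pair.values():
                assert np.all(np.isfinite(terms))
                if fm in bounds:
                    assert np.all(terms <= bounds[fm] + 1e-12)

    def test_tig_zero_observation_bins_are_plus_one(self, trained_table):
        pot = ig.build_potential(trained_table, "TIG")
        found = 0
        for key, stats in trained_table.sufficient_pairs().items():
            mask = (stats.frequencies == 0) & (trained_table.reference > 0)
            if mask.any():
                found += int(mask.sum())
                assert np.all(pot.per_pair[key][mask] == 1.0)
        assert found > 0  # clash-region bins must exist in a trained table

    def test_pmf_terms_dominate_tig_terms(self, trained_table):
        pmf = ig.build_potential(trained_table, "PMF")
        tig = ig.build_potential(trained_table, "TIG")
        for key in pmf.per_pair:
            assert np.all(pmf.per_pair[key] >= tig.per_pair[key] - 1e-12)

    def test_insufficient_pairs_omitted(self):
        ref = np.full(30, 1 / 30)
        table = ig.FrequencyTable(
            BinGrid(),
            {ig.PairTypeKey(("ALA", "CA"), ("ALA", "CA")): ig.PairStats(ref.copy(), 10),
             ig.PairTypeKey(("GLY", "CA"), ("GLY", "CA")): ig.PairStats(np.zeros(30), 1)},
            ref.copy())
        pot = ig.build_potential(table, "TIG")
        assert len(pot.per_pair) == 1

    def test_unknown_formalism_rejected(self, trained_table):
        with pytest.raises(ValueError):
            ig.build_potential(trained_table, "DOPE")


class TestScoreStructure:
    def test_no_qualifying_pairs_scores_zero(self, tig_potential):
        coords = [[40.0 * i, 0, 0] for i in range(4)]
        m = make_model(coords)
        rep = ig.score_structure(m, tig_potential)
        assert rep.total == 0.0
        assert rep.n_pairs_scored == 0

    def test_deterministic(self, small_corpus, tig_potential):
        r1 = ig.score_structure(small_corpus[0], tig_potential)
        r2 = ig.score_structure(small_corpus[0], tig_potential)
        assert r1.total == r2.total

    @pytest.mark.parametrize("formalism", ig.FORMALISMS)
    def test_matches_brute_force_oracle(self, formalism, trained_table):
        pot = ig.build_potential(trained_table, formalism)
        model = ig.generate_native(ig.SyntheticSpec(n_residues=50, seed=99))
        rep = ig.score_structure(model, pot)
        terms = []
        skipped = 0
        for key, d in brute_force_pairs(model, 4, 15.0):
            row = pot.per_pair.get(key)
            if row is None:
                skipped += 1
            else:
                terms.append(float(row[int(d / 0.5)]))
        assert rep.n_pairs_scored == len(terms)
        assert rep.n_pairs_skipped == skipped
        assert rep.total == pytest.approx(math.fsum(terms), abs=1e-9 * max(1.0, abs(rep.total)))

    def test_unknown_pair_types_skipped(self, trained_table):
        pot = ig.build_potential(trained_table, "TIG")
        # UNK-free model but with a pair type the ca_only table cannot contain
        m = make_model([[0, 0, 0], [6, 0, 0]], atom_names=["CB", "CB"],
                       resnames=["ALA", "ALA"], residue_indices=[0, 4])
        rep = ig.score_structure(m, pot, selection="all_heavy")
        assert rep.total == 0.0
        assert rep.n_pairs_skipped == 1

    def test_additivity_over_pair_partition(self, trained_table, tig_potential):
        # total equals the sum of per-pair term lookups in any grouping
        model = ig.generate_native(ig.SyntheticSpec(n_residues=60, seed=5))
        rep = ig.score_structure(model, tig_potential)
        per_key: dict = {}
        for key, d in brute_force_pairs(model, 4, 15.0):
            if key in tig_potential.per_pair:
                per_key.setdefault(key, []).append(tig_potential.per_pair[key][int(d / 0.5)])
        partition_total = math.fsum(math.fsum(v) for v in per_key.values())
        assert rep.total == pytest.approx(partition_total, abs=1e-9 * max(1.0, abs(rep.total)))

    def test_rigid_motion_invariance(self, tig_potential):
        model = ig.generate_native(ig.SyntheticSpec(n_residues=60, seed=12))
        rng = np.random.default_rng(1)
        R = random_rotation(rng)
        moved = model.with_coords(model.coords() @ R.T + np.array([10.0, -4.0, 2.0]))
        r1 = ig.score_structure(model, tig_potential)
        r2 = ig.score_structure(moved, tig_potential)
        assert r1.total == pytest.approx(r2.total, abs=1e-6)
        assert r1.n_pairs_scored == r2.n_pairs_scored

    def test_empty_after_selection_rejected(self, tig_potential):
        m = make_model([[0, 0, 0], [6, 0, 0]], atom_names=["CB", "CB"],
                       residue_indices=[0, 4])
        with pytest.raises(ig.EmptyChainError):
            ig.score_structure(m, tig_potential, selection="ca_only")


class TestScoreProfile:
    def test_profile_shape(self, tig_potential):
        key = next(iter(tig_potential.per_pair))
        prof = ig.score_profile(tig_potential, key)
        assert len(prof) == 30
        assert prof["bin_center"].iloc[0] == pytest.approx(0.25)
        assert prof["bin_center"].iloc[-1] == pytest.approx(14.75)

    def test_repulsive_plateaus(self, trained_table, tig_potential):
        # below the shortest observed distances: +1 where the reference has
        # support, +10 where nothing at all was ever observed
        short = trained_table.grid.centers < 4.0
        n_plateau1 = n_plateau10 = 0
        for key, stats in trained_table.sufficient_pairs().items():
            prof = ig.score_profile(tig_potential, key)["score"].to_numpy()
            plateau1 = short & (stats.frequencies == 0) & (trained_table.reference > 0)
            plateau10 = short & (trained_table.reference == 0)
            assert np.all(prof[plateau1] == 1.0)
            assert np.all(prof[plateau10] == 10.0)
            n_plateau1 += int(plateau1.sum())
            n_plateau10 += int(plateau10.sum())
        assert n_plateau1 > 0  # clash-region bins unobserved for some pair type

    def test_pmf_profile_dominates_tig_profile(self, trained_table):
        pmf = ig.build_potential(trained_table, "PMF")
        tig = ig.build_potential(trained_table, "TIG")
        key = next(iter(pmf.per_pair))
        p = ig.score_profile(pmf, key)["score"].to_numpy()
        t = ig.score_profile(tig, key)["score"].to_numpy()
        assert np.all(p >= t - 1e-12)

    def test_unknown_key_lists_near_matches(self, tig_potential):
        bogus = ig.PairTypeKey(("ZZZ", "XX"), ("ZZZ", "XX"))
        with pytest.raises(KeyError, match="nearest available"):
            ig.score_profile(tig_potential, bogus)
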