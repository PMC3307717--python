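import itertools
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hairpinhmm import hmm_core as hc
from hairpinhmm import simulator as sim

from conftest import make_pattern
from helpers import (
    brute_best_explanation,
    brute_loglik,
    brute_orientation_posterior,
    brute_state_marginals,
    random_locus,
    random_params,
    random_pattern,
)

probs = st.floats(0.0, 1.0, allow_nan=False)


class TestTransitions:
    def test_per_bp_direct_substitution(self):
        T = hc.per_bp_transition(hc.EnzymeProcessParams(0.12, 0.002))
        # staying associated = processivity (1-d) + fall-off-and-rebind (d*r)
        assert np.allclose(T, [[0.88, 0.12],
                               [0.002 * 0.88, 0.998 + 0.002 * 0.12]])

    def test_no_processivity_rows_identical(self):
        """d = 1 means the association state is independent site to site."""
        T = hc.per_bp_transition(hc.EnzymeProcessParams(0.3, 1.0))
        assert np.allclose(T[0], T[1])

    def test_absorbing_chain_is_identity(self):
        T = hc.per_bp_transition(hc.EnzymeProcessParams(0.0, 0.0))
        assert np.allclose(T, np.eye(2))

    def test_distance_one_equals_per_bp(self):
        p = hc.EnzymeProcessParams(0.4, 0.1)
        assert np.allclose(hc.transition_over_distance(p, 1),
                           hc.per_bp_transition(p))

    def test_matches_repeated_multiplication(self):
        p = hc.EnzymeProcessParams(0.12, 0.002)
        expected = np.linalg.matrix_power(hc.per_bp_transition(p), 6)
        assert np.allclose(hc.transition_over_distance(p, 6), expected,
                           atol=1e-14)

    def test_long_distance_reaches_stationary(self):
        p = hc.EnzymeProcessParams(0.12, 0.002)
        f = hc.stationary_association_frequency(p)
        T = hc.transition_over_distance(p, 10 ** 5)
        assert np.allclose(T, [[1 - f, f], [1 - f, f]], atol=1e-12)

    def test_rejects_zero_distance(self):
        with pytest.raises(ValueError):
            hc.transition_over_distance(hc.EnzymeProcessParams(0.1, 0.1), 0)

    @given(probs, probs, st.integers(1, 50))
    @settings(derandomize=True, deadline=None)
    def test_row_stochastic(self, r, d, L):
        T = hc.transition_over_distance(hc.EnzymeProcessParams(r, d), L)
        assert np.all(T >= -1e-12) and np.all(T <= 1 + 1e-12)
        assert np.allclose(T.sum(axis=1), 1.0, atol=1e-12)


class TestStationaryAndTracts:
    def test_association_frequency(self):
        """At the Xi-linked regime DNMT1 is associated ~99% of the time."""
        p = hc.EnzymeProcessParams(0.12, 0.002)
        f = hc.stationary_association_frequency(p)
        assert f == pytest.approx(0.12 / (0.12 + 0.002 * 0.88), rel=1e-12)
        assert round(f, 2) == 0.99

    def test_no_processivity_limit_is_reassociation_rate(self):
        """With d = 1 association is independent per site with probability r."""
        assert hc.stationary_association_frequency(
            hc.EnzymeProcessParams(0.3, 1.0)) == pytest.approx(0.3)

    def test_never_reassociates(self):
        assert hc.stationary_association_frequency(
            hc.EnzymeProcessParams(0.0, 0.5)) == 0.0

    def test_undefined_for_degenerate_chain(self):
        with pytest.raises(ValueError):
            hc.stationary_association_frequency(hc.EnzymeProcessParams(0.0, 0.0))

    def test_mean_tract_lengths(self):
        assoc, non = hc.mean_tract_lengths(hc.EnzymeProcessParams(0.1, 0.002))
        assert assoc == pytest.approx(500.0)
        assert non == pytest.approx(10.0)

    def test_dissociates_every_bp(self):
        assert hc.mean_tract_lengths(hc.EnzymeProcessParams(0.5, 1.0))[0] == 1.0

    def test_infinite_tract_reported_as_inf(self):
        assoc, non = hc.mean_tract_lengths(hc.EnzymeProcessParams(0.0, 0.0))
        assert assoc == np.inf and non == np.inf


class TestJointTransition:
    def test_identity_when_all_frozen(self, fmr1_params):
        frozen = replace(
            fmr1_params,
            process_dnmt1=hc.EnzymeProcessParams(0.0, 0.0),
            process_dnmt3_parent=hc.EnzymeProcessParams(0.0, 0.0),
            process_dnmt3_daughter=hc.EnzymeProcessParams(0.0, 0.0))
        assert np.allclose(hc.joint_transition(frozen, 5), np.eye(8))

    def test_entries_are_products_of_marginals(self, fmr1_params):
        L = 4
        mats = [hc.transition_over_distance(p, L) for p in fmr1_params.processes]
        J = hc.joint_transition(fmr1_params, L)
        for s_from in range(8):
            for s_to in range(8):
                bits_from = hc.state_bits(s_from)
                bits_to = hc.state_bits(s_to)
                expected = np.prod([mats[k][bits_from[k], bits_to[k]]
                                    for k in range(3)])
                assert J[s_from, s_to] == pytest.approx(expected, rel=1e-12)

    def test_matches_powered_single_bp_matrix(self):
        rng = np.random.default_rng(1)
        params = random_params(rng, 3)
        J1 = hc.joint_transition(params, 1)
        assert np.allclose(hc.joint_transition(params, 7),
                           np.linalg.matrix_power(J1, 7), atol=1e-12)

    def test_row_stochastic(self):
        rng = np.random.default_rng(2)
        J = hc.joint_transition(random_params(rng, 3), 9)
        assert np.allclose(J.sum(axis=1), 1.0, atol=1e-12)


class TestEmissions:
    def test_worked_maintenance_plus_double_de_novo_cell(self):
        """P(fully methylated | DNMT1+parent-DNMT3 associated) = m*mu1+(1-m)*delta1."""
        a = hc.ActivityParams(mu1=0.99, delta1=0.02)
        m = 0.88
        dist = hc.emission_true((1, 1, 0), m, a)
        assert dist[3] == pytest.approx(m * 0.99 + (1 - m) * 0.02, rel=1e-12)

    def test_nothing_can_methylate(self):
        dist = hc.emission_true((0, 0, 0), 0.0, hc.ActivityParams(0.9, 0.1))
        assert dist[0] == 1.0 and np.allclose(dist[1:], 0.0)

    def test_daughter_dnmt3_always_methylates(self):
        a = hc.ActivityParams(mu1=0.5, delta1=0.1, mu3=1.0, delta3=1.0)
        m = 0.3
        dist = hc.emission_true((1, 0, 1), m, a).reshape(2, 2)
        assert dist[:, 1].sum() == pytest.approx(1.0)   # daughter methylated
        assert dist[1].sum() == pytest.approx(m)        # parent methylated iff z=1

    @given(st.integers(0, 7), probs, probs, probs, probs, probs)
    @settings(derandomize=True, deadline=None)
    def test_true_emission_normalized(self, s, m, mu1, delta1, mu3, delta3):
        dist = hc.emission_true(s, m, hc.ActivityParams(mu1, delta1, mu3, delta3))
        assert np.all(dist >= 0)
        assert dist.sum() == pytest.approx(1.0, abs=1e-12)

    def test_error_free_channel_is_identity(self):
        a = hc.ActivityParams(0.9, 0.2, 0.7, 0.3)
        for s in range(8):
            assert np.allclose(
                hc.emission_observed(s, 0.6, a, hc.ErrorParams(0.0, 0.0)),
                hc.emission_true(s, 0.6, a))

    def test_independent_flips_of_unmethylated_truth(self):
        dist = hc.emission_observed((0, 0, 0), 0.0, hc.ActivityParams(1, 1),
                                    hc.ErrorParams(p_fail_conversion=0.1,
                                                   p_inappropriate=0.0))
        assert dist[3] == pytest.approx(0.01, rel=1e-12)

    @given(st.integers(0, 7), probs, st.floats(0, 0.5), st.floats(0, 0.5))
    @settings(derandomize=True, deadline=None)
    def test_observed_emission_normalized(self, s, m, pf, pi_):
        dist = hc.emission_observed(s, m, hc.ActivityParams(0.9, 0.1),
                                    hc.ErrorParams(pf, pi_))
        assert dist.sum() == pytest.approx(1.0, abs=1e-12)


class TestLikelihood:
    def test_matches_enumeration_two_sites(self, toy_locus):
        rng = np.random.default_rng(3)
        locus = random_locus(rng, 2)
        params = random_params(rng, 2)
        pat = random_pattern(rng, 2)
        assert hc.pattern_loglik(pat, locus, params) == pytest.approx(
            brute_loglik(pat, locus, params), rel=1e-10)

    @given(st.integers(0, 10 ** 6))
    @settings(derandomize=True, deadline=None, max_examples=20)
    def test_matches_enumeration_random(self, seed):
        """Forward likelihood equals the sum over all 2*8^S explanations."""
        rng = np.random.default_rng(seed)
        S = int(rng.integers(2, 6))
        locus = random_locus(rng, S)
        params = random_params(rng, S)
        pat = random_pattern(rng, S)
        assert hc.pattern_loglik(pat, locus, params) == pytest.approx(
            brute_loglik(pat, locus, params), rel=1e-10)

    def test_fully_missing_pattern_has_probability_one(self, toy_locus):
        rng = np.random.default_rng(4)
        params = random_params(rng, 3)
        pat = make_pattern("???", "???")
        assert hc.pattern_loglik(pat, toy_locus, params) == pytest.approx(0.0, abs=1e-12)

    def test_strand_swap_leaves_likelihood_unchanged(self, toy_locus):
        rng = np.random.default_rng(5)
        params = random_params(rng, 3)
        pat = make_pattern("101", "110")
        assert hc.pattern_loglik(pat, toy_locus, params) == pytest.approx(
            hc.pattern_loglik(pat.swapped(), toy_locus, params), rel=1e-12)

    def test_factorizes_when_dissociation_certain(self, toy_locus):
        """With d = 1 everywhere there is no spatial dependence: the pattern
        likelihood equals a product of independent per-site mixtures computed
        without any forward recursion, mixed over orientations."""
        rng = np.random.default_rng(6)
        params = random_params(rng, 3)
        params = replace(
            params,
            process_dnmt1=hc.EnzymeProcessParams(0.37, 1.0),
            process_dnmt3_parent=hc.EnzymeProcessParams(0.11, 1.0),
            process_dnmt3_daughter=hc.EnzymeProcessParams(0.62, 1.0))
        pat = make_pattern("110", "011")
        params_c = params.constrained()
        m = params_c.densities.as_array()

        # independent per-site computation: with d = 1 every site's association
        # is an independent Bernoulli(r) draw for each process
        def site_dist(i):
            ps = [np.array([1 - p.reassoc_per_bp, p.reassoc_per_bp])
                  for p in params_c.processes]
            out = np.zeros(4)
            for s1, s3p, s3d in itertools.product((0, 1), repeat=3):
                w = ps[0][s1] * ps[1][s3p] * ps[2][s3d]
                out += w * hc.emission_observed((s1, s3p, s3d), m[i],
                                                params_c.activity, params_c.errors)
            return out

        total = 0.0
        for obs_p, obs_d in ((pat.strand_a, pat.strand_b),
                             (pat.strand_b, pat.strand_a)):
            prob = 0.5
            for i in range(3):
                prob *= site_dist(i)[2 * int(obs_p[i]) + int(obs_d[i])]
            total += prob
        assert hc.pattern_loglik(pat, toy_locus, params) == pytest.approx(
            np.log(total), rel=1e-10)


class TestOrientationPosterior:
    def test_symmetric_pattern_is_half(self, toy_locus):
        rng = np.random.default_rng(7)
        params = random_params(rng, 3)
        pat = make_pattern("101", "101")
        assert hc.orientation_posterior(pat, toy_locus, params) == pytest.approx(0.5)

    def test_swap_complements_posterior(self, toy_locus):
        rng = np.random.default_rng(8)
        params = random_params(rng, 3)
        pat = make_pattern("110", "001")
        p = hc.orientation_posterior(pat, toy_locus, params)
        q = hc.orientation_posterior(pat.swapped(), toy_locus, params)
        assert p == pytest.approx(1.0 - q, abs=1e-12)

    def test_matches_enumeration(self, toy_locus):
        rng = np.random.default_rng(9)
        params = random_params(rng, 3)
        pat = make_pattern("100", "011")
        assert hc.orientation_posterior(pat, toy_locus, params) == pytest.approx(
            brute_orientation_posterior(pat, toy_locus, params), rel=1e-10)

    def test_concentrates_on_true_orientation(self, fmr1_locus):
        """Hemi-rich molecules (DNMT1 frequently detached) carry strong
        orientation signal: the methyl-bearing strand of a hemi run is the
        parent.  Decisive posteriors should agree with the simulated truth."""
        params = replace(
            sim.fmr1_regime_params(),
            process_dnmt1=hc.EnzymeProcessParams(0.05, 0.05),
            errors=hc.ErrorParams(0.0, 0.0))
        pats, truth = sim.simulate_dataset(sim.SimulationSpec(
            locus=fmr1_locus, true_params=params, n_patterns=120, seed=10))
        correct = total = 0
        for i, pat in enumerate(pats):
            p = hc.orientation_posterior(pat, fmr1_locus, params)
            if abs(p - 0.5) > 0.3:  # only judge decisively assigned molecules
                total += 1
                correct += (p > 0.5) == bool(truth.a_is_parent[i])
        assert total >= 20
        assert correct / total > 0.9


class TestStateMarginals:
    def test_marginals_sum_to_one(self, fmr1_locus, fmr1_params):
        pats, _ = sim.simulate_dataset(sim.SimulationSpec(
            locus=fmr1_locus, true_params=fmr1_params, n_patterns=3, seed=11))
        marg = hc.posterior_state_marginals(pats[0], fmr1_locus, fmr1_params)
        for key in ("A_is_parent", "B_is_parent", "mixed"):
            assert np.allclose(marg[key].sum(axis=1), 1.0, atol=1e-10)

    def test_in_vitro_variant_confines_mass_to_dnmt1_states(self, toy_locus):
        rng = np.random.default_rng(12)
        params = replace(random_params(rng, 3),
                         variant=hc.ModelVariant(kind=hc.VariantKind.IN_VITRO_DNMT1))
        pat = make_pattern("110", "010")
        marg = hc.posterior_state_marginals(pat, toy_locus, params)["mixed"]
        active = [hc.state_index(s1, 0, 0) for s1 in (0, 1)]
        inactive = [s for s in range(8) if s not in active]
        assert np.allclose(marg[:, inactive], 0.0, atol=1e-12)

    @pytest.mark.parametrize("seed", [13, 14, 15])
    def test_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        S = int(rng.integers(2, 5))
        locus = random_locus(rng, S)
        params = random_params(rng, S)
        pat = random_pattern(rng, S)
        marg = hc.posterior_state_marginals(pat, locus, params)["mixed"]
        assert np.allclose(marg, brute_state_marginals(pat, locus, params),
                           atol=1e-10)


class TestKBest:
    @pytest.mark.parametrize("seed", [16, 17, 18])
    def test_best_explanation_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        S = int(rng.integers(2, 5))
        locus = random_locus(rng, S)
        params = random_params(rng, S)
        pat = random_pattern(rng, S)
        top = hc.kbest_explanations(pat, locus, params, k=1)[0]
        orient, path, post = brute_best_explanation(pat, locus, params)
        assert top.orientation == ("A_is_parent", "B_is_parent")[orient]
        assert top.path == path
        assert top.posterior == pytest.approx(post, rel=1e-9)

    def test_probabilities_descending_and_bounded(self, toy_locus):
        rng = np.random.default_rng(19)
        params = random_params(rng, 3)
        pat = make_pattern("101", "011")
        expls = hc.kbest_explanations(pat, toy_locus, params, k=6)
        posts = [e.posterior for e in expls]
        assert all(0 <= p <= 1 for p in posts)
        assert posts == sorted(posts, reverse=True)

    def test_all_explanations_sum_to_one(self, toy_locus):
        """On a 3-site pattern the 2*8^3 explanation posteriors total 1."""
        rng = np.random.default_rng(20)
        params = random_params(rng, 3)
        pat = make_pattern("110", "100")
        expls = hc.kbest_explanations(pat, toy_locus, params, k=2 * 8 ** 3)
        assert len(expls) == 2 * 8 ** 3
        assert sum(e.posterior for e in expls) == pytest.approx(1.0, rel=1e-8)

    def test_rejects_nonpositive_k(self, toy_locus):
        pat = make_pattern("101", "011")
        with pytest.raises(ValueError):
            hc.kbest_explanations(pat, toy_locus,
                                  sim.fmr1_regime_params(n_sites=3), k=0)


class TestVariants:
    def test_default_variant_pins_dnmt3_activity(self):
        rng = np.random.default_rng(21)
        p = random_params(rng, 3).constrained()
        assert p.activity.mu3 == 1.0 and p.activity.delta3 == 1.0

    def test_dnmt3_hemi_variant_pins_dnmt1_activity(self):
        rng = np.random.default_rng(22)
        p = replace(random_params(rng, 3),
                    variant=hc.ModelVariant(kind=hc.VariantKind.DNMT3_HEMI))
        c = p.constrained()
        assert c.activity.mu1 == 1.0 and c.activity.delta1 == 0.0

    def test_errors_off_flag_zeroes_error_rates(self):
        rng = np.random.default_rng(23)
        p = replace(random_params(rng, 3),
                    variant=hc.ModelVariant(errors_off=True))
        c = p.constrained()
        assert c.errors.p_fail_conversion == 0.0
        assert c.errors.p_inappropriate == 0.0

    def test_state_packing_order(self):
        assert hc.state_index(1, 0, 0) == 4
        assert hc.state_index(0, 1, 0) == 2
        assert hc.state_index(0, 0, 1) == 1
        assert hc.state_bits(7) == (1, 1, 1)
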