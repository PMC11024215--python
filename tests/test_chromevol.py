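"""Chromosome-number CTMC: generator assembly, pruning likelihood, mapping."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.linalg import expm

import sharkpcm as sp
from sharkpcm.chromevol import (ChromModel, ChromObservations, ancestral_chrom_probs,
                                build_rate_matrix, chrom_likelihood, default_model_family,
                                expected_transitions, fit_chrom_model, select_chrom_model)
from sharkpcm.trees import transform_tree


class TestRateMatrix:
    def test_hand_assembled_gain_loss(self):
        Q = build_rate_matrix(ChromModel("t", bounds=(1, 3)), {"gain": 2.0, "loss": 1.0})
        np.testing.assert_allclose(Q, [[-2, 2, 0], [1, -3, 2], [0, 1, -1]])

    def test_rows_sum_to_zero_for_random_models(self, rng):
        for _ in range(20):
            m = ChromModel("t", duplication=True, demi=True,
                           linear=bool(rng.integers(2)), bounds=(5, 30))
            rates = {k: float(rng.uniform(0, 5)) for k in m.param_names}
            Q = build_rate_matrix(m, rates)
            np.testing.assert_allclose(Q.sum(axis=1), 0.0, atol=1e-12)
            off = Q - np.diag(np.diag(Q))
            assert np.all(off >= 0)

    def test_duplication_clipped_at_upper_bound(self):
        m = ChromModel("t", duplication=True, bounds=(28, 64))
        Q = build_rate_matrix(m, {"gain": 1.0, "loss": 1.0, "duplication": 2.0})
        i = 40 - 28
        # 40 -> 80 exceeds s_max: only gain/loss leave state 40
        assert -Q[i, i] == pytest.approx(2.0)

    def test_transition_matrix_rows_sum_to_one(self, rng):
        m = ChromModel("t", duplication=True, bounds=(10, 40))
        rates = {"gain": 3.0, "loss": 2.0, "duplication": 0.5}
        Q = build_rate_matrix(m, rates)
        for t in (0.01, 0.3, 2.0):
            P = expm(Q * t)
            np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-10)
            assert np.all(P >= -1e-12)


class TestObservations:
    def test_point_polymorphic_missing_coding(self):
        obs = ChromObservations.from_counts(
            {"a": 31, "b": "30:2;31:1", "c": "X"}, bounds=(29, 33))
        a, b, c = obs.probs
        np.testing.assert_allclose(a, [0, 0, 1, 0, 0])
        np.testing.assert_allclose(b, [0, 2 / 3, 1 / 3, 0, 0])
        np.testing.assert_allclose(c, 1.0)

    def test_default_bounds_rule(self):
        obs = ChromObservations.from_counts({"a": 28, "b": 54})
        assert obs.bounds == (27, 64)


class TestLikelihood:
    def test_zero_length_tree_point_root(self):
        # no time, no change: likelihood is the root mass (0 on the log scale)
        t = sp.parse_newick("(A:0,B:0);")
        m = ChromModel("t", bounds=(1, 3))
        obs = ChromObservations.from_counts({"A": 2, "B": 2}, bounds=(1, 3))
        from sharkpcm.chromevol import _pruning

        Q = build_rate_matrix(m, {"gain": 1.0, "loss": 1.0})
        *_, L, logscale = _pruning(t, obs, Q)
        root = L[-1] / L[-1].sum()
        assert np.log(L[-1] @ root) + logscale[-1] == pytest.approx(0.0)

    def test_single_branch_two_state_closed_form(self):
        t = sp.parse_newick("(A:1,B:0);")
        m = ChromModel("t", loss=False, bounds=(1, 2))
        obs = ChromObservations.from_counts({"A": 1, "B": 1}, bounds=(1, 2))
        lnl = chrom_likelihood(t, obs, m, {"gain": 1.0})
        # root is pinned at 1 by the zero-length tip; P(stay) = e^-1
        assert lnl == pytest.approx(-1.0, abs=1e-10)

    def test_pruning_equals_enumeration_on_three_tips(self):
        t = sp.parse_newick("((A:0.3,B:0.2):0.1,C:0.4);")
        m = ChromModel("t", duplication=True, bounds=(1, 6))
        rates = {"gain": 1.2, "loss": 0.7, "duplication": 0.4}
        obs = ChromObservations.from_counts({"A": 2, "B": 3, "C": "X"}, bounds=(1, 6))
        lnl = chrom_likelihood(t, obs, m, rates)
        # oracle: explicit sum over root and internal node states
        Q = build_rate_matrix(m, rates)
        P_ab = expm(Q * 0.1)
        P_a, P_b, P_c = expm(Q * 0.3), expm(Q * 0.2), expm(Q * 0.4)
        va, vb, vc = obs.probs[0], obs.probs[1], obs.probs[2]
        L_root = np.array([
            sum(P_ab[r, n] * (P_a[n] @ va) * (P_b[n] @ vb) for n in range(6)) * (P_c[r] @ vc)
            for r in range(6)])
        pi = L_root / L_root.sum()
        assert lnl == pytest.approx(np.log(L_root @ pi), abs=1e-8)

    def test_invariant_to_state_space_padding(self):
        t = sp.parse_newick("((A:0.3,B:0.2):0.1,C:0.4);")
        rates = {"gain": 1.0, "loss": 0.5}
        obs = ChromObservations.from_counts({"A": 5, "B": 6, "C": 4}, bounds=(3, 8))
        lnl1 = chrom_likelihood(t, obs, ChromModel("t", bounds=(3, 8)), rates)
        padded = obs.pad((3, 20))
        lnl2 = chrom_likelihood(t, padded, ChromModel("t", bounds=(3, 20)), rates)
        assert lnl2 == pytest.approx(lnl1, abs=1e-6)

    def test_unknown_species_rejected(self, three_taxon_tree):
        obs = ChromObservations.from_counts({"A": 2, "B": 2, "C": 2, "Z": 2}, bounds=(1, 3))
        with pytest.raises(ValueError, match="Z"):
            chrom_likelihood(three_taxon_tree, obs, ChromModel("t", bounds=(1, 3)),
                             {"gain": 1.0, "loss": 1.0}, normalize=True)


class TestFitting:
    def test_monomorphic_tips_push_rates_to_floor(self):
        t = transform_tree(sp.simulate_yule_tree(10, 1.0, seed=1), "normalize_length", 0.0)
        obs = ChromObservations.from_counts(
            {l: 40 for l in sp.trees.tip_labels(t)}, bounds=(38, 44))
        fit = fit_chrom_model(t, obs, ChromModel("t", bounds=(38, 44)), n_restarts=2)
        assert fit.rates["gain"] < 0.01 and fit.rates["loss"] < 0.01
        assert fit.lnl == pytest.approx(0.0, abs=1e-3)

    def test_model_family_and_selection(self):
        fam = default_model_family((10, 20))
        assert len(fam) == 8
        ks = sorted(m.n_params for m in fam)
        assert ks == [2, 3, 3, 4, 4, 5, 5, 6]
        t = transform_tree(sp.simulate_yule_tree(12, 1.0, seed=2), "normalize_length", 0.0)
        counts, _ = sp.simulate_chromosome_numbers(t, {"gain": 15.0, "loss": 25.0},
                                                   40, (30, 50), seed=3)
        obs = ChromObservations.from_counts(counts, bounds=(30, 50))
        fits = [fit_chrom_model(t, obs, m.with_bounds((30, 50)), n_restarts=1)
                for m in fam[:4]]
        best = select_chrom_model(fits)
        assert best.aic == min(f.aic for f in fits)
        assert best.aic == pytest.approx(2 * best.model.n_params - 2 * best.lnl)


class TestAncestralAndMapping:
    def test_near_frozen_chain_concentrates_on_tip_state(self):
        t = transform_tree(sp.simulate_yule_tree(6, 1.0, seed=4), "normalize_length", 0.0)
        obs = ChromObservations.from_counts(
            {l: 33 for l in sp.trees.tip_labels(t)}, bounds=(30, 36))
        m = ChromModel("t", bounds=(30, 36))
        from sharkpcm.chromevol import ChromFit

        fit = ChromFit(m, {"gain": 1e-6, "loss": 1e-6}, 0.0, 0.0)
        anc = ancestral_chrom_probs(t, obs, fit)
        for nid in anc.node_ids:
            assert anc.modal_state(nid) == 33
            assert anc.probs[anc.node_ids.index(nid)].max() > 0.999

    def test_two_tip_bayes_oracle(self):
        t = sp.parse_newick("(A:0.6,B:0.4);")
        m = ChromModel("t", bounds=(1, 4))
        rates = {"gain": 1.0, "loss": 2.0}
        obs = ChromObservations.from_counts({"A": 2, "B": 3}, bounds=(1, 4))
        from sharkpcm.chromevol import ChromFit, build_rate_matrix

        fit = ChromFit(m, rates, 0.0, 0.0)
        anc = ancestral_chrom_probs(t, obs, fit)
        Q = build_rate_matrix(m, rates)
        Pa, Pb = expm(Q * 0.6), expm(Q * 0.4)
        L = Pa[:, 1] * Pb[:, 2]  # tip states 2 and 3 are indices 1 and 2
        pi = L / L.sum()
        post = pi * L
        post /= post.sum()
        np.testing.assert_allclose(anc.probs[0], post, atol=1e-10)

    def test_marginals_match_mapping_frequencies(self):
        t = transform_tree(sp.simulate_yule_tree(8, 1.0, seed=5), "normalize_length", 0.0)
        counts, _ = sp.simulate_chromosome_numbers(t, {"gain": 8.0, "loss": 12.0},
                                                   20, (15, 25), seed=6)
        obs = ChromObservations.from_counts(counts, bounds=(15, 25))
        m = ChromModel("t", bounds=(15, 25))
        fit = fit_chrom_model(t, obs, m, n_restarts=1)
        anc = ancestral_chrom_probs(t, obs, fit)
        ex = expected_transitions(t, obs, fit, n_sims=4000, seed=7, return_states=True)
        root_id = anc.node_ids[0]
        freq = (ex.node_state_samples[root_id].value_counts(normalize=True)
                .reindex(anc.states, fill_value=0.0).to_numpy())
        np.testing.assert_allclose(freq, anc.probs[0], atol=0.03)

    def test_all_rates_zero_no_events(self):
        t = transform_tree(sp.simulate_yule_tree(5, 1.0, seed=8), "normalize_length", 0.0)
        obs = ChromObservations.from_counts(
            {l: 12 for l in sp.trees.tip_labels(t)}, bounds=(10, 14))
        from sharkpcm.chromevol import ChromFit

        fit = ChromFit(ChromModel("t", bounds=(10, 14)), {"gain": 0.0, "loss": 0.0}, 0.0, 0.0)
        with pytest.warns(UserWarning):
            ex = expected_transitions(t, obs, fit, n_sims=50, seed=9)
        assert all(v == 0.0 for v in ex.totals.values())

    def test_branch_expectation_matches_integral_oracle(self):
        """E[#i->j jumps | endpoints] has a closed integral form; mapping must agree."""
        m = ChromModel("t", bounds=(1, 3))
        rates = {"gain": 1.5, "loss": 1.0}
        Q = build_rate_matrix(m, rates)
        t_len, a, b = 0.8, 0, 0  # start = end = state 1 (index 0)
        P = expm(Q * t_len)
        expect = {}
        for (i, j) in itertools.product(range(3), range(3)):
            if i == j or Q[i, j] == 0:
                continue
            val = Q[i, j] / P[a, b] * quad(
                lambda s: expm(Q * s)[a, i] * expm(Q * (t_len - s))[j, b], 0, t_len)[0]
            expect[(i, j)] = val
        gain_oracle = expect.get((0, 1), 0) + expect.get((1, 2), 0)
        loss_oracle = expect.get((1, 0), 0) + expect.get((2, 1), 0)
        # mapping on a 2-tip tree pinning both endpoints via zero-length tip
        tree = sp.parse_newick(f"(A:{t_len},B:0);")
        obs = ChromObservations.from_counts({"A": 1, "B": 1}, bounds=(1, 3))
        from sharkpcm.chromevol import ChromFit

        fit = ChromFit(m, rates, 0.0, 0.0)
        ex = expected_transitions(tree, obs, fit, n_sims=8000, seed=10)
        assert ex.expected.loc["A", "gain"] == pytest.approx(gain_oracle, abs=0.05)
        assert ex.expected.loc["A", "loss"] == pytest.approx(loss_oracle, abs=0.05)

    def test_mapping_totals_converge_when_doubling_draws(self, sharklike):
        obs = ChromObservations.from_counts(sharklike.chromosomes)
        norm = transform_tree(sharklike.tree, "normalize_length", 0.0)
        m = ChromModel("Constant Rate with No Duplication", bounds=obs.bounds)
        fit = fit_chrom_model(norm, obs, m, n_restarts=1)
        a = expected_transitions(norm, obs, fit, n_sims=2000, seed=12)
        b = expected_transitions(norm, obs, fit, n_sims=4000, seed=13)
        for typ in ("gain", "loss"):
            if a.totals[typ] > 1.0:
                assert abs(b.totals[typ] - a.totals[typ]) / a.totals[typ] < 0.02

    def test_totals_are_branch_sums(self, sharklike):
        obs = ChromObservations.from_counts(sharklike.chromosomes)
        norm = transform_tree(sharklike.tree, "normalize_length", 0.0)
        m = ChromModel("Constant Rate with No Duplication", bounds=obs.bounds)
        fit = fit_chrom_model(norm, obs, m, n_restarts=1)
        ex = expected_transitions(norm, obs, fit, n_sims=200, seed=11)
        for typ in ("gain", "loss"):
            assert ex.totals[typ] == pytest.approx(ex.expected[typ].sum())
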