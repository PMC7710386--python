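"""8-state motif-evolution CTMC: generators, likelihoods, fitting, comparison."""

import itertools

import dendropy
import numpy as np
import pytest
from scipy.linalg import expm

from patternblend.traitevo import (
    MOTIF_NAMES,
    N_STATES,
    FitResult,
    RateModel,
    compare_models,
    ctmc_likelihood,
    expand_rates,
    fit_model,
    maze_rate_summary,
    prune_to_genus,
    scale_to_unit_height,
    simulate_ctmc,
    state_bits,
    state_index,
    state_label,
    stepping_stone_evidence,
)


def tree_from(nwk: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=nwk, schema="newick")


def make_dependent(d=8.0, abc=0.1, efg=2.0, h=0.1, spot_gain=3.0, spot_loss=0.5):
    """Dependent generator with Maze gain boosted in the both-spots context."""
    base = RateModel.create("dependent")
    rates = []
    for nm in base.names:
        motif, rest = nm.split(":", 1)
        if motif == "Maze":
            both = "Sp-D=1" in rest and "Sp-L=1" in rest
            rates.append((d if both else abc) if rest.startswith("gain") else (h if both else efg))
        else:
            rates.append(spot_gain if rest.startswith("gain") else spot_loss)
    return RateModel.create("dependent", rates)


class TestStateCoding:
    def test_bijection_and_labels(self):
        seen = set()
        for bits in itertools.product((0, 1), repeat=3):
            s = state_index(*bits)
            assert state_bits(s) == bits
            assert state_label(s) == "".join(map(str, bits))
            seen.add(s)
        assert seen == set(range(8))


class TestRateModel:
    @pytest.mark.parametrize(
        "model_class,n", [("independent", 6), ("dependent", 24), ("ind-Maze", 10), ("ind-Sp-D", 10)]
    )
    def test_parameter_counts(self, model_class, n):
        assert RateModel.create(model_class).n_params == n

    def test_generator_rows_sum_to_zero_single_flip_only(self):
        rng = np.random.default_rng(0)
        q = RateModel.create("dependent", rng.uniform(0.1, 5, 24)).generator()
        assert np.abs(q.sum(axis=1)).max() < 1e-12
        for s in range(N_STATES):
            for t in range(N_STATES):
                if s != t and bin(s ^ t).count("1") != 1:
                    assert q[s, t] == 0.0
                elif s != t:
                    assert q[s, t] >= 0.0

    def test_propagators_are_stochastic(self):
        q = RateModel.create("dependent", np.full(24, 2.0)).generator()
        for t in (0.01, 0.5, 5.0, 50.0):
            p = expm(q * t)
            assert np.all(p > -1e-12)
            assert np.abs(p.sum(axis=1) - 1).max() < 1e-9

    def test_expand_independent_into_dependent_contexts(self):
        ind = RateModel.create("independent", [1, 2, 3, 4, 5, 6])
        dep = RateModel.create("dependent", expand_rates(ind, "dependent"))
        s = maze_rate_summary(dep)
        assert len(set(s.gains.values())) == 1
        assert len(set(s.losses.values())) == 1

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            RateModel.create("independent", [-1, 1, 1, 1, 1, 1])


class TestLikelihood:
    def test_two_state_closed_form(self):
        # Maze gain lambda, loss 0, all other motifs frozen; root fixed at 000.
        # P(Maze present at a tip below a branch of length t) = 1 - exp(-lambda t)
        lam, t = 1.3, 0.7
        rates = {nm: 0.0 for nm in RateModel.create("independent").names}
        rates["Maze:gain"] = lam
        model = RateModel.create("independent", [rates[n] for n in RateModel.create("independent").names])
        tree = tree_from(f"(A:{t},B:{t});")
        ll = ctmc_likelihood(tree, {"A": state_index(0, 0, 1), "B": 0}, model, root=0)
        expected = (1 - np.exp(-lam * t)) * np.exp(-lam * t)
        assert ll == pytest.approx(np.log(expected), abs=1e-9)

    def test_zero_length_branch_forces_parent_state(self):
        model = RateModel.create("independent", np.full(6, 1.0))
        tree = tree_from("(A:0.0,B:0.0);")
        # both tips must then share the root state; opposite states are
        # (numerically) impossible and the shared state costs only the prior
        assert ctmc_likelihood(tree, {"A": 0, "B": 7}, model) < np.log(1e-12)
        ll_same = ctmc_likelihood(tree, {"A": 3, "B": 3}, model)
        assert ll_same == pytest.approx(np.log(1 / 8))  # uniform root prior

    def test_relabeling_symmetric_tips_preserves_likelihood(self):
        model = RateModel.create("dependent", np.random.default_rng(2).uniform(0.2, 2, 24))
        t1 = tree_from("((A:0.4,B:0.4):0.3,C:0.7);")
        states = {"A": 2, "B": 5, "C": 6}
        ll1 = ctmc_likelihood(t1, states, model)
        ll2 = ctmc_likelihood(t1, {"A": 5, "B": 2, "C": 6}, model)
        assert ll1 == pytest.approx(ll2, abs=1e-10)

    def test_pruning_matches_bruteforce_enumeration(self):
        # independent oracle: sum over all internal-node state assignments
        nwk = "((A:0.3,B:0.5):0.2,(C:0.4,D:0.1):0.6);"
        tree = tree_from(nwk)
        rng = np.random.default_rng(0)
        model = RateModel.create("dependent", rng.uniform(0.2, 3.0, 24))
        Q = model.generator()
        tips = {"A": 0, "B": 5, "C": 7, "D": 2}
        ll = ctmc_likelihood(tree, tips, model)
        PU, PV = expm(Q * 0.2), expm(Q * 0.6)
        PA, PB = expm(Q * 0.3), expm(Q * 0.5)
        PC, PD = expm(Q * 0.4), expm(Q * 0.1)
        tot = 0.0
        for r in range(8):
            for u in range(8):
                for v in range(8):
                    tot += (
                        (1 / 8)
                        * PU[r, u]
                        * PV[r, v]
                        * PA[u, tips["A"]]
                        * PB[u, tips["B"]]
                        * PC[v, tips["C"]]
                        * PD[v, tips["D"]]
                    )
        assert ll == pytest.approx(np.log(tot), abs=1e-10)

    def test_missing_tip_state_errors(self):
        model = RateModel.create("independent")
        with pytest.raises(ValueError, match="no trait state"):
            ctmc_likelihood(tree_from("(A:1,B:1);"), {"A": 0}, model)


class TestSimulateCtmc:
    def test_zero_rates_keep_root_state(self):
        model = RateModel.create("independent", np.zeros(6))
        tree = tree_from("((A:1,B:1):1,(C:1,D:1):1);")
        tips = simulate_ctmc(tree, model, root_state=5, seed=0)
        assert set(tips.values()) == {5}

    def test_deterministic_per_seed(self):
        model = RateModel.create("dependent", np.full(24, 1.5))
        tree = tree_from("((A:1,B:2):1,(C:1.5,D:0.5):1);")
        a = simulate_ctmc(tree, model, seed=3)
        b = simulate_ctmc(tree, model, seed=3)
        c = simulate_ctmc(tree, model, seed=4)
        assert a == b
        assert any(a != c for _ in [0]) or a != c

    def test_symmetric_chain_reaches_stationary_half(self):
        # one motif, gain = loss = mu, depth >> 1/mu: tip frequency ~ 0.5
        rates = {nm: 0.0 for nm in RateModel.create("independent").names}
        rates["Maze:gain"] = rates["Maze:loss"] = 5.0
        model = RateModel.create(
            "independent", [rates[n] for n in RateModel.create("independent").names]
        )
        nwk = "(" + ",".join(f"T{i}:3.0" for i in range(400)) + ");"
        tips = simulate_ctmc(tree_from(nwk), model, root_state=0, seed=1)
        frac = np.mean([s & 1 for s in tips.values()])
        assert 0.4 < frac < 0.6


class TestPruneToGenus:
    @pytest.fixture()
    def species_tree(self):
        return tree_from(
            "(((Aa_x:1,Aa_y:1):1,(Bb_x:1,Bb_y:1):1):1,(Cc_only:2,Dd_z:2):1);"
        )

    def test_one_tip_per_genus(self, species_tree):
        reps = prune_to_genus(species_tree, {"Aa", "Bb", "Cc"}, n_replicates=1, seed=0)
        labels = sorted(l.taxon.label for l in reps[0].leaf_node_iter())
        assert labels == ["Aa", "Bb", "Cc"]

    def test_reproducible_and_varying_selection(self, species_tree):
        reps1 = prune_to_genus(species_tree, {"Aa", "Bb"}, n_replicates=20, seed=5)
        reps2 = prune_to_genus(species_tree, {"Aa", "Bb"}, n_replicates=20, seed=5)
        for a, b in zip(reps1, reps2):
            assert a.as_string(schema="newick") == b.as_string(schema="newick")

    def test_singleton_genus_always_kept(self, species_tree):
        for seed in range(5):
            reps = prune_to_genus(species_tree, {"Cc", "Dd"}, n_replicates=1, seed=seed)
            assert {l.taxon.label for l in reps[0].leaf_node_iter()} == {"Cc", "Dd"}

    def test_no_overlap_errors(self, species_tree):
        with pytest.raises(ValueError, match="genera"):
            prune_to_genus(species_tree, {"Zz"}, 1, 0)


class TestFitAndCompare:
    def test_degenerate_data_drives_gain_rates_to_bound(self):
        from patternblend.traitevo import RATE_LB

        tree = tree_from("((A:1,B:1):1,(C:1,D:1):1);")
        tips = {k: 0 for k in "ABCD"}
        fit = fit_model(tree, tips, "independent", n_starts=1)
        gains = [r for n, r in fit.model.rate_dict().items() if "gain" in n]
        # optimizer terminates in the flat region just above the bound
        assert all(g <= 10 * RATE_LB for g in gains)

    def test_identical_fits_compare_to_zero(self):
        model = RateModel.create("independent")
        fit = FitResult(model=model, log_likelihood=-10.0, converged=True, n_trees=1, n_starts=1)
        c = compare_models(fit, fit, method="lrt")
        assert c.value == 0.0 and c.df == 0

    def test_maze_rate_summary_roundtrip(self):
        true = make_dependent(d=7.0, abc=0.3, efg=1.2, h=0.05)
        s = maze_rate_summary(true)
        assert s.gains == {"a": 0.3, "b": 0.3, "c": 0.3, "d": 7.0}
        assert s.losses == {"e": 1.2, "f": 1.2, "g": 1.2, "h": 0.05}

    def test_independent_rates_recovered_within_factor_two(self):
        # per-rate recovery over seeds at 200 tips
        from patternblend.synth import gen_trait_tree

        true = RateModel.create("independent", [2.0, 1.0, 2.0, 1.0, 2.0, 1.0])
        n_seeds = 10
        ok = np.zeros((n_seeds, 6), dtype=bool)
        for seed in range(n_seeds):
            tree, _ = gen_trait_tree(200, seed=100 + seed)
            tree = scale_to_unit_height(tree)
            tips = simulate_ctmc(tree, true, root_state=0, seed=seed)
            fit = fit_model(tree, tips, "independent", rescale=False, seed=seed, n_starts=1)
            ratios = fit.model.rates / true.rates
            ok[seed] = (ratios > 0.5) & (ratios < 2.0)
        # each of the six rates individually lands within a factor of two in
        # at least 80% of replicates
        assert (ok.mean(axis=0) >= 0.8).all()

    def test_stepping_stone_matches_prior_monte_carlo(self):
        tree = tree_from("((A:0.3,B:0.5):0.2,(C:0.4,D:0.1):0.6);")
        tips = {"A": 0, "B": 5, "C": 7, "D": 2}
        z_ss = stepping_stone_evidence(tree, tips, "independent", seed=1, rescale=False)
        rng = np.random.default_rng(0)
        vals = np.array(
            [
                ctmc_likelihood(tree, tips, RateModel.create("independent", rng.exponential(1.0, 6)))
                for _ in range(8000)
            ]
        )
        mx = vals.max()
        z_mc = np.log(np.mean(np.exp(vals - mx))) + mx
        assert z_ss == pytest.approx(z_mc, abs=0.3)

    def test_mcmc_ss_comparison_runs(self):
        tree = tree_from("((A:0.3,B:0.5):0.2,(C:0.4,D:0.1):0.6);")
        tips = {"A": 0, "B": 5, "C": 7, "D": 2}
        fit_i = fit_model(tree, tips, "independent", n_starts=1, rescale=False)
        fit_d = fit_model(
            tree, tips, "dependent", n_starts=1, rescale=False, warm_start=fit_i.model
        )
        c = compare_models(
            fit_i, fit_d, method="mcmc_ss", trees=tree, tip_states=tips,
            n_stones=4, n_iter=100, seed=2, rescale=False,
        )
        assert c.method == "mcmc_ss"
        assert np.isfinite(c.value)
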