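"""Rate matrices, pruning likelihood, and maximum-likelihood fitting."""

import numpy as np
import pytest
from scipy.linalg import expm

from dnds.codon_models import (
    CODONS,
    LikelihoodEngine,
    beta_category_means,
    branch_site_model,
    build_rate_matrix,
    class_rate_multipliers,
    codon_frequencies,
    equal_frequencies,
    fit_model,
    log_likelihood,
    m0_model,
    transition_matrix,
)
from dnds.codon_models import CODON_INDEX
from dnds.evolver_sim import simulate
from dnds.seqdata import tree_from_newick


# ---------------------------------------------------------------------------
# Rate matrix
# ---------------------------------------------------------------------------


class TestRateMatrix:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rows_sum_to_zero_and_reversibility(self, seed):
        rng = np.random.default_rng(seed)
        pi = rng.dirichlet(np.ones(61) * 2)
        kappa = float(rng.uniform(0.5, 10))
        omega = float(rng.uniform(0.01, 5))
        Q = build_rate_matrix(kappa, omega, pi)
        assert np.abs(Q.sum(axis=1)).max() < 1e-12
        flux = pi[:, None] * Q
        assert np.abs(flux - flux.T).max() < 1e-12
        # unit mean rate at stationarity
        assert -(pi * np.diag(Q)).sum() == pytest.approx(1.0)

    def test_kappa_omega_ratio(self):
        # TTT->TTC is a synonymous transition, TTT->TTA a nonsynonymous
        # transversion: with equal frequencies their rate ratio is kappa/omega
        Q = build_rate_matrix(2.0, 0.5, equal_frequencies())
        i = CODON_INDEX["TTT"]
        assert Q[i, CODON_INDEX["TTC"]] / Q[i, CODON_INDEX["TTA"]] == pytest.approx(4.0)

    def test_neutral_symmetric_rates_equal(self):
        Q = build_rate_matrix(1.0, 1.0, equal_frequencies())
        off = Q[Q > 0]
        assert np.allclose(off, off[0])

    def test_multi_step_rates_zero(self):
        Q = build_rate_matrix(2.0, 0.5, equal_frequencies())
        assert Q[CODON_INDEX["TTT"], CODON_INDEX["CCT"]] == 0.0

    def test_invalid_frequencies_rejected(self):
        bad = np.ones(61)
        with pytest.raises(ValueError):
            build_rate_matrix(2.0, 0.5, bad)


class TestTransitionMatrix:
    def test_zero_time_identity(self):
        Q = build_rate_matrix(2.0, 0.3, equal_frequencies())
        assert np.allclose(transition_matrix(Q, 0.0), np.eye(61))

    def test_rows_sum_to_one(self):
        pi = np.random.default_rng(3).dirichlet(np.ones(61) * 3)
        Q = build_rate_matrix(3.0, 0.7, pi)
        P = transition_matrix(Q, 0.8)
        assert np.abs(P.sum(axis=1) - 1).max() < 1e-10
        assert P.min() >= 0

    def test_long_time_reaches_stationarity(self):
        pi = np.random.default_rng(4).dirichlet(np.ones(61) * 3)
        Q = build_rate_matrix(2.0, 0.5, pi)
        P = transition_matrix(Q, 50.0)
        assert np.abs(P - pi[None, :]).max() < 1e-5

    def test_negative_time_rejected(self):
        Q = build_rate_matrix(2.0, 0.5, equal_frequencies())
        with pytest.raises(ValueError):
            transition_matrix(Q, -0.1)


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


def _brute_force_quartet_loglik(aln, pi, kappa, omega, lens):
    """Independent sum over the two internal nodes of an unrooted quartet
    (A,B,(C,D)) with edge lengths lens = (tA, tB, tC, tD, tE)."""
    Q = build_rate_matrix(kappa, omega, pi)
    PA, PB, PC, PD, PE = (expm(Q * t) for t in lens)
    rows = {t: aln.taxa.index(t) for t in "ABCD"}
    total = 0.0
    for s in range(aln.n_codons):
        obs = {t: CODON_INDEX[aln.codons[rows[t], s]] for t in "ABCD"}
        inner = PC[:, obs["C"]] * PD[:, obs["D"]]
        like = 0.0
        for r in range(61):
            like += (
                pi[r]
                * PA[r, obs["A"]]
                * PB[r, obs["B"]]
                * float(PE[r] @ inner)
            )
        total += np.log(like)
    return total


class TestLikelihood:
    def test_two_taxon_closed_form(self, usage):
        tree = tree_from_newick("(A:0.15,B:0.25);")
        model = m0_model(2.0, 0.4, usage)
        rep = simulate(tree, model, 40, seed=9)
        ll = log_likelihood(rep.alignment, tree, model)
        Q = build_rate_matrix(2.0, 0.4, usage)
        P = expm(Q * 0.4)  # reversibility: only the path length matters
        rows = {t: rep.alignment.taxa.index(t) for t in "AB"}
        expected = sum(
            np.log(
                usage[CODON_INDEX[rep.alignment.codons[rows["A"], s]]]
                * P[
                    CODON_INDEX[rep.alignment.codons[rows["A"], s]],
                    CODON_INDEX[rep.alignment.codons[rows["B"], s]],
                ]
            )
            for s in range(40)
        )
        assert ll == pytest.approx(expected, abs=1e-8)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_pruning_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        lens = np.round(rng.uniform(0.05, 0.6, size=5), 4)
        tree = tree_from_newick(
            "(A:{:.4f},B:{:.4f},(C:{:.4f},D:{:.4f}):{:.4f});".format(*lens)
        )
        pi = rng.dirichlet(np.ones(61) * 4)
        kappa = float(rng.uniform(1, 5))
        omega = float(rng.uniform(0.05, 3))
        model = m0_model(kappa, omega, pi)
        rep = simulate(tree, model, 6, seed=seed + 100)
        ll = log_likelihood(rep.alignment, tree, model)
        brute = _brute_force_quartet_loglik(rep.alignment, pi, kappa, omega, lens)
        assert ll == pytest.approx(brute, abs=1e-8)

    def test_rerooting_invariance(self, usage):
        # same unrooted tree written with two different rootings
        n1 = "(A:0.1,B:0.2,((C:0.15,D:0.25):0.3,E:0.12):0.18);"
        n2 = "(C:0.15,D:0.25,(E:0.12,(A:0.1,B:0.2):0.18):0.3);"
        t1, t2 = tree_from_newick(n1), tree_from_newick(n2)
        model = m0_model(2.5, 0.6, usage)
        rep = simulate(t1, model, 50, seed=12)
        assert log_likelihood(rep.alignment, t1, model) == pytest.approx(
            log_likelihood(rep.alignment, t2, model), abs=1e-8
        )

    def test_one_class_mixture_equals_m0(self, small_m0_data, seven_taxon_tree, usage):
        aln = small_m0_data.alignment
        m0 = m0_model(2.0, 0.3, usage)
        bs = branch_site_model(2.0, usage, 1.0, 0.0, 0.3, 1.0, model_name="A1")
        # degenerate branch-site mixture: all mass on class 0 with omega0
        assert log_likelihood(aln, seven_taxon_tree, bs) == pytest.approx(
            log_likelihood(aln, seven_taxon_tree, m0), abs=1e-6
        )

    def test_taxon_mismatch_rejected(self, small_m0_data, usage):
        bad_tree = tree_from_newick("(A:0.1,B:0.2,(C:0.3,Z:0.4):0.5);")
        with pytest.raises(ValueError, match="taxa"):
            log_likelihood(small_m0_data.alignment, bad_tree, m0_model(2, 0.3, usage))

    def test_branch_site_requires_foreground(self, small_m0_data, usage):
        tree = tree_from_newick(
            "((A:0.2,B:0.35):0.1,(C:0.15,D:0.28):0.12,(E:0.3,(F:0.2,G:0.1):0.15):0.2);"
        )
        model = branch_site_model(2.0, usage, 0.7, 0.2, 0.1, 5.0)
        with pytest.raises(ValueError, match="foreground"):
            log_likelihood(small_m0_data.alignment, tree, model)

    def test_branch_gradient_matches_finite_differences(
        self, small_m0_data, seven_taxon_tree, usage
    ):
        aln = small_m0_data.alignment
        eng = LikelihoodEngine(aln, seven_taxon_tree, usage)
        ll0, ratio = eng.class_edge_stats(2.0, (0.3, 1.7), mult=(0.8, 1.9))
        base = float(eng.pattern_counts @ ll0)
        h = 1e-5
        for v in range(seven_taxon_tree.n_nodes):
            if seven_taxon_tree.parent[v] < 0:
                continue
            bumped = seven_taxon_tree.lengths.copy()
            bumped[v] += h
            eng.set_lengths(bumped)
            up = float(
                eng.pattern_counts
                @ eng.class_pattern_loglik(2.0, (0.3, 1.7), mult=(0.8, 1.9))
            )
            eng.set_lengths(seven_taxon_tree.lengths.copy())
            numeric = (up - base) / h
            analytic = float(ratio[v] @ eng.pattern_counts)
            assert analytic == pytest.approx(numeric, rel=1e-3, abs=1e-3)


class TestScaling:
    def test_multipliers_increase_with_omega(self, usage):
        classes = [(0.8, 0.1), (0.15, 1.0), (0.05, (0.1, 9.0))]
        mults = class_rate_multipliers(2.0, classes, usage, "mixture")
        # higher omega => faster class, same generator scaling
        assert mults[0][0] < mults[1][0] < mults[2][1]

    def test_mixture_convention_averages_to_one(self, usage):
        classes = [(0.8, 0.1), (0.15, 1.0), (0.05, (0.1, 9.0))]
        mults = class_rate_multipliers(2.0, classes, usage, "mixture")
        props = [p for p, _ in classes]
        bg = sum(p * m[0] for p, m in zip(props, mults))
        fg = sum(p * m[1] for p, m in zip(props, mults))
        assert bg == pytest.approx(1.0) and fg == pytest.approx(1.0)

    def test_neutral_class_is_reference(self, usage):
        mults = class_rate_multipliers(2.0, [(0.5, 1.0), (0.5, 0.2)], usage, "neutral")
        assert mults[0] == pytest.approx((1.0, 1.0))


class TestBetaDiscretization:
    @pytest.mark.parametrize("p,q", [(0.5, 1.5), (2.0, 2.0), (0.1, 0.2)])
    def test_category_means(self, p, q):
        means = beta_category_means(p, q, 10)
        assert len(means) == 10
        assert np.all((means > 0) & (means < 1))
        assert np.all(np.diff(means) >= 0)
        # category means average to the distribution mean
        assert means.mean() == pytest.approx(p / (p + q), abs=1e-6)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


class TestFitting:
    def test_m0_parameter_recovery(self, usage):
        tree = tree_from_newick(
            "((A:0.2,B:0.35):0.1,(C:0.15,D:0.28):0.12,"
            "(E:0.3,(F:0.2,G:0.15):0.18):0.2,H:0.25);"
        )
        rep = simulate(tree, m0_model(2.0, 0.3, usage), 500, seed=21)
        fit = fit_model(rep.alignment, tree, "M0", restarts=2, seed=0)
        assert fit.converged
        assert fit.params["omega"] == pytest.approx(0.3, abs=0.1)
        assert fit.kappa == pytest.approx(2.0, abs=0.6)

    def test_site_model_nesting(self, seven_taxon_tree, usage):
        """Freeing a constrained parameter never lowers the optimum:
        lnL(M8) >= lnL(M8a) and lnL(M8) >= lnL(M7)."""
        from dnds.selection_tests import fit_nested_pair

        rep = simulate(seven_taxon_tree, m0_model(2.0, 0.4, usage), 60, seed=33)
        m7, m8, _ = fit_nested_pair(
            rep.alignment, seven_taxon_tree, "M7", "M8", restarts=1, seed=0
        )
        m8a = fit_model(rep.alignment, seven_taxon_tree, "M8a", restarts=1, seed=0)
        assert m8.lnL >= m8a.lnL - 1e-4
        assert m8.lnL >= m7.lnL - 1e-4
        assert m8.n_free_params - m7.n_free_params == 2

    def test_branch_site_nesting(self, seven_taxon_tree, usage):
        from dnds.selection_tests import fit_nested_pair

        model = branch_site_model(2.0, usage, 0.75, 0.2, 0.15, 6.0)
        rep = simulate(seven_taxon_tree, model, 80, seed=44)
        a1, a2, res = fit_nested_pair(
            rep.alignment, seven_taxon_tree, "A1", "A2", restarts=1, seed=0
        )
        assert a2.lnL >= a1.lnL - 1e-4
        assert res.two_delta >= 0
        assert a2.mixture_free_params - a1.mixture_free_params == 1

    def test_branch_site_fit_requires_foreground_flag(self, small_m0_data):
        tree = tree_from_newick(
            "((A:0.2,B:0.35):0.1,(C:0.15,D:0.28):0.12,(E:0.3,(F:0.2,G:0.1):0.15):0.2);"
        )
        with pytest.raises(ValueError, match="foreground"):
            fit_model(small_m0_data.alignment, tree, "A2")

    def test_free_param_counts_match_catalogue(self, quartet_fg_tree):
        from dnds.codon_models import MODEL_CATALOG

        expected = {
            "M0": 1, "M1a": 2, "M2a": 4, "M7": 2, "M8": 4, "M8a": 3,
            "branch0": 1, "branch2_strict": 2, "branch2_relaxed": 1,
            "A1": 3, "A2": 4,
        }
        B = quartet_fg_tree.n_branches
        for name, count in expected.items():
            assert MODEL_CATALOG[name].omega_param_count(B) == count
        assert MODEL_CATALOG["branch1"].omega_param_count(B) == B

    def test_branch_model_rates_report(self, small_m0_data, seven_taxon_tree):
        fit = fit_model(
            small_m0_data.alignment,
            seven_taxon_tree,
            "branch0",
            restarts=1,
            seed=0,
            compute_branch_rates=True,
        )
        df = fit.per_branch_dn_ds
        assert len(df) == seven_taxon_tree.n_branches
        ratio = df["dN"] / df["dS"]
        assert np.allclose(ratio, fit.params["omega"], rtol=1e-6)
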