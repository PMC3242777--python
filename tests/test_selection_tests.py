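"""LRTs between nested models and BEB site identification."""

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import chi2

from dnds.codon_models import (
    CODON_INDEX,
    FitResult,
    build_rate_matrix,
    branch_site_model,
    codon_frequencies,
)
from dnds.evolver_sim import simulate
from dnds.selection_tests import (
    BEBResult,
    beb_site_posteriors,
    classify_sites,
    lrt,
)
from dnds.seqdata import tree_from_newick


def _fake_fit(model_name, lnl, tree=None, kappa=2.0, freqs=None, branches=None):
    if tree is None:
        tree = tree_from_newick("(A:0.1,B:0.2,(C:0.3,D:0.4)#1:0.5);")
    lengths = tree.lengths if branches is None else branches
    return FitResult(
        model_name=model_name,
        lnL=lnl,
        kappa=kappa,
        params={},
        mixture={},
        branch_lengths=lengths,
        frequencies=freqs if freqs is not None else np.full(61, 1 / 61),
        tree=tree,
        classes=[],
        n_free_params=0,
        mixture_free_params=0,
        convergence={"converged": True},
    )


class TestLRT:
    def test_equal_likelihoods_give_p_one(self):
        res = lrt(_fake_fit("M1a", -100.0), _fake_fit("M2a", -100.0))
        assert res.two_delta == 0.0 and res.p_value == 1.0 and res.df == 2

    def test_chi2_quantile_identity(self):
        res = lrt(_fake_fit("M7", -102.9955), _fake_fit("M8", -100.0))
        assert res.two_delta == pytest.approx(5.991, abs=1e-3)
        assert res.p_value == pytest.approx(0.050, abs=1e-3)

    @pytest.mark.parametrize(
        "null,alt,df",
        [
            ("M1a", "M2a", 2),
            ("M7", "M8", 2),
            ("M8a", "M8", 1),
            ("branch0", "branch2_strict", 1),
            ("branch2_relaxed", "branch2_strict", 1),
            ("A1", "A2", 1),
        ],
    )
    def test_registered_degrees_of_freedom(self, null, alt, df):
        res = lrt(_fake_fit(null, -10.0), _fake_fit(alt, -9.0))
        assert res.df == df
        assert res.p_value == pytest.approx(chi2.sf(2.0, df))

    def test_branch_model_df_scales_with_tree(self):
        res = lrt(_fake_fit("branch0", -10.0), _fake_fit("branch1", -5.0))
        assert res.df == 5 - 1  # quartet: 2n-3 = 5 branches

    def test_small_negative_two_delta_clamped(self):
        res = lrt(_fake_fit("A1", -100.0), _fake_fit("A2", -100.00000001))
        assert res.two_delta == 0.0 and res.p_value == 1.0

    def test_non_nested_pair_rejected(self):
        with pytest.raises(ValueError, match="nested"):
            lrt(_fake_fit("M7", -10.0), _fake_fit("M2a", -9.0))

    def test_p_monotone_in_two_delta(self):
        ps = [
            lrt(_fake_fit("A1", -100.0), _fake_fit("A2", -100.0 + d / 2)).p_value
            for d in (0.5, 1.0, 2.0, 5.0, 10.0)
        ]
        assert all(a > b for a, b in zip(ps, ps[1:]))


class TestClassifySites:
    def test_one_site_per_tier(self):
        tiers = classify_sites(np.array([0.996, 0.97, 0.5]))
        assert tiers["P>0.99"] == [0]
        assert tiers["0.95<P<=0.99"] == [1]
        assert tiers["P>0.95"] == [0, 1]

    def test_all_zero_empty(self):
        tiers = classify_sites(np.zeros(5))
        assert tiers["P>0.99"] == [] and tiers["P>0.95"] == []

    def test_tiers_nested(self):
        rng = np.random.default_rng(0)
        post = rng.uniform(0, 1, 200)
        tiers = classify_sites(post)
        assert set(tiers["P>0.99"]).issubset(tiers["P>0.95"])


# ---------------------------------------------------------------------------
# BEB
# ---------------------------------------------------------------------------


def _beb_oracle(aln, tree, kappa, pi, n_grid=10):
    """Direct grid-summation BEB for an unrooted quartet (A,B,(C,D)#1) —
    plain loops and scipy expm, independent of the pruning engine."""
    # flux constants for the shared class scaling (relative to omega = 1)
    syn = nsyn = 0.0
    codons = list(CODON_INDEX)
    for ci, i in CODON_INDEX.items():
        for cj, j in CODON_INDEX.items():
            diff = [p for p in range(3) if ci[p] != cj[p]]
            if len(diff) != 1:
                continue
            p = diff[0]
            ts = {ci[p], cj[p]} in ({"A", "G"}, {"C", "T"})
            rate = pi[i] * pi[j] * (kappa if ts else 1.0)
            from dnds.seqdata import CODON_AA

            if CODON_AA[i] == CODON_AA[j]:
                syn += rate
            else:
                nsyn += rate

    def mult(w):
        return (syn + w * nsyn) / (syn + nsyn)

    idx = {}
    for v in range(tree.n_nodes):
        if tree.labels[v]:
            idx[tree.labels[v]] = aln.taxa.index(tree.labels[v])
    lens = {tree.labels[v] or "E": float(tree.lengths[v]) for v in range(tree.n_nodes) if tree.parent[v] >= 0}

    def site_liks(w_bg, w_fg):
        Qb = build_rate_matrix(kappa, w_bg, pi)
        Qf = build_rate_matrix(kappa, w_fg, pi)
        P = {n: expm(Qb * lens[n] * mult(w_bg)) for n in "ABCD"}
        PE = expm(Qf * lens["E"] * mult(w_fg))  # the flagged internal branch
        out = []
        for s in range(aln.n_codons):
            obs = {t: CODON_INDEX[aln.codons[idx[t], s]] for t in "ABCD"}
            inner = P["C"][:, obs["C"]] * P["D"][:, obs["D"]]
            lik = 0.0
            for r in range(61):
                lik += (
                    pi[r]
                    * P["A"][r, obs["A"]]
                    * P["B"][r, obs["B"]]
                    * float(PE[r] @ inner)
                )
            out.append(lik)
        return np.array(out)

    mid = (np.arange(n_grid) + 0.5) / n_grid
    w0s = mid
    w2s = 1.0 + 10.0 * mid
    pps = []
    for u in mid:
        for v in mid:
            r = np.sqrt(u)
            pps.append((1.0 - r, r * v))
    f1 = site_liks(1.0, 1.0)
    f0 = {w0: site_liks(w0, w0) for w0 in w0s}
    f2b = {w2: site_liks(1.0, w2) for w2 in w2s}
    f2a = {(w0, w2): site_liks(w0, w2) for w0 in w0s for w2 in w2s}

    n_sites = aln.n_codons
    post = np.zeros((n_sites, 4))
    marg = []
    combos = []
    for p0, p1 in pps:
        p2 = max(0.0, 1.0 - p0 - p1)
        den = p0 + p1
        w = np.array([p0, p1, p2 * p0 / den, p2 * p1 / den])
        for w0 in w0s:
            for w2 in w2s:
                fk = np.stack([f0[w0], f1, f2a[(w0, w2)], f2b[w2]])
                site = w @ fk
                combos.append((w, fk, site))
                marg.append(np.sum(np.log(site)))
    marg = np.array(marg)
    pg = np.exp(marg - marg.max())
    pg /= pg.sum()
    for g, (w, fk, site) in enumerate(combos):
        post += pg[g] * (w[:, None] * fk / site[None, :]).T
    return post


@pytest.fixture(scope="module")
def quartet_beb_case():
    tree = tree_from_newick("(A:0.2,B:0.35,(C:0.25,D:0.3)#1:0.3);")
    pi = np.random.default_rng(8).dirichlet(np.ones(61) * 8)
    model = branch_site_model(2.0, pi, 0.5, 0.3, 0.2, 8.0)
    rep = simulate(tree, model, 12, seed=5)
    fit = _fake_fit("A2", -1.0, tree=tree, kappa=2.0, freqs=pi)
    beb = beb_site_posteriors(rep.alignment, tree, fit)
    return rep, tree, pi, beb


class TestBEB:
    def test_posteriors_sum_to_one(self, quartet_beb_case):
        _, _, _, beb = quartet_beb_case
        assert np.allclose(beb.site_posteriors.sum(axis=1), 1.0, atol=1e-9)
        assert np.all((beb.positive_posterior >= 0) & (beb.positive_posterior <= 1))

    def test_matches_grid_enumeration_oracle(self, quartet_beb_case):
        rep, tree, pi, beb = quartet_beb_case
        oracle = _beb_oracle(rep.alignment, tree, 2.0, pi)
        np.testing.assert_allclose(beb.site_posteriors, oracle, atol=1e-6)

    def test_selected_site_ranks_top(self, usage):
        """A site evolving with high foreground omega should attain the
        maximum positive-selection posterior among all sites."""
        tree = tree_from_newick(
            "((A:0.2,B:0.3):0.15,(C:0.2,D:0.25):0.1,(E:0.3,F:0.2)#1:0.3);"
        )
        model = branch_site_model(2.0, usage, 0.93, 0.02, 0.05, 10.0)
        rep = simulate(tree, model, 60, seed=17)
        pos = rep.positive_sites()
        assert pos.size > 0
        fit = _fake_fit("A2", -1.0, tree=tree, kappa=2.0, freqs=usage)
        beb = beb_site_posteriors(rep.alignment, tree, fit)
        assert int(np.argmax(beb.positive_posterior)) in pos

    def test_invariant_sites_stay_below_095(self, usage):
        tree = tree_from_newick(
            "((A:0.2,B:0.3):0.15,(C:0.2,D:0.25):0.1,(E:0.3,F:0.2)#1:0.3);"
        )
        # strongly conserved data: invariant columns must never be flagged
        model = branch_site_model(2.0, usage, 1.0, 0.0, 0.01, 1.0, model_name="A1")
        rep = simulate(tree, model, 80, seed=23)
        aln = rep.alignment
        invariant = [
            s for s in range(aln.n_codons)
            if len(set(aln.site_column(s))) == 1
        ]
        assert invariant
        fit = _fake_fit("A1", -1.0, tree=tree, kappa=2.0, freqs=usage)
        fit.model_name = "A2"
        beb = beb_site_posteriors(aln, tree, fit)
        assert beb.positive_posterior[invariant].max() < 0.95

    def test_unconverged_fit_rejected(self, quartet_beb_case):
        rep, tree, pi, _ = quartet_beb_case
        bad = _fake_fit("A2", -1.0, tree=tree, freqs=pi)
        bad.convergence = {"converged": False}
        with pytest.raises(ValueError, match="converged"):
            beb_site_posteriors(rep.alignment, tree, bad)

    def test_site_table_has_flag_tiers(self, quartet_beb_case):
        _, _, _, beb = quartet_beb_case
        df = beb.to_frame()
        assert {"site", "P(omega>1)", "mean_omega", "flag"}.issubset(df.columns)
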