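"""Evolutionary-model likelihoods, fitting, selection and ancestral states."""
import numpy as np
import pytest
from scipy import optimize, stats

from earevol import phylo, synth
from earevol.phylo import ModelSpec
from earevol.trees import TreeArrays

from conftest import random_trees


# ----------------------------------------------------------------- oracles

def vcv_oracle(ta: TreeArrays) -> np.ndarray:
    """Shared root-to-MRCA path length via explicit ancestor-set walks."""
    def ancestors(v):
        out = {}
        d = 0.0
        path = []
        while v != -1:
            path.append(v)
            v = ta.parent[v]
        # depth of each node on the path from the root
        acc = {}
        for v in reversed(path):
            d += ta.blen[v]
            acc[v] = d
        return acc

    n = ta.n_tips
    V = np.zeros((n, n))
    anc = [ancestors(t) for t in ta.tip_nodes]
    for i in range(n):
        for j in range(n):
            shared = set(anc[i]) & set(anc[j])
            V[i, j] = max(anc[i][v] for v in shared)
    return V


def joint_ml_oracle(ta: TreeArrays, x, blen, s2):
    """Numerically maximize the joint branchwise Gaussian likelihood
    over all internal-node values."""
    internal = np.where(~ta.is_tip)[0]
    pos = {v: i for i, v in enumerate(internal)}
    obs = np.zeros(ta.n_nodes)
    obs[ta.tip_nodes] = x

    def neg_ll(u):
        val = obs.copy()
        val[internal] = u
        ll = 0.0
        for v in range(1, ta.n_nodes):
            ll += stats.norm.logpdf(val[v], val[ta.parent[v]],
                                    np.sqrt(s2 * blen[v]))
        return -ll

    u0 = np.full(internal.size, x.mean())
    res = optimize.minimize(neg_ll, u0, method="BFGS",
                            options={"gtol": 1e-10, "maxiter": 2000})
    return res.x, internal


# ------------------------------------------------------------------- VCV

def test_vcv_two_tip_star(star2):
    assert np.allclose(phylo.phylo_vcv(star2), np.eye(2))


def test_vcv_three_tip_hand_computed(tiny_tree):
    expect = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 2.0]])
    assert np.allclose(phylo.phylo_vcv(tiny_tree), expect)


def test_vcv_matches_path_enumeration_oracle():
    for ta in random_trees(10, 8, seed=7):
        assert np.allclose(phylo.phylo_vcv(ta), vcv_oracle(ta), atol=1e-12)


# ------------------------------------------------------------- model VCV

NEUTRAL = [("lambda", {"lambda": 1.0}), ("delta", {"delta": 1.0}),
           ("kappa", {"kappa": 1.0}), ("ACDC", {"r": 0.0}),
           ("BMS", {})]


@pytest.mark.parametrize("name,params", NEUTRAL)
def test_neutral_parameters_reduce_to_bm(name, params, tiny_tree):
    V = phylo.model_vcv(tiny_tree, name, {**params, "sigma2": 2.0})
    assert np.allclose(V, 2.0 * phylo.phylo_vcv(tiny_tree), atol=1e-10)


def test_lambda_zero_gives_star_phylogeny(tiny_tree):
    V = phylo.model_vcv(tiny_tree, "lambda", {"lambda": 0.0, "sigma2": 1.0})
    assert np.allclose(V, np.diag([2.0, 2.0, 2.0]))


def test_ou_small_alpha_approaches_bm():
    ta = TreeArrays.from_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
    V_ou = phylo.model_vcv(ta, "OU", {"alpha": 1e-8, "sigma2": 1.0})
    V_bm = phylo.model_vcv(ta, "BM", {"sigma2": 1.0})
    assert np.max(np.abs(V_ou - V_bm)) < 1e-4


def test_model_vcv_rejects_inadmissible_parameters(tiny_tree):
    with pytest.raises(ValueError):
        phylo.model_vcv(tiny_tree, "lambda", {"lambda": 1.5, "sigma2": 1.0})
    with pytest.raises(ValueError):
        phylo.model_vcv(tiny_tree, "delta", {"delta": -1.0, "sigma2": 1.0})
    with pytest.raises(ValueError):
        phylo.model_vcv(tiny_tree, "OU", {"alpha": -1.0, "sigma2": 1.0})


def test_bms_scales_covariance_of_shifted_clade(tiny_tree):
    # branch-only regime: only the stem branch below (A,B) is scaled
    spec = ModelSpec("BMS", 1, [("A", "B")], regime="branch")
    V = phylo.model_vcv(tiny_tree, spec, {"sigma2": 1.0, "rate_1": 10.0})
    assert V[0, 1] == pytest.approx(10.0)
    assert V[0, 0] == pytest.approx(11.0)
    assert V[2, 2] == pytest.approx(2.0)
    # clade regime: stem plus the A and B tip branches
    spec = ModelSpec("BMS", 1, [("A", "B")], regime="clade")
    V = phylo.model_vcv(tiny_tree, spec, {"sigma2": 1.0, "rate_1": 10.0})
    assert V[0, 1] == pytest.approx(10.0)
    assert V[0, 0] == pytest.approx(20.0)
    assert V[2, 2] == pytest.approx(2.0)


# ---------------------------------------------------------------- loglik

def test_loglik_two_tip_standard_normal(star2):
    ll = phylo.loglik(star2, {"A": 0.0, "B": 0.0}, "BM",
                      {"sigma2": 1.0, "z0": 0.0})
    assert ll == pytest.approx(-np.log(2 * np.pi), abs=1e-12)


def test_loglik_invariant_to_tip_relabelling(tiny_tree):
    traits = {"A": 1.0, "B": -0.5, "C": 2.0}
    ll1 = phylo.loglik(tiny_tree, traits, "BM", {"sigma2": 1.0, "z0": 0.5})
    tb = TreeArrays.from_newick("(C:2,(B:1,A:1):1);")
    ll2 = phylo.loglik(tb, traits, "BM", {"sigma2": 1.0, "z0": 0.5})
    assert ll1 == pytest.approx(ll2, abs=1e-12)


@pytest.mark.parametrize("name,params", [
    ("BM", {}), ("lambda", {"lambda": 0.6}), ("delta", {"delta": 1.7}),
    ("kappa", {"kappa": 0.5}), ("OU", {"alpha": 0.3}), ("ACDC", {"r": -0.05}),
])
def test_loglik_matches_dense_mvn_oracle(name, params):
    rng = np.random.default_rng(11)
    for ta in random_trees(8, 5, seed=23):
        x = rng.normal(size=5)
        traits = dict(zip(ta.tip_labels, x))
        p = {**params, "sigma2": 0.8, "z0": 0.3}
        V = phylo.model_vcv(ta, name, p)
        ref = stats.multivariate_normal.logpdf(x, mean=np.full(5, 0.3), cov=V)
        assert phylo.loglik(ta, traits, name, p) == pytest.approx(ref, abs=1e-8)


# ------------------------------------------------------------------ AICc

def test_aicc_closed_forms():
    assert phylo.aicc(0.0, 1, 10) == pytest.approx(2.5)
    assert phylo.aicc(-10.0, 2, 28) == pytest.approx(24.48)
    with pytest.raises(ValueError):
        phylo.aicc(0.0, 9, 10)


def test_aicc_decreases_with_loglik():
    a = [phylo.aicc(ll, 3, 20) for ll in (-5.0, -4.0, -3.0)]
    assert a[0] > a[1] > a[2]


def test_aicc_ordering_invariant_to_trait_location(fixture_tree):
    cfg = synth.SimConfig(seed=4, model_name="BM", model_params={"sigma2": 2.0})
    traits = synth.simulate_traits(fixture_tree, cfg)
    shifted = {k: v + 100.0 for k, v in traits.items()}
    names = ["BM", "lambda", "OU"]
    a1 = [phylo.fit_model(fixture_tree, traits, n).aicc for n in names]
    a2 = [phylo.fit_model(fixture_tree, shifted, n).aicc for n in names]
    assert np.argsort(a1).tolist() == np.argsort(a2).tolist()
    assert np.allclose(a1, a2, atol=1e-4)


# --------------------------------------------------------------- fitting

def test_bm_sigma2_recovery(fixture_tree):
    """ML sigma2 under BM is close to truth across replicates."""
    est = []
    for seed in range(40):
        cfg = synth.SimConfig(seed=seed, model_name="BM",
                              model_params={"sigma2": 3.0})
        traits = synth.simulate_traits(fixture_tree, cfg)
        est.append(phylo.fit_model(fixture_tree, traits, "BM").params["sigma2"])
    assert abs(np.median(est) / 3.0 - 1.0) < 0.15


def test_lambda_near_zero_on_star_data(fixture_tree):
    """Traits drawn independently of the tree should fit small lambda."""
    rng = np.random.default_rng(99)
    hits = 0
    for _ in range(20):
        traits = dict(zip(fixture_tree.tip_labels,
                          rng.normal(10.0, 3.0, fixture_tree.n_tips)))
        lam = phylo.fit_model(fixture_tree, traits, "lambda").params["lambda"]
        hits += lam < 0.1
    assert hits >= 18


def test_fit_model_reports_aicc_consistent_with_formula(fixture_tree):
    cfg = synth.SimConfig(seed=5, model_name="BM", model_params={"sigma2": 1.0})
    traits = synth.simulate_traits(fixture_tree, cfg)
    fit = phylo.fit_model(fixture_tree, traits, "OU")
    assert fit.aicc == pytest.approx(phylo.aicc(fit.loglik, fit.k, fit.n))
    assert fit.k == 3


def test_search_recovers_strong_planted_rate_shift(fixture_tree):
    """A strong (x30) rate shift on a well-populated internal branch is
    the top single-shift pick in nearly all replicates."""
    key = fixture_tree.branch_key(
        fixture_tree.mrca_of_tips(["Homo sapiens", "Macaca mulatta"]))
    hits = 0
    for seed in range(10):
        cfg = synth.SimConfig(seed=seed, model_name="BMS",
                              model_params={"sigma2": 1.0,
                                            "shifts": {key: 30.0}})
        traits = synth.simulate_traits(fixture_tree, cfg)
        fits = phylo.search_rate_shifts(fixture_tree, traits, max_shifts=1)
        hits += fits[1].spec.shift_locations[0] == key
    assert hits >= 8


# ------------------------------------------------------- ancestral states

def test_root_of_symmetric_two_tip_tree_is_midpoint(star2):
    fit = phylo.ModelFit(ModelSpec("BM"), {"sigma2": 1.0, "z0": 1.0},
                         0.0, 2, 2, 0.0)
    a = phylo.ancestral_states(star2, {"A": 0.0, "B": 2.0}, fit)
    assert a.root[0] == pytest.approx(1.0)


def test_tip_estimates_equal_observations():
    tiny_tree = TreeArrays.from_newick("(((A:1,B:1):1,C:2):1,D:3);")
    traits = {"A": 1.0, "B": 3.0, "C": -2.0, "D": 0.5}
    fit = phylo.fit_model(tiny_tree, traits, "BM")
    anc = phylo.ancestral_states(tiny_tree, traits, fit)
    for lab, node in zip(tiny_tree.tip_labels, tiny_tree.tip_nodes):
        est, var = anc.at_node(node)
        assert est == pytest.approx(traits[lab])
        assert var == pytest.approx(0.0, abs=1e-12)


def test_ancestral_states_match_joint_ml_oracle():
    rng = np.random.default_rng(3)
    for ta in random_trees(5, 6, seed=31):
        x = rng.normal(size=6)
        traits = dict(zip(ta.tip_labels, x))
        fit = phylo.fit_model(ta, traits, "BM")
        anc = phylo.ancestral_states(ta, traits, fit)
        u, internal = joint_ml_oracle(ta, x, ta.blen, fit.params["sigma2"])
        assert np.allclose(anc.estimates[internal], u, atol=1e-6)


def test_root_estimate_equals_gls_mean():
    for ta in random_trees(3, 7, seed=41):
        rng = np.random.default_rng(5)
        x = rng.normal(size=7)
        traits = dict(zip(ta.tip_labels, x))
        fit = phylo.fit_model(ta, traits, "BM")
        anc = phylo.ancestral_states(ta, traits, fit)
        V = phylo.phylo_vcv(ta)
        Vi = np.linalg.inv(V)
        one = np.ones(7)
        gls = one @ Vi @ x / (one @ Vi @ one)
        assert anc.root[0] == pytest.approx(gls, abs=1e-8)


def test_pseudo_tip_with_tiny_branch_pins_ancestor():
    """Conditioning an ancestor via a near-zero-length pseudo-tip
    reproduces the observed pseudo-tip value at that node."""
    ta = TreeArrays.from_newick("((A:1,B:1,P:1e-9):1,C:2);")
    traits = {"A": 0.0, "B": 2.0, "P": 5.0, "C": 1.0}
    fit = phylo.ModelFit(ModelSpec("BM"), {"sigma2": 1.0, "z0": 1.0},
                         0.0, 2, 4, 0.0)
    anc = phylo.ancestral_states(ta, traits, fit)
    node = ta.mrca_of_tips(["A", "B"])
    assert anc.at_node(node)[0] == pytest.approx(5.0, abs=1e-6)


def test_fit_all_scenarios_returns_ten(fixture_tree):
    cfg = synth.SimConfig(seed=8, model_name="BM", model_params={"sigma2": 1.0})
    traits = synth.simulate_traits(fixture_tree, cfg)
    fits = phylo.fit_all_scenarios(fixture_tree, traits, max_shifts=4)
    assert len(fits) == 10
    names = [f.spec.name for f in fits]
    assert names.count("BMS") == 4 and names.count("BM") == 1
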