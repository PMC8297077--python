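import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from clearwater import bayes as B


def joint_enumeration(net: B.BayesNet) -> dict[tuple[int, ...], float]:
    """Full-joint oracle: probability of every complete assignment by
    multiplying CPT entries directly."""
    out = {}
    for assign in itertools.product(*[range(net.card[v]) for v in net.nodes]):
        st = dict(zip(net.nodes, assign))
        p = 1.0
        for v in net.nodes:
            p *= net.cpts[v][st[v], net.config_index(v, st)]
        out[assign] = p
    return out


def enum_marginal(net, J, query, evidence=None):
    evidence = evidence or {}
    idx = {v: i for i, v in enumerate(net.nodes)}
    marg = np.zeros(net.card[query])
    for a, p in J.items():
        if all(a[idx[k]] == s for k, s in evidence.items()):
            marg[a[idx[query]]] += p
    return marg / marg.sum()


# ---------------------------------------------------------------------------
# BDeu score

def test_empty_graph_score_is_sum_of_dirichlet_marginals():
    rng = np.random.default_rng(0)
    data = pd.DataFrame({"a": rng.integers(0, 3, 60), "b": rng.integers(0, 3, 60)})
    ess = 50.0
    score = B.bdeu_score(data, {"a": (), "b": ()}, ess=ess)
    expected = 0.0
    for col in ("a", "b"):
        counts = np.bincount(data[col], minlength=3)
        expected += gammaln(ess) - gammaln(ess + 60)
        expected += sum(gammaln(ess / 3 + c) - gammaln(ess / 3) for c in counts)
    assert score == pytest.approx(expected, rel=1e-12)


def test_score_decomposability():
    rng = np.random.default_rng(1)
    data = pd.DataFrame({c: rng.integers(0, 3, 80) for c in "abc"})
    base = {"a": (), "b": (), "c": ()}
    withe = {"a": (), "b": ("a",), "c": ()}
    cache = B._ScoreCache(data, {c: 3 for c in "abc"}, 50.0)
    delta = B.bdeu_score(data, withe) - B.bdeu_score(data, base)
    assert delta == pytest.approx(
        cache.family("b", ("a",)) - cache.family("b", ()), rel=1e-12
    )


def test_identical_columns_favor_edge():
    rng = np.random.default_rng(2)
    a = rng.integers(0, 3, 200)
    data = pd.DataFrame({"a": a, "b": a.copy()})
    assert B.bdeu_score(data, {"a": (), "b": ("a",)}, ess=50.0) > B.bdeu_score(
        data, {"a": (), "b": ()}, ess=50.0
    )


def test_cyclic_graph_rejected():
    data = pd.DataFrame({"a": [0, 1, 2], "b": [0, 1, 2]})
    with pytest.raises(B.BayesNetError):
        B.bdeu_score(data, {"a": ("b",), "b": ("a",)})


# ---------------------------------------------------------------------------
# structure learning

def test_independent_columns_give_empty_graph():
    rng = np.random.default_rng(0)
    data = pd.DataFrame({c: rng.integers(0, 3, 1000) for c in "abc"})
    best, best_score = B.exhaustive_search(data)
    assert all(ps == () for ps in best.values())  # enumerated optimum is empty
    net = B.learn_structure(data, restarts=5, seed=0)
    assert net.edges == []
    assert B.bdeu_score(data, net.parents) == pytest.approx(best_score, rel=1e-12)


def test_deterministic_copy_gives_single_edge():
    rng = np.random.default_rng(4)
    a = rng.integers(0, 3, 1000)
    data = pd.DataFrame({"a": a, "b": a.copy()})
    net = B.learn_structure(data, restarts=5, seed=0)
    assert len(net.edges) == 1
    assert set(net.edges[0]) == {"a", "b"}


def test_tier_constraint_forces_direction():
    rng = np.random.default_rng(5)
    a = rng.integers(0, 3, 500)
    data = pd.DataFrame({"late": a, "early": a.copy()})
    tiers = {"late": 6, "early": 1}
    net = B.learn_structure(data, tiers=tiers, restarts=5, seed=0)
    assert net.edges == [("early", "late")]


def test_max_parents_respected():
    rng = np.random.default_rng(6)
    parents = {f"p{i}": rng.integers(0, 3, 400) for i in range(3)}
    child = (sum(parents.values()) % 3).astype(int)
    data = pd.DataFrame({**parents, "c": child})
    net = B.learn_structure(data, max_parents=2, restarts=10, seed=1)
    assert all(len(ps) <= 2 for ps in net.parents.values())


def test_hill_climb_matches_exhaustive_small():
    hits = 0
    for i in range(20):
        m = 3 + (i % 2)
        true, _ = B.benchmark_tiered_network(seed=500 + i, n_nodes=m)
        data = B.sample_from_net(true, 120, np.random.default_rng(i))
        learned = B.learn_structure(data, restarts=20, seed=i)
        _, best = B.exhaustive_search(data)
        if B.bdeu_score(data, learned.parents) >= best - 1e-9:
            hits += 1
    assert hits >= 19


# ---------------------------------------------------------------------------
# CPTs

def test_prior_only_cpts_uniform():
    net = B.BayesNet(nodes=["a", "b"], card={"a": 3, "b": 3},
                     parents={"a": (), "b": ("a",)})
    net = B.fit_cpts(net, None)
    assert np.allclose(net.cpts["a"], 1 / 3)
    assert np.allclose(net.cpts["b"], 1 / 3)


def test_cpt_columns_sum_to_one_and_posterior_mean():
    rng = np.random.default_rng(7)
    a = rng.integers(0, 3, 3000)
    b = a.copy()
    data = pd.DataFrame({"a": a, "b": b})
    net = B.BayesNet(nodes=["a", "b"], card={"a": 3, "b": 3},
                     parents={"a": (), "b": ("a",)}, ess=50.0)
    net = B.fit_cpts(net, data)
    assert np.allclose(net.cpts["b"].sum(axis=0), 1.0, atol=1e-12)
    # deterministic relation approaches 0/1 within O(ESS/n)
    for j in range(3):
        assert net.cpts["b"][j, j] > 1 - 60 / 1000


# ---------------------------------------------------------------------------
# inference

def test_point_mass_on_evidenced_query():
    net, _ = B.benchmark_tiered_network(seed=1, n_nodes=4)
    post = B.infer_posterior(net, {net.nodes[2]: 1}, net.nodes[2])
    assert post.tolist() == [0.0, 1.0, 0.0]


def test_chain_marginal_is_matrix_product():
    rng = np.random.default_rng(8)
    cpt_a = rng.dirichlet(np.ones(3)).reshape(3, 1)
    cpt_b = rng.dirichlet(np.ones(3), size=3).T   # (child, parent)
    net = B.BayesNet(nodes=["a", "b"], card={"a": 3, "b": 3},
                     parents={"a": (), "b": ("a",)},
                     cpts={"a": cpt_a, "b": cpt_b})
    marg = B.infer_posterior(net, {}, "b")
    assert marg == pytest.approx(cpt_b @ cpt_a[:, 0], abs=1e-12)


@pytest.mark.parametrize("seed", [2, 5, 9])
def test_variable_elimination_equals_enumeration(seed):
    net, _ = B.benchmark_tiered_network(seed=seed, n_nodes=6)
    net = B.fit_cpts(net, B.sample_from_net(net, 200, np.random.default_rng(seed)))
    J = joint_enumeration(net)
    for q in net.nodes:
        assert B.infer_posterior(net, {}, q) == pytest.approx(
            enum_marginal(net, J, q), abs=1e-10
        )
    ev = {net.nodes[0]: 2, net.nodes[3]: 0}
    for q in (net.nodes[1], net.nodes[5]):
        assert B.infer_posterior(net, ev, q) == pytest.approx(
            enum_marginal(net, J, q, ev), abs=1e-10
        )


def test_dseparated_evidence_leaves_query_unchanged():
    net = B.BayesNet(nodes=["a", "b"], card={"a": 3, "b": 3},
                     parents={"a": (), "b": ()})
    net = B.fit_cpts(net, None)
    assert B.infer_posterior(net, {"a": 0}, "b") == pytest.approx(
        B.infer_posterior(net, {}, "b")
    )


def test_impossible_evidence_raises():
    net = B.BayesNet(nodes=["a", "b"], card={"a": 3, "b": 3},
                     parents={"a": (), "b": ("a",)},
                     cpts={"a": np.array([[1.0], [0.0], [0.0]]),
                           "b": np.eye(3)})
    with pytest.raises(B.ImpossibleEvidenceError):
        B.infer_posterior(net, {"a": 2}, "b")


# ---------------------------------------------------------------------------
# sensitivity

def test_sensitivity_matches_finite_differences():
    net, _ = B.benchmark_tiered_network(seed=4, n_nodes=5)
    net = B.fit_cpts(net, B.sample_from_net(net, 300, np.random.default_rng(4)))
    target = net.nodes[-1]
    report = B.sensitivity_analysis(net, target)
    eps = 1e-4
    for x in net.nodes:
        if x == target:
            continue
        fd_best = 0.0
        cpt = net.cpts[x]
        p0 = B.joint_marginal(net, [target])
        for j in range(cpt.shape[1]):
            for k in range(net.card[x]):
                pert = B.perturb_proportional(net, x, j, k, eps)
                p1 = B.joint_marginal(pert, [target])
                fd_best = max(fd_best, float(np.abs((p1 - p0) / eps).max()))
        assert report.scores[x] == pytest.approx(fd_best, abs=1e-6)


def test_disconnected_node_scores_zero_and_target_excluded():
    net = B.BayesNet(nodes=["a", "t", "iso"], card={v: 3 for v in "a t iso".split()},
                     parents={"a": (), "t": ("a",), "iso": ()})
    net = B.fit_cpts(net, None)
    rng = np.random.default_rng(0)
    net.cpts["t"] = rng.dirichlet(np.ones(3), size=3).T
    report = B.sensitivity_analysis(net, "t")
    assert report.scores["iso"] == pytest.approx(0.0, abs=1e-12)
    assert "t" not in report.scores
    assert report.ranking[0][0] == "a"


def test_sensitivity_unknown_target():
    net, _ = B.benchmark_tiered_network(seed=0, n_nodes=3)
    with pytest.raises(B.BayesNetError):
        B.sensitivity_analysis(net, "nope")


# ---------------------------------------------------------------------------
# strength of influence

def _two_node_net(cpt_b):
    return B.BayesNet(nodes=["a", "b"], card={"a": 3, "b": 3},
                      parents={"a": (), "b": ("a",)},
                      cpts={"a": np.full((3, 1), 1 / 3), "b": cpt_b})


def test_strength_zero_iff_constant_cpt():
    s = B.strength_of_influence(_two_node_net(np.full((3, 3), 1 / 3)))
    assert s[0].strength == 0.0


def test_strength_of_deterministic_permutation_is_sqrt2():
    s = B.strength_of_influence(_two_node_net(np.eye(3)))
    assert s[0].strength == pytest.approx(math.sqrt(2))


def test_strength_hand_enumeration_two_distinct_rows():
    # parent states 0 and 1 give (1,0,0) vs (0,1,0): distance sqrt(2);
    # state 2 repeats state 1: pairs (0,1)=sqrt2, (0,2)=sqrt2, (1,2)=0
    cpt = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 1.0], [0.0, 0.0, 0.0]])
    s = B.strength_of_influence(_two_node_net(cpt))
    assert s[0].strength == pytest.approx(2 * math.sqrt(2) / 3)


def test_strength_weighting_by_coparent_frequency():
    # b has parents (a, c); the child distribution depends on a only when
    # c == 0, and c == 0 never occurs in the data -> weighted strength 0
    cpt = np.zeros((3, 9))
    for j in range(9):
        a_state, c_state = divmod(j, 3)
        if c_state == 0:
            cpt[a_state, j] = 1.0
        else:
            cpt[:, j] = 1 / 3
    net = B.BayesNet(nodes=["a", "c", "b"], card={"a": 3, "c": 3, "b": 3},
                     parents={"a": (), "c": (), "b": ("a", "c")},
                     cpts={"a": np.full((3, 1), 1 / 3),
                           "c": np.full((3, 1), 1 / 3), "b": cpt})
    data = pd.DataFrame({"a": [0, 1, 2, 0], "c": [1, 2, 1, 2], "b": [0, 0, 0, 0]})
    strengths = {(s.parent, s.child): s.strength for s in
                 B.strength_of_influence(net, data)}
    assert strengths[("a", "b")] == pytest.approx(0.0, abs=1e-12)
    uniform = {(s.parent, s.child): s.strength for s in B.strength_of_influence(net)}
    assert uniform[("a", "b")] > 0.3


def test_strength_bounded():
    net, _ = B.benchmark_tiered_network(seed=3, n_nodes=6)
    for s in B.strength_of_influence(net):
        assert 0.0 <= s.strength <= math.sqrt(2) + 1e-12


# ---------------------------------------------------------------------------
# k-fold validation

def test_kfold_deterministic_target_perfect_accuracy():
    rng = np.random.default_rng(10)
    x = rng.integers(0, 3, 240)
    data = pd.DataFrame({"x": x, "y": x.copy(), "z": rng.integers(0, 3, 240)})
    accs, mean = B.k_fold_validate(data, "y", k=5, seed=0, restarts=3)
    assert mean == 1.0 and len(accs) == 5


def test_kfold_independent_target_near_chance():
    rng = np.random.default_rng(11)
    data = pd.DataFrame(
        {"x": rng.integers(0, 3, 600), "y": rng.integers(0, 3, 600)}
    )
    _, mean = B.k_fold_validate(data, "y", k=5, seed=0, restarts=2)
    assert abs(mean - 1 / 3) < 0.08   # binomial tolerance at n=600


def test_kfold_seeded_reproducibility_and_errors():
    rng = np.random.default_rng(12)
    data = pd.DataFrame({"x": rng.integers(0, 3, 90), "y": rng.integers(0, 3, 90)})
    a1 = B.k_fold_validate(data, "y", k=3, seed=5, restarts=2)
    a2 = B.k_fold_validate(data, "y", k=3, seed=5, restarts=2)
    assert a1 == a2
    with pytest.raises(B.BayesNetError):
        B.k_fold_validate(data, "y", k=len(data) + 1)


# ---------------------------------------------------------------------------
# structure recovery & tier legality on synthetic benchmarks

def test_structure_recovery_benchmark():
    shds = []
    for seed in range(5):
        true, tiers = B.benchmark_tiered_network(seed=seed, n_nodes=8)
        data = B.sample_from_net(true, 2000, np.random.default_rng(100 + seed))
        learned = B.learn_structure(data, tiers=tiers, restarts=20, seed=seed)
        assert B.tier_violations(learned.edges, tiers) == []
        shds.append(B.shd(learned.edges, true.edges))
    assert float(np.mean(shds)) <= 2.0


def test_shd_counts_operations():
    assert B.shd([("a", "b")], [("a", "b")]) == 0
    assert B.shd([("a", "b")], [("b", "a")]) == 1          # reversal
    assert B.shd([("a", "b")], []) == 1                    # deletion
    assert B.shd([("a", "b"), ("b", "c")], [("b", "a")]) == 2
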