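"""Discrete Bayesian networks with temporal-tier constraints.

Structure is learned by greedy hill-climbing (add / delete / reverse moves,
random restarts) over the BDeu marginal-likelihood score with a uniform
structure prior. A move is legal only if the graph stays acyclic, every
edge u -> v satisfies tier(u) <= tier(v) (no retrogressive edge from a
later-occurring variable to an earlier one; within-tier edges are allowed
in both directions), and no node exceeds the parent limit. Parameters are
Dirichlet posterior means under the same equivalent sample size; inference
is exact variable elimination. Diagnostics: parameter-sensitivity of a
target's marginal (derivatives under proportional co-variation) and
per-edge strength of influence (mean distance between the child's
conditional distributions as one parent's state varies).

Conventions
-----------
States are integers 0..card-1. A node's CPT is an array of shape
``(card(child), q)`` where ``q`` is the number of parent configurations;
configuration index treats the first parent as most significant:
``j = s_1 * card_2 * ... * card_m + ... + s_m``. Every CPT column sums
to 1.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln

TierSpec = dict[str, int]


class BayesNetError(ValueError):
    pass


class ImpossibleEvidenceError(BayesNetError):
    """Evidence has probability exactly zero under the model."""


# ---------------------------------------------------------------------------
# structure containers

@dataclass
class BayesNet:
    """A discrete Bayesian network: DAG + CPTs.

    parents maps each node to an ordered tuple of parent names; cpts maps
    each node to its ``(card, q)`` conditional probability table.
    """

    nodes: list[str]
    card: dict[str, int]
    parents: dict[str, tuple[str, ...]]
    cpts: dict[str, np.ndarray] = field(default_factory=dict)
    ess: float = 50.0

    @property
    def edges(self) -> list[tuple[str, str]]:
        return [(u, v) for v in self.nodes for u in self.parents.get(v, ())]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def validate(self, tiers: TierSpec | None = None, max_parents: int | None = None) -> None:
        g = self.to_networkx()
        if not nx.is_directed_acyclic_graph(g):
            raise BayesNetError("graph has a cycle")
        for v, ps in self.parents.items():
            if max_parents is not None and len(ps) > max_parents:
                raise BayesNetError(f"{v} exceeds the parent limit")
            for u in ps:
                if tiers is not None and tiers[u] > tiers[v]:
                    raise BayesNetError(f"retrogressive edge {u} -> {v}")
        for v, cpt in self.cpts.items():
            if not np.allclose(cpt.sum(axis=0), 1.0, atol=1e-9):
                raise BayesNetError(f"CPT columns of {v} do not sum to 1")

    def n_configs(self, node: str) -> int:
        return int(np.prod([self.card[p] for p in self.parents[node]], dtype=np.int64))

    def config_index(self, node: str, states: dict[str, int]) -> int:
        j = 0
        for p in self.parents[node]:
            j = j * self.card[p] + states[p]
        return j

    def decode_config(self, node: str, j: int) -> dict[str, int]:
        out: dict[str, int] = {}
        for p in reversed(self.parents[node]):
            out[p] = j % self.card[p]
            j //= self.card[p]
        return out


def tier_violations(edges: list[tuple[str, str]], tiers: TierSpec) -> list[tuple[str, str]]:
    return [(u, v) for u, v in edges if tiers[u] > tiers[v]]


def shd(edges_a: list[tuple[str, str]], edges_b: list[tuple[str, str]]) -> int:
    """Structural Hamming distance: insertions + deletions + reversals."""
    a, b = set(edges_a), set(edges_b)
    d = 0
    seen = set()
    for u, v in a | b:
        key = frozenset((u, v))
        if key in seen:
            continue
        seen.add(key)
        in_a = (u, v) in a or (v, u) in a
        in_b = (u, v) in b or (v, u) in b
        if in_a and in_b:
            ea = (u, v) if (u, v) in a else (v, u)
            eb = (u, v) if (u, v) in b else (v, u)
            if ea != eb:
                d += 1          # reversal
        else:
            d += 1              # insertion/deletion
    return d


# ---------------------------------------------------------------------------
# BDeu scoring

def _parent_config_codes(
    data: dict[str, np.ndarray], card: dict[str, int], parents: tuple[str, ...]
) -> tuple[np.ndarray, int]:
    n = len(next(iter(data.values()))) if data else 0
    codes = np.zeros(n, dtype=np.int64)
    q = 1
    for p in parents:
        codes = codes * card[p] + data[p]
        q *= card[p]
    return codes, q


def family_counts(
    data: dict[str, np.ndarray],
    card: dict[str, int],
    child: str,
    parents: tuple[str, ...],
) -> np.ndarray:
    """Count table of shape (card(child), q) over parent configurations."""
    r = card[child]
    codes, q = _parent_config_codes(data, card, parents)
    flat = np.bincount(data[child] * q + codes, minlength=r * q)
    return flat.reshape(r, q)


def bdeu_family_score(counts: np.ndarray, ess: float) -> float:
    """Log BDeu marginal likelihood of one family (child given parents)."""
    r, q = counts.shape
    a_jk = ess / (r * q)
    a_j = ess / q
    nj = counts.sum(axis=0)
    score = float(np.sum(gammaln(a_j) - gammaln(a_j + nj)))
    score += float(np.sum(gammaln(a_jk + counts) - gammaln(a_jk)))
    return score


class _ScoreCache:
    """Memoized BDeu family scores for one dataset."""

    def __init__(self, data: pd.DataFrame, card: dict[str, int], ess: float):
        self.arrays = {c: data[c].to_numpy(dtype=np.int64) for c in data.columns}
        self.card = card
        self.ess = ess
        self._cache: dict[tuple[str, tuple[str, ...]], float] = {}

    def family(self, child: str, parents: tuple[str, ...]) -> float:
        key = (child, tuple(sorted(parents)))
        if key not in self._cache:
            counts = family_counts(self.arrays, self.card, child, parents)
            self._cache[key] = bdeu_family_score(counts, self.ess)
        return self._cache[key]

    def total(self, parents: dict[str, tuple[str, ...]]) -> float:
        return sum(self.family(v, ps) for v, ps in parents.items())


def bdeu_score(
    data: pd.DataFrame,
    parents: dict[str, tuple[str, ...]],
    ess: float = 50.0,
    card: dict[str, int] | None = None,
) -> float:
    """Log BDeu score of a DAG given complete discrete data."""
    card = card or infer_cardinalities(data)
    g = nx.DiGraph()
    g.add_nodes_from(parents)
    g.add_edges_from((u, v) for v, ps in parents.items() for u in ps)
    if not nx.is_directed_acyclic_graph(g):
        raise BayesNetError("graph has a cycle")
    return _ScoreCache(data, card, ess).total(parents)


def infer_cardinalities(data: pd.DataFrame, minimum: int = 3) -> dict[str, int]:
    return {c: max(minimum, int(data[c].max()) + 1) for c in data.columns}


# ---------------------------------------------------------------------------
# structure search

def _legal_add(g: nx.DiGraph, u: str, v: str, tiers: TierSpec | None,
               max_parents: int) -> bool:
    if u == v or g.has_edge(u, v):
        return False
    if tiers is not None and tiers[u] > tiers[v]:
        return False
    if g.in_degree(v) >= max_parents:
        return False
    return not nx.has_path(g, v, u)


def _hill_climb(
    cache: _ScoreCache,
    nodes: list[str],
    tiers: TierSpec | None,
    max_parents: int,
    rng: np.random.Generator,
    init_edges: list[tuple[str, str]],
) -> tuple[dict[str, tuple[str, ...]], float]:
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(init_edges)

    def parents_of(v: str) -> tuple[str, ...]:
        return tuple(sorted(g.predecessors(v)))

    fam = {v: cache.family(v, parents_of(v)) for v in nodes}
    total = sum(fam.values())

    while True:
        best_delta = 1e-9
        best_move = None
        pairs = [(u, v) for u in nodes for v in nodes if u != v]
        rng.shuffle(pairs)
        for u, v in pairs:
            if g.has_edge(u, v):
                # delete
                g.remove_edge(u, v)
                d = cache.family(v, parents_of(v)) - fam[v]
                g.add_edge(u, v)
                if d > best_delta:
                    best_delta, best_move = d, ("del", u, v)
                # reverse
                if (tiers is None or tiers[v] <= tiers[u]) and g.in_degree(u) < max_parents:
                    g.remove_edge(u, v)
                    cyclic = nx.has_path(g, u, v)
                    if not cyclic:
                        g.add_edge(v, u)
                        d = (cache.family(v, parents_of(v)) - fam[v]
                             + cache.family(u, parents_of(u)) - fam[u])
                        g.remove_edge(v, u)
                        if d > best_delta:
                            best_delta, best_move = d, ("rev", u, v)
                    g.add_edge(u, v)
            elif _legal_add(g, u, v, tiers, max_parents):
                g.add_edge(u, v)
                d = cache.family(v, parents_of(v)) - fam[v]
                g.remove_edge(u, v)
                if d > best_delta:
                    best_delta, best_move = d, ("add", u, v)
        if best_move is None:
            break
        op, u, v = best_move
        if op == "add":
            g.add_edge(u, v)
        elif op == "del":
            g.remove_edge(u, v)
        else:
            g.remove_edge(u, v)
            g.add_edge(v, u)
            fam[u] = cache.family(u, parents_of(u))
        fam[v] = cache.family(v, parents_of(v))
        total = sum(fam.values())

    return {v: parents_of(v) for v in nodes}, total


def _random_init(
    nodes: list[str],
    tiers: TierSpec | None,
    max_parents: int,
    rng: np.random.Generator,
    edge_prob: float = 0.2,
) -> list[tuple[str, str]]:
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    pairs = [(u, v) for u in nodes for v in nodes if u != v]
    rng.shuffle(pairs)
    for u, v in pairs:
        if rng.random() < edge_prob and _legal_add(g, u, v, tiers, max_parents):
            g.add_edge(u, v)
    return list(g.edges())


def learn_structure(
    data: pd.DataFrame,
    tiers: TierSpec | None = None,
    max_parents: int = 8,
    ess: float = 50.0,
    restarts: int = 20,
    seed: int = 0,
    card: dict[str, int] | None = None,
) -> BayesNet:
    """BDeu hill-climbing with random restarts under tier constraints.

    Restart 0 starts from the empty graph; later restarts from random legal
    DAGs. The best-scoring structure over all restarts is returned (CPTs
    not yet fitted; see :func:`fit_cpts`).
    """
    nodes = list(data.columns)
    if tiers is not None:
        missing = [v for v in nodes if v not in tiers]
        if missing:
            raise BayesNetError(f"variables without a tier: {missing}")
    card = card or infer_cardinalities(data)
    cache = _ScoreCache(data, card, ess)
    rng = np.random.default_rng(seed)

    best_parents: dict[str, tuple[str, ...]] | None = None
    best_score = -math.inf
    for r in range(max(1, restarts)):
        init = [] if r == 0 else _random_init(nodes, tiers, max_parents, rng)
        parents, score = _hill_climb(cache, nodes, tiers, max_parents, rng, init)
        if score > best_score:
            best_score, best_parents = score, parents
    assert best_parents is not None
    net = BayesNet(nodes=nodes, card=card, parents=best_parents, ess=ess)
    net.validate(tiers=tiers, max_parents=max_parents)
    return net


def exhaustive_search(
    data: pd.DataFrame,
    tiers: TierSpec | None = None,
    max_parents: int | None = None,
    ess: float = 50.0,
    card: dict[str, int] | None = None,
) -> tuple[dict[str, tuple[str, ...]], float]:
    """Globally optimal DAG by enumeration of all parent-set combinations.

    Only feasible for <= 5 nodes; used as the independent optimum oracle for
    the hill-climbing search.
    """
    nodes = list(data.columns)
    m = len(nodes)
    if m > 5:
        raise BayesNetError("exhaustive search limited to 5 nodes")
    card = card or infer_cardinalities(data)
    cache = _ScoreCache(data, card, ess)
    limit = m - 1 if max_parents is None else min(max_parents, m - 1)

    choices: list[list[tuple[tuple[str, ...], float]]] = []
    for v in nodes:
        cands = [u for u in nodes if u != v
                 and (tiers is None or tiers[u] <= tiers[v])]
        opts = []
        for k in range(limit + 1):
            for ps in itertools.combinations(cands, k):
                opts.append((ps, cache.family(v, ps)))
        choices.append(opts)

    def acyclic(parent_sets: tuple[tuple[str, ...], ...]) -> bool:
        indeg = {v: len(ps) for v, ps in zip(nodes, parent_sets)}
        children: dict[str, list[str]] = {v: [] for v in nodes}
        for v, ps in zip(nodes, parent_sets):
            for u in ps:
                children[u].append(v)
        stack = [v for v in nodes if indeg[v] == 0]
        seen = 0
        while stack:
            u = stack.pop()
            seen += 1
            for w in children[u]:
                indeg[w] -= 1
                if indeg[w] == 0:
                    stack.append(w)
        return seen == m

    best_score = -math.inf
    best: dict[str, tuple[str, ...]] | None = None
    for combo in itertools.product(*choices):
        score = sum(s for _, s in combo)
        if score <= best_score:
            continue
        ps = tuple(p for p, _ in combo)
        if acyclic(ps):
            best_score = score
            best = {v: p for v, p in zip(nodes, ps)}
    assert best is not None
    return best, best_score


# ---------------------------------------------------------------------------
# parameters

def fit_cpts(
    net: BayesNet,
    data: pd.DataFrame | None,
    ess: float | None = None,
) -> BayesNet:
    """Dirichlet posterior-mean CPTs: (N_jk + ess/(r q)) / (N_j + ess/q).

    With no data every column is uniform (the prior mean).
    """
    ess = net.ess if ess is None else ess
    arrays = (
        {c: data[c].to_numpy(dtype=np.int64) for c in data.columns}
        if data is not None else None
    )
    cpts = {}
    for v in net.nodes:
        r = net.card[v]
        q = net.n_configs(v)
        if arrays is None:
            counts = np.zeros((r, q))
        else:
            counts = family_counts(arrays, net.card, v, net.parents[v]).astype(float)
        a_jk = ess / (r * q)
        a_j = ess / q
        cpts[v] = (counts + a_jk) / (counts.sum(axis=0, keepdims=True) + a_j)
    return BayesNet(nodes=net.nodes, card=net.card, parents=net.parents,
                    cpts=cpts, ess=ess)


# ---------------------------------------------------------------------------
# exact inference: variable elimination

class _Factor:
    __slots__ = ("vars", "table")

    def __init__(self, vars_: tuple[str, ...], table: np.ndarray):
        self.vars = vars_
        self.table = table

    def reduce(self, var: str, state: int) -> "_Factor":
        ax = self.vars.index(var)
        return _Factor(
            self.vars[:ax] + self.vars[ax + 1:],
            np.take(self.table, state, axis=ax),
        )


def _multiply(f1: _Factor, f2: _Factor) -> _Factor:
    uvars = f1.vars + tuple(v for v in f2.vars if v not in f1.vars)

    def expand(f: _Factor) -> np.ndarray:
        present = [v for v in uvars if v in f.vars]
        t = np.transpose(f.table, axes=[f.vars.index(v) for v in present])
        shape = [t.shape[present.index(v)] if v in f.vars else 1 for v in uvars]
        return t.reshape(shape)

    return _Factor(uvars, expand(f1) * expand(f2))


def _sum_out(f: _Factor, var: str) -> _Factor:
    ax = f.vars.index(var)
    return _Factor(f.vars[:ax] + f.vars[ax + 1:], f.table.sum(axis=ax))


def _node_factor(net: BayesNet, v: str) -> _Factor:
    ps = net.parents[v]
    shape = (net.card[v],) + tuple(net.card[p] for p in ps)
    return _Factor((v,) + ps, net.cpts[v].reshape(shape))


def _eliminate(
    factors: list[_Factor], hidden: set[str], card: dict[str, int]
) -> list[_Factor]:
    factors = list(factors)
    hidden = set(hidden)
    while hidden:
        # greedy: eliminate the variable whose product factor is smallest
        best_var, best_size = None, None
        for h in hidden:
            union: set[str] = set()
            for f in factors:
                if h in f.vars:
                    union.update(f.vars)
            size = int(np.prod([card[v] for v in union - {h}], dtype=np.int64)) if union else 1
            if best_size is None or size < best_size:
                best_var, best_size = h, size
        h = best_var
        assert h is not None
        related = [f for f in factors if h in f.vars]
        rest = [f for f in factors if h not in f.vars]
        if related:
            prod = related[0]
            for f in related[1:]:
                prod = _multiply(prod, f)
            rest.append(_sum_out(prod, h))
        factors = rest
        hidden.discard(h)
    return factors


def joint_marginal(
    net: BayesNet,
    variables: list[str],
    evidence: dict[str, int] | None = None,
) -> np.ndarray:
    """Exact joint distribution over ``variables`` given evidence,
    normalized; axes follow the order of ``variables``."""
    evidence = evidence or {}
    for v, s in evidence.items():
        if not 0 <= s < net.card[v]:
            raise BayesNetError(f"evidence state {s} out of range for {v}")
    keep = [v for v in variables if v not in evidence]
    factors = []
    for v in net.nodes:
        f = _node_factor(net, v)
        for ev, s in evidence.items():
            if ev in f.vars:
                f = f.reduce(ev, s)
        factors.append(f)
    hidden = set(net.nodes) - set(keep) - set(evidence)
    factors = _eliminate(factors, hidden, net.card)
    result = _Factor((), np.array(1.0))
    for f in factors:
        result = _multiply(result, f)
    total = float(result.table.sum())
    if total == 0.0:
        raise ImpossibleEvidenceError("evidence has probability zero")
    table = result.table / total
    # expand evidenced query variables back as point masses
    full = _Factor(result.vars, table)
    for v in variables:
        if v in evidence:
            point = np.zeros(net.card[v])
            point[evidence[v]] = 1.0
            full = _multiply(full, _Factor((v,), point))
    order = [full.vars.index(v) for v in variables]
    return np.transpose(full.table, axes=order)


def infer_posterior(
    net: BayesNet,
    evidence: dict[str, int],
    query: str,
) -> np.ndarray:
    """Exact conditional distribution of ``query`` given evidence."""
    if query not in net.nodes:
        raise BayesNetError(f"unknown query variable {query!r}")
    return joint_marginal(net, [query], evidence)


# ---------------------------------------------------------------------------
# diagnostics

@dataclass
class SensitivityReport:
    target: str
    scores: dict[str, float]            # node -> max |dP(target=s)/d theta|
    ranking: list[tuple[str, float]]    # sorted descending


def perturb_proportional(
    net: BayesNet, node: str, config: int, state: int, eps: float
) -> BayesNet:
    """Shift one CPT entry by ``eps`` with proportional co-variation of the
    other entries in its column (used for finite-difference checks)."""
    cpt = net.cpts[node].copy()
    col = cpt[:, config].copy()
    t0 = col[state]
    rest = 1.0 - t0
    col *= (rest - eps) / rest
    col[state] = t0 + eps
    cpt[:, config] = col
    cpts = dict(net.cpts)
    cpts[node] = cpt
    return BayesNet(nodes=net.nodes, card=net.card, parents=net.parents,
                    cpts=cpts, ess=net.ess)


def sensitivity_analysis(net: BayesNet, target: str) -> SensitivityReport:
    """Max absolute derivative of any target-state prior marginal with
    respect to any CPT parameter of each node, under proportional
    co-variation, with no evidence.

    Because the joint is multilinear with exactly one factor per family,
    the derivative has the closed form

        dP(T=s)/d eps = P(T=s, X=k0, Pa=j)/theta_k0
                        - sum_{k != k0} P(T=s, X=k, Pa=j)/(1 - theta_k0)

    which is computed from one exact joint marginal per node.
    """
    if target not in net.nodes:
        raise BayesNetError(f"target {target!r} not in the network")
    scores: dict[str, float] = {}
    for x in net.nodes:
        if x == target:
            continue
        ps = net.parents[x]
        uvars = [target, x] + [p for p in ps if p not in (target, x)]
        joint = joint_marginal(net, uvars)
        cpt = net.cpts[x]
        r = net.card[x]
        q = cpt.shape[1]
        best = 0.0
        for j in range(q):
            states = net.decode_config(x, j)
            sl: list = [slice(None), slice(None)] + [states[p] for p in uvars[2:]]
            # block[s, k] = P(target=s, X=k, other parents at config j); if
            # the target is itself a parent of X, only s = states[target]
            # belongs to config j and the other rows are masked to zero
            block = joint[tuple(sl)]          # shape (card(target), r)
            for k0 in range(r):
                t0 = cpt[k0, j]
                if not (0.0 < t0 < 1.0):
                    continue
                d = block[:, k0] / t0
                others = np.delete(np.arange(r), k0)
                d = d - block[:, others].sum(axis=1) / (1.0 - t0)
                if target in states:
                    mask = np.zeros(net.card[target], dtype=bool)
                    mask[states[target]] = True
                    d = np.where(mask, d, 0.0)
                m = float(np.max(np.abs(d)))
                if m > best:
                    best = m
        scores[x] = best
    ranking = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return SensitivityReport(target=target, scores=scores, ranking=ranking)


@dataclass
class InfluenceStrength:
    parent: str
    child: str
    strength: float


def strength_of_influence(
    net: BayesNet,
    data: pd.DataFrame | None = None,
    metric: str = "euclidean",
) -> list[InfluenceStrength]:
    """Per-edge mean distance between the child's conditional distributions
    across all unordered pairs of the parent's states, averaged over
    co-parent configurations weighted by their empirical frequency (uniform
    when no data is given). Euclidean by default; ``metric='hellinger'``
    for the Hellinger distance.
    """
    if metric not in ("euclidean", "hellinger"):
        raise BayesNetError(f"unknown metric {metric!r}")
    out: list[InfluenceStrength] = []
    arrays = (
        {c: data[c].to_numpy(dtype=np.int64) for c in data.columns}
        if data is not None else None
    )
    for v in net.nodes:
        ps = net.parents[v]
        if not ps:
            continue
        r = net.card[v]
        cards = [net.card[p] for p in ps]
        table = net.cpts[v].reshape([r] + cards)
        for ai, u in enumerate(ps):
            ru = net.card[u]
            # move the parent axis right after the child axis
            t = np.moveaxis(table, ai + 1, 1)   # (r, ru, *other cards)
            other = [c for k, c in enumerate(cards) if k != ai]
            qo = int(np.prod(other, dtype=np.int64)) if other else 1
            t = t.reshape(r, ru, qo)
            if arrays is not None and other:
                others = tuple(p for p in ps if p != u)
                codes, _ = _parent_config_codes(arrays, net.card, others)
                w = np.bincount(codes, minlength=qo).astype(float)
                w = np.full(qo, 1.0 / qo) if w.sum() == 0 else w / w.sum()
            else:
                w = np.full(qo, 1.0 / qo)
            total = 0.0
            npairs = 0
            pair_means = np.zeros(qo)
            for a, b in itertools.combinations(range(ru), 2):
                da = t[:, a, :]
                db = t[:, b, :]
                if metric == "euclidean":
                    dist = np.sqrt(((da - db) ** 2).sum(axis=0))
                else:
                    dist = np.sqrt(
                        0.5 * ((np.sqrt(da) - np.sqrt(db)) ** 2).sum(axis=0)
                    )
                pair_means += dist
                npairs += 1
            total = float((pair_means / npairs) @ w)
            out.append(InfluenceStrength(parent=u, child=v, strength=total))
    return out


# ---------------------------------------------------------------------------
# validation

def k_fold_validate(
    data: pd.DataFrame,
    target: str,
    tiers: TierSpec | None = None,
    k: int = 10,
    seed: int = 0,
    ess: float = 50.0,
    restarts: int = 5,
    max_parents: int = 8,
) -> tuple[list[float], float]:
    """Stratified k-fold accuracy of predicting the target's most probable
    state from all other variables (learn + fit on training folds only)."""
    n = len(data)
    if k > n:
        raise BayesNetError("k exceeds the number of rows")
    if k < 2:
        raise BayesNetError("k must be >= 2")
    rng = np.random.default_rng(seed)
    y = data[target].to_numpy()
    folds = np.empty(n, dtype=int)
    for state in np.unique(y):
        idx = np.flatnonzero(y == state)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % k
    card = infer_cardinalities(data)
    accs: list[float] = []
    others = [c for c in data.columns if c != target]
    for f in range(k):
        train = data.loc[folds != f]
        test = data.loc[folds == f]
        present = set(train[target].unique())
        if len(present) < len(set(y)):
            raise BayesNetError(
                f"fold {f}: target state absent from the training folds"
            )
        net = learn_structure(train, tiers=tiers, max_parents=max_parents,
                              ess=ess, restarts=restarts,
                              seed=seed + 1000 + f, card=card)
        net = fit_cpts(net, train)
        hits = 0
        for _, row in test.iterrows():
            evidence = {c: int(row[c]) for c in others}
            post = infer_posterior(net, evidence, target)
            hits += int(np.argmax(post)) == int(row[target])
        accs.append(hits / len(test) if len(test) else float("nan"))
    return accs, float(np.mean(accs))


# ---------------------------------------------------------------------------
# synthetic networks for benchmarking

def random_tiered_dag(
    nodes: list[str],
    tiers: TierSpec,
    rng: np.random.Generator,
    edge_prob: float = 0.4,
    max_parents: int = 8,
) -> dict[str, tuple[str, ...]]:
    """Random tier-consistent DAG (cross-tier edges follow the tier order;
    within-tier edges follow a random node order)."""
    order = sorted(nodes, key=lambda v: (tiers[v], rng.random()))
    parents: dict[str, list[str]] = {v: [] for v in nodes}
    for i, v in enumerate(order):
        for u in order[:i]:
            if tiers[u] <= tiers[v] and len(parents[v]) < max_parents:
                if rng.random() < edge_prob:
                    parents[v].append(u)
    return {v: tuple(sorted(ps)) for v, ps in parents.items()}


def modular_cpts(
    nodes: list[str],
    card: dict[str, int],
    parents: dict[str, tuple[str, ...]],
    rng: np.random.Generator,
    strength: float = 0.85,
) -> dict[str, np.ndarray]:
    """Strong, identifiable CPTs: each child's dominant state is a modular
    function of its parents' states with probability ``strength``."""
    cpts = {}
    for v in nodes:
        r = card[v]
        ps = parents[v]
        q = int(np.prod([card[p] for p in ps], dtype=np.int64))
        if not ps:
            col = rng.dirichlet(np.full(r, 5.0))
            cpts[v] = col.reshape(r, 1)
            continue
        offset = int(rng.integers(r))
        cpt = np.full((r, q), (1.0 - strength) / (r - 1))
        for j in range(q):
            jj, ssum = j, 0
            for p in reversed(ps):
                ssum += jj % card[p]
                jj //= card[p]
            cpt[(ssum + offset) % r, j] = strength
        cpts[v] = cpt
    return cpts


def sample_from_net(net: BayesNet, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Forward (ancestral) sampling of n joint observations."""
    g = net.to_networkx()
    order = list(nx.topological_sort(g))
    cols: dict[str, np.ndarray] = {}
    for v in order:
        ps = net.parents[v]
        r = net.card[v]
        cpt = net.cpts[v]
        if not ps:
            cols[v] = rng.choice(r, size=n, p=cpt[:, 0])
            continue
        codes = np.zeros(n, dtype=np.int64)
        for p in ps:
            codes = codes * net.card[p] + cols[p]
        out = np.empty(n, dtype=np.int64)
        for j in np.unique(codes):
            mask = codes == j
            out[mask] = rng.choice(r, size=int(mask.sum()), p=cpt[:, j])
        cols[v] = out
    return pd.DataFrame({v: cols[v] for v in net.nodes})


def benchmark_tiered_network(seed: int = 0, n_nodes: int = 8) -> tuple[BayesNet, TierSpec]:
    """A known tiered ternary network with strong effects, for structure
    recovery benchmarks."""
    rng = np.random.default_rng(seed)
    nodes = [f"v{i}" for i in range(n_nodes)]
    tiers = {v: 1 + i * 4 // n_nodes for i, v in enumerate(nodes)}
    card = {v: 3 for v in nodes}
    parents = random_tiered_dag(nodes, tiers, rng, edge_prob=0.35, max_parents=4)
    cpts = modular_cpts(nodes, card, parents, rng)
    net = BayesNet(nodes=nodes, card=card, parents=parents, cpts=cpts)
    net.validate(tiers=tiers)
    return net, tiers
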