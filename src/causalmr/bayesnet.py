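"""Linear-Gaussian Bayesian-network structure learning with anchors.

Score-based causal discovery over continuous variables: each node is
modelled as a linear regression on its parents with Gaussian noise, scored
by BIC (log-likelihood minus (parameters/2)·log n, higher is better, and
decomposable over nodes).  A greedy hill-climbing search over single-edge
moves (add/delete/reverse) finds a local optimum, subject to a whitelist of
forced edges and a blacklist of forbidden edges.  Genetic directional
anchors — SNP→phenotype edges whitelisted, edges into SNPs blacklisted —
orient otherwise Markov-equivalent structures.

Edge confidence comes from a nonparametric bootstrap: the search is re-run
on row resamples, presence and direction frequencies are tallied per
adjacency, and a consensus graph keeps adjacencies above a presence
threshold (0.8 by default), oriented by majority direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

Edge = tuple[str, str]


@dataclass
class Dag:
    """Directed acyclic graph over named variables."""

    nodes: tuple[str, ...]
    edges: frozenset[Edge] = frozenset()

    def __post_init__(self) -> None:
        self.nodes = tuple(self.nodes)
        self.edges = frozenset(self.edges)
        known = set(self.nodes)
        for u, v in self.edges:
            if u == v:
                raise ValidationError(f"self-edge {u}->{v}")
            if u not in known or v not in known:
                raise ValidationError(f"edge {u}->{v} references unknown node")
        if not self.is_acyclic():
            raise ValidationError("graph contains a cycle")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.to_networkx())

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(u for u, v in self.edges if v == node))

    def with_edge(self, edge: Edge) -> "Dag":
        return Dag(self.nodes, self.edges | {edge})

    def without_edge(self, edge: Edge) -> "Dag":
        return Dag(self.nodes, self.edges - {edge})

    def to_edge_list(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.edges), columns=["parent", "child"])

    def to_dot(self) -> str:
        lines = ["digraph {"]
        lines += [f'  "{n}";' for n in self.nodes]
        lines += [f'  "{u}" -> "{v}";' for u, v in sorted(self.edges)]
        lines.append("}")
        return "\n".join(lines)


@dataclass
class EdgeConstraints:
    """Forced (whitelist) and forbidden (blacklist) directed edges."""

    whitelist: frozenset[Edge] = frozenset()
    blacklist: frozenset[Edge] = frozenset()

    def __post_init__(self) -> None:
        self.whitelist = frozenset(tuple(e) for e in self.whitelist)
        self.blacklist = frozenset(tuple(e) for e in self.blacklist)
        overlap = self.whitelist & self.blacklist
        if overlap:
            raise ValidationError(f"edges both white- and black-listed: {sorted(overlap)}")

    def validate(self, nodes: Sequence[str]) -> None:
        known = set(nodes)
        for u, v in self.whitelist | self.blacklist:
            if u not in known or v not in known:
                raise ValidationError(f"constraint edge {u}->{v} references unknown node")
        g = nx.DiGraph(list(self.whitelist))
        if not nx.is_directed_acyclic_graph(g):
            raise ValidationError("whitelist alone contains a cycle")

    @classmethod
    def anchors(cls, anchor_edges: Iterable[Edge], anchor_nodes: Iterable[str],
                nodes: Sequence[str]) -> "EdgeConstraints":
        """Genetic-anchor convenience: whitelist the known SNP→phenotype
        edges, blacklist every edge into any anchor node and all edges
        between anchors."""
        anchor_nodes = list(anchor_nodes)
        wl = frozenset(anchor_edges)
        bl = set()
        for a in anchor_nodes:
            for n in nodes:
                if n != a:
                    bl.add((n, a))
        bl -= wl
        return cls(whitelist=wl, blacklist=frozenset(bl))


@dataclass
class EdgeSupport:
    """Bootstrap presence/direction tallies per candidate adjacency.

    ``direction_prob`` is P(parent→child | adjacency present); the two
    orientations of one adjacency sum to 1."""

    table: pd.DataFrame  # parent, child, presence_prob, direction_prob
    n_boot: int

    def presence(self, u: str, v: str) -> float:
        t = self.table
        row = t[(t["parent"] == u) & (t["child"] == v)]
        return float(row["presence_prob"].iloc[0]) if len(row) else 0.0

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _local_bic(data: np.ndarray, child: int, parents: tuple[int, ...]) -> tuple[float, bool]:
    """Gaussian BIC contribution of one node given its parents.

    Returns (score, degenerate) where degenerate marks a rank-deficient
    parent design fitted with the pseudo-inverse."""
    n = data.shape[0]
    y = data[:, child]
    if parents:
        X = np.column_stack([np.ones(n), data[:, parents]])
    else:
        X = np.ones((n, 1))
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    degenerate = rank < X.shape[1]
    resid = y - X @ coef
    sigma2 = max(float(resid @ resid) / n, 1e-300)
    loglik = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    n_params = len(parents) + 2  # coefficients + intercept + variance
    return loglik - 0.5 * n_params * np.log(n), degenerate


class _Scorer:
    """Caches per-node local BIC scores for one dataset."""

    def __init__(self, data: pd.DataFrame):
        self.columns = list(data.columns)
        self.index = {c: i for i, c in enumerate(self.columns)}
        self.values = data.to_numpy(dtype=float)
        self.cache: dict[tuple[int, tuple[int, ...]], float] = {}
        self.degenerate_nodes: set[str] = set()

    def local(self, child: str, parents: tuple[str, ...]) -> float:
        key = (self.index[child], tuple(sorted(self.index[p] for p in parents)))
        if key not in self.cache:
            score, degen = _local_bic(self.values, key[0], key[1])
            self.cache[key] = score
            if degen:
                self.degenerate_nodes.add(child)
        return self.cache[key]

    def total(self, dag: Dag) -> float:
        return sum(self.local(n, dag.parents(n)) for n in dag.nodes)


def bic_score(data: pd.DataFrame, dag: Dag) -> tuple[float, dict[str, float]]:
    """Decomposable Gaussian BIC of ``dag`` on ``data`` (higher is better).

    Returns the total score and the per-node local scores.  The largest
    parent set must leave at least two residual degrees of freedom."""
    max_parents = max((len(dag.parents(n)) for n in dag.nodes), default=0)
    if data.shape[0] < max_parents + 2:
        raise ValidationError("need at least 2 more observations than the largest parent set")
    scorer = _Scorer(data[list(dag.nodes)])
    locals_ = {n: scorer.local(n, dag.parents(n)) for n in dag.nodes}
    if scorer.degenerate_nodes:
        logger.warning("degenerate (rank-deficient) parent design for: %s",
                       sorted(scorer.degenerate_nodes))
    return sum(locals_.values()), locals_


def _creates_cycle(g: nx.DiGraph, u: str, v: str) -> bool:
    return g.has_node(v) and g.has_node(u) and nx.has_path(g, v, u)


def _hill_climb_from(start: Dag, scorer: _Scorer, constraints: EdgeConstraints,
                     max_iter: int) -> Dag:
    dag = start
    g = dag.to_networkx()
    score_cache = {n: scorer.local(n, dag.parents(n)) for n in dag.nodes}
    nodes = dag.nodes

    for _ in range(max_iter):
        best_delta = 1e-10
        best_apply = None
        edges = dag.edges
        for u in nodes:
            for v in nodes:
                if u == v:
                    continue
                e = (u, v)
                if e not in edges and (v, u) not in edges:
                    if e in constraints.blacklist or _creates_cycle(g, u, v):
                        continue
                    delta = scorer.local(v, tuple(sorted(set(dag.parents(v)) | {u}))) - score_cache[v]
                    if delta > best_delta:
                        best_delta, best_apply = delta, ("add", e)
                elif e in edges:
                    if e not in constraints.whitelist:
                        delta = scorer.local(v, tuple(p for p in dag.parents(v) if p != u)) - score_cache[v]
                        if delta > best_delta:
                            best_delta, best_apply = delta, ("delete", e)
                        # reversal: delete u->v, add v->u
                        if (v, u) not in constraints.blacklist:
                            g.remove_edge(u, v)
                            cycle = _creates_cycle(g, v, u)
                            g.add_edge(u, v)
                            if not cycle:
                                d = (
                                    scorer.local(v, tuple(p for p in dag.parents(v) if p != u))
                                    - score_cache[v]
                                    + scorer.local(u, tuple(sorted(set(dag.parents(u)) | {v})))
                                    - score_cache[u]
                                )
                                if d > best_delta:
                                    best_delta, best_apply = d, ("reverse", e)
        if best_apply is None:
            break
        op, (u, v) = best_apply
        if op == "add":
            dag = dag.with_edge((u, v))
            g.add_edge(u, v)
            score_cache[v] = scorer.local(v, dag.parents(v))
        elif op == "delete":
            dag = dag.without_edge((u, v))
            g.remove_edge(u, v)
            score_cache[v] = scorer.local(v, dag.parents(v))
        else:
            dag = dag.without_edge((u, v)).with_edge((v, u))
            g.remove_edge(u, v)
            g.add_edge(v, u)
            score_cache[v] = scorer.local(v, dag.parents(v))
            score_cache[u] = scorer.local(u, dag.parents(u))
    return dag


def _random_start(nodes, constraints: EdgeConstraints, rng: np.random.Generator) -> Dag:
    order = list(nodes)
    rng.shuffle(order)
    pos = {n: i for i, n in enumerate(order)}
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(constraints.whitelist)
    for u in nodes:
        for v in nodes:
            if u == v or pos[u] >= pos[v]:
                continue
            e = (u, v)
            if e in constraints.blacklist or g.has_edge(u, v) or g.has_edge(v, u):
                continue
            if rng.random() < 0.2 and not _creates_cycle(g, u, v):
                g.add_edge(u, v)
    return Dag(tuple(nodes), frozenset(g.edges))


def hill_climb(
    data: pd.DataFrame,
    constraints: EdgeConstraints | None = None,
    max_iter: int | None = None,
    restarts: int = 0,
    seed: int | None = None,
) -> Dag:
    """Greedy BIC hill climbing over single-edge moves.

    Starts from the whitelist-only graph; whitelisted edges are never
    deleted or reversed, blacklisted edges never added.  Deterministic
    given the data; the seed matters only for optional random restarts,
    whose best-scoring result is returned."""
    constraints = constraints or EdgeConstraints()
    nodes = tuple(data.columns)
    constraints.validate(nodes)
    p = len(nodes)
    if max_iter is None:
        max_iter = 10 * p * p
    scorer = _Scorer(data)

    best = _hill_climb_from(Dag(nodes, constraints.whitelist), scorer, constraints, max_iter)
    best_score = scorer.total(best)
    if restarts:
        rng = np.random.default_rng(seed)
        for _ in range(restarts):
            cand = _hill_climb_from(_random_start(nodes, constraints, rng), scorer,
                                    constraints, max_iter)
            s = scorer.total(cand)
            if s > best_score:
                best, best_score = cand, s

    assert best.is_acyclic()
    assert constraints.whitelist <= best.edges
    assert not (best.edges & constraints.blacklist)
    return best


def bootstrap_edges(
    data: pd.DataFrame,
    constraints: EdgeConstraints | None = None,
    n_boot: int = 1000,
    threshold: float = 0.8,
    seed: int | None = None,
    restarts: int = 0,
) -> tuple[EdgeSupport, Dag]:
    """Bootstrap the structure search and build a consensus graph.

    ``n_boot`` nonparametric row-resamples (size n), hill climbing on each;
    presence_prob is the fraction of bootstrap graphs containing the
    adjacency in either direction, direction_prob the orientation share
    given presence.  The consensus keeps adjacencies with presence_prob ≥
    ``threshold`` oriented by majority direction; rare consensus cycles are
    broken by dropping the lowest-presence edge."""
    constraints = constraints or EdgeConstraints()
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    nodes = tuple(data.columns)
    constraints.validate(nodes)
    n = data.shape[0]
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_boot)

    directed_counts: dict[Edge, int] = {}
    for b in range(n_boot):
        rng = np.random.default_rng(child_seeds[b])
        idx = rng.integers(0, n, size=n)
        sample = data.iloc[idx].reset_index(drop=True)
        dag = hill_climb(sample, constraints, restarts=restarts,
                         seed=int(rng.integers(2**31)))
        for e in dag.edges:
            directed_counts[e] = directed_counts.get(e, 0) + 1

    adjacencies = {tuple(sorted(e)) for e in directed_counts}
    rows = []
    for a, bnode in sorted(adjacencies):
        c_ab = directed_counts.get((a, bnode), 0)
        c_ba = directed_counts.get((bnode, a), 0)
        present = c_ab + c_ba
        for parent, child, count in ((a, bnode, c_ab), (bnode, a, c_ba)):
            rows.append(
                {
                    "parent": parent,
                    "child": child,
                    "presence_prob": present / n_boot,
                    "direction_prob": count / present if present else 0.0,
                }
            )
    support = EdgeSupport(
        pd.DataFrame(rows, columns=["parent", "child", "presence_prob", "direction_prob"]),
        n_boot,
    )

    # consensus: majority orientation of every adjacency above threshold
    chosen: list[tuple[float, Edge]] = []
    for a, bnode in sorted(adjacencies):
        c_ab = directed_counts.get((a, bnode), 0)
        c_ba = directed_counts.get((bnode, a), 0)
        presence = (c_ab + c_ba) / n_boot
        if presence >= threshold:
            edge = (a, bnode) if c_ab >= c_ba else (bnode, a)
            chosen.append((presence, edge))

    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(e for _, e in chosen)
    while not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        weakest = min(
            cycle, key=lambda uv: next(p for p, e in chosen if e == (uv[0], uv[1]))
        )
        logger.warning("breaking consensus cycle by dropping %s->%s", *weakest)
        g.remove_edge(*weakest)
    consensus = Dag(nodes, frozenset(g.edges))
    return support, consensus
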