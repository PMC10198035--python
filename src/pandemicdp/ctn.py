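"""Privacy-preserving release of contact-tracing networks (CTNs).

A CTN is an undirected simple graph: nodes are people, edges are
close-contact events.  The release mechanism here is DP-ERGM: fit an
exponential random graph model to the network, draw its parameter from
a posterior induced by a Laplace-sanitized sufficient statistic,
sanitize the statistic itself with the other half of the budget, and
publish a surrogate network generated from the model conditional on
the sanitized statistic.  Edge-level DP is used throughout: flipping
one relation changes the edge count by at most 1 (sensitivity 1).

In scope is the edge-count-only ERGM, p(E) proportional to
exp(theta * E(graph)) — the Bernoulli random graph with
p = logit^{-1}(theta) — for which the MLE is closed-form and
conditioning on the edge count makes the surrogate law uniform over
graphs with that many edges.  A Warner-style randomized-response
edge flip is included as a baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.special import expit

from .dp_core import BudgetLedger, draw_laplace_noise

__all__ = [
    "Graph",
    "NetSummary",
    "ERGMSpec",
    "DPERGMRelease",
    "DPERGMReleaseSet",
    "BoundaryMLEError",
    "graph_stats",
    "espd_tvd",
    "fit_ergm_edge",
    "dp_ergm_release",
    "sample_graph_fixed_edges",
    "rr_flip",
    "rr_debias_edge_count",
    "simulate_ctn",
]


class BoundaryMLEError(RuntimeError):
    """Raised when the edge-count MLE sits on the boundary (E = 0 or N)."""


@dataclass(frozen=True)
class Graph:
    """Undirected simple graph with 0-based integer node ids."""

    n_nodes: int
    edges: frozenset

    def __post_init__(self) -> None:
        if int(self.n_nodes) != self.n_nodes or self.n_nodes < 1:
            raise ValueError("n_nodes must be a positive integer")
        norm = set()
        for e in self.edges:
            u, v = e
            if u == v:
                raise ValueError(f"self-loop at node {u}")
            if not (0 <= u < self.n_nodes and 0 <= v < self.n_nodes):
                raise ValueError(f"edge {e} references a node outside [0, n)")
            norm.add((min(u, v), max(u, v)))
        object.__setattr__(self, "edges", frozenset(norm))

    @property
    def n_dyads(self) -> int:
        return self.n_nodes * (self.n_nodes - 1) // 2

    @property
    def edge_count(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Graph":
        nodes = sorted(g.nodes())
        relabel = {u: i for i, u in enumerate(nodes)}
        return cls(
            n_nodes=len(nodes),
            edges=frozenset((relabel[u], relabel[v]) for u, v in g.edges()),
        )


@dataclass(frozen=True)
class ERGMSpec:
    """ERGM statistic list and natural parameters (edge count only)."""

    statistics: tuple[str, ...] = ("edges",)
    theta: tuple[float, ...] = (0.0,)

    def __post_init__(self) -> None:
        if self.statistics != ("edges",):
            raise ValueError(
                "only the edge-count statistic is supported in this release"
            )
        if len(self.theta) != 1:
            raise ValueError("theta must have one entry per statistic")


@dataclass(frozen=True)
class NetSummary:
    """Structural summary of one graph.

    degree_dist[k] is the number of nodes with exactly k neighbors
    (sums to n).  espd[k] is the fraction of edges whose endpoints have
    exactly k common neighbors (sums to 1 when there are edges).
    Closeness follows (A_i/(n-1))^2 / C_i with A_i reachable nodes and
    C_i the summed shortest-path distances; an isolated node gets 0.
    """

    n_nodes: int
    edge_count: int
    triangle_count: int
    degree_dist: np.ndarray
    espd: np.ndarray
    betweenness: np.ndarray
    closeness: np.ndarray


def graph_stats(g: Graph) -> NetSummary:
    """Exact structural summary statistics of a graph."""
    n = g.n_nodes
    nxg = g.to_networkx()

    triangles = sum(nx.triangles(nxg).values()) // 3

    degrees = np.array([d for _, d in nxg.degree()], dtype=int)
    degree_dist = np.bincount(degrees, minlength=n)[:n]

    adj = {u: set(nxg.neighbors(u)) for u in range(n)}
    esp_counts = np.zeros(max(n - 1, 1), dtype=float)
    for u, v in g.edges:
        esp_counts[len(adj[u] & adj[v])] += 1
    espd = esp_counts / g.edge_count if g.edge_count > 0 else esp_counts

    betweenness = np.array(
        [nx.betweenness_centrality(nxg, normalized=True)[u] for u in range(n)]
    )

    closeness = np.zeros(n)
    for u in range(n):
        lengths = nx.single_source_shortest_path_length(nxg, u)
        a = len(lengths) - 1
        if a > 0:
            c = sum(lengths.values())
            closeness[u] = (a / (n - 1)) ** 2 / c

    return NetSummary(
        n_nodes=n,
        edge_count=g.edge_count,
        triangle_count=int(triangles),
        degree_dist=degree_dist,
        espd=espd,
        betweenness=betweenness,
        closeness=closeness,
    )


def espd_tvd(a: NetSummary, b: NetSummary) -> float:
    """Total variation distance between two shared-partner distributions."""
    if a.edge_count == 0 or b.edge_count == 0:
        raise ValueError("ESPD is undefined for a graph with no edges")
    size = max(a.espd.size, b.espd.size)
    pa = np.zeros(size)
    pb = np.zeros(size)
    pa[: a.espd.size] = a.espd
    pb[: b.espd.size] = b.espd
    return 0.5 * float(np.abs(pa - pb).sum())


def fit_ergm_edge(g: Graph) -> tuple[float, float]:
    """Closed-form MLE of the edge-only ERGM.

    The edge-count model is exactly the Bernoulli graph on N dyads, so
    theta_hat = log(E/(N-E)) with Var(theta_hat) = 1/E + 1/(N-E) — the
    log-odds of a dyad being an edge, identical to a logistic
    regression on the N dyad indicators with intercept only.
    """
    e, n_dyads = g.edge_count, g.n_dyads
    if e == 0 or e == n_dyads:
        raise BoundaryMLEError(
            f"edge count {e} of {n_dyads} dyads: no finite MLE"
        )
    theta = float(np.log(e / (n_dyads - e)))
    se = float(np.sqrt(1.0 / e + 1.0 / (n_dyads - e)))
    return theta, se


def sample_graph_fixed_edges(
    n: int, e: int, rng: np.random.Generator
) -> Graph:
    """Uniform draw over simple graphs with n nodes and exactly e edges.

    For the edge-only ERGM this is the conditional law given the edge
    count (theta cancels), so it doubles as the surrogate generator.
    """
    if int(n) != n or n < 1:
        raise ValueError("n must be a positive integer")
    n_dyads = n * (n - 1) // 2
    if int(e) != e or not 0 <= e <= n_dyads:
        raise ValueError(f"edge count must lie in [0, {n_dyads}]")
    iu, iv = np.triu_indices(n, k=1)
    chosen = rng.choice(n_dyads, size=int(e), replace=False)
    return Graph(
        n_nodes=int(n),
        edges=frozenset(
            (int(iu[c]), int(iv[c])) for c in chosen
        ),
    )


@dataclass(frozen=True)
class DPERGMRelease:
    """One sanitized release: parameter draw, statistic, surrogate."""

    theta_draw: float
    sanitized_edge_count: int
    surrogate: Graph
    epsilon_release: float

    def __post_init__(self) -> None:
        if self.surrogate.edge_count != self.sanitized_edge_count:
            raise ValueError(
                "surrogate edge count must equal the sanitized edge count"
            )


@dataclass
class DPERGMReleaseSet:
    releases: list[DPERGMRelease] = field(default_factory=list)
    ledger: BudgetLedger | None = None

    @property
    def m(self) -> int:
        return len(self.releases)


def dp_ergm_release(
    g: Graph,
    epsilon_total: float,
    rng: np.random.Generator,
    m: int = 1,
) -> DPERGMReleaseSet:
    """DP-ERGM synthesis of m surrogate networks.

    Per release (budget epsilon/m, split equally across two stages):

    * stage A — sanitize the edge count with Laplace noise, clamp to
      [0, N], and draw theta from the induced posterior: with a
      uniform prior on the dyad probability p, the sanitized count
      gives p ~ Beta(E~ + 1, N - E~ + 1) and theta = logit(p).  E is
      sufficient for the edge-only ERGM, so privacy follows from
      post-processing of the sanitized statistic.
    * stage B — independently sanitize the edge count again, round and
      clamp, and generate the surrogate from ERGM(theta) conditional
      on that edge count (uniform over graphs with that many edges).
    """
    if not epsilon_total > 0:
        raise ValueError("epsilon_total must be positive")
    if int(m) != m or m < 1:
        raise ValueError("m must be a positive integer")
    n_dyads = g.n_dyads
    e_true = g.edge_count
    eps_stage = epsilon_total / m / 2.0
    scale = 1.0 / eps_stage  # edge-count sensitivity is 1
    ledger = BudgetLedger(epsilon_total)
    out = DPERGMReleaseSet(ledger=ledger)
    for l in range(int(m)):
        ledger.spend(f"release-{l}/posterior", eps_stage)
        e_post = float(
            np.clip(e_true + draw_laplace_noise(scale, 1, rng)[0], 0, n_dyads)
        )
        p_draw = rng.beta(e_post + 1.0, n_dyads - e_post + 1.0)
        theta_draw = float(np.log(p_draw / (1.0 - p_draw)))

        ledger.spend(f"release-{l}/edge-count", eps_stage)
        e_san = int(
            np.clip(
                np.round(e_true + draw_laplace_noise(scale, 1, rng)[0]),
                0,
                n_dyads,
            )
        )
        surrogate = sample_graph_fixed_edges(g.n_nodes, e_san, rng)
        out.releases.append(
            DPERGMRelease(
                theta_draw=theta_draw,
                sanitized_edge_count=e_san,
                surrogate=surrogate,
                epsilon_release=epsilon_total / m,
            )
        )
    return out


def rr_flip(g: Graph, epsilon: float, rng: np.random.Generator) -> Graph:
    """Warner randomized response on every dyad.

    Each dyad state is kept with probability e^eps/(1 + e^eps) and
    flipped with probability 1/(1 + e^eps), independently — epsilon-
    edge-DP by direct computation of the likelihood ratio.
    """
    if not epsilon > 0:
        raise ValueError("epsilon must be positive")
    n = g.n_nodes
    iu, iv = np.triu_indices(n, k=1)
    adj = np.zeros(iu.size, dtype=bool)
    edge_idx = {e: i for i, e in enumerate(zip(iu.tolist(), iv.tolist()))}
    for e in g.edges:
        adj[edge_idx[e]] = True
    q = float(expit(-epsilon))
    flip = rng.random(iu.size) < q
    adj ^= flip
    keep = np.nonzero(adj)[0]
    return Graph(
        n_nodes=n,
        edges=frozenset((int(iu[i]), int(iv[i])) for i in keep),
    )


def rr_debias_edge_count(
    sanitized_count: float, n: int, epsilon: float
) -> float:
    """Inverse-probability unbiased estimate of the true edge count.

    With flip probability q = 1/(1+e^eps), E[sanitized] =
    E(1-q) + (N-E)q, so (sanitized - N q)/(1 - 2q) is unbiased.
    """
    if not epsilon > 0:
        raise ValueError("epsilon must be positive (epsilon = 0 leaves q = 1/2)")
    n_dyads = n * (n - 1) // 2
    q = float(expit(-epsilon))
    return float((sanitized_count - n_dyads * q) / (1.0 - 2.0 * q))


def simulate_ctn(
    n: int,
    expected_edges: float,
    rng: np.random.Generator,
    clustering: float = 0.0,
) -> Graph:
    """Simulate a sparse CTN-like graph.

    Default: Bernoulli (edge-only ERGM) graph with dyad probability
    expected_edges/N.  A positive ``clustering`` knob performs that
    fraction (of the edge count) of triangle-closing rewires, each
    replacing a random edge by a wedge-closing edge, preserving the
    edge count exactly — a qualitative stand-in for the excess
    triangles real contact networks show.
    """
    if int(n) != n or n < 2:
        raise ValueError("n must be an integer >= 2")
    n_dyads = n * (n - 1) // 2
    if not 0 <= expected_edges < n_dyads:
        raise ValueError("expected_edges must lie in [0, N)")
    iu, iv = np.triu_indices(n, k=1)
    present = rng.random(n_dyads) < (expected_edges / n_dyads)
    edges = {(int(iu[i]), int(iv[i])) for i in np.nonzero(present)[0]}

    if clustering > 0 and edges:
        adj: dict[int, set[int]] = {u: set() for u in range(n)}
        for u, v in edges:
            adj[u].add(v)
            adj[v].add(u)
        n_rewires = int(np.ceil(clustering * len(edges)))
        for _ in range(n_rewires):
            elist = sorted(edges)
            u, v = elist[rng.integers(len(elist))]
            # wedge closures: nodes adjacent to exactly one of u, v
            candidates = sorted((adj[u] ^ adj[v]) - {u, v})
            if not candidates:
                continue
            w = candidates[rng.integers(len(candidates))]
            new_edge = (min(v if w in adj[u] else u, w),
                        max(v if w in adj[u] else u, w))
            old = elist[rng.integers(len(elist))]
            if new_edge in edges or old == new_edge:
                continue
            edges.remove(old)
            adj[old[0]].discard(old[1])
            adj[old[1]].discard(old[0])
            edges.add(new_edge)
            adj[new_edge[0]].add(new_edge[1])
            adj[new_edge[1]].add(new_edge[0])
    return Graph(n_nodes=int(n), edges=frozenset(edges))
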