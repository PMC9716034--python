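"""I-DEG-anchored correlation screening and co-expression community discovery.

The screen proceeds in two stages with strict thresholds: DEGs with at
least one immune-DEG partner at |r| > 0.40 and p < 0.05 are "related"
genes; the co-expression network then connects related genes at
|r| > 0.70 and p < 0.05, edge weight |r| (signed r and p retained).
Communities are found by weighted Louvain modularity optimization
(resolution 1), modules below 30 genes are discarded, and each module's
classic graph density 2E / (n(n-1)) is reported.

The Louvain implementation here is self-contained: two phases (greedy
local moving, then community aggregation) iterated to convergence, node
visit order shuffled by the seed, ties broken by the first best-gain
community encountered.  Seeded restarts (default 5) keep the best-Q
partition, which makes small-graph optima reliable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .study import ExpressionStudy


# ---------------------------------------------------------------------------
# Pearson correlation with p-values
# ---------------------------------------------------------------------------

def _pearson_matrix(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlations between two gene blocks (genes x samples)."""
    za = xa - xa.mean(axis=1, keepdims=True)
    zb = xb - xb.mean(axis=1, keepdims=True)
    sa = np.sqrt((za**2).sum(axis=1))
    sb = np.sqrt((zb**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (za @ zb.T) / np.outer(sa, sb)
    return np.clip(r, -1.0, 1.0)


def correlation_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r via t = r sqrt(n-2) / sqrt(1-r^2), n-2 df."""
    r = np.asarray(r, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    return np.where(np.abs(r) >= 1.0, np.zeros_like(p), p)


def pearson_with_p(study: ExpressionStudy, genes_a, genes_b) -> pd.DataFrame:
    """All a × b gene-pair correlations (identical genes excluded).

    Returns a long table with columns gene_a, gene_b, r, p, n.
    Zero-variance genes are excluded with a warning.
    """
    genes_a = [g for g in genes_a if g in study.genes]
    genes_b = [g for g in genes_b if g in study.genes]
    n = len(study.samples)
    if n < 3:
        raise ValueError("need at least 3 shared samples")
    xa = study.expr.loc[genes_a].to_numpy(dtype=float)
    xb = study.expr.loc[genes_b].to_numpy(dtype=float)

    var_a, var_b = xa.var(axis=1), xb.var(axis=1)
    if np.any(var_a == 0) or np.any(var_b == 0):
        warnings.warn("zero-variance genes dropped from correlation table")
        genes_a = [g for g, v in zip(genes_a, var_a) if v > 0]
        genes_b = [g for g, v in zip(genes_b, var_b) if v > 0]
        xa, xb = xa[var_a > 0], xb[var_b > 0]

    r = _pearson_matrix(xa, xb)
    p = correlation_p(r, n)
    ia, ib = np.meshgrid(np.arange(len(genes_a)), np.arange(len(genes_b)),
                         indexing="ij")
    tab = pd.DataFrame(
        {
            "gene_a": np.asarray(genes_a, dtype=object)[ia.ravel()],
            "gene_b": np.asarray(genes_b, dtype=object)[ib.ravel()],
            "r": r.ravel(),
            "p": p.ravel(),
            "n": n,
        }
    )
    return tab[tab.gene_a != tab.gene_b].reset_index(drop=True)


def select_related_genes(cors: pd.DataFrame, r_min: float = 0.40,
                         alpha: float = 0.05) -> set[str]:
    """DEGs with >= 1 immune-DEG partner at |r| > r_min and p < alpha (strict).

    ``cors`` is a pearson_with_p table with immune DEGs as ``gene_a`` and
    candidate DEGs as ``gene_b``; the retained set is over ``gene_b``.
    """
    if not (0 <= r_min < 1 and 0 < alpha < 1):
        raise ValueError("thresholds out of range")
    hit = (cors["r"].abs() > r_min) & (cors["p"] < alpha)
    return set(cors.loc[hit, "gene_b"])


# ---------------------------------------------------------------------------
# Co-expression network
# ---------------------------------------------------------------------------

@dataclass
class CoexprNetwork:
    """Undirected simple graph over genes; weight = |r|, signed r and p kept."""

    nodes: list[str]
    edges: pd.DataFrame  # gene_a, gene_b, r, p, weight

    def adjacency(self) -> dict[str, dict[str, float]]:
        adj: dict[str, dict[str, float]] = {v: {} for v in self.nodes}
        for a, b, w in zip(self.edges["gene_a"], self.edges["gene_b"],
                           self.edges["weight"]):
            adj[a][b] = w
            adj[b][a] = w
        return adj

    def nonisolated(self) -> list[str]:
        touched = set(self.edges["gene_a"]) | set(self.edges["gene_b"])
        return [v for v in self.nodes if v in touched]


def build_network(study: ExpressionStudy, related_genes, r_min: float = 0.70,
                  alpha: float = 0.05) -> CoexprNetwork:
    """Connect related genes whose pairwise |r| > r_min and p < alpha.

    Isolated nodes remain in the node set (they are dropped only before
    clustering).  An empty edge set triggers a warning, not an error.
    """
    nodes = [g for g in study.genes if g in set(related_genes)]
    missing = set(related_genes) - set(nodes)
    if missing:
        raise ValueError(f"related genes absent from study: {sorted(missing)[:5]}")
    n = len(study.samples)
    x = study.expr.loc[nodes].to_numpy(dtype=float)
    r = _pearson_matrix(x, x)
    p = correlation_p(r, n)
    iu, ju = np.triu_indices(len(nodes), k=1)
    keep = (np.abs(r[iu, ju]) > r_min) & (p[iu, ju] < alpha)
    edges = pd.DataFrame(
        {
            "gene_a": np.asarray(nodes, dtype=object)[iu[keep]],
            "gene_b": np.asarray(nodes, dtype=object)[ju[keep]],
            "r": r[iu, ju][keep],
            "p": p[iu, ju][keep],
        }
    )
    edges["weight"] = edges["r"].abs()
    if edges.empty:
        warnings.warn("co-expression network has no edges")
    return CoexprNetwork(nodes=nodes, edges=edges)


# ---------------------------------------------------------------------------
# Weighted Louvain community discovery
# ---------------------------------------------------------------------------

@dataclass
class ModulePartition:
    assignment: dict[str, str]            # gene -> module id ("" = unassigned)
    modularity: float
    seed: int
    sizes: dict[str, int] = field(default_factory=dict)
    densities: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sizes:
            self.sizes = dict(
                pd.Series([m for m in self.assignment.values() if m])
                .value_counts()
            )

    def modules(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for g, m in self.assignment.items():
            if m:
                out.setdefault(m, []).append(g)
        return {m: sorted(gs) for m, gs in out.items()}


def modularity(adj: dict[str, dict[str, float]],
               communities: dict[str, int]) -> float:
    """Weighted Newman modularity Q of a node->community mapping."""
    two_m = sum(sum(nb.values()) for nb in adj.values())
    if two_m == 0:
        return 0.0
    q = 0.0
    sum_in: dict[int, float] = {}
    sum_tot: dict[int, float] = {}
    for v, nb in adj.items():
        c = communities[v]
        k_v = sum(nb.values())
        sum_tot[c] = sum_tot.get(c, 0.0) + k_v
        for u, w in nb.items():
            if communities[u] == c:
                sum_in[c] = sum_in.get(c, 0.0) + w
    for c in sum_tot:
        q += sum_in.get(c, 0.0) / two_m - (sum_tot[c] / two_m) ** 2
    return q


def _one_level(adj_idx: list[dict[int, float]], self_w: list[float],
               two_m: float, rng: np.random.Generator,
               init: list[int] | None = None) -> tuple[list[int], bool]:
    """Greedy local-moving phase on an aggregated graph.

    ``init`` seeds the starting communities (defaults to singletons),
    which allows a node-level refinement pass over a coarse partition.
    """
    n = len(adj_idx)
    comm = list(range(n)) if init is None else list(init)
    k = [sum(nb.values()) + 2.0 * self_w[i] for i, nb in enumerate(adj_idx)]
    if init is None:
        sum_tot = k.copy()
        empty: list[int] = []      # vacated community ids, reusable
    else:
        sum_tot = [0.0] * (max(comm) + 1)
        for i, c in enumerate(comm):
            sum_tot[c] += k[i]
        empty = [c for c, s in enumerate(sum_tot) if s == 0.0]
    improved_any = False
    order = np.arange(n)
    while True:
        moved = False
        rng.shuffle(order)
        for i in order:
            ci = comm[i]
            # weight from i to each neighboring community
            links: dict[int, float] = {}
            for j, w in adj_idx[i].items():
                links[comm[j]] = links.get(comm[j], 0.0) + w
            sum_tot[ci] -= k[i]
            comm[i] = -1
            # gain of staying is the baseline; ties keep the first best seen
            best_c = ci
            best_gain = links.get(ci, 0.0) - sum_tot[ci] * k[i] / two_m
            if best_gain < -1e-12:
                # splitting off into an empty community beats staying
                best_c, best_gain = -1, 0.0
            for c, w_ic in links.items():
                if c == ci:
                    continue
                gain = w_ic - sum_tot[c] * k[i] / two_m
                if gain > best_gain + 1e-12:
                    best_c, best_gain = c, gain
            if best_c == -1:
                if sum_tot[ci] == 0.0:
                    best_c = ci            # old community is already empty
                elif empty:
                    best_c = empty.pop()
                else:
                    best_c = len(sum_tot)
                    sum_tot.append(0.0)
            comm[i] = best_c
            sum_tot[best_c] += k[i]
            if best_c != ci:
                if sum_tot[ci] == 0.0:
                    empty.append(ci)
                moved = True
                improved_any = True
        if not moved:
            break
    return comm, improved_any


def _aggregate(adj_idx: list[dict[int, float]], self_w: list[float],
               comm: list[int]) -> tuple[list[dict[int, float]], list[float],
                                         list[int]]:
    labels = sorted(set(comm))
    remap = {c: i for i, c in enumerate(labels)}
    new_n = len(labels)
    new_adj: list[dict[int, float]] = [dict() for _ in range(new_n)]
    new_self = [0.0] * new_n
    for i, nb in enumerate(adj_idx):
        ci = remap[comm[i]]
        new_self[ci] += self_w[i]
        for j, w in nb.items():
            cj = remap[comm[j]]
            if ci == cj:
                if i < j:
                    new_self[ci] += w
            else:
                new_adj[ci][cj] = new_adj[ci].get(cj, 0.0) + w
    return new_adj, new_self, [remap[c] for c in comm]


def louvain_partition(net: CoexprNetwork, seed: int = 0,
                      n_restarts: int = 10) -> ModulePartition:
    """Two-phase weighted Louvain; isolated nodes are left unassigned.

    The best-Q partition over ``n_restarts`` seeded runs is returned,
    module ids relabelled ``M1, M2, ...`` by decreasing size.
    """
    if net.edges.empty:
        raise ValueError("cannot cluster an edgeless network")
    nodes = net.nonisolated()
    index = {v: i for i, v in enumerate(nodes)}
    adj0: list[dict[int, float]] = [dict() for _ in nodes]
    for a, b, w in zip(net.edges["gene_a"], net.edges["gene_b"],
                       net.edges["weight"]):
        ia, ib = index[a], index[b]
        adj0[ia][ib] = adj0[ia].get(ib, 0.0) + w
        adj0[ib][ia] = adj0[ib].get(ia, 0.0) + w
    two_m = sum(sum(nb.values()) for nb in adj0)

    full_adj = {v: {nodes[j]: w for j, w in adj0[index[v]].items()}
                for v in nodes}

    best_q, best_comm = -np.inf, None
    for restart in range(max(1, n_restarts)):
        rng = np.random.default_rng([seed, restart])
        adj_idx = [dict(nb) for nb in adj0]
        self_w = [0.0] * len(nodes)
        node2comm = list(range(len(nodes)))
        # restart 0 is classic Louvain (singleton start); later restarts
        # begin from random coarse partitions to escape single-move optima
        if restart == 0:
            init = None
        else:
            n_blocks = max(2, int(rng.integers(2, len(nodes) + 1)))
            init = [int(c) for c in rng.integers(0, n_blocks, len(nodes))]
        first = True
        while True:
            comm, improved = _one_level(adj_idx, self_w, two_m, rng,
                                        init=init if first else None)
            first = False
            if not improved and len(set(comm)) == len(adj_idx):
                break
            adj_idx, self_w, comm = _aggregate(adj_idx, self_w, comm)
            node2comm = [comm[c] for c in node2comm]
            if not improved:
                break
        # node-level refinement: local moving on the original graph seeded
        # from the coarse partition undoes unfavourable early merges
        refined, _ = _one_level(adj0, [0.0] * len(nodes), two_m, rng,
                                init=node2comm)
        mapping = {v: refined[index[v]] for v in nodes}
        q = modularity(full_adj, mapping)
        if q > best_q + 1e-12:
            best_q, best_comm = q, mapping

    by_size = pd.Series(best_comm).value_counts()
    relabel = {c: f"M{i + 1}" for i, c in enumerate(by_size.index)}
    assignment = {v: relabel[best_comm[v]] for v in nodes}
    for v in net.nodes:
        assignment.setdefault(v, "")
    return ModulePartition(assignment=assignment, modularity=float(best_q),
                           seed=seed)


def filter_modules(part: ModulePartition, min_size: int = 30
                   ) -> ModulePartition:
    """Delete modules with fewer than ``min_size`` genes (strict <)."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    keep = {m for m, s in part.sizes.items() if s >= min_size}
    if not keep:
        warnings.warn("all modules removed by the size filter")
    assignment = {g: (m if m in keep else "") for g, m in part.assignment.items()}
    return ModulePartition(assignment=assignment, modularity=part.modularity,
                           seed=part.seed)


def graph_density(net: CoexprNetwork, node_subset=None) -> float:
    """Classic density 2E/(n(n-1)) over a node subset (unweighted counts)."""
    nodes = set(node_subset) if node_subset is not None else set(net.nodes)
    n = len(nodes)
    if n < 2:
        raise ValueError("density needs at least 2 nodes")
    inside = net.edges["gene_a"].isin(nodes) & net.edges["gene_b"].isin(nodes)
    e = int(inside.sum())
    return 2.0 * e / (n * (n - 1))


def module_densities(net: CoexprNetwork, part: ModulePartition
                     ) -> dict[str, float]:
    return {m: graph_density(net, genes) for m, genes in part.modules().items()
            if len(genes) >= 2}
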