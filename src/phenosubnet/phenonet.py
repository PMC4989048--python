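"""Phenotype-guided differential sub-network discovery.

A heterogeneous network joins a protein-protein interaction (PPI) layer and
a phenotype-ontology layer through protein-phenotype annotation edges.
Disease phenotypes seed a random walk with restart (RWR) whose steady-state
visitation probabilities measure phenotype proximity; each protein also
carries a differential-expression score from the paired analysis. Candidate
sub-networks are grown greedily on the PPI layer by a combined score
(min-max scaled DE score times min-max scaled RWR probability), assigned
empirical p-values against size-matched connected sub-networks resampled
from the PPI layer, filtered at an empirical threshold, merged through
shared proteins, and annotated with their top enriched GO-style term by a
one-sided hypergeometric test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from scipy import sparse, stats

from ._utils import as_rng

__all__ = [
    "HetNet",
    "GeneSetCollection",
    "SubNetwork",
    "build_heterogeneous_network",
    "score_nodes",
    "rwr",
    "combined_node_scores",
    "extract_subnetworks",
    "sample_connected_subnetwork",
    "empirical_pvalue",
    "filter_and_merge",
    "annotate_top_go",
    "hypergeom_upper_tail",
]

PROTEIN = "protein"
PHENOTYPE = "phenotype"
LAYERS = ("ppi", "pheno_pheno", "protein_pheno")


@dataclass
class HetNet:
    """Typed heterogeneous graph of protein and phenotype nodes."""

    graph: nx.Graph

    @classmethod
    def from_edges(cls, ppi, pheno, bridges, phenotypes=None) -> "HetNet":
        g = nx.Graph()
        pheno_nodes = set(phenotypes or [])
        for u, v, *w in pheno:
            pheno_nodes.update((u, v))
        protein_nodes = set()
        for u, v, *w in ppi:
            protein_nodes.update((u, v))
        for u, v, *w in bridges:
            # exactly one endpoint must be a phenotype
            u_ph, v_ph = u in pheno_nodes, v in pheno_nodes
            if u_ph == v_ph:
                raise ValueError(f"bridge edge ({u}, {v}) must join a protein "
                                 "to a phenotype")
            protein_nodes.add(v if u_ph else u)
        for n in protein_nodes:
            g.add_node(n, kind=PROTEIN)
        for n in pheno_nodes:
            g.add_node(n, kind=PHENOTYPE)

        def add(edges, layer):
            for u, v, *rest in edges:
                if u == v:
                    continue  # never admit self-loops
                w = float(rest[0]) if rest else 1.0
                if w < 0:
                    raise ValueError(f"negative edge weight on ({u}, {v})")
                if g.has_edge(u, v):  # duplicate edges collapse keeping max weight
                    if g[u][v]["layer"] == layer:
                        g[u][v]["weight"] = max(g[u][v]["weight"], w)
                        continue
                g.add_edge(u, v, layer=layer, weight=w)

        add(ppi, "ppi")
        add(pheno, "pheno_pheno")
        add(bridges, "protein_pheno")
        return cls(graph=g)

    @property
    def proteins(self) -> list:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == PROTEIN)

    @property
    def phenotypes(self) -> list:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["kind"] == PHENOTYPE)

    def ppi_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(n for n, d in self.graph.nodes(data=True) if d["kind"] == PROTEIN)
        g.add_edges_from(
            (u, v, d) for u, v, d in self.graph.edges(data=True) if d["layer"] == "ppi"
        )
        return g


@dataclass
class GeneSetCollection:
    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self):
        for name, members in self.sets.items():
            extra = members - self.universe
            if extra:
                raise ValueError(f"gene set {name!r} has members outside the universe")


@dataclass
class SubNetwork:
    """A connected protein sub-graph with its aggregate differential score."""

    nodes: frozenset
    score: float
    empirical_p: float | None = None
    top_go_term: str | None = None
    top_go_p: float | None = None

    @property
    def size(self) -> int:
        return len(self.nodes)

    def sorted_nodes(self) -> list:
        return sorted(self.nodes)


def build_heterogeneous_network(ppi, pheno, bridges, expressed) -> HetNet:
    """Assemble a HetNet, restricting the PPI layer to expressed proteins.

    PPI and bridge edges touching a non-expressed protein are dropped;
    phenotype nodes are always retained (isolated ones included).
    """
    expressed = set(expressed)
    pheno_nodes = set()
    for u, v, *w in pheno:
        pheno_nodes.update((u, v))
    ppi_f = [e for e in ppi if e[0] in expressed and e[1] in expressed]
    bridges_f = []
    for e in bridges:
        u, v = e[0], e[1]
        protein = u if v in pheno_nodes else v
        if protein in expressed:
            bridges_f.append(e)
    return HetNet.from_edges(ppi_f, pheno, bridges_f, phenotypes=pheno_nodes)


def score_nodes(de_table, cap: float = 10.0) -> dict[str, float]:
    """Differential score per gene: -log10(padj) * |log2FC|, capped.

    ``de_table`` is the DataFrame of a DEResult (columns ``padj`` and
    ``log2FoldChange``). Genes with missing values score 0.
    """
    scores = {}
    padj = de_table["padj"]
    lfc = de_table["log2FoldChange"]
    for g in de_table.index:
        p, l = padj.loc[g], lfc.loc[g]
        if not (np.isfinite(p) and np.isfinite(l)) or p <= 0:
            score = cap if (np.isfinite(l) and p == 0) else 0.0
        else:
            score = min(-np.log10(p) * abs(l), cap)
        scores[g] = float(max(score, 0.0))
    return scores


def rwr(net: HetNet, seeds, restart: float = 0.7, tol: float = 1e-10,
        max_iter: int = 10000) -> dict[str, float]:
    """Random walk with restart on the weighted heterogeneous network.

    The walker follows the column-normalised weighted adjacency and restarts
    with probability ``restart`` to the uniform distribution over the seed
    nodes. Returns the steady-state visitation probability of every node
    (sums to 1). Convergence: successive iterates differ by < ``tol`` in L1.
    """
    if not 0 < restart <= 1:
        raise ValueError("restart must lie in (0, 1]")
    seeds = sorted(set(seeds))
    if not seeds:
        raise ValueError("seed set is empty")
    nodes = sorted(net.graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    for s in seeds:
        if s not in index:
            raise KeyError(f"seed {s!r} is not a node of the network")
    A = nx.to_scipy_sparse_array(net.graph, nodelist=nodes, weight="weight", format="csc")
    col_sums = np.asarray(A.sum(axis=0)).ravel()
    inv = np.divide(1.0, col_sums, out=np.zeros_like(col_sums), where=col_sums > 0)
    W = A @ sparse.diags(inv)
    e = np.zeros(len(nodes))
    e[[index[s] for s in seeds]] = 1.0 / len(seeds)
    p = e.copy()
    for _ in range(max_iter):
        # dangling nodes teleport back to the seeds to conserve probability
        dangling = p[col_sums == 0].sum()
        new = (1 - restart) * (W @ p + dangling * e) + restart * e
        if np.abs(new - p).sum() < tol:
            p = new
            break
        p = new
    return {n: float(p[index[n]]) for n in nodes}


def _minmax(values: dict[str, float]) -> dict[str, float]:
    if not values:
        return {}
    arr = np.array(list(values.values()), float)
    lo, hi = arr.min(), arr.max()
    if hi <= lo:
        return {k: 0.0 for k in values}
    return {k: (v - lo) / (hi - lo) for k, v in values.items()}


def combined_node_scores(net: HetNet, de_scores: dict[str, float],
                         rwr_scores: dict[str, float]) -> dict[str, float]:
    """Product of min-max scaled DE score and min-max scaled RWR probability
    over the protein nodes: high only for differential genes close to the
    seed phenotypes."""
    proteins = net.proteins
    de_mm = _minmax({g: de_scores.get(g, 0.0) for g in proteins})
    rwr_mm = _minmax({g: rwr_scores.get(g, 0.0) for g in proteins})
    return {g: de_mm[g] * rwr_mm[g] for g in proteins}


def extract_subnetworks(net: HetNet, combined: dict[str, float], max_size: int = 7,
                        max_candidates: int = 50, min_relative_score: float = 0.25,
                        min_seed_score: float = 0.0,
                        exclusive: bool = True) -> list[SubNetwork]:
    """Greedy candidate growth on the PPI layer.

    Proteins are ranked by combined score; from each top-ranked protein not
    yet part of a candidate, the neighbour maximising the mean combined score
    of the grown candidate is added repeatedly. Growth stops at ``max_size``
    or when the best neighbour's own score falls below ``min_relative_score``
    times the current candidate mean (so candidates stay homogeneously hot
    rather than absorbing cold neighbours). Ties break lexicographically.

    With ``exclusive`` (default) a protein belongs to at most one candidate:
    later candidates cannot re-absorb members of earlier, hotter ones, which
    keeps candidates from chaining into one giant component at the merge
    step. Set it False to allow overlapping candidates.
    """
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    ppi = net.ppi_graph()
    if ppi.number_of_nodes() == 0:
        return []
    ranked = sorted(combined, key=lambda g: (-combined[g], g))
    used: set = set()
    out: list[SubNetwork] = []
    for seed_node in ranked:
        if len(out) >= max_candidates:
            break
        if seed_node in used or seed_node not in ppi:
            continue
        if combined.get(seed_node, 0.0) <= min_seed_score:
            break
        members = {seed_node}
        mean = combined.get(seed_node, 0.0)
        while len(members) < max_size:
            frontier = {v for u in members for v in ppi.neighbors(u)} - members
            if exclusive:
                frontier -= used
            frontier = sorted(frontier)
            if not frontier:
                break
            best = max(
                frontier,
                key=lambda v: ((sum(combined.get(x, 0.0) for x in members)
                                + combined.get(v, 0.0)) / (len(members) + 1), v),
            )
            # tie-break deterministically: recompute with lexicographic order
            best_mean = (sum(combined.get(x, 0.0) for x in members)
                         + combined.get(best, 0.0)) / (len(members) + 1)
            cands = [v for v in frontier
                     if abs((sum(combined.get(x, 0.0) for x in members)
                             + combined.get(v, 0.0)) / (len(members) + 1) - best_mean) < 1e-15]
            best = min(cands)
            if combined.get(best, 0.0) < min_relative_score * mean:
                break
            members.add(best)
            mean = sum(combined.get(x, 0.0) for x in members) / len(members)
        out.append(SubNetwork(nodes=frozenset(members), score=float(mean)))
        used |= members
    return out


class PPISampler:
    """Uniform random-walk sampler of size-matched connected PPI sub-graphs."""

    def __init__(self, net: HetNet):
        ppi = net.ppi_graph()
        self.adj = {n: sorted(ppi.neighbors(n)) for n in ppi.nodes}
        comp_sizes = {}
        for comp in nx.connected_components(ppi):
            for n in comp:
                comp_sizes[n] = len(comp)
        self.comp_sizes = comp_sizes
        self.max_component = max(comp_sizes.values(), default=0)
        self._eligible_cache: dict[int, list] = {}

    def eligible_starts(self, size: int) -> list:
        if size not in self._eligible_cache:
            self._eligible_cache[size] = sorted(
                n for n, c in self.comp_sizes.items() if c >= size
            )
        return self._eligible_cache[size]

    def sample(self, size: int, rng) -> set:
        if size > self.max_component:
            raise ValueError("requested sub-network exceeds the largest PPI component")
        starts = self.eligible_starts(size)
        while True:
            start = starts[rng.integers(len(starts))]
            members = {start}
            frontier = list(self.adj[start])
            while len(members) < size and frontier:
                pick = frontier[rng.integers(len(frontier))]
                if pick not in members:
                    members.add(pick)
                    frontier.extend(self.adj[pick])
                frontier = [v for v in frontier if v not in members]
            if len(members) == size:
                return members


def sample_connected_subnetwork(net: HetNet, size: int, rng=None) -> set:
    """One uniform random-walk sample of a connected PPI sub-network.

    Convenience wrapper; batch callers should reuse a :class:`PPISampler`.
    """
    return PPISampler(net).sample(size, as_rng(rng))


def _aggregate(members, combined) -> float:
    return sum(combined.get(g, 0.0) for g in members) / len(members)


def empirical_pvalue(candidate: SubNetwork, net: HetNet, combined: dict[str, float],
                     n_samples: int = 10000, rng=None,
                     sampler: PPISampler | None = None) -> SubNetwork:
    """Empirical p-value of a candidate against resampled sub-networks.

    Samples ``n_samples`` connected PPI sub-networks of the candidate's size
    by random-walk growth, aggregates their scores identically (mean combined
    node score), and reports p = (1 + #{null >= observed}) / (n_samples + 1).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = as_rng(rng)
    sampler = sampler or PPISampler(net)
    observed = _aggregate(candidate.nodes, combined)
    exceed = 0
    for _ in range(n_samples):
        null = _aggregate(sampler.sample(candidate.size, rng), combined)
        if null >= observed:
            exceed += 1
    p = (1 + exceed) / (n_samples + 1)
    return replace(candidate, empirical_p=p)


def filter_and_merge(candidates: list[SubNetwork], alpha: float = 0.05) -> list[SubNetwork]:
    """Drop candidates above the empirical threshold, then merge survivors
    sharing at least one protein (union of nodes; merged p = min of members).
    Result sorted by p, then size, then node list."""
    kept = [c for c in candidates if c.empirical_p is not None and c.empirical_p <= alpha]
    merged = [dict(nodes=set(c.nodes), p=c.empirical_p, score=c.score) for c in kept]
    changed = True
    while changed:
        changed = False
        for i in range(len(merged)):
            for j in range(i + 1, len(merged)):
                if merged[i]["nodes"] & merged[j]["nodes"]:
                    merged[i]["nodes"] |= merged[j]["nodes"]
                    merged[i]["p"] = min(merged[i]["p"], merged[j]["p"])
                    merged[i]["score"] = max(merged[i]["score"], merged[j]["score"])
                    del merged[j]
                    changed = True
                    break
            if changed:
                break
    out = [
        SubNetwork(nodes=frozenset(m["nodes"]), score=m["score"], empirical_p=m["p"])
        for m in merged
    ]
    return sorted(out, key=lambda s: (s.empirical_p, -s.size, s.sorted_nodes()))


def hypergeom_upper_tail(overlap: int, universe_size: int, set_a: int, set_b: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(universe_size, set_a, set_b)."""
    if universe_size <= 0:
        raise ValueError("universe must be non-empty")
    return float(stats.hypergeom.sf(overlap - 1, universe_size, set_a, set_b))


def annotate_top_go(sub: SubNetwork, collection: GeneSetCollection) -> SubNetwork:
    """Attach the minimum-p GO-style term (one-sided hypergeometric over the
    collection's universe); ties resolve to the first term by name."""
    if not collection.sets:
        return sub
    members = set(sub.nodes) & collection.universe
    n_universe = len(collection.universe)
    best_name, best_p = None, None
    for name in sorted(collection.sets):
        term = collection.sets[name]
        p = hypergeom_upper_tail(len(members & term), n_universe, len(term), len(members))
        if best_p is None or p < best_p:
            best_name, best_p = name, p
    return replace(sub, top_go_term=best_name, top_go_p=best_p)
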