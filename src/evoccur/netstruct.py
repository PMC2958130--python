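"""Focus-gene network construction, scoring and structuring metrics.

Selected ("focus") genes are overlaid on an undirected interaction graph
and grouped into networks of at most ``max_size`` genes by a deterministic
greedy seed-and-grow procedure.  Each network is scored as the negative
base-10 logarithm of the hypergeometric upper-tail probability of drawing
at least its number of focus genes in ``|members|`` draws from the
background.  Per-stringency-level structuring metrics (eligible / common /
main-network / specific counts and percentages) and cross-level sharing
matrices drive the threshold optimizer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .occurrence import GeneSelection

logger = logging.getLogger("evoccur.netstruct")

__all__ = [
    "KnowledgeGraph",
    "GeneNetwork",
    "StringencyMetrics",
    "SharingMatrix",
    "MetaNetwork",
    "build_networks",
    "score_network",
    "score_from_p",
    "rank_networks",
    "compute_metrics",
    "structuring_percentages",
    "meta_network",
    "cross_level_sharing",
    "score_genesets",
]

_P_FLOOR = 1e-300


class KnowledgeGraph:
    """Undirected simple gene-interaction graph plus assay background size."""

    def __init__(self, graph: nx.Graph, background_size: int | None = None):
        g = nx.Graph()
        g.add_nodes_from(graph.nodes)
        for a, b, data in graph.edges(data=True):
            if a == b:
                continue
            g.add_edge(a, b, interaction=data.get("interaction", "direct"))
        self.graph = g
        n = g.number_of_nodes()
        self.background_size = int(background_size) if background_size else n
        if self.background_size < n:
            raise ValueError(
                f"background_size {self.background_size} < number of graph nodes {n}"
            )

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph

    def neighbors(self, gene: str) -> set[str]:
        return set(self.graph[gene])


@dataclass
class GeneNetwork:
    network_id: int
    members: frozenset[str]
    focus: frozenset[str]
    score: float = math.nan
    rank: int = 0

    def __post_init__(self):
        if not self.focus <= self.members:
            raise ValueError("focus genes must be a subset of members")


def score_from_p(p: float) -> float:
    """Network score: negative base-10 logarithm of the assembly p-value."""
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p must be in (0,1], got {p}")
    return max(0.0, -math.log10(max(p, _P_FLOOR)))


def score_network(network: GeneNetwork, graph: KnowledgeGraph, n_focus_total: int) -> float:
    """Hypergeometric enrichment score of a network.

    p = P(X >= |focus|) where X counts focus genes in ``|members|`` draws
    without replacement from ``background_size`` genes of which
    ``n_focus_total`` are focus genes.
    """
    k = len(network.focus)
    m = len(network.members)
    if k > m:
        raise ValueError("more focus genes than members")
    if n_focus_total < k:
        raise ValueError("n_focus_total smaller than network focus count")
    p = float(stats.hypergeom.sf(k - 1, graph.background_size, n_focus_total, m))
    p = min(max(p, _P_FLOOR), 1.0)
    return score_from_p(p)


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def _focus_within_two(gene: str, adj: Mapping[str, set[str]], focus: set[str]) -> int:
    reach = set(adj[gene])
    for nb in adj[gene]:
        reach |= adj[nb]
    reach.discard(gene)
    return len(reach & focus)


def build_networks(
    focus_genes: Iterable[str], graph: KnowledgeGraph, max_size: int = 35
) -> list[GeneNetwork]:
    """Greedy seeded construction of focus-gene networks.

    Repeats until every focus gene is covered or unreachable: seed with the
    uncovered focus gene having the most focus genes within graph distance
    2 (tie -> lexicographically smallest id); grow by adding the neighbor
    (focus or linker) that connects the most not-yet-covered focus genes
    (ties -> edges into current members, then id), stopping at ``max_size``
    or when no candidate brings an uncovered focus gene within distance 2.
    A seed with interaction partners but no focus gain forms a 2-node
    network with its best-connected partner.  After focus-driven growth
    stops, remaining capacity is padded with triangulating neighbors
    (>= 2 edges into the current members; non-focus "knowledge" genes
    first, best-connected first), which normalizes member counts across
    well-connected networks while leaving sparse 2-node networks
    untouched.  Networks from different seeds may
    overlap.  Focus genes absent from the graph or without edges are
    unreachable and appear in no network.
    """
    focus = {g for g in focus_genes}
    if not focus:
        raise ValueError("empty focus gene set")
    if max_size < 2:
        raise ValueError("max_size must be >= 2")
    g = graph.graph
    focus_in = {f for f in focus if f in g and g.degree(f) > 0}
    adj: dict[str, set[str]] = {n: set(g[n]) for n in g}

    reach2 = {f: _focus_within_two(f, adj, focus_in) for f in focus_in}
    uncovered = set(focus_in)
    raw: list[tuple[frozenset[str], frozenset[str]]] = []
    while uncovered:
        seed = min(uncovered, key=lambda f: (-reach2[f], f))
        members: set[str] = {seed}
        while len(members) < max_size:
            candidates: set[str] = set()
            for m in members:
                candidates |= adj[m]
            candidates -= members
            if not candidates:
                break
            best, best_key = None, None
            for c in candidates:
                gain = len((({c} | adj[c]) & uncovered) - members)
                key = (-gain, -len(adj[c] & members), c)
                if best_key is None or key < best_key:
                    best, best_key = c, key
            if best is None or -best_key[0] == 0:
                break
            members.add(best)
        if len(members) == 1 and adj[seed]:
            partner = min(adj[seed], key=lambda c: (-len(adj[c]), c))
            members.add(partner)
        while len(members) < max_size:
            candidates = set()
            for m in members:
                candidates |= adj[m]
            candidates -= members
            pad = [(c in focus_in, len(adj[c] & members), c) for c in candidates]
            pad = [(f, d, c) for f, d, c in pad if d >= 2]
            if not pad:
                break
            members.add(min(pad, key=lambda t: (t[0], -t[1], t[2]))[2])
        net_focus = frozenset(members & focus_in)
        raw.append((frozenset(members), net_focus))
        uncovered -= net_focus
        uncovered.discard(seed)

    networks = [
        GeneNetwork(network_id=i + 1, members=mem, focus=foc)
        for i, (mem, foc) in enumerate(raw)
    ]
    logger.info(
        "build_networks focus_in=%d/%d networks=%d",
        len(focus_in), len(focus), len(networks),
    )
    return networks


def rank_networks(
    networks: list[GeneNetwork], graph: KnowledgeGraph, n_focus_total: int
) -> list[GeneNetwork]:
    """Score all networks and order by (score desc, focus count desc, id).

    Ties beyond focus count break on the lexicographically smallest member,
    making the ordering total and deterministic.
    """
    for net in networks:
        net.score = score_network(net, graph, n_focus_total)
    ordered = sorted(
        networks, key=lambda n: (-n.score, -len(n.focus), min(n.members))
    )
    for rank, net in enumerate(ordered, start=1):
        net.rank = rank
        net.network_id = rank
    return ordered


# ---------------------------------------------------------------------------
# structuring metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StringencyMetrics:
    level: str
    genes_output: int
    eligible: int
    common: int
    common_pct: float
    main_size: int
    specific: int
    specific_pct: float
    best_score: float


def structuring_percentages(
    eligible: int, common: int, main_size: int, common_in_main: int | None = None
) -> tuple[float, int, float]:
    """(common %, specific count, specific %) from raw structuring counts.

    ``specific`` is the main network size minus the common genes found in
    the main network (all common genes when ``common_in_main`` is None,
    i.e. when the main network contains every common gene).
    """
    if eligible <= 0:
        raise ValueError("eligible must be positive")
    cim = common if common_in_main is None else common_in_main
    specific = main_size - cim
    return (
        round(100.0 * common / eligible, 2),
        specific,
        round(100.0 * specific / eligible, 2),
    )


def compute_metrics(
    networks: Sequence[GeneNetwork], genes_output: int, level: str = ""
) -> StringencyMetrics:
    """Table-style structuring metrics for one stringency level.

    eligible = focus genes placed in >= 1 network; common = focus genes in
    >= 2 networks; main network = rank-1 network; specific = main-network
    members minus common genes present in the main network.  Percentages
    are relative to the eligible count.
    """
    if not networks:
        raise ValueError("no networks")
    eligible_set: set[str] = set()
    counts: dict[str, int] = {}
    for net in networks:
        eligible_set |= net.focus
        for gene in net.members:
            counts[gene] = counts.get(gene, 0) + 1
    common_set = {g for g in eligible_set if counts.get(g, 0) >= 2}
    main = min(networks, key=lambda n: (-n.score, -len(n.focus), min(n.members)))
    common_in_main = len(common_set & main.members)
    common_pct, specific, specific_pct = structuring_percentages(
        len(eligible_set), len(common_set), len(main.members), common_in_main
    )
    return StringencyMetrics(
        level=level,
        genes_output=genes_output,
        eligible=len(eligible_set),
        common=len(common_set),
        common_pct=common_pct,
        main_size=len(main.members),
        specific=specific,
        specific_pct=specific_pct,
        best_score=main.score,
    )


# ---------------------------------------------------------------------------
# meta network & cross-level sharing
# ---------------------------------------------------------------------------

@dataclass
class MetaNetwork:
    graph: nx.Graph                  # nodes = network ids, edge weight = shared genes
    major_ids: list[int]
    components: list[set[int]]


def meta_network(networks: Sequence[GeneNetwork], major_min_focus: int = 15) -> MetaNetwork:
    """Network-of-networks linked by shared genes."""
    if not networks:
        raise ValueError("no networks")
    g = nx.Graph()
    for net in networks:
        g.add_node(net.network_id)
    nets = list(networks)
    for i, a in enumerate(nets):
        for b in nets[i + 1:]:
            shared = len(a.members & b.members)
            if shared >= 1:
                g.add_edge(a.network_id, b.network_id, weight=shared)
    majors = [n.network_id for n in nets if len(n.focus) >= major_min_focus]
    comps = [set(c) for c in nx.connected_components(g)]
    return MetaNetwork(graph=g, major_ids=majors, components=comps)


@dataclass
class SharingMatrix:
    """Percent of each strict-level network's focus genes found in each
    loose-level network (rows: strict, columns: loose)."""

    row_ids: list[int]
    col_ids: list[int]
    values: np.ndarray  # percentages, one decimal

    def row(self, i: int = 0) -> np.ndarray:
        return self.values[i]


def cross_level_sharing(
    best_networks_strict: Sequence[GeneNetwork],
    networks_loose: Sequence[GeneNetwork],
    top_k: int = 5,
) -> SharingMatrix:
    if not best_networks_strict or not networks_loose:
        raise ValueError("both network lists must be non-empty")
    rows = list(best_networks_strict)[:top_k]
    cols = list(networks_loose)
    values = np.zeros((len(rows), len(cols)))
    for i, r in enumerate(rows):
        nf = len(r.focus)
        for j, c in enumerate(cols):
            if nf == 0:
                values[i, j] = 0.0
            else:
                values[i, j] = round(100.0 * len(r.focus & c.members) / nf, 1)
    return SharingMatrix(
        row_ids=[r.network_id for r in rows],
        col_ids=[c.network_id for c in cols],
        values=values,
    )


# ---------------------------------------------------------------------------
# gene-set scoring
# ---------------------------------------------------------------------------

def score_genesets(
    selection: GeneSelection,
    genesets: Mapping[str, frozenset[str]],
    background_size: int,
) -> list[dict]:
    """One-sided Fisher exact enrichment of the selection in each gene set.

    Returns per-set dicts: name, set size, focus-gene hits, p, score
    (-log10 p), sorted by descending score then name.
    """
    if not genesets:
        raise ValueError("no gene sets")
    sel = set(selection.gene_ids)
    union = set().union(*genesets.values()) | sel
    if background_size < len(union):
        raise ValueError("background_size smaller than the union of gene sets")
    out = []
    for name in sorted(genesets):
        members = set(genesets[name])
        a = len(sel & members)
        b = len(members) - a
        c = len(sel) - a
        d = background_size - a - b - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        out.append(
            {
                "name": name,
                "n_set": len(members),
                "n_hit": a,
                "p": float(p),
                "score": score_from_p(float(p)),
            }
        )
    out.sort(key=lambda r: (-r["score"], r["name"]))
    return out
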