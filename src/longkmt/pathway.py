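"""Pathway networks, SNP-to-gene annotation, and synthetic topologies.

A pathway is modelled as an undirected simple graph on its member genes.
The adjacency matrix ``N`` carries a unit diagonal (every gene "interacts
with itself") and is the topology term of the network kernel
``K = G A N A^T G^T``.  Interaction types (activation, inhibition, ...) are
collapsed to plain undirected edges; chemical-compound nodes (CHEBI ids)
are dropped before graph construction since no SNP can be assigned to them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayNetwork",
    "AnnotationMap",
    "GeneCoordinates",
    "parse_network",
    "density",
    "map_snps_to_genes",
    "synthesize_topology",
]


@dataclass(frozen=True)
class GeneCoordinates:
    """1-based, inclusive genomic span of a gene."""

    gene_id: str
    chromosome: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.start <= 0:
            raise ValueError(f"{self.gene_id}: coordinates must be positive")


@dataclass
class PathwayNetwork:
    """Gene set plus undirected interaction structure.

    ``adjacency`` is the 0/1 symmetric matrix over ``gene_ids`` with an
    all-ones diagonal; ``edges`` stores each undirected pair once.
    """

    gene_ids: list[str]
    edges: set[frozenset]
    name: str = "pathway"

    def __post_init__(self):
        self.gene_ids = list(self.gene_ids)
        if not self.gene_ids:
            raise ValueError("empty gene set")
        members = set(self.gene_ids)
        for e in self.edges:
            if len(e) != 2 or not e <= members:
                raise ValueError(f"invalid edge {set(e)}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def adjacency(self) -> np.ndarray:
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        N = np.eye(self.n_genes)
        for e in self.edges:
            a, b = tuple(e)
            N[idx[a], idx[b]] = N[idx[b], idx[a]] = 1.0
        return N

    @property
    def density(self) -> float:
        return density(self)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.gene_ids)
        g.add_edges_from(tuple(e) for e in self.edges)
        return g

    def degrees(self) -> np.ndarray:
        g = self.to_graph()
        return np.array([g.degree(v) for v in self.gene_ids])


@dataclass
class AnnotationMap:
    """SNP-by-gene incidence and size-adjusted weights.

    ``incidence[r, g] = 1`` iff SNP ``r`` maps to gene ``g``; the weight
    matrix divides each gene column by ``sqrt(c_g)`` where ``c_g`` is the
    number of SNPs mapped to the gene, removing the advantage large genes
    would otherwise have in the network kernel.
    """

    snp_ids: list[str]
    gene_ids: list[str]
    incidence: np.ndarray

    def __post_init__(self):
        self.incidence = np.asarray(self.incidence, dtype=float)
        if self.incidence.shape != (len(self.snp_ids), len(self.gene_ids)):
            raise ValueError("incidence shape mismatch")
        if not np.isin(self.incidence, (0.0, 1.0)).all():
            raise ValueError("incidence entries must be 0/1")

    @property
    def weights(self) -> np.ndarray:
        counts = self.incidence.sum(axis=0)
        scale = np.divide(
            1.0, np.sqrt(counts), out=np.zeros_like(counts), where=counts > 0
        )
        return self.incidence * scale

    @property
    def mapped_snps(self) -> np.ndarray:
        """Boolean mask of SNPs assigned to at least one gene."""
        return self.incidence.sum(axis=1) > 0

    @classmethod
    def from_gene_assignment(cls, snp_ids, gene_index, gene_ids):
        """Build from a per-SNP gene index (one gene per SNP)."""
        inc = np.zeros((len(snp_ids), len(gene_ids)))
        inc[np.arange(len(snp_ids)), np.asarray(gene_index, int)] = 1.0
        return cls(list(snp_ids), list(gene_ids), inc)


_CHEBI_PREFIX = "CHEBI"


def parse_network(edge_records, gene_set, name: str = "pathway") -> PathwayNetwork:
    """Build a pathway graph from (geneA, geneB[, type]) records.

    Duplicate and reversed edges collapse to one undirected edge; interaction
    types are ignored (logged); self-edges and edges touching genes outside
    the set are dropped with a warning.  CHEBI nodes are removed from the
    gene set before construction.
    """
    genes = [g for g in gene_set if not str(g).upper().startswith(_CHEBI_PREFIX)]
    n_chebi = len(list(gene_set)) - len(genes)
    if n_chebi:
        logger.info("dropped %d CHEBI node(s) from %s", n_chebi, name)
    if not genes:
        raise ValueError("empty gene set")
    members = set(genes)
    edges: set[frozenset] = set()
    types_seen = set()
    for rec in edge_records:
        a, b = rec[0], rec[1]
        if len(rec) > 2:
            types_seen.add(rec[2])
        if a == b:
            warnings.warn(f"ignoring self-edge on {a}", stacklevel=2)
            continue
        if a not in members or b not in members:
            warnings.warn(
                f"dropping edge ({a}, {b}): gene outside the pathway set",
                stacklevel=2,
            )
            continue
        edges.add(frozenset((a, b)))
    if types_seen:
        logger.info(
            "collapsed interaction types %s to undirected edges", sorted(types_seen)
        )
    return PathwayNetwork(genes, edges, name=name)


def density(network: PathwayNetwork) -> float:
    """Edge density |E| / (P(P-1)/2); self-loops excluded by construction."""
    P = network.n_genes
    if P < 2:
        warnings.warn("density of a single-gene pathway is defined as 0")
        return 0.0
    return len(network.edges) / (P * (P - 1) / 2)


def map_snps_to_genes(
    snp_ids,
    snp_chromosomes,
    snp_positions,
    gene_coordinates: list[GeneCoordinates],
    window_bp: int = 500_000,
) -> AnnotationMap:
    """Positional SNP-to-gene assignment with a +- window (inclusive ends).

    A SNP maps to every gene whose window it falls into (overlapping windows
    give multi-gene SNPs).  SNPs mapping to no gene are retained in the map
    with an all-zero row and logged; kernel constructors exclude them.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    snp_ids = list(snp_ids)
    chrom = np.asarray(snp_chromosomes, dtype=object)
    pos = np.asarray(snp_positions, dtype=np.int64)
    gene_ids = [g.gene_id for g in gene_coordinates]
    inc = np.zeros((len(snp_ids), len(gene_ids)))
    for j, g in enumerate(gene_coordinates):
        lo, hi = g.start - window_bp, g.end + window_bp
        inc[:, j] = (chrom == g.chromosome) & (pos >= lo) & (pos <= hi)
    n_unmapped = int((inc.sum(axis=1) == 0).sum())
    if n_unmapped:
        logger.info("%d SNP(s) mapped to no gene; excluded from kernels", n_unmapped)
    return AnnotationMap(snp_ids, gene_ids, inc)


def synthesize_topology(
    base_network: PathwayNetwork,
    target_density: float,
    causal_genes,
    seed: int,
    max_tries: int = 20_000,
) -> PathwayNetwork:
    """Rewire a pathway to a target density, keeping it connected and the
    causal genes central (degree >= median degree).

    Edges are added or removed uniformly at random; a removal is rejected if
    it disconnects the graph or drops a causal gene below the median degree.
    The result's density is within one edge of the target.
    """
    if not 0 < target_density <= 1:
        raise ValueError("target_density must be in (0, 1]")
    causal = set(causal_genes)
    if not causal <= set(base_network.gene_ids):
        raise ValueError("causal_genes must be a subset of the pathway genes")
    P = base_network.n_genes
    max_edges = P * (P - 1) // 2
    target_edges = int(round(target_density * max_edges))
    target_edges = max(target_edges, P - 1)  # connectivity floor
    rng = np.random.default_rng(seed)
    g = base_network.to_graph()
    nodes = list(base_network.gene_ids)

    def _is_bridge(graph, edge):
        graph.remove_edge(*edge)
        ok = nx.is_connected(graph)
        graph.add_edge(*edge)
        return not ok

    def _median_degree():
        return float(np.median([g.degree(v) for v in nodes]))

    tries = 0
    while g.number_of_edges() != target_edges:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                "target density unreachable: connectivity / causal-gene "
                "centrality constraints rejected too many moves at "
                f"{g.number_of_edges()} edges (target {target_edges})"
            )
        if g.number_of_edges() < target_edges:
            a, b = rng.choice(len(nodes), size=2, replace=False)
            a, b = nodes[a], nodes[b]
            if not g.has_edge(a, b):
                g.add_edge(a, b)
        else:
            edges = list(g.edges())
            a, b = edges[rng.integers(len(edges))]
            # prefer trimming away from the causal genes; connectivity is the
            # only hard constraint here, centrality is restored afterwards
            if {a, b} & causal and rng.random() < 0.8:
                continue
            g.remove_edge(a, b)
            if not nx.is_connected(g):
                g.add_edge(a, b)

    # centrality repair: swap edges toward causal genes until each causal
    # gene sits at or above the median degree (edge count preserved)
    for _ in range(max_tries):
        med = _median_degree()
        low = [v for v in causal if g.degree(v) < med]
        if not low:
            break
        v = low[0]
        candidates = [u for u in nodes if u != v and not g.has_edge(v, u)]
        removable = [
            e
            for e in g.edges()
            if v not in e and not set(e) & causal and not _is_bridge(g, e)
        ]
        if not candidates or not removable:
            raise RuntimeError(
                "cannot raise causal gene degree to the median: graph too "
                "sparse for the centrality constraint at this density"
            )
        u = candidates[rng.integers(len(candidates))]
        a, b = removable[rng.integers(len(removable))]
        g.remove_edge(a, b)
        g.add_edge(v, u)
    else:
        raise RuntimeError("centrality repair did not converge")

    out = PathwayNetwork(
        nodes,
        {frozenset(e) for e in g.edges()},
        name=f"{base_network.name}_d{target_density:g}",
    )
    return out
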