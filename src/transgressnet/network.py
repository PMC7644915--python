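"""Signed, thresholded Pearson co-expression networks and their
cohesion/fragmentation metrics.

For a gene module and one genotype, each gene's profile is its temporal
log2-FC vector (by default prefixed with the control point, which is 0
by definition, lengthening 4-point profiles to 5). Edges connect gene
pairs whose Pearson correlation r reaches the positive threshold or
falls below the negative one — both inclusive ("at least"). A cohesive
module yields one large positively-connected component; a rewired or
disorganized one decomposes into sign-discordant sub-clusters and
isolated "straggler" nodes, which the fragmentation report quantifies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .types import FoldChangeTensor, UsageError

logger = logging.getLogger(__name__)

__all__ = [
    "Edge",
    "CoexpressionNetwork",
    "FragmentationReport",
    "temporal_profiles",
    "pcc",
    "build_network",
    "fragmentation_metrics",
    "compare_networks",
]


@dataclass(frozen=True)
class Edge:
    gene_a: str
    gene_b: str
    r: float
    sign: str  # "positive" | "negative"


@dataclass
class CoexpressionNetwork:
    genotype: str
    nodes: list[str]
    edges: set[Edge] = field(default_factory=set)
    pos_threshold: float = 0.95
    neg_threshold: float = -0.95

    def __post_init__(self) -> None:
        for e in self.edges:
            if e.gene_a >= e.gene_b:
                raise UsageError(f"edge endpoints must be ordered: {e}")
            if not (e.r >= self.pos_threshold or e.r <= self.neg_threshold):
                raise UsageError(f"edge below threshold: {e}")
            if e.sign != ("positive" if e.r > 0 else "negative"):
                raise UsageError(f"edge sign inconsistent with r: {e}")

    def graph(self, positive_only: bool = False) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            if positive_only and e.sign != "positive":
                continue
            g.add_edge(e.gene_a, e.gene_b, r=e.r, sign=e.sign)
        return g


def temporal_profiles(
    tensor: FoldChangeTensor,
    genes: Sequence[str],
    genotype: str,
    include_control_zero: bool = True,
) -> pd.DataFrame:
    """Gene x time-point profile table for one genotype, optionally
    prefixed with the (definitionally zero) control point."""
    missing = [g for g in genes if g not in tensor.fc.index]
    if missing:
        raise UsageError(f"genes absent from tensor: {missing[:10]}")
    block = tensor.genotype_block(genotype).loc[list(genes)]
    if include_control_zero:
        block = block.copy()
        block.insert(0, 0, 0.0)
    return block


def pcc(x: Iterable[float], y: Iterable[float]) -> float:
    """Pearson product-moment correlation of two equal-length profiles.

    Returns NaN (flagged missing, no edge) when either profile has zero
    variance; requires length >= 3.
    """
    xv = np.asarray(list(x), dtype=float)
    yv = np.asarray(list(y), dtype=float)
    if xv.shape != yv.shape:
        raise UsageError("profiles must share length")
    if xv.size < 3:
        raise UsageError("profiles must have length >= 3")
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    sx = float(np.sqrt(np.sum(xc * xc)))
    sy = float(np.sqrt(np.sum(yc * yc)))
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    r = float(np.sum(xc * yc) / (sx * sy))
    return max(-1.0, min(1.0, r))


def build_network(
    profiles: pd.DataFrame,
    pos_threshold: float = 0.95,
    neg_threshold: float = -0.95,
    genotype: str = "",
) -> CoexpressionNetwork:
    """Threshold the all-pairs correlation matrix of a profile table.

    Edge iff r >= pos_threshold or r <= neg_threshold (both inclusive).
    Every module gene appears as a node even if isolated; zero-variance
    profiles yield no edges and are logged once per gene.
    """
    if not (neg_threshold < 0 < pos_threshold):
        raise UsageError("need neg_threshold < 0 < pos_threshold")
    genes = list(profiles.index)
    values = profiles.to_numpy(dtype=float)
    sd = values.std(axis=1)
    degenerate = np.flatnonzero(sd == 0.0)
    for i in degenerate:
        logger.info("zero-variance profile for gene %s; no edges computed", genes[i])
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    corr = np.clip(corr, -1.0, 1.0)
    edges: set[Edge] = set()
    n = len(genes)
    for i in range(n):
        for j in range(i + 1, n):
            r = corr[i, j]
            if not np.isfinite(r):
                continue
            if r >= pos_threshold or r <= neg_threshold:
                a, b = sorted((genes[i], genes[j]))
                edges.add(Edge(a, b, float(r), "positive" if r > 0 else "negative"))
    return CoexpressionNetwork(
        genotype=genotype,
        nodes=genes,
        edges=edges,
        pos_threshold=pos_threshold,
        neg_threshold=neg_threshold,
    )


@dataclass
class FragmentationReport:
    """Quantitative cohesion/fragmentation summary of one network."""

    genotype: str
    n_nodes: int
    n_pos_edges: int
    n_neg_edges: int
    negative_edge_fraction: float
    n_components_all: int
    n_components_positive: int
    largest_positive_component_fraction: float
    n_isolated_nodes: int
    hub_degrees: Mapping[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "genotype": self.genotype,
            "n_nodes": self.n_nodes,
            "n_pos_edges": self.n_pos_edges,
            "n_neg_edges": self.n_neg_edges,
            "negative_edge_fraction": self.negative_edge_fraction,
            "n_components_all": self.n_components_all,
            "n_components_positive": self.n_components_positive,
            "largest_positive_component_fraction": self.largest_positive_component_fraction,
            "n_isolated_nodes": self.n_isolated_nodes,
        }
        for hub, deg in self.hub_degrees.items():
            out[f"hub_degree:{hub}"] = deg
        return out


def fragmentation_metrics(
    network: CoexpressionNetwork, hub_genes: Sequence[str] | None = None
) -> FragmentationReport:
    """Connected components (all edges and positive-only), isolated
    "straggler" nodes, signed edge counts, and degrees of supplied hubs.

    In an edgeless graph each node is its own component, so the largest
    positive component fraction is 1/n — the convention keeps the metric
    monotone with cohesion without a special case.
    """
    g_all = network.graph()
    g_pos = network.graph(positive_only=True)
    n_pos = sum(1 for e in network.edges if e.sign == "positive")
    n_neg = len(network.edges) - n_pos
    total = n_pos + n_neg
    comps_pos = list(nx.connected_components(g_pos))
    largest = max((len(c) for c in comps_pos), default=0)
    n_nodes = len(network.nodes)
    hub_degrees = {}
    for hub in hub_genes or ():
        if hub in g_all:
            hub_degrees[hub] = int(g_all.degree[hub])
        else:
            logger.warning("hub gene %s absent from network; degree 0", hub)
            hub_degrees[hub] = 0
    return FragmentationReport(
        genotype=network.genotype,
        n_nodes=n_nodes,
        n_pos_edges=n_pos,
        n_neg_edges=n_neg,
        negative_edge_fraction=(n_neg / total) if total else 0.0,
        n_components_all=nx.number_connected_components(g_all),
        n_components_positive=len(comps_pos),
        largest_positive_component_fraction=(largest / n_nodes) if n_nodes else 0.0,
        n_isolated_nodes=sum(1 for _, d in g_all.degree if d == 0),
        hub_degrees=hub_degrees,
    )


def compare_networks(reports: Sequence[FragmentationReport]) -> pd.DataFrame:
    """Rank genotypes by cohesion: largest positive component fraction
    descending, ties broken by negative edge fraction ascending. Stable
    with respect to input order."""
    if len(reports) < 2:
        raise UsageError("network comparison needs at least 2 reports")
    genotypes = [r.genotype for r in reports]
    if len(set(genotypes)) != len(genotypes):
        raise UsageError("duplicate genotype in reports")
    table = pd.DataFrame([r.to_dict() for r in reports])
    table = table.sort_values(
        by=["largest_positive_component_fraction", "negative_edge_fraction"],
        ascending=[False, True],
        kind="stable",
    ).reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table
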