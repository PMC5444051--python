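"""Directed causal disease network: construction, scaling, export, evaluation.

Each unordered disease pair with a nonzero alphaDCFC contributes exactly one
directed edge, oriented from the prior (cause) to the posterior (effect)
disease and weighted by the statistic's magnitude.  A node's in-degree is its
number of influencing diseases.  The graph container and GraphML round-trip
are delegated to networkx; Spearman's rank correlation (average ranks on
ties) to scipy.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import networkx as nx
import numpy as np
from scipy import stats

from .corpus import DiseaseVocabulary
from .lexicon import Lexicon
from .scoring import CausalityScore, EvidenceCounts, score_evidence


class NetworkError(ValueError):
    """Raised for malformed network inputs."""


@dataclass(frozen=True)
class CausalEdge:
    prior: str
    posterior: str
    strength: float
    scaled_strength: Optional[float] = None

    def __post_init__(self) -> None:
        if self.strength <= 0:
            raise NetworkError("edge strength must be positive")


class CausalNetwork:
    """A directed disease network backed by a networkx DiGraph."""

    def __init__(self, graph: Optional[nx.DiGraph] = None) -> None:
        self.graph = graph if graph is not None else nx.DiGraph()

    @property
    def edges(self) -> list[CausalEdge]:
        return [CausalEdge(prior=u, posterior=v,
                           strength=d["alpha_dcfc"],
                           scaled_strength=d.get("scaled"))
                for u, v, d in self.graph.edges(data=True)]

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def __len__(self) -> int:
        return self.graph.number_of_edges()


def build_network(scores: Iterable[CausalityScore],
                  vocab: Optional[DiseaseVocabulary] = None) -> CausalNetwork:
    """One directed edge per pair with a nonzero score.

    Pairs scoring exactly zero produce no edge (direction undefined).  Node
    attributes carry the vocabulary category (when known) and ``in_degree``,
    the number of influencing diseases.
    """
    graph = nx.DiGraph()
    seen: set[tuple[str, str]] = set()
    for s in scores:
        key = (s.disease_a, s.disease_b)
        if key in seen:
            raise NetworkError(f"duplicate unordered pair {key}")
        seen.add(key)
        if s.direction is None:
            continue
        prior, posterior = s.direction
        graph.add_edge(prior, posterior, alpha_dcfc=abs(s.score))
    for node in graph.nodes:
        if vocab is not None and node in vocab:
            category = vocab.get(node).category
            if category:
                graph.nodes[node]["category"] = category
    for node, deg in graph.in_degree():
        graph.nodes[node]["in_degree"] = int(deg)
    return CausalNetwork(graph)


def min_max_scale(values: Sequence[float]) -> np.ndarray:
    """Scale values to [0, 1] as (v - min) / (max - min)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise NetworkError("min-max scaling needs at least 2 values")
    lo, hi = arr.min(), arr.max()
    if lo == hi:
        raise NetworkError("min-max scaling undefined for all-equal values")
    return (arr - lo) / (hi - lo)


def attach_scaled_strengths(net: CausalNetwork) -> None:
    """Store min-max scaled alphaDCFC on every edge (scope: this network)."""
    edges = list(net.graph.edges)
    values = min_max_scale([net.graph.edges[e]["alpha_dcfc"] for e in edges])
    for e, v in zip(edges, values):
        net.graph.edges[e]["scaled"] = float(v)


def rank_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman's rho with average ranks on ties."""
    if len(x) != len(y):
        raise NetworkError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 2:
        raise NetworkError("rank correlation needs at least 2 observations")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def compare_with_document_frequency(
    evidence: Iterable[EvidenceCounts],
    lexicon: Lexicon,
) -> dict:
    """Rank-correlate alphaDCFC magnitudes with per-pair document frequency.

    Document frequency for an unordered pair is the total df over all terms
    and both orientations; a high correlation means the statistic ranks pairs
    consistently with how broadly the literature reports them.  Both columns
    are also min-max scaled over the compared pairs for side-by-side display.
    """
    rows = list(evidence)
    scores = score_evidence(rows, lexicon)
    df_total: dict[tuple[str, str], int] = {}
    for r in rows:
        key = tuple(sorted((r.prior, r.posterior)))
        df_total[key] = df_total.get(key, 0) + r.df
    pairs = [(s.disease_a, s.disease_b) for s in scores]
    strength = [abs(s.score) for s in scores]
    freq = [float(df_total[p]) for p in pairs]
    result = {
        "pairs": pairs,
        "alpha_dcfc": strength,
        "document_frequency": freq,
        "spearman_rho": rank_correlation(strength, freq),
    }
    if len(set(strength)) > 1 and len(set(freq)) > 1:
        result["alpha_dcfc_scaled"] = [float(v)
                                       for v in min_max_scale(strength)]
        result["document_frequency_scaled"] = [float(v)
                                               for v in min_max_scale(freq)]
    return result


def export_network(net: CausalNetwork, path: Union[str, Path],
                   format: str = "graphml") -> None:
    """Write the network as GraphML or an edge-list TSV."""
    if format == "graphml":
        nx.write_graphml(net.graph, path)
    elif format == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("prior\tposterior\talpha_dcfc\tscaled\n")
            for e in net.edges:
                scaled = "" if e.scaled_strength is None \
                    else f"{e.scaled_strength:.6f}"
                fh.write(f"{e.prior}\t{e.posterior}\t{e.strength:.6f}\t"
                         f"{scaled}\n")
    else:
        raise NetworkError(f"unknown export format {format!r}")


def import_network(path: Union[str, Path]) -> CausalNetwork:
    """Read a GraphML file written by :func:`export_network`."""
    graph = nx.read_graphml(path)
    out = nx.DiGraph()
    for u, v, d in graph.edges(data=True):
        out.add_edge(u, v, **{k: float(w) if k in ("alpha_dcfc", "scaled")
                              else w for k, w in d.items()})
    for n, d in graph.nodes(data=True):
        if n not in out:
            out.add_node(n)
        for k, w in d.items():
            out.nodes[n][k] = int(w) if k == "in_degree" else w
    return CausalNetwork(out)
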