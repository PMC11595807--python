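"""Minimal feature-based molecular networking.

Spectral similarity is the modified cosine: fragment peaks may match either
directly or shifted by the precursor m/z difference, peaks are paired
one-to-one so as to maximise the summed product of square-root, L2-normalised
intensities, and an edge is drawn when the score and the number of matched
peaks both clear their thresholds.  The optimal pairing is solved exactly as
a linear assignment problem rather than greedily.

The resulting graph carries features as nodes; annotations can be overlaid
as node attributes, and connected components are labelled so that clustering
behaviour (crambescins grouping by side-chain type rather than by core) can
be read off the component structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment

from .spectra import Ms2Spectrum

__all__ = ["NetworkConfig", "SpectralEdge", "modified_cosine", "build_network", "write_graphml"]


@dataclass(frozen=True)
class NetworkConfig:
    """Networking thresholds (defaults follow standard FBMN practice)."""

    precursor_tol: float = 0.02  # Da
    fragment_tol: float = 0.02  # Da
    min_cosine: float = 0.7
    min_matched_peaks: int = 6
    top_k: Optional[int] = None  # optional symmetric edge pruning

    def __post_init__(self):
        if self.precursor_tol <= 0 or self.fragment_tol <= 0:
            raise ValueError("tolerances must be positive")
        if not 0 <= self.min_cosine <= 1:
            raise ValueError("min_cosine must be in [0, 1]")
        if self.min_matched_peaks < 1:
            raise ValueError("min_matched_peaks must be >= 1")


@dataclass(frozen=True)
class SpectralEdge:
    node_a: str
    node_b: str
    cosine: float
    matched_peaks: int


def _normalized_weights(spectrum: Ms2Spectrum) -> np.ndarray:
    w = np.sqrt(np.clip(spectrum.intensity, 0, None))
    norm = np.linalg.norm(w)
    return w / norm if norm > 0 else w


def modified_cosine(
    a: Ms2Spectrum, b: Ms2Spectrum, frag_tol: float = 0.02
) -> tuple[float, int]:
    """Modified cosine similarity and matched-peak count of two MS2 spectra.

    Peaks match directly (|mz_a - mz_b| <= tol) or shifted by the precursor
    m/z difference (|mz_a - mz_b - shift| <= tol, shift = prec_a - prec_b).
    The returned score is the maximum over one-to-one peak assignments of the
    summed products of sqrt/L2-normalised intensities; it is symmetric and
    lies in [0, 1].  An empty spectrum scores (0.0, 0).
    """
    if len(a) == 0 or len(b) == 0:
        return 0.0, 0
    wa, wb = _normalized_weights(a), _normalized_weights(b)
    shift = a.precursor_mz - b.precursor_mz
    d = a.mz[:, None] - b.mz[None, :]
    candidate = (np.abs(d) <= frag_tol) | (np.abs(d - shift) <= frag_tol)
    if not candidate.any():
        return 0.0, 0
    profit = np.where(candidate, wa[:, None] * wb[None, :], 0.0)
    rows, cols = linear_sum_assignment(profit, maximize=True)
    used = candidate[rows, cols]
    score = float(profit[rows, cols][used].sum())
    matched = int(used.sum())
    return min(score, 1.0), matched


def build_network(
    spectra: Sequence[Ms2Spectrum],
    cfg: NetworkConfig = NetworkConfig(),
    node_ids: Optional[Sequence[str]] = None,
    node_attrs: Optional[Mapping[str, Mapping]] = None,
) -> nx.Graph:
    """Build the spectral-similarity graph over all pairs of spectra.

    Nodes are feature/spectrum identifiers (``node_ids`` or spectrum titles,
    falling back to positional names); ``node_attrs`` maps a node id to extra
    attributes to overlay (annotation name, subfamily, side-chain type, ...).
    Edges require score >= min cosine AND matched peaks >= the minimum;
    optional top-K pruning keeps an edge only if each endpoint ranks the
    other within its K best.  Connected components are labelled in the
    ``component`` node attribute.
    """
    if node_ids is None:
        node_ids = [s.title or f"node{i}" for i, s in enumerate(spectra)]
    if len(set(node_ids)) != len(node_ids):
        raise ValueError("node ids must be unique")
    g = nx.Graph()
    for nid, s in zip(node_ids, spectra):
        g.add_node(nid, precursor_mz=float(s.precursor_mz), rt=float(s.rt))
        if node_attrs and nid in node_attrs:
            g.nodes[nid].update(node_attrs[nid])
    edges = []
    for i in range(len(spectra)):
        for j in range(i + 1, len(spectra)):
            score, matched = modified_cosine(spectra[i], spectra[j], cfg.fragment_tol)
            if score >= cfg.min_cosine and matched >= cfg.min_matched_peaks:
                edges.append(
                    SpectralEdge(node_ids[i], node_ids[j], round(score, 6), matched)
                )
    if cfg.top_k is not None:
        edges = _prune_top_k(edges, cfg.top_k)
    for e in edges:
        g.add_edge(e.node_a, e.node_b, cosine=e.cosine, matched_peaks=e.matched_peaks)
    for comp_idx, comp in enumerate(
        sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])
    ):
        for nid in comp:
            g.nodes[nid]["component"] = comp_idx
    return g


def _prune_top_k(edges: list[SpectralEdge], k: int) -> list[SpectralEdge]:
    """Keep an edge only if it is within the top-K of both endpoints."""
    ranked: dict[str, list[SpectralEdge]] = {}
    for e in edges:
        ranked.setdefault(e.node_a, []).append(e)
        ranked.setdefault(e.node_b, []).append(e)
    keep: dict[str, set] = {}
    for node, es in ranked.items():
        es.sort(key=lambda e: (-e.cosine, e.node_a, e.node_b))
        keep[node] = {id(e) for e in es[:k]}
    return [e for e in edges if id(e) in keep[e.node_a] and id(e) in keep[e.node_b]]


def write_graphml(g: nx.Graph, path) -> None:
    """GraphML export; None attribute values are dropped (GraphML has no null)."""
    h = g.copy()
    for _, attrs in h.nodes(data=True):
        for key in [k for k, v in attrs.items() if v is None]:
            del attrs[key]
    nx.write_graphml(h, str(path))
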