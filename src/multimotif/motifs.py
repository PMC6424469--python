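"""Positive-feedback-loop enumeration and motif classification.

A positive feedback loop (PFL) is a simple directed cycle with an even
number of inhibitory regulations; a self-activation is a length-1 PFL.
Motif classes over triples of distinct PFLs:

* Type I  — the three loops share at least one common TF,
* Type II — two loops share no TF but both intersect the third,
* Hybrid  — the topology contains both motif types.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .attractors import AttractorSet, PreconditionError, classify_ordering
from .topology import Topology


@dataclass(frozen=True)
class FeedbackLoop:
    """A simple directed cycle with its signed regulations."""

    cycle: tuple[str, ...]  # node sequence, no repeats
    regulations: tuple[tuple[str, str, int], ...]
    n_negative: int

    @property
    def positive(self) -> bool:
        return self.n_negative % 2 == 0

    @property
    def node_set(self) -> frozenset[str]:
        return frozenset(self.cycle)

    def __len__(self) -> int:
        return len(self.cycle)


@dataclass
class MotifReport:
    pfls: list[FeedbackLoop]
    type_i: bool
    type_ii: bool
    type_i_triples: list[tuple[int, int, int]]
    type_ii_triples: list[tuple[int, int, int]]

    @property
    def hybrid(self) -> bool:
        return self.type_i and self.type_ii

    @property
    def motif_class(self) -> str:
        if self.hybrid:
            return "hybrid"
        if self.type_i:
            return "type_i"
        if self.type_ii:
            return "type_ii"
        return "none"


def enumerate_cycles(topology: Topology) -> list[FeedbackLoop]:
    """All simple directed cycles (any sign), deduplicated up to rotation."""
    g = topology.to_networkx()
    loops: list[FeedbackLoop] = []
    for cycle in nx.simple_cycles(g):
        # canonical rotation: start at lexicographically smallest node
        start = min(range(len(cycle)), key=lambda i: cycle[i])
        cyc = tuple(cycle[start:] + cycle[:start])
        regs = []
        n_neg = 0
        for i, src in enumerate(cyc):
            tgt = cyc[(i + 1) % len(cyc)]
            sign = g.edges[src, tgt]["sign"]
            regs.append((src, tgt, sign))
            if sign < 0:
                n_neg += 1
        loops.append(FeedbackLoop(cycle=cyc, regulations=tuple(regs), n_negative=n_neg))
    loops.sort(key=lambda l: (len(l), l.cycle))
    return loops


def enumerate_pfls(topology: Topology) -> list[FeedbackLoop]:
    """All positive feedback loops (even inhibition count), incl. self-loops."""
    return [l for l in enumerate_cycles(topology) if l.positive]


def _is_type_i(a: FeedbackLoop, b: FeedbackLoop, c: FeedbackLoop) -> bool:
    return bool(a.node_set & b.node_set & c.node_set)


def _is_type_ii(a: FeedbackLoop, b: FeedbackLoop, c: FeedbackLoop) -> bool:
    # some labelling of the triple has two node-disjoint loops bridged by the third
    for x, y, z in ((a, b, c), (a, c, b), (b, c, a)):
        if not (x.node_set & y.node_set):
            if (x.node_set & z.node_set) and (y.node_set & z.node_set):
                return True
    return False


def classify_motifs(topology: Topology) -> MotifReport:
    """Scan all triples of distinct PFLs for Type I / Type II motifs."""
    pfls = enumerate_pfls(topology)
    t1: list[tuple[int, int, int]] = []
    t2: list[tuple[int, int, int]] = []
    for i, j, k in itertools.combinations(range(len(pfls)), 3):
        if _is_type_i(pfls[i], pfls[j], pfls[k]):
            t1.append((i, j, k))
        if _is_type_ii(pfls[i], pfls[j], pfls[k]):
            t2.append((i, j, k))
    return MotifReport(pfls=pfls, type_i=bool(t1), type_ii=bool(t2),
                       type_i_triples=t1, type_ii_triples=t2)


def count_motif_instances(topology: Topology, max_shared_loops: int = 8) -> dict:
    """Exact instance counts for PFLs and motif tuples.

    An instance is an unordered tuple of distinct PFLs satisfying the
    predicate.  ``shared_node_tuples[m]`` generalizes Type I to tuples
    of ``m`` PFLs that all share at least one common TF.
    """
    report = classify_motifs(topology)
    pfls = report.pfls
    shared: dict[int, int] = {}
    for m in range(1, max_shared_loops + 1):
        if m > len(pfls):
            shared[m] = 0
            continue
        count = 0
        for combo in itertools.combinations(pfls, m):
            common = frozenset.intersection(*[l.node_set for l in combo])
            if common:
                count += 1
        shared[m] = count
    return {
        "n_pfls": len(pfls),
        "type_i": len(report.type_i_triples),
        "type_ii": len(report.type_ii_triples),
        "type_i_plus_ii": len(report.type_i_triples) + len(report.type_ii_triples),
        "shared_node_tuples": shared,
    }


# ---------------------------------------------------------------------------
# complexity atlas


def _signed_edge_set(t: Topology) -> frozenset[tuple[str, str, int]]:
    return t.regulations


def build_atlas(topologies: list[Topology],
                metadata: dict[str, dict] | None = None) -> nx.Graph:
    """Complexity atlas: vertices are capable topologies, edges connect
    pairs whose signed regulation sets differ by exactly one regulation.

    A sign flip on an existing pair is distance 2 (remove + add), hence
    not an edge.  Vertex attributes carry the motif class and regulation
    count; extra per-key ``metadata`` (e.g. ``minimal`` flags) is merged.
    """
    node_sets = {tuple(sorted(t.nodes)) for t in topologies}
    if len(node_sets) > 1:
        raise ValueError("atlas requires a common node set")
    g = nx.Graph()
    keyed: list[tuple[str, Topology]] = []
    for t in topologies:
        key = t.canonical_key()
        attrs = {
            "n_regulations": t.n_regulations,
            "motif_class": classify_motifs(t).motif_class,
        }
        if metadata and key in metadata:
            attrs.update(metadata[key])
        g.add_node(key, **attrs)
        keyed.append((key, t))
    for (k1, t1), (k2, t2) in itertools.combinations(keyed, 2):
        if len(_signed_edge_set(t1) ^ _signed_edge_set(t2)) == 1:
            g.add_edge(k1, k2)
    return g


def find_minimum_topologies(capability: "callable", capable: list[Topology]
                            ) -> tuple[list[Topology], list[Topology]]:
    """Split capable topologies into minimal and non-minimal.

    ``capability(topology)`` answers membership (True / False / None
    for unknown).  A topology is minimal iff it is capable and no
    single-regulation-removal child is capable; children of unknown
    status make the parent's minimality ``unknown`` and it is excluded
    from both lists (returned separately would hide the gap — callers
    get it via the second list of undecided topologies).

    Returns ``(minimal, undecided)``.
    """
    minimal: list[Topology] = []
    undecided: list[Topology] = []
    for topo in capable:
        child_states = []
        for edge in topo.sorted_edges():
            child = Topology.from_edges(
                topo.nodes, [e for e in topo.sorted_edges() if e != edge])
            child_states.append(capability(child))
        if any(s is True for s in child_states):
            continue
        if any(s is None for s in child_states):
            undecided.append(topo)
        else:
            minimal.append(topo)
    return minimal, undecided


# ---------------------------------------------------------------------------
# attractor geometry summaries


def zscore_overlay(values: np.ndarray) -> np.ndarray:
    """Normalize each TF's four attractor values to mean 0, unit variance.

    Population variance (divide by 4) is used, matching a unit-variance
    normalization of exactly four data points.  Input shape (4,) or
    (4, n_tf); constant quadruples are rejected.
    """
    arr = np.asarray(values, dtype=float)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[:, None]
    if arr.shape[0] != 4:
        raise PreconditionError("z-score overlay needs exactly 4 values per TF")
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0)  # population (ddof=0)
    if np.any(sd == 0):
        raise ValueError("constant quadruple: z-score normalization undefined")
    out = (arr - mean) / sd
    return out[:, 0] if squeeze else out


def order_states(states: list[np.ndarray]) -> list[np.ndarray]:
    """Arrange four ordered attractors along their monotone axis."""
    if classify_ordering(states) != "ordered":
        raise PreconditionError("states are not an ordered attractor set")
    mat = np.asarray(states)
    # sort along the TF with the largest spread (strictly monotone by construction)
    axis = int(np.argmax(mat.max(axis=0) - mat.min(axis=0)))
    idx = np.argsort(mat[:, axis])
    return [mat[i] for i in idx]


def interattractor_stats(states: list[np.ndarray] | AttractorSet) -> dict[str, float]:
    """Min, max and SD of the three neighbor distances along the ordering."""
    if isinstance(states, AttractorSet):
        states = states.stable_states
    ordered = order_states(states)
    d = [float(np.linalg.norm(b - a)) for a, b in zip(ordered[:-1], ordered[1:])]
    return {"min": min(d), "max": max(d), "sd": float(np.std(d))}
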