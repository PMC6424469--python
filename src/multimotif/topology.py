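"""Signed directed regulatory topologies.

A topology is a set of signed regulations (activations ``+1`` /
inhibitions ``-1``) over a fixed ordered list of transcription-factor
nodes, with at most one regulation per ordered ``(source, target)``
pair.  Self-regulations are allowed.  Topologies are hashable and
serialize to a JSON dialect and a 3-column TSV dialect.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

SIGN_TOKENS = {"+": 1, "-": -1, "−": -1, "1": 1, "-1": -1, "+1": 1}


class TopologyError(ValueError):
    """Raised for malformed topology definitions."""


@dataclass(frozen=True)
class Topology:
    """A signed directed graph over named transcription factors."""

    nodes: tuple[str, ...]
    regulations: frozenset[tuple[str, str, int]] = field(default_factory=frozenset)

    def __post_init__(self):
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise TopologyError("duplicate node names")
        seen: set[tuple[str, str]] = set()
        for src, tgt, sign in self.regulations:
            if src not in node_set or tgt not in node_set:
                raise TopologyError(f"regulation {src}->{tgt} references unknown node")
            if sign not in (1, -1):
                raise TopologyError(f"invalid sign {sign!r} for {src}->{tgt}")
            if (src, tgt) in seen:
                raise TopologyError(f"duplicate regulation on pair ({src}, {tgt})")
            seen.add((src, tgt))

    # -- construction -------------------------------------------------

    @classmethod
    def from_edges(cls, nodes: Iterable[str], edges: Iterable[tuple[str, str, int]]) -> "Topology":
        return cls(tuple(nodes), frozenset((s, t, int(g)) for s, t, g in edges))

    # -- basic queries ------------------------------------------------

    @property
    def n_regulations(self) -> int:
        return len(self.regulations)

    def sign(self, src: str, tgt: str) -> int:
        """Sign of the (src, tgt) regulation, 0 if absent."""
        for s, t, g in self.regulations:
            if s == src and t == tgt:
                return g
        return 0

    def regulators_of(self, tgt: str) -> list[tuple[str, int]]:
        """Sorted (source, sign) pairs regulating ``tgt``."""
        return sorted((s, g) for s, t, g in self.regulations if t == tgt)

    def sorted_edges(self) -> list[tuple[str, str, int]]:
        return sorted(self.regulations)

    # -- canonical form -----------------------------------------------

    def canonical_key(self) -> str:
        """Relabeling-invariant key.

        The key is the lexicographic minimum, over all node
        permutations, of the flattened signed adjacency encoding
        (``0`` absent / ``a`` activation / ``i`` inhibition).  Two
        topologies share a key iff they are identical up to a node
        relabeling; regulation signs are never permuted.
        """
        n = len(self.nodes)
        index = {name: i for i, name in enumerate(self.nodes)}
        adj = [[0] * n for _ in range(n)]
        for s, t, g in self.regulations:
            adj[index[s]][index[t]] = g
        sym = {0: "0", 1: "a", -1: "i"}
        best: str | None = None
        for perm in itertools.permutations(range(n)):
            enc = "".join(sym[adj[perm[i]][perm[j]]] for i in range(n) for j in range(n))
            if best is None or enc < best:
                best = enc
        assert best is not None
        return best

    # -- graph views --------------------------------------------------

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for s, t, sign in self.regulations:
            g.add_edge(s, t, sign=sign)
        return g

    # -- serialization ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "nodes": list(self.nodes),
            "regulations": [
                {"source": s, "target": t, "sign": g} for s, t, g in self.sorted_edges()
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Topology":
        try:
            nodes = tuple(d["nodes"])
            regs = [(r["source"], r["target"], int(r["sign"])) for r in d["regulations"]]
        except (KeyError, TypeError) as exc:
            raise TopologyError(f"malformed topology mapping: {exc}") from exc
        return cls.from_edges(nodes, regs)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "Topology":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))

    def to_tsv(self, path: str | Path | None = None) -> str:
        lines = [f"{s}\t{t}\t{'+' if g > 0 else '-'}" for s, t, g in self.sorted_edges()]
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_tsv(cls, source: str | Path, nodes: Iterable[str] | None = None) -> "Topology":
        """Parse the 3-column TSV dialect (source, target, sign).

        Node order defaults to first appearance; pass ``nodes`` to pin
        isolated nodes or a specific ordering.
        """
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        edges: list[tuple[str, str, int]] = []
        seen_pairs: set[tuple[str, str]] = set()
        order: list[str] = list(nodes) if nodes is not None else []
        for lineno, raw in enumerate(text.splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 3:
                raise TopologyError(f"line {lineno}: expected 3 fields, got {len(fields)}")
            src, tgt, tok = fields
            if tok not in SIGN_TOKENS:
                raise TopologyError(f"line {lineno}: unknown sign token {tok!r}")
            if (src, tgt) in seen_pairs:
                raise TopologyError(f"line {lineno}: duplicate regulation on pair ({src}, {tgt})")
            seen_pairs.add((src, tgt))
            for name in (src, tgt):
                if name not in order:
                    if nodes is not None:
                        raise TopologyError(f"line {lineno}: dangling node reference {name!r}")
                    order.append(name)
            edges.append((src, tgt, SIGN_TOKENS[tok]))
        return cls.from_edges(order, edges)


def parse_topology_file(path: str | Path) -> Topology:
    """Load a topology from a ``.json`` or TSV file, by extension."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return Topology.from_json(path)
    return Topology.from_tsv(path)
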