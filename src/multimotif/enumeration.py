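"""Enumeration and screening of network topology spaces.

The generic search space for ``n`` nodes and up to ``m`` regulations:

* templates — unsigned subsets of the ``n^2`` ordered node pairs,
* signed networks — every assignment of activation/inhibition to a
  template's regulations,
* canonical topologies — one representative per node-relabeling class.

For 3 nodes and up to 6 regulations this yields 465 templates, 12258
signed networks and 2114 canonical topologies.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from joblib import Parallel, delayed

from .attractors import find_attractors
from .model import ParameterSet, build_model, sample_parameter_sets, substream_seed
from .topology import Topology

_GENERIC_NODES = ("A", "B", "C", "D", "E")


@dataclass
class SearchSpace:
    n_nodes: int
    max_regulations: int
    templates: list[tuple[tuple[str, str], ...]]
    signed_networks: list[Topology]
    canonical_topologies: list[Topology]

    @property
    def counts(self) -> tuple[int, int, int]:
        return (len(self.templates), len(self.signed_networks),
                len(self.canonical_topologies))


def enumerate_search_space(n_nodes: int = 3, max_regulations: int = 6,
                           allow_large: bool = False) -> SearchSpace:
    """Deterministically enumerate templates, signed networks and canonical classes."""
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    if not 1 <= max_regulations <= n_nodes**2:
        raise ValueError("need 1 <= max_regulations <= n_nodes**2")
    if n_nodes > 4 and not allow_large:
        raise ValueError("n_nodes > 4 is combinatorially explosive; pass allow_large=True")

    nodes = _GENERIC_NODES[:n_nodes] if n_nodes <= 5 else tuple(
        f"N{i}" for i in range(n_nodes))
    pairs = [(s, t) for s in nodes for t in nodes]

    templates: list[tuple[tuple[str, str], ...]] = []
    signed: list[Topology] = []
    canonical: dict[str, Topology] = {}
    for r in range(1, max_regulations + 1):
        for subset in itertools.combinations(pairs, r):
            templates.append(subset)
            for signs in itertools.product((1, -1), repeat=r):
                topo = Topology.from_edges(
                    nodes, [(s, t, g) for (s, t), g in zip(subset, signs)])
                signed.append(topo)
                key = topo.canonical_key()
                if key not in canonical:
                    canonical[key] = topo
    return SearchSpace(n_nodes=n_nodes, max_regulations=max_regulations,
                       templates=templates, signed_networks=signed,
                       canonical_topologies=list(canonical.values()))


def canonical_form(topology: Topology) -> str:
    """Relabeling-invariant key (delegates to :meth:`Topology.canonical_key`)."""
    return topology.canonical_key()


def enumerate_subnetworks(base: Topology, include_empty: bool = False
                          ) -> tuple[list[Topology], int]:
    """All regulation subsets of ``base`` (nodes retained), plus canonical count.

    Returns ``(subnetworks, n_canonical)``.  Isometric copies are kept
    in the subnetwork list; the canonical count reports the number of
    relabeling classes among them.
    """
    edges = base.sorted_edges()
    if not edges and not include_empty:
        raise ValueError("base topology has no regulations")
    subs: list[Topology] = []
    keys: set[str] = set()
    lo = 0 if include_empty else 1
    for r in range(lo, len(edges) + 1):
        for subset in itertools.combinations(edges, r):
            topo = Topology.from_edges(base.nodes, subset)
            subs.append(topo)
            keys.add(topo.canonical_key())
    return subs, len(keys)


# ---------------------------------------------------------------------------
# capability screening


@dataclass
class CapabilityRecord:
    """Outcome of screening one topology for four-attractor capability."""

    topology_key: str
    n_regulations: int
    samples_drawn: int
    n_ordered_hits: int
    n_unordered_hits: int
    n_excess_stable: int  # parameter sets with >= 5 stable states, logged separately
    seed: int
    exemplar_ordered: ParameterSet | None = None
    exemplar_unordered: ParameterSet | None = None

    @property
    def capable(self) -> bool:
        return self.n_ordered_hits > 0

    def to_json_dict(self) -> dict:
        d = {
            "topology_key": self.topology_key,
            "n_regulations": self.n_regulations,
            "samples_drawn": self.samples_drawn,
            "n_ordered_hits": self.n_ordered_hits,
            "n_unordered_hits": self.n_unordered_hits,
            "n_excess_stable": self.n_excess_stable,
            "seed": self.seed,
        }
        if self.exemplar_ordered is not None:
            d["exemplar_ordered"] = self.exemplar_ordered.to_flat_dict()
        if self.exemplar_unordered is not None:
            d["exemplar_unordered"] = self.exemplar_unordered.to_flat_dict()
        return d

    @classmethod
    def from_json_dict(cls, d: Mapping) -> "CapabilityRecord":
        ex_o = d.get("exemplar_ordered")
        ex_u = d.get("exemplar_unordered")
        return cls(
            topology_key=d["topology_key"], n_regulations=d["n_regulations"],
            samples_drawn=d["samples_drawn"], n_ordered_hits=d["n_ordered_hits"],
            n_unordered_hits=d["n_unordered_hits"],
            n_excess_stable=d.get("n_excess_stable", 0), seed=d["seed"],
            exemplar_ordered=ParameterSet.from_flat_dict(ex_o) if ex_o else None,
            exemplar_unordered=ParameterSet.from_flat_dict(ex_u) if ex_u else None,
        )


def evaluate_parameter_set(topology: Topology, params: ParameterSet,
                           n_init: int = 125, seed: int = 0) -> str:
    """Classify one parameter set: ``ordered`` / ``unordered`` / ``excess`` / ``none``.

    A hit requires exactly four stable steady states, no sustained
    oscillation among the non-converged runs, and (for an ordered hit)
    a monotone arrangement of the four states.
    """
    model = build_model(topology, params)
    aset = find_attractors(model, n_init=n_init, seed=seed)
    if aset.n_oscillatory > 0:
        return "none"
    if aset.n_stable == 4:
        return "ordered" if aset.ordering == "ordered" else "unordered"
    if aset.n_stable >= 5:
        return "excess"
    return "none"


def screen_topology(topology: Topology, ranges: Mapping[str, Sequence[float]],
                    budget: int, seed: int, form: str = "additive",
                    n_init: int = 125) -> CapabilityRecord:
    """Randomly sample ``budget`` parameter sets and count four-attractor hits."""
    if budget < 1:
        raise ValueError("budget must be >= 1")
    key = topology.canonical_key()
    sample_seed = substream_seed(seed, "sampling", key)
    lhs_seed = substream_seed(seed, "lhs", key)
    n_ordered = n_unordered = n_excess = 0
    ex_o: ParameterSet | None = None
    ex_u: ParameterSet | None = None
    for params in sample_parameter_sets(topology, ranges, budget, sample_seed, form=form):
        outcome = evaluate_parameter_set(topology, params, n_init=n_init, seed=lhs_seed)
        if outcome == "ordered":
            n_ordered += 1
            ex_o = ex_o or params
        elif outcome == "unordered":
            n_unordered += 1
            ex_u = ex_u or params
        elif outcome == "excess":
            n_excess += 1
    return CapabilityRecord(topology_key=key, n_regulations=topology.n_regulations,
                            samples_drawn=budget, n_ordered_hits=n_ordered,
                            n_unordered_hits=n_unordered, n_excess_stable=n_excess,
                            seed=seed, exemplar_ordered=ex_o, exemplar_unordered=ex_u)


def run_screen(topologies: Iterable[Topology], ranges: Mapping[str, Sequence[float]],
               budget: int, seed: int, workers: int = 1, form: str = "additive",
               n_init: int = 125, checkpoint: str | Path | None = None,
               ) -> dict[str, CapabilityRecord]:
    """Screen many topologies; deterministic in ``seed`` for any worker count.

    Each topology's random substream is derived from ``seed`` and its
    canonical key, so the result table is independent of scheduling.
    With ``checkpoint`` set, per-topology JSON-lines records are
    appended and finished topologies are skipped on resume.
    """
    topo_list = list(topologies)
    done: dict[str, CapabilityRecord] = {}
    ckpt_path = Path(checkpoint) if checkpoint else None
    if ckpt_path and ckpt_path.exists():
        for line in ckpt_path.read_text().splitlines():
            if not line.strip():
                continue
            try:
                rec = CapabilityRecord.from_json_dict(json.loads(line))
            except (json.JSONDecodeError, KeyError) as exc:
                raise RuntimeError(f"corrupt checkpoint {ckpt_path}: {exc}") from exc
            done[rec.topology_key] = rec

    todo = [t for t in topo_list if t.canonical_key() not in done]
    if workers > 1 and len(todo) > 1:
        records = Parallel(n_jobs=workers)(
            delayed(screen_topology)(t, ranges, budget, seed, form, n_init) for t in todo)
    else:
        records = [screen_topology(t, ranges, budget, seed, form, n_init) for t in todo]
    for rec in records:
        done[rec.topology_key] = rec
        if ckpt_path:
            with ckpt_path.open("a") as fh:
                fh.write(json.dumps(rec.to_json_dict()) + "\n")
    return {t.canonical_key(): done[t.canonical_key()] for t in topo_list}
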