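"""Motif enrichment against randomized network ensembles.

Two null schemes:

* ``permute_regulations`` — each regulation of the base network is
  reassigned to a uniformly random unoccupied ordered node pair,
  preserving the regulation count and the multiset of signs;
* ``random_pairs`` — every ordered node pair (self-pairs included)
  independently receives an activation, an inhibition or nothing with
  probability 1/3 each.

Enrichment p-values are empirical right-tail probabilities: the
fraction of null networks whose motif count is >= the observed count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .motifs import count_motif_instances
from .topology import Topology

MOTIF_CLASSES = ("n_pfls", "type_i", "type_ii", "type_i_plus_ii")


def randomize_permute(base: Topology, rng: np.random.Generator,
                      include_self_pairs: bool = True) -> Topology:
    """Reassign each regulation's (source, target) pair uniformly at random.

    The sign multiset and the number of regulations are preserved;
    occupied pairs are rejected so the result keeps at most one
    regulation per ordered pair.
    """
    nodes = base.nodes
    pairs = [(s, t) for s in nodes for t in nodes
             if include_self_pairs or s != t]
    signs = [g for _s, _t, g in base.sorted_edges()]
    chosen: list[tuple[str, str]] = []
    occupied: set[tuple[str, str]] = set()
    for _ in signs:
        while True:
            pair = pairs[rng.integers(len(pairs))]
            if pair not in occupied:
                occupied.add(pair)
                chosen.append(pair)
                break
    return Topology.from_edges(nodes, [(s, t, g) for (s, t), g in zip(chosen, signs)])


def randomize_pairs(nodes, rng: np.random.Generator,
                    include_self_pairs: bool = True) -> Topology:
    """Assign +, - or none (probability 1/3 each) to every ordered pair."""
    nodes = tuple(nodes)
    if not nodes:
        raise ValueError("node list must be non-empty")
    edges = []
    for s in nodes:
        for t in nodes:
            if not include_self_pairs and s == t:
                continue
            u = rng.integers(3)
            if u == 0:
                edges.append((s, t, 1))
            elif u == 1:
                edges.append((s, t, -1))
    return Topology.from_edges(nodes, edges)


def empirical_pvalue(observed: int, null_counts) -> tuple[float, str]:
    """Right-tail empirical p-value with a "< 1/N" report for zero hits."""
    null_counts = np.asarray(list(null_counts))
    if null_counts.size == 0:
        raise ValueError("null_counts must be non-empty")
    n_ge = int(np.sum(null_counts >= observed))
    p = n_ge / null_counts.size
    label = f"< {1.0 / null_counts.size:g}" if n_ge == 0 else f"{p:g}"
    return p, label


@dataclass
class NullEnsemble:
    scheme: str
    n_networks: int
    seed: int
    counts: pd.DataFrame  # one row per network, columns = MOTIF_CLASSES


def sample_null_ensemble(base: Topology, scheme: str, n_networks: int, seed: int,
                         include_self_pairs: bool = True) -> NullEnsemble:
    rng = np.random.default_rng(int(seed))
    rows = []
    for _ in range(n_networks):
        if scheme == "permute_regulations":
            net = randomize_permute(base, rng, include_self_pairs)
        elif scheme == "random_pairs":
            net = randomize_pairs(base.nodes, rng, include_self_pairs)
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
        counts = count_motif_instances(net)
        rows.append({cls: counts[cls] for cls in MOTIF_CLASSES})
    return NullEnsemble(scheme=scheme, n_networks=n_networks, seed=seed,
                        counts=pd.DataFrame(rows, columns=list(MOTIF_CLASSES)))


def enrichment_report(base: Topology, scheme: str, n_networks: int, seed: int,
                      include_self_pairs: bool = True) -> pd.DataFrame:
    """Observed counts, null summaries and empirical p per motif class."""
    observed = count_motif_instances(base)
    ensemble = sample_null_ensemble(base, scheme, n_networks, seed, include_self_pairs)
    rows = []
    for cls in MOTIF_CLASSES:
        null = ensemble.counts[cls].to_numpy()
        p, label = empirical_pvalue(observed[cls], null)
        rows.append({
            "motif_class": cls,
            "observed": observed[cls],
            "null_mean": float(null.mean()),
            "null_sd": float(null.std(ddof=0)),
            "p_value": p,
            "p_label": label,
            "n_networks": n_networks,
            "scheme": scheme,
            "seed": seed,
        })
    return pd.DataFrame(rows)
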