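"""Tabular and graph writers, range configs, and packaged fixtures."""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from .model import DEFAULT_RANGES, ParameterSet
from .topology import Topology

CAPABILITY_COLUMNS = ["topology_key", "n_regulations", "samples_drawn",
                      "n_ordered_hits", "n_unordered_hits", "n_excess_stable",
                      "seed"]


def load_ranges(path: str | Path | None) -> dict[str, tuple[float, float]]:
    """Parameter-class sampling ranges from YAML/JSON; package defaults if None."""
    if path is None:
        return dict(DEFAULT_RANGES)
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return {str(k): (float(v[0]), float(v[1])) for k, v in data.items()}


def capability_table(records) -> pd.DataFrame:
    rows = [{c: getattr(r, c) for c in CAPABILITY_COLUMNS} for r in records]
    return pd.DataFrame(rows, columns=CAPABILITY_COLUMNS)


def write_results(records, path: str | Path, format: str | None = None) -> Path:
    """Write records (DataFrame / list of dicts / nx.Graph) to disk.

    Formats: csv, tsv, jsonl for tabular data; graphml, dot for graphs.
    Deterministic column order; an empty record list yields a
    header-only file.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if isinstance(records, nx.Graph):
        if fmt == "graphml":
            nx.write_graphml(records, path)
        elif fmt == "dot":
            lines = ["graph atlas {"]
            for node, attrs in records.nodes(data=True):
                attr_txt = ",".join(f'{k}="{v}"' for k, v in sorted(attrs.items()))
                lines.append(f'  "{node}" [{attr_txt}];')
            for a, b in records.edges():
                lines.append(f'  "{a}" -- "{b}";')
            lines.append("}")
            path.write_text("\n".join(lines) + "\n")
        else:
            raise ValueError(f"unsupported graph format {fmt!r}")
        return path
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "tsv":
        df.to_csv(path, index=False, sep="\t")
    elif fmt == "jsonl":
        with path.open("w") as fh:
            for _, row in df.iterrows():
                fh.write(json.dumps(row.to_dict()) + "\n")
    else:
        raise ValueError(f"unsupported format {fmt!r}")
    return path


# ---------------------------------------------------------------------------
# fixtures


def _data_text(name: str) -> str:
    return resources.files("multimotif.data").joinpath(name).read_text()


def fixtures(name: str):
    """Packaged inputs by name.

    ``tcell_full`` — the synthetic 4-TF early T-cell model definition;
    ``minimum_motifs_3node`` — synthetic parameterized minimum-motif
    exemplars (list of {topology, parameters} dicts);
    ``toy_toggle`` / ``toy_typeI`` / ``toy_typeII`` — small constructed
    (topology, parameters) pairs for demonstrations and tests.
    """
    if name == "tcell_full":
        return json.loads(_data_text("tcell_model_synthetic.json"))
    if name == "minimum_motifs_3node":
        return json.loads(_data_text("minimum_motifs_synthetic.json"))["models"]
    if name == "toy_toggle":
        topo = Topology.from_edges(("A", "B"), [("A", "B", -1), ("B", "A", -1)])
        params = ParameterSet(
            k0={"A": 0.1, "B": 0.1}, k={"A": 2.0, "B": 2.0},
            rd={"A": 1.0, "B": 1.0},
            K={("A", "B"): 1.0, ("B", "A"): 1.0},
            n={("A", "B"): 4.0, ("B", "A"): 4.0},
            beta={("A", "B"): 1.0, ("B", "A"): 1.0}, form="additive")
        return topo, params
    if name == "toy_typeI":
        # three positive loops closed at A: self-loop plus two 2-cycles
        return Topology.from_edges(("A", "B", "C"), [
            ("A", "A", 1), ("A", "B", 1), ("B", "A", 1),
            ("A", "C", 1), ("C", "A", 1)])
    if name == "toy_typeII":
        # two disjoint self-loops bridged by a double-negative loop
        return Topology.from_edges(("A", "B"), [
            ("A", "A", 1), ("B", "B", 1), ("A", "B", -1), ("B", "A", -1)])
    raise KeyError(f"unknown fixture {name!r}")
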