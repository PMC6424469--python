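import numpy as np
import pytest

from multimotif.model import ParameterSet, build_model
from multimotif.topology import Topology


@pytest.fixture(scope="session")
def toggle():
    """Symmetric mutual-inhibition toggle in its bistable regime."""
    top = Topology.from_edges(("A", "B"), [("A", "B", -1), ("B", "A", -1)])
    ps = ParameterSet(
        k0={"A": 0.1, "B": 0.1}, k={"A": 2.0, "B": 2.0}, rd={"A": 1.0, "B": 1.0},
        K={("A", "B"): 1.0, ("B", "A"): 1.0}, n={("A", "B"): 4.0, ("B", "A"): 4.0},
        beta={("A", "B"): 1.0, ("B", "A"): 1.0}, form="additive")
    return top, ps, build_model(top, ps)


@pytest.fixture(scope="session")
def toggle_nullcline_roots(toggle):
    """Independent oracle: fixed points of the symmetric toggle by 1D
    root-finding on the composed nullcline map x -> f(f(x))."""
    from scipy.optimize import brentq

    def f(x):  # steady A given B=x (and vice versa, by symmetry)
        return 0.1 + 2.0 / (1.0 + x**4)

    def g(x):
        return f(f(x)) - x

    grid = np.linspace(0.0, 3.0, 3001)
    vals = np.array([g(x) for x in grid])
    roots = []
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            roots.append(grid[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(g, grid[i], grid[i + 1], xtol=1e-12))
    # fixed points of the 2D system are (x, f(x)) for roots of g
    return [(r, f(r)) for r in roots]


def random_topology(rng, n_nodes=3, p_edge=0.4):
    nodes = tuple("ABCDE"[:n_nodes])
    edges = []
    for s in nodes:
        for t in nodes:
            u = rng.random()
            if u < p_edge / 2:
                edges.append((s, t, 1))
            elif u < p_edge:
                edges.append((s, t, -1))
    return Topology.from_edges(nodes, edges)
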