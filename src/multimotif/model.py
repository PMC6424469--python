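"""Hill-function ODE models of transcriptional networks.

Each transcription factor ``X_i`` follows

    dX_i/dt = k0_i + k_i * R_i(X) - rd_i * X_i

where ``R_i`` combines the Hill factors of the regulators of ``X_i``
either additively (weighted by ``beta``) or multiplicatively.  An
activator contributes ``(X/K)^n / (1 + (X/K)^n)`` and an inhibitor
``1 / (1 + (X/K)^n)``.  A node without regulators has ``R_i = 0``.

External signals (e.g. a Notch input) enter as additive production
drives ``k_s * H_act(S; K_s, n_s)`` on their target node, so that the
autonomous network is recovered exactly when the signal is zero.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import qmc

from .topology import Topology

ADDITIVE = "additive"
MULTIPLICATIVE = "multiplicative"


class ConfigurationError(ValueError):
    """Missing or inconsistent model parameters."""


class DomainError(ValueError):
    """Model evaluated at a negative concentration."""


def substream_seed(master_seed: int, *names) -> int:
    """Derive a reproducible child seed (< 2**31) from a master seed.

    All randomness in the package flows from one top-level seed through
    named substreams so that reruns are exact regardless of execution
    order or worker count.
    """
    h = hashlib.sha256(repr((int(master_seed),) + tuple(names)).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# parameter sets


@dataclass(frozen=True)
class ParameterSet:
    """All rate constants for one topology under one equation form.

    ``k0``/``k``/``rd`` are keyed by node name; ``K``/``n`` (and
    ``beta`` for the additive form) by the ``(source, target)`` pair.
    All rates and thresholds are strictly positive except ``k0`` which
    may be zero; Hill exponents satisfy ``n >= 1``.
    """

    k0: Mapping[str, float]
    k: Mapping[str, float]
    rd: Mapping[str, float]
    K: Mapping[tuple[str, str], float]
    n: Mapping[tuple[str, str], float]
    beta: Mapping[tuple[str, str], float] | None = None
    form: str = ADDITIVE

    def validate(self, topology: Topology) -> None:
        if self.form not in (ADDITIVE, MULTIPLICATIVE):
            raise ConfigurationError(f"unknown form {self.form!r}")
        for node in topology.nodes:
            for name, table in (("k0", self.k0), ("k", self.k), ("rd", self.rd)):
                if node not in table:
                    raise ConfigurationError(f"missing {name} for node {node}")
            # k0/k may be zero (k = 0 encodes a production knockout)
            if self.k0[node] < 0 or self.k[node] < 0 or self.rd[node] <= 0:
                raise ConfigurationError(f"negative rate or non-positive rd for node {node}")
        for src, tgt, _sign in topology.regulations:
            pair = (src, tgt)
            if pair not in self.K or pair not in self.n:
                raise ConfigurationError(f"missing K/n for regulation {src}->{tgt}")
            if self.K[pair] <= 0:
                raise ConfigurationError(f"non-positive K for {src}->{tgt}")
            if self.n[pair] < 1:
                raise ConfigurationError(f"Hill exponent < 1 for {src}->{tgt}")
            if self.form == ADDITIVE:
                if self.beta is None or pair not in self.beta:
                    raise ConfigurationError(f"missing beta for {src}->{tgt} (additive form)")
        if self.form == MULTIPLICATIVE and self.beta:
            raise ConfigurationError("beta given but form is multiplicative")

    # -- flat-JSON round trip ----------------------------------------

    def to_flat_dict(self) -> dict[str, float | str]:
        out: dict[str, float | str] = {"form": self.form}
        for name, table in (("k0", self.k0), ("k", self.k), ("rd", self.rd)):
            for node, value in sorted(table.items()):
                out[f"{name}.{node}"] = float(value)
        for name, table in (("K", self.K), ("n", self.n)):
            for (src, tgt), value in sorted(table.items()):
                out[f"{name}.{src}->{tgt}"] = float(value)
        if self.beta is not None:
            for (src, tgt), value in sorted(self.beta.items()):
                out[f"beta.{src}->{tgt}"] = float(value)
        return out

    @classmethod
    def from_flat_dict(cls, d: Mapping[str, float | str]) -> "ParameterSet":
        k0: dict[str, float] = {}
        k: dict[str, float] = {}
        rd: dict[str, float] = {}
        K: dict[tuple[str, str], float] = {}
        n: dict[tuple[str, str], float] = {}
        beta: dict[tuple[str, str], float] = {}
        form = str(d.get("form", ADDITIVE))
        tables = {"k0": k0, "k": k, "rd": rd}
        pair_tables = {"K": K, "n": n, "beta": beta}
        for key, value in d.items():
            if key == "form":
                continue
            name, _, rest = key.partition(".")
            if name in tables:
                tables[name][rest] = float(value)
            elif name in pair_tables:
                src, _, tgt = rest.partition("->")
                pair_tables[name][(src, tgt)] = float(value)
            else:
                raise ConfigurationError(f"unknown parameter key {key!r}")
        return cls(k0=k0, k=k, rd=rd, K=K, n=n, beta=beta or None, form=form)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_flat_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ParameterSet":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_flat_dict(json.loads(text))


@dataclass(frozen=True)
class InputDrive:
    """Additive external production drive on one target node.

    Contributes ``k * (S/K)^n / (1 + (S/K)^n)`` to the target's
    production, where ``S`` is the current signal level.  At ``S = 0``
    the drive vanishes and the autonomous network is recovered.
    """

    signal: str
    target: str
    k: float
    K: float
    n: float


# ---------------------------------------------------------------------------
# Hill factors


def hill_activation(x, K, n):
    u = (np.asarray(x, dtype=float) / K) ** n
    return u / (1.0 + u)


def hill_inhibition(x, K, n):
    u = (np.asarray(x, dtype=float) / K) ** n
    return 1.0 / (1.0 + u)


def _hill_value_and_deriv(x: float, K: float, n: float, sign: int) -> tuple[float, float]:
    u = min((x / K) ** n, 1e100)  # clamp: factor saturates, derivative vanishes
    denom = (1.0 + u) ** 2
    dudx = min(n * (x / K) ** (n - 1.0) / K, 1e100)
    if sign > 0:
        return u / (1.0 + u), dudx / denom
    return 1.0 / (1.0 + u), -dudx / denom


# ---------------------------------------------------------------------------
# compiled model


class HillModel:
    """Rate bundle: RHS and analytic Jacobian for one parameterized topology."""

    def __init__(self, topology: Topology, params: ParameterSet,
                 inputs: Sequence[InputDrive] = ()):
        params.validate(topology)
        self.topology = topology
        self.params = params
        self.nodes = topology.nodes
        self.n_dim = len(self.nodes)
        self._index = {name: i for i, name in enumerate(self.nodes)}
        self.form = params.form

        self._k0 = np.array([params.k0[v] for v in self.nodes])
        self._k = np.array([params.k[v] for v in self.nodes])
        self._rd = np.array([params.rd[v] for v in self.nodes])
        # per target: list of (source index, sign, K, n, beta)
        self._regs: list[list[tuple[int, int, float, float, float]]] = []
        for tgt in self.nodes:
            entries = []
            for src, sign in topology.regulators_of(tgt):
                pair = (src, tgt)
                beta = 1.0 if params.beta is None else params.beta.get(pair, 1.0)
                entries.append((self._index[src], sign, params.K[pair], params.n[pair], beta))
            self._regs.append(entries)

        self.inputs = list(inputs)
        self._input_values: dict[str, float] = {d.signal: 0.0 for d in self.inputs}

    # -- external signals ---------------------------------------------

    def set_input(self, signal: str, value: float) -> None:
        if signal not in self._input_values:
            raise ConfigurationError(f"unknown input signal {signal!r}")
        if value < 0:
            raise DomainError("signal levels must be non-negative")
        self._input_values[signal] = float(value)

    def get_input(self, signal: str) -> float:
        return self._input_values[signal]

    def state_bound(self) -> float:
        """Rigorous upper bound on any steady-state coordinate.

        Every Hill factor is below 1, so production is bounded by
        ``k0 + k * gain`` plus the saturated input drives, where the
        regulated gain is the ``beta`` sum in the additive form and 1 in
        the multiplicative form; no fixed point exceeds that over ``rd``.
        """
        drive = np.zeros(self.n_dim)
        for d in self.inputs:
            drive[self._index[d.target]] += d.k
        gain = np.ones(self.n_dim)
        if self.form == ADDITIVE:
            for i, entries in enumerate(self._regs):
                if entries:
                    gain[i] = max(1.0, sum(beta for *_rest, beta in entries))
        return float(np.max((self._k0 + self._k * gain + drive) / self._rd))

    def input_drive(self) -> np.ndarray:
        """Current additive drive vector from all external inputs."""
        drive = np.zeros(self.n_dim)
        for d in self.inputs:
            s = self._input_values[d.signal]
            drive[self._index[d.target]] += d.k * float(hill_activation(s, d.K, d.n))
        return drive

    # -- dynamics -----------------------------------------------------

    def _check_state(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_dim,):
            raise ValueError(f"state must have shape ({self.n_dim},)")
        if np.any(x < 0):
            raise DomainError("negative concentration")
        return x

    def rhs(self, x: np.ndarray) -> np.ndarray:
        x = self._check_state(x)
        out = self._k0 + self.input_drive() - self._rd * x
        for i, entries in enumerate(self._regs):
            if not entries:
                continue
            if self.form == ADDITIVE:
                acc = 0.0
                for j, sign, K, n, beta in entries:
                    h, _ = _hill_value_and_deriv(x[j], K, n, sign)
                    acc += beta * h
            else:
                acc = 1.0
                for j, sign, K, n, _beta in entries:
                    h, _ = _hill_value_and_deriv(x[j], K, n, sign)
                    acc *= h
            out[i] += self._k[i] * acc
        return out

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        x = self._check_state(x)
        J = np.diag(-self._rd.copy())
        for i, entries in enumerate(self._regs):
            if not entries:
                continue
            if self.form == ADDITIVE:
                for j, sign, K, n, beta in entries:
                    _, dh = _hill_value_and_deriv(x[j], K, n, sign)
                    J[i, j] += self._k[i] * beta * dh
            else:
                values = []
                derivs = []
                for j, sign, K, n, _beta in entries:
                    h, dh = _hill_value_and_deriv(x[j], K, n, sign)
                    values.append(h)
                    derivs.append(dh)
                for idx, (j, *_rest) in enumerate(entries):
                    prod = 1.0
                    for l, h in enumerate(values):
                        if l != idx:
                            prod *= h
                    J[i, j] += self._k[i] * prod * derivs[idx]
        return J

    def rhs_time(self, t: float, x: np.ndarray) -> np.ndarray:  # solve_ivp signature
        return self.rhs(np.maximum(x, 0.0))

    def jac_time(self, t: float, x: np.ndarray) -> np.ndarray:
        return self.jacobian(np.maximum(x, 0.0))


def build_model(topology: Topology, params: ParameterSet,
                inputs: Sequence[InputDrive] = ()) -> HillModel:
    """Compile a topology + parameter set into an ODE rate bundle."""
    return HillModel(topology, params, inputs)


# ---------------------------------------------------------------------------
# sampling


def latin_hypercube_points(count: int, dims: int, lo: float, hi: float,
                           seed: int) -> np.ndarray:
    """Latin-hypercube point set in the open box ``(lo, hi)^dims``.

    Each of the ``count`` equal-width strata per dimension contains
    exactly one point.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    if not lo < hi:
        raise ValueError("need lo < hi")
    sampler = qmc.LatinHypercube(d=dims, seed=int(seed))
    unit = sampler.random(n=count)
    return lo + (hi - lo) * unit


DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "k0": (0.0, 0.3),
    "k": (0.3, 3.0),
    "rd": (0.3, 1.5),
    "K": (0.1, 3.0),
    "n": (1.0, 6.0),
    "beta": (0.5, 2.0),
}


def sample_parameter_sets(topology: Topology, ranges: Mapping[str, Sequence[float]],
                          count: int, seed: int, form: str = ADDITIVE):
    """Yield ``count`` independent uniform parameter draws for ``topology``.

    ``ranges`` maps each parameter class (``k0 k rd K n`` and ``beta``
    for the additive form) to an inclusive ``[lo, hi]`` interval.  The
    stream is deterministic in ``seed`` and ordered: node parameters in
    node order, then regulation parameters in sorted edge order.
    """
    classes = ["k0", "k", "rd", "K", "n"] + (["beta"] if form == ADDITIVE else [])
    for cls_name in classes:
        if cls_name not in ranges:
            raise ConfigurationError(f"missing sampling range for class {cls_name!r}")
    rng = np.random.default_rng(int(seed))
    edges = topology.sorted_edges()

    def draw(cls_name: str) -> float:
        lo, hi = ranges[cls_name]
        return float(rng.uniform(lo, hi))

    for _ in range(count):
        k0 = {v: draw("k0") for v in topology.nodes}
        k = {v: draw("k") for v in topology.nodes}
        rd = {v: draw("rd") for v in topology.nodes}
        K = {(s, t): draw("K") for s, t, _g in edges}
        n = {(s, t): draw("n") for s, t, _g in edges}
        beta = {(s, t): draw("beta") for s, t, _g in edges} if form == ADDITIVE else None
        yield ParameterSet(k0=k0, k=k, rd=rd, K=K, n=n, beta=beta, form=form)
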