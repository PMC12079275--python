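"""Equivalent-circuit impedance elements and composition algebra.

Implements the small-signal impedance of the element zoo used in
electrochemical impedance spectroscopy (EIS) of proteinoid/actin cells
and the three equivalent-circuit topologies the analyses rely on:

* **actin** — (R1∥C1) – (R2∥Q1) – R3: two relaxation arcs (ideal and
  constant-phase) plus a series resistance;
* **proteinoid** — R1 – W1 – O1 – (R2∥C1): series resistance, semi-infinite
  Warburg diffusion, a finite-length (open) diffusion element, and an RC arc;
* **mixture** — (R1∥C1) – W1 – (R2∥Q1): interfacial RC, Warburg diffusion,
  and a constant-phase arc.

Element impedances (ω in rad/s)::

    R    : Z = R
    C    : Z = 1 / (jωC)
    L    : Z = jωL
    CPE  : Z = 1 / (Q (jω)^n),           n ∈ [0, 1]
    W    : Z = W (1 − j) / sqrt(2ω)  ≡  W / sqrt(jω)
    O    : Z = coth(B sqrt(jω)) / (Y0 sqrt(jω))   (open finite-length
           diffusion; a tanh variant — the "short" boundary — is available)

A circuit is a series list of nodes; each node is an element or a
parallel group of nodes. Parallel groups combine by admittance sum.
All complex powers use the principal branch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import ImpedanceSpectrum
from .errors import DomainError, InvalidSpecError

__all__ = [
    "CircuitElement",
    "Parallel",
    "CircuitModel",
    "element_impedance",
    "circuit_impedance",
    "build_named_circuit",
    "ACTIN_FIT_PARAMS",
    "PROTEINOID_FIT_PARAMS",
    "MIXTURE_FIT_PARAMS",
]

# element kind -> required parameter names
_ELEMENT_PARAMS: dict[str, tuple[str, ...]] = {
    "resistor": ("r_ohm",),
    "capacitor": ("c_farad",),
    "inductor": ("l_henry",),
    "cpe": ("q", "n"),
    "warburg": ("w_ohm_s",),  # coefficient in Ω·s^-1/2
    "o_element": ("y0", "b"),  # admittance coefficient S·s^1/2, B in s^1/2
}


@dataclass(frozen=True)
class CircuitElement:
    """One impedance element with named, unit-carrying parameters."""

    kind: str
    params: dict[str, float]
    label: str = ""
    variant: str = "coth"  # o_element branch: "coth" (open) or "tanh" (short)

    def __post_init__(self) -> None:
        if self.kind not in _ELEMENT_PARAMS:
            raise InvalidSpecError(
                f"unknown element kind {self.kind!r}; known: {sorted(_ELEMENT_PARAMS)}"
            )
        required = _ELEMENT_PARAMS[self.kind]
        missing = [p for p in required if p not in self.params]
        if missing:
            raise InvalidSpecError(f"{self.kind} element missing parameters {missing}")
        for name in required:
            value = self.params[name]
            if self.kind == "cpe" and name == "n":
                if not 0.0 <= value <= 1.0:
                    raise InvalidSpecError(f"CPE exponent n must lie in [0, 1], got {value}")
            elif value <= 0:
                raise InvalidSpecError(f"{self.kind} parameter {name} must be positive, got {value}")
        if self.variant not in ("coth", "tanh"):
            raise InvalidSpecError(f"o_element variant must be 'coth' or 'tanh', got {self.variant!r}")


@dataclass(frozen=True)
class Parallel:
    """A parallel group of two or more nodes (elements or nested groups)."""

    children: tuple

    def __post_init__(self) -> None:
        if len(self.children) < 2:
            raise InvalidSpecError("parallel groups need at least 2 children")


@dataclass(frozen=True)
class CircuitModel:
    """A series chain of nodes; each node is an element or a Parallel group."""

    series: tuple
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.series) == 0:
            raise InvalidSpecError("circuit model must contain at least one node")


def element_impedance(element: CircuitElement, omega) -> complex | np.ndarray:
    """Complex impedance of one element at angular frequency ω (rad/s).

    Accepts a scalar or an array of ω; ω must be strictly positive.
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0):
        raise DomainError("omega must be strictly positive")
    p = element.params
    jw = 1j * omega
    if element.kind == "resistor":
        return np.broadcast_to(p["r_ohm"] + 0j, omega.shape).copy() if omega.ndim else complex(p["r_ohm"])
    if element.kind == "capacitor":
        return 1.0 / (jw * p["c_farad"])
    if element.kind == "inductor":
        return jw * p["l_henry"]
    if element.kind == "cpe":
        # principal branch of (jω)^n
        return 1.0 / (p["q"] * jw ** p["n"])
    if element.kind == "warburg":
        # semi-infinite diffusion: W(1-j)/sqrt(2ω) == W / sqrt(jω)
        return p["w_ohm_s"] * (1.0 - 1j) / np.sqrt(2.0 * omega)
    if element.kind == "o_element":
        s = np.sqrt(jw)
        x = p["b"] * s
        ratio = np.tanh(x) if element.variant == "tanh" else 1.0 / np.tanh(x)
        return ratio / (p["y0"] * s)
    raise InvalidSpecError(f"unknown element kind {element.kind!r}")  # pragma: no cover


def _node_impedance(node, omega):
    if isinstance(node, CircuitElement):
        return element_impedance(node, omega)
    if isinstance(node, Parallel):
        admittance = sum(1.0 / _node_impedance(child, omega) for child in node.children)
        return 1.0 / admittance
    raise InvalidSpecError(f"invalid circuit node of type {type(node).__name__}")


def circuit_impedance(model: CircuitModel, frequencies_hz) -> ImpedanceSpectrum:
    """Evaluate the model impedance at the given frequencies (Hz).

    Series nodes sum; parallel groups combine by admittance. The output
    spectrum is aligned with the input frequency order (which must be
    strictly increasing, as required by :class:`ImpedanceSpectrum`).
    """
    frequencies_hz = np.asarray(frequencies_hz, dtype=float)
    omega = 2.0 * np.pi * frequencies_hz
    z = sum(np.asarray(_node_impedance(node, omega), dtype=complex) for node in model.series)
    return ImpedanceSpectrum(frequencies_hz, z)


def evaluate_impedance(model: CircuitModel, frequencies_hz) -> np.ndarray:
    """Model impedance as a bare complex array, for arbitrary frequency order."""
    omega = 2.0 * np.pi * np.asarray(frequencies_hz, dtype=float)
    if np.any(omega <= 0):
        raise DomainError("frequencies must be strictly positive")
    return sum(np.asarray(_node_impedance(node, omega), dtype=complex) for node in model.series)


# Published fit parameters for the three cells (Ω, F, Ω·s^-1/2, CPE in S·s^n).
ACTIN_FIT_PARAMS: dict[str, float] = {
    "r1_ohm": 74.79,
    "c1_farad": 6.983e-5,
    "r2_ohm": 835.1,
    "q1": 1.130e-4,
    "n1": 0.489,
    "r3_ohm": 143.3,
}

# O element reported as magnitude 9741 Ω·s^-1/2 with characteristic
# parameters 0.329 and 1.000; mapped to Y0 = 1/9741 S·s^1/2, B = 0.329 s^1/2.
PROTEINOID_FIT_PARAMS: dict[str, float] = {
    "r1_ohm": 4334.0,
    "w1_ohm_s": 8224.0,
    "o_y0": 1.0 / 9741.0,
    "o_b": 0.329,
    "r2_ohm": 1068.0,
    "c1_farad": 1.000e-12,
}

MIXTURE_FIT_PARAMS: dict[str, float] = {
    "r1_ohm": 3694.0,
    "c1_farad": 1.0e-12,
    "w1_ohm_s": 308.0,
    "r2_ohm": 1.0e4,
    "q1": 25.97e-6,
    "n1": 0.632,
}

_NAMED_REQUIRED = {
    "actin": tuple(ACTIN_FIT_PARAMS),
    "proteinoid": tuple(PROTEINOID_FIT_PARAMS),
    "mixture": tuple(MIXTURE_FIT_PARAMS),
}


def build_named_circuit(name: str, params: dict[str, float] | None = None) -> CircuitModel:
    """Construct one of the three published circuit topologies.

    Parameters default to the published fit values; pass ``params`` to
    override all of them (every required name must be supplied).

    Topologies:
      actin       (R1∥C1) – (R2∥Q1) – R3
      proteinoid  R1 – W1 – O1 – (R2∥C1)
      mixture     (R1∥C1) – W1 – (R2∥Q1)
    """
    if name not in _NAMED_REQUIRED:
        raise InvalidSpecError(f"unknown circuit name {name!r}; known: {sorted(_NAMED_REQUIRED)}")
    defaults = {"actin": ACTIN_FIT_PARAMS, "proteinoid": PROTEINOID_FIT_PARAMS, "mixture": MIXTURE_FIT_PARAMS}[name]
    p = dict(defaults) if params is None else dict(params)
    missing = [k for k in _NAMED_REQUIRED[name] if k not in p]
    if missing:
        raise InvalidSpecError(f"{name} circuit missing parameters {missing}")

    def R(key, label):
        return CircuitElement("resistor", {"r_ohm": p[key]}, label)

    def C(key, label):
        return CircuitElement("capacitor", {"c_farad": p[key]}, label)

    if name == "actin":
        series = (
            Parallel((R("r1_ohm", "R1"), C("c1_farad", "C1"))),
            Parallel((R("r2_ohm", "R2"), CircuitElement("cpe", {"q": p["q1"], "n": p["n1"]}, "Q1"))),
            R("r3_ohm", "R3"),
        )
    elif name == "proteinoid":
        series = (
            R("r1_ohm", "R1"),
            CircuitElement("warburg", {"w_ohm_s": p["w1_ohm_s"]}, "W1"),
            CircuitElement("o_element", {"y0": p["o_y0"], "b": p["o_b"]}, "O1"),
            Parallel((R("r2_ohm", "R2"), C("c1_farad", "C1"))),
        )
    else:  # mixture
        series = (
            Parallel((R("r1_ohm", "R1"), C("c1_farad", "C1"))),
            CircuitElement("warburg", {"w_ohm_s": p["w1_ohm_s"]}, "W1"),
            Parallel((R("r2_ohm", "R2"), CircuitElement("cpe", {"q": p["q1"], "n": p["n1"]}, "Q1"))),
        )
    return CircuitModel(series, name=name)


def circuit_to_dict(model: CircuitModel) -> dict:
    """Serializable description (name, topology, parameters) of a model."""

    def node_to_dict(node):
        if isinstance(node, CircuitElement):
            return {"kind": node.kind, "params": dict(node.params), "label": node.label,
                    "variant": node.variant}
        return {"parallel": [node_to_dict(c) for c in node.children]}

    return {"name": model.name, "series": [node_to_dict(n) for n in model.series]}


def circuit_from_dict(data: dict) -> CircuitModel:
    """Inverse of :func:`circuit_to_dict`."""

    def node_from_dict(d):
        if "parallel" in d:
            return Parallel(tuple(node_from_dict(c) for c in d["parallel"]))
        return CircuitElement(d["kind"], dict(d["params"]), d.get("label", ""),
                              d.get("variant", "coth"))

    return CircuitModel(tuple(node_from_dict(n) for n in data["series"]), name=data.get("name", ""))
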