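"""Serialisable function-valued model parameters.

Motility, fitness and sensitivity coefficients are functions of the
phenotype ``y`` (or of space ``x``).  To keep experiment configurations
reproducible and round-trippable through YAML/JSON, these are restricted to
a small family of named built-ins with numeric coefficients, plus tabulated
values on grid centres; arbitrary code is not accepted in config files.
Plain Python callables remain usable programmatically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Profile", "constant", "linear", "quadratic", "gaussian", "tabulated", "as_profile"]


@dataclass(frozen=True)
class Profile:
    """A named scalar function of one variable.

    kinds:
      - ``constant``: value
      - ``linear``: intercept + slope * v
      - ``quadratic``: c0 + c1 * v + c2 * v**2
      - ``gaussian``: amplitude * exp(-(v - center)**2 / (2 * width**2))
      - ``tabulated``: values on supplied nodes, linearly interpolated
    """

    kind: str
    params: dict

    def __call__(self, v):
        v = np.asarray(v, dtype=float)
        p = self.params
        if self.kind == "constant":
            return np.full_like(v, p["value"], dtype=float) if v.ndim else float(p["value"])
        if self.kind == "linear":
            return p.get("intercept", 0.0) + p["slope"] * v
        if self.kind == "quadratic":
            return p.get("c0", 0.0) + p.get("c1", 0.0) * v + p.get("c2", 0.0) * v**2
        if self.kind == "gaussian":
            return p["amplitude"] * np.exp(-((v - p["center"]) ** 2) / (2.0 * p["width"] ** 2))
        if self.kind == "tabulated":
            return np.interp(v, np.asarray(p["nodes"], float), np.asarray(p["values"], float))
        raise ValueError(f"unknown profile kind {self.kind!r}")

    def to_dict(self) -> dict:
        d = {"kind": self.kind}
        d.update(
            {
                k: (list(np.asarray(val, float)) if isinstance(val, (list, tuple, np.ndarray)) else float(val))
                for k, val in self.params.items()
            }
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Profile":
        d = dict(d)
        kind = d.pop("kind")
        return cls(kind, d)


def constant(value: float) -> Profile:
    return Profile("constant", {"value": float(value)})


def linear(slope: float, intercept: float = 0.0) -> Profile:
    return Profile("linear", {"slope": float(slope), "intercept": float(intercept)})


def quadratic(c0: float = 0.0, c1: float = 0.0, c2: float = 0.0) -> Profile:
    return Profile("quadratic", {"c0": float(c0), "c1": float(c1), "c2": float(c2)})


def gaussian(amplitude: float, center: float, width: float) -> Profile:
    return Profile("gaussian", {"amplitude": float(amplitude), "center": float(center), "width": float(width)})


def tabulated(nodes, values) -> Profile:
    return Profile("tabulated", {"nodes": list(map(float, nodes)), "values": list(map(float, values))})


def as_profile(f):
    """Coerce a Profile, dict, number or callable into something callable."""
    if f is None:
        return None
    if isinstance(f, Profile) or callable(f):
        return f
    if isinstance(f, dict):
        return Profile.from_dict(f)
    if isinstance(f, (int, float)):
        return constant(float(f))
    raise TypeError(f"cannot interpret {f!r} as a profile")
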