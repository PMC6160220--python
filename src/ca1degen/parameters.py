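"""Bounded, named parameter spaces for peak conductances and passive properties.

Parameter names follow the ``g<channel>bar <s|a|b|d>`` convention (s = soma,
a = axon, b = basal, d = apical/dendritic) plus the passive entries
``g_pas c``, ``e_pas c`` (c = common to all classes), ``Cm`` and ``Ra``.
Conductance bounds span at least one order of magnitude and are sampled on a
log scale; additive parameters (e_pas) are linear.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SpaceEntry", "ParameterSpace", "SUFFIX_TO_CLASS", "CLASS_TO_SUFFIX"]

SUFFIX_TO_CLASS = {"s": "soma", "a": "axon", "b": "basal", "d": "apical", "c": "all"}
CLASS_TO_SUFFIX = {"soma": "s", "axon": "a", "basal": "b", "apical": "d"}


@dataclass(frozen=True)
class SpaceEntry:
    name: str
    compartment_class: str
    lower: float
    upper: float
    scale: str = "log"  # log | linear

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"{self.name}: lower bound must be < upper bound")
        if self.scale not in ("log", "linear"):
            raise ValueError(f"{self.name}: unknown scale {self.scale!r}")
        if self.scale == "log" and self.lower <= 0:
            raise ValueError(f"{self.name}: log-scale bounds must be positive")

    @property
    def span_ratio(self) -> float:
        return self.upper / self.lower if self.lower > 0 else np.inf


class ParameterSpace:
    """An ordered collection of bounded parameters."""

    def __init__(self, entries: list[SpaceEntry]):
        if len({e.name for e in entries}) != len(entries):
            raise ValueError("duplicate parameter names")
        for e in entries:
            if e.name.startswith("g") and "bar" in e.name and e.span_ratio < 10.0:
                raise ValueError(
                    f"{e.name}: conductance bounds must span at least one order of magnitude"
                )
        self.entries = list(entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def dim(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, name: str) -> SpaceEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.array([e.lower for e in self.entries]),
            np.array([e.upper for e in self.entries]),
        )

    def contains(self, vector: np.ndarray, atol: float = 0.0) -> bool:
        lo, hi = self.bounds_arrays()
        v = np.asarray(vector, dtype=float)
        return bool(np.all(v >= lo - atol) and np.all(v <= hi + atol))

    def to_internal(self, vector: np.ndarray) -> np.ndarray:
        """Map raw values to the optimizer's working scale (log10 for log entries)."""
        v = np.asarray(vector, dtype=float).copy()
        for i, e in enumerate(self.entries):
            if e.scale == "log":
                v[i] = np.log10(v[i])
        return v

    def from_internal(self, vector: np.ndarray) -> np.ndarray:
        v = np.asarray(vector, dtype=float).copy()
        for i, e in enumerate(self.entries):
            if e.scale == "log":
                v[i] = 10.0 ** v[i]
        return v

    def internal_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = self.bounds_arrays()
        return self.to_internal(lo), self.to_internal(hi)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform sampling on each entry's scale (log-uniform for log entries)."""
        ilo, ihi = self.internal_bounds()
        u = rng.uniform(ilo, ihi, size=(n, self.dim))
        out = np.empty_like(u)
        for j in range(n):
            out[j] = self.from_internal(u[j])
        return out

    def as_dict(self, vector: np.ndarray) -> dict[str, float]:
        return dict(zip(self.names, np.asarray(vector, dtype=float)))

    def from_dict(self, d: dict[str, float]) -> np.ndarray:
        return np.array([d[name] for name in self.names], dtype=float)
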