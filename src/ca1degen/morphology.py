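"""Simplified neuron morphologies: SWC I/O, synthetic generators, morphometrics,
and spatial discretization for the cable equation.

A :class:`Morphology` is a tree of :class:`Section` objects, each tagged with a
compartment class (soma, axon, basal, apical) and carrying piecewise-cylinder
geometry.  Path distances are measured in µm from the soma centre along the
tree; children of the soma start at the soma radius.  The soma is represented
as a single isopotential compartment (sphere surface area for a single-point
soma), because the models optimize a single somatic conductance set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Section",
    "Morphology",
    "Morphometrics",
    "CompartmentalMesh",
    "SwcError",
    "load_swc",
    "write_swc",
    "make_synthetic_morphology",
    "morphometrics",
    "discretize",
    "CLASSES",
]

CLASSES = ("soma", "axon", "basal", "apical")
_SWC_TYPE_TO_CLASS = {1: "soma", 2: "axon", 3: "basal", 4: "apical"}
_CLASS_TO_SWC_TYPE = {v: k for k, v in _SWC_TYPE_TO_CLASS.items()}


class SwcError(ValueError):
    """Structural problem in an SWC file (missing parent, no soma, ...)."""


@dataclass
class Section:
    """An unbranched run of cylinders with a single compartment class.

    ``segments`` is a list of ``(length_um, diameter_um)`` pairs.  ``parent``
    is the index of the parent section in the owning morphology (``None`` for
    the soma/root).  ``path_distance_start`` is the path distance of the
    section's proximal end from the soma centre.
    """

    klass: str
    segments: list[tuple[float, float]]
    parent: int | None = None
    path_distance_start: float = 0.0

    def __post_init__(self) -> None:
        if self.klass not in CLASSES:
            raise ValueError(f"unknown compartment class {self.klass!r}")
        for L, d in self.segments:
            if L <= 0 or d <= 0:
                raise ValueError("segment length and diameter must be positive")

    @property
    def length(self) -> float:
        return float(sum(L for L, _ in self.segments))

    @property
    def path_distance_end(self) -> float:
        return self.path_distance_start + self.length


@dataclass
class Morphology:
    """A sectioned neurite tree.  Section 0 is always the soma."""

    sections: list[Section]
    identifier: str = "morphology"

    def __post_init__(self) -> None:
        somas = [s for s in self.sections if s.klass == "soma"]
        if len(somas) != 1:
            raise ValueError(f"expected exactly one soma section, got {len(somas)}")
        if self.sections[0].klass != "soma":
            raise ValueError("section 0 must be the soma")
        for i, sec in enumerate(self.sections):
            if i == 0:
                if sec.parent is not None:
                    raise ValueError("soma section must have no parent")
            else:
                if sec.parent is None or not (0 <= sec.parent < len(self.sections)):
                    raise ValueError(f"section {i} has invalid parent {sec.parent}")
                if sec.parent >= i:
                    raise ValueError("sections must be topologically ordered")

    @property
    def soma(self) -> Section:
        return self.sections[0]

    @property
    def soma_diameter(self) -> float:
        return self.sections[0].segments[0][1]

    def sections_of_class(self, klass: str) -> list[int]:
        return [i for i, s in enumerate(self.sections) if s.klass == klass]

    def max_path_distance(self, klass: str | None = None) -> float:
        secs = self.sections if klass is None else [
            self.sections[i] for i in self.sections_of_class(klass)
        ]
        return max((s.path_distance_end for s in secs), default=0.0)


@dataclass
class Morphometrics:
    soma_area: float  # µm²
    total_volume: float  # µm³
    n_sections: int


# ---------------------------------------------------------------------------
# SWC I/O


def load_swc(path: str | Path) -> Morphology:
    """Read a standard 7-column SWC file into a :class:`Morphology`.

    SWC type codes map 1→soma, 2→axon, 3→basal, 4→apical; any other code is
    mapped to basal with a warning.  Contiguous same-class chains between
    branch points become sections.  Raises :class:`SwcError` for a point whose
    parent id does not exist.
    """
    path = Path(path)
    ids: list[int] = []
    rows: dict[int, tuple[int, float, float, float, float, int]] = {}
    for line_no, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 7:
            raise SwcError(f"{path}:{line_no}: expected 7 columns, got {len(parts)}")
        pid = int(parts[0])
        rows[pid] = (
            int(parts[1]),
            float(parts[2]),
            float(parts[3]),
            float(parts[4]),
            float(parts[5]),
            int(parts[6]),
        )
        ids.append(pid)
    if not rows:
        raise SwcError(f"{path}: no data lines")

    children: dict[int, list[int]] = {pid: [] for pid in ids}
    roots: list[int] = []
    for pid in ids:
        parent = rows[pid][5]
        if parent == -1:
            roots.append(pid)
        else:
            if parent not in rows:
                raise SwcError(f"point {pid} references missing parent {parent}")
            children[parent].append(pid)

    soma_ids = [pid for pid in ids if rows[pid][0] == 1]
    if not soma_ids:
        raise SwcError(f"{path}: no soma (type 1) points")

    unknown = sorted({rows[pid][0] for pid in ids} - set(_SWC_TYPE_TO_CLASS))
    if unknown:
        warnings.warn(
            f"SWC type codes {unknown} are not in {{1,2,3,4}}; mapping to basal",
            stacklevel=2,
        )

    def point_class(pid: int) -> str:
        return _SWC_TYPE_TO_CLASS.get(rows[pid][0], "basal")

    def xyz(pid: int) -> np.ndarray:
        t = rows[pid]
        return np.array([t[1], t[2], t[3]])

    def radius(pid: int) -> float:
        return rows[pid][4]

    # Soma section: single point -> sphere (one segment radius x diameter);
    # multi-point -> stacked cylinders.
    if len(soma_ids) == 1:
        r = radius(soma_ids[0])
        soma_segments = [(r, 2.0 * r)]
    else:
        soma_segments = []
        for pid in soma_ids:
            parent = rows[pid][5]
            if parent in soma_ids and parent != pid:
                L = float(np.linalg.norm(xyz(pid) - xyz(parent)))
                if L > 0:
                    soma_segments.append((L, 2.0 * radius(pid)))
        if not soma_segments:
            r = radius(soma_ids[0])
            soma_segments = [(r, 2.0 * r)]

    sections: list[Section] = [Section("soma", soma_segments)]
    soma_len = sections[0].length
    soma_set = set(soma_ids)
    sec_of_point: dict[int, int] = {pid: 0 for pid in soma_ids}

    # Walk the tree from soma/neurite roots, splitting sections at branch
    # points and class changes.
    def neurite_starts() -> list[int]:
        starts = []
        for pid in ids:
            if pid in soma_set:
                continue
            parent = rows[pid][5]
            if parent == -1 or parent in soma_set:
                starts.append(pid)
        return starts

    stack: list[tuple[int, int]] = [(pid, 0) for pid in neurite_starts()]
    while stack:
        start, parent_sec = stack.pop()
        klass = point_class(start)
        parent_pid = rows[start][5]
        segments: list[tuple[float, float]] = []
        pid = start
        prev = parent_pid if parent_pid != -1 else start
        while True:
            if prev != pid and prev in rows:
                L = float(np.linalg.norm(xyz(pid) - xyz(prev)))
            else:
                L = 0.0
            if L > 0:
                segments.append((L, 2.0 * radius(pid)))
            kids = children[pid]
            same = [k for k in kids if k not in soma_set]
            if len(same) == 1 and point_class(same[0]) == klass:
                prev, pid = pid, same[0]
                continue
            break
        if not segments:  # zero-length chain; give it a token stub
            segments = [(1e-6, 2.0 * radius(start))]
        start_dist = (
            soma_len
            if parent_sec == 0
            else sections[parent_sec].path_distance_end
        )
        sections.append(
            Section(klass, segments, parent=parent_sec, path_distance_start=start_dist)
        )
        sec_idx = len(sections) - 1
        sec_of_point[pid] = sec_idx
        for k in children[pid]:
            if k not in soma_set:
                stack.append((k, sec_idx))

    return Morphology(sections, identifier=path.stem)


def write_swc(morph: Morphology, path: str | Path) -> None:
    """Write a morphology as 7-column SWC (straight-line layout per section)."""
    path = Path(path)
    lines = ["# generated by ca1degen"]
    next_id = 1
    # soma: single point sphere when one segment of (r, 2r), else cylinder chain
    soma = morph.soma
    soma_r = soma.segments[0][1] / 2.0
    lines.append(f"{next_id} 1 0.0 0.0 0.0 {soma_r:.6f} -1")
    soma_tip_id = next_id
    next_id += 1

    # unit direction per top-level neurite, rotated around z
    dirs = {}
    angle = 0.0
    last_point_of_sec = {0: (soma_tip_id, np.zeros(3))}
    for i, sec in enumerate(morph.sections):
        if i == 0:
            continue
        parent_id, origin = last_point_of_sec[sec.parent]
        if sec.parent == 0:
            direction = np.array([math.cos(angle), math.sin(angle), 0.0])
            angle += 2.4  # golden-ish spread between root neurites
            # neurites start at the soma centre point so that re-reading the
            # file reproduces segment lengths exactly (the path-distance
            # offset is the soma-radius convention, applied on load)
        else:
            direction = dirs[sec.parent]
            c, s = math.cos(0.35), math.sin(0.35)
            direction = np.array(
                [c * direction[0] - s * direction[1], s * direction[0] + c * direction[1], 0.0]
            )
            direction /= np.linalg.norm(direction)
        dirs[i] = direction
        pos = origin.copy()
        prev_id = parent_id
        stype = _CLASS_TO_SWC_TYPE[sec.klass]
        for L, d in sec.segments:
            pos = pos + direction * L
            lines.append(
                f"{next_id} {stype} {pos[0]:.6f} {pos[1]:.6f} {pos[2]:.6f} {d / 2.0:.6f} {prev_id}"
            )
            prev_id = next_id
            next_id += 1
        last_point_of_sec[i] = (prev_id, pos)
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Synthetic morphologies


@dataclass
class GeometryConfig:
    """Geometry of the synthetic ball-and-stick templates (all µm)."""

    soma_diameter: float = 20.0
    apical_length: float = 400.0
    apical_diameter: tuple[float, float] = (3.0, 1.0)  # proximal -> distal taper
    basal_length: float = 200.0
    basal_diameter: tuple[float, float] = (2.0, 1.0)
    n_basal: int = 1
    axon_length: float = 60.0
    axon_diameter: float = 1.0
    dend_length: float = 150.0  # interneuron dendrites
    dend_diameter: tuple[float, float] = (1.5, 1.0)
    n_dend: int = 2
    segment_length: float = 25.0

    def validate(self) -> None:
        vals = [
            self.soma_diameter,
            self.apical_length,
            *self.apical_diameter,
            self.basal_length,
            *self.basal_diameter,
            self.axon_length,
            self.axon_diameter,
            self.dend_length,
            *self.dend_diameter,
            self.segment_length,
        ]
        if any(v <= 0 for v in vals) or self.n_basal < 1 or self.n_dend < 2:
            raise ValueError("geometry parameters must be positive (>=2 interneuron dendrites)")


def _tapered_segments(length: float, d0: float, d1: float, seg_len: float) -> list[tuple[float, float]]:
    n = max(1, int(math.ceil(length / seg_len)))
    L = length / n
    mids = (np.arange(n) + 0.5) / n
    return [(L, float(d0 + (d1 - d0) * x)) for x in mids]


def make_synthetic_morphology(
    config: GeometryConfig | dict | None = None,
    class_template: str = "pyramidal",
    identifier: str | None = None,
) -> Morphology:
    """Build a deterministic stylized morphology.

    ``pyramidal``: spherical soma, tapering apical trunk, basal dendrite(s) and
    a stub axon.  ``interneuron``: soma, >=2 dendrites (mapped to the basal
    class) and a stub axon.  Identical config always yields an identical
    (bit-equal) morphology.
    """
    if config is None:
        config = GeometryConfig()
    elif isinstance(config, dict):
        config = GeometryConfig(**config)
    config.validate()
    if class_template not in ("pyramidal", "interneuron"):
        raise ValueError(f"unknown template {class_template!r}")

    r = config.soma_diameter / 2.0
    sections = [Section("soma", [(r, config.soma_diameter)])]

    def add(klass: str, segs: list[tuple[float, float]]) -> None:
        sections.append(Section(klass, segs, parent=0, path_distance_start=r))

    add("axon", _tapered_segments(config.axon_length, config.axon_diameter,
                                  config.axon_diameter, config.segment_length))
    if class_template == "pyramidal":
        add("apical", _tapered_segments(config.apical_length, *config.apical_diameter,
                                        config.segment_length))
        for _ in range(config.n_basal):
            add("basal", _tapered_segments(config.basal_length, *config.basal_diameter,
                                           config.segment_length))
    else:
        for _ in range(config.n_dend):
            add("basal", _tapered_segments(config.dend_length, *config.dend_diameter,
                                           config.segment_length))
    return Morphology(sections, identifier=identifier or class_template)


# ---------------------------------------------------------------------------
# Morphometrics


def soma_area(morph: Morphology) -> float:
    """Soma membrane area in µm²: sphere πd² for a single-segment soma,
    stacked-cylinder lateral area otherwise."""
    soma = morph.soma
    if len(soma.segments) == 1:
        d = soma.segments[0][1]
        return math.pi * d * d
    return float(sum(math.pi * d * L for L, d in soma.segments))


def morphometrics(morph: Morphology) -> Morphometrics:
    total_volume = 0.0
    for i, sec in enumerate(morph.sections):
        if i == 0 and len(sec.segments) == 1:
            d = sec.segments[0][1]
            total_volume += math.pi * d**3 / 6.0  # sphere
        else:
            total_volume += sum(math.pi * (d / 2.0) ** 2 * L for L, d in sec.segments)
    return Morphometrics(
        soma_area=soma_area(morph),
        total_volume=float(total_volume),
        n_sections=len(morph.sections),
    )


# ---------------------------------------------------------------------------
# Discretization


@dataclass
class CompartmentalMesh:
    """Flat compartment arrays ready for the cable solver.

    Compartment 0 is the soma (isopotential; sphere area).  ``parent`` holds
    the axial neighbour toward the soma (-1 for the soma itself).  Areas in
    µm², lengths/diameters/path distances in µm.
    """

    class_id: np.ndarray  # int, index into CLASSES
    area: np.ndarray
    length: np.ndarray
    diameter: np.ndarray  # effective (volume-preserving) diameter
    path_mid: np.ndarray
    parent: np.ndarray  # int
    section_index: np.ndarray  # int, originating section
    identifier: str = "mesh"

    @property
    def n(self) -> int:
        return int(self.class_id.size)

    def compartments_of_class(self, klass: str) -> np.ndarray:
        return np.nonzero(self.class_id == CLASSES.index(klass))[0]

    def nearest_compartment(self, klass: str, path_distance: float) -> int:
        idx = self.compartments_of_class(klass)
        if idx.size == 0:
            raise ValueError(f"mesh has no {klass} compartments")
        return int(idx[np.argmin(np.abs(self.path_mid[idx] - path_distance))])


def discretize(morph: Morphology, max_compartment_length: float = 40.0) -> CompartmentalMesh:
    """Split each section into ⌈L/max⌉ equal-length compartments.

    Membrane area and volume are conserved exactly: each compartment's area
    (and volume) is the integral of the section's piecewise-cylinder lateral
    area (volume) over the compartment's arc-length span.  The soma is always
    a single compartment.
    """
    if max_compartment_length <= 0:
        raise ValueError("max_compartment_length must be positive")

    class_id, area, length, diameter, path_mid, parent, section_index = (
        [], [], [], [], [], [], []
    )
    last_comp_of_sec: dict[int, int] = {}

    for si, sec in enumerate(morph.sections):
        if si == 0:
            class_id.append(CLASSES.index("soma"))
            area.append(soma_area(morph))
            length.append(sec.length)
            diameter.append(sec.segments[0][1])
            path_mid.append(0.0)
            parent.append(-1)
            section_index.append(0)
            last_comp_of_sec[0] = 0
            continue
        L_total = sec.length
        ncomp = max(1, int(math.ceil(L_total / max_compartment_length)))
        Lc = L_total / ncomp
        # cumulative segment boundaries
        seg_edges = np.concatenate([[0.0], np.cumsum([L for L, _ in sec.segments])])
        seg_d = np.array([d for _, d in sec.segments])
        prev = last_comp_of_sec[sec.parent]
        for j in range(ncomp):
            a, b = j * Lc, (j + 1) * Lc
            A = V = 0.0
            for k in range(len(seg_d)):
                lo, hi = max(a, seg_edges[k]), min(b, seg_edges[k + 1])
                if hi > lo:
                    A += math.pi * seg_d[k] * (hi - lo)
                    V += math.pi * (seg_d[k] / 2.0) ** 2 * (hi - lo)
            d_eff = math.sqrt(4.0 * V / (math.pi * Lc))
            class_id.append(CLASSES.index(sec.klass))
            area.append(A)
            length.append(Lc)
            diameter.append(d_eff)
            path_mid.append(sec.path_distance_start + (a + b) / 2.0)
            parent.append(prev)
            section_index.append(si)
            prev = len(class_id) - 1
        last_comp_of_sec[si] = prev

    return CompartmentalMesh(
        class_id=np.array(class_id, dtype=np.int64),
        area=np.array(area),
        length=np.array(length),
        diameter=np.array(diameter),
        path_mid=np.array(path_mid),
        parent=np.array(parent, dtype=np.int64),
        section_index=np.array(section_index, dtype=np.int64),
        identifier=morph.identifier,
    )
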