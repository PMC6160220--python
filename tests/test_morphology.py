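import math

import numpy as np
import pytest

from ca1degen.morphology import (
    GeometryConfig,
    Morphology,
    Section,
    SwcError,
    discretize,
    load_swc,
    make_synthetic_morphology,
    morphometrics,
    write_swc,
)

SIMPLE_SWC = """# soma + two apical points extending 100 um
1 1 0 0 0 10 -1
2 4 0 60 0 1.5 1
3 4 0 110 0 1.0 2
"""


def test_load_swc_simple(tmp_path):
    f = tmp_path / "cell.swc"
    f.write_text(SIMPLE_SWC)
    m = load_swc(f)
    classes = [s.klass for s in m.sections]
    assert classes == ["soma", "apical"]
    apical = m.sections[1]
    # two segments: 60 um then 50 um, starting at the soma radius
    assert apical.length == pytest.approx(110.0)
    assert apical.path_distance_start == pytest.approx(10.0)
    assert apical.path_distance_end == pytest.approx(120.0)


def test_load_swc_missing_parent_raises(tmp_path):
    f = tmp_path / "bad.swc"
    f.write_text("1 1 0 0 0 10 -1\n2 3 5 0 0 1 99\n")
    with pytest.raises(SwcError, match="missing parent"):
        load_swc(f)


def test_load_swc_unknown_type_maps_to_basal(tmp_path):
    f = tmp_path / "odd.swc"
    f.write_text("1 1 0 0 0 10 -1\n2 7 20 0 0 1 1\n")
    with pytest.warns(UserWarning, match="mapping to basal"):
        m = load_swc(f)
    assert m.sections[1].klass == "basal"


def _random_swc(rng, n_points=50):
    """Random branched tree as SWC rows plus an independent parent-array record."""
    rows = ["1 1 0 0 0 8 -1"]
    xyz = {1: np.zeros(3)}
    parents = {1: -1}
    types = {1: 1}
    for pid in range(2, n_points + 1):
        parent = 1 if pid == 2 else int(rng.integers(2, pid))
        t = int(rng.choice([2, 3, 4])) if parent == 1 else types[parent]
        step = rng.normal(0, 10, 3)
        pos = np.round(xyz[parent] + step, 4)  # stored at file precision
        xyz[pid] = pos
        parents[pid] = parent
        types[pid] = t
        rows.append(f"{pid} {t} {pos[0]:.4f} {pos[1]:.4f} {pos[2]:.4f} 0.8 {parent}")
    return "\n".join(rows), parents, types, xyz


def test_load_swc_topology_matches_parent_array_oracle(tmp_path, rng):
    """Tip path distances agree with a brute-force walk up the parent column."""
    text, parents, types, xyz = _random_swc(rng)
    f = tmp_path / "rand.swc"
    f.write_text(text)
    m = load_swc(f)

    # oracle: path length of each point = soma radius + sum of euclidean steps
    def oracle_path(pid):
        d = 0.0
        while parents[pid] != -1 and parents[pid] != 1:
            d += float(np.linalg.norm(xyz[pid] - xyz[parents[pid]]))
            pid = parents[pid]
        if parents[pid] == 1:
            d += float(np.linalg.norm(xyz[pid] - xyz[1]))
        return 8.0 + d  # soma radius convention

    tips = [p for p in parents if p != 1 and all(q != p for q in parents.values())]
    oracle_max = max(oracle_path(t) for t in tips)
    assert m.max_path_distance() == pytest.approx(oracle_max, rel=1e-9)
    # every non-soma SWC point contributes exactly one segment
    n_segments = sum(len(s.segments) for s in m.sections[1:])
    assert n_segments == len(parents) - 1


def test_make_synthetic_morphology_defaults():
    m = make_synthetic_morphology()
    classes = {s.klass for s in m.sections}
    assert classes == {"soma", "axon", "basal", "apical"}
    assert len(m.sections) >= 4
    # apical tip at trunk length + soma radius
    assert m.max_path_distance("apical") == pytest.approx(400.0 + 10.0)


def test_make_synthetic_morphology_deterministic():
    cfg = GeometryConfig(apical_length=333.0)
    a = make_synthetic_morphology(cfg)
    b = make_synthetic_morphology(GeometryConfig(apical_length=333.0))
    for sa, sb in zip(a.sections, b.sections):
        assert sa.segments == sb.segments


def test_make_synthetic_morphology_rejects_bad_geometry():
    with pytest.raises(ValueError):
        make_synthetic_morphology(GeometryConfig(apical_length=-5.0))


def test_morphometrics_closed_forms():
    m = make_synthetic_morphology(GeometryConfig(soma_diameter=20.0))
    mm = morphometrics(m)
    assert mm.soma_area == pytest.approx(math.pi * 400.0)
    assert mm.n_sections == len(m.sections)

    cyl = Morphology([
        Section("soma", [(5.0, 10.0)]),
        Section("basal", [(100.0, 2.0)], parent=0, path_distance_start=5.0),
    ])
    vol = morphometrics(cyl).total_volume
    sphere = math.pi * 10.0**3 / 6.0
    assert vol == pytest.approx(sphere + math.pi * 1.0**2 * 100.0)


def test_morphometrics_matches_brute_force_sum(rng):
    sections = [Section("soma", [(6.0, 12.0)])]
    expected = math.pi * 12.0**3 / 6.0
    for i in range(9):
        segs = [
            (float(rng.uniform(5, 40)), float(rng.uniform(0.5, 4)))
            for _ in range(int(rng.integers(1, 5)))
        ]
        parent = int(rng.integers(0, len(sections)))
        start = sections[parent].path_distance_end
        sections.append(Section("basal", segs, parent=parent, path_distance_start=start))
        for L, d in segs:  # independent per-segment loop
            expected += math.pi * (d / 2.0) ** 2 * L
    assert morphometrics(Morphology(sections)).total_volume == pytest.approx(expected)


@pytest.mark.parametrize("max_len", [7.0, 25.0, 40.0, 1e6])
def test_discretize_conserves_area(max_len):
    m = make_synthetic_morphology()
    mesh = discretize(m, max_len)
    lateral = sum(
        math.pi * d * L for s in m.sections[1:] for L, d in s.segments
    )
    soma_area = math.pi * m.soma_diameter**2
    assert mesh.area.sum() == pytest.approx(soma_area + lateral, rel=1e-12)


def test_discretize_ceiling_rule():
    m = Morphology([
        Section("soma", [(5.0, 10.0)]),
        Section("basal", [(100.0, 2.0)], parent=0, path_distance_start=5.0),
    ])
    mesh = discretize(m, 40.0)
    basal = mesh.compartments_of_class("basal")
    assert basal.size == 3  # ceil(100/40)
    assert np.allclose(mesh.length[basal], 100.0 / 3.0)
    mesh1 = discretize(m, 200.0)
    basal1 = mesh1.compartments_of_class("basal")
    assert basal1.size == 1
    assert mesh1.area[basal1[0]] == pytest.approx(math.pi * 2.0 * 100.0)


def test_path_distances_monotone_from_root():
    m = make_synthetic_morphology()
    mesh = discretize(m, 30.0)
    for c in range(1, mesh.n):
        p = mesh.parent[c]
        if p > 0:
            assert mesh.path_mid[c] > mesh.path_mid[p]
        assert mesh.path_mid[c] >= 0


def test_swc_roundtrip(tmp_path):
    m = make_synthetic_morphology(GeometryConfig(apical_length=250.0, n_basal=2))
    f = tmp_path / "round.swc"
    write_swc(m, f)
    m2 = load_swc(f)
    assert len(m2.sections) == len(m.sections)
    assert sorted(s.klass for s in m2.sections) == sorted(s.klass for s in m.sections)
    assert m2.max_path_distance() == pytest.approx(m.max_path_distance(), rel=1e-6)
    v1, v2 = morphometrics(m).total_volume, morphometrics(m2).total_volume
    assert v2 == pytest.approx(v1, rel=1e-6)
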