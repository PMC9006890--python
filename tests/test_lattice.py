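"""Caspar-Klug lattice construction, symmetron decomposition, spikes."""

import collections

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capsidkit.lattice import (
    LatticeError,
    SymmetronDecompositionError,
    LatticeSpec,
    assign_spikes,
    build_lattice,
    decompose_symmetrons,
    icosahedral_rotations,
    pentasymmetron_edge,
    t_number,
    trisymmetron_edge,
)

from .oracles import oracle_is_pentasymmetron


@pytest.mark.parametrize(
    "h,k,T", [(7, 12, 277), (1, 0, 1), (1, 1, 3), (2, 1, 7), (5, 0, 25)]
)
def test_t_number_examples(h, k, T):
    assert t_number(h, k) == T


@pytest.mark.parametrize("h,k", [(-1, 2), (0, 0), (3, -3)])
def test_t_number_invalid(h, k):
    with pytest.raises(LatticeError):
        t_number(h, k)


@given(st.integers(0, 40), st.integers(0, 40))
@settings(deadline=None, max_examples=60)
def test_t_number_symmetry_and_growth(h, k):
    if (h, k) == (0, 0):
        return
    assert t_number(h, k) == t_number(k, h)
    assert t_number(h + 1, k) > t_number(h, k)


@pytest.mark.parametrize("h,k", [(1, 0), (1, 1), (2, 1), (3, 0), (3, 1), (2, 2), (7, 8)])
def test_site_count_conservation(h, k):
    lat = build_lattice((h, k))
    T = t_number(h, k)
    kinds = collections.Counter(s.kind for s in lat.sites)
    assert kinds["penton"] == 12
    assert kinds.get("hexavalent-trimer", 0) == 10 * (T - 1)


def test_t1_lattice_has_2772_sites(lattice_7_12):
    assert len(lattice_7_12.sites) == 2772
    assert sum(s.kind == "penton" for s in lattice_7_12.sites) == 12


def test_symmetron_partition_7_12(lattice_7_12):
    """12 pentasymmetrons of 31 sites (penton + 5 units of 6 = P1..P6) and
    20 trisymmetrons of 120 sites, exhaustively and disjointly."""
    sizes = collections.Counter(s.symmetron for s in lattice_7_12.sites)
    penta = [v for k, v in sizes.items() if k.startswith("penta")]
    tri = [v for k, v in sizes.items() if k.startswith("tri")]
    assert len(penta) == 12 and set(penta) == {31}
    assert len(tri) == 20 and set(tri) == {120}
    labels = collections.Counter(s.asym_label for s in lattice_7_12.sites)
    for i in range(1, 7):
        assert labels[f"P{i}"] == 60
    assert trisymmetron_edge(7, 12) == 15  # 15*16/2 = 120
    assert pentasymmetron_edge(7, 12) == 3  # 3*4/2 = 6 per asymmetric unit


@pytest.mark.parametrize("h,k", [(1, 1), (1, 2), (3, 0), (3, 1), (3, 3), (5, 1), (5, 0)])
def test_decomposition_matches_planar_oracle(h, k):
    """Pentasymmetron membership agrees with exact integer hexagonal
    arithmetic on the unrolled face (small lattices, T <= 50)."""
    lat = decompose_symmetrons(build_lattice((h, k)))
    P = pentasymmetron_edge(h, k)
    s = trisymmetron_edge(h, k)
    # conservation identity
    assert 30 * P * (P + 1) + 10 * s * (s + 1) == 10 * (t_number(h, k) - 1)
    for site in lat.sites:
        if site.kind == "penton":
            continue
        want = oracle_is_pentasymmetron(h, k, site.face_coords, P)
        got = site.symmetron.startswith("penta")
        assert got == want, f"site {site.site_id} ({h},{k})"


def test_even_even_lattice_has_no_decomposition():
    with pytest.raises(SymmetronDecompositionError):
        decompose_symmetrons(build_lattice((2, 2)))


def test_orientation_uniform_within_symmetron(lattice_7_12):
    """Trimer orientation is constant inside each trisymmetron and inside
    each pentasymmetron asymmetric unit except the corner trimer (P4)."""
    by_tri = collections.defaultdict(set)
    for s in lattice_7_12.sites:
        if s.symmetron.startswith("tri"):
            by_tri[s.symmetron].add(s.orientation_class)
    assert all(len(v) == 1 for v in by_tri.values())
    # pentasymmetron units: P1,P2,P3,P5,P6 share a class; the corner P4 differs
    by_unit = collections.defaultdict(dict)
    for s in lattice_7_12.sites:
        if s.asym_unit is not None:
            by_unit[s.asym_unit][s.asym_label] = s.orientation_class
    assert len(by_unit) == 60
    for unit, classes in by_unit.items():
        main = {classes[lab] for lab in ("P1", "P2", "P3", "P5", "P6")}
        assert len(main) == 1, unit
        assert classes["P4"] not in main, unit


def test_spike_counts(lattice_7_12):
    """Per asymmetric unit 3 wide + 1 long -> whole virion 180 wide, 60
    long; pentons carry no spike."""
    c = collections.Counter(s.spike_class for s in lattice_7_12.sites)
    assert c["wide"] == 180
    assert c["long"] == 60
    assert c["none"] == 12
    assert c["regular"] == 2772 - 180 - 60 - 12
    for s in lattice_7_12.sites:
        if s.kind == "penton":
            assert s.spike_class == "none"
    # wide spikes: on P3, P6 and T_W; long on T_L
    for s in lattice_7_12.sites:
        if s.asym_label in ("P3", "P6", "T_W"):
            assert s.spike_class == "wide"
        if s.asym_label == "T_L":
            assert s.spike_class == "long"


def test_icosahedral_rotation_invariance(lattice_7_12):
    """Each of the 60 icosahedral rotations permutes the sites and
    preserves kind, symmetron class and spike class."""
    from scipy.spatial import cKDTree

    xyz = lattice_7_12.xyz
    tree = cKDTree(xyz)
    kinds = np.array([s.kind for s in lattice_7_12.sites])
    spikes = np.array([s.spike_class for s in lattice_7_12.sites])
    is_penta = np.array(
        [s.symmetron.startswith("penta") for s in lattice_7_12.sites]
    )
    rng = np.random.default_rng(0)
    rots = icosahedral_rotations(lattice_7_12.vertices)
    for R in [rots[i] for i in rng.choice(len(rots), size=12, replace=False)]:
        d, idx = tree.query(xyz @ R.T)
        assert d.max() < 1e-6
        assert len(set(idx)) == len(idx)  # a permutation
        assert (kinds[idx] == kinds).all()
        assert (is_penta[idx] == is_penta).all()
        assert (spikes[idx] == spikes).all()


def test_export_dataframe(lattice_7_12, tmp_path):
    frame = lattice_7_12.to_dataframe()
    assert len(frame) == 2772
    assert set(frame.columns) >= {
        "site_id", "kind", "x", "y", "z", "symmetron", "asym_label",
        "spike_class",
    }
    np.testing.assert_allclose(
        np.hypot(np.hypot(frame.x, frame.y), frame.z), 1.0, atol=1e-9
    )
    from capsidkit.lattice import write_lattice_pdb

    path = tmp_path / "lat.pdb"
    write_lattice_pdb(lattice_7_12, path)
    n_atoms = sum(
        line.startswith(("ATOM", "HETATM"))
        for line in path.read_text().splitlines()
    )
    assert n_atoms == 2772


def test_spec_validation():
    with pytest.raises(LatticeError):
        LatticeSpec(0, 0)
    assert LatticeSpec(7, 12).T == 277
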