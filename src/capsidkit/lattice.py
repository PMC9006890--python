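"""Caspar-Klug icosahedral surface lattices and their symmetron decomposition.

A capsid with triangulation number ``T = h**2 + h*k + k**2`` carries 12
pentavalent capsomers (pentons) on the icosahedron vertices and ``10*(T-1)``
hexavalent capsomers (major-capsid-protein trimers in giant viruses).  The
hexavalent sites group into 12 pentasymmetrons around the 5-fold vertices and
20 trisymmetrons between them; trimer orientation is uniform inside each
symmetron.  For medusavirus, ``(h, k) = (7, 12)`` gives ``T = 277`` with a
pentasymmetron asymmetric unit of six capsomers (P1..P6) and 120-capsomer
trisymmetrons, and the capsid carries three spike classes: a wide spike on
P3, P6 and the adjacent trisymmetron site (T_W), a long spike on the
trisymmetron site adjacent to P5 (T_L), and regular spikes everywhere else.

Coordinates are stored on the unit sphere (gnomonic/central projection of the
planar hexagonal net on each face); scale by the capsid radius as needed.
Handedness convention: ``k`` counts counterclockwise from ``h`` viewed from
outside the capsid.
"""

from __future__ import annotations

import math
from collections import defaultdict, deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LatticeError",
    "SymmetronDecompositionError",
    "LatticeSpec",
    "CapsomerSite",
    "SpikeAssignment",
    "Lattice",
    "t_number",
    "build_lattice",
    "decompose_symmetrons",
    "assign_spikes",
    "pentasymmetron_edge",
    "trisymmetron_edge",
    "icosahedron_vertices",
    "icosahedral_rotations",
    "lattice_to_dataframe",
]

_WELD_DECIMALS = 6  # dedup tolerance on unit-sphere coordinates


class LatticeError(ValueError):
    """Invalid lattice indices or an inconsistent lattice."""


class SymmetronDecompositionError(LatticeError):
    """The lattice admits no penta/trisymmetron decomposition under the
    package's convention (requires h or k odd)."""


def t_number(h: int, k: int) -> int:
    """Triangulation number ``T = h**2 + h*k + k**2``.

    Raises :class:`LatticeError` for negative indices or ``(0, 0)``.
    """
    if h != int(h) or k != int(k):
        raise LatticeError(f"lattice indices must be integers, got ({h}, {k})")
    h, k = int(h), int(k)
    if h < 0 or k < 0 or (h == 0 and k == 0):
        raise LatticeError(f"invalid lattice indices ({h}, {k})")
    return h * h + h * k + k * k


@dataclass(frozen=True)
class LatticeSpec:
    """Icosahedral lattice indices; ``T`` is derived, never stored stale."""

    h: int
    k: int

    def __post_init__(self) -> None:
        t_number(self.h, self.k)  # validates

    @property
    def T(self) -> int:
        return t_number(self.h, self.k)


def pentasymmetron_edge(h: int, k: int) -> int:
    """Edge length P of the pentasymmetron asymmetric-unit triangle.

    P = (h-1)/2 for odd h, else (k-1)/2 for odd k.  Together with the
    trisymmetron edge ``s`` (see :func:`trisymmetron_edge`) this satisfies
    ``30*P*(P+1) + 10*s*(s+1) = 10*(T-1)`` identically, so the decomposition
    is exhaustive.  Lattices with h and k both even have no such solution.
    """
    t_number(h, k)
    if h % 2 == 1:
        return (h - 1) // 2
    if k % 2 == 1:
        return (k - 1) // 2
    raise SymmetronDecompositionError(
        f"(h, k) = ({h}, {k}): no pentasymmetron/trisymmetron decomposition "
        "with congruent units exists when h and k are both even"
    )


def trisymmetron_edge(h: int, k: int) -> int:
    """Edge length s of the trisymmetron triangle (s*(s+1)/2 capsomers)."""
    p = pentasymmetron_edge(h, k)
    return (k if h % 2 == 1 else h) + p


@dataclass
class CapsomerSite:
    """One capsomer position on the capsid surface."""

    site_id: int
    kind: str  # "penton" | "hexavalent-trimer"
    xyz: np.ndarray  # unit-sphere position
    face_coords: tuple[int, float, float, float]  # (face index, b0, b1, b2)
    symmetron: str | None = None  # e.g. "penta-3" | "tri-17"
    asym_label: str | None = None  # "P1".."P6" | "T" | "penton"
    asym_unit: tuple | None = None  # (penton index, sector 0..4) for penta sites
    orientation_class: int | None = None  # 0, 1, 2 (60 deg-related)
    spike_class: str | None = None  # "regular" | "wide" | "long" | "none"


@dataclass(frozen=True)
class SpikeAssignment:
    site_id: int
    spike_class: str


@dataclass
class Lattice:
    """A built lattice: sites plus the icosahedron frame used to build it."""

    spec: LatticeSpec
    sites: list[CapsomerSite]
    vertices: np.ndarray  # (12, 3) unit vectors
    faces: np.ndarray  # (20, 3) vertex indices, outward-ccw
    adjacency: dict[int, set[int]] = field(repr=False, default_factory=dict)
    decomposed: bool = False

    @property
    def xyz(self) -> np.ndarray:
        return np.array([s.xyz for s in self.sites])

    def penton_ids(self) -> list[int]:
        return [s.site_id for s in self.sites if s.kind == "penton"]

    def to_dataframe(self) -> pd.DataFrame:
        return lattice_to_dataframe(self)


# ---------------------------------------------------------------------------
# icosahedron frame


def icosahedron_vertices() -> tuple[np.ndarray, np.ndarray]:
    """Unit icosahedron with one vertex on +z.

    Returns ``(vertices, faces)``: 12 unit vectors and 20 index triples
    ordered counterclockwise viewed from outside.
    """
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    raw = []
    for a in (-1.0, 1.0):
        for b in (-phi, phi):
            raw.append((0.0, a, b))
            raw.append((a, b, 0.0))
            raw.append((b, 0.0, a))
    v = np.array(raw)
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    # rotate vertex closest to +z exactly onto +z
    top = v[np.argmax(v[:, 2])]
    axis = np.cross(top, [0.0, 0.0, 1.0])
    if np.linalg.norm(axis) > 1e-12:
        axis /= np.linalg.norm(axis)
        ang = math.acos(np.clip(top @ [0.0, 0.0, 1.0], -1, 1))
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        R = np.eye(3) + math.sin(ang) * K + (1 - math.cos(ang)) * (K @ K)
        v = v @ R.T
    from scipy.spatial import ConvexHull

    hull = ConvexHull(v)
    faces = []
    for simplex in hull.simplices:
        a, b, c = simplex
        n = np.cross(v[b] - v[a], v[c] - v[a])
        if n @ (v[a] + v[b] + v[c]) < 0:  # make outward-ccw
            a, b, c = a, c, b
        faces.append((a, b, c))
    return v, np.array(sorted(faces))


def icosahedral_rotations(vertices: np.ndarray | None = None) -> list[np.ndarray]:
    """The 60 rotation matrices of the icosahedral group I, generated
    numerically from a 5-fold and a 3-fold rotation and closed under
    multiplication."""
    if vertices is None:
        vertices, faces = icosahedron_vertices()
    else:
        from scipy.spatial import ConvexHull

        faces = ConvexHull(vertices).simplices

    def axis_rotation(axis: np.ndarray, angle: float) -> np.ndarray:
        axis = axis / np.linalg.norm(axis)
        K = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)

    g1 = axis_rotation(vertices[0], 2 * math.pi / 5)
    f0 = vertices[list(faces[0])].sum(axis=0)
    g2 = axis_rotation(f0, 2 * math.pi / 3)
    group = [np.eye(3)]

    def seen(R: np.ndarray) -> bool:
        return any(np.allclose(R, G, atol=1e-9) for G in group)

    frontier = [np.eye(3)]
    while frontier:
        nxt = []
        for R in frontier:
            for G in (g1, g2):
                C = G @ R
                if not seen(C):
                    group.append(C)
                    nxt.append(C)
        frontier = nxt
    assert len(group) == 60, f"group closure found {len(group)} elements"
    return group


# ---------------------------------------------------------------------------
# lattice construction

_HEX_NEIGHBORS = ((1, 0), (-1, 0), (0, 1), (0, -1), (1, -1), (-1, 1))


def _planar(i: np.ndarray, j: np.ndarray) -> np.ndarray:
    """Integer hex coordinates -> planar xy (a1=(1,0), a2=(1/2, sqrt3/2))."""
    return np.stack([i + 0.5 * j, (math.sqrt(3) / 2.0) * j], axis=-1)


def build_lattice(spec: LatticeSpec | tuple[int, int]) -> Lattice:
    """Enumerate all capsomer sites of the (h, k) lattice on the unit sphere.

    Yields exactly ``10*(T-1)`` hexavalent sites plus 12 pentons.  Also
    records the site adjacency graph (unit lattice steps, glued across faces
    through shared edge sites), used by the symmetron decomposition.
    """
    if not isinstance(spec, LatticeSpec):
        spec = LatticeSpec(*spec)
    h, k = spec.h, spec.k
    vertices, faces = icosahedron_vertices()

    # face corner images in the planar lattice: A=(0,0), B=(h,k), C=rot60(B)
    B = np.array(_planar(np.array(h), np.array(k)))
    C = np.array(_planar(np.array(-k), np.array(h + k)))
    M = np.column_stack([B, C])  # planar point = M @ (b1, b2)
    Minv = np.linalg.inv(M)

    span = h + k + 1
    ii, jj = np.meshgrid(np.arange(-span, span + 1), np.arange(-span, span + 1))
    ii, jj = ii.ravel(), jj.ravel()
    pts = _planar(ii, jj)
    b12 = pts @ Minv.T
    b0 = 1.0 - b12.sum(axis=1)
    eps = 1e-9
    keep = (b0 >= -eps) & (b12[:, 0] >= -eps) & (b12[:, 1] >= -eps)
    ii, jj = ii[keep], jj[keep]
    bary = np.column_stack([b0[keep], b12[keep]])

    weld: dict[tuple, int] = {}
    sites: list[CapsomerSite] = []
    adjacency: dict[int, set[int]] = defaultdict(set)

    for f_idx, (a, b, c) in enumerate(faces):
        tri = vertices[[a, b, c]]
        xyz = bary @ tri
        xyz /= np.linalg.norm(xyz, axis=1, keepdims=True)
        local_ids = {}
        rounded = np.round(xyz, _WELD_DECIMALS)
        pentonish = bary.max(axis=1) > 1.0 - 1e-9
        for m, key in enumerate(map(tuple, rounded)):
            if key not in weld:
                weld[key] = len(sites)
                sites.append(
                    CapsomerSite(
                        site_id=len(sites),
                        kind="penton" if pentonish[m] else "hexavalent-trimer",
                        xyz=xyz[m],
                        face_coords=(f_idx, *map(float, bary[m])),
                    )
                )
            local_ids[(ii[m], jj[m])] = weld[key]
        for (i0, j0), sid in local_ids.items():
            for di, dj in _HEX_NEIGHBORS:
                nid = local_ids.get((i0 + di, j0 + dj))
                if nid is not None and nid != sid:
                    adjacency[sid].add(nid)
                    adjacency[nid].add(sid)

    n_pent = sum(s.kind == "penton" for s in sites)
    n_hex = len(sites) - n_pent
    if n_pent != 12 or n_hex != 10 * (spec.T - 1):
        raise LatticeError(
            f"construction yielded {n_pent} pentons + {n_hex} hexavalent sites; "
            f"expected 12 + {10 * (spec.T - 1)} for T={spec.T}"
        )
    return Lattice(spec=spec, sites=sites, vertices=vertices, faces=faces,
                   adjacency=dict(adjacency))


# ---------------------------------------------------------------------------
# symmetron decomposition


def _bfs_distances(lattice: Lattice, source: int, radius: int) -> dict[int, int]:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        if dist[u] == radius:
            continue
        for v in lattice.adjacency.get(u, ()):
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def _azimuth(points: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Angles of points about ``axis`` in a fixed tangent frame."""
    axis = axis / np.linalg.norm(axis)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    e1 = ref - (ref @ axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return np.arctan2(points @ e2, points @ e1)


def decompose_symmetrons(lattice: Lattice) -> Lattice:
    """Fill ``symmetron``, ``asym_label`` and ``orientation_class`` in place.

    Pentasymmetron p: the penton plus all hexavalent sites within lattice
    graph distance P of penton p (ties toward the closer penton, then the
    smaller penton index).  Remaining sites form 20 trisymmetrons, one per
    face (the geodesic Voronoi cell of a face's 3-fold axis is exactly the
    face, so membership is the nearest face-centroid; boundary ties go to the
    smaller face index).

    Pentasymmetron asymmetric units are the five 72-degree sectors delimited
    by the ring-1 sites; labels P1..P{P(P+1)/2} run ring by ring, by azimuth
    within each ring (so for P=3 the pentagon-corner trimer is P4, whose
    orientation differs from the rest of its unit).
    """
    P = pentasymmetron_edge(lattice.spec.h, lattice.spec.k)
    pentons = lattice.penton_ids()

    best: dict[int, tuple[int, int]] = {}  # site -> (dist, penton index)
    for p_idx, pid in enumerate(pentons):
        if P == 0:
            dists = {pid: 0}
        else:
            dists = _bfs_distances(lattice, pid, P)
        for sid, d in dists.items():
            cur = best.get(sid)
            if cur is None or (d, p_idx) < cur:
                best[sid] = (d, p_idx)

    face_centers = np.array(
        [lattice.vertices[list(f)].mean(axis=0) for f in lattice.faces]
    )
    face_centers /= np.linalg.norm(face_centers, axis=1, keepdims=True)

    # per-face lattice orientation class: angle of the mapped a1 direction
    # against the first face edge, quantized to 60-degree bins
    face_orient = []
    h, k = lattice.spec.h, lattice.spec.k
    B = np.array(_planar(np.array(h), np.array(k)))
    C = np.array(_planar(np.array(-k), np.array(h + k)))
    Minv = np.linalg.inv(np.column_stack([B, C]))
    a1_b12 = np.array([1.0, 0.0]) @ Minv.T  # a1 in (b1, b2) increments
    for f in lattice.faces:
        v0, v1, v2 = lattice.vertices[list(f)]
        u = a1_b12[0] * (v1 - v0) + a1_b12[1] * (v2 - v0)  # a1 image in face
        e = v1 - v0
        n = np.cross(v0 + v1 + v2, e)
        ang = math.atan2(u @ n / np.linalg.norm(n), u @ e / np.linalg.norm(e))
        face_orient.append(int(round((math.degrees(ang) % 180.0) / 60.0)) % 3)

    # sector frames per penton
    ring1: dict[int, list[tuple[float, int]]] = {}
    for sid, (d, p_idx) in best.items():
        if d == 1:
            ring1.setdefault(p_idx, []).append(sid)

    sector_starts: dict[int, np.ndarray] = {}
    for p_idx, pid in enumerate(pentons):
        axis = lattice.sites[pid].xyz
        members = ring1.get(p_idx, [])
        if P > 0 and len(members) != 5:
            raise LatticeError(
                f"penton {pid}: expected 5 ring-1 sites, found {len(members)}"
            )
        if members:
            az = _azimuth(np.array([lattice.sites[s].xyz for s in members]), axis)
            sector_starts[p_idx] = np.sort(az)

    n_unit = P * (P + 1) // 2
    for site in lattice.sites:
        sid = site.site_id
        if site.kind == "penton":
            p_idx = pentons.index(sid)
            site.symmetron = f"penta-{p_idx}"
            site.asym_label = "penton"
            site.orientation_class = None
            continue
        hit = best.get(sid)
        if hit is not None and hit[0] <= P:
            d, p_idx = hit
            site.symmetron = f"penta-{p_idx}"
        else:
            dots = face_centers @ site.xyz
            f_idx = int(np.flatnonzero(dots >= dots.max() - 1e-9)[0])
            site.symmetron = f"tri-{f_idx}"
            site.asym_label = "T"
            site.orientation_class = face_orient[f_idx]

    # pentasymmetron asymmetric-unit labels
    for p_idx, pid in enumerate(pentons):
        if P == 0:
            continue
        axis = lattice.sites[pid].xyz
        starts = sector_starts[p_idx]
        members = [
            s
            for s in lattice.sites
            if s.symmetron == f"penta-{p_idx}" and s.kind != "penton"
        ]
        az = _azimuth(np.array([s.xyz for s in members]), axis)
        rings = {s.site_id: best[s.site_id][0] for s in members}
        sectors = np.searchsorted(starts, az - 1e-9, side="right") - 1
        sectors %= 5
        by_sector: dict[int, list] = defaultdict(list)
        for s, a, sec in zip(members, az, sectors):
            rel = (a - starts[sec]) % (2 * math.pi)
            by_sector[int(sec)].append((rings[s.site_id], rel, s))
        for sec, entries in by_sector.items():
            entries.sort(key=lambda e: (e[0], e[1]))
            if len(entries) != n_unit:
                raise LatticeError(
                    f"penton {pid} sector {sec}: {len(entries)} sites, "
                    f"expected {n_unit}"
                )
            unit_class = (p_idx * 5 + sec) % 3
            label_no = 0
            for ring, _rel, s in entries:
                label_no += 1
                s.asym_label = f"P{label_no}"
                s.asym_unit = (p_idx, int(sec))
                corner = ring == P and label_no == P * (P - 1) // 2 + 1
                s.orientation_class = (unit_class + 1) % 3 if corner else unit_class

    lattice.decomposed = True
    return lattice


# ---------------------------------------------------------------------------
# spikes


def assign_spikes(lattice: Lattice) -> list[SpikeAssignment]:
    """Assign spike classes: wide on P3, P6 and the trisymmetron site nearest
    P6 (T_W); long on the trisymmetron site nearest P5 (T_L); regular on every
    other hexavalent site; pentons carry none.

    Nearness is great-circle distance; each asymmetric unit claims unused
    trisymmetron sites greedily in (penton, sector) order, ties broken by the
    smaller site id.  Requires the symmetron decomposition and a
    pentasymmetron edge of at least 3 (so P3/P5/P6 exist).
    """
    if not lattice.decomposed:
        raise LatticeError("run decompose_symmetrons before assign_spikes")
    P = pentasymmetron_edge(lattice.spec.h, lattice.spec.k)
    if P < 3:
        raise LatticeError(
            "spike scheme requires a pentasymmetron asymmetric unit with at "
            f"least 6 capsomers (P>=3); this lattice has P={P}"
        )
    tri_sites = [s for s in lattice.sites if s.symmetron.startswith("tri-")]
    tri_xyz = np.array([s.xyz for s in tri_sites])
    tri_ids = np.array([s.site_id for s in tri_sites])
    order = np.argsort(tri_ids)
    tri_xyz, tri_ids = tri_xyz[order], tri_ids[order]

    spike: dict[int, str] = {}
    for s in lattice.sites:
        if s.kind == "penton":
            spike[s.site_id] = "none"
        elif s.asym_label in ("P3", "P6"):
            spike[s.site_id] = "wide"
        else:
            spike[s.site_id] = "regular"

    used: set[int] = set()

    def claim(anchor_xyz: np.ndarray, cls: str) -> None:
        d = tri_xyz @ anchor_xyz  # cos of angle; maximize
        for idx in np.argsort(-d, kind="stable"):
            sid = int(tri_ids[idx])
            if sid not in used:
                used.add(sid)
                spike[sid] = cls
                lattice.sites[sid].asym_label = "T_W" if cls == "wide" else "T_L"
                return
        raise LatticeError("no trisymmetron site available for spike anchor")

    pentons = lattice.penton_ids()
    anchors: dict[tuple[int, str], np.ndarray] = {}
    for s in lattice.sites:
        if s.asym_label in ("P5", "P6") and s.symmetron.startswith("penta-"):
            p_idx = int(s.symmetron.split("-")[1])
            sec_key = s.site_id  # one P5/P6 per sector; use site id ordering
            anchors[(p_idx, s.asym_label, sec_key)] = s.xyz

    for (p_idx, label, _sid) in sorted(anchors):
        claim(anchors[(p_idx, label, _sid)], "wide" if label == "P6" else "long")

    for s in lattice.sites:
        s.spike_class = spike[s.site_id]
    return [SpikeAssignment(s.site_id, s.spike_class) for s in lattice.sites]


# ---------------------------------------------------------------------------
# export


def lattice_to_dataframe(lattice: Lattice) -> pd.DataFrame:
    rows = []
    for s in lattice.sites:
        x, y, z = s.xyz
        rows.append(
            dict(
                site_id=s.site_id,
                kind=s.kind,
                x=x,
                y=y,
                z=z,
                symmetron=s.symmetron,
                asym_label=s.asym_label,
                orientation_class=s.orientation_class,
                spike_class=s.spike_class,
            )
        )
    return pd.DataFrame(rows)


def write_lattice_csv(lattice: Lattice, path) -> None:
    lattice.to_dataframe().to_csv(path, index=False)


def write_lattice_pdb(lattice: Lattice, path, radius_nm: float = 115.0) -> None:
    """Pseudo-atom point cloud (one CA per capsomer) for visualization."""
    import gemmi

    st = gemmi.Structure()
    st.name = "capsomer-lattice"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for s in lattice.sites:
        res = gemmi.Residue()
        res.name = "PEN" if s.kind == "penton" else "HEX"
        res.seqid = gemmi.SeqId(s.site_id % 9999 + 1, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        # PDB coordinates in Angstrom
        atom.pos = gemmi.Position(*(s.xyz * radius_nm * 10.0))
        res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
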