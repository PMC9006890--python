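"""Independent brute-force oracles used by the tests.

These never call back into the code paths they check: symmetron membership
is recomputed from each site's barycentric face coordinates with exact
integer hexagonal-lattice arithmetic, and expected distance-bin counts come
from rejection sampling.
"""

from __future__ import annotations

import math

import numpy as np


def hex_distance(di: int, dj: int) -> int:
    """Hexagonal lattice graph distance for an integer step (di, dj) in the
    (a1, a2) axial basis (cube-coordinate metric)."""
    return (abs(di) + abs(dj) + abs(di + dj)) // 2


def _planar(i, j):
    return np.array([i + 0.5 * j, math.sqrt(3) / 2.0 * j])


def site_hex_coords(h: int, k: int, b1: float, b2: float) -> tuple[int, int]:
    """Recover integer lattice coordinates of a site from its barycentric
    position on a face with corners (0,0), (h,k), rot60(h,k)."""
    B = _planar(h, k)
    C = _planar(-k, h + k)
    p = b1 * B + b2 * C
    # invert planar -> axial
    j = p[1] / (math.sqrt(3) / 2.0)
    i = p[0] - 0.5 * j
    ii, jj = round(i), round(j)
    assert abs(i - ii) < 1e-6 and abs(j - jj) < 1e-6, "site off-lattice"
    return ii, jj


def oracle_is_pentasymmetron(h: int, k: int, face_coords, P: int) -> bool:
    """Nearest-penton test: the site belongs to a pentasymmetron iff its
    hexagonal distance to some corner of its face is at most P."""
    _face, b0, b1, b2 = face_coords
    i, j = site_hex_coords(h, k, b1, b2)
    corners = [(0, 0), (h, k), (-k, h + k)]
    return min(hex_distance(i - ci, j - cj) for ci, cj in corners) <= P


def rejection_sample_distances(a_um: float, d_max: float, n: int, rng
                               ) -> np.ndarray:
    """Uniform points in the annulus a <= r <= a + d_max by rejection in the
    bounding square; returns distances from the inner circle."""
    out = np.empty(n)
    got = 0
    lim = a_um + d_max
    while got < n:
        xy = rng.uniform(-lim, lim, size=(4 * n, 2))
        r = np.hypot(xy[:, 0], xy[:, 1])
        r = r[(r >= a_um) & (r <= lim)]
        take = min(len(r), n - got)
        out[got:got + take] = r[:take] - a_um
        got += take
    return out
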