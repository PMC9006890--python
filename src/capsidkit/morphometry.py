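"""Layer morphometry of layered-particle volumes and sections.

Measurements mirror how radial size readings are made on rotationally
averaged density maps: layer edges are half-maximum crossings of the radial
profile, refined to subvoxel precision by parabolic interpolation, and layer
widths are full widths at half maximum.  The edge convention (half-max on
the flank, anchored at the layer's peak) is applied identically to every
profile so that inter-profile radius shifts are well defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .phantoms import DensityVolume, SectionImage

__all__ = [
    "MorphometryError",
    "NoEdgeError",
    "RadialProfile",
    "LayerWindow",
    "radial_profile",
    "edge_position",
    "peak_position",
    "radius_shift",
    "layer_width",
    "vertex_diameter",
    "membrane_gap",
    "detect_openings",
]


class MorphometryError(ValueError):
    pass


class NoEdgeError(MorphometryError):
    """The analysis window contains no usable density transition."""


@dataclass
class RadialProfile:
    """Spherically (3D) or rotationally (2D) averaged density vs radius."""

    radii: np.ndarray  # nm, bin centers, uniform from ~0
    density: np.ndarray
    counts: np.ndarray  # voxels per bin (for conservation checks)
    mode: str  # "spherical-3D" | "rotational-2D"
    voxel_size: float  # source sampling, Angstrom

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.radii) > 0):
            raise MorphometryError("radii must increase strictly")
        if not np.isfinite(self.density).all():
            raise MorphometryError("profile contains non-finite densities")

    @property
    def bin_width(self) -> float:
        return float(self.radii[1] - self.radii[0])

    def window_slice(self, window: "LayerWindow") -> slice:
        i0 = int(np.searchsorted(self.radii, window.r_min, side="left"))
        i1 = int(np.searchsorted(self.radii, window.r_max, side="right"))
        if i1 - i0 < 5:
            raise MorphometryError(
                f"window {window} covers fewer than 5 profile bins"
            )
        return slice(i0, i1)


@dataclass(frozen=True)
class LayerWindow:
    name: str
    r_min: float
    r_max: float

    def __post_init__(self) -> None:
        if not self.r_min < self.r_max:
            raise MorphometryError(f"empty window {self.name}")


def layer_windows() -> dict[str, LayerWindow]:
    """Preset-derived default analysis windows."""
    from . import presets

    return {
        name: LayerWindow(name, lo, hi)
        for name, (lo, hi) in presets.LAYER_WINDOWS.items()
    }


# ---------------------------------------------------------------------------
# profiles


def radial_profile(
    source: DensityVolume | SectionImage | np.ndarray,
    mode: str | None = None,
    center: tuple | None = None,
    bin_width_nm: float | None = None,
    voxel_size: float | None = None,
    recenter_tolerance_nm: float | None = None,
) -> RadialProfile:
    """Average density in concentric shells (3D volume) or annuli (2D image).

    The default bin width is one voxel.  The geometric grid center is used
    unless ``center`` (index units) is given; if ``recenter_tolerance_nm`` is
    set and the center of mass is further than that from the geometric
    center, the center of mass is used instead.
    """
    if isinstance(source, DensityVolume):
        data, vs = source.data, source.voxel_size
        mode = mode or "spherical-3D"
    elif isinstance(source, SectionImage):
        data, vs = source.data, source.pixel_size
        mode = mode or "rotational-2D"
    else:
        data = np.asarray(source)
        if voxel_size is None:
            raise MorphometryError("voxel_size required for bare arrays")
        vs = voxel_size
        mode = mode or ("spherical-3D" if data.ndim == 3 else "rotational-2D")
    if (mode == "spherical-3D") != (data.ndim == 3):
        raise MorphometryError(f"mode {mode} incompatible with ndim {data.ndim}")

    vox = vs / 10.0
    c = np.array([(s - 1) / 2.0 for s in data.shape])
    if recenter_tolerance_nm is not None:
        total = float(np.abs(data).sum())
        if total > 0:
            com = np.array(ndimage.center_of_mass(np.abs(data)))
            if np.linalg.norm(com - c) * vox > recenter_tolerance_nm:
                c = com
    if center is not None:
        c = np.asarray(center, dtype=float)

    bw = bin_width_nm or vox
    rmax = math.sqrt(sum(max(ci, s - 1 - ci) ** 2 for ci, s in zip(c, data.shape)))
    nbins = int(rmax * vox / bw) + 2
    sums = np.zeros(nbins)
    counts = np.zeros(nbins, dtype=np.int64)
    if data.ndim == 3:
        # stream over z-slices to keep memory flat on large grids
        jj, kk = np.meshgrid(
            (np.arange(data.shape[1]) - c[1]) * vox,
            (np.arange(data.shape[2]) - c[2]) * vox,
            indexing="ij",
        )
        rho2 = (jj * jj + kk * kk).astype(np.float32)
        for i in range(data.shape[0]):
            dz = (i - c[0]) * vox
            r = np.sqrt(rho2 + dz * dz)
            idx = np.minimum((r.ravel() / bw).astype(np.int64), nbins - 1)
            sums += np.bincount(idx, weights=data[i].ravel().astype(np.float64),
                                minlength=nbins)
            counts += np.bincount(idx, minlength=nbins)
    else:
        grids = np.ogrid[tuple(slice(0, s) for s in data.shape)]
        r = np.sqrt(sum(((g - ci) * vox) ** 2 for g, ci in zip(grids, c)))
        idx = np.minimum((r.ravel() / bw).astype(np.int64), nbins - 1)
        sums += np.bincount(idx, weights=data.ravel().astype(np.float64),
                            minlength=nbins)
        counts += np.bincount(idx, minlength=nbins)
    last = int(np.nonzero(counts)[0][-1]) + 1
    sums, counts = sums[:last], counts[:last]
    nbins = last
    dens = np.divide(sums, counts, out=np.zeros_like(sums),
                     where=counts > 0)
    radii = (np.arange(nbins) + 0.5) * bw
    return RadialProfile(radii=radii, density=dens.astype(np.float64),
                         counts=counts, mode=mode, voxel_size=vs)


# ---------------------------------------------------------------------------
# subvoxel estimators


def _parabolic_crossing(x: np.ndarray, y: np.ndarray, i: int, level: float
                        ) -> float:
    """Crossing of ``level`` between samples i and i+1, refined by a
    parabola through the three nearest points; falls back to linear."""
    x0, x1 = x[i], x[i + 1]
    lin = x0 + (level - y[i]) * (x1 - x0) / (y[i + 1] - y[i])
    j0 = max(0, min(i, len(x) - 3))
    xs, ys = x[j0:j0 + 3], y[j0:j0 + 3]
    a, b, c = np.polyfit(xs - xs[0], ys, 2)
    disc = b * b - 4 * a * (c - level)
    if abs(a) < 1e-12 or disc < 0:
        return float(lin)
    roots = xs[0] + (-b + np.array([1, -1]) * math.sqrt(disc)) / (2 * a)
    roots = roots[(roots >= min(x0, x1) - (x1 - x0)) &
                  (roots <= max(x0, x1) + (x1 - x0))]
    if len(roots) == 0:
        return float(lin)
    return float(roots[np.argmin(np.abs(roots - lin))])


def _flank_crossing(r, y, i_peak, level, direction: int) -> float:
    """First crossing of ``level`` walking from the peak in ``direction``."""
    i = i_peak
    while 0 <= i + direction < len(y):
        j = i + direction
        if (y[i] - level) * (y[j] - level) <= 0 and y[i] != y[j]:
            lo = min(i, j)
            return _parabolic_crossing(r, y, lo, level)
        i = j
    raise NoEdgeError("no half-maximum crossing on the requested flank")


def edge_position(profile: RadialProfile, window: LayerWindow,
                  flank: str = "outer") -> float:
    """Subvoxel radius (nm) of the half-maximum edge of the layer in
    ``window``, on its outer or inner flank.

    The level is halfway between the layer peak and the window baseline
    (minimum inside the window); the crossing is anchored at the peak so
    that neighbouring layers inside the window are ignored.
    """
    sl = profile.window_slice(window)
    r, y = profile.radii[sl], profile.density[sl]
    peak = float(y.max())
    base = float(y.min())
    if peak - base < 1e-9 or peak <= 0:
        raise NoEdgeError(f"window {window.name} is flat")
    level = base + 0.5 * (peak - base)
    return _flank_crossing(r, y, int(np.argmax(y)), level,
                           +1 if flank == "outer" else -1)


def peak_position(profile: RadialProfile, window: LayerWindow) -> float:
    """Layer position as the centroid of the above-half-maximum region
    (robust on flat-topped layers)."""
    sl = profile.window_slice(window)
    r, y = profile.radii[sl], profile.density[sl]
    base = float(y.min())
    level = base + 0.5 * (float(y.max()) - base)
    # contiguous above-half run containing the peak, so that other layers
    # inside the window cannot pull the centroid
    i = int(np.argmax(y))
    lo = i
    while lo > 0 and y[lo - 1] > level:
        lo -= 1
    hi = i
    while hi < len(y) - 1 and y[hi + 1] > level:
        hi += 1
    w = y[lo:hi + 1] - level
    if w.sum() <= 0:
        raise NoEdgeError(f"window {window.name} has no peak")
    return float((r[lo:hi + 1] * w).sum() / w.sum())


def radius_shift(profile_a: RadialProfile, profile_b: RadialProfile,
                 window: LayerWindow, statistic: str = "outer") -> float:
    """Radius difference (nm) of the layer in ``window``: a minus b.

    ``statistic='outer'`` compares outer half-max edges (the convention for
    the spike-edge reading); ``'max'`` takes the largest of the outer-edge,
    peak-centroid and inner-edge shifts by magnitude (the membrane-region
    reading, where the contraction is quoted as a maximum).  Antisymmetric:
    swapping the profiles flips the sign exactly.
    """
    if statistic == "outer":
        return edge_position(profile_a, window) - edge_position(profile_b, window)
    if statistic == "max":
        shifts = []
        for fn in (
            lambda p: edge_position(p, window, "outer"),
            lambda p: peak_position(p, window),
            lambda p: edge_position(p, window, "inner"),
        ):
            shifts.append(fn(profile_a) - fn(profile_b))
        return float(shifts[int(np.argmax(np.abs(shifts)))])
    raise MorphometryError(f"unknown statistic {statistic!r}")


def layer_width(profile: RadialProfile, window: LayerWindow) -> float:
    """Full width at half maximum (nm) of the layer envelope in ``window``."""
    sl = profile.window_slice(window)
    r, y = profile.radii[sl], profile.density[sl]
    i_peak = int(np.argmax(y))
    base = float(y.min())
    peak = float(y[i_peak])
    if peak - base < 1e-9:
        raise NoEdgeError(f"window {window.name} contains no layer")
    level = base + 0.5 * (peak - base)
    outer = _flank_crossing(r, y, i_peak, level, +1)
    inner = _flank_crossing(r, y, i_peak, level, -1)
    return outer - inner


# ---------------------------------------------------------------------------
# whole-particle measurements


def vertex_diameter(volume: DensityVolume, axis: tuple | None = None) -> float:
    """Capsid edge-to-edge distance (nm) along a 5-fold axis, spikes excluded.

    If ``axis`` is not given it is taken from the volume metadata, else
    recovered as the direction of the farthest above-half-maximum capsid
    density (the vertices are the most distal capsid points of a faceted
    shell).  The edge on each side is the outermost half-maximum crossing of
    the capsid plateau along the axial line profile; thin low-density spike
    protrusions stay below the half level and are ignored.
    """
    if axis is None:
        axis = volume.meta.get("vertex_axis")
    data = volume.data
    vox = volume.voxel_nm
    n = data.shape[0]
    c = (n - 1) / 2.0
    if axis is None:
        thr = 0.5 * float(np.percentile(data, 99.99))
        zz, yy, xx = np.nonzero(data > thr)
        if len(zz) == 0:
            raise MorphometryError("no capsid density found")
        r2 = (xx - c) ** 2 + (yy - c) ** 2 + (zz - c) ** 2
        seed_dir = np.array(
            [xx[np.argmax(r2)] - c, yy[np.argmax(r2)] - c, zz[np.argmax(r2)] - c]
        )
        seed_dir /= np.linalg.norm(seed_dir)
        # refine over the distal voxels inside a 15-degree cone of the seed
        # (all twelve 5-fold vertices are distal; the cone isolates one)
        vecs = np.stack([xx - c, yy - c, zz - c], axis=1)
        norms = np.sqrt(r2)
        distal = norms > 0.95 * norms.max()
        cone = (vecs @ seed_dir) / np.maximum(norms, 1e-9) > math.cos(
            math.radians(15)
        )
        pick = distal & cone
        if not np.any(pick):
            raise MorphometryError(
                "orientation search failed; best score "
                f"r={norms.max() * vox:.1f} nm"
            )
        direction = vecs[pick].mean(axis=0)
        axis = direction / np.linalg.norm(direction)
    axis = np.asarray(axis, dtype=float)
    axis /= np.linalg.norm(axis)

    tmax = c * vox
    t = np.arange(0.0, tmax, vox / 2.0)

    def edge_along(sign: float) -> float:
        pts = c + sign * np.outer(t / vox, axis[::-1])  # (z, y, x) order
        line = ndimage.map_coordinates(data, pts.T, order=1)
        peak = float(line.max())
        if peak <= 0:
            raise MorphometryError("empty line profile along axis")
        level = 0.5 * peak
        above = np.nonzero(line >= level)[0]
        i = int(above[-1])
        if i + 1 >= len(line):
            raise MorphometryError("capsid edge touches the volume boundary")
        return _parabolic_crossing(t, line, i, level)

    return edge_along(+1.0) + edge_along(-1.0)


def membrane_gap(profile_or_volume, membrane_window: LayerWindow | None = None
                 ) -> float:
    """Distance (nm) between the membrane inner half-max edge and the
    nucleoid outer half-max edge.

    Requires a nucleoid (s-Full/Full); raises :class:`MorphometryError` for
    DNA-free particles.  Returns 0 when membrane and nucleoid are in contact
    (no valley between them falls below half the nucleoid level).
    """
    profile = (
        radial_profile(profile_or_volume)
        if isinstance(profile_or_volume, DensityVolume)
        else profile_or_volume
    )
    if membrane_window is None:
        membrane_window = layer_windows()["membrane"]
    sl = profile.window_slice(membrane_window)
    y_m = profile.density[sl]
    i_peak_global = sl.start + int(np.argmax(y_m))
    r_all, y_all = profile.radii, profile.density
    r_peak = r_all[i_peak_global]

    core = (r_all > 0.3 * r_peak) & (r_all < 0.7 * r_peak)
    nuc_level = float(np.median(y_all[core]))
    mem_peak = float(y_all[i_peak_global])
    if nuc_level < 0.1 * mem_peak:
        raise MorphometryError("no nucleoid present; membrane gap undefined")

    between = slice(int(np.searchsorted(r_all, 0.7 * r_peak)), i_peak_global)
    if between.stop <= between.start:
        return 0.0
    vmin = float(y_all[between].min())
    if vmin > 0.5 * nuc_level:
        return 0.0  # membrane sits directly on the nucleoid
    i_valley = between.start + int(np.argmin(y_all[between]))
    # half-maximum edges relative to the zero background (the layer tails
    # overlap slightly at small gaps; referencing the valley would bias
    # both edges outward/inward)
    r_mem_in = _flank_crossing(r_all, y_all, i_peak_global, 0.5 * mem_peak, -1)
    i_core = int(np.searchsorted(r_all, 0.5 * r_peak))
    seg = slice(i_core, i_valley + 1)
    rn, yn = r_all[seg], y_all[seg]
    r_nuc_out = _flank_crossing(rn, yn, int(np.argmax(yn)), 0.5 * nuc_level, +1)
    return max(0.0, r_mem_in - r_nuc_out)


# ---------------------------------------------------------------------------
# membrane openings


def detect_openings(
    source: SectionImage | DensityVolume,
    radial_window: LayerWindow | None = None,
    min_arc_deg: float = 10.0,
    threshold: float = 0.5,
    angle_step_deg: float = 1.0,
    smooth_deg: float = 3.0,
) -> list[tuple[float, float]]:
    """Angular occupancy scan of the membrane ring in a central section.

    Returns a list of ``(start_deg, extent_deg)`` arcs where the ring density
    falls below ``threshold`` times its median level for at least
    ``min_arc_deg``.  Raises :class:`MorphometryError` when no membrane ring
    is detectable.
    """
    if isinstance(source, DensityVolume):
        from .phantoms import render_section

        source = render_section(source, thickness_nm=source.voxel_nm)
    img = source.data.astype(np.float64)
    vox = source.pixel_nm
    if radial_window is None:
        radial_window = layer_windows()["membrane"]
    n = img.shape[0]
    c = (n - 1) / 2.0
    angles = np.arange(0.0, 360.0, angle_step_deg)
    radii = np.arange(radial_window.r_min, radial_window.r_max, vox / 2.0)
    th = np.radians(angles)
    xs = c + np.outer(np.cos(th), radii) / vox
    ys = c + np.outer(np.sin(th), radii) / vox
    prof = ndimage.map_coordinates(img, [ys.ravel(), xs.ravel()], order=1)
    occ = prof.reshape(len(angles), len(radii)).mean(axis=1)
    if smooth_deg > 0:
        occ = ndimage.gaussian_filter1d(occ, smooth_deg / angle_step_deg,
                                        mode="wrap")
    level = float(np.median(occ))
    if level <= 1e-6 * max(1.0, float(np.abs(img).max())):
        raise MorphometryError("no membrane ring detected in section")
    is_open = occ < threshold * level
    if is_open.all():
        raise MorphometryError("membrane ring below threshold everywhere")
    # merge wrap-around runs
    arcs = []
    padded = np.concatenate([is_open, is_open])
    i = int(np.argmin(padded))  # start scan at a closed angle
    j = i
    while j < i + len(angles):
        if padded[j]:
            j0 = j
            while j < i + len(angles) and padded[j]:
                j += 1
            extent = (j - j0) * angle_step_deg
            if extent >= min_arc_deg:
                arcs.append(((j0 % len(angles)) * angle_step_deg, extent))
        else:
            j += 1
    return arcs
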