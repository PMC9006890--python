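"""Voxelized layered-particle phantoms of the four maturation states.

A particle is modelled as nested layers (outside -> in): a spike layer, the
8-nm capsid shell, the 5.7-nm internal membrane, a ~3-nm gap, and the
nucleoid.  The interior state encodes the maturation stage:

* ``p-Empty`` - spongy low-density scaffold texture inside the membrane;
* ``Empty``   - vacant interior, membrane discontinued at 1-2 openings;
* ``s-Full``  - partial (crescent) nucleoid, membrane closed;
* ``Full``    - complete nucleoid, membrane closed.

Shell edges are antialiased with a Gaussian edge of width 0.7 voxel so that
subvoxel edge estimators behave; densities are relative units on a zero
background (cryo-EM-map-like contrast; sections can be stain-inverted).
Geometry defaults come from :mod:`capsidkit.presets`.  Lengths are nm,
voxel sizes Angstrom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq
from scipy.special import erf

from . import presets

__all__ = [
    "PhantomError",
    "PhantomSpec",
    "DensityVolume",
    "SectionImage",
    "make_phantom",
    "render_section",
    "phantom_spec",
]

# icosahedron inradius / circumradius (face-center over vertex distance):
# (sqrt(3)/12)(3+sqrt(5)) * edge/R with edge/R = 4/sqrt(10+2 sqrt(5))
_ICO_INRADIUS = (math.sqrt(3) * (3 + math.sqrt(5))) / (3 * math.sqrt(10 + 2 * math.sqrt(5)))


class PhantomError(ValueError):
    """Invalid phantom specification or resolution."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric layered-particle geometry (nm; densities relative)."""

    particle_type: str
    capsid_outer_radius: float
    capsid_thickness: float = presets.CAPSID_THICKNESS
    membrane_outer_radius: float = 106.0
    membrane_thickness: float = presets.MEMBRANE_THICKNESS
    membrane_gap: float = presets.MEMBRANE_GAP
    nucleoid_fill_fraction: float = 0.0
    n_openings: int = 0
    opening_arc_deg: float = presets.OPENING_ARC_DEG
    spike_length: float = presets.SPIKE_LENGTH
    spongy: bool = False
    spongy_correlation_nm: float = presets.SPONGY_CORRELATION_NM
    densities: dict = field(default_factory=lambda: dict(presets.DENSITIES))

    def __post_init__(self) -> None:
        r = self.radii
        order = (r["nucleoid"], r["membrane_inner"], r["membrane_outer"],
                 r["capsid_inner"], r["capsid_outer"], r["spike_tip"])
        # nucleoid may touch the membrane (gap 0); all other layers strict
        if r["nucleoid"] > r["membrane_inner"] or not all(
            a < b for a, b in zip(order[1:], order[2:])
        ):
            raise PhantomError(f"layer radii are not nested: {r}")
        if not 0 <= self.nucleoid_fill_fraction <= 1:
            raise PhantomError("nucleoid_fill_fraction must lie in [0, 1]")
        if self.n_openings not in (0, 1, 2):
            raise PhantomError("n_openings must be 0, 1, or 2")
        if self.n_openings and self.nucleoid_fill_fraction > 0:
            raise PhantomError("membrane openings only occur in DNA-free particles")

    @property
    def radii(self) -> dict:
        c_in = self.capsid_outer_radius - self.capsid_thickness
        m_in = self.membrane_outer_radius - self.membrane_thickness
        return {
            "nucleoid": m_in - self.membrane_gap,
            "membrane_inner": m_in,
            "membrane_outer": self.membrane_outer_radius,
            "capsid_inner": c_in,
            "capsid_outer": self.capsid_outer_radius,
            "spike_tip": self.capsid_outer_radius + self.spike_length,
        }

    def analytic_integral(self) -> float:
        """Total density integral (density * nm^3) of the nominal geometry."""
        r, d = self.radii, self.densities

        def ball(radius: float) -> float:
            return 4.0 / 3.0 * math.pi * radius**3

        total = d["capsid"] * (ball(r["capsid_outer"]) - ball(r["capsid_inner"]))
        total += d["spike_layer"] * (ball(r["spike_tip"]) - ball(r["capsid_outer"]))
        mem = d["membrane"] * (ball(r["membrane_outer"]) - ball(r["membrane_inner"]))
        if self.n_openings:
            cap = 2 * math.pi * (1 - math.cos(math.radians(self.opening_arc_deg / 2)))
            mem *= 1.0 - self.n_openings * cap / (4 * math.pi)
        total += mem
        total += (d["nucleoid"] * self.nucleoid_fill_fraction * ball(r["nucleoid"]))
        if self.spongy:
            total += d["spongy_mean"] * ball(r["membrane_inner"] - 1.0)
        return total


def phantom_spec(particle_type: str, **overrides) -> PhantomSpec:
    """Preset PhantomSpec for one of p-Empty / Empty / s-Full / Full."""
    try:
        geo = presets.PRESET_GEOMETRY[particle_type]
    except KeyError:
        raise PhantomError(
            f"unknown particle type {particle_type!r}; expected one of "
            f"{presets.PARTICLE_TYPES}"
        ) from None
    kwargs = dict(particle_type=particle_type, **geo)
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


@dataclass
class DensityVolume:
    """Cubic voxel grid of relative density, origin at the particle center.

    ``data`` is indexed ``[z, y, x]``; voxel (i, j, k) sits at
    ``(index - (n - 1) / 2) * voxel_size`` along each axis.
    """

    data: np.ndarray
    voxel_size: float  # Angstrom
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise PhantomError("voxel_size must be positive")
        if self.data.ndim != 3 or len(set(self.data.shape)) != 1:
            raise PhantomError("density grid must be cubic")
        if not np.isfinite(self.data).all():
            raise PhantomError("density grid contains non-finite values")

    @property
    def voxel_nm(self) -> float:
        return self.voxel_size / 10.0

    def axis_coords_nm(self) -> np.ndarray:
        n = self.data.shape[0]
        return (np.arange(n) - (n - 1) / 2.0) * self.voxel_nm

    def integral(self) -> float:
        """Total density * nm^3."""
        return float(self.data.sum(dtype=np.float64)) * self.voxel_nm**3


@dataclass
class SectionImage:
    """Slab-projected 2D image (units: density * nm per pixel)."""

    data: np.ndarray
    pixel_size: float  # Angstrom
    thickness_nm: float
    offset_nm: float = 0.0
    empty: bool = False
    true_type: str | None = None
    meta: dict = field(default_factory=dict)

    @property
    def pixel_nm(self) -> float:
        return self.pixel_size / 10.0


# ---------------------------------------------------------------------------
# construction helpers


def _smooth_shell(r, r_in, r_out, density, sigma):
    s = math.sqrt(2.0) * sigma
    inner = erf((r - r_in) / s) if r_in > 0 else 2.0 * np.ones_like(r) - 1.0
    return density * 0.5 * ((inner + 1.0) - (erf((r - r_out) / s) + 1.0))


def _cap_plane_offset(fill: float) -> float:
    """Plane position c in [-1, 1] such that the unit-sphere volume with
    coordinate > c equals ``fill`` of the total."""
    if fill >= 1.0:
        return -1.0
    if fill <= 0.0:
        return 1.0
    return brentq(lambda c: (1 - c) ** 2 * (2 + c) / 4.0 - fill, -1.0, 1.0)


def _ico_normals() -> np.ndarray:
    from .lattice import icosahedron_vertices

    v, faces = icosahedron_vertices()
    n = np.array([np.cross(v[b] - v[a], v[c] - v[a]) for a, b, c in faces])
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    return n


def make_phantom(
    spec: PhantomSpec,
    voxel_size: float = 10.0,
    seed: int = 0,
    faceted: bool = False,
    decorate_spikes: bool = False,
    pad_nm: float = 6.0,
) -> DensityVolume:
    """Voxelize a particle phantom.

    ``faceted=True`` replaces the spherical shells by icosahedral ones whose
    capsid outer edge sits at the preset vertex radius (130 nm) on the 5-fold
    axes, with one vertex on +z; layer spacings are preserved.
    ``decorate_spikes`` adds explicit spike heads at the capsomer lattice
    sites (wide/long classes from the (7,12) lattice); the default represents
    the rotationally averaged spike layer as a thin shell instead.

    Deterministic for a fixed (spec, seed, voxel_size).
    """
    vox = voxel_size / 10.0  # nm
    if spec.capsid_thickness < 3 * vox:
        raise PhantomError(
            f"voxel too coarse: capsid thickness {spec.capsid_thickness} nm "
            f"spans < 3 voxels at {voxel_size} A"
        )
    rng = np.random.default_rng(seed)
    r = spec.radii
    sigma = 0.7 * vox  # antialias edge width
    shift = presets.VERTEX_RADIUS - spec.capsid_outer_radius if faceted else 0.0
    rmax = r["spike_tip"] + shift + pad_nm
    half = int(math.ceil(rmax / vox))
    n = 2 * half + 1
    coords = (np.arange(n) - half) * vox

    fine = np.arange(0.0, rmax + 4 * vox, vox / 4.0)
    d = spec.densities
    profile = np.zeros_like(fine)
    if spec.nucleoid_fill_fraction > 0:
        profile += _smooth_shell(fine, 0.0, r["nucleoid"], d["nucleoid"], sigma)
    profile += _smooth_shell(
        fine, r["membrane_inner"], r["membrane_outer"], d["membrane"], sigma
    )
    profile += _smooth_shell(
        fine, r["capsid_inner"], r["capsid_outer"], d["capsid"], sigma
    )
    profile += _smooth_shell(
        fine, r["capsid_outer"], r["spike_tip"], d["spike_layer"], sigma
    )

    normals = _ico_normals() if faceted else None
    cos_open = math.cos(math.radians(spec.opening_arc_deg / 2.0))
    # opening axes and crescent normal live in the equatorial plane so that a
    # central section reveals them; azimuths are seed-controlled
    azimuths = rng.uniform(0.0, 2 * math.pi, size=3)
    open_axes = []
    if spec.n_openings >= 1:
        open_axes.append((math.cos(azimuths[0]), math.sin(azimuths[0]), 0.0))
    if spec.n_openings == 2:
        a2 = azimuths[0] + math.pi + rng.uniform(-0.5, 0.5)
        open_axes.append((math.cos(a2), math.sin(a2), 0.0))
    crescent_axis = np.array([math.cos(azimuths[1]), math.sin(azimuths[1]), 0.0])
    c0 = _cap_plane_offset(spec.nucleoid_fill_fraction)

    data = np.empty((n, n, n), dtype=np.float32)
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    yy = yy.astype(np.float32)
    xx = xx.astype(np.float32)
    rho2 = xx * xx + yy * yy
    for iz, z in enumerate(coords):
        if faceted:
            pts = np.stack(
                [xx.ravel(), yy.ravel(), np.full(xx.size, z, np.float32)], axis=1
            )
            s = (pts @ normals.T.astype(np.float32)).max(axis=1)
            rr = (s / _ICO_INRADIUS).reshape(xx.shape) - shift
            rr = np.maximum(rr, 0.0)
        else:
            rr = np.sqrt(rho2 + z * z)
        plane = np.interp(rr, fine, profile).astype(np.float32)

        if open_axes:
            rad = np.sqrt(rho2 + z * z)
            with np.errstate(invalid="ignore", divide="ignore"):
                for ax, ay, _az in open_axes:
                    cosang = (xx * ax + yy * ay) / np.maximum(rad, 1e-6)
                    mask = (
                        (cosang > cos_open)
                        & (rr > r["membrane_inner"] - 2 * sigma)
                        & (rr < r["membrane_outer"] + 2 * sigma)
                    )
                    plane[mask] = 0.0
        if 0.0 < spec.nucleoid_fill_fraction < 1.0:
            dot = (xx * crescent_axis[0] + yy * crescent_axis[1]) / max(
                r["nucleoid"], 1e-6
            )
            mask = (rr < r["nucleoid"]) & (dot < c0)
            plane[mask] = 0.0
        data[iz] = plane

    if spec.spongy:
        interior = r["membrane_inner"] - 1.0
        noise = rng.standard_normal((n, n, n)).astype(np.float32)
        s_vox = (spec.spongy_correlation_nm / 2.355) / vox
        gaussian_filter(noise, s_vox, output=noise, mode="nearest")
        noise /= max(noise.std(), 1e-12)
        mean = d["spongy_mean"]
        tex = np.clip(mean + presets.SPONGY_REL_STD * mean * noise, 0.0, None)
        zz = coords[:, None, None].astype(np.float32)
        rad3 = np.sqrt(rho2[None, :, :] + zz * zz)
        w = 0.5 * (1.0 - erf((rad3 - interior) / (math.sqrt(2) * sigma)))
        data += (tex * w).astype(np.float32)

    if decorate_spikes:
        _decorate_spikes(data, coords, spec, shift, vox)

    meta = dict(
        particle_type=spec.particle_type,
        seed=int(seed),
        faceted=faceted,
        spec=spec,
        opening_axes=open_axes,
        crescent_axis=tuple(map(float, crescent_axis)),
        vertex_axis=(0.0, 0.0, 1.0) if faceted else None,
    )
    return DensityVolume(data=data, voxel_size=voxel_size, meta=meta)


def _decorate_spikes(data, coords, spec, shift, vox):
    """Add explicit spherical spike heads at the capsomer lattice sites."""
    from .lattice import assign_spikes, build_lattice, decompose_symmetrons

    lat = decompose_symmetrons(build_lattice((7, 12)))
    assign_spikes(lat)
    base = spec.capsid_outer_radius + shift
    n = data.shape[0]
    half = (n - 1) // 2
    dens = spec.densities["capsid"]
    for s in lat.sites:
        if s.spike_class in (None, "none"):
            continue
        length = (
            presets.LONG_SPIKE_LENGTH
            if s.spike_class == "long"
            else spec.spike_length
        )
        head_r = 4.5 if s.spike_class in ("wide", "long") else 3.0
        center = s.xyz * (base + length - head_r)
        ci = np.round(center / vox).astype(int) + half
        w = int(math.ceil(head_r / vox)) + 1
        sl = tuple(slice(max(0, c - w), min(n, c + w + 1)) for c in ci[::-1])
        zs, ys, xs = np.meshgrid(
            coords[sl[0]], coords[sl[1]], coords[sl[2]], indexing="ij"
        )
        ball = (
            (xs - center[0]) ** 2 + (ys - center[1]) ** 2 + (zs - center[2]) ** 2
        ) < head_r**2
        region = data[sl]
        region[ball] = np.maximum(region[ball], dens)


# ---------------------------------------------------------------------------
# sectioning


def slab_weights(volume: DensityVolume, thickness_nm: float, offset_nm: float
                 ) -> np.ndarray:
    """Per-slice integration weights (nm) of a z-slab through the volume."""
    if thickness_nm <= 0:
        raise PhantomError("section thickness must be positive")
    vox = volume.voxel_nm
    z = volume.axis_coords_nm()
    lo, hi = offset_nm - thickness_nm / 2.0, offset_nm + thickness_nm / 2.0
    return np.clip(np.minimum(z + vox / 2, hi) - np.maximum(z - vox / 2, lo),
                   0.0, vox)


def render_section(
    volume: DensityVolume,
    thickness_nm: float = 70.0,
    offset_nm: float = 0.0,
    noise: dict | None = None,
    seed: int = 0,
    invert: bool = False,
) -> SectionImage:
    """Project a z-slab of the volume into a 2D section image.

    The image is the integral of density across the slab (density * nm).
    ``noise`` is a Poisson-Gaussian model ``{"dose": counts per density*nm,
    "gaussian_sigma": absolute}``; a slab that misses the volume entirely is
    returned flagged ``empty`` rather than raising.  ``invert=True`` produces
    stained-TEM-like contrast (dark particle on light background).
    """
    w = slab_weights(volume, thickness_nm, offset_nm)
    empty = not np.any(w > 0)
    img = np.tensordot(w.astype(np.float32), volume.data, axes=(0, 0))
    if noise is not None and not empty:
        rng = np.random.default_rng(seed)
        dose = float(noise.get("dose", presets.DEFAULT_NOISE["dose"]))
        sig = float(noise.get("gaussian_sigma",
                              presets.DEFAULT_NOISE["gaussian_sigma"]))
        img = rng.poisson(np.clip(img, 0, None) * dose).astype(np.float32) / dose
        img += rng.normal(0.0, sig, size=img.shape).astype(np.float32)
    if invert:
        img = float(img.max()) - img
    return SectionImage(
        data=img.astype(np.float32),
        pixel_size=volume.voxel_size,
        thickness_nm=thickness_nm,
        offset_nm=offset_nm,
        empty=empty,
        true_type=volume.meta.get("particle_type"),
        meta=dict(seed=int(seed), noise=noise, invert=invert),
    )
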