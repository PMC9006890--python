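"""Cell-scene synthesis: nucleus + cytoplasm + placed particles.

A scene is a 2D thin section through an infected cell, modelled as a
circular nucleus of radius ``a`` inside a circular cell.  Particles of the
four maturation states are placed in the cytoplasm under a controllable
placement model:

* ``uniform``  - uniform per unit area of the section plane (the random
  null: counts in equal-width distance bins then grow linearly, in
  proportion to ``a + d``);
* ``shell``    - distances from the nuclear surface drawn from a truncated
  normal around ``d0`` (DNA-uptake-near-the-nucleus scenario).

Ground truth is exact: the returned records carry true type, position and
distance to the nuclear surface; the per-particle image crops are rendered
central sections of the type presets (micrograph-magnification views), while
the scene overview image is a coarse map of nucleus, cell boundary and
particle positions.  Everything is reproducible from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from . import presets
from .phantoms import PhantomError, make_phantom, phantom_spec, render_section

__all__ = [
    "SceneSpec",
    "ParticleRecord",
    "SceneSection",
    "PackingError",
    "make_scene",
    "records_to_frame",
    "simulate_maturation_records",
]

PARTICLE_RADIUS_UM = (presets.SPHERICAL_CAPSID_OUTER + presets.SPIKE_LENGTH) / 1000.0


class PackingError(ValueError):
    """Could not place the requested number of particles without overlap."""


@dataclass
class ParticleRecord:
    """One observed particle (the counting unit of the statistics)."""

    particle_id: int
    true_type: str
    assigned_type: str | None = None
    hpi: float | None = None
    distance_um: float = 0.0  # from the nuclear surface, in the section plane
    section_thickness_nm: float = 70.0
    scene_id: int | None = None
    x_um: float = 0.0
    y_um: float = 0.0

    def __post_init__(self) -> None:
        if self.distance_um < 0:
            raise ValueError("distance to the nuclear surface must be >= 0")
        valid = set(presets.PARTICLE_TYPES) | {"unknown"}
        if self.true_type not in valid:
            raise ValueError(f"unknown particle type {self.true_type!r}")


@dataclass(frozen=True)
class SceneSpec:
    """Scene geometry (um), per-type counts and placement model."""

    nucleus_radius_um: float = 5.0
    cell_radius_um: float = 15.0
    counts: dict = field(default_factory=lambda: {"Empty": 50, "Full": 10})
    placement: str = "uniform"  # "uniform" | "shell"
    shell_d0_um: float = 0.75
    shell_sigma_um: float = 0.15
    membrane_margin_um: float = 2.0
    max_distance_um: float | None = None  # observation window from nucleus
    section_thickness_nm: float = 70.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.nucleus_radius_um < self.cell_radius_um:
            raise ValueError("need 0 <= nucleus radius < cell radius")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be non-negative")
        if self.membrane_margin_um < 0:
            raise ValueError("margin must be >= 0")
        unknown = set(self.counts) - set(presets.PARTICLE_TYPES)
        if unknown:
            raise ValueError(f"unknown particle types {sorted(unknown)}")


@dataclass
class SceneSection:
    """A rendered scene: coarse overview + per-particle crops + truth."""

    image: np.ndarray  # coarse overview map
    pixel_size: float  # Angstrom, of the overview
    crops: list  # SectionImage per particle, micrograph magnification
    records: list  # ParticleRecord per particle
    spec: SceneSpec


def _sample_positions(spec: SceneSpec, n: int, rng: np.random.Generator
                      ) -> np.ndarray:
    # centers may sit on the nuclear surface (distance 0), so that the
    # uniform model yields the exact linear-in-distance null from d = 0
    a = spec.nucleus_radius_um
    r_lo = a
    r_hi = spec.cell_radius_um - spec.membrane_margin_um - PARTICLE_RADIUS_UM
    if spec.max_distance_um is not None:
        r_hi = min(r_hi, a + spec.max_distance_um)
    if r_hi <= r_lo:
        raise PhantomError("cytoplasm annulus is empty under these margins")
    if spec.placement == "uniform":
        r = np.sqrt(rng.uniform(r_lo**2, r_hi**2, size=n))
    elif spec.placement == "shell":
        r = np.empty(n)
        got = 0
        while got < n:
            d = rng.normal(spec.shell_d0_um, spec.shell_sigma_um, size=2 * n)
            d = d[(d >= r_lo - a) & (d <= r_hi - a)]
            take = min(len(d), n - got)
            r[got:got + take] = a + d[:take]
            got += take
    else:
        raise ValueError(f"unknown placement model {spec.placement!r}")
    theta = rng.uniform(0, 2 * math.pi, size=n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def make_scene(
    spec: SceneSpec,
    crop_voxel_size: float = 20.0,
    noise: dict | None = None,
    overview_pixel_um: float = 0.05,
    min_separation_um: float = 0.3,
    max_retries: int = 200,
) -> SceneSection:
    """Place particles in the cytoplasm and render the scene.

    Positions are rejection-sampled against a minimum separation; a
    :class:`PackingError` names the count reached if packing fails.  Crops
    are central sections of the per-type phantom presets (optionally noisy,
    seeded per particle); ground-truth type counts equal the spec exactly.
    """
    rng = np.random.default_rng(spec.seed)
    order = [t for t in presets.PARTICLE_TYPES for _ in range(spec.counts.get(t, 0))]
    n = len(order)
    # dart-throwing: place one particle at a time with bounded retries
    placed_list: list[np.ndarray] = []
    for i in range(n):
        for _ in range(max_retries):
            p = _sample_positions(spec, 1, rng)[0]
            if min_separation_um <= 0 or not placed_list or (
                np.min(np.linalg.norm(np.array(placed_list) - p, axis=1))
                >= min_separation_um
            ):
                placed_list.append(p)
                break
        else:
            raise PackingError(
                f"placed only {len(placed_list)} of {n} particles at "
                f"separation {min_separation_um} um after {max_retries} "
                "attempts each"
            )
    placed = np.array(placed_list) if placed_list else np.empty((0, 2))

    a = spec.nucleus_radius_um
    records = []
    for i, t in enumerate(order):
        x, y = placed[i] if n else (0.0, 0.0)
        records.append(
            ParticleRecord(
                particle_id=i,
                true_type=t,
                distance_um=float(math.hypot(x, y) - a),
                section_thickness_nm=spec.section_thickness_nm,
                scene_id=spec.seed,
                x_um=float(x),
                y_um=float(y),
            )
        )

    # per-type template volumes, one render per particle (noise per seed)
    vols = {
        t: make_phantom(phantom_spec(t), voxel_size=crop_voxel_size,
                        seed=spec.seed + 17 * presets.PARTICLE_TYPES.index(t))
        for t in set(order)
    }
    crops = []
    for rec in records:
        crops.append(
            render_section(
                vols[rec.true_type],
                thickness_nm=spec.section_thickness_nm,
                noise=noise,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )

    # coarse overview: nucleus disk, cell boundary, particle dots
    npx = int(2 * spec.cell_radius_um / overview_pixel_um) + 1
    c = (npx - 1) / 2.0
    yy, xx = np.ogrid[:npx, :npx]
    r_um = np.hypot(yy - c, xx - c) * overview_pixel_um
    img = np.zeros((npx, npx), dtype=np.float32)
    img[r_um < a] = 0.5
    img[np.abs(r_um - spec.cell_radius_um) < overview_pixel_um] = 0.8
    for rec in records:
        ix = int(round(rec.x_um / overview_pixel_um + c))
        iy = int(round(rec.y_um / overview_pixel_um + c))
        if 0 <= iy < npx and 0 <= ix < npx:
            img[iy, ix] = 1.0
    return SceneSection(
        image=img,
        pixel_size=overview_pixel_um * 1e4,
        crops=crops,
        records=records,
        spec=spec,
    )


def records_to_frame(records):
    """Records as a pandas DataFrame (CSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        [
            dict(
                particle_id=r.particle_id,
                true_type=r.true_type,
                assigned_type=r.assigned_type,
                hpi=r.hpi,
                distance_um=r.distance_um,
                section_thickness_nm=r.section_thickness_nm,
                scene_id=r.scene_id,
                x_um=r.x_um,
                y_um=r.y_um,
            )
            for r in records
        ]
    )


def simulate_maturation_records(
    n_particles: int,
    hpi_points,
    rates=(0.6, 0.25, 0.5),
    seed: int = 0,
):
    """Sample particle types along the maturation chain
    p-Empty -> Empty -> s-Full -> Full (first-order rates per hour).

    A cohort of capsids born at t=0 evolves by the continuous-time Markov
    chain with the given conversion rates; at each requested time point a
    fresh multinomial sample of ``n_particles`` is drawn from the state
    distribution.  Returns a list of :class:`ParticleRecord`.
    """
    k1, k2, k3 = rates
    Q = np.array(
        [
            [-k1, k1, 0.0, 0.0],
            [0.0, -k2, k2, 0.0],
            [0.0, 0.0, -k3, k3],
            [0.0, 0.0, 0.0, 0.0],
        ]
    )
    order = ("p-Empty", "Empty", "s-Full", "Full")
    rng = np.random.default_rng(seed)
    records = []
    pid = 0
    for t in hpi_points:
        probs = np.clip(expm(Q * float(t))[0], 0, None)
        probs /= probs.sum()
        counts = rng.multinomial(n_particles, probs)
        for typ, cnt in zip(order, counts):
            for _ in range(cnt):
                records.append(
                    ParticleRecord(particle_id=pid, true_type=typ, hpi=float(t))
                )
                pid += 1
    return records
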