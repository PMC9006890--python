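"""Geometry preset tables for the four medusavirus maturation states.

These tables are the single source of truth for phantom generation and for
the layer windows used by the morphometry round-trip tests.  All lengths are
nanometres; densities are relative (protein/DNA positive on zero background).

Measured geometry encoded here: a 260-nm vertex-to-vertex capsid diameter,
an 8-nm single-layer capsid, a 5.7-nm internal lipid bilayer, a ~3-nm gap
between membrane and nucleoid, 13-nm regular/wide spikes and 27-nm long
spikes, and the Full-particle contraction relative to Empty: 0.8 nm at the
capsid/spike edge and 1.6 nm at the internal membrane.  (One source states
14 nm for the regular spike length and another 13 nm; the tables use 13 nm.)

The spherical-approximation presets place the capsid outer edge at 115 nm,
between the faceted-shell inradius (103.3 nm) and the 130-nm vertex radius;
the faceted presets use the vertex radius so the 5-fold diameter is 260 nm.
"""

from __future__ import annotations

CAPSID_THICKNESS = 8.0
MEMBRANE_THICKNESS = 5.7
MEMBRANE_GAP = 3.0
SPIKE_LENGTH = 13.0  # regular and wide spikes; long spikes are 27 nm
LONG_SPIKE_LENGTH = 27.0
VERTEX_RADIUS = 130.0  # capsid outer edge on the 5-fold axis (260 nm / 2)
SPHERICAL_CAPSID_OUTER = 115.0  # spherical-equivalent capsid outer radius

# Full-particle contraction relative to Empty
SPIKE_EDGE_CONTRACTION = 0.8
MEMBRANE_CONTRACTION = 1.6

DENSITIES = {
    "capsid": 1.0,
    "membrane": 0.9,
    "nucleoid": 0.8,
    "spike_layer": 0.25,  # rotationally averaged spike shell
    "spongy_mean": 0.2,  # 25% of nucleoid density
}

SPONGY_CORRELATION_NM = 20.0
SPONGY_REL_STD = 0.5  # texture std relative to its mean

#: per-type geometry; radii are outer edges in the spherical approximation
PRESET_GEOMETRY = {
    "Empty": dict(
        capsid_outer_radius=SPHERICAL_CAPSID_OUTER,
        membrane_outer_radius=105.5,
        nucleoid_fill_fraction=0.0,
        n_openings=2,
        spongy=False,
    ),
    "p-Empty": dict(
        capsid_outer_radius=SPHERICAL_CAPSID_OUTER,
        membrane_outer_radius=105.5,
        nucleoid_fill_fraction=0.0,
        n_openings=1,
        spongy=True,
    ),
    "Full": dict(
        capsid_outer_radius=SPHERICAL_CAPSID_OUTER - SPIKE_EDGE_CONTRACTION,
        membrane_outer_radius=105.5 - MEMBRANE_CONTRACTION,
        nucleoid_fill_fraction=1.0,
        n_openings=0,
        spongy=False,
    ),
    "s-Full": dict(
        capsid_outer_radius=SPHERICAL_CAPSID_OUTER - SPIKE_EDGE_CONTRACTION,
        membrane_outer_radius=105.5 - MEMBRANE_CONTRACTION,
        nucleoid_fill_fraction=0.5,
        n_openings=0,
        spongy=False,
    ),
}

PARTICLE_TYPES = ("p-Empty", "Empty", "s-Full", "Full")

#: radial analysis windows (nm), wide enough to cover both Empty and Full
LAYER_WINDOWS = {
    "spike-edge": (118.5, 136.0),
    "capsid": (106.3, 118.5),
    "membrane": (92.0, 106.6),
    "nucleoid": (40.0, 96.9),
}

OPENING_ARC_DEG = 30.0  # not measured; free parameter of the generator
DEFAULT_NOISE = dict(dose=2.0, gaussian_sigma=0.5)  # stated section dose
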