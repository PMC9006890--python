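# Methods

This note records the models, conventions and free parameters behind
`capsidkit`, in the package's own words: what is simulated, how each
quantity is measured, and which choices were genuinely open.

## Lattice geometry

A Caspar–Klug lattice (h, k) is enumerated per icosahedron face as the
integer hexagonal lattice points inside the triangle with corners 0,
h·a₁+k·a₂ and its 60° rotation, mapped to the face by barycentric
coordinates and centrally projected to the unit sphere; duplicate sites on
shared edges/vertices are welded (10⁻⁶ tolerance on unit-sphere
coordinates). Handedness: k counts counterclockwise from h viewed from
outside; the mirror lattice (k, h) has the same T and counts, so only
labels, not counts, depend on this choice.

**Symmetron decomposition.** The pentasymmetron of a penton is the penton
plus every trimer within lattice graph distance P of it, with

- P = (h−1)/2 for odd h, else (k−1)/2 for odd k,
- trisymmetron edge s = (the other index) + P.

The identity 30·P(P+1) + 10·s(s+1) = 10(T−1) holds algebraically, so the
decomposition is exhaustive: each pentasymmetron has 5 asymmetric units of
P(P+1)/2 trimers, each trisymmetron s(s+1)/2. For (7,12) this gives P = 3
(six capsomers P₁…P₆ per unit, pentasymmetron 30+1) and s = 15
(trisymmetron 120) — the same decomposition known for other T = 277
capsids. Lattices with h and k both even admit no such decomposition under
this convention and raise a documented error. Remaining sites are assigned
to the trisymmetron of the nearest 3-fold axis; this is exact because the
geodesic Voronoi cell of a face centre is the face itself. Sites
equidistant between symmetrons go to the pentasymmetron, and boundary ties
between faces to the smaller face index (deterministic).

**Labels and orientations.** Within each pentasymmetron the five asymmetric
units are the 72° sectors delimited by the ring-1 sites; labels P₁…P₆ run
ring by ring, by azimuth, which places the pentagon-corner trimer at P₄.
Orientation classes (three 60°-related values) are exact for trisymmetrons
(quantized angle of the face's lattice vector); for pentasymmetron units
they are a combinatorial labelling that encodes the known pattern — uniform
within a unit except the corner trimer — because sub-capsomer orientation
is below the resolution this package models.

**Spikes.** Wide spikes sit on P₃, P₆ and the trisymmetron site nearest P₆
(T_W); the long spike on the trisymmetron site nearest P₅ (T_L); nearness
is great-circle distance, sites are claimed greedily in (penton, sector)
order, ties broken by the smaller site id. This yields 3 wide + 1 long per
icosahedral asymmetric unit: 180 wide and 60 long per virion.

## Phantoms

Particles are nested spherical shells (or icosahedral shells in faceted
mode) with relative densities on a zero background: capsid 1.0, membrane
0.9, nucleoid 0.8, rotationally-averaged spike layer 0.25, spongy scaffold
mean 0.2 (25% of nucleoid). Preset geometry (nm): capsid outer edge 115
(spherical equivalent), thickness 8; membrane outer edge 105.5, thickness
5.7; membrane–nucleoid gap 3; spikes 13 (regular/wide) and 27 (long). The
Full/s-Full presets contract by 0.8 nm at the capsid/spike edge and 1.6 nm
at the membrane, so the Full membrane stands further off the capsid than
the Empty one. Two stated lengths for the regular spike exist (13 vs
14 nm); the presets use 13 nm.

Free choices, set once: the 115-nm spherical-equivalent capsid radius lies
between the faceted inradius (103.3 nm) and the 130-nm vertex radius — only
the vertex diameter (260 nm) and layer spacings are measured quantities, so
the spherical radius is a package convention. Faceted mode anchors the
capsid outer edge at the 130-nm vertex radius with one 5-fold vertex on +z
and preserves all layer spacings. Membrane standoff from the capsid
(1.5 nm in Empty) is likewise a convention; only its Empty→Full increase is
an encoded observation.

Interior states: Full = complete nucleoid ball; s-Full = nucleoid cut by a
plane whose cap volume equals the fill fraction (default 0.5), cut normal
in the equatorial plane; Empty = vacant with 1–2 membrane openings
(30°-wide cones, axes in the equatorial plane so central sections reveal
them — the arc width is not a measured value); p-Empty = spongy texture
(Gaussian-correlated noise, 20-nm correlation length, std = 50% of its
mean, clipped at zero) with one opening. Shell edges are antialiased with a
Gaussian edge of 0.7 voxel so subvoxel estimators are well behaved. Volumes
are deterministic in (spec, seed, voxel size).

Sections integrate density across a z-slab with partial-voxel weights
(units: density·nm); the noise model is Poisson–Gaussian with a stated dose
of 2.0 counts per density·nm and additive σ = 0.5 — a moderate-SNR regime
in which the four states remain distinguishable by eye, as they are in real
micrographs. A stain-inverted toggle produces dark-on-light contrast.

Cell scenes place particles in the cytoplasmic annulus between the nucleus
(default radius 5 µm) and the cell boundary (15 µm) minus a 2-µm membrane
margin, by dart throwing with a 0.3-µm minimum separation. Placement models:
`uniform` (per unit area — centers may touch the nuclear surface so the
linear null holds exactly from d = 0) and `shell` (truncated normal around
d₀ = 0.75 µm, σ = 0.15 µm). The overview image is a coarse map; per-particle
evidence is a rendered central section per particle (micrograph
magnification), which is what the classifier consumes.

## Morphometry

Radial profiles average density in one-voxel shells (3D) or annuli (2D),
streamed slice-wise so 500³ grids stay within memory. Layer edges are
half-maximum crossings *anchored at the layer's peak* and refined by
3-point parabolic interpolation; the same convention is applied to both
profiles of a shift measurement, which makes inter-profile shifts
well-defined even though the original readings' convention was not stated.
"Maximum shift over the membrane window" is the largest-magnitude of the
outer-edge, peak-centroid and inner-edge shifts. Layer width is FWHM with
the window minimum as baseline. The membrane–nucleoid gap is the distance
from the membrane's inner half-max edge to the nucleoid's outer half-max
edge, each referenced to the zero background (valley-referenced levels bias
both edges when the tails overlap at small gaps); membrane in contact with
the nucleoid returns 0. The vertex diameter is the distance between the
outermost half-maximum crossings of the capsid plateau along a 5-fold axis;
if the orientation is unknown, the axis is recovered from the most distal
above-half-maximum density (a 15° cone isolates one vertex among twelve).
Membrane openings are contiguous sub-threshold arcs (≥10°, threshold 50% of
the ring median) in a 1°-resolution angular occupancy scan of the membrane
ring.

Accuracy: at 5-Å voxels the preset round-trips recover 0.8/1.6-nm shifts to
±0.02–0.05 nm, the 5.7-nm FWHM to ±0.01 nm and the 3.0-nm gap to
±0.01 nm; 10-Å voxels suffice for everything except the 0.8-nm shift class;
20-Å voxels are adequate only for classification, not edge metrology.

## Particle typing

Features from a centered crop: the particle boundary radius (outermost
radius where the rotational profile reaches 35% of its robust maximum — a
peak search fails on off-center slabs whose interior dome exceeds the rim);
ring detectability (rim peak against 5× the background MAD); occupancy
(fraction of deep-interior pixels, r < 0.45 × boundary radius, above 0.45 ×
the 95th-percentile rim signal); texture (excess band-passed standard
deviation of a further-eroded interior disk over the background, normalized
by the rim signal, filter matched to the 20-nm spongy correlation length);
and the ring-normalized interior mean.

Rule: unknown if ring detectability is low *or* the boundary radius falls
below 97% of the expected capsid radius — beyond that grazing point the
slab misses the particle equator and shell caps project into the interior,
which is also why deep-offset Empty profiles look dense in real sections;
otherwise Full if occupancy ≥ 0.9, s-Full if ≥ 0.15, else p-Empty if
texture ≥ τ, else Empty. The occupancy cutoffs are the rule's defaults;
τ = 0.015 is the midpoint between the Empty and p-Empty preset score
distributions (Otsu-style two-class calibration; `fit` can recalibrate it
from labelled features). The underlying by-eye criteria were never
quantified, so all thresholds are surfaced as parameters.

`ParticleTypeClassifier` wraps the rule as a scikit-learn estimator
(`get_params`/`set_params`/`fit`/`predict`) so it composes with sklearn
tooling; `predict` is a pure function of the feature matrix.

## Statistics

Fractions are count/total × 100 rounded to one decimal. The placement null:
uniform-per-area placement outside a circular nucleus of radius a gives
expected bin counts ∝ a·Δd + Δ(d²)/2 — linear growth with distance; a → ∞
recovers the flat-boundary limit. Goodness of fit is Pearson chi-square
per type over 0.5-µm bins on [0, 2) µm, α = 0.05, with deterministic
left-to-right merging of bins whose expectation falls below 1. Calibration:
under the null at n = 500 the test passes (p > 0.05) in ~95% of replicates;
against shell-concentrated placement at n = 200 it rejects essentially
always.

The sectioning-bias simulator draws slab offsets uniformly over the full
intersection range (every visible profile is counted, as in real
micrographs of thin sections). Thin sections are classified from the slab
projection; sections at least as thick as the particle diameter are
classified *tomographically* — from the particle's central-most 10-nm slice
within the slab — because a 3D reconstruction of a thick section shows each
particle's interior directly, which is exactly why thick-section tomography
is the reference counting method. Unknowns (grazing geometries) are
excluded and the confusion renormalized over the four types, mirroring the
"unknown" category of real counts; with the grazing gate in place the
classified 70-nm confusion is nearly diagonal, with a small residue in the
emptier direction at the gate boundary, and misclassification never
hallucinates a full nucleoid in a DNA-free particle. Bias correction uses
non-negative least squares on the transposed confusion (a raw inverse can
produce negative fractions).

The maturation-trajectory simulator is a continuous-time Markov chain
p-Empty → Empty → s-Full → Full (default rates 0.6, 0.25, 0.5 per hour) —
a modelling convenience for testing monotone time courses, not an
estimate of real kinetics.

## What the synthetic data does and does not emulate

Phantoms reproduce layered geometry, interior states, membrane openings,
slab projection and shot/readout noise. They do not include CTF effects,
beam-induced motion, missing-wedge artifacts, stain granularity, capsid
flexibility/distortion, or cellular clutter (organelles, cytoskeleton)
around particles in scenes. Classifier accuracies measured here therefore
bound idealized performance: they validate the rule's logic and the
geometry of sectioning bias, not performance on cluttered real micrographs,
where detection and occlusion dominate.

## Problem sizes and numerics

Default analysis sizes: 5-Å voxels (≈535³ grids) for profile metrology,
10-Å for the faceted vertex measurement and opening detection, 20-Å for
classification Monte Carlos (hundreds to thousands of sections). Radial
binning is one voxel; profile streaming keeps peak memory near one float32
volume. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical inputs give bit-identical volumes,
scenes and MRC files.

## Known limitations

- The symmetron convention covers lattices with at least one odd index;
  even–even lattices (and exotic decompositions with different unit sizes)
  are out of scope.
- Pentasymmetron orientation classes are labels, not measured orientations.
- The typing rule assumes centered single-particle crops; detection in
  cluttered images is out of scope.
- Edge metrology assumes the preset-derived analysis windows; strongly
  different geometries require overriding them.
- The 1.6-nm "maximum" membrane shift equals the uniform preset shift by
  construction; with radially non-uniform contraction the three flank
  statistics would differ and the maximum convention would matter more.
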