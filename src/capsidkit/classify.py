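"""Rule-based typing of particle sections into the four maturation states.

Micrograph analysts distinguish the states by the capsid ring and what the
ring encloses: a full nucleoid (Full), a partial one (s-Full), a spongy
scaffold texture (p-Empty) or nothing (Empty).  This module operationalizes
that call as explicit features and thresholds:

* ``ring_score``     - capsid ring detectability, gated on the boundary-disk
  radius reaching the expected capsid radius (grazing-geometry exclusion);
* ``occupancy``      - fraction of deep-interior pixels above an adaptive
  threshold referenced to the ring signal (robust to contrast inversion);
* ``texture_score``  - excess band-passed variance of the interior relative
  to the background noise, normalized by the ring signal (spongy indicator);
* ``interior_mean``  - ring-normalized mean interior density.

Decision rule: unclassifiable ("unknown") if the ring score is too low
(grazing slabs whose boundary disk falls short of the expected capsid
radius, or broken particles); else Full if occupancy >= theta_occ_full,
s-Full if >= theta_occ_sfull, else p-Empty if texture >= tau_spongy, else
Empty.  The thresholds are free parameters of the rule (the underlying
by-eye criteria were never quantified); defaults live in ``TypingRule``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import presets
from .phantoms import SectionImage

__all__ = [
    "TypingFeatures",
    "TypingRule",
    "FEATURE_NAMES",
    "extract_features",
    "classify",
    "classify_batch",
    "ParticleTypeClassifier",
]

log = logging.getLogger(__name__)

FEATURE_NAMES = ("ring_score", "occupancy", "texture_score", "interior_mean")

#: class order from emptiest to fullest (monotone in occupancy)
CLASS_ORDER = ("Empty", "p-Empty", "s-Full", "Full")


@dataclass(frozen=True)
class TypingFeatures:
    ring_score: float
    occupancy: float
    texture_score: float
    interior_mean: float
    ring_radius_nm: float = float("nan")

    def as_array(self) -> np.ndarray:
        return np.array([self.ring_score, self.occupancy, self.texture_score,
                         self.interior_mean])


@dataclass(frozen=True)
class TypingRule:
    """Thresholds of the typing rule; see the module docstring."""

    theta_occ_full: float = 0.9
    theta_occ_sfull: float = 0.15
    tau_spongy: float = 0.015  # Otsu-style midpoint, Empty vs p-Empty presets
    theta_ring: float = 0.8

    def __post_init__(self) -> None:
        if not 0 < self.theta_occ_sfull < self.theta_occ_full <= 1:
            raise ValueError(
                "occupancy cutoffs must satisfy 0 < sfull < full <= 1"
            )


def extract_features(
    section: SectionImage | np.ndarray,
    pixel_size: float | None = None,
    expected_radius_nm: float = presets.SPHERICAL_CAPSID_OUTER,
    interior_fraction: float = 0.45,
    grazing_fraction: float = 0.97,
) -> TypingFeatures:
    """Compute typing features from a centered single-particle crop.

    The capsid ring is located on the rotational-average profile; the
    interior statistics are taken on the deep-interior disk
    (``interior_fraction`` of the ring radius) so that grazing-geometry
    shells do not leak into the occupancy.  Deterministic.
    """
    if isinstance(section, SectionImage):
        img = np.asarray(section.data, dtype=np.float64)
        px = section.pixel_nm
        if section.meta.get("invert"):
            img = float(np.median(img)) - img  # restore bright-particle contrast
    else:
        img = np.asarray(section, dtype=np.float64)
        if pixel_size is None:
            raise ValueError("pixel_size (Angstrom) required for bare arrays")
        px = pixel_size / 10.0

    n = min(img.shape)
    c = (np.array(img.shape) - 1) / 2.0
    yy, xx = np.ogrid[: img.shape[0], : img.shape[1]]
    r_nm = np.hypot((yy - c[0]), (xx - c[1])) * px

    bg_mask = r_nm > min(1.15 * expected_radius_nm, (n // 2 - 1) * px)
    if not bg_mask.any():
        bg_mask = r_nm > r_nm.max() * 0.9
    bg = img[bg_mask]
    bg_med = float(np.median(bg))
    bg_mad = float(np.median(np.abs(bg - bg_med))) * 1.4826

    # particle boundary on the rotational average: the outermost radius
    # where the profile still reaches 35% of its robust maximum.  (A peak
    # search fails on off-center slabs, where the interior dome can exceed
    # the rim; the boundary radius is also the grazing-geometry gate: slabs
    # whose boundary disk falls short of the expected capsid radius project
    # shell caps into the interior and are not typable.)
    bw = px
    idx = (r_nm.ravel() / bw).astype(np.int64)
    nb = idx.max() + 1
    prof = np.bincount(idx, weights=(img - bg_med).ravel(), minlength=nb)
    cnt = np.bincount(idx, minlength=nb)
    prof = np.divide(prof, cnt, out=np.zeros_like(prof), where=cnt > 0)
    radii = (np.arange(nb) + 0.5) * bw
    inside = radii < 1.1 * expected_radius_nm
    if not inside.any() or not np.isfinite(prof[inside]).all():
        return TypingFeatures(0.0, 0.0, 0.0, 0.0)
    p_top = float(np.percentile(prof[inside], 98))
    above = inside & (prof >= 0.35 * p_top)
    if p_top <= 0 or not above.any():
        return TypingFeatures(0.0, 0.0, 0.0, 0.0)
    ring_radius = float(radii[np.flatnonzero(above)[-1]])
    rim_band = (radii > 0.75 * ring_radius) & (radii <= 1.02 * ring_radius)
    peak = float(prof[rim_band].max()) if rim_band.any() else 0.0
    noise = max(bg_mad, 1e-9)
    detectability = peak / (peak + 5.0 * noise) if peak > 0 else 0.0
    # grazing gate: a boundary disk short of the expected capsid radius means
    # the slab missed the equator and shell caps project into the interior;
    # such profiles are not typable regardless of contrast
    frac = ring_radius / expected_radius_nm
    gate = 1.0 if frac >= grazing_fraction else max(0.0, frac - 0.5)
    ring_score = float(np.clip(detectability * gate, 0, 1))

    ring_band = (r_nm > 0.88 * ring_radius) & (r_nm < 1.02 * ring_radius)
    S = float(np.percentile(img[ring_band] - bg_med, 95)) if ring_band.any() else 0.0
    if S <= 0:
        return TypingFeatures(ring_score, 0.0, 0.0, 0.0, ring_radius)

    interior = r_nm < interior_fraction * ring_radius
    vals = img[interior] - bg_med
    occupancy = float(np.mean(vals > 0.45 * S))
    interior_mean = float(vals.mean() / S)

    # band-passed texture, matched to the spongy correlation length; taken
    # on a further-eroded disk so rim/cap bleed cannot masquerade as texture
    sigma_px = max((presets.SPONGY_CORRELATION_NM / 2.355) / px, 1.0)
    hp = img - ndimage.gaussian_filter(img, sigma_px)
    tex_interior = r_nm < 0.8 * interior_fraction * ring_radius
    t_int = float(hp[tex_interior].std())
    # keep the noise reference clear of blur bleed from the particle edge
    tex_bg = bg_mask & (r_nm > r_nm[bg_mask].min() + 3 * sigma_px * px)
    if not tex_bg.any():
        tex_bg = bg_mask
    t_bg = float(hp[tex_bg].std())
    texture_score = max(0.0, t_int - t_bg) / S
    return TypingFeatures(ring_score, occupancy, texture_score, interior_mean,
                          ring_radius)


def classify(features: TypingFeatures, rule: TypingRule | None = None) -> str:
    """Apply the typing rule; total over valid features."""
    rule = rule or TypingRule()
    if features.ring_score < rule.theta_ring:
        return "unknown"
    f = features.occupancy
    if f >= rule.theta_occ_full:
        return "Full"
    if f >= rule.theta_occ_sfull:
        return "s-Full"
    if features.texture_score >= rule.tau_spongy:
        return "p-Empty"
    return "Empty"


def classify_batch(scene, rule: TypingRule | None = None,
                   overlap_distance_um: float = 0.27) -> list:
    """Type every particle crop of a scene section.

    Returns the scene's records with ``assigned_type`` filled.  Particles
    whose centers lie closer than ``overlap_distance_um`` are flagged
    ambiguous, assigned "unknown", and logged; order of the input never
    affects per-type counts.
    """
    rule = rule or TypingRule()
    records = [r for r in scene.records]
    pos = np.array([[r.x_um, r.y_um] for r in records]) if records else np.empty((0, 2))
    ambiguous = set()
    if len(records) > 1:
        from scipy.spatial import cKDTree

        tree = cKDTree(pos)
        for i, j in tree.query_pairs(overlap_distance_um):
            ambiguous.update((i, j))
    for i, (rec, crop) in enumerate(zip(records, scene.crops)):
        if i in ambiguous:
            rec.assigned_type = "unknown"
            log.info("particle %s flagged ambiguous (overlap)", rec.particle_id)
            continue
        rec.assigned_type = classify(extract_features(crop), rule)
    return records


class ParticleTypeClassifier(ClassifierMixin, BaseEstimator):
    """Scikit-learn-style wrapper around the deterministic typing rule.

    ``X`` is a feature matrix with columns ``FEATURE_NAMES`` (as produced by
    :func:`extract_features`).  ``fit`` validates the thresholds and, when
    given labelled features, recalibrates ``tau_spongy`` as the midpoint
    between the highest Empty and lowest p-Empty texture scores (an
    Otsu-style two-class split); no other parameter is learned.
    """

    def __init__(self, theta_occ_full: float = 0.9,
                 theta_occ_sfull: float = 0.15,
                 tau_spongy: float = 0.015,
                 theta_ring: float = 0.8):
        self.theta_occ_full = theta_occ_full
        self.theta_occ_sfull = theta_occ_sfull
        self.tau_spongy = tau_spongy
        self.theta_ring = theta_ring

    def _rule(self) -> TypingRule:
        return TypingRule(self.theta_occ_full, self.theta_occ_sfull,
                          self.tau_spongy, self.theta_ring)

    def fit(self, X=None, y=None):
        self._rule()  # validates threshold ordering
        if X is not None and y is not None:
            X = np.asarray(X, dtype=float)
            y = np.asarray(y)
            tex = X[:, FEATURE_NAMES.index("texture_score")]
            lo = tex[y == "Empty"]
            hi = tex[y == "p-Empty"]
            if len(lo) and len(hi):
                self.tau_spongy = float((lo.max() + hi.min()) / 2.0)
        self.classes_ = np.array(sorted(set(CLASS_ORDER) | {"unknown"}))
        self.n_features_in_ = len(FEATURE_NAMES)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 4:
            raise ValueError(
                f"X must be (n_samples, {len(FEATURE_NAMES)}) feature rows"
            )
        rule = self._rule()
        out = [
            classify(TypingFeatures(*row[:4]), rule) for row in X
        ]
        return np.array(out)

    def predict_sections(self, sections, **extract_kwargs) -> np.ndarray:
        check_is_fitted(self)
        rule = self._rule()
        return np.array(
            [classify(extract_features(s, **extract_kwargs), rule)
             for s in sections]
        )
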