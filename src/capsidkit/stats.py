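"""Maturation statistics: type fractions, the distance-from-nucleus null
model, and the thin-section counting-bias simulation.

The quantitative backbone of the maturation analysis:

* per-group type fractions (time course over hours post-infection, or
  inside/outside-cell groupings), printed to one decimal;
* the random-placement null for particle counts versus distance from the
  nuclear surface: for uniform placement per unit area outside a circular
  nucleus of radius ``a``, the expected count in a distance bin
  ``[d1, d2)`` is proportional to ``a*(d2-d1) + (d2^2 - d1^2)/2`` - i.e.
  counts grow linearly with distance - tested per type by Pearson
  chi-square;
* a stereology simulator quantifying how random 70-nm slab offsets through
  ~260-nm particles misclassify the interior state, versus thick sections
  that contain whole particles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import nnls

from . import presets
from .classify import TypingRule, classify, extract_features
from .phantoms import make_phantom, phantom_spec, slab_weights

__all__ = [
    "StatsError",
    "TYPE_ORDER",
    "FractionTable",
    "type_fractions",
    "combine_fractions",
    "linear_null_expected",
    "distance_fit_test",
    "DistanceFitResult",
    "SlabBiasResult",
    "slab_bias",
    "timecourse_table",
]

log = logging.getLogger(__name__)

#: printing order used for count vectors like (Full, s-Full, p-Empty, Empty)
TYPE_ORDER = ("Full", "s-Full", "p-Empty", "Empty")


class StatsError(ValueError):
    pass


@dataclass
class FractionTable:
    """Per-type counts and percentage fractions for one or more groups."""

    counts: pd.DataFrame  # index = group, columns = types
    fractions: pd.DataFrame  # same shape, % to one decimal

    def row(self, group) -> dict:
        return self.fractions.loc[group].to_dict()

    def to_frame(self) -> pd.DataFrame:
        c = self.counts.add_suffix(" (n)")
        f = self.fractions.add_suffix(" (%)")
        return pd.concat([c, f], axis=1)


def _counts_frame(records, group_by=None, type_field="true_type") -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        frame = records
    elif isinstance(records, dict):
        frame = pd.DataFrame(
            {type_field: [t for t, n in records.items() for _ in range(int(n))]}
        )
    else:
        from .scenes import records_to_frame

        frame = records_to_frame(records)
    if type_field not in frame.columns:
        raise StatsError(f"records lack a {type_field!r} column")
    frame = frame.copy()
    frame["_group"] = frame[group_by] if group_by else "all"
    out = (
        frame.groupby("_group")[type_field]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(TYPE_ORDER), fill_value=0)
    )
    out.index.name = group_by or None
    return out


def type_fractions(records, group_by=None, type_field="true_type"
                   ) -> FractionTable:
    """Count particles per type and report fractions in % to one decimal.

    ``records`` may be ParticleRecord objects, a DataFrame, or a mapping
    ``type -> count``.  Raises on an empty group.
    """
    counts = _counts_frame(records, group_by, type_field)
    totals = counts.sum(axis=1)
    if (totals == 0).any() or counts.empty:
        raise StatsError("empty group in fraction table")
    fractions = (100.0 * counts.div(totals, axis=0)).round(1)
    return FractionTable(counts=counts, fractions=fractions)


def combine_fractions(fractions, groups) -> float:
    """Sum the fractions (percent) of the named types."""
    if isinstance(fractions, FractionTable):
        if len(fractions.fractions) != 1:
            raise StatsError("combine_fractions expects a single-group table")
        fractions = fractions.fractions.iloc[0].to_dict()
    missing = [g for g in groups if g not in fractions]
    if missing:
        raise StatsError(f"unknown type name(s) {missing}")
    return float(sum(fractions[g] for g in groups))


# ---------------------------------------------------------------------------
# distance-from-nucleus null model


def linear_null_expected(nucleus_radius_um: float, bin_edges, total: float
                         ) -> np.ndarray:
    """Expected counts per distance bin under uniform-per-area placement
    outside a circular nucleus of radius ``a``.

    Annulus area between distances d1 and d2 from the surface is
    ``2*pi*(a*(d2-d1) + (d2^2-d1^2)/2)``: counts increase linearly with
    distance.  ``a = inf`` gives the flat-boundary limit (equal expected
    counts in equal-width bins).
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or not np.all(np.diff(edges) > 0):
        raise StatsError("bin edges must be increasing, length >= 2")
    if total <= 0:
        raise StatsError("total must be positive")
    d1, d2 = edges[:-1], edges[1:]
    a = nucleus_radius_um
    if np.isinf(a):
        w = d2 - d1
    else:
        if a < 0:
            raise StatsError("nucleus radius must be >= 0")
        w = a * (d2 - d1) + (d2**2 - d1**2) / 2.0
    return total * w / w.sum()


@dataclass
class DistanceFitResult:
    per_type: pd.DataFrame  # statistic, dof, p_value, n, verdict
    bin_edges: np.ndarray
    alpha: float


def _merge_low_expected(obs: np.ndarray, exp: np.ndarray, min_expected: float
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Merge adjacent bins left-to-right until every expected count reaches
    ``min_expected`` (deterministic)."""
    o, e = list(obs.astype(float)), list(exp.astype(float))
    i = 0
    while i < len(e):
        if e[i] < min_expected:
            j = i + 1 if i + 1 < len(e) else i - 1
            if j < 0:
                break
            e[j] += e[i]
            o[j] += o[i]
            del e[i], o[i]
            log.info("merged distance bin %d into its neighbour", i)
            i = 0
        else:
            i += 1
    return np.array(o), np.array(e)


def distance_fit_test(
    records,
    nucleus_radius_um: float,
    bin_edges=(0.0, 0.5, 1.0, 1.5, 2.0),
    alpha: float = 0.05,
    min_expected: float = 1.0,
    type_field="true_type",
) -> DistanceFitResult:
    """Pearson chi-square of observed distances against the linear null.

    Records beyond the last bin edge are excluded (the observation window
    stops 2 um from the nucleus by default; the membrane-margin exclusion
    is applied when scenes are generated).  Bins with expected counts below
    ``min_expected`` are merged into their neighbour, deterministically.
    """
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        from .scenes import records_to_frame

        frame = records_to_frame(records)
    edges = np.asarray(bin_edges, dtype=float)
    rows = []
    for typ, sub in frame.groupby(type_field):
        d = sub["distance_um"].to_numpy()
        d = d[(d >= edges[0]) & (d < edges[-1])]
        if len(d) == 0:
            continue
        obs, _ = np.histogram(d, bins=edges)
        exp = linear_null_expected(nucleus_radius_um, edges, obs.sum())
        obs_m, exp_m = _merge_low_expected(obs, exp, min_expected)
        if len(obs_m) < 2:
            log.warning("type %s: insufficient data after bin merging; skipped",
                        typ)
            continue
        stat, p = sps.chisquare(obs_m, exp_m)
        rows.append(
            dict(
                type=typ,
                statistic=float(stat),
                dof=len(obs_m) - 1,
                p_value=float(p),
                n=int(obs.sum()),
                consistent_with_null=bool(p > alpha),
            )
        )
    if not rows:
        raise StatsError(
            "no type had enough records inside the distance window"
        )
    per_type = pd.DataFrame(rows).set_index("type")
    return DistanceFitResult(per_type=per_type, bin_edges=edges, alpha=alpha)


# ---------------------------------------------------------------------------
# slab sectioning bias


@dataclass
class SlabBiasResult:
    """Monte-Carlo confusion of true type vs assigned type for one slab
    thickness.  ``confusion`` rows include the unknown column and sum to 1;
    ``classified_confusion`` renormalizes over the four types after
    excluding unknowns (the usable counts of a real section)."""

    thickness_nm: float
    confusion: pd.DataFrame
    n_samples: int
    seed: int

    @property
    def classified_confusion(self) -> pd.DataFrame:
        c = self.confusion[list(TYPE_ORDER)]
        return c.div(c.sum(axis=1), axis=0)

    def apply(self, true_fractions) -> dict:
        """Predicted observed fractions (%) given true fractions (%)."""
        f = np.array([true_fractions[t] for t in TYPE_ORDER], dtype=float)
        out = f @ self.classified_confusion.loc[list(TYPE_ORDER)].to_numpy()
        out = 100.0 * out / out.sum()
        return dict(zip(TYPE_ORDER, np.round(out, 1)))

    def correct(self, observed_fractions) -> dict:
        """Bias-corrected true fractions by non-negative least squares."""
        C = self.classified_confusion.loc[list(TYPE_ORDER)].to_numpy()
        b = np.array([observed_fractions[t] for t in TYPE_ORDER], dtype=float)
        if np.linalg.cond(C) > 1e8:
            log.warning("confusion matrix ill-conditioned; returning raw fractions")
            return dict(zip(TYPE_ORDER, b))
        x, _ = nnls(C.T, b)
        if x.sum() <= 0:
            return dict(zip(TYPE_ORDER, b))
        x = 100.0 * x / x.sum()
        return dict(zip(TYPE_ORDER, np.round(x, 1)))


def slab_bias(
    thickness_nm: float,
    n_per_type: int = 500,
    seed: int = 0,
    voxel_size: float = 20.0,
    rule: TypingRule | None = None,
    types=presets.PARTICLE_TYPES,
    noise: dict | None = None,
    tomographic: bool | None = None,
    tomo_slice_nm: float = 10.0,
) -> SlabBiasResult:
    """Simulate random-slab sectioning and classification of each type.

    For every true type, ``n_per_type`` slab offsets are drawn uniformly
    over the full intersection range (every visible profile is counted, as
    in real thin-section micrographs) and the typing rule applied.  Thin
    sections are classified from the slab projection (as in conventional
    TEM of plastic sections); thick sections - by default those at least as
    thick as the particle diameter - are classified *tomographically*, from
    the particle's central-most thin slice inside the slab, because a 3D
    reconstruction of such a section shows each particle's interior
    directly.  Grazing geometries classify as unknown.
    """
    if n_per_type < 1:
        raise StatsError("need at least one slab per type")
    rule = rule or TypingRule()
    if tomographic is None:
        tomographic = thickness_nm >= 2 * presets.SPHERICAL_CAPSID_OUTER
    rng = np.random.default_rng(seed)
    labels = list(TYPE_ORDER) + ["unknown"]
    rows = {}
    for typ in types:
        vol = make_phantom(phantom_spec(typ), voxel_size=voxel_size,
                           seed=seed + 977 * presets.PARTICLE_TYPES.index(typ))
        radius = phantom_spec(typ).radii["spike_tip"]
        lim = radius + thickness_nm / 2.0
        offsets = rng.uniform(-lim, lim, size=n_per_type)
        counts = dict.fromkeys(labels, 0)
        data = vol.data
        for off in offsets:
            if tomographic:
                # central-most slice of the particle available in the slab
                lo = off - thickness_nm / 2.0 + tomo_slice_nm / 2.0
                hi = off + thickness_nm / 2.0 - tomo_slice_nm / 2.0
                zc = float(np.clip(0.0, lo, hi))
                w = slab_weights(vol, tomo_slice_nm, zc)
            else:
                w = slab_weights(vol, thickness_nm, float(off))
            nz = np.nonzero(w)[0]
            if len(nz) == 0:
                counts["unknown"] += 1
                continue
            img = np.tensordot(
                w[nz[0]:nz[-1] + 1].astype(np.float32),
                data[nz[0]:nz[-1] + 1],
                axes=(0, 0),
            )
            if noise is not None:
                dose = float(noise.get("dose", presets.DEFAULT_NOISE["dose"]))
                sig = float(noise.get("gaussian_sigma",
                                      presets.DEFAULT_NOISE["gaussian_sigma"]))
                img = rng.poisson(np.clip(img, 0, None) * dose) / dose
                img = img + rng.normal(0.0, sig, size=img.shape)
            feats = extract_features(img, pixel_size=voxel_size)
            counts[classify(feats, rule)] += 1
        rows[typ] = [counts[lab] / n_per_type for lab in labels]
    confusion = pd.DataFrame.from_dict(rows, orient="index", columns=labels)
    confusion = confusion.reindex(index=[t for t in TYPE_ORDER if t in types])
    return SlabBiasResult(
        thickness_nm=thickness_nm,
        confusion=confusion,
        n_samples=n_per_type,
        seed=seed,
    )


def plot_fraction_table(table: FractionTable, path=None, ax=None):
    """Stacked-bar chart of type fractions per group (time course or
    location), one bar per group in the conventional colors (Full red,
    s-Full yellow, p-Empty green, Empty blue)."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    colors = {"Full": "#d62728", "s-Full": "#f5c542",
              "p-Empty": "#2ca02c", "Empty": "#1f77b4"}
    if ax is None:
        _fig, ax = plt.subplots(figsize=(6, 4))
    frac = table.fractions
    bottom = np.zeros(len(frac))
    x = np.arange(len(frac))
    for t in TYPE_ORDER:
        ax.bar(x, frac[t].to_numpy(), bottom=bottom, label=t,
               color=colors[t])
        bottom += frac[t].to_numpy()
    ax.set_xticks(x, [str(g) for g in frac.index])
    ax.set_ylabel("fraction (%)")
    ax.set_ylim(0, 100)
    ax.legend(frameon=False, fontsize=8)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(ax.figure)
    return ax


# ---------------------------------------------------------------------------
# time course


def timecourse_table(records, min_count: int = 20, type_field="true_type"
                     ) -> FractionTable:
    """Type fractions per hours-post-infection group, ordered by time.

    Groups with fewer than ``min_count`` particles are dropped with a log
    entry (insufficient counts make fractions unstable, which is why early
    time points are typically omitted from such analyses).
    """
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        from .scenes import records_to_frame

        frame = records_to_frame(records)
    if "hpi" not in frame.columns or frame["hpi"].isna().all():
        raise StatsError("records carry no hpi annotation")
    table = type_fractions(frame, group_by="hpi", type_field=type_field)
    keep = table.counts.sum(axis=1) >= min_count
    for hpi in table.counts.index[~keep]:
        log.info("dropping hpi group %s (fewer than %d particles)", hpi, min_count)
    if not keep.any():
        raise StatsError("no hpi group reaches the minimum count")
    return FractionTable(
        counts=table.counts[keep].sort_index(),
        fractions=table.fractions[keep].sort_index(),
    )
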