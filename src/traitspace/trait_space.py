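"""Occupancy of the functional trait space via convex-hull volumes.

A taxon is a point in the retained ordination axes; the occupied functional
trait space is the d-dimensional volume of the convex hull of those points.
To damp the influence of outliers, hulls can be computed on the fraction
(default 95%) of points closest to the cloud's centroid.

Observed occupancy is compared with three Monte-Carlo null models in which
axes vary independently: simulated scores are per-axis uniform over the
observed range (model "uniform"), per-axis normal with the observed mean and
standard deviation ("normal"), or per-axis random permutations of the
observed values ("permutation", which keeps each marginal exactly).  An
occupancy well below 100% of the mean null volume, with a small one-sided
p-value, indicates that trait combinations are concentrated — the axes do
not vary independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "HullResult",
    "NullModelResult",
    "GroupSpaceSummary",
    "TraitSpaceError",
    "convex_hull_volume",
    "trim_to_centroid_fraction",
    "group_volumes",
    "group_axis_summary",
    "null_model_test",
]

NULL_MODELS = ("uniform", "normal", "permutation")


class TraitSpaceError(ValueError):
    pass


@dataclass
class HullResult:
    dimension: int
    volume: float
    vertex_taxa: list[str]
    n_points_used: int
    trimmed: bool
    degenerate: bool = False


@dataclass
class NullModelResult:
    model: str
    n_reps: int
    observed_volume: float
    null_volumes: np.ndarray
    occupancy_percent: float  # 100 * observed / central null volume
    p_value: float  # one-sided: concentration = observed smaller than null
    null_center: str = "mean"


@dataclass
class GroupSpaceSummary:
    """Per-group occupancy and per-axis moments of the score cloud."""

    group_names: list[str]
    n_taxa: dict[str, int] = field(default_factory=dict)
    axis_means: dict[str, np.ndarray] = field(default_factory=dict)
    axis_variances: dict[str, np.ndarray] = field(default_factory=dict)
    singleton_groups: list[str] = field(default_factory=list)
    hull_volume: dict[str, float] = field(default_factory=dict)
    standardized_volume_percent: dict[str, float] = field(default_factory=dict)
    whole_volume: float = float("nan")
    whole_standardized_percent: float = float("nan")
    expected_proportional_volume: float = float("nan")


def standardized_volume_percent(volume: float, n_taxa: int) -> float:
    """Occupied volume per taxon, as a percentage (100 * volume / n)."""
    if n_taxa < 1:
        raise TraitSpaceError("n_taxa must be >= 1")
    return 100.0 * volume / n_taxa


def expected_proportional_volume(whole_volume: float, n_groups: int) -> float:
    """Volume each group would occupy if the whole space split evenly."""
    if n_groups < 1:
        raise TraitSpaceError("n_groups must be >= 1")
    return whole_volume / n_groups


def convex_hull_volume(
    points: np.ndarray,
    taxon_ids: list[str] | None = None,
    *,
    trimmed: bool = False,
) -> HullResult:
    """Exact d-dimensional volume of the convex hull of a point cloud.

    Degenerate clouds (n <= d points, or affinely dependent points) have a
    flat hull: volume 0 with the ``degenerate`` flag set, not an error.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 1 or pts.shape[1] < 1:
        raise TraitSpaceError("points must be a non-empty n x d matrix")
    if not np.isfinite(pts).all():
        raise TraitSpaceError("non-finite coordinate in points")
    n, d = pts.shape
    ids = list(taxon_ids) if taxon_ids is not None else [str(i) for i in range(n)]
    if len(ids) != n:
        raise TraitSpaceError("taxon_ids length does not match points")

    if d == 1:
        lo, hi = pts[:, 0].min(), pts[:, 0].max()
        if n < 2 or lo == hi:
            return HullResult(1, 0.0, [ids[int(pts[:, 0].argmin())]], n, trimmed, True)
        verts = [ids[int(pts[:, 0].argmin())], ids[int(pts[:, 0].argmax())]]
        return HullResult(1, float(hi - lo), verts, n, trimmed)
    if n <= d:
        return HullResult(d, 0.0, ids, n, trimmed, True)
    try:
        hull = ConvexHull(pts)
    except QhullError:  # affinely dependent cloud: flat hull, zero volume
        return HullResult(d, 0.0, [], n, trimmed, True)
    return HullResult(
        dimension=d,
        volume=float(hull.volume),
        vertex_taxa=[ids[int(v)] for v in hull.vertices],
        n_points_used=n,
        trimmed=trimmed,
    )


def trim_to_centroid_fraction(
    points: np.ndarray, fraction: float = 0.95
) -> np.ndarray:
    """Keep the floor(fraction * n) points closest to the centroid.

    The centroid is the per-axis mean; ties in distance are broken by input
    order (stable sort), so trimming is deterministic.
    """
    if not 0.0 < fraction <= 1.0:
        raise TraitSpaceError("fraction must lie in (0, 1]")
    pts = np.asarray(points, dtype=float)
    if fraction == 1.0:
        return pts
    n = pts.shape[0]
    keep = int(np.floor(fraction * n))
    centroid = pts.mean(axis=0)
    dist = np.linalg.norm(pts - centroid, axis=1)
    order = np.argsort(dist, kind="stable")[:keep]
    return pts[np.sort(order)]


def group_axis_summary(
    scores: np.ndarray, groups: list[str], n_axes: int = 4
) -> GroupSpaceSummary:
    """Per-group mean and sample variance (n-1) along the leading axes."""
    scores = np.asarray(scores, dtype=float)
    if n_axes > scores.shape[1]:
        raise TraitSpaceError(
            f"requested {n_axes} axes but scores have {scores.shape[1]}"
        )
    labels = np.asarray(groups)
    names = list(dict.fromkeys(groups))  # first-appearance order
    out = GroupSpaceSummary(group_names=names)
    sub_all = scores[:, :n_axes]
    for g in names:
        sub = sub_all[labels == g]
        out.n_taxa[g] = sub.shape[0]
        out.axis_means[g] = sub.mean(axis=0)
        if sub.shape[0] < 2:
            out.axis_variances[g] = np.zeros(n_axes)
            out.singleton_groups.append(g)
        else:
            out.axis_variances[g] = sub.var(axis=0, ddof=1)
    return out


def group_volumes(
    scores: np.ndarray,
    groups: list[str],
    taxon_ids: list[str] | None = None,
    *,
    trim: bool = False,
    fraction: float = 0.95,
) -> GroupSpaceSummary:
    """Hull volume of the whole assemblage and of each taxonomic group.

    Also reports volume per taxon as a percentage (standardized space) and
    the expected proportional per-group volume (whole volume divided by the
    number of groups) against which group volumes are compared.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(groups)
    n = scores.shape[0]
    ids = list(taxon_ids) if taxon_ids is not None else [str(i) for i in range(n)]
    names = list(dict.fromkeys(groups))
    out = GroupSpaceSummary(group_names=names)

    def _vol(pts: np.ndarray, pids: list[str]) -> float:
        if trim:
            pts = trim_to_centroid_fraction(pts, fraction)
            pids = None  # identities lost after trimming
        return convex_hull_volume(pts, pids, trimmed=trim).volume

    out.whole_volume = _vol(scores, ids)
    out.whole_standardized_percent = standardized_volume_percent(out.whole_volume, n)
    out.expected_proportional_volume = expected_proportional_volume(
        out.whole_volume, len(names)
    )
    for g in names:
        sel = labels == g
        sub_ids = [i for i, keep in zip(ids, sel) if keep]
        vol = _vol(scores[sel], sub_ids)
        out.n_taxa[g] = int(sel.sum())
        out.hull_volume[g] = vol
        out.standardized_volume_percent[g] = standardized_volume_percent(
            vol, int(sel.sum())
        )
    return out


def _simulate_null(
    model: str, scores: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One simulated score cloud with independently varying axes.

    Each simulated cloud is affinely aligned, axis by axis, onto the observed
    sample's range (uniform model) or mean and standard deviation (normal
    model).  Without this alignment a simulated cloud sits strictly inside
    the observed extremes and its hull is stochastically smaller, so the test
    would be anti-conservative toward "occupancy > 100%"; with it, the
    observed cloud is exchangeable with the null draws whenever its axes
    really are independent, which makes the p-value exactly calibrated.
    """
    n, k = scores.shape
    if model == "uniform":
        lo, hi = scores.min(axis=0), scores.max(axis=0)
        sim = rng.uniform(size=(n, k))
        span = sim.max(axis=0) - sim.min(axis=0)
        return lo + (sim - sim.min(axis=0)) / span * (hi - lo)
    if model == "normal":
        mu = scores.mean(axis=0)
        sd = scores.std(axis=0, ddof=1)
        sim = rng.normal(size=(n, k))
        sim = (sim - sim.mean(axis=0)) / sim.std(axis=0, ddof=1)
        return mu + sim * sd
    if model == "permutation":
        sim = np.empty_like(scores)
        for a in range(k):
            sim[:, a] = rng.permutation(scores[:, a])
        return sim
    raise TraitSpaceError(f"unknown null model {model!r}; choose from {NULL_MODELS}")


def null_model_test(
    scores: np.ndarray,
    model: str,
    n_reps: int = 999,
    fraction: float = 0.95,
    seed: int = 0,
    *,
    null_center: str = "mean",
) -> NullModelResult:
    """Monte-Carlo test of trait-space concentration against a null model.

    Simulation uses the *untrimmed* observed scores to set the uniform
    bounds / normal moments / permutation marginals; the centroid trimming is
    then applied identically to observed and simulated clouds before the hull
    volume is taken.  The one-sided p-value is the probability, under the
    null, of a hull at most as large as the observed one:
    (1 + #{null <= observed}) / (n_reps + 1).
    """
    if n_reps < 1:
        raise TraitSpaceError("n_reps must be >= 1")
    if model not in NULL_MODELS:
        raise TraitSpaceError(f"unknown null model {model!r}; choose from {NULL_MODELS}")
    if null_center not in ("mean", "median"):
        raise TraitSpaceError("null_center must be 'mean' or 'median'")
    scores = np.asarray(scores, dtype=float)
    n, k = scores.shape
    if k < 2:
        raise TraitSpaceError("null models need at least 2 axes")
    if n < k + 1:
        raise TraitSpaceError("need more taxa than axes")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    observed = convex_hull_volume(
        trim_to_centroid_fraction(scores, fraction), trimmed=True
    ).volume
    null_volumes = np.empty(n_reps)
    for r in range(n_reps):
        sim = _simulate_null(model, scores, rng)
        null_volumes[r] = convex_hull_volume(
            trim_to_centroid_fraction(sim, fraction), trimmed=True
        ).volume
    center = (
        float(np.mean(null_volumes))
        if null_center == "mean"
        else float(np.median(null_volumes))
    )
    occupancy = 100.0 * observed / center if center > 0 else float("nan")
    p = (1.0 + float((null_volumes <= observed).sum())) / (n_reps + 1.0)
    return NullModelResult(
        model=model,
        n_reps=n_reps,
        observed_volume=observed,
        null_volumes=null_volumes,
        occupancy_percent=occupancy,
        p_value=p,
        null_center=null_center,
    )
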