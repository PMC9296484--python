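"""Permutation tests of taxonomic constraint on the trait space.

PERMANOVA (one-way, Euclidean distance) asks whether taxa are more dissimilar
between taxonomic groups than within them: the total sum of squared pairwise
distances is partitioned into between- and within-group parts, and the
pseudo-F is referred to its permutation distribution under random relabelling
of taxa.  PERMDISP asks whether groups differ in multivariate *dispersion*:
each taxon's distance to its group's spatial median is computed, a one-way
ANOVA F on those distances is formed, and group labels are permuted (with the
medians and distances recomputed each time) to get a p-value.

Both tests run on ordination scores, typically the broken-stick-retained PCA
axes.  The spatial (geometric) median is found by Weiszfeld iteration with
the Vardi–Zhang correction for iterates landing on a data point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "PermanovaResult",
    "PermdispResult",
    "GroupTestError",
    "geometric_median",
    "permanova",
    "permdisp",
    "run_relatedness_suite",
]


class GroupTestError(ValueError):
    pass


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    df_between: int
    df_within: int
    p_value: float
    n_perms: int


@dataclass
class PermdispResult:
    F: float
    p_value: float
    n_perms: int
    distances: np.ndarray  # per-taxon distance to its group's spatial median
    group_mean_distance: dict[str, float]


def geometric_median(
    points: np.ndarray, tol: float = 1e-9, max_iter: int = 2000
) -> np.ndarray:
    """Spatial median: the point minimizing the sum of Euclidean distances.

    Weiszfeld iteration started at the centroid, with the Vardi–Zhang rule
    when the iterate coincides with a data point (where the plain update is
    undefined).  The minimizer always lies in the convex hull of the points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 1:
        raise GroupTestError("points must be a non-empty n x d matrix")
    if pts.shape[0] == 1:
        return pts[0].copy()
    y = pts.mean(axis=0)
    eps = tol
    for _ in range(max_iter):
        diff = pts - y
        d = np.linalg.norm(diff, axis=1)
        on_point = d < eps
        if on_point.all():  # all points coincide with y
            return y
        w = 1.0 / d[~on_point]
        t = (pts[~on_point] * w[:, None]).sum(axis=0) / w.sum()
        k = int(on_point.sum())
        if k == 0:
            y_new = t
        else:
            # Vardi & Zhang (2000): y is a data point; move only if the
            # pull of the remaining points exceeds the point's multiplicity.
            r_vec = (diff[~on_point] * w[:, None]).sum(axis=0)
            r = np.linalg.norm(r_vec)
            if r <= k:
                return y
            step = min(1.0, k / r)
            y_new = (1.0 - step) * t + step * y
        if np.linalg.norm(y_new - y) < tol * (1.0 + np.linalg.norm(y)):
            return y_new
        y = y_new
    return y


def _check_labels(scores: np.ndarray, groups: list[str]) -> np.ndarray:
    labels = np.asarray(groups)
    if labels.shape[0] != scores.shape[0]:
        raise GroupTestError("label vector length does not match scores")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise GroupTestError("need at least 2 groups")
    if uniq.size >= scores.shape[0]:
        raise GroupTestError("more groups than taxa (or one taxon per group)")
    return labels


def _permanova_ss(d2: np.ndarray, labels: np.ndarray, uniq: np.ndarray) -> float:
    """Within-group sum of squares: sum over groups of (pairwise d^2)/n_g."""
    ss_within = 0.0
    for g in uniq:
        idx = np.flatnonzero(labels == g)
        if idx.size > 1:
            block = d2[np.ix_(idx, idx)]
            ss_within += block.sum() / (2.0 * idx.size)
    return ss_within


def permanova(
    scores: np.ndarray, groups: list[str], n_perms: int = 999, seed: int = 0
) -> PermanovaResult:
    """One-way PERMANOVA on Euclidean distances between score rows.

    SS_total = sum of squared pairwise distances / n; SS_within sums each
    group's squared pairwise distances over its size; pseudo-F =
    (SS_between/df_between) / (SS_within/df_within); p-value from ``n_perms``
    random relabellings: (1 + #{F_perm >= F_obs}) / (n_perms + 1).
    """
    if n_perms < 1:
        raise GroupTestError("n_perms must be >= 1")
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = _check_labels(scores, groups)
    uniq = np.unique(labels)
    n = scores.shape[0]
    d2 = squareform(pdist(scores)) ** 2

    ss_total = d2.sum() / (2.0 * n)
    df_between = uniq.size - 1
    df_within = n - uniq.size

    def f_stat(lbl: np.ndarray) -> float:
        ss_within = _permanova_ss(d2, lbl, uniq)
        ss_between = ss_total - ss_within
        if ss_within <= 0:
            return np.inf if ss_between > 0 else 0.0
        return (ss_between / df_between) / (ss_within / df_within)

    ss_within_obs = _permanova_ss(d2, labels, uniq)
    ss_between_obs = max(ss_total - ss_within_obs, 0.0)
    f_obs = f_stat(labels)
    r2 = ss_between_obs / ss_total if ss_total > 0 else 0.0

    rng = np.random.default_rng(np.random.SeedSequence([seed, 505]))
    exceed = 0
    for _ in range(n_perms):
        if f_stat(labels[rng.permutation(n)]) >= f_obs:
            exceed += 1
    p = (1.0 + exceed) / (n_perms + 1.0)
    return PermanovaResult(
        pseudo_F=float(f_obs),
        R2=float(r2),
        df_between=df_between,
        df_within=df_within,
        p_value=p,
        n_perms=n_perms,
    )


def _dispersion_distances(
    scores: np.ndarray, labels: np.ndarray, uniq: np.ndarray, center: str
) -> np.ndarray:
    dist = np.empty(scores.shape[0])
    for g in uniq:
        idx = np.flatnonzero(labels == g)
        pts = scores[idx]
        c = geometric_median(pts) if center == "median" else pts.mean(axis=0)
        dist[idx] = np.linalg.norm(pts - c, axis=1)
    return dist


def _anova_f(values: np.ndarray, labels: np.ndarray, uniq: np.ndarray) -> float:
    n = values.size
    grand = values.mean()
    ssb = ssw = 0.0
    for g in uniq:
        v = values[labels == g]
        ssb += v.size * (v.mean() - grand) ** 2
        ssw += ((v - v.mean()) ** 2).sum()
    df_b, df_w = uniq.size - 1, n - uniq.size
    if ssw <= 0:
        return np.inf if ssb > 0 else 0.0
    return (ssb / df_b) / (ssw / df_w)


def permdisp(
    scores: np.ndarray,
    groups: list[str],
    n_perms: int = 999,
    seed: int = 0,
    *,
    center: str = "median",
) -> PermdispResult:
    """Homogeneity of multivariate dispersion around group spatial medians.

    ``center='centroid'`` swaps the spatial median for the per-axis mean.
    Labels are permuted raw and the group centres and distances recomputed in
    every permutation; a singleton group's distance (and dispersion) is 0.
    """
    if n_perms < 1:
        raise GroupTestError("n_perms must be >= 1")
    if center not in ("median", "centroid"):
        raise GroupTestError("center must be 'median' or 'centroid'")
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    labels = _check_labels(scores, groups)
    uniq = np.unique(labels)
    n = scores.shape[0]

    dist_obs = _dispersion_distances(scores, labels, uniq, center)
    f_obs = _anova_f(dist_obs, labels, uniq)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 606]))
    exceed = 0
    for _ in range(n_perms):
        lbl = labels[rng.permutation(n)]
        d = _dispersion_distances(scores, lbl, uniq, center)
        if _anova_f(d, lbl, uniq) >= f_obs:
            exceed += 1
    p = (1.0 + exceed) / (n_perms + 1.0)
    group_means = {
        str(g): float(dist_obs[labels == g].mean()) for g in uniq
    }
    return PermdispResult(
        F=float(f_obs),
        p_value=p,
        n_perms=n_perms,
        distances=dist_obs,
        group_mean_distance=group_means,
    )


def run_relatedness_suite(
    scores: np.ndarray,
    groups_pooled: list[str],
    groups_full: list[str],
    *,
    others_label: str = "Others",
    n_perms: int = 999,
    seed: int = 0,
) -> dict:
    """Taxonomic-constraint tests at three label resolutions.

    Runs PERMANOVA and PERMDISP (i) on the pooled labels where rare groups
    are aggregated under ``others_label``, (ii) on the full labels with the
    rare groups broken out, and (iii) on the full labels after dropping the
    taxa that were pooled — probing whether conclusions hinge on how the rare
    groups are handled.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    pooled = np.asarray(groups_pooled)
    full = np.asarray(groups_full)
    if pooled.shape[0] != scores.shape[0] or full.shape[0] != scores.shape[0]:
        raise GroupTestError("label vectors must align with scores")
    keep = pooled != others_label

    report = {}
    for key, (sc, lbl) in {
        "pooled": (scores, pooled),
        "full": (scores, full),
        "others_omitted": (scores[keep], full[keep]),
    }.items():
        report[key] = {
            "permanova": permanova(sc, list(lbl), n_perms=n_perms, seed=seed),
            "permdisp": permdisp(sc, list(lbl), n_perms=n_perms, seed=seed),
            "n_taxa": int(sc.shape[0]),
            "n_groups": int(np.unique(lbl).size),
        }
    return report
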