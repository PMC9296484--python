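"""Centred PCA tolerating missing cells, with broken-stick axis selection.

Variance-standardized PCA would equalize trait variances and destroy the
within-group relatedness that fuzzy coding carries, so only *centring* is
applied.  Missing cells are handled by pairwise deletion: each variable is
centred on its available-case mean, each covariance entry uses the rows where
both variables are observed, and a taxon's component score sums only over its
observed traits.  Pairwise-deletion covariance matrices need not be positive
semi-definite, so negative eigenvalues are clipped to zero and excluded from
variance proportions.

Axis significance uses the broken-stick null: the expected proportion of the
k-th largest piece when a unit stick is broken at random into p pieces is
b_k = (1/p) * sum_{i=k..p} 1/i; an axis is retained while its observed
variance proportion exceeds its stick.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .trait_data import StandardizedTraitTable

__all__ = [
    "PcaModel",
    "AxisSelection",
    "TraitAxisCorrelation",
    "IncompletePcaError",
    "pairwise_centred_covariance",
    "fit_incomplete_pca",
    "broken_stick_proportions",
    "select_axes",
    "trait_axis_correlations",
]

#: eigenvalues below this times the largest are treated as exactly zero
EIGEN_REL_TOL = 1e-12


class IncompletePcaError(ValueError):
    pass


@dataclass
class PcaModel:
    variable_means: np.ndarray  # (p,) available-case means
    eigenvalues: np.ndarray  # (p,) descending, clipped at 0
    loadings: np.ndarray  # (p, p) orthonormal columns
    scores: np.ndarray  # (n, p)
    variance_proportion: np.ndarray  # (p,) sums to 1 over positive eigs
    n_variables: int
    n_positive: int  # count of strictly positive eigenvalues


@dataclass
class AxisSelection:
    broken_stick: np.ndarray  # expected proportion per axis
    significant: np.ndarray  # boolean per axis: proportion > stick
    retained: int  # leading consecutive significant axes


@dataclass
class TraitAxisCorrelation:
    r: np.ndarray  # (p, n_axes) Pearson correlations
    retained_traits_per_axis: list[list[str]]
    threshold: float
    zero_variance_traits: list[str]  # r recorded as 0 for these


def _matrix_and_mask(table: StandardizedTraitTable) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(table.matrix, dtype=float)
    mask = np.asarray(table.mask, dtype=bool)
    return np.where(mask, x, 0.0), mask


def pairwise_centred_covariance(table: StandardizedTraitTable) -> np.ndarray:
    """Pairwise-deletion covariance of an incomplete standardized table.

    Entry (j, k) sums (x_j - mean_j)(x_k - mean_k) over the taxa where both
    traits are observed, divided by n_jk - 1; means are available-case means.
    On complete data this is exactly the sample covariance matrix.
    """
    x, mask = _matrix_and_mask(table)
    n_obs = mask.sum(axis=0)
    if (n_obs < 2).any():
        bad = [table.dictionary.abbreviations[j] for j in np.flatnonzero(n_obs < 2)]
        raise IncompletePcaError(f"traits with <2 observed values: {bad}")
    means = x.sum(axis=0) / n_obs
    centred = np.where(mask, x - means, 0.0)
    joint = mask.T.astype(float) @ mask.astype(float)  # n_jk
    if (joint < 2).any():
        j, k = map(int, np.argwhere(joint < 2)[0])
        abbrs = table.dictionary.abbreviations
        raise IncompletePcaError(
            f"trait pair ({abbrs[j]}, {abbrs[k]}) has fewer than 2 joint "
            "observations; drop one of the traits"
        )
    cov = (centred.T @ centred) / (joint - 1.0)
    return (cov + cov.T) / 2.0  # enforce exact symmetry


def fit_incomplete_pca(
    table: StandardizedTraitTable, *, rescale_scores: bool = False
) -> PcaModel:
    """Eigendecompose the pairwise covariance and score all taxa.

    A taxon's score on an axis sums (x_ij - mean_j) * loading_ja over its
    *observed* traits; missing terms contribute zero.  With
    ``rescale_scores`` the sum is inflated by p / p_observed for that taxon
    (sensitivity analysis for taxa with many gaps).  Axis signs are fixed by
    making the largest-|loading| entry of each axis positive.
    """
    cov = pairwise_centred_covariance(table)
    x, mask = _matrix_and_mask(table)
    n_obs = mask.sum(axis=0)
    means = x.sum(axis=0) / n_obs

    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = EIGEN_REL_TOL * max(eigvals.max(), 0.0)
    eigvals = np.where(eigvals > tol, eigvals, 0.0)

    # deterministic sign: largest-|loading| entry of each axis is positive
    flip = np.sign(eigvecs[np.argmax(np.abs(eigvecs), axis=0), np.arange(eigvecs.shape[1])])
    flip[flip == 0] = 1.0
    eigvecs = eigvecs * flip

    centred = np.where(mask, x - means, 0.0)
    scores = centred @ eigvecs
    if rescale_scores:
        p = mask.shape[1]
        p_obs = mask.sum(axis=1).astype(float)
        scores = scores * (p / np.maximum(p_obs, 1.0))[:, None]

    positive = eigvals > 0
    total = eigvals[positive].sum()
    proportion = np.where(positive, eigvals / total if total > 0 else 0.0, 0.0)
    return PcaModel(
        variable_means=means,
        eigenvalues=eigvals,
        loadings=eigvecs,
        scores=scores,
        variance_proportion=proportion,
        n_variables=cov.shape[0],
        n_positive=int(positive.sum()),
    )


def broken_stick_proportions(p: int) -> np.ndarray:
    """Expected ordered piece lengths of a unit stick broken into p pieces."""
    if p < 1:
        raise IncompletePcaError(f"broken stick needs p >= 1, got {p}")
    inv = 1.0 / np.arange(1, p + 1)
    return np.cumsum(inv[::-1])[::-1] / p


def select_axes(model: PcaModel, *, rule: str = "first_failure") -> AxisSelection:
    """Compare variance proportions with broken-stick expectations.

    ``first_failure`` (default) retains the leading run of axes whose
    proportion exceeds the stick; ``any`` counts every significant axis.
    Sticks are computed over the positive-eigenvalue axes so both sequences
    sum to one.
    """
    p = model.n_positive
    if p == 0:
        return AxisSelection(np.array([]), np.array([], dtype=bool), 0)
    sticks = broken_stick_proportions(p)
    props = model.variance_proportion[:p]
    significant = props > sticks
    if rule == "first_failure":
        retained = int(np.argmin(significant)) if not significant.all() else p
    elif rule == "any":
        retained = int(significant.sum())
    else:
        raise IncompletePcaError(f"unknown stopping rule {rule!r}")
    return AxisSelection(sticks, significant, retained)


def trait_axis_correlations(
    table: StandardizedTraitTable,
    model: PcaModel,
    n_axes: int,
    threshold: float = 0.5,
) -> TraitAxisCorrelation:
    """Pearson r between each trait and each axis's scores (available cases).

    Traits with zero variance over their observed cells get r = 0 and a
    warning; the retained list per axis holds traits with \\|r\\| > threshold.
    """
    if n_axes > model.scores.shape[1]:
        raise IncompletePcaError(
            f"requested {n_axes} axes but model has {model.scores.shape[1]}"
        )
    x = np.asarray(table.matrix, dtype=float)
    mask = np.asarray(table.mask, dtype=bool)
    abbrs = table.dictionary.abbreviations
    p = x.shape[1]
    r = np.zeros((p, n_axes))
    zero_var: list[str] = []
    for j in range(p):
        obs = mask[:, j]
        xj = x[obs, j]
        if xj.size < 2 or np.ptp(xj) == 0.0:
            zero_var.append(abbrs[j])
            continue
        for a in range(n_axes):
            if model.eigenvalues[a] == 0.0:  # degenerate axis: no signal
                continue
            sa = model.scores[obs, a]
            if np.ptp(sa) == 0.0:
                continue
            r[j, a] = np.corrcoef(xj, sa)[0, 1]
    if zero_var:
        warnings.warn(
            f"traits with zero variance, correlation set to 0: {zero_var}",
            stacklevel=2,
        )
    retained = [
        [abbrs[j] for j in range(p) if abs(r[j, a]) > threshold]
        for a in range(n_axes)
    ]
    return TraitAxisCorrelation(r, retained, threshold, zero_var)
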