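"""Desk-scale morph-contrast analysis on ROI-level beta profiles.

Each participant contributes 15 ROI betas, one per morph regressor.  Valence
and ambiguity are modelled by a linear and a quadratic contrast centered on
the middle morph (s = 8): the linear weights are proportional to ``s - 8``
(antisymmetric, coding happy-to-angry valence) and the quadratic weights to
``(s - 8)^2`` minus its mean (centered, hence orthogonal to the linear term,
coding ambiguity).  Both are normalised to unit sum of squares so projection
coefficients are comparable across ROIs.  Per-participant coefficients come
from a least-squares projection of the beta profile onto the two contrasts
(plus an intercept), and the linear coefficient is then associated with a
clinical score by Pearson correlation (with median-split group means for
plotting).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .group_stats import CorrelationResult, pearson_bonferroni

__all__ = [
    "ContrastWeights",
    "morph_contrast_weights",
    "fit_individual_slopes",
    "slope_symptom_association",
    "AssociationReport",
]


@dataclass(frozen=True)
class ContrastWeights:
    """Linear (valence) and quadratic (ambiguity) contrast weight vectors;
    each sums to zero, they are mutually orthogonal, and each has unit sum
    of squares."""

    linear: np.ndarray
    quadratic: np.ndarray


@dataclass(frozen=True)
class AssociationReport:
    """Coefficient-symptom association plus median-split summaries."""

    corr: CorrelationResult
    median_cutoff: float
    low_group_mean: float
    high_group_mean: float
    n_low: int
    n_high: int


def morph_contrast_weights(n_morphs: int = 15) -> ContrastWeights:
    """Centered linear and quadratic morph contrasts.

    Requires an odd ``n_morphs >= 3`` so a middle morph exists.  Integer
    weights ``s - mid`` and ``(s - mid)^2 - mean`` are built first, then each
    vector is scaled to unit sum of squares.
    """
    if n_morphs < 3 or n_morphs % 2 == 0:
        raise ValueError(f"n_morphs must be odd and >= 3, got {n_morphs}")
    s = np.arange(1, n_morphs + 1, dtype=float)
    mid = (1 + n_morphs) / 2.0
    lin = s - mid
    quad = lin**2 - np.mean(lin**2)
    lin = lin / np.sqrt(np.sum(lin**2))
    quad = quad / np.sqrt(np.sum(quad**2))
    return ContrastWeights(linear=lin, quadratic=quad)


def fit_individual_slopes(betas, n_morphs: int = 15) -> tuple[float, float]:
    """Project one participant's beta profile onto the two contrasts.

    Least squares with an intercept; because the regressors are orthonormal
    and centered the coefficients equal the dot products with the weights.
    Returns ``(linear_coef, quadratic_coef)``.
    """
    b = np.asarray(betas, dtype=float)
    if b.shape != (n_morphs,):
        raise ValueError(f"expected {n_morphs} betas, got shape {b.shape}")
    if not np.all(np.isfinite(b)):
        raise ValueError("betas must be finite")
    w = morph_contrast_weights(n_morphs)
    X = np.column_stack([np.ones(n_morphs), w.linear, w.quadratic])
    coef, *_ = np.linalg.lstsq(X, b, rcond=None)
    return float(coef[1]), float(coef[2])


def slope_symptom_association(coefs, scores, n_family: int = 1) -> AssociationReport:
    """Pearson association between per-participant linear coefficients and a
    symptom score, with median-split group means of the coefficient for
    display parity with the usual post hoc illustration.

    Ties at the median go to the high group.
    """
    coefs = np.asarray(coefs, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if coefs.shape != scores.shape or coefs.ndim != 1:
        raise ValueError("coefs and scores must be 1-D and the same length")
    if len(coefs) < 3:
        raise ValueError("need at least 3 participants")
    corr = pearson_bonferroni(coefs, scores, n_family)
    cutoff = float(np.median(scores))
    high = scores >= cutoff
    return AssociationReport(
        corr=corr,
        median_cutoff=cutoff,
        low_group_mean=float(np.mean(coefs[~high])) if np.any(~high) else np.nan,
        high_group_mean=float(np.mean(coefs[high])),
        n_low=int(np.sum(~high)),
        n_high=int(np.sum(high)),
    )
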