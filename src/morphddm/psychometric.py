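"""Group-level 4-parameter logistic psychometric fit and inflection comparison.

The group psychometric curve plots the mean proportion of angry judgments
against the morph index and is modelled as

    p(s) = gamma + (lam - gamma) / (1 + exp(-beta * (s - x0))),

with free lower/upper asymptotes ``gamma``/``lam`` (adjusting the inflection
for the maximum probability of either judgment), slope ``beta`` and
inflection ``x0``.  Group inflections are compared with a Wald test
``t = (x0_A - x0_B) / sqrt(se_A^2 + se_B^2)`` at a configured number of
degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .core_ddm import ANGRY, N_MORPHS, TrialRecord

__all__ = [
    "FourPLFit",
    "four_pl",
    "group_proportions",
    "fit_4pl",
    "compare_inflections",
    "wald_inflection_test",
]

#: Default degrees of freedom for the inflection comparison.  Not derivable
#: from the group sizes alone; a reporting convention, configurable.
DEFAULT_COMPARISON_DF = 50


@dataclass(frozen=True)
class FourPLFit:
    """4PL estimates with standard errors from the Jacobian at the optimum."""

    gamma: float
    lam: float
    beta: float
    x0: float
    se_x0: float
    cov: np.ndarray  # 4x4, parameter order (gamma, lam, beta, x0)
    converged: bool
    n_points: int
    rss: float

    def predict(self, s) -> np.ndarray:
        return four_pl(np.asarray(s, dtype=float), self.gamma, self.lam, self.beta, self.x0)


def four_pl(s, gamma: float, lam: float, beta: float, x0: float):
    """Evaluate the 4-parameter logistic."""
    return gamma + (lam - gamma) / (1.0 + np.exp(-beta * (np.asarray(s, float) - x0)))


def group_proportions(trials_by_participant: Mapping[str, Iterable[TrialRecord]]) -> pd.Series:
    """Mean over participants of each participant's per-morph proportion of
    angry responses.

    Morphs with no data in any participant are absent from the result (the
    caller sees the gap rather than an imputed value).
    """
    if len(trials_by_participant) == 0:
        raise ValueError("need at least one participant")
    per_part = []
    for pid, trials in trials_by_participant.items():
        trials = list(trials)
        if not trials:
            continue
        s = np.array([t.s for t in trials])
        angry = np.array([t.choice == ANGRY for t in trials], dtype=float)
        props = {int(lv): float(np.mean(angry[s == lv])) for lv in np.unique(s)}
        per_part.append(pd.Series(props, name=pid))
    if not per_part:
        raise ValueError("all participants empty")
    table = pd.DataFrame(per_part)
    means = table.mean(axis=0, skipna=True).sort_index()
    means.index.name = "morph"
    means.name = "p_angry"
    return means


def fit_4pl(
    morphs: Sequence[float],
    proportions: Sequence[float],
    n_per_point: Sequence[int] | None = None,
    weighted: bool = False,
) -> FourPLFit:
    """Least-squares 4PL fit of proportion-angry vs morph.

    Multi-start over a grid of candidate inflections; parameter bounds keep
    ``0 <= gamma, lam <= 1`` and ``beta > 0``.  Standard errors come from the
    Gauss-Newton covariance ``(J'J)^-1 * rss/(n-4)``.  With ``weighted=True``
    residuals are scaled by ``sqrt(n_per_point)`` (binomial precision
    weighting); the default is unweighted, matching a plain fit to group mean
    proportions.
    """
    x = np.asarray(morphs, dtype=float)
    y = np.asarray(proportions, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("morphs and proportions must be 1-D and the same length")
    if len(x) < 6:
        raise ValueError("need at least 6 points spanning both asymptote regions")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    if weighted:
        if n_per_point is None:
            raise ValueError("weighted fit requires n_per_point")
        w = np.sqrt(np.asarray(n_per_point, dtype=float))
    else:
        w = np.ones_like(x)

    lo = np.array([0.0, 0.0, 1e-3, x.min() - 5.0])
    hi = np.array([1.0, 1.0, 50.0, x.max() + 5.0])

    def resid(theta):
        return w * (four_pl(x, *theta) - y)

    best = None
    x0_grid = np.linspace(x.min() + 1.0, x.max() - 1.0, 7)
    for x0_start in x0_grid:
        theta0 = np.array([max(y.min(), 1e-3), min(y.max(), 1 - 1e-3), 1.0, x0_start])
        theta0 = np.clip(theta0, lo + 1e-9, hi - 1e-9)
        if theta0[0] >= theta0[1]:
            theta0[0], theta0[1] = 0.05, 0.95
        res = least_squares(resid, theta0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12)
        if best is None or res.cost < best.cost:
            best = res

    theta = best.x
    n, p = len(x), 4
    rss = float(2.0 * best.cost)
    dof = max(n - p, 1)
    J = best.jac
    try:
        cov = np.linalg.inv(J.T @ J) * (rss / dof)
        se_x0 = float(np.sqrt(max(cov[3, 3], 0.0)))
        converged = bool(best.success)
    except np.linalg.LinAlgError:
        cov = np.full((4, 4), np.nan)
        se_x0 = np.nan
        converged = False
    return FourPLFit(
        gamma=float(theta[0]), lam=float(theta[1]), beta=float(theta[2]),
        x0=float(theta[3]), se_x0=se_x0, cov=cov, converged=converged,
        n_points=n, rss=rss,
    )


def wald_inflection_test(
    x0_a: float, se_a: float, x0_b: float, se_b: float, df: int = DEFAULT_COMPARISON_DF
) -> tuple[float, float]:
    """Wald comparison of two inflection estimates.

    ``t = (x0_a - x0_b) / sqrt(se_a^2 + se_b^2)``; two-sided p from the t
    distribution with the configured ``df``.
    """
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    t = (x0_a - x0_b) / np.hypot(se_a, se_b)
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def compare_inflections(
    fit_a: FourPLFit, fit_b: FourPLFit, df: int = DEFAULT_COMPARISON_DF
) -> tuple[float, float]:
    """Wald test of the difference between two fitted group inflections."""
    if not (fit_a.converged and fit_b.converged):
        raise ValueError("both fits must have converged")
    return wald_inflection_test(fit_a.x0, fit_a.se_x0, fit_b.x0, fit_b.se_x0, df)
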