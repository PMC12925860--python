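"""Stimulus-dependent-drift diffusion model for binary happy--angry labeling.

The observer views one of 15 face-emotion morphs (``s = 1`` prototypically
happy, ``s = 15`` prototypically angry, ``s = 8`` maximally ambiguous) and a
Wiener diffusion accumulates noisy evidence between two absorbing boundaries:
the upper boundary codes an "angry" response, the lower codes "happy".  The
drift rate is linear in the morph index,

    v(s) = v_int + s * v_slope,

so two derived quantities summarise the observer: *sensitivity* (``v_slope``,
how steeply evidence strength tracks valence) and the *perceptual bias* or
indifference point ``s_indiff = -v_int / v_slope``, the morph at which drift
vanishes.  The diffusion constant is fixed at ``sigma = 1`` as the scaling
convention (only two of ``v``, ``a``, ``sigma`` are identifiable).

This module provides the forward model: drift mapping, analytic absorption
probabilities, the Wiener first-passage-time (WFPT) density via dual
small-time/large-time series expansions, an Euler--Maruyama trial simulator,
and the joint (choice, RT) log-likelihood.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "N_MORPHS",
    "MIDDLE_MORPH",
    "ANGRY",
    "HAPPY",
    "StimulusRangeError",
    "UndefinedBiasError",
    "DDMParams",
    "TrialRecord",
    "drift_rate",
    "indifference_point",
    "choice_probability",
    "wfpt_density",
    "simulate_trials",
    "negative_log_likelihood",
]

#: Number of steps on the happy-to-angry morph continuum.
N_MORPHS = 15
#: The maximally ambiguous middle morph.
MIDDLE_MORPH = 8

ANGRY = "angry"
HAPPY = "happy"

#: Per-evaluation truncation error bound for the WFPT series.
_WFPT_ERR = 1e-7

#: Continuity-correction constant for discretely monitored absorbing
#: boundaries (Broadie-Glasserman-Kou): the effective boundary is moved
#: inward by ``0.5826 * sigma * sqrt(dt)`` to compensate for within-step
#: excursions the Euler scheme cannot see.
_BGK_BETA = 0.5826


class StimulusRangeError(ValueError):
    """Morph index outside the 1..15 continuum."""


class UndefinedBiasError(ValueError):
    """Indifference point requested for an observer with zero sensitivity."""


@dataclass(frozen=True)
class DDMParams:
    """Parameters of one observer.

    Attributes
    ----------
    v_int : float
        Drift intercept (evidence / s).
    v_slope : float
        Drift increment per morph step; the sensitivity metric.
    a : float
        Boundary separation (> 0); distance between the happy and angry
        decision boundaries.
    z_r : float
        Relative starting point ``z / a`` in (0, 1); pre-stimulus response
        bias toward the angry (upper) boundary.
    t0 : float
        Non-decision time in seconds (>= 0).
    sigma : float
        Diffusion constant, fixed at 1 by convention.
    """

    v_int: float
    v_slope: float
    a: float
    z_r: float
    t0: float
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"boundary separation a must be > 0, got {self.a}")
        if not 0 < self.z_r < 1:
            raise ValueError(f"relative start z_r must be in (0, 1), got {self.z_r}")
        if self.t0 < 0:
            raise ValueError(f"non-decision time t0 must be >= 0, got {self.t0}")
        if not self.sigma > 0:
            raise ValueError(f"diffusion constant sigma must be > 0, got {self.sigma}")

    def with_(self, **kwargs) -> "DDMParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class TrialRecord:
    """One stimulus presentation: morph shown, response made, RT in seconds.

    Fixation-only schedule events never become TrialRecords.
    """

    participant: str
    run: int
    s: int
    choice: str
    rt: float

    def __post_init__(self) -> None:
        _check_stimulus(self.s)
        if self.choice not in (ANGRY, HAPPY):
            raise ValueError(f"choice must be {ANGRY!r} or {HAPPY!r}, got {self.choice!r}")
        if not self.rt > 0:
            raise ValueError(f"rt must be > 0, got {self.rt}")


def _check_stimulus(s) -> None:
    s_arr = np.asarray(s)
    if not np.all((s_arr >= 1) & (s_arr <= N_MORPHS)):
        raise StimulusRangeError(f"morph index must lie in 1..{N_MORPHS}, got {s}")
    if not np.all(s_arr == np.round(s_arr)):
        raise StimulusRangeError(f"morph index must be integer, got {s}")


def drift_rate(params: DDMParams, s) -> float | np.ndarray:
    """Drift rate ``v(s) = v_int + s * v_slope`` at morph index ``s``.

    ``s`` may be a scalar or array of integers in 1..15.
    """
    _check_stimulus(s)
    v = params.v_int + np.asarray(s, dtype=float) * params.v_slope
    return float(v) if np.isscalar(s) or np.ndim(s) == 0 else v


def indifference_point(params: DDMParams) -> float:
    """Perceptual bias ``s_indiff = -v_int / v_slope``: the morph at which
    drift is zero.

    The value is real-valued and may fall outside the physical 1..15
    continuum; callers flag, never clip, such values.

    Raises
    ------
    UndefinedBiasError
        If ``v_slope`` is zero (drift never crosses zero).
    """
    if params.v_slope == 0:
        raise UndefinedBiasError("indifference point undefined when v_slope is 0")
    return -params.v_int / params.v_slope


def choice_probability(params: DDMParams, s) -> float | np.ndarray:
    """Analytic probability of an "angry" (upper-boundary) response at morph ``s``.

    For drift v, start z = z_r * a and diffusion sigma,

        P(angry) = (1 - exp(-2 v z / sigma^2)) / (1 - exp(-2 v a / sigma^2)),

    with the continuous limit ``z_r`` as v -> 0.
    """
    v = drift_rate(params, s)
    p = _p_upper(np.asarray(v, dtype=float), params.a, params.z_r, params.sigma)
    return float(p) if np.ndim(v) == 0 else p


def _p_upper(v: np.ndarray, a: float, z_r: float, sigma: float) -> np.ndarray:
    """Absorption probability at the upper boundary, numerically stable.

    Uses expm1 throughout; for negative drift the complementary identity
    P_upper(v, z_r) = 1 - P_upper(-v, 1 - z_r) keeps all exponents negative.
    """
    shape = np.shape(v)
    v = np.atleast_1d(np.asarray(v, dtype=float))
    out = np.empty_like(v)
    k = 2.0 * a / sigma**2

    zero = v == 0.0
    out[zero] = z_r

    pos = v > 0
    if np.any(pos):
        vv = v[pos]
        out[pos] = np.expm1(-vv * k * z_r) / np.expm1(-vv * k)

    neg = v < 0
    if np.any(neg):
        vv = -v[neg]
        out[neg] = 1.0 - np.expm1(-vv * k * (1.0 - z_r)) / np.expm1(-vv * k)

    return out.reshape(shape)


# ---------------------------------------------------------------------------
# Wiener first-passage-time density (dual series expansion)
# ---------------------------------------------------------------------------

def _f0(tau: np.ndarray, w: np.ndarray, err: float = _WFPT_ERR) -> np.ndarray:
    """Density of the first passage through the LOWER boundary at normalised
    time ``tau`` for a zero-drift, unit-boundary, unit-diffusion process
    started at relative position ``w``.

    Switches between the small-time and large-time series, each truncated so
    the omitted tail is below ``err``.
    """
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    w = np.broadcast_to(np.asarray(w, dtype=float), tau.shape).copy()
    out = np.zeros(tau.shape)

    valid = tau > 0
    if not np.any(valid):
        return out

    t = tau[valid]
    ww = w[valid]

    # terms needed by each series (Navarro-Fuss style bounds)
    with np.errstate(invalid="ignore", divide="ignore"):
        arg_s = 2.0 * np.sqrt(2.0 * np.pi * t) * err
        ks = np.where(
            arg_s < 1.0,
            2.0 + np.sqrt(np.maximum(-2.0 * t * np.log(arg_s), 0.0)),
            2.0,
        )
        ks = np.maximum(ks, np.sqrt(t) + 1.0)
        arg_l = np.pi * t * err
        kl = np.where(
            arg_l < 1.0,
            np.sqrt(np.maximum(-2.0 * np.log(arg_l), 0.0) / (np.pi**2 * t)),
            1.0 / (np.pi * np.sqrt(t)),
        )
        kl = np.maximum(kl, 1.0 / (np.pi * np.sqrt(t)))

    use_small = ks < kl
    res = np.empty(t.shape)

    if np.any(use_small):
        ts, ws = t[use_small], ww[use_small]
        K = int(min(math.ceil(np.max(ks[use_small]) / 2.0) + 1, 64))
        kk = np.arange(-K, K + 1)[:, None]
        x = ws[None, :] + 2.0 * kk
        series = np.sum(x * np.exp(-(x**2) / (2.0 * ts[None, :])), axis=0)
        res[use_small] = series / np.sqrt(2.0 * np.pi * ts**3)

    if np.any(~use_small):
        tl, wl = t[~use_small], ww[~use_small]
        K = int(min(math.ceil(np.max(kl[~use_small])) + 1, 64))
        kk = np.arange(1, K + 1)[:, None]
        series = np.sum(
            kk * np.exp(-(kk**2) * np.pi**2 * tl[None, :] / 2.0)
            * np.sin(kk * np.pi * wl[None, :]),
            axis=0,
        )
        res[~use_small] = np.pi * series

    out[valid] = np.maximum(res, 0.0)  # guard tiny negative truncation residue
    return out


def _log_wfpt(
    rt: np.ndarray,
    v: np.ndarray,
    a: float,
    z_r: float,
    t0: float,
    upper: np.ndarray,
    sigma: float = 1.0,
) -> np.ndarray:
    """Log defective FPT density of each (rt, boundary) pair; -inf where the
    decision time is non-positive.

    The upper-boundary density is the lower-boundary density under the
    reflection v -> -v, w -> 1 - w.  General sigma is handled by rescaling
    to unit diffusion (v / sigma, a / sigma leave passage times unchanged).
    """
    rt = np.asarray(rt, dtype=float)
    v = np.broadcast_to(np.asarray(v, dtype=float), rt.shape)
    upper = np.broadcast_to(np.asarray(upper, dtype=bool), rt.shape)

    vn = v / sigma
    an = a / sigma
    veff = np.where(upper, -vn, vn)
    weff = np.where(upper, 1.0 - z_r, z_r)
    td = rt - t0

    logd = np.full(rt.shape, -np.inf)
    ok = td > 0
    if np.any(ok):
        f0 = _f0(td[ok] / an**2, weff[ok])
        with np.errstate(divide="ignore"):
            logd[ok] = (
                np.log(f0)
                - 2.0 * np.log(an)
                - veff[ok] * an * weff[ok]
                - 0.5 * veff[ok] ** 2 * td[ok]
            )
    return logd


def wfpt_density(t, params: DDMParams, s, boundary: str) -> float | np.ndarray:
    """Defective first-passage-time density (1/s) of observing response
    ``boundary`` at time ``t`` for morph ``s``.

    Zero for ``t <= t0``.  Integrates over t, summed with the opposite
    boundary, to 1; alone it integrates to the boundary's choice probability.
    """
    t_arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t_arr)):
        raise ValueError("t must be finite")
    if boundary not in (ANGRY, HAPPY):
        raise ValueError(f"boundary must be {ANGRY!r} or {HAPPY!r}")
    v = drift_rate(params, s)
    logd = _log_wfpt(
        np.atleast_1d(t_arr),
        v,
        params.a,
        params.z_r,
        params.t0,
        boundary == ANGRY,
        params.sigma,
    )
    dens = np.exp(logd)
    return float(dens[0]) if np.ndim(t) == 0 else dens.reshape(t_arr.shape)


# ---------------------------------------------------------------------------
# Trial simulation
# ---------------------------------------------------------------------------

def simulate_trials(
    params: DDMParams,
    schedule: Sequence[int],
    seed,
    *,
    participant: str = "sim",
    runs: Sequence[int] | None = None,
    dt: float = 1e-4,
    max_decision_time: float = 20.0,
) -> list[TrialRecord]:
    """Simulate one TrialRecord per schedule entry by Euler--Maruyama
    integration of the diffusion (step ``dt`` seconds).

    Absorption is checked against boundaries pulled inward by
    ``0.5826 * sigma * sqrt(dt)`` (continuity correction for discrete
    monitoring), which removes the leading-order discretisation bias in both
    choice fractions and passage times.  RT = decision time + t0.  The same
    seed always reproduces the same trials.
    """
    schedule = list(schedule)
    if len(schedule) == 0:
        raise ValueError("schedule must be non-empty")
    _check_stimulus(schedule)
    if runs is None:
        runs = [1] * len(schedule)

    rng = np.random.default_rng(seed)
    s_arr = np.asarray(schedule, dtype=int)
    v = params.v_int + s_arr * params.v_slope

    n = len(schedule)
    delta = _BGK_BETA * params.sigma * math.sqrt(dt)
    upper = params.a - delta
    lower = delta
    x = np.full(n, params.z_r * params.a)
    t_dec = np.zeros(n)
    hit_upper = np.zeros(n, dtype=bool)
    active = np.ones(n, dtype=bool)

    sqdt = math.sqrt(dt) * params.sigma
    max_steps = int(max_decision_time / dt)
    idx = np.arange(n)
    for _ in range(max_steps):
        act = idx[active]
        if act.size == 0:
            break
        noise = rng.standard_normal(act.size)
        x[act] += v[act] * dt + sqdt * noise
        t_dec[act] += dt
        up = x[act] >= upper
        dn = x[act] <= lower
        done = up | dn
        hit_upper[act[up]] = True
        active[act[done]] = False
    if np.any(active):  # pathological tail: absorb at the nearer boundary
        rem = idx[active]
        hit_upper[rem] = x[rem] >= params.z_r * params.a
        warnings.warn(
            f"{rem.size} path(s) not absorbed within {max_decision_time} s; "
            "forced absorption at the nearer boundary"
        )

    return [
        TrialRecord(
            participant=participant,
            run=int(runs[i]),
            s=int(s_arr[i]),
            choice=ANGRY if hit_upper[i] else HAPPY,
            rt=float(t_dec[i] + params.t0),
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def trials_to_arrays(trials: Iterable[TrialRecord]):
    """(s, rt, is_angry) numpy arrays from a trial list."""
    trials = list(trials)
    s = np.array([t.s for t in trials], dtype=int)
    rt = np.array([t.rt for t in trials], dtype=float)
    upper = np.array([t.choice == ANGRY for t in trials], dtype=bool)
    return s, rt, upper


def _nll_arrays(
    theta: np.ndarray,
    s: np.ndarray,
    rt: np.ndarray,
    upper: np.ndarray,
    sigma: float = 1.0,
) -> float:
    """Negative log-likelihood from parameter vector
    (v_int, v_slope, a, z_r, t0) and trial arrays; +inf when invalid."""
    v_int, v_slope, a, z_r, t0 = (float(x) for x in theta)
    if not (a > 0 and 0 < z_r < 1 and t0 >= 0):
        return np.inf
    v = v_int + s * v_slope
    logd = _log_wfpt(rt, v, a, z_r, t0, upper, sigma)
    if not np.all(np.isfinite(logd)):
        return np.inf
    return float(-np.sum(logd))


def negative_log_likelihood(params: DDMParams, trials: Iterable[TrialRecord]) -> float:
    """Joint (choice, RT) negative log-likelihood of the trials.

    Empty trial list returns 0 with a warning; any RT at or below ``t0``
    makes the likelihood zero, returned as +inf.
    """
    trials = list(trials)
    if len(trials) == 0:
        warnings.warn("negative_log_likelihood of an empty trial list is 0")
        return 0.0
    s, rt, upper = trials_to_arrays(trials)
    theta = np.array([params.v_int, params.v_slope, params.a, params.z_r, params.t0])
    return _nll_arrays(theta, s, rt, upper, params.sigma)
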