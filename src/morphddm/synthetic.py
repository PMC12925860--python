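"""Synthetic inputs for every pipeline stage.

Everything the analysis consumes can be generated offline and
deterministically from a seed:

* **Task schedules** mirroring the scanner task: 15 morphs x 30 presentations
  plus 90 fixation-only events (540 events over 4 runs), jittered ITIs drawn
  from a shifted exponential with a 500 ms floor, 10 s fixation at the start
  and end of each run, expected run length ~421 s.
* **DDM observer groups** with group-specific indifference-point
  distributions (DMDD mean 7.52, SD 0.95; healthy controls mean 8.48,
  SD 1.40) and configurable nuisance-parameter distributions.
* **Clinical cohorts**: child- and parent-report SCARED (41 items, 0-2 each,
  total 0-82) and ARI (6 items, 0-2 each, total 0-12) generated item-by-item
  through a Gaussian copula whose latent correlations are analytically
  de-attenuated (Hermite expansion of the item-mean function) so the
  *observed total-score* correlations hit the requested targets.
* **ROI beta profiles** with a configurable symptom-coupled valence slope for
  the morph-contrast analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .core_ddm import DDMParams, N_MORPHS, TrialRecord, simulate_trials
from .neural_contrasts import morph_contrast_weights

__all__ = [
    "ScheduleEvent",
    "TaskSchedule",
    "generate_task_schedule",
    "GroupSpec",
    "DEFAULT_GROUP_SPECS",
    "generate_observer_group",
    "simulate_observer_trials",
    "score_ari",
    "score_scared",
    "DEFAULT_CORRELATION_TARGETS",
    "generate_clinical_cohort",
    "generate_roi_betas",
    "coupling_for_target_r",
]

# ---------------------------------------------------------------------------
# Task schedule
# ---------------------------------------------------------------------------

#: Presentations of each morph across the session.
PRESENTATIONS_PER_MORPH = 30
#: Fixation-only events across the session.
N_FIXATION_EVENTS = 90
#: Session runs, with the stimulus/fixation split per run (total 450 + 90).
STIMULUS_SPLIT = (113, 113, 112, 112)
FIXATION_SPLIT = (23, 23, 22, 22)
#: Seconds of fixation at the start and end of each run.
RUN_PADDING_S = 10.0
#: Face (150 ms) + mask (250 ms) presentation slot.
EVENT_DURATION_S = 0.4
#: Jitter floor.
MIN_ITI_S = 0.5
#: Target expected run duration.
RUN_DURATION_S = 421.0


@dataclass(frozen=True)
class ScheduleEvent:
    kind: str  # "stimulus" or "fixation"
    s: int | None  # morph index for stimulus events, None for fixation
    onset: float  # seconds from run start
    iti: float  # jitter following this event, seconds


@dataclass(frozen=True)
class TaskSchedule:
    runs: tuple[tuple[ScheduleEvent, ...], ...]

    @property
    def events(self) -> list[ScheduleEvent]:
        return [e for run in self.runs for e in run]

    def stimulus_sequence(self) -> tuple[list[int], list[int]]:
        """Flat (morph index, run number) lists over stimulus events only."""
        s, runs = [], []
        for i, run in enumerate(self.runs, start=1):
            for e in run:
                if e.kind == "stimulus":
                    s.append(e.s)
                    runs.append(i)
        return s, runs


def generate_task_schedule(seed) -> TaskSchedule:
    """Pseudo-random task schedule satisfying the session invariants.

    Each morph appears exactly 30 times, 90 fixation-only events are mixed
    in, event order is shuffled per seed, ITIs are ``0.5 s + Exp(scale)``
    with the scale set so the expected run length is ~421 s including the
    10 s lead-in/out.
    """
    rng = np.random.default_rng(seed)
    morphs = np.repeat(np.arange(1, N_MORPHS + 1), PRESENTATIONS_PER_MORPH)
    rng.shuffle(morphs)

    runs = []
    consumed = 0
    for n_stim, n_fix in zip(STIMULUS_SPLIT, FIXATION_SPLIT):
        run_morphs = morphs[consumed:consumed + n_stim]
        consumed += n_stim
        kinds = ["stimulus"] * n_stim + ["fixation"] * n_fix
        order = rng.permutation(len(kinds))
        n_events = n_stim + n_fix
        mean_iti = (RUN_DURATION_S - 2 * RUN_PADDING_S - n_events * EVENT_DURATION_S) / n_events
        itis = MIN_ITI_S + rng.exponential(mean_iti - MIN_ITI_S, size=n_events)

        events = []
        t = RUN_PADDING_S
        stim_iter = iter(run_morphs)
        for pos, j in enumerate(order):
            kind = kinds[j]
            s = int(next(stim_iter)) if kind == "stimulus" else None
            events.append(ScheduleEvent(kind=kind, s=s, onset=t, iti=float(itis[pos])))
            t += EVENT_DURATION_S + itis[pos]
        runs.append(tuple(events))
    return TaskSchedule(runs=tuple(runs))


# ---------------------------------------------------------------------------
# Observer groups
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSpec:
    """Generative description of one diagnostic group's DDM observers.

    ``s_indiff`` moments for DMDD (7.52, 0.95) and healthy controls
    (8.48, 1.40) follow the reported group statistics; the remaining groups'
    moments and all nuisance-parameter distributions are generator choices
    (see docs/methods.md) exposed here for configuration.
    """

    name: str
    n: int
    s_indiff_mean: float
    s_indiff_sd: float
    v_slope_median: float = 0.25
    v_slope_sdlog: float = 0.2
    a_mean: float = 1.2
    a_sd: float = 0.2
    z_r_mean: float = 0.5
    z_r_sd: float = 0.05
    t0_mean: float = 0.25
    t0_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("group size must be positive")
        for nm in ("s_indiff_sd", "v_slope_sdlog", "a_sd", "z_r_sd", "t0_sd"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be >= 0")


DEFAULT_GROUP_SPECS: dict[str, GroupSpec] = {
    "DMDD": GroupSpec("DMDD", 27, 7.52, 0.95),
    "ADHD": GroupSpec("ADHD", 23, 8.20, 1.20),
    "Anxiety": GroupSpec("Anxiety", 19, 8.20, 1.20),
    "ODD": GroupSpec("ODD", 2, 8.20, 1.20),
    "Healthy": GroupSpec("Healthy", 24, 8.48, 1.40),
}


def generate_observer_group(spec: GroupSpec, seed) -> list[tuple[str, DDMParams]]:
    """Draw ``spec.n`` observers: ``s_indiff ~ N(mean, sd)``, ``v_slope``
    lognormal, then ``v_int = -s_indiff * v_slope``; nuisance parameters from
    truncated normals.  Deterministic in (spec, seed)."""
    rng = np.random.default_rng(seed)
    s_indiff = rng.normal(spec.s_indiff_mean, spec.s_indiff_sd, size=spec.n)
    v_slope = np.exp(rng.normal(math.log(spec.v_slope_median), spec.v_slope_sdlog, size=spec.n))
    a = np.clip(rng.normal(spec.a_mean, spec.a_sd, size=spec.n), 0.6, 2.5)
    z_r = np.clip(rng.normal(spec.z_r_mean, spec.z_r_sd, size=spec.n), 0.2, 0.8)
    t0 = np.clip(rng.normal(spec.t0_mean, spec.t0_sd, size=spec.n), 0.1, 0.5)
    out = []
    for i in range(spec.n):
        pid = f"{spec.name}_{i + 1:03d}"
        params = DDMParams(
            v_int=float(-s_indiff[i] * v_slope[i]),
            v_slope=float(v_slope[i]),
            a=float(a[i]),
            z_r=float(z_r[i]),
            t0=float(t0[i]),
        )
        out.append((pid, params))
    return out


def simulate_observer_trials(
    params: DDMParams, schedule: TaskSchedule, seed, participant: str
) -> list[TrialRecord]:
    """Simulate one observer through a task schedule (stimulus events only;
    fixation events produce no trials)."""
    s, runs = schedule.stimulus_sequence()
    return simulate_trials(params, s, seed, participant=participant, runs=runs)


# ---------------------------------------------------------------------------
# Questionnaires
# ---------------------------------------------------------------------------

ARI_N_ITEMS = 6
SCARED_N_ITEMS = 41
ITEM_MAX = 2  # items scored 0/1/2, inferred from the printed totals


def _score_items(items, n_items: int, name: str) -> int:
    arr = np.asarray(items)
    if arr.shape != (n_items,):
        raise ValueError(f"{name} expects {n_items} items, got shape {arr.shape}")
    if np.any((arr < 0) | (arr > ITEM_MAX)) or np.any(arr != np.round(arr)):
        raise ValueError(f"{name} items must be integers in 0..{ITEM_MAX}")
    return int(np.sum(arr))


def score_ari(items) -> int:
    """Total ARI irritability score: 6 items scored 0-2, total 0-12."""
    return _score_items(items, ARI_N_ITEMS, "ARI")


def score_scared(items) -> int:
    """Total SCARED anxiety score: 41 items scored 0-2, total 0-82."""
    return _score_items(items, SCARED_N_ITEMS, "SCARED")


# ---------------------------------------------------------------------------
# Clinical cohort via a calibrated Gaussian copula
# ---------------------------------------------------------------------------

_SCALES = ("scared_child", "scared_parent", "ari_child", "ari_parent")
_SCALE_ITEMS = {"scared_child": SCARED_N_ITEMS, "scared_parent": SCARED_N_ITEMS,
                "ari_child": ARI_N_ITEMS, "ari_parent": ARI_N_ITEMS}

#: Item-factor loading of each scale's items on its latent trait.  Chosen to
#: match the instruments' published internal consistencies (alpha ~ 0.9).
DEFAULT_LOADING = 0.9

#: Target Pearson correlations between observed total scores.  The four
#: reported cells are cross-informant (0.58 anxiety, 0.56 irritability) and
#: within-informant cross-measure (0.46 child, 0.50 parent); the two
#: cross-informant-cross-measure cells are unreported and set to a plausible
#: intermediate value.
DEFAULT_CORRELATION_TARGETS: dict[frozenset, float] = {
    frozenset(("scared_child", "scared_parent")): 0.58,
    frozenset(("ari_child", "ari_parent")): 0.56,
    frozenset(("scared_child", "ari_child")): 0.46,
    frozenset(("scared_parent", "ari_parent")): 0.50,
    frozenset(("scared_child", "ari_parent")): 0.35,
    frozenset(("scared_parent", "ari_child")): 0.35,
}

AGE_RANGE = (8.0, 22.0)

#: Primary-diagnosis sampling probabilities (proportions of the reported
#: 95-participant sample).
DIAGNOSIS_PROBS = {"DMDD": 27 / 95, "ADHD": 23 / 95, "Anxiety": 19 / 95,
                   "ODD": 2 / 95, "Healthy": 24 / 95}

# tercile cutpoints for 0/1/2 item discretisation (equal-mass)
_C1 = stats.norm.ppf(1.0 / 3.0)
_C2 = stats.norm.ppf(2.0 / 3.0)
_ITEM_VAR = 2.0 / 3.0  # variance of a uniform {0,1,2} item

_HERMITE_ORDER = 9
_GH_NODES = 80


def _item_mean_given_theta(theta: np.ndarray, lam: float) -> np.ndarray:
    """m(theta) = E[item | latent trait theta] for loading ``lam``."""
    s = math.sqrt(1.0 - lam**2)
    return stats.norm.cdf((lam * theta - _C1) / s) + stats.norm.cdf((lam * theta - _C2) / s)


def _hermite_coefs(lam: float, order: int = _HERMITE_ORDER) -> np.ndarray:
    """Probabilists'-Hermite expansion coefficients a_k of m(theta),
    k = 0..order, via Gauss-Hermite quadrature."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(_GH_NODES)
    weights = weights / math.sqrt(2.0 * math.pi)
    m = _item_mean_given_theta(nodes, lam)
    coefs = np.empty(order + 1)
    for k in range(order + 1):
        He_k = np.polynomial.hermite_e.hermeval(nodes, [0] * k + [1])
        coefs[k] = float(np.sum(weights * m * He_k)) / math.factorial(k)
    return coefs


def _total_score_moments(n_items: int, coefs: np.ndarray) -> tuple[float, np.ndarray]:
    """SD of the total score and the per-order cross-covariance weights.

    cov(T_A, T_B) = n_A n_B * sum_k a_k^A a_k^B k! rho^k for latent
    correlation rho; var(T) = n var(item) + n(n-1) var(m)."""
    ks = np.arange(1, len(coefs))
    var_m = float(np.sum(coefs[1:] ** 2 * np.array([math.factorial(k) for k in ks])))
    var_t = n_items * _ITEM_VAR + n_items * (n_items - 1) * var_m
    return math.sqrt(var_t), coefs


def _latent_correlation_for_target(
    target: float, n_a: int, coefs_a: np.ndarray, sd_a: float,
    n_b: int, coefs_b: np.ndarray, sd_b: float,
) -> float:
    """Invert the Hermite series to find the latent-trait correlation that
    yields the requested observed total-score correlation."""
    ks = np.arange(1, len(coefs_a))
    fact = np.array([math.factorial(k) for k in ks])
    weights = coefs_a[1:] * coefs_b[1:] * fact

    def observed_r(rho: float) -> float:
        return float(n_a * n_b * np.sum(weights * rho**ks) / (sd_a * sd_b))

    max_r = observed_r(1.0)
    if abs(target) >= abs(max_r):
        raise ValueError(
            f"target correlation {target} exceeds the attainable maximum "
            f"{max_r:.3f} after discretisation"
        )
    return brentq(lambda r: observed_r(r) - target, -0.9999, 0.9999, xtol=1e-10)


def generate_clinical_cohort(
    n: int,
    seed,
    correlation_targets: Mapping[frozenset, float] | None = None,
    loading: float = DEFAULT_LOADING,
    participants: Sequence[str] | None = None,
    diagnoses: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Synthetic clinical table: age, sex, primary diagnosis, and child- and
    parent-report SCARED and ARI totals with calibrated correlations.

    Latent traits are drawn from a multivariate normal whose correlation
    matrix is solved (per pair, by Hermite-series inversion) so that the
    correlations between the *discretised total scores* match
    ``correlation_targets``; item responses are the latent item values
    thresholded at equal-mass (tercile) cutpoints.  The latent matrix is
    checked for positive semi-definiteness before any sampling.  Ages are
    uniform on [8, 22].

    ``participants``/``diagnoses`` may be supplied to align the table with a
    simulated observer cohort; otherwise ids are generated and diagnoses
    drawn from the reported sample proportions.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    targets = dict(DEFAULT_CORRELATION_TARGETS)
    if correlation_targets:
        targets.update(correlation_targets)

    coefs = {sc: _hermite_coefs(loading) for sc in _SCALES}
    sds = {sc: _total_score_moments(_SCALE_ITEMS[sc], coefs[sc])[0] for sc in _SCALES}

    latent = np.eye(len(_SCALES))
    for i, sa in enumerate(_SCALES):
        for j, sb in enumerate(_SCALES):
            if j <= i:
                continue
            tgt = targets[frozenset((sa, sb))]
            latent[i, j] = latent[j, i] = _latent_correlation_for_target(
                tgt, _SCALE_ITEMS[sa], coefs[sa], sds[sa],
                _SCALE_ITEMS[sb], coefs[sb], sds[sb],
            )
    eigvals = np.linalg.eigvalsh(latent)
    if eigvals.min() < -1e-10:
        raise ValueError(
            f"latent correlation matrix is not positive semi-definite "
            f"(min eigenvalue {eigvals.min():.3g})"
        )

    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(latent + 1e-12 * np.eye(len(_SCALES)))
    theta = rng.standard_normal((n, len(_SCALES))) @ chol.T

    s_noise = math.sqrt(1.0 - loading**2)
    totals = {}
    for k, sc in enumerate(_SCALES):
        n_items = _SCALE_ITEMS[sc]
        x = loading * theta[:, [k]] + s_noise * rng.standard_normal((n, n_items))
        items = (x > _C1).astype(int) + (x > _C2).astype(int)
        totals[sc] = items.sum(axis=1)

    if participants is None:
        participants = [f"P{i + 1:04d}" for i in range(n)]
    if diagnoses is None:
        labels = list(DIAGNOSIS_PROBS)
        probs = np.array([DIAGNOSIS_PROBS[g] for g in labels])
        diagnoses = rng.choice(labels, size=n, p=probs)
    if len(participants) != n or len(diagnoses) != n:
        raise ValueError("participants/diagnoses must have length n")

    return pd.DataFrame({
        "participant": list(participants),
        "age": rng.uniform(*AGE_RANGE, size=n),
        "sex": rng.choice(["F", "M"], size=n),
        "diagnosis": list(diagnoses),
        "scared_child": totals["scared_child"],
        "scared_parent": totals["scared_parent"],
        "ari_child": totals["ari_child"],
        "ari_parent": totals["ari_parent"],
    })


# ---------------------------------------------------------------------------
# ROI betas
# ---------------------------------------------------------------------------

def coupling_for_target_r(target_r: float, noise_sd: float, base_slope_sd: float = 0.0) -> float:
    """Coupling strength giving an expected coefficient-symptom correlation
    of ``target_r`` when the symptom score is standardised: projection noise
    on the unit-norm linear contrast has SD ``noise_sd``."""
    if not 0 <= target_r < 1:
        raise ValueError("target_r must be in [0, 1)")
    return target_r * math.sqrt(noise_sd**2 + base_slope_sd**2) / math.sqrt(1.0 - target_r**2)


def generate_roi_betas(
    cohort: pd.DataFrame,
    coupling: float = 0.0,
    noise_sd: float = 0.5,
    seed=0,
    symptom: str = "ari_parent",
    base_slope: float = 0.5,
    base_quad: float = 0.3,
    intercept: float = 1.0,
) -> pd.DataFrame:
    """Per-participant 15-morph ROI beta profiles with a symptom-coupled
    valence slope.

    ``profile = intercept + (base_slope + coupling * z_symptom) * linear +
    base_quad * quadratic + N(0, noise_sd)`` where the contrasts are the
    unit-norm centered weights and ``z_symptom`` is the standardised symptom
    score.  ``coupling=0`` with ``noise_sd=0`` yields identical profiles."""
    if symptom not in cohort.columns:
        raise ValueError(f"cohort lacks symptom column {symptom!r}")
    rng = np.random.default_rng(seed)
    w = morph_contrast_weights(N_MORPHS)
    score = cohort[symptom].to_numpy(dtype=float)
    sd = score.std(ddof=0)
    z = (score - score.mean()) / sd if sd > 0 else np.zeros_like(score)
    slopes = base_slope + coupling * z
    profiles = (
        intercept
        + slopes[:, None] * w.linear[None, :]
        + base_quad * w.quadratic[None, :]
        + rng.normal(0.0, noise_sd, size=(len(cohort), N_MORPHS))
    )
    cols = [f"beta_{i}" for i in range(1, N_MORPHS + 1)]
    out = pd.DataFrame(profiles, columns=cols)
    out.insert(0, "participant", cohort["participant"].to_numpy())
    return out
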