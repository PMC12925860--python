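"""End-to-end pipeline: simulate -> QC -> fit -> psychometric -> stats -> contrasts.

Each stage reads its inputs from, and writes its artifacts to, a single
output directory, so any stage can be re-run from cached upstream outputs.
Every artifact is stamped (as a leading comment line) with the config hash
and master seed, and all numeric tables are written with a fixed float
format so identical (config, seed) runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import io_qc, synthetic
from .core_ddm import TrialRecord
from .fitting import FitConfig, fit_participant, fits_to_table
from .group_stats import (
    metric_clinical_correlations,
    oneway_anova,
    pairwise_t_bonferroni,
    replicate_age_sensitivity,
)
from .neural_contrasts import fit_individual_slopes, slope_symptom_association
from .psychometric import compare_inflections, fit_4pl, group_proportions
from .synthetic import (
    DEFAULT_GROUP_SPECS,
    GroupSpec,
    generate_clinical_cohort,
    generate_roi_betas,
    generate_observer_group,
    generate_task_schedule,
    simulate_observer_trials,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "run_stage", "STAGES"]

log = logging.getLogger("morphddm")

_FLOAT_FMT = "%.10g"

STAGES = ("simulate", "qc", "fit", "psychometric", "stats", "contrasts")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """All knobs of the pipeline; ``seed`` is mandatory and feeds every
    source of randomness through per-stage/per-participant substreams."""

    seed: int
    groups: dict[str, GroupSpec] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SPECS)
    )
    # QC
    rt_threshold_s: float = io_qc.FAST_RT_THRESHOLD_S
    accuracy_threshold: float = io_qc.EXTREME_ACCURACY_THRESHOLD
    qc_mode: str = "pooled"
    # fitting
    n_starts: int = 5
    # statistics
    df_inflection: int = 50
    psychometric_groups: tuple[str, str] = ("DMDD", "Healthy")
    anova_min_group_size: int = 2
    # contrasts
    contrast_symptom: str = "ari_parent"
    contrast_coupling: float = 0.19
    contrast_noise_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("config requires a seed")
        if self.rt_threshold_s <= 0 or not 0 < self.accuracy_threshold <= 1:
            raise ValueError("QC thresholds must be positive")
        for name, spec in list(self.groups.items()):
            if isinstance(spec, Mapping):
                self.groups[name] = GroupSpec(name=name, **spec)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("config file must specify 'seed'")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["groups"] = {k: dataclasses.asdict(v) for k, v in self.groups.items()}
        return d

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stamp(config: PipelineConfig) -> str:
    return f"# morphddm config_hash={config.config_hash} seed={config.seed}\n"


def _write_table(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_stamp(config))
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def _read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _write_text(text: str, path: Path, config: PipelineConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(_stamp(config) + text)


def _stage_seed(config: PipelineConfig, stage: str, k: int = 0) -> int:
    """Stable per-stage (and per-participant) substream seed < 2^31."""
    h = hashlib.sha256(f"{config.seed}:{stage}:{k}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, out: Path) -> None:
    """Generate schedule, observers, behavioral trials, clinical cohort and
    ROI betas."""
    schedule = generate_task_schedule(_stage_seed(config, "schedule"))
    observers: list[tuple[str, str, "DDMParams"]] = []
    for gi, (gname, spec) in enumerate(sorted(config.groups.items())):
        for pid, params in generate_observer_group(spec, _stage_seed(config, "observers", gi)):
            observers.append((pid, gname, params))
    log.info("simulate: %d observers, %d schedule events",
             len(observers), len(schedule.events))

    trials: list[TrialRecord] = []
    for k, (pid, _, params) in enumerate(observers):
        trials.extend(
            simulate_observer_trials(params, schedule, _stage_seed(config, "trials", k), pid)
        )
    truth = pd.DataFrame(
        [
            {"participant": pid, "diagnosis": g, "v_int": p.v_int,
             "v_slope": p.v_slope, "a": p.a, "z_r": p.z_r, "t0": p.t0,
             "s_indiff_true": -p.v_int / p.v_slope}
            for pid, g, p in observers
        ]
    )
    cohort = generate_clinical_cohort(
        len(observers),
        _stage_seed(config, "clinical"),
        participants=[pid for pid, _, _ in observers],
        diagnoses=[g for _, g, _ in observers],
    )
    betas = generate_roi_betas(
        cohort,
        coupling=config.contrast_coupling,
        noise_sd=config.contrast_noise_sd,
        seed=_stage_seed(config, "betas"),
        symptom=config.contrast_symptom,
    )

    trial_path = out / "trials.csv"
    trial_path.parent.mkdir(parents=True, exist_ok=True)
    io_qc.write_trials(trials, trial_path)
    _write_table(truth, out / "true_params.csv", config)
    _write_table(cohort, out / "cohort.csv", config)
    _write_table(betas, out / "roi_betas.csv", config)


def stage_qc(config: PipelineConfig, out: Path) -> None:
    """Apply the fast-RT trial filter and the extreme-morph inclusion rule."""
    trials = io_qc.read_trials(out / "trials.csv")
    by_part: dict[str, list[TrialRecord]] = {}
    for t in trials:
        by_part.setdefault(t.participant, []).append(t)
    kept_all, reports = [], []
    for pid, ts in by_part.items():
        kept, report = io_qc.qc_participant(
            ts, config.rt_threshold_s, config.accuracy_threshold, config.qc_mode
        )
        if report.included:
            kept_all.extend(kept)
        reports.append({
            "participant": pid,
            "n_trials_in": report.n_trials_in,
            "n_trials_fast_removed": report.n_trials_fast_removed,
            "extreme_morph_accuracy": report.extreme_morph_accuracy,
            "included": report.included,
        })
    log.info("qc: %d/%d participants included",
             sum(r["included"] for r in reports), len(reports))
    io_qc.write_trials(kept_all, out / "trials_qc.csv")
    _write_table(pd.DataFrame(reports), out / "qc_report.csv", config)


def stage_fit(config: PipelineConfig, out: Path) -> None:
    """Fit the DDM per included participant; emit the parameter table."""
    trials = io_qc.read_trials(out / "trials_qc.csv")
    by_part: dict[str, list[TrialRecord]] = {}
    for t in trials:
        by_part.setdefault(t.participant, []).append(t)
    fits = []
    for k, (pid, ts) in enumerate(sorted(by_part.items())):
        fit = fit_participant(
            ts, FitConfig(n_starts=config.n_starts, seed=_stage_seed(config, "fit", k))
        )
        log.debug("fit %s: bias=%s slope=%s nll=%.2f converged=%s",
                  pid, fit.perceptual_bias, fit.sensitivity, fit.nll, fit.converged)
        fits.append(fit)
    _write_table(fits_to_table(fits), out / "params.csv", config)


def _load_cohort_with_metrics(out: Path) -> pd.DataFrame:
    cohort = _read_table(out / "cohort.csv")
    params = _read_table(out / "params.csv")
    cols = ["participant", "sensitivity", "perceptual_bias", "a", "z_r", "t0", "converged"]
    return cohort.merge(params[cols], on="participant", how="inner")


def stage_psychometric(config: PipelineConfig, out: Path) -> None:
    """Group psychometric curves, 4PL fits and the inflection comparison."""
    trials = io_qc.read_trials(out / "trials_qc.csv")
    cohort = _read_table(out / "cohort.csv")
    diag = dict(zip(cohort["participant"], cohort["diagnosis"]))
    g_a, g_b = config.psychometric_groups
    curves = {}
    for gname in (g_a, g_b):
        by_part: dict[str, list[TrialRecord]] = {}
        for t in trials:
            if diag.get(t.participant) == gname:
                by_part.setdefault(t.participant, []).append(t)
        if not by_part:
            raise ValueError(f"no QC-passed trials for group {gname!r}")
        curves[gname] = group_proportions(by_part)

    fits = {g: fit_4pl(c.index.to_numpy(float), c.to_numpy()) for g, c in curves.items()}
    t, p = compare_inflections(fits[g_a], fits[g_b], df=config.df_inflection)

    curve_df = pd.DataFrame({
        "morph": curves[g_a].index,
        f"p_angry_{g_a}": curves[g_a].to_numpy(),
        f"p_angry_{g_b}": curves[g_b].reindex(curves[g_a].index).to_numpy(),
        f"fitted_{g_a}": fits[g_a].predict(curves[g_a].index.to_numpy(float)),
        f"fitted_{g_b}": fits[g_b].predict(curves[g_a].index.to_numpy(float)),
    })
    _write_table(curve_df, out / "psychometric_curves.csv", config)

    lines = []
    for g, f in fits.items():
        lines.append(
            f"group={g} gamma={f.gamma:.6g} lam={f.lam:.6g} beta={f.beta:.6g} "
            f"x0={f.x0:.6g} se_x0={f.se_x0:.6g} converged={f.converged}"
        )
    lines.append(
        f"inflection_comparison {g_a}-{g_b}: t({config.df_inflection})={t:.6g} p={p:.6g}"
    )
    _write_text("\n".join(lines) + "\n", out / "psychometric_report.txt", config)


def stage_stats(config: PipelineConfig, out: Path) -> None:
    """Correlation table, diagnostic ANOVAs with post hocs, and the
    age--sensitivity replication."""
    cohort = _load_cohort_with_metrics(out)
    cohort = cohort[cohort["converged"].astype(bool)]
    _write_table(metric_clinical_correlations(cohort), out / "correlations.csv", config)

    anova_rows, posthoc_tables = [], []
    sizes = cohort["diagnosis"].value_counts()
    usable = cohort[cohort["diagnosis"].map(sizes) >= config.anova_min_group_size]
    for metric in ("perceptual_bias", "sensitivity"):
        sub = usable.dropna(subset=[metric])
        f, df1, df2, p = oneway_anova(sub[metric], sub["diagnosis"])
        anova_rows.append({"metric": metric, "F": f, "df1": df1, "df2": df2, "p": p})
        ph = pairwise_t_bonferroni(sub[metric], sub["diagnosis"])
        ph.insert(0, "metric", metric)
        posthoc_tables.append(ph)
    _write_table(pd.DataFrame(anova_rows), out / "anova.csv", config)
    _write_table(pd.concat(posthoc_tables, ignore_index=True), out / "posthoc.csv", config)

    res = replicate_age_sensitivity(cohort.dropna(subset=["sensitivity"]))
    _write_text(
        f"age_sensitivity_patients: r={res.r:.6g} df={res.df} n={res.n} "
        f"p_raw={res.p_raw:.6g}\n",
        out / "age_sensitivity.txt",
        config,
    )


def stage_contrasts(config: PipelineConfig, out: Path) -> None:
    """ROI morph-contrast coefficients and their symptom association."""
    betas = _read_table(out / "roi_betas.csv")
    cohort = _read_table(out / "cohort.csv")
    merged = betas.merge(cohort[["participant", config.contrast_symptom]], on="participant")
    beta_cols = [f"beta_{i}" for i in range(1, 16)]
    coefs = np.array([
        fit_individual_slopes(row) for row in merged[beta_cols].to_numpy(dtype=float)
    ])
    coef_df = pd.DataFrame({
        "participant": merged["participant"],
        "linear_coef": coefs[:, 0],
        "quadratic_coef": coefs[:, 1],
    })
    _write_table(coef_df, out / "contrast_coefs.csv", config)
    rep = slope_symptom_association(coefs[:, 0], merged[config.contrast_symptom].to_numpy(float))
    _write_text(
        f"symptom={config.contrast_symptom} r={rep.corr.r:.6g} df={rep.corr.df} "
        f"p_raw={rep.corr.p_raw:.6g}\n"
        f"median_split cutoff={rep.median_cutoff:.6g} "
        f"low_mean={rep.low_group_mean:.6g} (n={rep.n_low}) "
        f"high_mean={rep.high_group_mean:.6g} (n={rep.n_high})\n",
        out / "contrast_association.txt",
        config,
    )


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "fit": stage_fit,
    "psychometric": stage_psychometric,
    "stats": stage_stats,
    "contrasts": stage_contrasts,
}


def run_stage(config: PipelineConfig, stage: str, out_dir) -> None:
    """Run one named stage against cached upstream artifacts in ``out_dir``."""
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        log.info("running stage %s", stage)
        _STAGE_FUNCS[stage](config, out)
    except Exception as exc:  # partial outputs are retained with a marker
        (out / f"FAILED_{stage}").write_text(repr(exc) + "\n")
        raise PipelineError(stage, exc) from exc


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Run all stages in order; returns the output directory."""
    out = Path(out_dir)
    for stage in STAGES:
        run_stage(config, stage, out)
    return out
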