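"""Trial-table I/O and the study's behavioral exclusion rules.

Trial files are plain delimited text with header
``participant,run,morph,choice,rt_s`` (RT in seconds; a millisecond column
can be read via ``rt_unit="ms"``).  Two QC rules apply:

* trial level — responses faster than 150 ms are discarded (strictly
  ``rt < 0.150``; exactly 150 ms is kept);
* participant level — inclusion requires at least 80% correct on the two
  most extreme morphs, where "correct" means happy at ``s = 1`` and angry at
  ``s = 15``, pooled over both extremes by default (a stricter per-morph
  minimum is available via ``mode="per_morph"``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .core_ddm import ANGRY, HAPPY, N_MORPHS, TrialRecord

__all__ = [
    "TrialValidationError",
    "QCReport",
    "read_trials",
    "write_trials",
    "filter_fast_rt",
    "inclusion_check",
    "qc_participant",
    "FAST_RT_THRESHOLD_S",
    "EXTREME_ACCURACY_THRESHOLD",
]

#: Trials faster than this (seconds) are excluded.
FAST_RT_THRESHOLD_S = 0.150
#: Minimum pooled accuracy on the extreme morphs for inclusion.
EXTREME_ACCURACY_THRESHOLD = 0.80

_COLUMNS = ["participant", "run", "morph", "choice", "rt_s"]


class TrialValidationError(ValueError):
    """Malformed trial table; carries per-line diagnostics."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid trial table:\n" + "\n".join(problems))


@dataclass(frozen=True)
class QCReport:
    """Per-participant QC outcome.

    ``included`` is True/False once decidable and None (indeterminate) when
    no extreme-morph trials exist.  Counts always reconcile:
    ``n_trials_in == n_trials_fast_removed + kept``.
    """

    participant: str
    n_trials_in: int
    n_trials_fast_removed: int
    extreme_morph_accuracy: float | None
    included: bool | None

    def __post_init__(self) -> None:
        if self.n_trials_fast_removed > self.n_trials_in:
            raise ValueError("removed count exceeds input count")


def read_trials(path, rt_unit: Literal["s", "ms"] = "s") -> list[TrialRecord]:
    """Read a trial CSV, validating every row.

    Malformed rows (missing values, non-numeric RT, morph outside 1..15,
    unknown choice labels) are collected and reported together with their
    1-based file line numbers.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise TrialValidationError([f"missing column(s): {', '.join(missing)}"])

    problems: list[str] = []
    records: list[TrialRecord] = []
    scale = 1e-3 if rt_unit == "ms" else 1.0
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            run = int(row.run)
            morph = int(row.morph)
            rt = float(row.rt_s) * scale
        except (TypeError, ValueError):
            problems.append(f"line {line}: non-numeric run/morph/rt_s")
            continue
        if not 1 <= morph <= N_MORPHS:
            problems.append(f"line {line}: morph {morph} outside 1..{N_MORPHS}")
            continue
        if row.choice not in (ANGRY, HAPPY):
            problems.append(f"line {line}: choice {row.choice!r} not angry/happy")
            continue
        if not rt > 0 or not np.isfinite(rt):
            problems.append(f"line {line}: rt_s {row.rt_s!r} must be a positive number")
            continue
        records.append(TrialRecord(str(row.participant), run, morph, row.choice, rt))
    if problems:
        raise TrialValidationError(problems)
    return records


def write_trials(trials: Iterable[TrialRecord], path) -> None:
    """Write trials to the standard CSV dialect (RT in seconds, full
    precision so a read round-trips exactly)."""
    df = pd.DataFrame(
        [(t.participant, t.run, t.s, t.choice, t.rt) for t in trials],
        columns=_COLUMNS,
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")


def filter_fast_rt(
    trials: Iterable[TrialRecord], threshold_s: float = FAST_RT_THRESHOLD_S
) -> tuple[list[TrialRecord], int]:
    """Drop trials with ``rt < threshold_s`` (strict), preserving order.

    Returns the kept trials and the number removed.  Idempotent.
    """
    trials = list(trials)
    kept = [t for t in trials if not t.rt < threshold_s]
    return kept, len(trials) - len(kept)


def _extreme_accuracy(trials: list[TrialRecord], mode: str) -> float | None:
    lo = [t for t in trials if t.s == 1]
    hi = [t for t in trials if t.s == N_MORPHS]
    if not lo and not hi:
        return None
    acc_parts = []
    if lo:
        acc_parts.append((sum(t.choice == HAPPY for t in lo), len(lo)))
    if hi:
        acc_parts.append((sum(t.choice == ANGRY for t in hi), len(hi)))
    if mode == "pooled":
        correct = sum(c for c, _ in acc_parts)
        total = sum(n for _, n in acc_parts)
        return correct / total
    if mode == "per_morph":
        return min(c / n for c, n in acc_parts)
    raise ValueError(f"unknown mode {mode!r}")


def inclusion_check(
    trials: Iterable[TrialRecord],
    threshold: float = EXTREME_ACCURACY_THRESHOLD,
    mode: Literal["pooled", "per_morph"] = "pooled",
    n_trials_in: int | None = None,
    n_trials_fast_removed: int = 0,
) -> QCReport:
    """Participant-level inclusion: accuracy on the extreme morphs must be at
    least ``threshold`` (>= comparison, so exactly 80% is included).

    Correct responses are happy at ``s=1`` and angry at ``s=15``.  With no
    extreme-morph trials the report is indeterminate (``included=None``),
    never silently passed.
    """
    trials = list(trials)
    participant = trials[0].participant if trials else ""
    acc = _extreme_accuracy(trials, mode)
    return QCReport(
        participant=participant,
        n_trials_in=len(trials) if n_trials_in is None else n_trials_in,
        n_trials_fast_removed=n_trials_fast_removed,
        extreme_morph_accuracy=acc,
        included=None if acc is None else bool(acc >= threshold),
    )


def qc_participant(
    trials: Iterable[TrialRecord],
    rt_threshold_s: float = FAST_RT_THRESHOLD_S,
    accuracy_threshold: float = EXTREME_ACCURACY_THRESHOLD,
    mode: Literal["pooled", "per_morph"] = "pooled",
) -> tuple[list[TrialRecord], QCReport]:
    """Full QC for one participant: fast-RT filtering first, then the
    extreme-morph inclusion check on the surviving trials."""
    trials = list(trials)
    kept, n_removed = filter_fast_rt(trials, rt_threshold_s)
    report = inclusion_check(
        kept,
        threshold=accuracy_threshold,
        mode=mode,
        n_trials_in=len(trials),
        n_trials_fast_removed=n_removed,
    )
    return kept, report
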