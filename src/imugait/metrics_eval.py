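"""Step construction, stream alignment, gait metrics and error summaries.

A *step* is an (HS, TO, HS) triple between consecutive heel strikes of the
same foot; it yields three temporal metrics:

* stance time = TO - HS1
* swing time  = HS2 - TO
* stride time = HS2 - HS1 (stored as stance + swing so the identity holds
  exactly in floating point)

Device and reference event streams are aligned on their first heel strikes,
trimmed of their first and last events (partial footfalls and gait
initiation/termination at the walkway edges), built into steps, and paired
by nearest first-heel-strike time.  Agreement is summarised per
(metric x algorithm x sensor location x walking task) cell as RMSE and mean
absolute bias (with SD), in milliseconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .signal_model import (
    DataError,
    EventKind,
    EventSeries,
    GaitWarning,
    UsageError,
)

__all__ = [
    "StepMetrics",
    "ErrorSummary",
    "METRIC_NAMES",
    "build_steps",
    "trim_boundary_events",
    "align_by_first_hs",
    "match_steps",
    "paired_steps",
    "error_summary",
    "factorial_report",
    "REPORT_COLUMNS",
]

METRIC_NAMES = ("stance", "swing", "stride")

#: maximum |Δ first HS| for two steps to be considered the same step, s
DEFAULT_MAX_LAG = 0.25

REPORT_COLUMNS = [
    "task",
    "metric",
    "algorithm",
    "location",
    "rmse_ms",
    "abs_bias_ms",
    "abs_bias_sd_ms",
    "n",
]


@dataclass(frozen=True)
class StepMetrics:
    """One step between consecutive heel strikes with its interior toe off."""

    hs1: float
    to: float
    hs2: float

    def __post_init__(self) -> None:
        if not self.hs1 < self.to < self.hs2:
            raise DataError(
                f"step events must satisfy hs1 < to < hs2, got "
                f"{self.hs1}, {self.to}, {self.hs2}"
            )

    @property
    def stance(self) -> float:
        return self.to - self.hs1

    @property
    def swing(self) -> float:
        return self.hs2 - self.to

    @property
    def stride(self) -> float:
        # stance + swing rather than hs2 - hs1: the decomposition identity
        # then holds exactly in floating point.
        return self.stance + self.swing

    def metric(self, name: str) -> float:
        if name not in METRIC_NAMES:
            raise UsageError(f"metric must be one of {METRIC_NAMES}, got {name!r}")
        return getattr(self, name)


@dataclass(frozen=True)
class ErrorSummary:
    """RMSE and mean absolute bias (ms) for one factorial cell."""

    rmse: float
    abs_bias_mean: float
    abs_bias_sd: float
    n_steps: int
    metric: str = ""
    algorithm: str = ""
    location: str = ""
    task: str = ""


def build_steps(series: EventSeries) -> list[StepMetrics]:
    """Assemble steps from an event stream.

    Consecutive HS pairs with exactly one TO strictly in between become
    steps; pairs with zero or multiple interior TOs are skipped with a
    warning (a dropped or spurious event upstream).
    """
    hs = series.times(EventKind.HS)
    to = series.times(EventKind.TO)
    steps: list[StepMetrics] = []
    skipped = 0
    for h1, h2 in zip(hs, hs[1:]):
        interior = to[(to > h1) & (to < h2)]
        if len(interior) == 1:
            steps.append(StepMetrics(hs1=float(h1), to=float(interior[0]), hs2=float(h2)))
        else:
            skipped += 1
    if skipped:
        warnings.warn(
            f"{series.source or 'event series'}: skipped {skipped} heel-strike "
            "pair(s) without exactly one interior toe off",
            GaitWarning,
            stacklevel=2,
        )
    return steps


def trim_boundary_events(series: EventSeries) -> EventSeries:
    """Drop the first and last event (walkway-edge partial footfalls)."""
    if len(series) < 3:
        warnings.warn(
            "fewer than 3 events; trimming leaves an empty series",
            GaitWarning,
            stacklevel=2,
        )
        return EventSeries((), source=series.source)
    return EventSeries(series.events[1:-1], source=series.source)


def align_by_first_hs(imu: EventSeries, ref: EventSeries) -> float:
    """Clock offset (s) putting the device stream on the reference clock.

    Returns ``t(first reference HS) - t(first device HS)``; add it to every
    device event of the trial (all sensors of a trial share one clock).
    """
    imu_hs = imu.times(EventKind.HS)
    ref_hs = ref.times(EventKind.HS)
    if len(imu_hs) == 0 or len(ref_hs) == 0:
        raise DataError("alignment requires at least one heel strike in each stream")
    return float(ref_hs[0] - imu_hs[0])


def match_steps(
    imu_steps: Sequence[StepMetrics],
    ref_steps: Sequence[StepMetrics],
    max_lag: float = DEFAULT_MAX_LAG,
) -> list[tuple[StepMetrics, StepMetrics]]:
    """Greedy nearest-in-time one-to-one pairing on first heel strike.

    Candidate pairs with |Δhs1| <= ``max_lag`` are taken in order of
    increasing time difference; each step is used at most once.  Unmatched
    steps are dropped.
    """
    candidates = [
        (abs(a.hs1 - b.hs1), i, j)
        for i, a in enumerate(imu_steps)
        for j, b in enumerate(ref_steps)
        if abs(a.hs1 - b.hs1) <= max_lag
    ]
    candidates.sort()
    used_i: set[int] = set()
    used_j: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, i, j in candidates:
        if i in used_i or j in used_j:
            continue
        used_i.add(i)
        used_j.add(j)
        pairs.append((i, j))
    pairs.sort(key=lambda ij: imu_steps[ij[0]].hs1)
    return [(imu_steps[i], ref_steps[j]) for i, j in pairs]


def paired_steps(
    imu: EventSeries,
    ref: EventSeries,
    max_lag: float = DEFAULT_MAX_LAG,
    offset: float | None = None,
) -> list[tuple[StepMetrics, StepMetrics]]:
    """Full per-trial chain: align, trim, build steps, and pair them.

    ``offset`` overrides first-HS alignment when the trial-level offset was
    computed from a designated sensor (the dorsal-foot convention).
    """
    if offset is None:
        offset = align_by_first_hs(imu, ref)
    imu = imu.shifted(offset)
    imu_steps = build_steps(trim_boundary_events(imu))
    ref_steps = build_steps(trim_boundary_events(ref))
    return match_steps(imu_steps, ref_steps, max_lag=max_lag)


def error_summary(
    pairs: Sequence[tuple[StepMetrics, StepMetrics]],
    metric: str,
    **labels: str,
) -> ErrorSummary:
    """RMSE and mean absolute bias (ms) of device-vs-reference differences."""
    if len(pairs) == 0:
        raise DataError("error summary undefined for an empty pairing")
    d = np.array(
        [(a.metric(metric) - b.metric(metric)) * 1000.0 for a, b in pairs]
    )
    abs_d = np.abs(d)
    return ErrorSummary(
        rmse=float(np.sqrt(np.mean(d**2))),
        abs_bias_mean=float(np.mean(abs_d)),
        abs_bias_sd=float(np.std(abs_d, ddof=1)) if len(d) > 1 else 0.0,
        n_steps=len(d),
        metric=metric,
        **labels,
    )


def factorial_report(
    cell_pairs: Mapping[tuple[str, str, str], Sequence[tuple[StepMetrics, StepMetrics]]],
    metrics: Iterable[str] = METRIC_NAMES,
    tasks: Sequence[str] | None = None,
    algorithms: Sequence[str] | None = None,
    locations: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Long-format error table over the task x algorithm x location factorial.

    ``cell_pairs`` maps ``(task, algorithm, location)`` to the pooled step
    pairs of that cell (all subjects/trials together).  Explicit factor
    lists force empty cells to appear as NA rows with n = 0.
    """
    keys = list(cell_pairs.keys())
    tasks = list(tasks) if tasks is not None else sorted({k[0] for k in keys})
    algorithms = (
        list(algorithms) if algorithms is not None else sorted({k[1] for k in keys})
    )
    locations = (
        list(locations) if locations is not None else sorted({k[2] for k in keys})
    )
    rows = []
    for task in tasks:
        for metric in metrics:
            for algorithm in algorithms:
                for location in locations:
                    pairs = cell_pairs.get((task, algorithm, location), ())
                    if len(pairs) == 0:
                        rows.append(
                            dict(
                                task=task,
                                metric=metric,
                                algorithm=algorithm,
                                location=location,
                                rmse_ms=np.nan,
                                abs_bias_ms=np.nan,
                                abs_bias_sd_ms=np.nan,
                                n=0,
                            )
                        )
                        continue
                    s = error_summary(
                        pairs,
                        metric,
                        algorithm=algorithm,
                        location=location,
                        task=task,
                    )
                    rows.append(
                        dict(
                            task=task,
                            metric=metric,
                            algorithm=algorithm,
                            location=location,
                            rmse_ms=s.rmse,
                            abs_bias_ms=s.abs_bias_mean,
                            abs_bias_sd_ms=s.abs_bias_sd,
                            n=s.n_steps,
                        )
                    )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def pivot_report(report: pd.DataFrame, metric: str, task: str) -> pd.DataFrame:
    """Algorithm-by-location RMSE view of one metric/task block."""
    block = report[(report["metric"] == metric) & (report["task"] == task)]
    return block.pivot(index="algorithm", columns="location", values="rmse_ms")
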