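"""Visual-search metrics from AOI-labelled gaze streams.

A fixation is a maximal run of four or more consecutive samples on the same
area of interest; untracked samples and AOI changes break runs.  Per-trial
metrics are the relative number of fixations and relative fixation time per
AOI, expressed as percentages, together with the tracking ratio used for
trial inclusion (threshold inclusive at 90%).

Note on "relative number of fixations": it is computed as percent of the
total fixation count in the trial (the per-condition columns then sum to
~100%).  An alternative reading — fixations per second of trial, i.e.
literally normalised by trial length — is available via
``counts_per_second=True`` in :func:`gaze_metrics`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from stepgaze.trial_io import AOI_LABELS, UNTRACKED, GazeStream

__all__ = [
    "Fixation",
    "GazeMetrics",
    "TrialSelection",
    "tracking_ratio",
    "detect_fixations",
    "aoi_relative_counts",
    "aoi_relative_time",
    "gaze_metrics",
    "present_aois",
    "select_analysis_trial",
    "interrater_icc",
]

#: AOIs present in the scene per condition: the phone is in a pocket
#: (no_phone) or held to the ear outside the visual field (talk).
_AOIS_BY_CONDITION = {
    "no_phone": ("travel_path", "surface_height_change", "other"),
    "talk": ("travel_path", "surface_height_change", "other"),
    "read": AOI_LABELS,
    "write": AOI_LABELS,
}


@dataclass(frozen=True)
class Fixation:
    """A contiguous dwell on one AOI meeting the sample-count threshold."""

    aoi: str
    start_time: float
    duration: float
    n_samples: int


@dataclass
class GazeMetrics:
    """Per-trial visual-search variable set."""

    trial_time: float
    tracking_ratio: float
    relative_counts: dict[str, float]
    relative_times: dict[str, float]
    present: tuple[str, ...]
    n_fixations: int
    undefined: bool = False  # no fixations at all in the trial


@dataclass(frozen=True)
class TrialSelection:
    """Outcome of the first-valid-trial rule for one participant-condition."""

    chosen_index: int | None  # 0-based among candidates, None if excluded
    ratios: tuple[float, ...]

    @property
    def excluded(self) -> bool:
        return self.chosen_index is None


def tracking_ratio(stream: GazeStream) -> float:
    """Fraction of samples with valid eye data (label != untracked)."""
    if stream.n_samples == 0:
        raise ValueError("empty gaze stream")
    labels = np.asarray(stream.labels, dtype=object)
    return float(np.sum(labels != UNTRACKED) / stream.n_samples)


def detect_fixations(
    stream: GazeStream,
    min_samples: int = 4,
    min_duration: float | None = None,
) -> list[Fixation]:
    """Find maximal same-AOI runs of at least ``min_samples`` samples.

    ``min_duration`` (seconds) switches to a duration threshold instead: a
    run qualifies when ``n_samples / rate >= min_duration``.  Untracked
    samples never form fixations and always break runs.
    """
    if min_duration is not None:
        min_samples = int(np.ceil(min_duration * stream.rate))
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    labels = list(stream.labels)
    out: list[Fixation] = []
    i, n = 0, len(labels)
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        run = j - i
        if labels[i] != UNTRACKED and run >= min_samples:
            out.append(
                Fixation(
                    aoi=labels[i],
                    start_time=i / stream.rate,
                    duration=run / stream.rate,
                    n_samples=run,
                )
            )
        i = j
    return out


def present_aois(condition: str) -> tuple[str, ...]:
    """AOIs present in the visual scene for a phone condition."""
    return _AOIS_BY_CONDITION[condition]


def aoi_relative_counts(
    fixations: Sequence[Fixation], present: Sequence[str] = AOI_LABELS
) -> dict[str, float]:
    """Per-AOI fixation count as percent of the total fixation count.

    AOIs not in ``present`` are omitted from the result entirely (reported
    as '-' in tables).  With zero fixations the metric is undefined and all
    present AOIs map to NaN.
    """
    total = len(fixations)
    if total == 0:
        return {aoi: float("nan") for aoi in present}
    counts = {aoi: 0 for aoi in present}
    for fx in fixations:
        if fx.aoi in counts:
            counts[fx.aoi] += 1
    return {aoi: 100.0 * c / total for aoi, c in counts.items()}


def aoi_relative_time(
    fixations: Sequence[Fixation],
    trial_time: float,
    present: Sequence[str] = AOI_LABELS,
) -> dict[str, float]:
    """Summed fixation duration per AOI as percent of trial time.

    Non-fixation time (saccades, sub-threshold runs, untracked samples) is
    the residual to 100%.
    """
    if not trial_time > 0:
        raise ValueError("trial_time must be positive")
    times = {aoi: 0.0 for aoi in present}
    for fx in fixations:
        if fx.aoi in times:
            times[fx.aoi] += fx.duration
    return {aoi: 100.0 * t / trial_time for aoi, t in times.items()}


def gaze_metrics(
    stream: GazeStream,
    condition: str,
    trial_time: float | None = None,
    min_samples: int = 4,
    min_duration: float | None = None,
    counts_per_second: bool = False,
) -> GazeMetrics:
    """Compute the full per-trial visual-search variable set."""
    if trial_time is None:
        trial_time = stream.duration
    present = present_aois(condition)
    fixations = detect_fixations(stream, min_samples, min_duration)
    counts = aoi_relative_counts(fixations, present)
    if counts_per_second and fixations:
        counts = {
            aoi: 100.0 * (c / 100.0 * len(fixations)) / trial_time
            for aoi, c in counts.items()
        }
    times = aoi_relative_time(fixations, trial_time, present)
    return GazeMetrics(
        trial_time=trial_time,
        tracking_ratio=tracking_ratio(stream),
        relative_counts=counts,
        relative_times=times,
        present=present,
        n_fixations=len(fixations),
        undefined=not fixations,
    )


def select_analysis_trial(
    ratios: Sequence[float],
    calibration_ok: Sequence[bool] | None = None,
    threshold: float = 0.90,
) -> TrialSelection:
    """First trial (in order of occurrence) with tracking ratio >= threshold
    and good pre/post calibration; exclusion if none qualifies."""
    if not 1 <= len(ratios):
        raise ValueError("need at least one candidate trial")
    if calibration_ok is None:
        calibration_ok = [True] * len(ratios)
    for i, (r, ok) in enumerate(zip(ratios, calibration_ok)):
        if r >= threshold and ok:
            return TrialSelection(chosen_index=i, ratios=tuple(ratios))
    return TrialSelection(chosen_index=None, ratios=tuple(ratios))


def interrater_icc(
    a: Sequence[float], b: Sequence[float]
) -> float:
    """Two-way mixed, average-measures, consistency ICC — ICC(3,k) — for two
    coders rating the same items.

    Computed from the two-way ANOVA decomposition: with rows = items and
    columns = coders, ``ICC = (MS_rows - MS_error) / MS_rows``.  Invariant
    under adding a constant to one coder.  Returns NaN when both coders show
    zero variance (undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need paired 1-D measurements with n >= 3")
    x = np.column_stack([a, b])
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_rows == 0:
        return float("nan")
    return float((ms_rows - ms_err) / ms_rows)
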