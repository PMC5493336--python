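"""Shared data model and canonical I/O for step-negotiation trials.

Coordinate convention (package-wide):

- ``x`` — anterior-posterior, increasing in the direction of travel toward the
  surface height change; origin at the trial start line.
- ``y`` — medial-lateral.
- ``z`` — vertical, up; origin on the floor.

Time is in seconds from trial start, frames are 0-based, and time intervals
are half-open ``[start, end)``.

Canonical on-disk formats are plain text: a marker CSV with columns
``time, <marker>_x, <marker>_y, <marker>_z`` (metres/seconds, empty cell =
missing sample), a gaze CSV with columns ``time, aoi``, and a YAML metadata
file per trial.  A minimal C3D reader is provided for interoperability with
motion-capture exports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AOI_LABELS",
    "CONDITIONS",
    "GAZE_LABELS",
    "MARKER_NAMES",
    "UNTRACKED",
    "TrialFormatError",
    "StepGeometry",
    "MarkerTrajectory",
    "GazeStream",
    "TrialBundle",
    "read_marker_csv",
    "write_marker_csv",
    "read_gaze_csv",
    "write_gaze_csv",
    "read_c3d",
    "read_trial_meta",
    "write_trial_meta",
    "read_trial",
    "write_trial",
    "interpolate_small_gaps",
    "validate_trial",
]

#: Phone conditions, in the study's reporting order.
CONDITIONS = ("no_phone", "talk", "read", "write")

#: Areas of interest a tracked gaze sample may be assigned to.
AOI_LABELS = ("phone", "travel_path", "surface_height_change", "other")

#: Label for gaze frames with no eye data.
UNTRACKED = "untracked"

#: Every admissible gaze sample label.
GAZE_LABELS = AOI_LABELS + (UNTRACKED,)

#: Canonical marker set: bilateral second metatarsal head, distal second toe,
#: lateral malleolus and calcaneus, plus sternum and four head markers
#: (antero-/postero-lateral, both sides).
MARKER_NAMES = (
    "l_met2",
    "r_met2",
    "l_toe",
    "r_toe",
    "l_malleolus",
    "r_malleolus",
    "l_calcaneus",
    "r_calcaneus",
    "sternum",
    "head_front_left",
    "head_front_right",
    "head_back_left",
    "head_back_right",
)

#: Default sampling rates for conformant data.
MARKER_RATE_HZ = 100.0
GAZE_RATE_HZ = 30.0

#: Missing-marker samples are linearly interpolated only across gaps of at
#: most this many frames (100 ms at 100 Hz); longer gaps stay missing.
MAX_INTERP_GAP_FRAMES = 10


class TrialFormatError(ValueError):
    """Raised when an input file violates the canonical trial formats."""


@dataclass(frozen=True)
class StepGeometry:
    """Geometry of the step-up box (the surface height change).

    Parameters
    ----------
    edge_x
        Anterior-posterior position of the front rising edge in the lab
        frame (m).
    height
        Step height above the floor (m).
    width
        Medial-lateral extent (m).
    depth
        Anterior-posterior extent (m).
    """

    edge_x: float
    height: float = 0.075
    width: float = 0.61
    depth: float = 0.61

    def __post_init__(self) -> None:
        if not self.height > 0:
            raise ValueError(f"step height must be > 0, got {self.height}")
        if not self.width > 0:
            raise ValueError(f"step width must be > 0, got {self.width}")
        if not self.depth > 0:
            raise ValueError(f"step depth must be > 0, got {self.depth}")

    def support_height(self, x: float) -> float:
        """Height of the supporting surface under anterior position ``x``."""
        return self.height if x >= self.edge_x else 0.0


@dataclass
class MarkerTrajectory:
    """One marker's uniformly sampled 3-D position track.

    ``xyz`` has shape ``(n_frames, 3)`` in metres; missing samples are NaN
    rows (all three components).
    """

    name: str
    xyz: np.ndarray
    rate: float = MARKER_RATE_HZ

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError(f"xyz must be (n, 3), got {self.xyz.shape}")
        if not self.rate > 0:
            raise ValueError("rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.xyz.shape[0]

    @property
    def duration(self) -> float:
        """Time between first and last sample, ``(n - 1) / rate`` seconds."""
        return (self.n_frames - 1) / self.rate if self.n_frames else 0.0

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate

    @property
    def x(self) -> np.ndarray:
        return self.xyz[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xyz[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.xyz[:, 2]

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.xyz).any(axis=1)


@dataclass
class GazeStream:
    """AOI-labelled gaze samples at a fixed rate.

    Every sample carries exactly one label from :data:`GAZE_LABELS`.
    """

    labels: np.ndarray
    rate: float = GAZE_RATE_HZ

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.ndim != 1:
            raise ValueError("labels must be one-dimensional")
        bad = sorted({str(l) for l in self.labels} - set(GAZE_LABELS))
        if bad:
            raise ValueError(f"unknown gaze labels: {bad}")
        if not self.rate > 0:
            raise ValueError("rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.labels.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate


@dataclass
class TrialBundle:
    """Everything recorded for one walking trial."""

    participant_id: str
    condition: str
    repetition: int
    markers: dict[str, MarkerTrajectory]
    step: StepGeometry
    gaze: GazeStream | None = None
    trial_duration: float | None = None
    calibration_ok: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition {self.condition!r} not in {CONDITIONS}"
            )
        if self.trial_duration is None and self.markers:
            any_traj = next(iter(self.markers.values()))
            self.trial_duration = any_traj.n_frames / any_traj.rate
        if self.trial_duration is not None and not self.trial_duration > 0:
            raise ValueError("trial_duration must be positive")


# ---------------------------------------------------------------------------
# Marker CSV
# ---------------------------------------------------------------------------

def write_marker_csv(
    path: str | Path, markers: Mapping[str, MarkerTrajectory]
) -> None:
    """Write markers to the canonical ``time, <m>_x, <m>_y, <m>_z`` CSV."""
    markers = dict(markers)
    if not markers:
        raise ValueError("no markers to write")
    rates = {t.rate for t in markers.values()}
    lengths = {t.n_frames for t in markers.values()}
    if len(rates) != 1 or len(lengths) != 1:
        raise ValueError("all marker trajectories must share rate and length")
    rate = rates.pop()
    n = lengths.pop()
    cols: dict[str, np.ndarray] = {"time": np.arange(n) / rate}
    for name, traj in markers.items():
        for i, axis in enumerate("xyz"):
            cols[f"{name}_{axis}"] = traj.xyz[:, i]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_marker_csv(path: str | Path) -> dict[str, MarkerTrajectory]:
    """Read a canonical marker CSV into named trajectories.

    The sampling rate is inferred from the ``time`` column, which must be
    strictly increasing and uniform.  Empty cells become NaN (missing).
    """
    path = Path(path)
    with open(path) as fh:  # raw header: pandas silently mangles duplicates
        header = fh.readline().strip().split(",")
    if len(set(header)) != len(header):
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise TrialFormatError(f"duplicate columns in {path.name}: {dupes}")
    if "time" not in header:
        raise TrialFormatError(f"{path.name}: missing 'time' column")
    df = pd.read_csv(path)
    t = df["time"].to_numpy(float)
    if len(t) < 2:
        raise TrialFormatError(f"{path.name}: need at least 2 frames")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise TrialFormatError(f"{path.name}: time column not monotonic")
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise TrialFormatError(f"{path.name}: non-uniform sampling")
    rate = 1.0 / dt[0]

    names: list[str] = []
    for col in header:
        if col.endswith("_x") and col != "time":
            name = col[:-2]
            for axis in "xyz":
                if f"{name}_{axis}" not in header:
                    raise TrialFormatError(
                        f"{path.name}: marker {name!r} missing _{axis} column"
                    )
            names.append(name)
    if not names:
        raise TrialFormatError(f"{path.name}: no marker columns found")

    out: dict[str, MarkerTrajectory] = {}
    for name in names:
        xyz = df[[f"{name}_x", f"{name}_y", f"{name}_z"]].to_numpy(float)
        # a partially missing frame counts as missing
        partial = np.isnan(xyz).any(axis=1)
        xyz[partial] = np.nan
        out[name] = MarkerTrajectory(name=name, xyz=xyz, rate=rate)
    return out


# ---------------------------------------------------------------------------
# Gaze CSV
# ---------------------------------------------------------------------------

def write_gaze_csv(path: str | Path, stream: GazeStream) -> None:
    """Write a gaze stream to the canonical ``time, aoi`` CSV."""
    pd.DataFrame(
        {"time": stream.times, "aoi": list(stream.labels)}
    ).to_csv(path, index=False, float_format="%.9g")


def read_gaze_csv(path: str | Path, rate: float | None = None) -> GazeStream:
    """Read a canonical gaze CSV, preserving sample order and labels.

    Unknown AOI labels raise :class:`TrialFormatError` naming the offending
    rows (1-based data rows, excluding the header).
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "aoi" not in df.columns:
        raise TrialFormatError(f"{path.name}: missing 'aoi' column")
    labels = df["aoi"].astype(str).to_numpy(object)
    bad_rows = [
        (i + 1, lab) for i, lab in enumerate(labels) if lab not in GAZE_LABELS
    ]
    if bad_rows:
        shown = ", ".join(f"row {i}: {lab!r}" for i, lab in bad_rows[:10])
        raise TrialFormatError(
            f"{path.name}: {len(bad_rows)} unknown AOI label(s) ({shown})"
        )
    if rate is None:
        if "time" in df.columns and len(df) >= 2:
            dt = np.diff(df["time"].to_numpy(float))
            if np.any(dt <= 0):
                raise TrialFormatError(f"{path.name}: time column not monotonic")
            rate = 1.0 / dt[0]
        else:
            rate = GAZE_RATE_HZ
    return GazeStream(labels=labels, rate=rate)


# ---------------------------------------------------------------------------
# C3D
# ---------------------------------------------------------------------------

def read_c3d(
    path: str | Path,
    axis_map: Mapping[str, str] | None = None,
) -> dict[str, MarkerTrajectory]:
    """Read labelled points from a C3D file into the package convention.

    Positions are converted to metres (honouring the file's POINT:UNITS) and
    remapped onto the package axes via ``axis_map``, a mapping from package
    axis to a signed file axis, e.g. ``{"x": "+X", "y": "+Y", "z": "+Z"}``
    (the default: file X anterior, Y lateral, Z up).
    """
    from stepgaze._c3d import read_c3d_points

    labels, points, rate, units = read_c3d_points(Path(path))
    scale = {"m": 1.0, "mm": 1e-3, "cm": 1e-2}.get(units.strip().lower())
    if scale is None:
        raise TrialFormatError(f"unsupported POINT:UNITS {units!r}")

    axis_map = dict(axis_map or {"x": "+X", "y": "+Y", "z": "+Z"})
    col_of = {"x": 0, "y": 1, "z": 2}
    out: dict[str, MarkerTrajectory] = {}
    for i, label in enumerate(labels):
        raw = points[:, i, :] * scale  # (n_frames, 3) in file axes
        xyz = np.empty_like(raw)
        for pkg_axis, spec in axis_map.items():
            spec = spec.strip()
            sign = -1.0 if spec.startswith("-") else 1.0
            file_axis = spec.lstrip("+-").lower()
            xyz[:, col_of[pkg_axis]] = sign * raw[:, col_of[file_axis]]
        out[label] = MarkerTrajectory(name=label, xyz=xyz, rate=rate)
    return out


# ---------------------------------------------------------------------------
# Trial metadata YAML and whole-trial round trips
# ---------------------------------------------------------------------------

def write_trial_meta(path: str | Path, bundle: TrialBundle) -> None:
    meta = {
        "participant": bundle.participant_id,
        "condition": bundle.condition,
        "repetition": int(bundle.repetition),
        "trial_duration": float(bundle.trial_duration),
        "calibration_ok": bool(bundle.calibration_ok),
        "step": {
            "edge_x": float(bundle.step.edge_x),
            "height": float(bundle.step.height),
            "width": float(bundle.step.width),
            "depth": float(bundle.step.depth),
        },
        "marker_rate": float(next(iter(bundle.markers.values())).rate)
        if bundle.markers
        else None,
        "gaze_rate": float(bundle.gaze.rate) if bundle.gaze else None,
    }
    Path(path).write_text(yaml.safe_dump(meta, sort_keys=False))


def read_trial_meta(path: str | Path) -> dict:
    meta = yaml.safe_load(Path(path).read_text())
    if not isinstance(meta, dict):
        raise TrialFormatError(f"{Path(path).name}: not a mapping")
    return meta


def write_trial(directory: str | Path, bundle: TrialBundle) -> Path:
    """Write one trial as ``markers.csv``, optional ``gaze.csv``, ``meta.yaml``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_marker_csv(directory / "markers.csv", bundle.markers)
    if bundle.gaze is not None:
        write_gaze_csv(directory / "gaze.csv", bundle.gaze)
    write_trial_meta(directory / "meta.yaml", bundle)
    return directory


def read_trial(directory: str | Path) -> TrialBundle:
    """Read a trial written by :func:`write_trial`."""
    directory = Path(directory)
    meta = read_trial_meta(directory / "meta.yaml")
    markers = read_marker_csv(directory / "markers.csv")
    gaze = None
    if (directory / "gaze.csv").exists():
        gaze = read_gaze_csv(directory / "gaze.csv")
    step = StepGeometry(**meta["step"])
    return TrialBundle(
        participant_id=str(meta["participant"]),
        condition=meta["condition"],
        repetition=int(meta["repetition"]),
        markers=markers,
        gaze=gaze,
        step=step,
        trial_duration=float(meta["trial_duration"]),
        calibration_ok=bool(meta.get("calibration_ok", True)),
    )


# ---------------------------------------------------------------------------
# Gap interpolation and validation
# ---------------------------------------------------------------------------

def interpolate_small_gaps(
    traj: MarkerTrajectory, max_gap: int = MAX_INTERP_GAP_FRAMES
) -> MarkerTrajectory:
    """Linearly interpolate missing runs of at most ``max_gap`` frames.

    Longer gaps — and missing samples at the trajectory boundaries — are left
    as NaN, which downstream extraction treats as invalidating dependent
    variables for the trial.
    """
    xyz = traj.xyz.copy()
    missing = np.isnan(xyz).any(axis=1)
    if not missing.any():
        return traj
    n = len(missing)
    i = 0
    while i < n:
        if not missing[i]:
            i += 1
            continue
        j = i
        while j < n and missing[j]:
            j += 1
        gap = j - i
        if gap <= max_gap and i > 0 and j < n:
            lo, hi = xyz[i - 1], xyz[j]
            for k in range(gap):
                frac = (k + 1) / (gap + 1)
                xyz[i + k] = lo + frac * (hi - lo)
        i = j
    return replace(traj, xyz=xyz)


def validate_trial(bundle: TrialBundle, strict: bool = True) -> list[str]:
    """Check a trial against the data-model invariants.

    Returns human-readable findings; an empty list means the trial is
    well-formed.  Pure: repeated calls give identical output.  With
    ``strict`` the study-conformant sampling rates (100 Hz markers, 30 Hz
    gaze) are also enforced.
    """
    findings: list[str] = []
    for name in MARKER_NAMES:
        if name not in bundle.markers:
            findings.append(f"marker {name} absent")
    rates = {t.rate for t in bundle.markers.values()}
    lengths = {t.n_frames for t in bundle.markers.values()}
    if len(rates) > 1:
        findings.append(f"marker rate mismatch: {sorted(rates)}")
    if len(lengths) > 1:
        findings.append(f"marker length mismatch: {sorted(lengths)}")
    if strict and rates and not math.isclose(
        next(iter(rates)), MARKER_RATE_HZ, rel_tol=1e-6
    ):
        if len(rates) == 1:
            findings.append(
                f"marker rate {next(iter(rates)):g} Hz != {MARKER_RATE_HZ:g} Hz"
            )
    if bundle.step is None:
        findings.append("step geometry absent")
    if bundle.gaze is not None and strict and not math.isclose(
        bundle.gaze.rate, GAZE_RATE_HZ, rel_tol=1e-6
    ):
        findings.append(
            f"gaze rate {bundle.gaze.rate:g} Hz != {GAZE_RATE_HZ:g} Hz"
        )
    for name, traj in bundle.markers.items():
        miss = traj.missing_mask()
        if miss.any():
            runs = _longest_run(miss)
            if runs > MAX_INTERP_GAP_FRAMES:
                findings.append(
                    f"marker {name}: missing gap of {runs} frames "
                    f"(> {MAX_INTERP_GAP_FRAMES})"
                )
    return findings


def _longest_run(mask: np.ndarray) -> int:
    best = cur = 0
    for m in mask:
        cur = cur + 1 if m else 0
        best = max(best, cur)
    return best
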