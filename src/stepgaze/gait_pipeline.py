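"""Adaptive-gait kinematics around a surface height change.

Extracts, for one trial, the full gait variable set: lead/trail foot
placement relative to the front rising edge (pre and post crossing), stride
lengths, vertical toe clearance and horizontal toe velocity at the crossing
instant, head flexion at five gait events, and the medial-lateral bivariate
variable error (BVE) of the sternum marker.

The lead limb is the first foot to land beyond the front rising edge; the
trail limb is the other foot.  All positions are metres in the lab frame,
clearances are reported in millimetres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import signal

from stepgaze.trial_io import (
    MarkerTrajectory,
    StepGeometry,
    TrialBundle,
    interpolate_small_gaps,
)

__all__ = [
    "FilterSpec",
    "FootContact",
    "GaitEvents",
    "GaitParameters",
    "GaitExtractionError",
    "HEAD_EVENTS",
    "lowpass",
    "velocity",
    "detect_foot_contacts",
    "assign_lead_trail",
    "crossing_instant",
    "toe_clearance",
    "horizontal_toe_velocity",
    "foot_positions",
    "stride_lengths",
    "head_pitch_series",
    "head_flexion",
    "ml_bve",
    "extract_gait_parameters",
]

#: The five gait events at which head flexion is evaluated, in trial order.
HEAD_EVENTS = (
    "penultimate_contact",
    "final_contact",
    "lead_crossing",
    "lead_contact_after",
    "trail_contact_after",
)


class GaitExtractionError(RuntimeError):
    """Raised when a gait variable cannot be extracted from a trial."""


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass filtering and differentiation settings.

    ``cutoff`` is the effective -3 dB frequency of a zero-phase Butterworth
    filter of order ``order`` (implemented as a forward-backward pass of an
    ``order/2`` filter); ``cutoff=None`` disables filtering.  Differentiation
    is by central differences.
    """

    cutoff: float | None = 6.0
    order: int = 4
    speed_threshold: float = 0.2  # m/s, stance detection
    height_threshold: float = 0.015  # m above support surface
    min_stance: float = 0.1  # s

    def __post_init__(self) -> None:
        if self.order < 2 or self.order % 2:
            raise ValueError("order must be an even integer >= 2")


@dataclass(frozen=True)
class FootContact:
    """One stance interval of one foot."""

    foot: str  # "left" or "right"
    start_time: float
    end_time: float  # half-open [start, end)
    toe_x: float
    heel_x: float
    z: float

    @property
    def time(self) -> float:
        """Representative contact time (stance onset)."""
        return self.start_time


@dataclass
class GaitEvents:
    """Labelled gait events around the step negotiation."""

    lead_foot: str
    penultimate: FootContact  # second-to-last floor contact (trail foot)
    final: FootContact  # last floor contact (lead foot)
    lead_landing: FootContact
    trail_landing: FootContact
    lead_crossing_time: float | None = None
    trail_crossing_time: float | None = None

    @property
    def trail_foot(self) -> str:
        return "left" if self.lead_foot == "right" else "right"

    def check_ordering(self) -> list[str]:
        problems = []
        if not self.penultimate.time < self.final.time:
            problems.append("penultimate contact not before final contact")
        if self.lead_crossing_time is not None:
            if not self.final.time < self.lead_crossing_time:
                problems.append("final contact not before lead crossing")
            if not self.lead_crossing_time < self.lead_landing.time:
                problems.append("lead crossing not before lead landing")
        if (
            self.lead_crossing_time is not None
            and self.trail_crossing_time is not None
            and not self.lead_crossing_time < self.trail_crossing_time
        ):
            problems.append("lead crossing not before trail crossing")
        return problems


@dataclass
class GaitParameters:
    """The per-trial gait variable set (one row of the study's gait table)."""

    lead_foot: str | None = None
    lead_foot_pre: float | None = None
    trail_foot_pre: float | None = None
    lead_foot_post: float | None = None
    trail_foot_post: float | None = None
    lead_stride: float | None = None
    trail_stride: float | None = None
    lead_clearance_mm: float | None = None
    trail_clearance_mm: float | None = None
    lead_velocity: float | None = None
    trail_velocity: float | None = None
    head_flexion: dict[str, float] = field(default_factory=dict)
    ml_bve: float | None = None
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float | None]:
        out = {
            k: getattr(self, k)
            for k in (
                "lead_foot_pre",
                "trail_foot_pre",
                "lead_foot_post",
                "trail_foot_post",
                "lead_stride",
                "trail_stride",
                "lead_clearance_mm",
                "trail_clearance_mm",
                "lead_velocity",
                "trail_velocity",
                "ml_bve",
            )
        }
        for ev in HEAD_EVENTS:
            out[f"head_{ev}"] = self.head_flexion.get(ev)
        return out


# ---------------------------------------------------------------------------
# Filtering and differentiation
# ---------------------------------------------------------------------------

def lowpass(traj: MarkerTrajectory, spec: FilterSpec) -> MarkerTrajectory:
    """Zero-phase Butterworth low-pass; identity when ``spec.cutoff`` is None."""
    if spec.cutoff is None:
        return traj
    nyquist = traj.rate / 2.0
    if spec.cutoff >= nyquist:
        raise ValueError(
            f"cutoff {spec.cutoff} Hz must be below Nyquist {nyquist} Hz"
        )
    if np.isnan(traj.xyz).any():
        raise GaitExtractionError(
            f"marker {traj.name}: cannot filter with missing samples"
        )
    sos = signal.butter(
        spec.order // 2, spec.cutoff / nyquist, output="sos"
    )
    xyz = signal.sosfiltfilt(sos, traj.xyz, axis=0)
    return replace(traj, xyz=np.ascontiguousarray(xyz))


def velocity(traj: MarkerTrajectory) -> np.ndarray:
    """Central-difference velocity, shape ``(n, 3)`` (one-sided at ends)."""
    return np.gradient(traj.xyz, 1.0 / traj.rate, axis=0)


def _interp_at(values: np.ndarray, rate: float, t: float) -> float:
    """Linear interpolation of a uniformly sampled series at time ``t``."""
    pos = t * rate
    i = int(math.floor(pos))
    i = max(0, min(i, len(values) - 2))
    frac = pos - i
    return float(values[i] + frac * (values[i + 1] - values[i]))


# ---------------------------------------------------------------------------
# Foot contacts and event labelling
# ---------------------------------------------------------------------------

def detect_foot_contacts(
    toe: MarkerTrajectory,
    heel: MarkerTrajectory,
    step: StepGeometry,
    spec: FilterSpec = FilterSpec(),
    foot: str = "?",
) -> list[FootContact]:
    """Stance intervals: both markers slow and near the supporting surface.

    A frame is in stance when toe and heel speeds are below
    ``spec.speed_threshold`` and each marker's height is within
    ``spec.height_threshold`` of its supporting surface (floor, or step top
    beyond the rising edge).  Intervals shorter than ``spec.min_stance`` are
    discarded.
    """
    toe_v = np.linalg.norm(velocity(toe), axis=1)
    heel_v = np.linalg.norm(velocity(heel), axis=1)
    toe_support = np.where(toe.x >= step.edge_x, step.height, 0.0)
    heel_support = np.where(heel.x >= step.edge_x, step.height, 0.0)
    stance = (
        (toe_v < spec.speed_threshold)
        & (heel_v < spec.speed_threshold)
        & (np.abs(toe.z - toe_support) < spec.height_threshold)
        & (np.abs(heel.z - heel_support) < spec.height_threshold)
    )
    min_frames = max(1, int(round(spec.min_stance * toe.rate)))
    out: list[FootContact] = []
    n = len(stance)
    i = 0
    prev_end = 0
    while i < n:
        if not stance[i]:
            i += 1
            continue
        j = i
        while j < n and stance[j]:
            j += 1
        if j - i >= min_frames:
            pose = np.concatenate(
                [np.median(toe.xyz[i:j], axis=0), np.median(heel.xyz[i:j], axis=0)]
            )
            # central differences smear touchdown speed across one frame:
            # claw back onset frames already sitting at the planted pose
            k = i
            while k > prev_end and np.all(
                np.abs(
                    np.concatenate([toe.xyz[k - 1], heel.xyz[k - 1]]) - pose
                )
                < 0.005
            ):
                k -= 1
            out.append(
                FootContact(
                    foot=foot,
                    start_time=k / toe.rate,
                    end_time=j / toe.rate,
                    toe_x=float(pose[0]),
                    heel_x=float(pose[3]),
                    z=float(pose[2]),
                )
            )
            prev_end = j
        i = j
    if not out:
        raise GaitExtractionError(f"no stance intervals found for {foot} foot")
    return out


def assign_lead_trail(
    contacts_left: Sequence[FootContact],
    contacts_right: Sequence[FootContact],
    step: StepGeometry,
) -> GaitEvents:
    """Label lead/trail feet and the four contacts framing the negotiation.

    Lead = foot of the first contact with toe beyond the rising edge.  The
    final floor contact is the lead foot's last stance short of the edge, the
    penultimate one is the trail foot's.
    """
    all_contacts = sorted(
        list(contacts_left) + list(contacts_right), key=lambda c: c.start_time
    )
    beyond = [c for c in all_contacts if c.toe_x > step.edge_x]
    if not beyond:
        raise GaitExtractionError("step never negotiated: no contact beyond edge")
    lead_landing = beyond[0]
    lead = lead_landing.foot
    trail_beyond = [c for c in beyond if c.foot != lead]
    if not trail_beyond:
        raise GaitExtractionError("trail foot never landed beyond the edge")
    trail_landing = trail_beyond[0]

    def last_floor(foot: str) -> FootContact:
        floor = [
            c
            for c in all_contacts
            if c.foot == foot
            and c.toe_x < step.edge_x
            and c.start_time < lead_landing.start_time
        ]
        if not floor:
            raise GaitExtractionError(f"no floor stance for {foot} foot")
        return floor[-1]

    final = last_floor(lead)
    penultimate = last_floor(trail_landing.foot)
    return GaitEvents(
        lead_foot=lead,
        penultimate=penultimate,
        final=final,
        lead_landing=lead_landing,
        trail_landing=trail_landing,
    )


# ---------------------------------------------------------------------------
# Crossing kinematics
# ---------------------------------------------------------------------------

def crossing_instant(
    toe: MarkerTrajectory,
    edge_x: float,
    window: tuple[float, float] | None = None,
) -> float:
    """Sub-frame instant at which the toe passes the rising edge.

    Linear interpolation between the last frame with ``x < edge_x`` and the
    first with ``x >= edge_x``; ``window`` restricts the search to a
    half-open time interval (e.g. the swing phase).
    """
    x = toe.x
    n = len(x)
    lo, hi = 0, n
    if window is not None:
        lo = max(0, int(math.floor(window[0] * toe.rate)))
        hi = min(n, int(math.ceil(window[1] * toe.rate)))
    seg = x[lo:hi]
    idx = np.nonzero(seg >= edge_x)[0]
    if len(idx) == 0 or idx[0] == 0:
        raise GaitExtractionError("toe does not cross the edge in the window")
    i = lo + int(idx[0])
    x0, x1 = x[i - 1], x[i]
    frac = (edge_x - x0) / (x1 - x0)
    return ((i - 1) + frac) / toe.rate


def toe_clearance(
    toe: MarkerTrajectory, crossing_time: float, step: StepGeometry
) -> float:
    """Vertical toe clearance over the upper front edge, in millimetres.

    Negative values mean the toe passed below the edge plane (virtual
    contact) and are flagged by the orchestrator, not raised here.
    """
    z = _interp_at(toe.z, toe.rate, crossing_time)
    return (z - step.height) * 1000.0


def horizontal_toe_velocity(
    toe: MarkerTrajectory,
    crossing_time: float,
    spec: FilterSpec = FilterSpec(),
) -> float:
    """Anterior-posterior toe velocity at the crossing instant (m/s)."""
    n = toe.n_frames
    if crossing_time < 2.0 / toe.rate or crossing_time > (n - 3) / toe.rate:
        raise GaitExtractionError("crossing too close to trial boundary")
    vx = velocity(toe)[:, 0]
    return _interp_at(vx, toe.rate, crossing_time)


# ---------------------------------------------------------------------------
# Foot placement and strides
# ---------------------------------------------------------------------------

def foot_positions(
    events: GaitEvents,
    edge_x: float,
    post_reference: str = "toe",
    signed: bool = False,
) -> dict[str, float]:
    """Anterior-posterior foot-to-edge distances before and after crossing.

    Pre-edge distances use the toe marker (margin to the edge); post-edge
    distances use ``post_reference`` ("toe" or "heel" — heel measures
    base-of-support quality on the step).  By default all four distances are
    reported as positive magnitudes; ``signed=True`` reports pre-edge
    placements as negative (placement prior to the rising edge).
    """
    if post_reference not in ("toe", "heel"):
        raise ValueError("post_reference must be 'toe' or 'heel'")
    post_x = lambda c: c.toe_x if post_reference == "toe" else c.heel_x
    pre_sign = -1.0 if signed else 1.0
    return {
        "lead_foot_pre": pre_sign * (edge_x - events.final.toe_x),
        "trail_foot_pre": pre_sign * (edge_x - events.penultimate.toe_x),
        "lead_foot_post": post_x(events.lead_landing) - edge_x,
        "trail_foot_post": post_x(events.trail_landing) - edge_x,
    }


def stride_lengths(events: GaitEvents) -> dict[str, float]:
    """Crossing stride lengths (m): same-foot floor plant to landing plant."""
    lead = events.lead_landing.toe_x - events.final.toe_x
    trail = events.trail_landing.toe_x - events.penultimate.toe_x
    out = {"lead_stride": lead, "trail_stride": trail}
    return out


# ---------------------------------------------------------------------------
# Head flexion
# ---------------------------------------------------------------------------

def head_pitch_series(
    head_markers: Mapping[str, MarkerTrajectory]
) -> tuple[np.ndarray, float]:
    """Sagittal pitch (degrees, positive = down) of the head's A-P axis.

    The axis runs from the midpoint of the posterior markers to the midpoint
    of the anterior markers.  Returns ``(pitch, rate)``.
    """
    required = (
        "head_front_left",
        "head_front_right",
        "head_back_left",
        "head_back_right",
    )
    missing = [m for m in required if m not in head_markers]
    if missing:
        raise GaitExtractionError(f"missing head markers: {missing}")
    front = 0.5 * (
        head_markers["head_front_left"].xyz + head_markers["head_front_right"].xyz
    )
    back = 0.5 * (
        head_markers["head_back_left"].xyz + head_markers["head_back_right"].xyz
    )
    v = front - back
    pitch = np.degrees(np.arctan2(-v[:, 2], v[:, 0]))
    return pitch, head_markers["head_front_left"].rate


def head_flexion(
    head_markers: Mapping[str, MarkerTrajectory],
    event_times: Mapping[str, float],
    calibration: Mapping[str, np.ndarray] | float = 0.0,
) -> dict[str, float]:
    """Head flexion (degrees; 0 = straight ahead, positive = down) at events.

    ``calibration`` is either the pitch (degrees) of the straight-ahead pose
    or a mapping of the four head marker names to static 3-D positions from
    which that pitch is computed.
    """
    pitch, rate = head_pitch_series(head_markers)
    if isinstance(calibration, Mapping):
        static = {
            name: MarkerTrajectory(name, np.asarray(pos, float)[None, :], rate)
            for name, pos in calibration.items()
        }
        cal_pitch = float(head_pitch_series(static)[0][0])
    else:
        cal_pitch = float(calibration)
    return {
        ev: _interp_at(pitch, rate, t) - cal_pitch
        for ev, t in event_times.items()
    }


# ---------------------------------------------------------------------------
# Medial-lateral bivariate variable error
# ---------------------------------------------------------------------------

def ml_bve(sternum: MarkerTrajectory, mode: str = "rms") -> float:
    """Per-trial dispersion of the sternum's medial-lateral coordinate.

    ``mode="rms"`` (default): root of the mean squared deviation about the
    trial mean.  ``mode="as_printed"``: the mean squared deviation without
    the root (the study's equation as typeset is ambiguous about the root;
    both readings are provided and the RMS one is the default).
    """
    y = sternum.y
    y = y[~np.isnan(y)]
    if len(y) < 2:
        raise ValueError("need at least 2 medial-lateral samples")
    msd = float(np.mean((y - y.mean()) ** 2))
    if mode == "rms":
        return math.sqrt(msd)
    if mode == "as_printed":
        return msd
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Orchestrator
# ---------------------------------------------------------------------------

def extract_gait_parameters(
    bundle: TrialBundle,
    spec: FilterSpec = FilterSpec(),
    calibration: Mapping[str, np.ndarray] | float = 0.0,
    bve_mode: str = "rms",
    post_reference: str = "toe",
) -> GaitParameters:
    """Extract the full gait variable set for one trial.

    Individual failures (missing markers, unnegotiated step) populate
    ``flags`` and leave the affected fields ``None`` rather than raising.
    """
    params = GaitParameters()
    markers = {
        name: interpolate_small_gaps(traj)
        for name, traj in bundle.markers.items()
    }

    def get(name: str) -> MarkerTrajectory | None:
        traj = markers.get(name)
        if traj is None:
            params.flags.append(f"marker {name} absent")
            return None
        if np.isnan(traj.xyz).any():
            params.flags.append(f"marker {name}: unrecoverable missing samples")
            return None
        return lowpass(traj, spec)

    feet: dict[str, tuple[MarkerTrajectory, MarkerTrajectory]] = {}
    for side, prefix in (("left", "l"), ("right", "r")):
        toe = get(f"{prefix}_toe")
        heel = get(f"{prefix}_calcaneus")
        if toe is not None and heel is not None:
            feet[side] = (toe, heel)

    events: GaitEvents | None = None
    if len(feet) == 2:
        try:
            contacts = {
                side: detect_foot_contacts(t, h, bundle.step, spec, foot=side)
                for side, (t, h) in feet.items()
            }
            events = assign_lead_trail(
                contacts["left"], contacts["right"], bundle.step
            )
        except GaitExtractionError as exc:
            params.flags.append(str(exc))
    else:
        params.flags.append("foot markers incomplete; gait events unavailable")

    if events is not None:
        params.lead_foot = events.lead_foot
        lead_toe = feet[events.lead_foot][0]
        trail_toe = feet[events.trail_foot][0]
        try:
            t_lead = crossing_instant(
                lead_toe,
                bundle.step.edge_x,
                window=(events.final.end_time, events.lead_landing.start_time),
            )
            t_trail = crossing_instant(
                trail_toe,
                bundle.step.edge_x,
                window=(
                    events.penultimate.end_time,
                    events.trail_landing.start_time,
                ),
            )
            events.lead_crossing_time = t_lead
            events.trail_crossing_time = t_trail
            params.lead_clearance_mm = toe_clearance(lead_toe, t_lead, bundle.step)
            params.trail_clearance_mm = toe_clearance(
                trail_toe, t_trail, bundle.step
            )
            if params.lead_clearance_mm < 0 or params.trail_clearance_mm < 0:
                params.flags.append("virtual contact: negative toe clearance")
            params.lead_velocity = horizontal_toe_velocity(lead_toe, t_lead, spec)
            params.trail_velocity = horizontal_toe_velocity(
                trail_toe, t_trail, spec
            )
        except GaitExtractionError as exc:
            params.flags.append(str(exc))

        positions = foot_positions(
            events, bundle.step.edge_x, post_reference=post_reference
        )
        params.lead_foot_pre = positions["lead_foot_pre"]
        params.trail_foot_pre = positions["trail_foot_pre"]
        params.lead_foot_post = positions["lead_foot_post"]
        params.trail_foot_post = positions["trail_foot_post"]
        strides = stride_lengths(events)
        params.lead_stride = strides["lead_stride"]
        params.trail_stride = strides["trail_stride"]
        if params.lead_stride <= 0 or params.trail_stride <= 0:
            params.flags.append("implausible non-positive stride length")

        ordering = events.check_ordering()
        params.flags.extend(ordering)

        head = {
            name: markers[name]
            for name in (
                "head_front_left",
                "head_front_right",
                "head_back_left",
                "head_back_right",
            )
            if name in markers and not np.isnan(markers[name].xyz).any()
        }
        if len(head) == 4:
            event_times = {
                "penultimate_contact": events.penultimate.time,
                "final_contact": events.final.time,
                "lead_crossing": events.lead_crossing_time,
                "lead_contact_after": events.lead_landing.time,
                "trail_contact_after": events.trail_landing.time,
            }
            event_times = {k: v for k, v in event_times.items() if v is not None}
            params.head_flexion = head_flexion(head, event_times, calibration)
        else:
            params.flags.append("head markers incomplete; head flexion unavailable")

    sternum = markers.get("sternum")
    if sternum is None:
        params.flags.append("marker sternum absent; BVE unavailable")
    else:
        try:
            params.ml_bve = ml_bve(sternum, mode=bve_mode)
        except ValueError as exc:
            params.flags.append(f"BVE: {exc}")
    return params
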