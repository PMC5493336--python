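"""Seeded generator of step-negotiation trials with known ground truth.

Marker trajectories are built from a parametric stride sequence: alternating
approach steps, a crossing swing whose toe arc attains a specified vertical
clearance above the rising edge and a specified horizontal velocity at the
crossing instant, and landing positions matching foot-placement targets.
Gaze streams are built as sequences of AOI dwell episodes whose realised
relative fixation counts and times match drawn targets.  Every realised
quantity is recorded in a :class:`GroundTruth` so downstream pipelines can
be verified without any external data.

Condition-level target means and SDs are the study's published group
statistics per phone condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from stepgaze.trial_io import (
    AOI_LABELS,
    CONDITIONS,
    UNTRACKED,
    GazeStream,
    MarkerTrajectory,
    StepGeometry,
    TrialBundle,
)
from stepgaze.gait_pipeline import HEAD_EVENTS

__all__ = [
    "ConditionPreset",
    "CohortDesign",
    "GroundTruth",
    "GenerationError",
    "GAIT_KEYS",
    "condition_presets",
    "simulate_trial",
    "simulate_cohort",
    "degrade_tracking",
]

#: Walkway length (m); the step edge is drawn uniformly in EDGE_RANGE.
WALKWAY_LENGTH = 5.6
EDGE_RANGE = (3.95, 4.05)

#: Anterior offsets of the foot markers relative to the distal toe marker (m).
HEEL_OFFSET = 0.18
MET2_OFFSET = 0.08
MALLEOLUS_OFFSET = 0.12
MALLEOLUS_HEIGHT = 0.07

#: Scalar gait targets held in a preset (means/SDs per condition).
GAIT_KEYS = (
    "lead_clearance_mm",
    "trail_clearance_mm",
    "lead_velocity",
    "trail_velocity",
    "lead_stride",
    "trail_stride",
    "lead_foot_pre",
    "trail_foot_post",
    "ml_bve",
)


class GenerationError(RuntimeError):
    """Raised when drawn targets cannot be realised on the walkway."""


MS = tuple[float, float]  # (mean, sd)


@dataclass(frozen=True)
class ConditionPreset:
    """Target means and SDs for every per-trial quantity, one condition."""

    condition: str
    trial_time: MS
    gait: Mapping[str, MS]
    head: Mapping[str, MS]  # keyed by HEAD_EVENTS
    gaze_counts: Mapping[str, MS]  # % of fixation count, per present AOI
    gaze_times: Mapping[str, MS]  # % of trial time, per present AOI
    tracking: MS = (0.97, 0.01)

    def __post_init__(self) -> None:
        for group in (
            {"trial_time": self.trial_time},
            self.gait,
            self.head,
            self.gaze_counts,
            self.gaze_times,
            {"tracking": self.tracking},
        ):
            for key, (_, sd) in group.items():
                if sd < 0:
                    raise ValueError(f"{key}: SD must be >= 0, got {sd}")
        for group in (self.gaze_counts, self.gaze_times):
            for key, (mean, _) in group.items():
                if not 0 <= mean <= 100:
                    raise ValueError(f"{key}: percentage out of [0, 100]")

    @property
    def present_aois(self) -> tuple[str, ...]:
        return tuple(a for a in AOI_LABELS if a in self.gaze_counts)


# Published group means (SDs) per phone condition: visual-search table
# (trial time, relative fixation counts/time per AOI) and gait table
# (clearances mm, crossing velocities m/s, strides m, foot placements m,
# BVE m, head flexion deg at the five events).
_T = {
    "no_phone": dict(
        trial_time=(4.79, 0.64),
        counts={
            "surface_height_change": (17.07, 14.52),
            "travel_path": (51.16, 19.20),
            "other": (29.74, 25.50),
        },
        times={
            "surface_height_change": (16.95, 13.71),
            "travel_path": (57.02, 20.29),
            "other": (16.25, 20.86),
        },
        gait=dict(
            lead_clearance_mm=(120, 22),
            lead_velocity=(3.84, 0.51),
            trail_clearance_mm=(84, 21),
            trail_velocity=(3.09, 0.67),
            ml_bve=(0.57, 0.50),
            lead_stride=(1.29, 0.14),
            trail_stride=(1.26, 0.15),
            lead_foot_pre=(0.22, 0.07),
            trail_foot_post=(0.94, 0.11),
        ),
        head=dict(
            penultimate_contact=(1, 9),
            final_contact=(-1, 11),
            lead_crossing=(2, 11),
            lead_contact_after=(0, 11),
            trail_contact_after=(-10, 9),
        ),
    ),
    "talk": dict(
        trial_time=(5.71, 0.57),
        counts={
            "surface_height_change": (10.24, 7.42),
            "travel_path": (37.35, 13.86),
            "other": (49.22, 21.56),
        },
        times={
            "surface_height_change": (9.74, 9.46),
            "travel_path": (46.49, 15.24),
            "other": (28.38, 18.94),
        },
        gait=dict(
            lead_clearance_mm=(123, 23),
            lead_velocity=(3.15, 0.53),
            trail_clearance_mm=(87, 23),
            trail_velocity=(2.61, 0.44),
            ml_bve=(0.72, 0.73),
            lead_stride=(1.11, 0.13),
            trail_stride=(1.07, 0.17),
            lead_foot_pre=(0.14, 0.08),
            trail_foot_post=(0.75, 0.17),
        ),
        head=dict(
            penultimate_contact=(2, 12),
            final_contact=(0, 15),
            lead_crossing=(1, 14),
            lead_contact_after=(1, 14),
            trail_contact_after=(-7, 12),
        ),
    ),
    "read": dict(
        trial_time=(6.27, 1.37),
        counts={
            "phone": (37.83, 23.27),
            "surface_height_change": (6.73, 6.58),
            "travel_path": (28.37, 17.33),
            "other": (23.05, 22.20),
        },
        times={
            "phone": (60.97, 21.57),
            "surface_height_change": (3.55, 5.36),
            "travel_path": (18.02, 14.94),
            "other": (8.14, 11.02),
        },
        gait=dict(
            lead_clearance_mm=(127, 30),
            lead_velocity=(3.40, 0.46),
            trail_clearance_mm=(97, 28),
            trail_velocity=(2.61, 0.39),
            ml_bve=(0.61, 0.44),
            lead_stride=(1.08, 0.17),
            trail_stride=(1.09, 0.17),
            lead_foot_pre=(0.21, 0.07),
            trail_foot_post=(0.84, 0.16),
        ),
        head=dict(
            penultimate_contact=(22, 15),
            final_contact=(17, 19),
            lead_crossing=(20, 15),
            lead_contact_after=(18, 17),
            trail_contact_after=(7, 16),
        ),
    ),
    "write": dict(
        trial_time=(10.46, 3.23),
        counts={
            "phone": (55.34, 24.75),
            "surface_height_change": (6.77, 11.06),
            "travel_path": (25.0, 18.60),
            "other": (9.62, 13.81),
        },
        times={
            "phone": (88.18, 13.47),
            "surface_height_change": (1.51, 2.22),
            "travel_path": (6.30, 9.52),
            "other": (0.01, 0.01),
        },
        gait=dict(
            lead_clearance_mm=(142, 28),
            lead_velocity=(2.32, 0.59),
            trail_clearance_mm=(90, 28),
            trail_velocity=(1.91, 0.41),
            ml_bve=(1.35, 0.73),
            lead_stride=(0.80, 0.18),
            trail_stride=(0.70, 0.25),
            lead_foot_pre=(0.13, 0.08),
            trail_foot_post=(0.49, 0.23),
        ),
        head=dict(
            penultimate_contact=(32, 11),
            final_contact=(34, 13),
            lead_crossing=(32, 11),
            lead_contact_after=(32, 11),
            trail_contact_after=(31, 12),
        ),
    ),
}


def condition_presets(condition: str) -> ConditionPreset:
    """The published per-condition target means and SDs."""
    if condition not in _T:
        raise ValueError(f"unknown condition {condition!r}; one of {CONDITIONS}")
    t = _T[condition]
    return ConditionPreset(
        condition=condition,
        trial_time=t["trial_time"],
        gait=dict(t["gait"]),
        head=dict(t["head"]),
        gaze_counts=dict(t["counts"]),
        gaze_times=dict(t["times"]),
    )


@dataclass(frozen=True)
class CohortDesign:
    """Layout of a simulated cohort."""

    n_participants: int = 21
    conditions: tuple[str, ...] = CONDITIONS
    repetitions: int = 3
    between_sd_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions {sorted(unknown)}")
        if not 0 <= self.between_sd_fraction <= 1:
            raise ValueError("between_sd_fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    """Exact per-trial values realised by the generator."""

    condition: str
    trial_time: float
    edge_x: float
    lead_foot: str
    gait: dict[str, float]  # GAIT_KEYS plus lead_foot_post, trail_foot_pre
    head: dict[str, float]  # degrees at the five events
    event_times: dict[str, float]  # stance onsets + crossing instants
    n_stances: dict[str, int]  # per foot
    gaze_counts: dict[str, float] = field(default_factory=dict)
    gaze_times: dict[str, float] = field(default_factory=dict)
    tracking_ratio: float | None = None
    n_fixations: int | None = None
    targets: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "condition": self.condition,
            "trial_time": self.trial_time,
            "edge_x": self.edge_x,
            "lead_foot": self.lead_foot,
            "gait": dict(self.gait),
            "head": dict(self.head),
            "event_times": dict(self.event_times),
            "n_stances": dict(self.n_stances),
            "gaze_counts": dict(self.gaze_counts),
            "gaze_times": dict(self.gaze_times),
            "tracking_ratio": self.tracking_ratio,
            "n_fixations": self.n_fixations,
            "targets": dict(self.targets),
        }


# ---------------------------------------------------------------------------
# Target drawing
# ---------------------------------------------------------------------------

def _draw(rng: np.random.Generator, ms: MS, offset: float = 0.0,
          sd_scale: float = 1.0, lo: float = -np.inf, hi: float = np.inf) -> float:
    mean, sd = ms
    val = mean + offset + sd_scale * sd * (rng.standard_normal() if sd else 0.0)
    return float(np.clip(val, lo, hi))


def _draw_targets(
    preset: ConditionPreset,
    rng: np.random.Generator,
    offsets: Mapping[str, float] | None,
    sd_scale: float,
) -> dict[str, float]:
    """Draw one trial's targets, applying feasibility clamps."""
    off = offsets or {}
    t: dict[str, float] = {}
    t["trial_time"] = _draw(
        rng, preset.trial_time, off.get("trial_time", 0.0), sd_scale, 3.0, 25.0
    )
    g = preset.gait
    o = lambda k: off.get(k, 0.0)
    t["lead_clearance_mm"] = _draw(rng, g["lead_clearance_mm"], o("lead_clearance_mm"), sd_scale, 25, 350)
    t["trail_clearance_mm"] = _draw(rng, g["trail_clearance_mm"], o("trail_clearance_mm"), sd_scale, 25, 350)
    t["lead_velocity"] = _draw(rng, g["lead_velocity"], o("lead_velocity"), sd_scale, 1.0, 6.0)
    t["trail_velocity"] = _draw(rng, g["trail_velocity"], o("trail_velocity"), sd_scale, 1.0, 6.0)
    t["lead_foot_pre"] = _draw(rng, g["lead_foot_pre"], o("lead_foot_pre"), sd_scale, 0.05, 0.5)
    t["trail_foot_post"] = _draw(rng, g["trail_foot_post"], o("trail_foot_post"), sd_scale, 0.25, 1.4)
    lead_stride = _draw(rng, g["lead_stride"], o("lead_stride"), sd_scale, 0.4, 1.8)
    # landing must stay on the walkway: post-edge distance capped at 1.45 m
    t["lead_stride"] = min(
        max(lead_stride, t["lead_foot_pre"] + 0.30),
        t["lead_foot_pre"] + 1.45,
    )
    # keep the edge crossing at >= 15% of the swing so the constant-velocity
    # plateau around the crossing stays resolvable at 100 Hz
    t["lead_foot_pre"] = max(t["lead_foot_pre"], 0.15 * t["lead_stride"])
    trail_stride = _draw(rng, g["trail_stride"], o("trail_stride"), sd_scale, 0.4, 1.9)
    t["trail_stride"] = max(
        trail_stride, t["trail_foot_post"] + 0.08, t["trail_foot_post"] / 0.85
    )
    t["ml_bve"] = _draw(rng, g["ml_bve"], o("ml_bve"), sd_scale, 0.003, 3.0)
    for ev in HEAD_EVENTS:
        t[f"head_{ev}"] = _draw(rng, preset.head[ev], o(f"head_{ev}"), sd_scale, -60, 80)
    for aoi in preset.present_aois:
        t[f"count_{aoi}"] = _draw(rng, preset.gaze_counts[aoi], o(f"count_{aoi}"), sd_scale, 0, 100)
        t[f"time_{aoi}"] = _draw(rng, preset.gaze_times[aoi], o(f"time_{aoi}"), sd_scale, 0, 100)
    # keep total fixation time feasible (leave room for saccades/untracked)
    total_time = sum(t[f"time_{a}"] for a in preset.present_aois)
    if total_time > 96.0:
        scale = 96.0 / total_time
        for aoi in preset.present_aois:
            t[f"time_{aoi}"] *= scale
    t["tracking"] = _draw(rng, preset.tracking, off.get("tracking", 0.0), sd_scale, 0.90, 1.0)
    return t


# ---------------------------------------------------------------------------
# Marker synthesis
# ---------------------------------------------------------------------------

def _smoothstep(s: np.ndarray) -> np.ndarray:
    return 3 * s**2 - 2 * s**3


def _smoothstep_d(s: float) -> float:
    return 6 * s * (1 - s)


def _crossing_phase(frac: float) -> float:
    """Phase s at which the smoothstep covers ``frac`` of the swing distance."""
    lo, hi = 0.0, 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if 3 * mid**2 - 2 * mid**3 < frac:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass
class _Plant:
    x: float
    arrive: float
    depart: float
    # swing into the NEXT plant; crossing swings carry arc constraints
    swing_apex: float = 0.05
    crossing: dict | None = None  # {"edge_x", "clearance_m", "s_c"}


def _foot_plan(
    plants_x: list[float],
    arrive_times: list[float],
    total_time: float,
) -> list[_Plant]:
    plan = []
    for i, (x, ta) in enumerate(zip(plants_x, arrive_times)):
        if i + 1 < len(plants_x):
            t_next = arrive_times[i + 1]
            gap = t_next - ta
            # stance must stay comfortably detectable (>= 0.14 s)
            swing = max(0.08, min(0.35 * gap, 0.6, gap - 0.14))
            depart = t_next - swing
        else:
            depart = total_time
        plan.append(_Plant(x=x, arrive=ta, depart=depart))
    return plan


def _toe_track(
    plan: list[_Plant],
    step: StepGeometry,
    n_frames: int,
    rate: float,
) -> np.ndarray:
    """Toe x/z track from a plant plan (y handled by the caller)."""
    t = np.arange(n_frames) / rate
    x = np.full(n_frames, plan[0].x)
    z = np.full(n_frames, step.support_height(plan[0].x))
    for i, p in enumerate(plan):
        in_stance = (t >= p.arrive) & (t < p.depart)
        x[in_stance] = p.x
        z[in_stance] = step.support_height(p.x)
        if i + 1 < len(plan):
            q = plan[i + 1]
            in_swing = (t >= p.depart) & (t < q.arrive)
            T = q.arrive - p.depart
            s = (t[in_swing] - p.depart) / T
            z0 = step.support_height(p.x)
            z1 = step.support_height(q.x)
            if p.crossing is not None:
                c = p.crossing
                s_c = c["s_c"]
                w = _trapezoid_progress(s, c["rise"], c["fall"])
                w_c = float(
                    _trapezoid_progress(np.array([s_c]), c["rise"], c["fall"])[0]
                )
                peak = (
                    step.height
                    + c["clearance_m"]
                    - (z0 + (z1 - z0) * w_c)
                ) / math.sin(math.pi * s_c)
            else:
                w = _smoothstep(s)
                peak = p.swing_apex
            x[in_swing] = p.x + (q.x - p.x) * w
            z[in_swing] = z0 + (z1 - z0) * w + peak * np.sin(math.pi * s)
    # after the last arrival the foot stays planted (handled by init of loop)
    last = plan[-1]
    tail = t >= last.arrive
    x[tail] = last.x
    z[tail] = step.support_height(last.x)
    return np.column_stack([x, z])


_FALL_FRAC = 0.30  # deceleration share of the crossing swing
_PLATEAU_MARGIN = 0.07  # phase margin of constant velocity around the edge


def _trapezoid_progress(s: np.ndarray, r: float, f: float) -> np.ndarray:
    """Normalised displacement of a smoothed-trapezoid velocity profile.

    Velocity rises as a smoothstep over phase ``[0, r]``, holds constant on
    ``[r, 1-f]`` and falls as a smoothstep over ``[1-f, 1]``; the return
    value is the displacement fraction ``Phi(s) / Phi(1)``.
    """
    s = np.asarray(s, dtype=float)

    def ramp_area(u):  # integral of smoothstep from 0 to u
        return u**3 - 0.5 * u**4

    phi1 = 1.0 - 0.5 * r - 0.5 * f
    out = np.empty_like(s)
    rising = s < r
    falling = s > 1.0 - f
    mid = ~rising & ~falling
    out[rising] = r * ramp_area(s[rising] / r)
    out[mid] = 0.5 * r + (s[mid] - r)
    u = (1.0 - s[falling]) / f
    out[falling] = phi1 - f * ramp_area(u)
    return out / phi1


def _crossing_swing(
    x_from: float,
    x_to: float,
    edge_x: float,
    clearance_m: float,
    v_cross: float,
) -> tuple[float, float, float, float]:
    """Crossing-swing profile meeting the velocity target at the edge.

    The horizontal velocity follows a smoothed trapezoid whose constant
    plateau spans the edge crossing, so the drawn crossing velocity is
    attained exactly and is locally constant there.  Returns
    ``(T_swing, s_c, rise_frac, fall_frac)``.
    """
    dx = x_to - x_from
    if dx <= 0:
        raise GenerationError("crossing stride not forward")
    frac = (edge_x - x_from) / dx
    if not 0.02 < frac < 0.98:
        raise GenerationError("edge not inside the crossing swing")
    m = _PLATEAU_MARGIN
    f = _FALL_FRAC
    for _ in range(3):  # shrink ramps so the plateau brackets the crossing
        r = min(0.30, (frac * (1.0 - 0.5 * f) - m) / (0.5 + 0.5 * frac))
        f = min(
            _FALL_FRAC,
            ((1.0 - frac) * (1.0 - 0.5 * r) - m) / (0.5 + 0.5 * (1.0 - frac)),
        )
    if r < 0.04 or f < 0.04:
        raise GenerationError(
            f"edge crossing too close to a swing boundary (fraction {frac:.3f})"
        )
    phi1 = 1.0 - 0.5 * r - 0.5 * f
    s_c = frac * phi1 + 0.5 * r  # crossing phase, inside the plateau
    if not r + 0.9 * m < s_c < 1.0 - f - 0.9 * m:
        raise GenerationError("crossing phase outside the velocity plateau")
    T = dx / (phi1 * v_cross)
    if not 0.05 < T < 6.0:
        raise GenerationError(f"infeasible crossing swing duration {T:.3f}s")
    return T, s_c, r, f


def _smooth_noise(rng: np.random.Generator, n: int, rate: float) -> np.ndarray:
    """Zero-mean band-limited noise (sum of low-frequency sinusoids)."""
    t = np.arange(n) / rate
    y = np.zeros(n)
    for _ in range(6):
        f = rng.uniform(0.2, 1.2)
        phase = rng.uniform(0, 2 * math.pi)
        amp = rng.uniform(0.5, 1.0)
        y += amp * np.sin(2 * math.pi * f * t + phase)
    y -= y.mean()
    return y


def _plan_trial(
    targets: dict[str, float],
    step: StepGeometry,
    lead_side: str,
    rate: float = 100.0,
) -> tuple[list[_Plant], list[_Plant], dict]:
    """Plan the stride sequence; returns (lead_plan, trail_plan, info).

    The plan — plant positions and timings, crossing-swing shapes, realised
    event times — is cheap to compute and fully determines the ground truth;
    rendering marker arrays from it is optional (see :func:`_render_markers`).
    """
    T = targets["trial_time"]
    edge = step.edge_x
    lead_pre = targets["lead_foot_pre"]
    lead_post = targets["lead_stride"] - lead_pre
    trail_post = targets["trail_foot_post"]
    trail_pre = targets["trail_stride"] - trail_post
    # the trail foot's final floor plant must stay behind the lead foot's
    if trail_pre <= lead_pre + 0.03:
        trail_pre = lead_pre + 0.05
    trail_stride = trail_pre + trail_post

    x_lead_floor = edge - lead_pre
    x_trail_floor = edge - trail_pre
    x_lead_land = edge + lead_post
    x_trail_land = edge + trail_post
    if x_trail_land > WALKWAY_LENGTH or x_lead_land > WALKWAY_LENGTH:
        raise GenerationError("stride sequence exceeds the walkway")

    # approach plants, walking backwards from the final floor plants
    app_lead = min(1.5, max(0.55, targets["lead_stride"]))
    app_trail = min(1.5, max(0.55, trail_stride))
    lead_xs = [x_lead_floor]
    while lead_xs[-1] - app_lead > 0.15:
        lead_xs.append(lead_xs[-1] - app_lead)
    lead_xs.append(max(0.02, lead_xs[-1] - app_lead))
    lead_xs.reverse()
    trail_xs = [x_trail_floor]
    while trail_xs[-1] - app_trail > 0.15:
        trail_xs.append(trail_xs[-1] - app_trail)
    trail_xs.append(max(0.0, trail_xs[-1] - app_trail))
    trail_xs.reverse()

    # crossing swings with exact clearance and velocity constraints
    T_lead, s_lead, r_lead, f_lead = _crossing_swing(
        x_lead_floor, x_lead_land, edge,
        targets["lead_clearance_mm"] / 1000.0, targets["lead_velocity"],
    )
    T_trail, s_trail, r_trail, f_trail = _crossing_swing(
        x_trail_floor, x_trail_land, edge,
        targets["trail_clearance_mm"] / 1000.0, targets["trail_velocity"],
    )

    # schedule floor-plant arrivals on an even step cadence, timed so the
    # lead crossing lands near 72% of the trial (the edge's share of the
    # walkway), after a 0.4 s gait-initiation delay
    merged = sorted(
        [(x, "lead") for x in lead_xs[1:]] + [(x, "trail") for x in trail_xs[1:]]
    )
    m = len(merged)
    # aim for the edge's share of the walkway, but leave room for the two
    # crossing swings so the realised duration stays at the drawn trial time
    tail = (1.0 - s_lead) * T_lead + 0.08 + T_trail + 0.35
    t_cross_nominal = min(0.72 * T, T - tail)
    tau = (t_cross_nominal - 0.4 - s_lead * T_lead) / (m + 0.35)
    tau = min(2.0, max(0.25, tau))
    lead_times, trail_times = [0.0], [0.0]
    for i, (x, which) in enumerate(merged):
        (lead_times if which == "lead" else trail_times).append(0.4 + (i + 1) * tau)

    # the pre-swing hold must comfortably exceed the stance-detection minimum
    hold = max(0.16, 0.35 * tau)
    lead_depart = lead_times[-1] + hold
    t_lead_land = lead_depart + T_lead
    trail_depart = max(t_lead_land + 0.08, trail_times[-1] + hold)
    t_trail_land = trail_depart + T_trail

    total = max(T, t_trail_land + 0.3)
    n_frames = int(round(total * rate))
    t_real = n_frames / rate

    lead_plan = _foot_plan(lead_xs + [x_lead_land], lead_times + [t_lead_land], t_real)
    lead_plan[-2].depart = lead_depart
    lead_plan[-2].crossing = {
        "edge_x": edge,
        "clearance_m": targets["lead_clearance_mm"] / 1000.0,
        "s_c": s_lead,
        "rise": r_lead,
        "fall": f_lead,
    }
    trail_plan = _foot_plan(trail_xs + [x_trail_land], trail_times + [t_trail_land], t_real)
    trail_plan[-2].depart = trail_depart
    trail_plan[-2].crossing = {
        "edge_x": edge,
        "clearance_m": targets["trail_clearance_mm"] / 1000.0,
        "s_c": s_trail,
        "rise": r_trail,
        "fall": f_trail,
    }

    trail_side = "left" if lead_side == "right" else "right"
    t_cross = lead_depart + s_lead * T_lead
    t_cross_trail = trail_depart + s_trail * T_trail
    info = {
        "trial_time": t_real,
        "n_frames": n_frames,
        "event_times": {
            "penultimate_contact": trail_plan[-2].arrive,
            "final_contact": lead_plan[-2].arrive,
            "lead_crossing": t_cross,
            "lead_contact_after": t_lead_land,
            "trail_contact_after": t_trail_land,
            "trail_crossing": t_cross_trail,
        },
        "n_stances": {
            lead_side: len(lead_plan),
            trail_side: len(trail_plan),
        },
        "gait": {
            "lead_foot_pre": lead_pre,
            "trail_foot_pre": trail_pre,
            "lead_foot_post": lead_post,
            "trail_foot_post": trail_post,
            "lead_stride": targets["lead_stride"],
            "trail_stride": trail_stride,
            "lead_clearance_mm": targets["lead_clearance_mm"],
            "trail_clearance_mm": targets["trail_clearance_mm"],
            "lead_velocity": targets["lead_velocity"],
            "trail_velocity": targets["trail_velocity"],
            "ml_bve": targets["ml_bve"],
        },
    }
    return lead_plan, trail_plan, info


def _render_markers(
    lead_plan: list[_Plant],
    trail_plan: list[_Plant],
    info: dict,
    targets: dict[str, float],
    step: StepGeometry,
    lead_side: str,
    rng: np.random.Generator,
    rate: float = 100.0,
) -> dict[str, MarkerTrajectory]:
    """Render the full marker set from a trial plan."""
    n_frames = info["n_frames"]
    t_real = info["trial_time"]
    trail_side = "left" if lead_side == "right" else "right"
    side_y = {"left": 0.10, "right": -0.10}
    prefix = {"left": "l", "right": "r"}

    markers: dict[str, MarkerTrajectory] = {}
    for side, plan in ((lead_side, lead_plan), (trail_side, trail_plan)):
        xz = _toe_track(plan, step, n_frames, rate)
        y = np.full(n_frames, side_y[side])
        p = prefix[side]
        toe = np.column_stack([xz[:, 0], y, xz[:, 1]])
        markers[f"{p}_toe"] = MarkerTrajectory(f"{p}_toe", toe, rate)
        for name, dx, dz in (
            ("met2", MET2_OFFSET, 0.0),
            ("malleolus", MALLEOLUS_OFFSET, MALLEOLUS_HEIGHT),
            ("calcaneus", HEEL_OFFSET, 0.0),
        ):
            m = toe.copy()
            m[:, 0] -= dx
            m[:, 2] += dz
            markers[f"{p}_{name}"] = MarkerTrajectory(f"{p}_{name}", m, rate)

    # body progression: monotone interpolation through mid-stance positions
    t_knots = [0.0]
    x_knots = [0.05]
    merged = sorted(
        [(p.arrive, p.x) for p in lead_plan + trail_plan if p.arrive > 0.0]
    )
    for ta, x in merged:
        if ta > t_knots[-1] + 1e-6 and x > x_knots[-1]:
            t_knots.append(ta)
            x_knots.append(x)
    if t_real > t_knots[-1] + 1e-6:
        t_knots.append(t_real)
        x_knots.append(x_knots[-1] + 1e-3)
    body_x = PchipInterpolator(t_knots, x_knots)(np.arange(n_frames) / rate)

    # sternum: medial-lateral noise scaled to the exact BVE target (RMS mode)
    noise = _smooth_noise(rng, n_frames, rate)
    rms = math.sqrt(np.mean(noise**2))
    sternum_y = noise / rms * targets["ml_bve"] if rms > 0 else noise
    sternum = np.column_stack(
        [body_x, sternum_y, np.full(n_frames, 1.35)]
    )
    markers["sternum"] = MarkerTrajectory("sternum", sternum, rate)

    # head: pitch piecewise-smooth through the five event targets
    event_times = info["event_times"]
    # pitch holds a short plateau around each event so sub-frame uncertainty
    # in downstream event timing cannot move the evaluated angle
    angles = [targets[f"head_{ev}"] for ev in HEAD_EVENTS]
    ev_ts = [event_times[ev] for ev in HEAD_EVENTS]
    plateau = 0.03
    knots: list[tuple[float, float]] = [(0.0, angles[0])]
    for t_ev, a_ev in zip(ev_ts, angles):
        for tk in (t_ev - plateau, t_ev, t_ev + plateau):
            if knots[-1][0] + 5e-3 < tk < t_real - 5e-3:
                knots.append((tk, a_ev))
    knots.append((t_real, angles[-1]))
    knots_t, knots_a = zip(*knots)
    pitch = np.radians(
        PchipInterpolator(knots_t, knots_a)(np.arange(n_frames) / rate)
    )
    r = 0.10
    half_w = 0.07
    head_c = np.column_stack([body_x, np.zeros(n_frames), np.full(n_frames, 1.70)])
    fwd = np.column_stack(
        [r * np.cos(pitch), np.zeros(n_frames), -r * np.sin(pitch)]
    )
    for name, sgn_f, sgn_y in (
        ("head_front_left", 1, 1),
        ("head_front_right", 1, -1),
        ("head_back_left", -1, 1),
        ("head_back_right", -1, -1),
    ):
        pos = head_c + sgn_f * fwd
        pos = pos.copy()
        pos[:, 1] = sgn_y * half_w
        markers[name] = MarkerTrajectory(name, pos, rate)

    return markers


# ---------------------------------------------------------------------------
# Gaze synthesis
# ---------------------------------------------------------------------------

def _build_gaze(
    targets: dict[str, float],
    present: Sequence[str],
    trial_time: float,
    rng: np.random.Generator,
    rate: float = 30.0,
    min_fix: int = 4,
) -> tuple[GazeStream, dict]:
    """Construct a gaze stream from dwell-episode targets.

    Fixation-time targets govern sample allocation; count targets set the
    number of episodes per AOI where feasible (an AOI with less than one
    fixation's worth of time gets no episodes).
    """
    n = max(min_fix + 1, int(round(trial_time * rate)))
    samples_per_aoi: dict[str, int] = {}
    for aoi in present:
        s = int(round(targets[f"time_{aoi}"] / 100.0 * n))
        samples_per_aoi[aoi] = s if s >= min_fix else 0
    total_fix = sum(samples_per_aoi.values())
    if total_fix > n - 1:  # leave at least one non-fixation sample
        excess = total_fix - (n - 1)
        big = max(samples_per_aoi, key=samples_per_aoi.get)
        samples_per_aoi[big] -= excess
        total_fix = n - 1

    active = [a for a in present if samples_per_aoi[a] > 0]
    if not active:
        # degenerate: all-sub-threshold trial; emit a plain scan pattern
        labels = np.array(
            [present[i % len(present)] for i in range(n)], dtype=object
        )[:n]
        stream = GazeStream(labels=labels, rate=rate)
        info = {
            "gaze_counts": {a: float("nan") for a in present},
            "gaze_times": {a: 0.0 for a in present},
            "tracking_ratio": 1.0,
            "n_fixations": 0,
        }
        return stream, info

    weights = np.array([max(targets[f"count_{a}"], 1e-6) for a in active])
    weights /= weights.sum()
    k_max = np.array([samples_per_aoi[a] // min_fix for a in active])
    k_total = int(np.clip(round(total_fix / 9.0), 1, k_max.sum()))
    k = np.maximum(1, np.round(weights * k_total).astype(int))
    k = np.minimum(k, k_max)
    # a dominant AOI can only repeat if a filler sample separates each pair
    # of its episodes; cap its count so the filler budget suffices
    filler_budget = n - total_fix
    dom = int(np.argmax(k))
    k[dom] = max(1, min(k[dom], int(k.sum() - k[dom]) + 1 + filler_budget // 2))

    episodes: list[tuple[str, int]] = []
    for aoi, ka in zip(active, k):
        s = samples_per_aoi[aoi]
        extra = rng.multinomial(s - min_fix * ka, np.full(ka, 1.0 / ka))
        for e in extra:
            episodes.append((aoi, min_fix + int(e)))

    # arrange to avoid same-AOI adjacency where possible
    order = list(rng.permutation(len(episodes)))
    arranged = [episodes[i] for i in order]
    for i in range(1, len(arranged)):
        if arranged[i][0] == arranged[i - 1][0]:
            for j in range(i + 1, len(arranged)):
                if (
                    arranged[j][0] != arranged[i - 1][0]
                    and (i + 1 >= len(arranged) or arranged[j][0] != arranged[i + 1][0])
                ):
                    arranged[i], arranged[j] = arranged[j], arranged[i]
                    break

    filler_budget = n - sum(length for _, length in arranged)
    n_untracked = min(
        filler_budget, int(round((1.0 - targets.get("tracking", 1.0)) * n))
    )

    # distribute filler into the gaps between episodes (and at the ends);
    # gaps separating same-AOI episodes must receive at least one sample
    n_gaps = len(arranged) + 1
    mandatory = np.zeros(n_gaps, dtype=int)
    for i in range(1, len(arranged)):
        if arranged[i][0] == arranged[i - 1][0]:
            mandatory[i] = 1
    if mandatory.sum() > filler_budget:
        # shave the longest episodes to free mandatory separator samples
        need = int(mandatory.sum() - filler_budget)
        lengths = [list(e) for e in arranged]
        by_len = sorted(range(len(lengths)), key=lambda i: -lengths[i][1])
        for idx in by_len:
            while need > 0 and lengths[idx][1] > min_fix:
                lengths[idx][1] -= 1
                need -= 1
        arranged = [(a, l) for a, l in lengths]
        filler_budget = n - sum(l for _, l in arranged)
    free = filler_budget - int(mandatory.sum())
    share = rng.multinomial(max(free, 0), np.full(n_gaps, 1.0 / n_gaps)) if free > 0 else np.zeros(n_gaps, dtype=int)
    gap_sizes = mandatory + share

    out: list[str] = []
    untracked_left = n_untracked

    def fill_gap(size: int, prev_aoi: str | None, next_aoi: str | None) -> None:
        nonlocal untracked_left
        last = prev_aoi
        while size > 0:
            chunk = min(3, size)
            if untracked_left > 0 and last != UNTRACKED:
                lab = UNTRACKED
                chunk = min(chunk, untracked_left)
                untracked_left -= chunk
            else:
                pool = list(present)
                choices = [
                    a for a in pool
                    if a != last and (size - chunk > 0 or a != next_aoi)
                ] or [a for a in pool if a != last] or [UNTRACKED]
                lab = choices[0]
            out.extend([lab] * chunk)
            last = lab
            size -= chunk

    for i, (aoi, length) in enumerate(arranged):
        prev = out[-1] if out else None
        fill_gap(int(gap_sizes[i]), prev, aoi)
        out.extend([aoi] * length)
    fill_gap(int(gap_sizes[-1]), out[-1] if out else None, None)

    labels = np.array(out[:n], dtype=object)
    stream = GazeStream(labels=labels, rate=rate)

    k_realised = {a: 0 for a in present}
    s_realised = {a: 0 for a in present}
    for aoi, length in arranged:
        k_realised[aoi] += 1
        s_realised[aoi] += length
    k_sum = sum(k_realised.values())
    info = {
        "gaze_counts": {
            a: 100.0 * k_realised[a] / k_sum if k_sum else float("nan")
            for a in present
        },
        "gaze_times": {a: 100.0 * s_realised[a] / n for a in present},
        "tracking_ratio": 1.0 - (n_untracked - untracked_left) / n,
        "n_fixations": k_sum,
    }
    return stream, info


# ---------------------------------------------------------------------------
# Trial and cohort simulation
# ---------------------------------------------------------------------------

def simulate_trial(
    preset: ConditionPreset,
    step: StepGeometry | None = None,
    seed: int | np.random.SeedSequence = 0,
    participant_offsets: Mapping[str, float] | None = None,
    sd_scale: float = 1.0,
    with_markers: bool = True,
    with_gaze: bool = True,
    participant_id: str = "P01",
    repetition: int = 1,
) -> tuple[TrialBundle, GroundTruth]:
    """Simulate one trial; deterministic under (preset, step, seed).

    ``sd_scale=0`` gives degenerate (noise-off) draws: every realised target
    equals the preset mean exactly.  ``with_markers=False`` skips marker
    synthesis (the drawn targets and gaze stream are unchanged), which is
    useful for large statistical simulations.
    """
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    ss_targets, ss_markers, ss_gaze, ss_misc = ss.spawn(4)
    rng_t = np.random.default_rng(ss_targets)
    rng_misc = np.random.default_rng(ss_misc)

    targets = _draw_targets(preset, rng_t, participant_offsets, sd_scale)
    if step is None:
        step = StepGeometry(edge_x=float(rng_misc.uniform(*EDGE_RANGE)))
    lead_side = "left" if rng_misc.random() < 0.5 else "right"

    # the stride plan (and with it every realised timing) is computed even
    # when marker rendering is skipped, so both modes agree exactly
    lead_plan, trail_plan, info = _plan_trial(targets, step, lead_side)
    trial_time = info["trial_time"]
    markers: dict[str, MarkerTrajectory] = {}
    if with_markers:
        markers = _render_markers(
            lead_plan, trail_plan, info, targets, step, lead_side,
            np.random.default_rng(ss_markers),
        )

    gt = GroundTruth(
        condition=preset.condition,
        trial_time=trial_time,
        edge_x=step.edge_x,
        lead_foot=lead_side,
        gait=info["gait"],
        head={ev: targets[f"head_{ev}"] for ev in HEAD_EVENTS},
        event_times=info["event_times"],
        n_stances=info["n_stances"],
        targets=dict(targets),
    )

    gaze = None
    if with_gaze:
        gaze, ginfo = _build_gaze(
            targets, preset.present_aois, trial_time,
            np.random.default_rng(ss_gaze),
        )
        gt.gaze_counts = ginfo["gaze_counts"]
        gt.gaze_times = ginfo["gaze_times"]
        gt.tracking_ratio = ginfo["tracking_ratio"]
        gt.n_fixations = ginfo["n_fixations"]

    bundle = TrialBundle(
        participant_id=participant_id,
        condition=preset.condition,
        repetition=repetition,
        markers=markers,
        gaze=gaze,
        step=step,
        trial_duration=trial_time,
    )
    return bundle, gt


def _participant_offsets(
    preset: ConditionPreset, rng: np.random.Generator, fraction: float
) -> dict[str, float]:
    """Additive per-participant offsets: N(0, (fraction * SD)^2) per target."""
    off: dict[str, float] = {}

    def add(key: str, ms: MS) -> None:
        off[key] = float(rng.standard_normal() * fraction * ms[1])

    add("trial_time", preset.trial_time)
    for k, ms in preset.gait.items():
        add(k, ms)
    for ev, ms in preset.head.items():
        add(f"head_{ev}", ms)
    for aoi in preset.present_aois:
        add(f"count_{aoi}", preset.gaze_counts[aoi])
        add(f"time_{aoi}", preset.gaze_times[aoi])
    return off


def simulate_cohort(
    design: CohortDesign,
    seed: int | np.random.SeedSequence = 0,
    with_markers: bool = True,
    with_gaze: bool = True,
) -> list[tuple[TrialBundle, GroundTruth]]:
    """Simulate a full cohort; deterministic under (design, seed).

    Per-participant offsets (between-participant variation) are applied to
    every preset mean; the remaining variance stays within-participant so
    total per-trial variance matches the preset SDs.
    """
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    within_scale = math.sqrt(max(0.0, 1.0 - design.between_sd_fraction**2))
    presets = {c: condition_presets(c) for c in design.conditions}
    out: list[tuple[TrialBundle, GroundTruth]] = []
    ss_parts = ss.spawn(design.n_participants)
    for p in range(design.n_participants):
        pid = f"P{p + 1:02d}"
        ss_off, ss_trials = ss_parts[p].spawn(2)
        rng_off = np.random.default_rng(ss_off)
        offsets = {
            c: _participant_offsets(
                presets[c], rng_off, design.between_sd_fraction
            )
            for c in design.conditions
        }
        trial_seeds = ss_trials.spawn(len(design.conditions) * design.repetitions)
        i = 0
        for c in design.conditions:
            for rep in range(1, design.repetitions + 1):
                bundle, gt = simulate_trial(
                    presets[c],
                    seed=trial_seeds[i],
                    participant_offsets=offsets[c],
                    sd_scale=within_scale,
                    with_markers=with_markers,
                    with_gaze=with_gaze,
                    participant_id=pid,
                    repetition=rep,
                )
                out.append((bundle, gt))
                i += 1
    return out


def degrade_tracking(
    stream: GazeStream,
    target_ratio: float,
    seed: int | np.random.SeedSequence = 0,
) -> GazeStream:
    """Replace randomly chosen tracked samples with ``untracked`` so the
    tracked fraction equals ``target_ratio`` within one sample.

    Only degrades: if the stream is already below the target it is returned
    unchanged.
    """
    if not 0.0 <= target_ratio <= 1.0:
        raise ValueError("target_ratio must be in [0, 1]")
    labels = np.array(stream.labels, dtype=object)
    n = len(labels)
    want_untracked = int(round((1.0 - target_ratio) * n))
    current = int(np.sum(labels == UNTRACKED))
    extra = want_untracked - current
    if extra <= 0:
        return GazeStream(labels=labels, rate=stream.rate)
    rng = np.random.default_rng(seed)
    tracked_idx = np.nonzero(labels != UNTRACKED)[0]
    chosen = rng.choice(tracked_idx, size=extra, replace=False)
    labels[chosen] = UNTRACKED
    return GazeStream(labels=labels, rate=stream.rate)
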