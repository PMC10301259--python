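"""Spatiotemporal and angular gait features from one gait cycle.

Forty features are computed from marker kinematics over the cycle bounded
by two successive touchdowns of the unperturbed (right) foot, which
brackets the perturbed (left) foot's liftoff (LO) and touchdown (post-TD):

* five gait speeds from the whole-body COM: average and maximum over the
  cycle, and the instantaneous anteroposterior COM velocity at pre-TD,
  LO and post-TD;
* the COM state at each of the three events: COM position relative to
  the posterior base of support (rear heel) and the margin of stability
  (MOS) in the extrapolated-COM sense of Hof;
* swing time (LO to post-TD), step time (pre-TD to post-TD), gait cycle
  time, step length (anteroposterior heel-to-heel distance between
  pre-TD and post-TD) and toe clearance (maximum perturbed-toe height in
  swing);
* sagittal trunk, hip, knee and foot segment angles, measured against
  the horizontal via atan2 in the x-y (sagittal) plane: trunk angle at
  LO and post-TD plus the maximum trunk flexion over the cycle, the six
  bilateral hip/knee/foot angles at each of the three events, and the
  perturbed limb's swing-phase extrema of hip flexion, knee flexion and
  foot angle.

Angle conventions follow the horizontal-reference definition: a vertical
trunk scores 90 deg, a fully extended knee 180 deg, a flat foot 0 deg.
"Maximum trunk flexion" and "maximum knee flexion" are reported as the
angle attained at peak flexion (the minimum of the angle signal, since
flexing lowers both measures).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .body import BodyModel
from .events import GaitEvents
from .markers import MarkerTrajectorySet

_EVENTS = ("pre-TD", "LO", "post-TD")

#: The canonical ordered 40-feature set.
FEATURE_NAMES: tuple[str, ...] = (
    "Gait speed in gait cycle",
    "Max gait speed in gait cycle",
    "COM velocity at pre-TD",
    "COM velocity at LO",
    "COM velocity at post-TD",
    "COM position at pre-TD",
    "COM position at LO",
    "COM position at post-TD",
    "MOS at pre-TD",
    "MOS at LO",
    "MOS at post-TD",
    "Swing time",
    "Step time",
    "Step length",
    "Toe clearance",
    "Gait cycle time",
    "Trunk angle at LO",
    "Trunk angle at post-TD",
    "Max trunk flexion in gait cycle",
    *(f"{s} {j} angle at {e}" for e in _EVENTS for s in ("L", "R")
      for j in ("hip", "knee", "foot")),
    "Max hip flexion in swing phase",
    "Max knee flexion in swing phase",
    "Max foot angle in swing phase",
)

assert len(FEATURE_NAMES) == 40 and len(set(FEATURE_NAMES)) == 40

#: Feature names measured in seconds (must be strictly positive).
_TIME_FEATURES = ("Swing time", "Step time", "Gait cycle time")


@dataclass
class FeatureVector:
    """The 40 named gait features for one trial, with unit conventions.

    Speeds are m/s, lengths m, times s, angles degrees; MOS is the
    extrapolated-COM margin in metres.
    """

    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = [n for n in FEATURE_NAMES if n not in self.values]
        extra = [n for n in self.values if n not in FEATURE_NAMES]
        if missing or extra:
            raise ValueError(
                f"feature vector must carry exactly the 40 canonical features; "
                f"missing={missing[:3]}..., extra={extra[:3]}..."
                if len(missing) > 3 or len(extra) > 3
                else f"missing={missing}, extra={extra}"
            )
        for name, v in self.values.items():
            if not math.isfinite(v):
                raise ValueError(f"feature {name!r} is not finite: {v}")
        for name in _TIME_FEATURES:
            if self.values[name] <= 0:
                raise ValueError(f"{name} must be positive")
        if self.values["Toe clearance"] <= 0:
            raise ValueError("Toe clearance must be positive")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def to_series(self) -> pd.Series:
        return pd.Series({n: self.values[n] for n in FEATURE_NAMES})


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

def segment_angle(distal, proximal) -> float:
    """Sagittal angle of the proximal→distal segment against the horizontal.

    ``atan2(distal_y - proximal_y, distal_x - proximal_x)`` in degrees,
    in (-180, 180].  Used with (shoulder, hip) for the trunk, (hip, knee)
    for the hip/thigh and (toe, heel) for the foot.
    """
    dx = float(distal[0]) - float(proximal[0])
    dy = float(distal[1]) - float(proximal[1])
    if dx == 0.0 and dy == 0.0:
        raise ValueError("segment endpoints coincide; angle undefined")
    ang = math.degrees(math.atan2(dy, dx))
    return 180.0 if ang == -180.0 else ang


def knee_angle(hip, knee, ankle) -> float:
    """Knee angle between thigh and shank, 180 deg at full extension.

    Composed from two horizontal-reference angles:
    ``atan2(knee_y - ankle_y, knee_x - ankle_x) + (180 - hip_angle)``
    where the hip angle is the thigh's own horizontal-reference angle.
    """
    theta_hip = segment_angle(hip, knee)
    theta_shank = segment_angle(knee, ankle)
    return theta_shank + (180.0 - theta_hip)


def margin_of_stability(com_x: float, bos_min_x: float, vcom_x: float,
                        model: BodyModel) -> float:
    """Anteroposterior margin of stability (extrapolated COM form).

    MOS = (COM - BOSmin) + vCOM / sqrt(g / l), with the rear-heel x
    coordinate as the posterior base-of-support boundary and l the leg
    length of the inverted pendulum.  The velocity term divides by the
    pendulum eigenfrequency sqrt(g/l) so that the margin has units of
    length.
    """
    if model.leg_length is None or model.leg_length <= 0:
        raise ValueError("BodyModel.leg_length must be set and positive for MOS")
    omega = math.sqrt(model.g / model.leg_length)
    return (com_x - bos_min_x) + vcom_x / omega


# ---------------------------------------------------------------------------
# whole-body COM
# ---------------------------------------------------------------------------

def _anchor_positions(traj: MarkerTrajectorySet, anchor) -> np.ndarray:
    try:
        pts = [traj.marker(m) for m in anchor]
    except KeyError as exc:
        raise KeyError(f"body model needs marker {exc.args[0]}") from None
    return np.mean(pts, axis=0)


def compute_com(traj: MarkerTrajectorySet, model: BodyModel):
    """Whole-body COM trajectory and velocity from the segmental model.

    Returns ``(com, vcom)``, both of shape (n_frames, 3) in metres and
    m/s.  Velocity uses central differences at the record's sampling
    rate (one-sided at the record ends).
    """
    com = np.zeros((traj.n_frames, 3))
    for seg in model.segments:
        prox = _anchor_positions(traj, seg.proximal)
        dist = _anchor_positions(traj, seg.distal)
        seg_com = prox + seg.com_fraction * (dist - prox)
        com += seg.mass_fraction * seg_com
    vcom = np.gradient(com, axis=0) * traj.sampling_rate
    return com, vcom


# ---------------------------------------------------------------------------
# full extraction
# ---------------------------------------------------------------------------

def estimate_leg_length(traj: MarkerTrajectorySet) -> float:
    """Leg length proxy: mean hip-midpoint height above the lowest heel."""
    hip_mid = 0.5 * (traj.marker("L_hip") + traj.marker("R_hip"))
    ground = min(float(np.min(traj.marker("L_heel")[:, 1])),
                 float(np.min(traj.marker("R_heel")[:, 1])))
    return float(np.mean(hip_mid[:, 1])) - ground


def _joint_angles_at(traj: MarkerTrajectorySet, side: str, frame: int):
    hip = traj.marker(f"{side}_hip")[frame, :2]
    knee = traj.marker(f"{side}_knee")[frame, :2]
    ankle = traj.marker(f"{side}_ankle")[frame, :2]
    heel = traj.marker(f"{side}_heel")[frame, :2]
    toe = traj.marker(f"{side}_toe")[frame, :2]
    return {
        "hip": segment_angle(hip, knee),
        "knee": knee_angle(hip, knee, ankle),
        "foot": segment_angle(toe, heel),
    }


def extract_features(traj: MarkerTrajectorySet, events: GaitEvents,
                     model: BodyModel | None = None) -> FeatureVector:
    """Compute the 40 canonical gait features for one gait cycle."""
    if model is None:
        model = BodyModel()
    events.validate_for(traj)
    rate = traj.sampling_rate
    pre, lo, post, nxt = events.pre_TD, events.LO, events.post_TD, events.next_TD
    cycle = slice(pre, nxt + 1)   # closed at both event frames
    swing = slice(lo, post + 1)

    if model.leg_length is None:
        model = BodyModel(sex=model.sex, leg_length=estimate_leg_length(traj),
                          g=model.g, segments=model.segments)

    com, vcom = compute_com(traj, model)
    v_ap = vcom[:, 0]
    cycle_time = (nxt - pre) / rate

    f: dict[str, float] = {}
    f["Gait speed in gait cycle"] = (com[nxt, 0] - com[pre, 0]) / cycle_time
    f["Max gait speed in gait cycle"] = float(np.max(v_ap[cycle]))
    for name, frame in zip(_EVENTS, (pre, lo, post)):
        f[f"COM velocity at {name}"] = float(v_ap[frame])

    l_heel_x = traj.marker("L_heel")[:, 0]
    r_heel_x = traj.marker("R_heel")[:, 0]
    for name, frame in zip(_EVENTS, (pre, lo, post)):
        bos_min = min(float(l_heel_x[frame]), float(r_heel_x[frame]))
        f[f"COM position at {name}"] = float(com[frame, 0]) - bos_min
        f[f"MOS at {name}"] = margin_of_stability(
            float(com[frame, 0]), bos_min, float(v_ap[frame]), model)

    f["Swing time"] = (post - lo) / rate
    f["Step time"] = (post - pre) / rate
    f["Gait cycle time"] = cycle_time
    f["Step length"] = abs(float(l_heel_x[post]) - float(r_heel_x[pre]))
    # clearance above the toe's stance-level baseline (translation invariant)
    l_toe_y = traj.marker("L_toe")[:, 1]
    f["Toe clearance"] = float(np.max(l_toe_y[swing]) - np.min(l_toe_y))

    shoulder_mid = 0.5 * (traj.marker("L_shoulder") + traj.marker("R_shoulder"))
    hip_mid = 0.5 * (traj.marker("L_hip") + traj.marker("R_hip"))
    trunk = np.array([
        segment_angle(shoulder_mid[i, :2], hip_mid[i, :2])
        for i in range(pre, nxt + 1)
    ])
    f["Trunk angle at LO"] = float(trunk[lo - pre])
    f["Trunk angle at post-TD"] = float(trunk[post - pre])
    # peak forward lean = smallest horizontal-reference trunk angle
    f["Max trunk flexion in gait cycle"] = float(np.min(trunk))

    for ev_name, frame in zip(_EVENTS, (pre, lo, post)):
        for side in ("L", "R"):
            ang = _joint_angles_at(traj, side, frame)
            for joint in ("hip", "knee", "foot"):
                f[f"{side} {joint} angle at {ev_name}"] = ang[joint]

    swing_angles = {"hip": [], "knee": [], "foot": []}
    for i in range(lo, post + 1):
        ang = _joint_angles_at(traj, "L", i)
        for joint in swing_angles:
            swing_angles[joint].append(ang[joint])
    f["Max hip flexion in swing phase"] = float(np.max(swing_angles["hip"]))
    # peak knee flexion = smallest knee angle (180 deg = full extension)
    f["Max knee flexion in swing phase"] = float(np.min(swing_angles["knee"]))
    f["Max foot angle in swing phase"] = float(np.max(swing_angles["foot"]))

    return FeatureVector(values=f)
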