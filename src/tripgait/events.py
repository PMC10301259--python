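"""Kinematic gait-event detection.

The analysed gait cycle runs from a touchdown of the unperturbed (right)
foot (pre-TD), through the perturbed (left) foot's liftoff (LO) and
touchdown (post-TD), to the next right touchdown.  Events are detected
from heel/toe vertical kinematics alone: a touchdown is the first frame
of a sustained "grounded" run of the heel (heel height below a threshold,
reached with downward velocity), and a liftoff is the onset of a
sustained rise of the toe out of its grounded band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .markers import MarkerTrajectorySet


@dataclass(frozen=True)
class GaitEvents:
    """Frame indices (0-based) of the event quadruple bounding one cycle."""

    pre_TD: int   # right (unperturbed) touchdown
    LO: int       # left (perturbed) liftoff
    post_TD: int  # left touchdown
    next_TD: int  # next right touchdown

    def __post_init__(self) -> None:
        if not (self.pre_TD < self.LO < self.post_TD < self.next_TD):
            raise ValueError(
                "gait events must be ordered pre_TD < LO < post_TD < next_TD; "
                f"got {self.pre_TD}, {self.LO}, {self.post_TD}, {self.next_TD}"
            )
        if self.pre_TD < 0:
            raise ValueError("event frames must be non-negative")

    def validate_for(self, traj: MarkerTrajectorySet) -> None:
        if self.next_TD >= traj.n_frames:
            raise ValueError(
                f"event frame {self.next_TD} outside record of {traj.n_frames} frames"
            )


class EventDetectionError(RuntimeError):
    """No usable gait cycle found in the record."""


def _grounded_runs(y: np.ndarray, frac: float) -> list[tuple[int, int]]:
    """Contiguous [start, stop) runs where y sits in its lowest band.

    The band is ``min(y) + frac * range(y)``; a flat signal has no band and
    yields no runs.
    """
    lo, hi = float(np.min(y)), float(np.max(y))
    if hi - lo < 1e-9:
        return []
    grounded = y <= lo + frac * (hi - lo)
    runs = []
    start = None
    for i, g in enumerate(grounded):
        if g and start is None:
            start = i
        elif not g and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(y)))
    return runs


def _band_level(y: np.ndarray, frac: float) -> float:
    return float(np.min(y) + frac * (np.max(y) - np.min(y)))


def _refine_down(y: np.ndarray, s: int, band: float) -> int:
    """Frame nearest the interpolated downward band crossing ending at s."""
    if s == 0 or y[s - 1] <= band:
        return s
    t = (y[s - 1] - band) / (y[s - 1] - y[s])
    return int(round(s - 1 + t))


def _refine_up(y: np.ndarray, e: int, band: float) -> int:
    """Frame nearest the interpolated upward band crossing starting at e-1."""
    if e >= len(y) or y[e] <= band:
        return e
    t = (band - y[e - 1]) / (y[e] - y[e - 1])
    return int(round(e - 1 + t))


def _touchdowns(y: np.ndarray, frac: float, min_run: int) -> list[int]:
    """First frames of grounded runs, skipping a run that starts the record."""
    band = _band_level(y, frac)
    return [_refine_down(y, s, band)
            for s, e in _grounded_runs(y, frac) if e - s >= min_run and s > 0]


def _liftoffs(y: np.ndarray, frac: float, min_run: int) -> list[int]:
    """Frames at which a sufficiently long grounded run ends (toe rises)."""
    n = len(y)
    band = _band_level(y, frac)
    return [_refine_up(y, e, band)
            for s, e in _grounded_runs(y, frac) if e - s >= min_run and e < n]


def detect_gait_events(
    traj: MarkerTrajectorySet,
    clearance_fraction: float = 0.10,
    min_contact_s: float = 0.1,
) -> GaitEvents:
    """Detect the pre-TD / LO / post-TD / next-TD quadruple.

    Parameters
    ----------
    traj
        Marker record with at least ~1.5 gait cycles.
    clearance_fraction
        Fraction of each signal's vertical range that defines its
        "grounded" band (default 10%).
    min_contact_s
        Minimum duration of a ground-contact run, to reject jitter.

    Raises
    ------
    EventDetectionError
        If either limb yields no detectable cycle, naming the failing limb.
    """
    min_run = max(2, int(round(min_contact_s * traj.sampling_rate)))
    r_td = _touchdowns(traj.marker("R_heel")[:, 1], clearance_fraction, min_run)
    l_td = _touchdowns(traj.marker("L_heel")[:, 1], clearance_fraction, min_run)
    l_lo = _liftoffs(traj.marker("L_toe")[:, 1], clearance_fraction, min_run)
    if len(r_td) < 2:
        raise EventDetectionError(
            "no gait cycle detectable on the right (unperturbed) limb: "
            f"found {len(r_td)} touchdown(s)"
        )
    if not l_td or not l_lo:
        raise EventDetectionError(
            "no gait cycle detectable on the left (perturbed) limb: "
            f"found {len(l_td)} touchdown(s), {len(l_lo)} liftoff(s)"
        )
    # first right TD followed by left LO < left TD < next right TD
    for i, pre in enumerate(r_td[:-1]):
        nxt = r_td[i + 1]
        lo_c = [f for f in l_lo if pre < f < nxt]
        td_c = [f for f in l_td if pre < f < nxt]
        if lo_c and td_c and lo_c[0] < td_c[0]:
            return GaitEvents(pre_TD=pre, LO=lo_c[0], post_TD=td_c[0], next_TD=nxt)
    raise EventDetectionError(
        "left-limb liftoff/touchdown never fell inside a right-limb step; "
        "record may be too short or event ordering is inconsistent"
    )
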