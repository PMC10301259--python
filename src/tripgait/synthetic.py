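"""Synthetic stand-ins for the trip-study cohort.

Two generators live here:

* a feature-level generator that draws labelled gait-feature tables from
  class-conditional Gaussian marginals (per-class means and SDs for the
  20 top-ranked features of the study cohort, published as group
  summaries), with exact class counts of 192 no-fall / 84 L-fall /
  22 E-fall;
* a marker-level generator that synthesises a planar (sagittal-dominant)
  periodic walking trial with known ground truth, so the feature
  extractors can be verified end to end.

Only marginal means and SDs are published for the cohort; between-feature
correlation defaults to identity and can be supplied per class.  Because
the published marginals overlap heavily between classes, a
``separation_boost`` factor can scale up the between-class mean
differences to create a separable regime for pipeline-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .markers import MarkerTrajectorySet

CLASS_NAMES: tuple[str, ...] = ("no_fall", "L_fall", "E_fall")
CLASS_COUNTS: tuple[int, ...] = (192, 84, 22)
OUTCOME_COLUMN = "outcome"

#: Cohort demographics: mean, sd (age in years, weight kg, height m).
DEMOGRAPHICS = {"age": (69.6, 6.33), "weight": (75.2, 17.2), "height": (1.67, 0.10)}
MALE_FRACTION = 128 / 298
DEMOGRAPHIC_COLUMNS = ("age", "gender", "height", "weight")

# Per-class mean ± SD of the 20 top-ranked features, in ranking order.
# Columns: (no_fall mean, sd), (L_fall mean, sd), (E_fall mean, sd).
_TOP20 = {
    "COM velocity at LO": ((1.03, 0.19), (1.19, 0.54), (1.17, 0.22)),
    "L hip angle at post-TD": ((108.08, 4.92), (109.91, 5.18), (110.22, 3.58)),
    "Gait speed in gait cycle": ((1.03, 0.19), (1.12, 0.19), (1.17, 0.21)),
    "Max knee flexion in swing phase": ((119.18, 9.15), (116.50, 10.21), (116.76, 6.62)),
    "R foot angle at post-TD": ((-9.09, 7.11), (-12.32, 8.33), (-12.23, 8.55)),
    "L knee angle at post-TD": ((178.15, 8.80), (177.07, 8.97), (176.36, 8.23)),
    "Toe clearance": ((0.16, 0.03), (0.16, 0.02), (0.16, 0.02)),
    "Max trunk flexion in gait cycle": ((86.08, 5.34), (86.67, 5.70), (84.88, 6.48)),
    "COM velocity at pre-TD": ((1.06, 0.21), (1.16, 0.20), (1.20, 0.24)),
    "R hip angle at post-TD": ((74.05, 6.46), (72.54, 4.46), (71.71, 6.32)),
    "Trunk angle at post-TD": ((89.23, 4.73), (89.87, 5.89), (88.11, 5.91)),
    "Max hip flexion in swing phase": ((112.44, 5.11), (114.19, 5.65), (112.86, 3.98)),
    "R knee angle at post-TD": ((171.79, 8.47), (172.08, 7.45), (173.67, 9.50)),
    "L hip angle at LO": ((87.71, 6.05), (86.05, 6.17), (87.15, 7.00)),
    "Max gait speed in gait cycle": ((1.11, 0.20), (1.28, 0.63), (1.25, 0.23)),
    "R knee angle at LO": ((164.41, 9.24), (164.37, 9.36), (162.50, 9.37)),
    "L foot angle at post-TD": ((15.68, 7.12), (16.81, 6.27), (17.54, 5.84)),
    "R hip angle at LO": ((102.18, 5.75), (103.60, 5.68), (104.43, 6.01)),
    "Trunk angle at LO": ((88.57, 4.80), (89.12, 5.62), (87.15, 6.25)),
    "L knee angle at LO": ((134.20, 10.42), (133.72, 10.32), (131.71, 10.11)),
}

# The remaining 20 canonical features, with realistic class-independent
# marginals (mean, sd).  These were not among the cohort's top-ranked
# features, so no per-class summaries exist; sampling them identically
# across classes makes them uninformative by construction, mirroring
# their non-selection.
_REST20 = {
    "COM velocity at post-TD": (1.05, 0.20),
    "COM position at pre-TD": (0.40, 0.08),
    "COM position at LO": (0.45, 0.08),
    "COM position at post-TD": (0.40, 0.08),
    "MOS at pre-TD": (0.72, 0.10),
    "MOS at LO": (0.77, 0.10),
    "MOS at post-TD": (0.72, 0.10),
    "Swing time": (0.38, 0.04),
    "Step time": (0.55, 0.05),
    "Step length": (0.62, 0.07),
    "Gait cycle time": (1.08, 0.09),
    "L hip angle at pre-TD": (76.0, 6.0),
    "R hip angle at pre-TD": (107.0, 5.0),
    "L knee angle at pre-TD": (172.0, 8.0),
    "R knee angle at pre-TD": (177.0, 8.5),
    "L foot angle at pre-TD": (-18.0, 7.0),
    "R foot angle at pre-TD": (16.0, 7.0),
    "L foot angle at LO": (-25.0, 8.0),
    "R foot angle at LO": (0.0, 5.0),
    "Max foot angle in swing phase": (20.0, 7.0),
}


@dataclass
class ClassDistributionSpec:
    """Class-conditional Gaussian spec for a labelled feature table.

    ``means`` and ``sds`` are DataFrames indexed by class name with one
    column per feature.  ``correlation`` optionally maps a class name to
    a symmetric PSD feature-correlation matrix (identity when absent).
    ``separation_boost`` scales the between-class mean differences about
    the count-weighted grand mean (1.0 = as configured).
    """

    class_names: tuple[str, ...]
    class_counts: tuple[int, ...]
    feature_names: tuple[str, ...]
    means: pd.DataFrame
    sds: pd.DataFrame
    correlation: dict[str, np.ndarray] = field(default_factory=dict)
    separation_boost: float = 1.0

    def __post_init__(self) -> None:
        if len(self.class_names) != len(self.class_counts):
            raise ValueError("class_names and class_counts lengths differ")
        if any(c < 1 for c in self.class_counts):
            raise ValueError("class_counts must be >= 1")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature_names must be unique")
        if self.separation_boost < 0:
            raise ValueError("separation_boost must be non-negative")
        for df, what in ((self.means, "means"), (self.sds, "sds")):
            if list(df.index) != list(self.class_names):
                raise ValueError(f"{what} must be indexed by class_names, in order")
            if list(df.columns) != list(self.feature_names):
                raise ValueError(f"{what} columns must equal feature_names, in order")
        if (self.sds.to_numpy() < 0).any():
            raise ValueError("sds must be non-negative")
        p = len(self.feature_names)
        for cls, corr in self.correlation.items():
            if cls not in self.class_names:
                raise ValueError(f"correlation given for unknown class {cls!r}")
            corr = np.asarray(corr, dtype=float)
            if corr.shape != (p, p) or not np.allclose(corr, corr.T, atol=1e-10):
                raise ValueError(f"correlation for class {cls!r} must be symmetric {p}x{p}")
            if np.min(np.linalg.eigvalsh(corr)) < -1e-8:
                raise ValueError(
                    f"correlation matrix for class {cls!r} is not positive semi-definite"
                )

    @property
    def n_total(self) -> int:
        return int(sum(self.class_counts))

    def boosted_means(self) -> pd.DataFrame:
        """Class means with between-class differences scaled by the boost."""
        if self.separation_boost == 1.0:
            return self.means
        w = np.asarray(self.class_counts, dtype=float)
        grand = (self.means.to_numpy() * w[:, None]).sum(axis=0) / w.sum()
        boosted = grand[None, :] + self.separation_boost * (self.means.to_numpy() - grand)
        return pd.DataFrame(boosted, index=self.means.index, columns=self.means.columns)

    def with_boost(self, boost: float) -> "ClassDistributionSpec":
        return replace(self, separation_boost=boost)

    # -- serialization -------------------------------------------------

    def to_yaml(self, path) -> None:
        data = {
            "class_names": list(self.class_names),
            "class_counts": [int(c) for c in self.class_counts],
            "feature_names": list(self.feature_names),
            "means": {c: [float(v) for v in self.means.loc[c]] for c in self.class_names},
            "sds": {c: [float(v) for v in self.sds.loc[c]] for c in self.class_names},
            "correlation": {c: np.asarray(m).tolist() for c, m in self.correlation.items()},
            "separation_boost": float(self.separation_boost),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ClassDistributionSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        names = tuple(data["class_names"])
        feats = tuple(data["feature_names"])
        means = pd.DataFrame([data["means"][c] for c in names], index=list(names),
                             columns=list(feats))
        sds = pd.DataFrame([data["sds"][c] for c in names], index=list(names),
                           columns=list(feats))
        corr = {c: np.asarray(m, dtype=float)
                for c, m in (data.get("correlation") or {}).items()}
        return cls(
            class_names=names,
            class_counts=tuple(int(c) for c in data["class_counts"]),
            feature_names=feats,
            means=means,
            sds=sds,
            correlation=corr,
            separation_boost=float(data.get("separation_boost", 1.0)),
        )


def _spec_from_tables(feature_map: dict) -> ClassDistributionSpec:
    feats = tuple(feature_map)
    means = pd.DataFrame(index=list(CLASS_NAMES), columns=list(feats), dtype=float)
    sds = pd.DataFrame(index=list(CLASS_NAMES), columns=list(feats), dtype=float)
    for feat, per_class in feature_map.items():
        for cls, (m, s) in zip(CLASS_NAMES, per_class):
            means.loc[cls, feat] = m
            sds.loc[cls, feat] = s
    return ClassDistributionSpec(
        class_names=CLASS_NAMES,
        class_counts=CLASS_COUNTS,
        feature_names=feats,
        means=means,
        sds=sds,
    )


def table1_spec() -> ClassDistributionSpec:
    """Published per-class marginals of the cohort's 20 top-ranked features."""
    return _spec_from_tables(_TOP20)


def cohort_spec() -> ClassDistributionSpec:
    """Full 40-feature cohort spec: the 20 published class-conditional
    marginals plus 20 class-independent features (realistic scales, no
    class signal), giving the ranking stage a 40-wide pool to select from.
    """
    full = dict(_TOP20)
    for feat, (m, s) in _REST20.items():
        full[feat] = ((m, s), (m, s), (m, s))
    return _spec_from_tables(full)


def _class_cov_factor(spec: ClassDistributionSpec, cls: str, sds: np.ndarray) -> np.ndarray | None:
    """Matrix L with cov = (L @ L.T) scaled by sds, or None for identity."""
    corr = spec.correlation.get(cls)
    if corr is None:
        return None
    corr = np.asarray(corr, dtype=float)
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        # PSD but singular: eigendecomposition with clipped eigenvalues
        vals, vecs = np.linalg.eigh(corr)
        return vecs * np.sqrt(np.clip(vals, 0.0, None))


def generate_feature_table(spec: ClassDistributionSpec, seed: int) -> pd.DataFrame:
    """Draw a labelled feature table from the class-conditional spec.

    Returns a DataFrame with the spec's feature columns plus an
    ``outcome`` label column; exactly ``class_counts[i]`` rows per class,
    in class order.  Deterministic given (spec, seed).
    """
    rng = np.random.default_rng(seed)
    means = spec.boosted_means()
    blocks = []
    for cls, count in zip(spec.class_names, spec.class_counts):
        mu = means.loc[cls].to_numpy()
        sd = spec.sds.loc[cls].to_numpy()
        z = rng.standard_normal((count, len(spec.feature_names)))
        factor = _class_cov_factor(spec, cls, sd)
        if factor is not None:
            z = z @ factor.T
        block = pd.DataFrame(mu + z * sd, columns=list(spec.feature_names))
        block[OUTCOME_COLUMN] = cls
        blocks.append(block)
    return pd.concat(blocks, ignore_index=True)


def attach_demographics(table: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Append age / gender / height / weight columns, independent of class.

    Gender is encoded numerically (1 = male, 0 = female) so it can enter
    the feature pool directly; P(male) matches the cohort sex ratio.
    """
    present = [c for c in DEMOGRAPHIC_COLUMNS if c in table.columns]
    if present:
        raise ValueError(f"table already has demographic columns: {present}")
    rng = np.random.default_rng(seed)
    n = len(table)
    out = table.copy()
    out["age"] = rng.normal(*DEMOGRAPHICS["age"], size=n)
    out["gender"] = (rng.random(n) < MALE_FRACTION).astype(float)
    out["height"] = rng.normal(*DEMOGRAPHICS["height"], size=n)
    out["weight"] = rng.normal(*DEMOGRAPHICS["weight"], size=n)
    return out


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format="%.9g")


def read_feature_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    if OUTCOME_COLUMN not in table.columns:
        raise ValueError(f"feature table must have an {OUTCOME_COLUMN!r} column")
    return table


# ---------------------------------------------------------------------------
# marker-level gait trial generator
# ---------------------------------------------------------------------------

@dataclass
class GaitTrialSpec:
    """Ground-truth parameters of a synthetic periodic walking trial.

    ``step_length`` defaults to gait_speed * 60 / cadence (the kinematic
    identity); supplying an inconsistent value is rejected, since the
    generator's ground truth could not then be honoured.
    ``trunk_lean`` is degrees forward of vertical; ``noise_sd`` is
    isotropic marker jitter in metres.
    """

    gait_speed: float = 1.05      # m/s
    cadence: float = 110.0        # steps/min
    trunk_lean: float = 3.0       # deg from vertical
    max_toe_height: float = 0.16  # m
    leg_length: float = 0.90      # m
    step_length: float | None = None
    sampling_rate: float = 120.0  # Hz
    n_cycles: int = 3
    noise_sd: float = 0.0         # m

    def __post_init__(self) -> None:
        for name in ("gait_speed", "cadence", "max_toe_height", "leg_length",
                     "sampling_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.trunk_lean < 0 or self.noise_sd < 0:
            raise ValueError("trunk_lean and noise_sd must be non-negative")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        derived = self.gait_speed * 60.0 / self.cadence
        if self.step_length is None:
            self.step_length = derived
        elif self.step_length <= 0:
            raise ValueError("step_length must be positive")
        elif abs(self.step_length - derived) > 0.02 * derived:
            raise ValueError(
                f"step_length {self.step_length:.3f} inconsistent with "
                f"gait_speed*60/cadence = {derived:.3f}"
            )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: getattr(self, k) for k in (
                    "gait_speed", "cadence", "trunk_lean", "max_toe_height",
                    "leg_length", "step_length", "sampling_rate", "n_cycles",
                    "noise_sd")},
                fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GaitTrialSpec":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


#: Swing phase occupies this fraction of the gait cycle (typical adult gait).
SWING_FRACTION = 0.38
_GROUND = 0.02        # heel/toe marker height on the shoe, m
_FOOT_LEN_FRAC = 0.17  # foot (heel->toe) length as fraction of leg length
_PUSHOFF_PITCH = -25.0  # peak plantarflexion at push-off/early swing, deg
_LANDING_PITCH = 15.0   # dorsiflexion at heel strike, deg
_BOB_FRAC = 0.045     # pelvic vertical excursion amplitude / leg length
_ROCKER_FRAC = 0.15   # heel-rocker fraction of stance (landing pitch -> flat)
_HEELOFF_FRAC = 0.65  # stance fraction at which heel-off pitching starts


def _foot_markers(t, td0, period, x0, step2, stance, swing, foot_len, peak):
    """Heel/toe/ankle sagittal positions for one foot over time ``t``.

    Footfalls occur at ``td0 + k*period`` with the heel landing at
    ``x0 + k*step2``.  Stance rolls through a heel rocker (dorsiflexed
    landing pitching flat about the planted heel), a flat phase, and a
    heel-off phase (plantarflexing about the planted toe).  In swing the
    toe advances with a raised-cosine profile and rises as sin(pi*tau)
    to ``peak``, landing dorsiflexed again.  Foot pitch is continuous
    throughout.
    """
    k = np.floor((t - td0) / period)
    phase = (t - td0) - k * period     # time since this foot's touchdown
    heel_anchor_x = x0 + k * step2

    in_swing = phase >= stance
    ps = np.where(in_swing, 0.0, phase / stance)          # stance progress
    tau = np.where(in_swing, (phase - stance) / swing, 0.0)  # swing progress

    rocker = (~in_swing) & (ps < _ROCKER_FRAC)
    heeloff = (~in_swing) & (ps >= _HEELOFF_FRAC)
    u_r = np.where(rocker, ps / _ROCKER_FRAC, 1.0)
    u_h = np.where(heeloff, (ps - _HEELOFF_FRAC) / (1.0 - _HEELOFF_FRAC), 0.0)
    pitch = np.zeros_like(t)
    pitch = np.where(rocker, _LANDING_PITCH * 0.5 * (1 + np.cos(np.pi * u_r)), pitch)
    pitch = np.where(heeloff, _PUSHOFF_PITCH * 0.5 * (1 - np.cos(np.pi * u_h)), pitch)
    pitch = np.where(
        in_swing,
        _PUSHOFF_PITCH + (_LANDING_PITCH - _PUSHOFF_PITCH) * 0.5 * (1 - np.cos(np.pi * tau)),
        pitch,
    )
    rad = np.radians(pitch)
    cos_p, sin_p = np.cos(rad), np.sin(rad)

    land_rad = math.radians(_LANDING_PITCH)
    toe_td_y = _GROUND + foot_len * math.sin(land_rad)
    # late-swing blend easing the toe onto its dorsiflexed landing pose
    s_land = np.where(tau > 0.7, ((tau - 0.7) / 0.3) ** 2, 0.0)

    # toe position: planted at heel-off pivot; driven during swing
    toe_x = np.where(
        in_swing,
        heel_anchor_x + foot_len
        + step2 * 0.5 * (1 - np.cos(np.pi * tau))
        - foot_len * (1 - math.cos(land_rad)) * s_land,
        np.where(
            rocker,
            heel_anchor_x + foot_len * cos_p,
            heel_anchor_x + foot_len,
        ),
    )
    # peak is the clearance above the toe's stance level, so the apex sits
    # at _GROUND + peak exactly
    toe_y = np.where(
        in_swing,
        _GROUND + peak * np.sin(np.pi * tau) + (toe_td_y - _GROUND) * s_land,
        np.where(rocker, _GROUND + foot_len * sin_p, _GROUND),
    )
    heel_x = np.where(in_swing | heeloff, toe_x - foot_len * cos_p,
                      heel_anchor_x)
    heel_y = np.where(in_swing | heeloff, toe_y - foot_len * sin_p,
                      np.full_like(t, _GROUND))
    # ankle in the foot frame (origin at toe): (-0.75, +0.45) * foot_len
    ax, ay = -0.75 * foot_len, 0.45 * foot_len
    ankle_x = toe_x + ax * cos_p - ay * sin_p
    ankle_y = toe_y + ax * sin_p + ay * cos_p
    return heel_x, heel_y, toe_x, toe_y, ankle_x, ankle_y


def _two_link_ik(hip_xy, ankle_xy, a, b):
    """Planar knee position between hip and ankle (thigh a, shank b).

    Picks the anterior (forward-flexing) solution; out-of-reach
    configurations are clamped onto the hip-ankle line.
    """
    d_vec = ankle_xy - hip_xy
    d = np.linalg.norm(d_vec, axis=1)
    d = np.maximum(d, 1e-9)
    reach = np.clip(d, abs(a - b) + 1e-9, a + b - 1e-9)
    along = (a * a - b * b + reach * reach) / (2.0 * reach)
    h = np.sqrt(np.maximum(a * a - along * along, 0.0))
    unit = d_vec / d[:, None]
    perp = np.stack([-unit[:, 1], unit[:, 0]], axis=1)  # +90deg: anterior knee
    return hip_xy + along[:, None] * unit + h[:, None] * perp


def generate_marker_trial(spec: GaitTrialSpec, seed: int) -> MarkerTrajectorySet:
    """Synthesize a periodic planar walking trial with known ground truth.

    The returned set carries ``meta['ground_truth']`` with the true event
    frames and the configured gait quantities (before marker noise).
    """
    v = spec.gait_speed
    t_step = 60.0 / spec.cadence
    period = 2.0 * t_step
    sl = spec.step_length
    swing = SWING_FRACTION * period
    stance = period - swing
    rate = spec.sampling_rate
    l = spec.leg_length
    foot_len = _FOOT_LEN_FRAC * l
    thigh, shank = 0.53 * l, 0.48 * l

    pad = 0.25 * period
    duration = pad + spec.n_cycles * period + 0.30 * period
    n_frames = int(round(duration * rate)) + 1
    t = np.arange(n_frames) / rate

    # pelvis: constant forward speed; vertical bob with minima at touchdowns
    ankle_h = _GROUND + 0.45 * foot_len
    h_off = 0.5 * sl + 0.25 * foot_len
    d_td = 1.0014 * (thigh + shank) / 1.01  # near-extended leg at touchdown
    y_low = ankle_h + math.sqrt(max(d_td * d_td - h_off * h_off, (0.5 * l) ** 2))
    bob = _BOB_FRAC * l
    pelvis_x = v * (t - pad) - 0.5 * sl
    pelvis_y = y_low + bob * np.sin(np.pi * (t - pad) / t_step) ** 2
    pelvis_z = 0.02 * np.sin(2 * np.pi * (t - pad) / period)

    # trunk: constant forward lean, shoulders above hip midpoint
    lean = math.radians(spec.trunk_lean)
    trunk_len = 0.55 * l
    shoulder_x = pelvis_x + trunk_len * math.sin(lean)
    shoulder_y = pelvis_y + trunk_len * math.cos(lean)

    markers: dict[str, np.ndarray] = {}
    side_z = {"L": 0.10, "R": -0.10}
    for side in ("L", "R"):
        zs = side_z[side]
        markers[f"{side}_hip"] = np.stack(
            [pelvis_x, pelvis_y, pelvis_z + 0.9 * zs], axis=1)
        markers[f"{side}_shoulder"] = np.stack(
            [shoulder_x, shoulder_y, pelvis_z * 0.5 + 1.7 * zs], axis=1)

        td0 = pad if side == "R" else pad - t_step
        x0 = 0.0 if side == "R" else -sl
        heel_x, heel_y, toe_x, toe_y, ankle_x, ankle_y = _foot_markers(
            t, td0, period, x0, 2.0 * sl, stance, swing, foot_len,
            spec.max_toe_height)

        hip_xy = np.stack([pelvis_x, pelvis_y], axis=1)
        ankle_xy = np.stack([ankle_x, ankle_y], axis=1)
        knee_xy = _two_link_ik(hip_xy, ankle_xy, thigh, shank)

        z_col = np.full(n_frames, zs)
        markers[f"{side}_toe"] = np.stack([toe_x, toe_y, z_col], axis=1)
        markers[f"{side}_heel"] = np.stack([heel_x, heel_y, z_col], axis=1)
        markers[f"{side}_ankle"] = np.stack([ankle_x, ankle_y, z_col], axis=1)
        markers[f"{side}_knee"] = np.stack(
            [knee_xy[:, 0], knee_xy[:, 1], z_col], axis=1)

    names = list(markers)
    positions = np.stack([markers[m] for m in names], axis=1)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        positions = positions + rng.normal(0.0, spec.noise_sd, size=positions.shape)

    def _frame(time_s: float) -> int:
        return int(round(time_s * rate))

    ground_truth = {
        "events": {
            "pre_TD": _frame(pad),
            "LO": _frame(pad + stance - t_step),  # left LO: its TD was at pad - t_step
            "post_TD": _frame(pad + t_step),
            "next_TD": _frame(pad + period),
        },
        "gait_speed": v,
        "step_time": t_step,
        "swing_time": swing,
        "step_length": sl,
        "trunk_angle": 90.0 - spec.trunk_lean,
        "toe_clearance": spec.max_toe_height,
        "cadence": spec.cadence,
    }
    return MarkerTrajectorySet(
        marker_names=names,
        positions=positions,
        sampling_rate=rate,
        meta={"ground_truth": ground_truth, "seed": seed},
    )
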