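"""Segmental anthropometric body model for whole-body COM estimation.

The centre of mass is computed from a 13-segment rigid-body model with
sex-dependent segmental mass and COM-location fractions adapted from the
de Leva (1996) adjustment of Zatsiorsky's tables.  Segments are anchored
to a 12-marker bilateral set (heel, toe, ankle, knee, hip, shoulder);
head and arm segments, whose endpoints are not in that marker set, are
anchored to the trunk line (shoulder/hip markers) — a documented
simplification that is adequate for level walking, where the arms hang
close to the trunk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

GRAVITY = 9.81  # m/s^2

# A marker anchor is either one marker name or a tuple whose positions are
# averaged (e.g. the shoulder midpoint).
Anchor = tuple[str, ...]


@dataclass(frozen=True)
class Segment:
    """One rigid segment: mass fraction and COM location along an anchor line.

    ``com_fraction`` measures from the proximal anchor towards the distal
    anchor; 0 places the segment COM at the proximal anchor.
    """

    name: str
    proximal: Anchor
    distal: Anchor
    mass_fraction: float
    com_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.com_fraction <= 1.0:
            raise ValueError(f"segment {self.name}: com_fraction must be in [0, 1]")
        if self.mass_fraction < 0:
            raise ValueError(f"segment {self.name}: negative mass fraction")


def _bilateral(name, prox_tpl, dist_tpl, mass, com):
    return [
        Segment(f"{s}_{name}", tuple(p.format(s=s) for p in prox_tpl),
                tuple(d.format(s=s) for d in dist_tpl), mass, com)
        for s in ("L", "R")
    ]


def _segment_table(sex: str) -> list[Segment]:
    """13 segments: head, torso, pelvis and bilateral arm/leg segments."""
    shoulders = ("L_shoulder", "R_shoulder")
    hips = ("L_hip", "R_hip")
    if sex == "M":
        head, torso, pelvis = 0.0694, 0.3229, 0.1117
        ua, fa, thigh, shank, foot = 0.0271, 0.0223, 0.1416, 0.0433, 0.0137
        torso_com, thigh_com, shank_com, foot_com = 0.4486, 0.4095, 0.4459, 0.4415
    elif sex == "F":
        head, torso, pelvis = 0.0668, 0.3011, 0.1247
        ua, fa, thigh, shank, foot = 0.0255, 0.0194, 0.1478, 0.0481, 0.0129
        torso_com, thigh_com, shank_com, foot_com = 0.4630, 0.3612, 0.4416, 0.4014
    else:
        raise ValueError(f"sex must be 'M' or 'F', got {sex!r}")
    segments = [
        Segment("head", shoulders, shoulders, head, 0.0),
        Segment("torso", shoulders, hips, torso, torso_com),
        Segment("pelvis", hips, hips, pelvis, 0.0),
    ]
    segments += _bilateral("upper_arm", ("{s}_shoulder",), ("{s}_hip",), ua, 0.30)
    segments += _bilateral("forearm_hand", ("{s}_shoulder",), ("{s}_hip",), fa, 0.80)
    segments += _bilateral("thigh", ("{s}_hip",), ("{s}_knee",), thigh, thigh_com)
    segments += _bilateral("shank", ("{s}_knee",), ("{s}_ankle",), shank, shank_com)
    segments += _bilateral("foot", ("{s}_heel",), ("{s}_toe",), foot, foot_com)
    return segments


@dataclass
class BodyModel:
    """Sex-tagged segmental model plus the pendulum parameters used by MOS.

    ``leg_length`` (m) feeds the inverted-pendulum eigenfrequency
    sqrt(g / l); when None, extractors estimate it from the hip marker
    height.
    """

    sex: str = "M"
    leg_length: float | None = None
    g: float = GRAVITY
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.segments:
            self.segments = _segment_table(self.sex)
        total = sum(s.mass_fraction for s in self.segments)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"segment mass fractions sum to {total}, expected 1")
        if self.leg_length is not None and self.leg_length <= 0:
            raise ValueError("leg_length must be positive")
        if self.g <= 0:
            raise ValueError("g must be positive")

    def required_markers(self) -> set[str]:
        out: set[str] = set()
        for s in self.segments:
            out.update(s.proximal)
            out.update(s.distal)
        return out

    # -- serialization -------------------------------------------------

    def to_yaml(self, path) -> None:
        data = {
            "sex": self.sex,
            "leg_length": self.leg_length,
            "g": self.g,
            "segments": [
                {
                    "name": s.name,
                    "proximal": list(s.proximal),
                    "distal": list(s.distal),
                    "mass_fraction": s.mass_fraction,
                    "com_fraction": s.com_fraction,
                }
                for s in self.segments
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "BodyModel":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        segments = [
            Segment(
                name=s["name"],
                proximal=tuple(s["proximal"]),
                distal=tuple(s["distal"]),
                mass_fraction=float(s["mass_fraction"]),
                com_fraction=float(s["com_fraction"]),
            )
            for s in data.get("segments", [])
        ]
        return cls(
            sex=data.get("sex", "M"),
            leg_length=data.get("leg_length"),
            g=float(data.get("g", GRAVITY)),
            segments=segments,
        )
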