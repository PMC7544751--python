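"""Default exposure scene: air world, gripping hand, shielded syringe.

Builds a :class:`~handdose.geometry.SceneGeometry` from a
:class:`SceneConfig`. The syringe lies on the z axis: a tungsten tube
(inner radius 0.5 cm, outer 1.45 cm, length 10 cm) open at the needle
end (+z) and closed at the plunger end by a 9 mm tungsten roller. The
barrel interior holds a water column (the radiopharmaceutical) at the
needle end and an air plunger column behind it.

The hand is a soft-tissue pastern cuboid plus ten two-phalanx fingers
built from elliptical tubes. Finger dimensions and the grip pose are
configurable: the dosimetry study this reproduces cites an
anthropometric atlas for them without printing values, so the defaults
here are stand-ins chosen to respect the printed hand envelope
(3.2 x 8.8 x 11.7 cm) and to place index and middle fingertips nearest
the open end of the shield with the thumb behind the plunger roller.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

from .geometry import Box, Cylinder, EllipticalTube, Region, SceneGeometry
from .materials import get_material

__all__ = ["FingerSpec", "SceneConfig", "build_scene", "FINGERS", "PHALANGES"]

FINGERS = ("thumb", "index", "middle", "ring", "small")
PHALANGES = ("proximal", "distal")


@dataclass(frozen=True)
class FingerSpec:
    """Placement and size of one two-phalanx finger.

    The finger is a pair of coaxial elliptical tubes along the y axis;
    the distal tube (fingertip) is centred at (x, y, z) and the proximal
    tube continues towards the palm (+y).
    """

    x: float  # cm, radial stand-off of the fingertip axis
    z: float  # cm, axial station along the syringe
    y: float = 0.0
    semi_x: float = 0.55  # transverse semi-axis, cm
    semi_z: float = 0.45  # axial-direction semi-axis, cm
    distal_len: float = 2.5  # cm
    proximal_len: float = 3.0  # cm


def _default_fingers() -> dict[str, FingerSpec]:
    # Grip: index and middle nearest the open (+z) needle end (the index
    # fingertip reaches past the aperture), ring and small further back
    # along the barrel, thumb behind the plunger roller (-z). Stations
    # chosen to reproduce the observed exposure ordering
    # index > middle > ring > small > thumb with resolvable gaps.
    return {
        "index": FingerSpec(x=1.70, z=5.75),
        "middle": FingerSpec(x=2.05, z=4.40),
        "ring": FingerSpec(x=2.05, z=0.60),
        "small": FingerSpec(x=2.05, z=-0.55),
        "thumb": FingerSpec(x=0.0, z=-6.95, semi_x=0.65),
    }


@dataclass
class SceneConfig:
    """All geometric knobs of the default scene (lengths in cm)."""

    world_side: float = 100.0
    # pastern cuboid full extents: thickness (x), width (z), length (y)
    pastern_a: float = 3.2
    pastern_b: float = 8.8
    pastern_c: float = 11.7
    pastern_gap: float = 0.3  # air gap between proximal phalanx and palm
    # syringe
    syringe_inner_radius: float = 0.5
    syringe_outer_radius: float = 1.45
    syringe_length: float = 10.0
    roller_thickness: float = 0.9
    fill_length: float = 4.0  # axial extent of the liquid column, cm
    interior_material: str = "water"  # "air" to match a dry barrel
    shield_material: str = "tungsten"
    hand_material: str = "soft_tissue"
    fingers: dict = field(default_factory=_default_fingers)

    def __post_init__(self):
        if self.syringe_inner_radius >= self.syringe_outer_radius:
            raise ValueError("inner radius must be < outer radius")
        if not 0 < self.fill_length <= self.syringe_length:
            raise ValueError("fill length must be in (0, syringe length]")
        fixed = {}
        for name, spec in self.fingers.items():
            if name not in FINGERS:
                raise ValueError(f"unknown finger {name!r}")
            fixed[name] = (
                spec if isinstance(spec, FingerSpec) else FingerSpec(**spec)
            )
        self.fingers = fixed

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fingers"] = {k: asdict(v) for k, v in self.fingers.items()}
        return d


def build_scene(config: SceneConfig | None = None) -> SceneGeometry:
    """Assemble the scene; later regions take containment priority."""
    cfg = config or SceneConfig()
    air = get_material("air")
    tissue = get_material(cfg.hand_material)
    shield_mat = get_material(cfg.shield_material)
    interior_mat = get_material(cfg.interior_material)

    half_len = cfg.syringe_length / 2.0
    fill = cfg.fill_length
    regions: list[Region] = [
        Region(
            "world",
            Box(center=(0, 0, 0), sides=(cfg.world_side,) * 3),
            air,
        )
    ]

    # hand: pastern beyond the proximal phalanges along +y
    specs = cfg.fingers
    palm_y0 = max(
        s.y + s.distal_len / 2 + s.proximal_len for s in specs.values()
    )
    regions.append(
        Region(
            "pastern",
            Box(
                center=(
                    specs["index"].x,
                    palm_y0 + cfg.pastern_gap + cfg.pastern_c / 2.0,
                    (cfg.syringe_length - cfg.pastern_b) / 2.0 + 1.0,
                ),
                sides=(cfg.pastern_a, cfg.pastern_c, cfg.pastern_b),
            ),
            tissue,
            scoring=True,
        )
    )
    for name, s in specs.items():
        distal = EllipticalTube(
            center=(s.x, s.y, s.z),
            axis=1,
            semi=(s.semi_x, s.semi_z),
            length=s.distal_len,
        )
        proximal = EllipticalTube(
            center=(s.x, s.y + (s.distal_len + s.proximal_len) / 2.0, s.z),
            axis=1,
            semi=(s.semi_x, s.semi_z),
            length=s.proximal_len,
        )
        regions.append(
            Region(f"{name}_distal", distal, tissue, scoring=True)
        )
        regions.append(
            Region(f"{name}_proximal", proximal, tissue, scoring=True)
        )

    # syringe: declared after the hand, deepest (interior) last
    regions.append(
        Region(
            "shield",
            Cylinder(
                center=(0, 0, 0),
                axis=2,
                r_outer=cfg.syringe_outer_radius,
                length=cfg.syringe_length,
                r_inner=cfg.syringe_inner_radius,
            ),
            shield_mat,
        )
    )
    regions.append(
        Region(
            "roller",
            Cylinder(
                center=(0, 0, -half_len - cfg.roller_thickness / 2.0),
                axis=2,
                r_outer=cfg.syringe_outer_radius,
                length=cfg.roller_thickness,
            ),
            shield_mat,
        )
    )
    if fill < cfg.syringe_length:
        regions.append(
            Region(
                "plunger",
                Cylinder(
                    center=(0, 0, -fill / 2.0),
                    axis=2,
                    r_outer=cfg.syringe_inner_radius,
                    length=cfg.syringe_length - fill,
                ),
                air,
            )
        )
    regions.append(
        Region(
            "syringe_interior",
            Cylinder(
                center=(0, 0, half_len - fill / 2.0),
                axis=2,
                r_outer=cfg.syringe_inner_radius,
                length=fill,
            ),
            interior_mat,
        )
    )
    return SceneGeometry(regions)
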