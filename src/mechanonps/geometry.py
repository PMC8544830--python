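"""Mechano-NPS device geometry.

A mechano-NPS channel is a single microfluidic channel segmented into wide
"nodes" and narrow "pores".  A transiting cell partially blocks the current,
producing one subpulse per narrow segment.  The segment sequence is: one or
more *reference* pores (sizing and free velocity), a long narrow *contraction*
segment (applies a defined strain), and several *recovery* pores (track shape
relaxation).  Nodes between segments return the current to baseline and are
treated as zero-amplitude gaps.

All lengths are in micrometres.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

__all__ = [
    "DeviceGeometry",
    "Segment",
    "SegmentPlan",
    "compute_strain",
    "nominal_diameter",
    "segment_plan",
    "effective_pore_diameter",
    "PRESETS",
    "get_preset",
    "load_geometry",
]

SegmentKind = Literal["reference_pore", "node", "contraction", "recovery_pore"]


class GeometryError(ValueError):
    """Invalid device geometry or a cell incompatible with it."""


@dataclass(frozen=True)
class DeviceGeometry:
    """Geometric dimensions of one mechano-NPS device design.

    ``targeted_strain`` is the design strain ``1 - contraction_width /
    nominal cell diameter`` the contraction segment applies to a cell of the
    nominal size the device was designed for.
    """

    device_id: str
    channel_height_um: float
    pore_width_um: float
    pore_length_um: float
    node_width_um: float
    node_length_um: float
    contraction_width_um: float
    contraction_length_um: float
    recovery_pore_length_um: float
    targeted_strain: float
    n_reference_pores: int = 2
    n_recovery_pores: int = 6

    def __post_init__(self) -> None:
        lengths = (
            self.channel_height_um, self.pore_width_um, self.pore_length_um,
            self.node_width_um, self.node_length_um, self.contraction_width_um,
            self.contraction_length_um, self.recovery_pore_length_um,
        )
        if any(not (x > 0) for x in lengths):
            raise GeometryError("all geometry dimensions must be strictly positive")
        if not self.contraction_width_um < self.pore_width_um:
            raise GeometryError("contraction must be narrower than the pores")
        if not 0 < self.targeted_strain < 1:
            raise GeometryError("targeted_strain must lie in (0, 1)")
        if self.n_reference_pores < 1:
            raise GeometryError("need at least one reference pore")
        if self.n_recovery_pores < 2:
            raise GeometryError(
                "need at least two recovery pores (recovery-constant fit "
                "requires >= 2 time points)"
            )

    # -- derived quantities -------------------------------------------------

    @property
    def reference_pore_effective_diameter_um(self) -> float:
        return effective_pore_diameter(self.pore_width_um, self.channel_height_um)

    @property
    def contraction_effective_diameter_um(self) -> float:
        return effective_pore_diameter(self.contraction_width_um, self.channel_height_um)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DeviceGeometry":
        return cls(**d)


def compute_strain(geometry: DeviceGeometry, d0_um: float) -> float:
    """Strain applied to a cell of diameter ``d0_um`` in the contraction segment.

    Defined as the fractional reduction in cell diameter along the axis of
    deformation, ``1 - w_c / d0``.
    """
    w_c = geometry.contraction_width_um
    if d0_um <= w_c:
        raise GeometryError(
            f"cell diameter {d0_um} um does not exceed contraction width "
            f"{w_c} um: the cell is not strained"
        )
    return 1.0 - w_c / d0_um


def nominal_diameter(geometry: DeviceGeometry) -> float:
    """Cell diameter for which the device achieves its targeted strain.

    Inverse of :func:`compute_strain` at ``targeted_strain``.
    """
    return geometry.contraction_width_um / (1.0 - geometry.targeted_strain)


def effective_pore_diameter(width_um: float, height_um: float) -> float:
    """Equal-area circular diameter of a rectangular channel cross-section.

    Standard resistive-pulse practice: a ``w x h`` rectangular pore is mapped
    to the circular pore of identical cross-sectional area, ``2 sqrt(w h / pi)``.
    """
    if width_um <= 0 or height_um <= 0:
        raise GeometryError("width and height must be positive")
    return 2.0 * math.sqrt(width_um * height_um / math.pi)


@dataclass(frozen=True)
class Segment:
    kind: SegmentKind
    length_um: float
    width_um: float
    #: threshold class used by edge detection ("pore" | "contraction");
    #: nodes carry no subpulse and have no class
    threshold_class: str | None = None


@dataclass(frozen=True)
class SegmentPlan:
    """Ordered channel layout, nodes included, with the expected subpulse order."""

    segments: tuple[Segment, ...]

    @property
    def subpulse_segments(self) -> tuple[Segment, ...]:
        return tuple(s for s in self.segments if s.kind != "node")

    @property
    def n_subpulses(self) -> int:
        return len(self.subpulse_segments)

    @property
    def total_length_um(self) -> float:
        return sum(s.length_um for s in self.segments)

    def expected_kinds(self) -> tuple[str, ...]:
        return tuple(s.kind for s in self.subpulse_segments)


def segment_plan(geometry: DeviceGeometry) -> SegmentPlan:
    """Expected segment sequence: reference pores -> contraction -> recovery pores.

    Adjacent sensing segments are separated by one node.  The total subpulse
    count is ``n_reference_pores + 1 + n_recovery_pores``.
    """
    g = geometry
    node = Segment("node", g.node_length_um, g.node_width_um)
    segs: list[Segment] = []
    for i in range(g.n_reference_pores):
        if i:
            segs.append(node)
        segs.append(Segment("reference_pore", g.pore_length_um, g.pore_width_um, "pore"))
    segs.append(node)
    segs.append(Segment("contraction", g.contraction_length_um,
                        g.contraction_width_um, "contraction"))
    for _ in range(g.n_recovery_pores):
        segs.append(node)
        segs.append(Segment("recovery_pore", g.recovery_pore_length_um,
                            g.pore_width_um, "pore"))
    return SegmentPlan(tuple(segs))


# -- shipped presets --------------------------------------------------------

PRESETS: dict[str, DeviceGeometry] = {
    "MCF-10A": DeviceGeometry(
        device_id="MCF-10A",
        channel_height_um=22.3,
        pore_width_um=22.0,
        pore_length_um=700.0,
        node_width_um=85.0,
        node_length_um=50.0,
        contraction_width_um=10.5,
        contraction_length_um=3000.0,
        recovery_pore_length_um=700.0,
        targeted_strain=0.30,
    ),
    "AP-1060": DeviceGeometry(
        device_id="AP-1060",
        channel_height_um=12.9,
        pore_width_um=13.0,
        pore_length_um=800.0,
        node_width_um=85.0,
        node_length_um=50.0,
        contraction_width_um=7.0,
        contraction_length_um=2000.0,
        recovery_pore_length_um=290.0,
        targeted_strain=0.35,
    ),
}


def get_preset(name: str, **overrides) -> DeviceGeometry:
    """Return a shipped device preset, optionally with overridden fields."""
    try:
        g = PRESETS[name]
    except KeyError:
        raise GeometryError(
            f"unknown geometry preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    if overrides:
        d = g.to_dict()
        d.update(overrides)
        return DeviceGeometry.from_dict(d)
    return g


def load_geometry(path: str | Path) -> DeviceGeometry:
    """Load a device geometry from a JSON config file (one geometry per file)."""
    with open(path) as fh:
        return DeviceGeometry.from_dict(json.load(fh))
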