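"""Schematic hand geometry: outline polygon, stimulation sites, scaling.

The assessment takes place on a 2D schematic hand (volar view).  Twenty-four
stimulation sites are distributed over the five digits and the palm:

* digit I (thumb, sites 1-4): distal phalanx, proximal phalanx, distal
  metacarpal and proximal metacarpal (thenar eminence);
* digits II-V (sites 5-8, 9-12, 13-16, 17-20): distal, intermediate and
  proximal phalanges plus the distal aspect of the metacarpal;
* palm (sites 21-24): four sites over the central palm.

Coordinate convention: origin at the wrist-crease midpoint, y increases
distally (fingertips up) and x increases toward the thumb on a right hand.
One template unit equals 1 mm on the 17 cm reference hand, so the default
``units_per_cm`` is 10 and the reference hand length is 170 units measured
from the tip of digit III to the wrist crease.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import Point, Polygon
from shapely.prepared import prep

TEMPLATE_VERSION = "1.0"

#: Reference hand length (middle fingertip to wrist crease) used for
#: normalized reporting, in cm.
REFERENCE_HAND_LENGTH_CM = 17.0

#: Fingertip sites (distal phalanges of digits I-V), used for the
#: fingertip-subset correct-localization rate.
FINGERTIP_SITES = (1, 5, 9, 13, 17)


class Digit(str, Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    V = "V"
    PALM = "palm"


class Segment(str, Enum):
    DISTAL_PHALANX = "distal_phalanx"
    INTERMEDIATE_PHALANX = "intermediate_phalanx"
    PROXIMAL_PHALANX = "proximal_phalanx"
    DISTAL_METACARPAL = "distal_metacarpal"
    PROXIMAL_METACARPAL = "proximal_metacarpal"
    PALM = "palm"


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"


# Segment sequence (distal -> proximal) per digit.  Digit I has no
# intermediate phalanx; its chain continues onto the thenar metacarpal.
_DIGIT_SEGMENTS: dict[Digit, tuple[Segment, ...]] = {
    Digit.I: (
        Segment.DISTAL_PHALANX,
        Segment.PROXIMAL_PHALANX,
        Segment.DISTAL_METACARPAL,
        Segment.PROXIMAL_METACARPAL,
    ),
    **{
        d: (
            Segment.DISTAL_PHALANX,
            Segment.INTERMEDIATE_PHALANX,
            Segment.PROXIMAL_PHALANX,
            Segment.DISTAL_METACARPAL,
        )
        for d in (Digit.II, Digit.III, Digit.IV, Digit.V)
    },
}

_DIGIT_FIRST_SITE = {Digit.I: 1, Digit.II: 5, Digit.III: 9, Digit.IV: 13, Digit.V: 17}


def digit_of_site(site_id: int) -> Digit:
    """Map a site ID (1-24) to its digit (palm for 21-24)."""
    if not 1 <= site_id <= 24:
        raise ValueError(f"site_id must be in 1..24, got {site_id}")
    if site_id >= 21:
        return Digit.PALM
    return [Digit.I, Digit.II, Digit.III, Digit.IV, Digit.V][(site_id - 1) // 4]


@dataclass(frozen=True)
class StimulationSite:
    site_id: int
    digit: Digit
    segment: Segment
    position: tuple[float, float]  # template units
    distal_rank: int  # 0 = most distal; drives the yellow->blue colormap

    def __post_init__(self) -> None:
        if not 1 <= self.site_id <= 24:
            raise ValueError(f"site_id must be in 1..24, got {self.site_id}")
        if self.digit is not digit_of_site(self.site_id):
            raise ValueError(
                f"site {self.site_id} must lie on digit {digit_of_site(self.site_id).value},"
                f" got {self.digit.value}"
            )
        if self.distal_rank < 0:
            raise ValueError("distal_rank must be >= 0")
        if self.digit is not Digit.PALM:
            expected = _DIGIT_SEGMENTS[self.digit][(self.site_id - _DIGIT_FIRST_SITE[self.digit])]
            if self.segment is not expected:
                raise ValueError(
                    f"site {self.site_id} on digit {self.digit.value} must be"
                    f" {expected.value}, got {self.segment.value}"
                )
        elif self.segment is not Segment.PALM:
            raise ValueError(f"palm site {self.site_id} must have segment 'palm'")


@dataclass(frozen=True)
class HandTemplate:
    """Simple-polygon hand outline plus 24 labeled stimulation sites.

    ``units_per_cm`` maps template units to centimeters on the subject's
    physical hand; on the unscaled default template it is 10 (1 unit = 1 mm
    on the 17 cm reference hand).
    """

    outline: tuple[tuple[float, float], ...]
    sites: tuple[StimulationSite, ...]
    hand_length: float  # template units, digit-III tip to wrist crease
    units_per_cm: float
    side: Side
    version: str = TEMPLATE_VERSION
    _polygon: Polygon = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        poly = Polygon(self.outline)
        if len(self.outline) < 3 or not poly.is_valid or poly.area <= 0:
            raise ValueError("outline must be a simple polygon with >= 3 vertices")
        if not _is_ccw(self.outline):
            raise ValueError("outline must be counter-clockwise")
        if len(self.sites) != 24:
            raise ValueError(f"template must define exactly 24 sites, got {len(self.sites)}")
        ids = sorted(s.site_id for s in self.sites)
        if ids != list(range(1, 25)):
            raise ValueError("site_ids must be exactly 1..24 with no duplicates")
        if self.hand_length <= 0 or self.units_per_cm <= 0:
            raise ValueError("hand_length and units_per_cm must be positive")
        object.__setattr__(self, "_polygon", poly)
        for s in self.sites:
            if not self.contains(s.position):
                raise ValueError(f"site {s.site_id} at {s.position} lies outside the outline")

    # -- geometry ---------------------------------------------------------

    @property
    def polygon(self) -> Polygon:
        return self._polygon

    def site(self, site_id: int) -> StimulationSite:
        for s in self.sites:
            if s.site_id == site_id:
                return s
        raise KeyError(f"no site {site_id} in template")

    def contains(self, p: Sequence[float]) -> bool:
        """True iff ``p`` is inside or on the outline (closed polygon).

        Points within 1e-9 template units of the boundary count as inside,
        so clamped points are always contained despite float roundoff.
        """
        pt = Point(p[0], p[1])
        return bool(self._polygon.covers(pt)) or self._polygon.distance(pt) <= 1e-9

    def clamp(self, p: Sequence[float]) -> tuple[float, float]:
        """Return ``p`` unchanged if inside, else the Euclidean-nearest
        boundary point.  Idempotent."""
        pt = Point(p[0], p[1])
        if self._polygon.covers(pt):
            return (float(p[0]), float(p[1]))
        boundary = self._polygon.exterior
        nearest = boundary.interpolate(boundary.project(pt))
        return (float(nearest.x), float(nearest.y))

    # -- unit conversion --------------------------------------------------

    def to_cm(self, length_units: float) -> float:
        """Convert a template-unit length to subject-physical centimeters."""
        return length_units / self.units_per_cm

    @property
    def hand_length_cm(self) -> float:
        return self.to_cm(self.hand_length)


def _is_ccw(vertices: Iterable[Sequence[float]]) -> bool:
    vs = list(vertices)
    area2 = 0.0
    for (x0, y0), (x1, y1) in zip(vs, vs[1:] + vs[:1]):
        area2 += x0 * y1 - x1 * y0
    return area2 > 0


# ---------------------------------------------------------------------------
# Default parametric template
# ---------------------------------------------------------------------------

# Right-hand geometry in mm on the 17 cm reference hand, thumb toward +x.
# Fingers are drawn as rectangular lobes with slightly domed tips separated
# by web notches down to the knuckle line (y = 95); the thumb is an oblique
# lobe on the radial palm edge.

_PALM_HALF_WIDTH = 40.0
_KNUCKLE_Y = 95.0

# per finger: (digit, centerline x, half width, side-top y, tip y)
_FINGERS = (
    (Digit.II, 30.0, 8.0, 158.0, 165.0),
    (Digit.III, 10.0, 8.0, 163.0, 170.0),
    (Digit.IV, -10.0, 8.0, 157.0, 164.0),
    (Digit.V, -30.0, 8.0, 135.0, 142.0),
)

_THUMB_BASE = np.array([42.0, 42.0])
_THUMB_TIP = np.array([84.0, 88.0])
_THUMB_HALF_WIDTH = 9.0


def _thumb_outline_points() -> list[tuple[float, float]]:
    """Thumb lobe vertices in CCW order along the radial (right) palm edge."""
    axis = _THUMB_TIP - _THUMB_BASE
    u = axis / np.linalg.norm(axis)
    n = np.array([-u[1], u[0]])  # points toward the fingers (ulnar)
    low_base = _THUMB_BASE - _THUMB_HALF_WIDTH * n
    low_tip = _THUMB_TIP - _THUMB_HALF_WIDTH * n
    high_tip = _THUMB_TIP + _THUMB_HALF_WIDTH * n
    high_base = _THUMB_BASE + _THUMB_HALF_WIDTH * n

    def cross_x40(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
        t = (_PALM_HALF_WIDTH - a[0]) / (b[0] - a[0])
        return (_PALM_HALF_WIDTH, float(a[1] + t * (b[1] - a[1])))

    low_junction = cross_x40(low_base, low_base - 20.0 * u)
    high_junction = cross_x40(high_tip, high_base)
    return [
        low_junction,
        (float(low_tip[0]), float(low_tip[1])),
        (float(high_tip[0]), float(high_tip[1])),
        high_junction,
    ]


def _right_outline() -> list[tuple[float, float]]:
    pts: list[tuple[float, float]] = [(-_PALM_HALF_WIDTH, 0.0), (_PALM_HALF_WIDTH, 0.0)]
    pts.extend(_thumb_outline_points())
    pts.append((_PALM_HALF_WIDTH, _KNUCKLE_Y))
    for _, cx, hw, side_y, tip_y in _FINGERS:  # radial -> ulnar = +x -> -x
        pts.extend(
            [
                (cx + hw, _KNUCKLE_Y),
                (cx + hw, side_y),
                (cx, tip_y),
                (cx - hw, side_y),
                (cx - hw, _KNUCKLE_Y),
            ]
        )
    pts.append((-_PALM_HALF_WIDTH, _KNUCKLE_Y))
    return pts


def _right_site_positions() -> dict[int, tuple[float, float]]:
    pos: dict[int, tuple[float, float]] = {}
    # thumb chain, distal -> proximal along the thumb axis into the thenar
    axis = _THUMB_TIP - _THUMB_BASE
    u = axis / np.linalg.norm(axis)
    chain = [
        _THUMB_TIP - 8.0 * u,  # distal phalanx
        _THUMB_TIP - 26.0 * u,  # proximal phalanx
        _THUMB_BASE + 8.0 * u,  # distal metacarpal
        np.array([30.0, 35.0]),  # proximal metacarpal / thenar eminence
    ]
    for i, p in enumerate(chain, start=1):
        pos[i] = (float(p[0]), float(p[1]))
    # fingers II-V: distal/intermediate/proximal phalanx + distal metacarpal
    finger_site_ys = {
        Digit.II: (150.0, 128.0, 105.0, 85.0),
        Digit.III: (155.0, 132.0, 107.0, 85.0),
        Digit.IV: (149.0, 127.0, 104.0, 85.0),
        Digit.V: (128.0, 112.0, 100.0, 85.0),
    }
    for digit, cx, _, _, _ in _FINGERS:
        first = _DIGIT_FIRST_SITE[digit]
        for k, y in enumerate(finger_site_ys[digit]):
            pos[first + k] = (cx, y)
    # central palm sites: two distal (upper), two proximal (lower)
    pos[21] = (12.0, 62.0)
    pos[22] = (-14.0, 62.0)
    pos[23] = (12.0, 32.0)
    pos[24] = (-16.0, 32.0)
    return pos


def default_template(side: Side | str = Side.RIGHT) -> HandTemplate:
    """Build the versioned default schematic hand for the given side.

    Left and right templates are exact mirror images about the vertical
    axis through the wrist-crease midpoint.
    """
    side = Side(side)
    positions = _right_site_positions()
    sites = []
    for sid in range(1, 25):
        digit = digit_of_site(sid)
        if digit is Digit.PALM:
            segment = Segment.PALM
            rank = 4 if sid in (21, 22) else 5
        else:
            k = sid - _DIGIT_FIRST_SITE[digit]
            segment = _DIGIT_SEGMENTS[digit][k]
            rank = k
        sites.append(StimulationSite(sid, digit, segment, positions[sid], rank))
    template = HandTemplate(
        outline=tuple(_right_outline()),
        sites=tuple(sites),
        hand_length=REFERENCE_HAND_LENGTH_CM * 10.0,
        units_per_cm=10.0,
        side=Side.RIGHT,
    )
    if side is Side.LEFT:
        template = mirror(template)
    return template


def mirror(template: HandTemplate) -> HandTemplate:
    """Mirror a template about the vertical axis (x -> -x), flipping side.

    The vertex order is reversed so the mirrored outline stays CCW.
    """
    outline = tuple((-x, y) for x, y in reversed(template.outline))
    sites = tuple(
        replace(s, position=(-s.position[0], s.position[1])) for s in template.sites
    )
    other = Side.LEFT if template.side is Side.RIGHT else Side.RIGHT
    return HandTemplate(
        outline=outline,
        sites=sites,
        hand_length=template.hand_length,
        units_per_cm=template.units_per_cm,
        side=other,
        version=template.version,
    )


def scale_to_hand(template: HandTemplate, measured_hand_length_cm: float) -> HandTemplate:
    """Adjust ``units_per_cm`` so template distances convert to the
    subject's physical centimeters.

    Normalizing back to the 17 cm reference hand is a separate
    multiplicative step applied in the metrics layer.
    """
    if measured_hand_length_cm <= 0:
        raise ValueError(f"hand length must be positive, got {measured_hand_length_cm}")
    factor = template.hand_length_cm / measured_hand_length_cm
    return replace(template, units_per_cm=template.units_per_cm * factor)


def contains(template: HandTemplate, p: Sequence[float]) -> bool:
    """True iff ``p`` is inside or on the outline (boundary counts as inside)."""
    return template.contains(p)


def clamp_to_hand(template: HandTemplate, p: Sequence[float]) -> tuple[float, float]:
    """Clamp a point into the hand: identity inside, else the nearest
    boundary point."""
    return template.clamp(p)


# ---------------------------------------------------------------------------
# Template file I/O
# ---------------------------------------------------------------------------


def write_template(template: HandTemplate, path: str | Path) -> None:
    doc = {
        "version": template.version,
        "side": template.side.value,
        "units_per_cm": template.units_per_cm,
        "hand_length": template.hand_length,
        "outline": [list(v) for v in template.outline],
        "sites": [
            {
                "site_id": s.site_id,
                "digit": s.digit.value,
                "segment": s.segment.value,
                "position": list(s.position),
                "distal_rank": s.distal_rank,
            }
            for s in template.sites
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_template(path: str | Path) -> HandTemplate:
    """Load and fully validate a template JSON file."""
    doc = json.loads(Path(path).read_text())
    try:
        sites = tuple(
            StimulationSite(
                site_id=int(s["site_id"]),
                digit=Digit(s["digit"]),
                segment=Segment(s["segment"]),
                position=(float(s["position"][0]), float(s["position"][1])),
                distal_rank=int(s["distal_rank"]),
            )
            for s in doc["sites"]
        )
        return HandTemplate(
            outline=tuple((float(x), float(y)) for x, y in doc["outline"]),
            sites=sites,
            hand_length=float(doc["hand_length"]),
            units_per_cm=float(doc["units_per_cm"]),
            side=Side(doc["side"]),
            version=str(doc.get("version", TEMPLATE_VERSION)),
        )
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed template file {path}: {exc}") from exc
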