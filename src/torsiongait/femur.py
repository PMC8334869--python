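"""Femoral geometry: torsion measurement and torsion morphing.

Femoral torsion is measured with the radiographic convention: the angle
between the femoral neck line (midline between the neck cortices, through
the caudally projected femoral head center) and the posterior condylar
line, both projected onto the plane perpendicular to the shaft axis.
Antetorsion (proximal femur rotated anteriorly relative to the distal
femur) is positive; the sign convention is side-aware so that a left and
a right femur with the same anatomy report the same torsion.

Morphing to a target torsion applies a smooth axial twist about the shaft
axis: distal structures (posterior condyles, distal shaft) stay fixed,
proximal structures (head, neck, trochanteric attachments) rotate by the
full torsion difference, and mid-shaft points blend smoothly in between.
The blend weight is a C^1 monotone smoothstep of the normalized shaft
coordinate, which makes the morph exactly composable and keeps every
point's distance to the shaft axis unchanged (each transverse plane is
rotated rigidly).

Template femur coordinates are millimetres in a right-handed frame with
X anterior, Y cranial (along the shaft), Z lateral for a right femur.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import GeometryError

__all__ = [
    "Attachment",
    "FemurGeometry",
    "measure_torsion",
    "morph_to_torsion",
    "generate_template_femur",
]

#: blend stations of the twist weight, as normalized shaft coordinate
#: (0 = distal shaft point, 1 = proximal shaft point)
TWIST_BLEND_START = 0.4
TWIST_BLEND_END = 0.7

#: torsion of the canonical (unmorphed) template, degrees antetorsion
TEMPLATE_TORSION = 5.5


@dataclass(frozen=True)
class Attachment:
    """A muscle attachment site carried by the femur."""

    muscle_id: str
    fascicle_id: str
    site: str  # origin | insertion | via
    point: np.ndarray  # (3,) mm

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        if self.point.shape != (3,):
            raise ValueError("attachment point must be a 3-vector")
        if self.site not in ("origin", "insertion", "via"):
            raise ValueError(f"unknown attachment site {self.site!r}")


@dataclass(frozen=True)
class FemurGeometry:
    """Landmark description of one femur (mm, right-handed axes).

    Attributes
    ----------
    side : {"R", "L"}
    head_center : (3,) femoral head center.
    neck_axis : (2, 3) two points on the neck midline, ordered shaft-ward
        to head-ward.
    condyles_posterior : (2, 3) posterior condyle points, ordered
        [medial, lateral].
    shaft_axis : (2, 3) two points on the diaphyseal axis, ordered
        [proximal, distal].
    attachments : muscle attachment sites on the femur.
    surface_points : optional (n, 3) surface point cloud.
    """

    side: str
    head_center: np.ndarray
    neck_axis: np.ndarray
    condyles_posterior: np.ndarray
    shaft_axis: np.ndarray
    attachments: tuple[Attachment, ...] = field(default_factory=tuple)
    surface_points: np.ndarray | None = None

    def __post_init__(self):
        if self.side not in ("R", "L"):
            raise ValueError("side must be 'R' or 'L'")
        for name in ("head_center", "neck_axis", "condyles_posterior", "shaft_axis"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.head_center.shape != (3,):
            raise ValueError("head_center must be a 3-vector")
        for name in ("neck_axis", "condyles_posterior", "shaft_axis"):
            if getattr(self, name).shape != (2, 3):
                raise ValueError(f"{name} must be (2, 3)")
        if self.surface_points is not None:
            object.__setattr__(
                self, "surface_points", np.asarray(self.surface_points, dtype=float)
            )
        pts = self.all_points()
        if not np.all(np.isfinite(pts)):
            raise GeometryError("femur geometry contains non-finite coordinates")
        if np.linalg.norm(self.shaft_axis[0] - self.shaft_axis[1]) < 1e-9:
            raise GeometryError("shaft axis has zero length")
        if np.linalg.norm(self.condyles_posterior[0] - self.condyles_posterior[1]) < 1e-9:
            raise GeometryError("posterior condyle points coincide")

    # -- convenience -----------------------------------------------------
    def all_points(self) -> np.ndarray:
        """All landmark/attachment coordinates stacked as (n, 3)."""
        parts = [
            self.head_center[None, :],
            self.neck_axis,
            self.condyles_posterior,
            self.shaft_axis,
        ]
        if self.attachments:
            parts.append(np.stack([a.point for a in self.attachments]))
        if self.surface_points is not None and len(self.surface_points):
            parts.append(self.surface_points)
        return np.vstack(parts)

    def attachment_points(self, muscle_id: str | None = None) -> np.ndarray:
        pts = [a.point for a in self.attachments if muscle_id in (None, a.muscle_id)]
        return np.stack(pts) if pts else np.empty((0, 3))

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "side": self.side,
            "head_center": self.head_center.tolist(),
            "neck_axis": self.neck_axis.tolist(),
            "condyles_posterior": self.condyles_posterior.tolist(),
            "shaft_axis": self.shaft_axis.tolist(),
            "attachments": [
                {
                    "muscle_id": a.muscle_id,
                    "fascicle_id": a.fascicle_id,
                    "site": a.site,
                    "point": a.point.tolist(),
                }
                for a in self.attachments
            ],
        }
        if self.surface_points is not None:
            d["surface_points"] = self.surface_points.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FemurGeometry":
        return cls(
            side=d["side"],
            head_center=d["head_center"],
            neck_axis=d["neck_axis"],
            condyles_posterior=d["condyles_posterior"],
            shaft_axis=d["shaft_axis"],
            attachments=tuple(
                Attachment(a["muscle_id"], a["fascicle_id"], a["site"], a["point"])
                for a in d.get("attachments", ())
            ),
            surface_points=d.get("surface_points"),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FemurGeometry":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# torsion measurement
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray, what: str = "vector") -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise GeometryError(f"degenerate {what} (zero length)")
    return v / n


def measure_torsion(femur: FemurGeometry) -> float:
    """Femoral torsion in degrees, antetorsion positive.

    Projects the neck line and the posterior condylar line onto the plane
    perpendicular to the shaft axis and returns their signed angle.

    Raises
    ------
    GeometryError
        If the neck line is (numerically) parallel to the shaft axis so
        its transverse projection vanishes.
    """
    up = _unit(femur.shaft_axis[0] - femur.shaft_axis[1], "shaft axis")

    # head-ward neck direction: shaft-ward point -> head-ward point,
    # re-oriented toward the head center for robustness
    neck = femur.neck_axis[1] - femur.neck_axis[0]
    if np.dot(neck, femur.head_center - femur.neck_axis[0]) < 0:
        neck = -neck

    # lateral -> medial condylar direction
    medial = femur.condyles_posterior[0] - femur.condyles_posterior[1]

    def project(v):
        return v - np.dot(v, up) * up

    n_t = project(neck)
    if np.linalg.norm(n_t) < 1e-9 * np.linalg.norm(neck):
        raise GeometryError("neck line parallel to shaft axis: torsion undefined")
    n_t = _unit(n_t, "projected neck line")
    m_t = _unit(project(medial), "projected condylar line")

    angle = np.degrees(np.arctan2(np.dot(np.cross(n_t, m_t), up), np.dot(n_t, m_t)))
    side_sign = 1.0 if femur.side == "R" else -1.0
    return float(side_sign * angle)


# ---------------------------------------------------------------------------
# torsion morphing
# ---------------------------------------------------------------------------

def _smoothstep(s: np.ndarray) -> np.ndarray:
    t = np.clip(
        (s - TWIST_BLEND_START) / (TWIST_BLEND_END - TWIST_BLEND_START), 0.0, 1.0
    )
    return t * t * (3.0 - 2.0 * t)


def _rotation_about_axis(axis: np.ndarray, angle_rad: np.ndarray) -> np.ndarray:
    """Rodrigues rotation matrices, one per angle: (n, 3, 3)."""
    a = np.atleast_1d(np.asarray(angle_rad, dtype=float))
    k = axis
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    eye = np.eye(3)
    s = np.sin(a)[:, None, None]
    c = np.cos(a)[:, None, None]
    return eye + s * K + (1 - c) * (K @ K)


def _twist_points(
    points: np.ndarray,
    origin: np.ndarray,
    axis: np.ndarray,
    length: float,
    delta_rad: float,
) -> np.ndarray:
    """Twist points about (origin, axis) by w(s) * delta, s = axial coordinate / length."""
    pts = np.atleast_2d(points)
    rel = pts - origin
    s = np.clip((rel @ axis) / length, 0.0, 1.0)
    w = _smoothstep(s)
    R = _rotation_about_axis(axis, w * delta_rad)
    out = origin + np.einsum("nij,nj->ni", R, rel)
    return out.reshape(points.shape)


def morph_to_torsion(femur: FemurGeometry, target: float) -> FemurGeometry:
    """Return a copy of ``femur`` twisted to the requested torsion (degrees).

    Distal landmarks (posterior condyles, distal shaft point) are fixed;
    the proximal femur rotates about the shaft axis by the torsion
    difference; attachment and surface points follow the smoothstep blend
    of their normalized shaft coordinate. ``measure_torsion`` of the
    result equals ``target``.
    """
    if not np.isfinite(target):
        raise ValueError("target torsion must be finite")
    current = measure_torsion(femur)
    delta = float(target) - current

    proximal, distal = femur.shaft_axis
    axis = _unit(proximal - distal, "shaft axis")
    length = float(np.dot(proximal - distal, axis))

    # positive antetorsion = proximal rotated anteriorly; for the
    # right-handed measurement above this is a rotation by -delta about
    # the cranial shaft direction on the right side, +delta on the left.
    side_sign = 1.0 if femur.side == "R" else -1.0
    delta_rad = -side_sign * np.radians(delta)

    def tw(points):
        return _twist_points(points, distal, axis, length, delta_rad)

    new_attachments = tuple(replace(a, point=tw(a.point)) for a in femur.attachments)
    return FemurGeometry(
        side=femur.side,
        head_center=tw(femur.head_center),
        neck_axis=tw(femur.neck_axis),
        condyles_posterior=tw(femur.condyles_posterior),
        shaft_axis=tw(femur.shaft_axis),
        attachments=new_attachments,
        surface_points=None if femur.surface_points is None else tw(femur.surface_points),
    )


# ---------------------------------------------------------------------------
# template construction
# ---------------------------------------------------------------------------

# femoral attachment sites of the canonical zero-torsion right femur
# (mm; X anterior, Y cranial, Z lateral). The greater/lesser trochanter
# sites sit proximal to the twist blend (rotate fully with the neck);
# shaft sites blend; the adductor tubercle is distal (fixed).
_FEMUR_ATTACHMENTS_ZERO = [
    # muscle_id, fascicle_id, site, (x, y, z)
    ("glut_med", "glut_med_1", "insertion", (5.0, -45.0, 48.0)),
    ("glut_med", "glut_med_2", "insertion", (-2.0, -48.0, 50.0)),
    ("glut_med", "glut_med_3", "insertion", (-9.0, -51.0, 47.0)),
    ("glut_min", "glut_min_1", "insertion", (20.0, -52.0, 38.0)),
    ("glut_min", "glut_min_2", "insertion", (3.0, -57.0, 44.0)),
    ("glut_min", "glut_min_3", "insertion", (-3.0, -59.0, 43.0)),
    ("piriformis", "piriformis_1", "insertion", (-8.0, -42.0, 40.0)),
    ("iliacus", "iliacus_1", "insertion", (-10.0, -92.0, -14.0)),
    ("psoas", "psoas_1", "insertion", (-12.0, -96.0, -16.0)),
    ("glut_max", "glut_max_1", "insertion", (-22.0, -110.0, 12.0)),
    ("glut_max", "glut_max_2", "insertion", (-26.0, -150.0, 8.0)),
    ("tfl", "tfl_1", "via", (2.0, -62.0, 52.0)),
    ("add_long", "add_long_1", "insertion", (-12.0, -250.0, -6.0)),
    ("add_mag", "add_mag_1", "insertion", (-16.0, -180.0, -10.0)),
    ("add_mag", "add_mag_2", "insertion", (-16.0, -270.0, -8.0)),
    ("add_mag", "add_mag_3", "insertion", (-10.0, -398.0, -28.0)),
]

#: neck inclination above the transverse plane (degrees); the projection
#: used by the torsion measurement removes it, so it only shapes the 3-D
#: neck geometry, not the measured angle.
_NECK_ELEVATION = 35.0
_NECK_LENGTH = 70.0


def _zero_torsion_template(side: str = "R") -> FemurGeometry:
    b = np.radians(_NECK_ELEVATION)
    lat = 1.0 if side == "R" else -1.0
    neck_dir = np.array([0.0, np.sin(b), -lat * np.cos(b)])
    base = np.array([0.0, -65.0, 0.0])
    atts = tuple(
        Attachment(m, f, s, np.array([p[0], p[1], lat * p[2]]))
        for m, f, s, p in _FEMUR_ATTACHMENTS_ZERO
    )
    return FemurGeometry(
        side=side,
        head_center=base + _NECK_LENGTH * neck_dir,
        neck_axis=np.stack([base + 25.0 * neck_dir, base + 50.0 * neck_dir]),
        condyles_posterior=np.array(
            [[-25.0, -420.0, -lat * 25.0], [-25.0, -420.0, lat * 25.0]]
        ),
        shaft_axis=np.array([[0.0, -60.0, 0.0], [0.0, -400.0, 0.0]]),
        attachments=atts,
    )


def generate_template_femur(torsion: float = TEMPLATE_TORSION, side: str = "R") -> FemurGeometry:
    """Parametric template femur at the requested torsion (degrees).

    Built by twisting a canonical zero-torsion femur, so
    ``measure_torsion(generate_template_femur(t)) == t`` to numerical
    precision for any finite ``t``.
    """
    if not np.isfinite(torsion):
        raise ValueError("torsion must be finite")
    return morph_to_torsion(_zero_torsion_template(side), torsion)
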