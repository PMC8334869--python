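"""Acetabular frame, HCF decomposition, and contact-force pathways.

The hip contact force is decomposed in a standardized acetabular frame:
origin at the hip joint centre, y axis perpendicular to the acetabular
opening plane (positive out of the socket, toward the femur), x axis
anterior (+) / posterior (-), z axis superolateral (+) / through the
mid-acetabular notch (-). The frame is built by rotating a permuted
pelvis triad by the anteversion angle about the pelvis cranial axis and
then by the inclination angle about the pelvis anterior axis (this
composition order is a documented package convention), standardized at
45 deg inclination and 20 deg anteversion; left and right frames are
mirror-symmetric about the pelvis sagittal plane.

The contact pathway is the central-ray intersection of the force line
through the joint centre with an idealized hemisphere of standardized
54 mm diameter: exact for a concentric hemisphere. Forces pointing into
the socket (component along -y positive) intersect the articular
surface; the cohort-mean pathway averages force vectors across subjects
first and intersects the mean vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import GeometryError
from .gait import GC_NODES, GaitCycleField

__all__ = [
    "AcetabularFrame",
    "PathwayPoint",
    "build_frame",
    "decompose",
    "intersect_hemisphere",
    "pathway_from_field",
    "mean_pathway",
    "pathway_frame",
    "plot_pathway",
    "DEFAULT_INCLINATION",
    "DEFAULT_ANTEVERSION",
    "DEFAULT_DIAMETER",
]

DEFAULT_INCLINATION = 45.0  # deg
DEFAULT_ANTEVERSION = 20.0  # deg
DEFAULT_DIAMETER = 54.0  # mm


@dataclass(frozen=True)
class AcetabularFrame:
    """Standardized acetabular coordinate frame."""

    origin: np.ndarray  # HJC, world/pelvis coordinates
    x_axis: np.ndarray  # anterior (+)
    y_axis: np.ndarray  # out of the socket (+); -y points at the pole
    z_axis: np.ndarray  # superolateral (+)
    inclination: float
    anteversion: float
    side: str

    def __post_init__(self):
        for name in ("origin", "x_axis", "y_axis", "z_axis"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        G = np.stack([self.x_axis, self.y_axis, self.z_axis])
        if not np.allclose(G @ G.T, np.eye(3), atol=1e-9):
            raise GeometryError("acetabular axes are not orthonormal")

    @property
    def rotation(self) -> np.ndarray:
        """(3, 3) matrix with axes as rows: v_acet = rotation @ v_pelvis."""
        return np.stack([self.x_axis, self.y_axis, self.z_axis])


@dataclass(frozen=True)
class PathwayPoint:
    """Contact point of the force ray on the acetabular hemisphere."""

    node: float  # % gait cycle
    point: np.ndarray  # 3D, mm, relative to the pelvis origin
    azimuth: float  # deg, in the opening plane, from +x toward +z
    polar: float  # deg, from the socket pole (-y axis)
    inside_acetabulum: bool
    magnitude: float  # carried force magnitude (BW)

    @property
    def quadrant(self) -> str:
        a = "anterior" if np.cos(np.radians(self.azimuth)) >= 0 else "posterior"
        s = "superolateral" if np.sin(np.radians(self.azimuth)) >= 0 else "inferomedial"
        return f"{a}/{s}"


def _rot(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    a = np.radians(angle_deg)
    k = axis / np.linalg.norm(axis)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


def build_frame(
    pelvis_R: np.ndarray,
    hjc: np.ndarray,
    inclination: float = DEFAULT_INCLINATION,
    anteversion: float = DEFAULT_ANTEVERSION,
    side: str = "R",
) -> AcetabularFrame:
    """Acetabular frame from the pelvis pose.

    ``pelvis_R`` has the pelvis axes as columns (X anterior, Y cranial,
    Z right); ``hjc`` is the hip joint centre. At zero inclination and
    anteversion the frame is the permuted pelvis triad
    (x = anterior, y = lateral, z = cranial); anteversion is then
    applied about the pelvis cranial axis and inclination about the
    pelvis anterior axis, with side-aware senses so the two hips mirror.
    """
    pelvis_R = np.asarray(pelvis_R, dtype=float)
    if pelvis_R.shape != (3, 3) or not np.allclose(
        pelvis_R @ pelvis_R.T, np.eye(3), atol=1e-8
    ):
        raise GeometryError("pelvis frame must be a 3x3 rotation matrix")
    s = 1.0 if side == "R" else -1.0
    X, Y, Z = pelvis_R[:, 0], pelvis_R[:, 1], pelvis_R[:, 2]
    R = _rot(X, s * inclination) @ _rot(Y, s * anteversion)
    return AcetabularFrame(
        origin=np.asarray(hjc, dtype=float),
        x_axis=R @ X,
        y_axis=R @ (s * Z),
        z_axis=R @ Y,
        inclination=inclination,
        anteversion=anteversion,
        side=side,
    )


def decompose(frame: AcetabularFrame, hcf: np.ndarray) -> np.ndarray:
    """(..., 3) acetabular-frame components (x, y, z) of force vectors."""
    v = np.asarray(hcf, dtype=float)
    return np.stack(
        [v @ frame.x_axis, v @ frame.y_axis, v @ frame.z_axis], axis=-1
    )


def intersect_hemisphere(
    frame: AcetabularFrame,
    hcf: np.ndarray,
    diameter: float = DEFAULT_DIAMETER,
    node: float = np.nan,
) -> PathwayPoint:
    """Central-ray intersection of one force vector with the hemisphere.

    The ray runs from the joint centre along the femur-on-acetabulum
    force direction; the point lies at radius ``diameter / 2`` from the
    origin. ``inside_acetabulum`` is True when the force points into the
    socket (positive component along -y); a force exactly in the opening
    plane (polar angle 90 deg) counts as the boundary, inside.
    """
    v = np.asarray(hcf, dtype=float)
    mag = float(np.linalg.norm(v))
    if mag < 1e-12:
        raise GeometryError("zero-magnitude force: contact direction undefined")
    u = v / mag
    r = diameter / 2.0
    comp = decompose(frame, u)
    into = -comp[1]  # component along -y (into the socket)
    return PathwayPoint(
        node=node,
        point=frame.origin + r * u,
        azimuth=float(np.degrees(np.arctan2(comp[2], comp[0]))),
        polar=float(np.degrees(np.arccos(np.clip(into, -1.0, 1.0)))),
        inside_acetabulum=bool(into >= -1e-12),  # boundary (polar 90) counts inside
        magnitude=mag,
    )


def pathway_from_field(
    hcf_field: GaitCycleField,
    frame: AcetabularFrame,
    diameter: float = DEFAULT_DIAMETER,
) -> list:
    """Per-node pathway of one subject's (hcf_x, hcf_y, hcf_z) field."""
    V = np.stack([hcf_field[c] for c in ("hcf_x", "hcf_y", "hcf_z")], axis=1)
    return [
        intersect_hemisphere(frame, V[i], diameter, node=float(GC_NODES[i]))
        for i in range(101)
    ]


def mean_pathway(
    cohort_fields,
    frame: AcetabularFrame,
    diameter: float = DEFAULT_DIAMETER,
) -> list:
    """Pathway of the cohort-mean HCF vector (vectors averaged first)."""
    fields = list(cohort_fields)
    if not fields:
        raise ValueError("empty cohort")
    V = np.mean(
        [
            np.stack([f["hcf_x"], f["hcf_y"], f["hcf_z"]], axis=1)
            for f in fields
        ],
        axis=0,
    )
    return [
        intersect_hemisphere(frame, V[i], diameter, node=float(GC_NODES[i]))
        for i in range(101)
    ]


def pathway_frame(points) -> pd.DataFrame:
    """Tidy export: (node, azimuth, polar, magnitude, quadrant, inside)."""
    return pd.DataFrame(
        {
            "node": [p.node for p in points],
            "azimuth": [p.azimuth for p in points],
            "polar": [p.polar for p in points],
            "magnitude": [p.magnitude for p in points],
            "quadrant": [p.quadrant for p in points],
            "inside_acetabulum": [p.inside_acetabulum for p in points],
        }
    )


#: gait-cycle landmarks highlighted on pathway plots (node -> marker)
_PATHWAY_MARKERS = {0: "s", 10: "D", 50: "^", 60: "*", 100: "X"}


def plot_pathway(points, ax=None, color="tab:red"):
    """Planar (opening-plane) view of a contact pathway.

    Points are projected on the acetabular opening plane (x right,
    z up); the gait-cycle landmarks 0/10/50/60/100 %GC use square,
    diamond, triangle, star and cross markers.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    pol = np.radians([p.polar for p in points])
    az = np.radians([p.azimuth for p in points])
    r = np.sin(pol)
    x, z = r * np.cos(az), r * np.sin(az)
    ax.plot(x, z, "-", color=color, lw=1, alpha=0.7)
    ax.scatter(x, z, s=8, color=color, alpha=0.5)
    for node, marker in _PATHWAY_MARKERS.items():
        i = int(node)
        ax.scatter([x[i]], [z[i]], marker=marker, s=70, color="k", zorder=3)
    circ = np.linspace(0, 2 * np.pi, 200)
    ax.plot(np.cos(circ), np.sin(circ), "k-", lw=0.8)
    ax.set_aspect("equal")
    ax.set_xlabel("anterior (+x)")
    ax.set_ylabel("superolateral (+z)")
    return ax
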