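"""Scaled linked-segment lower-limb model with muscle fascicles.

The model is a pelvis-thigh-shank-foot chain: a 3-DOF ball-and-socket
hip, 1-DOF hinge knee, ankle (talocrural) and subtalar joints, plus a
patella whose position is a function of knee flexion and acts as a via
point for the knee extensors. Muscle fascicles are polyline paths
through segment-fixed points; femoral attachment sites come from a
:class:`~torsiongait.femur.FemurGeometry`, so torsion morphing moves the
proximal femoral attachments while joint kinematics are untouched.

Conventions: right-handed frames with X anterior, Y cranial, Z to the
subject's right; angles in degrees at the API; geometry in metres
internally. Hip angle sequence is flexion (Z), adduction (X-floating),
internal rotation (long axis), side-aware so that adduction and
internal rotation are positive toward the midline on both sides.

Moment arms use the tendon-excursion definition, -dL/dq, by central
finite differences; positive moment arm = the muscle is an agonist for
the positive direction of the coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import GeometryError
from .femur import FemurGeometry, morph_to_torsion, TEMPLATE_TORSION

__all__ = [
    "Model",
    "MuscleFascicle",
    "Posture",
    "build_model",
    "forward_kinematics",
    "muscle_length",
    "moment_arm",
    "moment_arm_matrix",
    "lever_arm_sweep",
    "HIP_DOFS",
    "LEG_DOFS",
    "MUSCLE_GROUPS",
]

# ---------------------------------------------------------------------------
# template anthropometrics (50th percentile male) and inertial fractions
# ---------------------------------------------------------------------------

TEMPLATE_HEIGHT = 1.75  # m
TEMPLATE_MASS = 75.0  # kg
TEMPLATE_HJC_DISTANCE = 170.0  # mm between hip joint centres

# segment lengths as fractions of stature and masses as fractions of
# body mass (Winter's anthropometric tables)
LENGTH_FRACTIONS = {"thigh": 0.245, "shank": 0.246, "foot": 0.152}
MASS_FRACTIONS = {"pelvis": 0.142, "thigh": 0.100, "shank": 0.0465, "foot": 0.0145}
COM_FRACTIONS = {"thigh": 0.433, "shank": 0.433}  # distance from proximal joint
RADIUS_OF_GYRATION = {"thigh": 0.323, "shank": 0.302, "foot": 0.475}  # transverse, /L

LEG_DOFS = (
    "hip_flexion",
    "hip_adduction",
    "hip_rotation",
    "knee_flexion",
    "ankle_dorsiflexion",
    "subtalar_inversion",
)
HIP_DOFS = LEG_DOFS[:3]

JOINT_LIMITS = {
    "hip_flexion": (-30.0, 120.0),
    "hip_adduction": (-50.0, 40.0),
    "hip_rotation": (-50.0, 50.0),
    "knee_flexion": (-5.0, 140.0),
    "ankle_dorsiflexion": (-50.0, 40.0),
    "subtalar_inversion": (-30.0, 30.0),
}

#: patella centre in the thigh frame relative to the knee centre, as a
#: function of knee flexion (deg -> (anterior, cranial) offsets, mm)
PATELLA_TABLE = np.array(
    [
        [0.0, 45.0, 30.0],
        [30.0, 42.0, 15.0],
        [60.0, 35.0, 0.0],
        [90.0, 25.0, -12.0],
        [120.0, 15.0, -22.0],
    ]
)

#: subtalar joint axis in the foot frame (Inman-like obliquity), right side
_SUBTALAR_AXIS_R = np.array([0.781, 0.600, -0.172])
_SUBTALAR_AXIS_R /= np.linalg.norm(_SUBTALAR_AXIS_R)


@dataclass(frozen=True)
class Posture:
    """Generalized coordinates of the chain. Scalars or equal-shape arrays.

    Angles in degrees, pelvis translation in metres.
    """

    pelvis_tx: float = 0.0
    pelvis_ty: float = 0.95
    pelvis_tz: float = 0.0
    pelvis_tilt: float = 0.0  # about Z (anterior tilt positive)
    pelvis_list: float = 0.0  # about X
    pelvis_rotation: float = 0.0  # about Y
    hip_flexion: float = 0.0
    hip_adduction: float = 0.0
    hip_rotation: float = 0.0  # internal positive
    knee_flexion: float = 0.0
    ankle_dorsiflexion: float = 0.0
    subtalar_inversion: float = 0.0

    def replace(self, **kw) -> "Posture":
        return replace(self, **kw)

    def get(self, dof: str):
        return getattr(self, dof)

    def within_limits(self) -> bool:
        return all(
            np.all((getattr(self, d) >= lo) & (getattr(self, d) <= hi))
            for d, (lo, hi) in JOINT_LIMITS.items()
        )


@dataclass(frozen=True)
class MuscleFascicle:
    """One fascicle: an ordered polyline path through segment-fixed points."""

    muscle_id: str
    fascicle_id: str
    group: str  # hip_flexor | hip_extensor | hip_abductor | hip_adductor | other
    strength: float  # isometric strength S, N
    path: tuple  # ((segment_name, (3,) local point, m), ...)

    def __post_init__(self):
        if len(self.path) < 2:
            raise ValueError(f"{self.fascicle_id}: path needs >= 2 points")
        if self.strength <= 0:
            raise ValueError(f"{self.fascicle_id}: strength must be positive")
        object.__setattr__(
            self,
            "path",
            tuple((seg, np.asarray(p, dtype=float)) for seg, p in self.path),
        )

    @property
    def spans_hip(self) -> bool:
        segs = [s for s, _ in self.path]
        return "pelvis" in segs and any(s != "pelvis" for s in segs)


@dataclass
class Segment:
    name: str
    mass: float  # kg
    length: float  # m (0 for pelvis/patella bookkeeping)
    com: np.ndarray  # local, m
    inertia: np.ndarray  # (3,3) about COM, local axes, kg m^2


# ---------------------------------------------------------------------------
# rotation helpers (broadcast over leading axes)
# ---------------------------------------------------------------------------

def _rot(axis: int, angle_deg):
    a = np.radians(np.asarray(angle_deg, dtype=float))
    c, s = np.cos(a), np.sin(a)
    R = np.zeros(a.shape + (3, 3))
    i, j = {0: (1, 2), 1: (2, 0), 2: (0, 1)}[axis]
    R[..., axis, axis] = 1.0
    R[..., i, i] = c
    R[..., i, j] = -s
    R[..., j, i] = s
    R[..., j, j] = c
    return R


def _rot_axis(axis_vec: np.ndarray, angle_deg):
    a = np.radians(np.asarray(angle_deg, dtype=float))
    k = axis_vec / np.linalg.norm(axis_vec)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    s = np.sin(a)[..., None, None]
    c = np.cos(a)[..., None, None]
    return np.eye(3) + s * K + (1 - c) * (K @ K)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

@dataclass
class Model:
    """Scaled subject-specific lower-limb model (one instrumented limb)."""

    subject_id: str
    side: str  # "R" | "L"
    body_mass: float  # kg
    height: float  # m
    segments: dict  # name -> Segment
    muscles: list  # list[MuscleFascicle]
    hip_local: np.ndarray  # hip centre in pelvis frame, m
    knee_local: np.ndarray  # knee centre in thigh frame, m
    ankle_local: np.ndarray  # ankle centre in shank frame, m
    subtalar_axis: np.ndarray  # unit, foot frame
    scale_factors: dict = field(default_factory=dict)
    markers: dict = field(default_factory=dict)  # name -> (segment, local point)
    torsion: float = TEMPLATE_TORSION  # femoral torsion of the built femur, deg

    @property
    def side_sign(self) -> float:
        return 1.0 if self.side == "R" else -1.0

    # -- kinematics ------------------------------------------------------
    def forward_kinematics(self, posture: Posture) -> dict:
        """World pose of each segment: name -> (R (...,3,3), p (...,3))."""
        s = self.side_sign
        Rp = (
            _rot(2, posture.pelvis_tilt)
            @ _rot(0, posture.pelvis_list)
            @ _rot(1, posture.pelvis_rotation)
        )
        pp = np.stack(
            np.broadcast_arrays(
                np.asarray(posture.pelvis_tx, dtype=float),
                np.asarray(posture.pelvis_ty, dtype=float),
                np.asarray(posture.pelvis_tz, dtype=float),
            ),
            axis=-1,
        )
        R_hip = (
            _rot(2, posture.hip_flexion)
            @ _rot(0, s * np.asarray(posture.hip_adduction))
            @ _rot(1, s * np.asarray(posture.hip_rotation))
        )
        Rt = Rp @ R_hip
        pt = pp + np.einsum("...ij,j->...i", Rp, self.hip_local)
        Rs = Rt @ _rot(2, -np.asarray(posture.knee_flexion))
        ps = pt + np.einsum("...ij,j->...i", Rt, self.knee_local)
        Rf = (
            Rs
            @ _rot(2, posture.ankle_dorsiflexion)
            @ _rot_axis(self.subtalar_axis, s * np.asarray(posture.subtalar_inversion))
        )
        pf = ps + np.einsum("...ij,j->...i", Rs, self.ankle_local)
        out = {
            "pelvis": (Rp, pp),
            "thigh": (Rt, pt),
            "shank": (Rs, ps),
            "foot": (Rf, pf),
        }
        out["patella"] = (Rt, pt)  # patella points carry their own offset
        return out

    def _patella_offset(self, knee_flexion) -> np.ndarray:
        """Patella centre in the thigh frame (m), knee-flexion-indexed."""
        kf = np.asarray(knee_flexion, dtype=float)
        ant = np.interp(kf, PATELLA_TABLE[:, 0], PATELLA_TABLE[:, 1])
        up = np.interp(kf, PATELLA_TABLE[:, 0], PATELLA_TABLE[:, 2])
        h = self.scale_factors.get("height", 1.0)
        off = np.stack(
            [ant * h / 1000.0, up * h / 1000.0, np.zeros_like(ant)], axis=-1
        )
        return self.knee_local + off

    def point_world(self, segment: str, local_point: np.ndarray, fk: dict, posture=None):
        R, p = fk[segment]
        pt = np.asarray(local_point, dtype=float)
        if segment == "patella":
            pt = pt + self._patella_offset(posture.knee_flexion)
            return p + np.einsum("...ij,...j->...i", R, pt)
        return p + np.einsum("...ij,j->...i", R, pt)

    # -- muscle geometry -------------------------------------------------
    def muscle_path_world(self, fascicle: MuscleFascicle, posture: Posture, fk=None):
        fk = fk or self.forward_kinematics(posture)
        return [self.point_world(seg, pt, fk, posture) for seg, pt in fascicle.path]

    def muscle_length(self, fascicle: MuscleFascicle, posture: Posture, fk=None):
        pts = self.muscle_path_world(fascicle, posture, fk)
        L = 0.0
        for a, b in zip(pts[:-1], pts[1:]):
            L = L + np.linalg.norm(b - a, axis=-1)
        return L

    def muscle_lengths(self, posture: Posture) -> np.ndarray:
        """(n_fascicles, ...) lengths of all fascicles at once."""
        fk = self.forward_kinematics(posture)
        return np.stack([self.muscle_length(m, posture, fk) for m in self.muscles])

    def moment_arm(
        self, fascicle: MuscleFascicle, posture: Posture, dof: str, step: float = 0.25
    ):
        """Tendon-excursion moment arm -dL/dq (m), central difference."""
        if dof not in LEG_DOFS:
            raise ValueError(f"unknown model coordinate {dof!r}")
        lo = posture.replace(**{dof: np.asarray(posture.get(dof)) - step})
        hi = posture.replace(**{dof: np.asarray(posture.get(dof)) + step})
        dL = self.muscle_length(fascicle, hi) - self.muscle_length(fascicle, lo)
        pts = self.muscle_path_world(fascicle, posture)
        for a, b in zip(pts[:-1], pts[1:]):
            if np.any(np.linalg.norm(b - a, axis=-1) < 1e-9):
                raise GeometryError(
                    f"{fascicle.fascicle_id}: coincident path points, "
                    "moment arm undefined"
                )
        return -dL / np.radians(2 * step)

    def moment_arm_matrix(self, posture: Posture, dofs=LEG_DOFS, step: float = 0.25):
        """(n_fascicles, n_dofs[, ...]) tendon-excursion moment arm matrix."""
        cols = []
        for dof in dofs:
            lo = posture.replace(**{dof: np.asarray(posture.get(dof)) - step})
            hi = posture.replace(**{dof: np.asarray(posture.get(dof)) + step})
            dL = self.muscle_lengths(hi) - self.muscle_lengths(lo)
            cols.append(-dL / np.radians(2 * step))
        return np.stack(cols, axis=1)

    # -- bookkeeping -----------------------------------------------------
    def fascicles_of(self, muscle_id: str):
        return [m for m in self.muscles if m.muscle_id == muscle_id]

    @property
    def muscle_ids(self):
        seen = []
        for m in self.muscles:
            if m.muscle_id not in seen:
                seen.append(m.muscle_id)
        return seen

    @property
    def strengths(self) -> np.ndarray:
        return np.array([m.strength for m in self.muscles])

    def hip_spanning(self) -> np.ndarray:
        return np.array([m.spans_hip for m in self.muscles])

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "side": self.side,
            "body_mass": self.body_mass,
            "height": self.height,
            "torsion": self.torsion,
            "scale_factors": self.scale_factors,
            "hip_local": self.hip_local.tolist(),
            "knee_local": self.knee_local.tolist(),
            "ankle_local": self.ankle_local.tolist(),
            "muscles": [
                {
                    "muscle_id": m.muscle_id,
                    "fascicle_id": m.fascicle_id,
                    "group": m.group,
                    "strength": m.strength,
                    "path": [[seg, pt.tolist()] for seg, pt in m.path],
                }
                for m in self.muscles
            ],
        }


# ---------------------------------------------------------------------------
# muscle roster
# ---------------------------------------------------------------------------

#: functional groups (main hip function; uniarticular knee/ankle/subtalar
#: muscles needed for moment equilibrium are grouped as "other")
MUSCLE_GROUPS = {
    "iliacus": "hip_flexor",
    "psoas": "hip_flexor",
    "rect_fem": "hip_flexor",
    "sartorius": "hip_flexor",
    "glut_max": "hip_extensor",
    "bflh": "hip_extensor",
    "semimem": "hip_extensor",
    "semiten": "hip_extensor",
    "glut_med": "hip_abductor",
    "glut_min": "hip_abductor",
    "tfl": "hip_abductor",
    "add_long": "hip_adductor",
    "add_mag": "hip_adductor",
    "piriformis": "other",
    "vastus": "other",
    "gastroc": "other",
    "soleus": "other",
    "tib_ant": "other",
    "tib_post": "other",
    "peroneus": "other",
}

#: per-fascicle isometric strengths S (N); configuration constants, used
#: by the recruitment denominator. Hip-spanning strengths are
#: lumped-group equivalents: each modeled fascicle also stands in for
#: the unmodeled muscles of its compartment (pectineus, gracilis,
#: adductor brevis, short external rotators, deep gluteal fibres, ...),
#: so they exceed single-muscle PCSA-based values by ~50%.
FASCICLE_STRENGTHS = {
    "iliacus_1": 2250.0,
    "psoas_1": 2100.0,
    "rect_fem_1": 2250.0,
    "sartorius_1": 500.0,
    "tfl_1": 1050.0,
    "glut_max_1": 2100.0,
    "glut_max_2": 2100.0,
    "glut_med_1": 1500.0,
    "glut_med_2": 1500.0,
    "glut_med_3": 1500.0,
    "glut_min_1": 525.0,
    "glut_min_2": 525.0,
    "glut_min_3": 525.0,
    "piriformis_1": 750.0,
    "bflh_1": 1950.0,
    "semimem_1": 2700.0,
    "semiten_1": 900.0,
    "add_long_1": 1350.0,
    "add_mag_1": 1275.0,
    "add_mag_2": 1275.0,
    "add_mag_3": 1275.0,
    "vastus_1": 2500.0,
    "vastus_2": 2500.0,
    "gastroc_1": 2000.0,
    "soleus_1": 4000.0,
    "tib_ant_1": 1100.0,
    "tib_post_1": 1400.0,
    "peroneus_1": 900.0,
}

# pelvis-frame attachment points (mm, right side, origin at mid-HJC)
_PELVIS_POINTS = {
    ("iliacus_1", "origin"): (20.0, 70.0, 55.0),
    ("iliacus_1", "via"): (50.0, -5.0, 60.0),
    ("psoas_1", "origin"): (30.0, 110.0, 40.0),
    ("psoas_1", "via"): (47.0, -2.0, 55.0),
    ("rect_fem_1", "origin"): (45.0, 15.0, 75.0),
    ("sartorius_1", "origin"): (55.0, 35.0, 95.0),
    ("tfl_1", "origin"): (45.0, 55.0, 100.0),
    ("glut_max_1", "origin"): (-70.0, 60.0, 45.0),
    ("glut_max_2", "origin"): (-80.0, 20.0, 35.0),
    ("glut_med_1", "origin"): (35.0, 80.0, 92.0),
    ("glut_med_2", "origin"): (-10.0, 90.0, 90.0),
    ("glut_med_3", "origin"): (-45.0, 75.0, 78.0),
    ("glut_min_1", "origin"): (5.0, 55.0, 92.0),
    ("glut_min_2", "origin"): (-15.0, 52.0, 88.0),
    ("glut_min_3", "origin"): (-32.0, 48.0, 80.0),
    ("piriformis_1", "origin"): (-85.0, 15.0, 25.0),
    ("add_long_1", "origin"): (40.0, -15.0, 25.0),
    ("add_mag_1", "origin"): (-15.0, -40.0, 30.0),
    ("add_mag_2", "origin"): (-25.0, -45.0, 32.0),
    ("add_mag_3", "origin"): (-30.0, -48.0, 35.0),
    ("bflh_1", "origin"): (-50.0, -35.0, 52.0),
    ("semimem_1", "origin"): (-52.0, -33.0, 48.0),
    ("semiten_1", "origin"): (-48.0, -30.0, 50.0),
}

# shank-frame points (mm, right side, origin at knee centre)
_SHANK_POINTS = {
    ("rect_fem_1", "insertion"): (35.0, -60.0, 5.0),
    ("vastus_1", "insertion"): (35.0, -60.0, 5.0),
    ("vastus_2", "insertion"): (35.0, -60.0, 5.0),
    ("bflh_1", "insertion"): (-12.0, -45.0, 32.0),
    ("semimem_1", "insertion"): (-22.0, -40.0, -18.0),
    ("semiten_1", "insertion"): (-10.0, -65.0, -16.0),
    ("sartorius_1", "insertion"): (15.0, -75.0, -22.0),
    ("tfl_1", "insertion"): (18.0, -48.0, 28.0),
    ("soleus_1", "origin"): (-25.0, -90.0, 8.0),
    ("tib_ant_1", "origin"): (18.0, -110.0, 14.0),
    ("tib_post_1", "origin"): (-20.0, -130.0, 2.0),
    ("tib_post_1", "via"): (-18.0, -420.0, -28.0),
    ("peroneus_1", "origin"): (-8.0, -120.0, 30.0),
    ("peroneus_1", "via"): (-15.0, -420.0, 30.0),
}

# foot-frame points (mm, right side, origin at ankle centre)
_FOOT_POINTS = {
    ("soleus_1", "insertion"): (-60.0, -30.0, 0.0),
    ("gastroc_1", "insertion"): (-62.0, -28.0, 3.0),
    ("tib_ant_1", "insertion"): (55.0, -25.0, -25.0),
    ("tib_post_1", "insertion"): (35.0, -30.0, -32.0),
    ("peroneus_1", "insertion"): (35.0, -30.0, 30.0),
}

#: fascicle path layout: ordered (segment, key) pairs; "femur" points are
#: taken from the FemurGeometry attachment list, "patella" is the
#: knee-driven via point
_FASCICLE_PATHS = {
    "iliacus_1": [("pelvis", "origin"), ("pelvis", "via"), ("femur", "insertion")],
    "psoas_1": [("pelvis", "origin"), ("pelvis", "via"), ("femur", "insertion")],
    "rect_fem_1": [("pelvis", "origin"), ("patella", None), ("shank", "insertion")],
    "sartorius_1": [("pelvis", "origin"), ("shank", "insertion")],
    "tfl_1": [("pelvis", "origin"), ("femur", "via"), ("shank", "insertion")],
    "glut_max_1": [("pelvis", "origin"), ("femur", "insertion")],
    "glut_max_2": [("pelvis", "origin"), ("femur", "insertion")],
    "glut_med_1": [("pelvis", "origin"), ("femur", "insertion")],
    "glut_med_2": [("pelvis", "origin"), ("femur", "insertion")],
    "glut_med_3": [("pelvis", "origin"), ("femur", "insertion")],
    "glut_min_1": [("pelvis", "origin"), ("femur", "insertion")],
    "glut_min_2": [("pelvis", "origin"), ("femur", "insertion")],
    "glut_min_3": [("pelvis", "origin"), ("femur", "insertion")],
    "piriformis_1": [("pelvis", "origin"), ("femur", "insertion")],
    "add_long_1": [("pelvis", "origin"), ("femur", "insertion")],
    "add_mag_1": [("pelvis", "origin"), ("femur", "insertion")],
    "add_mag_2": [("pelvis", "origin"), ("femur", "insertion")],
    "add_mag_3": [("pelvis", "origin"), ("femur", "insertion")],
    "bflh_1": [("pelvis", "origin"), ("shank", "insertion")],
    "semimem_1": [("pelvis", "origin"), ("shank", "insertion")],
    "semiten_1": [("pelvis", "origin"), ("shank", "insertion")],
    "vastus_1": [("femur", "origin"), ("patella", None), ("shank", "insertion")],
    "vastus_2": [("femur", "origin"), ("patella", None), ("shank", "insertion")],
    "gastroc_1": [("femur", "origin"), ("foot", "insertion")],
    "soleus_1": [("shank", "origin"), ("foot", "insertion")],
    "tib_ant_1": [("shank", "origin"), ("foot", "insertion")],
    "tib_post_1": [("shank", "origin"), ("shank", "via"), ("foot", "insertion")],
    "peroneus_1": [("shank", "origin"), ("shank", "via"), ("foot", "insertion")],
}

#: extra femoral sites appended to the FemurGeometry attachment table at
#: model build (they belong on the femur but are distal / not part of the
#: morphology module's template): anterior-shaft vasti origins and the
#: posterior-condyle gastrocnemius origin
FEMUR_EXTRA_ATTACHMENTS = [
    ("vastus", "vastus_1", "origin", (15.0, -180.0, 8.0)),
    ("vastus", "vastus_2", "origin", (12.0, -230.0, -6.0)),
    ("gastroc", "gastroc_1", "origin", (-28.0, -398.0, -12.0)),
]

#: marker set (minimal per-segment clusters) for IK round trips; local mm
_MARKERS = {
    "SACR": ("pelvis", (-90.0, 30.0, 0.0)),
    "RASI": ("pelvis", (55.0, 35.0, 95.0)),
    "LASI": ("pelvis", (55.0, 35.0, -95.0)),
    "RPSI": ("pelvis", (-80.0, 25.0, 45.0)),
    "LPSI": ("pelvis", (-80.0, 25.0, -45.0)),
    "THI1": ("thigh", (40.0, -150.0, 40.0)),
    "THI2": ("thigh", (20.0, -250.0, 50.0)),
    "THI3": ("thigh", (45.0, -300.0, 10.0)),
    "KNE": ("thigh", (5.0, -420.0, 60.0)),  # lateral femoral epicondyle
    "TIB1": ("shank", (25.0, -120.0, 30.0)),
    "TIB2": ("shank", (10.0, -250.0, 40.0)),
    "TIB3": ("shank", (30.0, -350.0, 5.0)),
    "ANK": ("shank", (0.0, -425.0, 45.0)),  # lateral malleolus
    "HEEL": ("foot", (-70.0, -30.0, -5.0)),
    "MT2": ("foot", (150.0, -35.0, 10.0)),
    "MT5": ("foot", (110.0, -35.0, 45.0)),
}


def _mirror(point_mm, side: str) -> np.ndarray:
    p = np.asarray(point_mm, dtype=float)
    if side == "L":
        p = p * np.array([1.0, 1.0, -1.0])
    return p


def _femur_anchor_frame(femur: FemurGeometry):
    """Torsion-invariant mapping of femur coordinates into the thigh frame.

    Anchor = head centre of the femur morphed to the baseline torsion
    (the generic socket position, invariant under further morphs);
    the anchor->knee-centre line is aligned with the thigh -Y axis.
    """
    baseline = morph_to_torsion(femur, TEMPLATE_TORSION)
    anchor = baseline.head_center
    knee_center = femur.condyles_posterior.mean(axis=0) + np.array([20.0, 0.0, 0.0])
    u = knee_center - anchor
    length_mm = np.linalg.norm(u)
    u = u / length_mm
    target = np.array([0.0, -1.0, 0.0])
    v = np.cross(u, target)
    c = float(np.dot(u, target))
    if np.linalg.norm(v) < 1e-12:
        R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        V = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + V + V @ V * ((1 - c) / (np.linalg.norm(v) ** 2))
    return anchor, R, length_mm


def build_model(subject, femur: FemurGeometry) -> Model:
    """Build a scaled model for ``subject`` around ``femur``.

    Pelvic width is scaled so that the inter-HJC distance equals
    ``subject.hjc_distance``; thigh/shank/foot lengths scale with
    stature; femoral muscle attachments come from the (possibly
    torsion-morphed) femur geometry. Joint centres and axes are
    torsion-invariant, so morphing changes muscle lines of action only.
    """
    if femur.side != subject.side:
        raise ValueError(
            f"femur side {femur.side!r} does not match subject side {subject.side!r}"
        )
    side = subject.side
    s = 1.0 if side == "R" else -1.0
    h = subject.height / TEMPLATE_HEIGHT
    w = subject.hjc_distance / TEMPLATE_HJC_DISTANCE
    M = subject.mass

    lengths = {k: f * subject.height for k, f in LENGTH_FRACTIONS.items()}
    segments = {}
    segments["pelvis"] = Segment(
        "pelvis",
        MASS_FRACTIONS["pelvis"] * M,
        0.0,
        np.array([-0.01, 0.03, 0.0]) * h,
        MASS_FRACTIONS["pelvis"] * M * np.diag([0.01, 0.012, 0.008]) * h**2,
    )
    for name in ("thigh", "shank"):
        L = lengths[name]
        m = MASS_FRACTIONS[name] * M
        it = m * (RADIUS_OF_GYRATION[name] * L) ** 2
        segments[name] = Segment(
            name,
            m,
            L,
            np.array([0.0, -COM_FRACTIONS[name] * L, 0.0]),
            np.diag([it, m * (0.13 * L) ** 2, it]),
        )
    Lf = lengths["foot"]
    mf = MASS_FRACTIONS["foot"] * M
    itf = mf * (RADIUS_OF_GYRATION["foot"] * 0.4 * Lf) ** 2
    segments["foot"] = Segment(
        "foot", mf, Lf, np.array([0.05, -0.025, 0.0]) * h, np.diag([0.3 * itf, itf, itf])
    )

    # femur -> thigh mapping
    anchor, R_align, femur_len_mm = _femur_anchor_frame(femur)
    fem_scale = lengths["thigh"] / (femur_len_mm / 1000.0)

    def femur_to_thigh(point_mm):
        return R_align @ (np.asarray(point_mm) - anchor) / 1000.0 * fem_scale / 1.0

    femur_sites = {}
    all_att = list(femur.attachments) + [
        type(femur.attachments[0])(m, f, site, _mirror(p, side))
        for m, f, site, p in FEMUR_EXTRA_ATTACHMENTS
    ]
    for a in all_att:
        femur_sites[(a.fascicle_id, a.site)] = femur_to_thigh(a.point)

    def local_point(segment, fid, key):
        if segment == "femur":
            return "thigh", femur_sites[(fid, key)]
        if segment == "patella":
            return "patella", np.zeros(3)
        table = {"pelvis": _PELVIS_POINTS, "shank": _SHANK_POINTS, "foot": _FOOT_POINTS}[
            segment
        ]
        p = _mirror(table[(fid, key)], side) / 1000.0
        if segment == "pelvis":
            p = p * np.array([h, h, w])
        else:
            p = p * h
        return segment, p

    muscles = []
    for fid, layout in _FASCICLE_PATHS.items():
        mid = fid.rsplit("_", 1)[0]
        path = tuple(local_point(seg, fid, key) for seg, key in layout)
        muscles.append(
            MuscleFascicle(
                muscle_id=mid,
                fascicle_id=fid,
                group=MUSCLE_GROUPS[mid],
                strength=FASCICLE_STRENGTHS[fid],
                path=path,
            )
        )

    markers = {
        name: (seg, _mirror(p, side) / 1000.0 * (np.array([h, h, w]) if seg == "pelvis" else h))
        for name, (seg, p) in _MARKERS.items()
    }

    return Model(
        subject_id=getattr(subject, "id", "anon"),
        side=side,
        body_mass=M,
        height=subject.height,
        segments=segments,
        muscles=muscles,
        hip_local=np.array([0.0, 0.0, s * subject.hjc_distance / 2.0 / 1000.0]),
        knee_local=np.array([0.0, -lengths["thigh"], 0.0]),
        ankle_local=np.array([0.0, -lengths["shank"], 0.0]),
        subtalar_axis=_SUBTALAR_AXIS_R * np.array([1.0, 1.0, s]),
        scale_factors={"height": h, "pelvis_width": w, "mass": M / TEMPLATE_MASS},
        markers=markers,
        torsion=float(np.round(_measure_torsion_safe(femur), 9)),
    )


def _measure_torsion_safe(femur: FemurGeometry) -> float:
    from .femur import measure_torsion

    return measure_torsion(femur)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def forward_kinematics(model: Model, posture: Posture) -> dict:
    return model.forward_kinematics(posture)


def muscle_length(model: Model, posture: Posture, fascicle: MuscleFascicle):
    return model.muscle_length(fascicle, posture)


def moment_arm(model: Model, posture: Posture, fascicle: MuscleFascicle, dof: str,
               step: float = 0.25):
    return model.moment_arm(fascicle, posture, dof, step)


def moment_arm_matrix(model: Model, posture: Posture, dofs=LEG_DOFS, step: float = 0.25):
    return model.moment_arm_matrix(posture, dofs, step)


#: hip ranges of the lever-arm sweeps (deg): sagittal 20 ext - 90 flex,
#: frontal 30 add - 50 abd, transverse 40 int - 40 ext
SWEEP_RANGES = {
    "hip_flexion": (-20.0, 90.0),
    "hip_adduction": (-50.0, 30.0),
    "hip_rotation": (-40.0, 40.0),
}


def lever_arm_sweep(
    models: dict,
    dof_ranges: dict | None = None,
    grid_step: float = 1.0,
    base_posture: Posture | None = None,
) -> pd.DataFrame:
    """Per-muscle mean lever-arm curves over hip ranges of motion.

    Parameters
    ----------
    models : dict
        configuration label -> (Model, base Posture or None). A plain
        ``{label: Model}`` mapping is also accepted.
    dof_ranges : dict, optional
        dof -> (min, max) in degrees; defaults to :data:`SWEEP_RANGES`.

    Returns
    -------
    DataFrame with columns (configuration, muscle, dof, angle, lever_arm),
    lever arm in metres, averaged over each muscle's fascicles.
    """
    dof_ranges = dof_ranges or SWEEP_RANGES
    rows = []
    for label, entry in models.items():
        if isinstance(entry, tuple):
            model, posture = entry
        else:
            model, posture = entry, None
        posture = posture or base_posture or Posture()
        for dof, (lo, hi) in dof_ranges.items():
            angles = np.arange(lo, hi + 0.5 * grid_step, grid_step)
            p = posture.replace(**{dof: angles})
            arm_lo = p.replace(**{dof: angles - 0.25})
            arm_hi = p.replace(**{dof: angles + 0.25})
            dL = model.muscle_lengths(arm_hi) - model.muscle_lengths(arm_lo)
            arms = -dL / np.radians(0.5)  # (n_fascicles, n_angles)
            df = pd.DataFrame(arms.T, columns=[m.fascicle_id for m in model.muscles])
            df["angle"] = angles
            long = df.melt(id_vars="angle", var_name="fascicle", value_name="lever_arm")
            long["muscle"] = long["fascicle"].str.rsplit("_", n=1).str[0]
            agg = (
                long.groupby(["muscle", "angle"], as_index=False)["lever_arm"].mean()
            )
            agg["dof"] = dof
            agg["configuration"] = label
            rows.append(agg)
    out = pd.concat(rows, ignore_index=True)
    return out[["configuration", "muscle", "dof", "angle", "lever_arm"]]
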