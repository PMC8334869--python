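"""Inverse dynamics, cubic-criterion muscle recruitment, hip contact forces.

Net joint loads come from a bottom-up Newton-Euler recursion
(foot -> shank -> thigh) driven by the measured ground reaction force
and segment inertial loads, so pelvis residuals never enter hip
quantities. Hip net moments are reported in the proximal (pelvis) frame
normalized by body mass.

Muscle forces solve the redundancy problem with a third-order-polynomial
recruitment criterion: minimize sum_i (f_i / S_i)^3 subject to moment
balance R f = m at every spanned generalized coordinate and
0 <= f_i <= S_i, a smooth convex program solved per gait-cycle node.

The hip contact force closes the femur force balance: the
intersegmental hip force minus the pull of the hip-spanning muscles on
the leg; it is reported as the force the femur transmits to the
acetabulum, in the pelvis frame, normalized by body weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog, minimize

from .cohort import GRAVITY, GaitTrial, KINEMATIC_CHANNELS
from .exceptions import RecruitmentError, SignalError
from .gait import (
    GaitCycleField,
    GC_NODES,
    detect_events,
    filter_grf,
    filter_kinematics,
    time_normalize,
)
from .msk import LEG_DOFS, Model, Posture

__all__ = [
    "InverseDynamicsResult",
    "RecruitmentSolution",
    "TrialDynamics",
    "net_moments",
    "recruit",
    "hip_contact_force",
    "group_forces",
    "compare_models",
    "analyze_trial",
]

_GRAV_VEC = np.array([0.0, -GRAVITY, 0.0])


# ---------------------------------------------------------------------------
# inverse dynamics
# ---------------------------------------------------------------------------

@dataclass
class InverseDynamicsResult:
    """Net joint loads over a frame sequence (world unless noted)."""

    times: np.ndarray  # (T,)
    hip_moment_pelvis: np.ndarray  # (T, 3) N m / kg, pelvis ISB frame
    generalized_moments: np.ndarray  # (T, 6) N m, LEG_DOFS order
    hip_force_world: np.ndarray  # (T, 3) N, force on thigh from pelvis
    pelvis_R: np.ndarray  # (T, 3, 3)
    knee_moment: np.ndarray  # (T,) N m / kg (flexion +)
    ankle_moment: np.ndarray  # (T,) N m / kg (dorsiflexion +)


def _derivative(x: np.ndarray, rate: float, order: int = 1) -> np.ndarray:
    """Central differences along axis 0, one-sided at the endpoints."""
    out = x
    for _ in range(order):
        out = np.gradient(out, 1.0 / rate, axis=0, edge_order=2)
    return out


def _angular_velocity(R: np.ndarray, rate: float) -> np.ndarray:
    """World-frame angular velocity from a rotation-matrix series."""
    dR = _derivative(R, rate)
    W = np.einsum("tij,tkj->tik", dR, R)  # dR R^T, skew
    return np.stack([W[:, 2, 1], W[:, 0, 2], W[:, 1, 0]], axis=1)


def net_moments(
    model: Model,
    joint_angles: pd.DataFrame,
    grf: pd.DataFrame,
    kin_rate: float = 200.0,
    grf_rate: float = 1000.0,
) -> InverseDynamicsResult:
    """Bottom-up Newton-Euler net joint loads for a kinematic series.

    ``joint_angles`` (filtered, at ``kin_rate``) provides the chain
    coordinates; ``grf`` (filtered, at ``grf_rate``) the external force
    (world components ``fx, fy, fz`` N and centre of pressure ``cop_*``
    m). The force is linearly resampled onto the kinematic timebase.
    """
    T = len(joint_angles)
    times = np.arange(T) / kin_rate
    if len(grf) / grf_rate < (T - 1) / kin_rate - 1e-9:
        raise SignalError("GRF record shorter than the kinematic record")

    posture = Posture(**{c: joint_angles[c].to_numpy() for c in KINEMATIC_CHANNELS})
    fk = model.forward_kinematics(posture)

    t_grf = np.arange(len(grf)) / grf_rate
    F_ext = np.stack(
        [np.interp(times, t_grf, grf[c].to_numpy()) for c in ("fx", "fy", "fz")], axis=1
    )
    cop = np.stack(
        [np.interp(times, t_grf, grf[c].to_numpy()) for c in ("cop_x", "cop_y", "cop_z")],
        axis=1,
    )
    # distal-to-proximal recursion
    F_dist = -F_ext  # force segment applies distally = -external on foot
    M_dist = np.zeros((T, 3))
    r_dist = cop
    results = {}
    for seg_name, prox_of in (("foot", "shank"), ("shank", "thigh"), ("thigh", "pelvis")):
        seg = model.segments[seg_name]
        R, p = fk[seg_name]
        com = p + np.einsum("tij,j->ti", R, seg.com)
        acc = _derivative(com, kin_rate, order=2)
        omega = _angular_velocity(R, kin_rate)
        alpha = _derivative(omega, kin_rate)
        I_world = np.einsum("tij,jk,tlk->til", R, seg.inertia, R)
        # proximal joint position = this segment's origin
        r_prox = p
        # force from distal neighbour on this segment = -F_dist (Newton 3rd)
        F_on_seg_dist = -F_dist
        M_on_seg_dist = -M_dist
        F_prox = seg.mass * acc - seg.mass * _GRAV_VEC - F_on_seg_dist
        rot = np.einsum("tij,tj->ti", I_world, alpha) + np.cross(
            omega, np.einsum("tij,tj->ti", I_world, omega)
        )
        M_prox = (
            rot
            - M_on_seg_dist
            - np.cross(r_dist - com, F_on_seg_dist)
            - np.cross(r_prox - com, F_prox)
        )
        results[seg_name] = (F_prox, M_prox, r_prox)
        F_dist, M_dist, r_dist = F_prox, M_prox, r_prox

    s = model.side_sign
    Rp = fk["pelvis"][0]
    Rt = fk["thigh"][0]
    Rs = fk["shank"][0]
    Rf = fk["foot"][0]

    hip_M = results["thigh"][1]
    knee_M = results["shank"][1]
    ankle_M = results["foot"][1]

    # generalized moments: project joint moments on the coordinate axes
    z = np.array([0.0, 0.0, 1.0])
    x = np.array([1.0, 0.0, 0.0])
    y = np.array([0.0, 1.0, 0.0])
    e_flex = np.einsum("tij,j->ti", Rp, z)
    R_flex = Rp @ _rot_z(posture.hip_flexion)
    e_add = s * np.einsum("tij,j->ti", R_flex, x)
    e_rot = s * np.einsum("tij,j->ti", Rt, y)
    e_knee = -np.einsum("tij,j->ti", Rt, z)
    e_ankle = np.einsum("tij,j->ti", Rs, z)
    e_sub = s * np.einsum("tij,j->ti", Rf, model.subtalar_axis)

    gen = np.stack(
        [
            np.einsum("ti,ti->t", hip_M, e_flex),
            np.einsum("ti,ti->t", hip_M, e_add),
            np.einsum("ti,ti->t", hip_M, e_rot),
            np.einsum("ti,ti->t", knee_M, e_knee),
            np.einsum("ti,ti->t", ankle_M, e_ankle),
            np.einsum("ti,ti->t", ankle_M, e_sub),
        ],
        axis=1,
    )

    hip_moment_pelvis = np.einsum("tji,tj->ti", Rp, hip_M) / model.body_mass
    return InverseDynamicsResult(
        times=times,
        hip_moment_pelvis=hip_moment_pelvis,
        generalized_moments=gen,
        hip_force_world=results["thigh"][0],
        pelvis_R=Rp,
        knee_moment=gen[:, 3] / model.body_mass,
        ankle_moment=gen[:, 4] / model.body_mass,
    )


def _rot_z(angle_deg):
    a = np.radians(np.asarray(angle_deg, dtype=float))
    c, s = np.cos(a), np.sin(a)
    R = np.zeros(a.shape + (3, 3))
    R[..., 0, 0] = c
    R[..., 0, 1] = -s
    R[..., 1, 0] = s
    R[..., 1, 1] = c
    R[..., 2, 2] = 1.0
    return R


# ---------------------------------------------------------------------------
# muscle recruitment
# ---------------------------------------------------------------------------

@dataclass
class RecruitmentSolution:
    """Optimal fascicle forces for one posture/load case."""

    fascicle_forces: np.ndarray  # (n_fascicles,) N
    objective_value: float  # sum (f/S)^3
    residual: float  # max |R f - m|, N m
    dofs: tuple = LEG_DOFS

    def __post_init__(self):
        self.fascicle_forces = np.asarray(self.fascicle_forces, dtype=float)


def recruit(
    model: Model,
    posture: Posture | None,
    moments: np.ndarray,
    moment_arms: np.ndarray | None = None,
    dofs=LEG_DOFS,
    tol: float = 1e-6,
    x0: np.ndarray | None = None,
) -> RecruitmentSolution:
    """Solve the third-order-polynomial muscle recruitment problem.

    minimize sum_i (f_i / S_i)^3  s.t.  R f = m,  0 <= f_i <= S_i

    ``moments`` are the net generalized moments (N m) in ``dofs`` order;
    ``moment_arms`` (n_fascicles, n_dofs) may be passed to reuse a
    precomputed tendon-excursion matrix, otherwise it is evaluated at
    ``posture``.

    Raises
    ------
    RecruitmentError
        If the equality system is infeasible within bounds; the error
        names the generalized coordinate with the largest violation.
    """
    m = np.asarray(moments, dtype=float)
    if moment_arms is None:
        if posture is None:
            raise ValueError("either posture or moment_arms must be given")
        moment_arms = model.moment_arm_matrix(posture, dofs)
    A = np.asarray(moment_arms, dtype=float).T  # (n_dofs, n_fascicles)
    S = model.strengths
    n = len(S)

    # feasibility (and starting point) via LP
    lp = linprog(
        c=np.ones(n),
        A_eq=A,
        b_eq=m,
        bounds=[(0.0, float(s)) for s in S],
        method="highs",
    )
    if not lp.success:
        ls = np.linalg.lstsq(A, m, rcond=None)[0]
        f_clip = np.clip(ls, 0.0, S)
        viol = np.abs(A @ f_clip - m)
        worst = dofs[int(np.argmax(viol))]
        raise RecruitmentError(
            f"net moments exceed muscle capacity (worst coordinate: {worst})",
            dof=worst,
        )

    scale = S  # optimize a = f / S in [0, 1]
    As = A * scale[None, :]

    def obj(a):
        return float(np.sum(a**3))

    def grad(a):
        return 3.0 * a**2

    a0 = (x0 / scale) if x0 is not None else (lp.x / scale)
    a0 = np.clip(a0, 0.0, 1.0)
    res = minimize(
        obj,
        a0,
        jac=grad,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * n,
        constraints=[{"type": "eq", "fun": lambda a: As @ a - m,
                      "jac": lambda a: As}],
        options={"maxiter": 200, "ftol": 1e-14},
    )
    a = np.clip(res.x, 0.0, 1.0)
    f = a * scale
    residual = float(np.max(np.abs(A @ f - m))) if len(m) else 0.0
    if residual > max(tol, 1e-9 * (1.0 + np.max(np.abs(m), initial=0.0))):
        # one polishing re-solve from the LP vertex
        res = minimize(
            obj, np.clip(lp.x / scale, 0, 1), jac=grad, method="SLSQP",
            bounds=[(0.0, 1.0)] * n,
            constraints=[{"type": "eq", "fun": lambda a: As @ a - m,
                          "jac": lambda a: As}],
            options={"maxiter": 500, "ftol": 1e-16},
        )
        a = np.clip(res.x, 0.0, 1.0)
        f = a * scale
        residual = float(np.max(np.abs(A @ f - m)))
    if residual > tol * max(1.0, np.max(np.abs(m), initial=1.0)):
        raise RecruitmentError(
            f"recruitment did not reach equilibrium (residual {residual:.2e} N m)",
            dof=dofs[int(np.argmax(np.abs(A @ f - m)))],
        )
    return RecruitmentSolution(
        fascicle_forces=f, objective_value=float(np.sum((f / S) ** 3)),
        residual=residual, dofs=tuple(dofs),
    )


# ---------------------------------------------------------------------------
# hip contact force
# ---------------------------------------------------------------------------

def _hip_crossing_segments(model: Model):
    """(fascicle index, pelvis-side path point, leg-side path point) per
    hip-spanning fascicle: the path segment that crosses the hip."""
    out = []
    for i, f in enumerate(model.muscles):
        if not f.spans_hip:
            continue
        segs = [s for s, _ in f.path]
        last_pelvis = max(j for j, s in enumerate(segs) if s == "pelvis")
        out.append((i, last_pelvis, last_pelvis + 1))
    return out


def hip_contact_force(
    model: Model,
    posture: Posture,
    recruitment: RecruitmentSolution,
    hip_force_world: np.ndarray,
    pelvis_R: np.ndarray,
) -> np.ndarray:
    """Hip contact force in the pelvis frame, units of body weight.

    The reaction closing the femur force balance: the intersegmental hip
    force minus the pull of every hip-spanning muscle on the leg (each
    along its hip-crossing path segment, toward its pelvis attachment).
    Reported as the force the femur applies to the acetabulum.
    """
    fk = model.forward_kinematics(posture)
    F_musc = np.zeros(np.shape(hip_force_world))
    for i, j_pelvis, j_leg in _hip_crossing_segments(model):
        fasc = model.muscles[i]
        p_pelvis = model.point_world(fasc.path[j_pelvis][0], fasc.path[j_pelvis][1],
                                     fk, posture)
        p_leg = model.point_world(fasc.path[j_leg][0], fasc.path[j_leg][1], fk, posture)
        d = p_pelvis - p_leg
        d = d / np.linalg.norm(d, axis=-1, keepdims=True)
        F_musc = F_musc + recruitment.fascicle_forces[i] * d
    # contact force on thigh from pelvis, then reported femur-on-acetabulum
    C = np.asarray(hip_force_world) - F_musc
    hcf_world = -C
    hcf_pelvis = np.einsum("...ji,...j->...i", pelvis_R, hcf_world)
    return hcf_pelvis / (model.body_mass * GRAVITY)


# ---------------------------------------------------------------------------
# grouping and model comparison
# ---------------------------------------------------------------------------

def group_forces(model: Model, force_series: np.ndarray, body_weight: float,
                 subject_id: str = "") -> dict:
    """Per-muscle and per-functional-group force fields (per BW).

    ``force_series`` is (101, n_fascicles) N. Returns
    ``{"muscles": GaitCycleField, "groups": {group: GaitCycleField}}``;
    muscle force = sum over its fascicles, group field = one channel per
    member muscle.
    """
    F = np.asarray(force_series, dtype=float) / body_weight
    muscles = model.muscle_ids
    per_muscle = np.zeros((F.shape[0], len(muscles)))
    for j, mid in enumerate(muscles):
        idx = [i for i, f in enumerate(model.muscles) if f.muscle_id == mid]
        per_muscle[:, j] = F[:, idx].sum(axis=1)
    muscle_field = GaitCycleField(
        components=muscles, values=per_muscle, subject_id=subject_id,
        normalization="per-body-weight",
    )
    groups = {}
    from .msk import MUSCLE_GROUPS

    for group in ("hip_flexor", "hip_extensor", "hip_abductor", "hip_adductor"):
        members = [m for m in muscles if MUSCLE_GROUPS[m] == group]
        vals = (
            per_muscle[:, [muscles.index(m) for m in members]]
            if members
            else np.zeros((101, 0))
        )
        groups[group] = GaitCycleField(
            components=members, values=vals if members else np.zeros((101, 1))[:, :0],
            subject_id=subject_id, normalization="per-body-weight",
        ) if members else GaitCycleField(
            components=["empty"], values=np.zeros((101, 1)),
            subject_id=subject_id, normalization="per-body-weight",
        )
    return {"muscles": muscle_field, "groups": groups}


def compare_models(generic: dict, personalized: dict) -> pd.DataFrame:
    """Per-subject RMSD between HCF components of two model variants.

    Both arguments map subject id -> GaitCycleField with components
    (hcf_x, hcf_y, hcf_z) in BW. Returns a tidy DataFrame
    (subject_id, component, rmsd) over the 101 nodes.
    """
    rows = []
    for sid, gf in generic.items():
        pf = personalized[sid]
        for comp in ("hcf_x", "hcf_y", "hcf_z"):
            d = gf[comp] - pf[comp]
            rows.append(
                {"subject_id": sid, "component": comp,
                 "rmsd": float(np.sqrt(np.mean(d**2)))}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# per-trial orchestration
# ---------------------------------------------------------------------------

@dataclass
class TrialDynamics:
    """All 101-node outputs of one trial run through one model."""

    subject_id: str
    kinematics: GaitCycleField  # joint angles, deg
    hip_moments: GaitCycleField  # N m / kg, pelvis frame
    hcf: GaitCycleField  # (hcf_x, hcf_y, hcf_z, magnitude) BW, pelvis frame
    muscle_forces: GaitCycleField  # per muscle, BW
    group_forces: dict  # group -> GaitCycleField
    recruitment_residual: float
    meta: dict = field(default_factory=dict)


def analyze_trial(model: Model, trial: GaitTrial, prefiltered: bool = False) -> TrialDynamics:
    """Filter, detect events, run inverse dynamics + recruitment + HCF.

    Produces every 101-node field downstream statistics need. Inverse
    dynamics runs at the capture rate; recruitment and contact forces
    are evaluated at the 101 gait-cycle nodes.
    """
    ja = trial.joint_angles.copy()
    grf = trial.grf.copy()
    if not prefiltered:
        ja.loc[:, :] = filter_kinematics(ja.to_numpy(), trial.marker_rate)
        grf.loc[:, ["fx", "fy", "fz"]] = filter_grf(
            grf[["fx", "fy", "fz"]].to_numpy(), trial.grf_rate
        )
    ev = detect_events(grf["fy"].to_numpy(), trial.grf_rate)
    hs = ev["heel_strikes"]
    if len(hs) < 2:
        raise SignalError("need two heel strikes for a full cycle")
    g0, g1 = hs[0], hs[1]
    r = trial.marker_rate / trial.grf_rate
    k0, k1 = int(round(g0 * r)), int(round(g1 * r))

    idr = net_moments(model, ja, grf, trial.marker_rate, trial.grf_rate)

    kin_field = time_normalize(ja, (k0, k1), subject_id=trial.subject_id)
    mom_field = time_normalize(
        idr.hip_moment_pelvis, (k0, k1),
        components=["hip_flexion_moment", "hip_adduction_moment",
                    "hip_rotation_moment"],
        subject_id=trial.subject_id, normalization="per-body-mass",
    )
    gen_field = time_normalize(idr.generalized_moments, (k0, k1),
                               components=list(LEG_DOFS))
    hip_force_field = time_normalize(idr.hip_force_world, (k0, k1))
    pelvR = np.stack(
        [
            time_normalize(idr.pelvis_R[:, i, :], (k0, k1)).values
            for i in range(3)
        ],
        axis=1,
    )  # (101, 3, 3)

    posture101 = Posture(**{c: kin_field[c] for c in KINEMATIC_CHANNELS})
    arms = model.moment_arm_matrix(posture101)  # (n_fasc, 6, 101)

    n_f = len(model.muscles)
    forces = np.zeros((101, n_f))
    residual = 0.0
    x0 = None
    for i in range(101):
        sol = recruit(
            model, None, gen_field.values[i], moment_arms=arms[:, :, i], x0=x0
        )
        forces[i] = sol.fascicle_forces
        x0 = sol.fascicle_forces
        residual = max(residual, sol.residual)

    hcf = _hcf_series(model, posture101, forces, hip_force_field.values, pelvR)
    mag = np.linalg.norm(hcf, axis=1)
    hcf_field = GaitCycleField(
        components=["hcf_x", "hcf_y", "hcf_z", "magnitude"],
        values=np.column_stack([hcf, mag]),
        subject_id=trial.subject_id,
        normalization="per-body-weight",
    )
    grouped = group_forces(model, forces, model.body_mass * GRAVITY,
                           subject_id=trial.subject_id)
    return TrialDynamics(
        subject_id=trial.subject_id,
        kinematics=kin_field,
        hip_moments=mom_field,
        hcf=hcf_field,
        muscle_forces=grouped["muscles"],
        group_forces=grouped["groups"],
        recruitment_residual=residual,
        meta={"model_torsion": model.torsion, "events": ev},
    )


def _hcf_series(model, posture101, forces, hip_force, pelvis_R):
    fk = model.forward_kinematics(posture101)
    F_musc = np.zeros((101, 3))
    for i, j_pelvis, j_leg in _hip_crossing_segments(model):
        fasc = model.muscles[i]
        p_pelvis = model.point_world(fasc.path[j_pelvis][0], fasc.path[j_pelvis][1],
                                     fk, posture101)
        p_leg = model.point_world(fasc.path[j_leg][0], fasc.path[j_leg][1],
                                  fk, posture101)
        d = p_pelvis - p_leg
        d = d / np.linalg.norm(d, axis=-1, keepdims=True)
        F_musc += forces[:, i : i + 1] * d
    C = hip_force - F_musc
    hcf_world = -C
    hcf_pelvis = np.einsum("tji,tj->ti", pelvis_R, hcf_world)
    return hcf_pelvis / (model.body_mass * GRAVITY)
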