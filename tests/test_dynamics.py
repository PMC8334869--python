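"""Inverse dynamics, cubic recruitment, and hip contact forces."""

import copy
import dataclasses
import types

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from torsiongait.cohort import (
    EffectSpec,
    GRAVITY,
    KINEMATIC_CHANNELS,
    Subject,
    generate_trial,
)
from torsiongait.dynamics import (
    RecruitmentSolution,
    analyze_trial,
    compare_models,
    group_forces,
    hip_contact_force,
    net_moments,
    recruit,
)
from torsiongait.exceptions import RecruitmentError
from torsiongait.femur import generate_template_femur
from torsiongait.gait import GaitCycleField
from torsiongait.msk import LEG_DOFS, Posture, build_model


def massless(model):
    m = copy.deepcopy(model)
    for seg in m.segments.values():
        seg.mass = 1e-9
        seg.inertia = np.eye(3) * 1e-12
    return m


def static_frames(posture: Posture, T=60, rate=200.0):
    data = {c: np.full(T, float(getattr(posture, c))) for c in KINEMATIC_CHANNELS}
    return pd.DataFrame(data)


def constant_grf(F, cop, T_kin=60, kin_rate=200.0, grf_rate=1000.0):
    T = int(T_kin / kin_rate * grf_rate) + 5
    return pd.DataFrame(
        {
            "fx": np.full(T, F[0]), "fy": np.full(T, F[1]), "fz": np.full(T, F[2]),
            "cop_x": np.full(T, cop[0]), "cop_y": np.full(T, cop[1]),
            "cop_z": np.full(T, cop[2]),
        }
    )


# ---------------------------------------------------------------------------
# inverse dynamics statics oracles
# ---------------------------------------------------------------------------

class TestNetMoments:
    def test_zero_grf_massless_chain_gives_zero_moments(self, baseline_model):
        model = massless(baseline_model)
        ja = static_frames(Posture(hip_flexion=12.0, knee_flexion=8.0))
        grf = constant_grf([0, 0, 0], [0, 0, 0])
        idr = net_moments(model, ja, grf)
        mid = slice(10, 50)
        assert np.abs(idr.hip_moment_pelvis[mid]).max() < 1e-9
        assert np.abs(idr.generalized_moments[mid]).max() < 1e-6

    def test_static_lateral_grf_offset_gives_frontal_moment(self, baseline_model):
        """Vertical force through a point offset laterally from the hip:
        the frontal-plane hip moment equals force x lever / mass."""
        model = massless(baseline_model)
        posture = Posture()
        fk = model.forward_kinematics(posture)
        hip = fk["thigh"][1]
        d = 0.07  # m lateral offset
        F = 700.0
        ja = static_frames(posture)
        grf = constant_grf([0, F, 0], [hip[0], 0.0, hip[2] + d])
        idr = net_moments(model, ja, grf)
        mid = slice(10, 50)
        # external moment about the hip: (cop - hip) x F = (-F d, 0, 0);
        # the reported internal net moment balances it
        expected = np.array([F * d, 0.0, 0.0]) / model.body_mass
        assert np.allclose(idr.hip_moment_pelvis[mid], expected, atol=1e-9)

    def test_cop_shift_propagates_as_pure_couple(self, baseline_model):
        """Shifting the centre of pressure by delta changes the hip moment
        by exactly delta x F (a couple traverses the massless chain)."""
        model = massless(baseline_model)
        posture = Posture(hip_flexion=5.0)
        ja = static_frames(posture)
        F = np.array([40.0, 650.0, 10.0])
        cop0 = np.array([0.1, 0.0, 0.05])
        delta = np.array([0.04, 0.0, -0.03])
        m0 = net_moments(model, ja, constant_grf(F, cop0)).hip_moment_pelvis
        m1 = net_moments(model, ja, constant_grf(F, cop0 + delta)).hip_moment_pelvis
        expected = -np.cross(delta, F) / model.body_mass  # internal moment
        mid = slice(10, 50)
        assert np.allclose((m1 - m0)[mid], expected, atol=1e-9)

    def test_moments_reported_per_body_mass(self, baseline_model):
        model = massless(baseline_model)
        posture = Posture()
        ja = static_frames(posture)
        grf = constant_grf([0.0, 500.0, 0.0], [0.3, 0.0, 0.0])
        idr = net_moments(model, ja, grf)
        heavier = dataclasses.replace(model, body_mass=2 * model.body_mass)
        idr2 = net_moments(heavier, ja, grf)
        assert np.allclose(idr2.hip_moment_pelvis, idr.hip_moment_pelvis / 2)


# ---------------------------------------------------------------------------
# recruitment
# ---------------------------------------------------------------------------

def stub_model(strengths):
    return types.SimpleNamespace(strengths=np.asarray(strengths, dtype=float))


class TestRecruitment:
    def test_zero_moments_zero_forces(self):
        A = np.array([[0.05], [0.04]])  # (n_fascicles, n_dofs)
        sol = recruit(stub_model([1000.0, 800.0]), None, [0.0], moment_arms=A,
                      dofs=("d0",))
        assert np.allclose(sol.fascicle_forces, 0.0, atol=1e-8)
        assert sol.objective_value == pytest.approx(0.0, abs=1e-12)

    def test_identical_muscles_share_equally(self):
        r, S, m = 0.05, 1000.0, 40.0
        A = np.array([[r], [r]])
        sol = recruit(stub_model([S, S]), None, [m], moment_arms=A, dofs=("d0",))
        assert np.allclose(sol.fascicle_forces, m / (2 * r), rtol=1e-6)

    def test_cubic_criterion_strength_ratio_closed_form(self):
        """Two muscles, equal arms, S1 = 2 S2: stationarity of the cubic
        criterion gives f1/f2 = (S1/S2)^(3/2) = 2 sqrt(2)."""
        r, S2, m = 0.05, 500.0, 20.0
        S1 = 2 * S2
        sol = recruit(stub_model([S1, S2]), None, [m],
                      moment_arms=np.array([[r], [r]]), dofs=("d0",))
        f1, f2 = sol.fascicle_forces
        assert f1 / f2 == pytest.approx(2 * np.sqrt(2), abs=1e-9)
        # and the equilibrium is satisfied exactly
        assert r * (f1 + f2) == pytest.approx(m, abs=1e-9)

    def test_matches_independent_interior_point_resolve(self, rng):
        """Random feasible instances: the returned optimum matches an
        independent trust-region re-solve to 1e-8 in the objective."""
        for _ in range(20):
            n = int(rng.integers(2, 7))
            d = int(rng.integers(1, min(3, n) + 1))
            A = rng.uniform(-0.06, 0.06, size=(n, d))
            S = rng.uniform(300, 3000, size=n)
            f_true = rng.uniform(0, 0.5) * S * rng.uniform(0, 1, size=n)
            m = A.T @ f_true  # feasible by construction
            sol = recruit(stub_model(S), None, m, moment_arms=A,
                          dofs=tuple(f"d{i}" for i in range(d)))
            ref = minimize(
                lambda f: np.sum((f / S) ** 3), np.clip(f_true, 1e-6, None),
                jac=lambda f: 3 * f**2 / S**3,
                method="trust-constr",
                bounds=[(0, s) for s in S],
                constraints=[{"type": "eq", "fun": lambda f: A.T @ f - m}],
                options={"gtol": 1e-12, "xtol": 1e-14},
            )
            assert sol.objective_value <= ref.fun + 1e-8

    def test_infeasible_names_violated_dof(self):
        A = np.array([[0.05], [0.03]])
        with pytest.raises(RecruitmentError) as err:
            recruit(stub_model([100.0, 100.0]), None, [50.0], moment_arms=A,
                    dofs=("hip_flexion",))
        assert err.value.dof == "hip_flexion"

    def test_solution_invariants(self, rng):
        A = rng.uniform(-0.05, 0.05, size=(5, 2))
        S = np.full(5, 1500.0)
        m = A.T @ (0.3 * S)
        sol = recruit(stub_model(S), None, m, moment_arms=A, dofs=("a", "b"))
        assert (sol.fascicle_forces >= -1e-12).all()
        assert (sol.fascicle_forces <= S + 1e-9).all()
        assert sol.residual <= 1e-6 * max(1.0, np.abs(m).max())
        assert sol.objective_value == pytest.approx(
            float(np.sum((sol.fascicle_forces / S) ** 3)), rel=1e-12
        )


# ---------------------------------------------------------------------------
# hip contact force
# ---------------------------------------------------------------------------

class TestHipContactForce:
    def test_no_muscle_forces_gives_intersegmental_resultant(self, baseline_model):
        n = len(baseline_model.muscles)
        rec = RecruitmentSolution(np.zeros(n), 0.0, 0.0)
        F_hip = np.array([30.0, -700.0, 10.0])
        hcf = hip_contact_force(baseline_model, Posture(), rec, F_hip, np.eye(3))
        bw = baseline_model.body_mass * GRAVITY
        assert np.allclose(hcf, -F_hip / bw, atol=1e-12)

    def test_single_muscle_hand_computation(self, baseline_model):
        model = baseline_model
        idx = [i for i, f in enumerate(model.muscles)
               if f.fascicle_id == "glut_med_2"][0]
        forces = np.zeros(len(model.muscles))
        forces[idx] = 500.0
        rec = RecruitmentSolution(forces, 0.0, 0.0)
        posture = Posture()
        fk = model.forward_kinematics(posture)
        fasc = model.muscles[idx]
        p_orig = model.point_world("pelvis", fasc.path[0][1], fk)
        p_ins = model.point_world("thigh", fasc.path[1][1], fk)
        pull = 500.0 * (p_orig - p_ins) / np.linalg.norm(p_orig - p_ins)
        bw = model.body_mass * GRAVITY
        hcf = hip_contact_force(model, posture, rec, np.zeros(3), np.eye(3))
        assert np.allclose(hcf, pull / bw, atol=1e-12)

    def test_compressive_muscle_increases_magnitude(self, baseline_model):
        model = baseline_model
        F_hip = np.array([0.0, -700.0, 0.0])  # stance-like downward reaction
        n = len(model.muscles)
        rec0 = RecruitmentSolution(np.zeros(n), 0.0, 0.0)
        forces = np.zeros(n)
        idx = [i for i, f in enumerate(model.muscles)
               if f.fascicle_id == "glut_med_2"][0]
        forces[idx] = 800.0  # pulls the femur up into the joint
        rec1 = RecruitmentSolution(forces, 0.0, 0.0)
        h0 = hip_contact_force(model, Posture(), rec0, F_hip, np.eye(3))
        h1 = hip_contact_force(model, Posture(), rec1, F_hip, np.eye(3))
        assert np.linalg.norm(h1) > np.linalg.norm(h0)


# ---------------------------------------------------------------------------
# grouping and model comparison
# ---------------------------------------------------------------------------

class TestGroupingAndComparison:
    def test_muscle_force_is_fascicle_sum(self, baseline_model, rng):
        F = rng.uniform(0, 800, size=(101, len(baseline_model.muscles)))
        out = group_forces(baseline_model, F, body_weight=700.0)
        glut_idx = [i for i, f in enumerate(baseline_model.muscles)
                    if f.muscle_id == "glut_med"]
        manual = F[:, glut_idx].sum(axis=1) / 700.0
        assert np.allclose(out["muscles"]["glut_med"], manual)

    def test_group_totals_match_direct_summation(self, baseline_model, rng):
        from torsiongait.msk import MUSCLE_GROUPS

        F = rng.uniform(0, 500, size=(101, len(baseline_model.muscles)))
        out = group_forces(baseline_model, F, body_weight=700.0)
        for g in ("hip_flexor", "hip_extensor", "hip_abductor", "hip_adductor"):
            idx = [i for i, f in enumerate(baseline_model.muscles)
                   if MUSCLE_GROUPS[f.muscle_id] == g]
            manual = F[:, idx].sum(axis=1) / 700.0
            assert np.allclose(out["groups"][g].values.sum(axis=1), manual)

    def test_rmsd_identity_and_offset(self):
        vals = np.random.default_rng(0).normal(size=(101, 3))
        f = GaitCycleField(components=["hcf_x", "hcf_y", "hcf_z"], values=vals)
        g = GaitCycleField(components=["hcf_x", "hcf_y", "hcf_z"],
                           values=vals + np.array([0.25, 0.0, -0.1]))
        out = compare_models({"s": f}, {"s": f})
        assert np.allclose(out["rmsd"], 0.0)
        out = compare_models({"s": f}, {"s": g})
        by = dict(zip(out["component"], out["rmsd"]))
        assert by["hcf_x"] == pytest.approx(0.25, abs=1e-12)
        assert by["hcf_y"] == pytest.approx(0.0, abs=1e-12)
        assert by["hcf_z"] == pytest.approx(0.1, abs=1e-12)


# ---------------------------------------------------------------------------
# whole-trial pipeline properties
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def trial_run():
    sub = Subject(id="D", mass=72.0, height=1.74, sex="M", side="R",
                  torsion=18.0, hjc_distance=172.0, walking_speed=5.1)
    trial = generate_trial(sub, EffectSpec(), seed=21)
    model = build_model(sub, generate_template_femur(18.0, "R"))
    return sub, trial, model, analyze_trial(model, trial)


class TestTrialPipeline:
    def test_equilibrium_residual(self, trial_run):
        *_, td = trial_run
        assert td.recruitment_residual < 1e-6

    def test_hcf_magnitude_is_norm_of_vector(self, trial_run):
        *_, td = trial_run
        v = td.hcf.values
        assert np.allclose(v[:, 3], np.linalg.norm(v[:, :3], axis=1), atol=1e-12)

    def test_physiological_hcf_range(self, trial_run):
        *_, td = trial_run
        peak = td.hcf["magnitude"].max()
        assert 2.0 < peak < 10.0  # BW, walking

    def test_mass_scaling_invariance(self, trial_run):
        """Doubling body mass (with BW-scaled forces and strengths) leaves
        per-mass moments and per-BW HCF invariant (model linearity).

        Compared frame-by-frame at fixed samples: the absolute 20 N event
        threshold would otherwise shift the cycle window by a few ms.
        """
        sub, trial, model, td = trial_run
        sub2 = dataclasses.replace(sub, id="D2", mass=2 * sub.mass)
        trial2 = generate_trial(sub2, EffectSpec(), seed=21)
        model2 = build_model(sub2, generate_template_femur(18.0, "R"))
        model2.muscles = [
            dataclasses.replace(m, strength=2 * m.strength) for m in model2.muscles
        ]
        idr = net_moments(model, trial.joint_angles, trial.grf)
        idr2 = net_moments(model2, trial2.joint_angles, trial2.grf)
        assert np.allclose(idr2.hip_moment_pelvis, idr.hip_moment_pelvis,
                           atol=1e-9)
        assert np.allclose(idr2.generalized_moments,
                           2 * idr.generalized_moments, atol=1e-6)

        # recruitment + HCF at a mid-stance frame
        i = (trial.cycle_kin[0] + trial.cycle_kin[1]) // 2
        posture = Posture(**{c: float(trial.joint_angles[c].iloc[i])
                             for c in KINEMATIC_CHANNELS})
        arms = model.moment_arm_matrix(posture)
        sol = recruit(model, None, idr.generalized_moments[i], moment_arms=arms)
        sol2 = recruit(model2, None, idr2.generalized_moments[i], moment_arms=arms)
        assert np.allclose(sol2.fascicle_forces, 2 * sol.fascicle_forces,
                           rtol=1e-5, atol=1e-3)
        h = hip_contact_force(model, posture, sol, idr.hip_force_world[i],
                              idr.pelvis_R[i])
        h2 = hip_contact_force(model2, posture, sol2, idr2.hip_force_world[i],
                               idr2.pelvis_R[i])
        assert np.allclose(h, h2, atol=1e-6)
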