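"""Musculoskeletal model: scaling, kinematics, moment arms, sweeps."""

import numpy as np
import pytest

from torsiongait.cohort import Subject
from torsiongait.femur import generate_template_femur, morph_to_torsion
from torsiongait.msk import (
    HIP_DOFS,
    LEG_DOFS,
    Posture,
    build_model,
    lever_arm_sweep,
    moment_arm,
    moment_arm_matrix,
)


def make_subject(**kw):
    base = dict(id="S", mass=75.0, height=1.75, sex="M", side="R",
                torsion=5.5, hjc_distance=170.0, walking_speed=5.2)
    base.update(kw)
    return Subject(**base)


# ---------------------------------------------------------------------------
# build & scaling
# ---------------------------------------------------------------------------

class TestBuild:
    def test_identity_scaling_at_template_anthropometrics(self, baseline_model):
        assert baseline_model.scale_factors["height"] == pytest.approx(1.0)
        assert baseline_model.scale_factors["pelvis_width"] == pytest.approx(1.0)

    def test_hjc_distance_drives_pelvis_width_only(self):
        a = build_model(make_subject(), generate_template_femur(5.5))
        b = build_model(make_subject(hjc_distance=190.0), generate_template_femur(5.5))
        assert b.hip_local[2] == pytest.approx(0.095)
        assert a.knee_local[1] == b.knee_local[1]  # thigh length unchanged
        # non-pelvis attachment points identical
        for fa, fb in zip(a.muscles, b.muscles):
            for (sa, pa), (sb, pb) in zip(fa.path, fb.path):
                if sa != "pelvis":
                    assert np.allclose(pa, pb)

    def test_side_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_model(make_subject(side="L"), generate_template_femur(5.5, "R"))

    def test_morphed_femur_moves_proximal_attachments_only(self):
        sub = make_subject()
        a = build_model(sub, generate_template_femur(5.5))
        b = build_model(sub, generate_template_femur(45.0))
        moved, fixed = [], []
        for fa, fb in zip(a.muscles, b.muscles):
            for (sa, pa), (sb, pb) in zip(fa.path, fb.path):
                d = np.linalg.norm(pa - pb)
                if sa == "thigh":
                    (moved if d > 1e-9 else fixed).append(fa.fascicle_id)
        assert "vastus_1" in fixed and "gastroc_1" in fixed  # distal femur
        assert any(f.startswith("glut_med") for f in moved)  # trochanter
        # pelvis/shank/foot points never move
        for fa, fb in zip(a.muscles, b.muscles):
            for (sa, pa), (sb, pb) in zip(fa.path, fb.path):
                if sa in ("pelvis", "shank", "foot"):
                    assert np.allclose(pa, pb)

    def test_segment_mass_fractions(self, baseline_model):
        total = sum(s.mass for s in baseline_model.segments.values())
        assert total == pytest.approx(75.0 * (0.142 + 0.100 + 0.0465 + 0.0145))


# ---------------------------------------------------------------------------
# forward kinematics
# ---------------------------------------------------------------------------

class TestForwardKinematics:
    def test_neutral_hip_knee_distance(self, baseline_model):
        fk = baseline_model.forward_kinematics(Posture())
        d = np.linalg.norm(fk["shank"][1] - fk["thigh"][1])
        assert d == pytest.approx(0.245 * 1.75, abs=1e-12)

    def test_pure_pelvis_translation_is_equivariant(self, baseline_model):
        p0 = Posture(hip_flexion=20.0, knee_flexion=30.0)
        p1 = p0.replace(pelvis_tx=1.5, pelvis_ty=1.2, pelvis_tz=-0.3)
        fk0 = baseline_model.forward_kinematics(p0)
        fk1 = baseline_model.forward_kinematics(p1)
        shift = np.array([1.5, 1.2 - 0.95, -0.3])
        for seg in ("pelvis", "thigh", "shank", "foot"):
            assert np.allclose(fk1[seg][1], fk0[seg][1] + shift, atol=1e-12)
            assert np.allclose(fk1[seg][0], fk0[seg][0], atol=1e-12)

    def test_hip_flexion_90_puts_knee_anterior(self, baseline_model):
        fk = baseline_model.forward_kinematics(Posture(hip_flexion=90.0))
        knee = fk["shank"][1]
        hip = fk["thigh"][1]
        assert knee[0] - hip[0] == pytest.approx(0.245 * 1.75, abs=1e-9)
        assert abs(knee[1] - hip[1]) < 1e-9

    def test_vectorized_fk_matches_scalar(self, baseline_model, rng):
        angles = rng.uniform(-20, 40, size=(7,))
        p_arr = Posture(hip_flexion=angles, pelvis_ty=np.full(7, 0.95))
        fk_arr = baseline_model.forward_kinematics(p_arr)
        for i, a in enumerate(angles):
            fk_i = baseline_model.forward_kinematics(Posture(hip_flexion=float(a)))
            for seg in ("thigh", "foot"):
                assert np.allclose(fk_arr[seg][1][i], fk_i[seg][1], atol=1e-12)


# ---------------------------------------------------------------------------
# muscle lengths & moment arms
# ---------------------------------------------------------------------------

def straight_hip_fascicles(model):
    return [
        f for f in model.muscles
        if len(f.path) == 2 and f.path[0][0] == "pelvis" and f.path[1][0] == "thigh"
    ]


def hip_axis(model, posture, dof):
    """Instantaneous generalized-coordinate axis through the hip centre."""
    fk = model.forward_kinematics(posture)
    Rp, pp = fk["pelvis"]
    s = model.side_sign
    if dof == "hip_flexion":
        e = Rp @ np.array([0.0, 0.0, 1.0])
    elif dof == "hip_adduction":
        from torsiongait.msk import _rot

        e = s * (Rp @ _rot(2, posture.hip_flexion) @ np.array([1.0, 0.0, 0.0]))
    else:
        e = s * (fk["thigh"][0] @ np.array([0.0, 1.0, 0.0]))
    hjc = fk["thigh"][1]
    return e, hjc, fk


class TestMomentArms:
    def test_cross_product_oracle_for_straight_paths(self, baseline_model, rng):
        """Tendon-excursion arms equal r x f projected on the coordinate
        axis, for every straight pelvis->femur fascicle and hip DOF."""
        model = baseline_model
        for _ in range(25):
            posture = Posture(
                hip_flexion=rng.uniform(-20, 90),
                hip_adduction=rng.uniform(-30, 30),
                hip_rotation=rng.uniform(-30, 30),
            )
            for fasc in straight_hip_fascicles(model):
                for dof in HIP_DOFS:
                    e, hjc, fk = hip_axis(model, posture, dof)
                    p_orig = model.point_world("pelvis", fasc.path[0][1], fk)
                    p_ins = model.point_world("thigh", fasc.path[1][1], fk)
                    f_hat = (p_orig - p_ins) / np.linalg.norm(p_orig - p_ins)
                    oracle = float(e @ np.cross(p_ins - hjc, f_hat))
                    tendon = model.moment_arm(fasc, posture, dof)
                    assert tendon == pytest.approx(oracle, abs=1e-6)

    def test_unspanned_dof_gives_zero(self, baseline_model):
        soleus = [f for f in baseline_model.muscles if f.muscle_id == "soleus"][0]
        for dof in HIP_DOFS + ("knee_flexion",):
            assert baseline_model.moment_arm(soleus, Posture(), dof) == pytest.approx(
                0.0, abs=1e-12
            )

    def test_invariance_under_whole_model_rigid_motion(self, baseline_model):
        p0 = Posture(hip_flexion=30.0, knee_flexion=20.0)
        p1 = p0.replace(pelvis_tx=2.0, pelvis_tilt=25.0, pelvis_rotation=-40.0)
        fasc = [f for f in baseline_model.muscles if f.fascicle_id == "glut_med_1"][0]
        for dof in LEG_DOFS:
            a0 = baseline_model.moment_arm(fasc, p0, dof)
            a1 = baseline_model.moment_arm(fasc, p1, dof)
            assert a1 == pytest.approx(a0, abs=1e-9)

    def test_virtual_work_consistency(self, baseline_model, rng):
        """sum_i (-dL_i/dq) f_i equals the generalized muscle torque for
        random force vectors (the recruitment matrix is the transpose)."""
        posture = Posture(hip_flexion=15.0, knee_flexion=25.0,
                          ankle_dorsiflexion=5.0)
        R = moment_arm_matrix(baseline_model, posture)
        f = rng.uniform(0, 500, size=R.shape[0])
        tau = R.T @ f
        for j, dof in enumerate(LEG_DOFS):
            manual = sum(
                baseline_model.moment_arm(m, posture, dof) * fi
                for m, fi in zip(baseline_model.muscles, f)
            )
            assert tau[j] == pytest.approx(manual, abs=1e-9)


# ---------------------------------------------------------------------------
# lever-arm sweeps (torsion configurations)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def torsion_models():
    sub = make_subject()
    return {
        label: build_model(sub, generate_template_femur(t))
        for label, t in [("-15", -15.0), ("baseline", 5.5), ("+25", 25.0),
                         ("+45", 45.0)]
    }


class TestLeverArmSweep:
    def test_grid_point_count(self, torsion_models):
        df = lever_arm_sweep(
            {"baseline": torsion_models["baseline"]},
            {"hip_flexion": (-20.0, 90.0)},
        )
        one = df[(df.muscle == "glut_med") & (df.dof == "hip_flexion")]
        assert len(one) == 111

    def test_abductor_lever_arm_drops_with_antetorsion_and_recovers_with_internal_rotation(
        self, torsion_models
    ):
        def mean_abduction_arm(model, posture):
            arms = [
                -model.moment_arm(m, posture, "hip_adduction")
                for m in model.muscles
                if m.muscle_id in ("glut_med", "glut_min")
            ]
            return float(np.mean(arms))

        neutral = Posture()
        a_base = mean_abduction_arm(torsion_models["baseline"], neutral)
        a_25 = mean_abduction_arm(torsion_models["+25"], neutral)
        a_45 = mean_abduction_arm(torsion_models["+45"], neutral)
        a_45_ir = mean_abduction_arm(torsion_models["+45"], Posture(hip_rotation=20.0))
        assert a_base > a_25 > a_45
        assert a_45_ir >= a_45

    def test_adductor_arms_insensitive_to_torsion(self, torsion_models):
        neutral = Posture()
        means = []
        for model in torsion_models.values():
            arms = [
                model.moment_arm(m, neutral, "hip_adduction")
                for m in model.muscles
                if m.group == "hip_adductor"
            ]
            means.append(np.mean(arms))
        assert max(means) - min(means) < 0.002  # < 2 mm across configurations

    def test_sweep_averages_fascicles(self, torsion_models):
        model = torsion_models["baseline"]
        df = lever_arm_sweep({"b": model}, {"hip_adduction": (-10.0, 10.0)},
                             grid_step=10.0)
        row = df[(df.muscle == "glut_med") & (df.angle == 0.0)]
        manual = np.mean(
            [model.moment_arm(m, Posture(), "hip_adduction")
             for m in model.muscles if m.muscle_id == "glut_med"]
        )
        assert row["lever_arm"].iloc[0] == pytest.approx(manual, abs=1e-9)
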