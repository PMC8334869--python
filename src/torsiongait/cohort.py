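"""Synthetic cohort: subjects, femur geometries, and gait trials.

Generates a cohort of adults with heterogeneous femoral torsion
(truncated-normal distribution, default mean 16.2 deg, SD 10.0 deg,
support [-20, +50] deg) and, per subject, a dynamically usable gait
trial: smooth parametric joint-angle templates (periodic Gaussian-bump /
low-harmonic curves at 200 Hz), a double-bump vertical ground reaction
force scaled to body weight at 1000 Hz, and gait events stored as the
20 N threshold crossings of the generated force.

A configurable torsion-kinematics coupling (:class:`EffectSpec`) injects
linear-in-torsion offsets into the transverse-plane hip rotation inside
stated gait-cycle windows with smooth tapering, emulating the increased
hip internal rotation and in-toeing seen with higher antetorsion. The
generator is the study-condition definition for all downstream tests:
fixed seeds give bit-identical output.

The kinematic and kinetic templates are internally consistent at the
level the downstream analysis needs (events match force thresholds, the
foot progresses with the pelvis), but the forces are template-based, not
forward-dynamically consistent with the kinematics; hip loads are
computed bottom-up from the measured force, so pelvis residuals never
enter hip quantities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .femur import FemurGeometry, generate_template_femur

__all__ = [
    "Subject",
    "EffectSpec",
    "GaitTrial",
    "generate_cohort",
    "generate_trial",
    "subject_femur",
    "write_trial",
    "read_trial",
    "KINEMATIC_CHANNELS",
]

GRAVITY = 9.81  # m s^-2

#: joint-angle channel order of GaitTrial.joint_angles
KINEMATIC_CHANNELS = (
    "pelvis_tx",
    "pelvis_ty",
    "pelvis_tz",
    "pelvis_tilt",
    "pelvis_list",
    "pelvis_rotation",
    "hip_flexion",
    "hip_adduction",
    "hip_rotation",
    "knee_flexion",
    "ankle_dorsiflexion",
    "subtalar_inversion",
)

GRF_CHANNELS = ("fx", "fy", "fz", "cop_x", "cop_y", "cop_z")

#: default torsion distribution (deg): truncated normal
TORSION_MEAN = 16.2
TORSION_SD = 10.0
TORSION_SUPPORT = (-20.0, 50.0)


@dataclass(frozen=True)
class Subject:
    """One synthetic participant (one instrumented limb)."""

    id: str
    mass: float  # kg
    height: float  # m
    sex: str  # "F" | "M"
    side: str  # "L" | "R"
    torsion: float  # deg, antetorsion positive
    hjc_distance: float  # mm between hip joint centres
    walking_speed: float  # km/h

    def __post_init__(self):
        if self.mass <= 0 or self.height <= 0 or self.hjc_distance <= 0:
            raise ValueError("mass, height and hjc_distance must be positive")
        if self.sex not in ("F", "M") or self.side not in ("L", "R"):
            raise ValueError("sex must be F/M and side L/R")

    @property
    def weight(self) -> float:
        """Body weight, N."""
        return self.mass * GRAVITY


@dataclass(frozen=True)
class EffectSpec:
    """Injected torsion -> kinematics coupling.

    Slopes are degrees of angular offset per degree of femoral torsion;
    windows are [start, end] in % gait cycle; offsets taper smoothly to
    zero over ``taper`` % GC at the window edges. Smooth channel noise
    has standard deviation ``noise_sd`` (deg) and temporal smoothness
    ``noise_fwhm`` (% GC). The coupling magnitudes are free parameters of
    the generator, not measured values.
    """

    slope_rotation: float = 0.3  # hip internal rotation, deg/deg
    window_rotation: tuple = (57.0, 63.0)
    slope_foot_progression: float = 0.2  # in-toeing, deg/deg
    window_foot_progression: tuple = (39.0, 56.0)
    noise_fwhm: float = 20.0  # % GC
    noise_sd: float = 2.0  # deg
    taper: float = 3.0  # % GC

    def __post_init__(self):
        for w in (self.window_rotation, self.window_foot_progression):
            if not (0.0 <= w[0] <= w[1] <= 100.0):
                raise ValueError(f"effect window {w} outside [0, 100]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @classmethod
    def null(cls, noise_sd: float = 0.0) -> "EffectSpec":
        return cls(slope_rotation=0.0, slope_foot_progression=0.0, noise_sd=noise_sd)


@dataclass
class GaitTrial:
    """One gait trial: joint angles, ground reaction force, events."""

    subject_id: str
    marker_rate: float  # Hz, kinematics
    grf_rate: float  # Hz
    joint_angles: pd.DataFrame  # columns KINEMATIC_CHANNELS, index = sample
    grf: pd.DataFrame  # columns GRF_CHANNELS
    heel_strikes: list  # sample indices at grf_rate
    toe_offs: list
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        ev = sorted(self.heel_strikes)
        if len(ev) < 2:
            raise ValueError("at least one full cycle (two heel strikes) required")
        for to in self.toe_offs:
            if not (ev[0] < to < ev[-1]):
                raise ValueError("event ordering must be HS < TO < HS")
        if (self.grf["fy"].to_numpy() < -1e-9).any():
            raise ValueError("vertical GRF must be >= 0")

    @property
    def cycle_grf(self) -> tuple:
        """(start, end) GRF sample indices of the first full cycle."""
        return self.heel_strikes[0], self.heel_strikes[1]

    @property
    def cycle_kin(self) -> tuple:
        """(start, end) kinematics sample indices of the first full cycle."""
        r = self.marker_rate / self.grf_rate
        return (
            int(round(self.heel_strikes[0] * r)),
            int(round(self.heel_strikes[1] * r)),
        )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Rejection-sampled truncated normal; deterministic for a given rng."""
    if sd == 0:
        if not (lo <= mean <= hi):
            raise ValueError("degenerate truncated normal outside support")
        return np.full(size, float(mean))
    out = np.empty(size)
    need = np.ones(size, dtype=bool)
    while need.any():
        draw = rng.normal(mean, sd, int(need.sum()))
        ok = (draw >= lo) & (draw <= hi)
        idx = np.flatnonzero(need)[ok]
        out[idx] = draw[ok]
        need[idx] = False
    return out


def generate_cohort(
    n: int,
    torsion_mean: float = TORSION_MEAN,
    torsion_sd: float = TORSION_SD,
    seed: int = 0,
    torsion_support: tuple = TORSION_SUPPORT,
    female_fraction: float = 15.0 / 37.0,
) -> list:
    """Generate ``n`` subjects with truncated-normal femoral torsion.

    Anthropometrics are drawn from sex-conditional normal ranges
    (height, BMI-derived mass), the inter-HJC distance scales with
    stature, and walking speed is self-selected around 5.2 km/h.
    Reproducible for a fixed seed.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if torsion_sd < 0:
        raise ValueError("torsion_sd must be >= 0")
    rng = np.random.default_rng(seed)
    torsion = _truncated_normal(rng, torsion_mean, torsion_sd, *torsion_support, n)
    subjects = []
    for i in range(n):
        female = rng.random() < female_fraction
        height = rng.normal(1.63 if female else 1.76, 0.06)
        height = float(np.clip(height, 1.45, 2.05))
        bmi = float(np.clip(rng.normal(23.0, 2.6), 17.0, 33.0))
        mass = bmi * height**2
        hjc = float(np.clip(rng.normal(170.0, 8.0), 130.0, 210.0)) * height / 1.75
        speed = float(np.clip(rng.normal(5.21, 0.58), 3.2, 7.2))
        side = "L" if rng.random() < 0.5 else "R"
        subjects.append(
            Subject(
                id=f"S{i:03d}",
                mass=round(mass, 2),
                height=round(height, 4),
                sex="F" if female else "M",
                side=side,
                torsion=round(float(torsion[i]), 3),
                hjc_distance=round(hjc, 2),
                walking_speed=round(speed, 3),
            )
        )
    return subjects


def subject_femur(subject: Subject) -> FemurGeometry:
    """Template femur morphed to the subject's measured torsion."""
    return generate_template_femur(subject.torsion, subject.side)


# ---------------------------------------------------------------------------
# trial generation
# ---------------------------------------------------------------------------

def _pgauss(phi, center, width):
    """Periodic Gaussian bump on the 0-100 %GC circle."""
    d = np.mod(phi - center + 50.0, 100.0) - 50.0
    return np.exp(-0.5 * (d / width) ** 2)


def _angle_templates(phi, s):
    """Normative joint-angle curves (deg) vs %GC; s = side sign (R=+1)."""
    return {
        "pelvis_tilt": 3.0 + 1.5 * np.sin(4 * np.pi * phi / 100.0),
        "pelvis_list": s * 2.0 * np.sin(2 * np.pi * phi / 100.0),
        "pelvis_rotation": s * 4.0 * np.cos(2 * np.pi * phi / 100.0),
        "hip_flexion": 10.0 + 20.0 * np.cos(2 * np.pi * (phi - 95.0) / 100.0),
        "hip_adduction": -1.0
        + 3.0 * _pgauss(phi, 15.0, 15.0)
        - 4.0 * _pgauss(phi, 70.0, 15.0),
        "hip_rotation": 3.0 * np.sin(2 * np.pi * phi / 100.0),
        "knee_flexion": 8.0
        + 12.0 * _pgauss(phi, 12.0, 8.0)
        + 55.0 * _pgauss(phi, 72.0, 10.0),
        "ankle_dorsiflexion": 8.0 * _pgauss(phi, 40.0, 15.0)
        - 22.0 * _pgauss(phi, 63.0, 6.0)
        - 4.0 * _pgauss(phi, 3.0, 4.0),
        "subtalar_inversion": 3.0 * _pgauss(phi, 55.0, 15.0)
        - 2.0 * _pgauss(phi, 10.0, 10.0),
    }


#: per-channel scaling of the smooth noise: frontal-plane and intrinsic
#: foot channels vary about half as much as the sagittal channels in
#: normal gait, so EffectSpec.noise_sd is the sagittal-plane value
_NOISE_CHANNEL_SCALE = {
    "hip_adduction": 0.5,
    "pelvis_list": 0.5,
    "subtalar_inversion": 0.5,
}


def _window_taper(phi, window, taper):
    """Smooth 0->1->0 taper: 1 inside the window, raised-cosine edges."""
    a, b = window
    t = np.clip(taper, 1e-6, None)
    up = np.clip((phi - (a - t)) / t, 0.0, 1.0)
    down = np.clip(((b + t) - phi) / t, 0.0, 1.0)
    sm = lambda x: x * x * (3.0 - 2.0 * x)  # noqa: E731
    return sm(up) * sm(down)


def _smooth_periodic_noise(rng, phi, fwhm, sd, n_channels):
    """Smooth periodic noise curves, unit-free sd, sampled at phi (%GC)."""
    grid = np.arange(100)
    white = rng.standard_normal((n_channels, 100))
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    k = np.exp(-0.5 * ((np.mod(grid + 50, 100) - 50) / sigma) ** 2)
    K = np.fft.rfft(k)
    smooth = np.fft.irfft(np.fft.rfft(white, axis=1) * K, n=100, axis=1)
    scale = smooth.std(axis=1, keepdims=True)
    scale[scale == 0] = 1.0
    smooth = smooth / scale * sd
    ext = np.concatenate([smooth, smooth[:, :1]], axis=1)  # periodic closure
    return np.stack(
        [np.interp(np.mod(phi, 100.0), np.arange(101), row) for row in ext]
    )


def _stance_profiles(u):
    """Vertical / anteroposterior GRF shape (per BW) vs stance fraction u."""
    ramp = np.clip(u / 0.05, 0.0, 1.0) * np.clip((1.0 - u) / 0.05, 0.0, 1.0)
    ramp = ramp * ramp * (3.0 - 2.0 * ramp)
    g = lambda c, w: np.exp(-0.5 * ((u - c) / w) ** 2)  # noqa: E731
    fy = (0.752 * (g(0.25, 0.12) + g(0.75, 0.12)) + 0.607 * g(0.5, 0.25)) * ramp
    fx = 0.16 * (-g(0.18, 0.10) + g(0.82, 0.10)) * ramp
    return fy, fx


def generate_trial(subject: Subject, effects: EffectSpec | None = None,
                   seed: int = 0) -> GaitTrial:
    """Generate one gait trial (one full cycle plus lead-in/out).

    Joint angles at 200 Hz from smooth normative templates with the
    torsion-coupled offsets of ``effects`` added to the transverse-plane
    hip rotation inside the stated windows; ground reaction forces at
    1000 Hz with a double-bump vertical profile scaled to body weight
    and zero force in swing; events are the 20 N crossings of the
    generated vertical force. Bit-identical for a fixed seed.
    """
    effects = effects or EffectSpec()
    rng = np.random.default_rng(seed)
    s = 1.0 if subject.side == "R" else -1.0

    speed = subject.walking_speed / 3.6  # m/s
    stride_len = 0.87 * subject.height
    stride_time = stride_len / speed
    lead = 0.15  # s before first heel strike and after the second

    kin_rate, grf_rate = 200.0, 1000.0
    duration = stride_time + 2 * lead
    n_kin = int(np.floor(duration * kin_rate)) + 1
    n_grf = int(np.floor(duration * grf_rate)) + 1
    t_kin = np.arange(n_kin) / kin_rate
    t_grf = np.arange(n_grf) / grf_rate

    phi_kin = (t_kin - lead) / stride_time * 100.0  # %GC, cycle 0 at HS1
    phi_grf = (t_grf - lead) / stride_time * 100.0

    # --- joint angles ---------------------------------------------------
    ang = _angle_templates(np.mod(phi_kin, 100.0), s)
    coupled = effects.slope_rotation * subject.torsion * _window_taper(
        np.mod(phi_kin, 100.0), effects.window_rotation, effects.taper
    ) + effects.slope_foot_progression * subject.torsion * _window_taper(
        np.mod(phi_kin, 100.0), effects.window_foot_progression, effects.taper
    )
    ang["hip_rotation"] = ang["hip_rotation"] + coupled

    if effects.noise_sd > 0:
        noisy = KINEMATIC_CHANNELS[3:]  # angle channels only
        noise = _smooth_periodic_noise(
            rng, phi_kin, effects.noise_fwhm, effects.noise_sd, len(noisy)
        )
        for row, c in zip(noise, noisy):
            ang[c] = ang[c] + _NOISE_CHANNEL_SCALE.get(c, 1.0) * row

    pelvis_ty = 0.53 * subject.height + 0.012 * np.cos(
        4 * np.pi * np.mod(phi_kin, 100.0) / 100.0
    )
    data = {
        "pelvis_tx": speed * t_kin,
        "pelvis_ty": pelvis_ty,
        "pelvis_tz": s * 0.015 * np.sin(2 * np.pi * np.mod(phi_kin, 100.0) / 100.0),
    }
    for c in KINEMATIC_CHANNELS[3:]:
        data[c] = ang[c]
    joint_angles = pd.DataFrame(data, columns=list(KINEMATIC_CHANNELS))

    # --- ground reaction force -----------------------------------------
    # the centre of pressure rolls from the heel to the forefoot under
    # the foot of the generated kinematics (forward kinematics of the
    # baseline-scaled chain), keeping force placement and joint motion
    # consistent for the bottom-up inverse dynamics
    from .msk import Posture, build_model

    chain = build_model(subject, generate_template_femur(side=subject.side))
    posture = Posture(**{c: np.asarray(data[c]) for c in KINEMATIC_CHANNELS})
    fk = chain.forward_kinematics(posture)
    heel_w = chain.point_world(*chain.markers["HEEL"], fk, posture)
    mt2_w = chain.point_world(*chain.markers["MT2"], fk, posture)

    bw = subject.weight
    stance_frac = 0.60
    fy = np.zeros(n_grf)
    fx = np.zeros(n_grf)
    cop_x = np.zeros(n_grf)
    cop_z = np.zeros(n_grf)
    for cycle_start_phi in (0.0, 100.0):  # stance of cycle 1 and next stance
        u = (phi_grf - cycle_start_phi) / (100.0 * stance_frac)
        mask = (u >= 0.0) & (u <= 1.0)
        pf, px = _stance_profiles(np.clip(u, 0.0, 1.0))
        fy[mask] += bw * pf[mask]
        fx[mask] += bw * px[mask]
        u_kin = (phi_kin - cycle_start_phi) / (100.0 * stance_frac)
        su = np.clip(u_kin, 0.0, 1.0) ** 0.7
        cop_kin_x = (1.0 - su) * heel_w[:, 0] + su * mt2_w[:, 0]
        cop_kin_z = (1.0 - su) * heel_w[:, 2] + su * mt2_w[:, 2]
        cop_x[mask] = np.interp(t_grf[mask], t_kin, cop_kin_x)
        cop_z[mask] = np.interp(t_grf[mask], t_kin, cop_kin_z)
    grf = pd.DataFrame(
        {
            "fx": fx,
            "fy": fy,
            "fz": np.zeros(n_grf),
            "cop_x": cop_x,
            "cop_y": np.zeros(n_grf),
            "cop_z": cop_z,
        },
        columns=list(GRF_CHANNELS),
    )

    # --- events: threshold crossings of the generated vertical force ----
    above = fy > 20.0
    rising = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    falling = np.flatnonzero(~above[1:] & above[:-1]) + 1
    heel_strikes = [int(i) for i in rising[:2]]
    toe_offs = [int(i) for i in falling if heel_strikes[0] < i < heel_strikes[-1]]

    return GaitTrial(
        subject_id=subject.id,
        marker_rate=kin_rate,
        grf_rate=grf_rate,
        joint_angles=joint_angles,
        grf=grf,
        heel_strikes=heel_strikes,
        toe_offs=toe_offs,
        meta={
            "seed": int(seed),
            "stride_time": stride_time,
            "lead": lead,
            "subject": asdict(subject),
            "effects": asdict(effects),
        },
    )


# ---------------------------------------------------------------------------
# file interchange: CSV pair + JSON sidecar
# ---------------------------------------------------------------------------

def write_trial(trial: GaitTrial, directory, stem: str | None = None) -> dict:
    """Write a trial as ``<stem>_kinematics.csv``, ``<stem>_grf.csv`` and
    ``<stem>_meta.json``; returns the three paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = stem or trial.subject_id
    paths = {
        "kinematics": directory / f"{stem}_kinematics.csv",
        "grf": directory / f"{stem}_grf.csv",
        "meta": directory / f"{stem}_meta.json",
    }
    trial.joint_angles.to_csv(paths["kinematics"], index=False, float_format="%.9g")
    trial.grf.to_csv(paths["grf"], index=False, float_format="%.9g")
    with open(paths["meta"], "w") as fh:
        json.dump(
            {
                "subject_id": trial.subject_id,
                "marker_rate": trial.marker_rate,
                "grf_rate": trial.grf_rate,
                "heel_strikes": trial.heel_strikes,
                "toe_offs": trial.toe_offs,
                "meta": trial.meta,
            },
            fh,
            indent=1,
        )
    return paths


def read_trial(directory, stem: str) -> GaitTrial:
    directory = Path(directory)
    with open(directory / f"{stem}_meta.json") as fh:
        meta = json.load(fh)
    return GaitTrial(
        subject_id=meta["subject_id"],
        marker_rate=meta["marker_rate"],
        grf_rate=meta["grf_rate"],
        joint_angles=pd.read_csv(directory / f"{stem}_kinematics.csv"),
        grf=pd.read_csv(directory / f"{stem}_grf.csv"),
        heel_strikes=meta["heel_strikes"],
        toe_offs=meta["toe_offs"],
        meta=meta["meta"],
    )
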