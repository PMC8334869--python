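"""End-to-end study orchestration: cohort -> models -> dynamics -> SPM.

:class:`TorsionGaitStudy` reproduces the full analysis design at
configurable scale: generate (or load) a cohort with heterogeneous
femoral torsion, build a torsion-personalized and a generic
(baseline-torsion) musculoskeletal model per subject, process each gait
trial through inverse dynamics, muscle recruitment and hip contact
force assembly, map acetabular contact pathways, and run the
statistical parametric mapping analyses: vector-field CCA of hip
kinematics, net moments, HCFs and functional muscle-group forces
against femoral torsion, scalar regression of the foot progression
angle, a paired Hotelling T2 of generic vs personalized HCFs, and
Bonferroni post hoc component regressions. Results and a reproducibility
manifest are written as CSV/JSON artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import acetabulum as ace
from . import dynamics as dyn
from . import spm as spm_mod
from .cohort import (
    EffectSpec,
    Subject,
    TORSION_MEAN,
    TORSION_SD,
    TORSION_SUPPORT,
    generate_cohort,
    generate_trial,
    subject_femur,
)
from .exceptions import TorsionGaitError
from .femur import TEMPLATE_TORSION, generate_template_femur
from .gait import GaitCycleField, foot_progression_angle, synthesize_markers, time_normalize
from .msk import build_model

__all__ = ["RunConfig", "StudyResults", "TorsionGaitStudy", "run_study"]

log = logging.getLogger("torsiongait.study")


@dataclass
class RunConfig:
    """Full study configuration; defaults mirror the analysis constants."""

    n_subjects: int = 37
    torsion_mean: float = TORSION_MEAN
    torsion_sd: float = TORSION_SD
    torsion_support: tuple = TORSION_SUPPORT
    effects: EffectSpec = field(default_factory=EffectSpec)
    baseline_torsion: float = TEMPLATE_TORSION  # generic model torsion, deg
    inclination: float = ace.DEFAULT_INCLINATION
    anteversion: float = ace.DEFAULT_ANTEVERSION
    hemisphere_diameter: float = ace.DEFAULT_DIAMETER
    alpha: float = 0.05
    min_cluster_extent: float = 2.0  # %GC reporting rule
    seed: int = 0
    out_dir: str | None = None
    write_figures: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        d["effects"] = asdict(self.effects)
        d["torsion_support"] = list(self.torsion_support)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("effects"), dict):
            eff = dict(d["effects"])
            for key in ("window_rotation", "window_foot_progression"):
                if key in eff:
                    eff[key] = tuple(eff[key])
            d["effects"] = EffectSpec(**eff)
        if "torsion_support" in d:
            d["torsion_support"] = tuple(d["torsion_support"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class StudyResults:
    """Everything the study computes, in memory."""

    config: RunConfig
    subjects: list
    torsion: np.ndarray  # (n,)
    hip_kinematics: np.ndarray  # (n, 101, 3) deg
    foot_progression: np.ndarray  # (n, 101) deg, in-toeing +
    hip_moments: np.ndarray  # (n, 101, 3) N m/kg
    hcf_personalized: np.ndarray  # (n, 101, 3) BW
    hcf_generic: np.ndarray  # (n, 101, 3) BW
    hcf_magnitude: np.ndarray  # (n, 101) BW
    group_forces: dict  # group -> (n, 101, k_g)
    rmsd: pd.DataFrame  # per subject/component RMSD generic vs personalized
    spm: dict  # name -> SPMResults or list
    mean_pathway: list  # PathwayPoint series of cohort-mean HCF
    manifest: dict

    def summary(self) -> str:
        lines = [
            f"torsion-gait study  (n = {len(self.subjects)}, seed = "
            f"{self.manifest['seed']})",
            f"  torsion: mean {self.torsion.mean():.1f} deg, sd "
            f"{self.torsion.std(ddof=1):.1f} deg, range "
            f"[{self.torsion.min():.1f}, {self.torsion.max():.1f}]",
            f"  peak cohort-mean HCF: {self.hcf_magnitude.mean(0).max():.2f} BW",
        ]
        for name, res in self.spm.items():
            if isinstance(res, list):
                continue
            sig = ", ".join(
                f"[{c.start:.0f}-{c.end:.0f}]%" for c in res.clusters
            ) or "none"
            lines.append(
                f"  SPM {name}: {res.stat_name}* = {res.critical:.2f}, "
                f"clusters: {sig}"
            )
        return "\n".join(lines)


class TorsionGaitStudy:
    """The full torsion-personalized hip-loading analysis as a model object."""

    def __init__(self, config: RunConfig | None = None):
        self.config = config or RunConfig()

    # -- single subject --------------------------------------------------
    def _subject_run(self, subject: Subject, trial_seed: int):
        cfg = self.config
        trial = generate_trial(subject, cfg.effects, seed=trial_seed)
        model_p = build_model(subject, subject_femur(subject))
        model_g = build_model(
            subject, generate_template_femur(cfg.baseline_torsion, subject.side)
        )
        td_p = dyn.analyze_trial(model_p, trial)
        td_g = dyn.analyze_trial(model_g, trial)

        markers = synthesize_markers(model_p, trial.joint_angles)
        k0, k1 = trial.cycle_kin
        fpa = foot_progression_angle(
            markers["HEEL"], markers["MT2"], [k0, k1], side=subject.side
        )
        fpa_field = time_normalize(fpa, (k0, k1), components=["fpa"],
                                   subject_id=subject.id)
        return trial, td_p, td_g, fpa_field

    # -- cohort ----------------------------------------------------------
    def run(self, seed: int | None = None, subjects: list | None = None) -> StudyResults:
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        t_start = time.time()

        if subjects is None:
            subjects = generate_cohort(
                cfg.n_subjects, cfg.torsion_mean, cfg.torsion_sd,
                seed=seed, torsion_support=cfg.torsion_support,
            )
        n = len(subjects)
        if n == 0:
            raise ValueError("empty cohort")
        trial_seeds = np.random.default_rng(seed + 1).integers(
            0, 2**31 - 1, size=n
        )

        hip_kin = np.zeros((n, 101, 3))
        fpa = np.zeros((n, 101))
        moments = np.zeros((n, 101, 3))
        hcf_p = np.zeros((n, 101, 3))
        hcf_g = np.zeros((n, 101, 3))
        hcf_mag = np.zeros((n, 101))
        group_names = ("hip_flexor", "hip_extensor", "hip_abductor", "hip_adductor")
        group_vals = {g: [] for g in group_names}
        gen_fields, pers_fields = {}, {}

        for i, subject in enumerate(subjects):
            t0 = time.time()
            try:
                trial, td_p, td_g, fpa_field = self._subject_run(
                    subject, int(trial_seeds[i])
                )
            except TorsionGaitError as err:
                raise type(err)(
                    f"[subject {subject.id}] {err}"
                ) from err
            hip_kin[i] = np.stack(
                [td_p.kinematics[c] for c in
                 ("hip_flexion", "hip_adduction", "hip_rotation")], axis=1
            )
            fpa[i] = fpa_field["fpa"]
            moments[i] = td_p.hip_moments.values
            hcf_p[i] = td_p.hcf.values[:, :3]
            hcf_g[i] = td_g.hcf.values[:, :3]
            hcf_mag[i] = td_p.hcf["magnitude"]
            for g in group_names:
                group_vals[g].append(td_p.group_forces[g].values)
            pers_fields[subject.id] = td_p.hcf
            gen_fields[subject.id] = td_g.hcf
            log.info("subject %s done in %.2f s", subject.id, time.time() - t0)

        group_forces = {g: np.stack(v) for g, v in group_vals.items()}
        torsion = np.array([s.torsion for s in subjects])

        rmsd = dyn.compare_models(gen_fields, pers_fields)
        rmsd = rmsd.merge(
            pd.DataFrame({"subject_id": [s.id for s in subjects],
                          "torsion": torsion}),
            on="subject_id",
        )

        # --- SPM analyses -----------------------------------------------
        results = {}
        if n > 5:
            results["hip_kinematics_cca"] = spm_mod.cca_spm(
                hip_kin, torsion, alpha=cfg.alpha
            )
            results["hip_kinematics_posthoc"] = spm_mod.posthoc_components(
                hip_kin, torsion, alpha=cfg.alpha
            )
            results["foot_progression_regression"] = spm_mod.regression_spm(
                fpa, torsion, alpha=cfg.alpha
            )
            results["hip_moments_cca"] = spm_mod.cca_spm(
                moments, torsion, alpha=cfg.alpha
            )
            results["hcf_cca"] = spm_mod.cca_spm(hcf_p, torsion, alpha=cfg.alpha)
            results["hcf_posthoc"] = spm_mod.posthoc_components(
                hcf_p, torsion, alpha=cfg.alpha
            )
            for g in group_names:
                if group_forces[g].shape[2] >= 1 and n > group_forces[g].shape[2] + 2:
                    # inactive muscles have identically zero force at some
                    # nodes; evaluate on the non-degenerate subspace
                    results[f"{g}_cca"] = spm_mod.cca_spm(
                        group_forces[g], torsion, alpha=cfg.alpha,
                        rank_policy="reduce",
                    )
            results["hcf_generic_vs_personalized"] = spm_mod.hotelling_paired_spm(
                hcf_g, hcf_p, alpha=cfg.alpha
            )
            results = {
                k: spm_mod.report_filter(v, cfg.min_cluster_extent)
                for k, v in results.items()
            }

        # --- cohort-mean acetabular pathway ------------------------------
        frame = ace.build_frame(
            np.eye(3), np.zeros(3), cfg.inclination, cfg.anteversion, side="R"
        )
        mean_fields = [
            GaitCycleField(
                components=["hcf_x", "hcf_y", "hcf_z"],
                values=_mirror_to_right(hcf_p[i], subjects[i].side),
                subject_id=subjects[i].id,
            )
            for i in range(n)
        ]
        pathway = ace.mean_pathway(mean_fields, frame, cfg.hemisphere_diameter)

        manifest = {
            "seed": int(seed),
            "config": cfg.to_dict(),
            "config_hash": cfg.config_hash,
            "n_subjects": n,
            "trial_seeds": [int(s) for s in trial_seeds],
            "runtime_s": round(time.time() - t_start, 2),
        }
        res = StudyResults(
            config=cfg,
            subjects=subjects,
            torsion=torsion,
            hip_kinematics=hip_kin,
            foot_progression=fpa,
            hip_moments=moments,
            hcf_personalized=hcf_p,
            hcf_generic=hcf_g,
            hcf_magnitude=hcf_mag,
            group_forces=group_forces,
            rmsd=rmsd,
            spm=results,
            mean_pathway=pathway,
            manifest=manifest,
        )
        if cfg.out_dir:
            write_artifacts(res, cfg.out_dir)
        return res


def _mirror_to_right(hcf: np.ndarray, side: str) -> np.ndarray:
    """Express a left-hip HCF in right-hip pelvis coordinates (flip Z)."""
    if side == "R":
        return hcf
    out = hcf.copy()
    out[:, 2] = -out[:, 2]
    return out


# ---------------------------------------------------------------------------
# artifacts
# ---------------------------------------------------------------------------

def _spm_to_dict(res) -> dict:
    if isinstance(res, list):
        return {"components": [_spm_to_dict(r) for r in res]}
    return {
        "stat": res.stat_name,
        "dof": [float(d) for d in res.dof],
        "fwhm": res.fwhm,
        "resels": res.resels,
        "critical": res.critical,
        "alpha": res.alpha,
        "two_tailed": res.two_tailed,
        "clusters": [
            {"start": c.start, "end": c.end, "p": c.p_value} for c in res.clusters
        ],
        "statistic_field": [round(float(v), 6) for v in res.statistic_field],
    }


def write_artifacts(results: StudyResults, out_dir) -> dict:
    """Write the study's CSV/JSON artifact set; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    subs = pd.DataFrame([asdict(s) for s in results.subjects])
    paths["subjects"] = out / "subjects.csv"
    subs.to_csv(paths["subjects"], index=False)

    node = np.tile(np.arange(101), len(results.subjects))
    sid = np.repeat([s.id for s in results.subjects], 101)
    fields = pd.DataFrame({"subject_id": sid, "node": node})
    for j, c in enumerate(("hip_flexion", "hip_adduction", "hip_rotation")):
        fields[c] = results.hip_kinematics[:, :, j].ravel()
    fields["foot_progression"] = results.foot_progression.ravel()
    for j, c in enumerate(("moment_x", "moment_y", "moment_z")):
        fields[c] = results.hip_moments[:, :, j].ravel()
    for j, c in enumerate(("hcf_x", "hcf_y", "hcf_z")):
        fields[c] = results.hcf_personalized[:, :, j].ravel()
        fields[c + "_generic"] = results.hcf_generic[:, :, j].ravel()
    fields["hcf_magnitude"] = results.hcf_magnitude.ravel()
    paths["fields"] = out / "gait_cycle_fields.csv"
    fields.to_csv(paths["fields"], index=False, float_format="%.6g")

    paths["rmsd"] = out / "rmsd_generic_vs_personalized.csv"
    results.rmsd.to_csv(paths["rmsd"], index=False, float_format="%.6g")

    paths["pathway"] = out / "mean_pathway.csv"
    ace.pathway_frame(results.mean_pathway).to_csv(
        paths["pathway"], index=False, float_format="%.6g"
    )

    paths["spm"] = out / "spm_results.json"
    with open(paths["spm"], "w") as fh:
        json.dump({k: _spm_to_dict(v) for k, v in results.spm.items()}, fh, indent=1)

    paths["manifest"] = out / "manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump(results.manifest, fh, indent=1)

    if results.config.write_figures:
        _write_figures(results, out, paths)
    return paths


def _write_figures(results: StudyResults, out: Path, paths: dict) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    gc = np.arange(101)
    fig, axes = plt.subplots(1, 3, figsize=(11, 3), sharex=True)
    for j, (ax, name) in enumerate(
        zip(axes, ("hip flexion", "hip adduction", "hip rotation"))
    ):
        ax.plot(gc, results.hip_kinematics[:, :, j].T, color="0.8", lw=0.5)
        ax.plot(gc, results.hip_kinematics[:, :, j].mean(0), color="teal", lw=2)
        ax.set_title(name)
        ax.set_xlabel("% gait cycle")
    axes[0].set_ylabel("deg")
    fig.tight_layout()
    paths["fig_kinematics"] = out / "kinematics.png"
    fig.savefig(paths["fig_kinematics"], dpi=110)
    plt.close(fig)

    fig, axes = plt.subplots(1, 3, figsize=(11, 3), sharex=True)
    for j, (ax, name) in enumerate(zip(axes, ("HCF x", "HCF y", "HCF z"))):
        ax.plot(gc, results.hcf_generic[:, :, j].mean(0), color="0.5", lw=2,
                label="generic")
        ax.plot(gc, results.hcf_personalized[:, :, j].mean(0), color="purple",
                lw=2, label="personalized")
        ax.set_title(name)
        ax.set_xlabel("% gait cycle")
    axes[0].set_ylabel("BW")
    axes[0].legend(fontsize=7)
    fig.tight_layout()
    paths["fig_hcf"] = out / "hcf_generic_vs_personalized.png"
    fig.savefig(paths["fig_hcf"], dpi=110)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4, 4))
    ace.plot_pathway(results.mean_pathway, ax=ax)
    paths["fig_pathway"] = out / "mean_pathway.png"
    fig.savefig(paths["fig_pathway"], dpi=110)
    plt.close(fig)


def run_study(config: RunConfig | None = None, seed: int | None = None) -> StudyResults:
    """Functional entry point: run the configured study end to end."""
    return TorsionGaitStudy(config).run(seed=seed)
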