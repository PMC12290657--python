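"""End-to-end orchestration: phantom -> segmentation -> gradients -> GLM ->
step statistics -> centre-of-gravity analysis.

Every product is written under the output directory and checksummed into a
run manifest; the whole pipeline is deterministic given the master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisConfig
from .errors import CbgradError
from .glm import CONTRAST_NAMES, build_design_matrix, contrast_zmap, fit_glm, fixed_effects_combine, threshold_map
from .phantom import EffectSpec, NoiseSpec, build_task_design, compute_intrinsic_coords, generate_anatomy, generate_bold
from .stepstats import holm_posthoc, mean_gm_z, overlap_counts, paired_t, rm_anova, step_profile
from .cog import centre_of_gravity, cog_shift_analysis, quadrant_rois, EmptyClusterError
from .volio import write_design_tsv, write_volume

log = logging.getLogger("cbgrad")

__all__ = ["RunManifest", "PipelineStageError", "run_pipeline"]

DIRECTIONS = ("fissure_depth", "mediolateral", "posterior_anterior")


class PipelineStageError(CbgradError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"[stage: {stage}] {detail}")
        self.stage = stage


@dataclass
class RunManifest:
    version: str
    config_hash: str
    config: dict
    created: str
    checksums: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    stage_counts: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _subject_noise_seed(master_seed: int, subject: int) -> int:
    return (master_seed * 1_000_003 + 7_919 * subject + 1) % (2 ** 63)


def run_pipeline(config: AnalysisConfig, out_dir=None) -> RunManifest:
    """Run the full analysis on the synthetic scenario in ``config``.

    Returns the manifest (also written as ``manifest.json``); raises
    :class:`PipelineStageError` naming the failing stage.
    """
    out = Path(out_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        version=__version__,
        config_hash=config.config_hash(),
        config=config.to_dict(),
        created=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    written: list[Path] = []
    vs = config.voxel_size_mm

    def _write_vol(data, name, tr_s=None):
        p = out / name
        write_volume(data, p, vs, tr_s=tr_s)
        written.append(p)

    # ---- phantom anatomy -------------------------------------------------
    try:
        anatomy = generate_anatomy(
            grid_shape=config.grid_shape, n_lobules=config.n_lobules,
            fold_count=config.fold_count, seed=config.master_seed,
            band_thickness_vox=config.band_thickness_vox,
            fold_amplitude_vox=config.fold_amplitude_vox, voxel_size_mm=vs,
        )
        _write_vol(anatomy.lobule_labels, "lobule_labels.nii")
        _write_vol(anatomy.wm_probability, "wm_probability.nii")
        _write_vol(anatomy.cerebellum_mask, "cerebellum_mask.nii")
        _write_vol(anatomy.gm_mask, "gm_mask.nii")
    except CbgradError as e:
        raise PipelineStageError("phantom", str(e)) from e

    # ---- segmentation + gradients ---------------------------------------
    coords = {}
    step_rows = []
    try:
        coords = compute_intrinsic_coords(anatomy, config.target_lobules, n_steps=config.n_steps)
        for (lob, hemi), ic in coords.items():
            for direction, sm in ic.step_maps.items():
                _write_vol(sm.steps, f"steps_lob{lob}_{hemi}_{direction}.nii")
                for s, cnt in enumerate(sm.counts(), start=1):
                    step_rows.append((lob, hemi, direction, s, int(cnt)))
                if sm.n_unreachable:
                    manifest.warnings.append(
                        f"gradients: {sm.n_unreachable} unreachable voxels in lobule {lob} {hemi} {direction}")
    except CbgradError as e:
        raise PipelineStageError("gradients", str(e)) from e
    df_steps = pd.DataFrame(step_rows, columns=["lobule", "hemisphere", "direction", "step", "n_voxels"])
    df_steps.to_csv(out / "step_counts.tsv", sep="\t", index=False)
    written.append(out / "step_counts.tsv")

    # ---- task designs ----------------------------------------------------
    try:
        designs = [
            build_task_design(config.run_length_s, config.tr_s, config.on_s, config.off_s,
                              order=config.condition_order, run_id=r)
            for r in range(config.n_runs)
        ]
        for d in designs:
            p = out / f"design_run{d.run_id}.tsv"
            write_design_tsv(d, p)
            written.append(p)
    except CbgradError as e:
        raise PipelineStageError("design", str(e)) from e

    # ---- per-subject BOLD + GLM -----------------------------------------
    gm = anatomy.gm_mask
    subj_maps: dict[str, dict[str, object]] = {}
    overlap_rows = []
    meanz_rows = []
    profile_rows = []
    cog_rows = []
    quad_masks = quadrant_rois(anatomy.lobule_labels, config.superior_lobules,
                               config.inferior_lobules, anatomy.hemisphere_offset)
    profiles: dict[tuple, dict[str, np.ndarray]] = {}

    for s in range(config.n_subjects):
        subject = f"sub-{s:02d}"
        try:
            rng = np.random.default_rng([config.master_seed, s])
            gains = np.exp(config.subject_amplitude_jitter_sd * rng.standard_normal(len(config.effects)))
            effects = [
                EffectSpec(e.condition, e.lobule, tuple(e.centre_intrinsic),
                           e.spatial_sd_mm, e.amplitude_pct * g)
                for e, g in zip(config.effects, gains)
            ]
            noise = NoiseSpec(sigma_pct=config.noise_sigma_pct, ar1_rho=config.noise_ar1_rho,
                              seed=_subject_noise_seed(config.master_seed, s))
            runs = generate_bold(anatomy, designs, effects, noise, coords=coords,
                                 simulate_mask=anatomy.cerebellum_mask)
            per_contrast = {name: [] for name in CONTRAST_NAMES}
            for run in runs:
                X = build_design_matrix(run.design, drift_order=config.drift_order)
                fit = fit_glm(run, X, mask=anatomy.cerebellum_mask)
                for name in CONTRAST_NAMES:
                    per_contrast[name].append(contrast_zmap(fit, name, name))
            combined = {name: fixed_effects_combine(maps) for name, maps in per_contrast.items()}
            subj_maps[subject] = combined
            for name, cmap in combined.items():
                safe = name.replace(">", "_gt_")
                _write_vol(cmap.z.astype(np.float32), f"{subject}_z_{safe}.nii")

            act_a = threshold_map(combined["MCFT>rest"], config.z_threshold)
            act_b = threshold_map(combined["SUFF>rest"], config.z_threshold)
            oc = overlap_counts(act_a, act_b, gm)
            overlap_rows.append((subject, oc.only_a, oc.only_b, oc.both))
            for name in ("MCFT>rest", "SUFF>rest"):
                meanz_rows.append((subject, name, mean_gm_z(combined[name], gm)))

            for (lob, hemi), ic in coords.items():
                for direction, sm in ic.step_maps.items():
                    prof = step_profile(combined["MCFT>SUFF"], sm, gm, subject_id=subject)
                    key = (lob, hemi, direction)
                    profiles.setdefault(key, {})[subject] = prof.mean_z
                    for k in range(config.n_steps):
                        profile_rows.append((subject, lob, hemi, direction, k + 1,
                                             prof.mean_z[k], int(prof.voxel_counts[k])))

            for quadrant, qmask in quad_masks.items():
                for cond, cname in (("MCFT", "MCFT>rest"), ("SUFF", "SUFF>rest")):
                    try:
                        r = centre_of_gravity(combined[cname], qmask, vs,
                                              quadrant=quadrant, condition=cond)
                        cog_rows.append((subject, quadrant, cond) + r.cog_mm + (r.total_weight,))
                    except EmptyClusterError:
                        manifest.warnings.append(f"cog: {subject} {quadrant} {cond} has no z > 0 voxels")
        except CbgradError as e:
            raise PipelineStageError("glm", f"subject {subject}: {e}") from e

    for rows, name, cols in (
        (overlap_rows, "overlap_counts.tsv", ["subject", "only_mcft", "only_suff", "both"]),
        (meanz_rows, "mean_gm_z.tsv", ["subject", "contrast", "mean_z"]),
        (profile_rows, "step_profiles.tsv",
         ["subject", "lobule", "hemisphere", "direction", "step", "mean_z", "n_voxels"]),
        (cog_rows, "cog_per_subject.tsv",
         ["subject", "quadrant", "condition", "x_mm", "y_mm", "z_mm", "total_weight"]),
    ):
        pd.DataFrame(rows, columns=cols).to_csv(out / name, sep="\t", index=False)
        written.append(out / name)

    # ---- step statistics -------------------------------------------------
    anova_rows = []
    posthoc_rows = []
    try:
        if config.n_steps < 2:
            manifest.warnings.append("stats: n_steps < 2, repeated-measures ANOVA skipped")
        else:
            for (lob, hemi, direction), table in profiles.items():
                X = np.vstack([table[f"sub-{s:02d}"] for s in range(config.n_subjects)])
                res = rm_anova(X, gg_trigger_alpha=config.alpha)
                anova_rows.append((lob, hemi, direction, res.F, res.df1, res.df2, res.p,
                                   res.p_uncorrected, res.mauchly_W, res.mauchly_p,
                                   res.gg_epsilon, res.corrected, res.n_subjects))
                for r in holm_posthoc(X):
                    posthoc_rows.append((lob, hemi, direction, r.pair[0], r.pair[1],
                                         r.t, r.df, r.p, r.p_adjusted, r.mean_diff))
        mz = pd.DataFrame(meanz_rows, columns=["subject", "contrast", "mean_z"])
        wide = mz.pivot(index="subject", columns="contrast", values="mean_z")
        tt = paired_t(wide["MCFT>rest"].to_numpy(), wide["SUFF>rest"].to_numpy())
        pd.DataFrame([(tt.t, tt.df, tt.p, tt.mean_diff, tt.sd_diff)],
                     columns=["t", "df", "p", "mean_diff", "sd_diff"]).to_csv(
            out / "mean_gm_z_paired_t.tsv", sep="\t", index=False)
        written.append(out / "mean_gm_z_paired_t.tsv")
    except CbgradError as e:
        raise PipelineStageError("stats", str(e)) from e
    pd.DataFrame(anova_rows, columns=["lobule", "hemisphere", "direction", "F", "df1", "df2",
                                      "p", "p_uncorrected", "mauchly_W", "mauchly_p",
                                      "gg_epsilon", "corrected", "n_subjects"]).to_csv(
        out / "rm_anova.tsv", sep="\t", index=False)
    written.append(out / "rm_anova.tsv")
    pd.DataFrame(posthoc_rows, columns=["lobule", "hemisphere", "direction", "step_a", "step_b",
                                        "t", "df", "p", "p_holm", "mean_diff"]).to_csv(
        out / "posthoc_holm.tsv", sep="\t", index=False)
    written.append(out / "posthoc_holm.tsv")

    # ---- centre-of-gravity shifts ---------------------------------------
    try:
        cog_df = pd.DataFrame(cog_rows, columns=["subject", "quadrant", "condition",
                                                 "x_mm", "y_mm", "z_mm", "total_weight"])
        shift_rows = []
        if not cog_df.empty:
            for quadrant, shift in cog_shift_analysis(cog_df).items():
                for axis, d, sd, t in zip("xyz", shift.delta_mm, shift.sd_mm, shift.tests):
                    shift_rows.append((quadrant, axis, d, sd, t.t, t.df, t.p, shift.n_subjects))
        pd.DataFrame(shift_rows, columns=["quadrant", "axis", "delta_mm", "sd_mm",
                                          "t", "df", "p", "n_subjects"]).to_csv(
            out / "cog_shifts.tsv", sep="\t", index=False)
        written.append(out / "cog_shifts.tsv")
    except CbgradError as e:
        raise PipelineStageError("cog", str(e)) from e

    # ---- manifest --------------------------------------------------------
    manifest.stage_counts = {
        "n_subjects": config.n_subjects,
        "n_runs": config.n_runs,
        "n_anova_tables": len(anova_rows),
        "gm_voxels": int(np.count_nonzero(gm)),
    }
    for p in written:
        manifest.checksums[p.name] = _sha256(p)
    manifest.to_json(out / "manifest.json")
    log.info("pipeline complete: %d products, %d warnings", len(written), len(manifest.warnings))
    return manifest
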