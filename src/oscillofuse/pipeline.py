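"""End-to-end orchestration of the fusion analysis on simulated data.

``run_pipeline`` chains: simulate -> EEG cleanup -> time-frequency peak
extraction -> modulator orthogonalization -> first-level GLM -> group
contrast -> cluster inference -> ROI/trait correlations, and writes a
manifest. Everything is driven by one :class:`RunConfig` whose global
seed fans out deterministically to every randomness stream, so reruns
with the same configuration are numerically identical.
"""

from __future__ import annotations

import dataclasses
import json
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as ofio
from .config import CONDITIONS, SimConfig, child_seed
from .glm import (
    build_first_level_design,
    cluster_inference,
    fit_first_level_glm,
    orthogonalize_modulators,
    second_level_contrast,
)
from .preprocess import preprocess_recording
from .roi import ROISpec, correlate_rois_with_traits, sphere_roi_mean
from .simulate import (
    build_ground_truth,
    simulate_bold,
    simulate_eeg,
    simulate_motion,
    simulate_task,
    simulate_trait_scores,
)
from .timefreq import (
    BETA_WINDOW_MS,
    THETA_WINDOW_MS,
    aggregate_cell_means,
    baseline_normalize,
    build_frequency_grid,
    extract_peak_power,
    fit_power_lmm,
    morlet_power,
)


@dataclass
class RunConfig:
    """Pipeline parameters. Analysis defaults follow the published
    protocol (thresholds P<0.001 strict / P<0.005 with k=100 lenient,
    5 mm ROI spheres, FDR q<0.05); the simulation block is desk-scale by
    default so a demo run finishes in seconds."""

    sim: SimConfig = field(default_factory=lambda: SimConfig(
        n_subjects=2, n_blocks=2, trials_per_block=40,
        grid_shape=(10, 10, 10), eeg_sfreq=500.0,
        n_scans_per_block=210,
    ))
    band: str = "theta"  # which coupling model to run: "theta" or "beta"
    seed: int = 0
    voxel_p: float = 0.005
    extent_k: int = 100
    n_permutations: int = 200
    roi_radius_mm: float = 5.0
    fdr_q: float = 0.05
    smoothing_fwhm_mm: float = 0.0
    prewhiten: bool = True
    discard_volumes: int = 5
    trait_rho: float = 0.6
    out_dir: str = "oscillofuse_out"

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        self.sim.seed = child_seed(self.seed, "simulate")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        sim = d.pop("sim", {})
        for key in ("noise", "artifact"):
            if key in sim and isinstance(sim[key], dict):
                from .config import ArtifactConfig, NoiseConfig

                sim[key] = (NoiseConfig if key == "noise" else ArtifactConfig)(**sim[key])
        for key in ("grid_shape", "coupling_theta_conditions", "coupling_beta_conditions"):
            if key in sim and isinstance(sim[key], list):
                sim[key] = tuple(sim[key])
        if "condition_betas" not in sim or sim["condition_betas"] is None:
            sim.pop("condition_betas", None)
        return cls(sim=SimConfig(**sim), **d)


def _hash_params(cfg: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig, write_outputs: bool = True) -> dict:
    """Execute the full fusion analysis on a simulated session.

    Returns a manifest dict with per-stage outputs (tables as DataFrames,
    maps as arrays) and, when ``write_outputs`` is set, serializes the
    standard-format files under ``cfg.out_dir``.
    """
    out = Path(cfg.out_dir)
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "param_hash": _hash_params(cfg),
        "stages": {},
    }
    sim = cfg.sim
    stage = "simulate"
    trials = simulate_task(sim)
    gt = build_ground_truth(trials, sim)
    manifest["stages"][stage] = {"n_trials": len(trials)}

    grid = build_frequency_grid()
    layer = grid.theta_layer if cfg.band == "theta" else grid.beta_layer
    window = THETA_WINDOW_MS if cfg.band == "theta" else BETA_WINDOW_MS

    peak_tables = []
    condition_mod_maps: dict[int, dict[str, np.ndarray]] = {}
    for subject in range(sim.n_subjects):
        rec, _ = simulate_eeg(trials, sim, ground_truth=gt, subject=subject)
        sub_trials = trials[trials["subject"] == subject].reset_index(drop=True)
        epochs = preprocess_recording(
            rec,
            gradient=sim.artifact.gradient,
            bcg=sim.artifact.bcg,
            metadata=sub_trials[["subject", "block", "trial", "condition"]],
        )
        power = baseline_normalize(morlet_power(epochs, grid, layer))
        peaks = extract_peak_power(power, window)
        peak_tables.append(peaks)

        weights = orthogonalize_modulators(peaks)
        motion = simulate_motion(sim, subject)
        design = build_first_level_design(
            sub_trials, weights, sim.n_scans_per_block, sim.tr,
            motion=motion, discard=cfg.discard_volumes,
        )
        bold_blocks = simulate_bold(trials, gt, sim, subject=subject)
        data4d = np.concatenate(bold_blocks, axis=3)
        fit = fit_first_level_glm(
            data4d, design,
            prewhiten=cfg.prewhiten,
            smoothing_fwhm_mm=cfg.smoothing_fwhm_mm,
            voxel_size_mm=sim.voxel_size_mm,
            discard=cfg.discard_volumes,
        )
        maps = {}
        for cond in CONDITIONS:
            if f"mod_{cond}" in fit.columns:
                maps[cond] = fit.beta_map(f"mod_{cond}")
            else:
                # modulator unestimable (every cell of this condition had
                # <= 1 trial): contribute a zero effect, note it
                maps[cond] = np.zeros(sim.grid_shape)
                manifest["stages"].setdefault("degenerate_modulators", []).append(
                    {"subject": subject, "condition": cond}
                )
        condition_mod_maps[subject] = maps
    peak_table = pd.concat(peak_tables, ignore_index=True)
    manifest["stages"]["timefreq"] = {"n_peaks": len(peak_table)}
    if write_outputs:
        ofio.write_table(peak_table, out / "peak_table.tsv")
        ofio.write_table(trials, out / "trials.tsv")

    # group mixed model on peak power (valence/magnitude)
    lmm = None
    if sim.n_subjects >= 2:
        cells = aggregate_cell_means(peak_table)
        if cells.groupby("subject").size().min() >= 2:
            lmm = fit_power_lmm(cells)
            manifest["stages"]["lmm"] = {
                "p_values": lmm.p_values, "f_stats": lmm.f_stats,
            }

    contrast = "loss_gt_gain" if cfg.band == "theta" else "gain_gt_loss"
    group = second_level_contrast(condition_mod_maps, contrast)
    clusters = cluster_inference(
        group,
        shape=sim.grid_shape,
        voxel_p=cfg.voxel_p,
        extent_k=cfg.extent_k,
        n_permutations=cfg.n_permutations,
        seed=child_seed(cfg.seed, "permutation"),
        affine=sim.affine,
    )
    manifest["stages"]["cluster"] = {"n_clusters": len(clusters)}
    if write_outputs:
        ofio.write_table(clusters, out / "clusters.tsv")
        ofio.write_nifti(group.t_map.reshape(sim.grid_shape), sim.affine, out / "group_t.nii")

    # ROI correlations with simulated trait scores
    corr = None
    if len(clusters) > 0 and sim.n_subjects >= 3:
        traits = simulate_trait_scores(gt, sim, rho=cfg.trait_rho)
        rois = [
            ROISpec(
                center_mm=(row["peak_mm_x"], row["peak_mm_y"], row["peak_mm_z"]),
                radius_mm=cfg.roi_radius_mm,
                label=f"cluster_{int(row['label'])}",
            )
            for _, row in clusters.iterrows()
        ]
        score_maps = {
            s: group.subject_scores[i].reshape(sim.grid_shape)
            for i, s in enumerate(sorted(condition_mod_maps))
        }
        summaries = pd.DataFrame(
            {r.label: sphere_roi_mean(score_maps, r, sim.affine) for r in rois}
        )
        corr = correlate_rois_with_traits(summaries, traits)
        manifest["stages"]["roi_corr"] = {"n_tests": len(corr)}
        if write_outputs:
            ofio.write_table(corr, out / "roi_correlations.tsv")

    manifest["results"] = {
        "peak_table": peak_table,
        "lmm": lmm,
        "group": group,
        "clusters": clusters,
        "roi_correlations": corr,
        "ground_truth": gt,
    }
    if write_outputs:
        with open(out / "manifest.json", "w") as fh:
            json.dump(
                {k: v for k, v in manifest.items() if k != "results"},
                fh, indent=2, default=str,
            )
    return manifest
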