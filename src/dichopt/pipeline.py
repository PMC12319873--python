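"""End-to-end orchestration of the two analysis arms.

``run_fmri_arm`` simulates a laminar BOLD session on a synthetic cortical
ribbon and runs depth estimation, the block GLM, vein exclusion, depth
profiles, the amblyopic deficit index, and the inverted encoding model
with its binocular suppression profile, comparing every recovered
quantity against the planted truth.

``run_eeg_arm`` simulates a cohort of dichoptic SSVEP sessions and runs
the amplitude and phase pipelines, per-subject ADI/BSI/intermodulation
indices, multivariate outlier flagging, bootstrap confidence intervals,
circular phase tests, and the ADI-BSI correlation.

Every persisted table carries a provenance header (config hash + seed);
rerunning with the same configuration reproduces it exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .hrf import BlockHRF
from .iem import bsi_profile
from .laminar import (
    adi_table,
    equivolume_depth,
    fit_block_glm,
    laminar_profile,
    sample_ribbon,
    select_ocular_rois,
    surface_map,
    split_half_extract,
    vein_mask,
)
from .ssvep import (
    check_exact_bins,
    bandpass,
    condition_phase,
    condition_spectrum,
    im_amplitude,
    indices_from_amplitudes,
    phase_to_delay,
    tagged_amplitude,
    wrap_phase,
)
from .stats import (
    adi_bsi_correlation,
    bootstrap_ci,
    mahalanobis_outliers,
    paired_phase_test,
)
from .synth.boldsim import LaminarTruth, make_odc_weights, simulate_bold_run
from .synth.design import enumerate_conditions, make_block_design, tag_frequency_map
from .synth.eegsim import SSVEPTruth, simulate_ssvep_recording
from .synth.mesh import make_cortical_ribbon


@dataclass
class FMRIConfig:
    """Simulation + analysis settings for the laminar fMRI arm.

    Thresholds default to the published analysis values: vein exclusion
    at 70 % mean intensity / 10 PSC, 10 % ocular-bias vertices per side,
    18-s stimulus and 12-s fixation blocks (282-s runs).
    """

    shape: str = "wedge"
    n_vertices: int = 900
    thickness: float = 2.0
    area_ratio: float = 2.0
    voxel_size: float = 0.4
    n_surfaces: int = 11
    n_runs: int = 4
    n_per_condition: int = 3
    block_s: float = 18.0
    fix_s: float = 12.0
    tr: float = 2.0
    noise_sd: float = 0.2
    drift_order: int = 3
    adi: float = 0.3
    bsi_ae: tuple[float, float] = (0.45, 0.25)  # (pial, white), linear in depth
    bsi_fe: tuple[float, float] = (0.05, 0.10)
    vein_frac: float = 0.03
    vein_intensity_frac: float = 0.70
    vein_psc_max: float = 10.0
    roi_frac: float = 0.10
    odc_contrast: float = 0.8
    odc_gain: float = 0.9


@dataclass
class EEGConfig:
    """Simulation + analysis settings for the SSVEP EEG arm."""

    n_subjects: int = 12
    n_trials: int = 20
    srate: float = 1000.0
    trial_s: float = 6.0
    band: tuple[float, float] = (1.0, 30.0)
    phase_band: tuple[float, float] = (6.0, 9.0)
    amp_window: tuple[float, float] = (1.0, 6.0)
    phase_window: tuple[float, float] = (1.25, 5.0)
    noise_sd: float = 2.0
    adi_mono_mean: float = 0.35
    adi_mono_sd: float = 0.10
    bsi_ae_mean: float = 0.40
    bsi_ae_sd: float = 0.12
    bsi_fe_mean: float = 0.05
    bsi_fe_sd: float = 0.04
    ae_latency_ms: float = 12.81
    im_amp: float = 0.3
    outlier_alpha: float = 0.01


@dataclass
class PipelineConfig:
    """Full pipeline configuration (both arms)."""

    arm: str = "both"
    seed: int = 0
    fmri: FMRIConfig = field(default_factory=FMRIConfig)
    eeg: EEGConfig = field(default_factory=EEGConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        return dio.config_hash(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        fmri = FMRIConfig(**{k: tuple(v) if isinstance(v, list) else v
                             for k, v in d.pop("fmri", {}).items()})
        eeg = EEGConfig(**{k: tuple(v) if isinstance(v, list) else v
                           for k, v in d.pop("eeg", {}).items()})
        return cls(fmri=fmri, eeg=eeg, **d)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _provenance(config: PipelineConfig) -> dict:
    return {"config_hash": config.hash(), "seed": config.seed}


# ---------------------------------------------------------------------------
# fMRI arm


def run_fmri_arm(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Simulate and analyze a laminar fMRI session; return all artifacts.

    Returns a dict with the depth volume, per-run GLMs, vein mask, depth
    profiles per condition, the ADI table, the IEM BSI profile, the
    split-half ROI extraction, and a recovery report against the planted
    truth.
    """
    cfg = config.fmri
    rng = np.random.default_rng(config.seed)

    mesh = make_cortical_ribbon(
        cfg.shape, cfg.n_vertices, cfg.thickness, area_ratio=cfg.area_ratio
    )
    grid = sample_ribbon(mesh, voxel_size=cfg.voxel_size)
    depthvol = equivolume_depth(mesh, grid, n_surfaces=cfg.n_surfaces)
    grid = depthvol.grid  # vertices without area information are dropped

    n_vein = int(round(cfg.vein_frac * mesh.n_vertices))
    vein_vertices = rng.choice(mesh.n_vertices, size=n_vein, replace=False)
    dgrid = np.linspace(0.0, 1.0, 21)
    truth = LaminarTruth.from_adi(
        adi=cfg.adi,
        fe_profile=1.0,
        bsi_ae=np.interp(dgrid, [0, 1], cfg.bsi_ae),
        bsi_fe=np.interp(dgrid, [0, 1], cfg.bsi_fe),
        depth_grid=dgrid,
        vein_vertices=vein_vertices,
    )
    weights = make_odc_weights(
        mesh, contrast=cfg.odc_contrast, gain=cfg.odc_gain, seed=config.seed
    )
    hrf = BlockHRF()

    runs, glms = [], []
    for r in range(cfg.n_runs):
        events = make_block_design(
            cfg.n_per_condition, cfg.block_s, cfg.fix_s, seed=config.seed * 1000 + r
        )
        run = simulate_bold_run(
            mesh,
            grid,
            truth,
            events,
            tr=cfg.tr,
            noise_sd=cfg.noise_sd,
            seed=config.seed * 1000 + r,
            weights=weights,
            hrf=hrf,
            depth=depthvol.depth,
        )
        runs.append(run)
        glms.append(
            fit_block_glm(run.bold, events, cfg.tr, drift_order=cfg.drift_order, hrf=hrf)
        )

    mean_glm = glms[0]
    mean_glm = dataclasses.replace(
        mean_glm,
        beta=np.mean([g.beta for g in glms], axis=0),
        mean_epi=np.mean([g.mean_epi for g in glms], axis=0),
        residual_sd=np.mean([g.residual_sd for g in glms], axis=0),
    )
    veins = vein_mask(
        mean_glm, mesh, grid,
        intensity_frac=cfg.vein_intensity_frac, psc_max=cfg.vein_psc_max,
    )

    profile = laminar_profile(mean_glm, depthvol, mask=veins, n_bins=3)
    adi = adi_table(profile)
    bsi = bsi_profile(
        mean_glm.beta_for("AE"),
        mean_glm.beta_for("FE"),
        mean_glm.beta_for("binocular"),
        depthvol.depth,
        n_bins=3,
        voxel_mask=veins.voxel_keep,
    )

    # ocular-bias ROIs on the surface, plus the split-half extraction
    run_maps = np.stack(
        [
            np.stack(
                [surface_map(g.beta[ci], grid, mesh.n_vertices) for ci in range(3)]
            )
            for g in glms
        ]
    )
    run_maps = np.nan_to_num(run_maps)
    mean_maps = run_maps.mean(axis=0)
    conds = list(mean_glm.conditions)
    rois = select_ocular_rois(
        mean_maps[conds.index("AE")], mean_maps[conds.index("FE")], frac=cfg.roi_frac
    )
    split_half = split_half_extract(run_maps, conds, frac=cfg.roi_frac)

    # recovery report against planted truth
    centers = profile["depth_center"].to_numpy()
    truth_at = truth.at_depth(centers)
    adi_truth = (truth_at["profile_fe"] - truth_at["profile_ae"]) / truth_at["profile_fe"]
    vein_hit = (
        np.isin(np.flatnonzero(veins.vertex_flagged), vein_vertices).sum()
        / max(1, n_vein)
    )
    report = {
        "adi_by_layer": adi["adi"].to_list(),
        "adi_truth_by_layer": adi_truth.tolist(),
        "adi_max_abs_error": float(np.nanmax(np.abs(adi["adi"].to_numpy() - adi_truth))),
        "adi_flatness": float(
            np.nanmax(adi["adi"].to_numpy()) - np.nanmin(adi["adi"].to_numpy())
        ),
        "bsi_ae_by_layer": bsi["bsi_AE"].to_list(),
        "bsi_fe_by_layer": bsi["bsi_FE"].to_list(),
        "bsi_ae_truth_by_layer": np.interp(centers, [0, 1], cfg.bsi_ae).tolist(),
        "bsi_fe_truth_by_layer": np.interp(centers, [0, 1], cfg.bsi_fe).tolist(),
        "vein_recall": float(vein_hit),
        "n_gm_voxels": int(grid.n_voxels),
    }
    report["bsi_ae_max_abs_error"] = float(
        np.nanmax(np.abs(np.array(report["bsi_ae_by_layer"]) - report["bsi_ae_truth_by_layer"]))
    )

    results = {
        "mesh": mesh,
        "grid": grid,
        "depth": depthvol,
        "truth": truth,
        "glms": glms,
        "mean_glm": mean_glm,
        "veins": veins,
        "profile": profile,
        "adi": adi,
        "bsi": bsi,
        "rois": rois,
        "split_half": split_half,
        "report": report,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        prov = _provenance(config)
        config.save(outdir / "config.json")
        dio.save_nifti(outdir / "depth.nii.gz", depthvol.depth, grid)
        dio.save_nifti(
            outdir / "layers.nii.gz",
            np.searchsorted([1 / 3, 2 / 3], depthvol.depth, side="right").astype(float),
            grid,
        )
        dio.save_nifti(outdir / "vein_keep.nii.gz", veins.voxel_keep.astype(float), grid)
        dio.save_table(outdir / "profile.tsv", profile, prov)
        dio.save_table(outdir / "adi.tsv", adi, prov)
        dio.save_table(outdir / "bsi.tsv", bsi, prov)
        dio.save_table(outdir / "split_half.tsv", split_half, prov)
        (outdir / "report.json").write_text(json.dumps({**prov, **report}, indent=1))
    return results


# ---------------------------------------------------------------------------
# EEG arm


def _draw_subject_truth(cfg: EEGConfig, rng: np.random.Generator) -> SSVEPTruth:
    adi = float(np.clip(rng.normal(cfg.adi_mono_mean, cfg.adi_mono_sd), 0.0, 0.9))
    bsi_ae = float(np.clip(rng.normal(cfg.bsi_ae_mean, cfg.bsi_ae_sd), -0.2, 0.95))
    bsi_fe = float(np.clip(rng.normal(cfg.bsi_fe_mean, cfg.bsi_fe_sd), -0.2, 0.95))
    amp_fe = rng.uniform(1.5, 2.5)
    return SSVEPTruth(
        amp1={"AE": amp_fe * (1 - adi), "FE": amp_fe},
        amp2={"AE": 0.4 * amp_fe * (1 - adi), "FE": 0.4 * amp_fe},
        im_amp=cfg.im_amp,
        latency_ms={"AE": cfg.ae_latency_ms, "FE": 0.0},
        bsi={"AE": bsi_ae, "FE": bsi_fe},
        noise_sd=cfg.noise_sd,
    )


def analyze_ssvep_session(rec, cfg: EEGConfig, sf: str = "low") -> dict:
    """Amplitude + phase read-out for one subject at one spatial frequency.

    Tagged amplitudes are harmonic-summed per eye, then averaged over the
    two tag-frequency assignments; the intermodulation amplitude comes
    from the binocular conditions.  Phases are estimated per eye at each
    tag frequency from the monocular conditions.
    """
    filt_amp = bandpass(rec, *cfg.band)
    filt_phase = bandpass(rec, *cfg.phase_band)
    amps = {"AE": {"mono": [], "bino": []}, "FE": {"mono": [], "bino": []}}
    im_vals = []
    phases: dict[tuple[str, float], float] = {}
    for assignment in ("f1=AE", "f1=FE"):
        fmap = tag_frequency_map(assignment)
        for ocularity in ("AE", "FE", "binocular"):
            cond = f"{sf}/{ocularity}/{assignment}"
            spec = condition_spectrum(
                rec, cond, window=cfg.amp_window, prefiltered=filt_amp
            )
            if ocularity == "binocular":
                for eye in ("AE", "FE"):
                    amps[eye]["bino"].append(tagged_amplitude(spec, fmap[eye]).amp_sum)
                im_vals.append(im_amplitude(spec, *sorted(fmap.values())))
            else:
                amps[ocularity]["mono"].append(
                    tagged_amplitude(spec, fmap[ocularity]).amp_sum
                )
                est = condition_phase(
                    rec, cond, fmap[ocularity],
                    window=cfg.phase_window, prefiltered=filt_phase,
                )
                phases[(ocularity, fmap[ocularity])] = est.phase
    mono_ae = float(np.mean(amps["AE"]["mono"]))
    mono_fe = float(np.mean(amps["FE"]["mono"]))
    bino_ae = float(np.mean(amps["AE"]["bino"]))
    bino_fe = float(np.mean(amps["FE"]["bino"]))
    idx = indices_from_amplitudes(mono_ae, mono_fe, bino_ae, bino_fe)
    # AE-FE phase difference at each tag frequency; FE leads when AE is delayed
    deltas = {
        f: wrap_phase(phases[("FE", f)] - phases[("AE", f)]) for f in (7.2, 8.0)
    }
    delay_ms = float(np.mean([phase_to_delay(d, 0.0, f) for f, d in deltas.items()]))
    return {
        "mono_AE": mono_ae,
        "mono_FE": mono_fe,
        "bino_AE": bino_ae,
        "bino_FE": bino_fe,
        "im_amp": float(np.mean(im_vals)),
        **idx,
        "phase_delta_7.2": float(deltas[7.2]),
        "phase_delta_8.0": float(deltas[8.0]),
        "ae_fe_delay_ms": delay_ms,
    }


def run_eeg_arm(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Simulate and analyze an SSVEP cohort; return tables and tests."""
    cfg = config.eeg
    check_exact_bins(
        window_s=cfg.amp_window[1] - cfg.amp_window[0],
        phase_window_s=cfg.phase_window[1] - cfg.phase_window[0],
    )
    rng = np.random.default_rng(config.seed)
    conditions = enumerate_conditions()
    low_only = [c for c in conditions if c[0] == "low"]

    rows, truths = [], []
    for s in range(cfg.n_subjects):
        truth = _draw_subject_truth(cfg, rng)
        truths.append(truth)
        rec = simulate_ssvep_recording(
            truth,
            n_trials=cfg.n_trials,
            srate=cfg.srate,
            trial_s=cfg.trial_s,
            seed=config.seed * 10000 + s,
            conditions=low_only,
        )
        row = analyze_ssvep_session(rec, cfg, sf="low")
        row["subject"] = s
        row["bsi_ae_true"] = truth.bsi["AE"]
        row["bsi_fe_true"] = truth.bsi["FE"]
        row["adi_mono_true"] = 1 - truth.amp1["AE"] / truth.amp1["FE"]
        rows.append(row)
    table = pd.DataFrame(rows).set_index("subject")

    adi_diff = (table["ADI_bino"] - table["ADI_mono"]).to_numpy()
    bsi_diff = (table["BSI_AE"] - table["BSI_FE"]).to_numpy()
    outliers = mahalanobis_outliers(
        np.column_stack([adi_diff, bsi_diff]), alpha=cfg.outlier_alpha
    )
    keep = ~outliers["flagged"].to_numpy()
    corr = adi_bsi_correlation(adi_diff[keep], bsi_diff[keep])

    phase_tests = {
        f"{f}Hz": paired_phase_test(table[f"phase_delta_{f}"].to_numpy()[keep], f)
        for f in (7.2, 8.0)
    }
    cis = {
        col: bootstrap_ci(table[col].to_numpy()[keep], seed=config.seed)
        for col in ("ADI_mono", "ADI_bino", "BSI_AE", "BSI_FE", "im_amp")
    }

    results = {
        "table": table,
        "outliers": outliers,
        "correlation": corr,
        "phase_tests": phase_tests,
        "bootstrap_cis": cis,
        "truths": truths,
        "report": {
            "n_subjects": cfg.n_subjects,
            "n_conditions": len(conditions),
            "mean_ae_fe_delay_ms": float(table["ae_fe_delay_ms"][keep].mean()),
            "planted_ae_latency_ms": cfg.ae_latency_ms,
            "adi_bsi_r": corr["r"],
        },
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        prov = _provenance(config)
        config.save(outdir / "config.json")
        dio.save_table(outdir / "indices.tsv", table, prov)
        dio.save_table(outdir / "outliers.tsv", outliers, prov)
        (outdir / "group_tests.json").write_text(
            json.dumps(
                {
                    **prov,
                    "correlation": corr,
                    "phase_tests": phase_tests,
                    "bootstrap_cis": cis,
                    **results["report"],
                },
                indent=1,
                default=float,
            )
        )
    return results
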