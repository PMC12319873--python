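"""Simulate the laminar fMRI session and persist its raw artifacts.

Builds the curved cortical-ribbon fixture, plants a flat amblyopic
deficit (ADI 0.3) with depth-graded binocular suppression and a few
vein-contaminated columns, and simulates a multi-run block-design BOLD
session (18-s AE / FE / binocular blocks, 12-s fixation, 282 s per run).
Writes the meshes, an example events table, and the ground truth under
results/fmri/raw/; later stages regenerate the session deterministically
from the saved config instead of re-reading the large volumes.
"""

import json
import sys
from pathlib import Path

from dichopt import io as dio
from dichopt.pipeline import PipelineConfig, run_fmri_arm
from dichopt.synth import make_block_design

OUT = Path("results/fmri")


def main(seed: int = 1) -> None:
    cfg = PipelineConfig(seed=seed)
    raw = OUT / "raw"
    raw.mkdir(parents=True, exist_ok=True)
    cfg.save(raw / "config.json")

    res = run_fmri_arm(cfg)
    mesh, grid, truth = res["mesh"], res["grid"], res["truth"]
    dio.save_mesh_pair(raw / "ribbon", mesh)
    events = make_block_design(
        cfg.fmri.n_per_condition, cfg.fmri.block_s, cfg.fmri.fix_s, seed=cfg.seed * 1000
    )
    dio.save_events_tsv(raw / "run-01_events.tsv", events)
    (raw / "truth.json").write_text(
        json.dumps(
            {
                "adi_true": truth.adi_true.tolist(),
                "depth_grid": truth.depth_grid.tolist(),
                "bsi_ae": truth.bsi_ae.tolist(),
                "bsi_fe": truth.bsi_fe.tolist(),
                "n_vein_vertices": int(truth.vein_vertices.size),
                "seed": cfg.seed,
            },
            indent=1,
        )
    )
    print(f"ribbon: {mesh.metadata['shape']}, {mesh.n_vertices} vertices, "
          f"{grid.n_voxels} gray-matter voxels at {cfg.fmri.voxel_size} mm")
    print(f"session: {cfg.fmri.n_runs} runs x 282 s, TR {cfg.fmri.tr} s, "
          f"noise {cfg.fmri.noise_sd} PSC")
    print(f"planted: flat ADI {cfg.fmri.adi}, BSI_AE {cfg.fmri.bsi_ae} "
          f"(pial->white), BSI_FE {cfg.fmri.bsi_fe}, "
          f"{truth.vein_vertices.size} vein columns")
    print(f"raw artifacts -> {raw}/")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
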