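"""Group statistics on the SSVEP cohort: outliers, CIs, circular tests,
and the ADI-BSI correlation.

Reads the per-subject index table written by 05_ssvep_indices.py (or
recomputes it), flags multivariate outliers by the 1 % Mahalanobis rule,
bootstraps 95 % confidence intervals of the group means, tests the AE-FE
phase delay with the circular-mean test, and correlates the extra
binocular deficit (ADI_bino - ADI_mono) with the suppression asymmetry
(BSI_AE - BSI_FE).
"""

import json
import sys
from pathlib import Path

import numpy as np

from dichopt import io as dio
from dichopt.pipeline import PipelineConfig, run_eeg_arm
from dichopt.stats import (
    adi_bsi_correlation,
    bootstrap_ci,
    mahalanobis_outliers,
    paired_phase_test,
)

OUT = Path("results/eeg")


def main(seed: int = 1) -> None:
    cfg_path = OUT / "raw" / "config.json"
    cfg = PipelineConfig.load(cfg_path) if cfg_path.exists() else PipelineConfig(seed=seed)
    idx_path = OUT / "indices.tsv"
    if idx_path.exists():
        table = dio.load_table(idx_path)
    else:
        table = run_eeg_arm(cfg)["table"]

    adi_diff = (table["ADI_bino"] - table["ADI_mono"]).to_numpy()
    bsi_diff = (table["BSI_AE"] - table["BSI_FE"]).to_numpy()
    outliers = mahalanobis_outliers(
        np.column_stack([adi_diff, bsi_diff]), alpha=cfg.eeg.outlier_alpha
    )
    keep = ~outliers["flagged"].to_numpy()
    print(f"outlier rule (alpha={cfg.eeg.outlier_alpha}): "
          f"{(~keep).sum()} of {keep.size} subjects flagged")

    summary = {}
    for col in ("ADI_mono", "ADI_bino", "BSI_AE", "BSI_FE", "im_amp"):
        vals = table[col].to_numpy()[keep]
        lo, hi = bootstrap_ci(vals, seed=cfg.seed)
        summary[col] = {"mean": float(vals.mean()), "ci95": [lo, hi]}
        print(f"  {col:9s} mean {vals.mean():+.3f}  95% CI [{lo:+.3f}, {hi:+.3f}]")

    tests = {}
    for f in (7.2, 8.0):
        t = paired_phase_test(table[f"phase_delta_{f}"].to_numpy()[keep], f)
        tests[f"{f}Hz"] = t
        print(f"AE-FE phase delay @ {f} Hz: {t['mean_delay_ms']:.2f} ms, "
              f"reject H0(no delay): {t['reject']} (p~{t['p_proxy']:.2g})")

    corr = adi_bsi_correlation(adi_diff[keep], bsi_diff[keep])
    print(f"Pearson r between (ADI_bino - ADI_mono) and (BSI_AE - BSI_FE): "
          f"r = {corr['r']:.3f}, p = {corr['p']:.2g}, n = {corr['n']}")

    OUT.mkdir(parents=True, exist_ok=True)
    dio.save_table(OUT / "outliers.tsv", outliers,
                   {"config_hash": cfg.hash(), "seed": cfg.seed})
    (OUT / "group_summary.json").write_text(
        json.dumps({"summary": summary, "phase_tests": tests, "correlation": corr},
                   indent=1, default=float)
    )
    print(f"group tables -> {OUT}/outliers.tsv, {OUT}/group_summary.json")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
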