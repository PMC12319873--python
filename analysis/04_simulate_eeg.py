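"""Simulate the dichoptic SSVEP cohort and persist one example session.

Each synthetic subject views 6-s dichoptic trials in which the two eyes
are frequency-tagged at 7.2 and 8 Hz (both tag-frequency assignments,
monocular and binocular, 12 conditions in all), recorded on a
15-electrode occipito-parietal montage at 1000 Hz with 1/f + white
noise.  Per-subject amblyopic deficits, binocular suppression
asymmetries and a 12.81-ms amblyopic-eye latency are planted.  One
subject's recording is written as the flat-binary + JSON container.
"""

import json
import sys
from pathlib import Path

from dichopt import io as dio
from dichopt.pipeline import PipelineConfig, _draw_subject_truth
from dichopt.synth import enumerate_conditions, simulate_ssvep_recording

import numpy as np

OUT = Path("results/eeg")


def main(seed: int = 1) -> None:
    cfg = PipelineConfig(seed=seed)
    raw = OUT / "raw"
    raw.mkdir(parents=True, exist_ok=True)
    cfg.save(raw / "config.json")

    rng = np.random.default_rng(cfg.seed)
    truths = [_draw_subject_truth(cfg.eeg, rng) for _ in range(cfg.eeg.n_subjects)]
    (raw / "cohort_truth.json").write_text(
        json.dumps(
            [
                {
                    "bsi": t.bsi, "latency_ms": t.latency_ms,
                    "amp1": t.amp1, "amp2": t.amp2, "im_amp": t.im_amp,
                }
                for t in truths
            ],
            indent=1,
        )
    )
    low = [c for c in enumerate_conditions() if c[0] == "low"]
    rec = simulate_ssvep_recording(
        truths[0], n_trials=cfg.eeg.n_trials, srate=cfg.eeg.srate,
        trial_s=cfg.eeg.trial_s, seed=cfg.seed * 10000, conditions=low,
    )
    dio.save_eeg(raw / "sub-01", rec)
    print(f"cohort: {cfg.eeg.n_subjects} subjects x {len(low)} conditions x "
          f"{cfg.eeg.n_trials} trials ({cfg.eeg.trial_s} s @ {cfg.eeg.srate:.0f} Hz)")
    print(f"planted (cohort means): BSI_AE {cfg.eeg.bsi_ae_mean}, "
          f"BSI_FE {cfg.eeg.bsi_fe_mean}, mono ADI {cfg.eeg.adi_mono_mean}, "
          f"AE latency {cfg.eeg.ae_latency_ms} ms, IM {cfg.eeg.im_amp} uV")
    print(f"example recording ({rec.data.shape[0]} ch x {rec.data.shape[1]} samples) "
          f"-> {raw}/sub-01.eeg.f32 + .json; cohort truth -> cohort_truth.json")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
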