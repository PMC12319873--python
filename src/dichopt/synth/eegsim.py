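"""Synthetic dichoptic SSVEP recordings with planted ground truth.

Each 6-s trial tags the two eyes with sinusoids at 7.2 and 8 Hz (first and
second harmonics) on a 15-electrode occipito-parietal montage.  Binocular
trials carry both eyes' components scaled by ``1 - BSI`` plus an
intermodulation sinusoid at ``f1 + f2``; monocular trials carry only the
stimulated eye's components.  Signals project dominantly to the six
central electrodes (fixed central:surround gain); noise is 1/f-shaped plus
a white floor, independent per channel.

Planted per-eye latencies (ms) convert to phase as ``phi = -2*pi*f*tau``,
so the least-squares phase pipeline can recover them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..containers import CENTRAL_ELECTRODES, MONTAGE_15, SURROUND_ELECTRODES, EEGRecording
from .design import enumerate_conditions, tag_frequency_map


@dataclass
class SSVEPTruth:
    """Planted SSVEP ground truth for one synthetic subject.

    Amplitudes are scalp microvolts at a central electrode (before the
    Laplacian).  ``bsi`` is the fraction of each eye's amplitude lost
    under binocular viewing; ``latency_ms`` the eye's response latency,
    realized as a frequency-dependent phase lag.
    """

    amp1: dict = field(default_factory=lambda: {"AE": 1.0, "FE": 1.0})
    amp2: dict = field(default_factory=lambda: {"AE": 0.4, "FE": 0.4})
    im_amp: float = 0.3
    latency_ms: dict = field(default_factory=lambda: {"AE": 0.0, "FE": 0.0})
    bsi: dict = field(default_factory=lambda: {"AE": 0.0, "FE": 0.0})
    sf_amp_scale: dict = field(default_factory=lambda: {"low": 1.0, "high": 0.7})
    noise_exponent: float = 1.0
    noise_sd: float = 0.0  # total noise RMS per channel, microvolts
    white_floor: float = 0.2  # white fraction of the noise power
    central_gain: float = 1.0
    surround_gain: float = 0.2  # 5:1 central:surround projection

    def __post_init__(self) -> None:
        for eye in ("AE", "FE"):
            if self.amp1[eye] < 0 or self.amp2[eye] < 0:
                raise ValueError("harmonic amplitudes must be >= 0")
            if not -1 < self.bsi[eye] <= 1:
                raise ValueError("BSI must lie in (-1, 1]")
        if self.im_amp < 0:
            raise ValueError("intermodulation amplitude must be >= 0")

    def phase(self, eye: str, f: float) -> float:
        """Fundamental phase (radians) implied by the eye's latency at f."""
        return float(-2.0 * np.pi * f * self.latency_ms[eye] / 1000.0)


def _one_over_f_noise(rng, n_ch, n_samp, srate, sd, exponent, white_floor):
    """Per-channel noise with power ~ f^-exponent plus a white floor, RMS = sd."""
    freqs = np.fft.rfftfreq(n_samp, 1 / srate)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    shape[1:] /= np.sqrt(np.mean(shape[1:] ** 2))
    white = rng.standard_normal((n_ch, n_samp))
    colored = np.fft.irfft(np.fft.rfft(white, axis=1) * shape[None, :], n=n_samp, axis=1)
    colored /= colored.std(axis=1, keepdims=True) + 1e-30
    floor = rng.standard_normal((n_ch, n_samp))
    mix = np.sqrt(1 - white_floor) * colored + np.sqrt(white_floor) * floor
    return sd * mix / (mix.std(axis=1, keepdims=True) + 1e-30)


def _condition_signal(truth: SSVEPTruth, sf, ocularity, assignment, t):
    """Noise-free central-electrode waveform for one condition."""
    fmap = tag_frequency_map(assignment)
    scale_sf = truth.sf_amp_scale[sf]
    sig = np.zeros_like(t)
    eyes = ("AE", "FE") if ocularity == "binocular" else (ocularity,)
    for eye in eyes:
        f = fmap[eye]
        phi = truth.phase(eye, f)
        gain = scale_sf * ((1.0 - truth.bsi[eye]) if ocularity == "binocular" else 1.0)
        sig += gain * truth.amp1[eye] * np.cos(2 * np.pi * f * t + phi)
        sig += gain * truth.amp2[eye] * np.cos(2 * (2 * np.pi * f * t + phi))
    if ocularity == "binocular" and truth.im_amp > 0:
        f_im = sum(fmap.values())
        sig += scale_sf * truth.im_amp * np.cos(2 * np.pi * f_im * t)
    return sig


def simulate_ssvep_recording(
    truth: SSVEPTruth,
    n_trials: int = 20,
    srate: float = 1000.0,
    trial_s: float = 6.0,
    seed: int = 0,
    conditions: list[tuple[str, str, str]] | None = None,
    analysis_window_s: float = 5.0,
    gap_s: float = 1.0,
    gap_jitter_s: float = 0.5,
) -> EEGRecording:
    """Simulate a full 12-condition dichoptic SSVEP session.

    Trials of every condition are interleaved in ``n_trials`` pseudo-random
    sweeps and concatenated into one continuous record with a trial table.
    Trials are separated by stimulus-free gaps of ``gap_s`` plus a uniform
    jitter up to ``gap_jitter_s`` (trials are self-initiated, so onsets are
    asynchronous); the jitter also randomizes the phase at which one
    trial's tail leaks into its neighbor through zero-phase filtering.
    Emits a warning if a tag frequency is not an integer multiple of the
    analysis window's spectral resolution (off-bin leakage would follow).
    """
    if trial_s < 6.0:
        raise ValueError("trials must be at least 6 s (last 5 s are analyzed)")
    conditions = conditions if conditions is not None else enumerate_conditions()
    f_max = 2 * max(
        max(tag_frequency_map(a).values()) for _, _, a in conditions
    )
    if srate < 4 * f_max:
        raise ValueError(f"srate must be >= 4x the highest harmonic ({f_max} Hz)")
    res = 1.0 / analysis_window_s
    for _, _, a in conditions:
        for f in tag_frequency_map(a).values():
            if abs(f / res - round(f / res)) > 1e-9:
                warnings.warn(
                    f"tag frequency {f} Hz is off the {res} Hz analysis grid",
                    stacklevel=2,
                )

    rng = np.random.default_rng(seed)
    n_samp = int(round(trial_s * srate))
    t = np.arange(n_samp) / srate
    n_ch = len(MONTAGE_15)
    gains = np.array(
        [
            truth.central_gain if ch in CENTRAL_ELECTRODES else truth.surround_gain
            for ch in MONTAGE_15
        ]
    )

    order = []
    for _ in range(n_trials):
        order.extend(rng.permutation(len(conditions)))

    chunks, rows = [], []
    onset = 0
    for ci in order:
        sf, ocularity, assignment = conditions[ci]
        sig = _condition_signal(truth, sf, ocularity, assignment, t)
        trial = gains[:, None] * sig[None, :]
        if truth.noise_sd > 0:
            trial = trial + _one_over_f_noise(
                rng, n_ch, n_samp, srate, truth.noise_sd,
                truth.noise_exponent, truth.white_floor,
            )
        gap = int(round((gap_s + rng.uniform(0, gap_jitter_s)) * srate))
        rest = np.zeros((n_ch, gap))
        if truth.noise_sd > 0 and gap > 1:
            rest = _one_over_f_noise(
                rng, n_ch, gap, srate, truth.noise_sd,
                truth.noise_exponent, truth.white_floor,
            )
        chunks.extend([trial, rest])
        rows.append((f"{sf}/{ocularity}/{assignment}", sf, ocularity, assignment, onset))
        onset += n_samp + gap

    trials = pd.DataFrame(
        rows, columns=["condition", "sf", "ocularity", "assignment", "onset_sample"]
    )
    return EEGRecording(
        data=np.concatenate(chunks, axis=1),
        srate=srate,
        channel_labels=list(MONTAGE_15),
        trials=trials,
        trial_len_s=trial_s,
    )
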