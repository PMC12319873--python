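"""Shared in-memory containers and the occipito-parietal EEG montage."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Central electrodes of the surface-Laplacian reference.
CENTRAL_ELECTRODES = ("O1", "Oz", "O2", "PO3", "POz", "PO4")
#: Surround electrodes of the surface-Laplacian reference.
SURROUND_ELECTRODES = ("P5", "P3", "P1", "Pz", "P2", "P4", "P6", "PO7", "PO8")
#: Full 15-channel montage, central first.
MONTAGE_15 = CENTRAL_ELECTRODES + SURROUND_ELECTRODES


@dataclass
class EEGRecording:
    """Multi-channel EEG with montage labels and trial annotations.

    Attributes
    ----------
    data : (n_channels, n_samples) float array, microvolts
    srate : sampling rate, Hz
    channel_labels : unique montage names, one per row of ``data``
    trials : DataFrame with at least ``condition`` and ``onset_sample``
    trial_len_s : trial duration in seconds
    """

    data: np.ndarray
    srate: float
    channel_labels: list[str]
    trials: pd.DataFrame
    trial_len_s: float

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, float))
        if self.srate <= 0:
            raise ValueError("srate must be positive")
        if len(self.channel_labels) != len(set(self.channel_labels)):
            raise ValueError("channel labels must be unique")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one label per channel row is required")
        n_trial = int(round(self.trial_len_s * self.srate))
        if len(self.trials) and (
            self.trials["onset_sample"].max() + n_trial > self.data.shape[1]
        ):
            raise ValueError("trial windows extend beyond the recording")

    @property
    def n_samples_per_trial(self) -> int:
        return int(round(self.trial_len_s * self.srate))

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.data[self.channel_labels.index(label)]
        except ValueError:
            raise KeyError(f"channel {label!r} not in the recording") from None

    def with_data(self, data: np.ndarray) -> "EEGRecording":
        """Same annotations, new sample array (e.g. after filtering)."""
        return EEGRecording(
            data=data,
            srate=self.srate,
            channel_labels=list(self.channel_labels),
            trials=self.trials.copy(),
            trial_len_s=self.trial_len_s,
        )
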