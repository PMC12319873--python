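"""Canonical block hemodynamic response and GLM design construction.

The same :class:`BlockHRF` object is used by the BOLD simulator and by the
block GLM, so that in noiseless simulations the regression model is exactly
the generative model and planted percent-signal-change amplitudes are
recovered to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln


def _gamma_pdf(t: np.ndarray, shape: float, scale: float) -> np.ndarray:
    t = np.maximum(t, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = (
            (shape - 1) * np.log(t) - t / scale - shape * np.log(scale) - gammaln(shape)
        )
    out = np.where(t > 0, np.exp(logp), 0.0)
    return out


@dataclass(frozen=True)
class BlockHRF:
    """Gamma-difference impulse response for block designs.

    A canonical double-gamma shape (peak ~6 s, undershoot ~16 s with a
    1:6 amplitude ratio) sampled on a fine time grid.  Block regressors
    are normalized so the response to a single stimulus block peaks at
    1.0; a GLM beta is then the block response amplitude in the units of
    the data.

    Parameters
    ----------
    peak_delay, undershoot_delay : s
        Gamma means of the positive and undershoot lobes.
    undershoot_ratio :
        Peak:undershoot amplitude ratio.
    duration : s
        Kernel support.
    dt : s
        Internal sampling step for convolution.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    undershoot_ratio: float = 6.0
    duration: float = 32.0
    dt: float = 0.1

    def kernel(self) -> np.ndarray:
        """Impulse response sampled at ``dt`` (unit peak, arbitrary area)."""
        t = np.arange(0.0, self.duration + self.dt / 2, self.dt)
        h = _gamma_pdf(t, self.peak_delay, 1.0) - _gamma_pdf(
            t, self.undershoot_delay, 1.0
        ) / self.undershoot_ratio
        return h / h.max()

    def block_response(self, duration_s: float) -> np.ndarray:
        """Response to one block of ``duration_s`` seconds, at ``dt``."""
        n = max(1, int(round(duration_s / self.dt)))
        box = np.ones(n)
        return np.convolve(box, self.kernel())

    def regressor(
        self, onsets: np.ndarray, durations: np.ndarray, n_vols: int, tr: float
    ) -> np.ndarray:
        """Convolved, peak-normalized regressor sampled at volume times.

        Normalization divides by the peak of the single-block response for
        the (median) block duration, so an isolated block of that duration
        reaches 1.0.
        """
        total = n_vols * tr
        n_fine = int(round(total / self.dt))
        stim = np.zeros(n_fine)
        for onset, dur in zip(np.atleast_1d(onsets), np.atleast_1d(durations)):
            i0 = int(round(onset / self.dt))
            i1 = min(n_fine, i0 + int(round(dur / self.dt)))
            stim[i0:i1] = 1.0
        conv = np.convolve(stim, self.kernel())[:n_fine]
        peak = self.block_response(float(np.median(durations))).max()
        conv /= peak
        vol_idx = np.round(np.arange(n_vols) * tr / self.dt).astype(int)
        return conv[np.minimum(vol_idx, n_fine - 1)]


def legendre_drift(n_vols: int, order: int) -> np.ndarray:
    """Legendre polynomial drift regressors (n_vols, order + 1), P0 = 1."""
    x = np.linspace(-1.0, 1.0, n_vols)
    return np.polynomial.legendre.legvander(x, order)


def build_design(
    events: pd.DataFrame,
    n_vols: int,
    tr: float,
    hrf: BlockHRF | None = None,
    drift_order: int = 3,
    motion: np.ndarray | None = None,
    fixation_label: str = "fixation",
) -> tuple[np.ndarray, list[str], list[str]]:
    """Assemble the block GLM design matrix.

    Columns are, in order: one HRF-convolved boxcar per stimulus
    condition (sorted label order), Legendre drift polynomials up to
    ``drift_order`` (P0 is the intercept), then optional motion columns.

    Returns
    -------
    X : (n_vols, p) design matrix
    names : column names
    conditions : stimulus condition labels (order matches leading columns)
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    run_len = n_vols * tr
    if (events["onset"] + events["duration"]).max() > run_len + 1e-9:
        raise ValueError("events extend beyond the run length")
    hrf = hrf or BlockHRF()
    conditions = sorted(set(events["trial_type"]) - {fixation_label})
    cols, names = [], []
    for cond in conditions:
        sel = events[events["trial_type"] == cond]
        cols.append(
            hrf.regressor(
                sel["onset"].to_numpy(), sel["duration"].to_numpy(), n_vols, tr
            )
        )
        names.append(cond)
    drift = legendre_drift(n_vols, drift_order)
    for k in range(drift.shape[1]):
        cols.append(drift[:, k])
        names.append(f"drift{k}")
    if motion is not None:
        motion = np.atleast_2d(np.asarray(motion, float))
        if motion.shape[0] != n_vols:
            motion = motion.T
        for k in range(motion.shape[1]):
            cols.append(motion[:, k])
            names.append(f"motion{k}")
    return np.column_stack(cols), names, conditions
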