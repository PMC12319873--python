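"""Inverted encoding model for monocular channel unmixing.

Forward model: each voxel's response is a linear mix of two monocular
channel responses, ``Y = W C``, with non-negative per-voxel mixing weights
``W`` (voxels x 2).  The weights are solved from the monocular conditions
(channel design ``C_mono = I``) by non-negative least squares; the model is
then inverted on the binocular condition by ordinary least squares across
the voxels of a depth bin, giving the binocular channel responses
``C_bino`` and the binocular suppression index ``BSI = 1 - C_bino`` per
eye.  Because negative-going voxels are clamped rather than excluded, and
because inversion pools voxels with mixed weights, the IEM undoes the
partial-volume underestimation that raw voxel contrasts suffer.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import nnls

_COND_TOL = 1e8  # weight-matrix condition number beyond which a bin is ill-posed


def fit_weights_nnls(y_mono: np.ndarray, c_mono: np.ndarray | None = None) -> np.ndarray:
    """Solve per-voxel non-negative mixing weights from monocular betas.

    Parameters
    ----------
    y_mono : (N, n_cond)
        Voxel betas under the monocular conditions, column order matching
        the columns of ``c_mono``.
    c_mono : (n_channels, n_cond), optional
        Channel design; defaults to the 2x2 identity (condition j drives
        channel j alone), for which NNLS reduces to clamping negative
        betas at zero.  General designs are solved properly.

    Returns
    -------
    W : (N, n_channels), elementwise >= 0.
    """
    y_mono = np.atleast_2d(np.asarray(y_mono, float))
    if c_mono is None:
        c_mono = np.eye(2)
    c_mono = np.asarray(c_mono, float)
    if y_mono.shape[1] != c_mono.shape[1]:
        raise ValueError(
            f"need betas for all {c_mono.shape[1]} monocular conditions, "
            f"got {y_mono.shape[1]}"
        )
    # y_voxel (n_cond,) = C_mono.T @ w_voxel  ->  NNLS with matrix C_mono.T
    a = c_mono.T
    if np.array_equal(a, np.eye(a.shape[0])):
        return np.maximum(y_mono, 0.0)
    w = np.empty((y_mono.shape[0], c_mono.shape[0]))
    for i, y in enumerate(y_mono):
        w[i], _ = nnls(a, y)
    return w


def invert_channels(y_bino: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Estimate binocular channel responses by OLS across voxels.

    Solves ``C_bino = argmin_C || y_bino - W C ||^2`` over the voxels of
    one depth bin / ROI.  Requires at least two voxels with linearly
    independent weight rows; an ill-posed bin (rank(W) < 2, judged by the
    singular-value condition number) raises instead of returning numbers.
    """
    y_bino = np.asarray(y_bino, float).ravel()
    w = np.atleast_2d(np.asarray(w, float))
    if w.shape[0] != y_bino.size:
        raise ValueError("y_bino and W must have one row per voxel")
    if w.shape[0] < w.shape[1]:
        raise np.linalg.LinAlgError("fewer voxels than channels: ill-posed bin")
    s = np.linalg.svd(w, compute_uv=False)
    if s[-1] <= 0 or s[0] / s[-1] > _COND_TOL:
        raise np.linalg.LinAlgError(
            f"weight matrix is rank deficient (cond={np.inf if s[-1] == 0 else s[0] / s[-1]:.3g}): "
            "ill-posed bin"
        )
    c, *_ = np.linalg.lstsq(w, y_bino, rcond=None)
    return c


def compute_bsi_fmri(c_bino: np.ndarray) -> np.ndarray:
    """Binocular suppression index per channel: BSI = 1 - C_bino.

    ``C_bino`` is the binocular channel response in units of the
    monocular response (the identity monocular design makes monocular
    channel responses 1), so BSI is the fraction of each eye's monocular
    response suppressed under binocular viewing.
    """
    return 1.0 - np.asarray(c_bino, float)


def bsi_profile(
    beta_ae: np.ndarray,
    beta_fe: np.ndarray,
    beta_bino: np.ndarray,
    depth: np.ndarray,
    n_bins: int = 3,
    voxel_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Full IEM per depth bin: NNLS weights, OLS inversion, BSI.

    Weights are fit per voxel from the two monocular betas; within each
    equivolume-depth bin the binocular betas are inverted jointly.
    Ill-posed bins are reported as NaN with ``ill_posed`` set.

    Returns a DataFrame indexed by bin with columns ``depth_center``,
    ``c_bino_AE``, ``c_bino_FE``, ``bsi_AE``, ``bsi_FE``, ``n_voxels``,
    ``ill_posed``.
    """
    beta_ae = np.asarray(beta_ae, float)
    beta_fe = np.asarray(beta_fe, float)
    beta_bino = np.asarray(beta_bino, float)
    depth = np.asarray(depth, float)
    sel = np.ones(depth.size, bool) if voxel_mask is None else np.asarray(voxel_mask, bool)

    w_all = fit_weights_nnls(np.column_stack([beta_ae, beta_fe]))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(depth, edges) - 1, 0, n_bins - 1)

    rows = []
    for b in range(n_bins):
        in_bin = sel & (which == b)
        n = int(in_bin.sum())
        row = {
            "depth_center": 0.5 * (edges[b] + edges[b + 1]),
            "n_voxels": n,
            "ill_posed": False,
        }
        try:
            if n < 2:
                raise np.linalg.LinAlgError("too few voxels")
            c = invert_channels(beta_bino[in_bin], w_all[in_bin])
            bsi = compute_bsi_fmri(c)
            row.update(
                c_bino_AE=c[0], c_bino_FE=c[1], bsi_AE=bsi[0], bsi_FE=bsi[1]
            )
        except np.linalg.LinAlgError:
            row.update(
                c_bino_AE=np.nan, c_bino_FE=np.nan, bsi_AE=np.nan, bsi_FE=np.nan,
                ill_posed=True,
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    df.index.name = "bin"
    return df
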