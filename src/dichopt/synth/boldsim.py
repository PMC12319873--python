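"""Ground-truthed BOLD simulation on a synthetic cortical ribbon.

Each voxel mixes the two monocular channels (amblyopic eye AE, fellow eye
FE) with non-negative weights laid out in ocular-dominance-column-like
bands.  Planted laminar truth (response profiles, ADI, binocular
suppression) drives condition amplitudes per depth; the time series is the
amplitude-weighted HRF-convolved block design around a baseline, with
AR(1) Gaussian noise.  Vein columns get amplified responses and reduced
mean intensity so the vein-exclusion rule can find them.

Planted amplitudes are in percent signal change *relative to the voxel run
mean* (stimulus regressors are centered into the baseline), matching the
GLM's percent-signal-change convention, so noiseless recovery is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from typing import TYPE_CHECKING

from ..hrf import BlockHRF, build_design
from .mesh import MeshPair

if TYPE_CHECKING:  # avoid a circular import; RibbonGrid is only a type here
    from ..laminar import RibbonGrid


@dataclass
class LaminarTruth:
    """Planted depth-resolved ground truth.

    Profiles are response amplitudes (PSC) on ``depth_grid`` (0 pial, 1
    white); ``bsi_*`` are the per-depth fractions of each eye's response
    suppressed under binocular viewing (response scaled by ``1 - bsi``).
    """

    depth_grid: np.ndarray
    profile_ae: np.ndarray
    profile_fe: np.ndarray
    bsi_ae: np.ndarray
    bsi_fe: np.ndarray
    vein_vertices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        for name in ("depth_grid", "profile_ae", "profile_fe", "bsi_ae", "bsi_fe"):
            setattr(self, name, np.asarray(getattr(self, name), float))
        n = self.depth_grid.size
        for name in ("profile_ae", "profile_fe", "bsi_ae", "bsi_fe"):
            arr = getattr(self, name)
            if arr.size == 1:
                setattr(self, name, np.full(n, float(arr)))
            elif arr.size != n:
                raise ValueError(f"{name} does not match the depth grid")
        if (self.profile_ae < 0).any() or (self.profile_fe < 0).any():
            raise ValueError("response profiles must be non-negative")
        for name in ("bsi_ae", "bsi_fe"):
            b = getattr(self, name)
            if (b <= -1).any() or (b > 1).any():
                raise ValueError("BSI values must lie in (-1, 1]")
        self.vein_vertices = np.asarray(self.vein_vertices, dtype=int)

    @property
    def adi_true(self) -> np.ndarray:
        """Planted ADI per depth: (FE - AE) / FE."""
        return (self.profile_fe - self.profile_ae) / self.profile_fe

    @classmethod
    def from_adi(
        cls,
        adi: float | np.ndarray,
        fe_profile: float | np.ndarray = 1.0,
        bsi_ae: float | np.ndarray = 0.0,
        bsi_fe: float | np.ndarray = 0.0,
        depth_grid: np.ndarray | None = None,
        vein_vertices: np.ndarray | None = None,
    ) -> "LaminarTruth":
        """Build truth from a planted ADI: AE = FE * (1 - ADI)."""
        grid = np.linspace(0.0, 1.0, 21) if depth_grid is None else np.asarray(depth_grid)
        fe = np.broadcast_to(np.asarray(fe_profile, float), grid.shape).copy()
        adi = np.broadcast_to(np.asarray(adi, float), grid.shape)
        return cls(
            depth_grid=grid,
            profile_ae=fe * (1.0 - adi),
            profile_fe=fe,
            bsi_ae=bsi_ae,
            bsi_fe=bsi_fe,
            vein_vertices=vein_vertices if vein_vertices is not None else np.array([], int),
        )

    def at_depth(self, depth: np.ndarray) -> dict[str, np.ndarray]:
        """Interpolate all truth fields at arbitrary depths."""
        return {
            name: np.interp(depth, self.depth_grid, getattr(self, name))
            for name in ("profile_ae", "profile_fe", "bsi_ae", "bsi_fe")
        }


def make_odc_weights(
    mesh: MeshPair,
    band_width: float = 2.0,
    contrast: float = 0.8,
    gain: float = 1.0,
    jitter: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """Per-vertex non-negative ocular mixing weights in ODC-like bands.

    A smoothed band pattern (period ``2 * band_width`` mm along the first
    surface coordinate plus seeded jitter) sets each column's AE
    preference in (0, 1); ``contrast`` scales how far weights deviate from
    an even 50/50 split (partial-volume strength) and ``gain`` (<= 1) the
    total weight, so ``w_AE + w_FE = gain <= 1``.

    Returns (V, 2) array with columns (w_AE, w_FE).
    """
    if not 0 < gain <= 1:
        raise ValueError("gain must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    mid = 0.5 * (mesh.vertices_pial + mesh.vertices_white)
    phase = rng.uniform(0, 2 * np.pi)
    carrier = np.sin(np.pi * mid[:, 0] / band_width + phase)
    carrier = carrier + jitter * rng.standard_normal(mesh.n_vertices)
    pref = 0.5 + 0.5 * np.tanh(3.0 * carrier)  # AE preference in (0, 1)
    # recenter exactly: neither eye over-represented in the population
    dev = pref - pref.mean()
    dev *= min(1.0, 0.5 / np.abs(dev).max())
    pref = 0.5 + dev
    w_ae = gain * (0.5 + (pref - 0.5) * contrast)
    return np.column_stack([w_ae, gain - w_ae])


def condition_amplitudes(
    truth: LaminarTruth,
    grid: RibbonGrid,
    weights: np.ndarray,
    conditions: tuple[str, ...] = ("AE", "FE", "binocular"),
    depth: np.ndarray | None = None,
) -> np.ndarray:
    """Noise-free per-voxel response amplitude (PSC) per condition.

    The channel response vector per condition is ``[P_AE, 0]`` (AE
    stimulation), ``[0, P_FE]`` (FE), and
    ``[(1 - BSI_AE) P_AE, (1 - BSI_FE) P_FE]`` (binocular); the voxel
    amplitude is its mixing-weight dot product.  Truth profiles are
    evaluated at ``depth`` (equivolume) when given, else at the Euclidean
    column fraction (identical on a slab).
    """
    tv = truth.at_depth(grid.frac if depth is None else depth)
    w = weights[grid.vertex_id]  # (N, 2)
    amps = np.zeros((len(conditions), grid.n_voxels))
    for ci, cond in enumerate(conditions):
        if cond == "AE":
            c = np.stack([tv["profile_ae"], np.zeros_like(tv["profile_ae"])])
        elif cond == "FE":
            c = np.stack([np.zeros_like(tv["profile_fe"]), tv["profile_fe"]])
        elif cond == "binocular":
            c = np.stack(
                [
                    (1 - tv["bsi_ae"]) * tv["profile_ae"],
                    (1 - tv["bsi_fe"]) * tv["profile_fe"],
                ]
            )
        else:
            raise ValueError(f"unknown condition {cond!r}")
        amps[ci] = w[:, 0] * c[0] + w[:, 1] * c[1]
    return amps


def _ar1_noise(rng, shape, sd, rho):
    n_series, n_t = shape
    eps = rng.standard_normal((n_series, n_t)) * sd * np.sqrt(1 - rho**2)
    out = np.empty(shape)
    out[:, 0] = rng.standard_normal(n_series) * sd
    for t in range(1, n_t):
        out[:, t] = rho * out[:, t - 1] + eps[:, t]
    return out


@dataclass
class SimulatedRun:
    """A simulated BOLD run plus its ground-truth sidecar."""

    bold: np.ndarray  # (N voxels, T volumes) raw intensity
    events: pd.DataFrame
    tr: float
    grid: RibbonGrid
    truth: LaminarTruth
    weights: np.ndarray  # (V, 2) per-vertex mixing weights
    amplitudes: np.ndarray  # (C, N) planted PSC amplitudes
    conditions: tuple[str, ...]
    vein_vertices: np.ndarray


def simulate_bold_run(
    mesh: MeshPair,
    grid: RibbonGrid,
    truth: LaminarTruth,
    events: pd.DataFrame,
    tr: float = 2.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    weights: np.ndarray | None = None,
    hrf: BlockHRF | None = None,
    baseline: float = 1000.0,
    ar_rho: float = 0.3,
    vein_gain: float = 15.0,
    vein_intensity: float = 0.6,
    depth: np.ndarray | None = None,
) -> SimulatedRun:
    """Simulate one block-design BOLD run on the ribbon.

    Parameters
    ----------
    noise_sd :
        AR(1) noise standard deviation in percent signal change.
    vein_gain, vein_intensity :
        Response multiplier and baseline-intensity multiplier applied to
        voxels whose column is a planted vein (defaults push vein columns
        past the 10 PSC response and below the 70 % intensity criteria).
    """
    run_len = float(events["duration"].sum())
    n_vols = run_len / tr
    if abs(n_vols - round(n_vols)) > 1e-9:
        raise ValueError(f"TR {tr} s does not divide the run length {run_len} s")
    n_vols = int(round(n_vols))

    rng = np.random.default_rng(seed)
    if weights is None:
        weights = make_odc_weights(mesh, seed=seed)
    hrf = hrf or BlockHRF()
    X, _, conditions = build_design(events, n_vols, tr, hrf=hrf, drift_order=0)
    regs = X[:, : len(conditions)]
    regs = regs - regs.mean(axis=0, keepdims=True)  # center into the run mean

    amps = condition_amplitudes(truth, grid, weights, tuple(conditions), depth=depth)

    vein_col = np.isin(grid.vertex_id, truth.vein_vertices)
    amps_eff = np.where(vein_col[None, :], amps * vein_gain, amps)
    base = np.where(vein_col, baseline * vein_intensity, baseline)

    signal = base[:, None] * (1.0 + np.einsum("cn,tc->nt", amps_eff, regs) / 100.0)
    if noise_sd > 0:
        signal = signal + base[:, None] / 100.0 * _ar1_noise(
            rng, (grid.n_voxels, n_vols), noise_sd, ar_rho
        )
    return SimulatedRun(
        bold=signal,
        events=events,
        tr=tr,
        grid=grid,
        truth=truth,
        weights=weights,
        amplitudes=amps_eff,
        conditions=tuple(conditions),
        vein_vertices=truth.vein_vertices,
    )
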