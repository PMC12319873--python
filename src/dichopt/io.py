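"""Standard-format I/O: NIfTI volumes, surface meshes, BIDS-style event
TSVs, the flat-binary EEG container, and provenance-stamped tables."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .containers import EEGRecording
from .laminar import RibbonGrid
from .synth.mesh import MeshPair


# ---------------------------------------------------------------------------
# Volumes


def save_nifti(path, values: np.ndarray, grid: RibbonGrid, fill: float = np.nan) -> None:
    """Write per-gray-matter-voxel values (or stacked maps) as NIfTI-1."""
    values = np.asarray(values, float)
    if values.ndim == 1:
        vol = grid.to_volume(values, fill=fill)
    else:  # (k, N) -> 4-D
        vol = np.stack([grid.to_volume(v, fill=fill) for v in values], axis=-1)
    nib.save(nib.Nifti1Image(vol.astype(np.float32), grid.affine), str(path))


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


# ---------------------------------------------------------------------------
# Meshes


def save_mesh_pair(stem, mesh: MeshPair, fmt: str = "gii") -> list[Path]:
    """Write the pial/white pair as GIFTI surfaces or vertex/face text."""
    stem = Path(stem)
    paths = []
    for name, verts in (("pial", mesh.vertices_pial), ("white", mesh.vertices_white)):
        if fmt == "gii":
            img = nib.gifti.GiftiImage(
                darrays=[
                    nib.gifti.GiftiDataArray(
                        verts.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
                    ),
                    nib.gifti.GiftiDataArray(
                        mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
                    ),
                ]
            )
            p = stem.with_name(f"{stem.name}_{name}.surf.gii")
            nib.save(img, str(p))
        elif fmt == "txt":
            p = stem.with_name(f"{stem.name}_{name}.surf.txt")
            with open(p, "w") as fh:
                fh.write(f"# vertices {verts.shape[0]} faces {mesh.faces.shape[0]}\n")
                np.savetxt(fh, verts, fmt="%.6f", header="v", comments="# ")
                np.savetxt(fh, mesh.faces, fmt="%d", header="f", comments="# ")
        else:
            raise ValueError(f"unknown mesh format {fmt!r}")
        paths.append(p)
    return paths


def load_mesh_pair(stem, fmt: str = "gii") -> MeshPair:
    stem = Path(stem)
    parts = {}
    for name in ("pial", "white"):
        if fmt == "gii":
            img = nib.load(str(stem.with_name(f"{stem.name}_{name}.surf.gii")))
            verts = img.darrays[0].data.astype(float)
            faces = img.darrays[1].data.astype(np.int64)
        else:
            p = stem.with_name(f"{stem.name}_{name}.surf.txt")
            with open(p) as fh:
                header = fh.readline().split()
                n_v, n_f = int(header[2]), int(header[4])
            raw = np.loadtxt(p, comments="#")
            verts, faces = raw[:n_v], raw[n_v : n_v + n_f].astype(np.int64)
        parts[name] = (verts, faces)
    return MeshPair(parts["pial"][0], parts["white"][0], parts["pial"][1])


# ---------------------------------------------------------------------------
# Events and tables


def save_events_tsv(path, events: pd.DataFrame) -> None:
    """BIDS-style events table (onset / duration / trial_type)."""
    events.to_csv(path, sep="\t", index=False)


def load_events_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_table(path, df: pd.DataFrame, provenance: dict | None = None) -> None:
    """TSV with an optional commented provenance header (config hash, seed)."""
    with open(path, "w") as fh:
        if provenance:
            for k, v in provenance.items():
                fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=True)


def load_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


# ---------------------------------------------------------------------------
# EEG container: raw float32 samples + JSON sidecar


def save_eeg(stem, rec: EEGRecording) -> tuple[Path, Path]:
    stem = Path(stem)
    raw_path = stem.with_suffix(".eeg.f32")
    json_path = stem.with_suffix(".eeg.json")
    rec.data.astype("<f4").tofile(raw_path)
    sidecar = {
        "srate": rec.srate,
        "channel_labels": rec.channel_labels,
        "n_channels": rec.data.shape[0],
        "n_samples": rec.data.shape[1],
        "trial_len_s": rec.trial_len_s,
        "dtype": "<f4",
        "order": "channels x samples, C-order",
        "trials": rec.trials.to_dict(orient="list"),
    }
    json_path.write_text(json.dumps(sidecar, indent=1))
    return raw_path, json_path


def load_eeg(stem) -> EEGRecording:
    stem = Path(stem)
    sidecar = json.loads(stem.with_suffix(".eeg.json").read_text())
    data = np.fromfile(stem.with_suffix(".eeg.f32"), dtype=sidecar["dtype"]).reshape(
        sidecar["n_channels"], sidecar["n_samples"]
    )
    return EEGRecording(
        data=data.astype(float),
        srate=sidecar["srate"],
        channel_labels=sidecar["channel_labels"],
        trials=pd.DataFrame(sidecar["trials"]),
        trial_len_s=sidecar["trial_len_s"],
    )


# ---------------------------------------------------------------------------
# Provenance


def config_hash(config_dict: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
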