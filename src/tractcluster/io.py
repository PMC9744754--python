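"""NIfTI and JSON I/O for pipeline artifacts.

Volumes are NIfTI-1 with the pixel size recorded in the header (mm); 2D
axial maps are stored as (H, W, 1) volumes and soft atlases as 4D
(H, W, 1, T) with one tract per 4th-dimension channel.  Label images get a
sidecar JSON lookup table.  Every output directory carries a manifest with
the parameters and seeds that produced it.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .images import LabelAtlas, MetricStack, Parcellation, SoftAtlas


def _affine(pixel_size_um: float) -> np.ndarray:
    mm = pixel_size_um / 1000.0
    return np.diag([mm, mm, 1.0, 1.0])


def _save_nii(arr: np.ndarray, path: Path, pixel_size_um: float) -> None:
    if arr.ndim == 2:
        arr = arr[:, :, None]
    img = nib.Nifti1Image(np.asarray(arr), _affine(pixel_size_um))
    img.header.set_zooms((pixel_size_um / 1000.0,) * 2 + (1.0,) * (arr.ndim - 2))
    nib.save(img, str(path))


def _load_nii(path: Path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    pixel_size_um = float(img.header.get_zooms()[0]) * 1000.0
    return np.squeeze(data, axis=2) if data.ndim >= 3 and data.shape[2] == 1 else data, pixel_size_um


def save_stack(stack: MetricStack, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, ch in stack.channels.items():
        _save_nii(ch.astype(np.float32), out_dir / f"metric_{name}.nii", stack.pixel_size_um)
    _save_nii(stack.mask.astype(np.uint8), out_dir / "mask.nii", stack.pixel_size_um)
    meta = {
        "metric_names": list(stack.metric_names),
        "all_channels": list(stack.channels),
        "level": stack.level,
        "pixel_size_um": stack.pixel_size_um,
    }
    (out_dir / "stack.json").write_text(json.dumps(meta, indent=2))


def load_stack(out_dir: Path) -> MetricStack:
    out_dir = Path(out_dir)
    meta = json.loads((out_dir / "stack.json").read_text())
    channels = {}
    for name in meta["all_channels"]:
        arr, _ = _load_nii(out_dir / f"metric_{name}.nii")
        channels[name] = arr.astype(float)
    mask, px = _load_nii(out_dir / "mask.nii")
    return MetricStack(
        channels=channels,
        mask=mask.astype(bool),
        pixel_size_um=meta.get("pixel_size_um", px),
        level=meta["level"],
        metric_names=tuple(meta["metric_names"]),
    )


def save_labels(atlas: LabelAtlas, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _save_nii(atlas.labels.astype(np.int16), path, atlas.pixel_size_um)
    sidecar = {
        "names": {str(k): v for k, v in atlas.names.items()},
        "level": atlas.level,
        "pixel_size_um": atlas.pixel_size_um,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_labels(path: Path) -> LabelAtlas:
    path = Path(path)
    arr, px = _load_nii(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return LabelAtlas(
        labels=arr.astype(np.int32),
        names={int(k): v for k, v in sidecar["names"].items()},
        pixel_size_um=sidecar.get("pixel_size_um", px),
        level=sidecar.get("level"),
    )


def save_soft_atlas(soft: SoftAtlas, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    vol = np.moveaxis(soft.partial_volumes.astype(np.float32), 0, -1)[:, :, None, :]
    _save_nii(vol, path, soft.pixel_size_um)
    sidecar = {
        "tract_ids": list(soft.tract_ids),
        "names": {str(k): v for k, v in soft.names.items()},
        "pixel_size_um": soft.pixel_size_um,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_soft_atlas(path: Path) -> SoftAtlas:
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    pv = np.moveaxis(np.squeeze(data, axis=2), -1, 0)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return SoftAtlas(
        partial_volumes=pv.astype(float),
        tract_ids=tuple(sidecar["tract_ids"]),
        names={int(k): v for k, v in sidecar["names"].items()},
        pixel_size_um=sidecar["pixel_size_um"],
    )


def save_parcellation(parc: Parcellation, path: Path) -> None:
    path = Path(path)
    _save_nii(parc.labels.astype(np.int16), path, 50.0)
    sidecar = {"n_clusters": parc.n_clusters, "provenance": parc.provenance}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=str))


def load_parcellation(path: Path) -> Parcellation:
    path = Path(path)
    arr, _ = _load_nii(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return Parcellation(
        labels=arr.astype(np.int32),
        n_clusters=int(sidecar["n_clusters"]),
        provenance=sidecar.get("provenance", {}),
    )


def write_manifest(out_dir: Path, manifest: dict) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def read_manifest(out_dir: Path) -> dict:
    return json.loads((Path(out_dir) / "manifest.json").read_text())
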