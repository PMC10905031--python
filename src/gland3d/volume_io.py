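"""Reading, writing, downsampling and nnU-Net interchange of volumes and masks.

Two on-disk formats are supported: multi-page TIFF (the native microscopy
format; spacing carried in the shaped-metadata JSON tag) and NIfTI
(``.nii`` / ``.nii.gz``; spacing carried in the header zooms).  Arrays are
stored with the package's ``(channel, z, y, x)`` / ``(z, y, x)`` axis
convention; NIfTI files hold the conventional ``(x, y, z[, c])`` layout and
are transposed on the way in and out.

Intensities are written as 16-bit unsigned integers (the typical microscopy
range); label masks as 8-bit unsigned.  All internal computation is floating
point.
"""

from __future__ import annotations

import json
import os
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

from .types import (CHANNEL_NAMES, LABEL_NAMES, VALID_CODES,
                    SemanticMask, TwoChannelVolume, check_paired)

_TIFF_SUFFIXES = {".tif", ".tiff"}
_NIFTI_SUFFIXES = {".nii", ".nii.gz"}


def _format_of(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        return "nifti"
    if path.suffix.lower() in _TIFF_SUFFIXES:
        return "tiff"
    raise ValueError(
        f"unsupported file format for {path.name!r}; expected one of "
        f"{sorted(_TIFF_SUFFIXES | _NIFTI_SUFFIXES)}")


def _nifti_affine(spacing_zyx) -> np.ndarray:
    sz, sy, sx = spacing_zyx
    return np.diag([sx, sy, sz, 1.0])


def _write_nifti(array_zyx_or_czyx: np.ndarray, spacing_zyx, path: Path) -> None:
    a = array_zyx_or_czyx
    if a.ndim == 4:                       # (c, z, y, x) -> (x, y, z, c)
        a = np.transpose(a, (3, 2, 1, 0))
    else:                                 # (z, y, x) -> (x, y, z)
        a = np.transpose(a, (2, 1, 0))
    img = nib.Nifti1Image(np.ascontiguousarray(a), _nifti_affine(spacing_zyx))
    img.header.set_zooms(tuple(reversed(spacing_zyx)) + ((1.0,) if a.ndim == 4 else ()))
    nib.save(img, str(path))


def _read_nifti(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    a = np.asanyarray(img.dataobj)
    if a.ndim == 4:
        a = np.transpose(a, (3, 2, 1, 0))
    elif a.ndim == 3:
        a = np.transpose(a, (2, 1, 0))
    else:
        raise ValueError(f"{path.name}: expected a 3D or 4D NIfTI, got ndim={a.ndim}")
    zooms = img.header.get_zooms()[:3]
    # NIfTI stores zooms as float32; round off the representation error
    spacing = tuple(round(float(v), 6) for v in reversed(zooms))
    return a, spacing


def _write_tiff(array: np.ndarray, spacing_zyx, path: Path, axes: str) -> None:
    tifffile.imwrite(str(path), array, photometric="minisblack",
                     metadata={"axes": axes, "spacing_zyx": list(spacing_zyx)})


def _read_tiff(path: Path):
    with tifffile.TiffFile(str(path)) as tf:
        a = tf.asarray()
        spacing = None
        if tf.shaped_metadata:
            meta = tf.shaped_metadata[0]
            if "spacing_zyx" in meta:
                spacing = tuple(float(v) for v in meta["spacing_zyx"])
    return a, spacing


def write_volume(volume: TwoChannelVolume, path) -> Path:
    """Write a two-channel volume to TIFF or NIfTI (format from the suffix).

    Intensities are rounded and clipped into the unsigned 16-bit range.
    Returns the path written.
    """
    path = Path(path)
    data = np.clip(np.rint(np.asarray(volume.data, dtype=np.float64)),
                   0, np.iinfo(np.uint16).max).astype(np.uint16)
    if _format_of(path) == "nifti":
        _write_nifti(data, volume.spacing, path)
    else:
        _write_tiff(data, volume.spacing, path, axes="CZYX")
    return path


def read_volume(path, spacing_override=None) -> TwoChannelVolume:
    """Read a two-channel volume from TIFF/NIfTI.

    ``path`` may also be a pair of paths, one single-channel file per channel
    (nuclear first).  Spacing comes from file metadata unless
    ``spacing_override`` (µm per axis, ``(z, y, x)``) is given.
    """
    if isinstance(path, (tuple, list)):
        if len(path) != 2:
            raise ValueError(f"expected exactly 2 per-channel files, got {len(path)}")
        channels, spacings = [], []
        for p in path:
            a, s = (_read_nifti(Path(p)) if _format_of(Path(p)) == "nifti"
                    else _read_tiff(Path(p)))
            if a.ndim != 3:
                raise ValueError(f"{Path(p).name}: per-channel file must be 3D")
            channels.append(a)
            spacings.append(s)
        data = np.stack(channels, axis=0)
        spacing = spacing_override if spacing_override is not None else spacings[0]
        name = Path(path[0]).name.split(".")[0]
    else:
        path = Path(path)
        if _format_of(path) == "nifti":
            data, spacing = _read_nifti(path)
        else:
            data, spacing = _read_tiff(path)
        if spacing_override is not None:
            spacing = spacing_override
        name = path.name.split(".")[0]
    if data.ndim == 3:
        raise ValueError("channel count != 2 (got a single-channel file; "
                         "pass a pair of per-channel paths instead)")
    if data.ndim != 4 or data.shape[0] != 2:
        raise ValueError(f"channel count != 2 (got shape {data.shape})")
    if spacing is None:
        raise ValueError(f"no spacing in file metadata and no spacing_override given")
    return TwoChannelVolume(data=data, spacing=spacing, name=name)


def write_mask(mask: SemanticMask, path, format: str | None = None) -> Path:
    """Write a semantic mask losslessly (uint8) as TIFF or NIfTI.

    ``format`` is ``"tiff"`` or ``"nifti"``; by default it is inferred from
    the path suffix.
    """
    path = Path(path)
    if format is None:
        format = _format_of(path)
    if format not in ("tiff", "nifti"):
        raise ValueError(f"unsupported format {format!r}; expected 'tiff' or 'nifti'")
    labels = mask.labels.astype(np.uint8)
    if format == "nifti":
        _write_nifti(labels, mask.spacing, path)
    else:
        _write_tiff(labels, mask.spacing, path, axes="ZYX")
    return path


def read_mask(path, spacing_override=None) -> SemanticMask:
    """Read a semantic mask, validating that all codes are in {0, 1, 2, 3}."""
    path = Path(path)
    if _format_of(path) == "nifti":
        a, spacing = _read_nifti(path)
    else:
        a, spacing = _read_tiff(path)
    if spacing_override is not None:
        spacing = spacing_override
    if a.ndim != 3:
        raise ValueError(f"{path.name}: mask must be 3D, got shape {a.shape}")
    if np.issubdtype(a.dtype, np.floating):
        if not np.allclose(a, np.rint(a)):
            raise ValueError(f"{path.name}: non-integer label values")
        a = np.rint(a).astype(np.int64)
    bad = np.setdiff1d(np.unique(a), sorted(VALID_CODES))
    if bad.size:
        raise ValueError(
            f"{path.name}: out-of-range label code(s) {bad.tolist()}; allowed {sorted(VALID_CODES)}")
    if spacing is None:
        raise ValueError(f"{path.name}: no spacing in metadata and no spacing_override")
    return SemanticMask(labels=a.astype(np.uint8), spacing=spacing,
                        name=path.name.split(".")[0])


# ---------------------------------------------------------------------------
# downsampling

def _crop_even(a: np.ndarray, spatial_axes) -> np.ndarray:
    sl = [slice(None)] * a.ndim
    odd = False
    for ax in spatial_axes:
        n = a.shape[ax]
        if n % 2:
            sl[ax] = slice(0, n - 1)
            odd = True
    if odd:
        warnings.warn("odd spatial extent: trailing slice cropped before 2x pooling",
                      stacklevel=3)
    return a[tuple(sl)]


def _mean_pool_2x(a: np.ndarray) -> np.ndarray:
    z, y, x = a.shape[-3:]
    shaped = a.reshape(a.shape[:-3] + (z // 2, 2, y // 2, 2, x // 2, 2))
    return shaped.mean(axis=(-5, -3, -1))


def _mode_pool_2x(labels: np.ndarray) -> np.ndarray:
    """2×2×2 local mode; ties broken toward the highest code.

    The tie preference lumen(3) > epithelium(2) > stroma(1) > background(0)
    keeps thin lumens from being erased by downsampling.
    """
    z, y, x = labels.shape
    cells = labels.reshape(z // 2, 2, y // 2, 2, x // 2, 2)
    cells = cells.transpose(0, 2, 4, 1, 3, 5).reshape(z // 2, y // 2, x // 2, 8)
    counts = np.stack([(cells == c).sum(axis=-1) for c in range(4)], axis=0)
    # argmax on reversed code order returns the *highest* code among ties
    return (3 - np.argmax(counts[::-1], axis=0)).astype(labels.dtype)


def downsample_2x(obj):
    """Downsample a volume or mask by 2× per axis, doubling the spacing.

    Intensities are reduced by a 2×2×2 local mean (anti-aliased and
    sum-preserving), labels by a 2×2×2 local mode with ties broken toward the
    highest code.  Odd trailing slices are cropped first (with a warning).
    Applying this twice realizes the 0.45 → 0.9 → 1.8 µm resolution chain.
    """
    if isinstance(obj, TwoChannelVolume):
        if min(obj.shape) < 2:
            raise ValueError(f"every spatial extent must be >= 2, got {obj.shape}")
        data = _crop_even(np.asarray(obj.data, dtype=np.float64), spatial_axes=(1, 2, 3))
        return TwoChannelVolume(data=_mean_pool_2x(data),
                                spacing=tuple(2 * s for s in obj.spacing),
                                name=obj.name)
    if isinstance(obj, SemanticMask):
        if min(obj.shape) < 2:
            raise ValueError(f"every spatial extent must be >= 2, got {obj.shape}")
        labels = _crop_even(obj.labels, spatial_axes=(0, 1, 2))
        return SemanticMask(labels=_mode_pool_2x(labels),
                            spacing=tuple(2 * s for s in obj.spacing),
                            name=obj.name)
    raise TypeError(f"expected TwoChannelVolume or SemanticMask, got {type(obj).__name__}")


# ---------------------------------------------------------------------------
# nnU-Net dataset convention

def export_nnunet_dataset(cases, out_dir, dataset_id: int, dataset_name: str) -> Path:
    """Export paired (volume, mask) cases in the nnU-Net folder convention.

    Creates ``Dataset<id>_<name>/{imagesTr,labelsTr,dataset.json}`` under
    ``out_dir``, one NIfTI per channel per case (``<case>_0000.nii.gz`` /
    ``<case>_0001.nii.gz``) and one label NIfTI per case.  Returns the
    dataset directory.
    """
    cases = list(cases)
    if not cases:
        raise ValueError("empty case list")
    names = []
    for volume, mask in cases:
        check_paired(volume, mask)
        name = volume.name or mask.name
        if not name:
            raise ValueError("every exported case needs a non-empty name")
        names.append(name)
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate case name(s): {dupes}")

    root = Path(out_dir) / f"Dataset{int(dataset_id):03d}_{dataset_name}"
    images = root / "imagesTr"
    labels = root / "labelsTr"
    images.mkdir(parents=True, exist_ok=True)
    labels.mkdir(parents=True, exist_ok=True)

    for (volume, mask), name in zip(cases, names):
        data = np.clip(np.rint(np.asarray(volume.data, dtype=np.float64)),
                       0, np.iinfo(np.uint16).max).astype(np.uint16)
        for c in range(2):
            _write_nifti(data[c], volume.spacing, images / f"{name}_{c:04d}.nii.gz")
        _write_nifti(mask.labels.astype(np.uint8), mask.spacing,
                     labels / f"{name}.nii.gz")

    meta = {
        "channel_names": {str(c): CHANNEL_NAMES[c] for c in sorted(CHANNEL_NAMES)},
        "labels": {LABEL_NAMES[c]: c for c in sorted(LABEL_NAMES)},
        "numTraining": len(cases),
        "file_ending": ".nii.gz",
        "name": dataset_name,
    }
    with open(root / "dataset.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    return root


def import_predictions(pred_dir, case_names) -> list[SemanticMask]:
    """Import predicted masks (``<case>.nii.gz``) from an nnU-Net-style directory."""
    pred_dir = Path(pred_dir)
    masks = []
    for name in case_names:
        path = pred_dir / f"{name}.nii.gz"
        if not path.exists():
            path_alt = pred_dir / f"{name}.nii"
            if path_alt.exists():
                path = path_alt
            else:
                raise FileNotFoundError(f"missing prediction for case {name!r} in {pred_dir}")
        mask = read_mask(path)
        mask.name = name
        masks.append(mask)
    return masks
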