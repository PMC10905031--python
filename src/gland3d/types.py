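"""Core in-memory containers shared by every module.

Axis convention, used everywhere in this package:

* intensity volumes are indexed ``(channel, z, y, x)`` with channel 0 the
  nuclear (hematoxylin-analog) channel and channel 1 the eosin-analog channel;
* label volumes are indexed ``(z, y, x)``;
* ``spacing`` is the physical voxel pitch in micrometres per spatial axis,
  ordered ``(z, y, x)``; ``z`` is the optical/depth axis;
* all indexing is 0-based and ranges are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: semantic label codes
BACKGROUND = 0
STROMA = 1
EPITHELIUM = 2
LUMEN = 3

LABEL_NAMES = {BACKGROUND: "background", STROMA: "stroma",
               EPITHELIUM: "epithelium", LUMEN: "lumen"}
VALID_CODES = frozenset(LABEL_NAMES)

#: channel indices of a TwoChannelVolume
NUCLEAR_CHANNEL = 0
EOSIN_CHANNEL = 1
CHANNEL_NAMES = {NUCLEAR_CHANNEL: "hematoxylin_analog", EOSIN_CHANNEL: "eosin_analog"}


def _as_spacing(spacing) -> tuple[float, float, float]:
    s = tuple(float(v) for v in spacing)
    if len(s) != 3:
        raise ValueError(f"spacing must have 3 entries (z, y, x), got {len(s)}")
    if not all(np.isfinite(v) and v > 0 for v in s):
        raise ValueError(f"spacing must be strictly positive and finite, got {s}")
    return s


@dataclass
class TwoChannelVolume:
    """A two-channel 3D fluorescence volume with physical voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (2, Z, Y, X)
        Non-negative intensities; channel 0 nuclear, channel 1 eosin.
    spacing : tuple of float
        Voxel pitch in µm per spatial axis ``(z, y, x)``.
    name : str
        Case identifier, used for file naming.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    name: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"volume data must be 4D (channel, z, y, x), got ndim={self.data.ndim}")
        if self.data.shape[0] != 2:
            raise ValueError(f"channel count != 2 (got {self.data.shape[0]})")
        if min(self.data.shape[1:]) < 1:
            raise ValueError(f"all spatial extents must be >= 1, got {self.data.shape[1:]}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")
        if self.data.min() < 0:
            raise ValueError("intensities must be non-negative")
        self.spacing = _as_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        """Spatial shape ``(Z, Y, X)``."""
        return self.data.shape[1:]

    @property
    def nuclear(self) -> np.ndarray:
        return self.data[NUCLEAR_CHANNEL]

    @property
    def eosin(self) -> np.ndarray:
        return self.data[EOSIN_CHANNEL]

    def with_data(self, data, spacing=None) -> "TwoChannelVolume":
        return replace(self, data=data,
                       spacing=self.spacing if spacing is None else spacing)


@dataclass
class SemanticMask:
    """A 3D semantic label volume over {background, stroma, epithelium, lumen}.

    Codes: 0 background (outside tissue / unannotated), 1 stroma,
    2 epithelium, 3 lumen.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    name: str = ""

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"mask labels must be 3D (z, y, x), got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError(f"mask labels must be integer, got dtype={self.labels.dtype}")
        bad = np.setdiff1d(np.unique(self.labels), sorted(VALID_CODES))
        if bad.size:
            raise ValueError(f"invalid label code(s) {bad.tolist()}; allowed {sorted(VALID_CODES)}")
        self.spacing = _as_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def class_counts(self) -> dict[str, int]:
        """Voxel count per semantic class, by name."""
        counts = np.bincount(self.labels.ravel(), minlength=4)
        return {LABEL_NAMES[c]: int(counts[c]) for c in sorted(LABEL_NAMES)}

    def with_labels(self, labels, spacing=None) -> "SemanticMask":
        return replace(self, labels=labels,
                       spacing=self.spacing if spacing is None else spacing)


def check_paired(volume: TwoChannelVolume, mask: SemanticMask) -> None:
    """Raise if a volume/mask pair disagree on geometry."""
    if volume.shape != mask.shape:
        raise ValueError(f"shape mismatch: volume {volume.shape} vs mask {mask.shape}")
    if not np.allclose(volume.spacing, mask.spacing):
        raise ValueError(f"spacing mismatch: volume {volume.spacing} vs mask {mask.spacing}")


@dataclass
class VoxelSet:
    """A set of voxel indices with the spacing that maps them to physical points.

    A voxel index ``(z, y, x)`` maps to the physical point
    ``(z * spacing_z, y * spacing_y, x * spacing_x)`` (voxel centres on an
    anisotropic grid); distances between members are plain Euclidean distances
    between these points, in µm.
    """

    coords: np.ndarray            # (N, 3) int64, unique rows
    spacing: tuple[float, float, float]

    def __post_init__(self):
        c = np.asarray(self.coords)
        if c.size == 0:
            c = c.reshape(0, 3)
        if c.ndim != 2 or c.shape[1] != 3:
            raise ValueError("coords must be an (N, 3) array of voxel indices")
        if c.size and c.min() < 0:
            raise ValueError("voxel indices must be non-negative")
        self.coords = np.unique(c.astype(np.int64), axis=0)
        self.spacing = _as_spacing(self.spacing)

    @classmethod
    def from_mask(cls, mask: np.ndarray, spacing) -> "VoxelSet":
        """Build from a boolean occupancy array indexed (z, y, x)."""
        return cls(np.argwhere(np.asarray(mask, dtype=bool)), spacing)

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def points_um(self) -> np.ndarray:
        """Physical coordinates of the members, (N, 3) float64 in µm."""
        return self.coords.astype(np.float64) * np.asarray(self.spacing)

    def to_dense(self, shape=None) -> np.ndarray:
        """Boolean occupancy array covering the members (bounding shape by default)."""
        if shape is None:
            shape = tuple((self.coords.max(axis=0) + 1) if len(self) else (1, 1, 1))
        out = np.zeros(shape, dtype=bool)
        if len(self):
            out[tuple(self.coords.T)] = True
        return out
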