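"""Deterministic block decomposition and stitching of biopsy-scale volumes.

A whole biopsy (~1 mm × 0.7 mm × 20 mm, i.e. ~512 × 350 × 10000 voxels at
1.8 µm pitch) does not fit GPU or RAM budgets in one piece, so it is cut into
axis-aligned blocks of roughly 1 mm³ (default 512 × 350 × 512 voxels) that are
processed independently and stitched back.  Block enumeration is z-major
(z, then y, then x) so file naming and overlap resolution are reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .types import SemanticMask, TwoChannelVolume

#: default block shape (z, y, x) in voxels at 1.8 µm pitch
DEFAULT_BLOCK_SHAPE = (512, 350, 512)


def _axis_starts(extent: int, block: int, overlap: int) -> list[int]:
    if extent <= block:
        return [0]
    step = block - overlap
    n = -(-(extent - overlap) // step)       # ceil
    starts = [i * step for i in range(n)]
    starts[-1] = extent - block              # shift last block; no padding
    return starts


@dataclass
class BlockLayout:
    """A deterministic decomposition of a volume into half-open blocks.

    ``blocks[k]`` is a tuple of three ``(start, stop)`` ranges, one per
    spatial axis, in z-major enumeration order.
    """

    volume_shape: tuple[int, int, int]
    block_shape: tuple[int, int, int]
    overlap: tuple[int, int, int]
    blocks: list[tuple[tuple[int, int], tuple[int, int], tuple[int, int]]] = field(
        default_factory=list)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def block_slices(self, index: int) -> tuple[slice, slice, slice]:
        if not 0 <= index < len(self.blocks):
            raise IndexError(f"block index {index} out of range [0, {len(self.blocks)})")
        return tuple(slice(a, b) for a, b in self.blocks[index])

    def to_json(self, path=None) -> str:
        doc = {"volume_shape": list(self.volume_shape),
               "block_shape": list(self.block_shape),
               "overlap": list(self.overlap),
               "blocks": [[list(r) for r in blk] for blk in self.blocks]}
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "BlockLayout":
        if isinstance(source, (str, Path)) and Path(source).exists():
            doc = json.loads(Path(source).read_text())
        else:
            doc = json.loads(source)
        return cls(volume_shape=tuple(doc["volume_shape"]),
                   block_shape=tuple(doc["block_shape"]),
                   overlap=tuple(doc["overlap"]),
                   blocks=[tuple(tuple(r) for r in blk) for blk in doc["blocks"]])


def plan_blocks(volume_shape, block_shape=DEFAULT_BLOCK_SHAPE, overlap=(0, 0, 0)) -> BlockLayout:
    """Plan a blocked decomposition of ``volume_shape``.

    Per axis, block starts advance by ``block_shape - overlap``; the final
    block is shifted left so its end coincides with the volume extent (no
    padding, so exported blocks contain only real voxels).  Axes whose extent
    is at most the block size get a single full-extent block.
    """
    volume_shape = tuple(int(v) for v in volume_shape)
    block_shape = tuple(int(v) for v in block_shape)
    overlap = tuple(int(v) for v in overlap)
    if len(volume_shape) != 3 or len(block_shape) != 3 or len(overlap) != 3:
        raise ValueError("volume_shape, block_shape and overlap must each have 3 entries")
    if min(volume_shape) < 1 or min(block_shape) < 1:
        raise ValueError("shapes must be positive")
    for ax, (b, o) in enumerate(zip(block_shape, overlap)):
        if o < 0:
            raise ValueError(f"overlap must be >= 0 (axis {ax}: {o})")
        if o >= b:
            raise ValueError(f"overlap must be < block_shape per axis (axis {ax}: {o} >= {b})")

    per_axis = [_axis_starts(e, min(b, e), o)
                for e, b, o in zip(volume_shape, block_shape, overlap)]
    eff_block = [min(b, e) for b, e in zip(block_shape, volume_shape)]
    blocks = []
    for z0 in per_axis[0]:
        for y0 in per_axis[1]:
            for x0 in per_axis[2]:
                blocks.append(((z0, z0 + eff_block[0]),
                               (y0, y0 + eff_block[1]),
                               (x0, x0 + eff_block[2])))
    return BlockLayout(volume_shape=volume_shape, block_shape=block_shape,
                       overlap=overlap, blocks=blocks)


def extract_block(obj, layout: BlockLayout, block_index: int):
    """Restrict a volume or mask to one block of the layout (spacing unchanged)."""
    sl = layout.block_slices(int(block_index))
    if isinstance(obj, TwoChannelVolume):
        if obj.shape != layout.volume_shape:
            raise ValueError(f"volume shape {obj.shape} != layout {layout.volume_shape}")
        return obj.with_data(obj.data[(slice(None),) + sl])
    if isinstance(obj, SemanticMask):
        if obj.shape != layout.volume_shape:
            raise ValueError(f"mask shape {obj.shape} != layout {layout.volume_shape}")
        return obj.with_labels(obj.labels[sl])
    raise TypeError(f"expected TwoChannelVolume or SemanticMask, got {type(obj).__name__}")


def stitch_blocks(layout: BlockLayout, block_masks) -> SemanticMask:
    """Reassemble per-block masks into a whole-volume mask.

    With zero overlap every voxel is copied from its unique block; where
    blocks overlap, the later block in enumeration order wins
    (last-writer-wins).  ``extract_block`` of every block followed by
    ``stitch_blocks`` is the identity on any mask.
    """
    block_masks = list(block_masks)
    if len(block_masks) != layout.n_blocks:
        missing = layout.n_blocks - len(block_masks)
        raise ValueError(f"expected {layout.n_blocks} block masks, got {len(block_masks)} "
                         f"({missing:+d})")
    spacing = None
    out = None
    for k, mask in enumerate(block_masks):
        if mask is None:
            raise ValueError(f"missing block mask at index {k}")
        sl = layout.block_slices(k)
        expected = tuple(s.stop - s.start for s in sl)
        if mask.shape != expected:
            raise ValueError(f"block {k}: mask shape {mask.shape} != block shape {expected}")
        if out is None:
            spacing = mask.spacing
            out = np.zeros(layout.volume_shape, dtype=mask.labels.dtype)
        out[sl] = mask.labels
    return SemanticMask(labels=out, spacing=spacing)
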