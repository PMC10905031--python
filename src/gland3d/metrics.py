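"""Segmentation evaluation: Dice overlap, 3D Hausdorff distance, the
gland-level protocol, and pairwise two-sample statistics.

Dice(A, B) = 2|A∩B| / (|A| + |B|) is unitless in [0, 1].  The Hausdorff
distance H(A, B) = max(sup_a inf_b d(a, b), sup_b inf_a d(b, a)) is reported
in µm, with d the Euclidean metric between voxel centres after per-axis
spacing scaling, so anisotropic grids are handled correctly.  Because manual
gland annotations delineate only the epithelium/stroma interface, the
gland-level protocol compares the union of epithelium and lumen between
prediction and reference.

Per-case scores from competing methods are compared with two-sample t tests
(pooled-variance Student by default, Welch optional), two-sided, with no
multiple-comparison correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .types import EPITHELIUM, LUMEN, SemanticMask, VoxelSet


class EmptySetError(ValueError):
    """Raised when a metric is undefined because an operand set is empty."""


# ---------------------------------------------------------------------------
# set metrics

def _encode(coords: np.ndarray, dims: np.ndarray) -> np.ndarray:
    return (coords[:, 0] * dims[1] + coords[:, 1]) * dims[2] + coords[:, 2]


def _common_dims(*coord_arrays) -> np.ndarray:
    dims = np.ones(3, dtype=np.int64)
    for c in coord_arrays:
        if len(c):
            dims = np.maximum(dims, c.max(axis=0) + 1)
    return dims + 1


def dice_coefficient(A: VoxelSet, B: VoxelSet) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|) of two voxel sets on a common grid."""
    if len(A) == 0 and len(B) == 0:
        raise EmptySetError("Dice is undefined for two empty sets")
    dims = _common_dims(A.coords, B.coords)
    inter = np.intersect1d(_encode(A.coords, dims), _encode(B.coords, dims),
                           assume_unique=True).size
    return 2.0 * inter / (len(A) + len(B))


_FACE_OFFSETS = np.array([(-1, 0, 0), (0, -1, 0), (0, 0, -1),
                          (0, 0, 1), (0, 1, 0), (1, 0, 0)], dtype=np.int64)


def boundary_voxels(coords: np.ndarray) -> np.ndarray:
    """Members of a voxel set having at least one 6-neighbor outside the set."""
    if len(coords) == 0:
        return coords.reshape(0, 3)
    shifted = coords + 1  # keep 6-neighbor coordinates non-negative for encoding
    dims = _common_dims(shifted) + 1
    keys = np.sort(_encode(shifted, dims))
    interior = np.ones(len(coords), dtype=bool)
    for off in _FACE_OFFSETS:
        neigh = _encode(shifted + off, dims)
        idx = np.searchsorted(keys, neigh)
        idx = np.clip(idx, 0, keys.size - 1)
        interior &= keys[idx] == neigh
    return coords[~interior]


def hausdorff_3d(A: VoxelSet, B: VoxelSet, mode: str = "boundary") -> float:
    """Symmetric 3D Hausdorff distance between two voxel sets, in µm.

    ``mode="boundary"`` (default) first reduces each set to its face-boundary
    voxels, the segmentation-practice convention that makes the metric a
    contour-error measure; ``mode="full"`` uses every voxel.
    """
    if mode not in ("boundary", "full"):
        raise ValueError(f"mode must be 'boundary' or 'full', got {mode!r}")
    if len(A) == 0 or len(B) == 0:
        raise EmptySetError("Hausdorff is undefined for an empty set")
    if not np.allclose(A.spacing, B.spacing):
        raise ValueError(f"spacing mismatch: {A.spacing} vs {B.spacing}")
    ca, cb = A.coords, B.coords
    if mode == "boundary":
        ca, cb = boundary_voxels(ca), boundary_voxels(cb)
    s = np.asarray(A.spacing)
    pa = ca.astype(np.float64) * s
    pb = cb.astype(np.float64) * s
    d_ab = cKDTree(pb).query(pa, k=1)[0].max()
    d_ba = cKDTree(pa).query(pb, k=1)[0].max()
    return float(max(d_ab, d_ba))


def gland_mask(mask: SemanticMask) -> VoxelSet:
    """Voxels of the gland proper (epithelium plus lumen), as a VoxelSet."""
    return VoxelSet.from_mask(np.isin(mask.labels, (EPITHELIUM, LUMEN)), mask.spacing)


# ---------------------------------------------------------------------------
# case-level evaluation

def evaluate_case(predicted: SemanticMask, reference: SemanticMask,
                  level: str = "gland", hausdorff_mode: str = "boundary") -> pd.DataFrame:
    """Dice and Hausdorff between a predicted and a reference mask.

    ``level="gland"`` compares epithelium∪lumen (the protocol matching manual
    annotations of the gland/stroma interface); ``level="per_class"`` scores
    stroma, epithelium and lumen separately.  Returns one row per comparison
    with columns (case, comparison, dice, hausdorff_um).
    """
    if predicted.shape != reference.shape:
        raise ValueError(f"shape mismatch: {predicted.shape} vs {reference.shape}")
    if not np.allclose(predicted.spacing, reference.spacing):
        raise ValueError(f"spacing mismatch: {predicted.spacing} vs {reference.spacing}")
    if level not in ("gland", "per_class"):
        raise ValueError(f"level must be 'gland' or 'per_class', got {level!r}")

    name = predicted.name or reference.name
    rows = []
    if level == "gland":
        comparisons = [("gland", np.isin(predicted.labels, (EPITHELIUM, LUMEN)),
                        np.isin(reference.labels, (EPITHELIUM, LUMEN)))]
        if not comparisons[0][2].any():
            raise EmptySetError("reference gland (epithelium+lumen) is empty")
    else:
        from .types import LABEL_NAMES
        comparisons = [(LABEL_NAMES[c], predicted.labels == c, reference.labels == c)
                       for c in (1, 2, 3)]
    for tag, p, r in comparisons:
        if not p.any() and not r.any():
            continue  # class absent from both masks: nothing to score
        inter = int(np.count_nonzero(p & r))
        dice = 2.0 * inter / (int(p.sum()) + int(r.sum()))
        if p.any() and r.any():
            hd = hausdorff_3d(VoxelSet.from_mask(p, predicted.spacing),
                              VoxelSet.from_mask(r, reference.spacing),
                              mode=hausdorff_mode)
        else:
            hd = np.nan  # one side empty: Dice is 0, distance undefined
        rows.append({"case": name, "comparison": tag, "dice": dice, "hausdorff_um": hd})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cross-method statistics and reporting

@dataclass
class MetricReport:
    """Per-case metric rows plus optional pairwise test rows.

    ``per_case`` columns: case, method, dice, hausdorff_um.
    ``pairwise`` columns: method1, method2, metric, t, p, n.
    """

    per_case: pd.DataFrame
    pairwise: pd.DataFrame | None = None

    def aggregates(self) -> pd.DataFrame:
        """Mean / min / max of each metric per method."""
        if self.per_case.empty:
            raise ValueError("empty report")
        long = self.per_case.melt(id_vars=["case", "method"],
                                  value_vars=["dice", "hausdorff_um"],
                                  var_name="metric")
        agg = (long.groupby(["method", "metric"])["value"]
               .agg(["mean", "min", "max", "count"]).reset_index())
        return agg


def pairwise_ttests(scores: pd.DataFrame, reference_method: str,
                    metrics=("dice", "hausdorff_um"), equal_var: bool = True) -> pd.DataFrame:
    """Two-sample t tests of a reference method against every other method.

    ``scores`` is tidy with columns (case, method, <metric>...).  For each
    non-reference method and each metric, an independent two-sample t test
    (pooled variance unless ``equal_var=False``, then Welch) gives a two-sided
    p value; no multiple-comparison correction is applied.  ``n`` is the
    number of cases per group.
    """
    methods = scores["method"].unique().tolist()
    if reference_method not in methods:
        raise ValueError(f"unknown reference method {reference_method!r}; "
                         f"present: {sorted(methods)}")
    rows = []
    ref = scores[scores["method"] == reference_method]
    for other in methods:
        if other == reference_method:
            continue
        oth = scores[scores["method"] == other]
        for metric in metrics:
            a = ref[metric].to_numpy(dtype=float)
            b = oth[metric].to_numpy(dtype=float)
            a, b = a[~np.isnan(a)], b[~np.isnan(b)]
            if len(a) < 2 or len(b) < 2:
                raise ValueError(f"need >= 2 cases per group for {metric} "
                                 f"({reference_method}: {len(a)}, {other}: {len(b)})")
            t, p = stats.ttest_ind(a, b, equal_var=equal_var)
            if np.allclose(a, a.mean()) and np.allclose(b, b.mean()) and np.isclose(
                    a.mean(), b.mean()):
                t, p = 0.0, 1.0  # identical degenerate groups: no difference
            rows.append({"method1": reference_method, "method2": other,
                         "metric": metric, "t": float(t), "p": float(p),
                         "n": int(min(len(a), len(b)))})
    return pd.DataFrame(rows)


def summarize(report: MetricReport, out_dir=None) -> pd.DataFrame:
    """Aggregate a report (mean/min/max per method and metric).

    If ``out_dir`` is given, writes ``per_case.csv``, ``aggregates.csv``,
    ``pairwise.csv`` (when present) and a box-plot figure per metric.
    """
    if report.per_case.empty:
        raise ValueError("empty report")
    agg = report.aggregates()
    if out_dir is not None:
        from pathlib import Path
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.per_case.to_csv(out / "per_case.csv", index=False)
        agg.to_csv(out / "aggregates.csv", index=False)
        if report.pairwise is not None and not report.pairwise.empty:
            report.pairwise.to_csv(out / "pairwise.csv", index=False)
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        for ax, metric, label in zip(axes, ("dice", "hausdorff_um"),
                                     ("Dice coefficient", "3D Hausdorff distance (µm)")):
            groups, labels = [], []
            for method, sub in report.per_case.groupby("method"):
                vals = sub[metric].dropna().to_numpy()
                if len(vals):
                    groups.append(vals)
                    labels.append(method)
            ax.boxplot(groups, tick_labels=labels)
            ax.set_ylabel(label)
        fig.tight_layout()
        fig.savefig(out / "metrics_boxplot.png", dpi=120)
        plt.close(fig)
    return agg
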