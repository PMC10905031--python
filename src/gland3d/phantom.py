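"""Synthetic two-channel biopsy phantoms with exact ground truth.

A phantom emulates the geometry the segmentation baseline assumes: branching
tubular glands — a dark lumen tube wrapped in a nuclear-bright epithelial
shell — embedded in eosin-bright stroma, plus *decoys*: dark stromal blobs
(tears, vessels) that look like lumens in the eosin channel but are not
enclosed by epithelium.  Decoys are labeled stroma in the ground truth, which
is exactly what makes the boundary-adjacency elimination rule measurable:
a correct pipeline keeps every true lumen and rejects every decoy.

Realism is deliberately minimal (tubes + shells + spheres); the generator
exercises the algorithms' stated assumptions, not histological fidelity.
Every case is a pure function of its spec (seed included); volumes are
bit-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .types import (EPITHELIUM, LUMEN, STROMA, EOSIN_CHANNEL, NUCLEAR_CHANNEL,
                    SemanticMask, TwoChannelVolume)

#: default per-class mean intensities, (nuclear, eosin), arbitrary 8-bit-like units
DEFAULT_INTENSITY_TABLE = {
    "stroma": (80.0, 180.0),
    "epithelium": (200.0, 120.0),
    "lumen": (10.0, 10.0),
}

_CLASS_CODE = {"stroma": STROMA, "epithelium": EPITHELIUM, "lumen": LUMEN}


@dataclass
class PhantomSpec:
    """Generation parameters of one phantom case.

    Defaults mirror the evaluation-volume geometry the package targets:
    ~512×512×100 voxels at 1.8 µm isotropic pitch (~0.2 mm³ of tissue), with
    gland calibres of the order of benign prostate glands (lumen radius
    ~25 µm, single-cell epithelial shell ~12 µm).
    """

    volume_shape: tuple[int, int, int] = (100, 512, 512)
    spacing: tuple[float, float, float] = (1.8, 1.8, 1.8)
    n_glands: int = 6
    lumen_radius_um: float = 25.0
    lumen_radius_jitter: float = 0.2        # fractional ± spread of the radius
    epithelium_thickness_um: float = 12.0
    tortuosity: float = 0.3                 # 0 = straight tubes
    branching_prob: float = 0.02            # per centerline step
    n_decoys: int = 4
    decoy_radius_um: float = 15.0
    intensity_table: dict = field(default_factory=lambda: dict(DEFAULT_INTENSITY_TABLE))
    noise_sigma: float = 0.0
    seed: int = 42

    def __post_init__(self):
        self.volume_shape = tuple(int(v) for v in self.volume_shape)
        self.spacing = tuple(float(v) for v in self.spacing)
        if min(self.volume_shape) < 1 or min(self.spacing) <= 0:
            raise ValueError("volume_shape must be positive and spacing > 0")
        if self.lumen_radius_um <= 0 or self.epithelium_thickness_um <= 0:
            raise ValueError("radius and shell thickness must be positive")
        if not (0 <= self.tortuosity <= 1 and 0 <= self.branching_prob <= 1):
            raise ValueError("tortuosity and branching_prob must lie in [0, 1]")
        if not 0 <= self.lumen_radius_jitter < 1:
            raise ValueError("lumen_radius_jitter must lie in [0, 1)")
        if self.noise_sigma < 0 or self.n_glands < 0 or self.n_decoys < 0:
            raise ValueError("noise_sigma, n_glands, n_decoys must be >= 0")
        missing = set(_CLASS_CODE) - set(self.intensity_table)
        if missing:
            raise ValueError(f"intensity_table missing class(es): {sorted(missing)}")
        for cls, pair in self.intensity_table.items():
            if len(tuple(pair)) != 2 or min(pair) < 0:
                raise ValueError(f"intensity_table[{cls!r}] must be two non-negative "
                                 "values (nuclear, eosin)")
        if not (self.intensity_table["lumen"][1] < self.intensity_table["stroma"][1]):
            raise ValueError("eosin intensity of lumen must be below stroma "
                             "(the contrast the watershed baseline requires)")


@dataclass
class Centerline:
    """One gland-tube centerline polyline, in (z, y, x) voxel coordinates."""

    points: np.ndarray          # (N, 3) float
    radius_um: float
    gland_id: int


@dataclass
class PhantomCase:
    """A generated case: paired volume, ground truth, and provenance."""

    volume: TwoChannelVolume
    truth: SemanticMask
    spec: PhantomSpec
    centerlines: list[Centerline]
    decoy_centers: np.ndarray   # (M, 3) float voxel coords
    decoy_radii_um: np.ndarray  # (M,)

    def decoy_mask(self) -> np.ndarray:
        """Boolean mask of the decoy blobs (labeled stroma in the truth)."""
        return _rasterize_spheres(self.spec.volume_shape, self.spec.spacing,
                                  self.decoy_centers, self.decoy_radii_um)


# ---------------------------------------------------------------------------
# geometry sampling

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([0.0, 0.0, 1.0])


def _margins_vox(spec: PhantomSpec, extra_um: float) -> np.ndarray:
    return np.ceil(extra_um / np.asarray(spec.spacing)).astype(int) + 2


def _walk(rng, start, direction, spec, lo, hi, max_steps=400):
    """Random-walk polyline from ``start`` until it leaves the [lo, hi] box."""
    step_um = 3.0 * min(spec.spacing)
    step_vox = step_um / np.asarray(spec.spacing)
    points = [np.asarray(start, dtype=float)]
    d = _unit(np.asarray(direction, dtype=float))
    branch_sites = []
    for _ in range(max_steps):
        if spec.tortuosity > 0:
            d = _unit(d + spec.tortuosity * 0.35 * rng.normal(size=3))
        nxt = points[-1] + d * step_vox
        if np.any(nxt < lo) or np.any(nxt > hi):
            break
        points.append(nxt)
        if spec.branching_prob > 0 and rng.random() < spec.branching_prob:
            perp = _unit(np.cross(d, rng.normal(size=3)))
            branch_sites.append((nxt.copy(), _unit(d + 1.2 * perp)))
    return np.asarray(points), branch_sites


def sample_centerlines(spec: PhantomSpec, rng=None) -> list[Centerline]:
    """Sample gland centerline polylines, fully deterministic given the seed.

    Each gland is a random walk (direction perturbed in proportion to the
    tortuosity) that may spawn branches with probability ``branching_prob``
    per step.  Glands are kept mutually separated by at least the sum of
    their shell radii plus a safety margin; if a gland cannot be placed after
    bounded retries, a placement error is raised.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    shape = np.asarray(spec.volume_shape, dtype=float)
    out: list[Centerline] = []
    placed_points: list[np.ndarray] = []
    placed_shell_um: list[float] = []

    for gid in range(spec.n_glands):
        radius = spec.lumen_radius_um * (
            1.0 + spec.lumen_radius_jitter * rng.uniform(-1.0, 1.0))
        shell_um = radius + spec.epithelium_thickness_um
        margin = _margins_vox(spec, shell_um)
        lo, hi = margin.astype(float), shape - 1 - margin
        if np.any(hi <= lo):
            raise ValueError(
                f"volume {spec.volume_shape} too small for shell radius {shell_um:.1f} µm")
        tree = (cKDTree(np.vstack(placed_points) * spec.spacing)
                if placed_points else None)
        sep_um = (shell_um + (max(placed_shell_um) if placed_shell_um else 0.0)
                  + 3.0 * max(spec.spacing))

        def _truncate(pts):
            # cut a walk where it first approaches an already-placed gland
            if tree is None or not len(pts):
                return pts
            d = tree.query(pts * spec.spacing, k=1)[0]
            bad = np.flatnonzero(d < sep_um)
            return pts if not len(bad) else pts[:bad[0]]

        ok = False
        for _attempt in range(200):
            start = rng.uniform(lo, hi)
            main, branch_sites = _walk(rng, start, rng.normal(size=3), spec, lo, hi)
            main = _truncate(main)
            if len(main) < 10:
                continue
            polylines = [main]
            for site, bdir in branch_sites[:3]:
                if not np.any(np.all(np.isclose(main, site), axis=1)):
                    continue  # branch site fell in the truncated tail
                bpts, _ = _walk(rng, site, bdir, spec, lo, hi, max_steps=200)
                bpts = _truncate(bpts)
                if len(bpts) >= 5:
                    polylines.append(bpts)
            for pts in polylines:
                out.append(Centerline(points=pts, radius_um=radius, gland_id=gid))
                placed_points.append(pts)
                placed_shell_um.append(shell_um)
            ok = True
            break
        if not ok:
            raise ValueError(
                f"placement failure: could not fit gland {gid} of {spec.n_glands} "
                f"(radius {radius:.1f} µm) after bounded retries")
    return out


def sample_decoys(spec: PhantomSpec, centerlines: list[Centerline], rng=None):
    """Place decoy spheres strictly clear of every gland shell."""
    rng = np.random.default_rng(spec.seed + 1) if rng is None else rng
    shape = np.asarray(spec.volume_shape, dtype=float)
    spacing = np.asarray(spec.spacing)
    if centerlines:
        tree = cKDTree(np.vstack([c.points for c in centerlines]) * spacing)
        max_shell = max(c.radius_um for c in centerlines) + spec.epithelium_thickness_um
    else:
        tree, max_shell = None, 0.0
    centers, radii = [], []
    for _ in range(spec.n_decoys):
        r = spec.decoy_radius_um
        margin = _margins_vox(spec, r)
        lo, hi = margin.astype(float), shape - 1 - margin
        placed = False
        for _attempt in range(200):
            c = rng.uniform(lo, hi)
            clear_um = r + max_shell + 4.0 * max(spec.spacing)
            if tree is not None and tree.query(c * spacing, k=1)[0] < clear_um:
                continue
            if centers and min(np.linalg.norm((c - np.array(p)) * spacing)
                               for p in centers) < 2 * r + 4.0 * max(spec.spacing):
                continue
            centers.append(c)
            radii.append(r)
            placed = True
            break
        if not placed:
            raise ValueError("placement failure: could not fit all decoys")
    return (np.asarray(centers).reshape(-1, 3), np.asarray(radii))


# ---------------------------------------------------------------------------
# rasterization

def _dense_polyline_voxels(points: np.ndarray) -> np.ndarray:
    """Voxel indices along a polyline, sampled densely enough to leave no gaps."""
    out = []
    for a, b in zip(points[:-1], points[1:]):
        seg = b - a
        n = max(2, int(np.ceil(np.linalg.norm(seg) / 0.5)) + 1)
        out.append(a + np.linspace(0, 1, n)[:, None] * seg)
    if not out:
        out = [points]
    vox = np.rint(np.vstack(out)).astype(int)
    return np.unique(vox, axis=0)


def _rasterize_spheres(volume_shape, spacing, centers, radii_um) -> np.ndarray:
    mask = np.zeros(volume_shape, dtype=bool)
    spacing = np.asarray(spacing)
    for c, r in zip(np.asarray(centers).reshape(-1, 3), np.atleast_1d(radii_um)):
        rv = np.ceil(r / spacing).astype(int) + 1
        lo = np.maximum(np.rint(c).astype(int) - rv, 0)
        hi = np.minimum(np.rint(c).astype(int) + rv + 1, volume_shape)
        grid = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].astype(float)
        d2 = sum(((grid[i] - c[i]) * spacing[i]) ** 2 for i in range(3))
        mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= d2 <= r * r
    return mask


def rasterize_truth(centerlines: list[Centerline], spec: PhantomSpec) -> SemanticMask:
    """Rasterize centerlines into the ground-truth semantic mask.

    A voxel within ``radius_um`` (physical distance) of a gland's centerline
    is lumen; within ``radius_um + epithelium_thickness_um`` it is epithelium
    unless already lumen; everything else is stroma.  Distances are computed
    with a Euclidean distance transform of the rasterized centerline inside a
    per-gland bounding box, so the lumen is enclosed by its shell by
    construction.
    """
    if spec.epithelium_thickness_um < max(spec.spacing):
        raise ValueError(
            f"epithelium shell thinner than one voxel "
            f"({spec.epithelium_thickness_um} µm < max spacing {max(spec.spacing)} µm)")
    shape = spec.volume_shape
    spacing = np.asarray(spec.spacing)
    lumen = np.zeros(shape, dtype=bool)
    epi = np.zeros(shape, dtype=bool)

    by_gland: dict[int, list[Centerline]] = {}
    for c in centerlines:
        if not isinstance(c, Centerline):
            raise TypeError("rasterize_truth expects Centerline objects")
        by_gland.setdefault(c.gland_id, []).append(c)
    for gid, lines in by_gland.items():
        radius = lines[0].radius_um
        shell = radius + spec.epithelium_thickness_um
        pts = np.vstack([l.points for l in lines])
        pad = np.ceil(shell / spacing).astype(int) + 2
        lo = np.maximum(np.floor(pts.min(axis=0)).astype(int) - pad, 0)
        hi = np.minimum(np.ceil(pts.max(axis=0)).astype(int) + pad + 1, shape)
        box = tuple(slice(a, b) for a, b in zip(lo, hi))
        seeds = np.zeros(tuple(hi - lo), dtype=bool)
        vox = np.vstack([_dense_polyline_voxels(l.points) for l in lines]) - lo
        vox = np.clip(vox, 0, np.array(seeds.shape) - 1)
        seeds[tuple(vox.T)] = True
        dist = ndimage.distance_transform_edt(~seeds, sampling=spec.spacing)
        lumen[box] |= dist <= radius
        epi[box] |= dist <= shell
    labels = np.full(shape, STROMA, dtype=np.uint8)
    labels[epi] = EPITHELIUM
    labels[lumen] = LUMEN
    return SemanticMask(labels=labels, spacing=spec.spacing)


def render_channels(truth: SemanticMask, spec: PhantomSpec,
                    decoy_mask: np.ndarray | None = None,
                    rng=None) -> TwoChannelVolume:
    """Render the two fluorescence channels from the truth and decoy geometry.

    Each voxel takes its class-mean intensity from the intensity table;
    decoy voxels are rendered lumen-dark (in both channels) despite being
    labeled stroma in the truth.  Gaussian noise of scale ``noise_sigma`` is
    added and the result clipped at zero.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed + 2) if rng is None else rng
    shape = truth.shape
    data = np.zeros((2,) + shape, dtype=np.float32)
    for cls, (nuc, eos) in spec.intensity_table.items():
        sel = truth.labels == _CLASS_CODE[cls]
        data[NUCLEAR_CHANNEL][sel] = nuc
        data[EOSIN_CHANNEL][sel] = eos
    if decoy_mask is not None and decoy_mask.any():
        nuc, eos = spec.intensity_table["lumen"]
        data[NUCLEAR_CHANNEL][decoy_mask] = nuc
        data[EOSIN_CHANNEL][decoy_mask] = eos
    if spec.noise_sigma > 0:
        data = data + rng.normal(0.0, spec.noise_sigma, size=data.shape).astype(np.float32)
        np.clip(data, 0.0, None, out=data)
    return TwoChannelVolume(data=data, spacing=spec.spacing)


# ---------------------------------------------------------------------------
# case and suite assembly

def _face_neighbor_any(target: np.ndarray, of: np.ndarray) -> np.ndarray:
    """Voxels of ``of`` having at least one 6-neighbor in ``target``."""
    adj = np.zeros(of.shape, dtype=bool)
    for axis in range(3):
        for shift in (1, -1):
            t = np.roll(target, shift, axis=axis)
            edge = [slice(None)] * 3
            edge[axis] = slice(0, 1) if shift == 1 else slice(-1, None)
            t[tuple(edge)] = False
            adj |= t
    return adj & of


def verify_case(case: PhantomCase) -> dict:
    """Check the generator's structural invariants on one case.

    Returns fractions: ``lumen_enclosure`` (lumen boundary voxels with an
    epithelium face-neighbor; must be 1), ``decoy_epithelium_adjacency``
    (decoy boundary voxels with an epithelium face-neighbor; must be 0), and
    the rendered eosin class means (must order lumen < epithelium < stroma).
    """
    labels = case.truth.labels
    lum = labels == LUMEN
    epi = labels == EPITHELIUM
    interior = lum.copy()
    for axis in range(3):
        for shift in (1, -1):
            t = np.roll(lum, shift, axis=axis)
            edge = [slice(None)] * 3
            edge[axis] = slice(0, 1) if shift == 1 else slice(-1, None)
            t[tuple(edge)] = False
            interior &= t
    boundary = lum & ~interior
    enclosed = _face_neighbor_any(epi, boundary)
    enclosure = (np.count_nonzero(enclosed) / np.count_nonzero(boundary)
                 if boundary.any() else 1.0)

    dec = case.decoy_mask()
    dec_touch = _face_neighbor_any(epi, dec)
    decoy_adj = (np.count_nonzero(dec_touch) / max(np.count_nonzero(dec), 1))

    eosin = case.volume.eosin
    means = {cls: float(eosin[(labels == code) & ~dec].mean())
             for cls, code in _CLASS_CODE.items()
             if ((labels == code) & ~dec).any()}
    return {"lumen_enclosure": float(enclosure),
            "decoy_epithelium_adjacency": float(decoy_adj),
            "eosin_class_means": means}


def generate_case(spec: PhantomSpec) -> PhantomCase:
    """Generate one phantom case; raises if a structural invariant fails."""
    rng = np.random.default_rng(spec.seed)
    centerlines = sample_centerlines(spec, rng)
    decoy_centers, decoy_radii = sample_decoys(spec, centerlines, rng)
    truth = rasterize_truth(centerlines, spec)
    decoy_mask = _rasterize_spheres(spec.volume_shape, spec.spacing,
                                    decoy_centers, decoy_radii)
    volume = render_channels(truth, spec, decoy_mask, rng)
    name = f"phantom_{spec.seed:05d}"
    volume.name = name
    truth.name = name
    case = PhantomCase(volume=volume, truth=truth, spec=spec,
                       centerlines=centerlines, decoy_centers=decoy_centers,
                       decoy_radii_um=decoy_radii)
    checks = verify_case(case)
    if checks["lumen_enclosure"] < 1.0:
        raise AssertionError(f"enclosure invariant violated: {checks}")
    if checks["decoy_epithelium_adjacency"] > 0.0:
        raise AssertionError(f"decoy exposure invariant violated: {checks}")
    return case


def generate_suite(n_cases: int, spec: PhantomSpec | None = None,
                   base_seed: int = 42) -> tuple[list[PhantomCase], dict]:
    """Generate ``n_cases`` cases with seeds ``base_seed .. base_seed+n-1``.

    Returns the cases plus a manifest recording every spec field per case.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    spec = spec or PhantomSpec()
    cases, entries = [], []
    for i in range(int(n_cases)):
        case_spec = replace(spec, seed=int(base_seed) + i)
        case = generate_case(case_spec)
        cases.append(case)
        entry = asdict(case_spec)
        entry["name"] = case.volume.name
        entries.append(entry)
    manifest = {"n_cases": int(n_cases), "base_seed": int(base_seed), "cases": entries}
    return cases, manifest


def write_suite(cases, manifest, out_dir, fmt: str = "nifti") -> Path:
    """Write a suite to disk (volume + truth per case, plus manifest.json)."""
    from . import volume_io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ext = ".nii.gz" if fmt == "nifti" else ".tiff"
    for case in cases:
        volume_io.write_volume(case.volume, out / f"{case.volume.name}_image{ext}")
        volume_io.write_mask(case.truth, out / f"{case.truth.name}_truth{ext}", format=fmt)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
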