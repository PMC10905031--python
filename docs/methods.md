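# Methods

## Problem and scope

Non-destructive 3D pathology images intact prostate biopsies with open-top
light-sheet microscopy in two fluorescence channels that mimic H&E contrast:
a nuclear (hematoxylin-analog) channel and an eosin-analog channel.  Gland
segmentation in these volumes assigns every voxel to one of three tissue
compartments — stroma (1), epithelium (2), lumen (3) — with 0 reserved for
background/unannotated space.  `gland3d` implements the *classical* route to
such masks (a marker-seeded 3D watershed baseline), the evaluation metrics
and statistics used to benchmark segmentation methods against manual
annotations, block chunking for biopsy-scale volumes, interchange with the
nnU-Net dataset folder convention, and a phantom generator that makes all of
it testable without external data.  Deep-network training and inference are
out of scope; the toolkit only reads and writes datasets in the nnU-Net
layout.

## Segmentation baseline

The baseline exploits the two anatomical facts the imaging scheme provides:
lumens are empty space, hence dark in the eosin channel; epithelium is
nuclear-dense, hence bright in the nuclear channel; and a true lumen is
always enclosed by an epithelial cell layer.

1. **Candidate lumens.**  The eosin channel is Gaussian-smoothed
   (`smoothing_sigma_um`, default 1.8 µm ≈ one voxel at the working
   resolution), split into dark and bright classes by Otsu's threshold, and
   the face-connected components of the dark class seed a 3D watershed on
   the eosin landscape restricted to that class.  Components smaller than
   `min_lumen_volume_um3` (default 500 µm³) are discarded as specks.
2. **Epithelium.**  The nuclear channel is smoothed the same way,
   Otsu-split, and the bright components seed a watershed over the inverted
   nuclear intensity confined to the bright class; components below
   `min_epithelium_volume_um3` (default 1000 µm³) are removed.  An optional
   hole-filling flag (off by default) closes enclosed cavities.
3. **Elimination rule.**  For every candidate, the boundary voxels (those
   with a face neighbor outside the region) are classified by whether they
   have a face neighbor in the epithelium mask.  A candidate is eliminated
   iff the *non-adjacent* fraction strictly exceeds `adjacency_threshold`
   (default 0.5): a strict majority of exposed boundary eliminates, exactly
   half keeps.  This is what rejects dark stromal artifacts (tears,
   vessels) that imitate lumens.
4. **Composition.**  Surviving lumens overwrite epithelium
   (precedence lumen > epithelium > stroma); every in-volume voxel ends in
   {1, 2, 3}.

All region logic uses 6-connectivity — the conservative choice for thin
epithelial walls.  The working resolution is 1.8 µm; inputs at finer pitch
are mean-pooled 2× per axis until they reach it (logged).

### Watershed and Otsu primitives

Both primitives are implemented in the package so their tie-breaking is
documented and bit-reproducible:

* `watershed_3d` is a priority flood: a queue ordered by (landscape value,
  insertion age), seeds entering in lexicographic (z, y, x) order, each
  popped voxel claiming its unlabeled in-mask face neighbors in
  lexicographic offset order.  Equal-priority voxels therefore resolve by
  FIFO age, deterministically.  Tests verify exact agreement with an
  independent linear-scan flood oracle on random instances (including flat
  plateaus) and with scikit-image's watershed away from ridge ties.
* `otsu_threshold` returns the histogram *bin edge* maximizing the
  between-class variance w0·w1·(µ0−µ1)² over an `n_bins` histogram (default
  256), ties resolved toward the lowest qualifying edge; classifying with
  `value < t` reproduces the split exactly.  Tests verify equality with an
  exhaustive per-edge search.

In the pipeline's own calls every in-mask voxel is seeded (the markers are
the connected components of the mask itself), so the flood reduces to the
seeded labeling; a vectorized fast path returns it directly.  The general
flood is exercised by sparse-marker uses and by the oracle tests.

### A note on binary Otsu over three tissue classes

The eosin histogram of a phantom has three modes (lumen 10, epithelium 120,
stroma 180 by default).  A binary Otsu split then sits between two local
optima: dark = {lumen} or dark = {lumen, epithelium}.  At the default study
geometry (512×512×100 voxels, ~96 % stroma) the variance criterion selects
the lumen-only split and candidate lumens match true lumens with Dice
0.92–0.94; in much smaller volumes, where smoothed interface voxels are
proportionally more numerous, it can tip the other way.  Unit tests that
assert per-lumen candidate quality therefore use a strictly bimodal eosin
phantom (epithelium rendered at stroma brightness); the suite-level checks
run at the default geometry and intensity table.  On real tissue, where the
eosin histogram is broad, the thresholds can be fixed explicitly
(`eosin_threshold` / `nuclear_threshold`).

## Evaluation metrics

For voxel sets A, B on a common grid with per-axis spacing s (µm), a voxel
index maps to the physical point of its centre, x = (z·s_z, y·s_y, x·s_x):

* Dice(A, B) = 2|A∩B| / (|A| + |B|), unitless in [0, 1];
* H(A, B) = max( sup_{a∈A} inf_{b∈B} d(a, b), sup_{b∈B} inf_{a∈A} d(a, b) ),
  with d the Euclidean metric on physical points, reported in µm.
  By default each set is first reduced to its face-boundary voxels
  ("boundary" mode), the segmentation-practice convention that makes H a
  contour-error measure; "full" mode applies the definition to all voxels.
  Anisotropic spacing is fully supported.

Manual annotations of these specimens delineate only the gland/stroma
interface, so the *gland-level* protocol compares epithelium∪lumen between
prediction and reference; a per-class mode scores the three compartments
separately.  Degenerate inputs are signalled, not silently scored: Dice of
two empty sets and Hausdorff of any empty set raise, and aggregation skips
such rows.

Per-case scores of competing methods are compared with two-sample t tests —
pooled-variance (Student) by default, the textbook reading of "two-sample
t test", with Welch behind a flag — two-sided, and deliberately *without*
multiple-comparison correction, matching the benchmarking protocol the
package mirrors.  Identical degenerate (zero-variance) groups report
t = 0, p = 1.

## Blocking

Biopsy-scale volumes (~500×350×10000 voxels at 1.8 µm) are processed as
axis-aligned blocks (default 512×350×512 voxels ≈ 1 mm³).  Starts advance by
`block − overlap` per axis; the final block is shifted left so its end
coincides with the volume extent — no padding, so exported blocks contain
only real voxels, at the price of the last block re-covering part of its
neighbour when the block does not divide the extent.  Enumeration is
z-major, and stitching resolves overlaps last-writer-wins in that order;
extract-then-stitch is the identity for any mask and layout.  Blocked
segmentation estimates the two Otsu thresholds once globally so that all
blocks share one contrast model; disagreement with whole-volume segmentation
is then confined to seam bands (verified in tests), and a zero-overlap
blocked run warns that seam-crossing structures may be split.  Only hard
label masks are stitched; weighted blending of probability maps is a
non-goal.

## Phantom generator

Each case is a pure function of its spec (a dataclass whose `seed` drives a
PCG64 generator; suites use consecutive seeds).  Geometry: `n_glands`
(default 6) random-walk centerlines inside a 100×512×512-voxel volume at
1.8 µm pitch (~0.2 mm³ of tissue, the evaluation-volume geometry the
package targets), step 3 voxels, direction perturbed in proportion to
`tortuosity` (0.3), branches spawned with probability 0.02 per step, tube
lumen radius 25 µm ± 20 % and epithelial shell thickness 12 µm — the order
of magnitude of benign human prostate glands; the generator makes no claim
to cohort statistics.  Glands are kept mutually separated by their summed
shell radii plus a safety margin and away from the volume faces, so the
enclosure property (every lumen boundary voxel has an epithelium face
neighbor) holds by construction; it is asserted on every generated case, as
is the complementary guarantee that the 4 decoy spheres (radius 15 µm,
placed clear of every shell) have zero epithelium adjacency.  Distance to a
centerline is computed by a Euclidean distance transform of the rasterized
polyline inside a per-gland bounding box (error below half a voxel
diagonal).

Rendering assigns class-mean intensities (nuclear/eosin: stroma 80/180,
epithelium 200/120, lumen 10/10, arbitrary 8-bit-like units — chosen to
satisfy the required eosin ordering lumen < epithelium < stroma with wide
margins), renders decoys lumen-dark despite their stroma truth label, adds
optional Gaussian noise (`noise_sigma`, default 0: the reference conditions
are noise-free), and clips at zero.

What the phantom deliberately omits: light-sheet optics (anisotropic PSF,
stripe artifacts, depth attenuation), intensity inhomogeneity, textured
stroma, and cancerous architectures (cribriform, fused glands).  Passing
tests on phantoms therefore demonstrates that the algorithms honour their
stated geometric and contrast assumptions — not that the baseline reaches
any particular accuracy on real tissue, where those assumptions erode.

## Numerical and design choices

* Downsampling (unspecified in the protocol the package follows): 2×2×2
  local mean for intensities (anti-aliased, sum-preserving) and local mode
  for labels with ties broken toward the *highest* code
  (lumen > epithelium > stroma > background) so thin lumens survive; odd
  trailing slices are cropped with a warning.  Two applications realize the
  0.45 → 0.9 → 1.8 µm chain exactly.
* I/O: TIFF (native microscopy format, spacing in the shaped-metadata tag)
  and NIfTI (spacing in header zooms, stored float32 and rounded to 1e-6 µm
  on read).  Intensities are written as unsigned 16-bit, labels as unsigned
  8-bit; round trips are bit-exact for integral data.
* nnU-Net interchange: `Dataset<NNN>_<name>/{imagesTr,labelsTr,dataset.json}`
  with `_0000`/`_0001` channel suffixes; imports validate label codes and
  name missing cases.
* Configs are JSON with a versioned schema; unknown keys are rejected with
  a closest-match suggestion; every run directory receives the normalized
  config, tool version, log and a machine-readable summary.

## Problem sizes used by tests and the acceptance script

Unit tests run on 40×96×96-voxel phantoms with proportionally smaller
glands (lumen radius 10 µm, shell 7.2 µm).  The acceptance checks and
`scripts/acceptance.py` use the default study conditions: the 10-case
noise-free 100×512×512 suite (consecutive seeds from the given base seed),
whole-volume segmentation, gland-level evaluation; oracle-equivalence
checks use 200 random voxel-set pairs on grids ≤ 12³ and 100 random
watershed instances ≤ 8³.

## Known limitations

* The priority-flood watershed is implemented in Python with a binary heap;
  it is exact but not tuned for sparse-marker floods over full biopsy
  volumes (the pipeline's fully-seeded calls bypass the flood).
* Binary Otsu's knife edge on three-mode histograms (above) is inherent to
  the baseline being reconstructed; fixed thresholds are the escape hatch.
* The epithelium detector reduces to threshold + components + size floor on
  noise-free phantoms; its watershed formulation only matters on data with
  internal intensity structure.
* Hausdorff on "full" mode is quadratic in memory via KD-trees only; very
  large sets should use boundary mode (the default).
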