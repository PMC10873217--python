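"""Global Noise Index (GNI) estimation.

Pipeline: threshold the volume slice-by-slice to a tissue mask, tile each
slice into non-overlapping 8×8 blocks, assign each resulting macro pixel the
sample standard deviation of the in-mask SUV values in its block, pool all
valid macro-pixel values of the whole imaging volume into a uniform-bin
histogram, and report the mode bin center as the GNI.

The histogram of macro-pixel noise is typically right-skewed: blocks that
straddle anatomical borders mix tissues and produce large SDs, while the bulk
of blocks cover homogeneous tissue. The mode therefore tracks the noise level
of homogeneous tissue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu

from .errors import (
    DegenerateBlockError,
    NoNoiseSamplesError,
    NoTissueFoundWarning,
    SliceTooSmallError,
)
from .io import SuvVolume

DEFAULT_THRESHOLD = 0.15
DEFAULT_BLOCK_SIZE = 8
DEFAULT_BIN_WIDTH = 0.01
DEFAULT_MIN_VALID_FRACTION = 0.5


@dataclass
class NoiseParams:
    """Parameters of the GNI pipeline, echoed into every result."""

    threshold: float | str = DEFAULT_THRESHOLD  # SUV value, or "otsu"
    block_size: int = DEFAULT_BLOCK_SIZE
    bin_width: float = DEFAULT_BIN_WIDTH
    min_valid_fraction: float = DEFAULT_MIN_VALID_FRACTION
    largest_component: bool = True
    fill_holes: bool = True


@dataclass
class TissueMask:
    mask: np.ndarray  # boolean, congruent with the source volume
    threshold_used: float
    morphology_applied: dict = field(default_factory=dict)

    @property
    def is_empty(self) -> bool:
        return not bool(self.mask.any())


@dataclass
class NoiseMap:
    """Per-slice reduced-matrix grid of macro-pixel SD values."""

    values: np.ndarray  # 2-D float, SUV units; undefined where invalid
    valid: np.ndarray  # 2-D bool
    block_size: int
    slice_index: int

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]


@dataclass
class NoiseHistogram:
    bin_width: float
    bin_edges: np.ndarray  # uniform, left-closed right-open, starting at 0
    counts: np.ndarray
    n_total: int


@dataclass
class GNIResult:
    gni: float
    histogram: NoiseHistogram
    n_slices: int
    n_macro_pixels: int
    params: NoiseParams


@dataclass
class SliceGNISeries:
    """Per-slab GNI values; NaN marks slabs with no valid macro pixels."""

    gni: np.ndarray
    slab_thickness: int
    slab_starts: np.ndarray


# ---------------------------------------------------------------------------
# Masking
# ---------------------------------------------------------------------------


def tissue_mask(
    volume: SuvVolume,
    threshold: float | str = DEFAULT_THRESHOLD,
    largest_component: bool = True,
    fill_holes: bool = True,
) -> TissueMask:
    """Classify patient tissue by thresholding, slice by slice.

    Voxels with SUV strictly above ``threshold`` are tissue. Per slice, the
    mask is optionally restricted to the largest connected component and
    hole-filled (both on by default) so that low-uptake interior tissue such
    as lung stays inside the mask. ``threshold="otsu"`` derives the value
    automatically from the whole volume.

    Emits a :class:`NoTissueFoundWarning` if no tissue is found anywhere.
    """
    if threshold == "otsu":
        threshold = float(threshold_otsu(volume.voxels))
    threshold = float(threshold)
    if threshold < 0:
        raise ValueError("threshold must be non-negative")

    raw = volume.voxels > threshold
    out = np.zeros_like(raw)
    for k in range(raw.shape[0]):
        sl = raw[k]
        if largest_component and sl.any():
            labels = measure.label(sl, connectivity=2)
            counts = np.bincount(labels.ravel())
            counts[0] = 0
            sl = labels == int(np.argmax(counts))
        if fill_holes and sl.any():
            sl = ndimage.binary_fill_holes(sl)
        out[k] = sl
    if not out.any():
        warnings.warn("no tissue found", NoTissueFoundWarning, stacklevel=2)
    return TissueMask(
        mask=out,
        threshold_used=threshold,
        morphology_applied={"largest_component": largest_component, "fill_holes": fill_holes},
    )


# ---------------------------------------------------------------------------
# Macro-pixel noise maps
# ---------------------------------------------------------------------------


def block_sd(values: Sequence[float] | np.ndarray) -> float:
    """Sample standard deviation (denominator n−1) of ≥ 2 values."""
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise DegenerateBlockError("degenerate block: need at least 2 values")
    return float(np.std(values, ddof=1))


def slice_noise_map(
    slice_2d: np.ndarray,
    mask_slice: np.ndarray,
    block_size: int = DEFAULT_BLOCK_SIZE,
    min_valid_fraction: float = DEFAULT_MIN_VALID_FRACTION,
    slice_index: int = 0,
) -> NoiseMap:
    """Reduce one slice to its macro-pixel noise map.

    The slice is tiled into non-overlapping ``block_size``×``block_size``
    blocks anchored at index (0, 0); trailing partial rows/columns are
    dropped. A macro pixel is valid iff the in-mask fraction of its block is
    ≥ ``min_valid_fraction`` (and at least two pixels are in-mask); its value
    is the sample SD over the in-mask pixels only.
    """
    slice_2d = np.asarray(slice_2d, dtype=np.float64)
    mask_slice = np.asarray(mask_slice, dtype=bool)
    if slice_2d.shape != mask_slice.shape:
        raise ValueError("slice and mask must be congruent")
    if block_size < 2:
        raise ValueError("block_size must be >= 2")
    h, w = slice_2d.shape
    nby, nbx = h // block_size, w // block_size
    if nby == 0 or nbx == 0:
        raise SliceTooSmallError("slice too small for one macro-pixel block")

    b = block_size
    x = slice_2d[: nby * b, : nbx * b].reshape(nby, b, nbx, b)
    m = mask_slice[: nby * b, : nbx * b].reshape(nby, b, nbx, b)

    n = m.sum(axis=(1, 3)).astype(np.float64)
    valid = (n >= max(2.0, min_valid_fraction * b * b)) & (n / (b * b) >= min_valid_fraction)

    # Two-pass masked SD (numerically stable; matches brute force to float precision).
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = np.where(m, x, 0.0).sum(axis=(1, 3)) / n
        dev = np.where(m, x - mu[:, None, :, None], 0.0)
        ssd = (dev * dev).sum(axis=(1, 3))
        sd = np.sqrt(ssd / (n - 1.0))
    values = np.where(valid, sd, np.nan)
    return NoiseMap(values=values, valid=valid, block_size=b, slice_index=slice_index)


def volume_noise_maps(
    volume: SuvVolume,
    mask: TissueMask,
    block_size: int = DEFAULT_BLOCK_SIZE,
    min_valid_fraction: float = DEFAULT_MIN_VALID_FRACTION,
) -> list[NoiseMap]:
    """One noise map per slice of the volume."""
    return [
        slice_noise_map(
            volume.voxels[k],
            mask.mask[k],
            block_size=block_size,
            min_valid_fraction=min_valid_fraction,
            slice_index=k,
        )
        for k in range(volume.n_slices)
    ]


# ---------------------------------------------------------------------------
# Histogram and mode
# ---------------------------------------------------------------------------


def noise_histogram(maps: Iterable[NoiseMap], bin_width: float = DEFAULT_BIN_WIDTH) -> NoiseHistogram:
    """Pool all valid macro-pixel values into a uniform-bin histogram.

    Bins are [k·w, (k+1)·w), starting at 0 and extending to cover the maximum
    observed value. The counts conserve the number of valid macro pixels.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    vals = [nm.valid_values() for nm in maps]
    pooled = np.concatenate(vals) if vals else np.empty(0)
    return _histogram_from_values(pooled, bin_width)


def _histogram_from_values(pooled: np.ndarray, bin_width: float) -> NoiseHistogram:
    if pooled.size == 0:
        raise NoNoiseSamplesError("no noise samples: zero valid macro pixels")
    idx = np.floor(pooled / bin_width).astype(np.int64)
    counts = np.bincount(idx)
    edges = np.arange(counts.size + 1, dtype=np.float64) * bin_width
    return NoiseHistogram(
        bin_width=float(bin_width),
        bin_edges=edges,
        counts=counts,
        n_total=int(pooled.size),
    )


def histogram_mode(hist: NoiseHistogram) -> float:
    """Center of the maximal-count bin; ties resolved to the lowest bin."""
    if hist.n_total < 1 or hist.counts.size == 0:
        raise NoNoiseSamplesError("no noise samples: empty histogram")
    k = int(np.argmax(hist.counts))  # argmax returns the first (lowest) maximal bin
    return float((k + 0.5) * hist.bin_width)


# ---------------------------------------------------------------------------
# GNI
# ---------------------------------------------------------------------------


def global_noise_index(volume: SuvVolume, params: NoiseParams | None = None) -> GNIResult:
    """Compute the Global Noise Index of a whole imaging volume.

    Deterministic composition: tissue mask → per-slice macro-pixel noise maps
    → pooled histogram → mode.
    """
    params = params or NoiseParams()
    mask = tissue_mask(
        volume,
        threshold=params.threshold,
        largest_component=params.largest_component,
        fill_holes=params.fill_holes,
    )
    maps = volume_noise_maps(
        volume, mask, block_size=params.block_size, min_valid_fraction=params.min_valid_fraction
    )
    hist = noise_histogram(maps, bin_width=params.bin_width)
    return GNIResult(
        gni=histogram_mode(hist),
        histogram=hist,
        n_slices=volume.n_slices,
        n_macro_pixels=hist.n_total,
        params=params,
    )


def slicewise_gni(
    volume: SuvVolume, params: NoiseParams | None = None, slab_thickness: int = 1
) -> SliceGNISeries:
    """GNI computed per slice (or per slab of ``slab_thickness`` slices).

    Slabs with no valid macro pixels are marked NaN rather than raising, so
    the series always covers the full volume.
    """
    if slab_thickness < 1:
        raise ValueError("slab_thickness must be >= 1")
    params = params or NoiseParams()
    mask = tissue_mask(
        volume,
        threshold=params.threshold,
        largest_component=params.largest_component,
        fill_holes=params.fill_holes,
    )
    maps = volume_noise_maps(
        volume, mask, block_size=params.block_size, min_valid_fraction=params.min_valid_fraction
    )
    starts = np.arange(0, volume.n_slices, slab_thickness)
    out = np.full(starts.size, np.nan)
    for i, s in enumerate(starts):
        slab = maps[s : s + slab_thickness]
        vals = np.concatenate([nm.valid_values() for nm in slab]) if slab else np.empty(0)
        if vals.size:
            out[i] = histogram_mode(_histogram_from_values(vals, params.bin_width))
    return SliceGNISeries(gni=out, slab_thickness=slab_thickness, slab_starts=starts)


def noise_map_volume(maps: Sequence[NoiseMap], source: SuvVolume) -> SuvVolume:
    """Stack per-slice noise maps into a reduced-matrix volume for export.

    In-plane spacing is multiplied by the block factor; invalid macro pixels
    become NaN-free zeros with validity implied by a companion mask if needed.
    """
    b = maps[0].block_size
    stack = np.stack([np.where(nm.valid, nm.values, 0.0) for nm in maps], axis=0)
    dx, dy, dz = source.spacing
    return SuvVolume(
        voxels=stack,
        spacing=(dx * b, dy * b, dz),
        origin=source.origin,
        meta=source.meta,
    )
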