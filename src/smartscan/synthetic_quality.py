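"""Synthetic specimens, dwell-dependent noisy scans, and empirical quality curves.

This module is a self-contained, fully seeded stand-in for estimating a
quality curve from real data.  It draws membrane-like binary specimens
(boundaries of a random Voronoi partition), simulates fast and slow scans of
them with Poisson shot noise whose mean is proportional to dwell time,
composes mixed-dwell images through a rescan mask, scores them with a simple
classical segmenter (Gaussian smoothing + Otsu threshold), and fits a
monotone quality curve through the (rescan fraction, accuracy) samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import ValidationError
from .quality import QualityCurve, QualitySample, fit_monotone_curve

DEFAULT_FAST_DWELL_NS = 25.0
DEFAULT_SLOW_DWELL_NS = 1200.0
# Expected electron counts per ns of dwell.  At 0.04 a 25 ns fast scan
# expects ~1 count per membrane pixel (very noisy) while a 1200 ns slow scan
# expects ~48 (nearly clean), giving a quality curve with a usable dynamic
# range; much lower rates leave fast pixels saturated against the clip at 1
# and skew class means between mixed regions.
DEFAULT_BASE_RATE = 0.04
DEFAULT_CONTRAST = (0.3, 1.0)  # (background, membrane) relative brightness

MASK_STRATEGIES = ("random_blocks", "uniform_random")

# 95% two-sided normal quantile, used for replicate confidence intervals.
_Z95 = 1.959963984540054


def _child_seed(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


@dataclass(frozen=True)
class SpecimenImage:
    """Binary ground truth: membrane pixels are 1, background 0."""

    labels: np.ndarray
    seed: int

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    @property
    def membrane_fraction(self) -> float:
        return float(self.labels.mean())


@dataclass(frozen=True)
class ScanImage:
    """Simulated micrograph with intensities normalized to [0, 1]."""

    intensities: np.ndarray
    dwell_ns: Optional[float]
    seed: Optional[int]


@dataclass(frozen=True)
class RescanMask:
    """Binary mask of the area to re-image at the slow dwell time."""

    mask: np.ndarray
    target_fraction: float
    strategy: str


def generate_specimen(width: int, height: int, seed: int) -> SpecimenImage:
    """Draw a membrane-like binary specimen.

    Seeds a random Voronoi partition of the frame (about one cell per 1800
    pixels) and marks the boundaries between cells, dilated to roughly four
    pixels thick, as membrane.  Deterministic given ``(width, height, seed)``.
    """
    from skimage.morphology import dilation, disk
    from skimage.segmentation import find_boundaries

    if not (isinstance(width, int) and isinstance(height, int)):
        raise ValidationError("width and height must be integers")
    if width < 16 or height < 16:
        raise ValidationError(
            f"specimen must be at least 16x16 px, got {width}x{height}"
        )
    rng = _child_seed(seed, 0)
    n_cells = max(4, round(width * height / 1800))
    points = rng.uniform([0, 0], [height, width], size=(n_cells, 2))
    yy, xx = np.mgrid[0:height, 0:width]
    grid = np.column_stack([yy.ravel(), xx.ravel()])
    _, nearest = cKDTree(points).query(grid)
    cells = nearest.reshape(height, width)
    membrane = dilation(find_boundaries(cells, mode="thick"), disk(1))
    if membrane.all() or not membrane.any():
        raise ValidationError("degenerate geometry: specimen has a single class")
    return SpecimenImage(labels=membrane.astype(np.uint8), seed=seed)


def _contrast_map(spec: SpecimenImage, contrast) -> np.ndarray:
    low, high = contrast
    return np.where(spec.labels > 0, high, low).astype(float)


def simulate_scan(
    spec: SpecimenImage,
    dwell_ns: float,
    seed: int,
    base_rate: float = DEFAULT_BASE_RATE,
    contrast=DEFAULT_CONTRAST,
    noise: bool = True,
) -> ScanImage:
    """Simulate one scan of a specimen at the given dwell time.

    The expected electron count per pixel is ``base_rate * dwell_ns`` scaled
    by the class contrast; with ``noise=True`` counts are Poisson draws.
    Intensities are normalized by the maximum expected count and clipped to
    [0, 1], so signal-to-noise grows like the square root of the dwell time.
    With ``noise=False`` the normalized contrast map is returned exactly.
    """
    if not dwell_ns > 0:
        raise ValidationError(f"dwell_ns must be positive, got {dwell_ns!r}")
    if not base_rate > 0:
        raise ValidationError(f"base_rate must be positive, got {base_rate!r}")
    expected = base_rate * dwell_ns * _contrast_map(spec, contrast)
    scale = expected.max()
    if noise:
        rng = _child_seed(seed, 1)
        counts = rng.poisson(expected).astype(float)
    else:
        counts = expected
    img = np.clip(counts / scale, 0.0, 1.0)
    return ScanImage(intensities=img, dwell_ns=float(dwell_ns), seed=seed)


def build_rescan_mask(
    shape,
    fraction: float,
    strategy: str = "random_blocks",
    seed: int = 0,
    block_size: int = 32,
) -> RescanMask:
    """Build a binary rescan mask covering approximately ``fraction`` of the frame.

    ``uniform_random`` selects exactly ``round(fraction * n_pixels)`` pixels
    uniformly without replacement; ``random_blocks`` selects whole
    ``block_size``-square blocks (the spatially contiguous choice, and the
    default) until the rounded block count is reached.
    """
    if strategy not in MASK_STRATEGIES:
        raise ValidationError(
            f"unknown mask strategy {strategy!r}; expected one of {MASK_STRATEGIES}"
        )
    if not 0.0 <= fraction <= 1.0:
        raise ValidationError(f"fraction must lie in [0, 1], got {fraction!r}")
    height, width = shape
    rng = _child_seed(seed, 2)
    mask = np.zeros((height, width), dtype=np.uint8)
    if strategy == "uniform_random":
        n = height * width
        k = int(round(fraction * n))
        chosen = rng.choice(n, size=k, replace=False)
        mask.ravel()[chosen] = 1
    else:
        by = -(-height // block_size)  # ceil division
        bx = -(-width // block_size)
        n_blocks = by * bx
        k = int(round(fraction * n_blocks))
        for b in rng.choice(n_blocks, size=k, replace=False):
            i, j = divmod(int(b), bx)
            mask[
                i * block_size : (i + 1) * block_size,
                j * block_size : (j + 1) * block_size,
            ] = 1
    return RescanMask(mask=mask, target_fraction=float(fraction), strategy=strategy)


def compose_mixed(fast: ScanImage, slow: ScanImage, mask: RescanMask) -> ScanImage:
    """Mixed-dwell image: the slow scan inside the mask, the fast scan outside."""
    if fast.intensities.shape != slow.intensities.shape:
        raise ValidationError(
            f"scan shapes differ: {fast.intensities.shape} vs {slow.intensities.shape}"
        )
    if mask.mask.shape != fast.intensities.shape:
        raise ValidationError(
            f"mask shape {mask.mask.shape} does not match scans "
            f"{fast.intensities.shape}"
        )
    mixed = np.where(mask.mask > 0, slow.intensities, fast.intensities)
    return ScanImage(intensities=mixed, dwell_ns=None, seed=None)


def segment_and_score(img: ScanImage, truth: SpecimenImage) -> float:
    """Pixelwise accuracy of a classical membrane segmentation of ``img``.

    The image is smoothed with a Gaussian (sigma = 2 px) and thresholded
    with Otsu's method.  Membrane polarity is arbitrary, so the class
    mapping that maximizes accuracy is used.  A constant image yields a
    single-class prediction rather than an error.
    """
    from skimage.filters import gaussian, threshold_otsu

    if img.intensities.shape != truth.labels.shape:
        raise ValidationError(
            f"image shape {img.intensities.shape} does not match truth "
            f"{truth.labels.shape}"
        )
    smoothed = gaussian(img.intensities, sigma=2.0, preserve_range=True)
    if np.ptp(smoothed) == 0.0:
        pred = np.zeros_like(truth.labels, dtype=bool)
    else:
        pred = smoothed > threshold_otsu(smoothed)
    truth_b = truth.labels > 0
    acc = float(np.mean(pred == truth_b))
    return max(acc, 1.0 - acc)


def estimate_quality_curve(
    seeds: Sequence[int],
    fractions: Sequence[float],
    width: int = 256,
    height: int = 256,
    fast_dwell_ns: float = DEFAULT_FAST_DWELL_NS,
    slow_dwell_ns: float = DEFAULT_SLOW_DWELL_NS,
    strategy: str = "random_blocks",
    block_size: int = 32,
) -> tuple[list[QualitySample], QualityCurve]:
    """Estimate an empirical quality curve on synthetic mixed-dwell images.

    For each rescan fraction and each replicate seed: generate a specimen,
    simulate a fast and a slow scan, compose them through a freshly drawn
    rescan mask, and score the segmentation.  Returns per-fraction
    :class:`~smartscan.quality.QualitySample` records (mean accuracy with a
    normal-approximation 95% interval across replicates) and the monotone
    curve fitted through the means.
    """
    if len(fractions) < 2:
        raise ValidationError(f"need at least 2 fractions, got {len(fractions)}")
    if len(seeds) < 2:
        raise ValidationError(f"need at least 2 replicate seeds, got {len(seeds)}")
    # Specimens and scans depend only on the seed, so build them once per
    # seed and reuse them across fractions.
    replicates = []
    for seed in seeds:
        spec = generate_specimen(width, height, seed)
        replicates.append(
            (
                spec,
                simulate_scan(spec, fast_dwell_ns, seed=2 * seed),
                simulate_scan(spec, slow_dwell_ns, seed=2 * seed + 1),
            )
        )
    samples: list[QualitySample] = []
    for fi, fraction in enumerate(fractions):
        accs = []
        for seed, (spec, fast, slow) in zip(seeds, replicates):
            mask = build_rescan_mask(
                spec.labels.shape,
                fraction,
                strategy=strategy,
                seed=seed * len(fractions) + fi,
                block_size=block_size,
            )
            accs.append(segment_and_score(compose_mixed(fast, slow, mask), spec))
        accs = np.asarray(accs)
        mean = float(accs.mean())
        if len(accs) > 1:
            half = _Z95 * float(accs.std(ddof=1)) / np.sqrt(len(accs))
        else:
            half = 0.0
        samples.append(
            QualitySample(
                rescan_fraction=float(fraction),
                accuracy=mean,
                n_replicates=len(accs),
                ci_low=mean - half,
                ci_high=mean + half,
            )
        )
    return samples, fit_monotone_curve(samples)


def write_image(img: np.ndarray, path) -> None:
    """Save a [0, 1] float image as 16-bit grayscale PNG or TIFF."""
    import imageio.v3 as iio

    arr = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
    iio.imwrite(path, (arr * np.iinfo(np.uint16).max).round().astype(np.uint16))


def write_mask(mask: np.ndarray, path) -> None:
    """Save a binary mask as 8-bit PNG (0 / 255)."""
    import imageio.v3 as iio

    iio.imwrite(path, ((np.asarray(mask) > 0) * np.uint8(255)))


def read_image(path) -> np.ndarray:
    """Load a grayscale image and rescale it to [0, 1] floats."""
    import imageio.v3 as iio

    arr = iio.imread(path).astype(float)
    info_max = float(arr.max()) if arr.max() > 1 else 1.0
    return arr / info_max
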