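"""Frame-difference segmentation of low-contrast mosquito images.

Mosquitoes appear as small dark blobs against a bright background.  A signed
difference image between frame *n* and frame *n − i* turns a moving mosquito
into a pair of opposite-sign images: positive at its current position,
negative at the old one.  Because the contrast of a mosquito seen through
bednet mesh (1–2 greyscales) is comparable to the camera's temporal noise, a
large normalised Gaussian kernel is applied to the difference image before
thresholding.  The image is partitioned into a bright *background* region, a
darker *bednet* region and *occluded* areas (human bait, bed frame); the
background pass uses a higher detection threshold (default 3 greyscales) than
the bednet pass (default 1 greyscale), and the union of the two passes is
returned.

Processing stages per frame:

1. signed difference between frames ``n`` and ``n − i`` (``i`` default 5);
2. optional Gaussian denoising, kernel width set by :func:`compute_sigma`;
3. threshold positive differences inside the background region;
4. repeat with the lower threshold inside the bednet region;
5. combine, after dilation, connected-component labelling and area filtering.

Only the positive-difference twin (the current position) is segmented; the
negative image at the old position is discarded, so each pass yields at most
one detection per mosquito per frame.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.morphology import disk

logger = logging.getLogger(__name__)

#: Region codes used in :class:`RegionMap` label arrays.
BACKGROUND, BEDNET, OCCLUDED = 0, 1, 2
REGION_NAMES = ("background", "bednet", "occluded")


@dataclass
class SegmentationConfig:
    """Tunable parameters of the segmentation stage.

    Thresholds are in greyscales (8-bit intensity units).  ``region_threshold``
    separates the bright background from the attenuated bednet region on a
    mosquito-free reference image and is typically chosen in 40–60;
    ``occlusion_floor`` marks pixels too dark to carry any mosquito signal.
    """

    frame_lag_i: int = 5
    ksize: int = 15
    denoise_enabled: bool = True
    region_threshold: float = 50.0
    bright_threshold: float = 3.0
    dark_threshold: float = 1.0
    dilation_px: int = 5
    min_area_px: float = 4.0
    max_area_px: float = 2000.0
    morphology_enabled: bool = False
    occlusion_floor: float = 10.0

    def __post_init__(self) -> None:
        if self.frame_lag_i < 1:
            raise ValueError("frame_lag_i must be >= 1")
        if self.ksize < 3 or self.ksize % 2 == 0:
            raise ValueError("ksize must be odd and >= 3")
        if self.bright_threshold < 1 or self.dark_threshold < 1:
            raise ValueError("detection thresholds must be >= 1 greyscale")
        if not self.min_area_px < self.max_area_px:
            raise ValueError("min_area_px must be < max_area_px")
        if self.dilation_px < 0:
            raise ValueError("dilation_px must be >= 0")
        if self.occlusion_floor >= self.region_threshold:
            raise ValueError("occlusion_floor must be below region_threshold")


@dataclass
class RegionMap:
    """Per-pixel partition of the image into background / bednet / occluded.

    ``labels`` holds the integer codes :data:`BACKGROUND`, :data:`BEDNET`,
    :data:`OCCLUDED`.
    """

    labels: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def name_at(self, x: float, y: float) -> str:
        """Region name at (possibly sub-pixel) image coordinates."""
        h, w = self.labels.shape
        iy = int(np.clip(round(y), 0, h - 1))
        ix = int(np.clip(round(x), 0, w - 1))
        return REGION_NAMES[self.labels[iy, ix]]


@dataclass
class Detection:
    """A candidate mosquito image segmented from one difference frame."""

    frame: int
    x: float
    y: float
    area: float
    region: str
    peak_difference: float


def compute_sigma(ksize: int) -> float:
    """Standard deviation (pixels) of the denoising kernel for a given size.

    Follows the usual kernel-size heuristic ``σ = 0.3·((ksize−1)·0.5 − 1) + 0.8``,
    e.g. σ = 2.6 for the default 15 × 15 kernel.
    """
    if ksize % 2 == 0 or ksize < 3:
        raise ValueError(f"ksize must be odd and >= 3, got {ksize}")
    return 0.3 * ((ksize - 1) * 0.5 - 1.0) + 0.8


def _gaussian_kernel_1d(ksize: int) -> np.ndarray:
    sigma = compute_sigma(ksize)
    x = np.arange(ksize, dtype=float) - (ksize - 1) / 2.0
    g = np.exp(-(x**2) / (2.0 * sigma**2))
    return g / g.sum()


def gaussian_kernel(ksize: int) -> np.ndarray:
    """2-D Gaussian kernel with σ from :func:`compute_sigma`, integral 1."""
    g = _gaussian_kernel_1d(ksize)
    k = np.outer(g, g)
    return k / k.sum()


def difference_image(frame_n: np.ndarray, frame_n_minus_i: np.ndarray) -> np.ndarray:
    """Signed difference ``(n − i)th frame  −  nth frame``.

    With dark mosquitoes on a bright background this sign convention makes the
    mosquito's *current* (frame ``n``) position a positive peak and its old
    position a negative one; downstream stages segment the positive peaks only.
    """
    if frame_n.shape != frame_n_minus_i.shape:
        raise ValueError(
            f"frame dimensions differ: {frame_n.shape} vs {frame_n_minus_i.shape}"
        )
    return frame_n_minus_i.astype(np.int16) - frame_n.astype(np.int16)


def denoise(diff: np.ndarray, cfg: SegmentationConfig | int = 15) -> np.ndarray:
    """Convolve a signed difference image with the normalised Gaussian kernel.

    The kernel is separable, so two 1-D passes are used; borders are
    reflect-padded.  Accepts either a :class:`SegmentationConfig` or a bare
    kernel size.
    """
    ksize = cfg.ksize if isinstance(cfg, SegmentationConfig) else int(cfg)
    g = _gaussian_kernel_1d(ksize)
    out = ndi.correlate1d(diff.astype(np.float32), g, axis=0, mode="reflect")
    ndi.correlate1d(out, g, axis=1, mode="reflect", output=out)
    return out


def classify_regions(
    reference_frame: np.ndarray, cfg: SegmentationConfig
) -> RegionMap:
    """Partition a mosquito-free reference image into detection regions.

    ``reference_frame`` should be a temporal median (or mean) over enough
    frames (≥ 10, typically 50) that moving mosquitoes average out.  Pixels at
    or above ``region_threshold`` are background; pixels between the occlusion
    floor and the threshold belong to the (attenuated) bednet region; darker
    pixels are occluded and excluded from detection.
    """
    ref = np.asarray(reference_frame, dtype=float)
    labels = np.full(ref.shape, BEDNET, dtype=np.uint8)
    labels[ref >= cfg.region_threshold] = BACKGROUND
    labels[ref < cfg.occlusion_floor] = OCCLUDED
    if not (labels == BACKGROUND).any():
        warnings.warn("region map has no background pixels", stacklevel=2)
    if not (labels == BEDNET).any():
        warnings.warn("region map has no bednet pixels", stacklevel=2)
    return RegionMap(labels)


def _pass_mask(
    diff: np.ndarray,
    mask_region: np.ndarray,
    threshold: float,
    cfg: SegmentationConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """One threshold pass: (suprathreshold seed mask, dilated mask)."""
    mask = (diff >= threshold) & mask_region
    if not mask.any():
        return mask, mask
    if cfg.morphology_enabled:
        se = np.ones((3, 3), bool)
        mask_m = ndi.binary_closing(ndi.binary_opening(mask, se), se)
        if mask_m.any():  # opening can erase small genuine images entirely
            mask = mask_m
    if cfg.dilation_px > 0:
        dilated = ndi.binary_dilation(mask, structure=disk(cfg.dilation_px))
    else:
        dilated = mask
    return mask, dilated


def segment_frame(
    diff_denoised: np.ndarray,
    region_map: RegionMap,
    cfg: SegmentationConfig,
    frame: int = 0,
) -> list[Detection]:
    """Extract candidate mosquito detections from one (denoised) difference image.

    Two threshold passes are made over the positive differences: the
    background region at ``bright_threshold`` and the bednet region at
    ``dark_threshold``; occluded pixels are never searched.  Each pass's
    suprathreshold pixels are dilated by ``dilation_px`` to re-join
    broken-down images, and the two passes are then combined: the union of
    the dilated masks is labelled 8-connected, so a mosquito image straddling
    the region boundary yields exactly one candidate.  Components outside
    ``[min_area_px, max_area_px]`` (areas measured on the dilated components)
    are dropped.  Centroids are difference-weighted means of the pre-dilation
    suprathreshold pixels, hence sub-pixel; each detection's region label is
    taken at its peak-difference pixel.
    """
    if diff_denoised.shape != region_map.shape:
        raise ValueError("difference image and region map dimensions differ")
    lab = region_map.labels
    seed_b, dil_b = _pass_mask(
        diff_denoised, lab == BACKGROUND, cfg.bright_threshold, cfg
    )
    seed_d, dil_d = _pass_mask(diff_denoised, lab == BEDNET, cfg.dark_threshold, cfg)
    union = dil_b | dil_d
    if not union.any():
        return []
    seeds = seed_b | seed_d
    labels, n = ndi.label(union, structure=np.ones((3, 3), int))
    out: list[Detection] = []
    for comp_id, comp in enumerate(ndi.find_objects(labels), start=1):
        comp_mask = labels[comp] == comp_id
        area = float(comp_mask.sum())
        if not (cfg.min_area_px <= area <= cfg.max_area_px):
            continue
        seed = comp_mask & seeds[comp]
        ys, xs = np.nonzero(seed)
        w = diff_denoised[comp][ys, xs].astype(float)
        peak = int(np.argmax(w))
        y0, x0 = comp[0].start, comp[1].start
        wsum = w.sum()
        out.append(
            Detection(
                frame=frame,
                x=float(((xs + x0) * w).sum() / wsum),
                y=float(((ys + y0) * w).sum() / wsum),
                area=area,
                region=REGION_NAMES[lab[ys[peak] + y0, xs[peak] + x0]],
                peak_difference=float(w[peak]),
            )
        )
    return out


def reference_frame(frames: np.ndarray, n_reference: int = 50) -> np.ndarray:
    """Per-pixel temporal median of the first ``n_reference`` frames."""
    n = min(n_reference, len(frames))
    if n < 1:
        raise ValueError("need at least one frame for a reference image")
    return np.median(frames[:n].astype(float), axis=0)


def detections_to_frame(dets: list[Detection]) -> pd.DataFrame:
    """Detections as a tidy table (columns frame, x_px, y_px, area_px2, region, peak_diff)."""
    return pd.DataFrame(
        {
            "frame": [d.frame for d in dets],
            "x_px": [d.x for d in dets],
            "y_px": [d.y for d in dets],
            "area_px2": [d.area for d in dets],
            "region": [d.region for d in dets],
            "peak_diff": [d.peak_difference for d in dets],
        }
    )


def segment_stack(
    frames: np.ndarray,
    cfg: SegmentationConfig | None = None,
    region_map: RegionMap | None = None,
) -> tuple[pd.DataFrame, RegionMap]:
    """Run the full segmentation stage over an ordered frame stack.

    Returns the detection table and the region map used.  The region map, if
    not supplied, is classified from the temporal median of the first 50
    frames.  The first ``frame_lag_i`` frames yield no detections (no partner
    frame to difference against).
    """
    cfg = cfg or SegmentationConfig()
    if frames.ndim != 3:
        raise ValueError("expected a (frames, height, width) stack")
    if region_map is None:
        region_map = classify_regions(reference_frame(frames), cfg)
    all_dets: list[Detection] = []
    for n in range(cfg.frame_lag_i, len(frames)):
        diff = difference_image(frames[n], frames[n - cfg.frame_lag_i])
        img = denoise(diff, cfg) if cfg.denoise_enabled else diff.astype(np.float32)
        all_dets.extend(segment_frame(img, region_map, cfg, frame=n))
    logger.info("segmentation: %d detections over %d frames", len(all_dets), len(frames))
    return detections_to_frame(all_dets), region_map
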