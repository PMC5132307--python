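"""Worm-region extraction from bright-field micrographs.

Anesthetized dauer larvae appear as dark curvilinear tubes on an unevenly
illuminated transmitted-light background. The worm-occupied area ``Aw`` is
extracted with a four-step pipeline whose two length scales are set by the
worm width (estimated once from the images):

1. top-hat filtering with a disk of radius ~ worm width removes the slowly
   varying illumination background while keeping details at the worm scale;
2. Gaussian blurring with sigma = 2 x worm width homogenizes the worm
   regions in intensity;
3. a mean-intensity threshold converts the result to a binary mask;
4. connected components smaller than a typical worm area are discarded.

Unusable regions (air bubbles, out-of-focus worms) can afterwards be removed
with polygonal exclusion ROIs before ``Aw`` is measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import draw as skdraw
from skimage import measure as skmeasure
from skimage import morphology as skmorph

__all__ = [
    "SegmentationConfig",
    "WormMask",
    "ExclusionROI",
    "tophat_filter",
    "smooth",
    "threshold_mean",
    "filter_small_regions",
    "apply_exclusions",
    "segment_worms",
]

_POLARITIES = ("dark_worms", "bright_worms")


@dataclass(frozen=True)
class SegmentationConfig:
    """Parameters of the four-step worm detection.

    ``worm_width`` (pixels) is the apparent width of a single worm and drives
    both derived scales: the top-hat structuring-element radius defaults to
    the worm width and the Gaussian sigma to twice the worm width.
    ``typical_worm_area`` (pixels^2) is the area of a single worm, used to
    reject sub-worm-sized debris. ``polarity`` records whether worms are
    darker (transmitted light, the default) or brighter than the background.
    """

    worm_width: int
    typical_worm_area: int
    tophat_radius: int | None = None
    gaussian_sigma: float | None = None
    polarity: str = "dark_worms"

    def __post_init__(self) -> None:
        if self.worm_width < 1:
            raise ValueError("worm_width must be >= 1 pixel")
        if self.typical_worm_area < 1:
            raise ValueError("typical_worm_area must be >= 1 pixel")
        if self.polarity not in _POLARITIES:
            raise ValueError(f"polarity must be one of {_POLARITIES}")
        if self.tophat_radius is None:
            object.__setattr__(self, "tophat_radius", int(self.worm_width))
        if self.gaussian_sigma is None:
            object.__setattr__(self, "gaussian_sigma", 2.0 * self.worm_width)
        if self.tophat_radius < 1:
            raise ValueError("tophat_radius must be >= 1")
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be positive")


@dataclass(frozen=True)
class ExclusionROI:
    """A polygonal region to exclude, in (row, col) pixel coordinates."""

    roi_id: str
    vertices: np.ndarray  # (N, 2) float array of (row, col)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError(f"ROI {self.roi_id!r}: need an (N>=3, 2) vertex array")
        object.__setattr__(self, "vertices", v)

    def is_simple(self) -> bool:
        """True when the polygon boundary does not self-intersect."""
        from shapely.geometry import Polygon

        return Polygon(self.vertices[:, ::-1]).is_valid


@dataclass(frozen=True)
class WormMask:
    """Binary worm-region mask plus the derived area estimate ``Aw``."""

    mask: np.ndarray
    area_Aw: int
    n_components: int
    exclusions_applied: tuple[str, ...] = ()

    @classmethod
    def from_mask(cls, mask: np.ndarray, exclusions: Sequence[str] = ()) -> "WormMask":
        mask = np.asarray(mask, dtype=bool)
        n = int(skmeasure.label(mask, connectivity=2).max())
        return cls(mask, int(mask.sum()), n, tuple(exclusions))


def _normalize_polarity(image: np.ndarray, polarity: str) -> np.ndarray:
    """Return a float image in which worms are bright features."""
    img = np.asarray(image, dtype=float)
    if polarity == "dark_worms":
        return img.max() - img
    return img


def tophat_filter(
    image: np.ndarray, radius: int, polarity: str = "bright_worms"
) -> np.ndarray:
    """White top-hat: image minus its morphological opening by a disk.

    Removes background structure larger than the disk (radius ~ worm width)
    while retaining worm-scale detail. For ``dark_worms`` the image is first
    inverted so worms become the bright features the top-hat keeps. The
    output is nonnegative by construction of the opening.
    """
    if polarity not in _POLARITIES:
        raise ValueError(f"polarity must be one of {_POLARITIES}")
    if radius < 1:
        raise ValueError("structuring-element radius must be >= 1")
    image = np.asarray(image)
    if radius > min(image.shape):
        raise ValueError(
            f"radius {radius} exceeds the image's shorter side {min(image.shape)}"
        )
    img = _normalize_polarity(image, polarity)
    footprint = skmorph.disk(radius)
    opened = ndi.grey_opening(img, footprint=footprint)
    return img - opened


def smooth(image: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian blur with reflective boundaries (no border dimming)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return ndi.gaussian_filter(np.asarray(image, dtype=float), sigma, mode="reflect")


def threshold_mean(image: np.ndarray) -> np.ndarray:
    """Foreground = pixels strictly greater than the image's grand mean.

    The strict comparison makes the degenerate constant image deterministic:
    it yields an empty mask.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("cannot threshold an empty image")
    return image > image.mean()


def filter_small_regions(mask: np.ndarray, typical_worm_area: int) -> np.ndarray:
    """Drop 8-connected components smaller than a typical worm area."""
    if typical_worm_area < 1:
        raise ValueError("typical_worm_area must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    labels, n = skmeasure.label(mask, connectivity=2, return_num=True)
    if n == 0:
        return mask.copy()
    areas = np.bincount(labels.ravel())
    keep = areas >= typical_worm_area
    keep[0] = False
    return keep[labels]


def _rasterize_roi(roi: ExclusionROI, shape: tuple[int, int]) -> np.ndarray:
    rr, cc = skdraw.polygon(roi.vertices[:, 0], roi.vertices[:, 1], shape=shape)
    roi_mask = np.zeros(shape, dtype=bool)
    roi_mask[rr, cc] = True
    return roi_mask


def apply_exclusions(
    mask: np.ndarray, rois: Sequence[ExclusionROI] = ()
) -> WormMask:
    """Zero out manually excluded regions and recompute ``Aw``.

    ROI polygons are clipped to the image bounds; self-intersecting polygons
    are rejected by id since their interior is ambiguous. Applied ROI ids are
    recorded on the result for provenance.
    """
    mask = np.asarray(mask, dtype=bool).copy()
    applied: list[str] = []
    for roi in rois:
        if not roi.is_simple():
            raise ValueError(f"ROI {roi.roi_id!r} is self-intersecting")
        mask &= ~_rasterize_roi(roi, mask.shape)
        applied.append(roi.roi_id)
    return WormMask.from_mask(mask, applied)


def segment_worms(
    image: np.ndarray,
    config: SegmentationConfig,
    rois: Sequence[ExclusionROI] = (),
) -> WormMask:
    """Full worm detection: top-hat, blur, mean threshold, size filter, ROIs.

    The stages are applied in exactly this order; each consumes the previous
    stage's output.
    """
    filtered = tophat_filter(image, config.tophat_radius, config.polarity)
    blurred = smooth(filtered, config.gaussian_sigma)
    mask = threshold_mean(blurred)
    mask = filter_small_regions(mask, config.typical_worm_area)
    return apply_exclusions(mask, rois)
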