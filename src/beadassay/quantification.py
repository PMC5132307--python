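"""Microsphere-ingestion quantification.

Fed worms accumulate fluorescent microspheres in the gut; arrested dauers do
not. Ingestion is measured per field of view as the total microsphere
fluorescence inside the worm-occupied region, normalized by that region's
area: the ratio (Im*Am)/Aw in arbitrary units, where Im and Am are the mean
intensity and area of above-threshold bead pixels and Aw is the worm area.
The bead mask is a plain intensity threshold on the raw fluorescence channel
(instrument-specific: 1000 for the confocal setup, 50 for the
stereomicroscope setup), intersected with the worm mask so that stray beads
left outside the worms by imperfect washing are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import WormMask

__all__ = [
    "InstrumentProfile",
    "CONFOCAL",
    "STEREOMICROSCOPE",
    "ActivityMeasurement",
    "bead_mask",
    "measure_activity",
]


@dataclass(frozen=True)
class InstrumentProfile:
    """Acquisition profile: the bead threshold is chosen once per setup so
    that sensor noise and worm autofluorescence stay below it."""

    name: str
    bead_threshold: float

    def __post_init__(self) -> None:
        if self.bead_threshold <= 0:
            raise ValueError("bead_threshold must be positive")


#: Confocal setup used for the main bioassay results.
CONFOCAL = InstrumentProfile("confocal", 1000)
#: Stereomicroscope setup used for screening HPLC fractions.
STEREOMICROSCOPE = InstrumentProfile("stereomicroscope", 50)

PROFILES: dict[str, InstrumentProfile] = {
    p.name: p for p in (CONFOCAL, STEREOMICROSCOPE)
}


@dataclass(frozen=True)
class ActivityMeasurement:
    """Per-image ingestion record.

    ``bead_sum`` is the sum of raw fluorescence intensities over bead pixels
    inside the worm mask — the direct estimate of Im*Am. ``ratio`` is
    bead_sum/Aw in arbitrary units, or None for an invalid field of view
    (Aw = 0). ``saturation_fraction`` is the fraction of counted bead pixels
    at the saturation level when one is provided (acquisition gain is set to
    avoid bead saturation, so this should be ~0).
    """

    image_id: str
    Aw: int
    Am: int
    bead_sum: float
    ratio: float | None
    condition: str = ""
    solvent: str = ""
    saturation_fraction: float = 0.0

    @property
    def valid(self) -> bool:
        return self.ratio is not None


def bead_mask(fluor: np.ndarray, profile: InstrumentProfile) -> np.ndarray:
    """Threshold the raw fluorescence channel: pixels >= bead_threshold.

    No filtering is applied before thresholding; the comparison is
    inclusive, so a pixel exactly at the threshold counts as bead signal.
    """
    if profile.bead_threshold <= 0:
        raise ValueError("bead_threshold must be positive")
    fluor = np.asarray(fluor)
    info_max = (
        np.iinfo(fluor.dtype).max if np.issubdtype(fluor.dtype, np.integer) else None
    )
    if info_max is not None and profile.bead_threshold > info_max:
        raise ValueError(
            f"bead_threshold {profile.bead_threshold} not representable at "
            f"dtype {fluor.dtype}"
        )
    return fluor >= profile.bead_threshold


def measure_activity(
    worm_mask: WormMask,
    beads: np.ndarray,
    fluor: np.ndarray,
    image_id: str = "",
    condition: str = "",
    solvent: str = "",
    saturation_level: float | None = None,
) -> ActivityMeasurement:
    """Intersect the worm and bead masks and compute (Im*Am)/Aw.

    Am counts intersection pixels; bead_sum accumulates the raw fluorescence
    intensities over the intersection (saturated pixels enter at their
    recorded value). A field of view with Aw = 0 yields an invalid
    measurement with no ratio rather than a division error.
    """
    beads = np.asarray(beads, dtype=bool)
    fluor = np.asarray(fluor)
    if beads.shape != fluor.shape or worm_mask.mask.shape != fluor.shape:
        raise ValueError("worm mask, bead mask and fluorescence grids must share shape")
    intersection = worm_mask.mask & beads
    am = int(intersection.sum())
    bead_sum = float(np.asarray(fluor, dtype=float)[intersection].sum())
    aw = worm_mask.area_Aw
    ratio = bead_sum / aw if aw > 0 else None
    saturation = 0.0
    if saturation_level is not None and am > 0:
        saturation = float((fluor[intersection] >= saturation_level).mean())
    return ActivityMeasurement(
        image_id=image_id,
        Aw=aw,
        Am=am,
        bead_sum=bead_sum,
        ratio=ratio,
        condition=condition,
        solvent=solvent,
        saturation_fraction=saturation,
    )
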