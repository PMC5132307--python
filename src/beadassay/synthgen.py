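"""Synthetic two-channel micrographs with exact ground truth.

The generator emulates fields of view from the dauer-recovery bead-feeding
assay: anesthetized worms lying on an agarose pad, imaged in transmitted
light (worms as dark curvilinear tubes on a slowly varying illumination
background) and in a fluorescence channel in which worms that have resumed
feeding ("responders") carry punctate high-intensity microsphere signal
along the gut, on top of sub-threshold diffuse autofluorescence and sensor
noise. Stray microspheres not removed by washing appear outside the worms.

Every scene comes with exact ground-truth masks and the ground-truth values
of the quantities the analysis pipeline estimates (worm area Aw, in-gut bead
intensity sum, and their ratio), so segmentation and quantification can be
validated without real data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology as skmorph

from .io import ImagePair

__all__ = ["SceneParams", "GroundTruth", "generate_scene", "write_scene"]


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic field of view.

    Geometry defaults emulate a binned 10x confocal field: at 1.6 um/pixel a
    1024-pixel frame spans ~1.6 mm; a dauer larva (~20 um wide, ~450 um
    long) renders as a tube ~13 px wide and ~300 px long. Bead spots use the
    0.5 um microsphere diameter, which is sub-pixel at this scale and is
    rendered as single-pixel puncta. Bead intensities sit well above the
    confocal bead threshold of 1000 counts, while autofluorescence and noise
    stay below it.
    """

    image_height: int = 1024
    image_width: int = 1024
    n_worms: int = 10
    worm_width: int = 13
    worm_length_range: tuple[int, int] = (250, 350)
    responder_fraction: float = 1.0
    bead_intensity_range: tuple[float, float] = (1200.0, 4000.0)
    beads_per_responder_range: tuple[int, int] = (20, 60)
    stray_bead_rate: float = 3.0
    background_amplitude: float = 2000.0
    noise_sd: float = 40.0
    bit_depth: int = 16
    pixel_size: float = 1.6  # micrometers per pixel
    bead_diameter_um: float = 0.5
    seed: int = 0
    # Rendering attributes beyond the core geometry: bright-field polarity,
    # worm/background contrast, camera baseline and diffuse autofluorescence.
    polarity: str = "dark_worms"
    worm_contrast: float = 8000.0
    baseline: float = 20000.0
    autofluorescence_level: float = 300.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must lie in [0, 1]")
        if self.worm_width < 3:
            raise ValueError("worm_width must be >= 3 pixels")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.polarity not in ("dark_worms", "bright_worms"):
            raise ValueError("polarity must be 'dark_worms' or 'bright_worms'")
        max_int = 2**self.bit_depth - 1
        peaks = {
            "bead_intensity_range upper bound": self.bead_intensity_range[1],
            "baseline + background_amplitude": self.baseline
            + self.background_amplitude
            + (self.worm_contrast if self.polarity == "bright_worms" else 0.0),
            "autofluorescence_level": self.autofluorescence_level,
        }
        for name, value in peaks.items():
            if value > max_int:
                raise ValueError(
                    f"{name} = {value} is not representable at "
                    f"bit depth {self.bit_depth} (max {max_int})"
                )

    @property
    def max_intensity(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def dtype(self) -> np.dtype:
        return np.dtype(np.uint8 if self.bit_depth == 8 else np.uint16)


@dataclass(frozen=True)
class GroundTruth:
    """Exact ground truth for one scene.

    ``expected_bead_sum`` is the sum of the noiseless, quantized fluorescence
    over bead pixels inside the worm mask — the ground-truth counterpart of
    the Im*Am estimate; ``expected_ratio`` is expected_bead_sum/expected_Aw.
    Stray (out-of-worm) beads are included in ``bead_mask`` but excluded
    from the expected sums, since the assay statistic deliberately ignores
    them.
    """

    worm_mask: np.ndarray
    bead_mask: np.ndarray
    per_worm_labels: np.ndarray
    expected_Aw: int
    expected_bead_sum: float
    expected_ratio: float | None
    responder_worms: tuple[int, ...] = ()

    def worm_area(self, label: int) -> int:
        return int((self.per_worm_labels == label).sum())


def _worm_centerline(
    rng: np.random.Generator,
    length: int,
    height: int,
    width: int,
    margin: int,
) -> np.ndarray:
    """Random smooth open curve: unit steps with slowly wandering heading,
    reflected at a margin inside the frame."""
    pos = np.empty((length, 2), dtype=float)
    pos[0] = [
        rng.uniform(margin, height - margin),
        rng.uniform(margin, width - margin),
    ]
    heading = rng.uniform(0.0, 2.0 * np.pi)
    turn = rng.normal(0.0, 0.05, size=length - 1)
    lo = np.array([margin, margin], dtype=float)
    hi = np.array([height - 1 - margin, width - 1 - margin], dtype=float)
    for i in range(1, length):
        heading += turn[i - 1]
        step = np.array([np.sin(heading), np.cos(heading)])
        nxt = pos[i - 1] + step
        # Reflect off the margins so worms stay fully in frame.
        for ax in (0, 1):
            if nxt[ax] < lo[ax] or nxt[ax] > hi[ax]:
                step[ax] = -step[ax]
                nxt = pos[i - 1] + step
                heading = np.arctan2(step[0], step[1])
        pos[i] = np.clip(nxt, lo, hi)
    return pos


def _render_worms(
    rng: np.random.Generator, params: SceneParams
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Paint worm tubes; returns the label grid and each worm's centerline."""
    shape = (params.image_height, params.image_width)
    labels = np.zeros(shape, dtype=np.int32)
    radius = max(1, (params.worm_width - 1) // 2)
    footprint = skmorph.disk(radius)
    margin = params.worm_width
    centerlines = []
    for worm in range(params.n_worms):
        length = int(rng.integers(*params.worm_length_range, endpoint=True))
        path = _worm_centerline(rng, length, *shape, margin)
        centerlines.append(path)
        rr = np.clip(np.round(path[:, 0]).astype(int), 0, shape[0] - 1)
        cc = np.clip(np.round(path[:, 1]).astype(int), 0, shape[1] - 1)
        # Dilate within a bounding box only, for speed.
        r0, r1 = rr.min() - radius, rr.max() + radius + 1
        c0, c1 = cc.min() - radius, cc.max() + radius + 1
        r0, c0 = max(r0, 0), max(c0, 0)
        box = np.zeros((min(r1, shape[0]) - r0, min(c1, shape[1]) - c0), dtype=bool)
        box[rr - r0, cc - c0] = True
        body = ndi.binary_dilation(box, structure=footprint)
        labels[r0 : r0 + box.shape[0], c0 : c0 + box.shape[1]][body] = worm + 1
    return labels, centerlines


def _illumination_field(
    rng: np.random.Generator, params: SceneParams
) -> np.ndarray:
    """Slowly varying illumination: a bicubically upsampled coarse random
    grid, varying on a length scale of ~1/6 of the frame (>> worm width)."""
    coarse = rng.uniform(0.0, 1.0, size=(6, 6))
    zoom = (params.image_height / coarse.shape[0], params.image_width / coarse.shape[1])
    field = ndi.zoom(coarse, zoom, order=3, mode="nearest", grid_mode=True)
    return params.background_amplitude * np.clip(field, 0.0, 1.0)


def _quantize(image: np.ndarray, params: SceneParams) -> np.ndarray:
    return np.clip(np.round(image), 0, params.max_intensity).astype(params.dtype)


def generate_scene(params: SceneParams) -> tuple[ImagePair, GroundTruth]:
    """Render one two-channel field of view and its exact ground truth.

    Deterministic for a fixed seed. Bead puncta are placed along the middle
    60% of each responder worm's centerline (the gut region), jittered
    within the body; stray beads (Poisson-distributed count) land outside
    the worm mask. Ground truth is recorded from the noiseless quantized
    channels; sensor noise is added afterwards.
    """
    rng = np.random.default_rng(params.seed)
    shape = (params.image_height, params.image_width)
    labels, centerlines = _render_worms(rng, params)
    worm_mask = labels > 0

    # --- bright-field channel ---
    body = ndi.gaussian_filter(worm_mask.astype(float), 1.0)  # soft worm edges
    signed = -1.0 if params.polarity == "dark_worms" else 1.0
    bf = params.baseline + _illumination_field(rng, params) + signed * params.worm_contrast * body

    # --- fluorescence channel ---
    fl = np.zeros(shape, dtype=float)
    fl[worm_mask] = params.autofluorescence_level
    bead_mask = np.zeros(shape, dtype=bool)

    n_resp = int(round(params.responder_fraction * params.n_worms))
    responders = tuple(
        int(w) + 1 for w in rng.permutation(params.n_worms)[:n_resp]
    )
    bead_radius = int(round(0.5 * params.bead_diameter_um / params.pixel_size))
    for label in responders:
        path = centerlines[label - 1]
        gut = path[int(0.2 * len(path)) : int(0.8 * len(path))]
        n_beads = int(rng.integers(*params.beads_per_responder_range, endpoint=True))
        idx = rng.integers(0, len(gut), size=n_beads)
        jitter = rng.normal(0.0, params.worm_width / 6.0, size=(n_beads, 2))
        for center, off in zip(gut[idx], jitter):
            rr = int(round(center[0] + off[0]))
            cc = int(round(center[1] + off[1]))
            rr = min(max(rr, 0), shape[0] - 1)
            cc = min(max(cc, 0), shape[1] - 1)
            if not worm_mask[rr, cc]:  # keep ingested beads strictly in-body
                rr, cc = int(round(center[0])), int(round(center[1]))
            intensity = rng.uniform(*params.bead_intensity_range)
            if bead_radius < 1:
                spot = (np.array([rr]), np.array([cc]))
            else:
                disk = skmorph.disk(bead_radius).astype(bool)
                dr, dc = np.nonzero(disk)
                spot = (
                    np.clip(rr + dr - bead_radius, 0, shape[0] - 1),
                    np.clip(cc + dc - bead_radius, 0, shape[1] - 1),
                )
            fl[spot] = np.maximum(fl[spot], intensity)
            bead_mask[spot] = True

    n_stray = int(rng.poisson(params.stray_bead_rate))
    placed = 0
    attempts = 0
    while placed < n_stray and attempts < 100 * max(n_stray, 1):
        attempts += 1
        rr = int(rng.integers(0, shape[0]))
        cc = int(rng.integers(0, shape[1]))
        if worm_mask[rr, cc]:
            continue
        intensity = rng.uniform(*params.bead_intensity_range)
        fl[rr, cc] = max(fl[rr, cc], intensity)
        bead_mask[rr, cc] = True
        placed += 1

    # Ground truth from the noiseless quantized channels.
    fl_clean = _quantize(fl, params)
    ingested = bead_mask & worm_mask
    expected_aw = int(worm_mask.sum())
    expected_sum = float(fl_clean[ingested].astype(float).sum())
    expected_ratio = expected_sum / expected_aw if expected_aw > 0 else None
    truth = GroundTruth(
        worm_mask=worm_mask,
        bead_mask=bead_mask,
        per_worm_labels=labels,
        expected_Aw=expected_aw,
        expected_bead_sum=expected_sum,
        expected_ratio=expected_ratio,
        responder_worms=responders,
    )

    if params.noise_sd > 0:
        bf = bf + rng.normal(0.0, params.noise_sd, size=shape)
        fl = fl + rng.normal(0.0, params.noise_sd, size=shape)
    pair = ImagePair(
        bright_field=_quantize(bf, params),
        fluorescence=_quantize(fl, params),
        instrument="confocal",
        bit_depth=params.bit_depth,
    )
    return pair, truth


def write_scene(
    directory: str | Path,
    pair: ImagePair,
    truth: GroundTruth,
    params: SceneParams,
    stem: str = "scene",
) -> dict[str, Path]:
    """Write a scene to disk: two-page image TIFF, mask TIFFs, JSON manifest."""
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": directory / f"{stem}.tif",
        "worm_mask": directory / f"{stem}_worm_mask.tif",
        "bead_mask": directory / f"{stem}_bead_mask.tif",
        "labels": directory / f"{stem}_labels.tif",
        "manifest": directory / f"{stem}.json",
    }
    tifffile.imwrite(paths["image"], np.stack([pair.bright_field, pair.fluorescence]))
    tifffile.imwrite(paths["worm_mask"], truth.worm_mask.astype(np.uint8))
    tifffile.imwrite(paths["bead_mask"], truth.bead_mask.astype(np.uint8))
    tifffile.imwrite(paths["labels"], truth.per_worm_labels.astype(np.int32))
    manifest = asdict(params)
    manifest.update(
        expected_Aw=truth.expected_Aw,
        expected_bead_sum=truth.expected_bead_sum,
        expected_ratio=truth.expected_ratio,
        responder_worms=list(truth.responder_worms),
    )
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2)
    return paths
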