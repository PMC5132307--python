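"""Image and table I/O for the bead-feeding assay pipeline.

Fields of view are stored as two-channel TIFFs: page 1 is the transmitted
light (bright-field) channel, page 2 the microsphere fluorescence channel.
Run configuration is a YAML file; per-image metadata (condition, solvent,
replicate) is a CSV table; exclusion ROIs are JSON polygon lists.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
import yaml

from .segmentation import ExclusionROI, SegmentationConfig

__all__ = [
    "ImagePair",
    "RunConfig",
    "read_image_pair",
    "write_image_pair",
    "read_rois",
    "load_run_config",
]


@dataclass(frozen=True)
class ImagePair:
    """Registered bright-field and fluorescence grids for one field of view."""

    bright_field: np.ndarray
    fluorescence: np.ndarray
    instrument: str = "confocal"
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.bright_field.shape != self.fluorescence.shape:
            raise ValueError(
                "bright-field and fluorescence channels must share dimensions: "
                f"{self.bright_field.shape} vs {self.fluorescence.shape}"
            )


def _bit_depth_of(array: np.ndarray) -> int:
    if np.issubdtype(array.dtype, np.integer):
        return int(np.iinfo(array.dtype).bits)
    return 16


def read_image_pair(
    path: str | Path,
    fluorescence_path: str | Path | None = None,
    instrument: str = "confocal",
) -> ImagePair:
    """Load a field of view from a multi-page TIFF or two single-page TIFFs.

    With one path, the TIFF must contain at least two pages (bright-field
    first, fluorescence second). With two paths, each file supplies one
    channel. Channel dimensions must agree.
    """
    path = Path(path)
    try:
        if fluorescence_path is None:
            pages = tifffile.imread(path)
            if pages.ndim != 3 or pages.shape[0] < 2:
                raise ValueError(
                    f"{path}: expected a multi-page TIFF with >= 2 pages "
                    "(bright-field, fluorescence)"
                )
            bf, fl = pages[0], pages[1]
        else:
            bf = tifffile.imread(path)
            fl = tifffile.imread(Path(fluorescence_path))
    except (OSError, tifffile.TiffFileError) as exc:
        raise ValueError(f"cannot read image {path}: {exc}") from exc
    if bf.shape != fl.shape:
        raise ValueError(
            f"{path}: channel dimensions differ ({bf.shape} vs {fl.shape})"
        )
    return ImagePair(bf, fl, instrument=instrument, bit_depth=_bit_depth_of(bf))


def write_image_pair(path: str | Path, pair: ImagePair) -> Path:
    """Write a field of view as a two-page TIFF (bright-field, fluorescence)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.stack([pair.bright_field, pair.fluorescence]))
    return path


def read_rois(path: str | Path) -> list[ExclusionROI]:
    """Read exclusion ROIs from JSON: [{"id": ..., "vertices": [[r, c], ...]}]."""
    with open(path) as fh:
        raw = json.load(fh)
    return [
        ExclusionROI(str(entry["id"]), np.asarray(entry["vertices"], dtype=float))
        for entry in raw
    ]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to run the pipeline on a directory of images."""

    metadata_table: Path
    segmentation: SegmentationConfig
    instrument: str = "confocal"
    control_condition: str = "BE"
    negative_control: str = "water"
    alpha: float = 0.05
    output_dir: Path = Path("results")
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "metadata_table", Path(self.metadata_table))
        object.__setattr__(self, "output_dir", Path(self.output_dir))


def load_run_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration.

    Expected keys: metadata_table, worm_width, typical_worm_area, and
    optionally tophat_radius, gaussian_sigma, polarity, instrument,
    control_condition, negative_control, alpha, output_dir, seed.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    seg = SegmentationConfig(
        worm_width=int(raw["worm_width"]),
        typical_worm_area=int(raw["typical_worm_area"]),
        tophat_radius=raw.get("tophat_radius"),
        gaussian_sigma=raw.get("gaussian_sigma"),
        polarity=raw.get("polarity", "dark_worms"),
    )
    metadata = Path(raw["metadata_table"])
    if not metadata.exists():
        raise FileNotFoundError(f"metadata table not found: {metadata}")
    return RunConfig(
        metadata_table=metadata,
        segmentation=seg,
        instrument=raw.get("instrument", "confocal"),
        control_condition=raw.get("control_condition", "BE"),
        negative_control=raw.get("negative_control", "water"),
        alpha=float(raw.get("alpha", 0.05)),
        output_dir=Path(raw.get("output_dir", "results")),
        seed=int(raw.get("seed", 0)),
    )
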