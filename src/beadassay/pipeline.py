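"""End-to-end assay analysis: images + metadata -> tables.

Runs segmentation and quantification per image, groups measurements by
condition, normalizes to the positive control and performs the group
comparisons. All parameters that influence the result (filter scales,
thresholds, control keys, seed) are written to a provenance log next to the
output tables.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from .io import ImagePair, RunConfig, read_image_pair
from .quantification import PROFILES, ActivityMeasurement, bead_mask, measure_activity
from .segmentation import segment_worms
from .stats import AssayGroup, ComparisonResult, compare_groups, normalize

__all__ = ["PipelineResult", "run_pipeline", "measurements_to_frame"]


@dataclass(frozen=True)
class PipelineResult:
    """Results bundle: per-image measurements, normalized groups, comparisons."""

    measurements: list[ActivityMeasurement]
    groups: list[AssayGroup]
    comparisons: list[ComparisonResult]
    control_condition: str


def measurements_to_frame(measurements: list[ActivityMeasurement]) -> pd.DataFrame:
    return pd.DataFrame([asdict(m) for m in measurements])


def _group_measurements(
    measurements: list[ActivityMeasurement],
) -> list[AssayGroup]:
    by_key: dict[tuple[str, str], list[ActivityMeasurement]] = {}
    for m in measurements:
        by_key.setdefault((m.condition, m.solvent), []).append(m)
    return [
        AssayGroup(condition=cond, solvent=solv, measurements=tuple(ms))
        for (cond, solv), ms in by_key.items()
    ]


def quantify_image(
    pair: ImagePair, config: RunConfig, image_id: str, condition: str, solvent: str
) -> ActivityMeasurement:
    """Segment one field of view and measure its ingestion activity."""
    profile = PROFILES[config.instrument]
    worms = segment_worms(pair.bright_field, config.segmentation)
    beads = bead_mask(pair.fluorescence, profile)
    return measure_activity(
        worms,
        beads,
        pair.fluorescence,
        image_id=image_id,
        condition=condition,
        solvent=solvent,
        saturation_level=2**pair.bit_depth - 1,
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Analyze every image listed in the metadata table.

    The metadata CSV needs columns ``image`` (TIFF path, relative paths
    resolved against the table's directory), ``condition`` and ``solvent``.
    The control condition must be present; this is checked before any image
    is processed so a misconfigured run fails fast.
    """
    meta = pd.read_csv(config.metadata_table)
    required = {"image", "condition", "solvent"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata table lacks columns: {sorted(missing)}")
    if config.control_condition not in set(meta["condition"]):
        raise ValueError(
            f"control condition {config.control_condition!r} absent from metadata"
        )
    if config.instrument not in PROFILES:
        raise ValueError(f"unknown instrument profile {config.instrument!r}")

    base = config.metadata_table.parent
    measurements = []
    for row in meta.itertuples(index=False):
        path = Path(row.image)
        if not path.is_absolute():
            path = base / path
        pair = read_image_pair(path, instrument=config.instrument)
        measurements.append(
            quantify_image(pair, config, str(row.image), row.condition, row.solvent)
        )

    groups = normalize(_group_measurements(measurements), config.control_condition)
    comparisons = (
        compare_groups(groups, config.negative_control, alpha=config.alpha)
        if any(g.condition == config.negative_control for g in groups)
        else []
    )

    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    measurements_to_frame(measurements).to_csv(out / "measurements.csv", index=False)
    pd.DataFrame(
        [
            {
                "condition": g.condition,
                "solvent": g.solvent,
                "image_id": m.image_id,
                "normalized_pct": pct,
            }
            for g in groups
            for m, pct in zip([m for m in g.measurements if m.valid], g.normalized_pct)
        ]
    ).to_csv(out / "normalized.csv", index=False)
    pd.DataFrame([asdict(c) for c in comparisons]).to_csv(
        out / "comparisons.csv", index=False
    )
    log = {
        "segmentation": asdict(config.segmentation),
        "instrument": config.instrument,
        "bead_threshold": PROFILES[config.instrument].bead_threshold,
        "control_condition": config.control_condition,
        "negative_control": config.negative_control,
        "alpha": config.alpha,
        "seed": config.seed,
        "n_images": len(measurements),
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    return PipelineResult(measurements, groups, comparisons, config.control_condition)
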