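"""Readers, writers, schemas, and pipeline configuration.

All stage outputs are plain delimited text (CSV, UTF-8, header row, '.'
decimal, empty fields for missing values) or TIFF; no opaque binary state.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from signalome.scoring import ScoreMatrix
from signalome.simulate.images import ImageSet

CELL_TABLE_COLUMNS = (
    "well",
    "drug",
    "time_h",
    "clone",
    "cyto_mean",
    "nuc_mean",
    "bg_mean",
)
SCORE_COLUMNS = (
    "drug",
    "pathway",
    "time_h",
    "score",
    "n_treated",
    "n_control",
    "valid",
)


class SchemaError(ValueError):
    """A table failed validation; the message locates the offence."""


def _require_columns(frame: pd.DataFrame, required, what: str, path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{what} {path}: missing columns {missing}")


def read_cell_table(path) -> pd.DataFrame:
    """Read a per-cell table CSV and validate its schema."""
    frame = pd.read_csv(path)
    _require_columns(frame, CELL_TABLE_COLUMNS, "cell table", path)
    for col in ("cyto_mean", "nuc_mean", "bg_mean"):
        bad = frame.index[frame[col] < 0]
        if len(bad):
            raise SchemaError(
                f"cell table {path}: negative {col} at rows {bad[:5].tolist()}"
            )
    return frame


def write_cell_table(cells: pd.DataFrame, path) -> None:
    cells.to_csv(path, index=False)


def write_score_matrix(m: ScoreMatrix, path) -> None:
    """Long-format CSV: drug, pathway, time_h, score, n_treated, n_control, valid."""
    m.table[list(SCORE_COLUMNS)].to_csv(path, index=False)


def read_score_matrix(path) -> ScoreMatrix:
    table = pd.read_csv(path)
    _require_columns(table, SCORE_COLUMNS, "score matrix", path)
    table["valid"] = table["valid"].astype(bool)
    return ScoreMatrix(table=table)


def read_platemap(path) -> pd.DataFrame:
    """Read a well -> treatment map (CSV or YAML) and validate it.

    Fails fast if no vehicle-control (DMSO) wells are present.
    """
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml", ".json"}:
        with open(path) as fh:
            mapping = yaml.safe_load(fh)
        frame = pd.DataFrame(
            {"well": list(mapping), "treatment": list(mapping.values())}
        )
    else:
        frame = pd.read_csv(path)
    _require_columns(frame, ("well", "treatment"), "platemap", path)
    if frame["well"].duplicated().any():
        dupes = frame.loc[frame["well"].duplicated(), "well"].tolist()
        raise SchemaError(f"platemap {path}: duplicate wells {dupes}")
    if not (frame["treatment"].astype(str) == "DMSO").any():
        raise SchemaError(f"platemap {path}: no DMSO control wells")
    return frame


def save_image_set(image_set: ImageSet, out_dir) -> list[Path]:
    """Write one multi-page TIFF (page per channel) + label TIFF per field."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for clone_name, clone in image_set.clones.items():
        safe = clone_name.replace("/", "_")
        for i, (stack, labels) in enumerate(zip(clone.stacks, clone.label_maps)):
            img_path = out_dir / f"{safe}_f{i:02d}.tif"
            tifffile.imwrite(
                img_path,
                stack,
                photometric="minisblack",
                planarconfig="separate",
                metadata={"channels": list(image_set.channels)},
            )
            lbl_path = out_dir / f"{safe}_f{i:02d}_labels.tif"
            tifffile.imwrite(lbl_path, labels.astype(np.uint16))
            written += [img_path, lbl_path]
    image_set.truth.to_csv(out_dir / "truth.csv", index=False)
    return written


@dataclass
class PipelineConfig:
    """Seeds, thresholds, and stage toggles for a full pipeline run.

    Every default is a documented convention of the method: activity
    threshold 0.2, 30-cell minimum per scored group, cohorts need more than
    30 samples, 70/30 training split, 50 boosting stages, fivefold CV.
    """

    seed: int = 0
    score_threshold: float = 0.2
    min_cells: int = 30
    min_cohort_n: int = 30
    train_split: float = 0.7
    classifier_budget: int = 50
    cv_folds: int = 5
    n_drugs: int = 100
    cells_per_well: float = 656.0
    run_images: bool = False
    run_screen: bool = True
    run_states: bool = True
    run_growth: bool = True
    run_cohorts: bool = True
    n_cells_per_clone_images: int = 40
    cohort_n_samples: int = 500
    n_cohorts: int = 4

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise SchemaError(f"config {path}: unknown keys {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
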