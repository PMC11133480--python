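"""Table I/O and schema validation.

All tables are UTF-8 CSV with a header row; missing values are empty
fields.  Validation errors name the offending column and (1-based data)
row so malformed inputs can be traced back to the file.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .gating import CELL_TABLE_COLUMNS, MARKER_COLUMNS

LESION_COLUMNS = ["patient_id", "visit_day", "lesion_id", "diam1_mm",
                  "diam2_mm", "present_flag"]
EVENT_COLUMNS = ["patient_id", "clinical_pd_day", "death_day",
                 "new_therapy_day", "treatment_stop_reason",
                 "last_contact_day", "pseudo_progression_day"]
SURVIVAL_COLUMNS = ["patient_id", "endpoint", "time_days", "event", "reason"]
AE_COLUMNS = ["patient_id", "term", "grade", "relationship"]
PK_COLUMNS = ["patient_id", "day", "drug_um", "cxcl12_um", "dose_mg"]


class SchemaError(ValueError):
    pass


def _require(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def read_cell_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, CELL_TABLE_COLUMNS, path)
    for col in MARKER_COLUMNS:
        bad = df.index[(df[col] < 0) | (df[col] > 1)]
        if len(bad):
            row = int(bad[0]) + 1
            cid = df.loc[bad[0], "cell_id"]
            raise SchemaError(f"{path}: column {col}, row {row} (cell {cid}): "
                              f"value outside [0, 1]")
    bad = df.index[df["nuclear_area_um2"] <= 0]
    if len(bad):
        raise SchemaError(f"{path}: column nuclear_area_um2, row "
                          f"{int(bad[0]) + 1}: non-positive area")
    return df


def read_lesion_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, LESION_COLUMNS, path)
    df["present_flag"] = df["present_flag"].astype(bool)
    bad = df.index[(df["diam1_mm"] < 0) | (df["diam2_mm"] < 0)]
    if len(bad):
        raise SchemaError(f"{path}: negative diameter at row {int(bad[0]) + 1}")
    return df


def read_clinical_events(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["patient_id"], path)
    for col in EVENT_COLUMNS:
        if col not in df.columns:
            df[col] = None
    return df


def read_survival_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, SURVIVAL_COLUMNS, path)
    df["event"] = df["event"].astype(bool)
    bad = df.index[df["time_days"] <= 0]
    if len(bad):
        raise SchemaError(f"{path}: non-positive time_days at row "
                          f"{int(bad[0]) + 1}")
    return df


def read_ae_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, AE_COLUMNS, path)
    return df


def read_pk_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["patient_id", "day", "drug_um"], path)
    return df


def write_csv(df: pd.DataFrame, path, columns=None) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out = df[columns] if columns else df
    out.to_csv(path, index=False)


def write_cohort(bundle, outdir) -> dict:
    """Write a synthetic cohort bundle to CSV + a ground-truth JSON sidecar.

    Returns a manifest of written files and row counts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {}
    tables = {
        "cells.csv": (bundle.cells, CELL_TABLE_COLUMNS if len(bundle.cells) else None),
        "lesions.csv": (bundle.lesions, LESION_COLUMNS),
        "clinical_events.csv": (bundle.clinical_events, None),
        "pk.csv": (bundle.pk, None),
        "aes.csv": (bundle.aes, None),
        "survival_truth.csv": (bundle.survival, None),
    }
    for name, (df, cols) in tables.items():
        write_csv(df, outdir / name, cols)
        manifest[name] = int(len(df))
    truth = {"config": config_dict(bundle.config),
             "patients": [t.as_dict() for t in bundle.truths]}
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    manifest["truth.json"] = len(bundle.truths)
    return manifest


def config_dict(config) -> dict:
    from dataclasses import asdict
    return asdict(config)


def config_hash(config) -> str:
    blob = json.dumps(config_dict(config), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_synth_config(path):
    """Load a SynthConfig from YAML/JSON (keys = dataclass fields)."""
    from .synthetic import SynthConfig
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return SynthConfig(**data)
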