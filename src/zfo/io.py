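"""Readers, writers and run manifests shared by all pipeline stages.

Images travel as TIFF (16-bit grayscale preserved bit-exact, float images as
float32) or PNG; traces and cohort tables as CSV with a one-line header;
configuration as YAML.  Writers emit deterministic column order so identical
inputs produce byte-identical outputs.  Every output directory receives a
manifest recording inputs, parameters, the seed and package versions.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "read_image",
    "write_image",
    "read_trace",
    "write_trace",
    "read_cohort",
    "write_results",
    "read_config",
    "write_manifest",
]

COHORT_COLUMNS = ["fish_id", "genotype", "eye", "age", "body_length_mm",
                  "outcome", "value"]
TRACE_COLUMNS = {"okr": ["time_s", "angle_deg"], "erg": ["time_ms", "voltage_uv"]}


def read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        return tifffile.imread(path)
    import imageio.v3 as iio

    return iio.imread(path)


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write TIFF/PNG; integer arrays are preserved without rescaling."""
    path = Path(path)
    image = np.asarray(image)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        if image.dtype.kind == "f":
            image = image.astype(np.float32)
        tifffile.imwrite(path, image)
        return
    import imageio.v3 as iio

    if image.dtype.kind == "f":  # PNG needs integers: scale to 16-bit range
        lo, hi = float(image.min()), float(image.max())
        scale = 65535.0 / (hi - lo) if hi > lo else 1.0
        image = ((image - lo) * scale).astype(np.uint16)
    iio.imwrite(path, image)


def read_trace(path: str | Path, kind: str) -> pd.DataFrame:
    """Read a time-series CSV, validating the declared header."""
    if kind not in TRACE_COLUMNS:
        raise ValueError(f"unknown trace kind {kind!r}")
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS[kind]) - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: trace is missing required columns {sorted(missing)}"
        )
    return df


def write_trace(path: str | Path, df: pd.DataFrame, kind: str) -> None:
    cols = TRACE_COLUMNS[kind]
    extra = [c for c in df.columns if c not in cols]
    df[cols + extra].to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format cohort table."""
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: cohort table missing columns {sorted(missing)}"
        )
    for col in ("body_length_mm", "value"):
        bad = df.index[df[col].isna()]
        if len(bad):
            raise ValueError(
                f"{path}: missing {col!r} in row(s) {list(bad[:5])} "
                "(0-based, excluding header)"
            )
    return df


def write_results(out_dir: str | Path, name: str, df: pd.DataFrame) -> Path:
    """Write a tidy results CSV with deterministic column order."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{name}.csv"
    df.reindex(sorted(df.columns), axis=1).to_csv(path, index=False)
    return path


def read_config(path: str | Path, allowed_keys: set[str] | None = None) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    if allowed_keys is not None:
        unknown = set(cfg) - allowed_keys
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return cfg


def write_manifest(
    out_dir: str | Path, stage: str, seed: int | None, params: Mapping
) -> Path:
    """Record provenance (stage, seed, parameters, versions) beside outputs."""
    import zfo

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "seed": seed,
        "parameters": {k: _jsonable(v) for k, v in params.items()},
        "versions": {"zfo": zfo.__version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def _jsonable(v):
    if isinstance(v, (np.integer, np.floating)):
        return v.item()
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, Path):
        return str(v)
    return v
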