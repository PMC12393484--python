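"""Shared I/O: TIFF stacks, validated CSV tables, configs and run manifests.

Coordinates are physical micrometres throughout the analysis code; the
pixel-to-micrometre conversion happens only here, using the stack's pixel
size.  All readers reject malformed input rather than silently coercing it.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .nandb import ImageStack

__all__ = [
    "read_stack",
    "write_stack",
    "read_table",
    "write_table",
    "read_config",
    "write_manifest",
    "write_json",
    "TABLE_SCHEMAS",
]

TOOL_VERSION = "0.1.0"

#: required columns per named table schema; feature tables additionally
#: require at least one feature column beyond the listed ones.
TABLE_SCHEMAS = {
    "localizations": ["frame", "x_um", "y_um", "intensity"],
    "trajectories": ["track_id", "frame", "x_um", "y_um"],
    "dwells": ["duration_s", "censored"],
    "features": ["cell_id", "condition"],
}


# ---------------------------------------------------------------------------
# stacks
# ---------------------------------------------------------------------------

def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_stack(path, stack: ImageStack) -> None:
    """Write a multi-frame grayscale TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    data = stack.data
    if np.issubdtype(data.dtype, np.floating):
        tifffile.imwrite(path, data.astype(np.float32), photometric="minisblack")
    else:
        tifffile.imwrite(path, data.astype(np.uint16), photometric="minisblack")
    meta = {
        "pixel_size_um": stack.pixel_size,
        "dwell_time_us": stack.dwell_time,
        "frame_interval_s": stack.frame_interval,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_stack(
    path,
    pixel_size_um: float | None = None,
    dwell_time_us: float | None = None,
    frame_interval_s: float | None = None,
) -> ImageStack:
    """Read a multi-frame grayscale TIFF into an ImageStack.

    Metadata comes from the ``<name>.tif.meta.json`` sidecar if present;
    explicit arguments override it.  RGB or multi-series TIFFs are
    rejected; a missing pixel size with no override raises an error naming
    the field.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        if len(tf.series) != 1:
            raise ValueError(f"{path}: multi-series TIFF layout is unsupported")
        page = tf.pages[0]
        if page.samplesperpixel != 1:
            raise ValueError(f"{path}: RGB/multi-sample TIFF layout is unsupported")
        data = tf.series[0].asarray()
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a grayscale frames x rows x cols stack, "
            f"got shape {data.shape} (RGB/multi-channel layouts are unsupported)"
        )
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    if px is None:
        raise ValueError(f"{path}: missing required metadata field 'pixel_size_um' "
                         "(supply a sidecar or the pixel_size_um argument)")
    dw = dwell_time_us if dwell_time_us is not None else meta.get("dwell_time_us")
    fi = frame_interval_s if frame_interval_s is not None else meta.get("frame_interval_s")
    return ImageStack(data, pixel_size=float(px),
                      dwell_time=float(dw) if dw is not None else 0.0,
                      frame_interval=float(fi) if fi is not None else None)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV table against a named schema.

    Checks required columns, numeric parsability (reporting the first bad
    row), and per-schema uniqueness constraints; row order is preserved.
    """
    if schema not in TABLE_SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; known: {sorted(TABLE_SCHEMAS)}")
    df = pd.read_csv(path)
    required = TABLE_SCHEMAS[schema]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    numeric = [c for c in required if c not in ("censored", "cell_id", "condition")]
    if schema == "features":
        numeric += [c for c in df.columns if c not in required]
        if not [c for c in df.columns if c not in required]:
            raise ValueError(f"{path}: feature table has no feature columns")
    for col in numeric:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise ValueError(f"{path}: non-numeric value in column {col!r}, row {row}")
        if parsed.isna().any():
            row = int(np.nonzero(parsed.isna().to_numpy())[0][0])
            raise ValueError(f"{path}: missing value in column {col!r}, row {row}")
        df[col] = parsed
    if schema == "dwells":
        df["censored"] = df["censored"].astype(bool)
    if schema == "trajectories":
        if df.duplicated(subset=["track_id", "frame"]).any():
            raise ValueError(f"{path}: duplicated (track_id, frame) pair")
    return df


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configs and manifests
# ---------------------------------------------------------------------------

def read_config(path, known_keys: set[str] | None = None) -> dict:
    """Load a YAML run config; reject unknown top-level keys when given."""
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    if known_keys is not None:
        unknown = set(cfg) - known_keys
        if unknown:
            raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_json(path, payload: dict) -> None:
    """Deterministic JSON output: sorted keys, fixed float formatting."""
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))


def write_manifest(
    out_dir, cfg: dict, inputs: list, outputs: list, seed: int | None = None
) -> Path:
    """Record tool version, config hash, input checksums and outputs.

    The manifest carries a timestamp; all analysis payloads themselves are
    timestamp-free so identical runs are byte-identical.
    """
    out_dir = Path(out_dir)
    manifest = {
        "tool_version": TOOL_VERSION,
        "config_hash": config_hash(cfg),
        "seed": seed if seed is not None else cfg.get("seed"),
        "inputs": {str(p): _checksum(Path(p)) for p in inputs if Path(p).exists()},
        "outputs": sorted(str(p) for p in outputs),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
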