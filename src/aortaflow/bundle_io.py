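"""Read/write cine bundles, curves, centrelines and cohort index tables.

The canonical bundle format is a single NPZ file holding the velocity
and mask arrays next to a JSON sidecar with the physical metadata
(pixel spacing in mm, frame interval in ms, VENC in cm/s) and an
optional truth block. Velocity sign convention in a bundle is always
positive = forward; a reader mapping a scanner convention must flip
explicitly and record it via the ``sign_flipped`` sidecar flag.

Tables are plain CSV with a fixed, documented column order
(``SUBJECT_COLUMNS`` then ``INDEX_COLUMNS``); unknown columns survive a
round-trip but are reported via logging.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .datatypes import (
    INDEX_COLUMNS,
    SUBJECT_COLUMNS,
    Centreline,
    MaskSeries,
    VelocityCine,
    check_grid_match,
)
from .synthetic import SyntheticTruth

logger = logging.getLogger(__name__)

REQUIRED_SIDECAR_KEYS = ("pixel_spacing_mm", "frame_interval_ms", "venc_cm_s")


def write_bundle(
    path: str | Path,
    cine: VelocityCine,
    masks: MaskSeries,
    truth: Optional[SyntheticTruth] = None,
) -> Path:
    """Write a cine bundle directory: ``arrays.npz`` + ``sidecar.json``."""
    check_grid_match(cine, masks)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez(path / "arrays.npz", velocity=cine.velocity, mask=masks.mask.astype(np.uint8))
    sidecar = {
        "pixel_spacing_mm": list(cine.pixel_spacing),
        "frame_interval_ms": cine.frame_interval,
        "venc_cm_s": cine.venc,
        "sign_flipped": False,
    }
    if truth is not None:
        sidecar["truth"] = asdict(truth)
    (path / "sidecar.json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_bundle(
    path: str | Path,
) -> tuple[VelocityCine, MaskSeries, Optional[SyntheticTruth]]:
    """Read a bundle written by :func:`write_bundle` (lossless round-trip)."""
    path = Path(path)
    sidecar_path = path / "sidecar.json"
    if not sidecar_path.exists():
        raise FileNotFoundError(f"bundle sidecar not found: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    for key in REQUIRED_SIDECAR_KEYS:
        if key not in sidecar:
            raise KeyError(f"sidecar missing required key '{key}' in {sidecar_path}")
    with np.load(path / "arrays.npz") as arrays:
        velocity = arrays["velocity"]
        mask = arrays["mask"].astype(bool)
    if mask.shape != velocity.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match velocity shape {velocity.shape}"
        )
    cine = VelocityCine(
        velocity,
        tuple(sidecar["pixel_spacing_mm"]),
        sidecar["frame_interval_ms"],
        venc=sidecar["venc_cm_s"],
    )
    masks = MaskSeries(mask)
    truth = SyntheticTruth(**sidecar["truth"]) if "truth" in sidecar else None
    return cine, masks, truth


def write_indices(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a cohort index table as CSV in the canonical column order.

    Known columns come first (subject metadata, then flow indices);
    unknown columns are preserved at the end and flagged in the log.
    """
    path = Path(path)
    known = [c for c in SUBJECT_COLUMNS + INDEX_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in known]
    if extra:
        logger.warning("index table has unknown columns (preserved): %s", extra)
    table[known + extra].to_csv(path, index=False, float_format="%.10g")
    return path


def read_indices(path: str | Path) -> pd.DataFrame:
    """Read a cohort index table, validating numeric columns."""
    table = pd.read_csv(Path(path))
    numeric = [c for c in table.columns if c in INDEX_COLUMNS + ["age", "bsa"]]
    for col in numeric:
        coerced = pd.to_numeric(table[col], errors="coerce")
        bad = coerced.isna() & table[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"non-numeric value {table[col].iloc[row]!r} in column '{col}', row {row}"
            )
        table[col] = coerced
    extra = [c for c in table.columns if c not in SUBJECT_COLUMNS + INDEX_COLUMNS]
    if extra:
        logger.warning("index table has unknown columns (preserved): %s", extra)
    return table


def write_curve(curve_dict: dict, path: str | Path) -> Path:
    """Write per-frame diagnostics (rates, FD, RA) to CSV."""
    path = Path(path)
    cols = {k: v for k, v in curve_dict.items() if isinstance(v, np.ndarray)}
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.10g")
    return path


def write_waveforms(time: np.ndarray, ascending: np.ndarray, descending: np.ndarray, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"time_ms": time, "ascending": ascending, "descending": descending}
    ).to_csv(path, index=False, float_format="%.10g")
    return path


def read_waveforms(path: str | Path):
    df = pd.read_csv(Path(path))
    return df["time_ms"].to_numpy(), df["ascending"].to_numpy(), df["descending"].to_numpy()


def write_centreline(centreline: Centreline, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(centreline.points, columns=["x_mm", "y_mm", "z_mm"]).to_csv(
        path, index=False, float_format="%.10g"
    )
    return path


def read_centreline(path: str | Path) -> Centreline:
    df = pd.read_csv(Path(path))
    return Centreline(df[["x_mm", "y_mm", "z_mm"]].to_numpy())
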