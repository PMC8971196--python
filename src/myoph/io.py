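"""Readers/writers for the pipeline's plain-text and TIFF interfaces.

Coordinate conventions: peak intervals are 0-based half-open (BED style) on
disk and in memory.  TSS positions are 1-based in input TSVs (the common
annotation convention) and converted to 0-based on read; writers convert
back.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import tifffile

from .ph_calibration import CalibrationCurve

PathLike = Union[str, Path]


def read_tiff(path: PathLike) -> np.ndarray:
    return tifffile.imread(str(path))


def write_tiff_float(path: PathLike, image: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32))


def write_tiff_uint16(path: PathLike, image: np.ndarray) -> None:
    img = np.clip(np.asarray(image, dtype=float), 0, 65535)
    tifffile.imwrite(str(path), img.astype(np.uint16))


def write_tiff_mask(path: PathLike, mask: np.ndarray) -> None:
    tifffile.imwrite(str(path), (np.asarray(mask, dtype=bool) * 255).astype(np.uint8))


def read_diff_table(path: PathLike) -> pd.DataFrame:
    """TSV with columns id, log2fc, pvalue and optional padj, fraction."""
    df = pd.read_csv(path, sep="\t")
    required = {"id", "log2fc", "pvalue"}
    if not required.issubset(df.columns):
        raise ValueError(f"differential table needs columns {sorted(required)}")
    return df


def write_diff_table(path: PathLike, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_peak_table(path: PathLike) -> pd.DataFrame:
    """BED-like TSV: chrom, start, end (0-based half-open) + bool condition cols."""
    df = pd.read_csv(path, sep="\t")
    if not {"chrom", "start", "end"}.issubset(df.columns):
        raise ValueError("peak table needs chrom, start, end columns")
    for col in df.columns:
        if col not in ("chrom", "start", "end"):
            df[col] = df[col].astype(bool)
    return df


def write_peak_table(path: PathLike, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_tss_table(path: PathLike) -> pd.DataFrame:
    """TSV gene, chrom, tss (1-based on disk), strand; returns 0-based tss."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "chrom", "tss"}.issubset(df.columns):
        raise ValueError("TSS table needs gene, chrom, tss columns")
    df = df.copy()
    df["tss"] = df["tss"].astype(int) - 1
    return df


def write_tss_table(path: PathLike, table: pd.DataFrame) -> None:
    out = table.copy()
    out["tss"] = out["tss"].astype(int) + 1
    out.to_csv(path, sep="\t", index=False)


def write_curve_json(path: PathLike, curve: CalibrationCurve) -> None:
    Path(path).write_text(json.dumps(asdict(curve), indent=2) + "\n")


def read_curve_json(path: PathLike) -> CalibrationCurve:
    data = json.loads(Path(path).read_text())
    return CalibrationCurve(**data)
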