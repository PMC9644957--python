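"""Dentition metrics: tooth aspect ratios and per-specimen summaries.

Aspect ratio is crown diameter (width at the widest point) over crown length;
low ratios mark long, slender piercing teeth, high ratios shorter, more
conical crowns.  Full precision internally; presentation rounds to one
decimal place.
"""

from __future__ import annotations

from importlib import resources as _resources

import numpy as np
import pandas as pd

__all__ = ["aspect_ratio", "dentition_summary", "load_tooth_table"]


def aspect_ratio(length: float, diameter: float) -> float:
    """Crown diameter / crown length, full precision."""
    if not length > 0:
        raise ValueError(f"tooth length must be > 0, got {length!r}")
    if not diameter > 0:
        raise ValueError(f"tooth diameter must be > 0, got {diameter!r}")
    return diameter / length


def load_tooth_table(path: str | None = None) -> pd.DataFrame:
    """Packaged transcription of the printed tooth measurements
    (columns: specimen, tooth, length_mm, diameter_mm)."""
    if path is None:
        ref = _resources.files("ichthyofea").joinpath("data/tooth_measurements.csv")
        with ref.open() as fh:
            return pd.read_csv(fh)
    return pd.read_csv(path)


def dentition_summary(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-specimen mean crown length, diameter and aspect ratio.

    Means are arithmetic means of the unrounded per-tooth values; rounding to
    the printed precision happens at presentation.  Measurements from several
    specimens must carry a ``specimen`` label column.
    """
    df = measurements.copy()
    if "specimen" not in df.columns:
        if df[["length_mm", "diameter_mm"]].isna().any().any():
            raise ValueError("measurements lack a 'specimen' column and contain gaps")
        raise ValueError("mixed measurements need a 'specimen' label column")
    if df.empty:
        raise ValueError("no measurements supplied")
    bad = df[(df["length_mm"] <= 0) | (df["diameter_mm"] <= 0)]
    if not bad.empty:
        raise ValueError(f"non-positive tooth measurements in rows {list(bad.index)}")
    df["aspect_ratio"] = df["diameter_mm"] / df["length_mm"]
    out = (
        df.groupby("specimen", sort=True)
        .agg(
            n_teeth=("length_mm", "size"),
            mean_length_mm=("length_mm", "mean"),
            mean_diameter_mm=("diameter_mm", "mean"),
            mean_aspect_ratio=("aspect_ratio", "mean"),
        )
        .reset_index()
    )
    return out


def dentition_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """Presentation table with per-tooth aspect ratios rounded to 1 decimal."""
    df = measurements.copy()
    df["aspect_ratio"] = (df["diameter_mm"] / df["length_mm"]).round(1)
    return df
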