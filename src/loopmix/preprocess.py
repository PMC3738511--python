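"""Spot-level filtering and the log2 transform.

Two filters are applied before any model fitting: per-channel values below
the array background level (default 300) are set MISSING, and spots seen on
too few of the hybridized sample-channels (default fewer than 20 of 24) are
dropped outright.  Presence is counted per channel by default because the
experiments this pipeline targets hybridize 24 samples as 24 channels on 12
two-color sub-arrays; a per-array mode (both channels required) is provided
for layouts counted the other way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_design import ArrayDesign, ExpressionMatrix, IntensityMatrix


@dataclass
class FilterReport:
    n_spots_in: int
    n_low_intensity_cells: int
    n_spots_removed_presence: int
    n_spots_out: int
    min_intensity: float
    min_present: int
    n_arrays: int

    def __post_init__(self) -> None:
        assert self.n_spots_out == self.n_spots_in - self.n_spots_removed_presence


def filter_spots(
    raw: IntensityMatrix,
    design: ArrayDesign,
    min_intensity: float = 300.0,
    min_present: int = 20,
    count_mode: str = "channels",
) -> tuple[IntensityMatrix, FilterReport]:
    """Mask low-intensity cells and drop sparsely present spots.

    count_mode="channels" counts every non-missing sample-channel toward
    presence; count_mode="arrays" counts an array only when both of its
    channels are non-missing.
    """
    if min_intensity < 0:
        raise ValueError("min_intensity must be non-negative")
    if count_mode not in ("channels", "arrays"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    df = raw.values.copy()
    low = df["intensity"].notna() & (df["intensity"] < min_intensity)
    df.loc[low, "intensity"] = np.nan

    present = df[df["intensity"].notna()]
    if count_mode == "channels":
        counts = present.groupby("spot").size()
    else:
        per_array = present.groupby(["spot", "array"]).size()
        counts = (per_array >= 2).groupby("spot").sum()
    spots_in = df["spot"].unique()
    keep = {s for s in spots_in if counts.get(s, 0) >= min_present}
    out = df[df["spot"].isin(keep)].reset_index(drop=True)

    report = FilterReport(
        n_spots_in=len(spots_in),
        n_low_intensity_cells=int(low.sum()),
        n_spots_removed_presence=len(spots_in) - len(keep),
        n_spots_out=len(keep),
        min_intensity=min_intensity,
        min_present=min_present,
        n_arrays=design.n_arrays,
    )
    return IntensityMatrix(out), report


def log2_transform(filtered: IntensityMatrix) -> ExpressionMatrix:
    """Log2 each non-missing intensity; MISSING cells stay missing."""
    df = filtered.values.copy()
    vals = df["intensity"]
    nonpos = vals.notna() & (vals <= 0)
    if nonpos.any():
        raise ValueError(
            "non-positive intensity reached log2_transform; filter with a "
            "positive min_intensity first"
        )
    df["intensity"] = np.log2(vals)
    return ExpressionMatrix(df)
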