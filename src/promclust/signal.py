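"""Promoter x experiment signal matrix construction.

For every TSS and every ChIP-seq experiment, the height of the called
peak whose summit lies closest to the TSS within a symmetric window
(default ±1000 bp) is recorded; absence of a peak is recorded as 0.
Heights are then normalized per experiment by a linear map onto [0, 1],
after holding out the top fraction (default 0.05%) of values, which are
subsequently set to 1 (winsorization against outlier peaks).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PEAK_COLUMNS = ["chrom", "start", "end", "summit_offset", "height"]
TSS_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


@dataclass
class MatrixParams:
    """Parameters of matrix construction.

    tss_window
        Half-width (bp) of the symmetric window around the TSS searched
        for the nearest peak summit.
    winsor_fraction
        Fraction of the largest values per experiment held out before
        the linear [0, 1] mapping and set to 1 afterwards.
    """

    tss_window: int = 1000
    winsor_fraction: float = 0.0005

    def __post_init__(self) -> None:
        if self.tss_window <= 0:
            raise ValueError("tss_window must be positive")
        if not 0.0 <= self.winsor_fraction < 1.0:
            raise ValueError("winsor_fraction must be in [0, 1)")


@dataclass
class SignalMatrix:
    """Experiments (rows) x promoters (columns) of normalized heights in [0, 1]."""

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    col_meta: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("values shape inconsistent with ids")
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValueError("duplicate experiment ids")
        if len(set(self.col_ids)) != len(self.col_ids):
            raise ValueError("duplicate promoter ids")

    @property
    def n_experiments(self) -> int:
        return self.values.shape[0]

    @property
    def n_promoters(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="experiment")

    @classmethod
    def from_tsv(cls, path) -> "SignalMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(float), [str(r) for r in df.index],
                   [str(c) for c in df.columns])


def read_peak_file(path) -> pd.DataFrame:
    """Read a 5-column peak table (chrom, start, end, summit_offset, height).

    ``summit_offset`` is relative to ``start`` (MACS subpeak dialect); an
    absolute ``summit`` column is added.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=PEAK_COLUMNS,
                     comment="#")
    df["summit"] = df["start"] + df["summit_offset"]
    _validate_peaks(df)
    return df


def _validate_peaks(df: pd.DataFrame) -> None:
    if len(df) == 0:
        return
    if (df["start"] >= df["end"]).any():
        raise ValueError("peak with start >= end")
    bad = (df["summit"] < df["start"]) | (df["summit"] >= df["end"])
    if bad.any():
        raise ValueError("peak summit outside [start, end)")
    if (df["height"] < 0).any():
        raise ValueError("negative peak height")


def read_tss_bed(path) -> pd.DataFrame:
    """Read a BED6 TSS file; the TSS position is the interval start
    (+ strand) or end-1 (- strand)."""
    df = pd.read_csv(path, sep="\t", header=None, names=TSS_COLUMNS,
                     comment="#")
    df["pos"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    return df


def nearest_peak_height(tss_pos: int, peaks: pd.DataFrame,
                        tss_window: int = 1000) -> float:
    """Height of the peak whose summit is closest to ``tss_pos`` within
    ``±tss_window``; 0 when no summit qualifies.

    Ties in distance are broken by larger height, then smaller summit
    coordinate.  ``peaks`` must already be restricted to the TSS's
    chromosome and carry a ``summit`` column.
    """
    if tss_window < 0:
        raise ValueError("tss_window must be non-negative")
    if len(peaks) == 0:
        return 0.0
    summits = peaks["summit"].to_numpy()
    heights = peaks["height"].to_numpy(float)
    dist = np.abs(summits - tss_pos)
    in_win = dist <= tss_window
    if not in_win.any():
        return 0.0
    dist = dist[in_win]
    heights = heights[in_win]
    summits = summits[in_win]
    # lexicographic: min distance, then max height, then min coordinate
    order = np.lexsort((summits, -heights, dist))
    return float(heights[order[0]])


def normalize_experiment(heights: np.ndarray,
                         winsor_fraction: float = 0.0005) -> np.ndarray:
    """Map raw peak heights to [0, 1] per experiment.

    The ``k = floor(winsor_fraction * n)`` largest values are held out,
    the rest are mapped linearly so that min -> 0 and max -> 1, and the
    held-out values are set to 1.

    Degenerate constant input: all-zero -> all 0 (no signal); constant
    positive -> all 1 (saturated signal).
    """
    heights = np.asarray(heights, dtype=float)
    n = heights.size
    if n == 0:
        raise ValueError("empty height vector")
    if (heights < 0).any():
        raise ValueError("heights must be non-negative")
    k = math.floor(winsor_fraction * n)
    out = np.empty(n, dtype=float)
    if k > 0:
        held = np.argsort(heights, kind="stable")[n - k:]
    else:
        held = np.empty(0, dtype=int)
    keep_mask = np.ones(n, dtype=bool)
    keep_mask[held] = False
    kept = heights[keep_mask]
    lo = kept.min()
    hi = kept.max()
    if hi == lo:
        out[:] = 0.0 if hi == 0.0 else 1.0
        if hi == 0.0:
            return out  # all-zero stays all-zero, held-out included
        out[held] = 1.0
        return out
    out[keep_mask] = (kept - lo) / (hi - lo)
    out[held] = 1.0
    return out


def build_matrix(tss: pd.DataFrame, peak_sets: dict[str, pd.DataFrame],
                 params: MatrixParams | None = None) -> SignalMatrix:
    """Assemble the experiments x promoters matrix of normalized heights.

    ``tss`` needs columns ``name`` (unique promoter id), ``chrom`` and
    ``pos``; ``peak_sets`` maps experiment name -> peak table with a
    ``summit`` column.
    """
    params = params or MatrixParams()
    names = tss["name"].tolist()
    if len(set(names)) != len(names):
        raise ValueError("duplicate promoter ids in TSS table")
    row_ids = list(peak_sets)
    values = np.zeros((len(row_ids), len(names)))
    for i, exp in enumerate(row_ids):
        peaks = peak_sets[exp]
        by_chrom = {c: g for c, g in peaks.groupby("chrom")} if len(peaks) else {}
        raw = np.array([
            nearest_peak_height(int(p), by_chrom.get(c, peaks.iloc[0:0]),
                                params.tss_window)
            for c, p in zip(tss["chrom"], tss["pos"])
        ])
        values[i] = normalize_experiment(raw, params.winsor_fraction)
    meta_cols = [c for c in ("chrom", "pos", "strand") if c in tss.columns]
    meta = tss.set_index("name")[meta_cols] if meta_cols else None
    return SignalMatrix(values, row_ids, names, meta)
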