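"""Motif-hit reduction and motif-score matrices.

Motif scanning itself (MAST over JASPAR matrices) is upstream; this
module consumes a hit table with columns ``promoter_id, motif_id,
strand, position, score, p_value`` (a TSV dialect of MAST hit output,
positions TSS-relative and strand-oriented: downstream positive).

When a promoter region has several hits of the same motif, the hit
with the smallest p-value is kept; score matrices are laid out with
promoters in the biclustering heatmap column order so motif occurrence
can be read against the cluster bands.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

HIT_COLUMNS = ["promoter_id", "motif_id", "strand", "position", "score",
               "p_value"]

__all__ = ["read_hits", "best_hit_per_promoter", "motif_matrix",
           "motif_positions"]


def read_hits(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=HIT_COLUMNS,
                     comment="#")
    _validate(df)
    return df


def _validate(df: pd.DataFrame) -> None:
    if len(df) and ((df["p_value"] <= 0) | (df["p_value"] > 1)).any():
        raise ValueError("p_value must be in (0, 1]")


def best_hit_per_promoter(hits: pd.DataFrame) -> pd.DataFrame:
    """One hit per (promoter, motif): smallest p-value; ties broken by
    position closest to the TSS, then leftmost."""
    _validate(hits)
    if len(hits) == 0:
        return hits.copy()
    ordered = hits.assign(_abspos=hits["position"].abs()).sort_values(
        ["p_value", "_abspos", "position"], kind="stable")
    best = ordered.groupby(["promoter_id", "motif_id"], sort=False).head(1)
    return best.drop(columns="_abspos").reset_index(drop=True)


def motif_matrix(best_hits: pd.DataFrame, motifs: list[str],
                 col_order: list[str]) -> pd.DataFrame:
    """Motifs x promoters score grid in heatmap column order; missing
    hits are 0."""
    grid = pd.DataFrame(0.0, index=list(motifs), columns=list(col_order))
    if len(best_hits) == 0:
        return grid
    unknown = set(best_hits["promoter_id"]) - set(col_order)
    if unknown:
        raise KeyError(f"promoters not in column order: {sorted(unknown)[:5]}")
    for _, row in best_hits.iterrows():
        if row["motif_id"] in grid.index:
            grid.loc[row["motif_id"], row["promoter_id"]] = row["score"]
    return grid


def motif_positions(best_hits: pd.DataFrame, window: int = 200,
                    filter_p: float = 0.001) -> pd.DataFrame:
    """Best-hit positions with p below ``filter_p``, restricted to the
    symmetric ``[-window, window]`` promoter window."""
    if window <= 0:
        raise ValueError("window must be positive")
    sel = (best_hits["p_value"] < filter_p) & \
          (best_hits["position"].abs() <= window)
    return best_hits.loc[sel, ["promoter_id", "motif_id", "position",
                               "score", "p_value"]].reset_index(drop=True)
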