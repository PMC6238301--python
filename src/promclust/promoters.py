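"""Promoter definition and activity calling.

Two promoter definitions are supported:

* RefSeq-style: annotated TSSs, with any TSS having a neighbour within
  1 Kbp dropped entirely (the resolution of peak-called ChIP-seq data
  cannot distinguish such TSSs), then activity called from tiered CAGE
  peaks in a ±500 bp window.

* CAGE-cluster-style: CAGE-detected TSSs chained into clusters by
  single linkage at < 200 bp gaps; clusters spanning > 1000 bp, mixing
  strands, or mixing annotated genes are excluded.  Activity is called
  on the cluster span extended by 500 bp on each side, strand
  specifically.

Activity tiers follow the FANTOM robust/permissive CAGE peak sets: a
robust peak in the window makes the promoter *active*; not even a
permissive peak makes it *inactive*; a permissive-only signal leaves it
*low* (excluded from both the active and inactive analyses).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signal import SignalMatrix

ACTIVE, INACTIVE, LOW = "active", "inactive", "low"


@dataclass
class ActivityParams:
    activity_window: int = 500
    isolation_dist: int = 1000
    merge_gap: int = 200
    max_span: int = 1000

    def __post_init__(self) -> None:
        for name in ("activity_window", "isolation_dist", "merge_gap", "max_span"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TSSCluster:
    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    members: pd.DataFrame = field(repr=False)
    status: str = "unset"
    exclusion_reason: str | None = None

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def retained(self) -> bool:
        return self.status != "excluded"


def filter_isolated_tss(tss: pd.DataFrame,
                        isolation_dist: int = 1000) -> pd.DataFrame:
    """Drop every TSS that has another TSS within ``isolation_dist`` bp.

    The comparison is per chromosome but across strands and genes; all
    members of a violating group are removed, not just one of them.
    Idempotent.
    """
    keep = pd.Series(True, index=tss.index)
    for _, grp in tss.groupby("chrom"):
        pos = grp["pos"].to_numpy()
        order = np.argsort(pos, kind="stable")
        sp = pos[order]
        close_next = np.zeros(len(sp), dtype=bool)
        if len(sp) > 1:
            gaps = np.diff(sp) <= isolation_dist
            close_next[:-1] |= gaps
            close_next[1:] |= gaps
        bad_idx = grp.index.to_numpy()[order[close_next]]
        keep.loc[bad_idx] = False
    return tss.loc[keep].copy()


def _peaks_in_window(peaks: pd.DataFrame, chrom: str, lo: int, hi: int,
                     strand: str | None) -> pd.DataFrame:
    """Peaks overlapping the closed window [lo, hi] on ``chrom`` (peaks
    are half-open intervals); optionally restricted to one strand."""
    sel = peaks["chrom"] == chrom
    if strand is not None and "strand" in peaks.columns:
        sel &= peaks["strand"] == strand
    sub = peaks.loc[sel]
    return sub.loc[(sub["start"] <= hi) & (sub["end"] > lo)]


def call_activity(tss_pos: int, chrom: str, robust: pd.DataFrame,
                  permissive: pd.DataFrame, activity_window: int = 500,
                  strand: str | None = None) -> str:
    """Activity status of a single TSS from tiered CAGE peak sets."""
    lo, hi = tss_pos - activity_window, tss_pos + activity_window
    rob = _peaks_in_window(robust, chrom, lo, hi, strand)
    per = _peaks_in_window(permissive, chrom, lo, hi, strand)
    if len(rob) > 0:
        if len(per) == 0:
            raise ValueError(
                "robust peak without a permissive counterpart in window; "
                "tiers must be nested (robust subset of permissive)")
        return ACTIVE
    if len(per) == 0:
        return INACTIVE
    return LOW


def call_region_activity(start: int, end: int, chrom: str, strand: str,
                         robust: pd.DataFrame, permissive: pd.DataFrame,
                         activity_window: int = 500) -> str:
    """Strand-specific activity of a TSS-cluster region extended by
    ``activity_window`` bp on each side."""
    lo, hi = start - activity_window, end + activity_window
    rob = _peaks_in_window(robust, chrom, lo, hi, strand)
    per = _peaks_in_window(permissive, chrom, lo, hi, strand)
    if len(rob) > 0:
        if len(per) == 0:
            raise ValueError("robust peak without permissive counterpart")
        return ACTIVE
    return INACTIVE if len(per) == 0 else LOW


def cluster_cage_tss(tss: pd.DataFrame,
                     robust: pd.DataFrame | None = None,
                     permissive: pd.DataFrame | None = None,
                     merge_gap: int = 200, max_span: int = 1000,
                     activity_window: int = 500) -> list[TSSCluster]:
    """Single-linkage chaining of CAGE TSSs into promoter clusters.

    Consecutive TSSs (per chromosome, any strand) with a gap strictly
    below ``merge_gap`` join one cluster.  Clusters spanning more than
    ``max_span`` bp, containing TSSs on both strands, or containing
    TSSs of more than one annotated gene are marked excluded with a
    reason.  When tiered CAGE peak sets are supplied, retained clusters
    get an activity status on their ±``activity_window`` extended span,
    strand specifically.
    """
    clusters: list[TSSCluster] = []
    for chrom, grp in tss.groupby("chrom", sort=True):
        grp = grp.sort_values("pos", kind="stable")
        pos = grp["pos"].to_numpy()
        breaks = np.where(np.diff(pos) >= merge_gap)[0]
        bounds = np.concatenate(([0], breaks + 1, [len(pos)]))
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            members = grp.iloc[lo:hi]
            start = int(members["pos"].min())
            end = int(members["pos"].max())
            strands = set(members["strand"])
            genes = set(members["gene_id"].dropna())
            n_missing = members["gene_id"].isna().sum()
            cl = TSSCluster(chrom=str(chrom), start=start, end=end,
                            strand=members["strand"].iloc[0],
                            gene_id=next(iter(genes)) if len(genes) == 1 else "",
                            members=members)
            if end - start > max_span:
                cl.status, cl.exclusion_reason = "excluded", "span>1000"
            elif len(strands) > 1:
                cl.status, cl.exclusion_reason = "excluded", "mixed_strand"
            elif len(genes) > 1:
                cl.status, cl.exclusion_reason = "excluded", "multi_gene"
            elif n_missing > 0 or len(genes) == 0:
                cl.status, cl.exclusion_reason = ("excluded",
                                                  "multi_gene_unresolvable")
            elif robust is not None and permissive is not None:
                cl.status = call_region_activity(
                    start, end, str(chrom), cl.strand, robust, permissive,
                    activity_window)
            else:
                cl.status = "retained"
            clusters.append(cl)
    return clusters


def drop_intergenic_inactive(tss: pd.DataFrame, statuses: pd.Series,
                             gene_spans: pd.DataFrame) -> pd.Series:
    """Mask selecting TSSs to keep: inactive TSSs not overlapping any
    annotated gene span (intergenic) are dropped; others kept."""
    keep = pd.Series(True, index=tss.index)
    for idx, row in tss.iterrows():
        if statuses.loc[idx] != INACTIVE:
            continue
        g = gene_spans.loc[gene_spans["chrom"] == row["chrom"]]
        inside = ((g["start"] <= row["pos"]) & (g["end"] > row["pos"])).any()
        if not inside:
            keep.loc[idx] = False
    return keep


def reduce_inactive(matrix: SignalMatrix, statuses: dict[str, str],
                    cluster_of: dict[str, str] | None = None) -> SignalMatrix:
    """Drop all-zero *inactive* columns; within a TSS cluster, collapse
    columns with identical signal across all experiments to the first
    (by coordinate = input order)."""
    keep: list[int] = []
    seen: dict[tuple, int] = {}
    for j, cid in enumerate(matrix.col_ids):
        col = matrix.values[:, j]
        if statuses.get(cid) == INACTIVE and not col.any():
            continue
        if cluster_of is not None and cid in cluster_of:
            key = (cluster_of[cid], col.tobytes())
            if key in seen:
                continue
            seen[key] = j
        keep.append(j)
    meta = matrix.col_meta
    return SignalMatrix(matrix.values[:, keep], matrix.row_ids,
                        [matrix.col_ids[j] for j in keep],
                        meta.iloc[keep] if meta is not None else None)


def clusters_to_frame(clusters: list[TSSCluster]) -> pd.DataFrame:
    """Flat promoter table (one row per cluster) for TSV export."""
    return pd.DataFrame([
        dict(chrom=c.chrom, start=c.start, end=c.end, strand=c.strand,
             gene=c.gene_id, n_tss=len(c.members), status=c.status,
             exclusion_reason=c.exclusion_reason or "")
        for c in clusters
    ])
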