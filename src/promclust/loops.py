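"""Promoter-anchored chromatin loop analysis.

Loops (paired genomic anchors from CTCF ChIA-PET) with one anchor on a
promoter region are collected; the other anchor is the *remote region*
(putative enhancer side).  When several loops touch one promoter, the
loop with the highest H3K27ac signal over its remote anchor is chosen.
The remote region, padded by 500 bp on each side, is classified by
overlap with enhancer segmentation states (strong takes precedence over
weak), and re-centered on the position of maximum CTCF coverage,
extended ±1 Kbp, for coverage-profile display.

Intervals are 0-based half-open; overlap means >= 1 shared bp.
Coverage tracks are per-chromosome per-base arrays (dict chrom ->
numpy array).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Interval", "Loop", "RemoteRegion", "promoter_loops", "select_loop",
    "enhancer_class", "center_remote", "loop_report",
]


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("interval start must be < end")

    def overlap(self, other: "Interval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class Loop:
    anchor_a: Interval
    anchor_b: Interval
    id: str = ""


@dataclass
class RemoteRegion:
    interval: Interval
    loop_id: str
    h3k27ac_signal: float = float("nan")
    enhancer_class: str = "none"
    center: int | None = None
    center_flagged: bool = False   # True when coverage was flat zero


def read_bedpe(path) -> list[Loop]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom1", "start1", "end1",
                            "chrom2", "start2", "end2", "name"])
    return [Loop(Interval(r.chrom1, r.start1, r.end1),
                 Interval(r.chrom2, r.start2, r.end2), str(r.name))
            for r in df.itertuples()]


def promoter_loops(promoter: Interval,
                   loops: list[Loop]) -> list[tuple[Loop, Interval]]:
    """Loops with an anchor overlapping the promoter region; each is
    returned with its remote (non-promoter) anchor.  If both anchors
    overlap, the anchor with the larger overlap is the promoter side
    (ties: anchor A)."""
    out = []
    for lp in loops:
        ova = lp.anchor_a.overlap(promoter)
        ovb = lp.anchor_b.overlap(promoter)
        if ova == 0 and ovb == 0:
            continue
        remote = lp.anchor_b if ova >= ovb else lp.anchor_a
        out.append((lp, remote))
    return out


def _mean_coverage(track: dict[str, np.ndarray], iv: Interval) -> float:
    cov = track.get(iv.chrom)
    if cov is None:
        return 0.0
    lo = max(iv.start, 0)
    hi = min(iv.end, len(cov))
    if hi <= lo:
        return 0.0
    return float(cov[lo:hi].mean())


def _max_coverage(track: dict[str, np.ndarray], iv: Interval) -> float:
    cov = track.get(iv.chrom)
    if cov is None:
        return 0.0
    lo, hi = max(iv.start, 0), min(iv.end, len(cov))
    return float(cov[lo:hi].max()) if hi > lo else 0.0


def select_loop(candidates: list[tuple[Loop, Interval]],
                h3k27ac: dict[str, np.ndarray],
                summary: str = "mean") -> tuple[Loop, Interval]:
    """The loop whose remote anchor carries the highest H3K27ac signal
    (summary 'mean' over the anchor, switchable to 'max'); ties broken
    by leftmost remote start."""
    if not candidates:
        raise ValueError("no candidate loops")
    agg = _mean_coverage if summary == "mean" else _max_coverage
    scored = [(agg(h3k27ac, remote), remote.start, i)
              for i, (_, remote) in enumerate(candidates)]
    scored.sort(key=lambda t: (-t[0], t[1]))
    return candidates[scored[0][2]]


def enhancer_class(remote: Interval, enhancers: pd.DataFrame,
                   pad: int = 500) -> str:
    """'strong' | 'weak' | 'none' by >=1 bp overlap of the padded remote
    region with enhancer segments; strong takes precedence."""
    if pad < 0:
        raise ValueError("pad must be non-negative")
    lo, hi = remote.start - pad, remote.end + pad
    sel = enhancers.loc[(enhancers["chrom"] == remote.chrom) &
                        (enhancers["start"] < hi) & (enhancers["end"] > lo)]
    states = set(sel["state"])
    if "strong" in states:
        return "strong"
    if "weak" in states:
        return "weak"
    return "none"


def center_remote(remote: Interval, ctcf: dict[str, np.ndarray],
                  flank: int = 1000) -> tuple[Interval, bool]:
    """Re-center the remote region on its maximum CTCF coverage position
    (ties: leftmost) and extend ±``flank``; returns (interval, flagged)
    with ``flagged`` True when coverage was zero everywhere (geometric
    midpoint used instead)."""
    cov = ctcf.get(remote.chrom)
    lo, hi = remote.start, remote.end
    flagged = False
    if cov is None or min(hi, len(cov)) <= lo or not cov[lo:min(hi, len(cov))].any():
        center = (lo + hi) // 2
        flagged = True
    else:
        window = cov[lo:min(hi, len(cov))]
        center = lo + int(np.argmax(window))
    return Interval(remote.chrom, center - flank, center + flank), flagged


def loop_report(promoters: dict[str, Interval], loops: list[Loop],
                h3k27ac: dict[str, np.ndarray],
                ctcf: dict[str, np.ndarray],
                enhancers: pd.DataFrame, pad: int = 500,
                flank: int = 1000,
                summary: str = "mean") -> tuple[pd.DataFrame, dict]:
    """Per-promoter loop selection, enhancer class and re-centered
    window, plus the aggregate proportions (fraction of promoters with
    a loop; strong/weak/none mix among the looped) shown in the
    published bar plots."""
    rows = []
    for pid, region in promoters.items():
        cand = promoter_loops(region, loops)
        if not cand:
            rows.append(dict(promoter=pid, loop_id="", has_loop=False,
                             enhancer_class="", remote_start=-1,
                             remote_end=-1, center_start=-1, center_end=-1,
                             center_flagged=False))
            continue
        lp, remote = select_loop(cand, h3k27ac, summary)
        cls = enhancer_class(remote, enhancers, pad)
        centered, flagged = center_remote(remote, ctcf, flank)
        rows.append(dict(promoter=pid, loop_id=lp.id, has_loop=True,
                         enhancer_class=cls, remote_start=remote.start,
                         remote_end=remote.end,
                         center_start=centered.start,
                         center_end=centered.end, center_flagged=flagged))
    report = pd.DataFrame(rows)
    looped = report.loc[report["has_loop"]]
    n = len(report)
    props = {
        "fraction_looped": len(looped) / n if n else 0.0,
        "fraction_strong": float((looped["enhancer_class"] == "strong").mean())
        if len(looped) else 0.0,
        "fraction_weak": float((looped["enhancer_class"] == "weak").mean())
        if len(looped) else 0.0,
        "fraction_none": float((looped["enhancer_class"] == "none").mean())
        if len(looped) else 0.0,
    }
    return report, props
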