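"""Synthetic inputs with known ground truth.

Real inputs of the pipeline are ENCODE ChIP-seq peak calls, RefSeq TSS
annotations, FANTOM CAGE peak tiers, ChIA-PET loops and ChromHMM
enhancer segmentations.  This module generates statistically analogous
stand-ins so every downstream stage can be exercised and checked
against a recorded ground truth:

* ``make_planted_matrix`` — a promoters x experiments occupancy matrix
  with disjoint planted biclusters over sparse background (peak-call
  matrices are mostly exact zeros);
* ``make_toy_genome`` — TSS annotations plus tiered CAGE peaks arranged
  so that every promoter-definition rule (1 Kbp isolation, 200 bp
  chaining, span/strand/gene exclusions, robust/permissive activity
  tiers) fires at least once;
* ``make_expression`` — expression linearly driven by a known subset of
  experiments;
* ``make_loops`` — promoter-anchored loops whose remote anchors carry
  enhancer segments and coverage tracks with known class and argmax.

One seed fans out into independent substreams per generator, so adding
a generator never perturbs the others.  Fixed seed implies bit-identical
output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .loops import Interval, Loop
from .signal import SignalMatrix

__all__ = [
    "SyntheticConfig", "GroundTruth", "ToyGenome", "LoopFixture",
    "make_planted_matrix", "make_toy_genome", "make_expression",
    "make_loops",
    "write_bed6", "write_peaks", "write_bedpe", "write_expression_tsv",
    "write_truth_json",
]

BACKGROUND = "background"


@dataclass
class SyntheticConfig:
    """Planted-bicluster matrix layout.

    Defaults are the reference simulation conditions used throughout
    the test suite: a 30 x 300 matrix with three planted blocks of
    unequal shape (real promoter clusters are very unequal in size),
    full signal 1.0, Gaussian noise (sd 0.2, clipped back into [0, 1])
    and a 2% rate of spurious background peaks.
    """

    n_promoters: int = 300
    n_experiments: int = 30
    blocks: tuple[tuple[int, int, float], ...] = (
        (8, 120, 1.0), (7, 90, 1.0), (6, 60, 1.0))
    noise_sd: float = 0.2
    background_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.background_rate <= 1:
            raise ValueError("background_rate must be in [0, 1]")
        r = sum(b[0] for b in self.blocks)
        c = sum(b[1] for b in self.blocks)
        if r > self.n_experiments or c > self.n_promoters:
            raise ValueError("blocks exceed matrix dimensions")
        for _, _, s in self.blocks:
            if not 0 < s <= 1:
                raise ValueError("block mean_signal must be in (0, 1]")


@dataclass
class GroundTruth:
    """What the generators planted, for checking recovery."""

    column_labels: list = field(default_factory=list)
    row_labels: list = field(default_factory=list)
    true_predictors: tuple[int, ...] = ()
    true_weights: tuple[float, ...] = ()
    loop_truth: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), default=str)


def make_planted_matrix(config: SyntheticConfig) -> tuple[SignalMatrix, GroundTruth]:
    """Matrix with disjoint planted biclusters on disjoint row/column
    blocks; background cells are 0 with probability
    1 - background_rate, else a small positive spurious peak height."""
    ss = np.random.SeedSequence(config.seed)
    rng_block, rng_bg = (np.random.default_rng(s) for s in ss.spawn(2))
    m, n = config.n_experiments, config.n_promoters
    values = np.zeros((m, n))
    col_labels: list = [BACKGROUND] * n
    row_labels: list = [BACKGROUND] * m
    r0 = c0 = 0
    block_mask = np.zeros((m, n), dtype=bool)
    for k, (nr, nc, mean_signal) in enumerate(config.blocks):
        rows = slice(r0, r0 + nr)
        cols = slice(c0, c0 + nc)
        noise = rng_block.normal(0.0, config.noise_sd, size=(nr, nc)) \
            if config.noise_sd > 0 else 0.0
        values[rows, cols] = np.clip(mean_signal + noise, 0.0, 1.0)
        block_mask[rows, cols] = True
        for i in range(r0, r0 + nr):
            row_labels[i] = k
        for j in range(c0, c0 + nc):
            col_labels[j] = k
        r0 += nr
        c0 += nc
    if config.background_rate > 0:
        spurious = rng_bg.random((m, n)) < config.background_rate
        spurious &= ~block_mask
        values[spurious] = rng_bg.uniform(0.01, 0.2, size=int(spurious.sum()))
    matrix = SignalMatrix(values,
                          [f"exp_{i:03d}" for i in range(m)],
                          [f"prom_{j:04d}" for j in range(n)])
    return matrix, GroundTruth(column_labels=col_labels, row_labels=row_labels)


# ---------------------------------------------------------------------------
# toy genome


@dataclass
class ToyGenome:
    tss: pd.DataFrame                    # chrom, pos, strand, gene_id, name
    robust: pd.DataFrame                 # chrom, start, end, strand
    permissive: pd.DataFrame
    peak_sets: dict[str, pd.DataFrame]   # experiment -> peak table
    truth: dict = field(default_factory=dict)


_SCENARIOS = ("active", "low", "inactive", "iso_pair", "cage_cluster",
              "mixed_strand", "multi_gene", "long_chain")
_GENE_SPACING = 100_000


def make_toy_genome(n_genes: int = 16, seed: int = 0) -> ToyGenome:
    """Toy TSS annotation cycling through scenario types so that every
    promoter-definition rule fires at least once (for n_genes >= 8).

    Recorded ground truth: per-TSS activity label and RefSeq-isolation
    retention, per-scenario expected CAGE-cluster status/exclusion.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    tss_rows, rob_rows, perm_rows = [], [], []
    peak_rows: dict[str, list] = {"chip_active": [], "chip_broad": []}
    activity: dict[str, str] = {}
    refseq_retained: dict[str, bool] = {}
    cluster_truth: dict[str, dict] = {}
    chrom = "chrS"
    tid = 0

    def add_tss(pos, strand, gene):
        nonlocal tid
        name = f"tss_{tid:04d}"
        tid += 1
        tss_rows.append(dict(chrom=chrom, pos=pos, strand=strand,
                             gene_id=gene, name=name))
        return name

    def add_cage(pos, strand, tier):
        rec = dict(chrom=chrom, start=pos, end=pos + 20, strand=strand)
        perm_rows.append(rec)
        if tier == "robust":
            rob_rows.append(dict(rec))

    for g in range(n_genes):
        base = 50_000 + g * _GENE_SPACING
        kind = _SCENARIOS[g % len(_SCENARIOS)]
        gene = f"gene_{g:03d}"
        if kind == "active":
            name = add_tss(base, "+", gene)
            add_cage(base + 100, "+", "robust")
            activity[name] = "active"
            refseq_retained[name] = True
            # a called ChIP peak right on the promoter
            peak_rows["chip_active"].append(dict(
                chrom=chrom, start=base - 150, end=base + 150,
                summit_offset=150, height=float(10 + rng.integers(1, 40))))
            cluster_truth[gene] = dict(status="active", reason="")
        elif kind == "low":
            name = add_tss(base, "+", gene)
            add_cage(base - 50, "+", "permissive")
            activity[name] = "low"
            refseq_retained[name] = True
            cluster_truth[gene] = dict(status="low", reason="")
        elif kind == "inactive":
            name = add_tss(base, "-", gene)
            activity[name] = "inactive"
            refseq_retained[name] = True
            cluster_truth[gene] = dict(status="inactive", reason="")
        elif kind == "iso_pair":
            # two TSSs 800 bp apart: both dropped by the 1 Kbp isolation
            # rule; too far apart (>= 200 bp) to chain into one CAGE cluster
            n1 = add_tss(base, "+", gene)
            n2 = add_tss(base + 800, "+", gene)
            for nm in (n1, n2):
                activity[nm] = "inactive"
                refseq_retained[nm] = False
            cluster_truth[gene] = dict(status="inactive", reason="")
        elif kind == "cage_cluster":
            # three TSSs chained at 150 bp gaps into one retained cluster
            for off in (0, 150, 300):
                nm = add_tss(base + off, "+", gene)
                activity[nm] = "active"
                refseq_retained[nm] = False
            add_cage(base + 150, "+", "robust")
            peak_rows["chip_broad"].append(dict(
                chrom=chrom, start=base - 200, end=base + 500,
                summit_offset=350, height=float(15 + rng.integers(1, 30))))
            cluster_truth[gene] = dict(status="active", reason="")
        elif kind == "mixed_strand":
            n1 = add_tss(base, "+", gene)
            n2 = add_tss(base + 150, "-", gene)
            for nm in (n1, n2):
                activity[nm] = "inactive"
                refseq_retained[nm] = False
            cluster_truth[gene] = dict(status="excluded",
                                       reason="mixed_strand")
        elif kind == "multi_gene":
            n1 = add_tss(base, "+", gene)
            n2 = add_tss(base + 150, "+", gene + "b")
            for nm in (n1, n2):
                activity[nm] = "inactive"
                refseq_retained[nm] = False
            cluster_truth[gene] = dict(status="excluded", reason="multi_gene")
        elif kind == "long_chain":
            # 7 TSSs at 190 bp gaps: chained (gap < 200) but span 1140
            for j in range(7):
                nm = add_tss(base + j * 190, "+", gene)
                activity[nm] = "inactive"
                refseq_retained[nm] = False
            cluster_truth[gene] = dict(status="excluded", reason="span>1000")
    tss = pd.DataFrame(tss_rows)
    robust = pd.DataFrame(rob_rows, columns=["chrom", "start", "end", "strand"])
    permissive = pd.DataFrame(perm_rows,
                              columns=["chrom", "start", "end", "strand"])
    peak_sets = {}
    for exp, rows in peak_rows.items():
        df = pd.DataFrame(rows, columns=["chrom", "start", "end",
                                         "summit_offset", "height"])
        df["summit"] = df["start"] + df["summit_offset"]
        peak_sets[exp] = df
    truth = dict(activity=activity, refseq_retained=refseq_retained,
                 clusters=cluster_truth)
    return ToyGenome(tss, robust, permissive, peak_sets, truth)


# ---------------------------------------------------------------------------
# expression


def make_expression(matrix: SignalMatrix, true_predictors,
                    weights, noise_sd: float = 0.1,
                    seed: int = 0) -> tuple[np.ndarray, GroundTruth]:
    """Expression vector linearly driven by a known subset of rows:
    expression[j] = sum_i w_i * matrix[i, j] + N(0, noise_sd^2)."""
    preds = tuple(int(i) for i in true_predictors)
    w = tuple(float(v) for v in weights)
    if len(preds) != len(w):
        raise ValueError("weight count must equal predictor count")
    if preds and (min(preds) < 0 or max(preds) >= matrix.values.shape[0]):
        raise ValueError("predictor index out of range")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    expr = np.zeros(matrix.values.shape[1])
    for i, wi in zip(preds, w):
        expr += wi * matrix.values[i]
    if noise_sd > 0:
        expr = expr + rng.normal(0.0, noise_sd, size=expr.size)
    return expr, GroundTruth(true_predictors=preds, true_weights=w)


# ---------------------------------------------------------------------------
# loops


@dataclass
class LoopFixture:
    loops: list[Loop]
    enhancers: pd.DataFrame              # chrom, start, end, state
    h3k27ac: dict[str, np.ndarray]
    ctcf: dict[str, np.ndarray]
    promoters: dict[str, Interval]
    truth: GroundTruth


#: default enhancer-class mix at remote anchors: the strong/weak/none
#: proportions observed for promoters of the active CTCF cluster
#: (65.04% strong, 91.11% strong-or-weak).
DEFAULT_ENHANCER_FRACTION = (0.6504, 0.2607, 0.0889)

_REMOTE_WIDTH = 2000
_REMOTE_SPACING = 10_000


def make_loops(promoters: dict[str, Interval], n_loops: int,
               enhancer_fraction: tuple[float, float, float] = DEFAULT_ENHANCER_FRACTION,
               seed: int = 0) -> LoopFixture:
    """Loops anchored on the given promoters.

    Each loop's anchor A is a promoter region (promoters are cycled, so
    with n_loops > len(promoters) some promoters gain several loops);
    the remote anchor B lies in a dedicated distal range.  Remote
    anchors carry a 'strong' enhancer, only a 'weak' enhancer, or no
    enhancer, drawn per ``enhancer_fraction``; H3K27ac levels are
    distinct per promoter's loops so the max-signal loop is unambiguous,
    and CTCF coverage has a single known argmax per remote anchor.
    """
    if n_loops < 1:
        raise ValueError("n_loops must be >= 1")
    if not promoters:
        raise ValueError("empty promoter list")
    fr = np.asarray(enhancer_fraction, dtype=float)
    if fr.min() < 0 or abs(fr.sum() - 1.0) > 1e-6:
        raise ValueError("enhancer_fraction must be non-negative and sum to 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    pids = list(promoters)
    chrom = next(iter(promoters.values())).chrom
    remote_base = max(iv.end for iv in promoters.values()) + 100_000
    genome_len = remote_base + n_loops * _REMOTE_SPACING + 10_000
    h3k = np.zeros(genome_len)
    ctcf = np.zeros(genome_len)
    loops: list[Loop] = []
    enh_rows = []
    classes = rng.choice(3, size=n_loops, p=fr)
    per_prom: dict[str, list[int]] = {p: [] for p in pids}
    loop_class: dict[str, str] = {}
    remote_center: dict[str, int] = {}
    class_names = ("strong", "weak", "none")
    for i in range(n_loops):
        pid = pids[i % len(pids)]
        prom = promoters[pid]
        rstart = remote_base + i * _REMOTE_SPACING
        rend = rstart + _REMOTE_WIDTH
        lid = f"loop_{i:04d}"
        loops.append(Loop(Interval(chrom, prom.start, prom.end),
                          Interval(chrom, rstart, rend), lid))
        cls = class_names[classes[i]]
        loop_class[lid] = cls
        if cls == "strong":
            if i % 2 == 0:  # segment inside the remote anchor
                enh_rows.append(dict(chrom=chrom, start=rstart + 400,
                                     end=rstart + 700, state="strong"))
            else:           # segment reachable only through the 500 bp pad
                enh_rows.append(dict(chrom=chrom, start=rend + 300,
                                     end=rend + 600, state="strong"))
                # a weak segment too: strong must win the precedence
                enh_rows.append(dict(chrom=chrom, start=rstart + 100,
                                     end=rstart + 300, state="weak"))
        elif cls == "weak":
            enh_rows.append(dict(chrom=chrom, start=rstart + 400,
                                 end=rstart + 700, state="weak"))
        # H3K27ac level: distinct within each promoter's loop list
        level = 1.0 + 2.0 * len(per_prom[pid])
        h3k[rstart:rend] = level
        per_prom[pid].append(i)
        # CTCF: single triangular peak at a known position
        apex = rstart + 200 + (i * 137) % (_REMOTE_WIDTH - 400)
        span = 150
        xs = np.arange(apex - span, apex + span + 1)
        ctcf[xs] = np.maximum(ctcf[xs], span - np.abs(xs - apex))
        remote_center[lid] = int(apex)
    # ground-truth selection: the last loop added per promoter has the
    # highest H3K27ac level by construction
    selected = {pid: f"loop_{idxs[-1]:04d}" for pid, idxs in per_prom.items()
                if idxs}
    truth = GroundTruth(loop_truth=dict(
        loop_class=loop_class, selected_loop=selected,
        remote_center=remote_center))
    enhancers = pd.DataFrame(enh_rows,
                             columns=["chrom", "start", "end", "state"])
    return LoopFixture(loops, enhancers, {chrom: h3k}, {chrom: ctcf},
                       dict(promoters), truth)


# ---------------------------------------------------------------------------
# fixture writers (plain-text formats consumed downstream)


def write_bed6(df: pd.DataFrame, path, name_col: str = "name",
               score: int = 0) -> None:
    """BED6 writer for TSS tables (pos -> single-bp interval) and
    enhancer segments."""
    out = pd.DataFrame({
        "chrom": df["chrom"],
        "start": df["pos"] if "pos" in df.columns else df["start"],
        "end": (df["pos"] + 1) if "pos" in df.columns else df["end"],
        "name": df[name_col] if name_col in df.columns else ".",
        "score": score,
        "strand": df["strand"] if "strand" in df.columns else ".",
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def write_peaks(df: pd.DataFrame, path) -> None:
    df[["chrom", "start", "end", "summit_offset", "height"]].to_csv(
        path, sep="\t", header=False, index=False)


def write_bedpe(loops: list[Loop], path) -> None:
    rows = [(l.anchor_a.chrom, l.anchor_a.start, l.anchor_a.end,
             l.anchor_b.chrom, l.anchor_b.start, l.anchor_b.end, l.id)
            for l in loops]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_expression_tsv(ids: list[str], expr: np.ndarray, path) -> None:
    pd.DataFrame({"promoter": ids, "expression": expr}).to_csv(
        path, sep="\t", index=False)


def write_truth_json(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write(truth.to_json())
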