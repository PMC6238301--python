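"""Robust consensus biclustering.

The base engines are randomized: different runs give somewhat different
biclusters.  The consensus procedure turns this into a robustness
device:

1. run the base engine many times with distinct derived seeds;
2. the run with the most column clusters is the *target clustering*
   (ties broken randomly, seeded);
3. every other run's clusters are matched one-to-one to the target
   clusters by solving a linear assignment problem (LAP) on the
   confusion matrix of the two cluster systems, maximizing total
   column overlap;
4. per column, the frequency of being mapped into each target cluster
   is tallied over all runs; columns whose best frequency exceeds
   ``min_freq`` (default 0.5 — more than half the runs agree) are
   retained with that cluster;
5. rows are retained analogously via the row sides of the matched
   biclusters;
6. for every retained row and column cluster a Welch t-test compares
   the row's values inside the cluster's columns against the values
   outside; the -log10 p values are the bar heights drawn next to the
   heatmap.

``order_heatmap`` produces the row/column permutation used for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from . import bicluster as _bc
from .bicluster import BiclusterSolution, SSVDParams
from .signal import SignalMatrix
from .stats import neglog10p, welch_t

__all__ = [
    "ClusterMapping", "ConsensusSolution", "confusion_matrix",
    "assign_clusters", "consensus_biclust", "row_cluster_ttest",
    "order_heatmap",
]


@dataclass
class ClusterMapping:
    """Injective partial map of source clusters onto target clusters."""

    assignment: dict[int, int]
    total_overlap: int


@dataclass
class ConsensusSolution:
    target: BiclusterSolution | None
    column_frequency: np.ndarray   # n_cols x n_target_clusters, values in [0,1]
    row_frequency: np.ndarray      # n_rows x n_target_clusters
    retained_cols: dict[int, int]  # column index -> target cluster
    retained_rows: dict[int, int]  # row index -> target cluster
    row_tests: pd.DataFrame | None
    n_runs: int
    seed: int
    min_freq: float = 0.5
    runs: list[BiclusterSolution] = field(default_factory=list, repr=False)

    @property
    def n_clusters(self) -> int:
        return 0 if self.target is None else self.target.n_clusters

    def cluster_columns(self, k: int) -> list[int]:
        return sorted(c for c, kk in self.retained_cols.items() if kk == k)

    def cluster_rows(self, k: int) -> list[int]:
        return sorted(r for r, kk in self.retained_rows.items() if kk == k)

    def to_dict(self) -> dict:
        """JSON-ready summary: target clusters, retained sets,
        frequencies and row tests."""
        return {
            "n_runs": self.n_runs, "seed": self.seed,
            "min_freq": self.min_freq,
            "target": None if self.target is None else self.target.to_dict(),
            "retained_cols": {str(j): k for j, k in self.retained_cols.items()},
            "retained_rows": {str(i): k for i, k in self.retained_rows.items()},
            "column_frequency": self.column_frequency.tolist(),
            "row_tests": (None if self.row_tests is None
                          else self.row_tests.to_dict(orient="records")),
        }


def confusion_matrix(sol_a: BiclusterSolution,
                     sol_b: BiclusterSolution) -> np.ndarray:
    """Counts grid: entry (a, b) = number of columns in cluster a of
    ``sol_a`` and cluster b of ``sol_b``; unassigned columns count
    nowhere."""
    if sol_a.n_cols != sol_b.n_cols:
        raise ValueError("solutions are over different column universes")
    counts = np.zeros((sol_a.n_clusters, sol_b.n_clusters), dtype=int)
    for a, bca in enumerate(sol_a.biclusters):
        sa = set(bca.cols)
        for b, bcb in enumerate(sol_b.biclusters):
            counts[a, b] = len(sa.intersection(bcb.cols))
    return counts


def assign_clusters(confusion: np.ndarray) -> ClusterMapping:
    """Maximum-total-overlap one-to-one assignment of source (rows of
    the confusion grid) to target clusters, by LAP on negated counts.

    Rectangular grids are zero-padded to square; assignments landing on
    padding are dropped, so surplus source clusters stay unmapped.
    """
    confusion = np.asarray(confusion)
    if confusion.size == 0:
        return ClusterMapping({}, 0)
    if (confusion < 0).any():
        raise ValueError("confusion counts must be non-negative")
    ns, nt = confusion.shape
    dim = max(ns, nt)
    padded = np.zeros((dim, dim), dtype=float)
    padded[:ns, :nt] = confusion
    rows, cols = linear_sum_assignment(-padded)
    assignment = {int(r): int(c) for r, c in zip(rows, cols)
                  if r < ns and c < nt}
    total = int(sum(confusion[r, c] for r, c in assignment.items()))
    return ClusterMapping(assignment, total)


def _run_engine(matrix, engine: str, seed: int, engine_kwargs: dict):
    if engine == "ssvd":
        return _bc.run_ssvd(matrix, seed=seed, **engine_kwargs)
    if engine in ("kmeans", "kmeans_ttest"):
        kw = dict(engine_kwargs)
        k = kw.pop("k", None)
        if k is None:
            k = _bc.choose_k(matrix, kw.pop("k_range", (2, 8)), seed=seed)
        return _bc.kmeans_biclust(matrix, k=k, seed=seed, **kw)
    if callable(engine):
        return engine(matrix, seed=seed, **engine_kwargs)
    raise ValueError(f"unknown engine {engine!r}")


def consensus_biclust(matrix, engine: str = "ssvd", n_runs: int = 20,
                      min_freq: float = 0.5, seed: int = 0,
                      engine_kwargs: dict | None = None,
                      compute_row_tests: bool = True) -> ConsensusSolution:
    """Run the full consensus procedure (steps 1-6 above)."""
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    x = matrix.values if isinstance(matrix, SignalMatrix) else np.asarray(matrix, float)
    engine_kwargs = engine_kwargs or {}
    ss = np.random.SeedSequence(seed)
    run_seeds = [int(s) for s in ss.generate_state(n_runs) >> 1]  # < 2**31
    tie_rng = np.random.default_rng(ss.spawn(1)[0])
    runs = [_run_engine(x, engine, s, engine_kwargs) for s in run_seeds]

    sizes = np.array([r.n_clusters for r in runs])
    if sizes.max() == 0:
        m, n = x.shape
        return ConsensusSolution(None, np.zeros((n, 0)), np.zeros((m, 0)),
                                 {}, {}, None, n_runs, seed, min_freq, runs)
    best = np.flatnonzero(sizes == sizes.max())
    target_idx = int(best[tie_rng.integers(len(best))]) if len(best) > 1 else int(best[0])
    target = runs[target_idx]

    m, n = x.shape
    kt = target.n_clusters
    col_counts = np.zeros((n, kt))
    row_counts = np.zeros((m, kt))
    for r_i, run in enumerate(runs):
        if r_i == target_idx:
            mapping = {k: k for k in range(kt)}
        else:
            mapping = assign_clusters(confusion_matrix(run, target)).assignment
        for src, tgt in mapping.items():
            bc = run.biclusters[src]
            col_counts[list(bc.cols), tgt] += 1
            row_counts[list(bc.rows), tgt] += 1
    col_freq = col_counts / n_runs
    row_freq = row_counts / n_runs

    retained_cols = {
        int(j): int(np.argmax(col_freq[j]))
        for j in range(n) if col_freq[j].max() > min_freq
    }
    retained_rows = {
        int(i): int(np.argmax(row_freq[i]))
        for i in range(m) if row_freq[i].max() > min_freq
    }

    row_tests = None
    if compute_row_tests and retained_rows and retained_cols:
        records = []
        for k in range(kt):
            cols_k = [j for j, kk in retained_cols.items() if kk == k]
            if len(cols_k) < 2 or len(cols_k) > n - 2:
                continue  # t-test needs >= 2 columns on each side
            inside = np.zeros(n, dtype=bool)
            inside[cols_k] = True
            for i in sorted(retained_rows):
                t, p = welch_t(x[i, inside], x[i, ~inside])
                records.append(dict(row=i, cluster=k, t=t, p=p,
                                    neglog10p=neglog10p(p)))
        row_tests = pd.DataFrame(records) if records else None

    return ConsensusSolution(target, col_freq, row_freq, retained_cols,
                             retained_rows, row_tests, n_runs, seed,
                             min_freq, runs)


def row_cluster_ttest(matrix, col_cluster, row: int) -> tuple[float, float, float]:
    """Welch t-test of one row's values inside a column cluster vs
    outside; returns ``(t, p, -log10 p)``."""
    x = matrix.values if isinstance(matrix, SignalMatrix) else np.asarray(matrix, float)
    n = x.shape[1]
    inside = np.zeros(n, dtype=bool)
    inside[list(col_cluster)] = True
    if not inside.any() or inside.all():
        raise ValueError("column cluster must be a non-empty proper subset")
    t, p = welch_t(x[row, inside], x[row, ~inside])
    return t, p, neglog10p(p)


def order_heatmap(matrix, consensus: ConsensusSolution):
    """Row/column display order for the consensus heatmap.

    Columns are grouped by assigned cluster (clusters by retained size,
    descending), within a cluster by column mean signal descending;
    rows analogously by associated cluster and row mean.  Unassigned
    columns/rows are appended last.  Returns ``(row_order, col_order,
    col_boundaries, row_boundaries)`` with boundaries as cumulative
    group sizes for plotting separators.
    """
    x = matrix.values if isinstance(matrix, SignalMatrix) else np.asarray(matrix, float)
    m, n = x.shape
    if consensus.n_clusters == 0:
        return list(range(m)), list(range(n)), [], []
    kt = consensus.n_clusters
    sizes = [len(consensus.cluster_columns(k)) for k in range(kt)]
    cluster_order = sorted(range(kt), key=lambda k: (-sizes[k], k))

    col_mean = x.mean(axis=0)
    row_mean = x.mean(axis=1)
    col_order: list[int] = []
    col_bounds: list[int] = []
    for k in cluster_order:
        cols = consensus.cluster_columns(k)
        cols.sort(key=lambda j: (-col_mean[j], j))
        col_order.extend(cols)
        col_bounds.append(len(col_order))
    rest = [j for j in range(n) if j not in consensus.retained_cols]
    col_order.extend(rest)

    row_order: list[int] = []
    row_bounds: list[int] = []
    for k in cluster_order:
        rows = consensus.cluster_rows(k)
        rows.sort(key=lambda i: (-row_mean[i], i))
        row_order.extend(rows)
        row_bounds.append(len(row_order))
    rest_r = [i for i in range(m) if i not in consensus.retained_rows]
    row_order.extend(rest_r)
    return row_order, col_order, col_bounds, row_bounds
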