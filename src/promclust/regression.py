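"""Regression of expression on ChIP-seq signals and combinatorial
feature selection.

Expression (CAGE tag counts per promoter) is regressed by ordinary
least squares on the rows of the signal matrix.  The full-model Pearson
correlation r_full between fitted and observed values is the benchmark;
every subset of ``subset_size`` experiments (4 by default — C(60, 4) =
487635 subsets on a 60-experiment matrix) is then fitted and its
correlation recorded.  "Good sets" are the subsets with r above
``fraction * r_full`` (95% by default), and each experiment is scored
by the hypergeometric upper-tail probability of its observed count
among the good sets.

All subset fits are exact OLS: with the Gram matrix of the full design
precomputed, each subset needs only a small linear solve, so the full
C(60, 4) scan takes seconds.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .signal import SignalMatrix

__all__ = [
    "QuadrupleScan", "fit_full", "scan_quadruples", "good_sets",
    "enrich_variables",
]


@dataclass
class QuadrupleScan:
    subsets: np.ndarray            # n_subsets x subset_size row indices
    r_values: np.ndarray
    r_full: float
    subset_size: int = 4
    n_rows: int = 0
    row_ids: list[str] | None = field(default=None, repr=False)

    @property
    def n_subsets(self) -> int:
        return len(self.subsets)


def _design(matrix, expression, log_transform: bool):
    x = matrix.values if isinstance(matrix, SignalMatrix) else np.asarray(matrix, float)
    y = np.asarray(expression, dtype=float)
    if y.shape != (x.shape[1],):
        raise ValueError("expression length must equal n_promoters")
    if log_transform:
        if (y < 0).any():
            raise ValueError("log transform requires non-negative expression")
        y = np.log1p(y)
    if np.ptp(y) == 0:
        raise ValueError("constant expression: correlation undefined")
    return x, y


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float(a @ a) * float(b @ b))
    if denom == 0:
        raise ValueError("zero-variance input to Pearson correlation")
    return float(a @ b) / denom


def fit_full(matrix, expression, log_transform: bool = True) -> float:
    """Pearson r between observed expression and the OLS fit on all
    experiments (plus intercept)."""
    x, y = _design(matrix, expression, log_transform)
    a = np.column_stack([np.ones(x.shape[1]), x.T])
    beta, _, rank, _ = np.linalg.lstsq(a, y, rcond=None)
    if rank < a.shape[1]:
        warnings.warn("rank-deficient design; collinear experiments "
                      "effectively dropped (minimum-norm fit)")
    return _pearson(a @ beta, y)


def scan_quadruples(matrix, expression, subset_size: int = 4,
                    log_transform: bool = True,
                    chunk: int = 20000) -> QuadrupleScan:
    """Exact OLS fit and Pearson r for every size-``subset_size``
    subset of experiments.

    Uses the precomputed Gram matrix of the (intercept + all rows)
    design, so each subset costs one (s+1)x(s+1) solve; subsets are
    processed in vectorized chunks.
    """
    x, y = _design(matrix, expression, log_transform)
    m, n = x.shape
    if m < subset_size:
        raise ValueError(f"need at least {subset_size} experiments")
    a = np.column_stack([np.ones(n), x.T])          # n x (m+1)
    g = a.T @ a                                     # Gram, (m+1)^2
    b = a.T @ y
    y_c = y - y.mean()
    ss_y = float(y_c @ y_c)

    r_full = fit_full(matrix, expression, log_transform)

    combos = itertools.combinations(range(m), subset_size)
    subsets_all: list[np.ndarray] = []
    r_all: list[np.ndarray] = []
    while True:
        block = list(itertools.islice(combos, chunk))
        if not block:
            break
        sub = np.asarray(block, dtype=np.int32)
        idx = np.concatenate([np.zeros((len(sub), 1), dtype=np.int32),
                              sub + 1], axis=1)     # prepend intercept
        gs = g[idx[:, :, None], idx[:, None, :]]    # B x (s+1) x (s+1)
        bs = b[idx]
        try:
            beta = np.linalg.solve(gs, bs[..., None])[..., 0]
        except np.linalg.LinAlgError:
            beta = np.stack([np.linalg.lstsq(gi, bi, rcond=None)[0]
                             for gi, bi in zip(gs, bs)])
        # fitted-value moments from the Gram pieces
        yhat_dot_y = np.einsum("bi,bi->b", beta, bs)
        yhat_dot_yhat = np.einsum("bi,bij,bj->b", beta, gs, beta)
        yhat_sum = np.einsum("bi,bi->b", beta, g[0][idx])
        var_h = yhat_dot_yhat - yhat_sum ** 2 / n
        cov = yhat_dot_y - yhat_sum * y.sum() / n
        with np.errstate(invalid="ignore", divide="ignore"):
            r = cov / np.sqrt(np.maximum(var_h, 0.0) * ss_y)
        r = np.nan_to_num(r, nan=0.0)
        subsets_all.append(sub)
        r_all.append(r)
    subsets = np.concatenate(subsets_all)
    r_values = np.clip(np.concatenate(r_all), -1.0, 1.0)
    row_ids = matrix.row_ids if isinstance(matrix, SignalMatrix) else None
    return QuadrupleScan(subsets, r_values, r_full, subset_size, m, row_ids)


def good_sets(scan: QuadrupleScan, fraction: float = 0.95) -> np.ndarray:
    """Subsets whose correlation strictly exceeds ``fraction * r_full``."""
    if scan.n_subsets == 0:
        raise ValueError("empty scan")
    return scan.subsets[scan.r_values > fraction * scan.r_full]


def enrich_variables(good: np.ndarray, n_rows: int,
                     subset_size: int = 4,
                     row_ids: list[str] | None = None) -> pd.DataFrame:
    """Hypergeometric over-representation of each experiment among the
    good sets.

    Population: all C(n_rows, s) subsets, of which K = C(n_rows-1, s-1)
    contain a given experiment; draws: the good sets; observed: good
    sets containing the experiment; p = P(X >= observed), upper tail.
    """
    good = np.asarray(good)
    n_pop = math.comb(n_rows, subset_size)
    k_pop = math.comb(n_rows - 1, subset_size - 1)
    n_draw = len(good)
    records = []
    for v in range(n_rows):
        k_obs = int((good == v).any(axis=1).sum()) if n_draw else 0
        p = 1.0 if n_draw == 0 else float(
            hypergeom.sf(k_obs - 1, n_pop, k_pop, n_draw))
        records.append(dict(
            variable=row_ids[v] if row_ids else v, count=k_obs,
            n_good=n_draw, subsets_with_variable=k_pop,
            total_subsets=n_pop, p=p))
    return pd.DataFrame(records).sort_values("p", kind="stable").reset_index(drop=True)
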