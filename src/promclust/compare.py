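"""Cross-clustering comparison tables.

Promoters are assigned a single category per condition (cell line or
algorithm): their consensus cluster label when retained, otherwise one
of the special bands used in the published confusion matrices —
"intergenic" (no ChIP-seq peak in any experiment), "low" (CAGE tags
present but below the robust cutoff), or "active/inactive unassigned"
(dropped by the consensus frequency filter).  When several apply the
precedence is intergenic > low > unassigned > cluster label.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .consensus import ConsensusSolution
from .signal import SignalMatrix

__all__ = ["categorize", "categorize_all", "cross_tabulate", "roman"]

_ROMAN = [(1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
          (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
          (5, "V"), (4, "IV"), (1, "I")]


def roman(n: int) -> str:
    """Roman-numeral cluster labels, as used on the heatmaps."""
    out = []
    for v, s in _ROMAN:
        while n >= v:
            out.append(s)
            n -= v
    return "".join(out)


def categorize(col_index: int, consensus: ConsensusSolution,
               activity_status: str, matrix) -> str:
    """Single category of one promoter (by column index)."""
    x = matrix.values if isinstance(matrix, SignalMatrix) else np.asarray(matrix, float)
    if col_index < 0 or col_index >= x.shape[1]:
        raise KeyError(f"unknown promoter column {col_index}")
    if not x[:, col_index].any():
        return "intergenic"
    if activity_status == "low":
        return "low"
    if col_index in consensus.retained_cols:
        return roman(consensus.retained_cols[col_index] + 1)
    return f"{activity_status} unassigned"


def categorize_all(consensus: ConsensusSolution, statuses: list[str],
                   matrix) -> list[str]:
    n = (matrix.n_promoters if isinstance(matrix, SignalMatrix)
         else np.asarray(matrix).shape[1])
    if len(statuses) != n:
        raise ValueError("one status per promoter required")
    return [categorize(j, consensus, statuses[j], matrix) for j in range(n)]


def cross_tabulate(categories_a, categories_b,
                   ids: list | None = None) -> pd.DataFrame:
    """Confusion table of category labels over a shared promoter
    universe; the table total equals the universe size."""
    a = pd.Series(list(categories_a))
    b = pd.Series(list(categories_b))
    if len(a) != len(b):
        raise ValueError("category vectors cover different universes")
    if ids is not None:
        if len(ids) != len(a):
            raise ValueError("ids length mismatch")
        a.index = b.index = pd.Index(ids)
    return pd.crosstab(a, b, rownames=["A"], colnames=["B"])


def overlap_counts(categories_a, categories_b, label: str) -> dict[str, int]:
    """Venn-style overlap counts for one label (e.g. active promoters
    shared between two cell lines)."""
    a = np.asarray([c == label for c in categories_a])
    b = np.asarray([c == label for c in categories_b])
    if a.size != b.size:
        raise ValueError("category vectors cover different universes")
    return {
        "a_only": int((a & ~b).sum()),
        "b_only": int((~a & b).sum()),
        "both": int((a & b).sum()),
    }
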