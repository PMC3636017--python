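"""RPKM quantification, cross-library correlation, and expression ranking.

RPKM = 1e9 * C / (N * L) for mapped-read count C, transcript length L (bp)
and library mappable total N (reads mapped to the reference in that
library).  Ambiguously mapping reads are resolved to their best hit, never
fractionally split.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ExpressionRecord:
    unigene_id: str
    count: int
    length: int
    total_mapped: int
    rpkm: float


def compute_rpkm(
    counts: Mapping[str, int],
    lengths: Mapping[str, int],
    total_mapped: int | None = None,
) -> pd.DataFrame:
    """Per-unigene RPKM table.

    ``total_mapped`` defaults to the sum of the mapped counts.  RPKM is
    invariant under doubling every count and the total together, and is zero
    iff the count is zero.
    """
    if total_mapped is None:
        total_mapped = int(sum(counts.values()))
    if total_mapped <= 0:
        raise ValueError("total mapped reads must be positive")
    rows = []
    for uid in sorted(counts):
        L = lengths[uid]
        if L <= 0:
            raise ValueError(f"nonpositive length for {uid}")
        c = counts[uid]
        rows.append(
            {
                "unigene": uid,
                "count": c,
                "length": L,
                "total_mapped": total_mapped,
                "rpkm": 1e9 * c / (total_mapped * L),
            }
        )
    return pd.DataFrame(rows, columns=["unigene", "count", "length", "total_mapped", "rpkm"])


def correlate_shared(
    expr_a: pd.DataFrame,
    expr_b: pd.DataFrame,
    shared_unigenes: Sequence[str],
    log_transform: bool = True,
) -> dict:
    """Pearson correlation of RPKM over unigenes in shared orthogroups.

    Computed on log2(RPKM + 1) by default (raw scale via
    ``log_transform=False``); the transform used is recorded in the output.
    """
    a = expr_a.set_index("unigene")["rpkm"]
    b = expr_b.set_index("unigene")["rpkm"]
    shared = [u for u in shared_unigenes if u in a.index and u in b.index]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared unigenes")
    x = a.loc[shared].to_numpy(dtype=float)
    y = b.loc[shared].to_numpy(dtype=float)
    if log_transform:
        x, y = np.log2(x + 1), np.log2(y + 1)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("zero variance in one of the expression vectors")
    r, p = stats.pearsonr(x, y)
    return {
        "pearson_r": float(r),
        "p_value": float(p),
        "n": len(shared),
        "transform": "log2(rpkm+1)" if log_transform else "raw",
    }


def top_expressed(
    expr: pd.DataFrame,
    unigene_orthogroup: Mapping[str, str],
    partition,
    region: str,
    n: int = 20,
) -> pd.DataFrame:
    """The n highest-RPKM unigenes whose orthogroups fall in a Venn region.

    Deterministic: ties on RPKM order by unigene id.  A region with no
    unigenes yields an empty frame, not an error.
    """
    if region not in partition.regions:
        raise KeyError(f"unknown Venn region: {region}")
    ogs = partition.regions[region]
    sub = expr[expr["unigene"].map(lambda u: unigene_orthogroup.get(u) in ogs)].copy()
    sub["orthogroup"] = sub["unigene"].map(unigene_orthogroup)
    sub = sub.sort_values(["rpkm", "unigene"], ascending=[False, True], kind="mergesort")
    return sub.head(n).reset_index(drop=True)
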