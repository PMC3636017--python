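"""Relative qPCR quantification by the 2^-ddCt method.

Technical replicate Ct values average to a per-sample mean Ct per gene.
delta-Ct = mean Ct(target) - mean Ct(reference) within a sample;
delta-delta-Ct = delta-Ct(treatment sample) - mean delta-Ct(control);
fold change = 2^-ddCt.  The summary fold across biological replicates is
the geometric mean (equivalently 2 to the minus mean ddCt).  Group
comparison uses Welch's unequal-variance t-test, one-tailed, applied on the
delta-Ct scale (the approximately normal scale behind 2^-ddCt reporting).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def mean_ct(ct_values: Sequence[float]) -> float:
    vals = np.asarray(list(ct_values), dtype=float)
    if vals.size < 1:
        raise ValueError("need at least one technical replicate")
    return float(vals.mean())


def delta_ct(sample: pd.DataFrame, target: str, reference: str = "reference") -> float:
    """delta-Ct of one sample: mean Ct(target) - mean Ct(reference)."""
    genes = sample.groupby("gene")["ct"].mean()
    for g in (target, reference):
        if g not in genes.index:
            raise ValueError(f"gene {g!r} not measured in sample")
    return float(genes[target] - genes[reference])


def delta_ct_by_sample(
    table: pd.DataFrame, target: str, reference: str = "reference"
) -> pd.DataFrame:
    """Per-sample delta-Ct table from a long Ct replicate table.

    Expects columns: sample, condition, gene, ct (replicate columns may be
    present but are simply averaged).
    """
    rows = []
    for (sample, condition), grp in table.groupby(["sample", "condition"], sort=True):
        rows.append(
            {
                "sample": sample,
                "condition": condition,
                "delta_ct": delta_ct(grp, target, reference),
            }
        )
    return pd.DataFrame(rows, columns=["sample", "condition", "delta_ct"])


def fold_change_ddct(
    treatment_delta_ct: Sequence[float], control_delta_ct: Sequence[float]
) -> dict:
    """Per-treatment-sample 2^-ddCt folds and their geometric-mean summary."""
    t = np.asarray(list(treatment_delta_ct), dtype=float)
    c = np.asarray(list(control_delta_ct), dtype=float)
    if t.size == 0 or c.size == 0:
        raise ValueError("need at least one sample per condition")
    ddct = t - c.mean()
    folds = np.power(2.0, -ddct)
    return {
        "ddct": ddct.tolist(),
        "folds": folds.tolist(),
        "fold_geometric_mean": float(2.0 ** (-ddct.mean())),
    }


def welch_one_tailed(
    group1: Sequence[float],
    group2: Sequence[float],
    direction: str = "greater",
) -> dict:
    """Welch's unequal-variance t-test with a one-tailed p-value.

    ``direction`` states the alternative for group1 relative to group2
    ('greater' or 'less').  Degrees of freedom use the Welch-Satterthwaite
    approximation.
    """
    a = np.asarray(list(group1), dtype=float)
    b = np.asarray(list(group2), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    res = stats.ttest_ind(a, b, equal_var=False, alternative=direction)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    if va == 0 and vb == 0:
        df = float(na + nb - 2)
    else:
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    return {"t": float(res.statistic), "df": float(df), "p_value": float(res.pvalue)}


def analyze_qpcr(
    table: pd.DataFrame,
    target: str,
    reference: str = "reference",
    direction: str = "less",
) -> dict:
    """Full ddCt analysis of one target gene from a long Ct table.

    ``direction`` is the alternative for the treatment delta-Ct relative to
    control ('less' means the target is up-regulated in treatment, since
    lower Ct means more transcript).
    """
    dct = delta_ct_by_sample(table, target, reference)
    treat = dct.loc[dct.condition == "treatment", "delta_ct"].tolist()
    ctrl = dct.loc[dct.condition == "control", "delta_ct"].tolist()
    fold = fold_change_ddct(treat, ctrl)
    out = {"target": target, **fold}
    if len(treat) >= 2 and len(ctrl) >= 2:
        out.update(welch_one_tailed(treat, ctrl, direction))
    return out
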