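"""Orthogroup assignment, Venn partitioning, and GO Slim proportionality.

Orthogroups are inherited from the best significant hit against an
orthogroup-labelled reference.  Three transcriptome-level orthogroup sets
(interface on host A, interface on host B, above-ground reference) are
partitioned into the seven disjoint Venn regions, interface-only fractions
are derived, and GO Slim category-by-region count tables are tested for
proportionality with a Pearson chi-square; cells with |Pearson residual|
greater than 4 are flagged as strongly disproportionate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .similarity import MappingPolicy, SeedIndex, best_hit

logger = logging.getLogger(__name__)

REGIONS = (
    "shared_all",
    "interface_shared",
    "A_interface_unique",
    "B_interface_unique",
    "A_above_shared",
    "B_above_shared",
    "above_unique",
)


@dataclass
class OrthogroupAssignment:
    unigene_id: str
    orthogroup: str | None
    evidence: object = None


def assign_orthogroups(
    unigenes: Mapping[str, str],
    reference: Mapping[str, str],
    reference_labels: pd.DataFrame,
    policy: MappingPolicy | None = None,
) -> list:
    """Each unigene inherits the orthogroup of its best significant hit.

    ``reference_labels`` must map every reference ``subject_id`` to an
    ``orthogroup``; an unlabeled record is an error.  Queries without a
    significant hit are unassigned (orthogroup None).
    """
    policy = policy or MappingPolicy()
    ogmap = reference_labels.set_index("subject_id")["orthogroup"].to_dict()
    missing = [sid for sid in reference if sid not in ogmap]
    if missing:
        raise ValueError(f"reference records missing orthogroup label: {missing[:5]}")
    index = SeedIndex(reference, policy.seed_k)
    out = []
    for uid in sorted(unigenes):
        hit = best_hit(unigenes[uid], index, policy, query_id=uid)
        og = None
        if hit is not None:
            og = ogmap[hit.subject_id] or None
        out.append(OrthogroupAssignment(uid, og, hit))
    return out


@dataclass
class VennPartition:
    """Disjoint seven-region partition of observed orthogroups."""

    regions: dict  # region name -> frozenset of orthogroup ids

    @property
    def counts(self) -> dict:
        return {r: len(self.regions[r]) for r in REGIONS}

    @property
    def interface_only_total(self) -> int:
        return sum(
            len(self.regions[r])
            for r in ("interface_shared", "A_interface_unique", "B_interface_unique")
        )

    def all_orthogroups(self) -> frozenset:
        out: set = set()
        for s in self.regions.values():
            out |= s
        return frozenset(out)


def venn_partition(set_a: set, set_b: set, set_ref: set) -> VennPartition:
    """Three-way Venn over orthogroup id sets.

    ``set_a``/``set_b`` are the interface transcriptomes on hosts A and B;
    ``set_ref`` is the above-ground reference transcriptome.
    """
    a, b, r = set(set_a), set(set_b), set(set_ref)
    regions = {
        "shared_all": frozenset(a & b & r),
        "interface_shared": frozenset((a & b) - r),
        "A_interface_unique": frozenset(a - b - r),
        "B_interface_unique": frozenset(b - a - r),
        "A_above_shared": frozenset((a & r) - b),
        "B_above_shared": frozenset((b & r) - a),
        "above_unique": frozenset(r - a - b),
    }
    return VennPartition(regions)


def interface_fractions(partition: VennPartition) -> dict:
    """Interface-only orthogroups split as nearest-percent fractions.

    Exact rational arithmetic before rounding; the three values sum to
    100 +/- 1 (rounding).  Raises on an empty interface-only set.
    """
    total = partition.interface_only_total
    if total == 0:
        raise ValueError("no interface-only orthogroups")
    out = {}
    for key, region in (
        ("interface_shared", "interface_shared"),
        ("A_interface_unique", "A_interface_unique"),
        ("B_interface_unique", "B_interface_unique"),
    ):
        frac = Fraction(len(partition.regions[region]), total)
        out[key] = int(round(100 * frac))
    return out


@dataclass
class GoSlimContingency:
    table: pd.DataFrame  # observed counts, categories x regions
    expected: pd.DataFrame
    chi2: float
    dof: int
    p_value: float
    residuals: pd.DataFrame  # Pearson residuals (O - E) / sqrt(E)
    flags: pd.DataFrame  # +1 / -1 / 0 for residual > bound, < -bound, neither
    low_expected_cells: list = field(default_factory=list)  # expected < 5
    dropped: list = field(default_factory=list)  # zero-margin rows/columns


def goslim_chi_square(
    table: pd.DataFrame, residual_bound: float = 4.0, adjusted: bool = False
) -> GoSlimContingency:
    """Pearson chi-square proportionality test with per-cell residual flags.

    Expected counts come from the row/column margins; no continuity
    correction (tables here are large R x C).  Zero-margin rows or columns
    are dropped with a logged note.  ``adjusted=True`` switches to
    Haberman-adjusted residuals.
    """
    obs = table.astype(float).copy()
    if (obs.values < 0).any():
        raise ValueError("contingency counts must be nonnegative")
    dropped = []
    zero_rows = obs.index[obs.sum(axis=1) == 0].tolist()
    zero_cols = obs.columns[obs.sum(axis=0) == 0].tolist()
    if zero_rows or zero_cols:
        dropped = [("row", r) for r in zero_rows] + [("col", c) for c in zero_cols]
        logger.info("dropping zero-margin rows/columns: %s", dropped)
        obs = obs.drop(index=zero_rows, columns=zero_cols)
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table needs >= 2 rows and >= 2 columns")

    chi2, p, dof, expected = stats.chi2_contingency(obs.values, correction=False)
    exp = pd.DataFrame(expected, index=obs.index, columns=obs.columns)
    resid = (obs - exp) / np.sqrt(exp)
    if adjusted:
        n = obs.values.sum()
        row_p = obs.sum(axis=1) / n
        col_p = obs.sum(axis=0) / n
        adj = np.sqrt(np.outer(1 - row_p, 1 - col_p))
        resid = resid / adj
    flags = pd.DataFrame(0, index=obs.index, columns=obs.columns, dtype=int)
    flags[resid > residual_bound] = 1
    flags[resid < -residual_bound] = -1
    low = [
        (r, c)
        for r in obs.index
        for c in obs.columns
        if exp.loc[r, c] < 5
    ]
    return GoSlimContingency(
        table=obs,
        expected=exp,
        chi2=float(chi2),
        dof=int(dof),
        p_value=float(p),
        residuals=resid,
        flags=flags,
        low_expected_cells=low,
        dropped=dropped,
    )


def unigene_region_table(
    assignments: Sequence[OrthogroupAssignment],
    goslim: Mapping[str, str],
    partition: VennPartition,
    regions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Build the GO Slim category x Venn region unigene count table.

    ``goslim`` maps unigene id -> category ('' or missing means no
    category, recorded in the explicit ``none`` row).
    """
    regions = list(regions or REGIONS)
    og_region = {}
    for region, ogs in partition.regions.items():
        for og in ogs:
            og_region[og] = region
    counts: dict = {}
    for asn in assignments:
        if asn.orthogroup is None or asn.orthogroup not in og_region:
            continue
        region = og_region[asn.orthogroup]
        if region not in regions:
            continue
        cat = goslim.get(asn.unigene_id, "") or "none"
        counts.setdefault(cat, {}).setdefault(region, 0)
        counts[cat][region] += 1
    cats = sorted(counts)
    table = pd.DataFrame(0, index=cats, columns=regions, dtype=int)
    for cat, row in counts.items():
        for region, n in row.items():
            table.loc[cat, region] = n
    return table
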