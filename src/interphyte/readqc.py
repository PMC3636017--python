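"""Quality trimming, pair reconstruction, and host-read screening.

Trimming removes low-quality bases (below a Phred floor, default Q20) from
both ends of each read; a read survives only if the remaining fragment is at
least half (configurable) of its original length.  Interior low-quality
bases are untouched.  After trimming, pairs whose mates both survive are
reconstructed and single survivors become orphans.

Host screening maps surviving reads against host reference transcripts with
the package's own aligner; a read is host-assigned iff it maps under the
mapping policy.  A pair with exactly one host-assigned mate is discarded
whole (conservative against chimeric carry-through) and counted separately
in the accounting report.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .similarity import MappingPolicy, SeedIndex, best_hit


@dataclass(frozen=True)
class TrimPolicy:
    quality_floor: int = 20
    min_survival_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.quality_floor < 0:
            raise ValueError("quality_floor must be nonnegative")
        if not (0 < self.min_survival_fraction <= 1):
            raise ValueError("min_survival_fraction must be in (0, 1]")


@dataclass
class TrimmedRead:
    read_id: str
    sequence: str
    qualities: list
    trimmed: bool


def quality_trim(
    read_id: str,
    sequence: str,
    qualities: Sequence[int],
    policy: TrimPolicy | None = None,
) -> TrimmedRead | None:
    """End-trim a read; return the surviving fragment or None (discard).

    Strips the maximal prefix and suffix of bases with quality strictly
    below the floor, then keeps the read only when the surviving length is
    at least ``min_survival_fraction`` of the original length.
    """
    policy = policy or TrimPolicy()
    if len(sequence) != len(qualities):
        raise ValueError(f"record {read_id}: sequence/quality length mismatch")
    if not sequence:
        raise ValueError(f"record {read_id}: empty read")
    start = 0
    end = len(sequence)
    while start < end and qualities[start] < policy.quality_floor:
        start += 1
    while end > start and qualities[end - 1] < policy.quality_floor:
        end -= 1
    surviving = end - start
    if surviving < policy.min_survival_fraction * len(sequence):
        return None
    return TrimmedRead(
        read_id,
        sequence[start:end],
        list(qualities[start:end]),
        trimmed=(start > 0 or end < len(sequence)),
    )


def repair_pairs(
    mate1: Mapping[str, TrimmedRead | None],
    mate2: Mapping[str, TrimmedRead | None],
) -> tuple[dict, dict]:
    """Rebuild pairs from trimmed mate streams.

    Input maps read id -> surviving TrimmedRead (or None when discarded by
    trimming).  Returns ``(pairs, orphans)`` where pairs maps id ->
    (mate1, mate2) and orphans maps id -> the single surviving mate.
    2 * len(pairs) + len(orphans) equals the number of surviving reads.
    """
    for side in (mate1, mate2):
        ids = list(side)
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate read id within a mate file")
    pairs: dict = {}
    orphans: dict = {}
    for rid in set(mate1) | set(mate2):
        r1 = mate1.get(rid)
        r2 = mate2.get(rid)
        if r1 is not None and r2 is not None:
            pairs[rid] = (r1, r2)
        elif r1 is not None:
            orphans[rid] = r1
        elif r2 is not None:
            orphans[rid] = r2
    return pairs, orphans


def trim_pairs(
    pairs: Iterable[tuple[str, str, Sequence[int], str, Sequence[int]]],
    policy: TrimPolicy | None = None,
):
    """Trim both mates of each pair and rebuild pairs/orphans.

    Returns ``(pairs, orphans, accounting)`` with a per-stage count table.
    """
    policy = policy or TrimPolicy()
    m1: dict = {}
    m2: dict = {}
    n_in = 0
    for rid, s1, q1, s2, q2 in pairs:
        n_in += 2
        m1[rid] = quality_trim(rid, s1, q1, policy)
        m2[rid] = quality_trim(rid, s2, q2, policy)
    kept_pairs, orphans = repair_pairs(m1, m2)
    surviving = 2 * len(kept_pairs) + len(orphans)
    accounting = pd.DataFrame(
        [
            {"stage": "input_reads", "count": n_in},
            {"stage": "discarded_reads", "count": n_in - surviving},
            {"stage": "retained_paired_reads", "count": 2 * len(kept_pairs)},
            {"stage": "retained_orphan_reads", "count": len(orphans)},
        ]
    )
    return kept_pairs, orphans, accounting


def is_host_read(
    sequence: str, index: SeedIndex, policy: MappingPolicy
) -> bool:
    """True iff the read maps to a host transcript under the mapping policy."""
    hit = best_hit(sequence, index, policy, mode="local")
    if hit is None:
        return False
    return (
        hit.query_span / len(sequence) >= policy.length_fraction
        and hit.percent_identity / 100.0 >= policy.min_similarity
    )


def screen_host_reads(
    pairs: Mapping[str, tuple],
    orphans: Mapping[str, TrimmedRead],
    host_reference: Mapping[str, str],
    policy: MappingPolicy | None = None,
):
    """Remove host-origin reads by mapping to host reference transcripts.

    A pair is removed when either mate is host-assigned (half-host pairs are
    flagged in the accounting).  Returns
    ``(retained_pairs, retained_orphans, host_ids, accounting)``.
    """
    policy = policy or MappingPolicy()
    if not host_reference:
        raise ValueError("host reference set is empty")
    index = SeedIndex(host_reference, policy.seed_k)
    retained_pairs: dict = {}
    retained_orphans: dict = {}
    host_ids: list = []
    n_host_reads = 0
    n_half_host_pairs = 0
    for rid, (r1, r2) in pairs.items():
        h1 = is_host_read(r1.sequence, index, policy)
        h2 = is_host_read(r2.sequence, index, policy)
        if h1 or h2:
            host_ids.append(rid)
            n_host_reads += int(h1) + int(h2)
            if h1 != h2:
                n_half_host_pairs += 1
        else:
            retained_pairs[rid] = (r1, r2)
    for rid, r in orphans.items():
        if is_host_read(r.sequence, index, policy):
            host_ids.append(rid)
            n_host_reads += 1
        else:
            retained_orphans[rid] = r
    n_in = 2 * len(pairs) + len(orphans)
    n_retained = 2 * len(retained_pairs) + len(retained_orphans)
    accounting = pd.DataFrame(
        [
            {"stage": "input_reads", "count": n_in},
            {"stage": "host_assigned_reads", "count": n_host_reads},
            {"stage": "half_host_pairs_discarded", "count": n_half_host_pairs},
            {"stage": "removed_reads", "count": n_in - n_retained},
            {"stage": "retained_reads", "count": n_retained},
        ]
    )
    return retained_pairs, retained_orphans, sorted(host_ids), accounting


def read_filter_accounting(total_reads: int, host_reads: int) -> pd.DataFrame:
    """Host-filter arithmetic on read totals (the read-level book-keeping)."""
    if host_reads > total_reads:
        raise ValueError("host reads cannot exceed total reads")
    return pd.DataFrame(
        [
            {"stage": "reads_total", "count": total_reads},
            {"stage": "host_reads", "count": host_reads},
            {"stage": "host_filtered", "count": total_reads - host_reads},
        ]
    )
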