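"""Staged unigene classification with full count accounting.

The cascade assigns every unigene to exactly one category:

1. host screen      -- best-hit nucleotide identity >= tau_host against the
                       host transcript database  =>  ``host``
2. parasite screen  -- identity >= tau_parasite against the parasite
                       reference library         =>  ``parasite``
3. protein screen   -- significant best hit in a taxon-labeled annotation
                       database                  =>  ``other_plant`` / ``non_plant``
4. otherwise            ``no_hit``

Host-before-parasite order means a unigene above both thresholds is called
host, conservative against contamination.  Plant-labelled and no-hit
unigenes are pooled with parasite-screen survivors into the putative
parasite set used by all downstream comparative analyses.

The module also carries assembly post-processing: exact-duplicate and
contained-substring removal (either strand), an ORF-fraction translatability
heuristic, and assembly summary statistics including N50.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .similarity import AlignmentHit, MappingPolicy, SeedIndex, best_hit, revcomp

logger = logging.getLogger(__name__)

CATEGORIES = ("host", "parasite", "other_plant", "non_plant", "no_hit")


@dataclass
class ClassifiedUnigene:
    unigene_id: str
    category: str
    stage_decided: str  # host_screen | parasite_screen | protein_screen | unresolved
    evidence: dict = field(default_factory=dict)  # stage -> best AlignmentHit


def deduplicate(unigenes: Mapping[str, str]) -> tuple[dict, list]:
    """Remove exact duplicates and contained substrings (either strand).

    The longest representative is kept; equal-length duplicates keep the
    lexicographically smallest id.  Returns (retained, removed ids).
    """
    order = sorted(unigenes, key=lambda u: (-len(unigenes[u]), u))
    retained: dict = {}
    removed: list = []
    for uid in order:
        seq = unigenes[uid].upper()
        rc = revcomp(seq)
        contained = any(seq in kept or rc in kept for kept in retained.values())
        if contained:
            removed.append(uid)
        else:
            retained[uid] = seq
    return retained, removed


def longest_orf_length(sequence: str) -> int:
    """Longest stop-free stretch (in nucleotides) over all six reading frames."""
    seq = sequence.upper()
    best_aa = 0
    for strand_seq in (seq, revcomp(seq)):
        for frame in range(3):
            sub = strand_seq[frame:]
            sub = sub[: len(sub) - len(sub) % 3]
            if not sub:
                continue
            aa = str(Seq(sub).translate())
            best_aa = max(best_aa, max((len(p) for p in aa.split("*")), default=0))
    return best_aa * 3


def translatability_filter(sequence: str, min_orf_fraction: float = 0.3) -> bool:
    """Keep iff the longest ORF covers at least ``min_orf_fraction`` of the read.

    A permissive stand-in for a frame-shift-aware coding filter: sequences
    whose six-frame translations are all stop-riddled are dropped.
    """
    if len(sequence) < 3:
        logger.info("sequence shorter than one codon dropped by translatability filter")
        return False
    return longest_orf_length(sequence) >= min_orf_fraction * len(sequence)


@dataclass
class AssemblyStats:
    n_unigenes: int
    total_length: int
    min_length: int
    max_length: int
    n50: int
    n50_over_500: int | None = None


def n50(lengths: Sequence[int]) -> int:
    """Shortest length in the smallest descending-length prefix reaching half
    the total assembly length."""
    ls = sorted(lengths, reverse=True)
    if not ls:
        raise ValueError("empty length set")
    half = sum(ls) / 2
    acc = 0
    for L in ls:
        acc += L
        if acc >= half:
            return L
    return ls[-1]


def assembly_stats(unigenes: Mapping[str, str]) -> AssemblyStats:
    if not unigenes:
        raise ValueError("empty unigene set")
    lengths = [len(s) for s in unigenes.values()]
    over500 = [L for L in lengths if L > 500]
    return AssemblyStats(
        n_unigenes=len(lengths),
        total_length=sum(lengths),
        min_length=min(lengths),
        max_length=max(lengths),
        n50=n50(lengths),
        n50_over_500=n50(over500) if over500 else None,
    )


def _screen_hit(
    seq: str,
    index: SeedIndex,
    policy: MappingPolicy,
    uid: str,
    tau: float,
    min_alignment_fraction: float,
) -> tuple[bool, AlignmentHit | None]:
    hit = best_hit(seq, index, policy, query_id=uid)
    if hit is None:
        return False, None
    passes = (
        hit.percent_identity >= tau
        and hit.alignment_length >= min_alignment_fraction * len(seq)
    )
    return passes, hit


def classify_cascade(
    unigenes: Mapping[str, str],
    host_db: Mapping[str, str],
    parasite_db: Mapping[str, str],
    annotation_db: Mapping[str, str],
    annotation_labels: pd.DataFrame,
    tau_host: float = 95.0,
    tau_parasite: float = 95.0,
    policy: MappingPolicy | None = None,
    min_alignment_fraction: float = 0.5,
) -> tuple[list, pd.DataFrame]:
    """Run the three-stage cascade; returns (classified list, accounting table).

    ``annotation_labels`` must carry a ``kingdom`` label (``plant`` /
    ``non_plant``) for every record of ``annotation_db``; a missing label is
    a configuration error naming the record.  The significance surrogate for
    the protein screen is ``policy.min_score`` (hits below it are no-hits).
    """
    policy = policy or MappingPolicy()
    labels = annotation_labels.set_index("subject_id")["kingdom"].to_dict()
    missing = [sid for sid in annotation_db if sid not in labels]
    if missing:
        raise ValueError(f"annotation records missing taxon label: {missing[:5]}")

    host_index = SeedIndex(host_db, policy.seed_k) if host_db else None
    par_index = SeedIndex(parasite_db, policy.seed_k) if parasite_db else None
    anno_index = SeedIndex(annotation_db, policy.seed_k) if annotation_db else None

    classified: list[ClassifiedUnigene] = []
    for uid in sorted(unigenes):
        seq = unigenes[uid]
        evidence: dict = {}
        if host_index is not None:
            is_host, hit = _screen_hit(
                seq, host_index, policy, uid, tau_host, min_alignment_fraction
            )
            if hit is not None:
                evidence["host_screen"] = hit
            if is_host:
                classified.append(ClassifiedUnigene(uid, "host", "host_screen", evidence))
                continue
        if par_index is not None:
            is_par, hit = _screen_hit(
                seq, par_index, policy, uid, tau_parasite, min_alignment_fraction
            )
            if hit is not None:
                evidence["parasite_screen"] = hit
            if is_par:
                classified.append(
                    ClassifiedUnigene(uid, "parasite", "parasite_screen", evidence)
                )
                continue
        category, stage = "no_hit", "unresolved"
        if anno_index is not None:
            hit = best_hit(seq, anno_index, policy, query_id=uid)
            if hit is not None:
                evidence["protein_screen"] = hit
                kingdom = labels[hit.subject_id]
                category = "other_plant" if kingdom == "plant" else "non_plant"
                stage = "protein_screen"
        classified.append(ClassifiedUnigene(uid, category, stage, evidence))

    counts = {c: 0 for c in CATEGORIES}
    for cu in classified:
        counts[cu.category] += 1
    accounting = cascade_accounting(
        total=len(classified),
        host=counts["host"],
        non_plant=counts["non_plant"],
        parasite=counts["parasite"],
        other_plant=counts["other_plant"],
    )
    return classified, accounting


def cascade_accounting(
    total: int,
    host: int,
    non_plant: int,
    parasite: int,
    other_plant: int,
) -> pd.DataFrame:
    """Stage-by-stage count table for the cascade.

    The putative parasite pool is everything not assigned to a host or
    non-plant source: parasite-screen survivors, other-plant hits, and
    no-hit unigenes.  Conservation holds at every stage.
    """
    putative = total - host - non_plant
    no_hit = putative - parasite - other_plant
    if no_hit < 0:
        raise ValueError("inconsistent cascade counts")
    rows = [
        {"stage": "unigenes_total", "count": total},
        {"stage": "host_unigenes", "count": host},
        {"stage": "non_plant_unigenes", "count": non_plant},
        {"stage": "putative_parasite_unigenes", "count": putative},
        {"stage": "parasite_hits", "count": parasite},
        {"stage": "other_plant_hits", "count": other_plant},
        {"stage": "no_hits", "count": no_hit},
    ]
    return pd.DataFrame(rows, columns=["stage", "count"])


def ambiguous_band(
    unigenes: Mapping[str, str],
    host_db: Mapping[str, str],
    parasite_db: Mapping[str, str],
    tau_host: float = 95.0,
    tau_parasite: float = 95.0,
    policy: MappingPolicy | None = None,
    min_alignment_fraction: float = 0.5,
) -> list:
    """Unigenes whose category flips if the host and parasite stages swap.

    These are the dual-threshold sequences (>= tau to both databases); the
    cascade sends them to host, a reversed cascade would call them parasite.
    """
    policy = policy or MappingPolicy()
    host_index = SeedIndex(host_db, policy.seed_k)
    par_index = SeedIndex(parasite_db, policy.seed_k)
    out = []
    for uid in sorted(unigenes):
        seq = unigenes[uid]
        is_host, _ = _screen_hit(seq, host_index, policy, uid, tau_host, min_alignment_fraction)
        if not is_host:
            continue
        is_par, _ = _screen_hit(seq, par_index, policy, uid, tau_parasite, min_alignment_fraction)
        if is_par:
            out.append(uid)
    return out


def classification_table(classified: Sequence[ClassifiedUnigene]) -> pd.DataFrame:
    rows = []
    for cu in classified:
        hit = cu.evidence.get(
            {"host_screen": "host_screen", "parasite_screen": "parasite_screen",
             "protein_screen": "protein_screen", "unresolved": "protein_screen"}[cu.stage_decided]
        )
        rows.append(
            {
                "unigene": cu.unigene_id,
                "category": cu.category,
                "stage": cu.stage_decided,
                "best_subject": hit.subject_id if hit else "",
                "identity": round(hit.percent_identity, 2) if hit else np.nan,
                "score": hit.score if hit else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["unigene", "category", "stage", "best_subject", "identity", "score"])
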