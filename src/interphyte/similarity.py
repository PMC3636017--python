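"""Self-contained nucleotide similarity engine.

A k-mer-seeded, banded dynamic-programming aligner that reports percent
identity, best hits against an indexed reference set, and read-to-transcript
mapping.  It plays the role BLASTn and a short-read mapper play in a full
scale pipeline, at desk scale and with fully reproducible semantics.

Scoring follows the classic read-mapper convention: match +1, mismatch cost
2, insertion cost 3, deletion cost 3 (costs are subtracted from the score).
Percent identity is matches divided by alignment columns (gap columns
included), times 100 -- the convention behind the 95 % host-exclusion
threshold used throughout the pipeline.

The dynamic program optimises the triple (score, matches, -columns)
lexicographically.  Encoding the triple in a single integer makes the
optimum unique and symmetric in its arguments (insertion and deletion costs
are equal by default), so identity(a, b) == identity(b, a) in global mode
and repeated runs are bit-for-bit deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from numba import njit

NEG = -(1 << 60)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MappingPolicy:
    """Alignment and acceptance parameters for searching and read mapping.

    ``length_fraction`` and ``min_similarity`` are the acceptance rules for
    read mapping: a read counts toward a transcript only when at least
    ``length_fraction`` of the read aligns and the identity on the aligned
    part is at least ``min_similarity``.  ``min_score`` is the significance
    surrogate: hits scoring below it are treated as no-hit.
    """

    length_fraction: float = 0.5
    min_similarity: float = 0.8
    match_score: int = 1
    mismatch_cost: int = 2
    insertion_cost: int = 3
    deletion_cost: int = 3
    seed_k: int = 11
    band_width: int = 32
    min_score: float = 25.0
    max_candidates: int = 8

    def __post_init__(self) -> None:
        if not (0 < self.length_fraction <= 1):
            raise ValueError("length_fraction must be in (0, 1]")
        if not (0 < self.min_similarity <= 1):
            raise ValueError("min_similarity must be in (0, 1]")
        for name in ("mismatch_cost", "insertion_cost", "deletion_cost"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class AlignmentHit:
    """One query-subject alignment, the unit of every screening decision."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    score: int
    strand: str = "+"
    matches: int = 0
    query_start: int = 0
    query_end: int = 0
    subject_start: int = 0
    subject_end: int = 0

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start

    def sort_key(self):
        # score, then identity, then alignment length, then subject id
        # (lexicographically smallest id wins ties).
        return (
            -self.score,
            -self.percent_identity,
            -self.alignment_length,
            self.subject_id,
        )


def _to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


@dataclass
class _BandResult:
    score: int
    matches: int
    columns: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int


@njit(cache=True)
def _fill_band(q, s, W, dlo, add_match, add_mismatch, add_ins, add_del, mode, v_zero, neg):
    """Forward fill of the banded DP matrix (mode: 0 global, 1 glocal, 2 local)."""
    n, m = q.size, s.size
    M = np.full((n + 1, W), neg, dtype=np.int64)
    for k in range(W):
        j = dlo + k
        if 0 <= j <= m:
            M[0, k] = v_zero + add_del * j if mode == 0 else v_zero
    for i in range(1, n + 1):
        for k in range(W):
            j = i + dlo + k
            if j < 0 or j > m:
                continue
            best = neg
            if j >= 1:
                p = M[i - 1, k]  # diagonal predecessor shares the band index
                if p > neg // 2:
                    if s[j - 1] == q[i - 1]:
                        v = p + add_match
                    else:
                        v = p + add_mismatch
                    if v > best:
                        best = v
            if k + 1 < W:
                p = M[i - 1, k + 1]  # up: consume a query base
                if p > neg // 2:
                    v = p + add_ins
                    if v > best:
                        best = v
            if k >= 1 and j >= 1:
                p = M[i, k - 1]  # left: consume a subject base
                if p > neg // 2:
                    v = p + add_del
                    if v > best:
                        best = v
            if mode == 2 and best < v_zero:
                best = v_zero
            M[i, k] = best
    return M


@njit(cache=True)
def _traceback_start(M, q, s, i_end, k_end, dlo, add_match, add_mismatch,
                     add_ins, add_del, mode, v_zero):
    """Walk back from the end cell; return the (query, subject) start."""
    W = M.shape[1]
    i = i_end
    j = i_end + dlo + k_end
    while True:
        kk = j - i - dlo
        v_here = M[i, kk]
        if mode == 2 and v_here == v_zero:
            break
        if i == 0 and (mode != 0 or j == 0):
            break
        if mode == 0 and i == 0:
            j -= 1  # leading subject gap row
            continue
        moved = False
        if i >= 1 and j >= 1:
            step = add_match if s[j - 1] == q[i - 1] else add_mismatch
            if M[i - 1, kk] + step == v_here:
                i -= 1
                j -= 1
                moved = True
        if not moved and i >= 1 and kk + 1 < W:
            if M[i - 1, kk + 1] + add_ins == v_here:
                i -= 1
                moved = True
        if not moved and j >= 1 and kk >= 1:
            if M[i, kk - 1] + add_del == v_here:
                j -= 1
                moved = True
        if not moved:
            break  # band-initial cell
    return i, j


def _banded_dp(
    q: np.ndarray,
    s: np.ndarray,
    policy: MappingPolicy,
    mode: str,
    diag_center: int | None = None,
    band_width: int | None = None,
) -> _BandResult | None:
    """Banded alignment of query ``q`` against subject ``s``.

    Modes:
      * ``global``  -- end-to-end on both sequences; the band is widened
        automatically so it always connects the corners.
      * ``glocal``  -- the query aligns end-to-end, subject end gaps free.
      * ``local``   -- Smith-Waterman-style within the band.

    Cell values encode (score, matches, columns) in one int64 so that the
    lexicographic optimum is selected without tie ambiguity.
    """
    n, m = len(q), len(s)
    if n == 0 or m == 0:
        raise ValueError("cannot align empty sequences")
    w = policy.band_width if band_width is None else band_width
    if mode == "global":
        dlo = min(0, m - n) - w
        dhi = max(0, m - n) + w
    elif diag_center is None:
        dlo, dhi = -n, m  # no seed diagonal known: search the full matrix
    else:
        dlo, dhi = diag_center - w, diag_center + w
    dlo = max(dlo, -n)
    dhi = min(dhi, m)
    if dlo > dhi:
        return None
    W = dhi - dlo + 1

    K = n + m + 2  # capacity of the matches field
    K2 = n + m + 2  # capacity of the columns field
    KK = K * K2

    def enc(score: int, matches: int, columns: int) -> int:
        return score * KK + matches * K2 + (K2 - 1 - columns)

    v_zero = enc(0, 0, 0)  # local-mode restart value
    add_match = enc(policy.match_score, 1, 1) - v_zero
    add_mismatch = enc(-policy.mismatch_cost, 0, 1) - v_zero
    add_ins = enc(-policy.insertion_cost, 0, 1) - v_zero  # consumes query base
    add_del = enc(-policy.deletion_cost, 0, 1) - v_zero  # consumes subject base

    mode_code = {"global": 0, "glocal": 1, "local": 2}[mode]
    M = _fill_band(
        q, s, W, dlo, add_match, add_mismatch, add_ins, add_del, mode_code, v_zero, NEG
    )

    # pick the end cell
    if mode == "global":
        k_end = m - n - dlo
        if not (0 <= k_end < W) or M[n, k_end] <= NEG // 2:
            return None
        i_end, k = n, k_end
    elif mode == "glocal":
        k = int(np.argmax(M[n]))
        if M[n, k] <= NEG // 2:
            return None
        i_end = n
    else:
        flat = int(np.argmax(M))
        i_end, k = divmod(flat, W)
        if M[i_end, k] <= NEG // 2 or M[i_end, k] < v_zero:
            return None

    v = int(M[i_end, k])
    columns = K2 - 1 - (v % K2)
    matches = (v % KK) // K2
    score = v // KK
    if columns == 0:
        return None

    q_end, s_end = i_end, i_end + dlo + k
    q_start, s_start = _traceback_start(
        M, q, s, i_end, k, dlo, add_match, add_mismatch, add_ins, add_del,
        mode_code, v_zero
    )
    return _BandResult(score, matches, columns, q_start, q_end, s_start, s_end)


def align_identity(
    query: str,
    subject: str,
    policy: MappingPolicy | None = None,
    mode: str = "global",
    query_id: str = "query",
    subject_id: str = "subject",
    search_both_strands: bool = True,
) -> AlignmentHit:
    """Align two sequences and report percent identity of the best strand.

    Global mode is symmetric: ``identity(a, b) == identity(b, a)``.
    """
    policy = policy or MappingPolicy()
    if not query or not subject:
        raise ValueError("cannot align empty sequences")
    best: tuple | None = None
    strands = ["+", "-"] if search_both_strands else ["+"]
    for strand in strands:
        qseq = query if strand == "+" else revcomp(query)
        res = _banded_dp(_to_array(qseq), _to_array(subject), policy, mode)
        if res is None:
            continue
        key = (res.score, res.matches, -res.columns)
        if best is None or key > best[0]:
            best = (key, res, strand)
    if best is None:
        raise RuntimeError("banded alignment failed to connect endpoints")
    _, res, strand = best
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        percent_identity=100.0 * res.matches / res.columns,
        alignment_length=res.columns,
        score=res.score,
        strand=strand,
        matches=res.matches,
        query_start=res.query_start,
        query_end=res.query_end,
        subject_start=res.subject_start,
        subject_end=res.subject_end,
    )


class SeedIndex:
    """Exact k-mer postings over a reference set.

    References are indexed on their forward strand; queries are searched on
    both strands (the canonical convention here: the reported strand is the
    query strand that aligns to the forward reference).
    """

    def __init__(self, references: Mapping[str, str], k: int = 11):
        if k < 4:
            raise ValueError("seed length k must be at least 4")
        if not references:
            raise ValueError("reference set is empty")
        shortest = min(len(s) for s in references.values())
        if k > shortest:
            raise ValueError(
                f"seed length {k} exceeds shortest reference length {shortest}"
            )
        self.k = k
        self.references = {rid: seq.upper() for rid, seq in references.items()}
        self.postings: dict[str, list[tuple[str, int]]] = {}
        for rid, seq in self.references.items():
            for off in range(len(seq) - k + 1):
                self.postings.setdefault(seq[off : off + k], []).append((rid, off))

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self.postings.get(kmer.upper(), [])

    def __len__(self) -> int:
        return sum(len(v) for v in self.postings.values())


def _seed_candidates(
    query: str, index: SeedIndex, policy: MappingPolicy
) -> list[tuple[str, str, int, int]]:
    """Candidate (subject, strand, diagonal, seed_count) tuples, best first."""
    k = index.k
    step = max(policy.band_width // 2, 1)
    counts: dict[tuple[str, str, int], int] = {}
    for strand in ("+", "-"):
        seq = query.upper() if strand == "+" else revcomp(query.upper())
        for p in range(0, len(seq) - k + 1):
            for rid, off in index.lookup(seq[p : p + k]):
                bucket = (off - p) // step
                key = (rid, strand, bucket)
                counts[key] = counts.get(key, 0) + 1
    merged: dict[tuple[str, str], tuple[int, int]] = {}
    for (rid, strand, bucket), cnt in counts.items():
        key = (rid, strand)
        if key not in merged or cnt > merged[key][0]:
            merged[key] = (cnt, bucket * step + step // 2)
    cands = [
        (rid, strand, diag, cnt) for (rid, strand), (cnt, diag) in merged.items()
    ]
    cands.sort(key=lambda c: (-c[3], c[0], c[1]))
    return cands[: policy.max_candidates]


def best_hit(
    query: str,
    index: SeedIndex,
    policy: MappingPolicy | None = None,
    mode: str = "glocal",
    query_id: str = "query",
) -> AlignmentHit | None:
    """Best-scoring hit of ``query`` against the index, or None.

    Ties break by score, identity, alignment length, then lexicographically
    smallest subject id, so hit tables are deterministic.
    """
    policy = policy or MappingPolicy()
    if not query:
        raise ValueError("empty query")
    hits: list[AlignmentHit] = []
    for rid, strand, diag, _cnt in _seed_candidates(query, index, policy):
        qseq = query.upper() if strand == "+" else revcomp(query.upper())
        res = _banded_dp(
            _to_array(qseq), _to_array(index.references[rid]), policy, mode, diag
        )
        if res is None:
            continue
        hits.append(
            AlignmentHit(
                query_id=query_id,
                subject_id=rid,
                percent_identity=100.0 * res.matches / res.columns,
                alignment_length=res.columns,
                score=res.score,
                strand=strand,
                matches=res.matches,
                query_start=res.query_start,
                query_end=res.query_end,
                subject_start=res.subject_start,
                subject_end=res.subject_end,
            )
        )
    if not hits:
        return None
    hits.sort(key=AlignmentHit.sort_key)
    top = hits[0]
    if top.score < policy.min_score:
        return None
    return top


def map_reads(
    reads: Mapping[str, str],
    reference: Mapping[str, str],
    policy: MappingPolicy | None = None,
    index: SeedIndex | None = None,
) -> tuple[dict[str, AlignmentHit | None], dict[str, int]]:
    """Map reads to transcripts under the length-fraction/similarity rule.

    A read counts toward a transcript iff its aligned fraction is at least
    ``policy.length_fraction`` and identity on the aligned part is at least
    ``policy.min_similarity``; each mapped read goes to exactly one
    transcript (its best hit).
    Returns (per-read assignment, per-transcript mapped-read counts).
    """
    policy = policy or MappingPolicy()
    if not reference:
        raise ValueError("reference set is empty")
    if index is None:
        index = SeedIndex(reference, policy.seed_k)
    assignments: dict[str, AlignmentHit | None] = {}
    counts: dict[str, int] = {rid: 0 for rid in reference}
    for read_id, seq in reads.items():
        hit = best_hit(seq, index, policy, mode="local", query_id=read_id)
        if hit is not None:
            frac = hit.query_span / len(seq)
            ident = hit.percent_identity / 100.0
            if frac < policy.length_fraction or ident < policy.min_similarity:
                hit = None
        assignments[read_id] = hit
        if hit is not None:
            counts[hit.subject_id] += 1
    return assignments, counts


def hits_table(hits: Iterable[AlignmentHit]):
    """Hit list as a DataFrame column-compatible with BLAST outfmt-6 prefixes."""
    import pandas as pd

    rows = [
        {
            "query": h.query_id,
            "subject": h.subject_id,
            "pident": round(h.percent_identity, 3),
            "aln_length": h.alignment_length,
            "score": h.score,
            "strand": h.strand,
        }
        for h in hits
        if h is not None
    ]
    return pd.DataFrame(rows, columns=["query", "subject", "pident", "aln_length", "score", "strand"])
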