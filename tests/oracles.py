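"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (full O(nm) dynamic programming, linear
scans, all-pairs containment) kept separate from the package so they share
no code with the paths they check.
"""

from __future__ import annotations

NEG = -(1 << 60)


def full_dp(q: str, s: str, policy, mode: str) -> tuple[int, int, int]:
    """Unbanded DP with the lexicographic (score, matches, -columns) rule.

    Returns (score, matches, columns) of the optimum for the given mode
    ('global', 'glocal', or 'local').
    """
    n, m = len(q), len(s)
    K = K2 = n + m + 2
    KK = K * K2

    def enc(sc, ma, co):
        return sc * KK + ma * K2 + (K2 - 1 - co)

    v0 = enc(0, 0, 0)
    am = enc(policy.match_score, 1, 1) - v0
    ax = enc(-policy.mismatch_cost, 0, 1) - v0
    ai = enc(-policy.insertion_cost, 0, 1) - v0
    ad = enc(-policy.deletion_cost, 0, 1) - v0
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    for j in range(m + 1):
        M[0][j] = v0 + ad * j if mode == "global" else v0
    for i in range(1, n + 1):
        M[i][0] = v0 if mode == "local" else v0 + ai * i
    qu, su = q.upper(), s.upper()
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            d = M[i - 1][j - 1] + (am if qu[i - 1] == su[j - 1] else ax)
            u = M[i - 1][j] + ai
            l = M[i][j - 1] + ad
            v = max(d, u, l)
            if mode == "local":
                v = max(v, v0)
            M[i][j] = v
    if mode == "global":
        v = M[n][m]
    elif mode == "glocal":
        v = max(M[n])
    else:
        v = max(max(row) for row in M)
    columns = K2 - 1 - (v % K2)
    matches = (v % KK) // K2
    score = v // KK
    return score, matches, columns


def brute_trim(sequence: str, qualities, floor: int, min_fraction: float):
    """Reference end-trimmer: locate the first/last base at or above the
    floor, cut there, then apply the survival-length test."""
    good = [i for i, qv in enumerate(qualities) if qv >= floor]
    if not good:
        surviving = ""
        kept_q = []
    else:
        surviving = sequence[good[0] : good[-1] + 1]
        kept_q = list(qualities[good[0] : good[-1] + 1])
    if len(surviving) < min_fraction * len(sequence):
        return None
    return surviving, kept_q


def brute_containment(unigenes: dict) -> set:
    """All-pairs containment: ids removed because their sequence (or its
    reverse complement) occurs inside a longer retained sequence."""
    comp = str.maketrans("ACGT", "TGCA")

    def rc(x):
        return x.translate(comp)[::-1]

    order = sorted(unigenes, key=lambda u: (-len(unigenes[u]), u))
    removed = set()
    for idx, uid in enumerate(order):
        seq = unigenes[uid].upper()
        for other in order[:idx]:
            if other in removed:
                continue
            hay = unigenes[other].upper()
            if seq in hay or rc(seq) in hay:
                removed.add(uid)
                break
    return removed
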