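"""Brute-force affine-gap Smith-Waterman oracle for alignment tests.

Independent of the package's alignment backend: a plain dynamic program
(Gotoh recurrences) over the full score matrix, numba-compiled for speed.
Match +1, mismatch -1; a gap of length n costs 4 + (n - 1) * 1.
"""

import numpy as np
from numba import njit

GAP_OPEN = 4  # cost of the first gap column
GAP_EXT = 1


@njit(cache=False)
def _sw_best_score(q: np.ndarray, s: np.ndarray) -> int:
    n, m = len(q), len(s)
    NEG = -(10**9)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = 1 if q[i - 1] == s[j - 1] else -1
            E[i, j] = max(H[i, j - 1] - GAP_OPEN, E[i, j - 1] - GAP_EXT)
            F[i, j] = max(H[i - 1, j] - GAP_OPEN, F[i - 1, j] - GAP_EXT)
            h = H[i - 1, j - 1] + sub
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
    return best


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8).astype(np.int64)


def sw_score(query: str, subject: str) -> int:
    """Maximum local alignment score of query vs subject."""
    return int(_sw_best_score(_encode(query), _encode(subject)))


def best_hits(query: str, segments) -> tuple[int, set]:
    """(max score, set of segment_ids achieving it) over a germline collection."""
    scores = {seg.segment_id: sw_score(query, seg.nt_seq) for seg in segments}
    top = max(scores.values())
    return top, {k for k, v in scores.items() if v == top}
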