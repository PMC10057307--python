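"""Overlap-consensus merging of paired-end amplicon reads.

Amplicon libraries are designed so the forward and reverse mates overlap;
the merger reverse-complements the reverse mate, scans all candidate overlap
lengths and keeps the one maximizing ``matches - mismatches`` subject to a
minimum overlap length and a maximum mismatch fraction.  At disagreeing
overlap positions the base with the higher Phred quality wins and the
consensus quality is ``|q1 - q2|``; at agreeing positions it is
``min(q1 + q2, 41)``.  N bases are mismatch-neutral (score 0) and always
lose to a called base.

This is an explicit-parameter stand-in for read mergers such as PEAR; the
statistical (observed/expected alignment score) test of such tools is
deliberately not implemented — designed amplicon overlaps are long enough
that the simple maximum-score criterion suffices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np

__all__ = ["RawReadPair", "MergedRead", "MergeStats", "merge_pair", "merge_batch"]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class RawReadPair:
    read_id: str
    fwd_seq: str
    rev_seq: str
    fwd_qual: list[int]
    rev_qual: list[int]

    def __post_init__(self) -> None:
        if len(self.fwd_seq) != len(self.fwd_qual) or len(self.rev_seq) != len(self.rev_qual):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")


@dataclass
class MergedRead:
    read_id: str
    seq: str
    qual: list[int]
    overlap_len: int
    mismatches_in_overlap: int


@dataclass
class MergeStats:
    total: int = 0
    merged: int = 0
    failed: int = 0

    def as_dict(self) -> dict:
        return {"total": self.total, "merged": self.merged, "failed": self.failed}


def _to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def merge_pair(
    pair: RawReadPair,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.25,
) -> Optional[MergedRead]:
    """Merge one read pair; returns ``None`` on merge failure (no admissible overlap)."""
    if min_overlap < 10:
        raise ValueError("min_overlap must be >= 10")
    if not (0 <= max_mismatch_frac < 0.5):
        raise ValueError("max_mismatch_frac must be in [0, 0.5)")

    fwd = pair.fwd_seq
    rc = revcomp(pair.rev_seq)
    rc_qual = pair.rev_qual[::-1]

    f_arr, r_arr = _to_array(fwd), _to_array(rc)
    n_code = ord("N")
    best = None  # (score, overlap, mismatches)
    for o in range(min_overlap, min(len(fwd), len(rc)) + 1):
        x, y = f_arr[len(fwd) - o :], r_arr[:o]
        informative = (x != n_code) & (y != n_code)
        matches = int(np.count_nonzero((x == y) & informative))
        mismatches = int(np.count_nonzero((x != y) & informative))
        if mismatches > max_mismatch_frac * o:
            continue
        score = matches - mismatches
        if best is None or score > best[0]:
            best = (score, o, mismatches)
    if best is None or best[0] <= 0:
        return None

    _, o, mismatches = best
    head_seq, head_qual = fwd[: len(fwd) - o], pair.fwd_qual[: len(fwd) - o]
    tail_seq, tail_qual = rc[o:], rc_qual[o:]
    mid_seq: list[str] = []
    mid_qual: list[int] = []
    for i in range(o):
        b1, b2 = fwd[len(fwd) - o + i], rc[i]
        q1, q2 = pair.fwd_qual[len(fwd) - o + i], rc_qual[i]
        if b1 == b2:
            mid_seq.append(b1)
            mid_qual.append(min(q1 + q2, 41))
        elif b1 == "N":
            mid_seq.append(b2)
            mid_qual.append(q2)
        elif b2 == "N":
            mid_seq.append(b1)
            mid_qual.append(q1)
        else:
            # ties go to the forward mate
            mid_seq.append(b1 if q1 >= q2 else b2)
            mid_qual.append(abs(q1 - q2))
    seq = head_seq + "".join(mid_seq) + tail_seq
    qual = list(head_qual) + mid_qual + list(tail_qual)
    assert len(seq) == len(fwd) + len(rc) - o
    return MergedRead(pair.read_id, seq, qual, o, mismatches)


def merge_batch(
    pairs: Iterable[RawReadPair],
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.25,
) -> tuple[list[MergedRead], MergeStats]:
    """Merge a stream of pairs; failures are counted, not raised."""
    stats = MergeStats()
    merged: list[MergedRead] = []
    for pair in pairs:
        stats.total += 1
        result = merge_pair(pair, min_overlap, max_mismatch_frac)
        if result is None:
            stats.failed += 1
        else:
            stats.merged += 1
            merged.append(result)
    assert stats.merged + stats.failed == stats.total
    return merged, stats
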