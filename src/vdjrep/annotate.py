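"""V/J germline assignment, translation, Kabat transfer and productivity QC.

Each merged read is aligned locally (Smith-Waterman, match +1 / mismatch -1 /
gap-open -4 / gap-extend -1, the nucleotide defaults of IgBLAST-style
annotators) against every candidate V segment of the locus, then the region
downstream of the V alignment against every J segment.  The reading frame is
inherited from the V germline through the alignment, the read is translated,
Kabat numbering is transferred from the germline, junction (CDR3) residues
between the last V-templated position and the conserved J FR4 anchor are
labelled by the junction convention, and the productivity filters are
applied: internal stop codon, frameshift (net indel length in the V
alignment not a multiple of 3, or a J anchor out of frame relative to V),
and incomplete CDRs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import biotite.sequence as bseq
import biotite.sequence.align as balign
from Bio.Seq import Seq

from .germline import GermlineSegment, GermlineSet
from .kabat import (
    CDR_BOUNDARIES,
    J_ANCHOR_POSITION,
    KabatPosition,
    UnnumberableError,
    cdr_of,
    cdr_slice,
    junction_labels,
    number_v_region,
)
from .merge import MergedRead

__all__ = [
    "SegmentAlignment",
    "AnnotatedSequence",
    "FilterStats",
    "align_segment",
    "annotate_read",
    "qc_filter",
    "stringent_filter",
    "DEFAULT_V_MIN_SCORE",
    "DEFAULT_J_MIN_SCORE",
]

logger = logging.getLogger(__name__)

DEFAULT_V_MIN_SCORE = 40
DEFAULT_J_MIN_SCORE = 8

FAIL_REASONS = ("stop_codon", "frameshift", "incomplete_cdrs", "no_v", "no_j")


def _nt_matrix() -> balign.SubstitutionMatrix:
    """+1 match / -1 mismatch over A,C,G,T; anything involving an ambiguity
    code (incl. N) scores 0."""
    alph = bseq.NucleotideSequence.alphabet_amb
    n = len(alph)
    scores = np.zeros((n, n), dtype=np.int32)
    for i, a in enumerate(alph):
        for j, b in enumerate(alph):
            if a in "ACGT" and b in "ACGT":
                scores[i, j] = 1 if a == b else -1
    return balign.SubstitutionMatrix(alph, alph, scores)


_MATRIX = _nt_matrix()
_GAP_PENALTY = (-4, -1)


@dataclass
class SegmentAlignment:
    """A local alignment of a read region against one germline segment."""

    segment_id: str
    score: int
    identity: float
    query_start: int  # 0-based half-open on the read region
    query_end: int
    subject_start: int  # same on the germline
    subject_end: int
    trace: np.ndarray  # biotite trace: columns (query_idx, subject_idx), -1 = gap


def _trace_stats(trace: np.ndarray) -> tuple[int, int, int, int, int]:
    q_cols = trace[:, 0][trace[:, 0] != -1]
    s_cols = trace[:, 1][trace[:, 1] != -1]
    return int(q_cols.min()), int(q_cols.max()) + 1, int(s_cols.min()), int(s_cols.max()) + 1, len(trace)


def align_segment(
    query: str,
    candidates: Sequence[GermlineSegment],
    min_score: int,
) -> Optional[SegmentAlignment]:
    """Best local alignment of ``query`` against every candidate segment.

    Ties are broken by higher identity, then lexicographically smaller
    segment_id.  Returns ``None`` if the best score is below ``min_score``.
    """
    if not candidates:
        raise ValueError("empty candidate set")
    try:
        q_seq = bseq.NucleotideSequence(query)
    except Exception as exc:  # non-nucleotide characters
        raise ValueError(f"invalid query sequence: {exc}") from exc

    best: Optional[SegmentAlignment] = None
    for seg in sorted(candidates, key=lambda s: s.segment_id):
        aln = balign.align_optimal(
            q_seq,
            bseq.NucleotideSequence(seg.nt_seq),
            _MATRIX,
            gap_penalty=_GAP_PENALTY,
            local=True,
            max_number=1,
        )[0]
        identity = balign.get_sequence_identity(aln, mode="not_terminal")
        qs, qe, ss, se, _ = _trace_stats(aln.trace)
        cand = SegmentAlignment(seg.segment_id, int(aln.score), float(identity), qs, qe, ss, se, aln.trace)
        if (
            best is None
            or cand.score > best.score
            or (cand.score == best.score and cand.identity > best.identity)
        ):
            best = cand
    if best is None or best.score < min_score:
        return None
    return best


@dataclass
class AnnotatedSequence:
    """A translated, germline-annotated, Kabat-numbered V-domain read."""

    sequence_id: str
    nt_seq: str
    locus: str
    aa_seq: str = ""
    v_call: Optional[str] = None
    j_call: Optional[str] = None
    v_alignment: Optional[SegmentAlignment] = None
    j_alignment: Optional[SegmentAlignment] = None
    fail_reasons: set = field(default_factory=set)
    kabat_map: dict = field(default_factory=dict)
    #: germline residue at every V-templated Kabat position covered by the alignment
    germline_map: dict = field(default_factory=dict)
    #: Kabat positions of the germline deleted in the read
    deletions: set = field(default_factory=set)
    cdr1_aa: str = ""
    cdr2_aa: str = ""
    cdr3_aa: str = ""

    @property
    def productive(self) -> bool:
        return not self.fail_reasons

    @property
    def chain(self) -> str:
        return "H" if self.locus == "IGH" else "L"

    @property
    def v_identity(self) -> Optional[float]:
        return self.v_alignment.identity if self.v_alignment else None

    def framework_identity(self) -> Optional[float]:
        """Amino-acid identity to the germline over framework (non-CDR) positions."""
        shared = [
            p for p in self.germline_map
            if p in self.kabat_map and cdr_of(p) is None
        ]
        if not shared:
            return None
        matches = sum(self.kabat_map[p] == self.germline_map[p] for p in shared)
        return matches / len(shared)


def _codon_level_path(
    trace: np.ndarray,
    t0_query: int,
    g0_codon: int,
    n_codons: int,
) -> tuple[list[tuple[Optional[int], Optional[int]]], bool]:
    """Turn a nucleotide alignment trace into an amino-acid-level edit path.

    Returns ``(path, clean)`` where path pairs are (read codon index relative
    to t0_query, germline codon index); ``clean`` is False when a codon is
    disrupted (partially aligned, or gaps not in codon units), in which case
    the record is unnumberable.
    """
    s2q: dict[int, int] = {}
    deleted: set[int] = set()  # subject positions aligned to a query gap
    insertions: dict[int, list[int]] = {}  # keyed by preceding subject position
    last_s = None
    for q, s in trace:
        if q != -1 and s != -1:
            s2q[int(s)] = int(q)
            last_s = int(s)
        elif s == -1 and q != -1:
            insertions.setdefault(-1 if last_s is None else last_s, []).append(int(q))
        elif q == -1 and s != -1:
            deleted.add(int(s))
            last_s = int(s)

    path: list[tuple[Optional[int], Optional[int]]] = []
    clean = True
    for ci in range(g0_codon, g0_codon + n_codons):
        positions = [3 * ci + k for k in range(3)]
        nts = [s2q.get(p) for p in positions]
        in_trace = [p in s2q or p in deleted for p in positions]
        if not all(in_trace):
            # codon extends beyond the local alignment (5'/3' edge, e.g. a
            # trimmed germline tail): stop numbering here, record is fine
            break
        if all(v is None for v in nts):
            path.append((None, ci))
        elif all(v is not None for v in nts) and nts[1] == nts[0] + 1 and nts[2] == nts[0] + 2:
            if (nts[0] - t0_query) % 3 != 0:
                clean = False
                break
            path.append(((nts[0] - t0_query) // 3, ci))
        else:
            clean = False
            break
        ins = insertions.get(3 * ci + 2, [])
        if ins:
            if len(ins) % 3 != 0 or (ins[0] - t0_query) % 3 != 0:
                clean = False
                break
            for k in range(0, len(ins), 3):
                path.append(((ins[k] - t0_query) // 3, None))
    return path, clean


def annotate_read(
    read: MergedRead,
    germlines: GermlineSet,
    locus: str,
    v_min_score: int = DEFAULT_V_MIN_SCORE,
    j_min_score: int = DEFAULT_J_MIN_SCORE,
) -> AnnotatedSequence:
    """Annotate one merged read: V/J calls, translation, Kabat map, CDRs, QC flags."""
    if locus not in ("IGH", "IGK"):
        raise ValueError(f"locus must be IGH or IGK, got {locus!r}")
    annot = AnnotatedSequence(sequence_id=read.read_id, nt_seq=read.seq, locus=locus)
    chain = annot.chain

    v_candidates = germlines.by_type(locus, "V")
    j_candidates = germlines.by_type(locus, "J")

    v_aln = align_segment(read.seq, v_candidates, v_min_score)
    if v_aln is None:
        annot.fail_reasons.add("no_v")
        return annot
    annot.v_call = v_aln.segment_id
    annot.v_alignment = v_aln
    v_germ = germlines[v_aln.segment_id]

    # net indel within the V alignment
    n_ins = int(np.count_nonzero(v_aln.trace[:, 1] == -1))
    n_del = int(np.count_nonzero(v_aln.trace[:, 0] == -1))
    frameshift_v = (n_ins - n_del) % 3 != 0

    # reading frame: first aligned column sitting on a germline codon start
    t0 = None
    g0 = None
    aligned = v_aln.trace[(v_aln.trace[:, 0] != -1) & (v_aln.trace[:, 1] != -1)]
    for q, s in aligned:
        if s % 3 == 0:
            t0, g0 = int(q), int(s) // 3
            break
    if t0 is None:
        annot.fail_reasons.add("incomplete_cdrs")
        return annot
    annot.aa_seq = str(Seq(read.seq[t0 : t0 + 3 * ((len(read.seq) - t0) // 3)]).translate())

    if frameshift_v:
        annot.fail_reasons.add("frameshift")

    numbered = False
    if not frameshift_v:
        n_codons = (v_aln.subject_end + 2) // 3 - g0
        n_codons = min(n_codons, len(v_germ.aa_seq) - g0)
        path, clean = _codon_level_path(v_aln.trace, t0, g0, n_codons)
        # drop trailing partial-codon entries beyond read end
        path = [
            (q, g) for q, g in path
            if q is None or q < len(annot.aa_seq)
        ]
        if clean:
            try:
                annot.kabat_map = number_v_region(annot.aa_seq, v_germ, path)
                annot.germline_map = {
                    v_germ.kabat_numbers[g]: v_germ.aa_seq[g]
                    for _, g in path
                    if g is not None
                }
                annot.deletions = {
                    v_germ.kabat_numbers[g] for q, g in path if q is None and g is not None
                }
                numbered = True
            except UnnumberableError:
                annot.fail_reasons.add("incomplete_cdrs")
        else:
            annot.fail_reasons.add("incomplete_cdrs")

    # J assignment downstream of the V alignment
    j_region_start = v_aln.query_end
    j_query = read.seq[j_region_start:]
    j_aln = align_segment(j_query, j_candidates, j_min_score) if len(j_query) >= 12 else None
    if j_aln is None:
        annot.fail_reasons.add("no_j")
        return annot
    j_aln.query_start += j_region_start
    j_aln.query_end += j_region_start
    trace = j_aln.trace.copy()
    trace[trace[:, 0] != -1, 0] += j_region_start
    j_aln.trace = trace
    annot.j_call = j_aln.segment_id
    annot.j_alignment = j_aln
    j_germ = germlines[j_aln.segment_id]

    if j_germ.anchor_nt is None:
        annot.fail_reasons.add("incomplete_cdrs")
        return annot
    anchor_cols = j_aln.trace[
        (j_aln.trace[:, 1] == j_germ.anchor_nt) & (j_aln.trace[:, 0] != -1)
    ]
    if len(anchor_cols) == 0:
        annot.fail_reasons.add("incomplete_cdrs")
        return annot
    q_anchor = int(anchor_cols[0][0])
    if (q_anchor - t0) % 3 != 0:
        annot.fail_reasons.add("frameshift")

    if numbered and "frameshift" not in annot.fail_reasons and annot.kabat_map:
        last_v = max(annot.kabat_map)
        # numbered V residues occupy consecutive read codons from t0 (deleted
        # germline codons consume none, inserted residues are numbered too),
        # so the junction starts right after len(kabat_map) codons
        last_codon_end = t0 + 3 * len(annot.kabat_map)
        n_junction = (q_anchor - last_codon_end) // 3
        try:
            labels = junction_labels(chain, last_v, n_junction)
            for k, lab in enumerate(labels):
                aa_idx = (last_codon_end - t0) // 3 + k
                annot.kabat_map[lab] = annot.aa_seq[aa_idx]
            # J-templated FR4 positions from the anchor onward
            n_j_aa = (j_aln.subject_end - j_germ.anchor_nt) // 3
            n_j_aa = min(n_j_aa, (len(annot.aa_seq) - (q_anchor - t0) // 3))
            for k in range(n_j_aa):
                pos = KabatPosition(chain, J_ANCHOR_POSITION[chain] + k, "")
                annot.kabat_map[pos] = annot.aa_seq[(q_anchor - t0) // 3 + k]
        except UnnumberableError:
            annot.fail_reasons.add("incomplete_cdrs")

    if annot.kabat_map:
        if "*" in annot.kabat_map.values():
            annot.fail_reasons.add("stop_codon")
        annot.cdr1_aa = cdr_slice(annot.kabat_map, chain, "cdr1")
        annot.cdr2_aa = cdr_slice(annot.kabat_map, chain, "cdr2")
        annot.cdr3_aa = cdr_slice(annot.kabat_map, chain, "cdr3")
        if numbered and not (annot.cdr1_aa and annot.cdr2_aa and annot.cdr3_aa):
            annot.fail_reasons.add("incomplete_cdrs")
    return annot


@dataclass
class FilterStats:
    total: int = 0
    retained: int = 0
    fail_counts: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"total": self.total, "retained": self.retained, "fail_counts": dict(self.fail_counts)}


def qc_filter(annots: Iterable[AnnotatedSequence]) -> tuple[list[AnnotatedSequence], FilterStats]:
    """Retain exactly the productive records; count every fail reason."""
    stats = FilterStats(fail_counts={r: 0 for r in FAIL_REASONS})
    kept: list[AnnotatedSequence] = []
    for a in annots:
        stats.total += 1
        if a.productive:
            stats.retained += 1
            kept.append(a)
        else:
            for r in a.fail_reasons:
                stats.fail_counts[r] = stats.fail_counts.get(r, 0) + 1
    return kept, stats


def stringent_filter(
    annots: Iterable[AnnotatedSequence],
    germlines: GermlineSet,
    min_v_identity: float = 0.8,
    require_full_cdr12_coverage: bool = True,
) -> tuple[list[AnnotatedSequence], FilterStats]:
    """Stricter filter ahead of SHM analysis: the V alignment must cover every
    germline CDR1/CDR2 position without deletions, and the framework
    amino-acid identity must be at least ``min_v_identity``."""
    stats = FilterStats()
    kept: list[AnnotatedSequence] = []
    for a in annots:
        stats.total += 1
        ok = True
        if require_full_cdr12_coverage:
            if a.v_call is None:
                ok = False
            else:
                germ = germlines[a.v_call]
                cdr12 = [p for p in germ.kabat_numbers if cdr_of(p) in ("cdr1", "cdr2")]
                ok = all(p in a.kabat_map for p in cdr12) and not any(
                    p in a.deletions for p in cdr12
                )
        if ok:
            fw_ident = a.framework_identity()
            ok = fw_ident is not None and fw_ident >= min_v_identity
        if ok:
            stats.retained += 1
            kept.append(a)
        else:
            stats.fail_counts["stringent"] = stats.fail_counts.get("stringent", 0) + 1
    return kept, stats
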