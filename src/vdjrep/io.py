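"""Readers and writers: FASTQ pairs, merged FASTQ, AIRR-dialect TSV, truth
tables and JSON reports.

Exported coordinates follow the AIRR Rearrangement convention (1-based,
inclusive); everything in memory is 0-based half-open.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import AnnotatedSequence, SegmentAlignment
from .kabat import deserialize_kabat_map, serialize_kabat_map
from .merge import MergedRead, RawReadPair
from .simulate import SimulatedTruth, SimulationResult

__all__ = [
    "read_fastq_pairs",
    "write_fastq_pairs",
    "read_merged_fastq",
    "write_merged_fastq",
    "annotations_to_airr",
    "write_airr_tsv",
    "read_airr_tsv",
    "write_truth_tsv",
    "read_truth_tsv",
    "write_json",
]

AIRR_COLUMNS = [
    "sequence_id", "sequence", "locus", "productive", "v_call", "j_call",
    "v_identity", "fail_reasons", "cdr1_aa", "cdr2_aa", "cdr3_aa",
    "v_sequence_start", "v_sequence_end", "j_sequence_start", "j_sequence_end",
    "kabat_map", "germline_map",
]


def read_fastq_pairs(r1_path, r2_path) -> Iterator[RawReadPair]:
    """Stream mate pairs from two FASTQ files; mate-count mismatch is a hard error."""
    it1 = SeqIO.parse(str(r1_path), "fastq")
    it2 = SeqIO.parse(str(r2_path), "fastq")
    sentinel = object()
    while True:
        rec1 = next(it1, sentinel)
        rec2 = next(it2, sentinel)
        if rec1 is sentinel and rec2 is sentinel:
            return
        if rec1 is sentinel or rec2 is sentinel:
            raise ValueError("R1/R2 mate count mismatch")
        yield RawReadPair(
            read_id=rec1.id,
            fwd_seq=str(rec1.seq),
            rev_seq=str(rec2.seq),
            fwd_qual=rec1.letter_annotations["phred_quality"],
            rev_qual=rec2.letter_annotations["phred_quality"],
        )


def _fastq_record(read_id: str, seq: str, qual: list[int]) -> SeqRecord:
    rec = SeqRecord(Seq(seq), id=read_id, description="")
    rec.letter_annotations["phred_quality"] = qual
    return rec


def write_fastq_pairs(pairs: Iterable[RawReadPair], r1_path, r2_path) -> None:
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for p in pairs:
            SeqIO.write(_fastq_record(p.read_id, p.fwd_seq, p.fwd_qual), f1, "fastq")
            SeqIO.write(_fastq_record(p.read_id, p.rev_seq, p.rev_qual), f2, "fastq")


def write_merged_fastq(reads: Iterable[MergedRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            SeqIO.write(_fastq_record(r.read_id, r.seq, r.qual), fh, "fastq")


def read_merged_fastq(path) -> Iterator[MergedRead]:
    for rec in SeqIO.parse(str(path), "fastq"):
        yield MergedRead(
            read_id=rec.id,
            seq=str(rec.seq),
            qual=rec.letter_annotations["phred_quality"],
            overlap_len=0,
            mismatches_in_overlap=0,
        )


def annotations_to_airr(annots: Iterable[AnnotatedSequence]) -> pd.DataFrame:
    rows = []
    for a in annots:
        v, j = a.v_alignment, a.j_alignment
        rows.append({
            "sequence_id": a.sequence_id,
            "sequence": a.nt_seq,
            "locus": a.locus,
            "productive": "T" if a.productive else "F",
            "v_call": a.v_call or "",
            "j_call": a.j_call or "",
            "v_identity": round(v.identity, 6) if v else "",
            "fail_reasons": ";".join(sorted(a.fail_reasons)),
            "cdr1_aa": a.cdr1_aa,
            "cdr2_aa": a.cdr2_aa,
            "cdr3_aa": a.cdr3_aa,
            # AIRR convention: 1-based inclusive
            "v_sequence_start": v.query_start + 1 if v else "",
            "v_sequence_end": v.query_end if v else "",
            "j_sequence_start": j.query_start + 1 if j else "",
            "j_sequence_end": j.query_end if j else "",
            "kabat_map": serialize_kabat_map(a.kabat_map),
            "germline_map": serialize_kabat_map(a.germline_map),
        })
    return pd.DataFrame(rows, columns=AIRR_COLUMNS)


def write_airr_tsv(annots: Iterable[AnnotatedSequence], path) -> None:
    annotations_to_airr(annots).to_csv(path, sep="\t", index=False)


def read_airr_tsv(path) -> list[AnnotatedSequence]:
    """Rehydrate annotated records from an AIRR-dialect TSV (alignment traces
    are not round-tripped; coordinate columns remain available in the file)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        a = AnnotatedSequence(
            sequence_id=row["sequence_id"],
            nt_seq=row["sequence"],
            locus=row["locus"],
            v_call=row["v_call"] or None,
            j_call=row["j_call"] or None,
            fail_reasons=set(filter(None, row["fail_reasons"].split(";"))),
            kabat_map=deserialize_kabat_map(row["kabat_map"]),
            germline_map=deserialize_kabat_map(row["germline_map"]),
            cdr1_aa=row["cdr1_aa"],
            cdr2_aa=row["cdr2_aa"],
            cdr3_aa=row["cdr3_aa"],
        )
        if row["v_call"] and row["v_identity"]:
            a.v_alignment = SegmentAlignment(
                segment_id=row["v_call"],
                score=0,
                identity=float(row["v_identity"]),
                query_start=int(row["v_sequence_start"]) - 1,
                query_end=int(row["v_sequence_end"]),
                subject_start=0,
                subject_end=0,
                trace=None,
            )
        out.append(a)
    return out


def write_truth_tsv(result: SimulationResult, path) -> None:
    rows = []
    for t in result.truths:
        rows.append({
            "sequence_id": t.sequence_id,
            "v_call": t.v_call,
            "j_call": t.j_call,
            "v_trim": t.v_trim,
            "j_trim": t.j_trim,
            "n_insertion": t.n_insertion,
            "shm_nt": ";".join(f"{p}:{a}>{b}" for p, a, b in t.shm_nt),
            "aa_changes": ";".join(f"{pos}:{a}>{b}" for pos, (a, b) in sorted(t.aa_changes.items())),
            "clean_sequence": t.clean_sequence,
            "productive": "T" if t.productive else "F",
            "stop_engineered": "T" if t.stop_engineered else "F",
            "stop_codon_index": "" if t.stop_codon_index is None else t.stop_codon_index,
            "cdr3_length": t.cdr3_length,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> list[SimulatedTruth]:
    from .kabat import parse_kabat_label

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        shm_nt = []
        for token in filter(None, row["shm_nt"].split(";")):
            pos, _, change = token.partition(":")
            shm_nt.append((int(pos), change[0], change[2]))
        aa_changes = {}
        for token in filter(None, row["aa_changes"].split(";")):
            label, _, change = token.partition(":")
            aa_changes[parse_kabat_label(label)] = (change[0], change[2])
        out.append(SimulatedTruth(
            sequence_id=row["sequence_id"],
            v_call=row["v_call"],
            j_call=row["j_call"],
            v_trim=int(row["v_trim"]),
            j_trim=int(row["j_trim"]),
            n_insertion=row["n_insertion"],
            shm_nt=shm_nt,
            aa_changes=aa_changes,
            clean_sequence=row["clean_sequence"],
            productive=row["productive"] == "T",
            stop_engineered=row["stop_engineered"] == "T",
            stop_codon_index=int(row["stop_codon_index"]) if row["stop_codon_index"] else None,
            cdr3_length=int(row["cdr3_length"]),
        ))
    return out


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
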