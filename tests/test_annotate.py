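import numpy as np
import pytest

from conftest import build_read
from sw_oracle import best_hits, sw_score

from vdjrep.annotate import (
    align_segment,
    annotate_read,
    qc_filter,
    stringent_filter,
)
from vdjrep.kabat import KabatPosition, cdr_of
from vdjrep.merge import MergedRead


def test_self_alignment_identity(igh_germlines):
    seg = igh_germlines["IGHV2-5*02"]
    aln = align_segment(seg.nt_seq, igh_germlines.by_type("IGH", "V"), 40)
    assert aln.segment_id == "IGHV2-5*02"
    assert aln.identity == 1.0
    assert aln.score == len(seg.nt_seq)
    assert (aln.query_start, aln.query_end) == (0, len(seg.nt_seq))


def test_substituted_query_keeps_top_hit_and_matches_oracle(igh_germlines):
    seg = igh_germlines["IGHV2-5*02"]
    q = list(seg.nt_seq)
    for pos in (50, 130, 200):  # interior substitutions
        q[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[q[pos]]
    q = "".join(q)
    candidates = igh_germlines.by_type("IGH", "V")
    aln = align_segment(q, candidates, 40)
    assert aln.segment_id == "IGHV2-5*02"
    L = len(seg.nt_seq)
    assert aln.identity == pytest.approx((L - 3) / L)
    top, hits = best_hits(q, candidates)
    assert aln.score == top and aln.segment_id in hits


def test_random_query_scores_below_threshold(igh_germlines):
    rng = np.random.default_rng(99)
    q = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
    candidates = igh_germlines.by_type("IGH", "V")
    assert align_segment(q, candidates, 40) is None
    top, _ = best_hits(q, candidates)
    assert top < 40


def test_alignment_agrees_with_bruteforce_oracle(igh_germlines, igk_germlines):
    """Score and call agree with an independent affine-gap Smith-Waterman DP
    on random germline-derived and random queries (<=120 nt)."""
    rng = np.random.default_rng(20230517)
    segments = list(igh_germlines.by_type("IGH", "V")) + list(igk_germlines.by_type("IGK", "V"))
    n_checked = 0
    for k in range(200):
        if k % 2 == 0:
            src = segments[int(rng.integers(len(segments)))].nt_seq
            start = int(rng.integers(0, len(src) - 60))
            q = list(src[start : start + int(rng.integers(40, 121))])
            for _ in range(int(rng.integers(0, 6))):  # sprinkle mutations
                pos = int(rng.integers(len(q)))
                q[pos] = "ACGT"[int(rng.integers(4))]
            q = "".join(q)
        else:
            q = "".join("ACGT"[i] for i in rng.integers(0, 4, int(rng.integers(30, 121))))
        aln = align_segment(q, segments, min_score=0)
        top, hits = best_hits(q, segments)
        if aln is None:
            assert top <= 0
            continue
        assert aln.score == top
        assert aln.segment_id in hits
        n_checked += 1
    assert n_checked >= 150


def test_empty_candidate_set_is_hard_error():
    with pytest.raises(ValueError, match="empty"):
        align_segment("ACGTACGTACGT", [], 10)


def test_noiseless_read_recovers_truth_calls(igh_germlines):
    read = build_read(igh_germlines, "IGHV4-34*01", "IGHJ4*02")
    a = annotate_read(read, igh_germlines, "IGH")
    assert a.productive
    assert a.v_call == "IGHV4-34*01" and a.j_call == "IGHJ4*02"
    germ = igh_germlines["IGHV4-34*01"]
    # every germline position recovered with the germline residue
    assert all(a.kabat_map[p] == r for p, r in zip(germ.kabat_numbers, germ.aa_seq))
    # CDR3 = 2 V-templated + 3 junction + 4 J-templated residues
    assert len(a.cdr3_aa) == 9


def test_engineered_stop_codon_flagged(igh_germlines):
    read = build_read(
        igh_germlines, "IGHV2-5*02", "IGHJ4*02",
        v_edit=lambda v: v[:120] + "TAA" + v[123:],
    )
    a = annotate_read(read, igh_germlines, "IGH")
    assert "stop_codon" in a.fail_reasons
    assert not a.productive


def test_single_nt_deletion_is_frameshift(igh_germlines):
    read = build_read(
        igh_germlines, "IGHV2-5*02", "IGHJ4*02",
        v_edit=lambda v: v[:120] + v[121:],  # 1-nt deletion in FR2
    )
    a = annotate_read(read, igh_germlines, "IGH")
    assert "frameshift" in a.fail_reasons


def test_out_of_frame_junction_is_frameshift(igh_germlines):
    read = build_read(igh_germlines, "IGHV2-5*02", "IGHJ4*02", n_region="GGTA")
    a = annotate_read(read, igh_germlines, "IGH")
    assert "frameshift" in a.fail_reasons


def test_codon_insertion_numbered_with_letters(igh_germlines):
    # 6 inserted nt right after the codon of Kabat H35 -> H35a, H35b
    read = build_read(
        igh_germlines, "IGHV2-5*02", "IGHJ4*02",
        v_edit=lambda v: v[:105] + "CCGTGG" + v[105:],
    )
    a = annotate_read(read, igh_germlines, "IGH")
    assert a.productive
    assert str(KabatPosition("H", 35, "a")) in [str(p) for p in a.kabat_map]
    assert a.kabat_map[KabatPosition("H", 35, "a")] == "P"
    assert a.kabat_map[KabatPosition("H", 35, "b")] == "W"
    assert len(a.cdr1_aa) == 7


def test_no_v_and_no_j_flags(igh_germlines):
    rng = np.random.default_rng(5)
    junk = "".join("ACGT"[i] for i in rng.integers(0, 4, 350))
    a = annotate_read(MergedRead("junk", junk, [30] * 350, 0, 0), igh_germlines, "IGH")
    assert "no_v" in a.fail_reasons
    v_only = igh_germlines["IGHV2-5*02"].nt_seq
    a = annotate_read(MergedRead("vonly", v_only, [30] * len(v_only), 0, 0), igh_germlines, "IGH")
    assert a.v_call == "IGHV2-5*02"
    assert "no_j" in a.fail_reasons


def test_qc_filter_counts_and_idempotence(igh_germlines):
    reads = [build_read(igh_germlines, "IGHV4-34*01", "IGHJ4*02", read_id=f"c{i}") for i in range(6)]
    reads += [
        build_read(igh_germlines, "IGHV2-5*02", "IGHJ4*02",
                   v_edit=lambda v: v[:120] + "TAA" + v[123:], read_id=f"s{i}")
        for i in range(3)
    ]
    reads += [
        build_read(igh_germlines, "IGHV2-5*02", "IGHJ4*02",
                   v_edit=lambda v: v[:120] + v[121:], read_id="fs")
    ]
    annots = [annotate_read(r, igh_germlines, "IGH") for r in reads]
    kept, stats = qc_filter(annots)
    assert len(kept) == 6
    assert stats.total == 10 and stats.retained == 6
    assert stats.fail_counts["stop_codon"] == 3
    assert stats.fail_counts["frameshift"] == 1
    again, stats2 = qc_filter(kept)
    assert [a.sequence_id for a in again] == [a.sequence_id for a in kept]
    assert stats2.retained == stats2.total == 6


def test_qc_filter_empty_input():
    kept, stats = qc_filter([])
    assert kept == [] and stats.total == 0


def test_stringent_filter_coverage_and_identity(igh_germlines):
    clean = [
        annotate_read(build_read(igh_germlines, "IGHV4-34*01", "IGHJ4*02", read_id=f"g{i}"),
                      igh_germlines, "IGH")
        for i in range(3)
    ]
    kept, _ = stringent_filter(clean, igh_germlines)
    assert len(kept) == 3  # germline-identical records are retained

    # a read whose V starts inside CDR1 violates CDR1/2 coverage
    germ = igh_germlines["IGHV4-34*01"]
    from vdjrep.simulate import CONST_3P
    j = igh_germlines["IGHJ4*02"].nt_seq
    core = germ.nt_seq[96:] + "GGTACTCGA" + j  # V truncated at codon 32
    read = MergedRead("trunc", core + CONST_3P, [35] * (len(core) + len(CONST_3P)), 0, 0)
    a = annotate_read(read, igh_germlines, "IGH")
    assert a.v_call == "IGHV4-34*01"
    kept, stats = stringent_filter(clean + [a], igh_germlines)
    assert len(kept) == 3 and stats.fail_counts.get("stringent") == 1

    # low framework identity removed: scatter single-nt changes over FR3 codons
    def heavy_mut(v):
        out = list(v)
        for i in range(199, 270, 9):  # 2nd position of every 3rd FR3 codon
            out[i] = "G" if out[i] != "G" else "C"
        return "".join(out)

    noisy = annotate_read(
        build_read(igh_germlines, "IGHV4-34*01", "IGHJ4*02", v_edit=heavy_mut, read_id="noisy"),
        igh_germlines, "IGH",
    )
    kept, _ = stringent_filter([noisy], igh_germlines, min_v_identity=0.95)
    assert kept == []
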