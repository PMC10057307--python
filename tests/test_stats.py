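import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vdjrep.annotate import AnnotatedSequence
from vdjrep.kabat import KabatPosition
from vdjrep.stats import (
    PositionComposition,
    cdr3_length_distribution,
    diversity_ratio,
    family_abundance,
    germline_position_composition,
    position_composition,
    positional_diversity,
    redundancy_profile,
    vj_pairing,
)


def annot(v_call=None, j_call=None, cdr3="", kabat=None, seq_id="x"):
    a = AnnotatedSequence(sequence_id=seq_id, nt_seq="", locus="IGH")
    a.v_call, a.j_call, a.cdr3_aa = v_call, j_call, cdr3
    a.kabat_map = kabat or {}
    return a


class TestRedundancy:
    def test_hand_counted_example(self):
        prof = redundancy_profile(["s1", "s1", "s2", "s3"])
        assert prof.histogram == {1: 0.5, 2: 0.5}
        assert prof.unique_fraction == 0.5

    def test_all_distinct(self):
        prof = redundancy_profile([f"s{i}" for i in range(100)])
        assert prof.unique_fraction == 1.0

    def test_single_class(self):
        prof = redundancy_profile(["s"] * 5)
        assert prof.histogram == {5: 1.0}
        assert prof.unique_fraction == 0.0

    def test_empty_is_hard_error(self):
        with pytest.raises(ValueError):
            redundancy_profile([])

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.text(alphabet="AB", min_size=1, max_size=3), min_size=1, max_size=40))
    def test_fractions_sum_to_one_and_permutation_invariant(self, seqs):
        prof = redundancy_profile(seqs)
        assert abs(sum(prof.histogram.values()) - 1.0) < 1e-9
        shuffled = list(reversed(seqs))
        assert redundancy_profile(shuffled).histogram == prof.histogram


class TestAbundance:
    def test_hand_counted_families(self):
        annots = (
            [annot(v_call="IGHV4-34*01") for _ in range(4)]
            + [annot(v_call="IGHV2-5*02") for _ in range(3)]
            + [annot(v_call="IGHV6-1*01") for _ in range(3)]
        )
        assert family_abundance(annots) == {"VH2": 30.0, "VH4": 40.0, "VH6": 30.0}

    def test_single_record(self):
        assert family_abundance([annot(v_call="IGKV4-1*01")]) == {"Vκ4": 100.0}

    def test_gene_level_refines_family_level(self):
        annots = (
            [annot(v_call="IGHV4-34*01")] * 3
            + [annot(v_call="IGHV4-59*01")] * 2
            + [annot(v_call="IGHV2-5*02")] * 5
        )
        fam = family_abundance(annots, "family")
        gene = family_abundance(annots, "gene")
        assert fam["VH4"] == pytest.approx(gene["VH4-34"] + gene["VH4-59"])
        assert fam["VH2"] == pytest.approx(gene["VH2-5"])
        assert sum(fam.values()) == pytest.approx(100.0, abs=1e-6)

    def test_empty_is_hard_error(self):
        with pytest.raises(ValueError):
            family_abundance([])


class TestVjPairing:
    def test_single_record_single_cell(self):
        mat = vj_pairing([annot(v_call="IGHV2-5*02", j_call="IGHJ4*02")])
        assert mat.loc["VH2", "JH4"] == 100.0

    def test_hand_counted_fixture_and_marginals(self):
        annots = (
            [annot(v_call="IGHV4-34*01", j_call="IGHJ4*02")] * 8
            + [annot(v_call="IGHV4-34*01", j_call="IGHJ6*01")] * 6
            + [annot(v_call="IGHV2-5*02", j_call="IGHJ4*02")] * 4
            + [annot(v_call="IGHV6-1*01", j_call="IGHJ1*01")] * 2
        )
        mat = vj_pairing(annots, "family")
        assert mat.loc["VH4", "JH4"] == 40.0
        assert mat.loc["VH4", "JH6"] == 30.0
        assert mat.values.sum() == pytest.approx(100.0, abs=1e-6)
        v_marg = mat.sum(axis=1).to_dict()
        assert v_marg == pytest.approx(family_abundance(annots, "family", "v"))
        j_marg = mat.sum(axis=0).to_dict()
        assert j_marg == pytest.approx(family_abundance(annots, "family", "j"))


class TestCdr3Lengths:
    def test_single_record(self):
        assert cdr3_length_distribution([annot(cdr3="A" * 13)]) == {13: 100.0}

    def test_hand_counted(self):
        annots = [annot(cdr3="A" * 8)] * 3 + [annot(cdr3="C" * 9)] * 7
        assert cdr3_length_distribution(annots) == {8: 30.0, 9: 70.0}

    def test_empty_is_hard_error(self):
        with pytest.raises(ValueError):
            cdr3_length_distribution([])


def kmap(chain, residues, start=31):
    return {KabatPosition(chain, start + i): r for i, r in enumerate(residues)}


class TestComposition:
    def test_two_records_differing_at_one_position(self):
        a1 = annot(kabat=kmap("H", "NDY"))
        a2 = annot(kabat=kmap("H", "DDY"))
        comp = position_composition([a1, a2])
        h31 = KabatPosition("H", 31)
        assert comp.frequencies[h31] == {"D": 0.5, "N": 0.5}
        for pos in (KabatPosition("H", 32), KabatPosition("H", 33)):
            assert max(comp.frequencies[pos].values()) == 1.0

    def test_frequencies_normalize(self):
        rng = np.random.default_rng(3)
        annots = [
            annot(kabat=kmap("H", "".join("ACDEFG"[i] for i in rng.integers(0, 6, 5))))
            for _ in range(50)
        ]
        comp = position_composition(annots)
        for freqs in comp.frequencies.values():
            assert sum(freqs.values()) == pytest.approx(1.0, abs=1e-9)

    def test_region_restriction(self, igh_germlines):
        comp = germline_position_composition(igh_germlines, "IGH", region="cdr1")
        assert all(31 <= p.number <= 35 for p in comp.frequencies)
        assert all(occ == 7 for occ in comp.occupancy.values())  # 7 toy V segments


class TestDiversity:
    def test_monomorphic_position(self):
        comp = PositionComposition({KabatPosition("H", 31): {"A": 1.0}}, {KabatPosition("H", 31): 4})
        div = positional_diversity(comp)
        assert div.diversity[KabatPosition("H", 31)] == 1.0

    def test_quoted_formula_examples(self):
        p = KabatPosition("H", 50)
        div = positional_diversity(
            PositionComposition({p: {"A": 0.5, "B": 0.25, "C": 0.25}}, {p: 4})
        )
        assert div.diversity[p] == pytest.approx(6.0)  # {A,A,B,C}: 3 / 0.5
        div = positional_diversity(PositionComposition({p: {"A": 0.5, "B": 0.5}}, {p: 10}))
        assert div.diversity[p] == pytest.approx(4.0)  # {Ax5,Bx5}: 2 / 0.5

    def test_matches_bruteforce_oracle_on_random_compositions(self):
        rng = np.random.default_rng(20230101)
        residues = "ACDEFGHIKLMNPQRSTVWY"
        for trial in range(100):
            counts = rng.integers(0, 30, size=20)
            if counts.sum() == 0:
                counts[0] = 1
            pool = [residues[i] for i, c in enumerate(counts) for _ in range(c)]
            p = KabatPosition("H", 31)
            total = counts.sum()
            freqs = {residues[i]: c / total for i, c in enumerate(counts) if c}
            div = positional_diversity(PositionComposition({p: freqs}, {p: int(total)}))
            # independent brute force: count distinct, find the mode
            from collections import Counter

            ctr = Counter(pool)
            expected = len(ctr) / (ctr.most_common(1)[0][1] / total)
            assert div.diversity[p] == pytest.approx(expected)
            assert div.distinct[p] <= div.diversity[p] <= div.distinct[p] ** 2 <= 400

    def test_ratio_identity_and_separated_positions(self):
        p1, p2, p3 = (KabatPosition("H", n) for n in (31, 32, 33))
        lib = positional_diversity(
            PositionComposition({p1: {"A": 0.5, "B": 0.5}, p2: {"A": 1.0}, p3: {"C": 1.0}},
                                {p1: 4, p2: 4, p3: 4})
        )
        ref = positional_diversity(
            PositionComposition({p1: {"A": 1.0}, p2: {"A": 1.0}}, {p1: 2, p2: 2})
        )
        res = diversity_ratio(lib, ref)
        assert res.per_position[p1] == pytest.approx(4.0)
        assert res.per_position[p2] == pytest.approx(1.0)
        assert res.mean == pytest.approx(2.5)
        assert res.library_only == [p3]
        same = diversity_ratio(lib, lib)
        assert same.mean == pytest.approx(1.0)

    def test_no_shared_positions_is_hard_error(self):
        p1, p2 = KabatPosition("H", 31), KabatPosition("H", 32)
        a = positional_diversity(PositionComposition({p1: {"A": 1.0}}, {p1: 1}))
        b = positional_diversity(PositionComposition({p2: {"A": 1.0}}, {p2: 1}))
        with pytest.raises(ValueError):
            diversity_ratio(a, b)


class TestShmDiversityMonotonicity:
    def test_mean_cdr12_diversity_never_decreases_with_shm_rate(self, igh_germlines):
        """More hypermutation can only broaden per-position residue usage, so
        the mean CDR1/2 positional diversity is non-decreasing in the SHM
        rate (checked at three rates with fixed seeds, on truth-derived
        residue maps)."""
        from vdjrep.kabat import cdr_of
        from vdjrep.simulate import SimulationConfig, simulate_repertoire
        from vdjrep.stats import _composition_from_maps

        means = []
        for rate in (0.0, 0.01, 0.03):
            res = simulate_repertoire(SimulationConfig(
                germlines=igh_germlines, locus="IGH", n_sequences=400, seed=555,
                shm_rate=rate, seq_error_rate=0.0, stop_codon_fraction=0.0,
            ))
            maps = []
            for t in res.truths:
                germ = igh_germlines[t.v_call]
                kmap = dict(zip(germ.kabat_numbers, germ.aa_seq))
                for pos, (_, obs) in t.aa_changes.items():
                    kmap[pos] = obs
                maps.append({
                    p: r for p, r in kmap.items() if cdr_of(p) in ("cdr1", "cdr2") and r != "*"
                })
            div = positional_diversity(_composition_from_maps(maps, None))
            means.append(sum(div.diversity.values()) / len(div.diversity))
        assert means[0] <= means[1] <= means[2]
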