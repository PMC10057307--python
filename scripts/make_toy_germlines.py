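"""One-off generator for the packaged synthetic toy germline set.

Run from repo root:  python scripts/make_toy_germlines.py
Writes src/vdjrep/data/toy_germline_{igh,igk}.fasta and toy_kabat_{igh,igk}.tsv.

Design constraints (see docs/methods.md):
- 7 V + 4 J per locus; segments within a locus pairwise >= 15% nt divergent
  (random independent codons give ~70%), so top-hit assignment is unambiguous.
- IGH V: 96 aa covering Kabat H1-H96 (two residues into HCDR3);
  IGK V: 95 aa covering Kabat L1-L95 (seven residues into LCDR3).
- Conserved landmarks for realism: C22/W36/C92 (H), C23/W35/C88 (L).
- J segments: CDR3-contributing residues (no W on H / no F on K before the
  anchor) followed by an FR4 with the conserved W-G-x-G / F-G-x-G anchor.
"""

import random
from pathlib import Path

CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "N": ["AAT", "AAC"], "D": ["GAT", "GAC"], "C": ["TGT", "TGC"],
    "Q": ["CAA", "CAG"], "E": ["GAA", "GAG"], "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"], "I": ["ATT", "ATC", "ATA"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"], "K": ["AAA", "AAG"],
    "M": ["ATG"], "F": ["TTT", "TTC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"], "T": ["ACT", "ACC", "ACA", "ACG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"], "V": ["GTT", "GTC", "GTA", "GTG"],
}

rng = random.Random(20230411)

AA_POOL = "ARNDQEGHILKMFPSTYV"  # no C/W in random draws; landmarks are fixed


def random_aa(n):
    return "".join(rng.choice(AA_POOL) for _ in range(n))


def encode(aa):
    return "".join(rng.choice(CODONS[c]) for c in aa)


def make_v(length, landmarks):
    aa = list(random_aa(length))
    for pos, res in landmarks.items():  # 1-based Kabat == index+1 (no insertions)
        aa[pos - 1] = res
    return "".join(aa)


def main():
    out = Path(__file__).resolve().parents[1] / "src" / "vdjrep" / "data"
    out.mkdir(parents=True, exist_ok=True)

    igh_v_ids = ["IGHV1-2*01", "IGHV1-69*01", "IGHV2-5*02", "IGHV3-23*01",
                 "IGHV4-34*01", "IGHV4-59*01", "IGHV6-1*01"]
    igk_v_ids = ["IGKV1-5*01", "IGKV1-39*01", "IGKV2-28*01", "IGKV2D-29*01",
                 "IGKV3-20*01", "IGKV4-1*01", "IGKV5-2*01"]
    igh_j = {
        "IGHJ1*01": ("AEYF", "WGQGTLVTVSS"),
        "IGHJ3*02": ("DAGD", "WGQGTMVTVSS"),
        "IGHJ4*02": ("YGDY", "WGQGTLVTVSS"),
        "IGHJ6*01": ("YYGM", "WGKGTTVTVSS"),
    }
    igk_j = {
        "IGKJ1*01": ("RT", "FGQGTKVEIK"),
        "IGKJ2*01": ("YS", "FGQGTKLEIK"),
        "IGKJ4*01": ("LT", "FGGGTKVEIK"),
    }

    for locus, v_ids, j_map, v_len, landmarks in [
        ("igh", igh_v_ids, igh_j, 96, {1: "E", 22: "C", 36: "W", 92: "C"}),
        ("igk", igk_v_ids, igk_j, 95, {1: "D", 23: "C", 35: "W", 88: "C"}),
    ]:
        fasta, sidecar = [], []
        chain = "H" if locus == "igh" else "L"
        for vid in v_ids:
            aa = make_v(v_len, landmarks)
            fasta.append(f">{vid}\n{encode(aa)}")
            sidecar.append(f"{vid}\t" + ",".join(f"{chain}{i}" for i in range(1, v_len + 1)))
        for jid, (cdr3_part, fr4) in j_map.items():
            fasta.append(f">{jid}\n{encode(cdr3_part + fr4)}")
        (out / f"toy_germline_{locus}.fasta").write_text("\n".join(fasta) + "\n")
        (out / f"toy_kabat_{locus}.tsv").write_text("\n".join(sidecar) + "\n")
        print(f"{locus}: {len(v_ids)} V + {len(j_map)} J written")


if __name__ == "__main__":
    main()
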