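import numpy as np
import pytest

from vdjrep.germline import GermlineSet, load_toy_germline_set
from vdjrep.merge import MergedRead


@pytest.fixture(scope="session")
def igh_germlines() -> GermlineSet:
    return load_toy_germline_set("IGH")


@pytest.fixture(scope="session")
def igk_germlines() -> GermlineSet:
    return load_toy_germline_set("IGK")


def build_read(
    germlines: GermlineSet,
    v_id: str,
    j_id: str,
    n_region: str = "GGTACTCGA",
    v_trim: int = 0,
    j_trim: int = 0,
    v_edit=None,
    read_id: str = "fixture",
) -> MergedRead:
    """Construct a clean merged read from germline parts.

    ``v_edit`` optionally transforms the V nucleotide string (to engineer
    stops, substitutions, indels or insertions).  With default arguments the
    junction stays in frame (toy V/J lengths and anchors are codon-aligned,
    so any ``n_region`` whose length compensates the trims keeps frame).
    """
    from vdjrep.simulate import CONST_3P, CONST_5P

    v = germlines[v_id].nt_seq
    j = germlines[j_id].nt_seq
    v_part = v[: len(v) - v_trim] if v_trim else v
    if v_edit is not None:
        v_part = v_edit(v_part)
    core = v_part + n_region + j[j_trim:]
    seq = CONST_5P + core + CONST_3P
    return MergedRead(read_id, seq, [40] * len(seq), overlap_len=len(seq), mismatches_in_overlap=0)
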