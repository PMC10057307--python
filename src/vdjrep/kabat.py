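"""Kabat numbering of antibody V domains.

The Kabat scheme assigns fixed positional labels to structurally equivalent
residues of heavy (H) and kappa light (L) chain variable domains, absorbing
loop-length variation with lettered insertion codes (e.g. H52a-c, L27a-f).
Numbering here is transferred from an aligned germline segment whose own
Kabat map is known, which makes the assignment deterministic and testable:
matched/substituted residues inherit the germline label, insertions receive
letters at the sanctioned sites, deletions drop labels.

CDR boundaries (Kabat definition, inclusive):
  H: CDR1 31-35, CDR2 50-65, CDR3 95-102
  L: CDR1 24-34, CDR2 50-56, CDR3 89-97
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "KabatPosition",
    "UnnumberableError",
    "CDR_BOUNDARIES",
    "INSERTION_SITES",
    "J_ANCHOR_POSITION",
    "parse_kabat_label",
    "cdr_of",
    "number_v_region",
    "cdr_slice",
    "junction_labels",
    "serialize_kabat_map",
    "deserialize_kabat_map",
]

_INSERTION_ALPHABET = "abcdefghijklmnopqrstuvwxyz"


@dataclass(frozen=True, order=False)
class KabatPosition:
    """A single Kabat label: chain ('H' or 'L'), number, optional insertion letter."""

    chain: str
    number: int
    insertion: str = ""

    def __post_init__(self) -> None:
        if self.chain not in ("H", "L"):
            raise ValueError(f"chain must be 'H' or 'L', got {self.chain!r}")
        if self.number < 1:
            raise ValueError(f"Kabat number must be >= 1, got {self.number}")
        if self.insertion and (len(self.insertion) != 1 or self.insertion not in _INSERTION_ALPHABET):
            raise ValueError(f"invalid insertion code {self.insertion!r}")

    # ordering: by number, then no-letter < 'a' < 'b' < ...
    def _key(self):
        return (self.number, self.insertion)

    def __lt__(self, other: "KabatPosition") -> bool:
        if self.chain != other.chain:
            raise TypeError("cannot order Kabat positions of different chains")
        return self._key() < other._key()

    def __le__(self, other: "KabatPosition") -> bool:
        return self == other or self < other

    def __str__(self) -> str:
        return f"{self.chain}{self.number}{self.insertion}"

    def __repr__(self) -> str:
        return f"KabatPosition({str(self)!r})"


_LABEL_RE = re.compile(r"^([HL])(\d+)([a-z]?)$")


def parse_kabat_label(label: str) -> KabatPosition:
    m = _LABEL_RE.match(label)
    if m is None:
        raise ValueError(f"cannot parse Kabat label {label!r}")
    return KabatPosition(m.group(1), int(m.group(2)), m.group(3))


class UnnumberableError(ValueError):
    """Raised when a sequence cannot be assigned a valid Kabat numbering
    (insertion at a non-sanctioned site, or more insertions than the scheme
    sanctions).  Such records are treated as incomplete downstream."""


#: Inclusive Kabat number ranges of the CDRs; insertion-lettered positions
#: within a range belong to that CDR.
CDR_BOUNDARIES: Mapping[str, Mapping[str, tuple[int, int]]] = {
    "H": {"cdr1": (31, 35), "cdr2": (50, 65), "cdr3": (95, 102)},
    "L": {"cdr1": (24, 34), "cdr2": (50, 56), "cdr3": (89, 97)},
}

#: Sanctioned insertion sites and their maximal letter runs.
INSERTION_SITES: Mapping[str, Mapping[int, str]] = {
    "H": {35: "ab", 52: "abc", 82: "abc", 100: "abcdefghijk"},
    "L": {27: "abcdef", 95: "abcdef"},
}

#: First framework-4 position encoded by the J segment (the conserved
#: W-G-x-G tryptophan on H, F-G-x-G phenylalanine on L).
J_ANCHOR_POSITION = {"H": 103, "L": 98}

# CDR3 junction conventions: insertion letters go after this position ...
_CDR3_INSERTION_POINT = {"H": 100, "L": 95}
# ... and short loops drop positions in this order (anchor-adjacent terminal
# residue, H102 / L97, is never dropped).
_CDR3_DELETION_ORDER = {
    "H": [100, 101, 99, 98, 97, 96, 95],
    "L": [95, 96, 94, 93, 92, 91, 90, 89],
}


def cdr_of(pos: KabatPosition) -> Optional[str]:
    """Return 'cdr1' / 'cdr2' / 'cdr3' if the position lies in a CDR, else None."""
    for name, (lo, hi) in CDR_BOUNDARIES[pos.chain].items():
        if lo <= pos.number <= hi:
            return name
    return None


def number_v_region(
    aa_seq: str,
    germline,
    edit_path: Sequence[tuple[Optional[int], Optional[int]]],
) -> dict[KabatPosition, str]:
    """Transfer Kabat numbering from an aligned germline onto ``aa_seq``.

    ``edit_path`` is an amino-acid-level alignment path: a sequence of
    ``(query_index, germline_index)`` pairs where ``None`` marks a gap
    (``(q, None)`` = insertion in the query, ``(None, g)`` = deletion).

    Returns an ordered mapping KabatPosition -> residue.  Raises
    :class:`UnnumberableError` for insertions at non-sanctioned sites or
    beyond the sanctioned letter run.
    """
    numbers = germline.kabat_numbers
    if not numbers:
        raise ValueError(f"germline {germline.segment_id} has no Kabat map")
    chain = numbers[0].chain
    sites = INSERTION_SITES[chain]

    out: dict[KabatPosition, str] = {}
    last_pos: Optional[KabatPosition] = None
    pending_insertions: list[int] = []

    def flush_insertions() -> None:
        nonlocal last_pos
        if not pending_insertions:
            return
        if last_pos is None:
            raise UnnumberableError("insertion before any numbered position")
        base = last_pos.number
        letters = sites.get(base)
        if letters is None:
            raise UnnumberableError(f"insertion at non-sanctioned site {last_pos}")
        start = 0 if not last_pos.insertion else letters.index(last_pos.insertion) + 1
        if start + len(pending_insertions) > len(letters):
            raise UnnumberableError(f"too many insertions at Kabat {chain}{base}")
        for k, qi in enumerate(pending_insertions):
            pos = KabatPosition(chain, base, letters[start + k])
            out[pos] = aa_seq[qi]
            last_pos = pos
        pending_insertions.clear()

    for q, g in edit_path:
        if g is None:
            if q is None:
                raise ValueError("edit path column with neither query nor germline index")
            pending_insertions.append(q)
            continue
        flush_insertions()
        if q is None:  # deletion: label dropped
            last_pos = numbers[g]
            continue
        pos = numbers[g]
        out[pos] = aa_seq[q]
        last_pos = pos
    flush_insertions()
    return out


def cdr_slice(kabat_map: Mapping[KabatPosition, str], chain: str, which_cdr: str) -> str:
    """Concatenate residues whose Kabat positions fall in the given CDR range."""
    lo, hi = CDR_BOUNDARIES[chain][which_cdr]
    positions = sorted(p for p in kabat_map if lo <= p.number <= hi)
    return "".join(kabat_map[p] for p in positions)


def junction_labels(
    chain: str,
    last_v: Optional[KabatPosition],
    n_residues: int,
) -> list[KabatPosition]:
    """Kabat labels for the CDR3 junction: the ``n_residues`` positions lying
    strictly between the last V-templated position and the J anchor
    (H103 / L98).

    Insertion letters go after H100 / L95; short loops drop positions
    working outward from that point (H102 / L97 are never dropped).
    """
    anchor = J_ANCHOR_POSITION[chain]
    ins_num = _CDR3_INSERTION_POINT[chain]
    start = (last_v.number + 1) if last_v is not None else CDR_BOUNDARIES[chain]["cdr3"][0]
    canonical = list(range(start, anchor))
    if n_residues < 0:
        raise UnnumberableError("negative junction length")

    if n_residues == len(canonical):
        kept = canonical
        extra = 0
    elif n_residues > len(canonical):
        extra = n_residues - len(canonical)
        kept = canonical
        letters = INSERTION_SITES[chain][ins_num]
        offset = 0
        if last_v is not None and last_v.number == ins_num:
            # V template reaches the insertion point itself; continue its letters
            offset = 0 if not last_v.insertion else letters.index(last_v.insertion) + 1
        if ins_num not in kept and not (last_v is not None and last_v.number == ins_num):
            raise UnnumberableError(
                f"junction of {n_residues} residues but insertion point "
                f"{chain}{ins_num} is not available"
            )
        if offset + extra > len(letters):
            raise UnnumberableError(
                f"junction needs {extra} insertions at {chain}{ins_num}; "
                f"only {len(letters) - offset} sanctioned"
            )
    else:
        extra = 0
        to_drop = len(canonical) - n_residues
        droppable = [n for n in _CDR3_DELETION_ORDER[chain] if n in canonical]
        if to_drop > len(droppable):
            raise UnnumberableError(
                f"junction of {n_residues} residues too short for positions {canonical}"
            )
        dropped = set(droppable[:to_drop])
        kept = [n for n in canonical if n not in dropped]

    labels: list[KabatPosition] = []
    for n in kept:
        labels.append(KabatPosition(chain, n, ""))
        if n == ins_num and extra:
            letters = INSERTION_SITES[chain][ins_num]
            labels.extend(KabatPosition(chain, ins_num, l) for l in letters[:extra])
    if extra and ins_num not in kept:
        # insertion letters continue from the V-templated insertion point
        letters = INSERTION_SITES[chain][ins_num]
        offset = 0
        if last_v is not None and last_v.insertion:
            offset = letters.index(last_v.insertion) + 1
        labels = [KabatPosition(chain, ins_num, l) for l in letters[offset : offset + extra]] + labels
    assert len(labels) == n_residues
    return labels


def serialize_kabat_map(kabat_map: Mapping[KabatPosition, str]) -> str:
    """Render a numbered map as ``"H31:N,H32:D,..."`` (AIRR-TSV friendly)."""
    return ",".join(f"{p}:{r}" for p, r in sorted(kabat_map.items()))


def deserialize_kabat_map(text: str) -> dict[KabatPosition, str]:
    out: dict[KabatPosition, str] = {}
    if not text or text != text:  # '' or NaN
        return out
    for token in str(text).split(","):
        label, _, residue = token.partition(":")
        out[parse_kabat_label(label)] = residue
    return out
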