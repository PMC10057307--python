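"""Aggregate repertoire statistics over annotated sequences.

Covers the library quality-control readouts of a combinatorial antibody
library: sequence redundancy, germline family/gene usage, V-J pairing,
CDR3 length distribution, position-specific amino-acid composition, the
positional diversity statistic

    D(p) = (number of distinct residues at p) / (relative frequency of the
           most common residue at p)

and the per-position library-vs-germline diversity ratio.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .annotate import AnnotatedSequence
from .germline import GermlineSet, family_of
from .kabat import CDR_BOUNDARIES, KabatPosition, cdr_of

__all__ = [
    "RedundancyProfile",
    "PositionComposition",
    "PositionDiversity",
    "redundancy_profile",
    "family_abundance",
    "vj_pairing",
    "cdr3_length_distribution",
    "position_composition",
    "germline_position_composition",
    "positional_diversity",
    "diversity_ratio",
]

logger = logging.getLogger(__name__)

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class RedundancyProfile:
    """Fraction of all sequences occurring exactly n times, keyed by n."""

    histogram: dict[int, float]
    unique_fraction: float
    total: int

    def validate(self) -> None:
        assert abs(sum(self.histogram.values()) - 1.0) < 1e-9
        assert self.unique_fraction == self.histogram.get(1, 0.0)


def redundancy_profile(seqs: Iterable[str], level: str = "aa") -> RedundancyProfile:
    """Exact multiset redundancy counting.

    ``histogram[n]`` is the fraction of *sequences* (not distinct classes)
    whose sequence occurs exactly n times.  ``level`` is a bookkeeping tag
    ('aa' or 'nt'); the caller chooses which strings to pass.
    """
    if level not in ("aa", "nt"):
        raise ValueError("level must be 'aa' or 'nt'")
    counts = Counter(seqs)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty input")
    class_sizes = Counter(counts.values())  # n -> number of distinct classes seen n times
    hist = {n: n * k / total for n, k in class_sizes.items()}
    profile = RedundancyProfile(dict(sorted(hist.items())), hist.get(1, 0.0), total)
    profile.validate()
    return profile


def _percentages(counter: Counter) -> dict[str, float]:
    total = sum(counter.values())
    return {k: 100.0 * v / total for k, v in sorted(counter.items())}


def family_abundance(
    annots: Iterable[AnnotatedSequence],
    level: str = "family",
    which: str = "v",
) -> dict[str, float]:
    """Percentage abundance of each germline family or gene among the records."""
    if level not in ("family", "gene"):
        raise ValueError("level must be 'family' or 'gene'")
    call_attr = "v_call" if which == "v" else "j_call"
    counts: Counter = Counter()
    for a in annots:
        call = getattr(a, call_attr)
        if call is None:
            continue
        fam, gene = family_of(call)
        counts[fam if level == "family" else gene] += 1
    if not counts:
        raise ValueError("empty input")
    return _percentages(counts)


def vj_pairing(annots: Iterable[AnnotatedSequence], level: str = "family") -> pd.DataFrame:
    """V x J pairing matrix as percentages of all records (grand total 100)."""
    if level not in ("family", "segment"):
        raise ValueError("level must be 'family' or 'segment'")
    counts: Counter = Counter()
    for a in annots:
        if a.v_call is None or a.j_call is None:
            continue
        if level == "family":
            key = (family_of(a.v_call)[0], family_of(a.j_call)[0])
        else:
            key = (a.v_call, a.j_call)
        counts[key] += 1
    if not counts:
        raise ValueError("empty input")
    total = sum(counts.values())
    v_labels = sorted({v for v, _ in counts})
    j_labels = sorted({j for _, j in counts})
    mat = pd.DataFrame(0.0, index=v_labels, columns=j_labels)
    for (v, j), n in counts.items():
        mat.loc[v, j] = 100.0 * n / total
    return mat


def cdr3_length_distribution(annots: Iterable[AnnotatedSequence]) -> dict[int, float]:
    """Histogram of CDR3 amino-acid length, as percentages."""
    counts: Counter = Counter(len(a.cdr3_aa) for a in annots if a.cdr3_aa)
    if not counts:
        raise ValueError("empty input")
    return {int(k): v for k, v in _percentages(counts).items()}


@dataclass
class PositionComposition:
    """Per-Kabat-position residue relative frequencies and occupancy counts."""

    frequencies: dict[KabatPosition, dict[str, float]]
    occupancy: dict[KabatPosition, int]

    def positions(self) -> list[KabatPosition]:
        return sorted(self.frequencies)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"position": str(p), "residue": r, "frequency": f, "occupancy": self.occupancy[p]}
            for p in self.positions()
            for r, f in sorted(self.frequencies[p].items())
        ]
        return pd.DataFrame(rows)


def _composition_from_maps(
    maps: Iterable[Mapping[KabatPosition, str]],
    region: Optional[str],
) -> PositionComposition:
    counts: dict[KabatPosition, Counter] = defaultdict(Counter)
    for kmap in maps:
        for pos, residue in kmap.items():
            if residue not in CANONICAL_AA:
                continue
            if region is not None and cdr_of(pos) != region:
                continue
            counts[pos][residue] += 1
    freqs: dict[KabatPosition, dict[str, float]] = {}
    occ: dict[KabatPosition, int] = {}
    for pos, ctr in counts.items():
        total = sum(ctr.values())
        freqs[pos] = {r: c / total for r, c in sorted(ctr.items())}
        occ[pos] = total
    if not freqs:
        logger.warning("region %r has zero occupancy", region)
    return PositionComposition(freqs, occ)


def position_composition(
    annots: Iterable[AnnotatedSequence],
    region: Optional[str] = None,
) -> PositionComposition:
    """Relative residue frequencies at each Kabat position, over the records
    possessing that position.  ``region`` restricts to 'cdr1'/'cdr2'/'cdr3'."""
    return _composition_from_maps((a.kabat_map for a in annots), region)


def germline_position_composition(
    germlines: GermlineSet,
    locus: str,
    region: Optional[str] = None,
) -> PositionComposition:
    """Reference composition over the germline set's own residues, each V
    segment weighted equally."""
    maps = [
        dict(zip(seg.kabat_numbers, seg.aa_seq))
        for seg in germlines.by_type(locus, "V")
    ]
    return _composition_from_maps(maps, region)


@dataclass
class PositionDiversity:
    """Per-position diversity D = distinct residue count / max residue frequency."""

    diversity: dict[KabatPosition, float]
    distinct: dict[KabatPosition, int]
    max_frequency: dict[KabatPosition, float]


def positional_diversity(comp: PositionComposition) -> PositionDiversity:
    if not comp.frequencies:
        raise ValueError("composition has no occupied positions")
    div: dict[KabatPosition, float] = {}
    distinct: dict[KabatPosition, int] = {}
    maxfreq: dict[KabatPosition, float] = {}
    for pos, freqs in comp.frequencies.items():
        d = len(freqs)
        m = max(freqs.values())
        distinct[pos] = d
        maxfreq[pos] = m
        div[pos] = d / m
    return PositionDiversity(div, distinct, maxfreq)


@dataclass
class DiversityRatio:
    per_position: dict[KabatPosition, float]
    mean: float
    #: positions present in the library but absent from the reference
    library_only: list[KabatPosition] = field(default_factory=list)


def diversity_ratio(lib: PositionDiversity, ref: PositionDiversity) -> DiversityRatio:
    """Per-position D_lib/D_ref over shared positions, plus their mean.
    Library positions absent from the reference are listed, not averaged."""
    shared = sorted(set(lib.diversity) & set(ref.diversity))
    if not shared:
        raise ValueError("no shared positions between library and reference")
    ratios = {p: lib.diversity[p] / ref.diversity[p] for p in shared}
    mean = sum(ratios.values()) / len(ratios)
    lib_only = sorted(set(lib.diversity) - set(ref.diversity))
    return DiversityRatio(ratios, mean, lib_only)
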