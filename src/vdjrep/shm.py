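"""Somatic hypermutation statistics: non-germline residues in the CDRs.

SHM is quantified at the amino-acid level as differences between the
observed residue and the residue of the closest germline segment at the
same Kabat position, restricted to germline-templated CDR positions.
Heavy-chain analyses use HCDR1+2 only (HCDR3 is junction-encoded and has no
single germline template); kappa analyses support LCDR1+2 and LCDR1+2+3.

Outputs mirror a library QC report: per-sequence mutation counts binned as
0 / 1-6 / >6, per-position mutation frequencies with introduced-residue
composition, and a ranking of the most frequently introduced residues.
Because one sequence can introduce several distinct residues, per-sequence
incidences deliberately sum to more than 100%; per-event shares (which sum
to 1) are reported alongside.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .annotate import AnnotatedSequence
from .kabat import KabatPosition, cdr_of

__all__ = [
    "REGION_SETS",
    "ShmRecord",
    "shm_count",
    "shm_bin_distribution",
    "shm_position_profile",
    "introduced_residue_ranking",
]

#: region-set name -> (chain, CDRs counted)
REGION_SETS: Mapping[str, tuple[str, frozenset]] = {
    "HCDR12": ("H", frozenset({"cdr1", "cdr2"})),
    "LCDR12": ("L", frozenset({"cdr1", "cdr2"})),
    "LCDR123": ("L", frozenset({"cdr1", "cdr2", "cdr3"})),
}


@dataclass
class ShmRecord:
    sequence_id: str
    region_set: str
    mutations: list[tuple[KabatPosition, str, str]]  # (position, germline, observed)
    #: germline-templated positions of the region set covered by this record
    covered: list[KabatPosition] = field(default_factory=list)

    @property
    def mutation_count(self) -> int:
        return len(self.mutations)


def shm_count(annot: AnnotatedSequence, region_set: str) -> ShmRecord:
    """Count positions in the region set where the observed residue differs
    from the germline residue.  Junction positions without a germline
    template (including insertion-coded positions absent from the germline)
    are never counted as mutations."""
    try:
        chain, cdrs = REGION_SETS[region_set]
    except KeyError:
        raise ValueError(f"unknown region set {region_set!r}") from None
    if annot.chain != chain:
        raise ValueError(
            f"region set {region_set} requires chain {chain}, record is {annot.chain}"
        )
    mutations = []
    covered = []
    for pos, germ_res in annot.germline_map.items():
        if cdr_of(pos) not in cdrs or pos not in annot.kabat_map:
            continue
        covered.append(pos)
        obs = annot.kabat_map[pos]
        if obs != germ_res:
            mutations.append((pos, germ_res, obs))
    return ShmRecord(annot.sequence_id, region_set, sorted(mutations), sorted(covered))


@dataclass
class ShmBinDistribution:
    fractions: dict[str, float]  # keys "0", "1-6", ">6"
    mean: float
    total: int


def shm_bin_distribution(records: Iterable[ShmRecord]) -> ShmBinDistribution:
    counts = [r.mutation_count for r in records]
    if not counts:
        raise ValueError("empty input")
    n = len(counts)
    bins = {
        "0": sum(c == 0 for c in counts) / n,
        "1-6": sum(1 <= c <= 6 for c in counts) / n,
        ">6": sum(c > 6 for c in counts) / n,
    }
    assert abs(sum(bins.values()) - 1.0) < 1e-9
    return ShmBinDistribution(bins, sum(counts) / n, n)


@dataclass
class ShmPositionProfile:
    #: fraction of covering records mutated at each position
    frequency: dict[KabatPosition, float]
    #: introduced-residue composition: position -> residue -> fraction of covering records
    composition: dict[KabatPosition, dict[str, float]]
    coverage: dict[KabatPosition, int]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pos in sorted(self.frequency):
            comp = self.composition.get(pos, {})
            if not comp:
                rows.append({"position": str(pos), "introduced_residue": "",
                             "frequency": 0.0, "position_frequency": self.frequency[pos],
                             "coverage": self.coverage[pos]})
            for res, f in sorted(comp.items()):
                rows.append({"position": str(pos), "introduced_residue": res,
                             "frequency": f, "position_frequency": self.frequency[pos],
                             "coverage": self.coverage[pos]})
        return pd.DataFrame(rows)


def shm_position_profile(records: Iterable[ShmRecord]) -> ShmPositionProfile:
    """Per-position SHM frequency and introduced-residue composition.
    Denominators are per-position coverage counts (records whose germline
    template covers that position), not total records."""
    records = list(records)
    if not records:
        raise ValueError("empty input")
    coverage: Counter = Counter()
    mutated: Counter = Counter()
    introduced: dict[KabatPosition, Counter] = defaultdict(Counter)
    for rec in records:
        for pos in rec.covered:
            coverage[pos] += 1
        for pos, _, obs in rec.mutations:
            mutated[pos] += 1
            introduced[pos][obs] += 1
    frequency = {p: mutated.get(p, 0) / c for p, c in coverage.items()}
    composition = {
        p: {r: n / coverage[p] for r, n in sorted(ctr.items())}
        for p, ctr in introduced.items()
    }
    return ShmPositionProfile(frequency, composition, dict(coverage))


def introduced_residue_ranking(records: Iterable[ShmRecord]) -> pd.DataFrame:
    """Ranking of introduced residues.

    ``incidence``: fraction of records containing at least one mutation to
    that residue (the primary statistic; the values can sum to > 1).
    ``event_share``: fraction of all mutation events introducing the residue
    (sums to 1).  Sorted by descending incidence.
    """
    records = list(records)
    if not records:
        raise ValueError("empty input")
    n = len(records)
    per_seq: Counter = Counter()
    per_event: Counter = Counter()
    for rec in records:
        residues = {obs for _, _, obs in rec.mutations}
        for r in residues:
            per_seq[r] += 1
        for _, _, obs in rec.mutations:
            per_event[obs] += 1
    total_events = sum(per_event.values())
    rows = [
        {
            "residue": r,
            "incidence": per_seq[r] / n,
            "event_share": per_event[r] / total_events,
        }
        for r in per_seq
    ]
    df = pd.DataFrame(rows, columns=["residue", "incidence", "event_share"])
    return df.sort_values(
        ["incidence", "residue"], ascending=[False, True]
    ).reset_index(drop=True)
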