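"""Ground-truthed V(D)J + SHM repertoire simulator.

Emulates the amplicon structure of a combinatorial antibody library
sequencing run so that every pipeline stage is testable without external
data.  Per sequence:

1. a V and a J segment are drawn from configurable usage distributions;
2. somatic hypermutation is applied as independent per-nucleotide
   substitutions over the V region, with a multiplier inside the CDR1/2
   nucleotide spans (uniform-rate model; hotspot motifs are out of scope);
3. a junction is built: geometric V-3' and J-5' trimming plus a
   Poisson-length N-insertion of uniform base composition, with the
   N-length adjusted so the J segment stays in frame and the CDR3 length
   falls in the locus' designed range (4-19 aa for heavy, 8-15 for kappa);
4. optionally a stop codon is engineered into the V framework
   (``stop_codon_fraction``), making the sequence non-productive;
5. constant-region primer tails are attached and a read pair of fixed
   length with designed overlap is emitted, with per-base substitution
   errors at ``seq_error_rate`` and Phred qualities drawn accordingly.

Everything is deterministic under a fixed seed.  The emitted truth records
allow exact replay: applying the recorded mutations and junction onto the
germline reproduces the clean sequence byte for byte.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
from Bio.Seq import Seq

from .germline import GermlineSet
from .kabat import (
    CDR_BOUNDARIES,
    KabatPosition,
    UnnumberableError,
    cdr_of,
    junction_labels,
)
from .merge import RawReadPair, revcomp

__all__ = [
    "SimulationConfig",
    "SimulatedTruth",
    "SimulationResult",
    "simulate_repertoire",
    "RecoveryReport",
    "truth_compare",
]

# constant-region primer tails flanking every amplicon (5' leader-side and
# 3' constant-domain side), as in primer-amplified V-domain libraries
CONST_5P = "GGTGGACAGTCTACAGCAGC"
CONST_3P = "GCCTCCACCAAGGGCCCATCGGTC"

_BASES = "ACGT"

#: designed CDR3 amino-acid length window per locus
CDR3_RANGE = {"IGH": (4, 19), "IGK": (8, 15)}


@dataclass
class SimulationConfig:
    """Study conditions for one simulated repertoire."""

    germlines: GermlineSet
    locus: str
    n_sequences: int = 2000
    seed: int = 0
    v_usage: Optional[Mapping[str, float]] = None  # default: uniform
    j_usage: Optional[Mapping[str, float]] = None
    p_trim: float = 0.25  # geometric parameter; mean trim = (1-p)/p = 3 nt
    n_insert_mean: Optional[float] = None  # Poisson mean; default per locus
    shm_rate: float = 0.01  # per-nt substitution probability in the V region
    cdr_rate_multiplier: float = 3.0  # applied inside CDR1/2 nt spans
    stop_codon_fraction: float = 0.05
    read_length: int = 300
    overlap_length: int = 50  # guaranteed minimum designed overlap
    seq_error_rate: float = 0.002

    def __post_init__(self) -> None:
        if self.locus not in ("IGH", "IGK"):
            raise ValueError(f"locus must be IGH or IGK, got {self.locus!r}")
        for name in ("p_trim", "shm_rate", "stop_codon_fraction", "seq_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.cdr_rate_multiplier < 1.0:
            raise ValueError("cdr_rate_multiplier must be >= 1")
        if self.n_insert_mean is None:
            self.n_insert_mean = 21.0 if self.locus == "IGH" else 4.0
        for usage, seg_type in ((self.v_usage, "V"), (self.j_usage, "J")):
            if usage is not None:
                known = {s.segment_id for s in self.germlines.by_type(self.locus, seg_type)}
                unknown = set(usage) - known
                if unknown:
                    raise ValueError(f"usage map references unknown segment ids {sorted(unknown)}")
                if abs(sum(usage.values()) - 1.0) > 1e-9:
                    raise ValueError(f"{seg_type} usage map must sum to 1")


@dataclass
class SimulatedTruth:
    """Ground truth for one simulated sequence."""

    sequence_id: str
    v_call: str
    j_call: str
    v_trim: int
    j_trim: int
    n_insertion: str
    #: nt substitutions applied to the V segment: (position, from, to)
    shm_nt: list[tuple[int, str, str]]
    #: induced amino-acid changes on fully intact V codons: Kabat pos -> (germline, observed)
    aa_changes: dict[KabatPosition, tuple[str, str]]
    clean_sequence: str  # error-free amplicon
    productive: bool
    stop_engineered: bool
    #: codon index of an engineered framework stop (None if not engineered)
    stop_codon_index: Optional[int]
    cdr3_length: int

    def cdr_mutation_count(self, cdrs: Iterable[str]) -> int:
        wanted = set(cdrs)
        return sum(1 for pos in self.aa_changes if cdr_of(pos) in wanted)


@dataclass
class SimulationResult:
    config: SimulationConfig
    truths: list[SimulatedTruth]
    read_pairs: list[RawReadPair]

    def truth_by_id(self) -> dict[str, SimulatedTruth]:
        return {t.sequence_id: t for t in self.truths}


def _choose(rng: np.random.Generator, ids: list[str], usage: Optional[Mapping[str, float]]) -> str:
    if usage is None:
        return ids[int(rng.integers(len(ids)))]
    keys = sorted(usage)
    probs = np.array([usage[k] for k in keys])
    return keys[int(rng.choice(len(keys), p=probs / probs.sum()))]


def _cdr12_nt_mask(v_germ) -> np.ndarray:
    mask = np.zeros(len(v_germ.nt_seq), dtype=bool)
    for i, pos in enumerate(v_germ.kabat_numbers):
        if cdr_of(pos) in ("cdr1", "cdr2"):
            mask[3 * i : 3 * i + 3] = True
    return mask


def _translate(nt: str) -> str:
    return str(Seq(nt[: 3 * (len(nt) // 3)]).translate())


def simulate_repertoire(config: SimulationConfig) -> SimulationResult:
    """Generate a ground-truthed repertoire and its paired-end reads."""
    rng = np.random.default_rng(config.seed)
    locus = config.locus
    chain = "H" if locus == "IGH" else "L"
    v_ids = [s.segment_id for s in config.germlines.by_type(locus, "V")]
    j_ids = [s.segment_id for s in config.germlines.by_type(locus, "J")]
    if not v_ids or not j_ids:
        raise ValueError(f"germline set lacks V or J segments for {locus}")
    lo, hi = CDR3_RANGE[locus]

    truths: list[SimulatedTruth] = []
    pairs: list[RawReadPair] = []
    for i in range(config.n_sequences):
        seq_id = f"sim_{locus}_{i:06d}"
        v_id = _choose(rng, v_ids, config.v_usage)
        j_id = _choose(rng, j_ids, config.j_usage)
        v_germ = config.germlines[v_id]
        j_germ = config.germlines[j_id]
        anchor_nt = j_germ.anchor_nt
        assert anchor_nt is not None

        # --- SHM over the V region
        v_nt = list(v_germ.nt_seq)
        rates = np.full(len(v_nt), config.shm_rate)
        rates[_cdr12_nt_mask(v_germ)] = min(1.0, config.shm_rate * config.cdr_rate_multiplier)
        hit = rng.random(len(v_nt)) < rates
        shm_nt: list[tuple[int, str, str]] = []
        for pos in np.flatnonzero(hit):
            old = v_nt[pos]
            new = [b for b in _BASES if b != old][int(rng.integers(3))]
            v_nt[int(pos)] = new
            shm_nt.append((int(pos), old, new))
        v_mut = "".join(v_nt)

        # --- engineered stop codon (framework-1/2 region, codons 10..45)
        stop_engineered = bool(rng.random() < config.stop_codon_fraction)
        stop_codon_index: Optional[int] = None
        if stop_engineered:
            stop_codon_index = int(rng.integers(10, 46))
            v_mut = v_mut[: 3 * stop_codon_index] + "TAA" + v_mut[3 * stop_codon_index + 3 :]

        # --- junction: trims + in-frame, length-constrained, stop-free N
        # insertion.  Geometry (trims, N length) and N composition are drawn
        # together: with a zero-length N region a junction stop can only be
        # removed by re-drawing the trims themselves.
        n_fr_codons = sum(1 for p in v_germ.kabat_numbers if cdr_of(p) != "cdr3")
        junction = None
        for _attempt in range(500):
            v_trim = min(int(rng.geometric(config.p_trim)) - 1, 6)
            j_trim = min(int(rng.geometric(config.p_trim)) - 1, 6, anchor_nt)
            n_len = int(rng.poisson(config.n_insert_mean))
            anchor_off = (len(v_mut) - v_trim) + n_len + (anchor_nt - j_trim)
            n_len += (-anchor_off) % 3  # keep the J anchor in the V frame
            n_full_v = (len(v_mut) - v_trim) // 3
            junction_aa = ((len(v_mut) - v_trim) + n_len + (anchor_nt - j_trim)) // 3 - n_full_v
            cdr3_len = (n_full_v - n_fr_codons) + junction_aa
            if not (lo <= cdr3_len <= hi):
                continue
            last_v = v_germ.kabat_numbers[n_full_v - 1] if n_full_v else None
            try:
                junction_labels(chain, last_v, junction_aa)
            except UnnumberableError:
                continue
            v_part = v_mut[: len(v_mut) - v_trim] if v_trim else v_mut
            j_part = j_germ.nt_seq[j_trim:]
            n_region = "".join(_BASES[b] for b in rng.integers(0, 4, n_len))
            core = v_part + n_region + j_part
            junction_start_codon = (len(v_part) // 3) * 3
            if "*" in _translate(core[junction_start_codon:]):
                continue
            junction = (v_trim, j_trim, n_len, cdr3_len)
            break
        if junction is None:  # pragma: no cover - vanishingly unlikely
            raise RuntimeError("could not build an admissible stop-free junction")
        v_trim, j_trim, n_len, cdr3_len = junction

        # --- truth amino-acid changes on fully intact V codons
        n_full_v = len(v_part) // 3
        germ_aa = v_germ.aa_seq
        obs_aa = _translate(v_part)
        aa_changes: dict[KabatPosition, tuple[str, str]] = {}
        for ci in range(n_full_v):
            if obs_aa[ci] != germ_aa[ci]:
                aa_changes[v_germ.kabat_numbers[ci]] = (germ_aa[ci], obs_aa[ci])

        productive = "*" not in _translate(core)

        amplicon = CONST_5P + core + CONST_3P
        max_len = 2 * config.read_length - config.overlap_length
        if not (config.read_length <= len(amplicon) <= max_len):
            raise ValueError(
                f"amplicon length {len(amplicon)} outside "
                f"[read_length, 2*read_length - overlap_length] = "
                f"[{config.read_length}, {max_len}]"
            )

        truths.append(
            SimulatedTruth(
                sequence_id=seq_id,
                v_call=v_id,
                j_call=j_id,
                v_trim=v_trim,
                j_trim=j_trim,
                n_insertion=n_region,
                shm_nt=shm_nt,
                aa_changes=aa_changes,
                clean_sequence=amplicon,
                productive=productive,
                stop_engineered=stop_engineered,
                stop_codon_index=stop_codon_index,
                cdr3_length=cdr3_len,
            )
        )

        fwd = amplicon[: config.read_length]
        rev = revcomp(amplicon)[: config.read_length]
        fwd_seq, fwd_qual = _apply_errors(rng, fwd, config.seq_error_rate)
        rev_seq, rev_qual = _apply_errors(rng, rev, config.seq_error_rate)
        pairs.append(RawReadPair(seq_id, fwd_seq, rev_seq, fwd_qual, rev_qual))

    return SimulationResult(config, truths, pairs)


def _apply_errors(
    rng: np.random.Generator, seq: str, error_rate: float
) -> tuple[str, list[int]]:
    bases = list(seq)
    quals = [int(q) for q in rng.integers(33, 41, len(seq))]
    if error_rate > 0:
        for pos in np.flatnonzero(rng.random(len(seq)) < error_rate):
            old = bases[pos]
            new = old
            while new == old:
                new = _BASES[int(rng.integers(4))]
            bases[int(pos)] = new
            quals[int(pos)] = int(rng.integers(3, 16))
    return "".join(bases), quals


@dataclass
class RecoveryReport:
    n_compared: int
    v_call_accuracy: float
    j_call_accuracy: float
    #: fraction of records whose SHM count matches truth exactly, per region set
    shm_exactness: dict[str, float]
    #: total-variation distance between pipeline and truth V-usage distributions
    usage_tv_distance: float


def truth_compare(
    annots,
    truths: list[SimulatedTruth],
    shm_records: Optional[Mapping[str, "object"]] = None,
) -> RecoveryReport:
    """Compare pipeline output against simulator ground truth.

    ``annots`` is an iterable of AnnotatedSequence; every annotated
    sequence_id must exist in the truth table (hard error otherwise).
    ``shm_records`` optionally maps region-set name -> {sequence_id: ShmRecord}
    for per-sequence mutation-count exactness.
    """
    truths_by_id = {t.sequence_id: t for t in truths}
    if not truths_by_id:
        raise ValueError("empty truth table")
    annots = list(annots)
    unknown = [a.sequence_id for a in annots if a.sequence_id not in truths_by_id]
    if unknown:
        raise ValueError(f"sequence ids missing from truth: {unknown[:5]}")
    if not annots:
        raise ValueError("no pipeline records to compare")

    v_ok = sum(a.v_call == truths_by_id[a.sequence_id].v_call for a in annots)
    j_ok = sum(a.j_call == truths_by_id[a.sequence_id].j_call for a in annots)

    pipeline_usage = Counter(a.v_call for a in annots)
    truth_usage = Counter(truths_by_id[a.sequence_id].v_call for a in annots)
    n = len(annots)
    all_vs = set(pipeline_usage) | set(truth_usage)
    tv = 0.5 * sum(abs(pipeline_usage.get(v, 0) - truth_usage.get(v, 0)) / n for v in all_vs)

    exactness: dict[str, float] = {}
    if shm_records:
        from .shm import REGION_SETS

        for region, by_id in shm_records.items():
            _, cdrs = REGION_SETS[region]
            hits = total = 0
            for seq_id, rec in by_id.items():
                truth_count = truths_by_id[seq_id].cdr_mutation_count(cdrs)
                total += 1
                hits += rec.mutation_count == truth_count
            exactness[region] = hits / total if total else float("nan")

    return RecoveryReport(n, v_ok / n, j_ok / n, exactness, tv)
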