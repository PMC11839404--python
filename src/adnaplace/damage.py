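"""Briggs-model ancient-DNA damage simulator.

The model describes post-mortem degradation of double-stranded libraries
with four probabilities:

* ``nu`` — probability of a nick at each junction between consecutive
  bases; nicks fragment the molecule into short reads.
* ``lam`` — success probability of the geometric distribution from which
  each read's single-stranded overhang length is drawn (support 0, 1, 2,
  ...; ``lam = 1`` means the overhang always has length zero).
* ``delta_ss`` — deamination probability per eligible base inside the
  overhang (single-stranded, unprotected) region.
* ``delta_ds`` — deamination probability per eligible base in the
  double-stranded remainder of the read.

Each read receives one overhang, on the 5' side for half of the reads and
on the 3' side for the other half.  Library preparation converts
deamination on the 3' overhang into G->A on the reported strand, so a
5'-overhang read can only accumulate C->T changes and a 3'-overhang read
only G->A changes — a single read never mixes the two kinds.

Gap columns of aligned input are not physical nucleotides: nick junctions
exist only between consecutive non-gap residues, overhang lengths are
counted in non-gap residues, and gaps or IUPAC ambiguity codes are never
deaminated.  Reads retain their source coordinates (0-based, half-open) so
alignment columns are preserved.

Randomness: all operations draw from a caller-supplied
:class:`numpy.random.Generator`.  The draw order is fixed and documented —
nicks left to right (one uniform per junction), then per fragment the
overhang side, the overhang length, and one uniform per eligible base left
to right — so a given seed reproduces a run exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Alignment, SequenceRecord, damage_log_frame

__all__ = [
    "FIVE_PRIME",
    "THREE_PRIME",
    "C_TO_T",
    "G_TO_A",
    "SINGLE_STRANDED",
    "DOUBLE_STRANDED",
    "DamageParameters",
    "ReadFilters",
    "DamageEvent",
    "DamagedRead",
    "SimulationError",
    "mark_nicks",
    "fragment_at_nicks",
    "sample_overhang",
    "apply_deamination",
    "damage_sequence",
    "filter_reads",
    "simulate",
    "reads_to_records",
]

GAP = "-"
FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"
C_TO_T = "C_to_T"
G_TO_A = "G_to_A"
SINGLE_STRANDED = "single_stranded"
DOUBLE_STRANDED = "double_stranded"

_STANDARD = frozenset("ACGTacgt")


class SimulationError(RuntimeError):
    """Raised when the simulation cannot satisfy its contracts."""


@dataclass(frozen=True)
class DamageParameters:
    """The four Briggs-model probabilities (see module docstring)."""

    nu: float
    lam: float
    delta_ss: float
    delta_ds: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.nu <= 1.0:
            raise ValueError(f"nu must be in [0, 1], got {self.nu}")
        if not 0.0 < self.lam <= 1.0:
            raise ValueError(f"lam must be in (0, 1], got {self.lam}")
        for name in ("delta_ss", "delta_ds"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")

    @classmethod
    def no_damage(cls) -> "DamageParameters":
        return cls(nu=0.0, lam=1.0, delta_ss=0.0, delta_ds=0.0)


@dataclass(frozen=True)
class ReadFilters:
    """Read filtering and accumulation settings.

    ``min_length`` counts non-gap sites only (default 15 bp, the permissive
    end of the length prefilter used in aDNA studies, where cutoffs of
    ~30 bp are common).  ``min_reads`` (default 10) triggers repeated damage
    passes over the source until that many reads survive the filters.
    ``max_accumulation_passes`` bounds that loop so that parameter settings
    which can never yield a surviving read still terminate.
    """

    min_length: int = 15
    min_reads: int = 10
    max_reads: int | None = None
    max_accumulation_passes: int = 1000

    def __post_init__(self) -> None:
        if self.min_length < 0 or self.min_reads < 0:
            raise ValueError("min_length and min_reads must be >= 0")
        if self.max_reads is not None:
            if self.max_reads < 1:
                raise ValueError("max_reads must be >= 1 when set")
            if self.min_reads > self.max_reads:
                raise ValueError("min_reads must not exceed max_reads")
        if self.max_accumulation_passes < 1:
            raise ValueError("max_accumulation_passes must be >= 1")

    @classmethod
    def none(cls) -> "ReadFilters":
        """Disable all filtering: single pass, every fragment kept."""
        return cls(min_length=0, min_reads=0, max_reads=None)


@dataclass(frozen=True)
class DamageEvent:
    """A single deamination: position within the read (0-based, counting
    gap columns), kind (C->T or G->A), and strandedness of the region."""

    position: int
    kind: str
    region: str


@dataclass
class DamagedRead:
    """One simulated fragment, aligned to its source coordinates."""

    read_id: str
    source_id: str
    start: int
    end: int
    residues: str
    overhang_side: str
    overhang_length: int
    events: list[DamageEvent] = field(default_factory=list)

    @property
    def nongap_length(self) -> int:
        return len(self.residues) - self.residues.count(GAP)

    @property
    def sequence(self) -> str:
        """Residues with gap columns removed."""
        return self.residues.replace(GAP, "")


# --------------------------------------------------------------------- #
# the four model steps


def mark_nicks(residues: str, nu: float, rng: np.random.Generator) -> list[int]:
    """Mark nick junctions along a sequence.

    Junction ``i`` sits after the i-th non-gap residue (0-based); each of
    the ``n_nongap - 1`` junctions is an independent Bernoulli(nu) trial.
    Returns the strictly increasing list of nicked junction indices.
    """
    if not 0.0 <= nu <= 1.0:
        raise ValueError(f"nu must be in [0, 1], got {nu}")
    n_nongap = len(residues) - residues.count(GAP)
    if n_nongap <= 1 or nu == 0.0:
        # still consume no draws for nu == 0? draws are per junction, and a
        # zero rate cannot mark any, so skipping keeps runs cheap; the draw
        # count difference is irrelevant because nu is fixed per run.
        return []
    hits = rng.random(n_nongap - 1) < nu
    return [int(i) for i in np.flatnonzero(hits)]


def fragment_at_nicks(residues: str, nicks: list[int]) -> list[tuple[int, int]]:
    """Split a sequence at nicked junctions into (start, end) spans.

    Spans are 0-based half-open over the full residue string (gap columns
    included) and jointly cover it; gap columns adjacent to a nick travel
    with the preceding fragment, i.e. each cut falls immediately before the
    next non-gap residue.
    """
    if not residues:
        return []
    nongap_positions = [i for i, c in enumerate(residues) if c != GAP]
    cuts = []
    for j in nicks:
        if not 0 <= j < len(nongap_positions) - 1:
            raise ValueError(f"nick junction {j} out of range")
        cuts.append(nongap_positions[j + 1])
    boundaries = [0] + sorted(cuts) + [len(residues)]
    return [
        (boundaries[i], boundaries[i + 1])
        for i in range(len(boundaries) - 1)
        if boundaries[i] < boundaries[i + 1]
    ]


def sample_overhang(lam: float, rng: np.random.Generator) -> tuple[str, int]:
    """Draw a read's overhang side and length.

    The side is 5' or 3' with equal probability; the length is geometric
    with success probability ``lam`` counted as failures before the first
    success, ``P(L = k) = (1 - lam)^k * lam`` for k >= 0, so ``lam = 1``
    always yields a zero-length overhang.
    """
    if not 0.0 < lam <= 1.0:
        raise ValueError(f"lam must be in (0, 1], got {lam}")
    side = FIVE_PRIME if rng.random() < 0.5 else THREE_PRIME
    length = int(rng.geometric(lam)) - 1
    return side, length


def apply_deamination(
    residues: str,
    side: str,
    overhang_length: int,
    delta_ss: float,
    delta_ds: float,
    rng: np.random.Generator,
) -> tuple[str, list[DamageEvent]]:
    """Deaminate eligible bases of one read.

    On a 5'-overhang read only C (case-insensitive) can flip, to T; on a
    3'-overhang read only G can flip, to A.  The overhang spans the first
    (5') or last (3') ``overhang_length`` non-gap residues; eligible bases
    inside it flip with probability ``delta_ss``, outside with
    ``delta_ds``.  Gaps and ambiguity codes are never altered; case is
    preserved.  One uniform is drawn per eligible base, left to right.
    """
    if overhang_length < 0:
        raise ValueError("overhang length must be >= 0")
    if side not in (FIVE_PRIME, THREE_PRIME):
        raise ValueError(f"unknown overhang side {side!r}")

    arr = np.array(list(residues))
    upper = np.char.upper(arr)
    nongap = arr != GAP
    n_nongap = int(nongap.sum())
    L = min(overhang_length, n_nongap)

    # overhang membership per position, counted in non-gap residues
    ordinal = np.cumsum(nongap) - 1  # non-gap ordinal at each position
    if side == FIVE_PRIME:
        in_overhang = nongap & (ordinal < L)
        target, replacement, kind = "C", "T", C_TO_T
    else:
        in_overhang = nongap & (ordinal >= n_nongap - L)
        target, replacement, kind = "G", "A", G_TO_A

    eligible = np.flatnonzero(upper == target)
    if eligible.size == 0:
        return residues, []
    draws = rng.random(eligible.size)
    thresholds = np.where(in_overhang[eligible], delta_ss, delta_ds)
    flips = eligible[draws < thresholds]

    events = []
    for pos in flips:
        was_upper = arr[pos].isupper()
        arr[pos] = replacement if was_upper else replacement.lower()
        region = SINGLE_STRANDED if in_overhang[pos] else DOUBLE_STRANDED
        events.append(DamageEvent(position=int(pos), kind=kind, region=region))
    return "".join(arr), events


def damage_sequence(
    record: SequenceRecord,
    params: DamageParameters,
    rng: np.random.Generator,
    pass_index: int = 0,
) -> list[DamagedRead]:
    """One full damage pass over a source sequence.

    Nick -> fragment -> per-fragment overhang -> deamination.  Reads keep
    their source coordinates and internal gap columns; read ids are
    ``<source_id>/<pass>/<ordinal>``.
    """
    if not record.residues:
        raise SimulationError(f"source sequence {record.id!r} is empty")
    nicks = mark_nicks(record.residues, params.nu, rng)
    fragments = fragment_at_nicks(record.residues, nicks)
    reads = []
    for ordinal, (start, end) in enumerate(fragments):
        piece = record.residues[start:end]
        side, length = sample_overhang(params.lam, rng)
        nongap_len = len(piece) - piece.count(GAP)
        length = min(length, nongap_len)  # capped at the read length
        damaged, events = apply_deamination(
            piece, side, length, params.delta_ss, params.delta_ds, rng
        )
        reads.append(
            DamagedRead(
                read_id=f"{record.id}/{pass_index}/{ordinal}",
                source_id=record.id,
                start=start,
                end=end,
                residues=damaged,
                overhang_side=side,
                overhang_length=length,
                events=events,
            )
        )
    return reads


# --------------------------------------------------------------------- #
# filtering


def _reference_column_mask(reference) -> np.ndarray:
    """True for alignment columns where >= 1 reference row is non-gap."""
    records = reference.records if isinstance(reference, Alignment) else list(reference)
    mask = np.zeros(len(records[0].residues), dtype=bool)
    for rec in records:
        mask |= np.array(list(rec.residues)) != GAP
    return mask


def filter_reads(
    reads: list[DamagedRead],
    filters: ReadFilters,
    reference=None,
    rng: np.random.Generator | None = None,
) -> list[DamagedRead]:
    """Apply the read filters, in order:

    1. drop reads consisting entirely of gap and/or ambiguity characters;
    2. drop reads whose non-gap length is below ``min_length``;
    3. with a reference alignment given, drop reads sharing no alignment
       column with a non-gap reference character (premasking — such reads
       could not be aligned, hence not placed);
    4. with ``max_reads`` set, downsample uniformly without replacement.
    """
    ref_mask = _reference_column_mask(reference) if reference is not None else None
    kept = []
    for read in reads:
        if not any(c in _STANDARD for c in read.residues):
            continue  # fully gap/ambiguous
        if read.nongap_length < filters.min_length:
            continue
        if ref_mask is not None:
            span = ref_mask[read.start : read.end]
            read_nongap = np.array(list(read.residues)) != GAP
            if not bool((span & read_nongap).any()):
                continue
        kept.append(read)
    if filters.max_reads is not None and len(kept) > filters.max_reads:
        if rng is None:
            rng = np.random.default_rng()
        chosen = rng.choice(len(kept), size=filters.max_reads, replace=False)
        kept = [kept[i] for i in sorted(chosen)]
    return kept


# --------------------------------------------------------------------- #
# the full loop


def simulate(
    records,
    params: DamageParameters,
    filters: ReadFilters | None = None,
    reference=None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[DamagedRead], pd.DataFrame]:
    """Damage every source sequence, with accumulation and downsampling.

    Per source: damage passes repeat, accumulating filter-surviving reads,
    until at least ``min_reads`` survive or ``max_accumulation_passes`` is
    reached; then, if ``max_reads`` is set, reads are downsampled uniformly.
    Returns the reads plus the damage-log table.  Reproducible given
    ``seed`` (or an explicit generator).
    """
    if filters is None:
        filters = ReadFilters()
    if rng is None:
        rng = np.random.default_rng(seed)
    if isinstance(records, (SequenceRecord,)):
        records = [records]
    elif isinstance(records, Alignment):
        records = records.records

    per_pass_filters = ReadFilters(
        min_length=filters.min_length,
        min_reads=filters.min_reads,
        max_reads=None,
        max_accumulation_passes=filters.max_accumulation_passes,
    )
    all_reads: list[DamagedRead] = []
    for record in records:
        survivors: list[DamagedRead] = []
        for pass_index in range(filters.max_accumulation_passes):
            fresh = damage_sequence(record, params, rng, pass_index=pass_index)
            survivors.extend(filter_reads(fresh, per_pass_filters, reference=reference))
            if len(survivors) >= filters.min_reads:
                break
        else:
            if not survivors:
                raise SimulationError(
                    f"no read from source {record.id!r} survives the filters "
                    f"after {filters.max_accumulation_passes} accumulation passes"
                )
            warnings.warn(
                f"source {record.id!r}: accumulation stopped at "
                f"{filters.max_accumulation_passes} passes with only "
                f"{len(survivors)} surviving reads (min_reads={filters.min_reads})",
                stacklevel=2,
            )
        if filters.max_reads is not None and len(survivors) > filters.max_reads:
            chosen = rng.choice(len(survivors), size=filters.max_reads, replace=False)
            survivors = [survivors[i] for i in sorted(chosen)]
        all_reads.extend(survivors)
    return all_reads, damage_log_frame(all_reads)


def reads_to_records(
    reads: list[DamagedRead],
    aligned: bool = True,
    source_length: int | None = None,
) -> list[SequenceRecord]:
    """Convert reads to sequence records for FASTA output.

    In aligned mode each read is padded with gaps to its source
    coordinates, so column indices match the original alignment
    (``source_length`` defaults to the largest read end seen per source).
    Otherwise gap columns are stripped.
    """
    if not aligned:
        return [SequenceRecord(r.read_id, r.sequence) for r in reads]
    out = []
    for read in reads:
        total = source_length if source_length is not None else read.end
        if total < read.end:
            raise ValueError(
                f"source_length {total} shorter than read end {read.end}"
            )
        padded = GAP * read.start + read.residues + GAP * (total - read.end)
        out.append(SequenceRecord(read.read_id, padded))
    return out
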