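"""Readers and writers: FASTA, jplace, and the tab-separated damage log.

Conventions
-----------
* Coordinates are 0-based, half-open everywhere.
* FASTA comment lines starting with ``;`` or ``#`` are skipped on input, so
  files carrying a provenance header (tool version, parameters, seed) still
  parse as plain FASTA with standard tools that tolerate comments.
* jplace: version >= 3 key layout; both ``n`` and ``nm`` query-name lists
  are accepted and ``nm`` multiplicities are ignored (only the branch number
  and the likelihood weight ratio are consumed downstream).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from io import StringIO
from typing import IO, Iterable

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .tree import ReferenceTree, parse_newick_edges

__all__ = [
    "SequenceRecord",
    "Alignment",
    "PlacementSet",
    "FastaError",
    "JplaceError",
    "read_fasta",
    "write_fasta",
    "parse_jplace",
    "parse_newick_edges",
    "write_damage_log",
    "read_damage_log",
    "damage_log_frame",
    "read_truth_table",
    "write_truth_table",
]

GAP = "-"

DAMAGE_LOG_COLUMNS = [
    "read_id",
    "source_id",
    "start",
    "end",
    "overhang_side",
    "overhang_length",
    "event_position",
    "event_kind",
    "event_region",
]


class FastaError(ValueError):
    """Raised on malformed or inconsistent FASTA input."""


class JplaceError(ValueError):
    """Raised on malformed jplace input."""


@dataclass
class SequenceRecord:
    """One named nucleotide sequence; may contain IUPAC codes and ``-`` gaps."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaError("sequence id must be non-empty")
        if any(c.isspace() for c in self.residues):
            raise FastaError(f"residues of {self.id!r} contain whitespace")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Alignment:
    """An ordered collection of equal-length sequence records."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) > 1:
            raise ValueError(f"alignment rows differ in length: {sorted(lengths)}")
        if self.records and len(self.records[0].residues) < 1:
            raise ValueError("alignment must have at least one column")

    @property
    def length(self) -> int:
        return len(self.records[0].residues) if self.records else 0

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def get(self, seq_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == seq_id:
                return r
        raise KeyError(seq_id)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class PlacementSet:
    """Per-query placements: lists of ``(edge_num, likelihood weight ratio)``."""

    placements: dict[str, list[tuple[int, float]]]
    tree_text: str = ""

    def __iter__(self):
        return iter(self.placements)

    def __len__(self) -> int:
        return len(self.placements)


# --------------------------------------------------------------------- #
# FASTA


def _as_handle(stream: IO[str] | str) -> IO[str]:
    # a str argument is FASTA *content*, not a path
    if isinstance(stream, str):
        return StringIO(stream)
    return stream


def read_fasta(stream: IO[str] | str) -> list[SequenceRecord]:
    """Parse FASTA from a handle or a string of content.

    Wrapped sequence lines are concatenated; the id is the first
    whitespace-delimited token of the header, the remainder is kept as the
    record description.  Duplicate ids and empty sequences are errors.
    """
    handle = _as_handle(stream)
    filtered = StringIO(
        "".join(
            line for line in handle if not line.lstrip().startswith((";", "#"))
        )
    )
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for title, seq in SimpleFastaParser(filtered):
        parts = title.split(None, 1)
        if not parts:
            raise FastaError("FASTA header with empty id")
        seq_id = parts[0]
        description = parts[1] if len(parts) > 1 else ""
        if seq_id in seen:
            raise FastaError(f"duplicate sequence id {seq_id!r}")
        seen.add(seq_id)
        seq = "".join(seq.split())
        if not seq:
            raise FastaError(f"sequence {seq_id!r} is empty")
        records.append(SequenceRecord(seq_id, seq, description))
    return records


def write_fasta(
    records: Iterable[SequenceRecord],
    line_width: int = 60,
    header_comment: str | None = None,
) -> str:
    """Serialise records to a FASTA string (gaps written verbatim).

    ``header_comment`` lines, if given, are emitted first prefixed with
    ``;`` (the classic FASTA comment character); :func:`read_fasta` skips
    them on the way back in.
    """
    out = StringIO()
    if header_comment:
        for line in header_comment.splitlines():
            out.write(f";{line}\n")
    for rec in records:
        header = rec.id if not rec.description else f"{rec.id} {rec.description}"
        out.write(f">{header}\n")
        if line_width and line_width > 0:
            for i in range(0, len(rec.residues), line_width):
                out.write(rec.residues[i : i + line_width] + "\n")
        else:
            out.write(rec.residues + "\n")
    return out.getvalue()


# --------------------------------------------------------------------- #
# jplace


def parse_jplace(text: str | dict) -> tuple[ReferenceTree, PlacementSet]:
    """Parse a jplace document (string or already-decoded JSON object)."""
    doc = json.loads(text) if isinstance(text, str) else text
    for key in ("tree", "placements", "fields"):
        if key not in doc:
            raise JplaceError(f"jplace document missing required field {key!r}")
    fields = doc["fields"]
    for needed in ("edge_num", "like_weight_ratio"):
        if needed not in fields:
            raise JplaceError(f"jplace 'fields' lacks required entry {needed!r}")
    edge_idx = fields.index("edge_num")
    lwr_idx = fields.index("like_weight_ratio")

    tree = parse_newick_edges(doc["tree"])

    placements: dict[str, list[tuple[int, float]]] = {}
    for entry in doc["placements"]:
        if "n" in entry:
            names = list(entry["n"])
        elif "nm" in entry:
            names = [pair[0] for pair in entry["nm"]]
        else:
            raise JplaceError("placement entry lacks both 'n' and 'nm' name lists")
        rows: list[tuple[int, float]] = []
        for p in entry.get("p", []):
            edge_num = int(p[edge_idx])
            lwr = float(p[lwr_idx])
            if not tree.has_edge(edge_num):
                raise JplaceError(f"placement references edge {edge_num} absent from tree")
            if not 0.0 <= lwr <= 1.0:
                raise JplaceError(f"likelihood weight ratio {lwr} outside [0, 1]")
            rows.append((edge_num, lwr))
        for name in names:
            placements[name] = list(rows)
    return tree, PlacementSet(placements=placements, tree_text=doc["tree"])


# --------------------------------------------------------------------- #
# damage log


def damage_log_frame(reads) -> pd.DataFrame:
    """Tabulate damaged reads: one summary row per read, one row per event."""
    rows = []
    for read in reads:
        base = dict(
            read_id=read.read_id,
            source_id=read.source_id,
            start=read.start,
            end=read.end,
            overhang_side=read.overhang_side,
            overhang_length=read.overhang_length,
        )
        rows.append({**base, "event_position": "", "event_kind": "summary",
                     "event_region": ""})
        for ev in read.events:
            rows.append({**base, "event_position": ev.position,
                         "event_kind": ev.kind, "event_region": ev.region})
    return pd.DataFrame(rows, columns=DAMAGE_LOG_COLUMNS)


def write_damage_log(reads, header_comment: str | None = None) -> str:
    """Serialise the damage log as TSV (UTF-8 text, ``\\n`` line ends)."""
    out = StringIO()
    if header_comment:
        for line in header_comment.splitlines():
            out.write(f"#{line}\n")
    frame = damage_log_frame(reads)
    frame.to_csv(out, sep="\t", index=False, lineterminator="\n")
    return out.getvalue()


def read_damage_log(stream: IO[str] | str) -> pd.DataFrame:
    frame = pd.read_csv(
        _as_handle(stream), sep="\t", comment="#", keep_default_na=False,
        dtype={"event_position": str},
    )
    return frame


# --------------------------------------------------------------------- #
# truth tables (read_id -> true edge number)


def write_truth_table(truth: dict[str, int], header_comment: str | None = None) -> str:
    out = StringIO()
    if header_comment:
        for line in header_comment.splitlines():
            out.write(f"#{line}\n")
    out.write("read_id\ttrue_edge_num\n")
    for read_id, edge in truth.items():
        out.write(f"{read_id}\t{edge}\n")
    return out.getvalue()


def read_truth_table(stream: IO[str] | str) -> dict[str, int]:
    frame = pd.read_csv(_as_handle(stream), sep="\t", comment="#")
    return dict(zip(frame["read_id"].astype(str), frame["true_edge_num"].astype(int)))
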