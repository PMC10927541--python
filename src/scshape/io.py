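"""Readers and writers for every external format the pipeline touches.

Coordinate conventions
----------------------
Internally everything is 0-based, half-open.  The two formats that are
1-based by their own standards — CT structure files and two-column SHAPE
reactivity files — are converted at this boundary and nowhere else.

Formats handled here:

* base-count TSV: ``cell_id  transcript_id  position  coverage  mutated
  condition`` — the ingestion contract downstream of alignment and
  per-base mutation counting;
* dot-bracket and CT secondary-structure files;
* BED (3 columns + name) feature/RBP intervals in transcript coordinates;
* two-column SHAPE reactivity files (1-based position, −999 = missing);
* per-cell expression TSV and region-annotation TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("treated", "control")

BASECOUNT_COLUMNS = [
    "cell_id",
    "transcript_id",
    "position",
    "coverage",
    "mutated",
    "condition",
]


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class ValidationError(ValueError):
    """Well-formed input that violates a semantic invariant."""


# ---------------------------------------------------------------------------
# Base-count matrix
# ---------------------------------------------------------------------------


@dataclass
class BaseCountMatrix:
    """Per cell × transcript-position coverage and mutated-read counts.

    Thin, validated wrapper around a DataFrame with columns
    ``cell_id, transcript_id, position, coverage, mutated, condition``.
    ``position`` is a 0-based transcript coordinate; ``condition`` is
    ``treated`` (reagent) or ``control`` (mock/DMSO channel).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in BASECOUNT_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"base-count table missing column(s): {missing}")
        df = df[BASECOUNT_COLUMNS].copy()
        df["position"] = df["position"].astype(np.int64)
        df["coverage"] = df["coverage"].astype(np.int64)
        df["mutated"] = df["mutated"].astype(np.int64)
        bad_cond = set(df["condition"].unique()) - set(CONDITIONS)
        if bad_cond:
            raise ValidationError(f"unknown condition value(s): {sorted(bad_cond)}")
        for col in ("position", "coverage", "mutated"):
            neg = np.flatnonzero(df[col].to_numpy() < 0)
            if neg.size:
                raise ValidationError(
                    f"negative {col} at row {int(neg[0])}"
                )
            # row numbers are positions in the frame, 0-based
        excess = np.flatnonzero(df["mutated"].to_numpy() > df["coverage"].to_numpy())
        if excess.size:
            raise ValidationError(
                f"mutated > coverage at row {int(excess[0])}"
            )
        key = ["cell_id", "transcript_id", "position", "condition"]
        if df.duplicated(subset=key).any():
            dup = df[df.duplicated(subset=key, keep=False)].iloc[0]
            raise ValidationError(
                "duplicate record for "
                f"({dup.cell_id}, {dup.transcript_id}, {dup.position}, {dup.condition})"
            )
        self.data = df.reset_index(drop=True)

    # -- convenience accessors used throughout the pipeline -----------------

    @property
    def cells(self) -> list[str]:
        return sorted(self.data["cell_id"].unique())

    @property
    def transcripts(self) -> list[str]:
        return sorted(self.data["transcript_id"].unique())

    def subset(
        self,
        *,
        cells: Iterable[str] | None = None,
        transcript_id: str | None = None,
        condition: str | None = None,
    ) -> pd.DataFrame:
        df = self.data
        if cells is not None:
            df = df[df["cell_id"].isin(set(cells))]
        if transcript_id is not None:
            df = df[df["transcript_id"] == transcript_id]
        if condition is not None:
            df = df[df["condition"] == condition]
        return df

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BaseCountMatrix):
            return NotImplemented
        key = ["cell_id", "transcript_id", "position", "condition"]
        a = self.data.sort_values(key).reset_index(drop=True)
        b = other.data.sort_values(key).reset_index(drop=True)
        return a.equals(b)


def read_base_counts(path: str | Path) -> BaseCountMatrix:
    """Read a base-count TSV, validating counts and uniqueness."""
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "transcript_id": str})
    return BaseCountMatrix(df)


def write_base_counts(matrix: BaseCountMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Secondary structures
# ---------------------------------------------------------------------------

# bracket tiers balance independently, supporting pseudoknots
_BRACKET_TIERS = [("(", ")"), ("[", "]"), ("{", "}"), ("<", ">")]
_OPENERS = {o: i for i, (o, _) in enumerate(_BRACKET_TIERS)}
_CLOSERS = {c: i for i, (_, c) in enumerate(_BRACKET_TIERS)}


@dataclass
class ReferenceStructure:
    """Base-pairing state per position, with optional solvent accessibility.

    ``partner_index[i]`` is the 0-based pairing partner, −1 when unpaired.
    ``solvent_accessibility`` is the 2′-OH exposure in Å² where known.
    """

    transcript_id: str
    partner_index: np.ndarray
    sequence: str | None = None
    solvent_accessibility: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.partner_index = np.asarray(self.partner_index, dtype=np.int64)
        paired = np.flatnonzero(self.partner_index >= 0)
        for i in paired:
            j = self.partner_index[i]
            if j >= len(self.partner_index) or self.partner_index[j] != i:
                raise ValidationError(
                    f"asymmetric pairing: partner({i})={j} but partner({j})!="
                    f"{i}"
                )
        if self.sequence is not None and len(self.sequence) != len(self.partner_index):
            raise ValidationError("structure/sequence length mismatch")
        if self.solvent_accessibility is not None:
            self.solvent_accessibility = np.asarray(
                self.solvent_accessibility, dtype=float
            )
            if len(self.solvent_accessibility) != len(self.partner_index):
                raise ValidationError("accessibility length mismatch")

    def __len__(self) -> int:
        return len(self.partner_index)

    @property
    def paired(self) -> np.ndarray:
        """Boolean vector, True where the base is paired."""
        return self.partner_index >= 0

    @property
    def unpaired(self) -> np.ndarray:
        return self.partner_index < 0


def parse_dot_bracket(structure: str, transcript_id: str = "", sequence: str | None = None) -> ReferenceStructure:
    """Parse a dot-bracket string into symmetric partner indices.

    Each bracket tier ``() [] {} <>`` balances independently (pseudoknot
    support).  Any other character except ``.`` is a hard error: silent
    treat-as-unpaired would corrupt benchmark labels.
    """
    partner = np.full(len(structure), -1, dtype=np.int64)
    stacks: list[list[int]] = [[] for _ in _BRACKET_TIERS]
    for pos, ch in enumerate(structure):
        if ch == ".":
            continue
        if ch in _OPENERS:
            stacks[_OPENERS[ch]].append(pos)
        elif ch in _CLOSERS:
            tier = _CLOSERS[ch]
            if not stacks[tier]:
                raise FormatError(
                    f"unmatched '{ch}' at position {pos} (bracket tier {tier})"
                )
            j = stacks[tier].pop()
            partner[j] = pos
            partner[pos] = j
        else:
            raise FormatError(f"unknown structure character {ch!r} at position {pos}")
    for tier, stack in enumerate(stacks):
        if stack:
            raise FormatError(
                f"{len(stack)} unmatched '{_BRACKET_TIERS[tier][0]}' "
                f"(bracket tier {tier}), first at position {stack[0]}"
            )
    return ReferenceStructure(transcript_id, partner, sequence=sequence)


def read_dot_bracket(path: str | Path) -> ReferenceStructure:
    """Read a FASTA-like dot-bracket record: name, sequence, structure."""
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(lines) < 3 or not lines[0].startswith(">"):
        raise FormatError("expected '>name', sequence line, structure line")
    name = lines[0][1:].split()[0]
    sequence, structure = lines[1], lines[2]
    if len(sequence) != len(structure):
        raise FormatError(
            f"structure length {len(structure)} != sequence length {len(sequence)}"
        )
    return parse_dot_bracket(structure, transcript_id=name, sequence=sequence)


def write_dot_bracket(structure: ReferenceStructure, path: str | Path) -> None:
    seq = structure.sequence or "N" * len(structure)
    chars = ["."] * len(structure)
    for i, j in enumerate(structure.partner_index):
        if j > i:
            chars[i], chars[int(j)] = "(", ")"
    Path(path).write_text(
        f">{structure.transcript_id}\n{seq}\n{''.join(chars)}\n"
    )


def read_ct(path: str | Path) -> ReferenceStructure:
    """Read a connectivity-table (CT) structure file.

    Standard layout: count header line, then per base six 1-based columns
    (index, base, previous, next, pairing partner, natural index).  A pair
    column of 0 means unpaired; everything is converted to 0-based here.
    """
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError("empty CT file")
    header = lines[0].split()
    try:
        n = int(header[0])
    except ValueError as exc:
        raise FormatError(f"bad CT header: {lines[0]!r}") from exc
    name = header[1] if len(header) > 1 else ""
    if len(lines) - 1 < n:
        raise FormatError(f"CT declares {n} bases but has {len(lines) - 1} rows")
    partner = np.full(n, -1, dtype=np.int64)
    bases = []
    for row in lines[1 : n + 1]:
        cols = row.split()
        if len(cols) < 6:
            raise FormatError(f"CT row has {len(cols)} columns, expected 6: {row!r}")
        idx = int(cols[0]) - 1
        bases.append(cols[1])
        pair = int(cols[4])
        partner[idx] = pair - 1 if pair > 0 else -1
    for i in range(n):
        j = partner[i]
        if j >= 0 and partner[j] != i:
            raise ValidationError(
                f"asymmetric CT pairing between positions {i + 1} and {j + 1} (1-based)"
            )
    return ReferenceStructure(name, partner, sequence="".join(bases))


# ---------------------------------------------------------------------------
# Region annotation and intervals
# ---------------------------------------------------------------------------


@dataclass
class RegionAnnotation:
    """CDS boundaries of one transcript, 0-based half-open."""

    transcript_id: str
    transcript_length: int
    cds_start: int
    cds_end: int

    def __post_init__(self) -> None:
        if not (0 <= self.cds_start < self.cds_end <= self.transcript_length):
            raise ValidationError(
                f"{self.transcript_id}: require 0 <= cds_start < cds_end <= length, "
                f"got ({self.cds_start}, {self.cds_end}, {self.transcript_length})"
            )


def read_region_annotation(path: str | Path) -> dict[str, RegionAnnotation]:
    """Read TSV: transcript_id, transcript_length, cds_start, cds_end."""
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    required = {"transcript_id", "transcript_length", "cds_start", "cds_end"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"annotation missing column(s): {sorted(missing)}")
    out = {}
    for row in df.itertuples(index=False):
        out[row.transcript_id] = RegionAnnotation(
            row.transcript_id,
            int(row.transcript_length),
            int(row.cds_start),
            int(row.cds_end),
        )
    return out


def write_region_annotation(annotations: dict[str, RegionAnnotation], path: str | Path) -> None:
    rows = [
        (a.transcript_id, a.transcript_length, a.cds_start, a.cds_end)
        for a in annotations.values()
    ]
    pd.DataFrame(
        rows, columns=["transcript_id", "transcript_length", "cds_start", "cds_end"]
    ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class Interval:
    transcript_id: str
    start: int
    end: int
    feature_name: str


@dataclass
class IntervalSet:
    """Feature/RBP binding intervals in transcript coordinates (half-open)."""

    intervals: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        for iv in self.intervals:
            if iv.start >= iv.end:
                raise ValidationError(
                    f"interval {iv.transcript_id}:{iv.start}-{iv.end}: start >= end"
                )
            if not iv.feature_name:
                raise ValidationError("empty feature name")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    @property
    def feature_names(self) -> list[str]:
        return sorted({iv.feature_name for iv in self.intervals})

    def by_feature(self) -> dict[str, list[Interval]]:
        out: dict[str, list[Interval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.feature_name, []).append(iv)
        return out


def read_intervals_bed(path: str | Path) -> IntervalSet:
    """Read BED3+name (chrom column carries the transcript id).

    Columns past the fourth are ignored, so standard 6- or 12-column BED
    also parses.
    """
    intervals = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.rstrip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t")
        if len(cols) < 4:
            raise FormatError(f"line {lineno}: expected >= 4 BED columns")
        start, end = int(cols[1]), int(cols[2])
        if start >= end:
            raise FormatError(f"line {lineno}: start {start} >= end {end}")
        intervals.append(Interval(cols[0], start, end, cols[3]))
    return IntervalSet(intervals)


def write_intervals_bed(intervals: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.transcript_id}\t{iv.start}\t{iv.end}\t{iv.feature_name}\n")


# ---------------------------------------------------------------------------
# SHAPE reactivity files
# ---------------------------------------------------------------------------

SHAPE_MISSING = -999.0


def write_shape(reactivity: np.ndarray, mask: np.ndarray, path: str | Path) -> None:
    """Write a two-column SHAPE file: 1-based position, reactivity.

    Positions where ``mask`` is False are written as −999 (the standard
    missing-value sentinel).
    """
    reactivity = np.asarray(reactivity, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    with open(path, "w") as fh:
        for i in range(len(reactivity)):
            value = reactivity[i] if mask[i] else SHAPE_MISSING
            fh.write(f"{i + 1}\t{value:.6g}\n")


def read_shape(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column SHAPE file back into (reactivity, mask)."""
    positions, values = [], []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        cols = line.split()
        if len(cols) != 2:
            raise FormatError(f"line {lineno}: expected 2 columns")
        positions.append(int(cols[0]) - 1)
        values.append(float(cols[1]))
    n = max(positions) + 1 if positions else 0
    reactivity = np.zeros(n)
    mask = np.zeros(n, dtype=bool)
    for pos, val in zip(positions, values):
        if val != SHAPE_MISSING:
            reactivity[pos] = val
            mask[pos] = True
    return reactivity, mask


# ---------------------------------------------------------------------------
# Expression table
# ---------------------------------------------------------------------------


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read TSV of cell_id, gene_id, expression (non-negative reals).

    Carries externally normalized expression for QC gene detection and
    quartile stratification; duplicates of (cell, gene) are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "gene_id": str})
    required = {"cell_id", "gene_id", "expression"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"expression table missing column(s): {sorted(missing)}")
    if (df["expression"] < 0).any():
        row = int(np.flatnonzero(df["expression"].to_numpy() < 0)[0])
        raise ValidationError(f"negative expression at row {row}")
    if df.duplicated(subset=["cell_id", "gene_id"]).any():
        dup = df[df.duplicated(subset=["cell_id", "gene_id"], keep=False)].iloc[0]
        raise ValidationError(f"duplicate (cell, gene) entry: ({dup.cell_id}, {dup.gene_id})")
    return df.reset_index(drop=True)


def write_expression_table(df: pd.DataFrame, path: str | Path) -> None:
    df[["cell_id", "gene_id", "expression"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Accessibility table (1-based at the file boundary)
# ---------------------------------------------------------------------------


def read_accessibility(path: str | Path, length: int | None = None) -> np.ndarray:
    """Read TSV of 1-based position, solvent accessibility (Å², 2′-OH).

    Returns a dense vector with NaN where no value was given.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["position", "accessibility"],
                     comment="#")
    pos = df["position"].to_numpy(dtype=np.int64) - 1
    if length is None:
        length = int(pos.max()) + 1 if len(pos) else 0
    out = np.full(length, np.nan)
    out[pos] = df["accessibility"].to_numpy(dtype=float)
    return out
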