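"""Readers and writers for interval and tabular formats.

All in-memory coordinates are BED-native: 0-based, half-open. Readers
normalise every supported dialect to that convention, so downstream code
never has to reason about source formats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "FragmentRecord",
    "FeatureInterval",
    "PeakSet",
    "read_bed",
    "read_fragments",
    "write_fragments",
    "write_bed",
    "write_matrix",
    "read_matrix",
]


@dataclass(frozen=True)
class FragmentRecord:
    """One sequenced fragment as a half-open genomic interval.

    ``midpoint`` is floored for odd-length fragments so it is always an
    integer base position.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"fragment end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def size(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class FeatureInterval:
    """A named, stranded genomic interval (e.g. one PWM motif instance)."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def center(self) -> int:
        """Center base; even-length intervals round down."""
        return self.start + (self.end - self.start) // 2


@dataclass
class PeakSet:
    """Accessibility peak intervals, sorted by (chrom, start) after loading."""

    intervals: list[FeatureInterval] = field(default_factory=list)
    dialect: str = "bed3"

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda p: (p.chrom, p.start))

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


_DIALECT_MIN_COLS = {"bed3": 3, "bed6": 3, "narrowPeak": 4, "broadPeak": 4}


def _parse_line(line: str, lineno: int, dialect: str) -> FeatureInterval:
    fields = line.rstrip("\n").split("\t")
    min_cols = _DIALECT_MIN_COLS.get(dialect, 3)
    if len(fields) < min_cols:
        raise ValueError(
            f"line {lineno}: expected at least {min_cols} tab-separated columns, "
            f"got {len(fields)}"
        )
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ValueError(f"line {lineno}: non-integer coordinates") from exc
    if end <= start:
        raise ValueError(f"line {lineno}: end ({end}) <= start ({start})")
    name = fields[3] if len(fields) > 3 and fields[3] else "."
    score = 0.0
    if len(fields) > 4 and fields[4] not in (".", ""):
        try:
            score = float(fields[4])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-numeric score {fields[4]!r}") from exc
    strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
    return FeatureInterval(fields[0], start, end, name, score, strand)


def read_bed(path: str | Path, dialect: str = "bed6") -> list[FeatureInterval]:
    """Read a BED-family file into 0-based half-open :class:`FeatureInterval`.

    Supported dialects: ``bed3``, ``bed6``, ``narrowPeak``, ``broadPeak``.
    Missing strand becomes ``"."`` and missing score 0; columns beyond the
    dialect's are ignored. Malformed lines raise with their line number.
    """
    if dialect not in _DIALECT_MIN_COLS:
        raise ValueError(f"unknown BED dialect {dialect!r}")
    out: list[FeatureInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            out.append(_parse_line(line, lineno, dialect))
    return out


def read_peaks(path: str | Path, dialect: str = "narrowPeak") -> PeakSet:
    """Read peak calls (narrowPeak / broadPeak / bed3) as a sorted PeakSet."""
    return PeakSet(read_bed(path, dialect=dialect), dialect=dialect)


def read_fragments(
    path: str | Path, known_chroms: Iterable[str] | None = None
) -> list[FragmentRecord]:
    """Read ATAC-seq fragments from a BED3+ file (one record per fragment).

    Records on chromosomes not in ``known_chroms`` are retained; a single
    warning reports how many such records were seen.
    """
    known = set(known_chroms) if known_chroms is not None else None
    out: list[FragmentRecord] = []
    n_unknown = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: expected at least 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer coordinates") from exc
            if end <= start:
                raise ValueError(f"line {lineno}: end ({end}) <= start ({start})")
            if known is not None and fields[0] not in known:
                n_unknown += 1
            out.append(FragmentRecord(fields[0], start, end))
    if not out:
        warnings.warn(f"no fragments read from {path}", stacklevel=2)
    if n_unknown:
        warnings.warn(
            f"{n_unknown} fragment(s) on chromosomes outside the known set",
            stacklevel=2,
        )
    return out


def write_bed(features: Iterable[FeatureInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in features:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.name}\t{f.score:g}\t{f.strand}\n")


def write_fragments(fragments: Iterable[FragmentRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for fr in fragments:
            fh.write(f"{fr.chrom}\t{fr.start}\t{fr.end}\n")


def write_matrix(matrix, path: str | Path) -> None:
    """Write a VPlotMatrix as TSV: one row per fragment size, one column per
    window, header row of window centers, first column the fragment sizes.

    Grid parameters and bookkeeping counts are stored in ``#key=value``
    comment lines so that :func:`read_matrix` can reconstruct the object.
    """
    g = matrix.grid
    with open(path, "w") as fh:
        fh.write(
            f"#flank={g.flank}\n#width={g.width}\n#step={g.step}\n"
            f"#min_size={matrix.min_size}\n#max_size={matrix.max_size}\n"
            f"#n_features={matrix.n_features}\n#n_fragments={matrix.n_fragments}\n"
        )
        header = "size\t" + "\t".join(f"{c:g}" for c in g.centers)
        fh.write(header + "\n")
        for i, size in enumerate(range(matrix.min_size, matrix.max_size + 1)):
            row = "\t".join(str(int(v)) for v in matrix.counts[i])
            fh.write(f"{size}\t{row}\n")


def read_matrix(path: str | Path):
    """Read a V-plot matrix TSV written by :func:`write_matrix` (lossless)."""
    from .vplot import VPlotMatrix, build_window_grid

    meta: dict[str, int] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key] = int(value)
            body_start = i + 1
        else:
            break
    required = {"flank", "width", "step", "min_size", "max_size", "n_features", "n_fragments"}
    if not required.issubset(meta):
        raise ValueError(f"matrix file missing metadata keys: {sorted(required - set(meta))}")
    grid = build_window_grid(meta["flank"], meta["width"], meta["step"])
    body = lines[body_start:]
    if not body:
        raise ValueError("matrix file has no header row")
    header = body[0].rstrip("\n").split("\t")
    centers = np.array([float(c) for c in header[1:]])
    if centers.size != grid.n_windows or not np.allclose(centers, grid.centers):
        raise ValueError("header window centers do not match the stored grid parameters")
    n_sizes = meta["max_size"] - meta["min_size"] + 1
    rows = [r.rstrip("\n").split("\t") for r in body[1:] if r.strip()]
    if len(rows) != n_sizes:
        raise ValueError(
            f"expected {n_sizes} size rows ({meta['min_size']}..{meta['max_size']}), got {len(rows)}"
        )
    counts = np.zeros((n_sizes, grid.n_windows), dtype=np.int64)
    for i, row in enumerate(rows):
        if len(row) != grid.n_windows + 1:
            raise ValueError(f"size row {i}: expected {grid.n_windows + 1} columns, got {len(row)}")
        counts[i] = [int(v) for v in row[1:]]
    mat = VPlotMatrix(
        counts=counts,
        grid=grid,
        min_size=meta["min_size"],
        max_size=meta["max_size"],
        n_features=meta["n_features"],
        n_fragments=meta["n_fragments"],
    )
    return mat


def read_group_map(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV (member, group), e.g. motif -> DNA-binding domain."""
    df = pd.read_csv(path, sep="\t", header=None, names=["member", "group"], comment="#")
    return dict(zip(df["member"].astype(str), df["group"].astype(str)))
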