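"""Reading and writing the genomic text formats the pipeline touches.

Coordinate convention: 0-based, half-open everywhere in memory.  Conversion
(if any) happens only at a format boundary; BED and bedGraph are themselves
0-based half-open, so the readers and writers here are identity maps on
coordinates.  Chromosome name matching is exact — no ``chr`` aliasing;
a name that is not in the attached genome is an error, never a silent drop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Interval",
    "CoverageTrack",
    "FormatError",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_ct_table",
    "write_ct_table",
    "normalize_track",
]

CT_COLUMNS = ["sample", "target", "condition", "replicate", "ct"]


class FormatError(ValueError):
    """A malformed record in a genomic text file; carries the line number."""

    def __init__(self, path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


@dataclass(frozen=True)
class Interval:
    """A genomic interval, 0-based half-open, BED-style.

    ``start`` is inclusive, ``end`` exclusive; length is ``end - start``.
    """

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class CoverageTrack:
    """Per-chromosome base-resolution signal for one assay/condition.

    ``values`` maps chromosome name to a float array of length equal to the
    chromosome.  ``library_size`` is the normalization denominator (total
    read count in the sequencing use case); when unknown it defaults to the
    track's total signal, with a warning at normalization time.
    """

    values: dict[str, np.ndarray]
    library_size: float | None = None
    label: str = ""

    def __post_init__(self):
        for chrom, arr in self.values.items():
            arr = np.asarray(arr, dtype=float)
            if (arr < 0).any():
                raise ValueError(f"negative coverage on {chrom}")
            self.values[chrom] = arr

    @property
    def chromosomes(self) -> dict[str, int]:
        return {c: len(a) for c, a in self.values.items()}

    def total(self) -> float:
        return float(sum(a.sum() for a in self.values.values()))

    def __getitem__(self, chrom: str) -> np.ndarray:
        if chrom not in self.values:
            raise KeyError(
                f"chromosome {chrom!r} not in track "
                f"(has {sorted(self.values)})"
            )
        return self.values[chrom]


def _check_chrom(chrom: str, genome: dict[str, int] | None, path, lineno: int):
    if genome is not None and chrom not in genome:
        raise FormatError(path, lineno, f"unknown chromosome {chrom!r}")


def read_bed(path, genome: dict[str, int] | None = None) -> list[Interval]:
    """Read BED3/BED6 into a list of :class:`Interval`.

    Malformed records raise :class:`FormatError` with the 1-based line number.
    ``genome`` (name -> length) enables chromosome-bound validation.
    """
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(path, lineno, "fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(path, lineno, f"non-integer coordinate: {exc}")
            _check_chrom(chrom, genome, path, lineno)
            if start < 0:
                raise FormatError(path, lineno, f"negative start {start}")
            if start >= end:
                raise FormatError(path, lineno, f"start {start} >= end {end}")
            if genome is not None and end > genome[chrom]:
                raise FormatError(
                    path, lineno, f"end {end} beyond {chrom} length {genome[chrom]}"
                )
            name = fields[3] if len(fields) > 3 else "."
            score = float(fields[4]) if len(fields) > 4 else 0.0
            strand = fields[5] if len(fields) > 5 else "."
            try:
                out.append(Interval(chrom, start, end, name, score, strand))
            except ValueError as exc:
                raise FormatError(path, lineno, str(exc))
    return out


def write_bed(intervals, path) -> None:
    """Write intervals as BED6, sorted by (chrom, start, end)."""
    ordered = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    with open(path, "w") as fh:
        for iv in ordered:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t"
                f"{_fmt(iv.score)}\t{iv.strand}\n"
            )


def _fmt(x: float) -> str:
    # shortest round-tripping decimal; integers without trailing .0
    if float(x) == int(x):
        return str(int(x))
    return repr(float(x))


def read_bedgraph(path, genome: dict[str, int], label: str = "",
                  library_size: float | None = None) -> CoverageTrack:
    """Read a bedGraph into a base-resolution :class:`CoverageTrack`.

    Uncovered bases get value 0.  Overlapping records with conflicting values
    raise :class:`FormatError` naming the first conflicting line; overlaps
    that agree in value are tolerated.
    """
    values = {c: np.zeros(n, dtype=float) for c, n in genome.items()}
    covered = {c: np.zeros(n, dtype=bool) for c, n in genome.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(path, lineno, "bedGraph needs 4 columns")
            chrom = fields[0]
            _check_chrom(chrom, genome, path, lineno)
            try:
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError as exc:
                raise FormatError(path, lineno, f"bad record: {exc}")
            if start < 0 or start >= end:
                raise FormatError(path, lineno, f"bad interval {start}-{end}")
            if end > genome[chrom]:
                raise FormatError(
                    path, lineno, f"end {end} beyond {chrom} length {genome[chrom]}"
                )
            if value < 0:
                raise FormatError(path, lineno, f"negative value {value}")
            seg = slice(start, end)
            clash = covered[chrom][seg] & (values[chrom][seg] != value)
            if clash.any():
                base = start + int(np.flatnonzero(clash)[0])
                raise FormatError(
                    path, lineno,
                    f"overlapping records with conflicting values at {chrom}:{base}",
                )
            values[chrom][seg] = value
            covered[chrom][seg] = True
    return CoverageTrack(values=values, library_size=library_size, label=label)


def write_bedgraph(track: CoverageTrack, path) -> None:
    """Write a track as sorted bedGraph; zero runs are omitted."""
    with open(path, "w") as fh:
        for chrom in sorted(track.values):
            arr = track.values[chrom]
            if arr.size == 0:
                continue
            # run boundaries of the piecewise-constant signal
            edges = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], edges))
            ends = np.concatenate((edges, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0.0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{_fmt(v)}\n")


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column UCSC chrom.sizes file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(path, lineno, "chrom.sizes needs 2 columns")
            try:
                n = int(fields[1])
            except ValueError:
                raise FormatError(path, lineno, f"non-integer length {fields[1]!r}")
            if n <= 0:
                raise FormatError(path, lineno, f"non-positive length {n}")
            if fields[0] in sizes:
                raise FormatError(path, lineno, f"duplicate chromosome {fields[0]!r}")
            sizes[fields[0]] = n
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


def read_ct_table(path) -> pd.DataFrame:
    """Read a tab-delimited qPCR Ct table (sample, target, condition, replicate, ct)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(path, 1, f"Ct table missing columns {missing}")
    if not np.isfinite(df["ct"]).all() or (df["ct"] <= 0).any():
        bad = df.index[~np.isfinite(df["ct"]) | (df["ct"] <= 0)][0]
        raise FormatError(path, int(bad) + 2, "Ct must be finite and positive")
    key = df[["sample", "target", "condition", "replicate"]]
    if key.duplicated().any():
        raise FormatError(path, 1, "duplicate (sample, target, condition, replicate)")
    return df


def write_ct_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=CT_COLUMNS)


def normalize_track(track: CoverageTrack, scale: str = "per_million") -> CoverageTrack:
    """Library-size normalization: every value times ``1e6 / library_size``.

    The output track's library_size is 1e6, so normalization is idempotent.
    When library_size is unset it defaults to the track's total signal
    (with a warning), mirroring total-read-count normalization when the
    read count is unavailable.
    """
    if scale != "per_million":
        raise ValueError(f"unknown scale {scale!r}")
    lib = track.library_size
    if lib is None:
        lib = track.total()
        warnings.warn(
            f"track {track.label!r} has no library_size; using total signal {lib:g}",
            stacklevel=2,
        )
    if lib <= 0:
        raise ValueError(f"library_size must be positive, got {lib}")
    factor = 1e6 / lib
    return CoverageTrack(
        values={c: a * factor for c, a in track.values.items()},
        library_size=1e6,
        label=track.label,
    )
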