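"""Readers, writers and domain types for the genomic formats the pipeline touches.

All internal coordinates are 0-based half-open.  BED input is consumed
natively; wiggle (which is 1-based) is converted on read.  Uncovered bases
of a signal track read as 0.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

TSS_CATEGORIES = {
    "protein_coding",
    "lincRNA",
    "miRNA",
    "snoRNA",
    "snRNA",
    "pseudogene",
    "artificial",
}
TSS_LABELS = {"cell_cycle", "non_cell_cycle", "unknown"}


class ParseError(ValueError):
    """Malformed input file; carries the offending line number when known."""


@dataclass(frozen=True)
class TssRecord:
    """One transcription start site.

    ``pos`` is the 0-based coordinate of the TSS base itself.  For a BED
    feature on the '-' strand the TSS is ``end - 1`` of the interval.
    ``peak_time`` is on the 0-100 scale used for cell-cycle expression
    maxima and is only meaningful for ``label == "cell_cycle"``.
    """

    chrom: str
    pos: int
    strand: str
    gene_id: str
    category: str = "protein_coding"
    label: str | None = None
    peak_time: float | None = None
    expression: float | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.category not in TSS_CATEGORIES:
            raise ValueError(f"unknown TSS category {self.category!r}")
        if self.label is not None and self.label not in TSS_LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.peak_time is not None:
            if not (0 <= self.peak_time < 100):
                raise ValueError(f"peak_time {self.peak_time} outside [0, 100)")
            if self.label != "cell_cycle":
                raise ValueError("peak_time is only valid for cell_cycle records")


class SignalTrack:
    """Per-base non-negative signal over named chromosomes.

    Stored sparsely as per-chromosome sorted, non-overlapping
    ``(start, end, value)`` intervals; any base not covered by an interval
    reads as 0.
    """

    def __init__(
        self,
        chrom_lengths: Mapping[str, int],
        intervals: Mapping[str, Iterable[tuple[int, int, float]]] | None = None,
    ) -> None:
        self.chrom_lengths: dict[str, int] = dict(chrom_lengths)
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._values: dict[str, np.ndarray] = {}
        intervals = intervals or {}
        for chrom in self.chrom_lengths:
            ivs = sorted(intervals.get(chrom, []))
            starts = np.array([iv[0] for iv in ivs], dtype=np.int64)
            ends = np.array([iv[1] for iv in ivs], dtype=np.int64)
            values = np.array([iv[2] for iv in ivs], dtype=np.float64)
            self._validate(chrom, starts, ends, values)
            self._starts[chrom] = starts
            self._ends[chrom] = ends
            self._values[chrom] = values
        unknown = set(intervals) - set(self.chrom_lengths)
        if unknown:
            raise ValueError(f"intervals on unknown chromosomes: {sorted(unknown)}")

    def _validate(self, chrom, starts, ends, values) -> None:
        if len(starts) == 0:
            return
        length = self.chrom_lengths[chrom]
        if starts[0] < 0 or np.any(ends > length):
            raise ValueError(f"{chrom}: interval outside [0, {length})")
        if np.any(starts >= ends):
            raise ValueError(f"{chrom}: empty or inverted interval")
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"{chrom}: overlapping intervals")
        if np.any(values < 0):
            raise ValueError(f"{chrom}: negative signal value")

    @classmethod
    def from_dense(
        cls, arrays: Mapping[str, np.ndarray], chrom_lengths: Mapping[str, int] | None = None
    ) -> "SignalTrack":
        """Build a track from per-chromosome dense per-base arrays.

        Runs of equal value are collapsed into single intervals; zero runs
        are dropped (they are implicit).
        """
        chrom_lengths = dict(chrom_lengths or {c: len(a) for c, a in arrays.items()})
        intervals: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, arr in arrays.items():
            arr = np.asarray(arr, dtype=np.float64)
            if len(arr) != chrom_lengths[chrom]:
                raise ValueError(f"{chrom}: dense array length mismatch")
            breaks = np.flatnonzero(arr[1:] != arr[:-1]) + 1
            starts = np.concatenate(([0], breaks))
            ends = np.concatenate((breaks, [len(arr)]))
            vals = arr[starts]
            keep = vals != 0
            intervals[chrom] = list(
                zip(starts[keep].tolist(), ends[keep].tolist(), vals[keep].tolist())
            )
        return cls(chrom_lengths, intervals)

    def intervals(self, chrom: str) -> list[tuple[int, int, float]]:
        return list(
            zip(
                self._starts[chrom].tolist(),
                self._ends[chrom].tolist(),
                self._values[chrom].tolist(),
            )
        )

    def query(self, chrom: str, pos: int) -> float:
        """Signal at a single base (0 if uncovered or out of range)."""
        return float(self.values(chrom, pos, pos + 1)[0])

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Dense per-base signal over ``[start, end)``.

        Positions outside the chromosome read as 0, so windows hanging off
        either end come back zero-padded at full length.
        """
        if chrom not in self.chrom_lengths:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if end < start:
            raise ValueError("end < start")
        out = np.zeros(end - start, dtype=np.float64)
        starts, ends, values = self._starts[chrom], self._ends[chrom], self._values[chrom]
        if len(starts) == 0:
            return out
        # first interval that ends after `start`, last that starts before `end`
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for i in range(lo, hi):
            a = max(starts[i], start) - start
            b = min(ends[i], end) - start
            if b > a:
                out[a:b] = values[i]
        return out


def read_signal_track(path: str | Path, genome: Mapping[str, int]) -> SignalTrack:
    """Read a bedGraph or wiggle (fixedStep/variableStep) file into a SignalTrack.

    Wiggle coordinates are 1-based and converted to the internal 0-based
    half-open convention.  Overlapping intervals and unknown chromosomes
    are rejected.
    """
    intervals: dict[str, list[tuple[int, int, float]]] = {c: [] for c in genome}
    mode = "bedgraph"
    chrom = ""
    step = span = 1
    nextpos = 0  # 0-based start of next fixedStep value

    def check_chrom(name: str, lineno: int) -> None:
        if name not in genome:
            raise ParseError(f"line {lineno}: unknown chromosome {name!r}")

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if fields[0] == "fixedStep":
                mode = "fixed"
                kv = dict(f.split("=", 1) for f in fields[1:])
                chrom = kv["chrom"]
                check_chrom(chrom, lineno)
                nextpos = int(kv["start"]) - 1
                step = int(kv.get("step", 1))
                span = int(kv.get("span", 1))
                continue
            if fields[0] == "variableStep":
                mode = "variable"
                kv = dict(f.split("=", 1) for f in fields[1:])
                chrom = kv["chrom"]
                check_chrom(chrom, lineno)
                span = int(kv.get("span", 1))
                continue
            try:
                if mode == "bedgraph":
                    if len(fields) != 4:
                        raise ValueError("expected 4 bedGraph fields")
                    c, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
                    check_chrom(c, lineno)
                    intervals[c].append((start, end, value))
                elif mode == "fixed":
                    value = float(fields[0])
                    intervals[chrom].append((nextpos, nextpos + span, value))
                    nextpos += step
                else:  # variable
                    pos, value = int(fields[0]) - 1, float(fields[1])
                    intervals[chrom].append((pos, pos + span, value))
            except ParseError:
                raise
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
    return SignalTrack(genome, intervals)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chrom_lengths:
            for start, end, value in track.intervals(chrom):
                fh.write(f"{chrom}\t{start}\t{end}\t{value:.10g}\n")


def _fmt_opt(x) -> str:
    return "." if x is None else f"{x:.10g}" if isinstance(x, float) else str(x)


def read_tss_bed(path: str | Path) -> list[TssRecord]:
    """Read TSS records from BED6 with optional extension columns.

    Columns 7-10 of the extended dialect carry category, label, peak_time
    and expression; '.' marks a missing value.  For '-' strand features the
    TSS is taken at ``end - 1``.  Records come back sorted by
    ``(chrom, pos)``; duplicates (alternative promoters) are allowed.
    """
    records: list[TssRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ParseError(f"line {lineno}: need >= 6 BED columns (strand required)")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                gene_id, strand = f[3], f[5]
                category = f[6] if len(f) > 6 and f[6] != "." else "protein_coding"
                label = f[7] if len(f) > 7 and f[7] != "." else None
                peak_time = float(f[8]) if len(f) > 8 and f[8] != "." else None
                expression = float(f[9]) if len(f) > 9 and f[9] != "." else None
                pos = start if strand == "+" else end - 1
                records.append(
                    TssRecord(chrom, pos, strand, gene_id, category, label, peak_time, expression)
                )
            except ParseError:
                raise
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records


def write_tss_bed(records: Sequence[TssRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            start = r.pos if r.strand == "+" else r.pos
            end = r.pos + 1
            fh.write(
                "\t".join(
                    [
                        r.chrom,
                        str(start),
                        str(end),
                        r.gene_id,
                        "0",
                        r.strand,
                        r.category,
                        r.label or ".",
                        _fmt_opt(r.peak_time),
                        _fmt_opt(r.expression),
                    ]
                )
                + "\n"
            )


BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class PfmMatrix:
    """A position frequency matrix in TRANSFAC orientation (L rows x ACGT).

    ``core_start``/``core_len`` delimit the core window used for the core
    similarity score; when a matrix carries no annotation the core defaults
    to the 5 consecutive most informative positions.  ``cutoff_mss`` and
    ``cutoff_css`` are the retained-hit thresholds on the matrix and core
    similarity scores.
    """

    motif_id: str
    counts: np.ndarray
    core_start: int | None = None
    core_len: int = 5
    cutoff_mss: float = 0.85
    cutoff_css: float = 0.75

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must be an L x 4 matrix")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if np.any(self.counts.sum(axis=1) <= 0):
            raise ValueError("every position must have positive total count")
        L = self.length
        self.core_len = min(self.core_len, L)
        if self.core_start is None:
            self.core_start = self._default_core_start()
        if not (0 <= self.core_start and self.core_start + self.core_len <= L):
            raise ValueError("core window outside matrix")

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    def frequencies(self, pseudocount: float = 1.0) -> np.ndarray:
        c = self.counts + pseudocount
        return c / c.sum(axis=1, keepdims=True)

    def information(self, pseudocount: float = 1.0) -> np.ndarray:
        """Per-position information weight I(i) = sum_b f(i,b) ln(4 f(i,b))."""
        f = self.frequencies(pseudocount)
        return (f * np.log(4.0 * f)).sum(axis=1)

    def _default_core_start(self) -> int:
        info = self.information()
        k = self.core_len
        window_sums = np.convolve(info, np.ones(k), mode="valid")
        return int(np.argmax(window_sums))

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=1))

    def reverse_complement(self) -> "PfmMatrix":
        rc = self.counts[::-1, ::-1].copy()
        return PfmMatrix(
            self.motif_id,
            rc,
            core_start=self.length - (self.core_start + self.core_len),
            core_len=self.core_len,
            cutoff_mss=self.cutoff_mss,
            cutoff_css=self.cutoff_css,
        )


def read_transfac(
    path: str | Path, cutoffs: Mapping[str, tuple[float, float]] | None = None
) -> list[PfmMatrix]:
    """Read TRANSFAC flat-file matrices (AC/ID, P0 header, 01..0L rows, //).

    ``cutoffs`` maps motif id -> (cutoff_mss, cutoff_css), typically parsed
    from a sidecar table (see :func:`read_cutoffs`); matrices without an
    entry fall back to the package defaults (0.85, 0.75).
    """
    matrices: list[PfmMatrix] = []
    motif_id: str | None = None
    rows: list[list[float]] = []
    in_matrix = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            tag = line[:2]
            if tag == "AC":
                motif_id = line[2:].strip()
            elif tag == "ID" and motif_id is None:
                motif_id = line[2:].strip()
            elif tag == "P0" or tag == "PO":
                in_matrix = True
                rows = []
            elif tag == "//":
                if motif_id is not None and rows:
                    m = PfmMatrix(motif_id, np.array(rows))
                    if cutoffs and motif_id in cutoffs:
                        m.cutoff_mss, m.cutoff_css = cutoffs[motif_id]
                    matrices.append(m)
                motif_id, rows, in_matrix = None, [], False
            elif in_matrix and tag.strip().isdigit():
                parts = line.split()
                nums = parts[1:5]
                if len(nums) < 4:
                    raise ParseError(f"line {lineno}: matrix row with < 4 numbers")
                try:
                    rows.append([float(x) for x in nums])
                except ValueError as exc:
                    raise ParseError(f"line {lineno}: {exc}") from exc
    if motif_id is not None and rows:  # unterminated final matrix
        matrices.append(PfmMatrix(motif_id, np.array(rows)))
    return matrices


def write_transfac(matrices: Sequence[PfmMatrix], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in matrices:
            fh.write(f"AC {m.motif_id}\nID {m.motif_id}\nP0      A      C      G      T\n")
            for i, row in enumerate(m.counts, start=1):
                cells = "  ".join(f"{x:7.10g}" for x in row)
                fh.write(f"{i:02d}  {cells}  {BASES[int(np.argmax(row))]}\n")
            fh.write("//\n")


def read_cutoffs(path: str | Path) -> dict[str, tuple[float, float]]:
    """Read a sidecar cutoff table: TSV of motif_id, cutoff_mss, cutoff_css."""
    out: dict[str, tuple[float, float]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith("motif_id"):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ParseError(f"line {lineno}: need motif_id, mss, css")
            out[f[0]] = (float(f[1]), float(f[2]))
    return out


def write_cutoffs(cutoffs: Mapping[str, tuple[float, float]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("motif_id\tcutoff_mss\tcutoff_css\n")
        for mid, (mss, css) in cutoffs.items():
            fh.write(f"{mid}\t{mss:.6g}\t{css:.6g}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a dict of uppercase sequences."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
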