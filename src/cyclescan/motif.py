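"""MATCH-style motif scanning of promoter sequences.

Each position frequency matrix is scored against every window of a
promoter on both strands with the information-weighted matrix similarity
score (MSS) and the core similarity score (CSS, same score restricted to
the matrix's 5-position core).  With per-position frequencies
``f(i, b)`` (pseudocount-adjusted) and information weights
``I(i) = sum_b f(i,b) ln(4 f(i,b))``, a window with bases ``b_1..b_L``
scores ``sum_i I(i) f(i, b_i)``, min-max normalised over the matrix's
attainable range so that the consensus scores 1 and the anti-consensus 0.
Hits passing both cutoffs are aggregated per gene x motif into the binding
score matrix B (sum of MSS by default; 0 when a promoter has no hit).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from cyclescan.genomic_io import BASES, PfmMatrix, TssRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifHit:
    """One retained motif match inside a promoter."""

    gene_id: str
    motif_id: str
    offset: int
    strand: str
    mss: float
    css: float


def promoter_sequence(genome, tss: TssRecord, upstream: int = 1000) -> str:
    """Upstream promoter sequence of a TSS, 5'->3' of the gene.

    '+' strand: bases ``[pos - upstream, pos)``.  '-' strand: the reverse
    complement of bases ``[pos + 1, pos + 1 + upstream)``.  Truncated at
    chromosome ends, so the result may be shorter than ``upstream``.
    ``genome`` is any mapping of chromosome name to a sliceable sequence
    (a plain dict of strings or a ``pyfaidx.Fasta``).
    """
    try:
        contig = genome[tss.chrom]
    except KeyError as exc:
        raise KeyError(f"unknown chromosome {tss.chrom!r}") from exc
    n = len(contig)
    if not (0 <= tss.pos < n):
        raise ValueError(f"TSS position {tss.pos} outside contig {tss.chrom} (length {n})")
    if tss.strand == "+":
        seq = str(contig[max(0, tss.pos - upstream) : tss.pos])
    else:
        seq = reverse_complement(str(contig[tss.pos + 1 : tss.pos + 1 + upstream]))
    return seq.upper()


def _encode(seq: str) -> np.ndarray:
    """Map ACGT -> 0..3 and anything else (N) -> -1."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(len(arr), -1, dtype=np.int64)
    for i, b in enumerate(BASES):
        out[arr == ord(b)] = i
    return out


def _window_scores(enc: np.ndarray, psv: np.ndarray, info: np.ndarray) -> np.ndarray:
    """Raw information-weighted scores of all windows of one strand.

    ``psv[i, b] = I(i) * f(i, b)``; positions with N take the matrix
    minimum for that position.
    """
    L = psv.shape[0]
    n_win = len(enc) - L + 1
    if n_win <= 0:
        return np.empty(0)
    idx = np.arange(n_win)[:, None] + np.arange(L)[None, :]
    bases = enc[idx]  # (n_win, L)
    pos_min = psv.min(axis=1)
    safe = np.where(bases >= 0, bases, 0)
    scores = psv[np.arange(L)[None, :], safe]
    scores = np.where(bases >= 0, scores, pos_min[None, :])
    return scores.sum(axis=1)


def _minmax(psv: np.ndarray) -> tuple[float, float]:
    return float(psv.min(axis=1).sum()), float(psv.max(axis=1).sum())


def _normalise(raw: np.ndarray, lo: float, hi: float) -> np.ndarray:
    if hi > lo:
        return (raw - lo) / (hi - lo)
    # zero attainable range (fully degenerate matrix): every window is
    # simultaneously the best and worst match; score it as a perfect match
    return np.ones_like(raw)


def match_scan(
    seq: str,
    matrix: PfmMatrix,
    gene_id: str = "",
    pseudocount: float = 1.0,
    cutoff_mss: float | None = None,
    cutoff_css: float | None = None,
) -> list[MotifHit]:
    """Scan one sequence with one matrix on both strands.

    Returns hits with ``mss >= cutoff_mss`` and ``css >= cutoff_css``
    (cutoffs default to the matrix's own), sorted by offset.  Offsets are
    0-based positions of the match start in ``seq`` regardless of strand.
    A sequence shorter than the matrix yields no hits.
    """
    cm = matrix.cutoff_mss if cutoff_mss is None else cutoff_mss
    cc = matrix.cutoff_css if cutoff_css is None else cutoff_css
    L = matrix.length
    if len(seq) < L:
        return []
    f = matrix.frequencies(pseudocount)
    info = matrix.information(pseudocount)
    psv = info[:, None] * f
    lo, hi = _minmax(psv)
    core = slice(matrix.core_start, matrix.core_start + matrix.core_len)
    core_psv = psv[core]
    clo, chi = _minmax(core_psv)

    enc_fwd = _encode(seq.upper())
    hits: list[MotifHit] = []
    for strand in ("+", "-"):
        enc = enc_fwd if strand == "+" else _encode(reverse_complement(seq.upper()))
        raw = _window_scores(enc, psv, info)
        mss = _normalise(raw, lo, hi)
        raw_core = _window_scores(enc, core_psv, info[core])
        # core windows inside each full window start core_start later
        css_all = _normalise(raw_core, clo, chi)
        css = css_all[matrix.core_start : matrix.core_start + len(mss)]
        keep = np.flatnonzero((mss >= cm) & (css >= cc))
        for j in keep:
            offset = int(j) if strand == "+" else len(seq) - int(j) - L
            hits.append(MotifHit(gene_id, matrix.motif_id, offset, strand, float(mss[j]), float(css[j])))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def aggregate_scores(
    hits: Iterable[MotifHit],
    gene_ids: Sequence[str],
    motif_ids: Sequence[str],
    method: str = "sum",
) -> pd.DataFrame:
    """Build the gene x motif binding score matrix B from retained hits.

    ``B[i, j]`` aggregates the MSS of all retained hits of motif j in the
    promoter of gene i — a sum by default, so the score grows with the
    number of sites; ``method="max"`` keeps the single best site.  Genes
    with no hit score exactly 0.
    """
    if method not in ("sum", "max"):
        raise ValueError("method must be 'sum' or 'max'")
    B = pd.DataFrame(0.0, index=list(gene_ids), columns=list(motif_ids))
    for h in hits:
        if h.gene_id not in B.index or h.motif_id not in B.columns:
            continue
        if method == "sum":
            B.loc[h.gene_id, h.motif_id] += h.mss
        else:
            B.loc[h.gene_id, h.motif_id] = max(B.loc[h.gene_id, h.motif_id], h.mss)
    return B


def scan_promoters(
    promoters: Mapping[str, str],
    matrices: Sequence[PfmMatrix],
    method: str = "sum",
    pseudocount: float = 1.0,
) -> tuple[list[MotifHit], pd.DataFrame]:
    """Scan every promoter with every matrix; return (hits, B matrix)."""
    hits: list[MotifHit] = []
    for gene_id, seq in promoters.items():
        for m in matrices:
            hits.extend(match_scan(seq, m, gene_id=gene_id, pseudocount=pseudocount))
    B = aggregate_scores(hits, list(promoters), [m.motif_id for m in matrices], method=method)
    return hits, B
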