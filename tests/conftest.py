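"""Shared builders for the test suite.

Everything is generated programmatically; no stored fixtures.
"""

from __future__ import annotations

import numpy as np
import pytest

from cyclescan.genomic_io import PfmMatrix, SignalTrack, TssRecord


def make_random_track(
    rng: np.random.Generator,
    chrom_lengths: dict[str, int],
    n_intervals: int = 100,
    max_value: float = 10.0,
) -> SignalTrack:
    """Random sparse non-overlapping track over the given chromosomes."""
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    for chrom, length in chrom_lengths.items():
        cuts = np.sort(rng.choice(length, size=min(2 * n_intervals, length - 1), replace=False))
        ivs = []
        for a, b in zip(cuts[::2], cuts[1::2]):
            if b > a and rng.uniform() < 0.8:
                ivs.append((int(a), int(b), float(rng.uniform(0, max_value))))
        intervals[chrom] = ivs
    return SignalTrack(chrom_lengths, intervals)


def dense_expand(track: SignalTrack, chrom: str) -> np.ndarray:
    """Brute-force per-base expansion of a track, independent of values()."""
    arr = np.zeros(track.chrom_lengths[chrom])
    for start, end, value in track.intervals(chrom):
        for i in range(start, end):
            arr[i] = value
    return arr


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def toy_matrix() -> PfmMatrix:
    """4-position matrix with consensus ACGT."""
    counts = np.array(
        [
            [10, 1, 1, 1],
            [1, 10, 1, 1],
            [1, 1, 10, 1],
            [1, 1, 1, 10],
        ],
        dtype=float,
    )
    return PfmMatrix("TOY", counts, cutoff_mss=0.0, cutoff_css=0.0)


def make_tss(chrom="chr1", pos=5000, strand="+", gene_id="g1", **kw) -> TssRecord:
    return TssRecord(chrom, pos, strand, gene_id, **kw)
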