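"""TIP regulatory scoring of genes from TF ChIP-seq signal.

TIP (Target Identification from Profiles) averages a TF's binding signal
around the TSS of *all* genes into a characteristic profile, normalises the
profile into positional weights, and scores each gene by the weighted sum
of the signal around its own TSS.  Genes whose promoters carry signal where
the TF characteristically binds therefore score high; the same amount of
signal far from the characteristic binding zone contributes little.  The
unweighted mean signal in a 2 kb TSS-centred window (``average_signal``)
is the baseline this scheme is compared against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from cyclescan.genomic_io import SignalTrack, TssRecord


class DegenerateProfileError(ValueError):
    """The characteristic profile is identically zero; weights are undefined."""


@dataclass
class BindingProfile:
    """Characteristic TSS-centred binding profile of one ChIP-seq dataset.

    ``profile[k]`` is the mean signal at strand-oriented offset ``k - h``
    from the TSS, averaged over all genes; ``weights`` is the profile
    normalised to sum to 1.
    """

    half_width: int
    profile: np.ndarray
    weights: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.profile = np.asarray(self.profile, dtype=np.float64)
        if self.profile.shape != (2 * self.half_width + 1,):
            raise ValueError("profile length must be 2*half_width + 1")
        total = self.profile.sum()
        if total <= 0:
            raise DegenerateProfileError("all-zero characteristic profile")
        self.weights = self.profile / total


class _DenseCache(dict):
    """Lazily materialised per-chromosome dense signal arrays.

    Batch operations (profiles, score sets over thousands of TSSs) pay the
    per-chromosome expansion once instead of re-walking the sparse
    intervals for every window.
    """

    def __init__(self, track: SignalTrack) -> None:
        super().__init__()
        self._track = track

    def __missing__(self, chrom: str) -> np.ndarray:
        arr = self._track.values(chrom, 0, self._track.chrom_lengths[chrom])
        self[chrom] = arr
        return arr


def _window_from_dense(
    dense: np.ndarray, pos: int, half: tuple[int, int], strand: str
) -> np.ndarray:
    """Zero-padded strand-oriented window [pos - half[0], pos + half[1]) of a dense array."""
    lo, hi = pos - half[0], pos + half[1]
    out = np.zeros(hi - lo, dtype=np.float64)
    a, b = max(0, lo), min(len(dense), hi)
    if b > a:
        out[a - lo : b - lo] = dense[a:b]
    return out[::-1] if strand == "-" else out


def _tss_window(
    track: SignalTrack, tss: TssRecord, h: int, cache: _DenseCache | None = None
) -> np.ndarray:
    """Strand-oriented per-base signal over the (2h+1)-window centred at the TSS.

    Index order is 5'->3' of the gene; windows truncated at chromosome
    edges are zero-padded.
    """
    if cache is not None:
        return _window_from_dense(cache[tss.chrom], tss.pos, (h, h + 1), tss.strand)
    w = track.values(tss.chrom, tss.pos - h, tss.pos + h + 1)
    return w[::-1] if tss.strand == "-" else w


def characteristic_profile(
    track: SignalTrack,
    tss: Sequence[TssRecord],
    h: int = 5000,
    smooth: int = 0,
    _cache: "_DenseCache | None" = None,
) -> BindingProfile:
    """Average strand-oriented signal windows over all TSSs into a profile.

    Parameters
    ----------
    h
        Half-width in bp; the profile covers ``[-h, +h]`` around the TSS
        (10 kb total at the default).
    smooth
        Optional moving-average width (bp) applied to the averaged profile
        before normalisation; 0 disables smoothing.  Raw per-base averages
        are noisy when few TSSs are available.
    """
    if len(tss) == 0:
        raise ValueError("need at least one TSS")
    acc = np.zeros(2 * h + 1)
    for r in tss:
        acc += _tss_window(track, r, h, _cache)
    c = acc / len(tss)
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        c = np.convolve(c, kernel, mode="same")
    return BindingProfile(h, c)


def regulatory_score(profile: BindingProfile, track: SignalTrack, tss: TssRecord) -> float:
    """TIP score of one gene: weighted sum of its own TSS-window signal.

    Because the weights sum to 1 this is a weighted average, bounded by the
    min and max signal inside the window.
    """
    s = _tss_window(track, tss, profile.half_width)
    return float(np.dot(profile.weights, s))


def regulatory_scores(
    profile: BindingProfile,
    track: SignalTrack,
    tss: Sequence[TssRecord],
    _cache: "_DenseCache | None" = None,
) -> dict[str, float]:
    """TIP scores for a list of TSSs, keyed by gene id."""
    cache = _cache if _cache is not None else _DenseCache(track)
    h = profile.half_width
    return {
        r.gene_id: float(np.dot(profile.weights, _tss_window(track, r, h, cache)))
        for r in tss
    }


def average_signals(
    track: SignalTrack,
    tss: Sequence[TssRecord],
    half_width: int = 1000,
    _cache: "_DenseCache | None" = None,
) -> dict[str, float]:
    """Average-signal comparator for a list of TSSs, keyed by gene id."""
    cache = _cache if _cache is not None else _DenseCache(track)
    return {
        r.gene_id: float(
            _window_from_dense(cache[r.chrom], r.pos, (half_width, half_width), r.strand).mean()
        )
        for r in tss
    }


def average_signal(track: SignalTrack, tss: TssRecord, half_width: int = 1000) -> float:
    """Unweighted mean signal over the 2*half_width window centred at the TSS.

    The window is ``[pos - half_width, pos + half_width)``; truncated
    windows stay zero-padded so the denominator is always 2*half_width.
    """
    s = track.values(tss.chrom, tss.pos - half_width, tss.pos + half_width)
    return float(s.mean())


@dataclass
class RegScoreSet:
    """Standardised regulatory scores of one ChIP-seq dataset over genes."""

    dataset_id: str
    scores: dict[str, float]
    z: dict[str, float]
    p: dict[str, float]
    q: dict[str, float]
    q_threshold: float = 0.01

    @property
    def targets(self) -> set[str]:
        """Genes called as targets of this TF (BH-adjusted q below threshold)."""
        return {g for g, q in self.q.items() if q < self.q_threshold}


def standardize_and_call(
    raw: Mapping[str, float],
    dataset_id: str = "",
    q_threshold: float = 0.01,
    ddof: int = 1,
) -> RegScoreSet:
    """Standardise raw regulatory scores and call targets.

    z-scores use the across-gene mean and (sample, ``ddof=1``) standard
    deviation; p is the one-sided upper-tail normal probability and q the
    Benjamini-Hochberg adjustment.
    """
    genes = list(raw)
    if len(genes) < 3:
        raise ValueError("need at least 3 genes to standardise")
    x = np.array([raw[g] for g in genes], dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite score")
    sd = x.std(ddof=ddof)
    if sd == 0:
        raise ValueError("all scores equal; z-scores undefined")
    z = (x - x.mean()) / sd
    p = stats.norm.sf(z)
    q = stats.false_discovery_control(p, method="bh")
    return RegScoreSet(
        dataset_id=dataset_id,
        scores=dict(zip(genes, x.tolist())),
        z=dict(zip(genes, z.tolist())),
        p=dict(zip(genes, p.tolist())),
        q=dict(zip(genes, q.tolist())),
        q_threshold=q_threshold,
    )


def score_class_contrast(
    scores: Mapping[str, float],
    labels: Mapping[str, int],
    equal_var: bool = False,
) -> tuple[float, float]:
    """Two-sample t contrast of scores between positive and negative genes.

    Returns ``(t, p)`` for positives (label 1) versus negatives (label 0);
    Welch's t by default, pooled-variance with ``equal_var=True``.
    """
    pos = [scores[g] for g, y in labels.items() if y == 1 and g in scores]
    neg = [scores[g] for g, y in labels.items() if y == 0 and g in scores]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("both classes need at least 2 members")
    t, p = stats.ttest_ind(pos, neg, equal_var=equal_var)
    return float(t), float(p)
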