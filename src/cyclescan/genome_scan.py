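"""Genome-wide application of a trained model with empirical FDR control.

A trained Random Forest is applied to an arbitrary TSS catalogue
(protein-coding, lincRNA, pseudogene, ... promoters), and to a set of
artificial TSSs drawn uniformly over the genome as negative controls.
At a probability threshold t the empirical false discovery rate is
``FDR(t) = F_rand / F_real`` — the fraction of artificial TSSs called
positive divided by the fraction of real TSSs called positive — and the
precision is reported as ``PPV = 1 - FDR`` wherever FDR <= 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cyclescan.classifier import FeatureTable
from cyclescan.genomic_io import TssRecord


class NoPositivePredictions(ValueError):
    """F_real = 0 at the requested threshold; the FDR ratio is undefined."""


@dataclass
class PredictionSet:
    """Per-TSS positive-class probabilities with category annotations."""

    tss_ids: list[str]
    probabilities: np.ndarray
    categories: list[str]

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=np.float64)
        if not (len(self.tss_ids) == len(self.probabilities) == len(self.categories)):
            raise ValueError("length mismatch")
        if np.any((self.probabilities < 0) | (self.probabilities > 1)):
            raise ValueError("probabilities outside [0, 1]")

    def positive_fraction(self, threshold: float) -> float:
        return float((self.probabilities >= threshold).mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tss_id": self.tss_ids,
                "probability": self.probabilities,
                "category": self.categories,
            }
        )


def predict_tss(model, table: FeatureTable, categories: Mapping[str, str] | None = None) -> PredictionSet:
    """Score a TSS catalogue with a trained forest.

    The probability of each TSS is the fraction of trees voting for the
    positive class; the result is deterministic given the model and
    features.  ``categories`` maps TSS id -> category (defaults to
    ``protein_coding``).
    """
    pos_col = list(model.classes_).index(1)
    prob = model.predict_proba(table.X)[:, pos_col]
    cats = [
        (categories or {}).get(g, "protein_coding") for g in table.gene_ids
    ]
    return PredictionSet(list(table.gene_ids), prob, cats)


def random_tss(
    genome: Mapping[str, int],
    n: int = 10000,
    seed: int | None = 0,
    exclusion: Sequence[tuple[str, int, int]] | None = None,
) -> list[TssRecord]:
    """Artificial TSSs drawn uniformly over the genome as null controls.

    Positions are uniform over total genome length (so per-chromosome
    counts are proportional to chromosome lengths), strands uniform, and
    category ``artificial``.  ``exclusion`` optionally lists
    ``(chrom, start, end)`` intervals (e.g. +/-1 kb around real TSSs) that
    positions must avoid; by default no exclusion is applied.
    """
    rng = np.random.default_rng(seed)
    chroms = list(genome)
    lengths = np.array([genome[c] for c in chroms], dtype=np.int64)
    total = int(lengths.sum())
    excl: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    excluded_len = 0
    for c, a, b in exclusion or []:
        a, b = max(0, a), min(genome[c], b)
        if b > a:
            excl[c].append((a, b))
            excluded_len += b - a
    if excluded_len >= total:
        raise ValueError("exclusion covers the whole genome")
    offsets = np.concatenate(([0], np.cumsum(lengths)))
    records: list[TssRecord] = []
    i = 0
    attempts = 0
    while len(records) < n:
        attempts += 1
        if attempts > 1000 * n:
            raise ValueError("exclusion too dense; cannot place random TSSs")
        g = int(rng.integers(0, total))
        ci = int(np.searchsorted(offsets, g, side="right") - 1)
        chrom, pos = chroms[ci], g - int(offsets[ci])
        if any(a <= pos < b for a, b in excl[chrom]):
            continue
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        records.append(
            TssRecord(chrom, pos, strand, f"random_{i}", category="artificial")
        )
        i += 1
    return records


def empirical_fdr(
    real: PredictionSet, artificial: PredictionSet, threshold: float
) -> float:
    """Empirical FDR at one threshold: F_rand / F_real.

    ``F_rand`` and ``F_real`` are the fractions of artificial and real
    TSSs with probability >= threshold.  Raises
    :class:`NoPositivePredictions` when no real TSS passes.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    f_real = real.positive_fraction(threshold)
    f_rand = artificial.positive_fraction(threshold)
    if f_real == 0:
        raise NoPositivePredictions(f"no real TSS passes threshold {threshold}")
    return f_rand / f_real


def fdr_ppv_curves(
    real: PredictionSet, artificial: PredictionSet, step: float = 0.01
) -> pd.DataFrame:
    """FDR and PPV over a threshold grid (0 to 1, default step 0.01).

    FDR is reported unclipped in ``fdr`` and clipped to 1 in
    ``fdr_clipped``; PPV = 1 - FDR wherever FDR <= 1, else 0.  Rows where
    F_real = 0 carry NaN.
    """
    thresholds = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    rows = []
    for t in thresholds:
        f_real = real.positive_fraction(t)
        f_rand = artificial.positive_fraction(t)
        fdr = f_rand / f_real if f_real > 0 else np.nan
        rows.append(
            {
                "threshold": t,
                "f_real": f_real,
                "f_rand": f_rand,
                "fdr": fdr,
                "fdr_clipped": min(fdr, 1.0) if np.isfinite(fdr) else np.nan,
                "ppv": max(0.0, 1.0 - fdr) if np.isfinite(fdr) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def category_summary(predictions: PredictionSet, threshold: float = 0.7) -> pd.DataFrame:
    """Per-category counts and percentages of positive TSSs at a threshold."""
    df = predictions.to_frame()
    df["positive"] = df["probability"] >= threshold
    out = (
        df.groupby("category", sort=True)
        .agg(n_tss=("tss_id", "size"), n_positive=("positive", "sum"))
        .reset_index()
    )
    out["pct_positive"] = 100.0 * out["n_positive"] / out["n_tss"]
    return out


def alternative_promoter_report(
    predictions: PredictionSet,
    gene_to_tss: Mapping[str, Sequence[str]],
    split_margin: float = 0.4,
) -> pd.DataFrame:
    """Per-gene view over alternative promoters.

    For each gene with several TSSs, reports the per-TSS probabilities and
    flags the gene as a *split-promoter* gene when the spread
    (max - min probability) exceeds ``split_margin`` — i.e. some of its
    promoters look cell-cycle driven and others do not.
    """
    prob_of = dict(zip(predictions.tss_ids, predictions.probabilities))
    rows = []
    for gene, tss_ids in gene_to_tss.items():
        probs = [prob_of[t] for t in tss_ids if t in prob_of]
        if not probs:
            continue
        spread = max(probs) - min(probs)
        rows.append(
            {
                "gene_id": gene,
                "n_tss": len(probs),
                "probabilities": probs,
                "max_prob": max(probs),
                "min_prob": min(probs),
                "split_promoter": spread > split_margin,
            }
        )
    return pd.DataFrame(rows)
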