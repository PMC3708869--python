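"""Validation statistics for predicted cell-cycle genes.

Three independent checks:

* circular sliding-window enrichment of a TF's target genes over the
  cell-cycle peak-time axis (Fisher's exact test per window),
* overlap of a predicted gene set with an external reference set
  (knockdown screens) against an explicit gene universe,
* protein-protein-interaction partner statistics per gene class with
  chi-squared tests on aggregate partner counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class WindowEnrichment:
    """Enrichment of a target set in one circular phase window."""

    window_center: float  # degrees in [0, 360)
    window_size: float
    table: tuple[int, int, int, int]  # (in&target, in&non, out&target, out&non)
    odds_ratio: float
    p: float


def _in_window(theta: np.ndarray, center: float, size: float) -> np.ndarray:
    """Membership of angles in the circular window [center - size/2, center + size/2)."""
    d = np.mod(theta - (center - size / 2.0), 360.0)
    return d < size


def phase_window_enrichment(
    peak_times: Mapping[str, float],
    targets: Iterable[str],
    window: float = 30.0,
    step: float = 20.0,
    alternative: str = "greater",
) -> list[WindowEnrichment]:
    """Sliding-window enrichment of TF targets over the cell-cycle circle.

    Peak times on the 0-100 scale are mapped to degrees (theta = 3.6 *
    peak_time).  Windows of ``window`` degrees slide in steps of ``step``
    degrees and wrap around 360; adjacent 30-degree windows at the default
    20-degree step share 10 degrees of overlap.  Each window's 2x2 table
    of (in-window vs out) x (target vs non-target) is tested with a
    one-sided Fisher's exact test (enrichment direction) by default.
    """
    genes = list(peak_times)
    theta = np.array([3.6 * peak_times[g] for g in genes])
    is_target = np.array([g in set(targets) for g in genes])
    centers = np.arange(0.0, 360.0, step)
    out: list[WindowEnrichment] = []
    for c in centers:
        inside = _in_window(theta, c, window)
        a = int((inside & is_target).sum())
        b = int((inside & ~is_target).sum())
        cc = int((~inside & is_target).sum())
        d = int((~inside & ~is_target).sum())
        orat, p = stats.fisher_exact([[a, b], [cc, d]], alternative=alternative)
        out.append(WindowEnrichment(float(c), window, (a, b, cc, d), float(orat), float(p)))
    return out


def set_overlap_test(
    predicted: Iterable[str],
    reference: Iterable[str],
    universe_size: int,
    alternative: str = "greater",
) -> tuple[int, float, float]:
    """Fisher's exact test of the overlap between two gene sets.

    The universe size must be supplied explicitly (it is an assumption,
    never inferred from the inputs).  Returns
    ``(overlap, odds_ratio, p)``.
    """
    P, R = set(predicted), set(reference)
    k = len(P & R)
    if universe_size < len(P | R):
        raise ValueError("universe smaller than the union of the sets")
    table = [
        [k, len(P) - k],
        [len(R) - k, universe_size - len(P) - len(R) + k],
    ]
    orat, p = stats.fisher_exact(table, alternative=alternative)
    return k, float(orat), float(p)


def ppi_partner_stats(
    edges: Iterable[tuple[str, str]],
    gene_classes: Mapping[str, str],
    cell_cycle_genes: Iterable[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Interaction-partner statistics per gene class.

    Builds an undirected simple graph from the edge list and reports, per
    class: mean number of partners, mean number of cell-cycle partners,
    and mean percentage of partners that are cell-cycle genes.  For every
    pair of classes, a chi-squared test on the aggregate 2x2 table
    (class x partner-is-cell-cycle) tests whether the classes differ in
    their share of cell-cycle partners.

    Returns ``(per_class_table, pairwise_pvalues_table)``.
    """
    classes = dict(gene_classes)
    if len(set(classes.values())) < 1:
        raise ValueError("no gene classes")
    cc = set(cell_cycle_genes)
    G = nx.Graph()
    G.add_edges_from((a, b) for a, b in edges if a != b)
    rows = []
    agg: dict[str, list[int]] = {}
    for cls in sorted(set(classes.values())):
        members = [g for g, c in classes.items() if c == cls]
        partners = [list(G.neighbors(g)) if g in G else [] for g in members]
        n_part = np.array([len(p) for p in partners], dtype=float)
        n_cc = np.array([sum(1 for x in p if x in cc) for p in partners], dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(n_part > 0, 100.0 * n_cc / n_part, np.nan)
        rows.append(
            {
                "gene_class": cls,
                "n_genes": len(members),
                "mean_partners": float(n_part.mean()) if len(members) else np.nan,
                "mean_cc_partners": float(n_cc.mean()) if len(members) else np.nan,
                "mean_pct_cc_partners": float(np.nanmean(pct)) if np.any(n_part > 0) else np.nan,
            }
        )
        agg[cls] = [int(n_cc.sum()), int(n_part.sum() - n_cc.sum())]
    per_class = pd.DataFrame(rows)
    pair_rows = []
    names = sorted(agg)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            table = np.array([agg[a], agg[b]])
            if table.sum() == 0 or np.any(table.sum(axis=1) == 0) or np.any(table.sum(axis=0) == 0):
                p = np.nan
            else:
                p = float(stats.chi2_contingency(table, correction=False).pvalue)
            pair_rows.append({"class_a": a, "class_b": b, "chi2_p": p})
    return per_class, pd.DataFrame(pair_rows)
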