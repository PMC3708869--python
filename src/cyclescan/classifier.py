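"""Random-Forest classification of cell-cycle versus non-cell-cycle genes.

Feature tables combine TF regulatory-score columns (one per ChIP-seq
dataset) and promoter motif-score columns (one per matrix).  Models are
evaluated by unstratified 10-fold cross-validation with out-of-fold
probabilities, ROC curves sampled at 100 trapezoidal partitions, Gini
(MDG) and out-of-fold permutation (%IncMSE) importance, iterative
most-important-feature ablation, reduced top-k models, phase-specific
training sets, and expression-matched negative sets for confounder
control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold, StratifiedKFold

DEFAULT_N_TREES = 500


@dataclass
class FeatureTable:
    """Genes x features matrix with binary labels (1 = cell cycle)."""

    gene_ids: list[str]
    X: np.ndarray
    feature_names: list[str]
    feature_kinds: list[str]  # 'tf' or 'motif', parallel to feature_names
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        n, p = self.X.shape
        if len(self.gene_ids) != n or len(self.y) != n:
            raise ValueError("row count mismatch")
        if len(self.feature_names) != p or len(self.feature_kinds) != p:
            raise ValueError("column count mismatch")
        if np.any(~np.isfinite(self.X)):
            raise ValueError("feature table contains non-finite values")
        if not set(self.feature_kinds) <= {"tf", "motif"}:
            raise ValueError("feature kinds must be 'tf' or 'motif'")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset_features(self, names: Sequence[str]) -> "FeatureTable":
        idx = [self.feature_names.index(f) for f in names]
        return FeatureTable(
            self.gene_ids,
            self.X[:, idx],
            [self.feature_names[i] for i in idx],
            [self.feature_kinds[i] for i in idx],
            self.y,
        )

    def subset_genes(self, genes: Sequence[str]) -> "FeatureTable":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        idx = [pos[g] for g in genes]
        return FeatureTable(
            [self.gene_ids[i] for i in idx],
            self.X[idx],
            self.feature_names,
            self.feature_kinds,
            self.y[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, index=self.gene_ids, columns=self.feature_names)
        df["label"] = self.y
        return df


def build_feature_table(
    tf_scores: Mapping[str, Mapping[str, float]] | None,
    motif_matrix: pd.DataFrame | None,
    labels: Mapping[str, int],
    feature_subset: str = "both",
) -> FeatureTable:
    """Assemble a FeatureTable from TF score sets and/or a motif score matrix.

    ``tf_scores`` maps dataset id -> {gene -> regulatory score};
    ``motif_matrix`` is the genes x motifs B matrix.  ``feature_subset``
    selects ``"tf"``, ``"motif"`` or ``"both"``.  A gene missing from a
    score set gets 0 in that column.  Column order is deterministic: TF
    columns then motif columns, lexicographic by id.
    """
    if feature_subset not in ("tf", "motif", "both"):
        raise ValueError("feature_subset must be 'tf', 'motif' or 'both'")
    genes = sorted(labels)
    if not genes:
        raise ValueError("no labelled genes")
    cols: list[np.ndarray] = []
    names: list[str] = []
    kinds: list[str] = []
    if feature_subset in ("tf", "both") and tf_scores:
        for ds in sorted(tf_scores):
            s = tf_scores[ds]
            cols.append(np.array([s.get(g, 0.0) for g in genes]))
            names.append(ds)
            kinds.append("tf")
    if feature_subset in ("motif", "both") and motif_matrix is not None:
        for motif in sorted(motif_matrix.columns):
            col = motif_matrix[motif]
            cols.append(np.array([float(col.get(g, 0.0)) for g in genes]))
            names.append(str(motif))
            kinds.append("motif")
    if not cols:
        raise ValueError("no features selected")
    X = np.column_stack(cols)
    y = np.array([labels[g] for g in genes])
    return FeatureTable(genes, X, names, kinds, y)


@dataclass
class CvResult:
    """Cross-validation outcome: out-of-fold probabilities, ROC and AUC.

    ``auc`` is the trapezoidal AUC over 100 threshold partitions (the
    headline metric); ``auc_exact`` the equivalent rank-statistic
    (Mann-Whitney) AUC, kept alongside for verification.
    """

    fold_assignments: np.ndarray
    probabilities: np.ndarray
    labels: np.ndarray
    roc: np.ndarray  # (n_points, 2) of (fpr, tpr)
    auc: float
    auc_exact: float
    fold_sensitivity: list[float] = field(default_factory=list)
    fold_specificity: list[float] = field(default_factory=list)


def _roc_points(scores: np.ndarray, labels: np.ndarray, n_partitions: int = 100) -> np.ndarray:
    """ROC sampled at score-quantile thresholds plus both endpoints.

    Quantile placement keeps the partitions informative regardless of the
    score scale; evenly spaced values would waste partitions whenever the
    scores cluster.
    """
    thresholds = np.unique(np.quantile(scores, np.linspace(0.0, 1.0, n_partitions + 1)))
    pos = labels == 1
    n1, n0 = pos.sum(), (~pos).sum()
    pts = [(1.0, 1.0)]
    for t in thresholds:
        called = scores >= t
        tpr = (called & pos).sum() / n1
        fpr = (called & ~pos).sum() / n0
        pts.append((fpr, tpr))
    pts.append((0.0, 0.0))
    pts = np.array(sorted(set(pts)))
    return pts


def roc_auc(scores, labels, n_partitions: int = 100) -> CvResult:
    """ROC curve and AUC of a score vector against binary labels.

    The curve is sampled at ``n_partitions`` trapezoidal threshold
    partitions; the AUC is the trapezoid-rule area.  The exact
    Mann-Whitney rank AUC is reported alongside as ``auc_exact``.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    pos, neg = scores[labels == 1], scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    roc = _roc_points(scores, labels, n_partitions)
    auc = float(np.trapezoid(roc[:, 1], roc[:, 0]))
    # exact rank AUC = U / (n1 * n0), ties counted half
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    auc_exact = float(u / (len(pos) * len(neg)))
    return CvResult(
        fold_assignments=np.zeros(len(scores), dtype=np.int64),
        probabilities=scores,
        labels=labels,
        roc=roc,
        auc=auc,
        auc_exact=auc_exact,
    )


def _forest(seed: int | None, n_trees: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    )


def train_model(
    table: FeatureTable, seed: int | None = 0, n_trees: int = DEFAULT_N_TREES
) -> RandomForestClassifier:
    """Fit a Random Forest on the full table (for genome-wide application)."""
    clf = _forest(seed, n_trees)
    clf.fit(table.X, table.y)
    return clf


def cross_validate(
    table: FeatureTable,
    k: int = 10,
    seed: int | None = 0,
    n_trees: int = DEFAULT_N_TREES,
    stratified: bool = False,
) -> CvResult:
    """k-fold cross-validation with out-of-fold probabilities.

    Folds are unstratified by default (genes are partitioned at random
    irrespective of label); each gene is scored exactly once out-of-fold
    by the fraction of trees voting positive, and the ROC/AUC is built
    from the pooled out-of-fold probabilities.
    """
    if table.n < k:
        raise ValueError("fewer genes than folds")
    splitter = (
        StratifiedKFold(k, shuffle=True, random_state=seed)
        if stratified
        else KFold(k, shuffle=True, random_state=seed)
    )
    prob = np.zeros(table.n)
    fold_of = np.zeros(table.n, dtype=np.int64)
    sens, spec = [], []
    split = splitter.split(table.X, table.y)
    for fold, (tr, te) in enumerate(split):
        if len(np.unique(table.y[tr])) < 2:
            warnings.warn(f"fold {fold}: training partition has a single class")
            prob[te] = float(table.y[tr][0])
            fold_of[te] = fold
            continue
        clf = _forest(None if seed is None else seed + fold, n_trees)
        clf.fit(table.X[tr], table.y[tr])
        pos_col = list(clf.classes_).index(1)
        prob[te] = clf.predict_proba(table.X[te])[:, pos_col]
        fold_of[te] = fold
        called = prob[te] >= 0.5
        yt = table.y[te]
        if (yt == 1).any():
            sens.append(float((called & (yt == 1)).sum() / (yt == 1).sum()))
        if (yt == 0).any():
            spec.append(float((~called & (yt == 0)).sum() / (yt == 0).sum()))
    frag = roc_auc(prob, table.y)
    return CvResult(
        fold_assignments=fold_of,
        probabilities=prob,
        labels=table.y,
        roc=frag.roc,
        auc=frag.auc,
        auc_exact=frag.auc_exact,
        fold_sensitivity=sens,
        fold_specificity=spec,
    )


@dataclass
class ImportanceRanking:
    """Per-feature importance: Gini (MDG) and permutation (%IncMSE)."""

    feature_names: list[str]
    mdg: np.ndarray
    pct_inc_mse: np.ndarray

    def normalized(self, metric: str = "mdg") -> np.ndarray:
        v = self.mdg if metric == "mdg" else self.pct_inc_mse
        top = v.max()
        return v / top if top > 0 else np.zeros_like(v)

    def ranked(self, metric: str = "mdg") -> list[str]:
        """Feature names from most to least important; ties broken lexicographically."""
        v = self.mdg if metric == "mdg" else self.pct_inc_mse
        order = sorted(range(len(v)), key=lambda i: (-v[i], self.feature_names[i]))
        return [self.feature_names[i] for i in order]


def importance(
    table: FeatureTable,
    seed: int | None = 0,
    n_trees: int = DEFAULT_N_TREES,
    n_permutations: int = 10,
    k: int = 5,
) -> ImportanceRanking:
    """Gini (MDG) and out-of-fold permutation (%IncMSE) importance.

    MDG comes from a forest fit on the full table.  %IncMSE is estimated
    out-of-fold: for each CV fold, each feature of the held-out partition
    is permuted ``n_permutations`` times and the relative increase in mean
    squared error of the predicted probability (in percent) is averaged.
    """
    clf = _forest(seed, n_trees)
    clf.fit(table.X, table.y)
    mdg = clf.feature_importances_.copy()

    rng = np.random.default_rng(seed)
    inc = np.zeros(table.p)
    splitter = KFold(k, shuffle=True, random_state=seed)
    for fold, (tr, te) in enumerate(splitter.split(table.X)):
        if len(np.unique(table.y[tr])) < 2:
            continue
        fclf = _forest(None if seed is None else seed + 1000 + fold, n_trees)
        fclf.fit(table.X[tr], table.y[tr])
        pos_col = list(fclf.classes_).index(1)
        Xte, yte = table.X[te], table.y[te]
        base = fclf.predict_proba(Xte)[:, pos_col]
        base_mse = np.mean((base - yte) ** 2)
        for j in range(table.p):
            mses = []
            for _ in range(n_permutations):
                Xp = Xte.copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                pp = fclf.predict_proba(Xp)[:, pos_col]
                mses.append(np.mean((pp - yte) ** 2))
            if base_mse > 0:
                inc[j] += 100.0 * (np.mean(mses) - base_mse) / base_mse
            else:
                inc[j] += 100.0 * np.mean(mses)
    inc /= k
    return ImportanceRanking(list(table.feature_names), mdg, inc)


def ablate_features(
    table: FeatureTable,
    seed: int | None = 0,
    n_trees: int = DEFAULT_N_TREES,
    k: int = 10,
    metric: str = "mdg",
) -> list[tuple[str | None, float]]:
    """Iteratively remove the most important feature and re-evaluate.

    At each step the current table's importance is re-estimated, the most
    important feature (ties broken lexicographically) is dropped, and the
    cross-validated AUC of the remaining features is recorded.  The first
    entry is ``(None, full-model AUC)``; the loop stops when one feature
    remains.
    """
    current = table
    curve: list[tuple[str | None, float]] = [
        (None, cross_validate(current, k=k, seed=seed, n_trees=n_trees).auc)
    ]
    step = 0
    while current.p > 1:
        step += 1
        rank = _mdg_only(current, seed=None if seed is None else seed + step, n_trees=n_trees)
        worst = rank.ranked(metric="mdg")[0]
        keep = [f for f in current.feature_names if f != worst]
        current = current.subset_features(keep)
        auc = cross_validate(
            current, k=k, seed=None if seed is None else seed + step, n_trees=n_trees
        ).auc
        curve.append((worst, auc))
    return curve


def _mdg_only(table: FeatureTable, seed, n_trees) -> ImportanceRanking:
    clf = _forest(seed, n_trees)
    clf.fit(table.X, table.y)
    return ImportanceRanking(list(table.feature_names), clf.feature_importances_.copy(), np.zeros(table.p))


def topk_model(
    table: FeatureTable,
    k_tf: int = 10,
    k_motif: int = 10,
    seed: int | None = 0,
    n_trees: int = DEFAULT_N_TREES,
    k_folds: int = 10,
    metric: str = "mdg",
) -> tuple[CvResult, list[str]]:
    """Reduced model on the top-k TF and top-k motif features.

    Features are chosen by their importance in the full model, then the
    cross-validation is rerun on the reduced table.  Returns the CV result
    and the selected feature names.
    """
    rank = _mdg_only(table, seed, n_trees) if metric == "mdg" else importance(table, seed, n_trees)
    ordered = rank.ranked(metric=metric)
    kind_of = dict(zip(table.feature_names, table.feature_kinds))
    top_tf = [f for f in ordered if kind_of[f] == "tf"][:k_tf]
    top_motif = [f for f in ordered if kind_of[f] == "motif"][:k_motif]
    selected = [f for f in table.feature_names if f in set(top_tf + top_motif)]
    if not selected:
        raise ValueError("no features selected (both k values 0?)")
    reduced = table.subset_features(selected)
    return cross_validate(reduced, k=k_folds, seed=seed, n_trees=n_trees), selected


@dataclass
class PhaseBinSpec:
    """Peak-time selection ranges (0-100 scale) for phase-specific models.

    The default ranges deliberately overlap, so one gene can enter several
    phase training sets.
    """

    ranges: dict[str, list[tuple[float, float]]] = field(
        default_factory=lambda: {
            "M/G1": [(95.0, 100.0), (0.0, 20.0)],
            "G2/M": [(80.0, 95.0)],
            "G2": [(70.0, 90.0)],
            "S": [(47.0, 70.0)],
            "G1/S": [(20.0, 60.0)],
        }
    )

    def phases_of(self, peak_time: float) -> list[str]:
        return [
            phase
            for phase, spans in self.ranges.items()
            if any(lo <= peak_time < hi for lo, hi in spans)
        ]


def phase_training_sets(
    table: FeatureTable,
    peak_times: Mapping[str, float],
    bins: PhaseBinSpec | None = None,
) -> dict[str, FeatureTable]:
    """Split the positives into phase-specific training sets.

    Each phase table holds the positives whose peak time falls in that
    phase's range(s) versus *all* negatives; because ranges overlap, one
    gene may appear in several phase tables.
    """
    bins = bins or PhaseBinSpec()
    negatives = [g for g, y in zip(table.gene_ids, table.y) if y == 0]
    out: dict[str, FeatureTable] = {}
    for phase in bins.ranges:
        pos = [
            g
            for g, y in zip(table.gene_ids, table.y)
            if y == 1 and g in peak_times and phase in bins.phases_of(peak_times[g])
        ]
        out[phase] = table.subset_genes(pos + negatives)
    return out


def match_expression_negatives(
    positive_expression: Mapping[str, float],
    negative_expression: Mapping[str, float],
    n_bins: int = 10,
    seed: int | None = 0,
) -> list[str]:
    """Sample a negative gene set whose expression matches the positives.

    The positive expression distribution is cut into ``n_bins`` quantile
    bins; for each bin, as many negatives falling in that expression range
    are sampled (without replacement) as there are positives in the bin.
    A bin with too few available negatives is filled best-effort from the
    nearest adjacent bins, with a warning.
    """
    rng = np.random.default_rng(seed)
    pos = np.array(list(positive_expression.values()))
    neg_genes = np.array(list(negative_expression.keys()))
    neg = np.array([negative_expression[g] for g in neg_genes])
    edges = np.quantile(pos, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    pos_bin = np.clip(np.searchsorted(edges, pos, side="right") - 1, 0, n_bins - 1)
    need = np.bincount(pos_bin, minlength=n_bins)
    neg_bin = np.clip(np.searchsorted(edges, neg, side="right") - 1, 0, n_bins - 1)
    selected: list[str] = []
    available = {b: list(rng.permutation(np.flatnonzero(neg_bin == b))) for b in range(n_bins)}
    for b in range(n_bins):
        want = int(need[b])
        got = available[b][:want]
        available[b] = available[b][len(got) :]
        shortfall = want - len(got)
        if shortfall > 0:
            warnings.warn(f"expression bin {b}: only {len(got)}/{want} negatives available")
            for dist in range(1, n_bins):
                for nb in (b - dist, b + dist):
                    if shortfall == 0 or not (0 <= nb < n_bins):
                        continue
                    take = available[nb][:shortfall]
                    available[nb] = available[nb][len(take) :]
                    got = list(got) + list(take)
                    shortfall -= len(take)
                if shortfall == 0:
                    break
        selected.extend(neg_genes[i] for i in got)
    return selected
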