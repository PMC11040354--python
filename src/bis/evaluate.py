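"""Evaluation metrics for imputation quality and clustering agreement.

All partition and silhouette metrics are implemented here directly from
their defining formulas (contingency counts, pair counting, per-cell
silhouette widths) rather than delegated, so each one can be checked against
independent brute-force enumerations and against scikit-learn in the tests.

Conventions for degenerate cases: 0*log 0 = 0 throughout; a correlation of a
constant vector is an error (it is undefined, not zero); NMI of two
partitions with zero entropy is 1 if they are identical and 0 otherwise;
singleton clusters contribute a silhouette width of 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .data_io import ExpressionMatrix

__all__ = [
    "ContingencyTable",
    "ConfusionCounts",
    "SilhouetteContext",
    "pearson",
    "pcc_panels",
    "nmi",
    "ari",
    "jaccard_index",
    "silhouette_samples",
    "cell_type_asw",
    "batch_asw",
    "confusion_metrics",
    "auc_score",
    "pca_embed",
    "kmeans_labels",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class ContingencyTable:
    """K x J cross-tabulation of two labelings of the same n items."""

    counts: np.ndarray

    @classmethod
    def from_labels(cls, labels_a, labels_b) -> "ContingencyTable":
        a = np.asarray(labels_a)
        b = np.asarray(labels_b)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("label vectors must be 1-D and of equal length")
        _, ai = np.unique(a, return_inverse=True)
        _, bi = np.unique(b, return_inverse=True)
        counts = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
        np.add.at(counts, (ai, bi), 1)
        return cls(counts)

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be nonnegative")


@dataclass
class SilhouetteContext:
    """Embedding plus the label vectors silhouette metrics are computed on."""

    embedding: np.ndarray
    cell_labels: np.ndarray
    batch_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.embedding = np.asarray(self.embedding, dtype=float)
        self.cell_labels = np.asarray(self.cell_labels)
        n = self.embedding.shape[0]
        if self.cell_labels.shape != (n,):
            raise ValueError("cell_labels length must match embedding rows")
        if self.batch_labels is not None:
            self.batch_labels = np.asarray(self.batch_labels)
            if self.batch_labels.shape != (n,):
                raise ValueError("batch_labels length must match embedding rows")


# ---------------------------------------------------------------------------
# correlation


def pearson(x, y) -> float:
    """Pearson correlation sum((x-xbar)(y-ybar)) / sqrt(ss_x * ss_y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("pearson requires two equal-length vectors of size >= 2")
    dx = x - x.mean()
    dy = y - y.mean()
    ssx = float(dx @ dx)
    ssy = float(dy @ dy)
    if ssx == 0.0 or ssy == 0.0:
        raise ValueError("correlation undefined for a constant vector")
    return float(dx @ dy / np.sqrt(ssx * ssy))


def _rowwise_pcc(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Correlation of each row of a with the matching row of b; NaN where constant."""
    da = a - a.mean(axis=1, keepdims=True)
    db = b - b.mean(axis=1, keepdims=True)
    ssa = np.sum(da * da, axis=1)
    ssb = np.sum(db * db, axis=1)
    denom = np.sqrt(ssa * ssb)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.sum(da * db, axis=1) / denom
    r[denom == 0] = np.nan
    return r


def pcc_panels(
    reference: ExpressionMatrix, test: ExpressionMatrix
) -> tuple[np.ndarray, np.ndarray, dict[str, float]]:
    """Gene-wise (across cells) and cell-wise (across genes) correlations.

    Rows of ``test`` are realigned to ``reference`` by identifier before
    comparison.  Genes or cells that are constant in either matrix yield
    NaN and are excluded from the reported means.
    """
    if set(test.row_ids) != set(reference.row_ids) or list(test.col_ids) != list(reference.col_ids):
        raise ValueError("matrices must share identical cell and gene identifier sets")
    if test.row_ids != reference.row_ids:
        pos = {r: i for i, r in enumerate(test.row_ids)}
        test = test.subset(rows=np.array([pos[r] for r in reference.row_ids]))
    ref, tst = reference.values, test.values
    gene_pcc = _rowwise_pcc(ref.T, tst.T)
    cell_pcc = _rowwise_pcc(ref, tst)
    means = {
        "gene_wise_mean": float(np.nanmean(gene_pcc)),
        "cell_wise_mean": float(np.nanmean(cell_pcc)),
    }
    return gene_pcc, cell_pcc, means


# ---------------------------------------------------------------------------
# partition agreement


def _entropy(counts: np.ndarray, n: int) -> float:
    p = counts[counts > 0] / n
    return float(-(p * np.log(p)).sum())


def nmi(labels_a, labels_b) -> float:
    """Mutual information normalized by the mean of the two entropies.

    MI and entropies use natural logarithms; returns 1 for identical
    partitions and 0 when the labelings are independent or one side carries
    no information (0/0 is defined as 0, or 1 when both partitions are
    identical single-cluster labelings).
    """
    ct = ContingencyTable.from_labels(labels_a, labels_b)
    n = ct.n
    nij = ct.counts
    ai = ct.row_totals
    bj = ct.col_totals
    nz = nij > 0
    outer = np.outer(ai, bj)
    mi = float(np.sum(nij[nz] / n * np.log(n * nij[nz] / outer[nz])))
    ha = _entropy(ai, n)
    hb = _entropy(bj, n)
    denom = (ha + hb) / 2.0
    if denom == 0.0:
        # both partitions are single clusters: identical by construction
        return 1.0
    if mi <= 0.0:
        return 0.0
    return min(mi / denom, 1.0)


def _comb2(x: np.ndarray | int):
    x = np.asarray(x, dtype=float)
    return x * (x - 1) / 2.0


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index from the contingency table.

    (sum_ij C(n_ij,2) - E) / (max - E) with E = sum_i C(a_i,2) *
    sum_j C(b_j,2) / C(N,2) and max = (sum_i C(a_i,2) + sum_j C(b_j,2)) / 2.
    1 for a perfect match, ~0 under random labeling.
    """
    ct = ContingencyTable.from_labels(labels_a, labels_b)
    if ct.n < 2:
        raise ValueError("ari requires at least two items")
    sum_ij = _comb2(ct.counts).sum()
    sum_a = _comb2(ct.row_totals).sum()
    sum_b = _comb2(ct.col_totals).sum()
    total = _comb2(ct.n)
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        # both partitions all-singletons or all-one-cluster: define as 1
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def jaccard_index(labels_a, labels_b) -> float:
    """Pair-counting Jaccard index S11 / (S11 + S10 + S01).

    S11 counts item pairs co-clustered in both partitions, S10/S01 pairs
    co-clustered in exactly one.  Defined as 0 when no pair is co-clustered
    in either partition.
    """
    ct = ContingencyTable.from_labels(labels_a, labels_b)
    if ct.n < 2:
        raise ValueError("jaccard_index requires at least two items")
    s11 = _comb2(ct.counts).sum()
    pairs_a = _comb2(ct.row_totals).sum()
    pairs_b = _comb2(ct.col_totals).sum()
    denom = pairs_a + pairs_b - s11  # S11 + S10 + S01
    if denom == 0:
        return 0.0
    return float(s11 / denom)


# ---------------------------------------------------------------------------
# silhouettes


def silhouette_samples(embedding: np.ndarray, labels) -> np.ndarray:
    """Per-point silhouette widths s(i) with Euclidean distance.

    s(i) = (b(i) - a(i)) / max(a(i), b(i)) with a(i) the mean distance to
    the other members of i's cluster and b(i) the smallest mean distance to
    any other cluster.  Points in singleton clusters get s(i) = 0.
    """
    x = np.asarray(embedding, dtype=float)
    labels = np.asarray(labels)
    classes, idx = np.unique(labels, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("silhouette requires at least two label classes")
    n = x.shape[0]
    d = cdist(x, x)
    sizes = np.bincount(idx, minlength=len(classes))
    # mean distance from each point to each cluster
    sums = np.zeros((n, len(classes)))
    for c in range(len(classes)):
        sums[:, c] = d[:, idx == c].sum(axis=1)
    own = idx
    s = np.zeros(n)
    for i in range(n):
        c = own[i]
        if sizes[c] == 1:
            s[i] = 0.0
            continue
        a = sums[i, c] / (sizes[c] - 1)
        other = [sums[i, j] / sizes[j] for j in range(len(classes)) if j != c]
        b = min(other)
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return s


def cell_type_asw(ctx: SilhouetteContext) -> float:
    """Mean silhouette on cell labels, rescaled to [0, 1] via (ASW + 1) / 2."""
    s = silhouette_samples(ctx.embedding, ctx.cell_labels)
    return float((s.mean() + 1.0) / 2.0)


def batch_asw(ctx: SilhouetteContext) -> float:
    """Batch-mixing score: mean over cell labels of mean(1 - |s_batch(i)|).

    Within each cell-label group the silhouette is computed on batch labels
    restricted to that group; |s| near 0 (batches interleaved) scores near
    1.  A group containing a single batch is perfectly mixed by convention
    and contributes 1.
    """
    if ctx.batch_labels is None:
        raise ValueError("batch_asw requires batch_labels")
    scores = []
    for lab in np.unique(ctx.cell_labels):
        sel = ctx.cell_labels == lab
        batches = ctx.batch_labels[sel]
        if len(np.unique(batches)) < 2:
            scores.append(1.0)
            continue
        s = silhouette_samples(ctx.embedding[sel], batches)
        scores.append(float(np.mean(1.0 - np.abs(s))))
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# classification metrics


def confusion_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, recall and F1 from confusion counts.

    Ratios with zero denominators are reported as 0.
    """
    total = c.TP + c.FP + c.FN + c.TN
    if total == 0:
        raise ValueError("confusion counts sum to zero")
    acc = (c.TP + c.TN) / total
    precision = c.TP / (c.TP + c.FP) if c.TP + c.FP > 0 else 0.0
    recall = c.TP / (c.TP + c.FN) if c.TP + c.FN > 0 else 0.0
    f1 = 2 * c.TP / (2 * c.TP + c.FP + c.FN) if 2 * c.TP + c.FP + c.FN > 0 else 0.0
    return {"accuracy": acc, "precision": precision, "recall": recall, "f1": f1}


def auc_score(scores, truth) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve; ties count 1/2."""
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth).astype(int)
    if s.shape != t.shape or s.ndim != 1:
        raise ValueError("scores and truth must be equal-length vectors")
    n_pos = int(t.sum())
    n_neg = int(t.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auc_score requires both classes present")
    from scipy.stats import rankdata

    ranks = rankdata(s)  # average ranks handle ties
    rank_sum_pos = float(ranks[t == 1].sum())
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# plumbing helpers (not part of the metric definitions)


def pca_embed(m: ExpressionMatrix | np.ndarray, n_components: int = 50, seed: int = 0) -> np.ndarray:
    """Principal-component embedding used as the silhouette/clustering space."""
    from sklearn.decomposition import PCA

    x = m.values if isinstance(m, ExpressionMatrix) else np.asarray(m, dtype=float)
    k = min(n_components, min(x.shape) - 1)
    return PCA(n_components=k, random_state=seed).fit_transform(x)


def kmeans_labels(embedding: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Fixed-seed k-means labels on an embedding (evaluation plumbing)."""
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    return km.fit_predict(np.asarray(embedding, dtype=float))
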