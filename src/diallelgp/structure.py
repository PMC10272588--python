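"""Population structure and between-platform concordance statistics.

Covers Rogers genetic distances, principal-coordinate analysis of those
distances (with a genotype-matrix PCA alternative), K-means clustering with
the within-cluster-sum-of-squares elbow rule, Kendall coincidence between
cluster partitions from different marker platforms, Mantel permutation tests
between distance matrices, and eigenvector-by-eigenvector R-squared grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kendalltau
from sklearn.cluster import KMeans

from .genotypes import GenotypeMatrix

__all__ = [
    "DistanceMatrix",
    "PCAResult",
    "ClusterResult",
    "MantelResult",
    "rogers_distance",
    "pcoa",
    "pca_genotypes",
    "kmeans_partition",
    "kendall_coincidence",
    "mantel_test",
    "eigenvector_r2",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with a zero diagonal."""

    ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-10):
            raise ValueError("distance matrix diagonal is not zero")

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="id")

    @classmethod
    def read(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(ids=df.index.to_numpy(dtype=object), values=df.to_numpy(float))


@dataclass
class PCAResult:
    """Ordination coordinates: eigenvectors scaled by sqrt(eigenvalue)."""

    ids: np.ndarray
    coordinates: np.ndarray  # n x k
    eigenvalues: np.ndarray  # non-increasing, clipped at zero
    explained: np.ndarray  # fractions of (non-negative) total

    def __post_init__(self) -> None:
        if np.any(np.diff(self.eigenvalues) > 1e-8):
            raise ValueError("eigenvalues must be non-increasing")
        if self.explained.sum() > 1 + 1e-8:
            raise ValueError("explained fractions exceed 1")


@dataclass
class ClusterResult:
    labels: np.ndarray  # values in 1..k
    k: int
    wss: dict  # candidate k -> within-cluster sum of squares
    k_range: tuple
    seed: int | None = None


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int


def rogers_distance(G: GenotypeMatrix) -> DistanceMatrix:
    """Rogers genetic distance between all line pairs.

    Per locus the distance is ``sqrt(0.5 * sum_alleles (p_i - p_j)^2)`` with
    within-line allele frequency = dosage/2; averaged over loci. For
    biallelic dosages this reduces exactly to ``|g_i - g_j| / 2`` per locus,
    so the full matrix is a scaled Manhattan distance, bounded in [0, 1].
    """
    if G.n_markers == 0:
        raise ValueError("no markers")
    if np.isnan(G.dosages).any():
        raise ValueError("missing dosages; impute first")
    d = pdist(G.dosages, metric="cityblock") / (2.0 * G.n_markers)
    return DistanceMatrix(ids=G.line_ids, values=squareform(d))


def pcoa(D: DistanceMatrix, k: int) -> PCAResult:
    """Classical metric scaling (principal coordinates) of a distance matrix.

    Negative eigenvalues of the double-centered matrix are truncated to zero
    before normalizing explained-variance fractions.
    """
    if k > D.n:
        raise ValueError(f"k={k} exceeds {D.n} samples")
    import warnings

    import skbio

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # full-decomposition note
        res = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(D.values, ids=[str(i) for i in D.ids]),
            method="eigh",
            warn_neg_eigval=False,
        )
    eig = np.clip(res.eigvals.to_numpy(), 0.0, None)
    total = eig.sum()
    return PCAResult(
        ids=D.ids,
        coordinates=res.samples.to_numpy()[:, :k],
        eigenvalues=eig[:k],
        explained=(eig[:k] / total) if total > 0 else np.zeros(k),
    )


def pca_genotypes(G: GenotypeMatrix, k: int) -> PCAResult:
    """PCA directly on the centered dosage matrix (alternative to the
    distance-based ordination, which is the pipeline default)."""
    if k > min(G.n_lines, G.n_markers):
        raise ValueError("k exceeds matrix rank bound")
    X = G.dosages - G.dosages.mean(axis=0)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    eig = (s**2) / (G.n_lines - 1)
    total = eig.sum()
    return PCAResult(
        ids=G.line_ids,
        coordinates=U[:, :k] * s[:k],
        eigenvalues=eig[:k],
        explained=eig[:k] / total if total > 0 else np.zeros(k),
    )


def kmeans_partition(
    X: np.ndarray,
    k_range,
    seed: int | None = None,
    n_init: int = 100,
    chosen_k: int | None = None,
) -> ClusterResult:
    """Lloyd K-means over a range of k with the WSS elbow rule.

    For each candidate k, k-means++ with ``n_init`` restarts keeps the
    best-WSS solution. The elbow is the k maximizing the second difference
    of the WSS curve; ``chosen_k`` overrides it. Labels are 1..k.
    """
    X = np.asarray(X, dtype=float)
    k_range = sorted(int(k) for k in k_range)
    if X.shape[0] < max(k_range):
        raise ValueError("fewer rows than the largest candidate k")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate input: all rows identical")
    wss: dict[int, float] = {}
    fits: dict[int, np.ndarray] = {}
    for k in k_range:
        km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
        labels = km.fit_predict(X)
        wss[k] = float(km.inertia_)
        fits[k] = labels + 1
    if chosen_k is None:
        chosen_k = _elbow(k_range, wss)
    elif chosen_k not in wss:
        km = KMeans(n_clusters=chosen_k, init="k-means++", n_init=n_init, random_state=seed)
        fits[chosen_k] = km.fit_predict(X) + 1
        wss[chosen_k] = float(km.inertia_)
    return ClusterResult(labels=fits[chosen_k], k=chosen_k, wss=wss, k_range=tuple(k_range), seed=seed)


def _elbow(k_range: list[int], wss: dict[int, float]) -> int:
    if len(k_range) == 1:
        return k_range[0]
    if len(k_range) == 2:
        return k_range[0]  # no curvature information: parsimony
    curve = np.array([wss[k] for k in k_range])
    second = curve[:-2] - 2 * curve[1:-1] + curve[2:]
    return k_range[1 + int(np.argmax(second))]


def _align_labels(ref: np.ndarray, other: np.ndarray) -> np.ndarray:
    """Relabel ``other`` to maximize agreement with ``ref`` via optimal
    assignment on the contingency table; unmatched labels keep distinct codes."""
    ref_codes, other_codes = pd.factorize(ref)[0], pd.factorize(other)[0]
    table = pd.crosstab(other_codes, ref_codes).to_numpy()
    rows, cols = linear_sum_assignment(-table)
    mapping = dict(zip(rows, cols))
    next_code = table.shape[1]
    out = np.empty(len(other), dtype=int)
    for code in range(table.shape[0]):
        if code not in mapping:
            mapping[code] = next_code
            next_code += 1
    for i, c in enumerate(other_codes):
        out[i] = mapping[c]
    return out


def kendall_coincidence(labels_a, labels_b, alpha: float = 0.01):
    """Kendall tau agreement between two cluster partitions of the same lines.

    Partition b is first relabeled to best match a (optimal assignment), so
    the statistic is invariant to arbitrary label names; tau and its
    large-sample p-value are then computed on the aligned label vectors.
    Returns ``(tau, p, significant_at_alpha)``.
    """
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if len(labels_a) != len(labels_b):
        raise ValueError("partitions cover different numbers of lines")
    a = pd.factorize(labels_a)[0]
    b = _align_labels(labels_a, labels_b)
    tau, p = kendalltau(a, b)
    return float(tau), float(p), bool(p < alpha)


def mantel_test(
    D1: DistanceMatrix, D2: DistanceMatrix, n_perm: int = 1000, seed: int | None = None
) -> MantelResult:
    """One-sided Mantel permutation test between two distance matrices.

    r is the Pearson correlation over off-diagonal entries; the p-value is
    the add-one permutation estimator ``(1 + #{r_perm >= r_obs}) / (n_perm
    + 1)`` under joint row/column permutation of one matrix.
    """
    if not np.array_equal(D1.ids, D2.ids):
        raise ValueError("distance matrices must share ids in the same order")
    for D in (D1, D2):
        if np.std(D.condensed()) == 0:
            raise ValueError("constant distance matrix: correlation undefined")
    import skbio

    r, p, _ = skbio.stats.distance.mantel(
        skbio.DistanceMatrix(D1.values, ids=[str(i) for i in D1.ids]),
        skbio.DistanceMatrix(D2.values, ids=[str(i) for i in D2.ids]),
        method="pearson",
        permutations=n_perm,
        alternative="greater",
        seed=seed,
    )
    return MantelResult(r=float(r), p=float(p), n_perm=n_perm)


def eigenvector_r2(P1: PCAResult, P2: PCAResult, n: int = 10) -> np.ndarray:
    """n x n grid of squared Pearson correlations between the leading
    eigenvectors of two ordinations of the same lines."""
    if not np.array_equal(P1.ids, P2.ids):
        raise ValueError("ordinations cover different line sets")
    if P1.coordinates.shape[1] < n or P2.coordinates.shape[1] < n:
        raise ValueError(f"need at least {n} eigenvectors in each ordination")
    A = P1.coordinates[:, :n]
    B = P2.coordinates[:, :n]
    Az = (A - A.mean(0)) / A.std(0)
    Bz = (B - B.mean(0)) / B.std(0)
    R = Az.T @ Bz / A.shape[0]
    return R**2
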