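"""Functional supertype clustering of PSS-reduced allele sequences.

Alleles are reduced to their residues at positively selected sites, encoded
with the five physicochemical z-descriptors per residue (lipophilicity,
steric bulk/polarisability, polarity, and two electronic-property scales),
and clustered: K-means over principal components with a BIC-based "goodfit"
choice of K, a discriminant-analysis (DAPC-style) assignment step whose
retained PC count is picked by cross-validation, and a consensus over
repeated seeded runs (5 batches x 10 seeds by default).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.preprocessing import StandardScaler

__all__ = [
    "Z_DESCRIPTORS",
    "encode_z",
    "cluster_once",
    "consensus_supertypes",
    "consensus_from_labels",
    "ClusterRun",
    "SupertypeAssignment",
]

#: Five z-scale descriptors per standard residue (Sandberg et al. 1998).
Z_DESCRIPTORS: dict[str, tuple[float, float, float, float, float]] = {
    "A": (0.24, -2.32, 0.60, -0.14, 1.30),
    "R": (3.52, 2.50, -3.50, 1.99, -0.17),
    "N": (3.05, 1.62, 1.04, -1.15, 1.61),
    "D": (3.98, 0.93, 1.93, -2.46, 0.75),
    "C": (0.84, -1.67, 3.71, 0.18, -2.65),
    "Q": (1.75, 0.50, -1.44, -1.34, 0.66),
    "E": (3.11, 0.26, -0.11, -3.04, -0.25),
    "G": (2.05, -4.06, 0.36, -0.82, -0.38),
    "H": (2.47, 1.95, 0.26, 3.90, 0.09),
    "I": (-3.89, -1.73, -1.71, -0.84, 0.26),
    "L": (-4.28, -1.30, -1.49, -0.72, 0.84),
    "K": (2.29, 0.89, -2.49, 1.49, 0.31),
    "M": (-2.85, -0.22, 0.47, 1.94, -0.98),
    "F": (-4.22, 1.94, 1.06, 0.54, -0.62),
    "P": (-1.66, 0.27, 1.84, 0.70, 2.00),
    "S": (2.39, -1.07, 1.15, -1.39, 0.67),
    "T": (0.75, -2.18, -1.12, -1.46, -0.40),
    "W": (-4.36, 3.94, 0.59, 3.44, -1.59),
    "Y": (-2.54, 2.44, 0.43, 0.04, -1.47),
    "V": (-2.59, -2.64, -1.54, -0.85, -0.02),
}


def encode_z(
    sequences: Sequence[str],
    table: Mapping[str, Sequence[float]] = Z_DESCRIPTORS,
    gap_policy: str = "mean",
) -> np.ndarray:
    """Encode equal-length amino-acid strings as a (n x 5L) descriptor matrix.

    Gap residues ('-', from the in-frame deletion allele) are imputed with
    the column mean over non-gap rows (``gap_policy='mean'``) or rejected
    (``gap_policy='error'``).
    """
    sequences = list(sequences)
    if not sequences:
        raise ValueError("no sequences to encode")
    L = len(sequences[0])
    if any(len(s) != L for s in sequences):
        raise ValueError("sequences must have equal length")
    n_desc = len(next(iter(table.values())))
    X = np.full((len(sequences), n_desc * L), np.nan)
    for i, s in enumerate(sequences):
        for j, aa in enumerate(s):
            if aa in table:
                X[i, n_desc * j : n_desc * (j + 1)] = table[aa]
            elif aa == "-" and gap_policy == "mean":
                continue  # imputed below
            else:
                raise ValueError(f"unknown residue {aa!r} in sequence {i} position {j + 1}")
    if np.isnan(X).any():
        warnings.warn("gap residues imputed with column means")
        col_mean = np.nanmean(X, axis=0)
        idx = np.nonzero(np.isnan(X))
        X[idx] = col_mean[idx[1]]
    return X


@dataclass
class ClusterRun:
    seed: int
    k: int
    bic_curve: dict[int, float]
    labels: np.ndarray
    n_pcs_kmeans: int
    n_pcs_lda: int
    xval_score: float


def _kmeans_bic(X: np.ndarray, labels: np.ndarray, k: int) -> float:
    """BIC of a K-means partition: n*d*ln(WSS/(n*d)) + K*d*ln(n).

    WSS is the total within-cluster sum of squares; each of the K centroids
    contributes d free parameters.  Lower is better.
    """
    n, d = X.shape
    wss = 0.0
    for lab in np.unique(labels):
        sub = X[labels == lab]
        wss += ((sub - sub.mean(axis=0)) ** 2).sum()
    wss = max(wss, 1e-12)
    return n * d * np.log(wss / (n * d)) + k * d * np.log(n)


def _goodfit_k(bic: dict[int, float], threshold: float = 0.9) -> int:
    """Smallest K reaching >= ``threshold`` of the max BIC improvement over K=1."""
    base = bic[1]
    improvements = {k: base - v for k, v in bic.items()}
    best = max(improvements.values())
    if best <= 0:
        return 1
    for k in sorted(improvements):
        if improvements[k] >= threshold * best:
            return k
    return max(bic)


def cluster_once(
    X: np.ndarray,
    k_range: Iterable[int] = range(2, 21),
    seed: int = 0,
    goodfit_threshold: float = 0.9,
    n_xval_splits: int = 10,
) -> ClusterRun:
    """One seeded clustering: scale -> PCA -> K-means/BIC -> DAPC assignment.

    K is chosen by the "goodfit" elbow rule on the K-means BIC curve
    (including K=1); the discriminant step is trained on the K-means labels
    with its retained-PC count selected by held-out assignment success over
    90/10 stratified splits.  Returned labels are the discriminant
    assignments (1-based).
    """
    n = X.shape[0]
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range or min(k_range) < 2:
        raise ValueError("k_range must contain integers >= 2")
    k_range = [k for k in k_range if k <= n]
    if not k_range:
        raise ValueError("k_range exceeds the number of sequences")
    scaler = StandardScaler()
    keep = X.std(axis=0) > 1e-12
    if not keep.any():
        # all rows identical: a single trivial cluster
        return ClusterRun(seed=seed, k=1, bic_curve={1: 0.0},
                          labels=np.ones(n, dtype=int), n_pcs_kmeans=0,
                          n_pcs_lda=0, xval_score=1.0)
    Xs = scaler.fit_transform(X[:, keep])
    pca = PCA(n_components=min(n - 1, Xs.shape[1]), random_state=seed)
    P = pca.fit_transform(Xs)
    # retain PCs carrying >99.9% of variance for the K-means step
    ev = pca.explained_variance_ratio_.cumsum()
    n_pcs_km = int(np.searchsorted(ev, 0.999) + 1)
    Pk = P[:, :n_pcs_km]

    bic: dict[int, float] = {1: _kmeans_bic(Pk, np.zeros(n, dtype=int), 1)}
    label_store: dict[int, np.ndarray] = {}
    rng = np.random.default_rng(seed)
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=10, random_state=int(rng.integers(2**31)))
        labels = km.fit_predict(Pk)
        bic[k] = _kmeans_bic(Pk, labels, k)
        label_store[k] = labels
    k_best = _goodfit_k(bic, goodfit_threshold)
    if k_best == 1:
        return ClusterRun(seed=seed, k=1, bic_curve=bic,
                          labels=np.ones(n, dtype=int),
                          n_pcs_kmeans=n_pcs_km, n_pcs_lda=0, xval_score=1.0)
    km_labels = label_store[k_best]

    # DAPC step: pick the PC count by cross-validated assignment success
    counts = Counter(km_labels)
    max_pcs = max(1, min(P.shape[1], n - k_best))
    candidates = sorted({max(1, max_pcs // 4), max(1, max_pcs // 2),
                         max(1, (3 * max_pcs) // 4), max_pcs})
    test_size = max(k_best, int(np.ceil(0.1 * n)))
    can_split = (min(counts.values()) >= 2 and n - test_size >= k_best
                 and test_size < n)
    best_score, n_pcs_lda = -1.0, candidates[-1]
    if can_split:
        splitter = StratifiedShuffleSplit(n_splits=n_xval_splits, test_size=test_size,
                                          random_state=seed)
        splits = list(splitter.split(P, km_labels))
        for npc in candidates:
            scores = []
            for tr, te in splits:
                lda = LinearDiscriminantAnalysis()
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    lda.fit(P[tr, :npc], km_labels[tr])
                scores.append(float((lda.predict(P[te, :npc]) == km_labels[te]).mean()))
            score = float(np.mean(scores))
            if score > best_score:
                best_score, n_pcs_lda = score, npc
    lda = LinearDiscriminantAnalysis()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lda.fit(P[:, :n_pcs_lda], km_labels)
        labels = lda.predict(P[:, :n_pcs_lda])
    return ClusterRun(seed=seed, k=int(len(np.unique(labels))), bic_curve=bic,
                      labels=np.asarray(labels) + 1, n_pcs_kmeans=n_pcs_km,
                      n_pcs_lda=n_pcs_lda, xval_score=max(best_score, 0.0))


@dataclass
class SupertypeAssignment:
    labels: dict[str, int]          # sequence/allele key -> supertype (1..K)
    support: dict[str, float]       # mean co-assignment with own cluster
    k: int
    runs: list[ClusterRun] = field(default_factory=list)

    def propagate(self, allele_to_key: Mapping[str, str]) -> "SupertypeAssignment":
        """Map an assignment on reduced sequences back to allele ids."""
        return SupertypeAssignment(
            labels={a: self.labels[key] for a, key in allele_to_key.items()},
            support={a: self.support[key] for a, key in allele_to_key.items()},
            k=self.k, runs=self.runs,
        )


def consensus_from_labels(label_matrix: np.ndarray, k_final: int | None = None,
                          method: str = "average") -> tuple[np.ndarray, np.ndarray]:
    """Consensus partition from per-run label vectors (runs x items).

    Builds the co-assignment matrix (fraction of runs placing two items in
    the same cluster), clusters 1 - co-assignment by hierarchical linkage,
    and cuts at ``k_final`` (default: smallest modal per-run K).  Invariant
    to any relabelling of clusters within runs.  Returns (labels 1..K,
    per-item support = mean co-assignment with its final co-members).
    """
    label_matrix = np.asarray(label_matrix)
    n_runs, n = label_matrix.shape
    if n_runs < 2:
        raise ValueError("need at least 2 runs for a consensus")
    co = np.zeros((n, n))
    for r in range(n_runs):
        lab = label_matrix[r]
        co += (lab[:, None] == lab[None, :]).astype(float)
    co /= n_runs
    if k_final is None:
        ks = [len(np.unique(label_matrix[r])) for r in range(n_runs)]
        counts = Counter(ks)
        top = max(counts.values())
        k_final = min(k for k, c in counts.items() if c == top)
        if len({k for k, c in counts.items() if c == top}) > 1:
            warnings.warn(f"runs disagree on K; using smallest modal K = {k_final}")
    if k_final == 1 or n == 1:
        return np.ones(n, dtype=int), np.ones(n)
    dist = 1.0 - co
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method=method)
    labels = fcluster(Z, t=k_final, criterion="maxclust")
    support = np.empty(n)
    for i in range(n):
        mates = labels == labels[i]
        support[i] = co[i, mates].mean() if mates.sum() > 1 else 1.0
    return labels, support


def consensus_supertypes(
    X: np.ndarray,
    keys: Sequence[str] | None = None,
    k_range: Iterable[int] = range(2, 21),
    n_batches: int = 5,
    n_runs_per_batch: int = 10,
    seed: int = 0,
    method: str = "average",
) -> SupertypeAssignment:
    """Consensus supertype assignment over ``n_batches x n_runs_per_batch`` runs.

    Each run is an independently seeded :func:`cluster_once`; the consensus
    partition comes from the co-assignment matrix cut at the modal K.
    """
    n = X.shape[0]
    if keys is None:
        keys = [str(i) for i in range(n)]
    ss = np.random.SeedSequence([seed])
    run_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                 ss.spawn(n_batches * n_runs_per_batch)]
    runs = [cluster_once(X, k_range=k_range, seed=s) for s in run_seeds]
    label_matrix = np.stack([r.labels for r in runs])
    labels, support = consensus_from_labels(label_matrix, method=method)
    return SupertypeAssignment(
        labels=dict(zip(keys, (int(l) for l in labels))),
        support=dict(zip(keys, (float(s) for s in support))),
        k=int(len(np.unique(labels))),
        runs=runs,
    )
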