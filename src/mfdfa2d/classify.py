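"""SVM identification with a heavy-tailed RBF kernel.

The kernel family k(x, y) = exp(-(1/sigma_k) sum_d |x_d^a - y_d^a|^b)
generalizes the Gaussian (a=1, b=2) and Laplacian (a=1, b=1) radial basis
functions; powers of negative coordinates use the signed convention
sign(v)|v|^a so the kernel stays well defined for any real features.
On top of it: stratified K-fold cross-validation (soft-margin SVM,
one-vs-one), pairwise species accuracies, hierarchical clustering that
uses the pairwise accuracy itself as the inter-species distance (similar
species are hard to tell apart, hence merged early), subsample-size
robustness curves and feature-combination comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .io_surfaces import FeatureTable

__all__ = [
    "KernelSpec",
    "CVResult",
    "MulticlassResult",
    "Dendrogram",
    "signed_power",
    "htrbf_kernel",
    "htrbf_gram",
    "median_bandwidth",
    "kfold_cv",
    "pairwise_accuracy_matrix",
    "accuracy_clustering",
    "multiclass_experiment",
    "subsample_experiment",
    "combination_comparison",
]


@dataclass(frozen=True)
class KernelSpec:
    """Heavy-tailed RBF configuration.

    ``bandwidth=None`` resolves sigma_k per training fold by the median
    pairwise-distance heuristic.  Defaults a=1, b=1 give the heavy-tailed
    Laplacian-like case; a=1, b=2 recovers the Gaussian RBF exactly.
    """

    kind: str = "htrbf"
    bandwidth: Optional[float] = None
    power_a: float = 1.0
    power_b: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("htrbf", "rbf"):
            raise ValueError("kind must be 'htrbf' or 'rbf'")
        if self.bandwidth is not None and self.bandwidth <= 0:
            raise ValueError("bandwidth sigma_k must be > 0")
        if self.power_a <= 0 or self.power_b <= 0:
            raise ValueError("kernel powers a, b must be > 0")

    @property
    def effective_powers(self) -> tuple[float, float]:
        if self.kind == "rbf":
            return 1.0, 2.0
        return self.power_a, self.power_b


def signed_power(x: np.ndarray, a: float) -> np.ndarray:
    """sign(x) |x|^a — keeps x^a real for negative coordinates and a < 1."""
    x = np.asarray(x, dtype=float)
    if a == 1.0:
        return x
    return np.sign(x) * np.abs(x) ** a


def _power_distances(X: np.ndarray, Y: np.ndarray, a: float, b: float) -> np.ndarray:
    """D[i, j] = sum_d |X[i, d]^a - Y[j, d]^a|^b."""
    Xa = signed_power(np.atleast_2d(X), a)
    Ya = signed_power(np.atleast_2d(Y), a)
    diff = np.abs(Xa[:, None, :] - Ya[None, :, :])
    return (diff ** b).sum(axis=2)


def htrbf_gram(
    X: np.ndarray, Y: np.ndarray, spec: KernelSpec, bandwidth: Optional[float] = None
) -> np.ndarray:
    """Gram matrix exp(-D/sigma_k) between rows of X and rows of Y."""
    sigma = bandwidth if bandwidth is not None else spec.bandwidth
    if sigma is None:
        raise ValueError("bandwidth is unresolved; pass one or use median_bandwidth")
    a, b = spec.effective_powers
    X = np.atleast_2d(np.asarray(X, float))
    Y = np.atleast_2d(np.asarray(Y, float))
    if not (np.isfinite(X).all() and np.isfinite(Y).all()):
        raise ValueError("kernel inputs must be finite")
    return np.exp(-_power_distances(X, Y, a, b) / sigma)


def htrbf_kernel(x: np.ndarray, y: np.ndarray, spec: KernelSpec) -> float:
    """Single kernel evaluation k(x, y); always 1 at x == y."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    return float(htrbf_gram(x[None, :], y[None, :], spec)[0, 0])


def median_bandwidth(X: np.ndarray, spec: KernelSpec) -> float:
    """Median of the pairwise power distances; 1.0 if all points coincide."""
    a, b = spec.effective_powers
    D = _power_distances(X, X, a, b)
    iu = np.triu_indices_from(D, k=1)
    med = float(np.median(D[iu])) if iu[0].size else 0.0
    return med if med > 0 else 1.0


def _seed_stream(seed: int, *key: int) -> np.random.Generator:
    """Deterministic child generator for a tagged sub-experiment."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def _child_seed(seed: int, *key: int) -> int:
    return int(_seed_stream(seed, *key).integers(2**31 - 1))


@dataclass
class CVResult:
    """Cross-validation outcome pooled over folds and repeats."""

    K: int
    fold_accuracies: np.ndarray         # K * repeats values in [0, 1]
    mean_accuracy: float                # trace(confusion) / total
    confusion: np.ndarray               # C x C ints, rows = true class
    classes: tuple[str, ...]
    seed: int


@dataclass
class MulticlassResult:
    overall_accuracy: float
    per_class_accuracy: np.ndarray      # recall per class
    confusion: np.ndarray
    classes: tuple[str, ...]


def _standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score both sets with statistics from the training set only."""
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (train - mu) / sd, (test - mu) / sd


def kfold_cv(
    table: FeatureTable,
    features: Sequence[str],
    K: int = 10,
    spec: KernelSpec | None = None,
    repeats: int = 10,
    seed: int = 0,
    C: float = 10.0,
) -> CVResult:
    """Stratified K-fold CV of a soft-margin SVM with the heavy-tailed kernel.

    Features are z-scored with training-fold statistics only; an
    unresolved bandwidth is set per fold by the median heuristic on the
    training block.  Fold accuracies and the confusion matrix are pooled
    over all folds of all repeats, so ``mean_accuracy`` equals
    trace(confusion)/total exactly.  Deterministic for a fixed seed.
    """
    spec = spec or KernelSpec()
    if K < 2:
        raise ValueError("K must be >= 2")
    classes = tuple(sorted(set(table.species)))
    counts = {c: table.species.count(c) for c in classes}
    small = [c for c, n in counts.items() if n < K]
    if small:
        raise ValueError(f"class(es) {small} have fewer than K={K} samples")
    X = table.columns(features)
    y = np.array([classes.index(sp) for sp in table.species])
    C_n = len(classes)
    confusion = np.zeros((C_n, C_n), dtype=int)
    fold_accs = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=K, shuffle=True,
                              random_state=_child_seed(seed, rep))
        for tr, te in skf.split(X, y):
            Xtr, Xte = _standardize(X[tr], X[te])
            sigma = spec.bandwidth or median_bandwidth(Xtr, spec)
            clf = SVC(C=C, kernel="precomputed")
            clf.fit(htrbf_gram(Xtr, Xtr, spec, sigma), y[tr])
            pred = clf.predict(htrbf_gram(Xte, Xtr, spec, sigma))
            fold_accs.append(float(np.mean(pred == y[te])))
            np.add.at(confusion, (y[te], pred), 1)
    mean_acc = float(np.trace(confusion) / confusion.sum())
    return CVResult(K, np.asarray(fold_accs), mean_acc, confusion, classes, seed)


def pairwise_accuracy_matrix(
    table: FeatureTable,
    features: Sequence[str],
    K: int = 10,
    spec: KernelSpec | None = None,
    seed: int = 0,
    repeats: int = 10,
    C: float = 10.0,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Mean binary CV accuracy for every species pair; diagonal 1.

    Symmetric by construction (one experiment per unordered pair).
    """
    classes = tuple(sorted(set(table.species)))
    n = len(classes)
    if n < 2:
        raise ValueError("need at least 2 species")
    A = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sub = table.subset_species([classes[i], classes[j]])
            res = kfold_cv(sub, features, K, spec, repeats,
                           seed=_child_seed(seed, i, j), C=C)
            A[i, j] = A[j, i] = res.mean_accuracy
    return A, classes


@dataclass
class Dendrogram:
    """Agglomerative merge tree over species, scipy linkage encoding."""

    Z: np.ndarray
    labels: tuple[str, ...]
    distance: str = "accuracy"

    def cut(self, g: int) -> dict[str, int]:
        """Flat cut into g groups; returns species -> group id (1-based)."""
        flat = hierarchy.fcluster(self.Z, t=g, criterion="maxclust")
        return dict(zip(self.labels, (int(v) for v in flat)))

    def to_text(self) -> str:
        """Newick-style bracketed tree with merge heights as labels."""
        tree = hierarchy.to_tree(self.Z)

        def render(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            return f"({render(node.left)},{render(node.right)}):{node.dist:.4f}"

        return render(tree) + ";"


def accuracy_clustering(
    matrix: np.ndarray,
    labels: Sequence[str] | None = None,
    transform: str = "identity",
    linkage_method: str = "average",
) -> Dendrogram:
    """Hierarchical clustering of species from the pairwise-accuracy matrix.

    The accuracy itself is used as the distance (``transform='identity'``,
    the literal reading: two species that are hard to distinguish have LOW
    mutual accuracy and merge early); ``transform='one-minus'`` clusters
    on 1 - accuracy instead.  Average linkage by default; equal distances
    are merged in lowest-index order (scipy's deterministic tie rule).
    """
    A = np.asarray(matrix, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(A, A.T):
        raise ValueError("matrix must be symmetric")
    if A.min() < 0 or A.max() > 1:
        raise ValueError("entries must be accuracies in [0, 1]")
    if transform == "one-minus":
        D = 1.0 - A
    elif transform == "identity":
        D = A.copy()
    else:
        raise ValueError("transform must be 'identity' or 'one-minus'")
    np.fill_diagonal(D, 0.0)
    Z = hierarchy.linkage(squareform(D, checks=False), method=linkage_method)
    if labels is None:
        labels = tuple(f"S{i + 1:02d}" for i in range(A.shape[0]))
    return Dendrogram(Z, tuple(labels), distance=transform)


def multiclass_experiment(
    table: FeatureTable,
    features: Sequence[str],
    K: int = 10,
    spec: KernelSpec | None = None,
    seed: int = 0,
    repeats: int = 10,
    C: float = 10.0,
) -> MulticlassResult:
    """All-species CV with per-class recall from the pooled confusion matrix."""
    res = kfold_cv(table, features, K, spec, repeats, seed, C)
    row_sums = res.confusion.sum(axis=1)
    per_class = np.diag(res.confusion) / np.where(row_sums > 0, row_sums, 1)
    return MulticlassResult(res.mean_accuracy, per_class, res.confusion, res.classes)


def subsample_experiment(
    table: FeatureTable,
    features: Sequence[str],
    K: int = 10,
    spec: KernelSpec | None = None,
    n_values: Sequence[int] = (),
    repeats: int = 10,
    seed: int = 0,
    C: float = 10.0,
) -> dict[int, tuple[float, float]]:
    """Accuracy vs per-species sample size n: mean and SD over repeats.

    Per repeat each species is subsampled to n without replacement and a
    single CV pass is run.  When n equals the full class size the
    subsample is the whole table, so the result coincides with
    ``kfold_cv(table, ..., repeats=repeats, seed=_child_seed(seed, n))``.
    """
    classes = sorted(set(table.species))
    min_size = min(table.species.count(c) for c in classes)
    if not n_values:
        raise ValueError("n_values must be non-empty")
    if max(n_values) > min_size:
        raise ValueError(f"max n={max(n_values)} exceeds smallest class size {min_size}")
    out: dict[int, tuple[float, float]] = {}
    for n in n_values:
        n_seed = _child_seed(seed, n)
        if n == min_size and all(table.species.count(c) == n for c in classes):
            res = kfold_cv(table, features, K, spec, repeats, n_seed, C)
            accs = [
                float(np.mean(res.fold_accuracies[r * K:(r + 1) * K]))
                for r in range(repeats)
            ]
        else:
            rng = np.random.default_rng(n_seed)
            accs = []
            for rep in range(repeats):
                idx: list[int] = []
                for c in classes:
                    members = np.flatnonzero(np.asarray(table.species) == c)
                    idx.extend(rng.choice(members, size=n, replace=False))
                sub = table.subset_rows(sorted(idx))
                res = kfold_cv(sub, features, K, spec, repeats=1,
                               seed=_child_seed(n_seed, rep), C=C)
                accs.append(res.mean_accuracy)
        out[int(n)] = (float(np.mean(accs)), float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0)
    return out


def combination_comparison(
    table: FeatureTable,
    combos: Sequence[Sequence[str]],
    K_values: Sequence[int] = (10,),
    spec: KernelSpec | None = None,
    seed: int = 0,
    repeats: int = 10,
    C: float = 10.0,
) -> dict[tuple[str, ...], dict[int, float]]:
    """Mean CV accuracy for each feature combination at each fold count K."""
    valid = set(table.feature_names)
    out: dict[tuple[str, ...], dict[int, float]] = {}
    for ci, combo in enumerate(combos):
        unknown = [f for f in combo if f not in valid]
        if unknown:
            raise ValueError(f"unknown feature name(s) {unknown}")
        row: dict[int, float] = {}
        for K in K_values:
            res = kfold_cv(table, list(combo), K, spec, repeats,
                           seed=_child_seed(seed, ci, K), C=C)
            row[int(K)] = res.mean_accuracy
        out[tuple(combo)] = row
    return out
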