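"""Radial-kernel SVM feature ranking by recursive feature elimination.

The classification task is binary (control vs. one exposure level).  An RBF
SVM is tuned over cost/gamma grids by repeated stratified k-fold
cross-validation; recursive feature elimination then retrains the SVM on the
surviving bins each round, scores every surviving bin by how much the fitted
dual objective would change if that bin were removed (with the dual
coefficients held fixed — the kernel generalization of weight-based RFE),
and eliminates the lowest-scoring chunk.  The elimination order, reversed,
is the importance ranking: rank 1 is the last bin standing.

The implementation exploits the separability of the squared euclidean
distance across features: the RBF kernel with feature ``i`` removed is
``K * exp(gamma * d_i)`` where ``d_i`` is that feature's squared-difference
matrix.  Per-feature difference matrices are cached once, so each
elimination round costs one precomputed-kernel SVM fit plus a single tensor
contraction over the support vectors, and accuracy-vs-k curves reuse one
kernel per k.

A cheaper per-round criterion (squared weights of a linear SVM refitted on
the surviving bins) is available via ``SVMConfig.criterion = "linear-weight"``
for speed comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC

from .errors import ConfigurationError, DataError
from .feature_table import FeatureTable

logger = logging.getLogger(__name__)

GRID_MIN, GRID_MAX = 1e-11, 1e11

#: memory ceiling (bytes) for the cached per-feature squared-difference tensor
_CACHE_LIMIT = int(1.5e9)


def default_grid(decade_step: int = 1) -> tuple[float, ...]:
    """Powers of ten spanning [1e-11, 1e11]; ``decade_step=2`` coarsens to every
    second decade for faster tuning."""
    return tuple(float(10.0 ** e) for e in range(-11, 12, decade_step))


@dataclass
class SVMConfig:
    """Kernel, tuning grids and cross-validation layout of every SVM step."""

    kernel: str = "radial"
    cost_grid: tuple[float, ...] = field(default_factory=default_grid)
    gamma_grid: tuple[float, ...] = field(default_factory=default_grid)
    folds: int = 3
    repeats: int = 250
    tune_repeats: int = 5
    stratified: bool = True
    seed: int = 0
    cost: float | None = None        # fixed hyperparameters skip tuning
    gamma: float | None = None
    criterion: str = "kernel-dual"   # or "linear-weight"
    retune_each_round: bool = False

    def validate(self) -> None:
        if self.kernel != "radial":
            raise ConfigurationError("only the radial kernel is supported")
        for name, grid in (("cost_grid", self.cost_grid), ("gamma_grid", self.gamma_grid)):
            if not grid:
                raise ConfigurationError(f"{name} must be non-empty")
            if any(not (GRID_MIN * (1 - 1e-12) <= g <= GRID_MAX * (1 + 1e-12)) for g in grid):
                raise ConfigurationError(f"{name} values must lie within [1e-11, 1e11]")
        if self.folds < 2:
            raise ConfigurationError("folds must be >= 2")
        if self.repeats < 1 or self.tune_repeats < 1:
            raise ConfigurationError("repeats must be >= 1")
        if self.criterion not in ("kernel-dual", "linear-weight"):
            raise ConfigurationError("criterion must be 'kernel-dual' or 'linear-weight'")


@dataclass
class RankedBins:
    """Importance permutation of all bin ids; ``order[0]`` is the top bin."""

    order: list[str]
    criterion: list[float]
    schedule: list[int]
    seed: int

    def __post_init__(self) -> None:
        if len(set(self.order)) != len(self.order):
            raise DataError("ranking order contains duplicate bin ids")

    def to_tsv(self, path) -> None:
        pd.DataFrame({"rank": np.arange(1, len(self.order) + 1), "bin_id": self.order,
                      "criterion": self.criterion}).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "RankedBins":
        df = pd.read_csv(path, sep="\t").sort_values("rank")
        return cls(list(df["bin_id"]), list(df["criterion"]), schedule=[], seed=-1)


@dataclass
class AccuracyCurve:
    """Repeated-CV accuracy as a function of the number of top bins retained."""

    points: list[tuple[int, float, float, int]]  # (k, mean, sd, n_estimates)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.points, columns=["k", "mean_accuracy", "sd_accuracy",
                                           "n_estimates"]).to_csv(path, sep="\t", index=False)

    def as_dict(self) -> dict[int, float]:
        return {k: m for k, m, _, _ in self.points}


@dataclass
class CVResult:
    mean: float
    sd: float
    per_repeat: list[float]


# ---------------------------------------------------------------------------
# shared helpers


def _binary_y(labels) -> np.ndarray:
    arr = np.asarray(labels)
    classes = np.unique(arr)
    if len(classes) != 2:
        raise DataError(f"binary classification requires exactly 2 classes, got {len(classes)}")
    return (arr == classes[1]).astype(int)


def _check_class_sizes(y: np.ndarray, folds: int) -> None:
    counts = np.bincount(y)
    if counts.min() < folds:
        raise DataError(f"smallest class has {counts.min()} samples, fewer than "
                        f"{folds} folds")


def _splitter(folds: int, stratified: bool, seed: int):
    cls = StratifiedKFold if stratified else KFold
    return cls(n_splits=folds, shuffle=True, random_state=int(seed))


def _repeat_accuracy(K: np.ndarray, y: np.ndarray, folds: int, stratified: bool,
                     seed: int, cost: float) -> float:
    """Pooled held-out accuracy of one randomized fold assignment."""
    correct = 0
    for tr, te in _splitter(folds, stratified, seed).split(K, y):
        svc = SVC(C=cost, kernel="precomputed")
        svc.fit(K[np.ix_(tr, tr)], y[tr])
        correct += int((svc.predict(K[np.ix_(te, tr)]) == y[te]).sum())
    return correct / len(y)


def _rbf_kernel(X: np.ndarray, gamma: float) -> np.ndarray:
    return np.exp(-gamma * squareform(pdist(X, "sqeuclidean")))


def _fold_seeds(seed: int, tag: int, n: int) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence([seed, tag]))
    return rng.integers(0, 2 ** 31 - 1, size=n)


# ---------------------------------------------------------------------------
# hyperparameter tuning


def tune_svm(table: FeatureTable, labels, config: SVMConfig) -> tuple[float, float, float]:
    """Grid-search cost and gamma by repeated stratified k-fold CV accuracy.

    All grid points are evaluated on identical fold assignments (paired
    comparison); ties are broken toward smaller cost, then smaller gamma.
    Returns ``(best_cost, best_gamma, best_mean_accuracy)``.
    """
    config.validate()
    X = table.values()
    y = _binary_y(labels)
    _check_class_sizes(y, config.folds)
    costs = tuple(sorted(set(config.cost_grid)))
    gammas = tuple(sorted(set(config.gamma_grid)))
    seeds = _fold_seeds(config.seed, 1, config.tune_repeats)
    D = squareform(pdist(X, "sqeuclidean"))

    acc = np.empty((len(costs), len(gammas)))
    for gi, gamma in enumerate(gammas):
        K = np.exp(-gamma * D)
        for ci, cost in enumerate(costs):
            reps = [_repeat_accuracy(K, y, config.folds, config.stratified, s, cost)
                    for s in seeds]
            acc[ci, gi] = float(np.mean(reps))

    best = (-np.inf, 0, 0)
    for ci in range(len(costs)):          # lexicographic scan implements the tie-break
        for gi in range(len(gammas)):
            if acc[ci, gi] > best[0]:
                best = (acc[ci, gi], ci, gi)
    return costs[best[1]], gammas[best[2]], float(best[0])


def _resolve_hyperparams(table: FeatureTable, labels,
                         config: SVMConfig) -> tuple[float, float]:
    if config.cost is not None and config.gamma is not None:
        return float(config.cost), float(config.gamma)
    cost, gamma, acc = tune_svm(table, labels, config)
    logger.info("tuned SVM: cost=%g gamma=%g (CV accuracy %.3f)", cost, gamma, acc)
    return cost, gamma


# ---------------------------------------------------------------------------
# repeated cross-validation


def repeated_cv_accuracy(table: FeatureTable, labels, config: SVMConfig) -> CVResult:
    """Repeated stratified k-fold CV accuracy at fixed (or freshly tuned)
    hyperparameters; one pooled accuracy per repeat."""
    config.validate()
    y = _binary_y(labels)
    _check_class_sizes(y, config.folds)
    cost, gamma = _resolve_hyperparams(table, labels, config)
    K = _rbf_kernel(table.values(), gamma)
    seeds = _fold_seeds(config.seed, 2, config.repeats)
    per_repeat = [_repeat_accuracy(K, y, config.folds, config.stratified, s, cost)
                  for s in seeds]
    return CVResult(float(np.mean(per_repeat)), float(np.std(per_repeat, ddof=1))
                    if len(per_repeat) > 1 else 0.0, per_repeat)


# ---------------------------------------------------------------------------
# recursive feature elimination


def chunk_schedule(n_bins: int, frac: float = 0.1, switch_at: int = 500) -> list[int]:
    """Elimination chunk sizes: drop ``frac`` of the survivors per round until
    ``switch_at`` remain, then one bin per round."""
    if n_bins <= 0:
        raise ConfigurationError("n_bins must be positive")
    sizes = []
    f = n_bins
    while f > switch_at:
        c = min(max(1, int(frac * f)), f - switch_at)
        sizes.append(c)
        f -= c
    sizes.extend([1] * f)
    return sizes


def rfe_rank(table: FeatureTable, labels, config: SVMConfig,
             schedule: list[int] | None = None) -> RankedBins:
    """Rank all bins by recursive feature elimination around the tuned SVM.

    Each round fits the SVM on the surviving bins, scores each surviving bin
    by the elimination criterion, removes the lowest-scoring chunk (stable
    ties by bin position), and records the removal order.  The returned
    order lists every bin exactly once, best (last-eliminated) first, with
    the criterion value each bin had when it was eliminated.
    """
    config.validate()
    X = table.values().astype(np.float64)
    y = _binary_y(labels)
    n, f = X.shape
    if f == 0:
        raise DataError("feature table has no bins")
    _check_class_sizes(y, config.folds)
    cost, gamma = _resolve_hyperparams(table, labels, config)
    if schedule is None:
        schedule = chunk_schedule(f)
    if sum(schedule) != f:
        raise ConfigurationError(f"schedule removes {sum(schedule)} bins, table has {f}")

    if config.criterion == "linear-weight":
        eliminated = _rfe_linear(X, y, cost, schedule)
    else:
        eliminated = _rfe_kernel_dual(X, y, cost, gamma, schedule)

    bin_ids = table.bin_ids
    order = [bin_ids[i] for i, _ in reversed(eliminated)]
    crit = [c for _, c in reversed(eliminated)]
    return RankedBins(order=order, criterion=crit, schedule=list(schedule),
                      seed=config.seed)


def _rfe_kernel_dual(X: np.ndarray, y: np.ndarray, cost: float, gamma: float,
                     schedule: list[int]) -> list[tuple[int, float]]:
    n, f = X.shape
    cache_bytes = n * n * f * 4
    if cache_bytes > _CACHE_LIMIT:
        raise ConfigurationError(
            "per-feature kernel cache would exceed memory; subset samples or use "
            "the 'linear-weight' criterion")
    # d[i, j, k] = (x_ik - x_jk)^2; the RBF kernel factorizes over features,
    # so the kernel without feature k is K * exp(gamma * d_k) and the dual
    # objective changes by 0.5 * |sum_ij M_ij * (1 - exp(gamma * d_ijk))| with
    # M the alpha-weighted kernel.  expm1 keeps the criterion accurate when
    # gamma * d is tiny (cancellation-free), and the cache is only used when
    # gamma * d cannot overflow float32.
    d = np.ascontiguousarray((X[:, None, :] - X[None, :, :]) ** 2, dtype=np.float32)
    tot_d = d.sum(axis=2, dtype=np.float64)
    fast = gamma * float(d.max()) < 80.0
    Em1 = np.expm1(gamma * d.astype(np.float64)).astype(np.float32) if fast else None

    surv = np.arange(f)
    eliminated: list[tuple[int, float]] = []
    for chunk in schedule:
        K = np.exp(-gamma * tot_d)
        svc = SVC(C=cost, kernel="precomputed")
        svc.fit(K, y)
        sv = svc.support_
        a = svc.dual_coef_[0]          # already y_i * alpha_i
        a = a / np.abs(a).max()        # criterion scale does not affect ranking
        M = np.outer(a, a) * K[np.ix_(sv, sv)]
        if fast:
            gone = np.einsum("ij,ijf->f", M.astype(np.float32),
                             Em1[np.ix_(sv, sv, surv)], optimize=True)
        else:
            gd = gamma * d[np.ix_(sv, sv, surv)].astype(np.float64)
            with np.errstate(over="ignore"):
                gone = np.einsum("ij,ijf->f", M, np.expm1(gd))
        crit = 0.5 * np.abs(gone)

        order_in_round = np.argsort(crit, kind="stable")
        removed = order_in_round[:chunk]
        eliminated.extend((int(surv[r]), float(crit[r])) for r in removed)
        tot_d -= d[:, :, surv[removed]].sum(axis=2, dtype=np.float64)
        surv = np.delete(surv, removed)
    return eliminated


def _rfe_linear(X: np.ndarray, y: np.ndarray, cost: float,
                schedule: list[int]) -> list[tuple[int, float]]:
    surv = np.arange(X.shape[1])
    eliminated: list[tuple[int, float]] = []
    for chunk in schedule:
        svc = SVC(C=cost, kernel="linear")
        svc.fit(X[:, surv], y)
        crit = np.asarray(svc.coef_).ravel() ** 2
        order_in_round = np.argsort(crit, kind="stable")
        removed = order_in_round[:chunk]
        eliminated.extend((int(surv[r]), float(crit[r])) for r in removed)
        surv = np.delete(surv, removed)
    return eliminated


# ---------------------------------------------------------------------------
# accuracy as a function of retained bins


def accuracy_curve(table: FeatureTable, labels, ranking: RankedBins,
                   k_values: list[int], config: SVMConfig) -> AccuracyCurve:
    """Repeated-CV accuracy of the SVM restricted to the top-k ranked bins.

    The same fold assignments are reused for every k, so points along the
    curve are paired.  Hyperparameters are taken from the config when fixed,
    otherwise tuned once on the full table.
    """
    config.validate()
    ks = sorted(set(int(k) for k in k_values))
    if not ks or ks[0] < 1:
        raise ConfigurationError("k values must be positive")
    if ks[-1] > len(ranking.order):
        raise ConfigurationError(f"k={ks[-1]} exceeds the number of ranked bins "
                                 f"({len(ranking.order)})")
    y = _binary_y(labels)
    _check_class_sizes(y, config.folds)
    cost, gamma = _resolve_hyperparams(table, labels, config)
    # same fold-seed stream as repeated_cv_accuracy: the k = n_bins point of
    # the curve reproduces the plain repeated-CV accuracy exactly
    seeds = _fold_seeds(config.seed, 2, config.repeats)
    points = []
    for k in ks:
        sub = table.select_bins(ranking.order[:k])
        K = _rbf_kernel(sub.values(), gamma)
        reps = [_repeat_accuracy(K, y, config.folds, config.stratified, s, cost)
                for s in seeds]
        sd = float(np.std(reps, ddof=1)) if len(reps) > 1 else 0.0
        points.append((k, float(np.mean(reps)), sd, len(reps)))
    return AccuracyCurve(points)
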