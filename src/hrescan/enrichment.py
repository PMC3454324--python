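"""Motif-enrichment statistics for core versus background region sets.

Two complementary analyses of the binary region x PWM presence matrix:

* per-PWM 2x2 Fisher's exact tests (one-sided "greater" by default,
  uncorrected at p < 0.05, with an informational BH column), and
* correlation-based feature selection (CFS): a best-first search for the
  PWM subset maximizing merit = k r_cf / sqrt(k + k(k-1) r_ff), where the
  "correlation" is the symmetrical uncertainty SU(X, Y) =
  2 I(X;Y) / (H(X) + H(Y)) of binary variables, run inside repeated
  stratified cross-validation and summarized as the number of folds in
  which each PWM was selected (0..folds*iterations).
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .chip import benjamini_hochberg

logger = logging.getLogger(__name__)


@dataclass
class ContingencyResult:
    pwm_id: str
    a: int  # core regions with a conserved hit
    b: int  # core without
    c: int  # background with
    d: int  # background without
    odds_ratio: float | None
    p: float
    significant: bool
    adjusted_p: float | None = None


@dataclass
class SelectionCount:
    pwm_id: str
    times_chosen: int


def _as_binary_matrix(features):
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=int), list(features.columns)
    X = np.asarray(features, dtype=int)
    return X, [str(j) for j in range(X.shape[1])]


def fisher_enrichment(presence, labels, alternative: str = "greater") -> list[ContingencyResult]:
    """Per-PWM Fisher's exact test of conserved-hit presence, core vs
    background.  Constant columns get p = 1 with an undefined odds ratio."""
    X, names = _as_binary_matrix(presence)
    y = np.asarray([1 if l == "core" else 0 for l in labels])
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("both core and background labels must be present")
    results = []
    pvals = []
    for j, name in enumerate(names):
        col = X[:, j]
        a = int(np.sum(col[y == 1]))
        b = int(np.sum(y == 1) - a)
        c = int(np.sum(col[y == 0]))
        d = int(np.sum(y == 0) - c)
        if col.min() == col.max():
            oratio, p = None, 1.0
        else:
            oratio, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
            oratio = float(oratio) if math.isfinite(oratio) else float("inf")
        results.append(ContingencyResult(name, a, b, c, d, oratio, float(p), p < 0.05))
        pvals.append(p)
    for r, adj in zip(results, benjamini_hochberg(np.array(pvals))):
        r.adjusted_p = float(adj)
    return results


def enrichment_to_tsv(results: list[ContingencyResult]) -> str:
    lines = ["pwm_id\ta\tb\tc\td\todds_ratio\tp\tsignificant\tadjusted_p"]
    for r in results:
        orr = "" if r.odds_ratio is None else f"{r.odds_ratio:.6g}"
        lines.append(
            f"{r.pwm_id}\t{r.a}\t{r.b}\t{r.c}\t{r.d}\t{orr}\t{r.p:.6g}"
            f"\t{int(r.significant)}\t{r.adjusted_p:.6g}"
        )
    return "\n".join(lines) + "\n"


# -- correlation-based feature selection -------------------------------

def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def symmetrical_uncertainty(x: np.ndarray, y: np.ndarray) -> float:
    """SU(X, Y) = 2 I(X;Y) / (H(X) + H(Y)) for binary vectors (0 when both
    entropies vanish)."""
    joint = np.bincount(2 * x + y, minlength=4).astype(float)
    hx = _entropy(joint.reshape(2, 2).sum(axis=1))
    hy = _entropy(joint.reshape(2, 2).sum(axis=0))
    if hx + hy == 0:
        return 0.0
    mi = hx + hy - _entropy(joint)
    return max(0.0, 2 * mi / (hx + hy))


class _SUCache:
    def __init__(self, X: np.ndarray, y: np.ndarray):
        self.X, self.y = X, y
        self.cf = {}
        self.ff = {}

    def feature_label(self, j: int) -> float:
        if j not in self.cf:
            self.cf[j] = symmetrical_uncertainty(self.X[:, j], self.y)
        return self.cf[j]

    def feature_feature(self, i: int, j: int) -> float:
        key = (min(i, j), max(i, j))
        if key not in self.ff:
            self.ff[key] = symmetrical_uncertainty(self.X[:, key[0]], self.X[:, key[1]])
        return self.ff[key]


def _merit(subset: tuple, cache: _SUCache) -> float:
    k = len(subset)
    r_cf = np.mean([cache.feature_label(j) for j in subset])
    if k == 1:
        return float(r_cf)
    r_ff = np.mean([
        cache.feature_feature(a, b)
        for idx, a in enumerate(subset) for b in subset[idx + 1:]
    ])
    return float(k * r_cf / math.sqrt(k + k * (k - 1) * r_ff))


def cfs_merit(subset, features, labels) -> float:
    """CFS merit of a feature subset (higher is better)."""
    X, _ = _as_binary_matrix(features)
    y = np.asarray(labels, dtype=int)
    subset = tuple(sorted(subset))
    if not subset:
        raise ValueError("subset must be non-empty")
    return _merit(subset, _SUCache(X, y))


def cfs_select(features, labels, patience: int = 5) -> set:
    """Best-first forward search for the merit-maximizing feature subset.

    The open list is ordered by merit (ties: smaller subset, then
    lexicographically smallest index tuple, so the search is
    deterministic); the search stops after ``patience`` consecutive node
    expansions that fail to improve the best merit found.
    """
    X, _ = _as_binary_matrix(features)
    y = np.asarray(labels, dtype=int)
    nf = X.shape[1]
    cache = _SUCache(X, y)
    start = ()
    best_subset, best_merit = start, 0.0
    heap = [(0.0, 0, start)]  # (-merit, size, subset)
    seen = {start}
    stale = 0
    while heap and stale <= patience:
        _, _, node = heapq.heappop(heap)
        improved = False
        for j in range(nf):
            if j in node:
                continue
            child = tuple(sorted(node + (j,)))
            if child in seen:
                continue
            seen.add(child)
            m = _merit(child, cache)
            if m > best_merit + 1e-12:
                best_merit, best_subset = m, child
                improved = True
            heapq.heappush(heap, (-m, len(child), child))
        stale = 0 if improved else stale + 1
    return set(best_subset)


def cfs_select_exhaustive(features, labels) -> set:
    """Enumerate every non-empty subset (small feature counts only)."""
    X, _ = _as_binary_matrix(features)
    y = np.asarray(labels, dtype=int)
    nf = X.shape[1]
    if nf > 20:
        raise ValueError("exhaustive search is limited to 20 features")
    cache = _SUCache(X, y)
    best, best_merit = (), 0.0
    for mask in range(1, 1 << nf):
        subset = tuple(j for j in range(nf) if mask >> j & 1)
        m = _merit(subset, cache)
        if m > best_merit + 1e-12 or (
            abs(m - best_merit) <= 1e-12 and best and
            (len(subset), subset) < (len(best), best)
        ):
            best, best_merit = subset, m
    return set(best)


def stratified_folds(labels, folds: int, rng: np.random.Generator) -> np.ndarray:
    """Per-class proportional fold assignment (round-robin after a
    seeded shuffle within each class)."""
    y = np.asarray(labels)
    assignment = np.empty(y.size, dtype=int)
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        rng.shuffle(idx)
        assignment[idx] = np.arange(idx.size) % folds
    return assignment


def cfs_cross_validate(features, labels, folds: int = 10, iterations: int = 10,
                       seed=0) -> list[SelectionCount]:
    """Repeated stratified cross-validated CFS selection counts.

    For each of ``iterations`` seeded fold assignments, CFS runs on every
    training split; ``times_chosen`` counts the folds (0..folds*iterations)
    in which each feature was selected.
    """
    X, names = _as_binary_matrix(features)
    y = np.asarray([1 if l == "core" else 0 for l in labels]) \
        if not np.issubdtype(np.asarray(labels).dtype, np.number) else np.asarray(labels, dtype=int)
    min_class = min(np.sum(y == 1), np.sum(y == 0))
    if min_class < folds:
        logger.warning("smallest class has %d members; reducing folds from %d",
                       min_class, folds)
        folds = max(int(min_class), 2)
    rng = np.random.default_rng(seed)
    counts = np.zeros(X.shape[1], dtype=int)
    for _ in range(iterations):
        assignment = stratified_folds(y, folds, rng)
        for f in range(folds):
            train = assignment != f
            for j in cfs_select(X[train], y[train]):
                counts[j] += 1
    return [SelectionCount(n, int(c)) for n, c in zip(names, counts)]


def selection_to_tsv(counts: list[SelectionCount]) -> str:
    lines = ["pwm_id\ttimes_chosen"]
    for c in sorted(counts, key=lambda s: -s.times_chosen):
        lines.append(f"{c.pwm_id}\t{c.times_chosen}")
    return "\n".join(lines) + "\n"
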