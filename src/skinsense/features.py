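"""Descriptor matrices and feature selection.

Two selection stages mirror the QSAR-building protocol: a Welch two-sample
two-tailed t-test keeps descriptors whose means differ between sensitizers
and non-sensitizers at the chosen significance level, and a correlation-based
subset evaluator (CFS) with forward best-first search reduces a candidate
list to a mutually independent subset. Five recipes combine the statistically
selected descriptors [A] with the skin-protein-reactive-group fingerprints
[B] and the literature mechanism fingerprints [C] into the descriptor sets
used by the QSAR model variants.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, check_X_y

from .errors import DegenerateInputError

FEATURE_GROUPS = ("A", "B", "C")


@dataclass
class DescriptorMatrix:
    """Molecules x named numeric features.

    ``feature_group`` maps each feature to A (statistically selected
    descriptors), B (skin-protein-reactive-group fingerprints) or C
    (literature mechanism fingerprints). Fingerprint columns are 0/1.
    """

    row_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    feature_group: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.feature_names)):
            raise ValueError(
                f"values shape {self.values.shape} != "
                f"({len(self.row_ids)}, {len(self.feature_names)})"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("all descriptor values must be finite")
        for name, group in self.feature_group.items():
            if group not in FEATURE_GROUPS:
                raise ValueError(f"unknown feature group {group!r} for {name!r}")
            if group in ("B", "C"):
                col = self.values[:, self.feature_names.index(name)]
                if not np.isin(col, (0.0, 1.0)).all():
                    raise ValueError(f"fingerprint column {name!r} must be 0/1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.row_ids, columns=self.feature_names
        )

    def columns(self, features: Sequence[str]) -> np.ndarray:
        idx = [self.feature_names.index(f) for f in features]
        return self.values[:, idx]

    def rows(self, ids: Sequence[str]) -> "DescriptorMatrix":
        pos = {r: i for i, r in enumerate(self.row_ids)}
        idx = [pos[i] for i in ids]
        return DescriptorMatrix(
            row_ids=list(ids),
            feature_names=list(self.feature_names),
            values=self.values[idx],
            feature_group=dict(self.feature_group),
        )

    def group_features(self, group: str) -> list[str]:
        return [f for f in self.feature_names
                if self.feature_group.get(f) == group]

    def save(self, path: str | Path) -> None:
        """CSV with row ids in the first column; feature groups in a JSON sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, index_label="id")
        sidecar = path.with_suffix(path.suffix + ".groups.json")
        sidecar.write_text(json.dumps(self.feature_group, indent=0))

    @classmethod
    def load(cls, path: str | Path) -> "DescriptorMatrix":
        path = Path(path)
        frame = pd.read_csv(path, index_col=0)
        sidecar = path.with_suffix(path.suffix + ".groups.json")
        groups = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(
            row_ids=[str(i) for i in frame.index],
            feature_names=list(frame.columns),
            values=frame.to_numpy(dtype=float),
            feature_group=groups,
        )


@dataclass
class FeatureSet:
    """A named, ordered feature subset with its construction recipe."""

    name: str
    features: list[str]
    recipe: str = ""

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError("a feature set cannot be empty")
        if len(set(self.features)) != len(self.features):
            raise ValueError("feature set contains duplicates")


def _as_binary(labels: Sequence) -> np.ndarray:
    """Coerce labels to a 0/1 vector; exactly two distinct values required."""
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise DegenerateInputError(
            f"need exactly two classes, got {list(classes)}"
        )
    return (y == classes[1]).astype(float)


class TTestSelector(SelectorMixin, BaseEstimator):
    """Keep features with Welch two-sample two-tailed p-value below alpha.

    The default ``alpha=0.05`` corresponds to the 95% confidence level used
    to build descriptor set [A]. Features with zero variance in both classes
    carry no class signal and are excluded (their names are reported in
    ``zero_variance_``).

    Attributes
    ----------
    pvalues_ : ndarray of shape (n_features,)
        Welch p-values (NaN for zero-variance-in-both-classes features).
    support_ : ndarray of bool
        Mask of selected features.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X, y):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        X, y = check_X_y(X, y)
        y01 = _as_binary(y)
        n0, n1 = int((y01 == 0).sum()), int((y01 == 1).sum())
        if min(n0, n1) < 2:
            raise DegenerateInputError(
                f"each class needs >= 2 members, got {n0} and {n1}"
            )
        a, b = X[y01 == 0], X[y01 == 1]
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_ind(a, b, equal_var=False, axis=0)
        pvalues = np.asarray(res.pvalue, dtype=float)
        flat = (a.var(axis=0) == 0) & (b.var(axis=0) == 0)
        pvalues[flat] = np.nan
        self.n_features_in_ = X.shape[1]
        self.pvalues_ = pvalues
        self.zero_variance_ = np.flatnonzero(flat)
        self.support_ = np.where(np.isnan(pvalues), False,
                                 pvalues < self.alpha)
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def select_by_ttest(
    matrix: DescriptorMatrix, labels: Sequence, alpha: float = 0.05,
    features: Sequence[str] | None = None,
) -> list[str]:
    """Names of features passing the Welch t-test at ``alpha``."""
    features = list(features) if features is not None else matrix.feature_names
    sel = TTestSelector(alpha=alpha).fit(matrix.columns(features), labels)
    return [f for f, keep in zip(features, sel.support_) if keep]


def _correlations(X: np.ndarray, y01: np.ndarray):
    """Absolute feature-class and feature-feature Pearson correlations.

    Point-biserial correlation against the binary class is Pearson on the
    0/1 coding. Zero-variance columns get correlation 0 everywhere.
    """
    Xs = X - X.mean(axis=0)
    sd = Xs.std(axis=0)
    ok = sd > 0
    Z = np.zeros_like(Xs)
    Z[:, ok] = Xs[:, ok] / sd[ok]
    yc = y01 - y01.mean()
    ysd = yc.std()
    r_cf = np.abs(Z.T @ yc / (len(y01) * ysd)) if ysd > 0 else np.zeros(X.shape[1])
    r_ff = np.abs(Z.T @ Z / len(y01))
    np.fill_diagonal(r_ff, 1.0)
    return r_cf, r_ff


def _merit_from_corr(idx: Sequence[int], r_cf: np.ndarray,
                     r_ff: np.ndarray) -> float:
    k = len(idx)
    if k == 0:
        raise ValueError("empty subset has no merit")
    mean_cf = float(r_cf[list(idx)].mean())
    if k == 1:
        return mean_cf
    sub = r_ff[np.ix_(idx, idx)]
    mean_ff = float((sub.sum() - k) / (k * (k - 1)))
    return k * mean_cf / np.sqrt(k + k * (k - 1) * mean_ff)


def cfs_merit(
    subset: Sequence[str], matrix: DescriptorMatrix, labels: Sequence
) -> float:
    """CFS subset merit  k·r̄_cf / sqrt(k + k(k−1)·r̄_ff).

    r̄_cf is the mean absolute feature-class correlation and r̄_ff the mean
    absolute pairwise feature-feature correlation within the subset: merit
    rises with class relevance and falls with redundancy. For a singleton the
    formula reduces to the feature's absolute class correlation.
    """
    subset = list(subset)
    if not subset:
        raise ValueError("empty subset has no merit")
    X = matrix.columns(subset)
    r_cf, r_ff = _correlations(X, _as_binary(labels))
    return _merit_from_corr(range(len(subset)), r_cf, r_ff)


class CFSBestFirstSelector(SelectorMixin, BaseEstimator):
    """Correlation-based feature-subset selection with best-first search.

    Best-first search over the feature-subset lattice maximizing the CFS
    merit: an open list of evaluated subsets is kept ordered by merit; the
    best unexpanded subset is expanded into every neighbor reachable by
    adding or removing a single feature; the search stops after
    ``max_stale`` consecutive expansions that fail to improve the best
    merit found. The removal moves let the search back out of a greedy
    path that picked up a redundant feature. Ties in merit are broken
    lexicographically by the subset's sorted feature indices, so the search
    is deterministic.

    Attributes
    ----------
    support_ : ndarray of bool
        Mask of the selected subset.
    merit_ : float
        CFS merit of the selected subset.
    """

    def __init__(self, max_stale: int = 5):
        self.max_stale = max_stale

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        y01 = _as_binary(y)
        n0 = int((y01 == 0).sum())
        if min(n0, len(y01) - n0) < 2:
            raise DegenerateInputError("each class needs >= 2 members")
        r_cf, r_ff = _correlations(X, y01)
        p = X.shape[1]
        best_subset, best_merit = self._search(p, r_cf, r_ff)
        self.n_features_in_ = p
        self.merit_ = best_merit
        self.support_ = np.zeros(p, dtype=bool)
        self.support_[list(best_subset)] = True
        return self

    def _search(self, p: int, r_cf: np.ndarray, r_ff: np.ndarray):
        # Heap entries: (-merit, sorted index tuple); the tuple doubles as
        # the deterministic tie-break.
        start: tuple[int, ...] = ()
        open_heap: list[tuple[float, tuple[int, ...]]] = [(0.0, start)]
        evaluated: set[tuple[int, ...]] = {start}
        best_subset: tuple[int, ...] = ()
        best_merit = -np.inf
        stale = 0
        while open_heap and stale < self.max_stale:
            _, subset = heapq.heappop(open_heap)
            improved = False
            members = set(subset)
            children = [tuple(sorted(members | {j}))
                        for j in range(p) if j not in members]
            children += [tuple(sorted(members - {j}))
                         for j in members if len(members) > 1]
            for child in children:
                if child in evaluated:
                    continue
                evaluated.add(child)
                merit = _merit_from_corr(child, r_cf, r_ff)
                heapq.heappush(open_heap, (-merit, child))
                if merit > best_merit or (
                    merit == best_merit and child < best_subset
                ):
                    best_merit, best_subset = merit, child
                    improved = True
            if improved:
                stale = 0
            else:
                stale += 1
        if not best_subset:  # all-zero correlations: keep the first feature
            best_subset, best_merit = (0,), float(r_cf[0])
        return best_subset, best_merit

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def reduce_best_first(
    matrix: DescriptorMatrix,
    labels: Sequence,
    candidate: Sequence[str],
    max_stale: int = 5,
    name: str = "reduced",
) -> FeatureSet:
    """Reduce ``candidate`` to a CFS-optimal subset via best-first search.

    Candidates are considered in lexicographic name order so the result is
    independent of input ordering.
    """
    candidate = sorted(set(candidate))
    if not candidate:
        raise ValueError("candidate feature list is empty")
    sel = CFSBestFirstSelector(max_stale=max_stale)
    sel.fit(matrix.columns(candidate), np.asarray(labels))
    chosen = [f for f, keep in zip(candidate, sel.support_) if keep]
    return FeatureSet(
        name=name, features=chosen,
        recipe=f"cfs-best-first({len(candidate)} candidates)",
    )


def _union(*lists: Iterable[str]) -> list[str]:
    seen: dict[str, None] = {}
    for lst in lists:
        for f in lst:
            seen.setdefault(f)
    return list(seen)


def build_descriptor_set(
    setA: Sequence[str],
    setB: Sequence[str],
    setC: Sequence[str],
    set_id: int,
    matrix: DescriptorMatrix,
    labels: Sequence,
) -> FeatureSet:
    """Assemble descriptor set 1-5 from the component feature lists.

    * set-1: reduce(A ∪ B)
    * set-2: reduce(A) ∪ B   (all reactive-group fingerprints retained)
    * set-3: reduce(A) ∪ C   (all literature fingerprints retained)
    * set-4: reduce(A) ∪ reduce(B)
    * set-5: A ∪ B ∪ C       (no reduction)

    The literature set [C] is never reduced, so every mechanism-derived
    fingerprint stays available to the classifier.
    """
    if set_id not in (1, 2, 3, 4, 5):
        raise ValueError(f"set_id must be 1..5, got {set_id}")
    A, B, C = list(setA), list(setB), list(setC)

    def reduce(features: Sequence[str]) -> list[str]:
        return reduce_best_first(matrix, labels, features).features

    if set_id == 1:
        features, recipe = reduce(_union(A, B)), "reduce(A ∪ B)"
    elif set_id == 2:
        features, recipe = _union(reduce(A), B), "reduce(A) ∪ B"
    elif set_id == 3:
        features, recipe = _union(reduce(A), C), "reduce(A) ∪ C"
    elif set_id == 4:
        features, recipe = _union(reduce(A), reduce(B)), "reduce(A) ∪ reduce(B)"
    else:
        features, recipe = _union(A, B, C), "A ∪ B ∪ C"
    return FeatureSet(name=f"set-{set_id}", features=features, recipe=recipe)
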