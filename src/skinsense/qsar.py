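"""QSAR model assembly, splits, classifier variants and Y-randomization.

Four binary QSAR models contrast different sensitizer potency classes with
non-sensitizers: model-1 uses Extreme and Strong sensitizers against a
diversity-selected non-sensitizer subset, model-2 generalizes over Extreme,
Strong and unknown-potency sensitizers, model-3 covers Moderate and model-4
Weak sensitizers, each against all non-sensitizers. Each model is trained in
many variants — a descriptor set (1-5), a train/test segregation method
(direct D, per-class separation S, or 10-fold cross-validation C) and a
classifier family (decision tree J48, multi-layer perceptron MLP, 100-tree
random forest RF, regularized logistic SL, linear-kernel SVM SMO) — named by
an alphanumeric code such as ``1D4RF``. Y-randomization refits a variant on
permuted labels to rule out chance correlation.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .chemio import LabeledDataset, MoleculeRecord
from .errors import DegenerateInputError, UnknownClassifierError
from .features import (
    DescriptorMatrix,
    FeatureSet,
    build_descriptor_set,
    select_by_ttest,
)
from .similarity import pairwise_tanimoto, path_fingerprint

#: Package-wide default seed for stochastic operations.
DEFAULT_SEED = 20160607

CLASSIFIERS = ("J48", "MLP", "RF", "SL", "SMO")
SPLIT_METHODS = ("D", "S", "C")

_CODE_RE = re.compile(r"^([1-4])([DSC])([1-5])(J48|MLP|RF|SL|SMO)$")

#: Representative-test-set class quotas: equal sensitizer representation
#: across potency classes and an equal number of non-sensitizers.
RTS_QUOTAS = {"X": 10, "St": 10, "S": 10, "M": 10, "W": 10, "N": 50}


@dataclass(frozen=True)
class VariantCode:
    """Alphanumeric variant identifier ``<model><split><set><classifier>``."""

    model_id: int
    split_method: str
    set_id: int
    classifier: str

    def __post_init__(self) -> None:
        if not _CODE_RE.match(str(self)):
            raise UnknownClassifierError(f"invalid variant code {self!s}")

    def __str__(self) -> str:
        return (
            f"{self.model_id}{self.split_method}{self.set_id}{self.classifier}"
        )

    @classmethod
    def parse(cls, code: str) -> "VariantCode":
        m = _CODE_RE.match(code)
        if m is None:
            raise UnknownClassifierError(f"invalid variant code {code!r}")
        return cls(int(m.group(1)), m.group(2), int(m.group(3)), m.group(4))


def all_variant_codes() -> list[VariantCode]:
    """The full 4 x 3 x 5 x 5 = 300-variant grid."""
    return [
        VariantCode(m, s, d, c)
        for m in (1, 2, 3, 4)
        for s in SPLIT_METHODS
        for d in (1, 2, 3, 4, 5)
        for c in CLASSIFIERS
    ]


def make_classifier(name: str, seed: int = DEFAULT_SEED):
    """Instantiate the classifier family named by a variant-code token.

    Defaults throughout, except the tree ensemble which uses 100 trees.
    """
    rng = int(seed) % (2**31)
    if name == "J48":
        return DecisionTreeClassifier(random_state=rng)
    if name == "MLP":
        return MLPClassifier(hidden_layer_sizes=(16,), max_iter=800,
                             random_state=rng)
    if name == "RF":
        return RandomForestClassifier(n_estimators=100, random_state=rng)
    if name == "SL":
        return LogisticRegression(max_iter=2000)
    if name == "SMO":
        return SVC(kernel="linear", random_state=rng)
    raise UnknownClassifierError(f"unknown classifier {name!r}")


def assemble_model_dataset(
    eo: LabeledDataset, model_id: int, diverse_nonsens_k: int = 49
) -> LabeledDataset:
    """Build the per-model training pool from the energy-optimized set.

    model-1: Extreme + Strong sensitizers plus the ``diverse_nonsens_k``
    non-sensitizers with least average similarity (avoids biasing the model
    toward the much larger non-sensitizer class); model-2: X + St + S with
    all non-sensitizers; model-3: Moderate with all non-sensitizers;
    model-4: Weak with all non-sensitizers.
    """
    sens_classes = {1: ("X", "St"), 2: ("X", "St", "S"), 3: ("M",),
                    4: ("W",)}.get(model_id)
    if sens_classes is None:
        raise ValueError(f"model_id must be 1..4, got {model_id}")
    sensitizers = eo.with_potency(*sens_classes)
    nonsens = eo.with_potency("N")
    for cls in sens_classes:
        if not any(r.potency == cls for r in sensitizers):
            raise ValueError(f"model-{model_id} requires class {cls}: empty")
    if not nonsens:
        raise ValueError("no non-sensitizers available")
    if model_id == 1:
        if diverse_nonsens_k > len(nonsens):
            raise ValueError(
                f"requested {diverse_nonsens_k} diverse non-sensitizers, "
                f"pool has {len(nonsens)}"
            )
        pool = LabeledDataset(records=list(nonsens), name="nonsens-pool")
        nonsens = list(select_diverse(pool, diverse_nonsens_k,
                                      mode="least-average-similarity"))
    return LabeledDataset(
        records=sensitizers + list(nonsens), name=f"model-{model_id}"
    )


@dataclass
class TrainTestSplit:
    """Train/test segregation (D or S) or a cross-validation partition (C)."""

    method: str
    seed: int
    train_ids: list[str] = field(default_factory=list)
    test_ids: list[str] = field(default_factory=list)
    fold_of: dict[str, int] = field(default_factory=dict)
    n_folds: int = 0

    def folds(self) -> list[tuple[list[str], list[str]]]:
        """Per-fold (train_ids, test_ids) lists for the C method."""
        if self.method != "C":
            return [(self.train_ids, self.test_ids)]
        ids = list(self.fold_of)
        return [
            (
                [i for i in ids if self.fold_of[i] != f],
                [i for i in ids if self.fold_of[i] == f],
            )
            for f in range(self.n_folds)
        ]


def split(
    dataset: LabeledDataset,
    method: str,
    seed: int = DEFAULT_SEED,
    n_folds: int = 10,
    train_fraction: float = 0.8,
) -> TrainTestSplit:
    """Split a dataset by the direct, separation or cross-validation method.

    D shuffles then cuts 80/20; S applies the 80/20 cut per class after
    pre-segregating sensitizers from non-sensitizers, guaranteeing
    proportional representation; C partitions into ``n_folds`` shuffled
    folds, each serving as the test part once.
    """
    labels = dataset.binary_labels()
    if len(set(labels)) < 2:
        raise DegenerateInputError("both classes must be present to split")
    rng = np.random.default_rng(seed)
    ids = dataset.ids
    if method == "D":
        order = rng.permutation(len(ids))
        n_train = round(train_fraction * len(ids))
        shuffled = [ids[i] for i in order]
        return TrainTestSplit(method="D", seed=seed,
                              train_ids=shuffled[:n_train],
                              test_ids=shuffled[n_train:])
    if method == "S":
        train: list[str] = []
        test: list[str] = []
        for side in (1, -1):
            side_ids = [i for i, y in zip(ids, labels) if y == side]
            order = rng.permutation(len(side_ids))
            n_train = round(train_fraction * len(side_ids))
            shuffled = [side_ids[i] for i in order]
            train += shuffled[:n_train]
            test += shuffled[n_train:]
        return TrainTestSplit(method="S", seed=seed, train_ids=train,
                              test_ids=test)
    if method == "C":
        if len(ids) < n_folds:
            raise DegenerateInputError(
                f"{len(ids)} molecules cannot fill {n_folds} folds"
            )
        kf = KFold(n_splits=n_folds, shuffle=True,
                   random_state=int(seed) % (2**31))
        fold_of: dict[str, int] = {}
        for f, (_, test_idx) in enumerate(kf.split(ids)):
            for i in test_idx:
                fold_of[ids[i]] = f
        return TrainTestSplit(method="C", seed=seed, fold_of=fold_of,
                              n_folds=n_folds)
    raise ValueError(f"unknown split method {method!r}")


class QSARVariantClassifier:
    """One trained QSAR model variant (scikit-learn-style estimator).

    Parameters
    ----------
    code : str or VariantCode
        Alphanumeric variant code, e.g. ``"2C4RF"``.
    seed : int
        Seed for the split and any stochastic classifier internals.
    alpha : float
        Significance level for the t-test building descriptor set [A].
    diverse_nonsens_k : int
        Non-sensitizer quota for model-1 assembly.

    ``fit(dataset, matrix)`` assembles the model's training pool from the
    labeled dataset, derives the variant's descriptor set, splits by the
    coded method and fits the coded classifier family. ``predict`` maps
    feature rows to +1 (sensitizer) / -1 (non-sensitizer).
    """

    def __init__(self, code: str | VariantCode = "2C4RF",
                 seed: int = DEFAULT_SEED, alpha: float = 0.05,
                 diverse_nonsens_k: int = 49):
        self.code = code
        self.seed = seed
        self.alpha = alpha
        self.diverse_nonsens_k = diverse_nonsens_k

    def get_params(self, deep: bool = True) -> dict:
        return {"code": self.code, "seed": self.seed, "alpha": self.alpha,
                "diverse_nonsens_k": self.diverse_nonsens_k}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    @property
    def code_(self) -> VariantCode:
        return (self.code if isinstance(self.code, VariantCode)
                else VariantCode.parse(self.code))

    def fit(self, dataset: LabeledDataset, matrix: DescriptorMatrix,
            assemble: bool = True):
        code = self.code_
        pool = (assemble_model_dataset(dataset, code.model_id,
                                       self.diverse_nonsens_k)
                if assemble else dataset)
        sub = matrix.rows(pool.ids)
        labels = np.array(pool.binary_labels())
        A = select_by_ttest(sub, labels, alpha=self.alpha,
                            features=sub.group_features("A"))
        if not A:  # degenerate inputs: fall back to all group-A descriptors
            A = sub.group_features("A")
        self.feature_set_ = build_descriptor_set(
            A, sub.group_features("B"), sub.group_features("C"),
            code.set_id, sub, labels,
        )
        self.split_ = split(pool, code.split_method, seed=self.seed)
        id_pos = {r: i for i, r in enumerate(pool.ids)}
        X = sub.columns(self.feature_set_.features)

        fold_accs: list[float] = []
        for train_ids, test_ids in self.split_.folds():
            tr = [id_pos[i] for i in train_ids]
            te = [id_pos[i] for i in test_ids]
            clf = make_classifier(code.classifier, self.seed)
            clf.fit(X[tr], labels[tr])
            if te:
                fold_accs.append(float(
                    (clf.predict(X[te]) == labels[te]).mean()))
        # Final model: C refits on the full pool (the CV estimate stands in
        # for the held-out accuracy); D/S keep the train-portion fit.
        if code.split_method == "C":
            self.classifier_ = make_classifier(code.classifier, self.seed)
            self.classifier_.fit(X, labels)
            self.train_ids_ = pool.ids
            self.test_ids_: list[str] = []
        else:
            tr = [id_pos[i] for i in self.split_.train_ids]
            self.classifier_ = make_classifier(code.classifier, self.seed)
            self.classifier_.fit(X[tr], labels[tr])
            self.train_ids_ = list(self.split_.train_ids)
            self.test_ids_ = list(self.split_.test_ids)
        self.test_accuracy_ = float(np.mean(fold_accs)) if fold_accs else np.nan
        self.pool_ids_ = pool.ids
        return self

    def _features_from(self, matrix: DescriptorMatrix,
                       ids: Sequence[str] | None = None) -> np.ndarray:
        sub = matrix.rows(ids) if ids is not None else matrix
        return sub.columns(self.feature_set_.features)

    def predict(self, X) -> np.ndarray:
        """Predict +1/-1 from a feature array or a DescriptorMatrix."""
        if isinstance(X, DescriptorMatrix):
            X = self._features_from(X)
        return np.asarray(self.classifier_.predict(X), dtype=int)

    def save(self, directory: str | Path) -> None:
        """Persist as a reloadable bundle (model file + metadata)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        joblib.dump(self.classifier_, directory / "model.joblib")
        meta = {
            "code": str(self.code_),
            "seed": self.seed,
            "alpha": self.alpha,
            "features": self.feature_set_.features,
            "recipe": self.feature_set_.recipe,
            "train_ids": self.train_ids_,
            "test_ids": self.test_ids_,
        }
        (directory / "variant.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "QSARVariantClassifier":
        directory = Path(directory)
        meta = json.loads((directory / "variant.json").read_text())
        obj = cls(code=meta["code"], seed=meta["seed"], alpha=meta["alpha"])
        obj.classifier_ = joblib.load(directory / "model.joblib")
        obj.feature_set_ = FeatureSet(
            name=f"set-{obj.code_.set_id}", features=meta["features"],
            recipe=meta.get("recipe", ""),
        )
        obj.train_ids_ = meta["train_ids"]
        obj.test_ids_ = meta["test_ids"]
        return obj


def train_variant(
    code: str | VariantCode,
    dataset: LabeledDataset,
    matrix: DescriptorMatrix,
    seed: int = DEFAULT_SEED,
    assemble: bool = True,
) -> QSARVariantClassifier:
    """Train one variant; thin wrapper over :class:`QSARVariantClassifier`."""
    return QSARVariantClassifier(code=code, seed=seed).fit(
        dataset, matrix, assemble=assemble
    )


def select_diverse(
    pool: LabeledDataset,
    k: int,
    mode: str = "least-average-similarity",
    quotas: dict[str, int] | None = None,
) -> LabeledDataset:
    """Pick structurally diverse molecules by Tanimoto similarity.

    ``least-average-similarity`` returns the k molecules with the smallest
    mean pairwise Tanimoto coefficient to the rest of the pool (ties broken
    by id, so the result is input-order invariant).
    ``stratified-representative`` fills per-class quotas (default: the
    representative-test-set quotas) by a greedy max-min pick: start from the
    least-similar molecule of the class, then repeatedly add the molecule
    whose maximal similarity to those already chosen is smallest.
    """
    if k > len(pool):
        raise ValueError(f"k={k} exceeds pool size {len(pool)}")
    if mode == "least-average-similarity":
        if k == len(pool):
            return LabeledDataset(records=list(pool), name=pool.name)
        fps = [path_fingerprint(r) for r in pool]
        sim = pairwise_tanimoto(fps)
        n = len(pool)
        mean_sim = (sim.sum(axis=1) - 1.0) / (n - 1) if n > 1 else np.zeros(1)
        ranked = sorted(range(n), key=lambda i: (mean_sim[i], pool[i].id))
        chosen = sorted(ranked[:k])
        return LabeledDataset(records=[pool[i] for i in chosen],
                              name=f"{pool.name}-diverse{k}")
    if mode == "stratified-representative":
        quotas = dict(quotas or RTS_QUOTAS)
        counts = pool.class_counts()
        for cls, quota in quotas.items():
            if quota > counts.get(cls, 0):
                raise ValueError(
                    f"quota {quota} for class {cls} exceeds pool count "
                    f"{counts.get(cls, 0)}"
                )
        picked: list[MoleculeRecord] = []
        for cls, quota in quotas.items():
            members = sorted(pool.with_potency(cls), key=lambda r: r.id)
            fps = [path_fingerprint(r) for r in members]
            sim = pairwise_tanimoto(fps)
            n = len(members)
            mean_sim = ((sim.sum(axis=1) - 1.0) / (n - 1)
                        if n > 1 else np.zeros(n))
            chosen = [min(range(n),
                          key=lambda i: (mean_sim[i], members[i].id))]
            while len(chosen) < quota:
                remaining = [i for i in range(n) if i not in chosen]
                # smallest maximal similarity to the picked set
                best = min(
                    remaining,
                    key=lambda i: (sim[i, chosen].max(), members[i].id),
                )
                chosen.append(best)
            picked += [members[i] for i in sorted(chosen)]
        return LabeledDataset(records=picked, name=f"{pool.name}-rts")
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class YRandomizationResult:
    """Real-label accuracy versus accuracies under label permutation."""

    code: str
    real_accuracy: float
    randomized_accuracies: list[float]

    @property
    def margin(self) -> float:
        """Real accuracy minus the best permuted-label accuracy."""
        return self.real_accuracy - max(self.randomized_accuracies)


def y_randomize(
    code: str | VariantCode,
    dataset: LabeledDataset,
    matrix: DescriptorMatrix,
    runs: int = 10,
    seed: int = DEFAULT_SEED,
    assemble: bool = True,
) -> YRandomizationResult:
    """Y-randomization: refit on permuted labels to rule out chance fits.

    The variant is trained once on the true labels, then ``runs`` times on
    random label permutations of the training portion, each evaluated
    against the untouched true test labels. A sound model scores far above
    every permuted run.
    """
    code = code if isinstance(code, VariantCode) else VariantCode.parse(code)
    real = QSARVariantClassifier(code=code, seed=seed).fit(
        dataset, matrix, assemble=assemble
    )
    pool = dataset.subset(real.pool_ids_)
    sub = matrix.rows(pool.ids)
    labels = np.array(pool.binary_labels())
    id_pos = {r: i for i, r in enumerate(pool.ids)}
    X = sub.columns(real.feature_set_.features)

    rng = np.random.default_rng(seed)
    randomized: list[float] = []
    for _ in range(runs):
        fold_accs = []
        for train_ids, test_ids in real.split_.folds():
            tr = [id_pos[i] for i in train_ids]
            te = [id_pos[i] for i in test_ids]
            y_perm = labels[tr][rng.permutation(len(tr))]
            clf = make_classifier(code.classifier, seed)
            clf.fit(X[tr], y_perm)
            if te:
                fold_accs.append(float(
                    (clf.predict(X[te]) == labels[te]).mean()))
        randomized.append(float(np.mean(fold_accs)))
    return YRandomizationResult(
        code=str(code),
        real_accuracy=real.test_accuracy_,
        randomized_accuracies=randomized,
    )
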