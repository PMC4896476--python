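"""Weighted consensus of QSAR votes, similarity and sub-structure alerts.

The final classification combines five signed component votes — QSAR models
m2, m3, m4, the similarity vote and the sub-structure vote — as a weighted
sum:

    score = m2·w_m2 + m3·w_m3 + m4·w_m4
          + s_similarity·w_similarity + s_substr·w_substr

where each weight is direction-specific: a component predicting "sensitizer"
may carry a different weight than the same component predicting
"non-sensitizer" (knowledge-based schemes KB-a..KB-d). A positive score
classifies the molecule as a sensitizer, a negative score as a
non-sensitizer, and exactly zero is indeterminate. Alternatively, the five
votes can be consolidated by a trained meta-classifier, which always commits
to one of the two classes.

Two reference workflow bundles combine the best variants of models 2-4:
PW-1 = {2C2RF, 3C2RF, 4C2RF} and PW-2 = {2C4RF, 3C2RF, 4C2RF}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from sklearn.model_selection import cross_val_score

from .alerts import Alert, AlertVerdict, SubstructureComponent, \
    default_alert_library
from .chemio import LabeledDataset, MoleculeRecord, load_dataset, \
    write_dataset
from .descriptors import builtin_provider, compute_descriptor_matrix
from .errors import (
    DegenerateInputError,
    IncompleteComponentsError,
    UnknownSchemeError,
)
from .features import DescriptorMatrix
from .metrics import PerformanceReport, compute_metrics, tally
from .qsar import DEFAULT_SEED, QSARVariantClassifier, make_classifier
from .similarity import SimilarityComponent, SimilarityVerdict

logger = logging.getLogger(__name__)

COMPONENTS = ("m2", "m3", "m4", "similarity", "substructure")

#: Direction vocabulary per component.
DIRECTIONS = {
    "m2": ("S", "N"),
    "m3": ("S", "N"),
    "m4": ("S", "N"),
    "similarity": ("S", "N", "NS", "NoMatch"),
    "substructure": ("Present", "Absent"),
}

#: Workflow bundles: variant codes for models 2, 3 and 4.
WORKFLOWS = {
    "PW-1": ("2C2RF", "3C2RF", "4C2RF"),
    "PW-2": ("2C4RF", "3C2RF", "4C2RF"),
}


@dataclass(frozen=True)
class ComponentScore:
    """One component's vote: value in {-1, 0, +1} plus its provenance.

    Only the similarity component may vote 0 (tie or no match); QSAR and
    sub-structure votes are strictly +/-1.
    """

    component: str
    value: int
    direction: str
    detail: object = None

    def __post_init__(self) -> None:
        if self.component not in COMPONENTS:
            raise IncompleteComponentsError(
                f"unknown component {self.component!r}"
            )
        if self.direction not in DIRECTIONS[self.component]:
            raise IncompleteComponentsError(
                f"direction {self.direction!r} invalid for {self.component}"
            )
        allowed = (-1, 0, 1) if self.component == "similarity" else (-1, 1)
        if self.value not in allowed:
            raise IncompleteComponentsError(
                f"{self.component} vote must be in {allowed}, "
                f"got {self.value}"
            )


def qsar_score(component: str, value: int, detail: object = None
               ) -> ComponentScore:
    return ComponentScore(component, value, "S" if value > 0 else "N", detail)


def similarity_score(verdict: SimilarityVerdict) -> ComponentScore:
    return ComponentScore("similarity", verdict.score, verdict.direction,
                          verdict)


def substructure_score(verdict: AlertVerdict) -> ComponentScore:
    return ComponentScore(
        "substructure", verdict.score,
        "Present" if verdict.score > 0 else "Absent", verdict,
    )


@dataclass(frozen=True)
class WeightScheme:
    """Direction-specific component weights for the consensus sum."""

    name: str
    weights: Mapping[tuple[str, str], float]

    def __post_init__(self) -> None:
        for comp, dirs in DIRECTIONS.items():
            for d in dirs:
                if (comp, d) not in self.weights:
                    raise UnknownSchemeError(
                        f"scheme {self.name!r} missing weight ({comp}, {d})"
                    )
                if self.weights[(comp, d)] < 0:
                    raise UnknownSchemeError(
                        f"scheme {self.name!r}: negative weight ({comp}, {d})"
                    )

    def weight(self, component: str, direction: str) -> float:
        return self.weights[(component, direction)]


def _scheme(name: str, m2: tuple, m3: tuple, m4: tuple, sim: tuple,
            sub: tuple) -> WeightScheme:
    w: dict[tuple[str, str], float] = {}
    for comp, vals in (("m2", m2), ("m3", m3), ("m4", m4),
                       ("similarity", sim), ("substructure", sub)):
        for d, v in zip(DIRECTIONS[comp], vals):
            w[(comp, d)] = float(v)
    return WeightScheme(name=name, weights=w)


#: The four built-in knowledge-based weight schemes. Sub-structure absence
#: keeps a nonzero weight (0.5): missing reactive groups argue for
#: non-sensitizer, while similarity ties and misses contribute nothing.
BUILTIN_SCHEMES: dict[str, WeightScheme] = {
    "KB-a": _scheme("KB-a", (1, 1), (0.4, 0.4), (0.3, 0.3), (1, 1, 0, 0),
                    (1, 0.5)),
    "KB-b": _scheme("KB-b", (1, 0.8), (0.8, 0.4), (0.3, 0.4), (1, 1, 0, 0),
                    (1, 0.5)),
    "KB-c": _scheme("KB-c", (1, 0.8), (0.6, 0.4), (0.3, 0.4), (1, 1, 0, 0),
                    (1, 0.5)),
    "KB-d": _scheme("KB-d", (1, 0.8), (0.4, 0.3), (0.3, 0.3), (1, 1, 0, 0),
                    (1, 0.5)),
}


def get_scheme(scheme: str | WeightScheme) -> WeightScheme:
    if isinstance(scheme, WeightScheme):
        return scheme
    try:
        return BUILTIN_SCHEMES[scheme]
    except KeyError:
        raise UnknownSchemeError(f"unknown weight scheme {scheme!r}") from None


def lookup_weight(scheme: str | WeightScheme, component: str,
                  direction: str) -> float:
    """The tabulated weight for (component, direction) under a scheme."""
    return get_scheme(scheme).weight(component, direction)


def load_scheme(path: str | Path) -> WeightScheme:
    """Read a custom weight scheme from YAML.

    Layout mirrors the built-in table: a ``name`` and one mapping per
    component with its direction weights, e.g. ``m2: {S: 1, N: 0.8}``.
    """
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    weights: dict[tuple[str, str], float] = {}
    for comp in COMPONENTS:
        for d, v in doc[comp].items():
            weights[(comp, d)] = float(v)
    return WeightScheme(name=str(doc.get("name", "custom")), weights=weights)


@dataclass
class ConsensusResult:
    """Final weighted-vote classification of one molecule."""

    id: str
    score: float
    label: str
    components: list[ComponentScore]
    scheme: str
    workflow: str = ""

    @property
    def is_indeterminate(self) -> bool:
        return self.label == "indeterminate"


@dataclass
class WorkflowFailure:
    """Per-molecule failure record (errors never abort a batch)."""

    id: str
    error: str


def consensus_score(
    components: Sequence[ComponentScore],
    scheme: str | WeightScheme,
    ablate: Iterable[str] = (),
    molecule_id: str = "",
    workflow: str = "",
) -> ConsensusResult:
    """Combine the five component votes into the weighted consensus.

    ``ablate`` names component groups (``qsar``, ``similarity``,
    ``substructure``) whose contribution is zeroed, supporting leave-one-out
    analysis. The sum is rounded to 10 decimal places before the sign test;
    all built-in weights are exact tenths, so the zero comparison is exact.
    """
    scheme = get_scheme(scheme)
    by_comp = {c.component: c for c in components}
    if len(by_comp) != len(components) or set(by_comp) != set(COMPONENTS):
        raise IncompleteComponentsError(
            f"need exactly one score per component {COMPONENTS}, "
            f"got {[c.component for c in components]}"
        )
    ablate = set(ablate)
    unknown = ablate - {"qsar", "similarity", "substructure"}
    if unknown:
        raise ValueError(f"unknown ablation group(s) {sorted(unknown)}")

    def ablated(component: str) -> bool:
        group = "qsar" if component.startswith("m") else component
        return group in ablate

    total = 0.0
    for comp in COMPONENTS:
        c = by_comp[comp]
        if ablated(comp):
            continue
        total += c.value * scheme.weight(comp, c.direction)
    total = round(total, 10)
    if total > 0:
        label = "sensitizer"
    elif total < 0:
        label = "non-sensitizer"
    else:
        label = "indeterminate"
    return ConsensusResult(
        id=molecule_id, score=total, label=label,
        components=list(components), scheme=scheme.name, workflow=workflow,
    )


class MetaIntegrator:
    """Meta-classifier over the five component votes.

    ``method`` is ``perceptron-net`` (one-hidden-layer perceptron) or
    ``max-margin`` (linear-kernel SVM); trained with ``n_folds``-fold
    cross-validation reporting (``cv_accuracy_``). Unlike the weighted sum,
    the meta-classifier never returns an indeterminate call.
    """

    def __init__(self, method: str = "perceptron-net", n_folds: int = 10,
                 seed: int = DEFAULT_SEED):
        self.method = method
        self.n_folds = n_folds
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {"method": self.method, "n_folds": self.n_folds,
                "seed": self.seed}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _make(self):
        name = {"perceptron-net": "MLP", "max-margin": "SMO"}.get(self.method)
        if name is None:
            raise ValueError(f"unknown meta method {self.method!r}")
        return make_classifier(name, self.seed)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise DegenerateInputError("labels are single-class")
        if not np.isin(X, (-1.0, 0.0, 1.0)).all():
            raise ValueError("component votes must be in {-1, 0, +1}")
        if not X.any():
            logger.warning(
                "all-zero component matrix: no signal, the meta-model "
                "reduces to the majority class"
            )
        clf = self._make()
        self.cv_accuracy_ = float(np.mean(cross_val_score(
            self._make(), X, y, cv=self.n_folds)))
        clf.fit(X, y)
        self.classifier_ = clf
        self.classes_ = clf.classes_
        return self

    def predict(self, X) -> np.ndarray:
        return np.asarray(self.classifier_.predict(np.asarray(X, dtype=float)),
                          dtype=int)


def meta_integrate(component_matrix, labels, method: str = "perceptron-net",
                   n_folds: int = 10, seed: int = DEFAULT_SEED
                   ) -> MetaIntegrator:
    """Fit a meta-classifier on component votes (thin wrapper)."""
    return MetaIntegrator(method=method, n_folds=n_folds, seed=seed).fit(
        component_matrix, labels
    )


class ConsensusWorkflow:
    """End-to-end integrated prediction workflow (estimator interface).

    Parameters
    ----------
    workflow : str
        ``PW-1`` or ``PW-2`` (selects the QSAR variant codes), or ``custom``
        with ``variant_codes`` given explicitly. PW-2 is the default shipped
        configuration.
    scheme : str or WeightScheme
        Knowledge-based weight scheme (default KB-b, the best performing).
    cutoff : float
        Tanimoto similarity cutoff for the similarity component.
    library : sequence of Alert, optional
        Alert library; the shipped default when omitted.
    meta : MetaIntegrator or None
        When set, final labels come from the trained meta-classifier instead
        of the weighted sum.

    ``fit(dataset, matrix=None)`` trains the three QSAR variants on the
    labeled dataset, fingerprints it as the similarity reference and
    compiles the alert library. ``predict_results`` produces one
    :class:`ConsensusResult` per molecule.
    """

    def __init__(
        self,
        workflow: str = "PW-2",
        variant_codes: Sequence[str] | None = None,
        scheme: str | WeightScheme = "KB-b",
        cutoff: float = 0.6,
        library: Sequence[Alert] | None = None,
        seed: int = DEFAULT_SEED,
        meta: MetaIntegrator | None = None,
    ):
        self.workflow = workflow
        self.variant_codes = variant_codes
        self.scheme = scheme
        self.cutoff = cutoff
        self.library = library
        self.seed = seed
        self.meta = meta

    def get_params(self, deep: bool = True) -> dict:
        return {
            "workflow": self.workflow, "variant_codes": self.variant_codes,
            "scheme": self.scheme, "cutoff": self.cutoff,
            "library": self.library, "seed": self.seed, "meta": self.meta,
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _codes(self) -> tuple[str, str, str]:
        if self.variant_codes is not None:
            codes = tuple(self.variant_codes)
            if len(codes) != 3:
                raise ValueError("need exactly three variant codes (m2/m3/m4)")
            return codes
        try:
            return WORKFLOWS[self.workflow]
        except KeyError:
            raise ValueError(f"unknown workflow {self.workflow!r}") from None

    def _matrix(self, dataset: LabeledDataset) -> DescriptorMatrix:
        return compute_descriptor_matrix(
            dataset, provider=builtin_provider,
            reactive_alerts=self.library_,
        )

    def fit(self, dataset: LabeledDataset,
            matrix: DescriptorMatrix | None = None):
        self.library_ = (list(self.library) if self.library is not None
                         else default_alert_library())
        if matrix is None:
            matrix = self._matrix(dataset)
        self.variants_ = {}
        for comp, code in zip(("m2", "m3", "m4"), self._codes()):
            self.variants_[comp] = QSARVariantClassifier(
                code=code, seed=self.seed
            ).fit(dataset, matrix)
        self.similarity_ = SimilarityComponent(cutoff=self.cutoff).fit(dataset)
        self.substructure_ = SubstructureComponent(
            library=self.library_).fit()
        self.reference_ = dataset
        return self

    def component_scores(
        self, record: MoleculeRecord, matrix: DescriptorMatrix
    ) -> list[ComponentScore]:
        scores = []
        row = matrix.rows([record.id])
        for comp in ("m2", "m3", "m4"):
            variant = self.variants_[comp]
            vote = int(variant.predict(
                row.columns(variant.feature_set_.features))[0])
            scores.append(qsar_score(comp, vote, detail=str(variant.code_)))
        scores.append(similarity_score(self.similarity_.verdict(record)))
        scores.append(substructure_score(self.substructure_.verdict(record)))
        return scores

    def predict_results(
        self,
        molecules: LabeledDataset | Sequence[MoleculeRecord],
        matrix: DescriptorMatrix | None = None,
        ablate: Iterable[str] = (),
    ) -> tuple[list[ConsensusResult], list[WorkflowFailure]]:
        """Score molecules; component errors become per-molecule failures."""
        records = list(molecules)
        if matrix is None:
            matrix = self._matrix(
                LabeledDataset(records=records, name="query"))
        results: list[ConsensusResult] = []
        failures: list[WorkflowFailure] = []
        ablate = tuple(ablate)
        for record in records:
            try:
                comps = self.component_scores(record, matrix)
                if self.meta is not None:
                    votes = [[c.value for c in comps]]
                    label = ("sensitizer" if self.meta.predict(votes)[0] > 0
                             else "non-sensitizer")
                    result = ConsensusResult(
                        id=record.id, score=float("nan"), label=label,
                        components=comps, scheme=f"meta:{self.meta.method}",
                        workflow=self.workflow,
                    )
                else:
                    result = consensus_score(
                        comps, self.scheme, ablate=ablate,
                        molecule_id=record.id, workflow=self.workflow,
                    )
                results.append(result)
            except Exception as exc:  # noqa: BLE001 - per-molecule capture
                logger.warning("molecule %s failed: %s", record.id, exc)
                failures.append(WorkflowFailure(id=record.id, error=str(exc)))
        return results, failures

    def predict(self, molecules, matrix: DescriptorMatrix | None = None
                ) -> list[str]:
        results, failures = self.predict_results(molecules, matrix)
        if failures:
            raise RuntimeError(
                f"{len(failures)} molecule(s) failed; use predict_results"
            )
        return [r.label for r in results]

    def evaluate(
        self,
        molecules: LabeledDataset,
        matrix: DescriptorMatrix | None = None,
        ablate: Iterable[str] = (),
    ) -> PerformanceReport:
        """Score a labeled set and tally the four performance measures."""
        results, failures = self.predict_results(molecules, matrix,
                                                 ablate=ablate)
        ok_ids = {r.id for r in results}
        truth = ["sensitizer" if r.is_sensitizer else "non-sensitizer"
                 for r in molecules if r.id in ok_ids]
        preds = [r.label for r in results]
        return compute_metrics(tally(preds, truth))

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for comp, variant in self.variants_.items():
            variant.save(directory / comp)
        write_dataset(self.reference_, directory / "reference.csv")
        scheme = get_scheme(self.scheme)
        with open(directory / "bundle.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {
                    "workflow": self.workflow,
                    "scheme": {
                        "name": scheme.name,
                        **{c: {d: scheme.weight(c, d)
                               for d in DIRECTIONS[c]}
                           for c in COMPONENTS},
                    },
                    "cutoff": self.cutoff,
                    "seed": self.seed,
                    "alerts": [
                        {"id": a.id, "smarts": a.smarts,
                         "mechanism": a.mechanism, "source": a.source}
                        for a in self.library_
                    ],
                },
                fh,
            )

    @classmethod
    def load(cls, directory: str | Path) -> "ConsensusWorkflow":
        directory = Path(directory)
        doc = yaml.safe_load((directory / "bundle.yaml").read_text())
        library = [Alert(**entry) for entry in doc["alerts"]]
        sdoc = doc["scheme"]
        scheme = WeightScheme(
            name=sdoc["name"],
            weights={(c, d): float(w) for c in COMPONENTS
                     for d, w in sdoc[c].items()},
        )
        obj = cls(workflow=doc["workflow"], scheme=scheme,
                  cutoff=doc["cutoff"], library=library, seed=doc["seed"])
        obj.library_ = library
        obj.variants_ = {
            comp: QSARVariantClassifier.load(directory / comp)
            for comp in ("m2", "m3", "m4")
        }
        obj.reference_ = load_dataset(directory / "reference.csv")
        obj.similarity_ = SimilarityComponent(cutoff=obj.cutoff).fit(
            obj.reference_)
        obj.substructure_ = SubstructureComponent(library=library).fit()
        return obj


def run_workflow(
    molecules: LabeledDataset | Sequence[MoleculeRecord],
    bundle: ConsensusWorkflow,
    matrix: DescriptorMatrix | None = None,
    ablate: Iterable[str] = (),
) -> tuple[list[ConsensusResult], list[WorkflowFailure]]:
    """Run a fitted workflow bundle over molecules (thin wrapper)."""
    return bundle.predict_results(molecules, matrix, ablate=ablate)
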