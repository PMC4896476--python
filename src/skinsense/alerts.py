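"""SMARTS alert library and the sub-structure component vote.

Sensitization begins with covalent modification of skin proteins, so the
presence of an electrophilic reactive group is strong evidence for a
sensitizer. A molecule matching any alert in the library votes +1; a
molecule matching none votes -1 (not 0), because the absence of a reactive
group argues actively against protein binding. Matched mechanisms (Michael
addition, Schiff base formation, acyl transfer, SN2, SNAr, ...) and atom
indices are reported so reactive groups can be highlighted.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from rdkit import Chem
from sklearn.base import BaseEstimator

from .chemio import MoleculeRecord
from .errors import (
    DuplicateIdError,
    EmptyLibraryError,
    FormatError,
    InvalidSmartsError,
)


@dataclass(frozen=True)
class Alert:
    """One reactive-group alert: a compiled SMARTS with a mechanism label."""

    id: str
    smarts: str
    mechanism: str
    source: str = ""

    def pattern(self) -> Chem.Mol:
        patt = Chem.MolFromSmarts(self.smarts)
        if patt is None:  # pragma: no cover - guarded at load time
            raise InvalidSmartsError(f"{self.id}: {self.smarts!r}")
        return patt


@dataclass
class AlertVerdict:
    """Sub-structure component vote: +1 iff any alert matched.

    ``matches`` lists (alert id, mechanism, matched atom index tuples), one
    entry per alert that matched, with every unique atom set reported.
    """

    score: int
    matches: list[tuple[str, str, tuple[tuple[int, ...], ...]]] = field(
        default_factory=list
    )

    @property
    def mechanisms(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, mech, _ in self.matches:
            seen.setdefault(mech)
        return list(seen)


def _build_library(entries: Iterable[dict]) -> list[Alert]:
    library: list[Alert] = []
    seen: set[str] = set()
    for entry in entries:
        alert = Alert(
            id=str(entry["id"]),
            smarts=str(entry["smarts"]),
            mechanism=str(entry.get("mechanism", "")),
            source=str(entry.get("source", "")),
        )
        if alert.id in seen:
            raise DuplicateIdError(f"duplicate alert id {alert.id!r}")
        seen.add(alert.id)
        if Chem.MolFromSmarts(alert.smarts) is None:
            raise InvalidSmartsError(
                f"alert {alert.id!r}: invalid SMARTS {alert.smarts!r}"
            )
        library.append(alert)
    return library


def load_alert_library(path: str | Path) -> list[Alert]:
    """Load an ordered alert library from YAML or CSV.

    YAML: top-level ``alerts:`` list of mappings with keys ``id``,
    ``smarts``, ``mechanism`` and optional ``source``. CSV: header row with
    the same column names. Every pattern is compiled at load time; an entry
    that does not compile raises :class:`InvalidSmartsError` naming the id.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if path.suffix.lower() in (".yaml", ".yml"):
        doc = yaml.safe_load(path.read_text(encoding="utf-8"))
        entries = doc.get("alerts", doc) if isinstance(doc, dict) else doc
        if not isinstance(entries, list):
            raise FormatError(f"{path}: expected a list of alert entries")
        return _build_library(entries)
    if path.suffix.lower() == ".csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "smarts" not in reader.fieldnames:
                raise FormatError(f"{path}: CSV needs 'id' and 'smarts' columns")
            return _build_library(list(reader))
    raise FormatError(f"unsupported alert library format: {path.suffix}")


def default_alert_library() -> list[Alert]:
    """The shipped reactive-group library (domain-standard SMARTS)."""
    ref = resources.files("skinsense.data") / "default_alerts.yaml"
    with resources.as_file(ref) as path:
        return load_alert_library(path)


class SubstructureComponent(BaseEstimator):
    """Alert-matching component of the prediction workflow.

    ``fit`` compiles the library (the default one when none is given);
    ``predict`` maps molecules to votes in {-1, +1}. Matching uses unique
    atom sets, so overlapping hits of one pattern count once per atom set.
    """

    def __init__(self, library: Sequence[Alert] | None = None):
        self.library = library

    def fit(self, X=None, y=None):
        lib = list(self.library) if self.library is not None \
            else default_alert_library()
        if not lib:
            raise EmptyLibraryError("alert library is empty")
        self.alerts_ = lib
        self.patterns_ = [a.pattern() for a in lib]
        return self

    def verdict(self, record: MoleculeRecord | str | Chem.Mol) -> AlertVerdict:
        if not hasattr(self, "alerts_"):
            self.fit()
        if isinstance(record, MoleculeRecord):
            mol = record.mol()
        elif isinstance(record, str):
            mol = Chem.MolFromSmiles(record)
            if mol is None:
                raise ValueError(f"invalid SMILES {record!r}")
        else:
            mol = record
        matches = []
        for alert, patt in zip(self.alerts_, self.patterns_):
            hits = mol.GetSubstructMatches(patt, uniquify=True)
            if hits:
                matches.append((alert.id, alert.mechanism, tuple(hits)))
        return AlertVerdict(score=1 if matches else -1, matches=matches)

    def predict(self, X: Iterable) -> list[int]:
        return [self.verdict(x).score for x in X]


def substructure_component(
    mol: MoleculeRecord | str, library: Sequence[Alert]
) -> AlertVerdict:
    """Score one molecule against an alert library (+1 match / -1 none)."""
    if not library:
        raise EmptyLibraryError("alert library is empty")
    return SubstructureComponent(library=library).fit().verdict(mol)
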