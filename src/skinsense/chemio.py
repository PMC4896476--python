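"""Molecule parsing, canonicalization and labeled-dataset I/O.

Molecules enter the workflow as SMILES strings (line lists or a CSV column)
or as SDF records. Each is sanitized and canonicalized with RDKit, assigned
an InChIKey for exact-identity checks, and tagged with a skin-sensitization
potency class: Extreme (X), Strong (St), unknown-potency sensitizer (S),
Moderate (M), Weak (W) or non-sensitizer (N). Prediction-time molecules
carry the UNKNOWN label.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem  # noqa: F401  (registers SDF property tooling)

from .errors import DuplicateError, FormatError, LabelError, ParseError

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

#: Allowed potency vocabulary. Any class except N counts as a sensitizer.
POTENCY_CLASSES = ("X", "St", "S", "M", "W", "N")
UNKNOWN = "UNKNOWN"

_INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")


@dataclass(frozen=True)
class MoleculeRecord:
    """One labeled molecule.

    Attributes
    ----------
    id : str
        Opaque identifier, preserved verbatim from the input.
    smiles_input : str
        The structure string as supplied.
    smiles_canonical : str
        RDKit canonical SMILES; canonicalizing twice is the identity.
    inchikey : str
        27-character hashed structure key used for exact identity checks.
    potency : str
        One of ``X, St, S, M, W, N`` or ``UNKNOWN`` for unlabeled molecules.
    cas : str or None
        Optional CAS registry number.
    source : str
        Free-text provenance tag.
    """

    id: str
    smiles_input: str
    smiles_canonical: str
    inchikey: str
    potency: str = UNKNOWN
    cas: str | None = None
    source: str = ""

    @property
    def is_sensitizer(self) -> bool:
        """True for any potency class except N; undefined label raises."""
        if self.potency == UNKNOWN:
            raise LabelError(f"record {self.id!r} has no potency label")
        return self.potency != "N"

    def mol(self) -> Chem.Mol:
        """Return the RDKit molecule for the canonical structure."""
        return Chem.MolFromSmiles(self.smiles_canonical)


def _check_potency(potency: str | None) -> str:
    if potency is None or potency == "" or potency == UNKNOWN:
        return UNKNOWN
    if potency not in POTENCY_CLASSES:
        raise LabelError(
            f"potency {potency!r} not in {POTENCY_CLASSES} or UNKNOWN"
        )
    return potency


def parse_molecule(
    smiles: str,
    id: str,
    potency: str | None = None,
    cas: str | None = None,
    source: str = "",
) -> MoleculeRecord:
    """Parse a SMILES string into a validated, canonicalized record.

    Raises
    ------
    ParseError
        If the SMILES is syntactically or chemically invalid (mirrors the
        exclusion of molecules that fail structure conversion upstream of
        model building).
    LabelError
        If the potency label is outside the allowed vocabulary.
    """
    if not smiles or not smiles.strip():
        raise ParseError("empty SMILES string")
    potency = _check_potency(potency)
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"invalid SMILES for {id!r}: {smiles!r}")
    canonical = Chem.MolToSmiles(mol)
    inchikey = Chem.MolToInchiKey(mol)
    if not inchikey or not _INCHIKEY_RE.match(inchikey):
        raise ParseError(f"could not derive InChIKey for {id!r}: {smiles!r}")
    return MoleculeRecord(
        id=id,
        smiles_input=smiles,
        smiles_canonical=canonical,
        inchikey=inchikey,
        potency=potency,
        cas=cas or None,
        source=source,
    )


def is_identical(a: MoleculeRecord, b: MoleculeRecord) -> bool:
    """Exact structural identity: full 27-character InChIKey equality."""
    if not a.inchikey or not b.inchikey:
        raise ValueError("both records must have an InChIKey")
    return a.inchikey == b.inchikey


@dataclass
class LabeledDataset:
    """An ordered, deduplicated collection of molecule records.

    Invariants: no two records share an InChIKey, and no two records share a
    non-empty CAS number. ``skipped`` counts input rows dropped for parse
    failure or structural duplication.
    """

    records: list[MoleculeRecord] = field(default_factory=list)
    name: str = ""
    skipped: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[MoleculeRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> MoleculeRecord:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.potency] = counts.get(r.potency, 0) + 1
        return counts

    def subset(self, ids: Iterable[str], name: str = "") -> "LabeledDataset":
        wanted = set(ids)
        return LabeledDataset(
            records=[r for r in self.records if r.id in wanted],
            name=name or self.name,
        )

    def with_potency(self, *classes: str) -> list[MoleculeRecord]:
        return [r for r in self.records if r.potency in classes]

    def binary_labels(self) -> list[int]:
        """+1 for sensitizers (any class but N), -1 for non-sensitizers."""
        return [1 if r.is_sensitizer else -1 for r in self.records]


def build_dataset(
    records: Iterable[MoleculeRecord], name: str = "", skipped: int = 0
) -> LabeledDataset:
    """Assemble a dataset, deduplicating on InChIKey and validating CAS.

    The first record with a given InChIKey wins; later structural duplicates
    are dropped and counted in ``skipped``. Two records sharing a CAS but
    differing in structure raise :class:`DuplicateError` — CAS uniqueness is
    a curation criterion, so a conflict signals corrupt input rather than a
    harmless repeat.
    """
    seen_keys: set[str] = set()
    cas_to_key: dict[str, str] = {}
    kept: list[MoleculeRecord] = []
    for rec in records:
        if rec.cas:
            prior = cas_to_key.get(rec.cas)
            if prior is not None and prior != rec.inchikey:
                raise DuplicateError(
                    f"CAS {rec.cas} maps to two different structures"
                )
            cas_to_key[rec.cas] = rec.inchikey
        if rec.inchikey in seen_keys:
            skipped += 1
            logger.warning("dropping structural duplicate %s", rec.id)
            continue
        seen_keys.add(rec.inchikey)
        kept.append(rec)
    return LabeledDataset(records=kept, name=name, skipped=skipped)


def _parse_rows(
    rows: Iterable[tuple[str, str, str | None, str | None]],
    name: str,
    source: str,
) -> LabeledDataset:
    records: list[MoleculeRecord] = []
    skipped = 0
    for mol_id, smiles, cas, potency in rows:
        try:
            records.append(
                parse_molecule(smiles, mol_id, potency, cas, source=source)
            )
        except ParseError as exc:
            skipped += 1
            logger.warning("skipping unparsable row %s: %s", mol_id, exc)
    ds = build_dataset(records, name=name, skipped=skipped)
    if ds.skipped:
        logger.warning("%s: skipped %d rows", name, ds.skipped)
    return ds


def load_dataset(
    path: str | Path,
    format: str | None = None,
    name: str | None = None,
    sdf_potency_property: str = "potency",
) -> LabeledDataset:
    """Load a labeled dataset from a SMILES list, CSV or SDF file.

    ``format`` is one of ``smiles-list``, ``csv``, ``sdf``; when omitted it
    is inferred from the suffix (.smi/.txt, .csv, .sdf). Rows that fail to
    parse are skipped with a logged warning and counted, mirroring the
    exclusion of molecules that fail structure conversion.

    CSV dialect: UTF-8, header row required, columns ``id``, ``smiles``,
    optional ``cas`` and ``potency``. SMILES lists: whitespace-separated
    ``smiles [id [potency]]`` per line. SDF: V2000, potency read from the
    property named by ``sdf_potency_property``.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format is None:
        format = {
            ".smi": "smiles-list",
            ".txt": "smiles-list",
            ".csv": "csv",
            ".sdf": "sdf",
        }.get(path.suffix.lower())
        if format is None:
            raise FormatError(f"cannot infer format from suffix: {path}")
    name = name or path.stem

    if format == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "smiles" not in reader.fieldnames:
                raise FormatError(f"{path}: CSV needs a header with 'smiles'")
            if "id" not in reader.fieldnames:
                raise FormatError(f"{path}: CSV needs an 'id' column")
            rows = [
                (
                    row["id"],
                    row["smiles"],
                    row.get("cas") or None,
                    row.get("potency") or None,
                )
                for row in reader
            ]
        return _parse_rows(rows, name, source=str(path))

    if format == "smiles-list":
        rows = []
        with open(path, encoding="utf-8") as fh:
            for i, line in enumerate(fh):
                parts = line.split()
                if not parts or parts[0].startswith("#"):
                    continue
                smiles = parts[0]
                mol_id = parts[1] if len(parts) > 1 else f"{name}-{i + 1}"
                potency = parts[2] if len(parts) > 2 else None
                rows.append((mol_id, smiles, None, potency))
        return _parse_rows(rows, name, source=str(path))

    if format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        records: list[MoleculeRecord] = []
        skipped = 0
        for i, mol in enumerate(supplier):
            if mol is None:
                skipped += 1
                logger.warning("skipping unreadable SDF record %d", i)
                continue
            mol_id = (
                mol.GetProp("_Name")
                if mol.HasProp("_Name") and mol.GetProp("_Name")
                else f"{name}-{i + 1}"
            )
            potency = (
                mol.GetProp(sdf_potency_property)
                if mol.HasProp(sdf_potency_property)
                else None
            )
            cas = mol.GetProp("cas") if mol.HasProp("cas") else None
            try:
                records.append(
                    parse_molecule(
                        Chem.MolToSmiles(mol), mol_id, potency, cas,
                        source=str(path),
                    )
                )
            except (ParseError, LabelError) as exc:
                skipped += 1
                logger.warning("skipping SDF record %s: %s", mol_id, exc)
        return build_dataset(records, name=name, skipped=skipped)

    raise FormatError(f"unknown format {format!r}")


def write_dataset(dataset: LabeledDataset, path: str | Path,
                  format: str | None = None) -> None:
    """Write a dataset as CSV, SMILES list or SDF (inferred from suffix)."""
    path = Path(path)
    if format is None:
        format = {
            ".smi": "smiles-list",
            ".txt": "smiles-list",
            ".csv": "csv",
            ".sdf": "sdf",
        }.get(path.suffix.lower())
        if format is None:
            raise FormatError(f"cannot infer format from suffix: {path}")
    if format == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "smiles", "cas", "potency"])
            for r in dataset:
                writer.writerow(
                    [r.id, r.smiles_canonical, r.cas or "",
                     "" if r.potency == UNKNOWN else r.potency]
                )
    elif format == "smiles-list":
        with open(path, "w", encoding="utf-8") as fh:
            for r in dataset:
                line = f"{r.smiles_canonical} {r.id}"
                if r.potency != UNKNOWN:
                    line += f" {r.potency}"
                fh.write(line + "\n")
    elif format == "sdf":
        writer = Chem.SDWriter(str(path))
        try:
            for r in dataset:
                mol = r.mol()
                mol.SetProp("_Name", r.id)
                if r.potency != UNKNOWN:
                    mol.SetProp("potency", r.potency)
                if r.cas:
                    mol.SetProp("cas", r.cas)
                writer.write(mol)
        finally:
            writer.close()
    else:
        raise FormatError(f"unknown format {format!r}")


def relabel(record: MoleculeRecord, potency: str) -> MoleculeRecord:
    """Return a copy of ``record`` with a new (validated) potency label."""
    return replace(record, potency=_check_potency(potency))
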