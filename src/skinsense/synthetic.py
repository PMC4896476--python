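"""Synthetic labeled molecule sets and descriptor tables.

Desk-scale stand-ins for the curated sensitization datasets: sensitizers
are built by grafting a reactive (electrophilic) fragment drawn from the
alert library onto a randomly chosen drug-like scaffold, non-sensitizers
use the same scaffolds with inert substituents only. The class structure
(sensitizer prevalence, potency mix) defaults to the proportions of the
curated parent set. Descriptor tables with class-separated means exercise
the t-test selection and classifier stages without any chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem

from .alerts import Alert, default_alert_library
from .chemio import LabeledDataset, MoleculeRecord, parse_molecule
from .errors import GenerationError, ParseError
from .features import DescriptorMatrix
from .qsar import DEFAULT_SEED

#: Scaffold templates: {x} receives the class-determining substituent and
#: {r} an inert decoration, giving combinatorial fingerprint diversity.
SCAFFOLD_TEMPLATES: tuple[str, ...] = (
    "c1ccc({x})c({r})c1",
    "c1cc({x})ccc1{r}",
    "c1cc({x})cc({r})c1",
    "C1CCC({x})C({r})C1",
    "c1ccc2cc({x})c({r})cc2c1",
    "c1ccnc({x})c1{r}",
    "C1CCN(C1)C({x}){r}",
    "c1csc({x})c1{r}",
    "c1coc({x})c1{r}",
    "C1CCOC1({x}){r}",
    "C1CCCCC1({x}){r}",
    "c1cnc({x})nc1{r}",
    "c1ccc(N({x}){r})cc1",
    "C1CCCC1({x}){r}",
    "C({x})({r})CCO",
    "CC(C)C({x}){r}",
    "c1ccc(OC({x}){r})cc1",
    "C1CC1C({x}){r}",
    "c1ccc(CC({x}){r})cc1",
    "C1COCCN1C({x}){r}",
    "C1CCNCC1C({x}){r}",
    "c1ccc(S(=O)(=O)N({r})C{x})cc1",
    "CC({x})({r})CC",
    "c1ccc(C({x})({r})O)cc1",
    "C1CCC(CC1)OC({x}){r}",
    "c1ccc(-c2ccc({x})cc2{r})cc1",
)

#: Inert substituents: no entry matches any default alert.
INERT_SUBSTITUENTS: tuple[str, ...] = (
    "C", "CC", "CCC", "CCCC", "C(C)C", "C(C)(C)C", "OC", "CO", "CCO",
    "OCC", "CN", "N(C)C", "CCN", "CC(C)O", "COC",
)

#: Reactive fragments keyed by the alert id they plant.
PLANTABLE_FRAGMENTS: dict[str, str] = {
    "michael_acceptor_enone": "C(=O)C=C",
    "aldehyde_schiff": "C=O",
    "acyl_halide": "C(=O)Cl",
    "alkyl_halide_sn2": "CBr",
    "epoxide": "CC5OC5",
    "isocyanate": "N=C=O",
}

#: Sensitizer potency proportions mirroring the curated parent set
#: (X:18, St:32, S:206, M:90, W:74 of 420 sensitizers).
PARENT_POTENCY_MIX: dict[str, float] = {
    "X": 18 / 420, "St": 32 / 420, "S": 206 / 420,
    "M": 90 / 420, "W": 74 / 420,
}

#: Sensitizer prevalence of the curated parent set (420 of 571).
PARENT_PREVALENCE = 420 / 571


@dataclass
class BenchmarkSpec:
    """Recipe for one synthetic benchmark dataset."""

    n: int = 400
    prevalence: float = PARENT_PREVALENCE
    planted_alerts: tuple[str, ...] = tuple(PLANTABLE_FRAGMENTS)
    potency_mix: dict[str, float] = field(
        default_factory=lambda: dict(PARENT_POTENCY_MIX))
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        total = sum(self.potency_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"potency_mix sums to {total}, expected 1")
        unknown = set(self.potency_mix) - {"X", "St", "S", "M", "W"}
        if unknown:
            raise ValueError(f"unknown potency classes {sorted(unknown)}")


def _largest_remainder(total: int, proportions: Sequence[float]) -> list[int]:
    raw = [p * total for p in proportions]
    counts = [int(x) for x in raw]
    rest = total - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i],
                   reverse=True)
    for i in order[:rest]:
        counts[i] += 1
    return counts


def generate_benchmark(
    spec: BenchmarkSpec,
    library: Sequence[Alert] | None = None,
    max_retries: int = 10,
) -> LabeledDataset:
    """Generate a labeled benchmark of grafted-scaffold molecules.

    Every sensitizer carries at least one planted reactive fragment (and so
    matches its alert); every non-sensitizer matches no alert in the
    library. Structures are unique by InChIKey; each molecule gets up to
    ``max_retries`` graft attempts before :class:`GenerationError`.
    """
    library = list(library) if library is not None else \
        default_alert_library()
    by_id = {a.id: a for a in library}
    missing = [a for a in spec.planted_alerts if a not in by_id]
    if missing:
        raise GenerationError(f"planted alerts not in library: {missing}")
    unknown_frag = [a for a in spec.planted_alerts
                    if a not in PLANTABLE_FRAGMENTS]
    if unknown_frag:
        raise GenerationError(
            f"no graftable fragment for alert(s) {unknown_frag}")
    patterns = [(a.id, a.pattern()) for a in library]
    planted_patterns = {a: by_id[a].pattern() for a in spec.planted_alerts}

    rng = np.random.default_rng(spec.seed)
    n_sens = round(spec.prevalence * spec.n)
    classes = list(spec.potency_mix)
    class_counts = _largest_remainder(
        n_sens, [spec.potency_mix[c] for c in classes])
    plan: list[tuple[str, str | None]] = []  # (potency, planted alert id)
    for cls, count in zip(classes, class_counts):
        for _ in range(count):
            alert_id = spec.planted_alerts[
                int(rng.integers(len(spec.planted_alerts)))]
            plan.append((cls, alert_id))
    plan += [("N", None)] * (spec.n - n_sens)

    seen_keys: set[str] = set()
    records: list[MoleculeRecord] = []
    for i, (potency, alert_id) in enumerate(plan):
        record = None
        for _ in range(max_retries):
            template = SCAFFOLD_TEMPLATES[
                int(rng.integers(len(SCAFFOLD_TEMPLATES)))]
            r = INERT_SUBSTITUENTS[
                int(rng.integers(len(INERT_SUBSTITUENTS)))]
            x = (PLANTABLE_FRAGMENTS[alert_id] if alert_id is not None
                 else INERT_SUBSTITUENTS[
                     int(rng.integers(len(INERT_SUBSTITUENTS)))])
            smiles = template.format(x=x, r=r)
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                continue
            if alert_id is not None:
                if not mol.HasSubstructMatch(planted_patterns[alert_id]):
                    continue
            elif any(mol.HasSubstructMatch(p) for _, p in patterns):
                continue
            try:
                candidate = parse_molecule(
                    smiles, id=f"syn-{i + 1:04d}", potency=potency,
                    source="synthetic-benchmark",
                )
            except ParseError:
                continue
            if candidate.inchikey in seen_keys:
                continue
            record = candidate
            break
        if record is None:
            raise GenerationError(
                f"could not build molecule {i + 1} ({potency}) in "
                f"{max_retries} attempts"
            )
        seen_keys.add(record.inchikey)
        records.append(record)
    return LabeledDataset(records=records, name=f"synthetic-n{spec.n}")


def generate_descriptor_table(
    n_per_class: int,
    p_features: int,
    n_informative: int,
    effect: float,
    seed: int = DEFAULT_SEED,
) -> tuple[DescriptorMatrix, np.ndarray]:
    """Gaussian descriptor table with ``n_informative`` separated features.

    Informative columns have class means 0 and ``effect`` (in units of the
    within-class standard deviation, which is 1); the remaining columns are
    pure noise. Labels are -1 (first ``n_per_class`` rows) and +1.
    """
    if n_informative > p_features:
        raise ValueError("n_informative exceeds p_features")
    if effect < 0:
        raise ValueError("effect must be non-negative")
    if n_per_class < 2:
        raise ValueError("need at least 2 molecules per class")
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    values = rng.standard_normal((n, p_features))
    values[n_per_class:, :n_informative] += effect
    labels = np.array([-1] * n_per_class + [1] * n_per_class)
    matrix = DescriptorMatrix(
        row_ids=[f"row-{i + 1:04d}" for i in range(n)],
        feature_names=[f"f{j + 1:04d}" for j in range(p_features)],
        values=values,
        feature_group={f"f{j + 1:04d}": "A" for j in range(p_features)},
    )
    return matrix, labels
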