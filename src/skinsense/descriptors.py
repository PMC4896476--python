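"""Pluggable molecular descriptor computation.

The full published descriptor engine (hundreds of 2D/3D descriptors plus
thousands of fingerprint bits) is treated as a pluggable provider: any
callable mapping an RDKit molecule to a name→value dict can stand in. The
built-in provider ships a compact 2D set — atom/bond/ring counts, polarity
and lipophilicity surrogates — sufficient for end-to-end runs and testing.
Alert libraries double as sub-structure fingerprint generators, yielding the
0/1 reactive-group columns (group B) and literature mechanism columns
(group C) of the descriptor matrix.
"""

from __future__ import annotations

from typing import Callable, Mapping, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

from .alerts import Alert
from .chemio import LabeledDataset
from .features import DescriptorMatrix

DescriptorProvider = Callable[[Chem.Mol], Mapping[str, float]]

_BUILTIN: list[tuple[str, Callable[[Chem.Mol], float]]] = [
    ("MolWt", Descriptors.MolWt),
    ("MolLogP", Crippen.MolLogP),
    ("MolMR", Crippen.MolMR),
    ("TPSA", rdMolDescriptors.CalcTPSA),
    ("NumHBD", rdMolDescriptors.CalcNumHBD),
    ("NumHBA", rdMolDescriptors.CalcNumHBA),
    ("NumRotatableBonds", rdMolDescriptors.CalcNumRotatableBonds),
    ("NumRings", rdMolDescriptors.CalcNumRings),
    ("NumAromaticRings", rdMolDescriptors.CalcNumAromaticRings),
    ("NumHeteroatoms", rdMolDescriptors.CalcNumHeteroatoms),
    ("FractionCSP3", rdMolDescriptors.CalcFractionCSP3),
    ("HeavyAtomCount", lambda m: float(m.GetNumHeavyAtoms())),
    ("NumAtomsO", lambda m: float(sum(1 for a in m.GetAtoms()
                                      if a.GetSymbol() == "O"))),
    ("NumAtomsN", lambda m: float(sum(1 for a in m.GetAtoms()
                                      if a.GetSymbol() == "N"))),
    ("NumAtomsHalogen", lambda m: float(sum(1 for a in m.GetAtoms()
                                            if a.GetSymbol() in
                                            ("F", "Cl", "Br", "I")))),
    ("NumAtomsS", lambda m: float(sum(1 for a in m.GetAtoms()
                                      if a.GetSymbol() == "S"))),
    ("NumDoubleBonds", lambda m: float(sum(
        1 for b in m.GetBonds()
        if b.GetBondType() == Chem.BondType.DOUBLE))),
    ("NumTripleBonds", lambda m: float(sum(
        1 for b in m.GetBonds()
        if b.GetBondType() == Chem.BondType.TRIPLE))),
    ("BalabanJ", Descriptors.BalabanJ),
    ("BertzCT", Descriptors.BertzCT),
]


def builtin_provider(mol: Chem.Mol) -> dict[str, float]:
    """The built-in 2D descriptor set (20 descriptors)."""
    return {name: float(fn(mol)) for name, fn in _BUILTIN}


def compute_descriptor_matrix(
    dataset: LabeledDataset,
    provider: DescriptorProvider = builtin_provider,
    reactive_alerts: Sequence[Alert] = (),
    literature_alerts: Sequence[Alert] = (),
) -> DescriptorMatrix:
    """Compute descriptors (group A) and alert fingerprint bits (B/C).

    ``reactive_alerts`` become group-B columns named ``B:<alert id>`` and
    ``literature_alerts`` group-C columns named ``C:<alert id>``; each holds
    1 when the molecule matches the alert's SMARTS and 0 otherwise.
    """
    b_patterns = [(f"B:{a.id}", a.pattern()) for a in reactive_alerts]
    c_patterns = [(f"C:{a.id}", a.pattern()) for a in literature_alerts]

    rows: list[list[float]] = []
    names: list[str] | None = None
    for record in dataset:
        mol = record.mol()
        values = dict(provider(mol))
        desc_names = list(values)
        if names is None:
            names = desc_names + [n for n, _ in b_patterns + c_patterns]
        row = [values[n] for n in desc_names]
        for _, patt in b_patterns + c_patterns:
            row.append(1.0 if mol.HasSubstructMatch(patt) else 0.0)
        rows.append(row)
    if names is None:
        raise ValueError("dataset is empty")

    groups = {n: "A" for n in names[: len(names) - len(b_patterns)
                                    - len(c_patterns)]}
    groups.update({n: "B" for n, _ in b_patterns})
    groups.update({n: "C" for n, _ in c_patterns})
    return DescriptorMatrix(
        row_ids=dataset.ids,
        feature_names=names,
        values=np.array(rows, dtype=float),
        feature_group=groups,
    )
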