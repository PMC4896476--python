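"""Path-based fingerprints, Tanimoto similarity and the similarity vote.

The similarity component embodies the similar-property principle: a test
molecule that closely resembles a known sensitizer is itself suspect. Each
molecule is hashed into a fixed-length path-based fingerprint (linear paths
of 1-7 bonds, 1024 bits — the widely available equivalent of OpenBabel's
FP2), and compared against a labeled reference set with the Tanimoto
coefficient |A∩B| / |A∪B|. A test molecule votes +1 when its most similar
reference neighbors (at coefficient >= 0.6) are all sensitizers, -1 when all
non-sensitizers, and 0 when it fails the cutoff or both classes tie at the
maximum. A coefficient of exactly 1.0 triggers an InChIKey check to confirm
the structures are indeed identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from rdkit import Chem
from sklearn.base import BaseEstimator

from .chemio import LabeledDataset, MoleculeRecord, is_identical
from .errors import EmptyReferenceError, LengthMismatchError

#: Similarity cutoff: coefficient >= 0.6 (60% similarity) counts as similar.
DEFAULT_CUTOFF = 0.6


@dataclass(frozen=True)
class FingerprintBits:
    """Fixed-length fingerprint bit set for one molecule."""

    molecule_id: str
    bits: frozenset[int]
    length: int = 1024

    @property
    def n_set(self) -> int:
        return len(self.bits)


def path_fingerprint(
    record: MoleculeRecord | str | Chem.Mol,
    n_bits: int = 1024,
    max_path: int = 7,
    molecule_id: str = "",
) -> FingerprintBits:
    """Hashed linear-path fingerprint (paths of 1..max_path bonds)."""
    if isinstance(record, MoleculeRecord):
        mol, molecule_id = record.mol(), record.id
    elif isinstance(record, str):
        mol = Chem.MolFromSmiles(record)
        if mol is None:
            raise ValueError(f"invalid SMILES {record!r}")
    else:
        mol = record
    fp = Chem.RDKFingerprint(mol, minPath=1, maxPath=max_path, fpSize=n_bits)
    return FingerprintBits(
        molecule_id=molecule_id,
        bits=frozenset(fp.GetOnBits()),
        length=n_bits,
    )


def tanimoto(a: FingerprintBits, b: FingerprintBits) -> float:
    """Tanimoto coefficient |a ∧ b| / |a ∨ b| in [0, 1].

    Two empty fingerprints are defined as maximally similar (1.0): both
    structures are featureless at this resolution.
    """
    if a.length != b.length:
        raise LengthMismatchError(
            f"fingerprint lengths differ: {a.length} != {b.length}"
        )
    union = len(a.bits | b.bits)
    if union == 0:
        return 1.0
    return len(a.bits & b.bits) / union


@dataclass
class SimilarityVerdict:
    """Similarity component vote with its supporting evidence.

    ``score`` is +1/-1/0; ``direction`` spells out the provenance needed to
    look up the weight: ``S`` (nearest neighbors all sensitizers), ``N``
    (all non-sensitizers), ``NS`` (both classes tie at the maximum) or
    ``NoMatch`` (best coefficient below the cutoff). ``neighbors`` holds
    (reference id, reference class, coefficient) sorted by coefficient
    descending.
    """

    score: int
    direction: str
    best_coefficient: float
    neighbors: list[tuple[str, str, float]] = field(default_factory=list)
    identical_match: str | None = None


class SimilarityComponent(BaseEstimator):
    """Similarity component of the prediction workflow.

    ``fit`` stores and fingerprints the labeled reference set; ``verdict``
    scores one test molecule and ``predict`` maps molecules to votes in
    {-1, 0, +1}.
    """

    def __init__(
        self,
        cutoff: float = DEFAULT_CUTOFF,
        fingerprint: Callable[..., FingerprintBits] = path_fingerprint,
    ):
        self.cutoff = cutoff
        self.fingerprint = fingerprint

    def fit(self, reference: LabeledDataset, y=None):
        if len(reference) == 0:
            raise EmptyReferenceError("reference set is empty")
        self.reference_ = reference
        self.reference_fps_ = [self.fingerprint(r) for r in reference]
        return self

    def verdict(self, test: MoleculeRecord | str) -> SimilarityVerdict:
        if isinstance(test, str):
            from .chemio import parse_molecule

            test = parse_molecule(test, id="query")
        fp = self.fingerprint(test)
        coeffs = np.array(
            [tanimoto(fp, ref_fp) for ref_fp in self.reference_fps_]
        )
        order = np.argsort(-coeffs, kind="stable")
        neighbors = [
            (
                self.reference_[int(i)].id,
                self.reference_[int(i)].potency,
                float(coeffs[int(i)]),
            )
            for i in order
            if coeffs[int(i)] >= self.cutoff
        ]
        best = float(coeffs.max()) if len(coeffs) else 0.0
        if best < self.cutoff:
            return SimilarityVerdict(
                score=0, direction="NoMatch", best_coefficient=best,
                neighbors=neighbors,
            )
        at_max = [int(i) for i in np.flatnonzero(coeffs == best)]
        top_classes = {self.reference_[i].is_sensitizer for i in at_max}
        identical = None
        if best == 1.0:
            for i in at_max:
                if is_identical(test, self.reference_[i]):
                    identical = self.reference_[i].id
                    break
        if top_classes == {True}:
            score, direction = 1, "S"
        elif top_classes == {False}:
            score, direction = -1, "N"
        else:  # both classes attain the maximal coefficient
            score, direction = 0, "NS"
        return SimilarityVerdict(
            score=score, direction=direction, best_coefficient=best,
            neighbors=neighbors, identical_match=identical,
        )

    def predict(self, X: Iterable) -> list[int]:
        return [self.verdict(x).score for x in X]


def similarity_component(
    test: MoleculeRecord,
    reference: LabeledDataset,
    cutoff: float = DEFAULT_CUTOFF,
) -> SimilarityVerdict:
    """Score one molecule against a labeled reference set."""
    return SimilarityComponent(cutoff=cutoff).fit(reference).verdict(test)


def pairwise_tanimoto(fps: Sequence[FingerprintBits]) -> np.ndarray:
    """Symmetric matrix of Tanimoto coefficients (1.0 on the diagonal)."""
    n = len(fps)
    out = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = tanimoto(fps[i], fps[j])
    return out
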