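# skinsense

Integrated computational prediction of the skin-sensitization potential of
small molecules.

Skin sensitization — an allergic immune response to topical exposure — is a
key toxicological endpoint for cosmetic and dermatological ingredients, and
animal assays (LLNA, GPMT) are increasingly restricted. `skinsense`
implements an integrated in-silico workflow for the people who screen such
molecules: it combines **potency-stratified QSAR classifiers**, **structural
similarity to known sensitizers and non-sensitizers**, and **SMARTS alerts
for skin-protein reactive groups** into a weighted knowledge-based consensus
that labels each molecule *sensitizer*, *non-sensitizer* or *indeterminate*.

## The model

Three binary QSAR models (m₂, m₃, m₄) contrast different sensitizer potency
classes — Extreme/Strong/unknown (m₂), Moderate (m₃) and Weak (m₄) — against
non-sensitizers. Each is trained as a *variant* coded
`<model><split><set><classifier>` (e.g. `2C4RF`: model-2, 10-fold
cross-validation, descriptor set-4, 100-tree random forest), where the
descriptor sets combine t-test-selected descriptors [A] with
reactive-group [B] and literature mechanism [C] fingerprints, reduced by
correlation-based feature selection (CFS) with best-first search:

    merit(S) = k·r̄_cf / √(k + k(k−1)·r̄_ff)

Each component votes mᵢ, s_similarity, s_substr ∈ {−1, 0, +1} and the
consensus is the weighted sum

    Score = m₂·w_m2 + m₃·w_m3 + m₄·w_m4
          + s_similarity·w_similarity + s_substr·w_substr

with direction-specific weights (schemes KB-a…KB-d). Score > 0 ⇒
sensitizer, < 0 ⇒ non-sensitizer, = 0 ⇒ indeterminate. The similarity vote
uses path-based fingerprints and a Tanimoto cutoff of 0.6; an exact match
(coefficient 1.0) is confirmed by InChIKey identity. A molecule matching
any electrophilic alert (Michael acceptor, Schiff-base former,
acyl-transfer agent, SN2/SNAr electrophile, …) votes +1, else −1.
Performance is reported as sensitivity, specificity, accuracy and CCR
(mean of sensitivity and specificity), with indeterminate calls excluded
from denominators and counted separately.

## Worked example

Train a PW-2 workflow bundle on a synthetic benchmark (sensitizers carry
planted electrophilic fragments on drug-like scaffolds) and evaluate the
held-out fifth:

```python
from skinsense import BenchmarkSpec, ConsensusWorkflow, generate_benchmark
from skinsense.qsar import split

dataset = generate_benchmark(BenchmarkSpec(n=400, seed=7))
sp = split(dataset, "S", seed=11)          # per-class 80/20
train, test = dataset.subset(sp.train_ids), dataset.subset(sp.test_ids)

workflow = ConsensusWorkflow(workflow="PW-2", scheme="KB-b", seed=3)
workflow.fit(train)

report = workflow.evaluate(test)
print("held-out performance:", report.rounded(),
      "indeterminate:", report.n_indeterminate)

results, failures = workflow.predict_results(test.records[:3])
for r in results:
    votes = {c.component: c.value for c in r.components}
    print(f"{r.id}: score={r.score:+.1f} label={r.label} votes={votes}")
```

which prints:

```
held-out performance: {'sensitivity': 100.0, 'specificity': 100.0, 'accuracy': 100.0, 'ccr': 100.0} indeterminate: 0
syn-0001: score=+3.1 label=sensitizer votes={'m2': 1, 'm3': 1, 'm4': 1, 'similarity': 0, 'substructure': 1}
syn-0005: score=+4.1 label=sensitizer votes={'m2': 1, 'm3': 1, 'm4': 1, 'similarity': 1, 'substructure': 1}
syn-0006: score=+4.1 label=sensitizer votes={'m2': 1, 'm3': 1, 'm4': 1, 'similarity': 1, 'substructure': 1}
```

The first molecule scores +3.1 under KB-b: all three QSAR votes agree
(+1·1 + 1·0.8 + 1·0.3), the similarity component found no neighbor at
Tanimoto ≥ 0.6 (contributes 0), and a reactive substructure is present
(+1·1). The planted alerts make the synthetic task nearly separable, so the
held-out metrics sit at 100%.

The same pipeline is available from the shell:

```sh
skinsense train-workflow --train train.csv --bundle bundle/
skinsense predict --in query.smi --bundle bundle/ --out results.csv
skinsense evaluate --in labeled.csv --bundle bundle/
skinsense ablate --in labeled.csv --bundle bundle/
```

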