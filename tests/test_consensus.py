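from itertools import product

import numpy as np
import pytest

from skinsense import (
    ComponentScore,
    ConsensusWorkflow,
    MetaIntegrator,
    WeightScheme,
    consensus_score,
    lookup_weight,
    run_workflow,
)
from skinsense.consensus import BUILTIN_SCHEMES, DIRECTIONS, qsar_score
from skinsense.errors import (
    DegenerateInputError,
    IncompleteComponentsError,
    UnknownSchemeError,
)


def votes(m2, m3, m4, sim_value, sim_dir, sub):
    return [
        qsar_score("m2", m2),
        qsar_score("m3", m3),
        qsar_score("m4", m4),
        ComponentScore("similarity", sim_value, sim_dir),
        ComponentScore("substructure", sub,
                       "Present" if sub > 0 else "Absent"),
    ]


SIM_STATES = [(1, "S"), (-1, "N"), (0, "NS"), (0, "NoMatch")]


class TestWeightLookup:
    @pytest.mark.parametrize("scheme,component,direction,expected", [
        ("KB-a", "substructure", "Absent", 0.5),
        ("KB-b", "m3", "S", 0.8),
        ("KB-b", "similarity", "NoMatch", 0.0),
        ("KB-a", "m2", "N", 1.0),
        ("KB-c", "m3", "S", 0.6),
        ("KB-d", "m3", "N", 0.3),
    ])
    def test_tabulated_weights(self, scheme, component, direction, expected):
        assert lookup_weight(scheme, component, direction) == expected

    def test_unknown_scheme_raises(self):
        with pytest.raises(UnknownSchemeError):
            lookup_weight("KB-z", "m2", "S")

    def test_incomplete_custom_scheme_raises(self):
        with pytest.raises(UnknownSchemeError):
            WeightScheme(name="partial", weights={("m2", "S"): 1.0})


class TestConsensusScore:
    def test_all_sensitizer_direction_hand_sum(self):
        r = consensus_score(votes(1, 1, 1, 1, "S", 1), "KB-b")
        assert r.score == pytest.approx(4.1)
        assert r.label == "sensitizer"

    def test_all_nonsensitizer_direction_hand_sum(self):
        r = consensus_score(votes(-1, -1, -1, 0, "NoMatch", -1), "KB-b")
        assert r.score == pytest.approx(-2.1)
        assert r.label == "non-sensitizer"

    def test_exact_cancellation_is_indeterminate(self):
        weights = {(c, d): 0.0 for c in DIRECTIONS for d in DIRECTIONS[c]}
        weights[("m2", "S")] = 1.0
        weights[("m3", "N")] = 1.0
        scheme = WeightScheme(name="cancel", weights=weights)
        r = consensus_score(votes(1, -1, 1, 0, "NoMatch", 1), scheme)
        assert r.score == 0.0
        assert r.label == "indeterminate"

    def test_missing_component_raises(self):
        with pytest.raises(IncompleteComponentsError):
            consensus_score(votes(1, 1, 1, 1, "S", 1)[:4], "KB-b")

    def test_qsar_vote_of_zero_rejected(self):
        with pytest.raises(IncompleteComponentsError):
            ComponentScore("m2", 0, "S")

    def test_full_vote_grid_against_brute_force_oracle(self):
        # Independent oracle: the weight table transcribed as plain rows
        table = {
            "KB-a": {"m2": (1, 1), "m3": (0.4, 0.4), "m4": (0.3, 0.3),
                     "sim": {"S": 1, "N": 1, "NS": 0, "NoMatch": 0},
                     "sub": (1, 0.5)},
            "KB-b": {"m2": (1, 0.8), "m3": (0.8, 0.4), "m4": (0.3, 0.4),
                     "sim": {"S": 1, "N": 1, "NS": 0, "NoMatch": 0},
                     "sub": (1, 0.5)},
            "KB-c": {"m2": (1, 0.8), "m3": (0.6, 0.4), "m4": (0.3, 0.4),
                     "sim": {"S": 1, "N": 1, "NS": 0, "NoMatch": 0},
                     "sub": (1, 0.5)},
            "KB-d": {"m2": (1, 0.8), "m3": (0.4, 0.3), "m4": (0.3, 0.3),
                     "sim": {"S": 1, "N": 1, "NS": 0, "NoMatch": 0},
                     "sub": (1, 0.5)},
        }
        for scheme, row in table.items():
            for m2, m3, m4, (sv, sd), sub in product(
                (-1, 1), (-1, 1), (-1, 1), SIM_STATES, (-1, 1)
            ):
                expected = 0.0
                for name, vote in (("m2", m2), ("m3", m3), ("m4", m4)):
                    expected += vote * row[name][0 if vote > 0 else 1]
                expected += sv * row["sim"][sd]
                expected += sub * row["sub"][0 if sub > 0 else 1]
                r = consensus_score(votes(m2, m3, m4, sv, sd, sub), scheme)
                assert r.score == pytest.approx(expected, abs=1e-9)
                if expected > 1e-9:
                    assert r.label == "sensitizer"
                elif expected < -1e-9:
                    assert r.label == "non-sensitizer"
                else:
                    assert r.label == "indeterminate"

    def test_flipping_a_vote_up_never_lowers_score(self):
        # equal direction weights so only the vote sign moves the sum
        weights = {(c, d): 0.5 for c in DIRECTIONS for d in DIRECTIONS[c]}
        scheme = WeightScheme(name="flat", weights=weights)
        base = [-1, -1, -1]
        for i in range(3):
            flipped = list(base)
            flipped[i] = 1
            low = consensus_score(votes(*base, 0, "NoMatch", -1), scheme)
            high = consensus_score(votes(*flipped, 0, "NoMatch", -1), scheme)
            assert high.score >= low.score

    def test_positive_weight_scaling_preserves_labels(self):
        kb = BUILTIN_SCHEMES["KB-b"]
        scaled = WeightScheme(
            name="scaled",
            weights={k: 7.3 * v for k, v in kb.weights.items()},
        )
        for m2, m3, m4, (sv, sd), sub in product(
            (-1, 1), (-1, 1), (-1, 1), SIM_STATES, (-1, 1)
        ):
            a = consensus_score(votes(m2, m3, m4, sv, sd, sub), kb)
            b = consensus_score(votes(m2, m3, m4, sv, sd, sub), scaled)
            assert a.label == b.label

    def test_builtin_scores_are_tenths(self):
        for scheme in BUILTIN_SCHEMES.values():
            for m2, m3, m4, (sv, sd), sub in product(
                (-1, 1), (-1, 1), (-1, 1), SIM_STATES, (-1, 1)
            ):
                score = consensus_score(
                    votes(m2, m3, m4, sv, sd, sub), scheme).score
                assert round(score * 10, 6) == round(score * 10)


class TestMetaIntegrator:
    def test_concordant_components_reach_perfect_cv(self):
        rng = np.random.default_rng(0)
        y = rng.choice([-1, 1], size=100)
        X = np.tile(y[:, None], (1, 5))
        meta = MetaIntegrator(method="max-margin").fit(X, y)
        assert meta.n_folds == 10  # default fold count
        assert meta.cv_accuracy_ == pytest.approx(1.0)
        assert np.array_equal(meta.predict(X), y)

    def test_single_class_labels_raise(self):
        X = np.ones((10, 5))
        with pytest.raises(DegenerateInputError):
            MetaIntegrator().fit(X, np.ones(10))

    def test_all_zero_matrix_warns_and_predicts_majority(self, caplog):
        rng = np.random.default_rng(1)
        y = np.array([1] * 30 + [-1] * 20)
        rng.shuffle(y)
        X = np.zeros((50, 5))
        with caplog.at_level("WARNING"):
            meta = MetaIntegrator(method="max-margin").fit(X, y)
        assert "no signal" in caplog.text
        assert set(meta.predict(np.zeros((4, 5)))) <= {-1, 1}


@pytest.fixture(scope="module")
def fitted_workflow(small_benchmark):
    return ConsensusWorkflow(seed=9).fit(small_benchmark)


class TestWorkflow:
    def test_every_molecule_gets_five_components(self, fitted_workflow,
                                                 small_benchmark):
        results, failures = run_workflow(small_benchmark, fitted_workflow)
        assert not failures
        assert len(results) == len(small_benchmark)
        for r in results:
            assert sorted(c.component for c in r.components) == \
                sorted(("m2", "m3", "m4", "similarity", "substructure"))

    def test_substructure_only_ablation_never_indeterminate(
            self, fitted_workflow, small_benchmark):
        results, _ = run_workflow(small_benchmark, fitted_workflow,
                                  ablate=("qsar", "similarity"))
        assert all(r.label != "indeterminate" for r in results)

    def test_qsar_ablation_sign_logic(self, fitted_workflow,
                                      small_benchmark):
        # with QSAR zeroed, an absent alert and a similarity miss leave
        # only -w(substructure, Absent) = -0.5 under KB-b
        results, _ = run_workflow(small_benchmark, fitted_workflow,
                                  ablate=("qsar",))
        for r in results:
            by = {c.component: c for c in r.components}
            if (by["similarity"].direction == "NoMatch"
                    and by["substructure"].value == -1):
                assert r.score == pytest.approx(-0.5)
                assert r.label == "non-sensitizer"

    def test_training_set_performance_is_high(self, fitted_workflow,
                                              small_benchmark):
        report = fitted_workflow.evaluate(small_benchmark)
        assert report.ccr >= 90.0

    def test_bundle_round_trip(self, fitted_workflow, small_benchmark,
                               tmp_path):
        fitted_workflow.save(tmp_path / "bundle")
        loaded = ConsensusWorkflow.load(tmp_path / "bundle")
        a, _ = fitted_workflow.predict_results(small_benchmark)
        b, _ = loaded.predict_results(small_benchmark)
        assert [r.label for r in a] == [r.label for r in b]
        assert [r.score for r in a] == [r.score for r in b]
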