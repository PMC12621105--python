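"""Routing, switch function, and assembly properties.

Several tests use deterministic stub models whose per-type accuracy is exact
by construction: a stub answers sample i correctly iff i falls in its
designed "competence" subset for that question type.
"""

import numpy as np
import pytest

from fundusvqa.core_types import ANSWER_ORDER, QTYPE_ORDER, AnswerLabel, QuestionType
from fundusvqa.data import ArrayDataset
from fundusvqa.metrics import per_type_accuracy
from fundusvqa.multilevel import (
    ComponentRouter,
    MultiLevelModel,
    NoisyRouter,
    OracleRouter,
    RoutingTable,
    build_bilevel,
    derive_routing,
    per_type_accuracy_of_answerer,
    switch_decision,
)


# ---------------------------------------------------------------------------
# Deterministic fixture: a labeled dataset with no pixels needed


def make_label_dataset(n_per_type: int = 40) -> ArrayDataset:
    ids, answer_idx, qtype_idx, qtypes = [], [], [], []
    i = 0
    for t_i, qtype in enumerate(QTYPE_ORDER):
        for k in range(n_per_type):
            ids.append(f"s{i:04d}")
            if qtype is QuestionType.GRADE:
                answer_idx.append(k % 3)  # grades 0/1/2
            else:
                answer_idx.append(3 + (k % 2))  # no/yes
            qtype_idx.append(t_i)
            qtypes.append(qtype)
            i += 1
    n = len(ids)
    return ArrayDataset(
        ids=ids,
        token_ids=np.zeros((n, 2), dtype=np.int64),
        images=np.zeros((n, 1, 1, 1)),
        answer_idx=np.array(answer_idx),
        qtype_idx=np.array(qtype_idx),
        question_types=qtypes,
    )


class StubAnswerer:
    """Answers correctly with a designed per-type rate, deterministically.

    For each question type the stub answers the first ``rate * count``
    samples (in dataset order) correctly and the rest wrongly, so its
    per-type accuracy equals the designed rate exactly.
    """

    def __init__(self, rates: dict[QuestionType, float]):
        self.rates = rates

    def predict_answer_indices(self, dataset: ArrayDataset) -> np.ndarray:
        out = np.zeros(len(dataset), dtype=np.int64)
        seen: dict[QuestionType, int] = {t: 0 for t in QuestionType}
        totals: dict[QuestionType, int] = {
            t: sum(q is t for q in dataset.question_types) for t in QuestionType
        }
        for i, qtype in enumerate(dataset.question_types):
            k = seen[qtype]
            seen[qtype] += 1
            correct = k < round(self.rates.get(qtype, 0.0) * totals[qtype])
            truth = dataset.answer_idx[i]
            out[i] = truth if correct else (truth + 1) % len(ANSWER_ORDER)
        return out


TABLE_RATES = {
    # the per-type pattern of three differently specialized models
    "model1": {
        QuestionType.GRADE: 0.8473,
        QuestionType.WHOLE: 0.9084,
        QuestionType.FOVEA: 0.8529,
        QuestionType.REGION: 0.8322,
    },
    "model2": {
        QuestionType.GRADE: 0.8321,
        QuestionType.WHOLE: 0.9237,
        QuestionType.FOVEA: 0.9084,
        QuestionType.REGION: 0.8595,
    },
    "model3": {
        QuestionType.GRADE: 0.8244,
        QuestionType.WHOLE: 0.8855,
        QuestionType.FOVEA: 0.8702,
        QuestionType.REGION: 0.8802,
    },
}


class TestDeriveRouting:
    def test_per_type_argmax_pattern(self):
        routing = derive_routing(TABLE_RATES)
        assert routing.to_dict() == {
            "grade": "model1",
            "whole": "model2",
            "fovea": "model2",
            "region": "model3",
        }

    def test_single_model_takes_all_types(self):
        routing = derive_routing({"only": {t: 0.5 for t in QuestionType}})
        assert set(routing.to_dict().values()) == {"only"}

    def test_ties_resolve_to_earlier_model(self):
        routing = derive_routing(
            {"a": {t: 0.7 for t in QuestionType}, "b": {t: 0.7 for t in QuestionType}}
        )
        assert set(routing.to_dict().values()) == {"a"}

    def test_uncovered_type_is_an_error(self):
        with pytest.raises(ValueError, match="region"):
            derive_routing({"a": {QuestionType.WHOLE: 0.9}})


class TestSwitchDecision:
    def test_no_next_level_is_final(self):
        routing = RoutingTable({t: "m" for t in QuestionType})
        d = switch_decision(QuestionType.GRADE, routing, has_next_level=False)
        assert d.code == "final" and d.target is None
        assert d.intermediate is QuestionType.GRADE

    def test_routes_by_predicted_type(self):
        routing = derive_routing(TABLE_RATES)
        for qtype, expect in [
            (QuestionType.GRADE, "model1"),
            (QuestionType.WHOLE, "model2"),
            (QuestionType.FOVEA, "model2"),
            (QuestionType.REGION, "model3"),
        ]:
            d = switch_decision(qtype, routing, has_next_level=True)
            assert d.code == "route" and d.target == expect

    def test_final_decision_cannot_carry_target(self):
        from fundusvqa.multilevel import Decision

        with pytest.raises(ValueError):
            Decision(code="final", target="m", intermediate=None)


class TestRoutingTable:
    def test_must_be_total(self):
        with pytest.raises(ValueError, match="missing"):
            RoutingTable({QuestionType.GRADE: "m"})

    def test_assembly_rejects_unknown_target(self):
        routing = RoutingTable({t: "ghost" for t in QuestionType})
        with pytest.raises(ValueError, match="ghost"):
            MultiLevelModel(
                router=OracleRouter(), answerers={"m": StubAnswerer({})}, routing=routing
            )

    def test_auto_requires_validation_data(self):
        with pytest.raises(ValueError):
            build_bilevel(OracleRouter(), {"m": StubAnswerer({})}, "auto", None)


@pytest.fixture(scope="module")
def ds():
    return make_label_dataset(40)


@pytest.fixture(scope="module")
def answerers():
    return {mid: StubAnswerer(rates) for mid, rates in TABLE_RATES.items()}


class TestAssemblyProperties:
    def test_stub_per_type_accuracy_is_exact(self, ds, answerers):
        acc = per_type_accuracy_of_answerer(answerers["model2"], ds)
        for t, rate in TABLE_RATES["model2"].items():
            assert acc[t] == pytest.approx(round(rate * 40) / 40)

    def test_oracle_routed_assembly_matches_routed_components(self, ds, answerers):
        """With a perfect router, each type's accuracy equals the routed
        model's own accuracy on that type, and the overall accuracy is at
        least every single component's."""
        tables = {m: per_type_accuracy_of_answerer(a, ds) for m, a in answerers.items()}
        assembled = build_bilevel(OracleRouter(), answerers, derive_routing(tables))
        answers, traces = assembled.answer_batch(ds)
        truths = [ANSWER_ORDER[i] for i in ds.answer_idx]
        by_type, overall = per_type_accuracy(ds.question_types, truths, answers)
        for t in QuestionType:
            routed = assembled.routing[t]
            assert by_type[t] == pytest.approx(tables[routed][t], abs=1e-12)
        for m, a in answerers.items():
            pred = a.predict_answer_indices(ds)
            comp_overall = float((pred == ds.answer_idx).mean())
            assert overall >= comp_overall - 1e-12

    def test_identical_answerers_make_routing_irrelevant(self, ds):
        rates = TABLE_RATES["model1"]
        same = {f"m{i}": StubAnswerer(rates) for i in range(3)}
        accs = []
        for target in same:
            routing = RoutingTable({t: target for t in QuestionType})
            assembled = build_bilevel(OracleRouter(), same, routing)
            answers, _ = assembled.answer_batch(ds)
            truths = [ANSWER_ORDER[i] for i in ds.answer_idx]
            accs.append(np.mean([a is b for a, b in zip(answers, truths)]))
        assert len(set(np.round(accs, 12))) == 1

    def test_misrouting_degrades_accuracy_monotonically(self, ds, answerers):
        tables = {m: per_type_accuracy_of_answerer(a, ds) for m, a in answerers.items()}
        assembled = build_bilevel(OracleRouter(), answerers, derive_routing(tables))
        truths = [ANSWER_ORDER[i] for i in ds.answer_idx]
        accs = []
        for eps in (0.0, 0.25, 0.5):
            router = NoisyRouter(OracleRouter(), epsilon=eps, seed=77)
            answers, _ = assembled.answer_batch(ds, router=router)
            accs.append(np.mean([a is b for a, b in zip(answers, truths)]))
        assert accs[0] >= accs[1] >= accs[2]

    def test_assembly_never_emits_a_question_type(self, ds, answerers):
        assembled = build_bilevel(
            OracleRouter(),
            answerers,
            derive_routing(
                {m: per_type_accuracy_of_answerer(a, ds) for m, a in answerers.items()}
            ),
        )
        answers, traces = assembled.answer_batch(ds)
        assert all(isinstance(a, AnswerLabel) for a in answers)
        assert all(t["decision"] == "route" for t in traces)


class TestComponentRouter:
    def test_trained_router_predicts_grade_template(self, trained_qtype, tiny_dataset):
        model, _ = trained_qtype
        router = ComponentRouter(model)
        val = tiny_dataset["val"]
        scores = router.predict_type_scores(val)
        assert scores.shape[1] == 4
        np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-9)
        # the level-1 classifier separates the closed template set
        acc = float((router.predict_type_indices(val) == val.qtype_idx).mean())
        assert acc >= 0.95
        grade_rows = val.qtype_idx == QTYPE_ORDER.index(QuestionType.GRADE)
        pred = router.predict_type_indices(val)
        assert (pred[grade_rows] == QTYPE_ORDER.index(QuestionType.GRADE)).mean() >= 0.9

    def test_wrong_role_rejected(self, trained_answer):
        model, _ = trained_answer
        with pytest.raises(ValueError):
            ComponentRouter(model)

    def test_deterministic_predictions(self, trained_qtype, tiny_dataset):
        model, _ = trained_qtype
        router = ComponentRouter(model)
        p1 = router.predict_type_indices(tiny_dataset["test"])
        p2 = router.predict_type_indices(tiny_dataset["test"])
        np.testing.assert_array_equal(p1, p2)
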