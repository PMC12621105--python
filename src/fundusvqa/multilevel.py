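"""Multi-level VQA assembly: question-type level, switch function, routing.

The general system is a sequence of levels; every level before the last
predicts a routing key (here: the question type) that the switch function
uses to forward the (image, question) pair, and the last level predicts the
answer.  Only the bi-level instantiation is exercised end to end: one
question-type classifier at level 1, several specialized answer models at
level 2, and a routing table derived from per-type validation accuracy.

Intermediate predictions are consumed by the switch function only - they are
never passed to the next level's model, and a misclassified type is routed
per the (wrong) prediction, not corrected.

Level models are duck-typed: a level-1 router needs ``predict_type_indices``
and a level-2 answerer needs ``predict_answer_indices`` (both mapping an
:class:`~fundusvqa.data.ArrayDataset` to integer label indices).
:class:`~fundusvqa.encoders.ComponentModel` satisfies these through the
adapters below.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Optional, Protocol, Sequence

import numpy as np

from .core_types import (
    ANSWER_ORDER,
    QTYPE_ORDER,
    AnswerLabel,
    QuestionType,
)
from .data import ArrayDataset
from .encoders import ComponentModel


class Router(Protocol):
    def predict_type_indices(self, dataset: ArrayDataset) -> np.ndarray: ...


class Answerer(Protocol):
    def predict_answer_indices(self, dataset: ArrayDataset) -> np.ndarray: ...


class ComponentRouter:
    """Adapter: a role=qtype ComponentModel as a level-1 router."""

    def __init__(self, model: ComponentModel):
        if model.config.role != "qtype":
            raise ValueError("level-1 model must have role 'qtype'")
        self.model = model

    def predict_type_indices(self, dataset: ArrayDataset) -> np.ndarray:
        return self.model.predict_indices(dataset.token_ids, dataset.images)

    def predict_type_scores(self, dataset: ArrayDataset) -> np.ndarray:
        return self.model.predict_proba(dataset.token_ids, dataset.images)


class ComponentAnswerer:
    """Adapter: a role=answer ComponentModel as a level-2 answer model."""

    def __init__(self, model: ComponentModel):
        if model.config.role != "answer":
            raise ValueError("level-2 model must have role 'answer'")
        self.model = model

    def predict_answer_indices(self, dataset: ArrayDataset) -> np.ndarray:
        return self.model.predict_indices(dataset.token_ids, dataset.images)


class OracleRouter:
    """Routes by the true question type (perfect level-1)."""

    def predict_type_indices(self, dataset: ArrayDataset) -> np.ndarray:
        return dataset.qtype_idx.copy()


class NoisyRouter:
    """Corrupts another router's prediction with probability epsilon."""

    def __init__(self, base: Router, epsilon: float, seed: int):
        self.base = base
        self.epsilon = float(epsilon)
        self.seed = int(seed)

    def predict_type_indices(self, dataset: ArrayDataset) -> np.ndarray:
        pred = self.base.predict_type_indices(dataset).copy()
        rng = np.random.Generator(np.random.PCG64(self.seed))
        flip = rng.uniform(size=pred.shape[0]) < self.epsilon
        for i in np.nonzero(flip)[0]:
            others = [k for k in range(len(QTYPE_ORDER)) if k != pred[i]]
            pred[i] = others[int(rng.integers(len(others)))]
        return pred


@dataclasses.dataclass(frozen=True)
class RoutingTable:
    """Total mapping from question type to the level-2 model id."""

    mapping: Mapping[QuestionType, str]

    def __post_init__(self):
        missing = [t for t in QuestionType if t not in self.mapping]
        if missing:
            raise ValueError(f"routing table missing types: {[t.value for t in missing]}")

    def __getitem__(self, t: QuestionType) -> str:
        return self.mapping[t]

    def to_dict(self) -> dict:
        return {t.value: self.mapping[t] for t in QuestionType}

    @classmethod
    def from_dict(cls, d: Mapping[str, str]) -> "RoutingTable":
        return cls({QuestionType.parse(k): str(v) for k, v in d.items()})


@dataclasses.dataclass(frozen=True)
class Decision:
    """Switch outcome: emit the carried answer, or route onward."""

    code: str  # "final" or "route"
    target: Optional[str]
    intermediate: object  # the level's own prediction (switch-internal only)

    def __post_init__(self):
        if self.code == "final" and self.target is not None:
            raise ValueError("a final decision carries no routing target")


def switch_decision(
    predicted_type: QuestionType, routing: RoutingTable, has_next_level: bool
) -> Decision:
    if not has_next_level:
        return Decision(code="final", target=None, intermediate=predicted_type)
    return Decision(code="route", target=routing[predicted_type], intermediate=predicted_type)


def derive_routing(
    per_type_accuracy: Mapping[str, Mapping[QuestionType, float]]
) -> RoutingTable:
    """Route each type to the model with the best per-type accuracy.

    ``per_type_accuracy`` maps model id -> {type: validation accuracy}; ties
    go to the earlier model (insertion order).
    """
    mapping: dict[QuestionType, str] = {}
    for t in QuestionType:
        best_id, best_acc = None, -1.0
        for model_id, table in per_type_accuracy.items():
            if t in table and table[t] > best_acc:
                best_id, best_acc = model_id, table[t]
        if best_id is None:
            raise ValueError(f"no model reports accuracy for type {t.value!r}")
        mapping[t] = best_id
    return RoutingTable(mapping)


@dataclasses.dataclass
class MultiLevelModel:
    """The assembled system; n >= 2 with a single router level for bi-level."""

    router: Router
    answerers: dict  # model id -> Answerer
    routing: RoutingTable
    n_levels: int = 2

    def __post_init__(self):
        if self.n_levels < 2:
            raise ValueError("the bi-level instantiation requires n >= 2")
        for t in QuestionType:
            if self.routing[t] not in self.answerers:
                raise ValueError(f"routing target {self.routing[t]!r} not assembled")

    # -- inference ---------------------------------------------------------

    def answer_batch(
        self, dataset: ArrayDataset, router: Optional[Router] = None
    ) -> tuple[list[AnswerLabel], list[dict]]:
        """Answer every sample; returns labels plus per-sample traces.

        The trace records the predicted type, the switch decision, the routed
        model id and the final answer - the intermediate type prediction is
        used only for routing.
        """
        router = router if router is not None else self.router
        type_idx = router.predict_type_indices(dataset)
        answers: list[Optional[AnswerLabel]] = [None] * len(dataset)
        traces: list[Optional[dict]] = [None] * len(dataset)
        for t_i, qtype in enumerate(QTYPE_ORDER):
            rows = np.nonzero(type_idx == t_i)[0]
            if rows.size == 0:
                continue
            decision = switch_decision(qtype, self.routing, has_next_level=True)
            model = self.answerers[decision.target]
            pred = model.predict_answer_indices(dataset.subset(rows))
            for local, global_i in enumerate(rows):
                label = ANSWER_ORDER[int(pred[local])]
                answers[global_i] = label
                traces[global_i] = {
                    "id": dataset.ids[global_i],
                    "predicted_type": qtype.value,
                    "decision": decision.code,
                    "routed_model": decision.target,
                    "answer": label.value,
                }
        return answers, traces  # type: ignore[return-value]


def per_type_accuracy_of_answerer(
    answerer: Answerer, dataset: ArrayDataset
) -> dict[QuestionType, float]:
    """Validation accuracy of one answer model restricted to each true type."""
    pred = answerer.predict_answer_indices(dataset)
    correct = pred == dataset.answer_idx
    out: dict[QuestionType, float] = {}
    for t_i, qtype in enumerate(QTYPE_ORDER):
        rows = dataset.qtype_idx == t_i
        if rows.any():
            out[qtype] = float(correct[rows].mean())
    return out


def build_bilevel(
    router: Router,
    answerers: Mapping[str, Answerer],
    routing: "RoutingTable | str" = "auto",
    val_dataset: Optional[ArrayDataset] = None,
) -> MultiLevelModel:
    """Assemble the bi-level system.

    ``routing="auto"`` measures each answer model's per-type accuracy on the
    validation set and routes each type to its best model.
    """
    if routing == "auto":
        if val_dataset is None:
            raise ValueError("auto routing requires a validation dataset")
        table = {
            mid: per_type_accuracy_of_answerer(ans, val_dataset)
            for mid, ans in answerers.items()
        }
        routing = derive_routing(table)
    return MultiLevelModel(router=router, answerers=dict(answerers), routing=routing)
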