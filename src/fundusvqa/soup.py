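"""Greedy-soup parameter averaging over training checkpoints.

Checkpoints are sorted by descending validation accuracy (ties keep training
order), optionally pre-filtered to the top-k pool (default k=3).  The soup is
initialized with the best checkpoint; each remaining candidate is tentatively
averaged in (uniform over the would-be ingredient set, re-averaged from
scratch) and kept iff the evaluated validation accuracy does not drop below
the current soup's.  The acceptance rule guarantees the final soup validation
accuracy is at least the best single ingredient's.  A ``strict`` variant
requires a strict improvement instead.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Optional, Sequence

import numpy as np

from .core_types import Checkpoint, ParameterSet


@dataclasses.dataclass
class AuditEntry:
    candidate_id: str
    candidate_val_accuracy: float
    tried: bool
    accepted: bool
    accuracy_if_added: Optional[float]
    soup_accuracy_after: float


@dataclasses.dataclass
class SoupResult:
    ingredients: list[str]  # accepted checkpoint ids, in acceptance order
    final_params: ParameterSet
    final_val_accuracy: float
    audit: list[AuditEntry]

    def to_dict(self) -> dict:
        return {
            "ingredients": self.ingredients,
            "final_val_accuracy": self.final_val_accuracy,
            "audit": [dataclasses.asdict(a) for a in self.audit],
        }


def average_parameters(sets: Sequence[ParameterSet]) -> ParameterSet:
    """Entry-wise arithmetic mean across all named arrays (all components)."""
    if not sets:
        raise ValueError("cannot average an empty list of parameter sets")
    first = sets[0]
    for other in sets[1:]:
        offender = first.combinable_with(other)
        if offender is not None:
            raise ValueError(f"parameter sets not combinable: entry {offender!r}")
    return ParameterSet(
        {
            name: np.mean([s.entries[name] for s in sets], axis=0)
            for name in first.entries
        }
    )


def top_k_pool(checkpoints: Sequence[Checkpoint], k: int) -> list[Checkpoint]:
    """The k checkpoints with highest validation accuracy, sorted descending.

    Ties preserve the original (training) order; k=1 degenerates to plain
    best-checkpoint selection.
    """
    if not checkpoints:
        raise ValueError("empty checkpoint list")
    if k < 1:
        raise ValueError("k must be >= 1")
    order = sorted(
        range(len(checkpoints)), key=lambda i: (-checkpoints[i].val_accuracy, i)
    )
    return [checkpoints[i] for i in order[:k]]


def greedy_soup(
    pool: Sequence[Checkpoint],
    evaluator: Callable[[ParameterSet], float],
    rule: str = "alg5",
) -> SoupResult:
    """Greedily average checkpoints, keeping only accuracy-preserving adds.

    ``evaluator`` maps a ParameterSet to validation accuracy.  ``rule``:
    ``alg5`` accepts a candidate iff the averaged model's accuracy is >= the
    current soup's (the formal statement); ``strict`` requires >.
    """
    if rule not in ("alg5", "strict"):
        raise ValueError("rule must be 'alg5' or 'strict'")
    pool = top_k_pool(pool, k=len(pool))  # enforce descending order internally
    best = pool[0]
    members = [best]
    soup_params = average_parameters([c.params for c in members])
    try:
        soup_acc = evaluator(soup_params)
    except Exception as exc:
        raise RuntimeError(f"evaluator failed on candidate {best.id!r}") from exc
    audit = [
        AuditEntry(
            candidate_id=best.id,
            candidate_val_accuracy=best.val_accuracy,
            tried=True,
            accepted=True,
            accuracy_if_added=soup_acc,
            soup_accuracy_after=soup_acc,
        )
    ]
    for cand in pool[1:]:
        trial = average_parameters([c.params for c in members] + [cand.params])
        try:
            trial_acc = evaluator(trial)
        except Exception as exc:
            raise RuntimeError(f"evaluator failed on candidate {cand.id!r}") from exc
        accept = trial_acc > soup_acc if rule == "strict" else trial_acc >= soup_acc
        if accept:
            members.append(cand)
            soup_params, soup_acc = trial, trial_acc
        audit.append(
            AuditEntry(
                candidate_id=cand.id,
                candidate_val_accuracy=cand.val_accuracy,
                tried=True,
                accepted=accept,
                accuracy_if_added=trial_acc,
                soup_accuracy_after=soup_acc,
            )
        )
    return SoupResult(
        ingredients=[c.id for c in members],
        final_params=soup_params,
        final_val_accuracy=soup_acc,
        audit=audit,
    )


def soup_checkpoints(
    checkpoints: Sequence[Checkpoint],
    evaluator: Callable[[ParameterSet], float],
    k: int = 3,
    rule: str = "alg5",
) -> SoupResult:
    """Top-k pool pre-filter followed by the greedy soup."""
    return greedy_soup(top_k_pool(checkpoints, k), evaluator, rule=rule)
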