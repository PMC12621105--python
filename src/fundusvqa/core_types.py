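"""Shared domain types for the bi-level fundus VQA system.

The vocabulary here mirrors the DME-VQA task: questions about hard exudates
(bright lipid lesions on the retina) asked about the whole image, a masked
region, or the fovea, plus a macular-edema grading question.  Grades follow
the clinical convention: grade 0 = no hard exudates, grade 1 = exudates
confined to the peripheral retina, grade 2 = exudates within the macula.

Manifests are JSON-lines files, one sample per line, with images and masks
stored as PNG next to them.  Pixel coordinates are 0-based, row-major
(row, col); masks are {0, 1} in memory with 1 = inside the region, and
strictly {0, 255} on disk.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from collections import Counter
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np
from PIL import Image


class QuestionType(enum.Enum):
    """The four question families of the DME VQA task."""

    WHOLE = "whole"
    REGION = "region"
    FOVEA = "fovea"
    GRADE = "grade"

    @classmethod
    def parse(cls, token: str) -> "QuestionType":
        try:
            return cls(token.strip().lower())
        except ValueError:
            raise ValueError(f"unknown question type: {token!r}") from None


class AnswerLabel(enum.Enum):
    """The five-way global answer space (yes/no plus grades 0-2)."""

    GRADE_0 = "0"
    GRADE_1 = "1"
    GRADE_2 = "2"
    NO = "no"
    YES = "yes"

    @classmethod
    def parse(cls, token: str) -> "AnswerLabel":
        try:
            return cls(token.strip().lower())
        except ValueError:
            raise ValueError(f"unknown answer label: {token!r}") from None


#: Canonical index order of the 5-way answer head (grades first, then no/yes,
#: matching the usual result-table row order).
ANSWER_ORDER: tuple[AnswerLabel, ...] = (
    AnswerLabel.GRADE_0,
    AnswerLabel.GRADE_1,
    AnswerLabel.GRADE_2,
    AnswerLabel.NO,
    AnswerLabel.YES,
)

#: Canonical index order of the 4-way question-type head.
QTYPE_ORDER: tuple[QuestionType, ...] = (
    QuestionType.WHOLE,
    QuestionType.REGION,
    QuestionType.FOVEA,
    QuestionType.GRADE,
)

ANSWER_INDEX = {a: i for i, a in enumerate(ANSWER_ORDER)}
QTYPE_INDEX = {t: i for i, t in enumerate(QTYPE_ORDER)}

#: Which answers are legal for each question type.  GRADE questions take only
#: grade answers; the three presence questions take only yes/no.
COMPATIBLE_ANSWERS: dict[QuestionType, frozenset[AnswerLabel]] = {
    QuestionType.WHOLE: frozenset({AnswerLabel.YES, AnswerLabel.NO}),
    QuestionType.REGION: frozenset({AnswerLabel.YES, AnswerLabel.NO}),
    QuestionType.FOVEA: frozenset({AnswerLabel.YES, AnswerLabel.NO}),
    QuestionType.GRADE: frozenset(
        {AnswerLabel.GRADE_0, AnswerLabel.GRADE_1, AnswerLabel.GRADE_2}
    ),
}

SPLITS = ("train", "val", "test")


@dataclasses.dataclass(frozen=True)
class SampleRecord:
    """One manifest row: paths, not pixels."""

    id: str
    image_path: str
    mask_path: Optional[str]
    question: str
    question_type: QuestionType
    answer: AnswerLabel
    split: str

    def to_json(self) -> str:
        return json.dumps(
            {
                "id": self.id,
                "image_path": self.image_path,
                "mask_path": self.mask_path,
                "question": self.question,
                "question_type": self.question_type.value,
                "answer": self.answer.value,
                "split": self.split,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, line: str) -> "SampleRecord":
        d = json.loads(line)
        return cls(
            id=str(d["id"]),
            image_path=d["image_path"],
            mask_path=d.get("mask_path"),
            question=d["question"],
            question_type=QuestionType.parse(d["question_type"]),
            answer=AnswerLabel.parse(d["answer"]),
            split=d["split"],
        )


@dataclasses.dataclass
class VQASample:
    """A fully loaded sample: pixels plus question and labels.

    ``image`` is H×W×C float in [0, 1]; ``mask`` (present iff the question is
    a REGION question) is H×W uint8 in {0, 1} sharing the image's H and W.
    """

    id: str
    image: np.ndarray
    mask: Optional[np.ndarray]
    question: str
    question_type: QuestionType
    answer: AnswerLabel
    split: str


class DatasetManifest:
    """Ordered collection of :class:`SampleRecord` with per-split tallies."""

    def __init__(self, records: Sequence[SampleRecord], root: Optional[Path] = None):
        self.records: list[SampleRecord] = list(records)
        self.root = Path(root) if root is not None else None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SampleRecord]:
        return iter(self.records)

    def split(self, name: str) -> list[SampleRecord]:
        return [r for r in self.records if r.split == name]

    # -- tallies ----------------------------------------------------------

    def counts(self) -> dict[str, dict[str, dict[str, int]]]:
        """Per-split tallies by answer and by question type."""
        out: dict[str, dict[str, dict[str, int]]] = {}
        for s in SPLITS:
            rows = self.split(s)
            out[s] = {
                "n": {"total": len(rows)},
                "answer": dict(Counter(r.answer.value for r in rows)),
                "question_type": dict(Counter(r.question_type.value for r in rows)),
            }
        return out

    # -- persistence ------------------------------------------------------

    def to_jsonl(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(r.to_json() + "\n")

    @classmethod
    def from_jsonl(cls, path: str | Path) -> "DatasetManifest":
        path = Path(path)
        records = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    records.append(SampleRecord.from_json(line))
        return cls(records, root=path.parent)

    def resolve(self, rel: str) -> Path:
        return (self.root / rel) if self.root is not None else Path(rel)

    def load_sample(self, record: SampleRecord) -> VQASample:
        image = read_image(self.resolve(record.image_path))
        mask = (
            read_mask(self.resolve(record.mask_path))
            if record.mask_path is not None
            else None
        )
        return VQASample(
            id=record.id,
            image=image,
            mask=mask,
            question=record.question,
            question_type=record.question_type,
            answer=record.answer,
            split=record.split,
        )


# ---------------------------------------------------------------------------
# PNG I/O


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write an H×W×C float image in [0,1] as an 8-bit PNG (C=1 or 3)."""
    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    if arr.ndim != 3 or arr.shape[2] not in (1, 3):
        raise ValueError(f"expected H×W×1 or H×W×3 image, got shape {arr.shape}")
    data = np.round(arr * 255.0).astype(np.uint8)
    mode = "L" if arr.shape[2] == 1 else "RGB"
    Image.fromarray(data[:, :, 0] if mode == "L" else data, mode=mode).save(path)


def read_image(path: str | Path) -> np.ndarray:
    with Image.open(path) as im:
        arr = np.asarray(im, dtype=np.float64) / 255.0
    if arr.ndim == 2:
        arr = arr[:, :, None]
    return arr


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write an H×W {0,1} mask as a strictly {0,255} 8-bit PNG."""
    m = np.asarray(mask)
    if not np.isin(m, (0, 1)).all():
        raise ValueError("mask values must be 0 or 1")
    Image.fromarray((m.astype(np.uint8) * 255), mode="L").save(path)


def read_mask(path: str | Path) -> np.ndarray:
    with Image.open(path) as im:
        arr = np.asarray(im)
    bad = ~np.isin(arr, (0, 255))
    if bad.any():
        raise ValueError(f"mask {path} contains values other than 0/255")
    return (arr == 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Parameters and checkpoints


class ParameterSet:
    """Named real arrays partitioned into components theta1/theta2/theta3.

    Entry names are prefixed ``theta1/`` (visual encoder), ``theta2/`` (text
    encoder), ``theta3/`` (fusion head).  Two sets are combinable iff their
    name sets and per-name shapes agree.
    """

    COMPONENTS = ("theta1", "theta2", "theta3")

    def __init__(self, entries: Mapping[str, np.ndarray]):
        self.entries: dict[str, np.ndarray] = {
            k: np.asarray(v, dtype=np.float64) for k, v in entries.items()
        }

    def __getitem__(self, name: str) -> np.ndarray:
        return self.entries[name]

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def names(self) -> list[str]:
        return sorted(self.entries)

    def component(self, which: str) -> dict[str, np.ndarray]:
        if which not in self.COMPONENTS:
            raise ValueError(f"unknown component {which!r}")
        return {k: v for k, v in self.entries.items() if k.startswith(which + "/")}

    def combinable_with(self, other: "ParameterSet") -> Optional[str]:
        """Return None if combinable, else the name of the first offender."""
        mine, theirs = set(self.entries), set(other.entries)
        diff = mine.symmetric_difference(theirs)
        if diff:
            return sorted(diff)[0]
        for name in sorted(mine):
            if self.entries[name].shape != other.entries[name].shape:
                return name
        return None

    def copy(self) -> "ParameterSet":
        return ParameterSet({k: v.copy() for k, v in self.entries.items()})

    def allclose(self, other: "ParameterSet", **kw) -> bool:
        if self.combinable_with(other) is not None:
            return False
        return all(
            np.allclose(self.entries[k], other.entries[k], **kw) for k in self.entries
        )


@dataclasses.dataclass(frozen=True)
class Provenance:
    epoch: int
    phase: str  # "half" or "end"
    hyperparameters: dict
    seed: int

    def to_dict(self) -> dict:
        return {
            "epoch": self.epoch,
            "phase": self.phase,
            "hyperparameters": self.hyperparameters,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Provenance":
        return cls(
            epoch=int(d["epoch"]),
            phase=str(d["phase"]),
            hyperparameters=dict(d["hyperparameters"]),
            seed=int(d["seed"]),
        )


@dataclasses.dataclass
class Checkpoint:
    """A saved parameter set with its measured validation accuracy."""

    params: ParameterSet
    val_accuracy: float
    provenance: Provenance
    meta: dict = dataclasses.field(default_factory=dict)  # model config, vocab, ...

    @property
    def id(self) -> str:
        return f"seed{self.provenance.seed}-ep{self.provenance.epoch}-{self.provenance.phase}"


# ---------------------------------------------------------------------------
# Manifest validation


@dataclasses.dataclass(frozen=True)
class Violation:
    sample_id: Optional[str]
    rule: str
    message: str


def validate_manifest(
    manifest: DatasetManifest, check_files: bool = True
) -> list[Violation]:
    """Check every manifest invariant; return one record per breach.

    Rules checked: unique ids, mask present iff REGION, answer/type
    compatibility, known split names, and (optionally) that every referenced
    image/mask path exists.  An unreadable existing file raises ``OSError``
    rather than producing a violation.
    """
    violations: list[Violation] = []
    seen: set[str] = set()
    for r in manifest.records:
        if r.id in seen:
            violations.append(Violation(r.id, "unique-id", "duplicate sample id"))
        seen.add(r.id)
        if (r.mask_path is not None) != (r.question_type is QuestionType.REGION):
            violations.append(
                Violation(
                    r.id,
                    "mask-iff-region",
                    "mask must be present iff question_type is region",
                )
            )
        if r.answer not in COMPATIBLE_ANSWERS[r.question_type]:
            violations.append(
                Violation(
                    r.id,
                    "type-answer-compatibility",
                    f"answer {r.answer.value!r} illegal for type {r.question_type.value!r}",
                )
            )
        if r.split not in SPLITS:
            violations.append(Violation(r.id, "known-split", f"unknown split {r.split!r}"))
        if check_files:
            for kind, rel in (("image", r.image_path), ("mask", r.mask_path)):
                if rel is None:
                    continue
                p = manifest.resolve(rel)
                if not p.exists():
                    violations.append(
                        Violation(r.id, "file-exists", f"{kind} path missing: {rel}")
                    )
    return violations
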