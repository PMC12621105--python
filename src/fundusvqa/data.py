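"""In-memory dataset arrays for training and evaluation.

Loads a manifest split into dense arrays once: padded token ids, images (with
the region mask applied as a soft highlight, mirroring how region questions
are posed against masked images), and integer labels for both the 5-way
answer space and the 4-way question-type space.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from .core_types import (
    ANSWER_INDEX,
    QTYPE_INDEX,
    DatasetManifest,
    QuestionType,
    SampleRecord,
)
from .encoders import PAD, Vocabulary, tokenize

#: Pixels outside a region mask are dimmed by this factor so the region is
#: visually delineated in the model input while keeping global context.
MASK_DIM = 0.25


@dataclasses.dataclass
class ArrayDataset:
    ids: list[str]
    token_ids: np.ndarray  # (N, L) int64
    images: np.ndarray  # (N, H, W, C) float64
    answer_idx: np.ndarray  # (N,) int64
    qtype_idx: np.ndarray  # (N,) int64
    question_types: list[QuestionType]

    def __len__(self) -> int:
        return len(self.ids)

    def labels(self, role: str) -> np.ndarray:
        return self.answer_idx if role == "answer" else self.qtype_idx

    def subset(self, indices: Sequence[int]) -> "ArrayDataset":
        idx = list(indices)
        return ArrayDataset(
            ids=[self.ids[i] for i in idx],
            token_ids=self.token_ids[idx],
            images=self.images[idx],
            answer_idx=self.answer_idx[idx],
            qtype_idx=self.qtype_idx[idx],
            question_types=[self.question_types[i] for i in idx],
        )


def build_vocabulary(manifest: DatasetManifest) -> Vocabulary:
    return Vocabulary.from_questions([r.question for r in manifest.split("train")])


def load_split(
    manifest: DatasetManifest,
    split: str,
    vocab: Vocabulary,
    max_len: int = 12,
    apply_mask: bool = True,
    records: Optional[Sequence[SampleRecord]] = None,
) -> ArrayDataset:
    rows = list(records) if records is not None else manifest.split(split)
    if not rows:
        raise ValueError(f"split {split!r} is empty")
    pad = vocab.token_to_id[PAD]
    token_ids = np.full((len(rows), max_len), pad, dtype=np.int64)
    images = None
    answer_idx = np.zeros(len(rows), dtype=np.int64)
    qtype_idx = np.zeros(len(rows), dtype=np.int64)
    qtypes: list[QuestionType] = []
    ids: list[str] = []
    for i, rec in enumerate(rows):
        sample = manifest.load_sample(rec)
        if images is None:
            images = np.zeros((len(rows),) + sample.image.shape, dtype=np.float64)
        img = sample.image
        if apply_mask and sample.mask is not None:
            weight = MASK_DIM + (1.0 - MASK_DIM) * sample.mask[:, :, None]
            img = img * weight
        images[i] = img
        tok = tokenize(rec.question, vocab).ids[:max_len]
        token_ids[i, : len(tok)] = tok
        answer_idx[i] = ANSWER_INDEX[rec.answer]
        qtype_idx[i] = QTYPE_INDEX[rec.question_type]
        qtypes.append(rec.question_type)
        ids.append(rec.id)
    return ArrayDataset(ids, token_ids, images, answer_idx, qtype_idx, qtypes)


def image_stats(train: ArrayDataset) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean and standard deviation of the training images."""
    mu = train.images.mean(axis=(0, 1, 2))
    sigma = train.images.std(axis=(0, 1, 2))
    sigma = np.where(sigma <= 1e-8, 1.0, sigma)
    return mu, sigma
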