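"""Component VQA model: text encoder, patch image encoder, fusion head.

The component model mirrors the usual discriminator-style text encoder and
hierarchical patch image encoder contracts at reference scale: a word-level
tokenizer with [CLS]/[SEP] markers feeding a small self-attention stack whose
first-position ([CLS]) final hidden state is the text feature; an image branch
that normalizes, zero-pads to a multiple of the patch size, linearly embeds
non-overlapping patches, adds learned positional embeddings, runs the same
kind of attention stack, and mean-pools the patch states.  The two features
are each L2-normalized, concatenated text-first, and classified by a one
hidden-layer MLP over either the 5 answers or the 4 question types.

The operation signatures double as an adapter seam: a pretrained text or image
backbone exposing the same extract-features contract can stand behind them
without touching the rest of the system.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from typing import Mapping, Optional, Sequence

import numpy as np

from . import _autodiff as ad
from .core_types import (
    ANSWER_ORDER,
    QTYPE_ORDER,
    AnswerLabel,
    ParameterSet,
    QuestionType,
)

logger = logging.getLogger(__name__)

CLS, SEP, UNK, PAD = "[CLS]", "[SEP]", "[UNK]", "[PAD]"
RESERVED = (CLS, SEP, UNK, PAD)

_WORD_RE = re.compile(r"[a-z0-9]+")


class Vocabulary:
    """Word-level vocabulary with reserved marker tokens at ids 0-3."""

    def __init__(self, words: Sequence[str] = ()):
        self.token_to_id: dict[str, int] = {t: i for i, t in enumerate(RESERVED)}
        for w in words:
            if w not in self.token_to_id:
                self.token_to_id[w] = len(self.token_to_id)

    @classmethod
    def from_questions(cls, questions: Sequence[str]) -> "Vocabulary":
        words: list[str] = []
        for q in questions:
            words.extend(_WORD_RE.findall(q.lower()))
        return cls(sorted(set(words)))

    def __len__(self) -> int:
        return len(self.token_to_id)

    def to_dict(self) -> dict[str, int]:
        return dict(self.token_to_id)

    @classmethod
    def from_dict(cls, d: Mapping[str, int]) -> "Vocabulary":
        v = cls()
        v.token_to_id = {str(k): int(i) for k, i in d.items()}
        return v


@dataclasses.dataclass(frozen=True)
class TokenSequence:
    """Token ids wrapped by the summary ([CLS]) and separator ([SEP]) markers."""

    ids: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.ids)


def tokenize(question: str, vocab: Vocabulary) -> TokenSequence:
    """Lowercase, strip punctuation, map words to ids, wrap with markers."""
    words = _WORD_RE.findall(question.lower())
    unk = vocab.token_to_id[UNK]
    ids = [vocab.token_to_id[CLS]]
    ids.extend(vocab.token_to_id.get(w, unk) for w in words)
    ids.append(vocab.token_to_id[SEP])
    return TokenSequence(tuple(ids))


# ---------------------------------------------------------------------------
# Configuration and parameter initialization


@dataclasses.dataclass(frozen=True)
class EncoderConfig:
    """Shapes and sizes of the reference component model.

    d_text / d_vis are the text and image feature widths (D_t, D_v); the
    fused feature has length d_text + d_vis.  role selects the label space of
    the head: "answer" (5-way) or "qtype" (4-way).
    """

    d_text: int = 64
    d_vis: int = 64
    patch_size: int = 8
    text_blocks: int = 2
    vis_blocks: int = 2
    mlp_ratio: int = 2
    head_hidden: int = 128
    role: str = "answer"
    max_len: int = 12
    image_size: tuple[int, int] = (96, 96)
    channels: int = 1
    normalization: str = "l2"  # or "standard"

    @property
    def n_classes(self) -> int:
        return len(ANSWER_ORDER) if self.role == "answer" else len(QTYPE_ORDER)

    @property
    def n_patches(self) -> int:
        h, w = self.image_size
        p = self.patch_size
        return -(-h // p) * -(-w // p)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["image_size"] = list(self.image_size)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "EncoderConfig":
        d = dict(d)
        d["image_size"] = tuple(d["image_size"])
        return cls(**d)


def _init_block(rng: np.random.Generator, prefix: str, d: int, ratio: int, out: dict):
    s = 1.0 / np.sqrt(d)
    for name in ("wq", "wk", "wv", "wo"):
        out[f"{prefix}/{name}"] = rng.normal(0.0, s, (d, d))
    out[f"{prefix}/ln1_g"] = np.ones(d)
    out[f"{prefix}/ln1_b"] = np.zeros(d)
    out[f"{prefix}/mlp_w1"] = rng.normal(0.0, s, (d, ratio * d))
    out[f"{prefix}/mlp_b1"] = np.zeros(ratio * d)
    out[f"{prefix}/mlp_w2"] = rng.normal(0.0, 1.0 / np.sqrt(ratio * d), (ratio * d, d))
    out[f"{prefix}/mlp_b2"] = np.zeros(d)
    out[f"{prefix}/ln2_g"] = np.ones(d)
    out[f"{prefix}/ln2_b"] = np.zeros(d)


def init_parameters(
    config: EncoderConfig, vocab_size: int, rng: np.random.Generator
) -> ParameterSet:
    out: dict[str, np.ndarray] = {}
    # theta2: text encoder
    out["theta2/tok_emb"] = rng.normal(0.0, 0.02, (vocab_size, config.d_text))
    out["theta2/pos_emb"] = rng.normal(0.0, 0.02, (config.max_len, config.d_text))
    for b in range(config.text_blocks):
        _init_block(rng, f"theta2/blk{b}", config.d_text, config.mlp_ratio, out)
    # theta1: image encoder
    pdim = config.patch_size * config.patch_size * config.channels
    out["theta1/patch_emb"] = rng.normal(0.0, 1.0 / np.sqrt(pdim), (pdim, config.d_vis))
    out["theta1/patch_bias"] = np.zeros(config.d_vis)
    out["theta1/pos_emb"] = rng.normal(0.0, 0.02, (config.n_patches, config.d_vis))
    for b in range(config.vis_blocks):
        _init_block(rng, f"theta1/blk{b}", config.d_vis, config.mlp_ratio, out)
    # theta3: fusion head
    dfused = config.d_text + config.d_vis
    out["theta3/w1"] = rng.normal(0.0, 1.0 / np.sqrt(dfused), (dfused, config.head_hidden))
    out["theta3/b1"] = np.zeros(config.head_hidden)
    out["theta3/w2"] = rng.normal(
        0.0, 1.0 / np.sqrt(config.head_hidden), (config.head_hidden, config.n_classes)
    )
    out["theta3/b2"] = np.zeros(config.n_classes)
    return ParameterSet(out)


# ---------------------------------------------------------------------------
# Pure-numpy patchify (the image input carries no gradient)


def patchify(
    image: np.ndarray, patch_size: int, mu: np.ndarray, sigma: np.ndarray
) -> np.ndarray:
    """Normalize, zero-pad to a patch-size multiple, split row-major.

    Accepts H×W×C or B×H×W×C; returns (N, P*P*C) or (B, N, P*P*C) flattened
    patches, N = ceil(H/P) * ceil(W/P).
    """
    if patch_size < 1:
        raise ValueError("patch size must be >= 1")
    sigma = np.asarray(sigma, dtype=np.float64)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    x = np.asarray(image, dtype=np.float64)
    squeeze = x.ndim == 3
    if squeeze:
        x = x[None]
    b, h, w, c = x.shape
    x = (x - np.asarray(mu, dtype=np.float64)) / sigma
    p = patch_size
    hpad, wpad = (-h) % p, (-w) % p
    if hpad or wpad:
        x = np.pad(x, ((0, 0), (0, hpad), (0, wpad), (0, 0)))
    nh, nw = x.shape[1] // p, x.shape[2] // p
    x = x.reshape(b, nh, p, nw, p, c).transpose(0, 1, 3, 2, 4, 5)
    x = x.reshape(b, nh * nw, p * p * c)
    return x[0] if squeeze else x


# ---------------------------------------------------------------------------
# The component model


class ComponentModel:
    """A trainable text+image VQA classifier over answers or question types."""

    def __init__(
        self,
        config: EncoderConfig,
        vocab: Vocabulary,
        params: ParameterSet,
        mu: np.ndarray,
        sigma: np.ndarray,
    ):
        self.config = config
        self.vocab = vocab
        self.params = params
        self.mu = np.asarray(mu, dtype=np.float64)
        self.sigma = np.asarray(sigma, dtype=np.float64)

    @classmethod
    def initialize(
        cls,
        config: EncoderConfig,
        vocab: Vocabulary,
        mu: np.ndarray,
        sigma: np.ndarray,
        seed: int,
    ) -> "ComponentModel":
        rng = np.random.Generator(np.random.PCG64(seed))
        return cls(config, vocab, init_parameters(config, len(vocab), rng), mu, sigma)

    @property
    def label_order(self):
        return ANSWER_ORDER if self.config.role == "answer" else QTYPE_ORDER

    # -- forward graph -----------------------------------------------------

    def _block(self, x: ad.Tensor, p: Mapping[str, ad.Tensor], prefix: str, d: int):
        q = x @ p[f"{prefix}/wq"]
        k = x @ p[f"{prefix}/wk"]
        v = x @ p[f"{prefix}/wv"]
        att = ad.softmax((q @ k.swap_last()) * (1.0 / np.sqrt(d)), axis=-1)
        x = ad.layer_norm(
            x + (att @ v) @ p[f"{prefix}/wo"], p[f"{prefix}/ln1_g"], p[f"{prefix}/ln1_b"]
        )
        h = (x @ p[f"{prefix}/mlp_w1"] + p[f"{prefix}/mlp_b1"]).relu()
        return ad.layer_norm(
            x + h @ p[f"{prefix}/mlp_w2"] + p[f"{prefix}/mlp_b2"],
            p[f"{prefix}/ln2_g"],
            p[f"{prefix}/ln2_b"],
        )

    def _text_branch(self, p: Mapping[str, ad.Tensor], ids: np.ndarray) -> ad.Tensor:
        x = ad.embedding(p["theta2/tok_emb"], ids) + p["theta2/pos_emb"][: ids.shape[1]]
        for b in range(self.config.text_blocks):
            x = self._block(x, p, f"theta2/blk{b}", self.config.d_text)
        return x[:, 0, :]  # final hidden state at the summary-marker position

    def _vis_branch(
        self, p: Mapping[str, ad.Tensor], images: np.ndarray, return_states: bool = False
    ) -> ad.Tensor:
        patches = patchify(images, self.config.patch_size, self.mu, self.sigma)
        x = ad.as_tensor(patches) @ p["theta1/patch_emb"] + p["theta1/patch_bias"]
        x = x + p["theta1/pos_emb"]
        for b in range(self.config.vis_blocks):
            x = self._block(x, p, f"theta1/blk{b}", self.config.d_vis)
        if return_states:
            return x  # final per-patch hidden states, pre-pooling
        return x.mean(axis=1)  # global average pool over patch states

    def _fuse(self, text: ad.Tensor, vis: ad.Tensor) -> ad.Tensor:
        if self.config.normalization == "l2":
            text = ad.l2_normalize(text)
            vis = ad.l2_normalize(vis)
        else:  # per-vector standardization
            text = ad.layer_norm(text, ad.as_tensor(1.0), ad.as_tensor(0.0))
            vis = ad.layer_norm(vis, ad.as_tensor(1.0), ad.as_tensor(0.0))
        return ad.concat([text, vis], axis=-1)

    def forward_logits(
        self, p: Mapping[str, ad.Tensor], ids: np.ndarray, images: np.ndarray
    ) -> ad.Tensor:
        fused = self._fuse(self._text_branch(p, ids), self._vis_branch(p, images))
        h = (fused @ p["theta3/w1"] + p["theta3/b1"]).relu()
        return h @ p["theta3/w2"] + p["theta3/b2"]

    def wrap_params(
        self, params: Optional[ParameterSet] = None, requires_grad: bool = False
    ) -> dict[str, ad.Tensor]:
        src = params if params is not None else self.params
        return {
            k: ad.Tensor(v, requires_grad=requires_grad) for k, v in src.entries.items()
        }

    # -- inference ---------------------------------------------------------

    def batch_ids(self, questions: Sequence[str]) -> np.ndarray:
        """Tokenize and pad/truncate to the fixed max_len."""
        pad = self.vocab.token_to_id[PAD]
        out = np.full((len(questions), self.config.max_len), pad, dtype=np.int64)
        for i, q in enumerate(questions):
            ids = tokenize(q, self.vocab).ids[: self.config.max_len]
            out[i, : len(ids)] = ids
        return out

    def predict_proba(
        self,
        ids: np.ndarray,
        images: np.ndarray,
        params: Optional[ParameterSet] = None,
        batch_size: int = 64,
    ) -> np.ndarray:
        p = self.wrap_params(params)
        chunks = []
        for i in range(0, ids.shape[0], batch_size):
            logits = self.forward_logits(p, ids[i : i + batch_size], images[i : i + batch_size])
            chunks.append(ad.softmax(logits, axis=-1).data)
        return np.concatenate(chunks, axis=0)

    def predict_indices(
        self, ids: np.ndarray, images: np.ndarray, params: Optional[ParameterSet] = None
    ) -> np.ndarray:
        return np.argmax(self.predict_proba(ids, images, params), axis=-1)


# ---------------------------------------------------------------------------
# Single-sample operation surface (thin wrappers over the batched graph)


def extract_text_features(tokens: TokenSequence, model: ComponentModel) -> np.ndarray:
    """Final hidden state at the summary-marker position; length D_t."""
    ids = np.asarray(tokens.ids, dtype=np.int64)
    if ids.min(initial=0) < 0 or ids.max(initial=0) >= len(model.vocab):
        raise ValueError("token id out of vocabulary range")
    return model._text_branch(model.wrap_params(), ids[None, :]).data[0]


def extract_image_features(image: np.ndarray, model: ComponentModel) -> np.ndarray:
    """Mean-pooled final patch states; length D_v."""
    return model._vis_branch(model.wrap_params(), np.asarray(image)[None]).data[0]


def fuse(text: np.ndarray, vis: np.ndarray) -> np.ndarray:
    """L2-normalize each modality independently, concatenate text-first."""
    text = np.asarray(text, dtype=np.float64)
    vis = np.asarray(vis, dtype=np.float64)
    if not (np.isfinite(text).all() and np.isfinite(vis).all()):
        raise ValueError("non-finite feature entries")
    out = []
    for v in (text, vis):
        n = np.linalg.norm(v)
        if n == 0.0:
            logger.warning("fuse(): zero-norm modality vector maps to zero")
            out.append(v)
        else:
            out.append(v / n)
    return np.concatenate(out)


def classify(
    fused: np.ndarray, model: ComponentModel
) -> tuple[np.ndarray, "AnswerLabel | QuestionType"]:
    """Softmax scores over the head's label space and the argmax label.

    Ties break toward the lowest label index.
    """
    p = model.wrap_params()
    f = ad.as_tensor(np.asarray(fused, dtype=np.float64)[None, :])
    if f.shape[-1] != model.config.d_text + model.config.d_vis:
        raise ValueError("fused feature width does not match the head")
    h = (f @ p["theta3/w1"] + p["theta3/b1"]).relu()
    logits = h @ p["theta3/w2"] + p["theta3/b2"]
    scores = ad.softmax(logits, axis=-1).data[0]
    return scores, model.label_order[int(np.argmax(scores))]
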