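import numpy as np
import pytest

from fundusvqa.data import build_vocabulary, image_stats, load_split
from fundusvqa.encoders import EncoderConfig
from fundusvqa.synthgen import SynthConfig, generate_dataset
from fundusvqa.training import TrainConfig, train_component


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """A small uniform-mix dataset: manifest + loaded arrays."""
    out = tmp_path_factory.mktemp("tiny")
    cfg = SynthConfig(
        n_samples={"train": 80, "val": 20, "test": 20}, image_size=(32, 32), seed=7
    )
    manifest = generate_dataset(cfg, out)
    vocab = build_vocabulary(manifest)
    train = load_split(manifest, "train", vocab)
    val = load_split(manifest, "val", vocab)
    test = load_split(manifest, "test", vocab)
    mu, sigma = image_stats(train)
    return {
        "dir": out,
        "config": cfg,
        "manifest": manifest,
        "vocab": vocab,
        "train": train,
        "val": val,
        "test": test,
        "mu": mu,
        "sigma": sigma,
    }


def small_model_config(role: str, image_size=(32, 32)) -> EncoderConfig:
    return EncoderConfig(
        d_text=32,
        d_vis=32,
        patch_size=8,
        text_blocks=1,
        vis_blocks=1,
        head_hidden=64,
        role=role,
        image_size=image_size,
    )


@pytest.fixture(scope="session")
def trained_qtype(tiny_dataset):
    """A question-type classifier trained on the tiny fixture."""
    d = tiny_dataset
    model, ckpts = train_component(
        d["train"],
        d["val"],
        TrainConfig(role="qtype", batch_size=16, learning_rate=3e-3, epochs=3, seed=0),
        small_model_config("qtype"),
        d["vocab"],
        d["mu"],
        d["sigma"],
    )
    return model, ckpts


@pytest.fixture(scope="session")
def trained_answer(tiny_dataset):
    """An answer classifier (and its checkpoint stream) on the tiny fixture."""
    d = tiny_dataset
    model, ckpts = train_component(
        d["train"],
        d["val"],
        TrainConfig(role="answer", batch_size=16, learning_rate=3e-3, epochs=3, seed=1),
        small_model_config("answer"),
        d["vocab"],
        d["mu"],
        d["sigma"],
    )
    return model, ckpts


@pytest.fixture(scope="session")
def rng():
    return np.random.Generator(np.random.PCG64(1234))
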