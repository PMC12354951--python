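import numpy as np
import pytest

from guidegraph import gnn_model as M
from guidegraph.graph_builder import build_dataset
from guidegraph.synthetic_data import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def small_records():
    spec = SyntheticSpec(n=40, seed=7, hairpin_fraction=0.4)
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def small_graphs(small_records):
    return build_dataset(small_records).graphs


@pytest.fixture(scope="session")
def tiny_cfg():
    return M.ModelConfig(
        hidden_dim=16,
        attention_heads=2,
        max_epochs=8,
        patience=3,
        batch_size=16,
        seed=0,
    )


@pytest.fixture(scope="session")
def trained_small(small_graphs, tiny_cfg):
    """A small model trained for a few epochs, shared across tests."""
    model = M.init_model(tiny_cfg, small_graphs[0].feature_dim)
    return M.train(model, small_graphs[8:], small_graphs[:8], tiny_cfg)


def random_dot_bracket(rng: np.random.Generator, length: int) -> str:
    """Uniform-ish random *valid* dot-bracket string of the given length."""
    chars = []
    open_count = 0
    for i in range(length):
        remaining = length - i
        choices = ["."]
        if remaining > open_count:  # room to open and still close everything
            if remaining - 1 >= open_count + 1:
                choices.append("(")
        if open_count > 0:
            choices.append(")")
        if remaining == open_count:  # must close from here on
            choices = [")"]
        c = choices[rng.integers(len(choices))]
        if c == "(":
            open_count += 1
        elif c == ")":
            open_count -= 1
        chars.append(c)
    return "".join(chars)
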