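import itertools

import numpy as np
import pytest

from goalcat.gm_core import CPTBlock, GenerativeModel, VariableSpec
from goalcat.model_zoo import StructureConfig


def random_model(rng, n_vars=None, max_card=3, roles=None):
    """A random valid model: random topological DAG, random joint child groups,
    Dirichlet-distributed tables."""
    n_vars = n_vars or int(rng.integers(2, 6))
    names = [f"v{i}" for i in range(n_vars)]
    cards = rng.integers(2, max_card + 1, size=n_vars)
    roles = roles or ["feature"] * n_vars
    variables = [VariableSpec(n, r, int(c)) for n, r, c in zip(names, roles, cards)]

    # partition the (topologically ordered) variables into child groups
    blocks = []
    i = 0
    while i < n_vars:
        size = int(min(rng.integers(1, 3), n_vars - i))
        children = tuple(names[i : i + size])
        pool = names[:i]
        n_par = int(rng.integers(0, min(len(pool), 2) + 1)) if pool else 0
        parents = tuple(rng.choice(pool, size=n_par, replace=False)) if n_par else ()
        child_cards = tuple(int(cards[names.index(c)]) for c in children)
        parent_cards = tuple(int(cards[names.index(p)]) for p in parents)
        raw = rng.gamma(1.0, size=child_cards + parent_cards) + 1e-6
        table = raw / raw.sum(axis=tuple(range(len(children))), keepdims=True)
        blocks.append(CPTBlock(f"b{len(blocks)}", children, parents, table))
        i += size
    return GenerativeModel(variables, blocks, {"structure": "random"})


def random_config(rng, max_card=4, max_feats=3) -> StructureConfig:
    return StructureConfig(
        F=int(rng.integers(1, max_feats + 1)),
        n_f=int(rng.integers(2, max_card + 1)),
        F1=int(rng.integers(1, max_feats + 1)),
        F2=int(rng.integers(1, max_feats + 1)),
        n_f1=int(rng.integers(2, max_card + 1)),
        n_f2=int(rng.integers(2, max_card + 1)),
        n_L1=int(rng.integers(2, max_card + 1)),
        n_L2=int(rng.integers(2, max_card + 1)),
        n_c=int(rng.integers(2, max_card + 1)),
        n_a=int(rng.integers(2, max_card + 1)),
        n_g=int(rng.integers(2, max_card + 1)),
        epsilon=float(rng.uniform(0.0, 0.5)),
    )


def brute_force_joint(model):
    """Independent joint-table construction: loop every assignment, multiply cells."""
    from goalcat.gm_core import joint_probability

    names = model.variable_names
    cards = [model.cardinality(n) for n in names]
    table = np.zeros(cards)
    for states in itertools.product(*[range(c) for c in cards]):
        table[states] = joint_probability(model, dict(zip(names, states)))
    return table, names


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def minimal_cfg():
    return StructureConfig(epsilon=0.1)


@pytest.fixture
def animal_cfg():
    return StructureConfig(F1=2, F2=3, epsilon=0.1)
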