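"""Constructors for the four canonical goal-directed categorization structures.

Model one
    flat: independent features project (with their action) straight to the goal.
Model two
    a single latent cause generates all features jointly; the latent (not the
    features) projects, with the action, to the goal.
Model three
    two-level hierarchy: a high-order latent jointly generates a feature subset
    and the low-order latent; the low-order latent generates the other subset
    and drives the goal.
Model four
    Model three plus an explicit context variable gating the latent→goal
    mapping, with its own noisy observation.

Every feature has a noisy observation child: the observation reports the true
feature state with probability 1−epsilon and any other state with the
remaining mass spread uniformly (symmetric confusion). Observation blocks are
tagged ``common`` because they are shared by the structures being compared and
never enter characteristic-parameter counts.

Default tables are uniform wherever the structure does not pin them down;
callers (the environment simulator, tests) override tables by block name.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Mapping, Optional

import numpy as np
import yaml

from .gm_core import CPTBlock, GenerativeModel, VariableSpec

__all__ = [
    "ConfigError",
    "StructureConfig",
    "noise_table",
    "build_m1",
    "build_m2",
    "build_m2_split",
    "build_m3",
    "build_m3_context_folded",
    "build_m4",
    "BUILDERS",
]


class ConfigError(ValueError):
    """A structure configuration violates its invariants."""


@dataclass(frozen=True)
class StructureConfig:
    """Cardinalities parameterizing every structure and every counting formula.

    ``F``/``n_f`` describe the flat feature set of Models one and two;
    ``F1``/``n_f1`` and ``F2``/``n_f2`` the low- and high-order feature
    subsets of the hierarchical structures. ``n_L1`` is the low-order latent
    cardinality — in the context comparison it plays the role of the
    content-only latent, with the context's ``n_c`` states factored out.
    ``epsilon`` is the probability that an observation misreports its feature.
    """

    F: int = 2
    n_f: int = 2
    F1: int = 2
    F2: int = 2
    n_f1: int = 2
    n_f2: int = 2
    n_L1: int = 2
    n_L2: int = 2
    n_c: int = 2
    n_a: int = 2
    n_g: int = 2
    epsilon: float = 0.1

    def __post_init__(self) -> None:
        for field_name in ("n_f", "n_f1", "n_f2", "n_L1", "n_L2", "n_c", "n_a", "n_g"):
            v = getattr(self, field_name)
            if not isinstance(v, (int, np.integer)) or v < 2:
                raise ConfigError(f"{field_name} must be an integer >= 2, got {v!r}")
        for field_name in ("F", "F1", "F2"):
            v = getattr(self, field_name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ConfigError(f"{field_name} must be an integer >= 1, got {v!r}")
        if not (0.0 <= self.epsilon <= 0.5):
            raise ConfigError(f"epsilon must lie in [0, 0.5], got {self.epsilon!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "StructureConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {
            k: (float(v) if k == "epsilon" else int(v)) for k, v in mapping.items()
        }
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path) -> "StructureConfig":
        with open(path) as fh:
            text = fh.read()
        if str(path).endswith(".json"):
            return cls.from_mapping(json.loads(text))
        return cls.from_mapping(yaml.safe_load(text))


def noise_table(cardinality: int, epsilon: float) -> np.ndarray:
    """Symmetric confusion P(observation | feature): 1−epsilon on the diagonal."""
    if cardinality < 2:
        raise ConfigError("noise table needs cardinality >= 2")
    t = np.full((cardinality, cardinality), epsilon / (cardinality - 1))
    np.fill_diagonal(t, 1.0 - epsilon)
    return t


def _uniform(child_cards: tuple[int, ...], parent_cards: tuple[int, ...]) -> np.ndarray:
    n_child = int(np.prod(child_cards))
    t = np.full(child_cards + parent_cards, 1.0 / n_child)
    return t


def _apply_tables(model: GenerativeModel, tables: Optional[Mapping]) -> GenerativeModel:
    if not tables:
        return model
    for name, raw in tables.items():
        b = model.block(name)
        arr = np.asarray(raw, dtype=float).reshape(b.table.shape)
        b.table = arr
    return model


def _feature_chain(names, cards, epsilon, obs_prefix="o"):
    """Observation variables + noise blocks for a list of feature variables."""
    variables, blocks = [], []
    for fname, card in zip(names, cards):
        oname = obs_prefix + fname[1:] if fname.startswith("f") else obs_prefix + fname
        variables.append(VariableSpec(oname, "observation", card))
        blocks.append(
            CPTBlock(
                f"obs_{fname}",
                (oname,),
                (fname,),
                noise_table(card, epsilon),
                frozenset({"common", "observation"}),
            )
        )
    return variables, blocks


def build_m1(cfg: StructureConfig, tables: Optional[Mapping] = None) -> GenerativeModel:
    """Model one: features map directly to the goal, no latent variable."""
    feats = [f"f{i + 1}" for i in range(cfg.F)]
    variables = [VariableSpec(f, "feature", cfg.n_f) for f in feats]
    blocks = [
        CPTBlock(f"prior_{f}", (f,), (), _uniform((cfg.n_f,), ())) for f in feats
    ]
    ovars, oblocks = _feature_chain(feats, [cfg.n_f] * cfg.F, cfg.epsilon)
    variables += ovars
    blocks += oblocks
    variables += [VariableSpec("a", "action", cfg.n_a), VariableSpec("g", "goal", cfg.n_g)]
    blocks.append(CPTBlock("prior_a", ("a",), (), _uniform((cfg.n_a,), ())))
    blocks.append(
        CPTBlock(
            "goal",
            ("g",),
            tuple(feats) + ("a",),
            _uniform((cfg.n_g,), (cfg.n_f,) * cfg.F + (cfg.n_a,)),
        )
    )
    model = GenerativeModel(variables, blocks, {"structure": "m1", "config": cfg.to_dict()})
    return _apply_tables(model, tables)


def build_m2(cfg: StructureConfig, tables: Optional[Mapping] = None) -> GenerativeModel:
    """Model two: one latent cause jointly generates all features and drives the goal."""
    feats = [f"f{i + 1}" for i in range(cfg.F)]
    variables = [VariableSpec("l1", "latent_low", cfg.n_L1)]
    variables += [VariableSpec(f, "feature", cfg.n_f) for f in feats]
    blocks = [
        CPTBlock("prior_l1", ("l1",), (), _uniform((cfg.n_L1,), ())),
        CPTBlock(
            "features",
            tuple(feats),
            ("l1",),
            _uniform((cfg.n_f,) * cfg.F, (cfg.n_L1,)),
        ),
    ]
    ovars, oblocks = _feature_chain(feats, [cfg.n_f] * cfg.F, cfg.epsilon)
    variables += ovars
    blocks += oblocks
    variables += [VariableSpec("a", "action", cfg.n_a), VariableSpec("g", "goal", cfg.n_g)]
    blocks.append(CPTBlock("prior_a", ("a",), (), _uniform((cfg.n_a,), ())))
    blocks.append(
        CPTBlock("goal", ("g",), ("l1", "a"), _uniform((cfg.n_g,), (cfg.n_L1, cfg.n_a)))
    )
    model = GenerativeModel(variables, blocks, {"structure": "m2", "config": cfg.to_dict()})
    return _apply_tables(model, tables)


def _hier_feature_vars(cfg: StructureConfig):
    low = [f"f1_{i + 1}" for i in range(cfg.F1)]
    high = [f"f2_{j + 1}" for j in range(cfg.F2)]
    return low, high


def build_m2_split(cfg: StructureConfig, tables: Optional[Mapping] = None) -> GenerativeModel:
    """Model two over the two-subset feature set (the hierarchy comparison's flat rival).

    One latent jointly generates both subsets; block ``features`` therefore
    carries ``n_f1^F1 * n_f2^F2 * n_L1`` cells.
    """
    low, high = _hier_feature_vars(cfg)
    variables = [VariableSpec("l1", "latent_low", cfg.n_L1)]
    variables += [VariableSpec(f, "feature", cfg.n_f1) for f in low]
    variables += [VariableSpec(f, "feature", cfg.n_f2) for f in high]
    blocks = [
        CPTBlock("prior_l1", ("l1",), (), _uniform((cfg.n_L1,), ())),
        CPTBlock(
            "features",
            tuple(low + high),
            ("l1",),
            _uniform((cfg.n_f1,) * cfg.F1 + (cfg.n_f2,) * cfg.F2, (cfg.n_L1,)),
        ),
    ]
    ovars, oblocks = _feature_chain(
        low + high, [cfg.n_f1] * cfg.F1 + [cfg.n_f2] * cfg.F2, cfg.epsilon
    )
    variables += ovars
    blocks += oblocks
    variables += [VariableSpec("a", "action", cfg.n_a), VariableSpec("g", "goal", cfg.n_g)]
    blocks.append(CPTBlock("prior_a", ("a",), (), _uniform((cfg.n_a,), ())))
    blocks.append(
        CPTBlock("goal", ("g",), ("l1", "a"), _uniform((cfg.n_g,), (cfg.n_L1, cfg.n_a)))
    )
    model = GenerativeModel(
        variables, blocks, {"structure": "m2_split", "config": cfg.to_dict()}
    )
    return _apply_tables(model, tables)


def build_m3(cfg: StructureConfig, tables: Optional[Mapping] = None) -> GenerativeModel:
    """Model three: high-order latent jointly generates the high feature subset and L1.

    The high subset and L1 are grouped as one child block under L2 — that
    grouping, not separate L2→F2 and L2→L1 edges, is what the characteristic
    cell count ``n_f2^F2 * n_L1 * n_L2`` enumerates.
    """
    low, high = _hier_feature_vars(cfg)
    variables = [
        VariableSpec("l2", "latent_high", cfg.n_L2),
        VariableSpec("l1", "latent_low", cfg.n_L1),
    ]
    variables += [VariableSpec(f, "feature", cfg.n_f1) for f in low]
    variables += [VariableSpec(f, "feature", cfg.n_f2) for f in high]
    blocks = [
        CPTBlock("prior_l2", ("l2",), (), _uniform((cfg.n_L2,), ()), frozenset({"common"})),
        CPTBlock(
            "hier",
            tuple(high) + ("l1",),
            ("l2",),
            _uniform((cfg.n_f2,) * cfg.F2 + (cfg.n_L1,), (cfg.n_L2,)),
        ),
        CPTBlock(
            "features1",
            tuple(low),
            ("l1",),
            _uniform((cfg.n_f1,) * cfg.F1, (cfg.n_L1,)),
        ),
    ]
    ovars, oblocks = _feature_chain(
        low + high, [cfg.n_f1] * cfg.F1 + [cfg.n_f2] * cfg.F2, cfg.epsilon
    )
    variables += ovars
    blocks += oblocks
    variables += [VariableSpec("a", "action", cfg.n_a), VariableSpec("g", "goal", cfg.n_g)]
    blocks.append(CPTBlock("prior_a", ("a",), (), _uniform((cfg.n_a,), ())))
    blocks.append(
        CPTBlock("goal", ("g",), ("l1", "a"), _uniform((cfg.n_g,), (cfg.n_L1, cfg.n_a)))
    )
    model = GenerativeModel(variables, blocks, {"structure": "m3", "config": cfg.to_dict()})
    return _apply_tables(model, tables)


def build_m4(cfg: StructureConfig, tables: Optional[Mapping] = None) -> GenerativeModel:
    """Model four: Model three plus an observed context gating the latent→goal map."""
    model = build_m3(cfg)
    model.metadata["structure"] = "m4"
    model.variables.append(VariableSpec("c", "context", cfg.n_c))
    model.variables.append(VariableSpec("oc", "context_observation", cfg.n_c))
    model.__post_init__()
    goal_idx = model.block_index("goal")
    model.blocks[goal_idx] = CPTBlock(
        "goal",
        ("g",),
        ("l1", "c", "a"),
        _uniform((cfg.n_g,), (cfg.n_L1, cfg.n_c, cfg.n_a)),
    )
    model.blocks.insert(
        0, CPTBlock("prior_c", ("c",), (), _uniform((cfg.n_c,), ()), frozenset({"common"}))
    )
    model.blocks.append(
        CPTBlock(
            "obs_c",
            ("oc",),
            ("c",),
            noise_table(cfg.n_c, cfg.epsilon),
            frozenset({"common", "observation"}),
        )
    )
    return _apply_tables(model, tables)


def build_m3_context_folded(cfg: StructureConfig, tables: Optional[Mapping] = None) -> GenerativeModel:
    """The context-free rival of Model four: context folded into the latent.

    The latent gets ``n_L1 * n_c`` states (content × context). Features and
    goal are grouped as one joint child block given (latent, action); the
    block's ``n_f1^F1 * n_g * n_L1 * n_c * n_a`` cells are the characteristic
    count of this alternative.
    """
    low = [f"f1_{i + 1}" for i in range(cfg.F1)]
    n_lf = cfg.n_L1 * cfg.n_c
    variables = [VariableSpec("l1", "latent_low", n_lf)]
    variables += [VariableSpec(f, "feature", cfg.n_f1) for f in low]
    blocks = [
        CPTBlock("prior_l1", ("l1",), (), _uniform((n_lf,), ())),
    ]
    ovars, oblocks = _feature_chain(low, [cfg.n_f1] * cfg.F1, cfg.epsilon)
    variables += ovars
    variables += [VariableSpec("a", "action", cfg.n_a), VariableSpec("g", "goal", cfg.n_g)]
    blocks.append(
        CPTBlock(
            "features_goal",
            tuple(low) + ("g",),
            ("l1", "a"),
            _uniform((cfg.n_f1,) * cfg.F1 + (cfg.n_g,), (n_lf, cfg.n_a)),
        )
    )
    blocks += oblocks
    blocks.append(CPTBlock("prior_a", ("a",), (), _uniform((cfg.n_a,), ())))
    model = GenerativeModel(
        variables, blocks, {"structure": "m3_context_folded", "config": cfg.to_dict()}
    )
    return _apply_tables(model, tables)


BUILDERS = {
    "m1": build_m1,
    "m2": build_m2,
    "m2_split": build_m2_split,
    "m3": build_m3,
    "m3_context_folded": build_m3_context_folded,
    "m4": build_m4,
}
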