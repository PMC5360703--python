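"""Discrete generative models with block-structured conditional probability tables.

A model is a DAG of categorical variables. Parameters live in *blocks*: a block
holds the joint conditional distribution of an ordered group of child variables
given an ordered (possibly empty) group of parent variables. Grouping children
jointly is deliberate — the cell count of a block, ``prod(child cards) *
prod(parent cards)``, is the complexity currency used throughout the package,
and which variables are grouped determines that count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

__all__ = [
    "ROLES",
    "VariableSpec",
    "CPTBlock",
    "GenerativeModel",
    "Assignment",
    "IncompleteAssignmentError",
    "validate_model",
    "joint_probability",
    "log_joint_probability",
    "count_block_cells",
    "enumerate_joint",
    "save_model",
    "load_model",
    "model_to_dict",
    "model_from_dict",
]

ROLES = frozenset(
    {
        "feature",
        "observation",
        "latent_low",
        "latent_high",
        "context",
        "context_observation",
        "action",
        "goal",
    }
)

#: probability columns must renormalize to 1 within this
NORM_TOL = 1e-12

Assignment = Mapping[str, int]


class IncompleteAssignmentError(KeyError):
    """An assignment does not cover every variable of the model."""


@dataclass(frozen=True)
class VariableSpec:
    """A categorical variable: a name, a functional role, and a state count."""

    name: str
    role: str
    cardinality: int

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for variable {self.name!r}")
        if self.cardinality < 2:
            raise ValueError(
                f"variable {self.name!r}: cardinality must be >= 2, got {self.cardinality}"
            )


@dataclass
class CPTBlock:
    """Joint conditional table P(children | parents).

    ``table`` has shape ``child_cards + parent_cards`` (child axes first, in the
    order of ``children``). For every joint parent index the slice over child
    axes sums to one.
    """

    name: str
    children: tuple[str, ...]
    parents: tuple[str, ...]
    table: np.ndarray
    tags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.children = tuple(self.children)
        self.parents = tuple(self.parents)
        self.table = np.asarray(self.table, dtype=float)
        self.tags = frozenset(self.tags)

    @property
    def n_cells(self) -> int:
        return int(self.table.size)

    def cell(self, assignment: Assignment) -> float:
        idx = tuple(assignment[v] for v in self.children + self.parents)
        return float(self.table[idx])


@dataclass
class GenerativeModel:
    variables: list[VariableSpec]
    blocks: list[CPTBlock]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._by_name = {v.name: v for v in self.variables}

    @property
    def variable_names(self) -> list[str]:
        return [v.name for v in self.variables]

    def variable(self, name: str) -> VariableSpec:
        return self._by_name[name]

    def cardinality(self, name: str) -> int:
        return self._by_name[name].cardinality

    def variables_by_role(self, *roles: str) -> list[str]:
        return [v.name for v in self.variables if v.role in roles]

    def block(self, name: str) -> CPTBlock:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(f"no block named {name!r}")

    def block_index(self, name: str) -> int:
        for i, b in enumerate(self.blocks):
            if b.name == name:
                return i
        raise KeyError(f"no block named {name!r}")

    def dag(self) -> nx.DiGraph:
        """Variable-level graph: edge parent -> child for every block.

        Children grouped in one block are additionally linked by their shared
        block only, not by mutual edges, so the graph stays a DAG when blocks
        are well formed.
        """
        g = nx.DiGraph()
        g.add_nodes_from(self.variable_names)
        for b in self.blocks:
            for p in b.parents:
                for c in b.children:
                    g.add_edge(p, c)
        return g

    @property
    def joint_size(self) -> int:
        size = 1
        for v in self.variables:
            size *= v.cardinality
        return size


def validate_model(model: GenerativeModel) -> list[str]:
    """Return human-readable invariant violations; empty list means valid."""
    problems: list[str] = []

    names = [v.name for v in model.variables]
    seen: set[str] = set()
    for n in names:
        if n in seen:
            problems.append(f"duplicate variable name {n!r}")
        seen.add(n)

    covered: dict[str, int] = {}
    for i, b in enumerate(model.blocks):
        for c in b.children:
            covered[c] = covered.get(c, 0) + 1
        for v in b.children + b.parents:
            if v not in model._by_name:
                problems.append(f"block {b.name!r} references unknown variable {v!r}")
    for n in names:
        k = covered.get(n, 0)
        if k != 1:
            problems.append(f"variable {n!r} is a child of {k} blocks (expected exactly 1)")

    for b in model.blocks:
        if any(v not in model._by_name for v in b.children + b.parents):
            continue
        child_cards = tuple(model.cardinality(c) for c in b.children)
        parent_cards = tuple(model.cardinality(p) for p in b.parents)
        expected_shape = child_cards + parent_cards
        if b.table.shape != expected_shape:
            problems.append(
                f"block {b.name!r}: table shape {b.table.shape} != expected {expected_shape}"
            )
            continue
        if np.any(b.table < -NORM_TOL) or np.any(b.table > 1 + NORM_TOL):
            problems.append(f"block {b.name!r}: entries outside [0, 1]")
        sums = b.table.sum(axis=tuple(range(len(b.children))))
        if not np.allclose(sums, 1.0, atol=1e-12, rtol=0):
            problems.append(
                f"block {b.name!r}: child-state sums deviate from 1 "
                f"(max deviation {np.max(np.abs(sums - 1.0)):.3g})"
            )

    try:
        if not nx.is_directed_acyclic_graph(model.dag()):
            cyc = nx.find_cycle(model.dag())
            problems.append(f"parent structure is cyclic: {cyc}")
    except KeyError:
        pass

    return problems


def log_joint_probability(model: GenerativeModel, assignment: Assignment) -> float:
    missing = [v for v in model.variable_names if v not in assignment]
    if missing:
        raise IncompleteAssignmentError(
            f"assignment missing variables: {', '.join(missing)}"
        )
    for name, state in assignment.items():
        if name in model._by_name and not (0 <= state < model.cardinality(name)):
            raise ValueError(f"state {state} out of range for variable {name!r}")
    total = 0.0
    for b in model.blocks:
        p = b.cell(assignment)
        if p <= 0.0:
            return -np.inf
        total += np.log(p)
    return total


def joint_probability(model: GenerativeModel, assignment: Assignment) -> float:
    """P(full assignment) — product of one cell per block."""
    return float(np.exp(log_joint_probability(model, assignment)))


def count_block_cells(model: GenerativeModel, block_selector: Iterable[int]) -> int:
    """Total table cells over the selected blocks (the complexity oracle)."""
    indices = list(block_selector)
    total = 0
    for i in indices:
        if not (0 <= i < len(model.blocks)):
            raise IndexError(f"block index {i} out of range (model has {len(model.blocks)} blocks)")
        total += model.blocks[i].n_cells
    return total


def enumerate_joint(model: GenerativeModel) -> tuple[np.ndarray, list[str]]:
    """Full joint table, one axis per variable in model order.

    Built by broadcast-multiplying every block table into the joint; feasible
    only at desk scale (the callers enforce a budget).
    """
    names = model.variable_names
    axis = {n: i for i, n in enumerate(names)}
    shape = tuple(model.cardinality(n) for n in names)
    joint = np.ones(shape, dtype=float)
    for b in model.blocks:
        involved = b.children + b.parents
        # Expand the block table to the full rank with singleton axes, then
        # move its axes into model-variable positions.
        t = b.table.reshape(b.table.shape + (1,) * (len(names) - len(involved)))
        order = [axis[v] for v in involved]
        rest = [i for i in range(len(names)) if i not in order]
        t = np.moveaxis(t, range(len(names)), order + rest)
        joint = joint * t
    return joint, names


# ---------------------------------------------------------------------------
# serialization — JSON, tables flat in row-major (child-major) order
# ---------------------------------------------------------------------------

def model_to_dict(model: GenerativeModel) -> dict:
    return {
        "variables": [
            {"name": v.name, "role": v.role, "cardinality": v.cardinality}
            for v in model.variables
        ],
        "blocks": [
            {
                "name": b.name,
                "children": list(b.children),
                "parents": list(b.parents),
                "table": b.table.ravel(order="C").tolist(),
                "tags": sorted(b.tags),
            }
            for b in model.blocks
        ],
        "metadata": model.metadata,
    }


def model_from_dict(payload: Mapping) -> GenerativeModel:
    variables = [
        VariableSpec(v["name"], v["role"], int(v["cardinality"]))
        for v in payload["variables"]
    ]
    cards = {v.name: v.cardinality for v in variables}
    blocks = []
    for b in payload["blocks"]:
        children = tuple(b["children"])
        parents = tuple(b["parents"])
        shape = tuple(cards[c] for c in children) + tuple(cards[p] for p in parents)
        table = np.asarray(b["table"], dtype=float).reshape(shape, order="C")
        blocks.append(
            CPTBlock(b["name"], children, parents, table, frozenset(b.get("tags", ())))
        )
    return GenerativeModel(variables, blocks, dict(payload.get("metadata", {})))


def save_model(model: GenerativeModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1)


def load_model(path) -> GenerativeModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))
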