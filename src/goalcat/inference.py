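"""Exact planning-as-inference on desk-scale models.

Action selection is cast as inference: the goal variable is clamped to its
attained state (index 1 by convention) alongside the sensory observations, and
the posterior over the action variable is computed exactly by enumerating the
joint. Categorization is the same machinery querying the latent variables,
with the goal left unclamped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .gm_core import GenerativeModel, enumerate_joint

__all__ = [
    "Evidence",
    "PosteriorTable",
    "ImpossibleEvidenceError",
    "BudgetError",
    "ClampError",
    "GOAL_ATTAINED",
    "posterior",
    "infer_action",
    "infer_category",
]

#: goal-state convention: index 1 = goal attained
GOAL_ATTAINED = 1

#: roles that may be clamped as evidence (plus the goal variable)
_CLAMPABLE_ROLES = {"observation", "context_observation", "goal"}

DEFAULT_BUDGET = 10_000_000


class ImpossibleEvidenceError(ValueError):
    """The clamped evidence has zero marginal probability under the model."""


class BudgetError(RuntimeError):
    """The enumeration state space exceeds the configured budget."""


class ClampError(ValueError):
    """Evidence clamps a variable that is unknown or not observable."""


@dataclass(frozen=True)
class Evidence:
    """Clamped observations; ``clamp_goal`` additionally fixes G to attained."""

    clamped: Mapping[str, int] = field(default_factory=dict)
    clamp_goal: bool = False
    allow_any: bool = False  # diagnostic override: clamp non-observation variables

    def resolve(self, model: GenerativeModel) -> dict[str, int]:
        out = dict(self.clamped)
        if self.clamp_goal:
            for g in model.variables_by_role("goal"):
                out.setdefault(g, GOAL_ATTAINED)
        for name, state in out.items():
            try:
                var = model.variable(name)
            except KeyError:
                raise ClampError(f"clamped variable {name!r} not in model") from None
            if not self.allow_any and var.role not in _CLAMPABLE_ROLES:
                raise ClampError(
                    f"variable {name!r} has role {var.role!r}; only observations "
                    "and the goal may be clamped (set allow_any for diagnostics)"
                )
            if not (0 <= state < var.cardinality):
                raise ClampError(f"state {state} out of range for {name!r}")
        return out


@dataclass
class PosteriorTable:
    """Exact conditional distribution over the query variables' joint states."""

    variables: tuple[str, ...]
    probs: np.ndarray  # shape = cardinalities of `variables`

    def prob(self, assignment: Mapping[str, int]) -> float:
        return float(self.probs[tuple(assignment[v] for v in self.variables)])

    def marginal(self, name: str) -> np.ndarray:
        i = self.variables.index(name)
        axes = tuple(j for j in range(self.probs.ndim) if j != i)
        return self.probs.sum(axis=axes)

    def mode(self, atol: float = 1e-12) -> tuple[tuple[int, ...], list[tuple[int, ...]]]:
        """(best joint state, all tied joint states); ties broken by lowest index."""
        flat_best = int(np.argmax(self.probs))
        best = np.unravel_index(flat_best, self.probs.shape)
        top = self.probs.flat[flat_best]
        tied = np.argwhere(self.probs >= top - atol)
        ties = [tuple(int(i) for i in row) for row in tied]
        return tuple(int(i) for i in best), ties

    def entropy(self) -> float:
        p = self.probs[self.probs > 0]
        return float(-(p * np.log(p)).sum())


def posterior(
    model: GenerativeModel,
    evidence: Evidence,
    query: Sequence[str],
    budget: int = DEFAULT_BUDGET,
) -> PosteriorTable:
    """Exact P(query | evidence) by summing the enumerated joint."""
    clamped = evidence.resolve(model)
    query = list(query)
    for q in query:
        if q not in model.variable_names:
            raise KeyError(f"query variable {q!r} not in model")
        if q in clamped:
            raise ClampError(f"query variable {q!r} is clamped")

    free = [n for n in model.variable_names if n not in clamped]
    space = 1
    for n in free:
        space *= model.cardinality(n)
    if space > budget:
        cards = {n: model.cardinality(n) for n in free}
        raise BudgetError(
            f"non-clamped state space {space} exceeds budget {budget}: {cards}"
        )

    joint, names = enumerate_joint(model)
    indexer = tuple(
        clamped[n] if n in clamped else slice(None) for n in names
    )
    sub = joint[indexer]  # axes: free variables in model order
    z = float(sub.sum())
    if z <= 0.0:
        raise ImpossibleEvidenceError(f"evidence {clamped} has zero probability")

    keep = [free.index(q) for q in query]
    drop = tuple(i for i in range(sub.ndim) if i not in keep)
    marg = sub.sum(axis=drop) if drop else sub
    # sum() preserved model order among kept axes; permute into query order
    kept_order = [i for i in range(len(free)) if i in keep]
    perm = [kept_order.index(k) for k in keep]
    marg = np.transpose(marg, perm)
    return PosteriorTable(tuple(query), marg / z)


def infer_action(
    model: GenerativeModel,
    observations: Evidence,
    goal_state: int = GOAL_ATTAINED,
    budget: int = DEFAULT_BUDGET,
) -> PosteriorTable:
    """Posterior over the action with the goal clamped to ``goal_state``."""
    actions = model.variables_by_role("action")
    goals = model.variables_by_role("goal")
    if not actions or not goals:
        raise ValueError("model lacks an action or goal variable")
    clamped = dict(observations.clamped)
    for g in goals:
        clamped[g] = goal_state
    ev = Evidence(clamped, clamp_goal=False, allow_any=observations.allow_any)
    return posterior(model, ev, actions, budget=budget)


def infer_category(
    model: GenerativeModel,
    observations: Evidence,
    budget: int = DEFAULT_BUDGET,
) -> PosteriorTable:
    """Joint posterior over all latent variables given the observations.

    The goal is not clamped unless ``observations.clamp_goal`` is set — plain
    perceptual categorization by default, goal-conditioned as a diagnostic.
    """
    latents = model.variables_by_role("latent_low", "latent_high")
    if not latents:
        raise ValueError("model has no latent variables")
    return posterior(model, observations, latents, budget=budget)
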