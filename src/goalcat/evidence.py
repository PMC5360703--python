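"""Bayesian model evidence with its accuracy-minus-complexity decomposition.

Every conditional-probability block carries an independent symmetric Dirichlet
prior (concentration ``alpha`` per cell, per parent configuration). Three
evidence routes are provided:

``complete_closed_form``
    all variables observed: the marginal likelihood is a product of
    Dirichlet–multinomial normalizer ratios, and the decomposition
    log evidence = accuracy − complexity is exact, with accuracy the
    posterior-expected log-likelihood (digamma form) and complexity the KL
    divergence between the Dirichlet posterior and prior on each simplex.

``latent_exact``
    latents unobserved: the evidence is the sum of the complete-data evidence
    over every joint completion of the latent states across records — exact
    but exponential in the record count, so budgeted to tiny datasets.

``em_bic``
    MAP expectation-maximization over the latent states followed by the
    Bayesian-information-criterion penalty (k/2)·log n on the maximized
    log-likelihood. Here k is the standard free-parameter count (cells minus
    one normalization constraint per parent configuration) — deliberately a
    different convention from the whole-cell characteristic counts of
    :mod:`goalcat.complexity`; the two are never mixed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, logsumexp

from .gm_core import GenerativeModel, enumerate_joint, model_from_dict, model_to_dict

__all__ = [
    "Dataset",
    "EvidenceResult",
    "EMResult",
    "IncompleteDataError",
    "PriorError",
    "SchemaError",
    "CompletionBudgetError",
    "log_marginal_complete",
    "log_marginal_latent_exact",
    "fit_em",
    "approx_evidence_bic",
    "select_model",
    "free_parameter_count",
    "observation_block_names",
]


class IncompleteDataError(ValueError):
    """A variable required by the structure is missing from the data."""


class PriorError(ValueError):
    """Invalid Dirichlet concentration."""


class SchemaError(ValueError):
    """Candidate structure and dataset disagree on the observed columns."""


class CompletionBudgetError(RuntimeError):
    """Too many joint latent completions for exact summation."""


@dataclass
class Dataset:
    """Record collection of simulated experience.

    Columns are variable names; ``latent_columns`` flags ground-truth columns
    (true features, latent causes, context) that a learner would not see.
    """

    df: pd.DataFrame
    latent_columns: tuple[str, ...] = ()
    metadata: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def observed_columns(self) -> list[str]:
        return [c for c in self.df.columns if c not in self.latent_columns]

    def observed_view(self) -> "Dataset":
        """The dataset as a learner sees it: ground-truth columns dropped."""
        return Dataset(self.df[self.observed_columns].copy(), (), dict(self.metadata))

    def to_csv(self, path) -> None:
        """Write records as CSV; ground-truth columns are flagged by a ``gt_`` prefix."""
        df = self.df.rename(columns={c: f"gt_{c}" for c in self.latent_columns})
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, latent_columns: Sequence[str] = (), metadata=None) -> "Dataset":
        df = pd.read_csv(path).astype(int)
        prefixed = {c: c[3:] for c in df.columns if c.startswith("gt_")}
        df = df.rename(columns=prefixed)
        latent = tuple(latent_columns) or tuple(prefixed.values())
        return cls(df, latent, dict(metadata or {}))


@dataclass
class EvidenceResult:
    log_evidence: float
    accuracy: float
    complexity: float
    method: str  # complete_closed_form | latent_exact | em_bic
    detail: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "log_evidence": self.log_evidence,
            "accuracy": self.accuracy,
            "complexity": self.complexity,
            "method": self.method,
            "detail": self.detail,
        }


def _codes(data: Dataset, columns: Sequence[str]) -> np.ndarray:
    missing = [c for c in columns if c not in data.df.columns]
    if missing:
        raise IncompleteDataError(f"data lacks columns: {missing}")
    return data.df[list(columns)].to_numpy(dtype=int)


def _dirichlet_terms(counts: np.ndarray, n_child_axes: int, alpha: float):
    """Per-parent-configuration evidence, accuracy and KL for one block.

    ``counts`` has child axes first; child states are flattened so each parent
    configuration is one Dirichlet–multinomial with K = prod(child cards).
    """
    child_shape = counts.shape[:n_child_axes]
    K = int(np.prod(child_shape))
    flat = counts.reshape(K, -1)  # (child states, parent configs)
    a_post = flat + alpha
    n_per_cfg = flat.sum(axis=0)
    a0_post = K * alpha + n_per_cfg

    log_ev = (
        gammaln(K * alpha)
        - gammaln(a0_post)
        + (gammaln(a_post) - gammaln(alpha)).sum(axis=0)
    )
    expected_log_theta = digamma(a_post) - digamma(a0_post)[None, :]
    accuracy = (flat * expected_log_theta).sum(axis=0)
    kl = (
        gammaln(a0_post)
        - gammaln(a_post).sum(axis=0)
        - gammaln(K * alpha)
        + K * gammaln(alpha)
        + (flat * expected_log_theta).sum(axis=0)
    )
    return float(log_ev.sum()), float(accuracy.sum()), float(kl.sum())


def _complete_terms(
    structure: GenerativeModel, cols: Mapping[str, np.ndarray], alpha: float
):
    """(log evidence, accuracy, complexity, per-block detail) from code arrays."""
    total_ev = total_acc = total_kl = 0.0
    detail = {}
    for b in structure.blocks:
        names = b.children + b.parents
        missing = [v for v in names if v not in cols]
        if missing:
            raise IncompleteDataError(f"data lacks columns: {missing}")
        counts = np.zeros(b.table.shape)
        np.add.at(counts, tuple(cols[v] for v in names), 1.0)
        ev, acc, kl = _dirichlet_terms(counts, len(b.children), alpha)
        total_ev += ev
        total_acc += acc
        total_kl += kl
        detail[b.name] = {"log_evidence": ev, "accuracy": acc, "complexity": kl}
    return total_ev, total_acc, total_kl, detail


def log_marginal_complete(
    structure: GenerativeModel, data: Dataset, alpha: float = 1.0
) -> EvidenceResult:
    """Exact marginal likelihood when every variable (latents included) is observed."""
    if alpha <= 0:
        raise PriorError(f"alpha must be > 0, got {alpha}")
    cols = {c: data.df[c].to_numpy(dtype=int) for c in data.df.columns}
    ev, acc, kl, detail = _complete_terms(structure, cols, alpha)
    return EvidenceResult(
        ev, acc, kl, "complete_closed_form",
        {"alpha": alpha, "n": data.n, "blocks": detail},
    )


def hidden_variables(structure: GenerativeModel, data: Dataset) -> list[str]:
    return [v for v in structure.variable_names if v not in data.df.columns]


def log_marginal_latent_exact(
    structure: GenerativeModel,
    data: Dataset,
    alpha: float = 1.0,
    budget: int = 1_000_000,
) -> EvidenceResult:
    """Exact evidence by summing the complete-data evidence over all completions."""
    if alpha <= 0:
        raise PriorError(f"alpha must be > 0, got {alpha}")
    hidden = hidden_variables(structure, data)
    if not hidden:
        return log_marginal_complete(structure, data, alpha)
    cards = [structure.cardinality(h) for h in hidden]
    n_joint = int(np.prod(cards))
    if data.n * np.log(n_joint) > np.log(budget):
        raise CompletionBudgetError(
            f"{n_joint}^{data.n} completions exceed budget {budget}; use em_bic"
        )
    hidden_states = np.array(
        list(itertools.product(*[range(c) for c in cards])), dtype=int
    )
    cols = {c: data.df[c].to_numpy(dtype=int) for c in data.df.columns}

    log_terms = []
    acc_terms = []
    kl_terms = []
    for completion in itertools.product(range(len(hidden_states)), repeat=data.n):
        assigned = hidden_states[list(completion)]  # (n, len(hidden))
        for j, h in enumerate(hidden):
            cols[h] = assigned[:, j]
        ev, acc, kl, _ = _complete_terms(structure, cols, alpha)
        log_terms.append(ev)
        acc_terms.append(acc)
        kl_terms.append(kl)

    log_terms = np.asarray(log_terms)
    log_ev = float(logsumexp(log_terms))
    weights = np.exp(log_terms - log_ev)
    # completion-weighted decomposition: approximate for this method (the exact
    # identity holds per completion, not for the mixture)
    accuracy = float(np.dot(weights, acc_terms))
    complexity = float(np.dot(weights, kl_terms))
    return EvidenceResult(
        log_ev, accuracy, complexity, "latent_exact",
        {"alpha": alpha, "n": data.n, "n_completions": len(log_terms),
         "decomposition": "completion-weighted (approximate)"},
    )


# ---------------------------------------------------------------------------
# EM + BIC
# ---------------------------------------------------------------------------

def observation_block_names(structure: GenerativeModel) -> list[str]:
    return [b.name for b in structure.blocks if "observation" in b.tags]


def free_parameter_count(
    structure: GenerativeModel, exclude_blocks: Sequence[str] = ()
) -> int:
    """Standard free-parameter count: (prod child cards − 1) per parent config."""
    k = 0
    for b in structure.blocks:
        if b.name in exclude_blocks:
            continue
        n_child = int(np.prod(b.table.shape[: len(b.children)]))
        n_parent_cfgs = int(np.prod(b.table.shape[len(b.children):], initial=1))
        k += (n_child - 1) * n_parent_cfgs
    return k


@dataclass
class EMResult:
    model: GenerativeModel
    log_likelihood: float  # observed-data log-likelihood at the fitted tables
    trace: list[float]  # penalized objective per iteration (best restart)
    converged: bool
    n_iter: int
    restart: int
    seed: Optional[int]


def _clone_model(structure: GenerativeModel) -> GenerativeModel:
    return model_from_dict(model_to_dict(structure))


def _unique_rows(data: Dataset, columns: Sequence[str]):
    codes = _codes(data, columns)
    rows, counts = np.unique(codes, axis=0, return_counts=True)
    return rows, counts.astype(float)


def fit_em(
    structure: GenerativeModel,
    data: Dataset,
    alpha: float = 1.0,
    restarts: int = 1,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: Optional[int] = None,
    frozen_blocks: Sequence[str] = (),
) -> EMResult:
    """MAP expectation-maximization over the structure's hidden variables.

    Tables of ``frozen_blocks`` are kept at the structure's values (a known
    sensor model, typically the observation-noise blocks) and excluded from
    the update. The penalized objective (observed-data log-likelihood plus
    Dirichlet log-prior) is non-decreasing across iterations.
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    if seed is None:
        raise ValueError("fit_em requires an explicit seed")
    if alpha <= 0:
        raise PriorError(f"alpha must be > 0, got {alpha}")

    hidden = hidden_variables(structure, data)
    obs_cols = [v for v in structure.variable_names if v not in hidden]
    rows, weights = _unique_rows(data, obs_cols)
    names = structure.variable_names
    hidden_axis = {h: i for i, h in enumerate(hidden)}
    obs_state = [dict(zip(obs_cols, r)) for r in rows]
    free_names = [b.name for b in structure.blocks if b.name not in frozen_blocks]

    def e_step(model):
        """Expected counts per free block and the observed-data log-likelihood."""
        joint, _ = enumerate_joint(model)
        counts = {bn: np.zeros_like(model.block(bn).table) for bn in free_names}
        ll = 0.0
        for r, m in zip(obs_state, weights):
            indexer = tuple(r[v] if v in r else slice(None) for v in names)
            w = joint[indexer]  # axes = hidden vars in model order
            z = float(w.sum())
            if z <= 0.0:
                return counts, -np.inf
            ll += m * np.log(z)
            post = w / z
            for bn in free_names:
                b = model.block(bn)
                bvars = b.children + b.parents
                hidden_in_block = [v for v in bvars if v in hidden_axis]
                drop = tuple(
                    i for i, h in enumerate(hidden) if h not in bvars
                )
                marg = post.sum(axis=drop) if drop else post
                # marg axes follow hidden order; rearrange to block order
                kept = [h for h in hidden if h in bvars]
                perm = [kept.index(v) for v in hidden_in_block]
                marg = np.transpose(marg, perm) if perm else marg
                idx = tuple(
                    r[v] if v in r else slice(None) for v in bvars
                )
                counts[bn][idx] += m * marg
        return counts, ll

    def m_step(model, counts):
        for bn in free_names:
            b = model.block(bn)
            c = np.maximum(counts[bn] + (alpha - 1.0), 0.0)
            child_axes = tuple(range(len(b.children)))
            norm = c.sum(axis=child_axes, keepdims=True)
            uniform = 1.0 / np.prod([c.shape[i] for i in child_axes])
            with np.errstate(invalid="ignore", divide="ignore"):
                theta = np.where(norm > 0, c / np.where(norm > 0, norm, 1.0), uniform)
            b.table = theta

    def log_prior(model):
        if alpha == 1.0:
            return 0.0
        total = 0.0
        for bn in free_names:
            t = model.block(bn).table
            pos = t[t > 0]
            total += (alpha - 1.0) * np.log(pos).sum()
        return total

    rng = np.random.default_rng(seed)
    best: Optional[EMResult] = None
    for restart in range(restarts):
        model = _clone_model(structure)
        for bn in free_names:
            b = model.block(bn)
            child_axes = tuple(range(len(b.children)))
            raw = rng.gamma(1.0, size=b.table.shape) + 1e-3
            b.table = raw / raw.sum(axis=child_axes, keepdims=True)
        trace: list[float] = []
        converged = False
        ll = -np.inf
        if not hidden:
            # degenerate case: one closed-form MAP update from observed counts
            counts, ll0 = e_step(model)
            m_step(model, counts)
            _, ll = e_step(model)
            trace = [ll + log_prior(model)]
            converged = True
            it = 1
        else:
            for it in range(1, max_iter + 1):
                counts, ll = e_step(model)
                obj = ll + log_prior(model)
                if trace and obj - trace[-1] < tol:
                    trace.append(obj)
                    converged = obj >= trace[-2] - 1e-9
                    break
                trace.append(obj)
                m_step(model, counts)
            # refresh the likelihood at the final tables
            _, ll = e_step(model)
        cand = EMResult(
            model, float(ll), [float(x) for x in trace], bool(converged),
            len(trace), restart, seed,
        )
        if best is None or cand.log_likelihood > best.log_likelihood:
            best = cand
    return best


def approx_evidence_bic(
    structure: GenerativeModel,
    data: Dataset,
    alpha: float = 1.0,
    seed: Optional[int] = None,
    restarts: int = 2,
    max_iter: int = 200,
    tol: float = 1e-6,
    frozen_blocks: Sequence[str] = (),
) -> EvidenceResult:
    """BIC-penalized evidence approximation: max log-likelihood − (k/2)·log n."""
    em = fit_em(
        structure, data, alpha=alpha, restarts=restarts, max_iter=max_iter,
        tol=tol, seed=seed, frozen_blocks=frozen_blocks,
    )
    k = free_parameter_count(structure, exclude_blocks=frozen_blocks)
    penalty = 0.5 * k * np.log(data.n)
    return EvidenceResult(
        em.log_likelihood - penalty, em.log_likelihood, float(penalty), "em_bic",
        {"alpha": alpha, "n": data.n, "k": k, "seed": seed,
         "converged": em.converged, "n_iter": em.n_iter,
         "warning": None if em.converged else "EM did not converge within max_iter"},
    )


def select_model(
    candidates: Sequence[GenerativeModel],
    data: Dataset,
    method: str = "bic",
    alpha: float = 1.0,
    seed: Optional[int] = None,
    **kwargs,
) -> list[tuple[GenerativeModel, EvidenceResult]]:
    """Rank candidate structures by log evidence on a shared dataset.

    Ties are broken by fewer total table cells, then by input order.
    """
    for m in candidates:
        missing = [c for c in data.df.columns if c not in m.variable_names]
        if missing:
            raise SchemaError(
                f"candidate {m.metadata.get('structure', '?')} lacks variables "
                f"for data columns {missing}"
            )
    scored = []
    for i, m in enumerate(candidates):
        if method == "complete":
            res = log_marginal_complete(m, data, alpha)
        elif method == "exact":
            res = log_marginal_latent_exact(m, data, alpha, **kwargs)
        elif method == "bic":
            res = approx_evidence_bic(m, data, alpha=alpha, seed=seed, **kwargs)
        else:
            raise ValueError(f"unknown method {method!r}")
        cells = sum(b.n_cells for b in m.blocks)
        scored.append((i, cells, m, res))
    scored.sort(key=lambda t: (-t[3].log_evidence, t[1], t[0]))
    return [(m, res) for _, _, m, res in scored]
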