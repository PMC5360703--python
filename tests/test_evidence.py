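import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from goalcat.envsim import WorldSpec, make_world, simulate
from goalcat.evidence import (
    CompletionBudgetError,
    Dataset,
    IncompleteDataError,
    PriorError,
    SchemaError,
    approx_evidence_bic,
    fit_em,
    free_parameter_count,
    log_marginal_complete,
    log_marginal_latent_exact,
    observation_block_names,
    select_model,
)
from goalcat.gm_core import CPTBlock, GenerativeModel, VariableSpec
from goalcat.model_zoo import StructureConfig, build_m1, build_m2


def single_variable_model(card=2):
    return GenerativeModel(
        [VariableSpec("x", "feature", card)],
        [CPTBlock("px", ("x",), (), np.full(card, 1.0 / card))],
    )


def dataset(**cols):
    return Dataset(pd.DataFrame({k: list(v) for k, v in cols.items()}))


def latent_world_data(n, seed, epsilon=0.1, F=3):
    cfg = StructureConfig(F=F, n_f=2, n_L1=2, epsilon=epsilon)
    spec = WorldSpec(
        "latent", cfg, goal_rule={"type": "correct_action", "table": [0, 1]}, seed=seed
    )
    world = make_world(spec)
    return cfg, world, simulate(world, n, seed=seed + 1)


class TestCompleteDataEvidence:
    def test_single_record_uniform_predictive(self):
        res = log_marginal_complete(single_variable_model(), dataset(x=[0]))
        assert res.log_evidence == pytest.approx(math.log(0.5), abs=1e-12)

    def test_sequential_predictive_rule(self):
        # second identical observation has predictive probability (1+1)/(2+1)
        res = log_marginal_complete(single_variable_model(), dataset(x=[0, 0]))
        assert res.log_evidence == pytest.approx(math.log(0.5) + math.log(2 / 3), abs=1e-12)

    def test_matches_quadrature_over_the_simplex(self):
        # one binary block: evidence = ∫ θ^n1 (1−θ)^n0 p(θ) dθ under Beta(α, α)
        records = [0, 1, 1, 0, 1]
        n1, n0 = sum(records), len(records) - sum(records)
        for alpha in (0.5, 1.0, 2.5):
            res = log_marginal_complete(single_variable_model(), dataset(x=records), alpha)
            dens = lambda t: t ** (alpha - 1) * (1 - t) ** (alpha - 1)
            norm, _ = integrate.quad(dens, 0, 1)
            val, _ = integrate.quad(lambda t: t**n1 * (1 - t) ** n0 * dens(t) / norm, 0, 1)
            assert res.log_evidence == pytest.approx(math.log(val), abs=1e-9)

    def test_decomposition_identity_on_random_data(self, rng):
        cfg = StructureConfig(F=2, n_L1=2, epsilon=0.2)
        for alpha in (0.5, 1.0, 3.0):
            for seed in range(4):
                _, world, data = latent_world_data(40, seed=100 + seed)
                res = log_marginal_complete(world, data, alpha)
                assert res.log_evidence == pytest.approx(
                    res.accuracy - res.complexity, abs=1e-9
                )
                assert res.complexity >= 0

    def test_record_order_irrelevant(self, rng):
        _, world, data = latent_world_data(30, seed=7)
        shuffled = Dataset(data.df.sample(frac=1, random_state=3), data.latent_columns)
        a = log_marginal_complete(world, data)
        b = log_marginal_complete(world, shuffled)
        assert a.log_evidence == pytest.approx(b.log_evidence, abs=1e-10)

    def test_missing_latent_column_raises(self):
        _, world, data = latent_world_data(5, seed=7)
        with pytest.raises(IncompleteDataError):
            log_marginal_complete(world, data.observed_view())

    def test_bad_alpha_raises(self):
        with pytest.raises(PriorError):
            log_marginal_complete(single_variable_model(), dataset(x=[0]), alpha=0.0)


def brute_force_completion_sum(structure, data, hidden, alpha=1.0):
    """Independent oracle: predictive-rule evidence summed over completions.

    Complete-data evidence is computed by the sequential predictive rule
    P(x_i | past) = (α + count) / (Kα + total) block by block — a different
    route than the log-Gamma closed form.
    """
    cards = [structure.cardinality(h) for h in hidden]
    total = 0.0
    for completion in itertools.product(
        *[itertools.product(*[range(c) for c in cards]) for _ in range(data.n)]
    ):
        rows = data.df.to_dict("records")
        for r, states in zip(rows, completion):
            r.update(dict(zip(hidden, states)))
        prob = 1.0
        for b in structure.blocks:
            counts = {}
            K = int(np.prod(b.table.shape[: len(b.children)]))
            for r in rows:
                child = tuple(r[c] for c in b.children)
                parent = tuple(r[p] for p in b.parents)
                seen = counts.setdefault(parent, {})
                n_parent = sum(seen.values())
                prob *= (alpha + seen.get(child, 0)) / (K * alpha + n_parent)
                seen[child] = seen.get(child, 0) + 1
        total += prob
    return math.log(total)


class TestLatentExactEvidence:
    def test_disconnected_latent_marginalizes_out(self):
        m = GenerativeModel(
            [VariableSpec("x", "feature", 2), VariableSpec("h", "latent_low", 3)],
            [
                CPTBlock("px", ("x",), (), np.array([0.5, 0.5])),
                CPTBlock("ph", ("h",), (), np.full(3, 1 / 3)),
            ],
        )
        data = dataset(x=[0, 1, 0])
        rest = GenerativeModel(m.variables[:1], m.blocks[:1])
        exact = log_marginal_latent_exact(m, data)
        complete = log_marginal_complete(rest, data)
        assert exact.log_evidence == pytest.approx(complete.log_evidence, abs=1e-9)

    def test_two_record_binary_latent_equals_four_term_sum(self):
        cfg = StructureConfig(F=2, n_L1=2, epsilon=0.1)
        _, world, data = latent_world_data(2, seed=5, F=2)
        obs = Dataset(data.df.drop(columns=["l1"]))  # features kept, latent hidden
        got = log_marginal_latent_exact(world, obs)
        assert got.detail["n_completions"] == 4
        want = brute_force_completion_sum(world, obs, ["l1"])
        assert got.log_evidence == pytest.approx(want, abs=1e-9)

    def test_matches_completion_sum_on_random_small_instances(self, rng):
        for seed in range(6):
            n = int(rng.integers(1, 4))  # ≤ 2^3 = 8 ≤ 64 completions
            _, world, data = latent_world_data(n, seed=200 + seed, F=2)
            obs = Dataset(data.df.drop(columns=["l1"]))
            got = log_marginal_latent_exact(world, obs)
            want = brute_force_completion_sum(world, obs, ["l1"])
            assert got.log_evidence == pytest.approx(want, abs=1e-9)

    def test_deterministic_tables_restrict_contributing_completions(self):
        cfg = StructureConfig(F=2, n_L1=2, epsilon=0.0)
        feats = np.zeros((2, 2, 2))
        feats[0, 0, 0] = feats[1, 1, 1] = 1.0
        world = build_m2(cfg, tables={"features": feats})
        # features observed and consistent with exactly one latent state each
        data = dataset(
            f1=[0, 1], f2=[0, 1], o1=[0, 1], o2=[0, 1], a=[0, 1], g=[1, 1]
        )
        exact = log_marginal_latent_exact(world, data)
        completed = dataset(
            f1=[0, 1], f2=[0, 1], o1=[0, 1], o2=[0, 1], a=[0, 1], g=[1, 1], l1=[0, 1]
        )
        # the single surviving completion must carry all the evidence mass
        # except the latent block's own Dirichlet factor over other completions
        assert exact.log_evidence >= log_marginal_complete(world, completed).log_evidence

    def test_budget_exceeded_recommends_em(self):
        _, world, data = latent_world_data(50, seed=9)
        with pytest.raises(CompletionBudgetError, match="em_bic"):
            log_marginal_latent_exact(world, data.observed_view())


class TestEM:
    def test_objective_trace_is_monotone(self):
        cfg, world, data = latent_world_data(200, seed=21)
        m = build_m2(cfg)
        em = fit_em(m, data.observed_view(), seed=3, restarts=1, max_iter=60,
                    frozen_blocks=observation_block_names(m))
        diffs = np.diff(em.trace)
        assert np.all(diffs > -1e-8)

    def test_complete_data_reduces_to_count_estimate(self):
        cfg, world, data = latent_world_data(100, seed=31)
        em = fit_em(world, data, seed=3, restarts=1)  # all variables observed
        assert em.converged and em.n_iter == 1
        counts = np.zeros(2)
        np.add.at(counts, data.df["l1"].to_numpy(), 1.0)
        np.testing.assert_allclose(
            em.model.block("prior_l1").table, counts / counts.sum(), atol=1e-12
        )

    def test_frozen_blocks_keep_their_tables(self):
        cfg, world, data = latent_world_data(80, seed=41)
        m = build_m2(cfg)
        frozen = observation_block_names(m)
        before = {n: m.block(n).table.copy() for n in frozen}
        em = fit_em(m, data.observed_view(), seed=3, restarts=1, frozen_blocks=frozen)
        for n in frozen:
            np.testing.assert_array_equal(em.model.block(n).table, before[n])

    def test_recovers_deterministic_feature_templates(self):
        # identifiable regime: each latent state emits one fixed pattern and
        # the goal rule is deterministic, so observation noise is the only
        # stochastic element, every record's latent is pinned by its goal
        # contingency, and the maximum-likelihood tables sit at the truth
        cfg = StructureConfig(F=3, n_f=2, n_L1=2, epsilon=0.1)
        spec = WorldSpec(
            "latent", cfg,
            determinism={"feature_slack": 0.0, "goal_success": 1.0, "goal_fail": 0.0},
            goal_rule={"type": "correct_action", "table": [0, 1]}, seed=42,
        )
        world = make_world(spec)
        data = simulate(world, 500, seed=43)
        m = build_m2(cfg)
        em = fit_em(m, data.observed_view(), seed=7, restarts=3, max_iter=200,
                    frozen_blocks=observation_block_names(m))
        truth = world.block("features").table
        fitted = em.model.block("features").table
        best = min(
            max(
                0.5 * np.abs(fitted[..., perm[s]] - truth[..., s]).sum()
                for s in range(cfg.n_L1)
            )
            for perm in itertools.permutations(range(cfg.n_L1))
        )
        assert best <= 0.1


class TestBIC:
    def test_no_latents_equals_count_fit_minus_penalty(self):
        cfg, world, data = latent_world_data(60, seed=51)
        res = approx_evidence_bic(world, data, seed=3)  # complete data: no hidden
        k = free_parameter_count(world)
        assert res.complexity == pytest.approx(0.5 * k * math.log(60))
        assert res.log_evidence == pytest.approx(res.accuracy - res.complexity)

    def test_single_record_has_zero_penalty(self):
        res = approx_evidence_bic(single_variable_model(), dataset(x=[0]), seed=3)
        assert res.complexity == 0.0

    def test_free_parameter_count_subtracts_normalizations(self):
        m = build_m2(StructureConfig(F=2, n_L1=2, n_a=2, n_g=2))
        # prior_l1: 1; features (4−1)·2 = 6; obs 2·2; prior_a 1; goal 1·2·2 = 4
        assert free_parameter_count(m) == 1 + 6 + 4 + 1 + 4
        assert free_parameter_count(m, exclude_blocks=observation_block_names(m)) == 12

    def test_agrees_with_exact_evidence_ranking_on_tiny_data(self):
        # latent hidden, features observed: 2^10 completions per candidate
        agree = 0
        total = 50
        cfg = StructureConfig(F=2, n_L1=2, epsilon=0.1)
        for rep in range(total):
            _, world, data = latent_world_data(10, seed=300 + rep, F=2)
            obs = Dataset(data.df.drop(columns=["l1"]))
            m1, m2 = build_m1(cfg), build_m2(cfg)
            exact = [
                log_marginal_latent_exact(m, obs).log_evidence for m in (m1, m2)
            ]
            bic = [
                approx_evidence_bic(m, obs, seed=rep, restarts=2).log_evidence
                for m in (build_m1(cfg), build_m2(cfg))
            ]
            agree += (exact[0] > exact[1]) == (bic[0] > bic[1])
        assert agree / total >= 0.9


class TestSelectModel:
    def test_duplicate_candidates_tie_broken_by_input_order(self):
        cfg, world, data = latent_world_data(50, seed=61)
        c1, c2 = build_m2(cfg), build_m2(cfg)
        c1.metadata["tag"], c2.metadata["tag"] = "first", "second"
        ranked = select_model([c1, c2], data.observed_view(), method="bic", seed=5)
        assert ranked[0][0].metadata["tag"] == "first"
        assert ranked[0][1].log_evidence == pytest.approx(ranked[1][1].log_evidence)

    def test_schema_mismatch_raises(self):
        cfg, world, data = latent_world_data(10, seed=71)
        small = build_m1(StructureConfig(F=2))  # lacks o3
        with pytest.raises(SchemaError):
            select_model([small], data.observed_view(), method="bic", seed=5)

    def test_per_record_evidence_stabilizes_with_sample_size(self):
        cfg = StructureConfig(F=3, n_f=2, n_L1=2, epsilon=0.1)
        rates = {}
        for n in (50, 200, 800):
            _, world, data = latent_world_data(n, seed=81)
            m = build_m2(cfg)
            res = approx_evidence_bic(
                m, data.observed_view(), seed=5, restarts=2,
                frozen_blocks=observation_block_names(m),
            )
            rates[n] = res.log_evidence / n
        assert abs(rates[800] - rates[200]) < abs(rates[200] - rates[50]) + 0.05
        assert abs(rates[800] - rates[200]) < 0.2
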