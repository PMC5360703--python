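# Methods

## Model representation

A generative model is a DAG of categorical variables, each with a functional
role (feature, observation, low/high-order latent, context, context
observation, action, goal). Parameters live in *blocks*: a block is the joint
conditional table of an ordered group of child variables given shared
parents, stored child-axes-first. Grouping matters — the cell count
`prod(child cardinalities) × prod(parent cardinalities)` is the complexity
currency of the whole package, and the structural comparisons are defined by
which blocks two rivals do not share. Two conventions coexist deliberately
and are never mixed:

- **characteristic cell counts** (complexity module): every cell is counted,
  with no deduction for normalization constraints — the convention under
  which the closed-form counts match brute-force enumeration of the
  constructed models (64/40 in the hierarchy example, 64/24 in the context
  example, thresholds 2 and 3.5);
- **free-parameter counts** (BIC penalty): cells minus one normalization
  constraint per parent configuration, the standard statistical convention.

State indexing is 0-based. The goal variable's state 1 means "attained".
Joint probabilities are evaluated in log space; a full joint table is
materialized only at desk scale (enumeration budget 10⁷ states by default).

One documented wrinkle in the counting calculus: evaluated at all-minimal
cardinalities, the hierarchy threshold that reproduces 64, 40 and 3.5 equals
n_f1^F1·(n_f2^F2−1)/n_f2^F2 = 3 — a two-state high-order latent already
pays off there (24 < 32 cells). A published statement that this minimal
threshold equals one is inconsistent with those same counts; this package
follows the counts and asserts the value 3 in its tests.

## Observation model

Every feature has an observation child with the same cardinality and a
symmetric confusion table: the true state is reported with probability
1−ε, the remaining mass spread uniformly. Symmetric confusion is the
simplest single-parameter noise model; nothing downstream depends on this
choice beyond the value of ε. Observation blocks are tagged `common` and are
excluded from all characteristic counts.

In Model three the high feature subset and L₁ are grouped as one joint child
block under L₂. The narrative of separate L₂→features and L₂→L₁ edges gives
the same graph but a different parameter count; only the joint grouping
reproduces the worked-example count of 40, so it is the implemented
convention. Likewise the context-free rival of Model four groups features
and goal jointly given (latent, action), with the latent carrying content ×
context states — the grouping that yields its count of 64.

## Inference

Action selection and categorization are exact conditional queries on the
enumerated joint: clamp observations (and for action queries the goal, to
its attained state), sum out everything else, normalize. Ties in the action
argmax are reported explicitly and broken toward the lowest index. Category
queries do not clamp the goal by default (perception-only reading); a flag
clamps it for goal-conditioned diagnostics. Only observation-role variables
and the goal may be clamped unless a diagnostic override is set. Evidence
with zero marginal likelihood raises rather than returning NaNs.

## Evidence and its decomposition

Each block carries an independent symmetric Dirichlet prior with
concentration α per cell (default α = 1) for every parent configuration.

- **Complete data**: the marginal likelihood is a product of
  Dirichlet–multinomial normalizer ratios (log-Gamma form). Accuracy is the
  posterior-expected log-likelihood (digamma form); complexity is the KL
  divergence from prior to posterior on each simplex. Because the posterior
  is exact, log evidence = accuracy − complexity holds to machine precision
  and is asserted at 1e-9.
- **Exact latent sum**: evidence with hidden variables is the sum of
  complete-data evidence over all joint completions across records —
  exponential in n, budgeted to ≤10⁶ completions. The accuracy/complexity
  fields for this method are completion-weighted averages and are labeled
  approximate.
- **EM + BIC**: MAP expectation-maximization over hidden states (restarts
  from seeded Dirichlet draws; the penalized objective is non-decreasing and
  this is tested), followed by max log-likelihood − (k/2)·log n.

During fitting, observation-noise blocks are frozen at their known tables (a
known sensor model) and excluded from k. This is a deliberate design choice:
the factorization P(o|l) = Σ_f P(o|f) P(f|l) does not identify the split
between feature table and noise table, so fitting both is ill-posed;
treating sensor noise as known is the standard remedy and matches how the
synthetic worlds are actually generated.

### A known limitation: parameter recovery under double slack

With soft feature templates *and* a soft goal rule, the observed-data
likelihood identifies the feature table only up to a near-flat ridge:
solutions differing by ~0.1 total variation have log-likelihoods equal to
within hundredths of a nat (a rotation freedom of the two-view mixture —
observation patterns on one side, goal-given-action contingencies on the
other — whose anchor conditions fail when both views carry interior slack).
Moreover, records whose goal outcome went the slack's "wrong way" are
better explained by flipping their latent cause, so the global ML solution
carries cross-mass between categories on the order of the goal slack, while
the true tables are only a corner-local maximum. Consequently EM point
estimates of feature tables should not be expected to be closer than ~0.1
TV to the generating tables at n ≈ 500 under the default slack settings;
with deterministic templates and a deterministic goal rule (only
observation noise) recovery is exact up to label permutation, and the test
suite demonstrates both regimes. Structure *selection* is unaffected — it
compares likelihoods, which are well identified.

## Synthetic worlds

`envsim` builds fully parameterized ground-truth worlds:

- **flat**: independent uniform features; goal attached to the full
  feature×action combination;
- **latent**: each latent state has a feature template emitted with
  probability 1−`feature_slack` (default 0.1), remaining mass uniform;
- **hierarchical**: templates at both levels plus an L₁–L₂ coupling
  (P(l₁ aligned with l₂) = 0.8 by default);
- **contextual**: the hierarchical world plus a uniform context with its own
  noisy observation, gating the goal rule.

Goal rules are declarative: a `correct_action` table maps each cause (or
cause×context, or feature-combination) configuration to its rewarded action;
the goal is attained with probability 0.9 for the rewarded action and 0.1
otherwise (defaults; 1.0/0.0 in the deterministic lion world). These slack
values were fixed once as a realistic mostly-reliable-contingency regime.
Sampling is ancestral and vectorized by parent configuration; identical
(world, n, seed) gives bit-identical datasets. Actions never influence
features — only the goal — so the action policy (uniform, or an oracle that
picks the truly best action per record) is exogenous.

What the generator does *not* emulate: continuous or high-dimensional
stimuli, temporal structure, non-stationary contingencies, and model
misspecification beyond structure choice (the scoring families always
contain or approximate the world). Passing tests therefore demonstrate the
internal consistency of the selection machinery under its own assumptions,
not performance on behavioral or neural data.

## Experiments

All experiments run 20 seeded replicates by default, score candidates by
EM+BIC with frozen observation blocks, and report per-replicate evidences
and selection frequencies. Problem sizes were chosen to keep each experiment
in the seconds-to-a-minute range on one CPU.

- **E1 (flat vs latent)**: world with one binary cause, three binary
  features, ε = 0.1, n = 500; the cause rewards its own action. The latent
  structure should win ≥90% of replicates.
- **E1-null**: independent features, and a goal rule rewarding a *different
  action for every feature combination* (two features, four actions) — a
  full-rank contingency that no soft low-dimensional latent bottleneck can
  carry. Low-rank rules (parity, feature counts) are deliberately avoided:
  a two-state latent mixed softly through its posterior reproduces them
  almost perfectly, and the flat structure would not be the parsimonious
  truth. The flat structure should win the majority.
- **E2 (hierarchy)**: the five-feature animal world, n = 500; Model three
  vs the single-latent rival.
- **E3 (context)**: the deterministic lion world; exact inference must pick
  the context-appropriate action for every feature pattern in both contexts.
- **E4 (action-dependent granularity)**: four deterministic stimulus
  patterns over two binary features, candidates with two vs four latent
  states. Same-action condition: the rewarded action depends only on the
  two-pattern set, so the coarse model wins on complexity. Different-action
  condition: each stimulus rewards its own action, so only the fine model
  keeps accuracy. This experiment uses n = 1500 per replicate: merging
  costs ≈ 0.1 nat of accuracy per record while the BIC penalty for
  splitting grows only logarithmically, so the sample size is set where the
  linear term clearly dominates (a design power calculation, not a fit to
  data).

## Numerical choices

- Posteriors and joints normalized sums are asserted at 1e-10; CPT column
  normalization at 1e-12.
- EM: convergence when the penalized objective improves by <1e-6 (default),
  best of ≥2 restarts; a non-converged fit returns with a warning flag, not
  an exception. MAP updates clip negative pseudo-counts (α < 1) at zero;
  empty parent configurations fall back to uniform.
- Thresholds are computed as exact rationals and rendered to floats.
- All stochastic entry points require an explicit seed; derived per-replicate
  seeds are drawn below 2³¹ from a seeded generator.
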