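# Methods

`delphilearn` analyses two-round ordinal rating data from modified-Delphi
stakeholder panels. A panel asks each participant to rate every question
(goal × criterion) on a 1–10 scale in a first round (R1), exposes the group
feedback in a discussion round, and collects re-ratings in a final round
(R3). The package measures two indicators of collaborative learning per
participant group — whether individuals *articulate* their own beliefs more
sharply after discussion, and whether the group's beliefs move toward
*agreement* — discovers clusters of participants with similar change
profiles, classifies each cluster into a learning style, and optionally
aggregates a learning-weighted group judgment.

## Model

Observed scores are ordinal-probit readouts of a latent continuous response
centred on the participant's latent belief:

    z[p,q,r] ~ Normal(θ[p,q,r], 1 / v[p,r]),
    y[p,q,r] = k  ⇔  γ[k−1] < z[p,q,r] ≤ γ[k],

with fixed cutpoints γ[k] = k + 0.5 (k = 1..9, γ0 = −∞, γ10 = +∞).
Fixing the cutpoints at the category midpoints anchors the latent scale;
with free cutpoints *and* free precisions the model would not be
identified. `v[p,r]` is the **articulation** of participant p in round r:
the precision of their answers around their own beliefs, read off the
residual spread across the whole question battery within a round.

Beliefs decompose into cluster-level question means and a participant-level
position offset shared across questions within a round:

    θ[p,q,r] = m[s_p, q, r] + δ[p,r],      δ[p,r] ~ Normal(0, 1 / τ[s_p, r]),
    log v[p,r] ~ Normal(μ_v[s_p, r], σ_v²),
    s_p ~ DP(α)  (truncated stick-breaking, K_max components).

This decomposition is what makes the two indicators identifiable from a
single rating per cell. If instead every cell carried its own independent
belief deviation, the per-cell belief scatter and the per-cell articulation
noise would be statistically indistinguishable (both are (participant,
question)-indexed), and the split between them would be decided by the
priors — we verified empirically that such a model happily swaps the two
variance components. With participant-level offsets, articulation is pinned
by each participant's across-question residual spread (≈48 questions per
round) and the **agreement** level by the spread of member offsets around
the cluster mean. The cost is that member beliefs differ from the cluster
profile only by a constant shift per round; idiosyncratic per-question
opinion enters the articulation residual.

Clusters carry the change structure: each has its own per-round question
means `m`, belief concentration `τ` (rising τ = members contracting around
the cluster mean = increased agreement) and articulation location `μ_v`
(rising μ_v = increased articulation). Missing scores are
missing-at-random latent variables sampled along the chain, giving
posterior-predictive imputation for free.

### Priors and defaults

| parameter | prior / default | rationale |
|---|---|---|
| cutpoints γ | fixed at k + 0.5 | anchors latent scale; identifies v, τ |
| m[k,q,r] | Normal(5.5, 3²) | centred on the scale midpoint, covers 1–10 |
| τ[k,r] | Gamma(2, 2) | mean 1 on the unit-spaced latent scale, mild |
| μ_v[k,r] | Normal(0, 1.5²) | covers v from ≈0.05 to ≈20 |
| σ_v (fixed) | 0.4 | within-cluster spread of log-articulation |
| α | Gamma(1, 1) | standard weakly-informative DP concentration |
| K_max | 20 | stick-breaking truncation, ≈3× the expected cluster count |
| chains / warmup / draws | 2 / 500 / 500 | per-seed deterministic |

## Inference

A partially collapsed blocked Gibbs sampler:

1. **Labels s** — sampled with the offset δ integrated out: marginally a
   participant's round-r response vector is compound-symmetric normal
   (Cov = I/v + J/τ), evaluated in O(Q) per cluster via Sherman–Morrison.
   Collapsing matters: conditioning on an offset drawn under the current
   label anchors participants to their cluster and freezes the partition.
2. **Offsets δ, latent responses z** — conjugate normal and truncated
   normal (inverse-CDF) draws; z is unconstrained at missing cells.
3. **log v** — adaptive Metropolis-within-Gibbs (3 proposals per sweep;
   step sizes adapt toward 44% acceptance during warmup only).
4. **Cluster parameters m, τ, μ_v, sticks, α** — conjugate updates; empty
   clusters draw from their priors.
5. **Translation moves** — two joint proposals shift `m[k,q,r]` together
   with all member `z`, and `δ[p,r]` together with the participant's `z`.
   Without them, in high-articulation regimes z hugs its centre and the
   pair random-walks in lockstep inside one category interval, so
   posterior means depend on where warmup stopped. The moves are plain
   Metropolis steps whose acceptance involves only the prior ratio and the
   category bounds (the likelihood is translation-invariant).

**Warmup partition refinement.** Incremental label updates can merge
clusters but essentially never split them (a new cluster would have to be
instantiated from a prior draw of a 96-dimensional mean profile), and
occasional escapes create self-reinforcing overfit singletons. During
warmup only — at four fixed points — a greedy split/merge/reassign search
improves a plug-in partition posterior: marginal data likelihood at
moment-fitted cluster parameters (offset integrated analytically,
log-articulation by 9-point Gauss–Hermite quadrature), the
Chinese-restaurant prior, and a BIC-style charge of ½·(2Q+4)·log P per
cluster. Plug-in articulation is capped at v = 10: on a unit-spaced ordinal
scale, higher precision is sub-category resolution, i.e. pure overfit of
tiny clusters. The refinement is an initialisation device; the sampling
phase is untouched Gibbs. A few stray singletons per panel can still
appear; they are reported as-is.

Convergence is monitored with split-R̂ and bulk ESS (via arviz) on v, m and
τ; a fit with max split-R̂(v) above 1.05 records a warning in its
diagnostics rather than raising. Because chains may settle on slightly
different partitions (stragglers differ), R̂ for participant-level v is
routinely above the threshold even when the six main clusters agree —
the warning is informative, not fatal; the reported quantities are
label-invariant and partition-based.

## Posterior summaries

- **Co-clustering matrix**: posterior probability that two participants
  share a cluster; invariant to label switching.
- **Point partition**: minimiser of Binder loss against the co-clustering
  probabilities. For ≤10 participants the minimiser is exact (all set
  partitions enumerated); otherwise the candidate set is the unique sampled
  partitions plus every average-linkage cut of 1 − co-clustering. Ties go
  to fewer clusters, then the lexicographically smallest label vector.
  Clusters are renumbered 1..K by decreasing size.
- **Articulation summary**: posterior mean and central 95% interval of
  member-averaged v per round; Δ = v̄(R3) − v̄(R1) computed draw-wise, with
  P(Δ > 0).
- **Agreement change**: per item, the sample variance of member beliefs
  within a draw, R3 minus R1 (negative = toward agreement), plus the
  across-item average and two posterior probabilities: P(avg < 0) and
  P(avg < −margin × round-1 level). Singleton clusters have no
  between-member variance and are flagged not-available.

## Learning typology

Crossing the indicators gives four styles: both increased → *learning
towards consensus*; articulation only → *learning by contrast*; agreement
only → *groupthink*; neither → *no learning*. "Increased" means the
posterior probability of the change event is ≥ 0.8 (configurable).

For agreement the event carries a practical-significance margin: the
variance must drop by more than 25% of its round-1 level (configurable).
The posterior of the realised member variance is sharp, so without a margin
any trivial contraction — including the ±20% sampling fluctuation that a
finite group of members exhibits between rounds even when nothing changed
systematically — would register as certain agreement gain. A trivial
improvement is "little-to-no change", not learning towards consensus. The
25% default is well below any change worth reporting (the planted consensus
shifts in the synthetic scenario are 60–80% reductions) and well above the
fluctuation scale of groups of ≳15 members.

The dominant style is the one covering the most participants (ties: more
clusters, then a fixed order). Weighting schemes for the final group
judgment: `uniform`, `drop_no_learning` (no-learning members get zero),
`dominant_style` (dominant-style members up-weighted 2:1 by default,
no-learning zero), `engagement` (proportional to mean satisfaction,
no-learning zero); weights renormalise to one. In the full pipeline,
singleton clusters are classified from articulation alone, with agreement
treated as not-increased — one participant cannot exhibit group agreement.

## Synthetic panels

The generator runs the model forward and is the package's test bed. A
scenario emulating a large online stakeholder panel provides the default
study conditions: 172 participants in six clusters (50/38/32/18/18/16), 12
goals × 4 criteria, two rounds, four stakeholder groups, satisfaction
responses on a 1–7 scale, and participant-level missingness (10% affected
exclusively in R1, 15% exclusively in R3, 3% in both; within an affected
round each answer goes missing with probability 0.3). Planted styles:
three learning-by-contrast clusters (articulation precision rising from ≈1
to 4–5, belief precision flat), two learning-towards-consensus (both
rising), one groupthink (articulation flat, belief precision 0.6–0.8 →
2.5–3).

Design choices that make the scenario a usable benchmark:

- **Cluster profiles genuinely differ per question.** Cluster question
  means are a shared base profile (uniform 4–7) plus a cluster offset
  (±1.5) plus per-question jitter with SD 0.8. Constant offsets are
  absorbed by participant position offsets, so the jitter is what makes
  clusters identifiable; 0.8 corresponds to priority profiles differing by
  about one scale point RMS between stakeholder subgroups.
- **Planted conditions are exact, not sampled.** Member offsets are
  truncated-normal draws (±2.5σ) standardised within each cluster-round so
  the realised member-belief variance equals 1/τ* exactly. An
  "agreement-flat" cluster therefore has a genuinely flat realised
  agreement level, rather than one that drifts by sampling luck; extreme
  lone members that the clustering would shave off are avoided by the
  truncation.

What the generator does **not** emulate: correlation of a participant's
beliefs across rounds (offsets are drawn independently per round), response
styles (end-aversion, acquiescence), informative missingness, or any effect
of the discussion content. Passing the recovery tests therefore shows the
machinery identifies the structure it models, not that real panels satisfy
that structure.

## Problem sizes and checks

The test suite fits study-scale panels (172 × 48 × 2, two chains, 400
warmup + 500 kept draws each, ≈1000 post-warmup draws total, ≈12 s per fit)
for five generator seeds and requires adjusted Rand index ≥ 0.9 against the
generating partition plus full style recovery in at least four of them.
Calibration uses twenty 24-participant null panels (no planted change):
the 95% interval for Δarticulation must cover zero in at least 18.
Exactness checks: ordinal category probabilities against numerical
integration (≤1e−8), and the Binder point partition against exhaustive
minimisation over all 203 partitions of 6 and all 4140 of 8 elements.
`scripts/acceptance.py` reruns the same computations from scratch at sizes
chosen to finish in a few minutes.

## Known limitations

- The per-round independence of position offsets means the model does not
  exploit (or estimate) within-participant belief persistence between
  rounds.
- Mixing over partitions after warmup is local: the chain stays near the
  refined mode, so co-clustering probabilities understate partition
  uncertainty; the split-R̂ warning on v flags this honestly.
- A handful of participants can end up in straggler singletons or pairs;
  they are reported as their own clusters rather than force-merged.
- Agreement for singleton clusters is undefined; the pipeline classifies
  them from articulation alone.
- The satisfaction survey enters only reporting and engagement weighting,
  never the likelihood.
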