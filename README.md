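# delphilearn

Collaborative-learning analysis of two-round modified-Delphi stakeholder
panels.

Online Delphi panels collect ordinal ratings (here: 1–10) on a battery of
questions in a first round, let participants discuss the group feedback,
and re-rate in a final round. Classical analyses either force consensus or
average the final round; both discard what happened *between* the rounds.
`delphilearn` instead models the ratings of both rounds jointly and asks,
for data-revealed groups of participants, two questions:

- did individual **articulation** increase — the precision `v[p,r]` with
  which participant *p*'s answers concentrate around their own latent
  beliefs in round *r*;
- did group **agreement** increase — did the variance of member beliefs
  around their cluster's position shrink between rounds?

The model is a Bayesian ordinal-probit with fixed cutpoints
`γ_k = k + 0.5`, latent beliefs `θ[p,q,r] = m[s_p,q,r] + δ[p,r]` (cluster
question-profile plus participant position offset), per-participant
per-round articulation precision, and a Dirichlet-process mixture over
participants so the data choose the number of clusters. Inference is
blocked Gibbs sampling; missing answers are imputed from their posterior
predictive distributions. Crossing the two indicators classifies each
cluster into a learning style:

|                         | articulation ↑            | articulation not ↑ |
|-------------------------|---------------------------|--------------------|
| **agreement ↑**         | learning towards consensus | groupthink        |
| **agreement not ↑**     | learning by contrast       | no learning       |

and the style covering the most participants is the panel's dominant
learning style. Cluster styles can then weight the final group judgment
(e.g. drop or down-weight no-learning participants).

## Worked example

Simulate a study-like panel — 172 participants in six planted clusters,
12 goals × 4 criteria, rounds R1 and R3, realistic missingness — then run
the full pipeline (fit, cluster, classify, weight):

```sh
delphilearn simulate --seed 7 --out panel.csv --truth truth.csv
delphilearn run --panel panel.csv --out results --seed 7
```

which prints (abridged):

```
wrote 172 participants x 48 items (751 missing cells) to panel.csv
Typology of collaborative learning
====================================

learning by contrast: Cluster 1 (n = 46), Cluster 2 (n = 37), Cluster 3 (n = 32), ...
groupthink: Cluster 4 (n = 17)
learning towards consensus: Cluster 5 (n = 16), Cluster 6 (n = 16), ...

Dominant learning style: learning by contrast (4 of 11 clusters, 116 of 172 participants)
```

The three large clusters sharpened their members' articulation without
converging (learning by contrast), one cluster converged without
articulation gain (groupthink), two did both — matching the planted
structure. `results/` holds the point partition, per-cluster articulation
intervals (`articulation.csv`, below), per-item agreement changes,
stakeholder composition and engagement profiles, participant weights, the
weighted group judgment, figures, and a manifest with the config hash and
seed that reproduce every number:

```
cluster,n_members,v_mean_R1,...,v_mean_R3,...,delta_mean,...,p_delta_positive
1,46,1.03696,...,5.42661,...,4.38965,...,1
2,37,1.25189,...,4.35352,...,3.10163,...,1
```

Cluster 1's articulation rose from ≈1.0 to ≈5.4 (posterior P(Δ>0) = 1):
its members' answers ended up five times more concentrated around their own
positions after the discussion round.

The same steps are available as a library:

```python
import delphilearn as dl

panel, truth = dl.generate_panel(dl.paper_like_scenario(seed=7))
draws = dl.fit_clf(panel, dl.ModelConfig(seed=7))
partition = dl.point_partition(dl.coclustering_matrix(draws),
                               panel.participant_ids, sampled_labels=draws.s)
profiles = dl.cluster_change_profiles(draws, partition, panel)
styles = {p.cluster: dl.classify_cluster(p) for p in profiles if not p.singleton}
```

Real panels load with `dl.read_panel("ratings.csv")` from long-format
delimited text (one row per participant × goal × criterion × round, empty
score cells = missing), with an optional satisfaction table.

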