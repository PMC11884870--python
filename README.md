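# gamebrain

Brain markers of human prosocial behavior: a reusable, tested pipeline
linking decisions in 15 economic games (dictator, trust, ultimatum,
prisoner's dilemma, public goods with and without punishment, second- and
third-party punishment, faith, chicken, preemptive strike, stag hunt) to
multimodal brain features — cortical thickness, T1w/T2w myelin, NODDI
neurite indices, subcortical volumes, and graph-theoretic metrics of
functional and structural connectomes.

The package is aimed at social-neuroscience groups who want the whole
chain as auditable code: a payoff-faithful simulator of the games, the
confound-residualization and feature-assembly conventions, connectome
thresholding by maximal global cost efficiency, and a sparse multi-set
canonical correlation analysis with permutation inference — plus a
synthetic-study generator with a planted prosociality factor so every
stage can be validated by parameter recovery.

## The model

Four participant × variable blocks (games; structure; functional
connectivity; structural connectivity) are residualized on confounds,
z-scored, and PCA-reduced (30 / 60 / 60 / 60 components). Sparse
multi-set CCA then solves

```
max  Σ_{i<j} wᵢᵀ XᵢᵀXⱼ wⱼ    s.t.  ‖wᵢ‖₂ ≤ 1,  ‖wᵢ‖₁ ≤ cᵢ
```

by block coordinate ascent with an exact soft-threshold line solve. The
lasso bounds cᵢ are tuned by comparing each candidate against a
row-permutation null; significance of the resulting sum of canonical
correlations is assessed by permutation; and the result is interpreted
through *cross-loadings* — correlations of the original variables with the
other blocks' canonical variates — summarized per metric class (mean, 95%
CI, percent of regions per sign) and as top-30% region maps.

Brain features enumerate to 5,441 columns at full scale: 4 cortical
metrics × 360 parcels + 41 subcortical volumes + per modality (5 nodal
graph measures × 360 + 180 homotopic interhemispheric pairs).

## Worked example

```python
from gamebrain import RunConfig, run_pipeline

report = run_pipeline(RunConfig(seed=5, n_perm=199,
                                max_candidates=12, n_sources=24))
print(round(report["sum_cor"], 3))
print({k: round(v, 3) for k, v in report["pairwise_correlations"].items()})
print(report["p_value_add_one"])
print(report["recovery"]["sign_match"])
```

prints (exactly reproducible for this seed):

```
5.927
{'games~structure': 0.989, 'games~functional_connectivity': 0.991,
 'games~structural_connectivity': 0.982}
0.005
{'interhemispheric_f': True, 'interhemispheric_s': True, 'myelin': True,
 'thickness': True, 'path_length_f': True, 'path_length_s': True,
 'clustering_f': True, 'local_efficiency_f': True, 'ventricle': True,
 'corpus_callosum': True}
```

Reading this: the pipeline simulated a 217-participant study with a
planted latent prosociality factor, ran the full analysis, and found a
strong canonical association (sum of the six pairwise variate correlations
5.93; the three games–brain correlations are listed separately) that beats
all 199 permutation nulls (add-one p = 1/200). Every planted loading
direction was recovered from the cross-loadings: stronger homotopic
interhemispheric connectivity, thicker cortex, lower myelin, shorter
nodal path lengths, higher functional segregation, larger corpus callosum
and smaller ventricles all co-vary with prosocial behavior. On synthetic
data at the default signal-to-noise the correlations are near ceiling;
their values are a property of the generator, not a claim about real
cohorts (see `docs/methods.md`).

The payoff engine and generator are importable on their own:

```python
from gamebrain import compute_payoff, simulate_study
compute_payoff("TG", {"trustor": 1000, "trustee": 0.5})
# {'trustor': 1500.0, 'trustee': 1500.0}
study = simulate_study(217, seed=1)   # behavioral + MRI tables + truth
```

A thin CLI mirrors the stages: `gamebrain simulate`, `gamebrain run-all`,
`gamebrain robustness`, `gamebrain fit` (see `--help`).

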