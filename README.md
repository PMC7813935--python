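# diseasetraj

Matched comparison of disease trajectories in hospital-claims data.

Multimorbidity — the accumulation of multiple chronic conditions — is better
described by *trajectories* (typical temporal sequences of disease
combinations) than by counting diagnoses. `diseasetraj` implements a complete
trajectory pipeline for claims registries, aimed at epidemiologists and
health-services researchers comparing how fast different patient populations
(e.g., diabetic patients vs. matched non-diabetic controls, or male vs.
female patients) progress through multimorbid health states:

- **Health states.** Each patient's state at the end of half-year *t* is a
  cumulative binary vector **v** = (v₁, …, v_M) over M WHO disease blocks of
  3-character ICD-10 codes (default universe A00–N99, M = 131); v_d = 1 iff a
  diagnosis from block *d* occurred at or before *t*.
- **Monothetic divisive clustering (DIVCLUS-T).** States are clustered by
  recursively splitting on single blocks so that every cluster is described
  by human-readable inclusion and exclusion criteria; the split maximizing
  the reduction of within-cluster inertia n·Σ_d p_d(1−p_d) is applied
  greedily, the elbow of the inertia curve selects the number of clusters,
  and an upper cut of the same tree yields macro-clusters. Because states
  only gain coordinates over time and clusters are ordered exclusion-side
  first, the transition matrix is upper triangular *by construction*.
- **Transition tensors and matched comparison.** The rate
  q_{s,a,k,j} = N_{s,a,k,j} / E_{s,a,k} estimates the per-half-year
  probability that a patient of sex *s* and age group *a* steps from cluster
  *k* to *j* (death is absorbing; rows sum to 1). Cohort and control arms are
  compared elementwise by the risk difference RD = q^case − q^control, sexes
  by SRD = q^male − q^female, averaged over age/sex strata; thresholded
  trajectory networks (node size = cluster size, node color = in-hospital
  mortality) are exported as GraphML and node-link JSON.
- **Cohort construction.** Case selection by a washout window (no A00–N99
  code) plus a case-defining code range (default E10–E14) in observation, and
  exact 1:2 matching on age group, sex and region, without replacement,
  seeded.
- **Synthetic claims generator.** Registry data of this kind is
  access-restricted, so the package ships a seeded generator that plants a
  latent Markov trajectory model (cumulative block emissions, case/sex rate
  multipliers, state-dependent death) and exposes the planted truth, making
  every stage testable end to end.

## Worked example

```python
import numpy as np
import diseasetraj as dt

cfg = dt.PipelineConfig(
    simulation=dt.demo_config(n_cases=2000, rho=2.0, sex_multiplier=1.5),
    out_dir="out/demo", seed=42, max_leaves=24, n_clusters=14,
)
res = dt.run_pipeline(cfg)

print(f"matched cases: {len(res.assignment.case_ids)} "
      f"(controls: {len(res.assignment.control_ids)})")
print(f"clusters: {res.n_clusters}; macro-clusters: {res.cluster_to_macro.max() + 1}")
steps = res.tensor_case.N.sum(axis=(0, 1))
print(f"sub-diagonal steps (triangularity): {int(np.tril(steps, -1).sum())}")
rd = dt.average_strata(res.rd, over=("s", "a"))
off = ~np.eye(res.n_clusters, dtype=bool) & rd.defined
vals = rd.values[off]; vals = vals[vals != 0]
print(f"progression cells with RD > 0: {(vals > 0).sum()}/{vals.size} "
      f"(mean RD {vals.mean():+.4f})")
crit = res.tree.criteria(res.tree.n_leaves - 1)
labels = [res.states_case.table.label(d) for d in sorted(crit.inclusion)]
print("highest cluster includes:", "; ".join(labels))
```

prints

```
matched cases: 1972 (controls: 3944)
clusters: 14; macro-clusters: 11
sub-diagonal steps (triangularity): 0
progression cells with RD > 0: 16/18 (mean RD +0.0680)
highest cluster includes: Diabetes mellitus; Ischaemic heart diseases; Chronic lower respiratory diseases; Renal failure
```

Reading this: of 2,000 simulated diabetic-like cases, 1,972 were exactly
matched to two controls each; the elbow-overridden cut gives 14 clusters in
11 macro-clusters; no patient ever steps to a lower-ordered cluster; and
because the generator plants a doubled progression rate on heart-disease
transitions in the case arm, almost all observed progression transitions are
more frequent in cases (positive RD) — cases race ahead along the same
trajectories, ending in the high-mortality cluster whose inclusion criteria
combine diabetes, heart disease, chronic respiratory disease and renal
failure. The run directory contains every artifact (claims, cohort, states,
tree, tensors, RD/SRD tables, networks) plus a manifest with per-stage
parameters, seeds and artifact hashes; identical configs reproduce identical
manifests byte for byte.

The same stages are scriptable from a shell via the `diseasetraj` CLI
(`simulate`, `cohort`, `states`, `cluster`, `transitions`, `compare`,
`export`, `run-all`); see `diseasetraj --help`.

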