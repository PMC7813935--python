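# Methods

## Problem and data model

`diseasetraj` analyses hospital-claims registries in which each stay carries a
pseudonymized patient id, sex, a 5-year age group, a region, a half-year
timestamp, 3-character ICD-10 diagnosis codes and a discharge type (normal,
transfer, death). The analysis universe is the somatic code range A00–N99,
grouped into M contiguous WHO disease blocks (the packaged default table has
M = 131; any edited table can be substituted and every algorithm follows its
M). The health state of a patient at the end of half-year t is the cumulative
binary vector **v** ∈ {0,1}^M with v_d = 1 iff a diagnosis from block d was
recorded at or before t. States are monotone by construction: diagnoses
accumulate and are never removed.

The pipeline has five stages.

1. **Cohort** — cases are patients with a clean washout window (no A00–N99
   code) and at least one case-defining code (default E10–E14, diabetes
   mellitus) during the observation window; eligible controls are
   washout-clean patients never receiving a case code in observation. Each
   case is matched, without replacement within its exact
   (age group, sex, region) stratum, to `ratio` controls (default 2).
   Matching randomness is drawn from a per-stratum stream keyed on
   (seed, stratum), so removing one stratum from the data cannot perturb the
   matches in any other. Cases whose stratum runs out of controls are dropped
   and logged. The age used for matching is the age group at the start of the
   observation window, recovered from the patient's first observed stay
   (recorded group − (t − start)//10, since one 5-year group spans ten
   half-years).
2. **Health states** — one vector per patient per observed half-year, from
   observation start until death or window end. The death half-year is
   included as a terminal snapshot. Codes outside the block universe are
   dropped with a count.
3. **Clustering (DIVCLUS-T)** — see below. Fit on the case arm's pooled
   snapshots only (one vector per patient per half-year, no deduplication);
   control vectors are assigned to the frozen tree afterwards.
4. **Transition tensors** — steps N[s,a,k,j], exposures E[s,a,k] and rates
   q = N/E, with death absorbing (the final observed half-year contributes no
   exposure). Rows of q sum to 1 over all destinations including k itself
   wherever E > 0.
5. **Comparisons and networks** — risk difference RD = q^case − q^control,
   sex risk difference SRD = q^male − q^female within the case arm, averaged
   over age and/or sex; thresholded trajectory networks exported as GraphML
   and node-link JSON.

## DIVCLUS-T, binary specialization

Clusters are grown divisively. A split is monothetic: cluster members are
divided by the value of one coordinate d, so every cluster is exactly the set
of vectors satisfying the inclusion criteria (v_d = 1 edges) and exclusion
criteria (v_d = 0 edges) on its root path. The split criterion is the
reduction of within-cluster inertia (sum of squared Euclidean distances to
the centroid); for binary data the inertia of n vectors with coordinate means
p_d is n·Σ_d p_d(1−p_d), and all candidate splits of a cluster are scored
from its co-occurrence matrix S = XᵀX in closed form. Growth is greedy: at
each step the (cluster, coordinate) pair with the maximal reduction is split,
until `max_leaves` or no cluster is splittable. The recorded split order
yields the inertia curve I(K), any coarser cut (the macro-cluster level,
default 11), and the elbow choice of K (the interior K maximizing the second
difference of I; ties go to the smallest K; an override bypasses the
heuristic; a perfectly linear curve is flagged as having no distinct elbow).

Numerical choices. Reductions are rational numbers with small integer
numerators. Candidates within a relative 1e−9 of the float maximum are
re-compared exactly in integer arithmetic (`fractions.Fraction`), and ties
are resolved by lowest coordinate index, then lowest cluster id (creation
order). The tree is therefore fully deterministic, including on structurally
symmetric data, and provably agrees with exhaustive enumeration (tested
against an independent brute-force oracle on random instances). Minimum leaf
size for splitting defaults to 1. Empty input inertia is defined as 0.

Leaf ids are assigned in depth-first order visiting each split's exclusion
(0) child before its inclusion (1) child; cluster ids at any cut level follow
the same order. For two clusters, the one taking value 0 at their divergence
coordinate precedes the other; since state vectors only gain coordinates,
every observed transition goes to an equal-or-higher cluster id. The upper
triangularity of the step-count matrix is thus a theorem of the ordering, not
an empirical observation, and is asserted exactly in the tests.

## Transition, RD and SRD estimation

An occasion is a (patient, half-year) pair whose next half-year is observed;
dying in t+1 still makes t an occasion (the step into the death state is
real), while the death half-year itself, and the last half-year of the
window, expose nothing. Under this convention q rows sum to one and the
estimator is unbiased for a per-half-year Markov transition probability even
in the presence of state-dependent death.

Undefined cells (zero exposure in either arm) propagate as undefined rather
than zero, with per-cell support counts, so no risk difference is fabricated
for unobservable transitions. Averaging over age/sex strata is an unweighted
mean over the strata where the cell is defined in every constituent arm,
matching the convention of averaging RD over all age groups; an
exposure-weighted pooling (summing counts) is available as an option and is
what the rate-network export uses. Because both arms' q rows sum to one, RD
summed over a fully defined row is identically zero — summary statistics of
RD are therefore reported over progression (off-diagonal) cells; the
self-transition cell absorbs the compensating mass. Rendered networks exclude
self-loops for the same reason; the rate network is filtered at the default
threshold 0.007 while RD/SRD networks are exported unfiltered (threshold 0),
each overridable.

Cluster mortality is deaths while assigned to cluster k divided by all
(patient, half-year) occasions assigned to k — a per-occasion in-hospital
rate consistent with the half-year state machinery.

## Synthetic-data generator

The study registry is access-restricted, so the generator plants a known
trajectory model with the structure the pipeline assumes:

- a discrete-time absorbing Markov chain on a small latent DAG; each state,
  on entry, emits a fixed set of previously unseen blocks (so accumulation is
  monotone and cluster transitions triangular by construction);
- per half-year and patient: first at most one latent transition (categorical
  over successors; a case multiplier ρ on designated transitions in the case
  arm, a sex multiplier on designated transitions in one sex — applied in
  both arms, since population-level sex differences are not specific to the
  case condition), then in-hospital death with the post-transition state's
  hazard. Under this ordering the per-pair transition probabilities and the
  per-state hazards are exactly the targets of the downstream estimators,
  which is what makes the planted-recovery tests sharp;
- a washout window in which the chain is frozen (patients present but
  diagnosis-free, matching the eligibility design) followed by the
  observation window (defaults 12 + 24 half-years, emulating a 6-year washout
  and 12-year observation);
- case-defining block delivery: by default a truncated-geometric onset
  half-year within observation for case-arm patients (rate 0.12), leaving the
  comorbidity dynamics of the two arms identically distributed; alternatively
  a latent state flagged `is_case_entry` whose emission includes the case
  block, which control-arm patients traverse without receiving it. With
  `case_blocks` empty neither arm carries the case code and the arms are
  draws from the identical process — the configuration used for null
  calibration. A case patient who dies before onset records no case code and
  is (correctly) not selected as a case by the cohort stage;
- demographics: sex (53% male), entry age group and region drawn once per
  case; controls mirror their case's stratum so exact matching is well
  populated; age advances one 5-year group every ten half-years, with the
  clock anchored at observation start so the matching age is exactly
  recoverable from any stay row;
- output: one stay row per (patient, half-year) with new diagnoses or death —
  multiple real-world stays within a half-year are collapsed, which is
  harmless because downstream states are half-year cumulative unions. Byte
  identity of the claims table under a fixed seed is tested.

The default study-like configuration (`demo_config`) is a 7-state progression
chain with one branch — healthy → dorsopathies → metabolic disorders →
disorders of lens → heart disease (ischaemic + other forms) → {chronic lower
respiratory disease, renal failure} — with baseline per-half-year rates
0.06–0.25, hazards rising from 0.0005 (healthy) to 0.04 (heart + renal
failure), ρ = 2 on the heart-disease-involving transitions and a male
multiplier 1.5 on the late transitions toward renal failure. `chain_config`
builds pure chains (unique paths, hence a one-to-one map from latent states
to monothetic clusters) for recovery and null experiments.

What the generator does not emulate: real diagnostic coding noise
(mis-/under-coding), multiple stays per half-year, registry entry/exit in
mid-observation, realistic national age profiles, and non-Markov progression.
Passing tests therefore demonstrate correctness of the estimators and the
structural laws under the model's assumptions, not robustness of the method
to real-data violations of them.

## Problem sizes and tolerances

Recovery and null experiments use 5,000 cases with 2 matched controls each
(both arms ≥ 5,000 patients) and 20 seeded replicates; structural checks use
20 cohorts of about 2,000 patients. Planted rates are checked within 3
binomial standard errors, null RD within 3 Monte-Carlo standard errors over
replicates; inertia conservation at relative 1e−9; row normalization at
1e−12; triangularity and matching exactness exactly. Patients without any
stay row are invisible to a claims-only analysis; recovery experiments
therefore pass the generator's demographics to the state-matrix builder so
that event-free patients contribute exposure (omitting them would bias
early-state transition rates upward — conditioning on eventually having an
event). The pipeline over real claims has no such side channel, which is a
known, documented selection property of claims data rather than of the
estimator.

## Known limitations

- The elbow heuristic is only as good as the curve: smoothly decaying curves
  (no planted separation) yield K = 2; the `n_clusters` override exists for
  exactly that reason and the study-like demo uses it (14 = number of planted
  state profiles: 7 latent states × pre/post onset).
- Exact matching drops unmatchable cases rather than relaxing strata; no
  caliper or propensity alternatives.
- No confidence intervals on RD/SRD; comparisons are descriptive, as in the
  trajectory-network literature the package follows.
- 4-character ICD-10 codes, ICD-9 and SNOMED are out of scope; side and main
  diagnoses are treated identically (presence-based states).
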