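# Methods

`metactivity` couples two analysis arms that are often run together in
post-mortem brain studies of cholesterol metabolism: (1) prediction of
per-sample metabolic reaction activity by integrating transcriptomes with a
genome-scale metabolic model (GEM), followed by case–control comparison of
the binary activity calls; and (2) repeated-measures cohort statistics for
targeted metabolite (sterol/oxysterol) concentration panels measured in two
brain regions of two independent cohorts. This note describes the models,
their assumptions, the defaults and why they were chosen, what the synthetic
data emulate, and the known limitations.

## 1. Transcriptome-constrained activity prediction

### Model and state assignment

A GEM supplies a stoichiometric matrix **S** (metabolites × reactions), flux
bounds `lb ≤ v ≤ ub`, and gene–protein–reaction (GPR) rules. At steady state
mass balance requires `S·v = 0`. Expression is mapped onto reactions by
evaluating each GPR with OR → max (isoenzymes: any gene suffices) and
AND → min (complexes: the scarcest member limits the enzyme). Mapped
reaction values are discretized against the pooled 25th/75th percentiles of
all gene × sample values of one dataset (linear-interpolation quantiles):
strictly above the 75th percentile → highly expressed (set `R_H`), strictly
below the 25th → lowly expressed (`R_L`), everything else — including
values exactly at a threshold and reactions without gene evidence — is
moderate and exerts no pull on the optimization.

Pooling the quantiles globally (rather than per gene) is the default because
a single dataset-wide scale is what a rank-based "highly/lowly expressed"
classification means when the data are jointly normalized; a per-gene mode
is available (`quantile_mode="per_gene"`) for data where between-gene
intensity differences are not interpretable. An optional residualization on
sex/age (gene-wise OLS, gene means preserved) can be applied before
discretization; it is the default in the orchestrated pipeline when those
covariates are present.

### The iMAT program

For each sample the integrative metabolic analysis tool (iMAT) finds a flux
distribution maximizing agreement with the discretized expression:

```
maximize   Σ_{r∈R_H} (y⁺_r + y⁻_r) + Σ_{r∈R_L} y_r
subject to S·v = 0,  lb ≤ v ≤ ub
           v_r + y⁺_r (lb_r − ε) ≥ lb_r      r ∈ R_H
           v_r + y⁻_r (ub_r + ε) ≤ ub_r      r ∈ R_H
           y⁺_r + y⁻_r ≤ 1                   r ∈ R_H
           lb_r (1 − y_r) ≤ v_r ≤ ub_r (1 − y_r)   r ∈ R_L
           y ∈ {0,1}
```

so a satisfied `R_H` indicator forces `|v_r| ≥ ε` and a satisfied `R_L`
indicator forces `v_r = 0`. Big-M constants are taken per reaction from its
own bounds, which keeps the linear relaxation tight. The MILP is solved by
HiGHS (`scipy.optimize.milp`) with a zero relative MIP gap, i.e. to proven
optimality; the solver is deterministic for a fixed model and variable
ordering.

Parameters:

* **ε (minimum active flux)** — default 1.0 flux unit against the
  conventional ±1000 default bounds; configurable. The objective is
  invariant to jointly rescaling all bounds and ε.
* **media constraints** — a list of `(reaction, new lower bound)` pairs
  applied before solving; the canonical profile forces a glucose-like
  uptake, an oxygen-like uptake and a macromolecule-synthesis sink to
  0.01, 0.01 and 0.0001 respectively, so every personalized model shares a
  minimal guaranteed throughput and activity differences arise only from
  expression states and the rerouting they induce.
* **activity tolerance** — a reaction is called active when `|v_r| > 1e-6`
  at the returned optimum.

### Activity calling and alternate optima

The default activity call uses the single returned optimum. MILPs of this
kind generally admit alternate optima, and borderline reactions can flip
between them; cross-solver flux vectors may differ even when objectives
agree. A slower `robust` mode is provided that fixes the objective at its
optimum and asks, per reaction, whether **any** optimal solution can carry
`|v_r| ≥ ε` (two constrained re-solves per reaction); a reaction that can is
called active. The default remains the simple mode for speed; the
orchestrated pipeline records mode, ε, tolerance and solver in the activity
matrix provenance.

An exhaustive oracle (`enumerate_optimum`) tries every indicator assignment
(capped at |R_H|+|R_L| ≤ 16) and checks LP feasibility of the implied bound
tightenings; it shares no code path with the MILP and is used to verify MILP
optimality on hundreds of random toy instances.

### Group comparison

Per reaction, samples are tabulated into a 2×2 table (active/inactive ×
group) and tested with Fisher's exact test, two-sided by the
probability-mass rule (all tables with fixed margins whose probability does
not exceed the observed one); a double-the-smaller-tail rule is available
behind a flag. The effect size is the sample cross-product odds ratio
`(a·d)/(b·c)` with explicit zero-cell renderings: numerator zero → `0.000`,
denominator zero → `Inf`, both zero → `NA`. The cross-product form (not the
conditional MLE) is the default because only it produces those exact
degenerate renderings; both estimators' p-values come from the same exact
test. Network-level significance uses the raw p at 0.05 — the activity
screen is an a priori restricted reaction panel, not a genome-wide scan — and
a BH-adjusted column is emitted alongside for transparency.

### Differential expression stage

The per-gene stage fits ordinary least squares of expression on a two-level
group indicator plus covariates (sex, age, batch by default), reporting the
group coefficient, its two-sided t-test and BH adjustment across all tested
genes. This is deliberately an unmoderated per-gene model: the stage is
input preparation and reporting, not the headline computation, and with
dozens of samples per group the empirical-Bayes variance moderation of
microarray-era pipelines changes little. Constant genes are reported at
p = 1 with a flag; a group indicator collinear with covariates is an error.

## 2. Metabolite cohort statistics

### Ingestion

Long-format records carry subject, cohort, region, metabolite,
concentration, a below-LOD flag with the metabolite-specific LOD, a
missing-at-random flag, and subject covariates (group CN/ASY/AD, sex, age
at death, CERAD 0–3, Braak 0–6). Two rules are applied before modeling:

* **Missingness filter.** A metabolite whose fraction of absent values
  (left-censored included — censoring is the dominant and non-random source
  of absence in targeted panels) exceeds 30% in any cohort × region cell is
  excluded from all analyses; exactly 30% is retained. The cell-wise
  denominator reflects region-wise missingness accounting.
* **LOD/2 imputation.** Remaining below-LOD values are imputed at half the
  metabolite's LOD — the standard left-censoring point substitute for
  values known only to lie in (0, LOD).

### Repeated-measures model

Concentrations are log2-transformed. Per metabolite, one joint model covers
both regions with region-specific predictor coefficients:

```
log2(conc) ~ region + region:score + sex + age [+ cohort]
```

where `score` is the predictor: the ordinal disease coding CN=0, ASY=1,
AD=2 (a linear severity contrast consistent with the ordered-group design),
or the CERAD / Braak score for pathology models, which substitute the
continuous score for disease status and include all subjects. Age is
mean-centered. Estimation is by GEE with subjects as clusters and an
unstructured working covariance over the two regional measurements (with
two regions this is one correlation plus two variances); standard errors
are the cluster-robust (Huber–White) sandwich with the Mancl–DeRouen
small-sample bias correction. The correction matters at this design's size:
in the planted-effect simulation at ~100 subjects the plain sandwich gives
~0.91 coverage of a nominal 95% interval versus ~0.94–0.95 with the
correction; type-I error stays in the nominal band either way. A per-region
fallback (exchangeable working correlation) is used automatically if the
unstructured fit fails.

### Convergence pooling and cluster FDR

Cohorts are first fitted separately. For each metabolite × region ×
predictor, if the two cohort coefficients share a sign (an exactly-zero
estimate — a measure-zero event in practice — counts as concordant with
either sign), the association is refit on the combined data with a cohort
fixed effect and reported as a primary result at raw p < 0.05: agreement in
direction across two independent cohorts is itself the replication
safeguard. A combined-cohort refit is used rather than inverse-variance
meta-analysis because it weighs subjects, not estimates, and keeps the
covariate adjustment exact; meta-analytic pooling of the two cohort
estimates is a straightforward alternative the data layout supports.
Divergent associations stay cohort-specific and are BH-adjusted within
their a priori biochemical pathway cluster (biosynthesis / enzymatic
catabolism / non-enzymatic catabolism), with the adjustment family being
cluster × region × predictor × cohort — exactly the set of metabolite
comparisons one report row competes with.

## 3. Synthetic data

The generators produce every input the pipeline consumes, with the planted
truth serialized beside the data.

* **Toy networks** (`make_toy_network`): a mass-balanced backbone chain
  from an uptake to a secretion exchange, optional two-reaction parallel
  branches around single backbone conversions (alternative routes), random
  one/two-gene GPRs with a configurable AND fraction, and — for networks
  large enough — a designated oxygen-like auxiliary uptake and
  macromolecule-synthesis sink so the forced-rate media profile
  (0.01/0.01/0.0001) applies. The auxiliary is drained by the sink rather
  than by a backbone conversion so that no single conversion is pinned
  active by the auxiliary supply and parallel routes stay substitutable.
  Zero flux is feasible in every generated network before media constraints.
* **Cholesterol fixture** (`mini_cholesterol_fixture`): a fixed 12-reaction,
  11-metabolite pathway tracing acetyl-CoA → HMG-CoA → mevalonate →
  lanosterol → cholesterol through both the Bloch (desmosterol) and
  Kandutsch–Russell (7-dehydrocholesterol) routes, then on to
  24S-hydroxycholesterol and a lumped bile-acid sink, with an NADPH/NADP⁺
  regeneration loop closing the redox balance. GPRs carry the canonical
  enzyme names (ACAT2+HMGCS1 as a lumped complex, HMGCR, DHCR24, DHCR7,
  CYP46A1, HSD3B7, SOAT1). The SOAT1 esterification step is a deliberate
  dead end — cholesteryl ester has no consumer — so it can never carry
  steady-state flux; it exercises the blocked-reaction case and yields a
  null comparison row. Stoichiometry is pedagogical, not biochemical.
* **Expression** (`simulate_expression`): per-gene baselines
  N(mean, sd) shared across samples, planted genes starting two baseline
  SDs above the mean (clearly highly expressed) and shifted by Δ in the
  case group, i.i.d. noise on every value. The truth file records, from the
  noiseless group-level values, each reaction's expression state per group
  and the reactions whose state flips between high and low — with a forced
  backbone and an alternative branch these are the reactions whose activity
  difference is dictated by mass balance rather than solver choice.
* **Metabolomics** (`simulate_metabolomics`): log2 concentration =
  baseline + region-specific β·score + subject effect + noise, with the
  subject-effect variance set so the within-region-pair correlation equals
  ρ (default 0.5) and residual SD σ = 0.4 on the log2 scale. Default effect
  sizes are in the |β| ≈ 0.1–0.3 range typical of log2-scale brain sterol
  differences, so default power characteristics are realistic. CERAD and
  Braak are ordinal with group-ordered means (AD > ASY > CN). Left-censoring
  applies a per-metabolite LOD at a configurable concentration quantile;
  further records are removed completely at random.

What the generators do **not** emulate: probe-level microarray structure and
normalization artifacts, assay batch/plate effects, non-Gaussian
concentration tails, informative (pathology-dependent) missingness beyond
left-censoring, and any real coupling between the transcriptome and the
metabolome of the same subjects. Passing the recovery and calibration
checks therefore demonstrates correctness of the statistical machinery
under its stated model, not robustness to those real-data complications.

## 4. Validation runs and problem sizes

The acceptance script and `tests/test_acceptance.py` recompute, from
scratch (sizes chosen to exercise each property at meaningful
Monte-Carlo resolution):

* MILP vs exhaustive-oracle agreement on 200 random toy instances
  (≤12 reactions, ≤6 state labels);
* feasibility of 50 media-constrained solutions (mass-balance residual
  ≤ 1e-6, box bounds, forced rates honored);
* pipeline power on 50 seeded branch networks with threshold-crossing
  planted shifts at n = 20/20 samples, and the null false-flag rate at
  Δ = 0;
* exactness of the Fisher p against hypergeometric enumeration over all
  2×2 tables with total ≤ 40 (one representative per row/column-swap
  equivalence class; the swap invariances are verified separately);
* metabolomics-arm bias, 95% CI coverage and type-I error over 200
  replicates at ~50 subjects per cohort, plus the LOD/2 and 30%-missingness
  edge cases.

## 5. Numerical choices and degenerate inputs

* Quantiles use numpy's linear interpolation; values exactly at a threshold
  are moderate (strict inequalities), so a constant matrix discretizes to
  all-moderate rather than arbitrary states.
* MILP indicator variables are recovered by rounding the relaxed values at
  0.5; the objective is re-derived from the rounded indicators.
* A reaction whose GPR references a gene with no expression value is
  treated as evidence-free (moderate), logged, never guessed.
* Constant genes in the DE stage: p = 1 with a `constant` flag rather than
  a 0/0 t-statistic.
* `enumerate_optimum` orders assignments by descending indicator count and
  stops at the first feasible score, guaranteeing the exact optimum while
  skipping most LP solves.
* Fisher tables with an empty margin return p = 1; negative counts are
  errors.
* GEE fits that fail under the unstructured working covariance fall back to
  exchangeable; both paths use the bias-corrected sandwich.

## 6. Limitations

* Activity calls from a single optimum inherit alternate-optima ambiguity;
  the robust mode bounds it but costs two MILP solves per reaction.
* The iMAT formulation requires finite bounds; models with unbounded
  reactions must be boxed first.
* The exhaustive oracle is limited to small instances by design; MILP
  correctness on large models rests on the solver's optimality proof.
* The ordinal disease coding (CN=0, ASY=1, AD=2) asserts a linear severity
  contrast; a categorical coding would need a different reporting layout.
* Convergence pooling keys on the sign of point estimates only; two noisy
  near-zero estimates of opposite sign are routed to the (more
  conservative) cohort-specific path even when statistically
  indistinguishable.
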