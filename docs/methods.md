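# Methods

`connstats` implements a group-analysis pipeline for weighted structural
brain connectomes — per-subject symmetric matrices of mean fractional
anisotropy (FA) along tractography streamlines between parcellated gray-
matter regions (90-region AAL parcellation in the motivating use case),
compared across two disease groups (MS, NMOSD) and healthy controls (HC)
with age and sex as nuisance covariates. This note records the models,
the conventions chosen where several were defensible, and what the
synthetic validation does and does not demonstrate.

## Network model and metrics

A subject's network is a symmetric non-negative matrix `w` with zero
diagonal; `w_ij = 0` means "no connection" and the binary adjacency
`a_ij = 1{w_ij > 0}` is always derived, never stored. Path lengths use
the reciprocal transform: an edge's length is `1/w_ij`, so shortest path
lengths `d_ij` (Dijkstra) sum reciprocals along the strongest route.
Disconnected pairs have `d_ij = ∞`; they are *ignored* when averaging
the characteristic path length and contribute zero to efficiency-type
measures (inverse-distance sums). A fully disconnected network has no
defined characteristic path length and raises an error rather than
returning a sentinel.

Per node: degree `K_i` (count of neighbors), strength `S_i` (row sum of
weights), triangle intensity `t_i = Σ_{j<k} (w_ij w_jk w_ki)^{1/3}`
(geometric-mean weight per distinct triangle), clustering
`C_i = 2 t_i / (K_i (K_i − 1))` with `C_i = 0` when `K_i < 2`, local
efficiency over the neighbor subgraph, and regional efficiency (mean
inverse distance to every other node). Global measures are the five
reported in the motivating analysis: total strength `Σ_i S_i`, mean
clustering, characteristic path length, mean local efficiency, and
global efficiency.

Conventions worth stating because the definitional sources are loose:

* **Total strength sums nodal strengths**, so each undirected edge
  counts twice. This is the literal reading of "total strength = Σ S_i
  with S_i a full row sum"; halving it is a constant rescaling with no
  effect on any test.
* **Global clustering and local efficiency average over all n nodes**,
  including nodes whose value is zero by the `K_i < 2` convention.
* **Local efficiency** of node i is computed on the subgraph induced by
  the neighbors of i with i itself removed: `d_jk` is the shortest path
  within that subgraph (reciprocal-weight lengths, `1/d = 0` when the
  pair is disconnected there), and the ordered-pair sum
  `Σ_{j≠k} (w_ij w_ik / d_jk)^{1/3}` is divided by `K_i (K_i − 1)`.
  Definitional writeups of this quantity sometimes carry a stray global
  `(1/2) Σ_i` prefactor from collapsing the network average into the
  nodal formula; we follow the textual definition and the convention of
  the efficiency literature, and the brute-force oracle in the tests
  encodes the same literal reading, so the equivalence check is against
  an independent implementation of the *same* convention, not a
  tautology.
* Weights are FA values in (0, 1); no normalization is applied before
  the cube roots.

## Prevalence-based edge screening

Tractography produces spurious and missed connections. For every node
pair the *prevalence* is the fraction of control subjects with
`w_ij > 0`. For a candidate group threshold τ the "existing" edge set is
`{prevalence ≥ τ}`; each control subject then contributes false
negatives (existing edges it lacks) and false positives (non-existing
edges it has). Under these definitions FN(τ) is non-increasing and FP(τ)
non-decreasing in τ — prose descriptions of this procedure sometimes
state the opposite monotonicity, but it does not follow from the
definitions, and we implement the definitions. The optimal threshold
minimizes `max(FP, FN)` (the minimax point is where monotone curves
cross) over the grid {0, 0.01, …, 1}, with ties broken toward the
smaller τ so that more edges are retained. Prevalence and both counts
use control subjects only: letting patients shape the mask would leak
disease effects into edge selection. The control-derived mask is applied
to every subject.

## Permutation ANCOVA and FDR

Group effects are tested with the partial F statistic of the linear
model `y ~ intercept + age + sex + group`, against the reduced model
without the group columns:

    F = ((RSS_red − RSS_full)/(g−1)) / (RSS_full/(n − g − q))

Significance comes from Freedman–Lane residual permutation: fit the
reduced model once, permute its residuals, add them back to the reduced
fit, recompute F. This is the standard asymptotically exact scheme for
permutation tests with nuisance covariates, and it degenerates to plain
label permutation when no covariates are present (verified numerically).
p-values use the add-one convention `p = (1 + #{F* ≥ F})/(1 + P)`, so
the smallest attainable p is `1/(P+1)` and p-values are never zero.
Perfect model fits (RSS ≈ 0) are resolved by treating numerator sums of
squares below 1e−12 of the total SS as exactly zero signal, so constant
outcomes give F = 0 rather than 0/0.

Omnibus three-group tests are followed by three pairwise post-hoc
permutation ANCOVAs, each *refit on the two groups' subjects* (not
contrasts inside the three-group fit), with Benjamini–Hochberg FDR
across the three pairs. Nodal analyses FDR-correct the omnibus p across
the n nodes first and run post-hocs only at surviving nodes. Direction
labels ("MS < HC") come from covariate-adjusted group means (model
predictions at the grand covariate means). BH is used as the FDR method
throughout; note that BH is monotone but not idempotent — re-adjusting
an adjusted vector can only raise values.

## Network-based statistics

Edge-wise partial F values over the screened edges are thresholded at
the cluster-forming threshold (default 3.0, inclusive `F ≥ t`);
connected components of the suprathreshold graph are candidate
subnetworks whose size is their *edge count* (extent). The null
distribution of the maximum extent is built from the same Freedman–Lane
permutation stream (one permutation → one full edge-statistic matrix →
one max extent), giving each observed component a family-wise-error-
corrected p-value `(1 + #{max* ≥ extent})/(1 + P)`. Components
significant at α get per-edge pairwise post-hoc tables with FDR across
the three comparisons and direction labels. The statistic thresholded is
the partial F itself, recorded in the result metadata.

The cluster-forming threshold is an analyst's knob, not an estimated
quantity: practitioners raise it until clusters are stable. The demo and
the planted-recovery simulation use a threshold of 8.0 because with
df = (2, 40) and roughly 470 retained edges the default 3.0 admits about
6% of null edges (~28 scattered suprathreshold edges), several of which
would attach to the true component by chance; at 8.0 the expected count
of noise-only suprathreshold edges is below one, so recovered-component
membership is interpretable. FWER control itself is threshold-agnostic
and is validated at the default 3.0.

## Clinical associations

Within one disease group at a time, ordinary least squares fits

    clinical = β0 + β1·measure + β2·age + β3·sex + ε

with the clinical score as the response — the literal form of the stated
model, even though regressing the measure on the clinical score would be
the more natural causal direction. The reported quantity is the
unstandardized β1 with its partial-F p-value (equal to the two-sided
t-test for a single coefficient); a Freedman–Lane permutation p is
available by flag. EDSS is treated as continuous. Subjects with missing
clinical values are dropped pairwise; a group in which a clinical
variable is entirely missing (EDSS in controls) is skipped with a logged
notice. Fits with fewer than 5 complete subjects or collinear designs
are errors, not silent NaNs — note that in very small groups a constant
sex covariate triggers the collinearity error, which is the correct
diagnosis rather than a bug to paper over.

## Synthetic cohort generator

The generator is the test bed standing in for unavailable patient data,
so its defaults are the study conditions: group sizes 68/50/26
(MS/NMOSD/HC), ages HC and MS ~ N(35, 9²), NMOSD ~ N(44, 12²), 80%
female (sex coded female = 1). The population template is an
Erdős–Rényi graph with exactly `round(density·n(n−1)/2)` edges
(default density 0.6 on 90 nodes), resampled until connected, with
truncated-normal weights in [0.2, 0.7] (mean 0.45, SD 0.10) — an
FA-plausible range given that tracking typically seeds at FA > 0.2.
Subject networks are

    w = clip(template · group_scale · (1 + planted_delta)
             + β_age·(age − mean age) + β_sex·sex + noise, 0)

with zero template edges staying zero. Disease attenuation defaults to
group_scale 0.92 (the ratio of reported disease to control total
strength); the planted subnetwork is a connected edge set grown at
random in the template, attenuated more strongly in MS than NMOSD.
Subject noise has two parts chosen once to reproduce the reported ~10%
between-subject coefficient of variation of total strength: a global
multiplicative factor ~ N(1, 0.05²) and additive per-edge Gaussian noise
(SD 0.03). Clinical scores (EDSS-like, duration-like) are linear in the
subject's own realized total strength plus age and sex, with negative
measure coefficients so that weaker networks score worse, for disease
groups only.

What the generator does *not* emulate: spatially structured (non-ER)
topology, distance-dependent edge weights, heteroscedastic or spatially
correlated noise, missing edges in individual subjects (every subject
shares the template support, so prevalence screening on synthetic data
is degenerate unless a fixture adds dropout), lesion effects, or any
imaging-level artifact. Passing tests therefore demonstrate statistical
correctness of the machinery — calibration, FWER control, recovery of
planted effects under the stated noise model — not robustness to real
tractography pathologies.

## Validation design and problem sizes

The acceptance checks (in `tests/test_acceptance.py`, recomputed by
`scripts/acceptance.py`) use reduced problem sizes chosen as the
package's own validation design: type-I error from 1000 null cohorts of
15 subjects per group (20 nodes) at 500 permutations; NBS FWER from 500
null replicates on 40-node cohorts at 500 permutations, with the
family-wise rate bounded by 0.05 plus two Monte-Carlo standard errors;
planted-subnetwork recovery (edge-Jaccard ≥ 0.8) in 100 replicates;
GLM coverage over 500 replicates. The direction-pattern check runs at
the full study size (68/50/26 subjects, 90 nodes); the acceptance script
averages its agreement over five replicate cohorts because the
disease-vs-disease comparisons are true nulls and any single cohort
fails them at roughly the alpha rate. The published
post-hoc table ships as a packaged CSV (including one duplicated row
exactly as printed, which brings subnetwork 1 to its stated 29 edges)
and is used only for significance *counting* — none of the study's
patient-level results are recomputable from data.

## Known limitations

* Permutation p-values are granular at 1/(P+1); with the 10,000-
  permutation default the floor is ~1e−4.
* The post-hoc FDR is applied per edge across three comparisons, not
  jointly across edges; this mirrors the reported analysis but offers no
  edge-level FDR guarantee inside a component.
* `compare_nodal` runs post-hoc tests only at FDR-surviving nodes, so
  pairwise p-values at non-significant nodes are reported as missing.
* Under FDR, a node-level screen with several strong true signals admits
  each null node with probability ≈ α·k/m; "exact" recovery of a planted
  node set is therefore a high-probability event, not a certainty.
* The analytic GLM p for β1 assumes gaussian errors; the permutation
  option relaxes this at computational cost.
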