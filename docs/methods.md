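# Methods

This note records the models implemented in `sharkpcm`, the conventions the
implementation commits to where the field offers several, and what the
synthetic-data generator does and does not emulate.

## Trait models with measurement error

All three continuous-trait models are parameterized through the tip
covariance implied by the shared-path matrix `C` (entries: root-to-MRCA path
lengths). The likelihood of the species means `y` is the multivariate normal
density with mean `z0·1` and covariance `V_model(θ) + diag(SE²)`; the root
state `z0` is profiled analytically by GLS at every evaluation, so the
numerical optimization runs over at most two parameters (σ² always; α for
OU, r for EB).

Conventions:

- **OU root treatment**: non-stationary, root fixed at `z0` with variance
  accumulating from the root — `V[i,j] = σ²/(2α)·e^(−α d_ij)(1 − e^(−2α t_a))`.
  The stationary alternative adds a constant to every entry; with an
  ultrametric tree the two differ only in how the root is penalized, and the
  non-stationary form keeps the BM limit `α → 0` exact.
- **Optimizer**: L-BFGS-B on log-σ² (and log-α / raw r) with bounds
  σ² ∈ [1e−8, 100·var(y)], α ∈ [1e−8, 50/T], r ∈ [−10/T, 0] (T = tree
  depth), restarted from uniform draws inside those bounds; 50 restarts by
  default, configurable upward. A local-optimum guard in the test suite
  checks the returned optimum dominates 50 random parameter draws.
- **Parameter counts** for AIC: 2 (BM: σ², z0), 3 (OU, EB).
- **SE handling**: the standard error of a species mean is computed after ln
  transformation and is 0 for single-record species. The transform tests
  (λ/δ/κ) rescale only the phylogenetic part of the covariance and then add
  `diag(SE²)`.
- **Ancestral states** are conditional MVN expectations of internal-node
  states given the tips under the fitted model (the joint covariance is the
  same model kernel evaluated at all node pairs); back-transformation to pg
  is a plain exponential, no log-normal bias correction.

## Pagel transforms

λ multiplies the off-diagonal covariance entries; δ raises node depths
(normalized by tree depth) to the power δ and rescales so the total depth is
preserved, keeping δ comparable across trees; κ raises each branch length to
the power κ with the convention `0⁰ = 1`. ML estimation profiles σ² at each
candidate value on a coarse grid (21 points) refined by bounded search;
likelihood-ratio p-values use χ² with 1 df against the null values λ=1, λ=0,
δ=1, κ=1, κ=0. A flat λ surface (star phylogeny) triggers a warning and a
boundary report rather than a spurious estimate.

## Independent contrasts and rate comparison

Felsenstein's recursion with the standard branch-length extension
`b_i b_j/(b_i+b_j)`; a unifurcate root left by pruning a clade passes its
working value through without producing a contrast, so a clade of n tips
always yields n−1 contrasts. Zero-length sister pairs with equal values give
a contrast of 0 by convention; with unequal values they are an error. The
clade rate comparison is a two-sided Mann–Whitney U on |contrasts| — exact
when both groups are small and tie-free, mid-rank normal approximation with
continuity correction otherwise. Contrasts for the rate comparison are
computed on raw (pg) values: ln transformation would remove the
proportionality between genome size and its rate of change that the
comparison is meant to detect.

## Chromosome-number CTMC

States are the integers of `[s_min, s_max]`; when derived from data the
bounds are `[min observed − 1, max observed + 10]` (overridable). Gains and
losses move ±1 (optionally linear in `state − s_min`), duplication jumps to
`2s`, demi-duplication to `⌊1.5s⌋/⌈1.5s⌉` at half rate each; any jump whose
target leaves the interval is suppressed (reflecting-boundary convention,
matched exactly by the Gillespie simulator). The model family crosses
{constant, linear} × {±duplication} × {±demi-duplication} — eight models,
2–6 free parameters.

Conventions:

- **Root distribution**: normalized root conditional likelihoods (no free
  root-frequency parameters). A consequence worth knowing: the gain/loss
  *split* is weakly identified when per-lineage event counts are low,
  because the root estimate can absorb net drift; the *total* rate is
  recovered well. The recovery study in the acceptance suite (100 tips,
  rates 40/20 on a length-1 tree) quantifies this.
- **Tree scale**: likelihood fitting requires total branch length 1
  (asserted, or applied with `normalize=True`); long root-to-tip distances
  otherwise inflate inferred event counts. Ancestral probabilities and
  stochastic mapping accept any scale, since they condition on fitted rates.
- **Polymorphic tips** are probability vectors weighted by report
  frequencies; missing karyotypes are all-ones vectors. Averaged decimal
  counts are never fed to the CTMC — they appear only in summary statistics.
- **Stochastic mapping**: node states are sampled from the joint posterior;
  branch histories conditional on endpoints use rejection sampling with a
  uniformization-bridge fallback (triggered when the per-branch acceptance
  budget is exhausted), so histories are exact draws at bounded cost. Where
  one jump could arise from several mechanisms (e.g. `2 → 3` by gain or
  demi-duplication), the count is split across types in proportion to the
  component rates — a Rao-Blackwellized assignment with lower variance than
  sampling the type. "Total frequency" of an event type is the sum over
  branches of its expected count.

## PGLS and model selection

The residual covariance is `σ² C(λ)` (off-diagonals scaled by λ). λ is
profiled on a grid of step 0.01 and refined by bounded search; the full
profile curve ships with every fit so multimodal surfaces are visible — the
deterministic analogue of inspecting the λ likelihood surface by eye.
Coefficient SEs use the unbiased `σ̂² = RSS_gls/(n−p)`; log-likelihoods are
ML. Type-II F tests drop one term at a time at the full model's λ and case
set, with denominator df `n − rank(full design)`. Post-hoc level contrasts
re-run the fit with each level as the reference (the releveling approach)
and adjust the pairwise p-values by Benjamini–Hochberg within the factor.
Partial correlation regresses λ-PGLS residuals on λ-PGLS residuals (a flag
switches the first stage to OLS). Cases with |standardized residual| > 3 are
flagged on every fit; removal-and-refit is a caller decision.

Dredging enumerates all predictor subsets that contain the fixed covariates
and no forbidden co-occurrence pair, fits each by PGLS (λ re-estimated per
model) on the cases complete for the **full** pool — AICc values are only
comparable on a common case set — and ranks by AICc with `k` = number of
fixed-effect coefficients (the convention that reproduces the published
AICc/log-likelihood pairs of this study design; σ² and λ are not counted).
The best set is Δᵢ < 2; conditional averaging weights coefficients by the
Akaike weights of the models containing the term. GVIF is the
determinant-ratio generalization on the correlation matrix of the
non-intercept design columns, reported as `GVIF^(1/(2df))`.

Interaction terms are not implemented: every fitted model in the target
design is main-effects only (interactions were screened out as
non-significant upstream of this package's scope).

## Synthetic data: what it emulates, what it does not

`make_sharklike_dataset` reproduces the *statistical structure* of the study:
76 taxa (48 + 23 ingroup in two labeled clades, 5 outgroup), an Early-Burst
ln-scale trait affinely calibrated so ingroup C-values span the printed
2.86–17.05 pg range with the outgroup placed in a lower 2.6–4.6 pg band (the
clade shift that makes the stem carry a burst of size change), replicate
measurements with ln-scale noise (SD 0.06) for 18 species, a loss-dominated
gain/loss CTMC (gain 23, loss 42 per unit length on the normalized tree,
root 57, bounds 28–64) observed for 39 of 76 species with four polymorphic
entries, covariates constructed with known coefficients (nucleus area 0.78,
cell area 0.52, SMR −0.69, CFAR −0.12) plus tree-structured noise, and the
study's missingness pattern (SMR 17, nucleus area 25, cell area 34, r_max 33
observed cases, etc.).

It does **not** emulate: fossil-calibrated branch lengths or the real MCC
tree shape, the empirical correlation structure among all covariates,
taxonomic-diversity and heterozygosity variables, or measurement-technique
effects. Passing tests therefore demonstrate that the estimators recover
known truth under the study's sample sizes and missingness — not that the
published point estimates are reproduced; that requires the deposited data
(see README).

Because the affine calibration fixes the trait range rather than σ², trait
*rate* parameters are not recoverable on this fixture by design; recovery of
σ², λ and the regression coefficients is exercised on dedicated simulation
designs (200-tip trees for σ² and λ; 150/100-tip trees for PGLS coverage and
size; 100-tip trees with rates 40/20 for the chromosome model).

## Numerical choices and problem sizes

- Covariance PSD tolerance −1e−10 on eigenvalues; pruning-vs-enumeration and
  BM-vs-MVN oracles at 1e−8.
- Monte-Carlo study sizes were chosen for desk-scale runtimes: BM σ²
  recovery 100 replicates (acceptance script: 60), λ recovery 40 (script:
  30), CI coverage 200 (script: 150), type-I error 600 (script: 400) and
  chromosome-rate recovery 20 (script: 10) replicates; stochastic mapping
  defaults to 2000 draws, with the convergence property (doubling draws
  changes totals < 2%) checked at 2000 vs 4000.
- Yule simulation appends one final exponential waiting time after the n-th
  lineage appears so no tip branch is zero.
- MCC summarization scores only sample members (sum of log clade
  frequencies) and annotates node heights with the median height of each
  clade across supporting trees, clamping children to their parents; this is
  a declared convention — external summarizers do not document theirs.
- Degenerate inputs: all-rates-zero chromosome models are valid absorbing
  chains (warned); λ fitting on a star phylogeny warns and reports the
  boundary; EB at r = 0 equals BM exactly (guarded numerically below
  |r| < 1e−12).

## Known limitations

- The chromosome CTMC is non-reversible and the likelihood is therefore not
  re-rooting invariant; analyses fix the rooted topology.
- OU fits on ultrametric trees weakly identify α against λ-like attenuation;
  no attempt is made to disambiguate (the study design compares whole
  models, not α point estimates).
- The dredge fits every candidate on the full-pool complete cases; with
  heavy missingness this can discard many species, as in the original
  design, and no per-model case re-expansion is offered.
- Robustness summaries re-run analyses per tree serially; for very large
  tree samples callers should subsample.
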