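# Methods

## Scope and pipeline boundary

`pstfst` starts where a coalescent sampler ends: its inputs are posterior
draw tables of coalescent-scaled parameters (θ = 4N<sub>e</sub>μ, m = M/μ,
τ = tμ, or directly Nm), per-individual trait tables, and per-locus
haplotype alignments with a population map. Running the
isolation-with-migration MCMC itself, extracting non-recombining fragments,
phasing, or alignment construction are out of scope.

## F_ST from migration posteriors

Each Nm draw is mapped through the island model with the finite-deme
correction, F_ST = 1/(1 + 4·Nm·d²/(d−1)²), with d = 2 by default (two
islands) and exposed because the formula is general. Applying the transform
draw-by-draw preserves the full shape and asymmetry of the migration
posterior; directional Nm posteriors yield directional F_ST distributions.
Nm is formed as θ·m/4 from *same-iteration* draws — θ and m are correlated
in the joint posterior, so tables of unequal length are rejected rather
than resampled or recycled.

Natural-parameter conversions use N<sub>e</sub> = θ/4μ (per-generation μ)
and t = τ/μ (per-year μ), with the multilocus μ defined as the geometric
mean of per-locus substitution rates and the per-generation rate as the
per-year rate times the generation time (default 2 years, the focal taxon's
value). Human-readable summaries round N<sub>e</sub> to the nearest thousand
and times to two decimals in Ma; machine output always retains raw values.

Posterior summaries: the mode is the argmax of a Gaussian KDE (Silverman
bandwidth, `scipy.stats.gaussian_kde`) on a 512-point grid over the draw
range; the HPD interval is the shortest window of ⌈mass·n⌉ consecutive
order statistics; quantiles are linear-interpolated order statistics
(numpy's default "type 7"), so tail quantiles are bit-for-bit reproducible.
A mode falling outside the HPD (possible only for multimodal draws) is
flagged, not silently accepted. Coalescent samplers report joint-density
modes from their own density estimator, so modal values computed here from
the same draws can differ slightly; the KDE convention above is this
package's fixed choice.

## The hierarchical trait model

y_ij = μ + a_j + s_[j],sex(i) + Σ_k β_k x_ik + ε_ij, with island effects
a_j ~ N(0, σ²_B) and residuals ε ~ N(0, σ²_W). Priors: half-Cauchy(scale
`prior_scale_sd`, default 100) on σ_B and σ_W — a half-Cauchy has no finite
variance, so a "variance" of 10,000 is read as scale² = 10,000 on the
sd scale — and vague N(0, 1000²) on μ, sex effects and covariate
coefficients. Sex is coded with females as baseline; the male effect is
shared, island-specific, or absent. With island-specific effects the
(intercept, sex-effect) pair per island can get a joint bivariate prior
whose correlation ρ is uniform(−1, 1); σ_S (the sex-effect scale) then also
gets a half-Cauchy prior. Covariates are centered at their sample mean.
Records missing the modeled trait or covariates are dropped with a log
entry; records of unknown sex are dropped only when a sex effect is in the
model. Traits are modeled in raw units (kHz, g, mm); no standardization is
applied by default.

### Sampler

A seeded, pure-numpy component-wise Gibbs sweep in the centered
parameterization η_j = μ + a_j. The half-Cauchy priors are represented
exactly by the inverse-gamma scale mixture (σ² ~ IG(1/2, 1/a),
a ~ IG(1/2, 1/A²) ⟺ σ ~ half-Cauchy(A)), which makes every location and
variance update conjugate. In the correlated model the 2×2 random-effect
covariance is updated by random-walk Metropolis on (log σ_B, log σ_S,
atanh ρ) with the appropriate Jacobian, three proposals per iteration.
Chains are seeded by spawning from a single `SeedSequence`, so a fit is a
pure function of (data, spec, config).

Defaults: 4 chains, 25,000 burn-in, 25,000 further iterations thinned by 25
(1,000 retained per chain). Configurations retaining fewer than 200 draws
per chain are rejected. Simulation studies inside the test suite and the
acceptance script use 2 chains × (400 burn-in + 400 iterations, thin 2,
200 retained per chain), the package's standard small-simulation setting;
the short chains are adequate there because the conjugate sweep mixes
quickly on these small two-island designs (PSRF ≈ 1.00 throughout).

### Diagnostics

PSRF: sqrt(((n−1)/n·W + B/n)/W), W the mean within-chain variance (ddof 1),
B/n the sample variance of chain means; duplicated chains therefore give
sqrt((n−1)/n) ≈ 1, and zero within-chain variance returns 1 for identical
chains and +inf otherwise. ESS: n/(1 + 2Σρ_t) with autocorrelations summed
in consecutive pairs until the first non-positive pair (Geyer's
initial-positive-sequence rule), computed per chain and summed; constant
sequences report n with a logged flag. The posterior predictive check
simulates one replicate dataset per selected parameter draw and reports,
per (island × sex) cell, the two-sided tail probability
2·min(P(rep ≤ obs), P(rep ≥ obs)) of the observed mean and sd; under a
well-specified model small values (< 0.01) indicate misfit while values
near 1 simply mean the statistic sits at the replicate median.

### P_ST and the two-group caveat

P_ST is derived per retained draw from the variance *parameters*:
P_ST = r·σ²_B/(r·σ²_B + 2σ²_W) at r = c/h² = 1; `pst_from_variances`
evaluates other ratios from the stored draws. With only two populations
σ²_B is informed by essentially two observations, so its posterior — and
hence P_ST's — is wide and prior-sensitive: the σ_B posterior spreads over
roughly (data scale, prior scale) on a log scale, piling P_ST mass toward 1
whenever the islands differ at all. This is a property of the model class,
not an artifact: it is the reason two-island P_ST posteriors typically show
medians near 1 with long lower tails. Two consequences are documented and
tested: (i) P_ST is invariant to shifting the trait, and equivariant under
rescaling only when `prior_scale_sd` is rescaled with the data — with the
prior scale held fixed, rescaling the data moves the P_ST posterior; (ii)
σ²_B credible intervals are honest but very wide, whereas σ²_W is sharply
identified (coverage ≥ 90% required in simulation, ~95% observed).

## Sequence differentiation (G′_ST)

Sites with more than two nucleotide states violate the infinite-sites model
and are removed (case-insensitive; `-`/`N` do not count as states; removed
column indices are recorded). Whole haplotypes are the alleles; sequences
still containing missing data after filtering are dropped from haplotype
calling with a logged warning, since haplotype identity is undefined with
gaps.

Estimators are the haploid Nei–Chesser (1983) small-sample-corrected forms
with ñ the harmonic mean per-population sample size and k populations:
H_S = ñ/(ñ−1)·(1 − mean_i Σ_a p̂²_ia) and H_T = 1 − Σ_a p̄²_a + H_S/(ñk)
(observed-heterozygosity terms vanish for haploid data). Sampling noise can
produce H_T < H_S; H_T is then clamped to H_S with a flag. Hedrick's
standardization G′_ST = G_ST·(k−1+H_S)/((k−1)(1−H_S)) is clamped to [0, 1];
monomorphic loci return NaN and are excluded from pooling with a notice.
The multilocus value pools H_S and H_T by arithmetic means across
informative loci. The bootstrap resamples sequences with replacement within
each (locus, population) stratum — preserving the per-population sample
sizes the estimators correct for — and reports the 2.5/97.5 percentile
interval; loci may have different sample sets, so cross-locus linkage of
individuals is not preserved.

## Distribution comparison

Both P_ST and F_ST live on [0, 1], so each sample gets a Gaussian KDE with
Silverman's rule-of-thumb bandwidth (0.9·min(sd, IQR/1.34)·n^(−1/5)) and
boundary correction by reflection at 0 and 1 (each KDE integrates to
1 ± 0.01 on the grid); densities are evaluated on a shared 512-point grid
and the overlap is the Simpson integral of the pointwise minimum. The
critical ratio uses empirical 5%/95% *quantiles* — the tails its definition
names — not HPD bounds; when the P_ST 5% quantile is 0 or the F_ST 95%
quantile is 1 the ratio is reported as +inf. Overlaps are always reported
as proportions, never percentages. The verdict convention: drift is
rejected iff overlap < threshold (default 0.05) *and* the P_ST 5% tail
exceeds the F_ST 95% tail; both ingredients are always printed, and the
threshold is a reporting convention, not an error rate.

## Synthetic data

Generators are pure functions of their configuration (seed included). The
Nm posterior stand-in is lognormal with the requested median and log-sd —
the pipeline's contract starts at "posterior draws", so emulating the
sampler's output distribution suffices; defaults (median 0.325, log-sd
0.85) match the scale and spread of a weakly-migrating two-island system.
Trait tables add island mean + sex effect + Gaussian noise, with ~13
individuals per island × sex cell and a male effect of −0.7 within-sd by
default, the scale of the motivating system. Haplotype alignments draw
haplotype labels multinomially per population (defaults chosen to give
moderate differentiation, G′_ST ≈ 0.2) and realize them on a 60-bp backbone
where haplotype k substitutes only site k−1, so every column is biallelic
by construction and passes the infinite-sites filter unchanged.

Presets: `drift` places the island trait gap at sqrt(2σ²_B) with σ²_B
solving P_ST = F_ST(median Nm) at c = h² — the trait divergence the neutral
expectation itself predicts; `selection` uses a gap of 8 within-population
sd. What these simulations do *not* emulate: coalescent genealogical noise
in the Nm posterior, measurement error and repeated-measure structure in
traits, linkage and recombination in sequences. Passing tests therefore
validate the estimators and decision machinery, not the field-data
pipeline upstream of them.

## Known limitations

- Two-group σ²_B (and hence P_ST) is prior-sensitive by construction; see
  the caveat above. Analyses of more populations identify σ²_B better.
- P_ST approximates Q_ST only through the c/h² scaling; no pedigree or
  animal-model additive variance is estimated.
- The G′_ST bootstrap stratification is per (locus, population); linked
  resampling of individuals across loci is not implemented.
- The verdict is a screening convention; no Bayes-factor model comparison
  or multiple-trait joint test is provided.
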