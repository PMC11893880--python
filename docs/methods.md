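# Methods

## Clone fixation

Stem-cell clones fix in a crypt by monoclonal conversion. The model takes
fixation to occur at a constant per-crypt rate ΔC_fix (per crypt per year)
from birth, so the number of fixation events among `n` scored crypts at age
`t` is Binomial(n, ΔC_fix·t) with intercept fixed at zero. The posterior is
sampled with a half-normal prior on ΔC_fix (scale 1e-4 per crypt-year,
~100× the observed 1e-6 scale, i.e. weakly informative) by adaptive
random-walk Metropolis on the constrained slope, 4 chains, thinned 5×, with
a split-R̂ < 1.01 convergence guard. A Binomial likelihood rather than
least squares on frequencies respects the count nature of events at
frequencies of order 1e-5; `ols_slope_crosscheck` quantifies the
difference, and for exactly proportional data the two coincide.

**Response choice.** A fixed clone that has undergone fission occupies
several crypts. Counting every wholly populated crypt as a separate
fixation event would inflate the slope by the factor (e^{ρt}−1)/(ρt)
(1.3–2.6 at the rates and ages involved) and make it superlinear in age.
Since the patch-frequency identity Σ_n F_n(t) = ΔC_fix·t identifies
ΔC_fix as the rate of fixation *events*, the regression response defaults
to the number of distinct clones (patches, counting isolated WPCs);
`response="wpc"` applies the naive total-WPC reading for comparison with
raw tallies. The census schema keeps both quantities, with the invariant
`wpc_count = sum(patch_sizes)`.

C_part, the frequency of partially populated crypts, is the steady-state
footprint of drift: partial clones resolve (fix or vanish) within a few
years, so the frequency is treated as age-independent and pooled across
patients, with an exact Clopper–Pearson 95% interval. The drift-normalised
fixation bias ΔC_fix/C_part is formed draw-wise against the pooled point
estimate; its interval is the 2.5/97.5 percentile of the ratio draws.

## Crypt fission

A fixed clone founds a patch that grows by crypt fission, modelled as a
Yule pure-birth process at per-crypt rate ρ (per year). With fixation times
uniform over life (the constant-rate assumption), a patch observed at age t
has the logarithmic-series size distribution

    P(n) = q^n / (n · (−ln(1−q))),   q = 1 − e^{−ρt},

the normalisation of F_n(t) = ΔC_fix(1−e^{−ρt})^n/(ρn); ΔC_fix cancels, so
patch sizes alone identify ρ, and patients with no patches are dropped
(patch *number* informs the slope instead; patch count is independent of ρ,
so no selection bias arises). The likelihood conditions on observed patches
only — there is no zero-patch penalty term — matching the decoupled
reporting of slope and fission rate.

Patient-to-patient variability follows a Student-t hierarchy:

    ρ_i ~ StudentT(ν, μ, σ) truncated to ρ_i > 0
    μ ~ Normal(0, 0.01) truncated to μ ≥ 0
    σ ~ HalfNormal(0.01)
    ν ~ Gamma(shape 2, rate 0.1)    (prior mean ν = 20)

Prior widths are read as standard deviations (a scale of 0.01/yr brackets
the 0.007–0.019/yr rates seen in tissue; reading 10⁻² as a variance would
give an implausibly diffuse 0.1/yr scale) and the Gamma as shape/rate; all
are config-exposed. Truncation at zero is the default treatment of the
negative-rate mass (a crypt cannot un-fission), with the correct
(ν,μ,σ)-dependent renormalisation; `rate_transform="log"` instead places
the hierarchy on η_i = ln ρ_i with a weak Normal(0, 5) location prior, for
users who prefer strictly multiplicative variability.

### Sampling

No gradient-based PPL is used; the posterior is low-dimensional given the
conditional independence of the ρ_i, so the sampler is a vectorised
adaptive Metropolis-within-Gibbs:

1. elementwise random-walk updates of all patient rates (chains × patients
   in one numpy step, per-coordinate step sizes adapted to 44% acceptance);
2. a joint translation of (μ, all ρ_i) — the slow direction, since the t
   prior ties rates to the location;
3. a joint expansion of the rates about μ together with σ (the per-patient
   −ln σ in the t density cancels the expansion Jacobian exactly);
4. several rounds of scalar updates of μ, ln σ, ln ν plus a ridge move
   (μ traded against σ at fixed rates, with a scale-mixture proposal) and
   an independence refresh of (μ, σ) from their priors, which makes the
   rare excursions into the prior-dominated low-μ/high-σ region reversible.

Convergence is guarded by rank-normalised split-R̂ (arviz) on the
population location, raising rather than returning a doubtful summary. The
default threshold is 1.05: the fission posterior is heavy-tailed, and its
rare prior-dominated excursions inflate split-R̂ to ~1.02–1.04 at
practical draw counts even when the bulk, the 95% interval and empirical
coverage are stable; the one-dimensional slope fit holds the strict 1.01
line. Degenerate input — every patch of size 1 — leaves ρ identified only
as "small"; the fit warns and the posterior concentrates near the q→0
boundary.

## Mutational burden and passenger fraction

B(t) = Σ_{n≥1} n F_n(t) has the closed form ΔC_fix(e^{ρt}−1)/ρ, which is
the default compute path; the literal 500,000-term truncated sum is kept as
a faithful mode (`mode="sum"`) and as the counterpart in equivalence tests
(the geometric tail beyond the truncation order is below machine epsilon
for all parameter ranges of interest, so the two agree to 1e-9 relative).
ρ→0 limits are handled analytically (B = ΔC_fix·t; only size-1 patches),
and ρt > 700 switches to a log-space form to dodge overflow. The colon is
taken as 42 million crypts, a named, overridable constant.

Plug-in credible bands evaluate B at the endpoints of the parameter
intervals; since B is monotone increasing in both ΔC_fix and ρ, the
rectangle's extremes are (lo, lo) and (hi, hi) — the pairing follows from
monotonicity. The passenger fraction is 100·B(70)/f_gene, with f_gene the
user-supplied fraction of tumours carrying a truncating mutation in the
gene; the ratio is taken exactly as defined, per-crypt burden against
per-tumour frequency, and the dimensional looseness of comparing a crypt
fraction with a tumour fraction is documented here rather than silently
corrected. Values above 100% are legal (normal-tissue selection alone
over-explains tumour prevalence). A crossing-age solver inverts B(t) = f
by bracketed root finding on the monotone closed form.

## Amplicon SNV caller

Inputs are either a tidy count matrix (sample × amplicon × replicate ×
position base counts) or merged reads plus a panel. Read filtering is
exact: a read is assigned to an amplicon iff it begins with the forward
primer, ends with the reverse-complemented reverse primer, and has exactly
the expected length; ambiguous or non-matching reads are tallied and
dropped. A minimal exact-overlap merger (suffix/prefix identity ≥ 20
bases, no mismatches) is provided for paired reads; production assemblies
from a dedicated merger can be supplied instead.

Calling proceeds per (amplicon, replicate, position, alternate base):
samples under 500 reads are removed outright (they contribute to nothing,
including background statistics); across the remaining samples the VAF
mean and SD (n−1 denominator) define the background; a sample is a
candidate when VAF ≥ 1%, VAF > mean + 3.29·SD (the two-sided normal
0.001 quantile), and alt reads ≥ 2; a call requires candidacy in both
replicates of the dual-coverage group; and any variant called in three or
more samples is discarded as a recurrent artefact. With a zero background
SD the outlier test degenerates to VAF > mean. Every screened cell carries
its failing filters, so rejections are auditable.

The background mean includes the tested sample by default (the literal
protocol). This caps the attainable z-score at (n−1)/√n for n samples —
with 10 samples even an infinitely strong outlier cannot reach 3.29 SD —
so the rule only functions on runs multiplexing ~25+ samples, as the
assay's chips do. A `leave_one_out` flag excludes the tested sample,
restoring sensitivity on small runs; it is a documented deviation, off by
default. Background statistics are per (amplicon, position, alternate
base), never pooled across amplicons: that is the only reading under which
calling "for each amplicon independently" is coherent. Indels are out of
scope; the output schema (TSV and minimal VCF) leaves room for merging
indel records from alignment-based pipelines.

## Synthetic data

The generators realise exactly the structure the inference assumes:
Poisson fixation events with uniform times and geometric (Yule) patch
growth, whose marginal size law is the logarithmic series; positive-
truncated Student-t patient rates (rejection sampling, checked against the
analytic truncated CDF); binomial PPC counts at a constant C_part; and
amplicon backgrounds that are Normal on the VAF scale across samples, then
binomial on reads — precisely the error model behind the mean + z·SD rule
— with spike-ins present in both replicates. Defaults mirror the emulated
study: ~100 patients aged 30–91, 20,000 scored crypts each, slope of order
1e-6 per crypt-year, fission location/scale/dof 0.019/0.004/10 per year,
C_part 5e-5, amplicon depth ~2000 with 0.2% background. What the
generators deliberately omit: spatial geometry of partial clones, patch
adjacency/fusion, sequencing quality scores, strand bias and error
phasing. Tests passing on these fixtures therefore validate the
estimators under the model's own assumptions, not robustness to artefacts
real tissue or chemistry may add.

## Test scales and numerical choices

The recovery experiment runs 100 replicate cohorts of 100 patients ×
20,000 crypts (slope 1.6e-6, fission 0.019/0.004/10) and requires the 95%
intervals for the slope and the population fission rate to cover truth in
at least 90; MCMC uses 4 chains × 1000 draws per fit (with one longer
retry if the convergence guard trips), a draw count chosen for the R̂
contract. Caller fixtures use 30 samples (50 for the recurrence case) so
the inclusive background rule is mathematically able to fire, with VAF-5%
spikes at depth 2000 over a 0.2%/0.05% background. Equivalence tests pin
the truncated sum to the closed form at 1e-9 relative, logarithmic-series
normalisation at 1e-10, and simulation means within 3 Monte-Carlo SDs.
Ties and degenerate inputs: zero-σ backgrounds (see caller), all-size-1
patch censuses (warn + boundary posterior), ρ = 0 and t = 0 burden limits,
empty cohorts and empty tables all have defined behaviour and tests.

## Known limitations

* C_part is pooled, not age-resolved; an age trend in PPCs would indicate
  model misfit and is only surfaced by inspection.
* The fission hierarchy assumes patches are single-clone expansions; fused
  neighbouring clones would bias ρ upward.
* The plug-in burden band ignores posterior correlation between ΔC_fix
  and ρ (they are inferred from different data aspects, but a joint-draw
  band would generally be narrower).
* With ~2 patches per patient the fission posterior is prior-sensitive:
  the σ prior scale (0.01/yr) is then material, and the location mean
  shrinks a few percent below truth while coverage stays nominal.
* The caller's normal-background assumption is realised exactly by the
  generator; overdispersed real backgrounds (e.g. context-specific
  error hotspots) would raise the false-positive rate of the z-rule and
  are mitigated only by the recurrence filter.
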