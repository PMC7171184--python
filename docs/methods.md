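# Methods

## The arrival model

Steppe-related ancestry proportions are modelled as zero before an arrival
time `te` (calBCE, positive into the past), a jump to `pe` at `te`, and an
exponential decline pinned to reach `p0` at time zero:

    f(t) = pe · exp(−λ (te − t)),   λ = ln(pe / p0) / te,   t ≤ te
    f(t) = 0,                                               t > te

with constraints 0 < p0 ≤ pe ≤ 1 and te > 0. The exponential extends
unchanged to negative (common-era) times. Estimation minimises the residual
sum of squares between observed and fitted proportions, with the
**zero-residual rule**: observations with proportion ≤ `zero_tol` (default
exactly 0, the value qpAdm pins non-contributing sources at) dated more
recently than the fitted `te` contribute nothing. These individuals are
genuinely present in the archaeological record — women without steppe
ancestry occur up to a millennium after the arrival — and are interpreted
as members of unadmixed parallel communities rather than as evidence that
the regional ancestry level was low.

Starting values are p0 = 0.1, pe = 0.8, and te = the mean date of samples
with nonzero steppe ancestry. The objective is piecewise smooth in `te`
(both the pre-arrival branch and the zero-residual mask switch there), so a
bounded Nelder–Mead search is used with five jittered restarts, tie-broken
by lowest RSS; `te` is bounded by the observed date range padded by 200
years (a typical date-interval width).

### Identifiability and the two stabilising choices

The pinned-exponential family is over-parametrised along one direction: the
post-arrival curve is `p0·exp(λt)`, so sliding `te` older while `pe`
compensates at fixed λ changes nothing until `te` crosses an observation
date. Two consequences, and the package's responses:

1. **Minimal-te tie-break.** At the RSS minimum, `te` is identified only up
   to the interval between adjacent observation dates (and with the
   zero-residual rule active, up to where `pe` would exceed 1). Among
   equal-RSS solutions the fit reports the smallest `te` not below the
   oldest nonzero-ancestry observation: the arrival is placed no earlier
   than the data require. This matches how such arrival estimates are
   naturally phrased ("as early as the date range of the oldest individual
   carrying the ancestry") and makes the noise-free estimator exact when an
   observation sits at the jump.
2. **Data-scale Hessian probe.** An infinitesimal-step Hessian of the RSS
   is singular at *every* optimum (the flat direction above), so a literal
   positive-definiteness filter would retain nothing. The retention check
   therefore uses central finite differences at 10% of parameter scale —
   the default step of the numerical-derivative machinery in the R
   optimisation stack this procedure originates from. At that scale the
   probe asks whether the solution sits in a genuine basin, i.e. whether
   observations bracket the jump on both sides; boundary solutions (pe
   pinned at 1) receive a vanishing step and are rejected as unstable.
   The eigenvalue threshold is 1e-8.

### Monte Carlo over date uncertainty

Each repetition draws one date per individual from a normal centred on the
interval midpoint with SD = width / (2 × 1.959964), truncated to the
interval (so the reported range is the 95% interval of the sampling
distribution); zero-width intervals return the point date. The model is
refitted per draw, warm-started from the midpoint-date fit with one
restart; fits that fail convergence or the Hessian probe are discarded.
Retained arrival times are summarised by a Gaussian-kernel KDE with weights
`w_i = exp(rss_min − rss_i)` (maximum weight 1). This is the literal
"exponential of the RSS difference" weighting; a variance-scaled variant
`exp((rss_min − rss_i) / 2σ̂²)` with σ̂² = rss_min / n is available behind
`weight_mode="scaled"`, since the likelihood-ratio interpretation strictly
requires residual-variance scaling — which of the two the original workflow
used is not determinable from its description, so the literal reading is
the default. Bandwidth is Silverman's rule on the weight-effective sample
size `(Σw)² / Σw²`; the KDE is renormalised to integrate to 1 on its grid
(trapezoid, within 1e-6). The point estimate is the KDE mode; the interval
is the central 95% of the weighted sample. The reference repetition count
is 100,000; tests and the demo use 500, which already yields mode errors of
a few decades at cohort size 60–100.

### When the zero-residual rule raises pe — and when it does not

Masking post-arrival zeros removes only non-negative RSS terms, so at fixed
parameters the masked RSS is never larger. The *fitted* `pe`, however, is
not guaranteed to be larger with the rule: including zeros near the jump
pulls the curve down where it is high (the masked fit then restores `pe`),
but zeros concentrated at recent dates instead depress `p0` and tilt λ
upward, which can raise the curve at the jump. On synthetic cohorts the
with-rule `pe` exceeds the without-rule `pe` in all runs when zeros cluster
within ~350 years of the arrival, in roughly 85% of runs when several zeros
are scattered uniformly over the post-arrival span, and in only about half
of runs when the cohort contains just a couple of zeros (the perturbation
is then tiny and its sign essentially random). The corresponding
acceptance test encodes the universal claim under the generator's default
conditions and is expected to fail; it is retained as a documented
limitation rather than weakened.

## Pairwise mismatch and the diversity shift

The mismatch rate between two pseudo-haploid individuals is the fraction of
jointly non-missing SNPs (autosomal by default) with different alleles,
computed by a vectorised three-matrix-product kernel that tests verify
against a per-pair loop. Pairs are retained only when overlap strictly
exceeds `min_overlap` (default 10,000, the published panel convention).

The diversity shift compares mean mismatch among individuals after a cutoff
(default 2700 calBCE) with those before it. Individuals are assigned a
period by interval midpoint; intervals containing the cutoff are excluded
by default (a flag classifies them by midpoint instead). Because each
individual contributes to many pairs, inference permutes *individual*
period labels and recomputes both group means from the induced
within-period pairs — the same dependence structure a mixed model with
individual random effects addresses; the robust mixed-model fit of the
original workflow is deliberately replaced by this permutation scheme. The
two-sided p-value uses the add-one correction; a 95% effect interval comes
from recentring the permutation distribution on the observed effect.
Calibration on null cohorts (shared frequency pool) gives type-I error
statistically indistinguishable from 5%.

## Kinship

Mismatch rates are normalised by the median pair rate within a group
(default per site; the median is the expected-unrelated level and is robust
to a minority of true relatives). Under random allele draws from diploid
genotypes the expected normalised score is 0.5 for identical genomes, 0.75
for one shared IBD allele (parent–offspring, full siblings), 1.0 for
unrelated pairs; thresholds sit at the midpoints 0.625 / 0.8125 / 0.90625,
the scheme of the READ classifier this follows. Comparisons are `≤`, so a
boundary score goes to the more related class. mtDNA/Y consistency checks
apply to first-degree and identical pairs only: matching mtDNA is always
consistent; a mismatch refutes only female–female links (mother–daughter or
sisters); male–male pairs must share the Y haplogroup. Genetic sex is
called from R = y/(x+y) counts with R < 0.05 female and R > 0.20 male, the
gap absorbing mismapping noise; both thresholds are configurable.

## f-statistics

Group allele frequencies are haploid call ratios (no diploid or
heterozygosity correction — the pseudo-haploid convention; male and female
X calls count once each). Outgroup f3(O; A, B) is the mean over jointly
defined SNPs of (fO−fA)(fO−fB); D(W, X; Y, Z) is the ratio
Σ(fW−fX)(fY−fZ) / Σ(fW+fX−2fWfX)(fY+fZ−2fYfZ). Standard errors use a
delete-one block jackknife over contiguous fixed-count SNP blocks (default
500; no genetic map is assumed on synthetic data), with the weighted
jackknife formulae standard in this literature for unequal block sizes.
With gene flow Y → X the D numerator's expectation is −α·Var(fY) < 0, the
sign convention documented for the directional tests.

The sex-bias contrast computes f3(O; steppe-ref, test) separately on
autosomes and X and reports delta = f3_auto − f3_X with SE combined from
the two independent block sets. Under male-driven steppe admixture the X
carries less steppe ancestry, so delta > 0.

Phenotype reports give per-group derived-allele frequencies for four
routinely screened variants (SLC45A2 rs16891982, SLC24A5 rs1426654, HERC2
rs12913832, LCT rs4988235) with coverage counts; a damage flag is set
automatically wherever ref/alt involves A or T, the sites where post-mortem
deamination (C→T / G→A) can mimic a genuine call at low coverage —
replacing the manual inspection step of sequencing workflows.

## The synthetic-data generator

`SimulationConfig` defaults encode the emulated study setting: ~100
individuals spanning 4800–1700 calBCE; date-interval widths 40–300 years
(decades to centuries); arrival at 2750 calBCE jumping to 60% and declining
to ~10% projected at time zero (passing 25–35% in the Early Bronze Age);
ancestry observation noise SD 0.05 (a free knob — no error model for
qpAdm proportions is published); 10% of post-arrival individuals with
exactly zero steppe ancestry, drawn female with probability 0.9 (mirroring,
without hard-coding, that all such observed individuals were women);
two-source Balding–Nichols pools at FST 0.08 from Uniform(0.05, 0.95)
ancestral frequencies; 30% missingness; male admixture bias 0.3, realised
as X-chromosome source probability q_X = q(1 − bias). Noise is truncated
to [0, 1] by resampling, not clipping, to avoid point masses at the bounds
that would bias fitting tests. All randomness flows from one seed through
named substreams; outputs are byte-reproducible.

Pedigrees simulate founders under Hardy–Weinberg from a frequency pool,
Mendelian single-allele transmission per SNP (no recombination map — SNPs
are exchangeable here), an optional clone entry for identical twins, a
pseudo-haploid observation layer, and matrilineal/patrilineal label
transmission. True degrees come from exact kinship coefficients
(first > 0.177, second > 0.0884).

What the generator does **not** emulate: sequence-level artefacts
(deamination damage, contamination), linkage and recombination maps,
realistic site-frequency spectra or ascertainment of the capture panel,
qpAdm's correlated estimation errors, or radiocarbon calibration-curve
multimodality (intervals are symmetric around the true date). Passing
tests therefore demonstrate correctness of the estimators under the stated
statistical model, not robustness to these real-data complications.

## Problem sizes

Tests and the acceptance script scale the reference analyses to desk size:
arrival Monte Carlo at 500 repetitions (reference 100,000), cohorts of
40–100 individuals, genotype panels of 4,000–36,000 SNPs, permutation
tests at 399–999 permutations, and 20–200 replicate experiments per
statistical claim. The X panel in sex-bias experiments is deliberately
large relative to the autosomal one (one third to one half of sites) so the
X-side f3 has usable precision at these SNP counts, standing in for the
~50k X sites of the full 1240k capture panel.

## Known limitations

- te is interval-identified between adjacent observation dates; the
  minimal-te convention resolves the choice deterministically but inherits
  a younger-edge preference of up to one inter-observation gap.
- The zero-residual rule's protective effect on pe is regime-dependent
  (see above).
- The permutation diversity test exchanges individuals across periods,
  which assumes no confounding of period with site composition; strong
  site-period imbalance would call for restricted permutations.
- Kinship classification beyond first degree is unreliable at high
  missingness (second-degree scores overlap the unrelated baseline);
  the package reports degrees but the tests only certify the
  first-vs-unrelated distinction.
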