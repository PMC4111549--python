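# Methods

This note records the models implemented in `cnedfe`, the numerical choices
behind them, and what the synthetic-data tests do and do not demonstrate.

## Site classification

A CNE is a multi-species alignment (human, macaque, mouse, chicken, frog,
zebrafish, fugu by default) with the human row as the focal reference.
Classification masks the focal row: a column is **NVR** when every non-focal
row carries the same A/C/G/T base, **RVR** when at least one differs.
Masking the focal row avoids ascertainment circularity, since human
polymorphism is what the downstream analysis measures. A second pass flags
columns where the focal reference alone differs from an otherwise invariant
column; these remain NVR ("NVRs that are polymorphic") and the flagged count
is reported in the run log.

Choices the source material leaves open, decided here:

* A gap in a non-focal row counts as a difference (RVR) — conservative
  reading of "varies in at least one species".
* An ambiguity code (N, R, Y, …) in a non-focal row makes the column
  UNASSESSED; such columns are excluded from all totals, because identity
  cannot be asserted.
* Comparison is case-insensitive; sequences are uppercased on read.
* Coordinates are 0-based half-open internally and BED on disk. On minus
  strand anchors, alignment column k (counting focal non-gap columns) maps
  to genomic position end − 1 − k. Focal-gap columns are classified from the
  non-focal rows but carry no genomic coordinate and cannot receive
  variants.

## Variant polarization and categories

Only biallelic SNVs are used. The derived allele count is DAC = AC when the
ancestral allele equals REF and AN − AC when it equals ALT. Excluded, with
per-reason tallies: records with zero alternate-allele count, missing
ancestral annotation, lowercase (low-confidence) ancestral annotation
(configurable), ancestral allele matching neither REF nor ALT, and sites
monomorphic after polarization. VCF positions are converted to 0-based once,
at the parser boundary.

Codon degeneracy is computed per CDS position as the number of the three
alternative bases that leave the amino acid unchanged: 0 synonymous
alternatives → 0-fold (non-synonymous category), 3 → 4-fold, otherwise
2-fold; synonymous = 2-fold ∪ 4-fold. Transcript choice is "longest CDS",
ties broken lexicographically by transcript id.

The non-coding control is the union of the bands [start − 6 kb, start − 5 kb)
and [end + 5 kb, end + 6 kb) around each CNE anchor, minus known exons, all
CNEs, and any supplied excluded conserved elements (interval algebra via
pyranges; negative coordinates clip at 0). The 5–6 kb distance keeps the
control exposed to the same local background-selection environment as the
CNEs themselves.

Category precedence is CNE (NVR/RVR by mask column) > coding (by degeneracy
map) > non-coding control; anything unmatched is UNASSIGNED and excluded
from tables. A variant at an ancestral CpG is one whose ancestral base is
the C of an ancestral CpG dinucleotide or, strand-symmetrically, the G
preceded by an ancestral C; the ancestral context defaults to a supplied
ancestral FASTA (the synthetic bundle provides one; with real data an
ancestral-genome track or the alignment consensus of non-focal species both
work).

## Spectra and tests

The unfolded SFS for a category holds counts at DAC 1..n−1 plus the number
of sites surveyed. A DAC threshold (analyses are reported at ≥ 1 and ≥ 6;
the higher cut reflects the better imputation accuracy of low-coverage
calls at allele counts of at least six) zeroes classes below it, and those
classes are also excluded from all fitting likelihoods.

The chi-square comparison is the Pearson 2×2 test (polymorphic vs not ×
category pair), df = 1, **continuity correction off by default**: the
published p = 0.24 for the labile-CNE vs synonymous comparison matches the
uncorrected test (0.2432, Yates gives 0.2527), while at least one other
published cell (1.37E-11) matches the corrected test instead — both modes
are exposed, and the default reproduces the worked example. The KS test is
the standard two-sample statistic on per-variant derived allele frequencies
with the asymptotic p-value. Reported percentages round half-up to two
decimals; published tables mix rounding conventions across cells, so only
unambiguous cells are used as worked examples. CpG normalization is linear:
observed CpG-SNP % × (reference G+C / class G+C), one decimal.

## Poisson Random Field machinery

**Equilibrium.** E[ξᵢ] = θ ∫ C(n,i)xⁱ(1−x)ⁿ⁻ⁱ H(x;γ) dx with the sojourn
density H(x;γ) = (1−e^(−γ(1−x)))/[x(1−x)(1−e^(−γ))], γ the population-scaled
coefficient of the derived allele (negative = deleterious). Evaluated by
adaptive quadrature; γ = 0 uses the exact θ/i. For γ < −50 the integral is
split at x = 50/|γ| (the integrand concentrates below ~1/|γ|), and the
exponential ratio is computed in a form stable to |γ| of at least 10⁵
(checked against the asymptote E[ξ₁] → nθ/|γ|).

**Two-epoch demography.** Time is measured in units of 2Nₑ (current)
generations; the relative size ν(t) is ω (= ancestral/current) before the
change and 1 for the last τ units. The forward diffusion with drift
(γ/2)x(1−x) and diffusion x(1−x)/ν is discretized by a finite-volume
tridiagonal operator on a 400-point grid crowded toward x = 0 and 1
(logistic transform, crowding 8), with mutational influx θ/2 injected at
the lowest interior frequency and absorbing boundaries. The ancestral
equilibrium is obtained exactly (one banded solve of Lφ = −influx), then
implicit-Euler steps (default dt = 10⁻³) integrate the recent epoch.
Design-time validation: the discrete stationary density matches the closed
form to ~0.2% for γ ∈ [−10, 0] (1.7% at γ = −100), and the neutral
two-epoch spectrum at (ω = 0.75, τ = 0.45) matches msprime's branch-mode
expected SFS to ~2%; the test suite re-runs both checks.

**Gamma DFE.** The deleterious effect s ≥ 0 follows a gamma(shape, rate)
distribution over the *raw* coefficient; this convention reproduces the
published lethal fractions (32% and 21%) as P(s > 0.01) at the printed
(shape, rate) pairs. The scaled coefficient is γ = −4Nₑs (the factor is
configurable; 4 matches the "mean 4Nₑs" reporting convention).
E[ξᵢ] under the DFE is a Gauss–Legendre integral in log s over the DFE's
own quantile range [max(10⁻⁸, q₁₀⁻¹²), min(1, q₁₋₁₀⁻¹²)], with node count
doubled until the summed spectrum changes by < 10⁻⁴ relative. Mass below
the lower limit contributes the neutral spectrum; mass above s = 1 is
treated as fully lethal (no polymorphism). Inside the integral, per-s
spectra use the two-epoch solver for |γ| ≤ 500 and the equilibrium closed
form beyond — strongly selected alleles reach mutation–selection balance on
a time scale ≪ the demographic one, and this also sidesteps the grid
resolution the PDE would need at large |γ|. For repeated likelihood
evaluations a cache of per-s spectra on a fixed log grid (160 points)
reduces each DFE evaluation to a weighted trapezoid sum.

## Fitting

**Demography first.** (ω, τ, θ) are fitted on a putatively neutral class by
maximizing the Poisson likelihood Π Poisson(ξᵢ_obs; E[ξᵢ]); θ is profiled
analytically (θ̂ = Σobs/Σunit), leaving a 2-D bounded L-BFGS-B search in
(log ω, log τ) from 25 multi-starts (seeded; bounds ω ∈ [0.05, 20],
τ ∈ [10⁻³, 10]). The (ω, τ) likelihood ridge is shallow: recovery to 10%
needs a well-populated spectrum (the recovery tests use ~10⁴–10⁵ SNPs), and
equilibrium data correctly collapse to the nested equilibrium fit.

**DFE second.** With the demography fixed, (shape, rate, θ) are fitted the
same way (bounds shape ∈ [0.01, 10], rate ∈ [10⁻³, 10⁴]). When the fitted
mean effect is large the rate is weakly identified (the observable spectrum
becomes insensitive to the far-deleterious tail — the classic DFE ridge);
the honest summary is therefore the profile-likelihood interval on the
shape, computed by bisection on the profiled log-likelihood at the
χ²₁(0.95)/2 = 1.92 drop. Boundary convergence is flagged. Parameter
recovery: refits on spectra simulated at (shape 0.18, rate 7.8) under the
expansion demography cover the true shape in ≥ 18/20 replicates (run as a
test at n = 60 chromosomes, θ = 2500 — sized so the selected class carries
a few thousand SNPs, comparable to the real CNE classes).

**Nuisance-multiplier estimator.** The alternative estimator gives each DAC
class i a multiplier rᵢ applied to both the neutral (θₙ/i) and selected
(θₛ·mᵢ(shape, mean)) expectations, absorbing demography and class-specific
calling artifacts; r of the first retained class is 1 for identifiability,
and the selected expectation integrates equilibrium spectra over a gamma
distribution of the scaled effect S = 4Nₑs. Each rᵢ has a Gamma(2, 2) prior
(mean 1) and is integrated out analytically — the gamma/Poisson conjugacy
gives a closed negative-binomial-type likelihood — leaving only
(θₙ, θₛ, shape, mean) to sample. This collapse matters: sampling the rᵢ
explicitly couples them so tightly to (shape, mean) that the chain
effectively stops moving (acceptance ~3% in design testing). The four
remaining parameters use component-wise random-walk Metropolis on the log
scale (sd 0.05 for the θs, 0.25 for shape, 0.8 for mean), with two
additions for the flat ridge in the mean: DFE moves rescale θₛ to keep the
total expected count fixed (a log-space shear with unit Jacobian, so moves
compete on spectrum shape rather than overall scale), and one mean proposal
in four is a long-range uniform jump over the prior range
(log mean ∈ [ln 10⁻³, ln 10⁷], log shape ∈ [ln 10⁻³, ln 50]). Defaults:
4 chains × 50,000 iterations, 50% burn-in, seeded; convergence requires
split-chain R̂ ≤ 1.05 on log shape and log mean (log scale — both are
scale-like parameters with heavy-tailed posteriors), else the fit raises
with the traces attached. Reported: posterior medians and central 95%
intervals for shape and mean scaled effect, plus posterior-mean Nₑs-bin
proportions (bins <1, 1–10, …, >10⁴).

A known property, not a defect: when the data only bound the mean effect
from below (strong selection, classic for this estimator — published
intervals span orders of magnitude), the posterior upper tail runs to the
prior bound and the *mean's* credibility interval is prior-dependent; the
shape is well calibrated (simulated coverage 6/6 at truth shape 0.2 in
design checks, ≥ 18/20 required in the test suite for the ML fit).

## Synthetic-data generator

The generator emulates the statistical structure of the real inputs, with
defaults fixed at the study conditions:

* 40 elements of 120–320 bp (mean ≈ 220, matching the ~200 bp scale of real
  CNEs), invariant-column fraction 0.507 (the observed NVR share of
  assessed CNE columns), seven species with human focal.
* Substitutions at variable columns hit each non-focal species with
  probability 0.3, conditioned on at least one hit and on the column
  actually varying among non-focal rows — so the planted mask is exactly
  recoverable and classification accuracy on synthetic data must be 100%.
* G+C target 0.40 (CNE-like), CpG dinucleotides planted at rate 0.02.
* Polymorphism: per-category expected spectra from the PRF model under a
  two-epoch expansion (Nₑ = 16000, ω = 0.75, τ = 0.45) with class DFEs
  gamma(0.18, 7.8) at NVR-like, gamma(0.26, 590) at RVR-like (shape and
  mean scaled effect ≈ 28 from the nuisance-estimator fits), gamma(0.1,
  6.25) at non-synonymous, neutral at synonymous and non-coding; counts are
  Poisson draws, positions uniform within the class. θ = 0.001 per site
  (human-typical; a `theta_scale` multiplier exists because several tests
  need denser spectra than realism provides).
* Sample size n = 120 chromosomes (the order of a single 1000
  Genomes population panel); VCF REF is the derived allele with probability
  DAC/AN, exercising both polarization branches.
* Ascertainment: variants with minor allele frequency ≤ 0.05 are dropped,
  mimicking common-allele discovery panels. On synthetic data this shrinks
  the KS distance between constrained (pooled CNE) and neutral spectra —
  the same direction as the published HapMap-vs-whole-genome contrast.

What passing on synthetic data does **not** show: the generator has no
linkage, no mutation-rate heterogeneity beyond planted CpGs, no alignment
error, no variant-calling error, and independent substitutions instead of a
phylogeny — so end-to-end correctness here demonstrates the bookkeeping and
the statistics, not robustness to real-data artifacts.

## Problem sizes in the test suite

Tests scale the models down: sample sizes 10–120 chromosomes, diffusion
grids of 250–400 points, spectrum caches of 160–200 s-points, 20 replicates
for recovery checks, and a forward Wright–Fisher oracle at N = 200 diploids
(2000 burn-in generations, 25 batches × 10,000 generations, sampling every
10) whose batch-means standard errors define the 3-SE acceptance band.
These sizes were chosen so each check has clear statistical power while the
whole suite stays fast; the underlying machinery accepts larger values
throughout.

## Known limitations

* The two-epoch solver inherits O(grid, dt) discretization error (~0.5–2%
  near the singleton class at default resolution); equivalence with other
  PRF implementations is approximate by construction.
* Only deleterious (and neutral) DFEs are modelled; no positive selection.
* The demography is a single population with one size change; no migration
  or growth curves.
* The nuisance-multiplier mean-effect interval is prior-bounded above when
  the data cannot cap it (see above).
* Focal-gap columns are excluded from variant mapping rather than lifted
  through the alignment.
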