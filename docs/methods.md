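# Methods

## Model

The estimator is a Poisson-random-field composite likelihood over category
site-frequency spectra plus lineage-specific substitution counts. A
"category" is a direction of synonymous change: W→S / S→W / GC-conservative
for the gBGC analysis, U→P / P→U / preference-neutral for selection on
codon usage (SCU), and the 3 × 3 cross of the two for the joint model. For
a category with scaled coefficient γ the expected count in derived-frequency
class *i* of *n* chromosomes is proportional to

F_i(γ) = ∫₀¹ C(n,i) xⁱ(1−x)^{n−i} · (1−e^{−γ(1−x)}) / ((1−e^{−γ}) x(1−x)) dx,

the binomial sampling of the stationary diffusion density of a semidominant
allele, and the expected substitution count is proportional to the relative
fixation rate d(γ) = γ/(1−e^{−γ}). GC-directional categories take γ = ±B
(B = 4Nₑb), preference categories γ = ±S (S = 4Nₑs), and the joint model
assumes additivity, γ = sB·B + sS·S with signs per category. Polymorphism
uses the recent intensities (B₁, S₁); divergence the ancestral ones
(B₀, S₀), so a shift in fixation bias over time is identified by the
contrast between segregating and fixed variation under a shared, constant
mutation bias.

Full expectation for category c with reverse category c̄ (ancestral and
derived alleles swapped):

- polymorphism: μ_c(i) = r_i · [(1−e)·θ_c·F_i(γ₁(c)) + e·θ_c̄·F_{n−i}(γ₁(c̄))]
- divergence: μ_c(D) = τ · [(1−e)·θ_c·d(γ₀(c)) + e·θ_c̄·d(γ₀(c̄))]

The log-likelihood is the sum of independent Poisson terms over all classes
and categories. Treating classes as independent Poisson draws (rather than
multinomial) keeps the θ's free and the likelihood modular; total counts
then carry information through the θ's rather than being conditioned away.

## Parameters

| parameter | meaning | default / bounds |
|---|---|---|
| λ | ratio of S→W to W→S scaled mutation rates (AT bias > 1) | free, [0.05, 20] |
| θ_c | scaled mutational input per base category | free, > 0; reverse categories tied: θ_SW = λθ_WS (joint set: θ(SW,p) = λ·θ(WS, p̄)) |
| B₀, B₁, S₀, S₁ | ancestral / recent gBGC and SCU intensities | each "zero", "free" ([−50, 50]) or tied equal |
| e | polarization-error probability, shared by SNPs and substitutions | free, [0, 0.49] |
| r₂..r_{n−1} | per-class demographic distortion multipliers, shared across categories | free, r₁ ≡ 1 |
| τ | divergence scale (expected substitutions per θ unit) | free, > 0 |

The r_i multiply the true (pre-error) frequency class. The error term uses
one shared e for SNPs and substitutions because both are polarized with the
same two outgroups; a per-kind e would not be separately identifiable from
these data. Since demographic distortion enters as free per-class
multipliers, any demography that distorts all categories equally is
absorbed exactly — this is what makes the force estimates robust to
non-equilibrium demography, and it is also why the per-class distortions
themselves should not be interpreted.

## Numerics

- F_i(γ) is evaluated by a fixed 200-node Gauss–Legendre rule applied to
  the smooth factor (1−e^{−γ(1−x)})/(1−e^{−γ}); the rest of the integrand
  is a polynomial of degree ≤ n−2, so the rule is exact to ~1e−13 for the
  n used here (verified against adaptive quadrature in the tests). The
  neutral closed form F_i(0) = 1/i holds to < 1e−9 for n ≤ 50.
- |γ| < 1e−6 switches both the density and d(γ) to series expansions; the
  branch jump is below 1e−8.
- Maximization is bounded L-BFGS-B on log-transformed positive parameters
  with an analytic gradient, multi-started from a data-driven initial point
  plus seeded jitter; nested and scanned models warm-start from their
  smaller neighbours so a fuller model never scores below a submodel.
- Confidence intervals are profile likelihood at a 1.9207 logL drop (95%,
  1 df). The profile crossing is bracketed using the local curvature and
  polished with Brent's method; profile re-optimizations warm-start from
  the previous solution.
- LRTs use χ² with df = difference in free parameter counts. The joint
  scan ranks all 16 {B₀,B₁,S₀,S₁} ∈ {0, free} models by AIC
  (= 2·n_free − 2·logL over *all* free parameters); among models within
  2 AIC of the minimum the one with fewest free parameters is selected,
  and models within 0.01 AIC are reported as co-best.
- NI is reported as missing when a denominator cell is empty; a ±0.5
  Haldane correction is available behind a flag but not used by default.
- The skewness null test is a seeded percentile bootstrap (default 10⁴
  resamples, two-sided); the original significance procedure for this
  statistic is not documented, and a bootstrap makes the fewest
  distributional assumptions.

## Synthetic data

Three generators provide every input the pipeline consumes.

`simulate_counts` draws Poisson counts around the model's own expected
spectra — the reference conditions are n = 20 chromosomes, λ = 1.7
(mid-range of the 1.6–2.2 AT bias typical of plant transcriptomes),
B₀ = 0.3, B₁ = 0.5, e = 0.02, ~5·10⁴ SNPs, with the neutral category
carrying 1.5× the mutational input of the W→S category and τ = 0.5 so
divergence counts are a few thousand.

`simulate_wf_sfs` is a discrete forward Wright–Fisher simulator
(N ≤ 10⁴): new mutations enter at 1/(2N) at a Poisson rate, each
generation applies the deterministic term (γ/4N)·p(1−p) then binomial
drift, burn-in is 10N generations, and the sample SFS can be pooled over
spaced snapshots. It exists as an independent check of the diffusion
expectations (neutral 1/i shape, directional shifts under γ ≠ 0,
transient demographic distortion), not as a data-scale simulator.

`simulate_alignments` builds per-gene FASTA alignments (two haplotypes per
diploid individual plus two outgroups) with planted structure. Ancestral
third-position composition sits at the Li–Bulmer equilibrium of the
region's B and λ — including a per-family correction for isoleucine, the
one amino-acid family whose weak/strong codon counts are unbalanced — so
the zero-effect scenario is an exact null (skewness ≈ 0, DoS ≈ 0,
GC3 ≈ 1/(1+λ) at exchangeable sites). Per-site SNP and substitution rates
and derived-allele frequencies follow the spectrum model with a
region-specific B (first 252 bp vs rest, mirroring a 5′→3′ recombination
gradient); codon usage tilts toward a fixed truly-preferred set in
proportion to gene expression. Outgroups accumulate independent changes,
which creates unpolarizable sites but essentially no mispolarization.

What the generator does *not* emulate: linkage (sites are independent),
ancestral polymorphism shared with the outgroups, CpG hypermutability,
alignment error, and expression noise across individuals. Passing tests
therefore demonstrate correctness of the estimators under the stated
model, not robustness to those real-data complications. One known scale
mismatch is intentional: because alignment-level data are generated *at*
compositional equilibrium, the model-level λ̂ estimated from them equals
e^B times the per-site mutation bias (aggregate mutational input per
category is what the model's λ measures), while B̂ itself is unaffected.

## Problem sizes

The recovery study uses 100 replicates at the reference conditions; the
LRT calibration 200 replicates (n = 10, 2·10⁴ SNPs, B₀ = B₁ = 0.3); the
joint-scan study 50 replicates (n = 10, 2.5·10⁴ SNPs, B = 0.4, S = 0);
the end-to-end runs 120–900 genes of 600–900 bp. The whole suite runs in
about four minutes on one CPU.

A finding worth recording from the recovery study: with e and the r_i
estimated jointly — as the model requires — the expected-information
(Cramér–Rao) bound on the recent intensity B₁ at the reference conditions
is an SD of 0.077, and the empirical spread of the estimates matches it
(the suite computes both and asserts their agreement). Accuracy much
tighter than ±0.1 per replicate at 5·10⁴ SNPs is therefore not a matter of
implementation; it would require either more data or fixing a nuisance
parameter. The ancestral B₀ is about twice as precise (bound 0.039)
because divergence counts constrain it directly. CI coverage of both is
at the nominal 95%.

## Limitations

- Composite (independent-Poisson) likelihood: standard errors from the
  profile curvature are approximate when classes are correlated.
- The divergence expectation ignores ancestral polymorphism carried
  through the split (single τ·d(γ₀) term); with short internal branches
  this biases τ, and mildly B₀.
- The joint model assumes strict additivity of B and S and a single shared
  e and r vector across all nine categories.
- When preferred codons are overwhelmingly GC-ending, the joint scan
  cannot always separate gBGC from SCU; the AIC tie rule then prefers the
  sparser model, which is a modelling choice, not evidence of absence.
- The reader for externally deposited processed spectra expects the SFS
  exchange TSV layout documented in `gcforces.spectra`; reproducing the
  original study's per-species numbers requires its supplementary archive,
  which is not redistributable here.
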