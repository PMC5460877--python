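# gcforces

Quantifying the forces that shape base composition at synonymous sites:
mutational bias, GC-biased gene conversion (gBGC) and selection on codon
usage (SCU), estimated from polarized site-frequency spectra and
lineage-specific substitution counts.

## Who this is for

Population geneticists working with coding-sequence polymorphism data — a
focal population sample plus two outgroups per gene — who want to know
whether synonymous base composition is at mutation–drift equilibrium, and
if not, how strong the fixation biases pushing it away are, both recently
(from segregating variation) and ancestrally (from fixed differences).

## The model

Synonymous changes are classified by their effect on GC content
(W→S: A/T → G/C, S→W, or GC-conservative) and on codon preference
(unpreferred→preferred U→P, P→U, or neutral). For each category the counts
of derived variants in frequency class *i* (of *n* sampled chromosomes) and
of fixed differences are modelled as independent Poisson draws around the
expectations of a Wright–Fisher diffusion with scaled coefficient γ:

    f(x; γ) = (1 − e^{−γ(1−x)}) / ((1 − e^{−γ}) · x(1−x))          (density)
    F_i(γ)  = ∫₀¹ C(n,i) x^i (1−x)^{n−i} f(x; γ) dx               (sampled SFS)
    d(γ)    = γ / (1 − e^{−γ})                                     (fixation rate)

with γ = ±B for the two GC categories (B = 4Nₑb, the population-scaled
gBGC coefficient), γ = ±S for the preference categories (S = 4Nₑs), and
γ = B ± S etc. in the joint nine-category model where both forces act
additively. Polymorphism feels the *recent* intensity (B₁/S₁), divergence
the *ancestral* one (B₀/S₀). Nuisance parameters absorb what would
otherwise masquerade as selection: the AT-biased mutation ratio λ (tying
each category's mutational input θ to its reverse category), one
demographic distortion multiplier rᵢ per frequency class (shared across
categories, r₁ ≡ 1), and a polarization-error probability e that mixes
each spectrum with the frequency-mirrored spectrum of its reverse
category. Nested models (each force fixed at 0, free, or ancestral =
recent) are compared by likelihood-ratio tests; the joint 16-model scan is
ranked by AIC. The package also provides the supporting statistics: the
polarization-free skewness test of compositional equilibrium, the modified
McDonald–Kreitman table with NI = (P_WS/P_SW)/(D_WS/D_SW) and
DoS = D_WS/(D_WS+D_SW) − P_WS/(P_WS+P_SW), ΔRSCU codon-preference calling
from expression octiles, GC3 / RSCU / ENC / Fop / π_S / π_N, and the
Li–Bulmer stationary GC content GC* = 1/(1 + λe^{−B}).

## Worked example

Simulate spectra from a known regime (n = 20 chromosomes, mutation bias
λ = 1.7, ancestral B₀ = 0.3, recent B₁ = 0.5, 2% polarization error,
~50 000 SNPs) and re-estimate everything:

```python
from gcforces import SfsModel, SimScenario, simulate_counts, equilibrium_gc

scenario = SimScenario(n=20, lam=1.7, b0=0.3, b1=0.5, e=0.02,
                       target_snps=5e4, seed=1)
data = simulate_counts(scenario)
fit = SfsModel(b0="free", b1="free", n_starts=3, seed=0).fit(data).result_
```

which prints, formatted:

```
lambda = 1.679  (95% CI 1.620-1.740)
B0 (ancestral) = 0.285  (95% CI 0.204-0.360)
B1 (recent)    = 0.427  (95% CI 0.241-0.570)
polarization error e = 0.027
equilibrium GC3 at (lambda, B1): 0.477
```

All four generating parameters are recovered inside their 95% profile
intervals: mutation is AT-biased (λ > 1), gBGC is significantly positive in
both epochs, and the implied stationary GC content under the recent regime
(0.48) sits well above the mutation-only equilibrium 1/(1+λ) ≈ 0.37 — the
signature of a fixation bias toward strong alleles.

The same machinery runs from the shell on real or simulated data:

```bash
gcforces simulate --config scenario.yaml --out species_dir
gcforces report --config species.yaml --seed 1 --out reports/
```

`report` writes per-species TSVs: descriptive codon-usage statistics,
skewness/NI/DoS summaries, the separate gBGC and SCU two-epoch fits with
likelihood-ratio p-values, the best joint model by AIC, gene-category
stratifications (GC3 and expression octiles, the 2×2 GC3 × expression
design) and the 5′ first-252-bp versus rest-of-gene comparison.

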