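"""Synthetic inputs: model-matched spectra, forward Wright-Fisher spectra,
and toy codon alignments with planted gBGC / codon-preference / expression
structure.

All generators are pure functions of their scenario and seed, and emit
exactly the containers and file formats the rest of the pipeline consumes,
so every stage is testable without external data.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._codon import AA_TO_CODONS, CODON_TO_AA, STRONG
from .sfsmodel import (
    BASE_CATEGORIES,
    SpectrumParams,
    _SfsBasis,
    expected_counts,
    fixation_factor,
)
from .spectra import CategorySfsSet

# ---------------------------------------------------------------------------
# model-matched count simulation


@dataclass
class SimScenario:
    """Study conditions for count-level simulations.

    Defaults follow the regimes the estimators are meant for: a sample of
    n = 20 chromosomes, AT-biased mutation (lambda ~ 1.7, the middle of the
    1.6-2.2 range typical of plant transcriptomes), weak gBGC of order a few
    tenths, a small polarization-error probability and enough mutational
    input for ~5e4 SNPs.
    """

    n: int = 20
    set_name: str = "gBGC"
    lam: float = 1.7
    b0: float = 0.3
    b1: float = 0.5
    s0: float = 0.0
    s1: float = 0.0
    e: float = 0.02
    target_snps: float = 5e4
    tau: float = 0.5
    #: neutral-category mutational input relative to the forward category
    neutral_ratio: float = 1.5
    #: piecewise-constant demography: list of (size, generations) epochs,
    #: most recent first; only used by the Wright-Fisher simulator
    demography: tuple = ()
    seed: int = 0

    def params(self) -> SpectrumParams:
        """Model parameters with thetas scaled to hit ``target_snps``."""
        base = BASE_CATEGORIES[self.set_name]
        theta = {}
        for c in base:
            is_neutral = c == "NEUTRAL" or c.endswith("PREF_NEUTRAL")
            theta[c] = self.neutral_ratio if is_neutral else 1.0
        p = SpectrumParams(
            n=self.n, set_name=self.set_name, lam=self.lam, theta=theta,
            b0=self.b0, b1=self.b1, s0=self.s0, s1=self.s1, e=self.e,
            tau=self.tau,
        )
        mu_sfs, _ = expected_counts(p)
        total = sum(v.sum() for v in mu_sfs.values())
        scale = self.target_snps / total
        p.theta = {c: t * scale for c, t in theta.items()}
        return p


def simulate_counts(scenario: SimScenario, seed: int | None = None) -> CategorySfsSet:
    """Poisson draws around the model's expected spectra and divergence."""
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    p = scenario.params()
    mu_sfs, mu_div = expected_counts(p)
    sfs = {c: rng.poisson(mu_sfs[c]).astype(float) for c in mu_sfs}
    div = {c: float(rng.poisson(mu_div[c])) for c in mu_div}
    return CategorySfsSet(n=scenario.n, set_name=scenario.set_name, sfs=sfs, div=div)


# ---------------------------------------------------------------------------
# forward Wright-Fisher simulation


def simulate_wf_sfs(
    n: int,
    gamma: float = 0.0,
    N: int = 500,
    injections_per_gen: float = 50.0,
    n_generations: int | None = None,
    demography: tuple = (),
    e: float = 0.0,
    n_snapshots: int = 1,
    snapshot_every: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Sample SFS from a discrete forward Wright-Fisher population.

    New mutations enter at frequency 1/(2N) at a Poisson rate per
    generation; each segregating site is updated by the deterministic
    conversion/selection term gamma/(4N) * p(1-p) (semidominant) followed by
    binomial drift.  After a burn-in of 10N generations, the currently
    segregating sites are binomially sampled down to ``n`` chromosomes.
    Polarization error flips derived counts i -> n - i with probability
    ``e``.  ``demography`` gives (size, generations) epochs applied after
    burn-in, most ancient first.  When ``n_snapshots`` > 1 the sample SFS is
    pooled over snapshots spaced ``snapshot_every`` generations (N/2 by
    default) after burn-in.  Returns counts over classes 1..n-1.
    """
    if N > 10_000:
        raise ValueError("desk-scale simulator: N must be <= 1e4")
    rng = np.random.default_rng(seed)
    if n_generations is None:
        n_generations = 10 * N
    if snapshot_every is None:
        snapshot_every = max(1, N // 2)
    sizes = [(N, n_generations)] + list(demography)

    p = np.empty(0)

    def advance(size, gens, freqs):
        two_n = 2 * size
        s = gamma / (4.0 * size)
        for _ in range(gens):
            k = rng.poisson(injections_per_gen)
            if k:
                freqs = np.concatenate([freqs, np.full(k, 1.0 / two_n)])
            if freqs.size == 0:
                continue
            p_sel = freqs + s * freqs * (1 - freqs)
            counts = rng.binomial(two_n, np.clip(p_sel, 0.0, 1.0))
            freqs = counts / two_n
            freqs = freqs[(freqs > 0) & (freqs < 1)]
        return freqs

    for size, gens in sizes:
        p = advance(size, gens, p)
    final_size = sizes[-1][0]

    out = np.zeros(n - 1)

    def take_sample(freqs):
        sample = rng.binomial(n, freqs)
        sample = sample[(sample > 0) & (sample < n)]
        if e > 0:
            flip = rng.random(sample.size) < e
            sample = np.where(flip, n - sample, sample)
        return np.bincount(sample, minlength=n)[1:n].astype(float)

    out += take_sample(p)
    for _ in range(n_snapshots - 1):
        p = advance(final_size, snapshot_every, p)
        out += take_sample(p)
    return out


# ---------------------------------------------------------------------------
# alignment-level simulation


@dataclass
class AlignmentScenario:
    """Planted-signal toy transcriptome for the end-to-end pipeline.

    Focal haplotypes and two outgroups evolve from a generated ancestor.
    Ancestral third-position base composition sits at the Li-Bulmer
    equilibrium of the region's gBGC intensity (``b_first`` within the 5'
    cutoff, ``b_rest`` beyond) and the mutation bias lambda, so the
    zero-effect scenario is an exact pipeline-level null (GC3 = 1/(1+lambda),
    skewness ~ 0, DoS ~ 0).  Per-site SNP and substitution rates and derived
    frequencies follow the spectrum model: W sites gain S alleles at rates
    shaped by F_i(B) and d(B), S sites lose them at lambda-fold mutational
    input shaped by F_i(-B) and d(-B).  Codon usage is additionally tilted
    towards a fixed set of truly preferred codons in proportion to gene
    expression (``pref_strength``).
    """

    n_genes: int = 300
    gene_length: int = 900  # must be a multiple of 3
    n_individuals: int = 10
    lam: float = 1.7
    b_first: float = 0.0
    b_rest: float = 0.0
    first_part_cutoff: int = 252
    pref_strength: float = 0.0
    snp_rate: float = 0.02  # neutral per-W-site SNP probability
    sub_rate: float = 0.01
    outgroup_rate: float = 0.005
    gc_gradient: float = 0.0  # extra log-odds of S-ending codons at the 5' end
    expression_sd: float = 1.0
    seed: int = 0


_TWOFOLD_PLUS = {
    aa: codons
    for aa, codons in AA_TO_CODONS.items()
    if aa not in ("*", "M", "W") and len(codons) > 1
}


def preference_truth() -> dict[str, str]:
    """Fixed ground-truth codon preferences used by the generator.

    For every amino acid with a synonymous choice the alphabetically first
    GC-ending codon is preferred and the first AT-ending codon un-preferred
    (GC-ending preference dominates real transcriptomes); all other codons
    are non-significant.
    """
    truth = {}
    for aa, codons in _TWOFOLD_PLUS.items():
        gc_ending = [c for c in codons if c[2] in STRONG]
        at_ending = [c for c in codons if c[2] not in STRONG]
        if gc_ending:
            truth[gc_ending[0]] = "P"
        if at_ending:
            truth[at_ending[0]] = "U"
    return truth


def _family_balance() -> dict[str, float]:
    """Extra log-weight balancing W/S mutational flux within each family.

    A strong-ending codon's equilibrium weight is (n_W / n_S) * exp(B - ln
    lambda), where n_W / n_S count the family's weak/strong-ending codons
    that have a synonymous third-base alternative of the opposite class
    (isoleucine is the one unbalanced family, 2 W : 1 S).
    """
    from math import log

    out: dict[str, float] = {}
    for aa, codons in AA_TO_CODONS.items():
        if aa == "*":
            continue
        cross_w = cross_s = 0
        for c in codons:
            alts = _synonymous_third_substitutions(c)
            if c[2] in STRONG and alts["W"]:
                cross_s += 1
            elif c[2] not in STRONG and alts["S"]:
                cross_w += 1
        for c in codons:
            if c[2] in STRONG and cross_s and cross_w:
                out[c] = log(cross_w / cross_s)
    return out


_BALANCE = None


def _draw_codon(aa: str, z: float, gc_logodds: float, pref_strength: float,
                truth: dict[str, str], u: float) -> str:
    """Sample a codon for ``aa`` given a uniform draw ``u`` in [0, 1)."""
    from math import exp

    global _BALANCE
    if _BALANCE is None:
        _BALANCE = _family_balance()
    codons = AA_TO_CODONS[aa]
    weights = []
    total = 0.0
    for c in codons:
        lw = gc_logodds + _BALANCE.get(c, 0.0) if c[2] in STRONG else 0.0
        status = truth.get(c, "NS")
        if status == "P":
            lw += pref_strength * z
        elif status == "U":
            lw -= pref_strength * z
        w = exp(lw)
        weights.append(w)
        total += w
    acc = 0.0
    target = u * total
    for c, w in zip(codons, weights):
        acc += w
        if target < acc:
            return c
    return codons[-1]


def _synonymous_third_substitutions(codon: str) -> dict[str, list[str]]:
    """Synonymous alternative third bases, keyed by W/S class of the new base."""
    aa = CODON_TO_AA.get(codon)
    out: dict[str, list[str]] = {"W": [], "S": []}
    if aa is None or aa == "*":
        return out
    for b in "ACGT":
        if b == codon[2]:
            continue
        alt = codon[:2] + b
        if CODON_TO_AA.get(alt) == aa:
            out["S" if b in STRONG else "W"].append(b)
    return out


def simulate_alignments(scenario: AlignmentScenario):
    """Generate FASTA-ready alignments, an expression table and truth tables.

    Returns ``(alignments, expression, truth)`` where ``alignments`` is a
    list of dicts (contig_id, sequences by name), ``expression`` a
    pandas.Series of mean RPKM per contig, and ``truth`` a dict with the
    planted preferred-codon table and per-contig ancestral sequences.
    """
    if scenario.gene_length % 3:
        raise ValueError("gene_length must be a multiple of 3")
    rng = np.random.default_rng(scenario.seed)
    truth = preference_truth()
    lam = scenario.lam
    n_hap = 2 * scenario.n_individuals
    n_codons = scenario.gene_length // 3
    basis = _SfsBasis.for_n(n_hap)
    H = float(np.sum(1.0 / np.arange(1, n_hap)))

    # per-region, per-ancestral-class event rates and frequency distributions
    # under the spectrum model (normalised so that B = 0 and lambda = 1 give
    # exactly snp_rate / sub_rate per site)
    def region_rates(B):
        F_ws = basis.binned([B])[0]
        F_sw = basis.binned([-B])[0]
        rates = {
            # ancestral W: W->S events
            "W": (
                scenario.snp_rate * F_ws.sum() / H,
                scenario.sub_rate * float(fixation_factor(B)),
                F_ws / F_ws.sum(),
            ),
            # ancestral S: S->W events carry the lambda-fold mutational input
            "S": (
                lam * scenario.snp_rate * F_sw.sum() / H,
                lam * scenario.sub_rate * float(fixation_factor(-B)),
                F_sw / F_sw.sum(),
            ),
        }
        return rates

    region_cache = {
        "first": region_rates(scenario.b_first),
        "rest": region_rates(scenario.b_rest),
    }
    # ancestral composition at the Li-Bulmer equilibrium of each region
    gc_logodds = {
        "first": scenario.b_first - np.log(lam),
        "rest": scenario.b_rest - np.log(lam),
    }

    aas = [aa for aa in AA_TO_CODONS if aa != "*"]
    log_expr = rng.normal(1.0, scenario.expression_sd, size=scenario.n_genes)
    expression = pd.Series(
        10.0**log_expr,
        index=[f"contig{g:04d}" for g in range(scenario.n_genes)],
        name="rpkm",
    )
    z_scores = (log_expr - log_expr.mean()) / max(log_expr.std(), 1e-9)

    alignments = []
    ancestors = {}
    for g, contig in enumerate(expression.index):
        z = float(z_scores[g])
        aa_draws = rng.integers(0, len(aas), size=n_codons)
        codon_u = rng.random(n_codons)
        codons = ["ATG"]
        for j in range(1, n_codons):
            region = "first" if 3 * j < scenario.first_part_cutoff else "rest"
            logodds = gc_logodds[region] + scenario.gc_gradient * (1 - j / n_codons)
            codons.append(
                _draw_codon(
                    aas[aa_draws[j]], z, logodds, scenario.pref_strength,
                    truth, codon_u[j],
                )
            )
        ancestor = list("".join(codons))
        L = len(ancestor)
        haplotypes = [ancestor.copy() for _ in range(n_hap)]
        out1 = ancestor.copy()
        out2 = ancestor.copy()

        # synonymous W/S polymorphism and substitutions at third positions
        site_u = rng.random(n_codons)
        for j in range(1, n_codons):
            site = 3 * j + 2
            region = "first" if site < scenario.first_part_cutoff else "rest"
            rates = region_cache[region]
            base = ancestor[site]
            cls = "S" if base in STRONG else "W"
            p_snp, p_sub, fdist = rates[cls]
            u = site_u[j]
            if u >= p_snp + p_sub:
                continue
            codon = "".join(ancestor[site - 2 : site + 1])
            new_class = "W" if cls == "S" else "S"
            alts = _synonymous_third_substitutions(codon)[new_class]
            if not alts:
                continue
            derived = alts[rng.integers(len(alts))]
            if u < p_sub:
                for h in haplotypes:
                    h[site] = derived
            else:
                i = 1 + rng.choice(n_hap - 1, p=fdist)
                for h in rng.choice(n_hap, size=i, replace=False):
                    haplotypes[h][site] = derived

        # independent outgroup-branch changes (any position, any base)
        for out in (out1, out2):
            k = rng.poisson(scenario.outgroup_rate * L)
            for site in rng.integers(0, L, size=k):
                out[site] = "ACGT"[rng.integers(4)]

        seqs = {}
        for ind in range(scenario.n_individuals):
            seqs[f"ind{ind:02d}_1"] = "".join(haplotypes[2 * ind])
            seqs[f"ind{ind:02d}_2"] = "".join(haplotypes[2 * ind + 1])
        seqs["outgroup1"] = "".join(out1)
        seqs["outgroup2"] = "".join(out2)
        alignments.append({"contig_id": contig, "sequences": seqs})
        ancestors[contig] = "".join(ancestor)

    truth_tables = {"preferences": truth, "ancestors": ancestors}
    return alignments, expression, truth_tables


def to_codon_alignments(alignments):
    """Convert generator output directly to :class:`CodonAlignment` objects."""
    from .alignments import CodonAlignment

    out = []
    for aln in alignments:
        seqs = aln["sequences"]
        focal = [seqs[k] for k in sorted(seqs) if not k.startswith("outgroup")]
        out.append(
            CodonAlignment(
                contig_id=aln["contig_id"],
                focal_haplotypes=focal,
                outgroup1=seqs["outgroup1"],
                outgroup2=seqs["outgroup2"],
            )
        )
    return out


def write_alignment_fasta(alignments, out_dir) -> list[str]:
    """Write one wrapped FASTA per contig; returns the file paths."""
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for aln in alignments:
        path = os.path.join(out_dir, f"{aln['contig_id']}.fasta")
        with open(path, "w") as fh:
            for name, seq in aln["sequences"].items():
                fh.write(f">{name}\n")
                for k in range(0, len(seq), 70):
                    fh.write(seq[k : k + 70] + "\n")
        paths.append(path)
    return paths


def write_expression_table(expression: pd.Series, path) -> None:
    expression.rename("rpkm").rename_axis("contig_id").to_csv(path, sep="\t")
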