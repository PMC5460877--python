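"""Per-gene codon-usage statistics and expression-driven preference calls.

GC3, relative synonymous codon usage (RSCU), Wright's effective number of
codons (ENC), the frequency of optimal codons (Fop), pairwise synonymous and
non-synonymous diversity, and the delta-RSCU procedure that calls preferred
(P) / un-preferred (U) codons by comparing codon usage between the least-
and most-expressed octiles of genes.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from ._codon import (
    AA_TO_CODONS,
    SENSE_CODONS,
    SINGLE_CODON_AAS,
    STRONG,
    aa_of,
    is_valid_codon,
)

logger = logging.getLogger(__name__)


def iter_codons(sequence: str, frame_offset: int = 0):
    """Yield successive in-frame codons, skipping incomplete/ambiguous ones."""
    seq = sequence.upper()
    for start in range(frame_offset, len(seq) - 2, 3):
        codon = seq[start : start + 3]
        if is_valid_codon(codon):
            yield codon


def gc3(sequence: str, frame_offset: int = 0) -> float:
    """GC fraction at third codon positions (ambiguous bases ignored)."""
    if not sequence:
        raise ValueError("empty sequence")
    thirds = [c[2] for c in iter_codons(sequence, frame_offset)]
    if not thirds:
        raise ValueError("no complete codon in sequence")
    return sum(b in STRONG for b in thirds) / len(thirds)


def rscu(sequence: str, frame_offset: int = 0, classic: bool = False) -> dict[str, float]:
    """Relative synonymous codon usage per codon.

    By default a codon's usage is its frequency divided by the frequency of
    its amino acid (within-family proportion, summing to 1 per family).  With
    ``classic=True`` the proportion is multiplied by family size, giving the
    conventional RSCU scaled around 1.  Codons of absent amino acids are
    omitted from the result.
    """
    counts = Counter(iter_codons(sequence, frame_offset))
    aa_totals: Counter[str] = Counter()
    for codon, k in counts.items():
        aa_totals[aa_of(codon)] += k
    out = {}
    for aa, total in aa_totals.items():
        if aa == "*":
            continue
        family = AA_TO_CODONS[aa]
        for codon in family:
            v = counts.get(codon, 0) / total
            out[codon] = v * len(family) if classic else v
    return out


def enc(sequence: str, frame_offset: int = 0) -> float:
    """Wright's effective number of codons (Nc), in [20, 61].

    Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6 where Fk averages the codon
    homozygosity F = (n*sum(p^2) - 1)/(n - 1) over amino-acid families of
    degeneracy k.  Families with fewer than two codons observed (or F = 0)
    are excluded; a missing 3-fold class is imputed as the mean of the 2- and
    4-fold averages (Wright's rule).  Returns NaN when no class is computable.
    """
    counts = Counter(iter_codons(sequence, frame_offset))
    fam_F: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, family in AA_TO_CODONS.items():
        k = len(family)
        if aa == "*" or k == 1:
            continue
        n = sum(counts.get(c, 0) for c in family)
        if n < 2:
            continue
        p2 = sum((counts.get(c, 0) / n) ** 2 for c in family)
        F = (n * p2 - 1) / (n - 1)
        if F > 0:
            fam_F[k].append(F)
    mean_F = {k: float(np.mean(v)) for k, v in fam_F.items() if v}
    if 2 not in mean_F or 4 not in mean_F:
        if not mean_F:
            return float("nan")
        # degenerate gene: fall back to available classes only
        filler = float(np.mean(list(mean_F.values())))
        mean_F.setdefault(2, filler)
        mean_F.setdefault(4, filler)
    if 3 not in mean_F:
        mean_F[3] = (mean_F[2] + mean_F[4]) / 2
    if 6 not in mean_F:
        mean_F[6] = mean_F[4]
    nc = 2 + 9 / mean_F[2] + 1 / mean_F[3] + 5 / mean_F[4] + 3 / mean_F[6]
    return min(nc, 61.0)


def fop(sequence: str, prefs, frame_offset: int = 0) -> float:
    """Frequency of optimal codons.

    Counts preferred ("P") codons among codons whose amino acid has at least
    one preferred codon; NaN when no such codon occurs.
    """
    status = prefs.get if hasattr(prefs, "get") else prefs.status
    eligible_aas = {
        aa_of(c)
        for c in SENSE_CODONS
        if status(c, "NS") == "P"
    }
    n_pref = n_eligible = 0
    for codon in iter_codons(sequence, frame_offset):
        if aa_of(codon) in eligible_aas:
            n_eligible += 1
            if status(codon, "NS") == "P":
                n_pref += 1
    return n_pref / n_eligible if n_eligible else float("nan")


# ---------------------------------------------------------------------------
# pairwise diversity


def _syn_fraction(codon: str, pos: int) -> float:
    """Fraction of the three possible changes at ``pos`` that are synonymous."""
    aa = aa_of(codon)
    if aa is None or aa == "*":
        return 0.0
    syn = 0
    for b in "ACGT":
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1 :]
        if aa_of(alt) == aa:
            syn += 1
    return syn / 3


def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) site counts of one codon."""
    s = sum(_syn_fraction(codon, p) for p in range(3))
    return s, 3 - s


def _pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) differences between two codons.

    Multi-position differences are averaged over all mutational pathways
    that avoid stop codons (Nei-Gojobori pathway counting).
    """
    diff_pos = [p for p in range(3) if c1[p] != c2[p]]
    if not diff_pos:
        return 0.0, 0.0
    sd_total = nd_total = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0.0
        ok = True
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if aa_of(nxt) == "*" or aa_of(cur) == "*":
                ok = False
                break
            if aa_of(nxt) == aa_of(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            sd_total += sd
            nd_total += nd
            n_paths += 1
    if n_paths == 0:
        return 0.0, float(len(diff_pos))
    return sd_total / n_paths, nd_total / n_paths


_N_CODON_STATES = 65  # 64 codons + one invalid/ambiguous state


def _codon_tables():
    """Precomputed per-codon site counts and pairwise difference matrices."""
    codons = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
    valid = np.zeros(_N_CODON_STATES, dtype=bool)
    s_sites = np.zeros(_N_CODON_STATES)
    n_sites = np.zeros(_N_CODON_STATES)
    for k, c in enumerate(codons):
        if aa_of(c) == "*":
            continue
        valid[k] = True
        s, n = _codon_sites(c)
        s_sites[k], n_sites[k] = s, n
    sd = np.zeros((_N_CODON_STATES, _N_CODON_STATES))
    nd = np.zeros((_N_CODON_STATES, _N_CODON_STATES))
    for i, ci in enumerate(codons):
        for j, cj in enumerate(codons):
            if valid[i] and valid[j]:
                sd[i, j], nd[i, j] = _pair_differences(ci, cj)
    return valid, s_sites, n_sites, sd, nd


_CODON_TABLES: list = []


def _codon_indices(seq: str, frame_offset: int) -> np.ndarray:
    """Codon state per position: 0..63, or 64 for ambiguous codons."""
    base = np.full(256, -1, dtype=np.int64)
    for k, b in enumerate(b"ACGT"):
        base[b] = k
    codes = base[np.frombuffer(seq.encode(), dtype=np.uint8)]
    usable = (len(seq) - frame_offset) // 3 * 3
    codes = codes[frame_offset : frame_offset + usable].reshape(-1, 3)
    bad = (codes < 0).any(axis=1)
    idx = codes[:, 0] * 16 + codes[:, 1] * 4 + codes[:, 2]
    idx[bad] = 64
    return idx


def pi_stats(aln) -> tuple[float, float]:
    """Synonymous and non-synonymous pairwise nucleotide diversity.

    Average over all haplotype pairs of (differences / sites), with
    synonymous/non-synonymous sites counted fractionally per codon
    (Nei-Gojobori pathway counting).  Codons containing gaps, Ns or stops
    in either sequence of a pair are skipped.
    """
    haps = aln.focal_haplotypes
    if len(haps) < 2:
        raise ValueError("pi requires at least two haplotypes")
    if not _CODON_TABLES:
        _CODON_TABLES.append(_codon_tables())
    valid, s_sites, n_sites, sd_mat, nd_mat = _CODON_TABLES[0]
    idx = [_codon_indices(h, aln.frame_offset) for h in haps]
    pi_s_vals, pi_n_vals = [], []
    for ia, ib in itertools.combinations(idx, 2):
        mask = valid[ia] & valid[ib]
        a, b = ia[mask], ib[mask]
        S = (s_sites[a] + s_sites[b]).sum() / 2
        N = (n_sites[a] + n_sites[b]).sum() / 2
        pi_s_vals.append(sd_mat[a, b].sum() / S if S > 0 else np.nan)
        pi_n_vals.append(nd_mat[a, b].sum() / N if N > 0 else np.nan)
    return float(np.nanmean(pi_s_vals)), float(np.nanmean(pi_n_vals))


def gc3_expression_correlation(gc3_values, rpkm_values) -> float:
    """Pearson correlation of GC3 against log10 mean expression (RPKM)."""
    gc3_values = np.asarray(gc3_values, dtype=float)
    rpkm_values = np.asarray(rpkm_values, dtype=float)
    mask = np.isfinite(gc3_values) & (rpkm_values > 0)
    if mask.sum() < 3:
        raise ValueError("need at least 3 genes with positive expression")
    x = gc3_values[mask]
    y = np.log10(rpkm_values[mask])
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# delta-RSCU preference calling


class CodonPreferenceCaller(BaseEstimator):
    """Call preferred / un-preferred codons from expression octiles.

    Genes are ranked by mean expression and split into ``k_bins`` groups of
    (near-)identical size.  For each codon, per-gene RSCU values in the
    lowest and highest bins are compared with a two-sided Mann-Whitney U
    test; the codon is preferred (P) if its RSCU is significantly higher in
    highly expressed genes, un-preferred (U) if significantly lower, and
    non-significant (NS) otherwise.  Stop codons and single-codon amino
    acids (Met, Trp) are always NS.

    Parameters
    ----------
    k_bins : int
        Number of equal-size expression groups (8 octiles by default).
    alpha : float
        Significance level of the per-codon test (no multiple-testing
        correction, matching the classic delta-RSCU procedure).

    Attributes
    ----------
    table_ : pandas.DataFrame
        Per-codon results: amino acid, delta_rscu, p_value, status.
    status_ : dict
        codon -> status in {"P", "U", "NS"}.
    n_pref_gc_, n_pref_at_ : int
        Number of preferred codons ending in G/C resp. A/T.
    """

    def __init__(self, k_bins: int = 8, alpha: float = 0.05):
        self.k_bins = k_bins
        self.alpha = alpha

    def fit(self, sequences, expression):
        """Fit preference calls.

        Parameters
        ----------
        sequences : mapping contig_id -> coding sequence
        expression : mapping contig_id -> mean RPKM
        """
        ids = sorted(set(sequences) & set(expression))
        if len(ids) < 2 * self.k_bins:
            raise ValueError(
                f"need at least {2 * self.k_bins} genes with expression, got {len(ids)}"
            )
        expr = pd.Series({g: float(expression[g]) for g in ids})
        # stable rank: ties broken by contig_id via the sorted index
        order = expr.sort_values(kind="stable").index
        bins = np.array_split(np.arange(len(order)), self.k_bins)
        low_ids = order[bins[0]]
        high_ids = order[bins[-1]]

        rscu_rows = {g: rscu(sequences[g]) for g in ids}
        rscu_df = pd.DataFrame.from_dict(rscu_rows, orient="index")

        records = []
        for codon in SENSE_CODONS:
            aa = aa_of(codon)
            if aa in SINGLE_CODON_AAS:
                records.append((codon, aa, np.nan, np.nan, "NS"))
                continue
            col = rscu_df[codon] if codon in rscu_df else pd.Series(dtype=float)
            lo = col.reindex(low_ids).dropna()
            hi = col.reindex(high_ids).dropna()
            if len(lo) < 2 or len(hi) < 2:
                logger.warning("codon %s: amino acid absent from an octile", codon)
                records.append((codon, aa, np.nan, np.nan, "NS"))
                continue
            delta = float(hi.mean() - lo.mean())
            if np.allclose(lo.var(ddof=0) + hi.var(ddof=0), 0) and np.isclose(
                lo.mean(), hi.mean()
            ):
                p = 1.0
            else:
                p = float(
                    stats.mannwhitneyu(hi, lo, alternative="two-sided").pvalue
                )
            if p <= self.alpha and delta > 0:
                status = "P"
            elif p <= self.alpha and delta < 0:
                status = "U"
            else:
                status = "NS"
            records.append((codon, aa, delta, p, status))

        self.table_ = pd.DataFrame(
            records, columns=["codon", "aa", "delta_rscu", "p_value", "status"]
        ).set_index("codon")
        self.status_ = self.table_["status"].to_dict()
        pref = self.table_.index[self.table_["status"] == "P"]
        self.n_pref_gc_ = int(sum(c[2] in STRONG for c in pref))
        self.n_pref_at_ = int(sum(c[2] not in STRONG for c in pref))
        return self

    def status(self, codon: str, default: str = "NS") -> str:
        return self.status_.get(codon, default)

    def get(self, codon: str, default: str = "NS") -> str:  # dict-like view
        return self.status(codon, default)


def call_preferences(sequences, expression, k_bins: int = 8, alpha: float = 0.05):
    """Functional wrapper around :class:`CodonPreferenceCaller`."""
    return CodonPreferenceCaller(k_bins=k_bins, alpha=alpha).fit(sequences, expression)
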