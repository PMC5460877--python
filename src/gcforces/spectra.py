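"""Category site-frequency spectra and polarization-based summary statistics.

Builds per-category derived-allele frequency spectra (with lineage-specific
substitution counts), the polarization-free skewness test of GC-content
equilibrium, and the modified McDonald-Kreitman statistics (chi-square test,
neutrality index NI, direction of selection DoS) including gene-category
stratifications.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .alignments import GC_CONS, GC_SW, GC_WS, PREF_NEUTRAL, PREF_PU, PREF_UP

NEUTRAL = "NEUTRAL"

#: category labels per set
GBGC_CATEGORIES = (GC_WS, GC_SW, NEUTRAL)
SCU_CATEGORIES = (PREF_UP, PREF_PU, NEUTRAL)
JOINT_CATEGORIES = tuple(
    f"{gc}:{pref}"
    for gc in (GC_WS, GC_SW, GC_CONS)
    for pref in (PREF_UP, PREF_PU, PREF_NEUTRAL)
)

_GC_FLIP = {GC_WS: GC_SW, GC_SW: GC_WS, GC_CONS: GC_CONS}
_PREF_FLIP = {PREF_UP: PREF_PU, PREF_PU: PREF_UP, PREF_NEUTRAL: PREF_NEUTRAL}


def reverse_category(category: str, set_name: str) -> str:
    """The category obtained by swapping ancestral and derived alleles."""
    if set_name == "gBGC":
        return {GC_WS: GC_SW, GC_SW: GC_WS, NEUTRAL: NEUTRAL}[category]
    if set_name == "SCU":
        return {PREF_UP: PREF_PU, PREF_PU: PREF_UP, NEUTRAL: NEUTRAL}[category]
    if set_name == "joint":
        gc, pref = category.split(":")
        return f"{_GC_FLIP[gc]}:{_PREF_FLIP[pref]}"
    raise ValueError(f"unknown set {set_name!r}")


def categories_for(set_name: str) -> tuple[str, ...]:
    try:
        return {
            "gBGC": GBGC_CATEGORIES,
            "SCU": SCU_CATEGORIES,
            "joint": JOINT_CATEGORIES,
        }[set_name]
    except KeyError:
        raise ValueError(f"unknown set {set_name!r}") from None


@dataclass
class CategorySfsSet:
    """Per-category derived-allele spectra plus fixed (divergence) counts.

    ``sfs[category]`` holds counts over derived classes i = 1..n-1 (index
    ``i - 1``); ``div[category]`` the substitution count.
    """

    n: int
    set_name: str
    sfs: dict[str, np.ndarray] = field(default_factory=dict)
    div: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cats = categories_for(self.set_name)
        for c in cats:
            arr = np.asarray(self.sfs.get(c, np.zeros(self.n - 1)), dtype=float)
            if arr.shape != (self.n - 1,):
                raise ValueError(
                    f"category {c}: SFS length {arr.shape} != n-1 = {self.n - 1}"
                )
            if (arr < 0).any():
                raise ValueError(f"category {c}: negative SFS counts")
            self.sfs[c] = arr
            self.div[c] = float(self.div.get(c, 0.0))

    @property
    def categories(self) -> tuple[str, ...]:
        return categories_for(self.set_name)

    def total_snps(self) -> float:
        return float(sum(a.sum() for a in self.sfs.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.categories:
            for i, k in enumerate(self.sfs[c], start=1):
                rows.append((self.set_name, c, str(i), k))
            rows.append((self.set_name, c, "fixed", self.div[c]))
        return pd.DataFrame(rows, columns=["set_name", "category", "class_i", "count"])


def write_sfs_table(data: CategorySfsSet, path) -> None:
    """Write the SFS exchange TSV (``# n=<chromosomes>`` header comment)."""
    with open(path, "w") as fh:
        fh.write(f"# n={data.n}\n")
        data.to_frame().to_csv(fh, sep="\t", index=False)


def read_sfs_table(path, set_name: str | None = None) -> CategorySfsSet:
    """Read an SFS exchange TSV written by :func:`write_sfs_table`."""
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# n="):
            raise ValueError("missing '# n=<chromosomes>' header line")
        n = int(first.split("=", 1)[1])
        df = pd.read_csv(fh, sep="\t", dtype={"class_i": str})
    if set_name is None:
        names = df["set_name"].unique()
        if len(names) != 1:
            raise ValueError(f"file contains multiple sets {names}; pass set_name")
        set_name = names[0]
    df = df[df["set_name"] == set_name]
    sfs: dict[str, np.ndarray] = {}
    div: dict[str, float] = {}
    for c, grp in df.groupby("category"):
        arr = np.zeros(n - 1)
        for _, row in grp.iterrows():
            if row["class_i"] == "fixed":
                div[c] = float(row["count"])
            else:
                arr[int(row["class_i"]) - 1] = float(row["count"])
        sfs[c] = arr
    return CategorySfsSet(n=n, set_name=set_name, sfs=sfs, div=div)


def build_sfs(changes: pd.DataFrame, set_name: str) -> CategorySfsSet:
    """Tally a ChangeTable into a :class:`CategorySfsSet`.

    The gBGC set uses all W/S changes (GC-conservative changes as the
    neutral category); the SCU and joint sets use synonymous changes only.
    """
    n_values = changes["n"].unique() if len(changes) else np.array([], dtype=int)
    if len(n_values) > 1:
        raise ValueError(f"mixed sample sizes in change table: {sorted(n_values)}")
    n = int(n_values[0]) if len(n_values) else 2
    cats = categories_for(set_name)
    data = CategorySfsSet(
        n=n,
        set_name=set_name,
        sfs={c: np.zeros(n - 1) for c in cats},
        div={c: 0.0 for c in cats},
    )
    for _, row in changes.iterrows():
        if set_name == "gBGC":
            cat = row["gc_class"] if row["gc_class"] != GC_CONS else NEUTRAL
        elif set_name == "SCU":
            if not row["synonymous"] or row["pref_class"] == "NA":
                continue
            cat = row["pref_class"] if row["pref_class"] != PREF_NEUTRAL else NEUTRAL
        else:  # joint
            if not row["synonymous"] or row["pref_class"] == "NA":
                continue
            cat = f"{row['gc_class']}:{row['pref_class']}"
        if row["kind"] == "substitution":
            data.div[cat] += 1
        else:
            i = int(row["i"])
            if not 1 <= i <= n - 1:
                raise ValueError(f"SNP derived count {i} outside 1..{n - 1}")
            data.sfs[cat][i - 1] += 1
    return data


# ---------------------------------------------------------------------------
# skewness equilibrium test


def gc_allele_frequencies(changes: pd.DataFrame) -> np.ndarray:
    """Frequency of the S (G/C) allele per W/S SNP, ignoring polarization.

    For a W->S SNP the S allele is derived (frequency i/n); for S->W it is
    ancestral (frequency 1 - i/n).  GC-conservative SNPs are excluded.
    """
    snps = changes[(changes["kind"] == "SNP") & (changes["gc_class"] != GC_CONS)]
    freq = snps["i"].to_numpy(float) / snps["n"].to_numpy(float)
    return np.where(snps["gc_class"].to_numpy() == GC_WS, freq, 1 - freq)


def preferred_allele_frequencies(changes: pd.DataFrame) -> np.ndarray:
    """Frequency of the preferred allele per U/P synonymous SNP."""
    snps = changes[
        (changes["kind"] == "SNP") & changes["pref_class"].isin([PREF_UP, PREF_PU])
    ]
    freq = snps["i"].to_numpy(float) / snps["n"].to_numpy(float)
    return np.where(snps["pref_class"].to_numpy() == PREF_UP, freq, 1 - freq)


def skewness(freqs) -> float:
    """Third standardized central moment g1 = m3 / m2^(3/2).

    Zero is expected when base composition sits at mutation-drift
    equilibrium; negative values indicate GC (or preferred-codon) content
    above its equilibrium, positive values below.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size < 3:
        raise ValueError("skewness requires at least 3 values")
    if np.var(freqs) == 0:
        raise ValueError("skewness undefined for zero-variance sample")
    return float(stats.skew(freqs, bias=True))


def skewness_test(freqs, n_boot: int = 10000, seed: int = 0) -> float:
    """Two-sided bootstrap p-value for the null hypothesis skewness = 0.

    Percentile bootstrap: the sample is resampled with replacement and the
    p-value is twice the smaller tail probability of 0 under the resampled
    g1 distribution.  Deterministic given ``seed``.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size < 10:
        raise ValueError("skewness test requires at least 10 values")
    if np.var(freqs) == 0:
        raise ValueError("skewness test undefined for zero-variance sample")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, freqs.size, size=(n_boot, freqs.size))
    g1 = stats.skew(freqs[idx], axis=1, bias=True)
    p_low = (np.count_nonzero(g1 <= 0) + 1) / (n_boot + 1)
    p_high = (np.count_nonzero(g1 >= 0) + 1) / (n_boot + 1)
    return float(min(1.0, 2 * min(p_low, p_high)))


# ---------------------------------------------------------------------------
# modified MK test


@dataclass(frozen=True)
class ContingencyTable:
    """Polymorphism/divergence counts for the two focal categories of a set.

    For the gBGC set the entries are P_WS, P_SW, D_WS, D_SW; for the SCU set
    the same slots hold U->P / P->U counts.
    """

    p_ws: float
    p_sw: float
    d_ws: float
    d_sw: float

    def __post_init__(self) -> None:
        if min(self.p_ws, self.p_sw, self.d_ws, self.d_sw) < 0:
            raise ValueError("negative contingency counts")


def mk_table(changes: pd.DataFrame, set_name: str) -> ContingencyTable:
    """Tally the 2x2 polymorphism/divergence table for a change set."""
    if set_name == "gBGC":
        fwd, rev, col = GC_WS, GC_SW, "gc_class"
        sub = changes
    elif set_name == "SCU":
        fwd, rev, col = PREF_UP, PREF_PU, "pref_class"
        sub = changes[changes["synonymous"]]
    else:
        raise ValueError(f"unknown set {set_name!r}")
    is_snp = sub["kind"] == "SNP"
    return ContingencyTable(
        p_ws=int(((sub[col] == fwd) & is_snp).sum()),
        p_sw=int(((sub[col] == rev) & is_snp).sum()),
        d_ws=int(((sub[col] == fwd) & ~is_snp).sum()),
        d_sw=int(((sub[col] == rev) & ~is_snp).sum()),
    )


def table_from_sfs(data: CategorySfsSet) -> ContingencyTable:
    """Contingency table from a 3-category spectra set (gBGC or SCU)."""
    fwd, rev = data.categories[0], data.categories[1]
    return ContingencyTable(
        p_ws=float(data.sfs[fwd].sum()),
        p_sw=float(data.sfs[rev].sum()),
        d_ws=data.div[fwd],
        d_sw=data.div[rev],
    )


def mk_chi2(t: ContingencyTable) -> float:
    """Pearson chi-square p-value (1 df, no continuity correction)."""
    table = np.array([[t.p_ws, t.p_sw], [t.d_ws, t.d_sw]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined with a zero margin")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p)


def ni(t: ContingencyTable) -> float:
    """Neutrality index (P_WS/P_SW)/(D_WS/D_SW); NaN when undefined.

    Values below 1 indicate a fixation bias toward S (or preferred) alleles
    at the divergence level relative to polymorphism.
    """
    if t.p_sw == 0 or t.d_ws == 0 or t.d_sw == 0:
        return float("nan")
    return (t.p_ws / t.p_sw) / (t.d_ws / t.d_sw)


def dos(t: ContingencyTable) -> float:
    """Direction of selection D_WS/(D_WS+D_SW) - P_WS/(P_WS+P_SW)."""
    d_tot, p_tot = t.d_ws + t.d_sw, t.p_ws + t.p_sw
    if d_tot == 0 or p_tot == 0:
        return float("nan")
    return t.d_ws / d_tot - t.p_ws / p_tot


# ---------------------------------------------------------------------------
# gene-category stratifications


def _octile_bins(metric: pd.Series, k: int) -> pd.Series:
    """Assign genes to k rank bins of near-identical size (stable ties)."""
    order = metric.sort_values(kind="stable").index
    bins = pd.Series(index=order, dtype=int)
    for b, idx in enumerate(np.array_split(np.arange(len(order)), k)):
        bins.iloc[idx] = b
    return bins


def binned_mk(changes: pd.DataFrame, gene_metric: pd.Series, k: int = 8, set_name: str = "gBGC") -> pd.DataFrame:
    """NI/DoS per gene-metric octile.

    Changes are assigned to bins by their gene's metric (GC3 or mean
    expression).  Returns one row per bin with the contingency counts, NI,
    DoS and the chi-square p-value (NaN where undefined).
    """
    missing = set(changes["contig_id"]) - set(gene_metric.index)
    if missing:
        raise ValueError(f"gene metric missing for contigs: {sorted(missing)[:5]}...")
    bins = _octile_bins(gene_metric, k)
    rows = []
    for b in range(k):
        contigs = bins.index[bins == b]
        sub = changes[changes["contig_id"].isin(contigs)]
        t = mk_table(sub, set_name)
        row = {
            "bin": b,
            "metric_mean": float(gene_metric.loc[contigs].mean()),
            "p_fwd": t.p_ws,
            "p_rev": t.p_sw,
            "d_fwd": t.d_ws,
            "d_rev": t.d_sw,
            "ni": ni(t),
            "dos": dos(t),
        }
        try:
            row["p_value"] = mk_chi2(t)
        except ValueError:
            row["p_value"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def crossed_mk(changes: pd.DataFrame, gc3_metric: pd.Series, expr_metric: pd.Series, set_name: str = "gBGC") -> pd.DataFrame:
    """2x2 design: GC3 halves crossed with expression halves (median splits)."""
    gc_high = gc3_metric >= gc3_metric.median()
    ex_high = expr_metric >= expr_metric.median()
    rows = []
    for gc_flag in (False, True):
        for ex_flag in (False, True):
            contigs = gc3_metric.index[
                (gc_high == gc_flag) & (ex_high.reindex(gc3_metric.index) == ex_flag)
            ]
            sub = changes[changes["contig_id"].isin(contigs)]
            t = mk_table(sub, set_name)
            rows.append(
                {
                    "gc3_group": "high" if gc_flag else "low",
                    "expr_group": "high" if ex_flag else "low",
                    "ni": ni(t),
                    "dos": dos(t),
                    "n_changes": len(sub),
                }
            )
    return pd.DataFrame(rows)


def split_first_part(
    changes: pd.DataFrame,
    cutoff: int = 252,
    require_start: bool = False,
    start_contigs=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split changes at the 5' cutoff (first-exon proxy) vs the rest.

    With ``require_start`` only contigs beginning with a start codon (their
    ids given in ``start_contigs``) are kept at all.
    """
    if require_start:
        if start_contigs is None:
            raise ValueError("require_start needs the set of ATG-starting contigs")
        changes = changes[changes["contig_id"].isin(set(start_contigs))]
    first = changes[changes["position"] < cutoff]
    rest = changes[changes["position"] >= cutoff]
    return first, rest
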