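"""Polarization of SNPs and substitutions from codon-aware alignments.

A focal population sample (two haplotype sequences per diploid individual)
is aligned with two outgroup sequences per contig.  Sites are filtered to
gapless, fully genotyped, at most bi-allelic positions; changes are
polarized by parsimony (ancestral allele = allele shared by both outgroups)
and classified as W->S, S->W or GC-conservative, and -- for synonymous
changes -- by their effect on codon preference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._codon import STRONG, WEAK, aa_of, is_valid_codon

logger = logging.getLogger(__name__)

GC_WS = "WS"
GC_SW = "SW"
GC_CONS = "GC_CONS"

PREF_UP = "UP"
PREF_PU = "PU"
PREF_NEUTRAL = "PREF_NEUTRAL"
PREF_NA = "NA"

#: columns of the tabular change representation ("ChangeTable")
CHANGE_COLUMNS = [
    "contig_id",
    "position",
    "kind",
    "ancestral",
    "derived",
    "i",
    "n",
    "gc_class",
    "pref_class",
    "synonymous",
    "in_first_part",
]

_ALPHABET = set("ACGTN-")


class MalformedAlignmentError(ValueError):
    """Raised when a contig alignment violates the length/alphabet contract."""


@dataclass
class CodonAlignment:
    """One contig: focal haplotypes plus two outgroup sequences.

    ``focal_haplotypes`` holds two sequences per diploid individual, in
    individual order (``ind_1``, ``ind_2`` pairs).  All sequences share the
    same length; the reading frame starts at ``frame_offset``.
    """

    contig_id: str
    focal_haplotypes: list[str]
    outgroup1: str
    outgroup2: str
    frame_offset: int = 0
    has_start_codon: bool = field(default=False)

    def __post_init__(self) -> None:
        seqs = [*self.focal_haplotypes, self.outgroup1, self.outgroup2]
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise MalformedAlignmentError(
                f"contig {self.contig_id}: sequences of unequal length {sorted(lengths)}"
            )
        for s in seqs:
            bad = set(s) - _ALPHABET
            if bad:
                raise MalformedAlignmentError(
                    f"contig {self.contig_id}: invalid characters {sorted(bad)}"
                )
        if not 0 <= self.frame_offset <= 2:
            raise MalformedAlignmentError(
                f"contig {self.contig_id}: frame offset {self.frame_offset} not in 0..2"
            )
        # derive start-codon flag from the sequence itself when not supplied
        cons = self.consensus()
        self.has_start_codon = (
            cons[self.frame_offset : self.frame_offset + 3] == "ATG"
        )

    @property
    def length(self) -> int:
        return len(self.outgroup1)

    @property
    def n_haplotypes(self) -> int:
        return len(self.focal_haplotypes)

    def consensus(self) -> str:
        """Majority base of the focal haplotypes at every site ('N' on ties)."""
        mat = np.stack(
            [
                _BASE_CODE[np.frombuffer(h.encode(), dtype=np.uint8)]
                for h in self.focal_haplotypes
            ]
        )
        counts = np.stack([(mat == b).sum(axis=0) for b in range(4)])
        order = np.sort(counts, axis=0)
        best = np.argmax(counts, axis=0)
        ok = (order[-1] > 0) & (order[-1] > order[-2])
        out = np.where(ok, best, 4)
        return "".join("ACGTN"[k] for k in out)


def read_alignments(paths, frame_offset: int = 0) -> list[CodonAlignment]:
    """Read per-contig FASTA alignments into :class:`CodonAlignment` objects.

    Focal haplotypes are records named ``<ind>_1`` / ``<ind>_2``; the two
    outgroups are named ``outgroup1`` and ``outgroup2``.  A contig missing an
    outgroup is skipped with a warning; unequal sequence lengths raise
    :class:`MalformedAlignmentError` naming the contig.
    """
    if isinstance(paths, (str, bytes)) or hasattr(paths, "read"):
        paths = [paths]
    alignments = []
    for path in paths:
        records = list(SeqIO.parse(path, "fasta"))
        contig_id = getattr(path, "name", str(path))
        contig_id = contig_id.rsplit("/", 1)[-1]
        for suffix in (".fasta", ".fa", ".fna"):
            if contig_id.endswith(suffix):
                contig_id = contig_id[: -len(suffix)]
        by_name = {r.id: str(r.seq).upper() for r in records}
        out1 = by_name.pop("outgroup1", None)
        out2 = by_name.pop("outgroup2", None)
        if out1 is None or out2 is None:
            logger.warning("contig %s: missing outgroup, skipped", contig_id)
            continue
        focal = [by_name[k] for k in sorted(by_name)]
        alignments.append(
            CodonAlignment(
                contig_id=contig_id,
                focal_haplotypes=focal,
                outgroup1=out1,
                outgroup2=out2,
                frame_offset=frame_offset,
            )
        )
    return alignments


def usable_sites(aln: CodonAlignment) -> list[int]:
    """Sites with no gap/N anywhere and at most two focal alleles."""
    sites = []
    for j in range(aln.length):
        col = [h[j] for h in aln.focal_haplotypes] + [aln.outgroup1[j], aln.outgroup2[j]]
        if any(b not in "ACGT" for b in col):
            continue
        if len(set(col[:-2])) > 2:
            continue
        sites.append(j)
    return sites


def haploidize(aln: CodonAlignment, seed: int) -> CodonAlignment:
    """Collapse each diploid individual to a single haplotype.

    Homozygous sites keep their base; heterozygous sites take one of the two
    alleles uniformly at random (deterministic given ``seed``).  Used for
    highly selfing species where excess homozygosity distorts the diploid
    frequency spectrum.
    """
    if aln.n_haplotypes % 2:
        raise ValueError("haploidize requires two haplotypes per individual")
    rng = np.random.default_rng(seed)
    merged = []
    for k in range(0, aln.n_haplotypes, 2):
        h1 = np.frombuffer(aln.focal_haplotypes[k].encode(), dtype="S1")
        h2 = np.frombuffer(aln.focal_haplotypes[k + 1].encode(), dtype="S1")
        pick = rng.integers(0, 2, size=h1.size).astype(bool)
        merged.append(np.where(pick, h2, h1).tobytes().decode())
    return CodonAlignment(
        contig_id=aln.contig_id,
        focal_haplotypes=merged,
        outgroup1=aln.outgroup1,
        outgroup2=aln.outgroup2,
        frame_offset=aln.frame_offset,
    )


def classify_gc(ancestral: str, derived: str) -> str:
    """W->S / S->W / GC-conservative class of a base change."""
    if ancestral == derived:
        raise ValueError("ancestral and derived bases are identical")
    if ancestral in WEAK and derived in STRONG:
        return GC_WS
    if ancestral in STRONG and derived in WEAK:
        return GC_SW
    return GC_CONS


def classify_pref(ancestral_codon: str, derived_codon: str, prefs) -> str:
    """Preference class of a synonymous codon change.

    ``prefs`` maps codons to a status in {"P", "U", "NS"} (see
    :mod:`gcforces.codonbias`).  Changes that increase preference
    (U->NS, U->P, NS->P) are UP, decreasing ones are PU, and changes between
    equal-status codons are preference-neutral.  Non-synonymous or ambiguous
    codons return NA.
    """
    if not (is_valid_codon(ancestral_codon) and is_valid_codon(derived_codon)):
        return PREF_NA
    aa_a, aa_d = aa_of(ancestral_codon), aa_of(derived_codon)
    if aa_a is None or aa_d is None or aa_a != aa_d or aa_a == "*":
        return PREF_NA
    rank = {"U": 0, "NS": 1, "P": 2}
    status = prefs.get if hasattr(prefs, "get") else prefs.status
    sa = status(ancestral_codon, "NS")
    sd = status(derived_codon, "NS")
    if rank[sd] > rank[sa]:
        return PREF_UP
    if rank[sd] < rank[sa]:
        return PREF_PU
    return PREF_NEUTRAL


def polarize_snp(aln: CodonAlignment, site: int):
    """Parsimony polarization of a bi-allelic focal site.

    The ancestral allele is the one carried by both outgroups; if the
    outgroups disagree, or match neither focal allele, the SNP cannot be
    polarized and None is returned.  Returns
    ``(ancestral, derived, derived_count)`` otherwise.
    """
    col = [h[site] for h in aln.focal_haplotypes]
    alleles = sorted(set(col))
    if len(alleles) != 2:
        return None
    o1, o2 = aln.outgroup1[site], aln.outgroup2[site]
    if o1 != o2 or o1 not in alleles:
        return None
    ancestral = o1
    derived = alleles[0] if alleles[1] == ancestral else alleles[1]
    return ancestral, derived, sum(1 for b in col if b == derived)


def call_substitution(aln: CodonAlignment, site: int):
    """Lineage-specific substitution call at a focal-monomorphic site.

    Requires both outgroups to share a base differing from the fixed focal
    base; returns ``(ancestral, derived)`` or None.
    """
    col = {h[site] for h in aln.focal_haplotypes}
    if len(col) != 1:
        return None
    focal = next(iter(col))
    o1, o2 = aln.outgroup1[site], aln.outgroup2[site]
    if o1 != o2 or o1 == focal:
        return None
    return o1, focal


def _codon_context(aln: CodonAlignment, consensus: str, site: int):
    """Consensus codon around ``site`` and the in-codon position, or None.

    The two non-variant positions take the focal majority consensus; an
    ambiguous consensus ('N', e.g. a tie or a second polymorphic position
    without majority) disqualifies the codon context.
    """
    rel = site - aln.frame_offset
    if rel < 0:
        return None
    codon_idx, pos_in_codon = divmod(rel, 3)
    start = aln.frame_offset + 3 * codon_idx
    if start + 3 > aln.length:
        return None
    codon = list(consensus[start : start + 3])
    for k in range(3):
        if k != pos_in_codon and codon[k] not in "ACGT":
            return None
    return codon, pos_in_codon


_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _k, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _k
_CODE_BASE = "ACGT"


def _seq_codes(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _polarized_events(aln: CodonAlignment):
    """Vectorized site scan: yields (site, kind, ancestral, derived, i).

    Equivalent to running :func:`polarize_snp` / :func:`call_substitution`
    over :func:`usable_sites`; implemented on a base-count matrix for speed.
    """
    H = aln.n_haplotypes
    mat = np.stack([_seq_codes(h) for h in aln.focal_haplotypes])
    o1, o2 = _seq_codes(aln.outgroup1), _seq_codes(aln.outgroup2)
    counts = np.stack([(mat == b).sum(axis=0) for b in range(4)])
    focal_ok = counts.sum(axis=0) == H
    out_ok = (o1 < 4) & (o2 < 4)
    n_alleles = (counts > 0).sum(axis=0)
    usable = focal_ok & out_ok & (n_alleles <= 2)

    # SNPs: outgroups agree and carry one of the two focal alleles
    snp_sites = np.nonzero(usable & (n_alleles == 2) & (o1 == o2))[0]
    for site in snp_sites:
        anc = int(o1[site])
        if counts[anc, site] == 0:
            continue
        alleles = np.nonzero(counts[:, site])[0]
        der = int(alleles[0] if alleles[1] == anc else alleles[1])
        yield int(site), "SNP", _CODE_BASE[anc], _CODE_BASE[der], int(counts[der, site])

    # substitutions: focal fixed, both outgroups share a different base
    sub_sites = np.nonzero(usable & (n_alleles == 1) & (o1 == o2))[0]
    for site in sub_sites:
        focal = int(np.nonzero(counts[:, site])[0][0])
        anc = int(o1[site])
        if anc == focal:
            continue
        yield int(site), "substitution", _CODE_BASE[anc], _CODE_BASE[focal], H


def extract_changes(
    alignments,
    prefs=None,
    first_part_cutoff: int = 252,
    selfing: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Polarize every usable site of every contig into a ChangeTable.

    Returns a DataFrame with columns :data:`CHANGE_COLUMNS`, one row per
    polarized SNP or substitution.  ``prefs`` (optional codon-status mapping)
    drives the preference classification of synonymous changes; without it
    all preference classes are NA.
    """
    rows = []
    for aln in alignments:
        if selfing:
            aln = haploidize(aln, seed=seed)
        n = aln.n_haplotypes
        consensus = aln.consensus()
        for site, kind, ancestral, derived, count in _polarized_events(aln):
            ctx = _codon_context(aln, consensus, site)
            synonymous = False
            pref_class = PREF_NA
            if ctx is not None:
                codon, pos = ctx
                anc_codon = codon.copy()
                anc_codon[pos] = ancestral
                der_codon = codon.copy()
                der_codon[pos] = derived
                anc_codon, der_codon = "".join(anc_codon), "".join(der_codon)
                aa_a, aa_d = aa_of(anc_codon), aa_of(der_codon)
                synonymous = (
                    aa_a is not None and aa_a == aa_d and aa_a != "*"
                )
                if synonymous and prefs is not None:
                    pref_class = classify_pref(anc_codon, der_codon, prefs)
                elif synonymous:
                    pref_class = PREF_NA
            rows.append(
                (
                    aln.contig_id,
                    site,
                    kind,
                    ancestral,
                    derived,
                    count,
                    n,
                    classify_gc(ancestral, derived),
                    pref_class,
                    synonymous,
                    site < first_part_cutoff,
                )
            )
    return pd.DataFrame(rows, columns=CHANGE_COLUMNS)


def write_change_table(changes: pd.DataFrame, path) -> None:
    changes.to_csv(path, sep="\t", index=False)


def read_change_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CHANGE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"change table missing columns: {sorted(missing)}")
    return df
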