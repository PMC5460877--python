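"""Genetic-code helpers shared across modules.

Everything here derives from the standard nuclear code as shipped with
Biopython; nothing is hard-coded except the weak/strong base grouping.
"""

from __future__ import annotations

from Bio.Data import CodonTable

BASES = ("A", "C", "G", "T")

#: weak (A/T) and strong (G/C) base groups used to classify changes with
#: respect to GC-biased gene conversion
WEAK = frozenset("AT")
STRONG = frozenset("GC")

_standard = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid ('*' for stops)
CODON_TO_AA: dict[str, str] = dict(_standard.forward_table)
for _stop in _standard.stop_codons:
    CODON_TO_AA[_stop] = "*"

STOP_CODONS = frozenset(_standard.stop_codons)

#: amino acid -> tuple of synonymous codons (stops under '*')
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, ())
    AA_TO_CODONS[_aa] += (_codon,)

#: sense codons only (61 entries)
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in sorted(CODON_TO_AA) if CODON_TO_AA[c] != "*"
)

#: amino acids with a single codon (no synonymous choice)
SINGLE_CODON_AAS = frozenset(
    aa for aa, codons in AA_TO_CODONS.items() if aa != "*" and len(codons) == 1
)


def is_valid_codon(codon: str) -> bool:
    return len(codon) == 3 and all(b in BASES for b in codon)


def aa_of(codon: str) -> str | None:
    """Amino acid for ``codon``, or None for ambiguous/invalid codons."""
    return CODON_TO_AA.get(codon)


def synonymous_codons(codon: str) -> tuple[str, ...]:
    """All codons encoding the same amino acid (including ``codon``)."""
    aa = CODON_TO_AA.get(codon)
    if aa is None:
        return ()
    return AA_TO_CODONS[aa]


def degeneracy(codon: str) -> int:
    return len(synonymous_codons(codon))


def gc_base(base: str) -> bool:
    return base in STRONG
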