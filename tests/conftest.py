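import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gcforces.alignments import CodonAlignment

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_alignment(focal, out1, out2, contig_id="contig0", frame_offset=0):
    return CodonAlignment(
        contig_id=contig_id,
        focal_haplotypes=list(focal),
        outgroup1=out1,
        outgroup2=out2,
        frame_offset=frame_offset,
    )


@pytest.fixture
def simple_alignment():
    """10 haplotypes, 300 bp, with one known SNP and one substitution.

    Ancestral sequence = outgroups.  Site 5 (third codon position, GCA->GCG,
    Ala synonymous) carries derived G in 2 haplotypes; site 11 (ACT->ACC,
    Thr synonymous) is fixed derived C in all focal haplotypes.
    """
    rng = np.random.default_rng(42)
    codons = ["ATG", "GCA", "CGT", "ACT", "GGA", "TTA", "CCT", "GAA"]
    ancestor = "".join(codons) * 12  # 288 bp
    ancestor += "GCTGCAGCGACT"  # pad to 300
    haps = [list(ancestor) for _ in range(10)]
    for h in haps:
        h[11] = "C"  # fixed derived: ACT -> ACC at codon 3
    for h in haps[:2]:
        h[5] = "G"  # SNP: GCA -> GCG at codon 1, derived count 2
    return make_alignment(
        ["".join(h) for h in haps], ancestor, ancestor, contig_id="fix1"
    )
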