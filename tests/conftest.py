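import pytest

from cyp2c19sup.calling import all_haplogenotypes
from cyp2c19sup.genotype_io import RSID_17, RSID_2, SampleGenotypes, SnpGenotype

_G17_TOKENS = {0: "CC", 1: "CT", 2: "TT"}
_G2_TOKENS = {0: "GG", 1: "GA", 2: "AA"}


def make_sample(sample_id: str, g17: str | None, g2: str | None) -> SampleGenotypes:
    """Build a sample from two-character genotype tokens (None = missing)."""
    s17 = (SnpGenotype.missing_at(RSID_17) if g17 is None
           else SnpGenotype.from_alleles(RSID_17, g17[0], g17[1]))
    s2 = (SnpGenotype.missing_at(RSID_2) if g2 is None
          else SnpGenotype.from_alleles(RSID_2, g2[0], g2[1]))
    return SampleGenotypes(sample_id, s17, s2)


@pytest.fixture(scope="session")
def nine_haplogenotype_samples() -> list[SampleGenotypes]:
    """One sample per haplogenotype (6 canonical + 3 unknown-phenotype)."""
    return [
        make_sample(f"HG{ix}", _G17_TOKENS[hg._n17], _G2_TOKENS[hg._n2])
        for ix, hg in enumerate(all_haplogenotypes(), start=1)
    ]


@pytest.fixture(scope="session")
def full_genotype_space() -> list[SampleGenotypes]:
    """All 16 combinations of {CC, CT, TT, missing} x {GG, GA, AA, missing}."""
    g17s = ["CC", "CT", "TT", None]
    g2s = ["GG", "GA", "AA", None]
    return [make_sample(f"S{i}_{j}", g17, g2)
            for i, g17 in enumerate(g17s) for j, g2 in enumerate(g2s)]
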