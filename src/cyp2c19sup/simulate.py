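"""Seeded synthetic cohort generator for the two CYP2C19 markers.

Samples are drawn under the same model the frequency projection assumes:
each individual receives two star haplotypes independently from {*1, *2,
*17} with probabilities (h1, h2, h17) — Hardy-Weinberg equilibrium — and the
haplotypes are converted to the two SNP genotypes. Because no haplotype
carries both variant alleles, simulated samples are canonical unless
non-canonical injection is switched on, which replaces a small fraction of
samples with uniformly chosen unknown-phenotype haplogenotypes (the observed
real-world rate of such carriers is about 0.045 per mille).

Randomness is counter-based (Philox keyed by the seed, a fixed number of
draws per sample), so the first n samples of a cohort do not change when
n_samples is increased.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .calling import (
    StarHaplotypePair,
    all_haplogenotypes,
    haplotypes_to_genotypes,
)
from .errors import FrequencyError
from .genotype_io import (
    RSID_17,
    RSID_2,
    SampleGenotypes,
    SnpGenotype,
    write_genotype_table,
    write_vcf,
)
from .popfreq import HaplotypeFrequencySet

#: Observed rate of unknown-phenotype haplogenotype carriers (0.045 per
#: mille) in the largest experimentally genotyped cohort.
REPORTED_NON_CANONICAL_RATE = 0.000045

_STARS = ("*1", "*2", "*17")


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort simulation parameters."""

    h: HaplotypeFrequencySet
    n_samples: int
    seed: int
    allow_non_canonical: bool = False
    non_canonical_rate: float = 0.0

    def __post_init__(self):
        if self.n_samples <= 0:
            raise FrequencyError("n_samples must be positive")
        if not (0.0 <= self.non_canonical_rate <= 0.01):
            raise FrequencyError(
                "non_canonical_rate must lie in [0, 0.01]; such carriers "
                "are extremely rare")


def _genotype_from_counts(n17: int, n2: int, sample_id: str) -> SampleGenotypes:
    g17 = SnpGenotype.from_alleles(
        RSID_17, *("CC", "CT", "TT")[n17])
    g2 = SnpGenotype.from_alleles(
        RSID_2, *("GG", "GA", "AA")[n2])
    return SampleGenotypes(sample_id, g17, g2)


def simulate_cohort(cfg: SimulationConfig) -> list[SampleGenotypes]:
    """Draw a cohort of genotypes under HWE with the LD constraint.

    Each sample consumes exactly four uniform draws (two haplotypes, one
    replacement decision, one non-canonical choice), so cohort prefixes are
    stable under changes of ``n_samples``.
    """
    rng = np.random.Generator(np.random.Philox(key=cfg.seed))
    u = rng.random((cfg.n_samples, 4))
    cum = np.cumsum(cfg.h.as_tuple())
    hap_ix = np.searchsorted(cum, u[:, :2], side="right")
    hap_ix = np.minimum(hap_ix, 2)  # guard the u ~ 1.0 edge
    non_canonical = [hg for hg in all_haplogenotypes() if not hg.canonical]
    width = len(str(cfg.n_samples))
    samples: list[SampleGenotypes] = []
    for i in range(cfg.n_samples):
        sid = f"S{i + 1:0{width}d}"
        if cfg.allow_non_canonical and u[i, 2] < cfg.non_canonical_rate:
            hg = non_canonical[min(int(u[i, 3] * 3), 2)]
            samples.append(_genotype_from_counts(hg._n17, hg._n2, sid))
            continue
        pair = StarHaplotypePair(_STARS[hap_ix[i, 0]], _STARS[hap_ix[i, 1]])
        samples.append(haplotypes_to_genotypes(pair, sample_id=sid))
    return samples


#: Synthetic population frequency grid spanning PM-dominant to *17-rich
#: regimes, for demos and tests. These are invented values, not database
#: exports.
SYNTHETIC_POPULATIONS: dict[str, dict[str, float]] = {
    "european_like": {"*1": 0.62, "*2": 0.15, "*17": 0.23},
    "african_like": {"*1": 0.61, "*2": 0.17, "*17": 0.22},
    "near_eastern_like": {"*1": 0.66, "*2": 0.12, "*17": 0.22},
    "latino_like": {"*1": 0.77, "*2": 0.11, "*17": 0.12},
    "east_asian_like": {"*1": 0.655, "*2": 0.31, "*17": 0.035},
    "oceanian_like": {"*1": 0.2227, "*2": 0.7141, "*17": 0.0632},
}

_FIXTURE_SEED = 20220711
_FIXTURE_COHORT_N = 50
_FIXTURE_COHORT_H = (0.6, 0.2, 0.2)


def make_fixture_suite(outdir: str | Path) -> dict[str, str]:
    """Write deterministic demo/test fixtures into ``outdir``.

    Produces the canonical 9-sample genotype table (one sample per
    haplogenotype, 3 of them non-canonical), a synthetic 6-population allele
    frequency CSV, a simulated VCF cohort, and a JSON manifest. Output is
    byte-identical across runs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    nine = [
        _genotype_from_counts(hg._n17, hg._n2,
                              f"HG{ix + 1}_{hg.display.replace('/', '_')}")
        for ix, hg in enumerate(all_haplogenotypes())
    ]
    table_path = outdir / "haplogenotypes_9.tsv"
    write_genotype_table(nine, table_path)

    freq_path = outdir / "populations_synthetic.csv"
    with open(freq_path, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write("population,allele,frequency\n")
        for pop, freqs in SYNTHETIC_POPULATIONS.items():
            for allele in ("*1", "*2", "*17"):
                fh.write(f"{pop},{allele},{freqs[allele]}\n")

    cohort = simulate_cohort(SimulationConfig(
        h=HaplotypeFrequencySet(*_FIXTURE_COHORT_H),
        n_samples=_FIXTURE_COHORT_N, seed=_FIXTURE_SEED))
    vcf_path = outdir / "cohort_simulated.vcf"
    write_vcf(cohort, vcf_path)

    manifest = {
        "seed": _FIXTURE_SEED,
        "files": {
            "haplogenotypes_9.tsv":
                "all 9 haplogenotypes (6 canonical, 3 unknown-phenotype)",
            "populations_synthetic.csv":
                "synthetic *1/*2/*17 allele frequencies for 6 populations",
            "cohort_simulated.vcf":
                f"{_FIXTURE_COHORT_N} samples simulated at "
                f"h={_FIXTURE_COHORT_H}",
        },
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "wt", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {name: str(outdir / name) for name in
            ("haplogenotypes_9.tsv", "populations_synthetic.csv",
             "cohort_simulated.vcf", "manifest.json")}
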