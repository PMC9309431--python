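"""Population haplogenotype-frequency profiles and comparisons.

From the haplotype (star allele) frequencies h1, h2, h17 of *1, *2 and *17,
random mating (Hardy-Weinberg equilibrium) combined with the *2/*17 linkage-
disequilibrium constraint gives the six canonical haplogenotype — hence
phenotype — frequencies:

    EM = h1**2      IM = 2*h1*h2     PM = h2**2
    RM = 2*h1*h17   UM = h17**2      AM = 2*h2*h17

(the three non-canonical haplogenotypes have frequency zero under the LD
constraint). Population profiles are compared with a Pearson chi-square
statistic on the 2 x 6 contingency table; the "exact" p-value is a seeded
Monte Carlo conditional test (tables resampled under fixed margins), with a
chi-square asymptotic mode as fallback. Effect size is Cramer's phi,
phi = sqrt(chi2 / (N * (min(rows, cols) - 1))) = sqrt(chi2 / N) for a 2 x k
table, binned as medium for 0.3 <= phi < 0.5 and large for phi >= 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calling import PHENOTYPE_ORDER, Phenotype, call_haplogenotype
from .errors import EmptyCohortError, FrequencyError
from .genotype_io import SampleGenotypes

_CANONICAL_ALLELES = ("*1", "*2", "*17")
_PHENOTYPE_LABELS = tuple(p.value for p in PHENOTYPE_ORDER)


@dataclass(frozen=True)
class HaplotypeFrequencySet:
    """Frequencies of the three star haplotypes; must sum to one."""

    h1: float
    h2: float
    h17: float

    def __post_init__(self):
        for name, v in (("h1", self.h1), ("h2", self.h2), ("h17", self.h17)):
            if not (0.0 <= v <= 1.0):
                raise FrequencyError(f"{name}={v} outside [0, 1]")
        total = self.h1 + self.h2 + self.h17
        if abs(total - 1.0) > 1e-9:
            raise FrequencyError(
                f"haplotype frequencies sum to {total}, not 1 "
                "(use renormalize_alleles for raw allele tables)")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.h1, self.h2, self.h17)


@dataclass(frozen=True)
class PopulationProfile:
    """Named haplogenotype/phenotype frequency profile of one population."""

    name: str
    freq: Mapping[str, float]            # haplogenotype display -> frequency
    phenotype_freq: Mapping[str, float]  # PM..UM -> frequency

    def __post_init__(self):
        for label, m in (("haplogenotype", self.freq),
                         ("phenotype", self.phenotype_freq)):
            total = sum(m.values())
            if abs(total - 1.0) > 1e-9:
                raise FrequencyError(
                    f"{self.name}: {label} frequencies sum to {total}, not 1")

    def phenotype_vector(self) -> np.ndarray:
        return np.array([self.phenotype_freq[p] for p in _PHENOTYPE_LABELS])


@dataclass(frozen=True)
class HaplotypeFrequencyEstimate:
    """Allele-counting estimate with binomial standard errors."""

    freqs: HaplotypeFrequencySet
    se_h1: float
    se_h2: float
    se_h17: float
    n_samples: int
    n_non_canonical: int          # counted in the estimate but flagged
    non_canonical_ids: tuple[str, ...]


@dataclass(frozen=True)
class ComparisonResult:
    """Chi-square comparison of two population profiles."""

    chi2: float
    dof: int
    p_value: float
    phi: float
    effect_label: str
    n_a: int
    n_b: int
    mode: str


def effect_label(phi: float) -> str:
    """Bin Cramer's phi: medium for 0.3 <= phi < 0.5, large for phi >= 0.5.

    Values below 0.3 are labeled "below-medium" (no finer scale is used).
    """
    if phi >= 0.5:
        return "large"
    if phi >= 0.3:
        return "medium"
    return "below-medium"


def renormalize_alleles(raw: Mapping[str, float]) -> HaplotypeFrequencySet:
    """Keep *1/*2/*17 from a raw allele-frequency map and renormalize.

    Other star alleles (rare reduced-function alleles such as *3) are
    dropped; a warning records the neglected mass.
    """
    missing = [a for a in _CANONICAL_ALLELES if a not in raw]
    if missing:
        raise FrequencyError(f"allele map lacks {missing}")
    kept = {a: float(raw[a]) for a in _CANONICAL_ALLELES}
    if any(v < 0 for v in kept.values()):
        raise FrequencyError("negative allele frequency")
    total = sum(kept.values())
    if total <= 0:
        raise FrequencyError("frequencies of *1, *2, *17 sum to zero")
    dropped = sum(float(v) for a, v in raw.items()
                  if a not in _CANONICAL_ALLELES)
    if dropped > 0:
        warnings.warn(
            f"dropped {dropped:.6g} total frequency of alleles other than "
            "*1/*2/*17 before renormalization", stacklevel=2)
    return HaplotypeFrequencySet(
        kept["*1"] / total, kept["*2"] / total, kept["*17"] / total)


def expand_hwe(h: HaplotypeFrequencySet, name: str) -> PopulationProfile:
    """Project haplotype frequencies to a haplogenotype/phenotype profile.

    Hardy-Weinberg expansion of (h1 + h2 + h17)^2 under the LD constraint;
    the three non-canonical haplogenotypes receive frequency zero and are
    omitted from the profile.
    """
    h1, h2, h17 = h.as_tuple()
    phenotype_freq = {
        Phenotype.EM.value: h1 * h1,
        Phenotype.IM.value: 2 * h1 * h2,
        Phenotype.PM.value: h2 * h2,
        Phenotype.RM.value: 2 * h1 * h17,
        Phenotype.UM.value: h17 * h17,
        Phenotype.AM.value: 2 * h2 * h17,
    }
    hg_freq = {
        "*1*1/*1*1": phenotype_freq["EM"],
        "*1*1/*1*2": phenotype_freq["IM"],
        "*1*1/*2*2": phenotype_freq["PM"],
        "*1*17/*1*1": phenotype_freq["RM"],
        "*17*17/*1*1": phenotype_freq["UM"],
        "*1*17/*1*2": phenotype_freq["AM"],
    }
    return PopulationProfile(name=name, freq=hg_freq,
                             phenotype_freq=phenotype_freq)


def profile_from_counts(name: str, counts: Mapping[str, int],
                        merge_unknown_into_am: bool = True) -> PopulationProfile:
    """Profile from observed phenotype counts (e.g. an experimental cohort).

    Carriers of unknown-phenotype haplogenotypes are merged into the AM
    class by default, matching how experimentally determined cohorts are
    displayed alongside HWE-projected ones.
    """
    counts = dict(counts)
    unknown = counts.pop(Phenotype.UNKNOWN.value, 0)
    vec = {p: float(counts.get(p, 0)) for p in _PHENOTYPE_LABELS}
    if merge_unknown_into_am:
        vec[Phenotype.AM.value] += unknown
    elif unknown:
        raise FrequencyError(
            f"{name}: {unknown} unknown-phenotype carriers present but "
            "merge_unknown_into_am is false")
    total = sum(vec.values())
    if total <= 0:
        raise EmptyCohortError(f"{name}: no callable samples")
    phenotype_freq = {p: v / total for p, v in vec.items()}
    hg_freq = {
        "*1*1/*2*2": phenotype_freq["PM"],
        "*1*1/*1*2": phenotype_freq["IM"],
        "*1*17/*1*2": phenotype_freq["AM"],
        "*1*1/*1*1": phenotype_freq["EM"],
        "*1*17/*1*1": phenotype_freq["RM"],
        "*17*17/*1*1": phenotype_freq["UM"],
    }
    return PopulationProfile(name=name, freq=hg_freq,
                             phenotype_freq=phenotype_freq)


def estimate_haplotype_freqs(
    cohort: Sequence[SampleGenotypes],
) -> HaplotypeFrequencyEstimate:
    """Estimate (h1, h2, h17) from a cohort by allele counting.

    h17 is the fraction of T alleles at rs12248560 over 2N chromosomes, h2
    the fraction of A alleles at rs4244285, h1 the remainder. Standard
    errors are binomial, sqrt(p*(1-p)/(2N)). The estimator assumes the LD
    constraint; samples whose haplogenotype is non-canonical are still
    counted but their ids are flagged, since for them the two variant
    alleles cannot live on distinct haplotypes.
    """
    callable_samples = [s for s in cohort if s.callable]
    if not callable_samples:
        raise EmptyCohortError("no callable samples in cohort")
    n = len(callable_samples)
    chroms = 2 * n
    t_count = sum(s.g_rs12248560.alt_count for s in callable_samples)
    a_count = sum(s.g_rs4244285.alt_count for s in callable_samples)
    h17 = t_count / chroms
    h2 = a_count / chroms
    h1 = 1.0 - h17 - h2
    if h1 < 0:
        raise FrequencyError(
            "allele counting gave h1 < 0: the cohort violates the "
            "linkage-disequilibrium assumption too strongly to estimate "
            "haplotype frequencies")
    flagged = tuple(
        s.sample_id for s in callable_samples
        if not call_haplogenotype(s).canonical)

    def se(p: float) -> float:
        return float(np.sqrt(p * (1 - p) / chroms))

    return HaplotypeFrequencyEstimate(
        freqs=HaplotypeFrequencySet(h1, h2, h17),
        se_h1=se(h1), se_h2=se(h2), se_h17=se(h17),
        n_samples=n, n_non_canonical=len(flagged),
        non_canonical_ids=flagged)


def largest_remainder_counts(freqs: Sequence[float], n: int) -> np.ndarray:
    """Round frequencies to integer counts summing exactly to ``n``.

    Largest-remainder allocation; ties break on lower index, so the result
    is deterministic.
    """
    freqs = np.asarray(freqs, dtype=float)
    if n <= 0:
        raise FrequencyError("n must be positive")
    raw = freqs * n
    floors = np.floor(raw).astype(int)
    remainder = int(round(n - floors.sum()))
    frac = raw - floors
    order = np.lexsort((np.arange(len(frac)), -frac))
    counts = floors.copy()
    for ix in order[:remainder]:
        counts[ix] += 1
    return counts


def _as_counts(pop, n: int | None, label: str) -> np.ndarray:
    if isinstance(pop, PopulationProfile):
        if n is None:
            raise FrequencyError(
                f"{label}: sample size required for a frequency profile")
        return largest_remainder_counts(pop.phenotype_vector(), n)
    counts = np.asarray(
        [pop[p] for p in _PHENOTYPE_LABELS] if isinstance(pop, Mapping)
        else pop, dtype=float)
    if counts.shape != (len(_PHENOTYPE_LABELS),):
        raise FrequencyError(
            f"{label}: expected counts over {len(_PHENOTYPE_LABELS)} "
            "phenotype classes")
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        raise FrequencyError(f"{label}: counts must be non-negative integers")
    return counts.astype(int)


def _pearson_chi2(table: np.ndarray) -> float:
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    return float(((table - expected) ** 2 / expected).sum())


DEFAULT_EXACT_REPS = 100_000


def compare_populations(
    a, b,
    n_a: int | None = None,
    n_b: int | None = None,
    mode: str = "exact",
    reps: int = DEFAULT_EXACT_REPS,
    seed: int | None = None,
    pool_empty: bool = True,
) -> ComparisonResult:
    """Chi-square comparison of two populations over the 6 phenotype classes.

    ``a``/``b`` are :class:`PopulationProfile` objects (converted to counts
    of size ``n_a``/``n_b`` by largest-remainder rounding) or phenotype
    count vectors/maps. ``mode="exact"`` computes a Monte Carlo conditional
    p-value from ``reps`` tables sampled under the observed margins (seeded,
    reproducible); ``mode="asymptotic"`` uses the chi-square distribution.
    Classes empty in both populations are pooled out before testing.
    """
    if mode not in ("exact", "asymptotic"):
        raise FrequencyError(f"unknown mode {mode!r}")
    counts_a = _as_counts(a, n_a, "population a")
    counts_b = _as_counts(b, n_b, "population b")
    table = np.vstack([counts_a, counts_b])
    total = int(table.sum())
    if total == 0:
        raise FrequencyError("zero-total contingency table")
    if pool_empty:
        keep = table.sum(axis=0) > 0
        table = table[:, keep]
    k = table.shape[1]
    n_a_used, n_b_used = int(table[0].sum()), int(table[1].sum())
    if k < 2 or min(n_a_used, n_b_used) == 0:
        # degenerate: everything in one class or one empty population
        chi2, dof, p = 0.0, 0, 1.0
    else:
        chi2 = _pearson_chi2(table)
        dof = (table.shape[0] - 1) * (k - 1)
        if mode == "asymptotic":
            p = float(stats.chi2.sf(chi2, dof)) if chi2 > 0 else 1.0
        else:
            rng = np.random.default_rng(seed)
            dist = stats.random_table(table.sum(axis=1), table.sum(axis=0))
            sims = dist.rvs(reps, random_state=rng)
            expected = (np.outer(table.sum(axis=1), table.sum(axis=0))
                        / total)
            sim_stats = ((sims - expected) ** 2 / expected).sum(axis=(1, 2))
            hits = int(np.sum(sim_stats >= chi2 - 1e-12))
            p = (hits + 1) / (reps + 1)
    phi = float(np.sqrt(chi2 / total)) if total else 0.0
    return ComparisonResult(
        chi2=chi2, dof=dof, p_value=p, phi=phi,
        effect_label=effect_label(phi),
        n_a=n_a_used, n_b=n_b_used, mode=mode)


def profile_report(
    profiles: Iterable[PopulationProfile],
    plot_path: str | None = None,
) -> pd.DataFrame:
    """Long-format phenotype frequency table, optionally with a stacked bar.

    One row per population x phenotype class, every class present even at
    frequency zero, matching how population profiles are usually displayed.
    """
    profiles = list(profiles)
    if not profiles:
        raise FrequencyError("at least one profile is required")
    rows = [
        {"population": prof.name, "phenotype": p,
         "frequency": float(prof.phenotype_freq.get(p, 0.0))}
        for prof in profiles for p in _PHENOTYPE_LABELS
    ]
    df = pd.DataFrame(rows, columns=["population", "phenotype", "frequency"])
    if plot_path is not None:
        _stacked_bar(df, plot_path)
    return df


def _stacked_bar(df: pd.DataFrame, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    wide = df.pivot(index="population", columns="phenotype",
                    values="frequency")[list(_PHENOTYPE_LABELS)]
    ax = wide.plot(kind="bar", stacked=True, figsize=(8, 4.5),
                   colormap="viridis")
    ax.set_ylabel("frequency")
    ax.set_title("CYP2C19 predictive phenotype distribution")
    ax.legend(title="phenotype", bbox_to_anchor=(1.02, 1), loc="upper left")
    ax.figure.tight_layout()
    ax.figure.savefig(path)
    plt.close(ax.figure)
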