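# Methods

## Model

The toolkit models CYP2C19-dependent PPI metabolism with exactly two marker
SNPs: rs12248560 (C>T, tagging the gain-of-function promoter allele \*17)
and rs4244285 (G>A, tagging the loss-of-function splice allele \*2). All
other reduced-function star alleles (\*3–\*27) are treated as negligible
and are out of scope; allele-frequency inputs that include them are
renormalized over {\*1, \*2, \*17} with the dropped mass reported as a
warning.

Two assumptions carry the whole pipeline:

1. **Linkage disequilibrium (LD):** \*2 and \*17 never occur on the same
   haplotype. This makes 6 of the 9 two-SNP genotype combinations
   ("haplogenotypes") uniquely phaseable — the phasing is obtained by
   allocating one \*17 per T allele and one \*2 per A allele, which is the
   only allocation consistent with LD (verified exhaustively in the tests
   by brute-force enumeration of allowed haplotype pairs). The other 3
   combinations are carried as first-class UNKNOWN-phenotype objects, not
   errors: real cohorts contain such carriers at ~0.045‰, and a clinical
   tool must respond to them (they route to CYP2C19-independent therapy).
2. **Random mating (HWE):** population haplogenotype frequencies are the
   square expansion of the haplotype frequencies, EM = h₁², IM = 2h₁h₂,
   PM = h₂², RM = 2h₁h₁₇, UM = h₁₇², AM = 2h₂h₁₇; the non-canonical
   combinations have frequency zero under LD.

The phenotype system is categorical by design; no quantitative activity
score is computed. AM ("ambivalent metabolizer", one \*2 plus one \*17 in
trans) is a provisional class: the evidence that \*17 cannot fully
compensate \*2 is limited, so AM is dosed with the reduced-function group
and every AM recommendation carries `provisional=True` end-to-end.

## Dosing rules engine

Rules live in a versioned, declarative YAML table
(`src/cyp2c19sup/rules/sup_rules.yaml`) interpreted top-down with
first-match-wins semantics, rather than hard-coded branches — guideline
content of this kind evolves (consortium guidelines are periodically
revised), and a data table with rule ids keeps every emitted recommendation
traceable and the rationale strings in 1:1 correspondence with the table.

Priority order, encoded as table order:

1. PPI hypersensitivity → switch to a non-PPI agent (H₂ receptor
   antagonist or gastric mucosa protectant); dominates all genotype logic.
2. Genotype unavailable, UNKNOWN phenotype, or interacting CYP2C19/CYP3A4
   co-medication → CYP2C19-independent therapy (rabeprazole preferred, at
   standard dose).
3. Rabeprazole → standard dose for every metabolizer group (predominantly
   non-enzymatic degradation).
4. The ultrarapid metabolizer who is also H. pylori-positive under SUP
   prefers standard-dose rabeprazole even though the generic UM rule would
   otherwise double the dose; this is encoded as an explicit
   higher-priority rule.
5. Esomeprazole: dose increase of 50–100% only for UM under H. pylori
   eradication therapy; otherwise no genotype-specific recommendation
   exists, and the engine says so rather than guessing a multiplier. One
   open point was whether the 50–100% increase for EM/RM treating
   H. pylori infection or erosive esophagitis extends to esomeprazole; the
   engine applies it (the EM/RM rule is drug-agnostic), on the reading that
   esomeprazole is CYP2C19-dependent and the published EM/RM guidance is
   about acid-intensive indications generally.
6. PM/IM/AM on a CYP2C19-dependent PPI: standard starting dose with
   rabeprazole preferred; for chronic therapy (>12 weeks), consider a 50%
   dose reduction.
7. EM/RM: standard dose; 50–100% increase (split dosing allowed) for
   H. pylori eradication or erosive esophagitis. RM has no published rule
   distinct from EM and is treated identically.
8. UM on a CYP2C19-dependent PPI: +100% for SUP (and erosive esophagitis,
   where no separate UM figure exists); drug-specific fold increases for
   H. pylori eradication (omeprazole 3×, lansoprazole 4×, pantoprazole 5×).
9. Dexlansoprazole inherits all first-generation rules (metabolization
   similar to lansoprazole, including the 4× eradication fold), but has no
   published standard SUP dose, so its recommendations stay multiplier/
   text-only and `absolute_dose` refuses to fabricate mg/day values.

Dose adjustments are multiplier **intervals** relative to the standard
daily dose (omeprazole 20, lansoprazole 30, pantoprazole 20, esomeprazole
20, rabeprazole 20 mg/day): "increase by 50–100%" is [1.5, 2.0] and the
consumer chooses within it; point rules are degenerate intervals.

## Population statistics

"Chi-square exact test" is implemented as a seeded Monte Carlo conditional
test: `reps` contingency tables (default 100,000) are sampled under the
observed margins (Patefield's algorithm via `scipy.stats.random_table`),
and the p-value is `(hits + 1) / (reps + 1)` for the Pearson statistic; an
asymptotic χ² mode is available. The Monte Carlo p-value therefore has a
floor of 1/(reps+1) and agrees with the asymptotic p to well within 0.02
at n = 2000 per population for moderate effects (tested).

Cramér's phi is √(χ²/(N·(min(r,c)−1))) = √(χ²/N) for the 2×k table. Only
the medium (0.3 ≤ φ < 0.5) and large (φ ≥ 0.5) bins are defined; everything
below is labeled "below-medium" rather than inventing finer categories.

When populations are given as frequency profiles without sample sizes, the
comparison uses an equal synthetic n per population (frequencies are
converted to counts by largest-remainder rounding, ties broken on lower
index so results are deterministic). Under equal n, phi is invariant to the
choice of n, which is the quantity of interest when the underlying sample
sizes are unknown; p-values, by contrast, do depend on the chosen n and
should be read accordingly. Classes empty in both populations are pooled
out before testing; a table with fewer than two remaining classes (or an
empty population) degenerates to χ² = 0, φ = 0, p = 1.

Haplotype frequencies are estimated from cohorts by allele counting:
h₁₇ = (T alleles)/(2N), h₂ = (A alleles)/(2N), h₁ the remainder, with
binomial standard errors √(p(1−p)/2N). The estimator is valid only under
LD; non-canonical samples are counted (their alleles are real) but their
ids are flagged, and an impossible configuration (h₁ < 0) is an error.

## Synthetic cohort generator

The simulator inverts the HWE model: each sample draws two haplotypes
independently from {\*1, \*2, \*17} with probabilities (h₁, h₂, h₁₇) and
converts them to SNP genotypes, so simulated cohorts satisfy both model
assumptions exactly. Optional non-canonical injection replaces a configured
fraction of samples (cap 1%, default 0; 0.000045 reproduces the observed
real-world carrier rate) with uniformly chosen unknown-phenotype
haplogenotypes — replacement rather than a cis-haplotype frequency model,
because no such frequency model has been published.

Randomness is counter-based: a Philox generator keyed by the seed produces
exactly four uniforms per sample (two haplotype draws, one replacement
decision, one non-canonical choice), so the first n samples are unchanged
when `n_samples` grows, and identical seeds give byte-identical fixtures.

What the generator does **not** emulate: genotyping error, missingness
patterns, population admixture or relatedness, departure from HWE, and any
cis \*2–\*17 haplotype dynamics. Tests passing on simulated cohorts
therefore validate the pipeline's internal consistency (calling, phasing,
estimation, projection), not robustness to real-world data artifacts.

The bundled synthetic population grid (`populations_synthetic.csv`) spans a
PM-dominant regime to \*17-rich regimes; the values are invented for demos
and tests and are not database exports. The test suite's problem sizes —
10,000-sample cohorts for parameter recovery, 100,000 for law-of-large-
numbers checks, 100,000 Monte Carlo replicates, n = 2000 per population for
profile comparisons — were chosen as the package's own testing conditions;
4 binomial standard errors is the convergence tolerance throughout.

## Numerical and interface choices

* Genotypes are normalized reference-allele-first at construction, making
  unphased genotypes order-insensitive by representation rather than by
  comparison logic.
* VCF records are matched by rsID in the ID column; chrom/pos matching
  exists only as an explicit config override because no genome build is
  assumed, and the placeholder coordinates written by the VCF writer are
  not meaningful. Phase separators in input are accepted and discarded.
* Haplotype frequency sets must sum to 1 within 1e-9 at construction;
  `renormalize_alleles` is the entry point for raw allele tables (it also
  handles near-miss sums such as rounded published frequencies).
* The degenerate comparison cases (identical monomorphic profiles, empty
  classes) short-circuit before the χ² machinery to avoid 0/0 expected
  counts.

## Known limitations

* No activity-score system, no alleles beyond \*1/\*2/\*17, no CYP3A4
  genotyping, no genotype imputation or likelihood handling.
* No pediatric, renal or hepatic dose adjustment; drug–drug interactions
  are a single boolean flag.
* No HWE hypothesis testing of cohorts and no confidence intervals on
  projected profiles.
* Exact reproduction of published population p-values requires the
  original allele-frequency tables and sample sizes, which are external
  inputs; only phi under the equal-n convention is size-independent.
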