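# cyp2c19sup

CYP2C19-guided personalized stress ulcer prophylaxis (SUP) for critically
ill patients: a toolkit for calling *CYP2C19* haplogenotypes from two marker
SNPs, classifying predictive metabolizer phenotypes, emitting proton pump
inhibitor (PPI) dosing recommendations, and projecting/comparing population
haplogenotype frequency profiles.

## The problem

Most PPIs used for SUP in intensive care (omeprazole, esomeprazole,
lansoprazole, pantoprazole; rabeprazole is the exception) are degraded by
the hepatic enzyme CYP2C19, whose activity is strongly genotype-dependent.
Two common variants dominate:

* **CYP2C19\*17** (rs12248560, c.-806C>T) — promoter variant causing
  overexpression and ultrarapid drug degradation;
* **CYP2C19\*2** (rs4244285, c.681G>A) — splice-defect variant producing a
  truncated, inactive enzyme.

Because \*2 and \*17 are in linkage disequilibrium (they never co-occur on
one haplotype), the unphased two-SNP genotype pair — the *haplogenotype*,
written e.g. `*1*17/*1*2` — is phaseable in 6 of its 9 combinations, and
each phaseable combination maps to one predictive metabolizer phenotype:

| haplogenotype | phenotype | metabolizer |
|---|---|---|
| `*1*1/*2*2`   | PM | poor |
| `*1*1/*1*2`   | IM | intermediate |
| `*1*17/*1*2`  | AM | ambivalent (provisional) |
| `*1*1/*1*1`   | EM | extensive (normal) |
| `*1*17/*1*1`  | RM | rapid |
| `*17*17/*1*1` | UM | ultrarapid |

The remaining 3 combinations (`*1*17/*2*2`, `*17*17/*2*2`, `*17*17/*1*2`)
would require a cis \*2–\*17 haplotype; they are observed at ~0.045‰ in very
large cohorts, carry an unknown phenotype, and are routed to
CYP2C19-independent therapy rather than rejected.

Population phenotype profiles follow from star-allele frequencies
(h₁, h₂, h₁₇) under Hardy–Weinberg equilibrium:

    EM = h₁²   IM = 2h₁h₂   PM = h₂²   RM = 2h₁h₁₇   UM = h₁₇²   AM = 2h₂h₁₇

Profiles are compared with a Pearson χ² on the 2×6 contingency table (exact
p by seeded Monte Carlo under fixed margins, or asymptotic), with Cramér's
phi φ = √(χ²/N) as effect size (0.3 ≤ φ < 0.5 medium, φ ≥ 0.5 large).

## Worked example

Generate the deterministic fixture suite, call the full haplogenotype
space, and get dosing recommendations for chronic omeprazole SUP:

```sh
cyp2c19sup fixtures --outdir fx
cyp2c19sup recommend --table fx/haplogenotypes_9.tsv \
    --drug omeprazole --indication SUP --chronic --format text
```

```
rule table version 1.0
HG1_*1*1_*1*1   EM      omeprazole  STANDARD_DOSE [20 mg/day]                                       [R15-em-rm-standard]
HG2_*1*1_*1*2   IM      omeprazole  REDUCE_CONSIDER [10 mg/day] -> prefer rabeprazole               [R12-reduced-function-chronic]
HG3_*1*1_*2*2   PM      omeprazole  REDUCE_CONSIDER [10 mg/day] -> prefer rabeprazole               [R12-reduced-function-chronic]
HG4_*1*17_*1*1  RM      omeprazole  STANDARD_DOSE [20 mg/day]                                       [R15-em-rm-standard]
HG5_*1*17_*1*2  AM      omeprazole  REDUCE_CONSIDER [10 mg/day] -> prefer rabeprazole (provisional) [R12-reduced-function-chronic]
HG6_*1*17_*2*2  UNKNOWN omeprazole  SWITCH_AGENT [20 mg/day] -> prefer rabeprazole                  [R07-unknown-phenotype]
HG7_*17*17_*1*1 UM      omeprazole  INCREASE [40 mg/day]                                            [R19-um-first-generation]
...
```

Reading the output: extensive/rapid metabolizers stay on the 20 mg/day
standard dose; poor/intermediate/ambivalent metabolizers on chronic
(>12-week) therapy get the 50% reduction (10 mg/day) with rabeprazole as
the preferred agent; ultrarapid metabolizers get a 100% increase
(40 mg/day); unknown-phenotype carriers are switched to CYP2C19-independent
therapy. The AM row is flagged provisional because the gain-of-function
\*17 allele may not fully compensate the no-function \*2 allele.

Population comparison against a reference (synthetic demo frequencies):

```sh
cyp2c19sup popfreq-compare --freqs fx/populations_synthetic.csv \
    --ref european_like --mode exact --seed 7
```

```
population         reference      chi2     dof p_value     phi       effect       n_a  n_b  mode
african_like       european_like  6.20765  5   0.284136    0.0393943 below-medium 2000 2000 exact
near_eastern_like  european_like  19.1794  5   0.00109995  0.0692449 below-medium 2000 2000 exact
latino_like        european_like  221.64   5   4.99975e-05 0.235393  below-medium 2000 2000 exact
east_asian_like    european_like  751.893  5   4.99975e-05 0.433559  medium       2000 2000 exact
oceanian_like      european_like  1990.99  5   4.99975e-05 0.705513  large        2000 2000 exact
```

Each row is one population's 6-class phenotype profile (projected under
HWE at n = 2000 per population) tested against the reference; `phi` is the
effect size and `effect` its bin. The same operations are available as
library calls (`cyp2c19sup.expand_hwe`, `cyp2c19sup.compare_populations`,
`cyp2c19sup.recommend`, ...).

To reproduce published population PM/UM extremes, supply a real star-allele
frequency export (e.g. from PharmGKB) as the `population,allele,frequency`
CSV; no external data ships with the package.

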