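# cunigs

Stochastic simulation of **cost-efficient genomic selection with genotype
imputation in maternal rabbit breeding lines**.

Genotyping cost is the main obstacle to genomic selection in meat rabbits:
litter size has low heritability (h² ≈ 0.11), is expressed only in does,
and the animals are cheap relative to a high-density (HD) SNP array.  A
standard workaround genotypes ancestors at HD and candidates on sparser
panels, then imputes candidates to HD before single-step GBLUP (ssGBLUP).
`cunigs` asks: *which combination of array densities across pedigree roles
gives the best trade-off between genotyping cost, imputation accuracy,
breeding-value accuracy and response to selection?*

The package simulates the whole experiment end to end:

* **founder genomes** with linkage disequilibrium (neutral Wright–Fisher
  burn-in over 20 chromosomes of 100 cM / 124.43 Mb),
* a **polygenic litter-size trait** (QTNs with signed Gamma(0.60, 0.80)
  effects, base additive variance σ²ₐ = 0.675, h² = 0.113),
* a **maternal-line breeding program** (foundation of 138 does + 77
  sires, 5 generations of random mating, 20 generations of pedigree-BLUP
  truncation selection of 70 does / 35 sires, then two genomic
  generations ending in 1 500 candidate does + 1 500 bucks),
* **genotyping strategies** S1–S7 and S3_A that assign HD / MD / LD
  platforms (MD = 30% of HD, LD = 0.3% of HD) or no genotyping to
  grand-dams, grand-sires, dams, sires and candidates, with per-animal
  prices of EUR 100 / 50 / 11,
* **pedigree-based imputation** to HD (iterative phasing with surrogate
  haplotypes and a haplotype library, then per-parent hidden-Markov
  haplotype tracking with Haldane transitions),
* **genetic evaluation** with the animal model `y = 1μ + Za + e` under
  pedigree BLUP (A⁻¹ with inbreeding) or ssGBLUP
  (`H⁻¹ = A⁻¹ + [0 0; 0 G⁻¹ − A22⁻¹]`, VanRaden G blended 0.95/0.05 with
  A22),
* **endpoints** per scenario: imputation accuracy (per-individual Pearson
  r at untyped markers), genotype yield, gEBV accuracy r(EBV, TBV) on the
  candidates, response to selection in kits, percentage of correctly
  selected does, and genotyping cost.

See `docs/methods.md` for the full model description and numerical
choices.

## Worked example

The deterministic cost bookkeeping needs no simulation:

```sh
$ cunigs costs
S1      112,000 EUR
S2      53,500 EUR
S3      37,750 EUR
S3_A    37,750 EUR
S4      38,500 EUR
S5      26,800 EUR
S6      31,000 EUR
S7      23,500 EUR
BLUP    0 EUR
```

S1 (everything HD, candidates MD) costs EUR 112,000; dropping candidate
density to LD (S2) more than halves it; skipping grand-dams (S6) reaches
EUR 31,000, EUR 6,750 cheaper than genotyping half the candidates (S3).

A desk-scale replicated run (20 chromosomes × 1 000 HD markers, one
replicate here for brevity; a scenario takes ~15–30 s after the ~1 min
program build):

```sh
$ cunigs simulate --scenarios S1,S6,BLUP --qtn-model QTN_44 --replicates 1 --seed 1 --out results/demo
qtn_model scenario_id  n_replicates  response  ...  accuracy   mean_ia  cost_eur
   QTN_44          S1             1  0.350866  ...  0.269013  0.988048  112000.0
   QTN_44          S6             1  0.349214  ...  0.232094  0.916999   31000.0
   QTN_44        BLUP             1  0.307114  ...  0.198289       NaN       0.0
```

Reading the output: with all ancestors at HD and candidates at MD, the
imputer recovers candidate genomes almost perfectly (mean imputation
accuracy 0.988) and ssGBLUP lifts candidate EBV accuracy from the
pedigree-BLUP baseline of 0.198 to 0.269, raising the selection response
from 0.31 to 0.35 kits.  S6 — grand-dams not genotyped, dams on the
medium panel — keeps most of that gain (accuracy 0.232, IA 0.917) at just
over a quarter of S1's genotyping cost, which is why it is the
best-trade-off strategy.  `cunigs report --in results/demo` rebuilds the
summary table and plots accuracy against cost.

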