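# Methods

`cunigs` simulates a closed maternal rabbit nucleus selected for litter
size and evaluates genotyping/imputation strategies for moving the line
from pedigree BLUP to single-step GBLUP (ssGBLUP).  This note documents the
models, the numerical choices, and what the synthetic data do and do not
represent.

## Founder genomes

Founder haplotypes carry linkage disequilibrium generated by a
forward-in-time neutral Wright–Fisher burn-in over a tracked set of
candidate sites per chromosome.  The genome is 20 chromosomes of 100 cM /
124.43 Mb with per-bp recombination 8.57×10⁻⁹ and mutation 1.74×10⁻⁹;
candidate sites are placed uniformly on the physical map, and each site
absorbs the mutation pressure of the base pairs it stands for.  Crossovers
are a Poisson process on the linear bp→cM map (no interference, no
hotspots).  Initial allele frequencies are drawn from the neutral 1/x
spectrum (option `sfs`), so the burn-in's job is shaping LD and the allele
frequency distribution by drift rather than building polymorphism from
scratch; a `monomorphic` start is available and then mutation is the only
source of polymorphism.

The effective-size schedule is two-epoch — a larger ancestral epoch
followed by a small recent epoch typical of a closed commercial line.  The
real line's demographic history is not published; this schedule is a
deliberate approximation, and LD beyond the qualitative decay pattern
(near-range r² ≫ long-range r²) should not be over-interpreted.

Desk-scale defaults (the shipped preset): 600 founder haplotypes per
chromosome, 3 500 candidate sites, 100 burn-in generations with Ne
250→100.  This yields ≈1 300–1 600 segregating founder sites per
chromosome, enough for a 1 000-site HD panel plus up to 44 QTNs with
margin.  These sizes are the package's desk preset; the full-scale
experiment (200 K SNP, 2 000 haplotypes, 36 replicates) uses the same code
paths via the `paper` preset but is not what the shipped tests run.

## Trait architecture

Litter size is strictly additive.  QTNs are drawn uniformly from
segregating founder sites, the same count per chromosome: 5 (QTN_5) or 44
(QTN_44) per chromosome.  Absolute effects are Gamma(shape 0.60, scale
0.80); signs are ±1 with probability ½ each (the Gamma is positive-valued
and no sign convention is documented for the reference simulator; random
signs avoid a directional founder bias).  A single multiplicative constant
rescales the effects so that the variance of true breeding values (TBV)
over the founder diploids is exactly σ²ₐ = 0.675; the residual variance
follows from the heritability, σ²ₑ = σ²ₐ(1−h²)/h² with h² = 0.113, giving
σ²ₑ ≈ 5.2985 and λ = σ²ₑ/σ²ₐ ≈ 7.85.  Because both QTN models are scaled
to the same base variance, their comparison isolates architecture, not
total genetic variance.  TBV is Σ(dosage−2p)·effect with p the founder
frequency; phenotypes are y = μ + TBV + N(0, σ²ₑ) for does only (one
record per doe; μ = 10 kits, an arbitrary constant — only differences
matter).  Dominance, epistasis and repeated parities are out of scope.

## Breeding program

Generation 1 founds the line with 138 does and 77 sires drawn from the
founder haplotype pool; generations 2–6 mate randomly at constant size.
Generations 7–26 are truncation selection: each 150-doe/150-buck cohort is
evaluated with an in-program pedigree BLUP (5-generation sliding window,
true variance ratio, candidate cohort's own records excluded because
litter size cannot be observed before first mating) and the top 70 does
and 35 sires breed the next cohort, kits allocated equally across dams
with sires assigned round-robin after shuffling, each litter split 1:1 by
sex.  In the genomic phase all 150 cohort does serve as dams: generation
27 is another 150+150 cohort and generation 28 is the candidate cohort of
1 500 does + 1 500 bucks (10+10 kits per dam).  The last three generations
carry the genotyping roles: grand-dams (150) and grand-sires (35) in
generation 26, dams (150) and sires (35) in generation 27, candidate does
(1 500) in generation 28; candidate males are never genotyped.  No mating
restrictions are imposed, so inbreeding accumulates naturally and the
inbreeding-aware A⁻¹ is genuinely exercised.

## Panels, masking and costs

The HD panel (1 000 sites/chromosome at desk scale) is drawn from non-QTN
segregating sites; MD is a random 30% of HD and LD a random 0.3% of HD,
nested and allocated per chromosome, so the missing rates versus HD are
70% and 99.7% at any scale.  Defining panels by fractions sidesteps an
internal inconsistency in the absolute MD panel sizes quoted in the source
material; every checked identity (missing rates, per-animal prices, all
scenario costs) depends only on the fractions.  Observed genotypes equal
gene-drop dosages exactly — no genotyping-error model.  Costs are flat per
animal (platform price over 96 chips: EUR 100 / 50 / 11 for HD / MD / LD),
summed over the genotyped animals of the last three generations; the
half-genotyped scenarios count half the candidate cohort.

## Imputation

The imputer emulates the long-range-phasing → haplotype-library →
pedigree-imputation pipeline of reference livestock software in three
deliberately simple stages:

1. **Phasing** of HD/MD reference animals: homozygous sites; then parental
   origin wherever a genotyped parent is homozygous (with a Mendelian
   conflict screen at 1% of co-typed sites that demotes impossible
   parents); then iterative surrogate resolution, matching candidate
   surrogate haplotypes (parents, grandparents, and the corresponding
   parental haplotype of phased offspring) against the animal's resolved
   alleles inside 50-site windows.  Only sites where the two haplotypes
   are known to differ discriminate surrogates, so matches are required on
   those.  A final haplotype-library pass completes unresolved stretches
   that are consistent with exactly one family of fully-phased window
   segments seen at least twice in the reference, filling only unanimous
   positions.
2. **Haplotype tracking** for low-density-typed animals: per chromosome
   and parent, a two-state hidden Markov chain over the animal's typed
   sites — states are the two parental haplotypes, transitions follow the
   Haldane map function of the genetic distances, emissions penalise
   (error rate 0.01) haplotype alleles incompatible with the animal's
   homozygous genotypes.  The forward–backward posterior is interpolated
   into the gaps and untyped alleles are imputed by posterior expectation,
   falling back to the parent's own imputed dosage (over two) or the
   reference allele frequency where the haplotype is unresolved.  The
   output is therefore a genotype probability, which is also what the
   accuracy metric (per-individual Pearson correlation at untyped sites)
   is designed to score.  An earlier hard-Viterbi variant was measurably
   worse at the 0.3% typing density — committed wrong-haplotype segments
   scrambled the expected scenario ordering — and was replaced by the
   posterior; the smoothing is the method, not a tuning knob.
3. **Whole-genome copies** for entirely ungenotyped candidates (the S3_A
   strategy): the animal receives the committed reconstruction (MAP
   haplotype path, integer calls) of its lowest-id genotyped full sib, so
   all ungenotyped full sibs carry identical genomes — the sib-copying
   degeneracy that reference software exhibits when asked for whole
   genomes, which both depresses those animals' accuracy (a sib's genome
   differs by Mendelian sampling) and plants duplicate rows in G.  The
   mid-parent expectation (`impute_whole_genome`) is used only when no
   genotyped full sib exists.  The committed copy matters: a smoothed
   expectation would score *better* than sparse-typed imputation and the
   strategy's well-known failure mode would disappear from view.

Non-HD ancestors are imputed first (in generation order) so their
fractional dosages can serve as fallbacks for their offspring.  Hard calls
(within 0.1 of an integer) exist only for the genotype-yield statistic;
fractional dosages feed the genomic relationship matrix.

## Genetic evaluation

The model is y = 1μ + Za + e with a ~ N(0, Kσ²ₐ), K = A (BLUP) or H
(ssGBLUP), using the true simulation variance components throughout (the
reference analysis reports none being estimated, and truth is available in
simulation).  A⁻¹ uses Henderson's rules with Mendelian-sampling variance
dᵢ = ½ − ¼(F_s + F_d) and unknown-parent adjustments; F comes from a
memoised kinship recursion.  G is VanRaden's first method on
frequency-centred dosages (observed frequencies of the genotyped set,
configurable), blended 0.95 G₀ + 0.05 A22 for invertibility — the default
blend of the reference software, since no tuning is documented; no
Chen/Vitezica mean adjustment is applied, which can shift accuracies by a
small systematic amount.  H⁻¹ = A⁻¹ + (G⁻¹ − A22⁻¹) on the genotyped
block.  Quality control drops markers with MAF < 0.05 or call rate < 0.90
and animals with call rate < 0.90.  The mixed-model equations are solved
directly (symmetric dense solve) up to 6 000 equations and by Jacobi-
preconditioned conjugate gradients (relative tolerance 10⁻¹⁰) above; desk
systems (~3 000 equations) take the dense path.

Evaluation data follow the reference layout: pedigree of the last six
generations (candidate males dropped — they are never genotyped,
phenotyped or selected), phenotypes of does from the five pre-candidate
generations, genotypes of male ancestors always, of female ancestors only
in the strategies that keep them (S1, S2), and the candidates' imputed
genotypes.  In S3 the ungenotyped candidate half is ranked on mid-parent
EBVs.

## Endpoints

Per scenario and replicate: mean imputation accuracy (per-individual
Pearson r at untyped sites; zero-variance individuals excluded and
counted), mean genotype yield, gEBV accuracy r(EBV, TBV) over the 1 500
candidate does, its difference to the same replicate's BLUP, selection
response (mean TBV of the EBV-top-150 minus cohort mean, in kits), and the
percentage of correctly selected animals, defined as the overlap of the
EBV-top-150 with the TBV-top-150 (chance level 10% by the hypergeometric
mean; the definition is a package decision — the source material does not
define "correctly selected").  Summaries report means and standard errors
over replicates plus the fraction of replicates in which each genomic
strategy beats BLUP.

One consequence of pedigree-only evaluation at this design is worth
flagging: full sisters share parents, records and genotypes (none), so
BLUP candidate EBVs are tied within litters and top-150 selection operates
on whole litters.  This depresses the BLUP %ACS relative to an evaluation
that can rank within litters, and is the main reason the desk-scale BLUP
%ACS sits a few points below full-scale reported values while the BLUP
accuracy itself matches closely.

## What the desk scale does and does not show

Desk runs use 20 chromosomes × 1 000 HD sites and 4–8 replicates.  The
panel is 10× sparser and the founder sample 3× smaller than the full
experiment, and allele frequencies drift further in a small simulated
line, which compresses the spread between imputation-accuracy values
(e.g. the lowest-information strategies score ~0.90 instead of ~0.81)
while preserving their order.  Quantities that survive scaling — cost
identities, missing rates, the IA ordering, near-ceiling S1 behaviour,
S1 gEBV accuracy, the BLUP-vs-genomic comparisons — are asserted in the
tests; full-scale figures that do not (per-scenario IA to three decimals,
the 2.53-kit 20-generation response) are not claimed.

## Determinism

One root seed; per-(QTN model, replicate) streams spawn per-stage streams
(founders, QTN positions, effects, founder pairing, program, masking).
Masking shares a stream across scenarios of a replicate so S3 and S3_A
genotype the identical candidate half.  Identical configuration and seed
reproduce byte-identical outcome tables.
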