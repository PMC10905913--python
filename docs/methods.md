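# Methods

## The screen

The screen targets recessive alleles that kill (or severely impair)
homozygotes before genotyping age, using only phased SNP genotypes and a
pedigree. It generalizes the missing-homozygote strategy used in dairy
cattle and sheep genomic-selection populations.

**Windows and haplotypes.** The genome is covered with dense sliding
windows of `window_size` SNPs (default 20, step 1; both configurable).
Within a window, haplotypes are the exact allele strings of the phased
chromosomes. Candidate haplotypes are those with frequency strictly
above `freq_min` (default 1%) **on the maternal phase** — the haplotype
each animal inherited from its dam. The maternal phase is used because
the trio structure of AI populations is asymmetric: sires are densely
genotyped, dams rarely, so the dam-side transmission is the quantity
that needs a population-frequency prior, and the maternal-phase
frequency is the matching estimator.

**Expected homozygotes.** For each candidate haplotype k,

    N_Exp(k) = Σ over trio offspring of P(sire transmits k) · P(dam transmits k)

with `P = copies(k)/2` for a genotyped parent. When the dam is
ungenotyped but her sire (MGS) is genotyped,

    P(dam transmits k) = ½ · (copies_MGS(k)/2 + g · f_k),

i.e. the dam's paternal allele is traced through the MGS and her
maternal allele through the unobserved granddam. The default mode
(`frequency-augmented`, g = 1) credits the granddam with the
maternal-phase population frequency f_k; mode `conservative` (g = 0)
bounds her contribution at zero. The augmented mode is the default
because it is an unbiased plug-in estimate when granddams are draws from
the population haplotype pool (which is exactly how the synthetic
generator creates them), and because in MGS-dominated pedigrees the
conservative mode halves N_Exp and with it the power of the screen: a
haplotype can only ever reach significance when N_Exp exceeds
−ln(p_max) ≈ 8.57, so halving N_Exp makes 4–5%-frequency lethals
undetectable at realistic trio counts. The conservative mode remains
available for users who prefer a strict lower bound (any deficit it
reports is a fortiori real).

**Test and deficit.** N_Obs(k) counts trio offspring whose two phases
both equal k exactly. The deficiency test is the lower Poisson tail
P(X ≤ N_Obs), X ~ Poisson(N_Exp), computed by log-space summation
(`logsumexp` of the term series; P(X ≤ 0) = e^(−N_Exp) exactly). The
Poisson approximation to the true Poisson-binomial null is conservative
in the lower tail. A window haplotype is significant when
p < `p_max` (default 1.9×10⁻⁴; an alternative helper computes a
Bonferroni threshold α / number of tested haplotypes) **and** the
deficit (N_Exp − N_Obs)/N_Exp lies in `deficit_range` (default
[0.75, 1.0], bounds inclusive). Homozygote *excess* yields a negative
deficit and is never flagged.

**Clustering.** Significant windows merge into a region when their SNP
spans overlap or abut and their alleles agree on every shared SNP.
Allele-consistency-plus-overlap operationalizes "consecutive windows
with the same deficit": overlapping windows tracking the same carrier
haplotype necessarily have near-equal deficits, while exact numeric
equality of deficits would be fragile. The region's carrier haplotype is
the union of member alleles; region-level N_Obs/N_Exp/p come from the
member window with minimum p (tie → smallest start). The procedure
sorts its input, so the region set is invariant to input order. Carrier
status of an animal for a region is the number of its phases matching
the carrier haplotype exactly over the whole span — a phase differing at
one SNP (a recombinant) counts zero; such animals surface later in the
variant-concordance report instead. LD between regions is the squared
Pearson correlation of status vectors, undefined (NaN) for constant
vectors.

## Quality control

SNPs are kept when call rate > 97%, minor allele frequency > 1% and the
Hardy–Weinberg exact p-value > 10⁻⁵ (all strict, matching "higher than"
phrasing; thresholds configurable). The HWE test is the plain exact test
(no mid-p): the summed probability of heterozygote counts no more likely
than the observed one, conditional on allele counts; a chi-square
alternative is provided since the upstream evaluation pipelines that
define such filters do not always document which test they use.
Monomorphic SNPs drop with reason `maf`. The scan itself refuses missing
alleles: it expects imputed, complete input, as in the source data.

## Fertility and trait comparisons

A mating is **at-risk** when the ram and the ewe's sire each carry ≥ 1
copy of the region haplotype; every other combination is safe. AIS = 1
iff a lambing occurs within 151 ± 7 days of insemination (inclusive
bounds — the convention adopted here since "±" does not state
inclusivity); SBR is defined only for successful inseminations and is 1
iff any lamb of the litter is dead at birth or within 24 h.

AIS and SBR are compared across mating classes with a logit-link
binomial GLM (fixed effects: mating type, AI season, lactation number,
prolificacy for SBR, and herd × year). Two deliberate approximations:
herd × year enters as fixed-effect blocks rather than a random effect
(the original mixed-model software is proprietary and the random-effect
fit is not reproducible without the restricted national data; penalized
alternatives gave indistinguishable mating-type estimates on synthetic
data), and "lsmeans" is computed as marginal standardization — the
population-averaged predicted probability with the mating type forced to
each level — since no reference grid is canonical. Complete separation
(a class with all-0 or all-1 outcomes) is flagged non-estimable, never
fitted. Sire sDYD (daughter yield deviation / genetic SD) is compared
carrier vs non-carrier by OLS with a birth-year fixed effect, excluding
rams with fewer than 20 daughters; selection indexes are compared with a
two-sided Wilcoxon rank-sum test (exact for small tie-free samples).

The r×c Fisher–Freeman–Halton exact test enumerates all tables with the
observed margins and sums hypergeometric probabilities ≤ the observed
table's probability (relative tie tolerance 10⁻⁷, the convention of
standard statistical software); above ~10⁷ candidate tables it falls
back, flagged, to Monte-Carlo sampling of margin-fixed tables. On 2×2
tables it reduces to the classical two-sided Fisher test.

## Variant concordance

Variants inside a region padded by 1 Mb are kept when biallelic, QUAL
strictly > 30 and call rate strictly > 95%. Concordance is the squared
Pearson correlation between carrier status (0/1/2) and allele dosage
(0/1/2), with missing dosages excluded pairwise; "r² = 1" is implemented
as ≥ 1 − 10⁻⁹ as a floating-point guard. Discordant animals are reported
with the maximal run of region SNPs over which each phase matches the
carrier haplotype around the focal variant; for a variant carried on a
shorter ancestral recombinant of the haplotype, that run ends exactly at
the historical crossover. Functional annotation is pass-through text.

## The synthetic generator

`simdata.simulate_population` emulates the data-generating process the
screen assumes, not any particular genome:

- **Map**: `n_chroms` × `n_snps_per_chrom` biallelic SNPs (default
  2 × 500 → 962 windows of 20), evenly spaced at 50 kb.
- **Founder pool**: `n_founder_haplotypes` (default 30) haplotypes with
  per-SNP allele frequencies uniform on [0.05, 0.5]; pool sampling
  weights are Dirichlet-distributed so common and rare haplotypes
  coexist. Each planted lethal rides one dedicated pool haplotype whose
  interval alleles are forced unique.
- **Pedigree**: founder sires (400) and MGS (600); each dam is an
  MGS × granddam offspring; matings (default 9000 AI records) pair a
  random sire with each dam. At the baseline insemination success of
  60.9% this leaves ≈ 5000 genotyped trio offspring and a genotyped set
  of ≈ 6200 (sires + MGS + 1.6% of dams + surviving offspring), the
  scale of the motivating study (6845 genotyped, 4876 trios, 77 with
  genotyped dams).
- **Transmission**: gene drop with a per-interval phase-switch
  probability (default 0.001 ≈ 1 cM per 20-SNP window at the study's
  marker density; a cM-scale genetic map is deliberately not modelled —
  window-scale LD is all the screen uses). Chromosomes re-draw the
  starting phase.
- **Lethality**: the lethal allele is tracked by descent at the interval
  midpoint. Homozygous concepti are, per mode: `embryonic` — recorded as
  AI failure, never born; `perinatal` — born dead within 24 h
  (stillbirth), never genotyped; `juvenile` — alive at 24 h but
  genotyped only with probability `juvenile_survival` (default 0.15,
  producing the 84–91%-deficit pattern); `none` — unaffected.
  Penetrance scales all of these. Founders and dams are conditioned on
  survival (a lethal homozygote cannot be a breeding adult), so the
  survivor-scale allele frequency is a/(1+a) for a planted conceptus
  frequency a.
- **Records**: AI/lambing dates consistent with the gestation window,
  baseline AIS 60.9% and SBR 7.5% as published, season/lactation/herd
  covariates with null effects; lamb viability records with ear-punch
  genotypes for all born lambs; a focal-region variant file containing
  the causal variant, fully linked variants, a variant shared with a
  planted historical recombinant background (r² < 1 by construction),
  low-quality / low-call-rate variants and an unlinked variant, giving
  the concordance filter positive and negative controls.
- **Determinism**: every output is a pure function of the config
  including its mandatory seed; identical configs give byte-identical
  file bundles. No recurrent mutation and no multi-generation selection
  or drift are modelled.

What passing tests on these populations shows — and what they cannot
show: the screen's operating characteristics hold when phasing is exact,
genotypes are complete, and pedigree records are error-free. Real data
add phasing/imputation error (the motivating study itself found one
haplotype carrier without the causal variant, attributed to array or
phasing error), pedigree misassignment, and LD structure richer than a
30-haplotype pool; none of these failure modes is represented here.

## Numerical and design notes

- Window haplotypes are bit-packed into 64-bit integers (windows ≤ 62
  SNPs), making the per-window frequency and matching operations
  O(animals).
- Iteration order (chromosome, start, haplotype string) is fixed so all
  outputs are byte-stable.
- Detection is only possible when N_Exp > −ln(p_max) ≈ 8.57 (the
  p-value at zero observed homozygotes is e^(−N_Exp)). At a 10% carrier
  frequency and ~5000 trios the realized N_Exp fluctuates around 11–12
  with the founder-count drift of a few hundred sires, so roughly one
  seed in ten is an honest non-detection; the recovery acceptance test
  therefore requires 18 of 20 seeded successes rather than 20.
- Statistical checks on stochastic quantities use seeded replicates:
  the planted sDYD effect must fall inside its 95% CI in ≥ 4 of 5
  replicates (a single-replicate coverage check would fail 5% of the
  time by design); null-simulation significance rates are bounded over
  20 seeds.
- Problem sizes in tests and in `scripts/acceptance.py` (2 × 500-SNP
  genome, 20 seeds per operating-characteristic estimate, 10⁵
  Monte-Carlo gene-drop replicates, 30 000 simulated matings) were
  chosen to estimate each property to comfortably sub-threshold error
  on a single CPU in minutes.

## Known limitations

- The SIRE_MGS transmission formula with the granddam frequency term is
  a plug-in approximation; it ignores uncertainty in f_k and any
  non-random granddam sampling (e.g. maternal lines enriched for the
  haplotype), which would bias N_Exp.
- Fixed-effect herd × year blocks approximate the random-effect fit;
  with very sparse blocks the binomial GLM can overfit where a mixed
  model would shrink.
- Coordinates are single-assembly; cross-assembly liftover is out of
  scope, as are imputation/phasing themselves.
- The clusterer reports one region per carrier haplotype; two distinct
  lethals on the same haplotype background would merge.
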