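# dhhscan

A reverse-genetic screen for **deficient homozygous haplotypes (DHH)** in
pedigreed livestock populations, built for geneticists running genomic
selection programs who want to flag recessive lethal alleles from routine
SNP-chip data — no case phenotypes or affected-animal samples required.

## The idea

A fully penetrant recessive lethal allele never shows up as a living
homozygote. With phased genotypes and a pedigree, its absence is
detectable: for every haplotype `k` in a sliding window of 20 SNPs
(kept if its maternal-phase frequency exceeds 1%), compare the observed
number of homozygous offspring `N_Obs(k)` with the Mendelian expectation
from trio transmission probabilities,

```
N_Exp(k) = Σ_trios  P(sire transmits k) · P(dam transmits k)
```

where a genotyped parent transmits `k` with probability `copies(k)/2`,
and an ungenotyped dam with genotyped maternal grandsire (MGS)
contributes `½·(copies_MGS(k)/2 + f_k)` with `f_k` the maternal-phase
population frequency standing in for the ungenotyped granddam (a
"conservative" mode dropping the `f_k` term is also provided).
A lower-tail Poisson test `P(X ≤ N_Obs)`, `X ~ Poisson(N_Exp)`, below
`1.9×10⁻⁴` together with a homozygote deficit
`(N_Exp − N_Obs)/N_Exp ∈ [75%, 100%]` flags a window haplotype;
consecutive allele-consistent significant windows are clustered into DHH
regions. Downstream, the package assigns 0/1/2 carrier statuses, compares
insemination success (AIS) and stillbirth rate (SBR) between *at-risk*
matings (carrier ram × ewe born to a carrier sire) and safe matings with
a logit-link binomial model, compares sire daughter-yield deviations by
carrier status, and filters sequence variants in a region (±1 Mb) by
requiring a perfect squared correlation (r² = 1) between carrier status
and allele dosage — with a recombinant-haplotype report for the animals
that break the correlation.

A seeded synthetic-population generator (`dhhscan.simdata`) produces
phased genotypes, pedigrees with both trio kinds, mating and lamb
records, and focal-region variant files with planted lethals of known
position, frequency and lethality mode (embryonic / perinatal /
juvenile), so the entire pipeline is testable at desk scale.

## Worked example

```python
from dhhscan import simdata, dhh_scan, genotype_io

cfg = simdata.SimConfig(
    seed=1,
    lethals=[simdata.LethalSpec(mode="perinatal", carrier_frequency=0.10)],
)
bundle = simdata.simulate_population(cfg)
ped = genotype_io.Pedigree(bundle.pedigree.assign(
    sire=bundle.pedigree["sire"].where(bundle.pedigree["sire"] != "0", None),
    dam=bundle.pedigree["dam"].where(bundle.pedigree["dam"] != "0", None)))
trios = genotype_io.build_trios(ped, bundle.geno)
result = dhh_scan.scan(bundle.geno, trios, bundle.snp_map)
regions = dhh_scan.cluster_regions(result.significant, bundle.snp_map)
```

prints (via `dhh_scan.regions_to_frame`):

```
6193 genotyped animals, 5030 trios (90 sire+dam)
20241 haplotypes tested in 962 windows, 227 significant
region chrom  n_markers  start_bp   end_bp  n_exp  n_obs  deficit_pct  p_poisson  het_carrier_freq_pct
  DHH1     1        246         1 12250001   12.1      0          100    5.5e-06                  7.52
```

Read: 12.1 homozygous offspring were expected for the clustered carrier
haplotype but none was observed (a 100% deficit, Poisson p = 5.5×10⁻⁶) —
the planted perinatal lethal, recovered as a single region overlapping
its true interval, with 7.5% of genotyped animals heterozygous (the
survivor-scale frequency implied by planting a 10% conceptus-level
carrier frequency and killing every homozygote before genotyping).

The same pipeline is available from the shell:

```bash
dhhscan simulate --seed 1 --out sim/
dhhscan scan --vcf sim/genotypes.vcf --pedigree sim/pedigree.tsv --out scan/
dhhscan status --vcf sim/genotypes.vcf --regions scan/regions.json --out statuses.tsv
dhhscan assoc  --matings sim/matings.tsv --statuses statuses.tsv --out assoc.tsv
dhhscan concord --variants sim/variants.vcf --geno-vcf sim/genotypes.vcf \
    --regions scan/regions.json --region DHH1 --statuses statuses.tsv --out concord.tsv
```

## Layout

| module | role |
| --- | --- |
| `dhhscan.genotype_io` | phased VCF / pedigree / record I/O, SNP QC (call rate, MAF, exact HWE), trio construction |
| `dhhscan.dhh_scan` | window enumeration, maternal haplotype frequencies, transmission expectations, Poisson deficiency test, region clustering, carrier statuses, inter-region LD |
| `dhhscan.trait_assoc` | at-risk mating classification, AIS/SBR coding, binomial and linear model comparisons, Wilcoxon, exact Fisher–Freeman–Halton r×c test |
| `dhhscan.variant_concordance` | region variant filtering, status–dosage r², recombinant-span report |
| `dhhscan.simdata` | seeded synthetic populations with planted lethals and known truth |
| `dhhscan.cli` | `dhhscan` command-line front end |

See `docs/methods.md` for the statistical model, default parameters and
known limitations.
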