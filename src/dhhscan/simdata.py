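"""Seeded synthetic populations with planted recessive lethal haplotypes.

The generator emulates the statistical structure the screen assumes: a
phased biallelic SNP map, a founder haplotype pool with a frequency
spectrum, a two-generation pedigree producing both trio kinds
(sire + genotyped dam; sire + maternal grandsire when the dam is not
genotyped), gene-drop transmission with per-interval recombination, and
planted lethal haplotypes whose homozygotes are removed before
genotyping (embryonic: AI failure; perinatal: stillbirth within 24 h)
or partially removed (juvenile: death before genotyping age), plus
mating records with baseline insemination-success and stillbirth rates
and a focal-region variant file with positive and negative concordance
controls. All outputs are pure functions of the configuration (the seed
is part of it).

What it does *not* emulate: coalescent-accurate linkage disequilibrium,
recurrent mutation, and selection across generations — none of which
the screen relies on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .genotype_io import PhasedGenotypes, SnpMap, write_phased_vcf

__all__ = [
    "LethalSpec",
    "RecombinantSpec",
    "SimConfig",
    "SimBundle",
    "gene_drop",
    "simulate_population",
    "emit_viability_table",
    "simulate_fertility_records",
    "simulate_sdyd",
]

BASES = np.array(list("ACGT"))


class LethalSpec(BaseModel):
    """A planted deleterious allele riding one founder haplotype."""

    chrom: int = 0  # chromosome index
    start_snp: int = 100  # offset within the chromosome
    n_snps: int = 20
    carrier_frequency: float = Field(0.10, gt=0, lt=1)  # heterozygote fraction ~ 2 x allele freq
    mode: Literal["embryonic", "perinatal", "juvenile", "none"] = "perinatal"
    penetrance: float = Field(1.0, ge=0, le=1)
    juvenile_survival: float = Field(0.15, ge=0, le=1)  # P(genotyped | affected, juvenile)

    @property
    def allele_frequency(self) -> float:
        return self.carrier_frequency / 2.0


class RecombinantSpec(BaseModel):
    """A historical recombinant of the first lethal haplotype.

    The recombinant background matches the carrier haplotype from the
    interval start through ``crossover_offset`` SNPs (and carries any
    variant located there) but diverges after the crossover, so it never
    counts as a region carrier.
    """

    frequency: float = Field(0.02, gt=0, lt=0.5)
    crossover_offset: int = 13  # last matching SNP, 0-based within the interval


class SimConfig(BaseModel):
    """Study-scale defaults for the synthetic population.

    Sizes mirror the screened study population: 9000 AI records at the
    baseline insemination success of 60.9% leave ~5000 genotyped trio
    offspring, dominated by the sire+maternal-grandsire kind (dam
    genotyped fraction 77/4876 ~ 0.016), a genotyped set of ~6000
    animals, and a genome of 2 x 500 SNPs (~962 sliding windows).
    """

    n_chroms: int = 2
    n_snps_per_chrom: int = 500
    allele_freq_range: tuple[float, float] = (0.05, 0.5)
    n_founder_haplotypes: int = 30
    n_sires: int = 400
    n_mgs: int = 600
    n_matings: int = 9000
    offspring_per_mating: int = 1
    dam_genotyped_fraction: float = Field(0.016, ge=0, le=1)
    recomb_prob: float = Field(0.001, ge=0, le=0.5)
    lethals: list[LethalSpec] = []
    recombinant: RecombinantSpec | None = None
    baseline_ais: float = Field(0.609, ge=0, le=1)
    baseline_sbr: float = Field(0.075, ge=0, le=1)
    n_herds: int = 20
    snp_spacing_bp: int = 50_000
    seed: int  # mandatory: every output is a pure function of the config

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        total = sum(l.allele_frequency for l in self.lethals)
        if self.recombinant is not None:
            if not self.lethals:
                raise ValueError("a recombinant background requires a lethal haplotype")
            total += self.recombinant.frequency
        if total >= 0.5:
            raise ValueError("combined planted haplotype frequency infeasible for the pool")
        for l in self.lethals:
            if l.chrom >= self.n_chroms:
                raise ValueError("lethal chromosome outside the map")
            if l.start_snp + l.n_snps > self.n_snps_per_chrom:
                raise ValueError("lethal interval outside the chromosome")
        if self.recombinant is not None:
            if self.recombinant.crossover_offset >= self.lethals[0].n_snps - 1:
                raise ValueError("crossover must leave at least one diverging SNP")
        return self


@dataclass
class SimBundle:
    """In-memory simulation output; `write` emits the text-file bundle."""

    config: SimConfig
    snp_map: SnpMap
    geno: PhasedGenotypes  # genotyped animals only
    pedigree: pd.DataFrame
    matings: pd.DataFrame
    lambs: pd.DataFrame
    variants_vcf: str  # focal-region variant VCF text ('' when no lethal)
    truth: dict

    def write(self, outdir) -> dict[str, str]:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        write_phased_vcf(out / "genotypes.vcf", self.geno, self.snp_map)
        paths["genotypes"] = str(out / "genotypes.vcf")
        self.pedigree.to_csv(out / "pedigree.tsv", sep="\t", index=False)
        paths["pedigree"] = str(out / "pedigree.tsv")
        self.matings.to_csv(out / "matings.tsv", sep="\t", index=False)
        paths["matings"] = str(out / "matings.tsv")
        self.lambs.to_csv(out / "lambs.tsv", sep="\t", index=False)
        paths["lambs"] = str(out / "lambs.tsv")
        if self.variants_vcf:
            (out / "variants.vcf").write_text(self.variants_vcf)
            paths["variants"] = str(out / "variants.vcf")
        (out / "truth.json").write_text(json.dumps(self.truth, indent=2, sort_keys=True) + "\n")
        paths["truth"] = str(out / "truth.json")
        return paths


# ---------------------------------------------------------------------------
# Gene drop


def _gene_drop_batch(pat, mat, chrom_bounds, recomb_prob, rng):
    """Vectorized gamete formation for many parents at once.

    Returns (gametes, origins); origin 0 = paternal phase, 1 = maternal.
    Each chromosome re-draws the starting phase; phase switches between
    adjacent SNPs independently with ``recomb_prob``.
    """
    n, m = pat.shape
    switch = rng.random((n, m)) < recomb_prob
    origin = np.zeros((n, m), dtype=np.int8)
    for lo, hi in chrom_bounds:
        start = rng.integers(0, 2, size=n, dtype=np.int8)
        origin[:, lo] = start
        if hi - lo > 1:
            cum = np.cumsum(switch[:, lo + 1: hi], axis=1, dtype=np.int64) & 1
            origin[:, lo + 1: hi] = (start[:, None] + cum) & 1
    gam = np.where(origin == 0, pat, mat)
    return gam, origin


def gene_drop(
    parent: tuple[np.ndarray, np.ndarray],
    recomb_prob: float,
    rng: np.random.Generator,
    chrom_bounds: Sequence[tuple[int, int]] | None = None,
) -> np.ndarray:
    """Form one gamete from a parent's phase pair.

    With ``recomb_prob`` 0 the gamete equals one parental phase chosen
    uniformly; chromosome boundaries always re-draw the starting phase.
    """
    pat = np.asarray(parent[0])[None, :]
    mat = np.asarray(parent[1])[None, :]
    if pat.shape != mat.shape:
        raise ValueError("parent phases must have the same length")
    if chrom_bounds is None:
        chrom_bounds = [(0, pat.shape[1])]
    gam, _ = _gene_drop_batch(pat, mat, chrom_bounds, recomb_prob, rng)
    return gam[0]


# ---------------------------------------------------------------------------
# Population simulation


def _draw_founder_copies(rng, n_copies, probs):
    """Categorical pool-haplotype identities for founder chromosome copies."""
    return rng.choice(len(probs), size=n_copies, p=probs)


def simulate_population(cfg: SimConfig) -> SimBundle:
    rng = np.random.default_rng(cfg.seed)
    n_snps = cfg.n_chroms * cfg.n_snps_per_chrom
    chrom_bounds = [
        (c * cfg.n_snps_per_chrom, (c + 1) * cfg.n_snps_per_chrom)
        for c in range(cfg.n_chroms)
    ]

    # --- marker map
    chrom = np.repeat([str(c + 1) for c in range(cfg.n_chroms)], cfg.n_snps_per_chrom)
    pos = np.tile(
        1 + cfg.snp_spacing_bp * np.arange(cfg.n_snps_per_chrom, dtype=np.int64),
        cfg.n_chroms,
    )
    ref_i = rng.integers(0, 4, size=n_snps)
    alt_i = (ref_i + rng.integers(1, 4, size=n_snps)) % 4
    snp_map = SnpMap(
        snp_id=np.array([f"snp{j:05d}" for j in range(n_snps)], dtype=object),
        chrom=chrom.astype(object),
        pos=pos,
        ref=BASES[ref_i].astype(object),
        alt=BASES[alt_i].astype(object),
    )

    # --- founder haplotype pool
    lo, hi = cfg.allele_freq_range
    p_alt = rng.uniform(lo, hi, size=n_snps)
    pool = (rng.random((cfg.n_founder_haplotypes, n_snps)) < p_alt).astype(np.int8)

    lethal_ids = list(range(len(cfg.lethals)))  # pool rows 0..L-1 carry the lethals
    rec_id = len(cfg.lethals) if cfg.recombinant is not None else None
    tracked: list[int] = []  # global index of each lethal's tracked (mid) SNP
    intervals: list[tuple[int, int]] = []
    for li, spec in enumerate(cfg.lethals):
        base = chrom_bounds[spec.chrom][0]
        first = base + spec.start_snp
        last = first + spec.n_snps - 1
        intervals.append((first, last))
        tracked.append(first + spec.n_snps // 2)
        # carrier haplotype must be unique over its interval: nudge clashes
        seg = pool[li, first: last + 1]
        for other in range(cfg.n_founder_haplotypes):
            if other == li:
                continue
            if np.array_equal(pool[other, first: last + 1], seg):
                pool[other, first] ^= 1
    if rec_id is not None:
        first, last = intervals[0]
        xo = first + cfg.recombinant.crossover_offset
        pool[rec_id, first: xo + 1] = pool[0, first: xo + 1]
        # guarantee divergence right after the crossover
        pool[rec_id, xo + 1] = 1 - pool[0, xo + 1]

    # --- founder identity sampling probabilities
    probs = np.zeros(cfg.n_founder_haplotypes)
    for li, spec in enumerate(cfg.lethals):
        probs[li] = spec.allele_frequency
    if rec_id is not None:
        probs[rec_id] = cfg.recombinant.frequency
    n_special = len(cfg.lethals) + (1 if rec_id is not None else 0)
    rest = cfg.n_founder_haplotypes - n_special
    if rest < 1:
        raise ValueError("founder pool too small for the planted haplotypes")
    w = rng.dirichlet(np.ones(rest))
    probs[n_special:] = w * (1.0 - probs.sum())

    def founders(n):
        """(ids a, ids b) pool identities; no founder is lethal-homozygous."""
        a = _draw_founder_copies(rng, n, probs)
        b = _draw_founder_copies(rng, n, probs)
        for li in lethal_ids:  # lethal homozygotes were purged before adulthood
            clash = (a == li) & (b == li)
            while clash.any():
                b[clash] = _draw_founder_copies(rng, int(clash.sum()), probs)
                clash = (a == li) & (b == li)
        return a, b

    sire_a, sire_b = founders(cfg.n_sires)
    mgs_a, mgs_b = founders(cfg.n_mgs)
    gd_a, gd_b = founders(cfg.n_matings)  # one granddam per dam line

    def phases(ids_a, ids_b):
        return pool[ids_a], pool[ids_b]

    n_loci = len(tracked)

    def founder_ident(ids):
        # identity at every tracked locus is the pool id of the whole copy
        return np.repeat(ids[:, None], max(n_loci, 1), axis=1) if n_loci else np.zeros((len(ids), 0), dtype=np.int64)

    # --- dams: MGS x granddam
    dam_mgs = rng.integers(0, cfg.n_mgs, size=cfg.n_matings)
    mgs_pat, mgs_mat = pool[mgs_a[dam_mgs]], pool[mgs_b[dam_mgs]]
    dam_pat, dam_pat_orig = _gene_drop_batch(mgs_pat, mgs_mat, chrom_bounds, cfg.recomb_prob, rng)
    gd_pat, gd_mat = pool[gd_a], pool[gd_b]
    dam_mat, dam_mat_orig = _gene_drop_batch(gd_pat, gd_mat, chrom_bounds, cfg.recomb_prob, rng)

    def gamete_ident(orig, ident_pat, ident_mat):
        if not n_loci:
            return np.zeros((orig.shape[0], 0), dtype=np.int64)
        cols = orig[:, tracked]
        return np.where(cols == 0, ident_pat, ident_mat)

    dam_ident_pat = gamete_ident(dam_pat_orig, founder_ident(mgs_a[dam_mgs]), founder_ident(mgs_b[dam_mgs]))
    dam_ident_mat = gamete_ident(dam_mat_orig, founder_ident(gd_a), founder_ident(gd_b))

    # a lethal homozygote could never have grown into a breeding ewe:
    # redraw the granddam gamete of affected dams (conditioning on survival)
    def _dam_death_prob(spec) -> float:
        if spec.mode in ("embryonic", "perinatal"):
            return spec.penetrance
        if spec.mode == "juvenile":
            return spec.penetrance * (1.0 - spec.juvenile_survival)
        return 0.0

    for _ in range(64):
        doomed = np.zeros(cfg.n_matings, dtype=bool)
        for li, spec in enumerate(cfg.lethals):
            hom = (dam_ident_pat[:, li] == li) & (dam_ident_mat[:, li] == li)
            doomed |= hom & (rng.random(cfg.n_matings) < _dam_death_prob(spec))
        if not doomed.any():
            break
        redo = np.flatnonzero(doomed)
        new_mat, new_orig = _gene_drop_batch(
            gd_pat[redo], gd_mat[redo], chrom_bounds, cfg.recomb_prob, rng
        )
        dam_mat[redo] = new_mat
        dam_ident_mat[redo] = gamete_ident(
            new_orig, founder_ident(gd_a[redo]), founder_ident(gd_b[redo])
        )

    # --- matings and offspring (one conceptus per mating slot)
    n_off = cfg.n_matings * cfg.offspring_per_mating
    mate_dam = np.repeat(np.arange(cfg.n_matings), cfg.offspring_per_mating)
    mate_sire = rng.integers(0, cfg.n_sires, size=n_off)
    s_pat, s_mat = pool[sire_a[mate_sire]], pool[sire_b[mate_sire]]
    off_pat, off_pat_orig = _gene_drop_batch(s_pat, s_mat, chrom_bounds, cfg.recomb_prob, rng)
    off_mat, off_mat_orig = _gene_drop_batch(
        dam_pat[mate_dam], dam_mat[mate_dam], chrom_bounds, cfg.recomb_prob, rng
    )
    off_ident_pat = gamete_ident(off_pat_orig, founder_ident(sire_a[mate_sire]), founder_ident(sire_b[mate_sire]))
    off_ident_mat = gamete_ident(off_mat_orig, dam_ident_pat[mate_dam], dam_ident_mat[mate_dam])

    # --- lethality
    affected = np.zeros((n_off, max(n_loci, 1)), dtype=bool)
    for li, spec in enumerate(cfg.lethals):
        hom = (off_ident_pat[:, li] == li) & (off_ident_mat[:, li] == li)
        pen = rng.random(n_off) < spec.penetrance
        affected[:, li] = hom & pen
    embryonic = np.zeros(n_off, dtype=bool)
    perinatal = np.zeros(n_off, dtype=bool)
    juvenile_dead = np.zeros(n_off, dtype=bool)
    for li, spec in enumerate(cfg.lethals):
        if spec.mode == "embryonic":
            embryonic |= affected[:, li]
        elif spec.mode == "perinatal":
            perinatal |= affected[:, li]
        elif spec.mode == "juvenile":
            survives = rng.random(n_off) < spec.juvenile_survival
            juvenile_dead |= affected[:, li] & ~survives

    ais = (rng.random(n_off) < cfg.baseline_ais) & ~embryonic
    born = ais  # singleton litters: a successful AI produces one lamb
    base_dead = rng.random(n_off) < cfg.baseline_sbr
    dead24 = born & (perinatal | base_dead)
    alive30 = born & ~dead24 & ~juvenile_dead
    scan_genotyped = alive30  # perinatal/juvenile deaths never reach genotyping

    # --- ids
    sires = [f"S{i:04d}" for i in range(cfg.n_sires)]
    mgss = [f"G{i:04d}" for i in range(cfg.n_mgs)]
    gds = [f"W{i:05d}" for i in range(cfg.n_matings)]
    dams = [f"D{i:05d}" for i in range(cfg.n_matings)]
    offs = [f"O{i:05d}" for i in range(n_off)]
    dam_genotyped = rng.random(cfg.n_matings) < cfg.dam_genotyped_fraction

    # --- pedigree (granddams included, ungenotyped)
    ped_rows = []
    for i, a in enumerate(sires):
        ped_rows.append((a, "0", "0", "M", 2015))
    for i, a in enumerate(mgss):
        ped_rows.append((a, "0", "0", "M", 2015))
    for i, a in enumerate(gds):
        ped_rows.append((a, "0", "0", "F", 2015))
    for i, a in enumerate(dams):
        ped_rows.append((a, mgss[dam_mgs[i]], gds[i], "F", 2017))
    off_sex = rng.integers(0, 2, size=n_off)
    for i, a in enumerate(offs):
        if born[i]:
            ped_rows.append((a, sires[mate_sire[i]], dams[mate_dam[i]], "MF"[off_sex[i]], 2019))
    pedigree = pd.DataFrame(ped_rows, columns=["animal", "sire", "dam", "sex", "birth_year"])

    # --- genotyped set
    g_animals = list(sires) + list(mgss)
    pat_rows = [pool[sire_a], pool[mgs_a]]
    mat_rows = [pool[sire_b], pool[mgs_b]]
    dam_keep = np.flatnonzero(dam_genotyped)
    g_animals += [dams[i] for i in dam_keep]
    pat_rows.append(dam_pat[dam_keep])
    mat_rows.append(dam_mat[dam_keep])
    off_keep = np.flatnonzero(scan_genotyped)
    g_animals += [offs[i] for i in off_keep]
    pat_rows.append(off_pat[off_keep])
    mat_rows.append(off_mat[off_keep])
    geno = PhasedGenotypes(
        animals=g_animals,
        pat=np.vstack(pat_rows).astype(np.int8),
        mat=np.vstack(mat_rows).astype(np.int8),
        source="imputed",
    )

    # --- mating records
    base_day = date(2019, 3, 1)
    ai_offsets = rng.integers(0, 61, size=n_off)
    gest = rng.integers(148, 155, size=n_off)  # within the 151 +/- 7 window
    seasons = np.where(rng.random(n_off) < 0.5, "spring", "summer")
    lactation = rng.integers(1, 5, size=n_off)
    herds = rng.integers(0, cfg.n_herds, size=n_off)
    mrows = []
    for i in range(n_off):
        ai_d = base_day + timedelta(days=int(ai_offsets[i]))
        lamb_d = ai_d + timedelta(days=int(gest[i])) if ais[i] else ""
        mrows.append(
            (
                sires[mate_sire[i]], dams[mate_dam[i]], mgss[dam_mgs[mate_dam[i]]],
                ai_d.isoformat(), seasons[i], int(lactation[i]), f"H{herds[i]:03d}",
                2019, lamb_d.isoformat() if lamb_d else "", int(born[i]), int(dead24[i]),
            )
        )
    matings = pd.DataFrame(
        mrows,
        columns=["ram", "ewe", "ewe_sire", "ai_date", "season", "lactation",
                 "herd", "year", "lambing_date", "n_lambs", "n_dead24h"],
    )

    # --- lamb viability records at the first lethal (ear-punch genotyping of
    # every born lamb, dead or alive, as in an at-risk mating experiment)
    lrows = []
    if cfg.lethals:
        for i in np.flatnonzero(born):
            dosage = int(off_ident_pat[i, 0] == 0) + int(off_ident_mat[i, 0] == 0)
            lrows.append(
                (offs[i], sires[mate_sire[i]], dams[mate_dam[i]], dosage,
                 int(not dead24[i]), int(alive30[i]))
            )
    lambs = pd.DataFrame(
        lrows, columns=["lamb", "sire", "dam", "lethal_dosage", "alive_24h", "alive_30d"]
    )

    # --- focal-region variant VCF (first lethal)
    variants_vcf = ""
    truth_variants = {}
    if cfg.lethals:
        first, last = intervals[0]
        g_idx_pat, g_idx_mat = _genotyped_ident(
            sire_a, sire_b, mgs_a, mgs_b, dam_ident_pat, dam_ident_mat,
            off_ident_pat, off_ident_mat, dam_keep, off_keep, n_loci,
        )
        variants_vcf, truth_variants = _build_variant_vcf(
            cfg, snp_map, g_animals, g_idx_pat[:, 0], g_idx_mat[:, 0],
            first, last, rec_id, rng,
        )

    # --- truth
    truth: dict = {"schema": "dhhscan-sim-truth/1", "seed": cfg.seed, "lethals": []}
    maternal = geno.mat
    for li, spec in enumerate(cfg.lethals):
        first, last = intervals[li]
        seg = pool[li, first: last + 1]
        is_carrier_phase_p = (geno.pat[:, first: last + 1] == seg).all(axis=1)
        is_carrier_phase_m = (maternal[:, first: last + 1] == seg).all(axis=1)
        status = is_carrier_phase_p.astype(int) + is_carrier_phase_m.astype(int)
        hom_concepti = int(
            ((off_ident_pat[:, li] == li) & (off_ident_mat[:, li] == li)).sum()
        )
        # Mendelian expectation given realized parental carriage at the
        # tracked locus (Poisson-binomial mean and SE over concepti)
        p_s = ((sire_a[mate_sire] == li).astype(float) + (sire_b[mate_sire] == li)) / 2.0
        p_d = ((dam_ident_pat[mate_dam, li] == li).astype(float)
               + (dam_ident_mat[mate_dam, li] == li)) / 2.0
        p_hom = p_s * p_d
        expected_hom = float(p_hom.sum())
        hom_se = float(np.sqrt((p_hom * (1 - p_hom)).sum()))
        truth["lethals"].append(
            {
                "id": li,
                "chrom": str(spec.chrom + 1),
                "first_snp": int(first),
                "last_snp": int(last),
                "start_bp": int(snp_map.pos[first]),
                "end_bp": int(snp_map.pos[last]),
                "carrier_codes": [int(x) for x in seg],
                "mode": spec.mode,
                "penetrance": spec.penetrance,
                "carrier_frequency_config": spec.carrier_frequency,
                "realized_maternal_freq": float(is_carrier_phase_m.mean()),
                "realized_het_freq_genotyped": float((status == 1).mean()),
                "realized_hom_freq_genotyped": float((status == 2).mean()),
                "hom_conceptus_count": hom_concepti,
                "expected_hom_concepti": expected_hom,
                "hom_concepti_se": hom_se,
            }
        )
    if rec_id is not None:
        truth["recombinant"] = {
            "frequency": cfg.recombinant.frequency,
            "crossover_snp": int(intervals[0][0] + cfg.recombinant.crossover_offset),
        }
    truth["variants"] = truth_variants

    return SimBundle(
        config=cfg, snp_map=snp_map, geno=geno, pedigree=pedigree,
        matings=matings, lambs=lambs, variants_vcf=variants_vcf, truth=truth,
    )


def _genotyped_ident(sire_a, sire_b, mgs_a, mgs_b, dam_ip, dam_im,
                     off_ip, off_im, dam_keep, off_keep, n_loci):
    """Tracked-locus identities for the genotyped animals, in VCF order."""
    def f(ids):
        return np.repeat(ids[:, None], max(n_loci, 1), axis=1)

    pat = np.vstack([f(sire_a), f(mgs_a), dam_ip[dam_keep], off_ip[off_keep]])
    mat = np.vstack([f(sire_b), f(mgs_b), dam_im[dam_keep], off_im[off_keep]])
    return pat, mat


def _build_variant_vcf(cfg, snp_map, animals, ident_pat, ident_mat,
                       first, last, rec_id, rng):
    """Focal-region variants: causal, fully linked, recombinant-background,
    low-quality, low-call-rate and unlinked controls."""
    chrom = str(snp_map.chrom[first])
    mid_bp = int((snp_map.pos[first] + snp_map.pos[last]) // 2)
    causal = ((ident_pat == 0).astype(np.int8) + (ident_mat == 0)).astype(np.int8)
    records = []  # (pos, id, ref, alt, qual, dosages)
    records.append((mid_bp + 1, "causal", "G", "A", 999.0, causal))
    for i, dp in enumerate((-15_000, -5_000, 7_000)):
        records.append((mid_bp + 1 + dp, f"linked{i}", "C", "T", 600.0, causal))
    if rec_id is not None:
        on_rec = (
            np.isin(ident_pat, [0, rec_id]).astype(np.int8)
            + np.isin(ident_mat, [0, rec_id])
        ).astype(np.int8)
        records.append((mid_bp + 3, "recbg", "T", "C", 800.0, on_rec))
    records.append((mid_bp + 5, "lowqual", "A", "G", 25.0, causal))
    miss = causal.copy()
    miss[rng.random(len(miss)) < 0.08] = -1
    records.append((mid_bp + 9, "lowcall", "A", "C", 500.0, miss))
    p_neutral = 0.3
    neutral = rng.binomial(2, p_neutral, size=len(animals)).astype(np.int8)
    records.append((mid_bp + 12, "unlinked", "G", "C", 700.0, neutral))
    records.sort(key=lambda r: r[0])

    lines = [
        "##fileformat=VCFv4.2",
        "##source=dhhscan-sim",
        f"##contig=<ID={chrom}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(animals),
    ]
    gt = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    for pos, vid, ref, alt, qual, dos in records:
        cells = "\t".join(gt[int(d)] for d in dos)
        lines.append(f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t{qual:g}\tPASS\t.\tGT\t{cells}")
    truth_variants = {
        "causal_pos": mid_bp + 1,
        "recombinant_pos": (mid_bp + 3) if rec_id is not None else None,
        "low_qual_pos": mid_bp + 5,
        "low_callrate_pos": mid_bp + 9,
        "unlinked_pos": mid_bp + 12,
    }
    return "\n".join(lines) + "\n", truth_variants


# ---------------------------------------------------------------------------
# Viability tables


GENO_LABELS = {0: "G/G", 1: "G/A", 2: "A/A"}


def emit_viability_table(lambs: pd.DataFrame,
                         *,
                         genotype_col: str = "genotype",
                         alive_col: str = "alive") -> tuple[pd.DataFrame, dict]:
    """Genotype x alive/dead count table with its headline percentages.

    ``lambs`` holds one row per born lamb with a genotype label (NaN for
    lambs that could not be genotyped) and a 0/1 alive flag. Summaries
    follow the convention of reporting mortality among *genotyped* lambs
    over *all* born lambs (so an ungenotyped dead lamb enlarges the
    denominator but not the numerator), the share of deaths per genotype
    over genotyped deaths, and the within-genotype mortality rates. An
    empty input yields an all-zero table.
    """
    if len(lambs) == 0:
        table = pd.DataFrame(columns=["alive", "dead"])
        return table, {
            "n_lambs": 0, "n_deaths_genotyped": 0, "overall_mortality_pct": 0.0,
            "share_of_deaths_pct": {}, "mortality_by_genotype_pct": {},
        }
    df = lambs.copy()
    genotyped = df[df[genotype_col].notna()]
    table = (
        genotyped.assign(state=np.where(genotyped[alive_col].astype(int) == 1, "alive", "dead"))
        .groupby([genotype_col, "state"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=["alive", "dead"], fill_value=0)
    )
    table.index.name = "genotype"
    n_total = len(df)
    deaths = int(table["dead"].sum())
    summaries = {
        "n_lambs": int(n_total),
        "n_deaths_genotyped": deaths,
        "overall_mortality_pct": 100.0 * deaths / n_total,
        "share_of_deaths_pct": {
            str(g): 100.0 * int(table.loc[g, "dead"]) / deaths if deaths else 0.0
            for g in table.index
        },
        "mortality_by_genotype_pct": {
            str(g): 100.0 * int(table.loc[g, "dead"]) / int(table.loc[g].sum())
            for g in table.index
        },
    }
    return table, summaries


# ---------------------------------------------------------------------------
# Dedicated record generators for the trait analyses


def simulate_fertility_records(
    n_matings: int,
    *,
    at_risk_fraction: float = 0.2,
    baseline_ais: float = 0.609,
    baseline_sbr: float = 0.075,
    mode: Literal["perinatal", "embryonic", "none"] = "perinatal",
    penetrance: float = 1.0,
    n_herds: int = 30,
    seed: int,
) -> pd.DataFrame:
    """Mating records for at-risk vs safe fertility comparisons.

    At-risk matings are heterozygous ram x ewe born to a heterozygous
    sire, with singleton litters: the lamb is homozygous with the
    Mendelian probability 0.5 * (0.5 * 0.5) = 0.125. A perinatal lethal
    turns the homozygote into a stillbirth; an embryonic one fails the
    insemination; 'none' plants no effect (null simulation).
    """
    rng = np.random.default_rng(seed)
    at_risk = rng.random(n_matings) < at_risk_fraction
    ewe_carrier = rng.random(n_matings) < 0.5  # daughter of a het sire
    ram_transmits = rng.random(n_matings) < 0.5
    ewe_transmits = rng.random(n_matings) < 0.5
    hom = at_risk & ewe_carrier & ram_transmits & ewe_transmits
    affected = hom & (rng.random(n_matings) < penetrance) & (mode != "none")
    ais = rng.random(n_matings) < baseline_ais
    if mode == "embryonic":
        ais &= ~affected
    dead = rng.random(n_matings) < baseline_sbr
    if mode == "perinatal":
        dead |= affected
    base_day = date(2019, 3, 1)
    ai_off = rng.integers(0, 61, size=n_matings)
    gest = rng.integers(148, 155, size=n_matings)
    rows = []
    for i in range(n_matings):
        ai_d = base_day + timedelta(days=int(ai_off[i]))
        lamb_d = (ai_d + timedelta(days=int(gest[i]))).isoformat() if ais[i] else ""
        rows.append(
            (
                f"R{i:05d}", f"E{i:05d}", f"ES{i:05d}",
                "at_risk" if at_risk[i] else "safe",
                ai_d.isoformat(),
                "spring" if rng.random() < 0.5 else "summer",
                int(rng.integers(1, 5)), f"H{int(rng.integers(0, n_herds)):03d}", 2019,
                lamb_d, int(ais[i]), int(ais[i] and dead[i]),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["ram", "ewe", "ewe_sire", "mating_type", "ai_date", "season",
                 "lactation", "herd", "year", "lambing_date", "n_lambs", "n_dead24h"],
    )


def simulate_sdyd(
    n_rams: int = 2000,
    *,
    carrier_freq: float = 0.1,
    effect: float = 0.10,
    year_range: tuple[int, int] = (2000, 2016),
    year_slope: float = 0.05,
    noise_sd: float = 1.0,
    traits: Sequence[str] = ("MY",),
    genetic_sd: float = 1.0,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sire trait records with a planted carrier effect and a year trend.

    Returns (trait table, carrier statuses). sDYD = dyd / genetic_sd;
    daughter counts straddle the 20-daughter inclusion threshold so the
    filter is exercised.
    """
    rng = np.random.default_rng(seed)
    sires = [f"S{i:05d}" for i in range(n_rams)]
    carrier = rng.random(n_rams) < carrier_freq
    years = rng.integers(year_range[0], year_range[1] + 1, size=n_rams)
    n_daughters = rng.integers(5, 200, size=n_rams)
    rows = []
    for trait in traits:
        sdyd = (
            effect * carrier
            + year_slope * (years - year_range[0])
            + rng.normal(0, noise_sd, size=n_rams)
        )
        for i in range(n_rams):
            rows.append((sires[i], trait, sdyd[i] * genetic_sd, genetic_sd,
                         int(n_daughters[i]), int(years[i])))
    trait_df = pd.DataFrame(
        rows, columns=["sire", "trait", "dyd", "genetic_sd", "n_daughters", "birth_year"]
    )
    statuses = pd.DataFrame(
        {"animal": sires, "region": "SIM1", "status": carrier.astype(int)}
    )
    return trait_df, statuses
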