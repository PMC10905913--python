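"""Phased-genotype, pedigree and record I/O plus SNP quality control.

Phase convention
----------------
The screen depends on identifying the *maternal phase* — the haplotype an
animal inherited from its dam. VCF genotypes ``a|b`` are read as
``a`` = paternal allele, ``b`` = maternal allele. Files produced by
:mod:`dhhscan.simdata` obey this convention; external users must assert it
(``assume_paternal_first=True``) because a generic phasing tool does not
guarantee it.

Alleles are stored as small integers over a biallelic map: 0 = REF,
1 = ALT, -1 = missing. Missing calls are allowed only before quality
control; the scan itself refuses incomplete genotypes (the study used
imputed, complete data).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

__all__ = [
    "SnpMap",
    "PhasedGenotypes",
    "Pedigree",
    "TrioKind",
    "Trio",
    "TrioSet",
    "QcReport",
    "read_phased_vcf",
    "write_phased_vcf",
    "read_pedigree",
    "hwe_exact_p",
    "hwe_chi2_p",
    "snp_qc",
    "build_trios",
]

MISSING = -1


@dataclass(frozen=True)
class SnpMap:
    """Ordered biallelic marker map (the coordinate system for windows).

    Positions are 1-based base pairs, strictly increasing within each
    chromosome; SNP ids are unique. Chromosomes keep file order.
    """

    snp_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.snp_id)
        for name in ("chrom", "pos", "ref", "alt"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"SnpMap field {name!r} length mismatch")
        if len(set(self.snp_id)) != n:
            raise ValueError("SNP ids are not unique")
        for c, (lo, hi) in self.chrom_slices().items():
            p = self.pos[lo:hi]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")

    @property
    def n_snps(self) -> int:
        return len(self.snp_id)

    def chrom_slices(self) -> dict[str, tuple[int, int]]:
        """Half-open index range of each chromosome, in file order."""
        out: dict[str, tuple[int, int]] = {}
        chroms = np.asarray(self.chrom)
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                c = str(chroms[start])
                if c in out:
                    raise ValueError(f"chromosome {c} is not contiguous in the map")
                out[c] = (start, i)
                start = i
        return out

    def subset(self, idx: np.ndarray) -> "SnpMap":
        return SnpMap(
            snp_id=self.snp_id[idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
        )


@dataclass
class PhasedGenotypes:
    """Per-animal pair of haplotype allele vectors over a :class:`SnpMap`.

    ``pat[i, j]`` / ``mat[i, j]`` are the paternal / maternal allele of
    animal ``i`` at SNP ``j`` (0/1, -1 missing pre-QC only).
    """

    animals: list[str]
    pat: np.ndarray
    mat: np.ndarray
    source: str = "raw"  # raw | imputed

    def __post_init__(self) -> None:
        n, m = self.pat.shape
        if self.mat.shape != (n, m):
            raise ValueError("paternal/maternal phase shapes differ")
        if len(self.animals) != n:
            raise ValueError("animal list length does not match phase rows")
        if len(set(self.animals)) != n:
            raise ValueError("duplicate animal id")

    @property
    def n_animals(self) -> int:
        return len(self.animals)

    @property
    def n_snps(self) -> int:
        return self.pat.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool((self.pat == MISSING).any() or (self.mat == MISSING).any())

    def index_of(self, animal_ids: Iterable[str]) -> np.ndarray:
        lookup = {a: i for i, a in enumerate(self.animals)}
        return np.array([lookup[a] for a in animal_ids], dtype=np.int64)

    def subset_snps(self, idx: np.ndarray) -> "PhasedGenotypes":
        return PhasedGenotypes(
            animals=list(self.animals),
            pat=self.pat[:, idx],
            mat=self.mat[:, idx],
            source=self.source,
        )


@dataclass
class Pedigree:
    """Pedigree records (animal, sire, dam, sex, birth_year); unknown parent = None."""

    table: pd.DataFrame

    REQUIRED = ("animal", "sire", "dam", "sex", "birth_year")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"pedigree missing columns: {missing}")
        if self.table["animal"].duplicated().any():
            dup = self.table.loc[self.table["animal"].duplicated(), "animal"].iloc[0]
            raise ValueError(f"duplicate pedigree entry for animal {dup!r}")
        self._sire = dict(zip(self.table["animal"], self.table["sire"]))
        self._dam = dict(zip(self.table["animal"], self.table["dam"]))
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # iterative colouring; an animal reachable from itself through
        # parent links means a corrupt pedigree
        state: dict[str, int] = {}
        for start in self._sire:
            if state.get(start):
                continue
            stack: list[tuple[str, int]] = [(start, 0)]
            while stack:
                node, phase = stack.pop()
                if phase == 0:
                    if state.get(node) == 1:
                        raise ValueError(f"pedigree cycle involving {node!r}")
                    if state.get(node) == 2:
                        continue
                    state[node] = 1
                    stack.append((node, 1))
                    for p in (self._sire.get(node), self._dam.get(node)):
                        if p is not None and p in self._sire and state.get(p) != 2:
                            stack.append((p, 0))
                else:
                    state[node] = 2

    def sire_of(self, animal: str) -> str | None:
        return self._sire.get(animal)

    def dam_of(self, animal: str) -> str | None:
        return self._dam.get(animal)

    @property
    def animals(self) -> list[str]:
        return list(self.table["animal"])


class TrioKind(str, Enum):
    SIRE_DAM = "SIRE_DAM"
    SIRE_MGS = "SIRE_MGS"


@dataclass(frozen=True)
class Trio:
    offspring: str
    sire: str
    dam_or_mgs: str
    kind: TrioKind


@dataclass
class TrioSet:
    trios: list[Trio]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for t in self.trios:
            if t.offspring in seen:
                raise ValueError(f"offspring {t.offspring!r} appears in two trios")
            seen.add(t.offspring)

    def __len__(self) -> int:
        return len(self.trios)

    def __iter__(self):
        return iter(self.trios)

    def of_kind(self, kind: TrioKind) -> list[Trio]:
        return [t for t in self.trios if t.kind == kind]


@dataclass
class QcReport:
    """Per-SNP QC metrics with kept/dropped flag and the reasons for drops."""

    table: pd.DataFrame  # snp_id, call_rate, maf, hwe_p, kept, reason

    @property
    def kept_mask(self) -> np.ndarray:
        return self.table["kept"].to_numpy()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# VCF I/O


def read_phased_vcf(path, *, assume_paternal_first: bool = True,
                    require_phased: bool = True) -> tuple[PhasedGenotypes, SnpMap]:
    """Read a diploid VCF into phase matrices and a marker map.

    The first GT allele becomes the paternal phase, the second the
    maternal phase (``assume_paternal_first`` documents that the caller
    accepts this convention; passing ``False`` raises, as the screen is
    meaningless without it). Multi-allelic sites are rejected. A
    non-missing heterozygous genotype written with ``/`` raises when
    ``require_phased`` (unphased homozygotes are accepted: their phase
    assignment is unambiguous).
    """
    from cyvcf2 import VCF

    if not assume_paternal_first:
        raise ValueError(
            "the scan requires GT order paternal|maternal; re-order phases upstream"
        )
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate animal id in VCF sample line")
    snp_id, chrom, pos, ref, alt = [], [], [], [], []
    pat_rows, mat_rows = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"multi-allelic site {var.ID or var.CHROM + ':' + str(var.POS)} not supported"
            )
        g = np.array(var.genotypes, dtype=np.int64)  # (n, 3): a, b, phased
        a, b, phased = g[:, 0], g[:, 1], g[:, 2].astype(bool)
        nonmissing = (a >= 0) & (b >= 0)
        het = nonmissing & (a != b)
        if require_phased and np.any(het & ~phased):
            bad = int(np.flatnonzero(het & ~phased)[0])
            raise ValueError(
                f"unphased genotype at SNP {var.ID or f'{var.CHROM}:{var.POS}'} "
                f"for animal {samples[bad]!r}"
            )
        a = np.where(nonmissing, a, MISSING)
        b = np.where(nonmissing, b, MISSING)
        snp_id.append(var.ID or f"{var.CHROM}:{var.POS}")
        chrom.append(var.CHROM)
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0])
        pat_rows.append(a.astype(np.int8))
        mat_rows.append(b.astype(np.int8))
    snp_map = SnpMap(
        snp_id=np.array(snp_id, dtype=object),
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
    )
    if pat_rows:
        pat = np.stack(pat_rows, axis=1)
        mat = np.stack(mat_rows, axis=1)
    else:
        pat = np.zeros((len(samples), 0), dtype=np.int8)
        mat = np.zeros((len(samples), 0), dtype=np.int8)
    geno = PhasedGenotypes(animals=samples, pat=pat, mat=mat)
    return geno, snp_map


def write_phased_vcf(path, geno: PhasedGenotypes, snp_map: SnpMap) -> None:
    """Write genotypes to a canonical plain-text phased VCF (v4.2)."""
    if geno.n_snps != snp_map.n_snps:
        raise ValueError("genotypes and map have different SNP counts")

    def fmt(a: int, b: int) -> str:
        if a == MISSING or b == MISSING:
            return ".|."
        return f"{a}|{b}"

    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write("##source=dhhscan\n")
    for c in snp_map.chrom_slices():
        buf.write(f"##contig=<ID={c}>\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
    buf.write("\t".join(geno.animals) + "\n")
    pat, mat = geno.pat, geno.mat
    for j in range(snp_map.n_snps):
        cols = [
            str(snp_map.chrom[j]),
            str(snp_map.pos[j]),
            str(snp_map.snp_id[j]),
            str(snp_map.ref[j]),
            str(snp_map.alt[j]),
            ".",
            "PASS",
            ".",
            "GT",
        ]
        cols.extend(fmt(int(pat[i, j]), int(mat[i, j])) for i in range(geno.n_animals))
        buf.write("\t".join(cols) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_pedigree(path) -> Pedigree:
    """Read a pedigree TSV with header ``animal sire dam sex birth_year``.

    Unknown parents are coded ``0`` (or empty) and become ``None``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sire", "dam"):
        df[col] = df[col].where(~df[col].isin(["0", "", "nan"]), other=None)
        df[col] = df[col].where(df[col].notna(), other=None)
    df["birth_year"] = df["birth_year"].astype(int)
    return Pedigree(df)


# ---------------------------------------------------------------------------
# Quality control


def hwe_exact_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy–Weinberg test p-value from genotype counts.

    Plain exact test (no mid-p): the probability, under HWE with the
    observed allele counts fixed, of a heterozygote count at least as
    improbable as the one observed.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("negative genotype count")
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 1.0
    n_a = 2 * n_aa + n_ab  # count of one allele
    rare = min(n_a, 2 * n - n_a)
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(n_het = h | allele counts) up to a common constant
    logp = (
        gammaln(n + 1)
        - gammaln((rare - hets) / 2 + 1)
        - gammaln(hets + 1)
        - gammaln(n - (rare + hets) / 2 + 1)
        + hets * math.log(2.0)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, n_ab)]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def hwe_chi2_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Asymptotic 1-df chi-square HWE test (offered as an alternative)."""
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 1.0
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1 - p
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.nansum(np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0))
    return float(chi2.sf(stat, df=1))


def snp_qc(
    geno: PhasedGenotypes,
    snp_map: SnpMap,
    *,
    call_rate_min: float = 0.97,
    maf_min: float = 0.01,
    hwe_p_min: float = 1e-5,
    hwe_test: str = "exact",
) -> tuple[PhasedGenotypes, SnpMap, QcReport]:
    """Apply per-SNP quality control: call rate, MAF and HWE thresholds.

    A SNP is kept iff call rate > ``call_rate_min``, minor allele
    frequency > ``maf_min`` and HWE p-value > ``hwe_p_min`` (all strict,
    as the thresholds are stated as "higher than"). HWE is computed on
    unphased genotype counts of complete calls. Monomorphic SNPs drop
    with reason ``maf``. Idempotent by construction.
    """
    if hwe_test not in ("exact", "chi2"):
        raise ValueError("hwe_test must be 'exact' or 'chi2'")
    hwe = hwe_exact_p if hwe_test == "exact" else hwe_chi2_p
    pat, mat = geno.pat, geno.mat
    complete = (pat != MISSING) & (mat != MISSING)
    n_animals = geno.n_animals
    call_rate = complete.sum(axis=0) / n_animals

    rows = []
    kept = np.zeros(geno.n_snps, dtype=bool)
    for j in range(geno.n_snps):
        ok = complete[:, j]
        a = pat[ok, j]
        b = mat[ok, j]
        dos = a + b
        n_bb = int((dos == 2).sum())  # ALT hom
        n_ab = int((dos == 1).sum())
        n_aa = int((dos == 0).sum())
        n = n_aa + n_ab + n_bb
        maf = 0.0
        if n:
            f_alt = (2 * n_bb + n_ab) / (2 * n)
            maf = min(f_alt, 1 - f_alt)
        hwe_p = hwe(n_aa, n_ab, n_bb) if n else 1.0
        reasons = []
        if call_rate[j] <= call_rate_min:
            reasons.append("call_rate")
        if maf <= maf_min:
            reasons.append("maf")
        if hwe_p <= hwe_p_min:
            reasons.append("hwe")
        kept[j] = not reasons
        rows.append(
            (snp_map.snp_id[j], call_rate[j], maf, hwe_p, kept[j], ",".join(reasons))
        )
    report = QcReport(
        pd.DataFrame(
            rows, columns=["snp_id", "call_rate", "maf", "hwe_p", "kept", "reason"]
        )
    )
    idx = np.flatnonzero(kept)
    return geno.subset_snps(idx), snp_map.subset(idx), report


# ---------------------------------------------------------------------------
# Trio construction


def build_trios(ped: Pedigree, geno: PhasedGenotypes) -> TrioSet:
    """Link genotyped offspring to genotyped sire + (dam | maternal grandsire).

    An offspring enters iff it and its sire are genotyped and either its
    dam is genotyped (kind SIRE_DAM — the dam carries more information,
    so she wins when both dam and MGS are genotyped) or, failing that,
    its maternal grandsire is (kind SIRE_MGS). Everything else is
    silently excluded.
    """
    genotyped = set(geno.animals)
    trios: list[Trio] = []
    for off in geno.animals:
        sire = ped.sire_of(off)
        if sire is None or sire not in genotyped:
            continue
        dam = ped.dam_of(off)
        if dam is not None and dam in genotyped:
            trios.append(Trio(off, sire, dam, TrioKind.SIRE_DAM))
            continue
        if dam is not None:
            mgs = ped.sire_of(dam)
            if mgs is not None and mgs in genotyped:
                trios.append(Trio(off, sire, mgs, TrioKind.SIRE_MGS))
    return TrioSet(trios)
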