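"""Haplotype-status / allele-dosage concordance filtering of variants.

Sequence variants inside a deficient region (padded by 1 Mb on each
side) are filtered on site quality and call rate, then ranked by the
squared Pearson correlation (r^2) between per-animal carrier status
(0/1/2 copies of the region haplotype) and allele dosage (0/1/2).
Only variants in perfect concordance (r^2 = 1, up to a 1e-9
floating-point guard) remain candidates for causality; animals breaking
the concordance are reported with the maximal run of SNPs over which
their phase still matches the carrier haplotype around the variant — the
signature of a recombinant version of the haplotype.

Functional annotation is pass-through text only; it is never computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dhh_scan import DHHRegion
from .genotype_io import PhasedGenotypes, SnpMap

__all__ = [
    "VariantRecord",
    "ConcordanceResult",
    "RecombinantSpan",
    "filter_variants",
    "status_dosage_r2",
    "recombinant_report",
]

logger = logging.getLogger(__name__)

DOSAGE_MISSING = -1
R2_ONE = 1.0 - 1e-9


@dataclass
class VariantRecord:
    """One biallelic sequence variant with per-animal allele dosages."""

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float
    dosages: np.ndarray  # int8 per animal; -1 missing
    annotation: str = ""

    @property
    def call_rate(self) -> float:
        return float((self.dosages != DOSAGE_MISSING).mean())

    @property
    def vid(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass
class ConcordanceResult:
    variant: VariantRecord
    r2: float
    n_informative: int
    computable: bool
    discordant: list[str] = field(default_factory=list)

    @property
    def candidate(self) -> bool:
        return bool(self.computable and self.r2 >= R2_ONE)


@dataclass
class RecombinantSpan:
    """Maximal carrier-haplotype match of one phase around the focal variant."""

    animal: str
    phase: int  # 0 paternal, 1 maternal
    matched_first: int | None  # global SNP indices, inclusive; None = no match
    matched_last: int | None
    contains_focal: bool


def filter_variants(
    vcf_path,
    chrom: str,
    start_bp: int,
    end_bp: int,
    *,
    pad: int = 1_000_000,
    qual_min: float = 30.0,
    callrate_min: float = 0.95,
    animals: Sequence[str] | None = None,
) -> list[VariantRecord]:
    """Stream biallelic variants inside [start-pad, end+pad] passing QC.

    Keeps variants with QUAL strictly above ``qual_min`` and call rate
    strictly above ``callrate_min``; malformed or multi-allelic records
    are skipped with a logged warning. Order-preserving and idempotent.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    if animals is not None:
        keep_idx = np.array([samples.index(a) for a in animals])
    else:
        keep_idx = np.arange(len(samples))
    lo, hi = start_bp - pad, end_bp + pad
    out: list[VariantRecord] = []
    for var in vcf:
        try:
            if str(var.CHROM) != str(chrom) or not (lo <= var.POS <= hi):
                continue
            if len(var.ALT) != 1:
                logger.warning("skipping multi-allelic record at %s:%d", var.CHROM, var.POS)
                continue
            qual = var.QUAL
            if qual is None or qual <= qual_min:
                continue
            g = np.array(var.genotypes, dtype=np.int64)[keep_idx]
            a, b = g[:, 0], g[:, 1]
            dos = np.where((a >= 0) & (b >= 0), a + b, DOSAGE_MISSING).astype(np.int8)
            rec = VariantRecord(
                chrom=str(var.CHROM), pos=int(var.POS), ref=var.REF, alt=var.ALT[0],
                qual=float(qual), dosages=dos,
                annotation=str(var.INFO.get("ANN") or ""),
            )
            if rec.call_rate <= callrate_min:
                continue
            out.append(rec)
        except Exception as exc:  # malformed record: skip, keep going
            logger.warning("skipping malformed record: %s", exc)
    return out


def status_dosage_r2(
    statuses: Sequence[int],
    variant: VariantRecord | Sequence[int],
    *,
    animals: Sequence[str] | None = None,
) -> ConcordanceResult:
    """r^2 between carrier status and allele dosage, missing excluded pairwise.

    A constant vector (after pairwise deletion) makes r^2 undefined: the
    result is flagged not-computable and is never a candidate. The
    discordant list names informative animals whose dosage differs from
    their status.
    """
    if isinstance(variant, VariantRecord):
        dos = variant.dosages
        rec = variant
    else:
        dos = np.asarray(variant, dtype=np.int8)
        rec = VariantRecord("?", 0, "N", "N", 99.0, dos)
    st = np.asarray(statuses, dtype=float)
    if len(st) != len(dos):
        raise ValueError("status and dosage vectors must cover the same animals")
    ok = dos != DOSAGE_MISSING
    n_inf = int(ok.sum())
    names = list(animals) if animals is not None else [str(i) for i in range(len(st))]
    disc = [names[i] for i in np.flatnonzero(ok & (dos != st))]
    if n_inf < 2 or np.ptp(st[ok]) == 0 or np.ptp(dos[ok].astype(float)) == 0:
        return ConcordanceResult(rec, float("nan"), n_inf, computable=False, discordant=disc)
    r = np.corrcoef(st[ok], dos[ok].astype(float))[0, 1]
    return ConcordanceResult(rec, float(r * r), n_inf, computable=True, discordant=disc)


def recombinant_report(
    geno: PhasedGenotypes,
    snp_map: SnpMap,
    region: DHHRegion,
    focal: VariantRecord,
    discordant: Sequence[str],
    *,
    pad: int = 1_000_000,
) -> list[RecombinantSpan]:
    """Locate the carrier-haplotype match span around the focal variant.

    For each discordant animal and each phase, reports the maximal run
    of consecutive region SNPs matching the carrier haplotype that
    contains the focal position (the two markers bracketing it), or the
    longest abutting run on either side when the variant falls outside
    every matching run. ``contains_focal`` is True when the span covers
    both bracketing markers.
    """
    lo_bp = int(snp_map.pos[region.first]) - pad
    hi_bp = int(snp_map.pos[region.last]) + pad
    if str(focal.chrom) != str(region.chrom) or not (lo_bp <= focal.pos <= hi_bp):
        raise ValueError("focal variant lies outside the padded region")
    sl = slice(region.first, region.last + 1)
    pos = snp_map.pos[sl]
    # bracketing markers of the focal position, clipped to the region
    j_right = int(np.searchsorted(pos, focal.pos, side="left"))
    j_right = min(j_right, len(pos) - 1)
    j_left = max(j_right - 1, 0) if focal.pos < pos[j_right] else j_right
    idx = geno.index_of(discordant)
    out: list[RecombinantSpan] = []
    for ai, animal in zip(idx, discordant):
        for phase, matrix in ((0, geno.pat), (1, geno.mat)):
            match = matrix[ai, sl] == region.carrier_codes
            first, last = _run_around(match, j_left, j_right)
            contains = first is not None and first <= j_left and last >= j_right
            out.append(
                RecombinantSpan(
                    animal=animal,
                    phase=phase,
                    matched_first=None if first is None else region.first + first,
                    matched_last=None if last is None else region.first + last,
                    contains_focal=bool(contains),
                )
            )
    return out


def _run_around(match: np.ndarray, j_left: int, j_right: int):
    """Maximal True-run containing (or nearest to) the focal bracket."""
    if not match.any():
        return None, None
    runs = []
    start = None
    for i, m in enumerate(match):
        if m and start is None:
            start = i
        if not m and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(match) - 1))
    # prefer a run overlapping the bracket; otherwise the nearest one
    overlapping = [r for r in runs if r[0] <= j_right and r[1] >= j_left]
    if overlapping:
        return max(overlapping, key=lambda r: r[1] - r[0])
    return min(runs, key=lambda r: min(abs(r[0] - j_right), abs(r[1] - j_left)))
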