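"""Core missing-homozygote screen.

The genome is scanned with a sliding window of ``window_size`` SNPs
(default 20, step 1). Within each window, every haplotype with maternal-
phase frequency above ``freq_min`` (default 1%) is tested: the observed
number of trio offspring homozygous for the haplotype, ``n_obs``, is
compared to the expectation under Mendelian transmission,

    n_exp = sum over trios of P(sire transmits k) * P(dam transmits k),

with a lower-tail Poisson test P(X <= n_obs), X ~ Poisson(n_exp).
Haplotypes with p below ``p_max`` (default 1.9e-4) and a homozygote
deficit (n_exp - n_obs)/n_exp within [0.75, 1.0] are significant.
Consecutive, allele-consistent significant windows are clustered into
DHH regions, per-animal carrier statuses (0/1/2 copies) are assigned by
exact haplotype match, and linkage disequilibrium between regions is the
squared Pearson correlation of status vectors.

Transmission probability for an offspring whose dam is not genotyped but
whose maternal grandsire (MGS) is:

    P(dam transmits k) = 0.5 * (copies_MGS(k)/2 + g * f_k)

where f_k is the maternal-phase population frequency of k. The default
mode ``frequency-augmented`` (g = 1) credits the ungenotyped granddam
with a population-frequency chance of carrying k; ``conservative``
(g = 0) bounds her contribution at zero, which halves n_exp in
MGS-dominated pedigrees and with it the power of the screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .genotype_io import MISSING, PhasedGenotypes, SnpMap, Trio, TrioKind, TrioSet

__all__ = [
    "Window",
    "WindowResult",
    "DHHRegion",
    "ScanResult",
    "enumerate_windows",
    "maternal_haplotype_frequencies",
    "transmission_prob",
    "count_homozygotes",
    "poisson_deficit_test",
    "deficit",
    "scan",
    "cluster_regions",
    "assign_status",
    "region_ld_r2",
]

logger = logging.getLogger(__name__)

MODES = ("conservative", "frequency-augmented")
DEFAULT_MODE = "frequency-augmented"


@dataclass(frozen=True)
class Window:
    """A run of ``size`` consecutive SNPs on one chromosome.

    ``start``/``end`` are 0-based inclusive indices into the full SNP map.
    """

    chrom: str
    start: int
    end: int

    @property
    def size(self) -> int:
        return self.end - self.start + 1


@dataclass
class WindowResult:
    """One tested (window, haplotype) pair."""

    chrom: str
    start: int
    end: int
    alleles: str  # haplotype allele letters over the window
    codes: np.ndarray  # 0/1 allele codes over the window
    freq_maternal: float
    n_obs: int
    n_exp: float
    p_poisson: float

    @property
    def deficit(self) -> float | None:
        if self.n_exp <= 0:
            return None
        return (self.n_exp - self.n_obs) / self.n_exp


@dataclass
class DHHRegion:
    """Clustered deficient region with its consensus carrier haplotype."""

    region_id: str
    chrom: str
    first: int  # global SNP index, inclusive
    last: int
    carrier_codes: np.ndarray  # 0/1 codes, length last-first+1
    carrier_haplotype: str  # allele letters
    member_windows: list[WindowResult]
    n_obs: int
    n_exp: float
    p_poisson: float

    @property
    def deficit(self) -> float:
        return (self.n_exp - self.n_obs) / self.n_exp


@dataclass
class ScanResult:
    results: list[WindowResult]
    significant: list[WindowResult]
    n_windows: int
    n_tested: int
    params: dict

    def to_frame(self, snp_map: SnpMap) -> pd.DataFrame:
        sig = {id(w) for w in self.significant}
        rows = []
        for w in self.results:
            rows.append(
                {
                    "chrom": w.chrom,
                    "start_snp": w.start,
                    "end_snp": w.end,
                    "start_bp": int(snp_map.pos[w.start]),
                    "end_bp": int(snp_map.pos[w.end]),
                    "haplotype": w.alleles,
                    "freq_maternal": w.freq_maternal,
                    "n_obs": w.n_obs,
                    "n_exp": w.n_exp,
                    "p_poisson": w.p_poisson,
                    "deficit": w.deficit,
                    "significant": id(w) in sig,
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Elementary statistics


def poisson_deficit_test(n_obs: int, n_exp: float) -> float:
    """Lower-tail Poisson probability P(X <= n_obs) for X ~ Poisson(n_exp).

    Summed in log space for numerical stability; P(X <= 0) = e^{-lambda}
    exactly. ``poisson_deficit_test(0, 0) == 1``.
    """
    if n_obs < 0 or n_exp < 0:
        raise ValueError("n_obs and n_exp must be non-negative")
    if n_exp == 0:
        return 1.0
    i = np.arange(0, int(n_obs) + 1)
    log_terms = i * np.log(n_exp) - n_exp - gammaln(i + 1)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def deficit(n_obs: int, n_exp: float) -> float:
    """Homozygote deficit (n_exp - n_obs)/n_exp; negative means excess."""
    if n_exp <= 0:
        raise ValueError("deficit undefined for n_exp <= 0")
    return (n_exp - n_obs) / n_exp


def transmission_prob(
    parent_phases: tuple[str, str],
    k: str,
    *,
    kind: TrioKind | str = TrioKind.SIRE_DAM,
    f_k: float = 0.0,
    mode: str = DEFAULT_MODE,
) -> float:
    """Probability that the (possibly partly inferred) parent transmits k.

    For a genotyped parent: copies(k)/2. For an ungenotyped dam with a
    genotyped MGS (``kind=SIRE_MGS``): 0.5*(copies_MGS(k)/2 + g*f_k)
    with g per ``mode``.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if not 0.0 <= f_k <= 1.0:
        raise ValueError("f_k must lie in [0, 1]")
    copies = sum(1 for ph in parent_phases if ph == k)
    kind = TrioKind(kind)
    if kind == TrioKind.SIRE_DAM:
        return copies / 2.0
    g = 1.0 if mode == "frequency-augmented" else 0.0
    return 0.5 * (copies / 2.0 + g * f_k)


# ---------------------------------------------------------------------------
# Windows and haplotype frequencies


def enumerate_windows(snp_map: SnpMap, window_size: int = 20, step: int = 1) -> list[Window]:
    """Dense sliding windows per chromosome at offsets 0, step, 2*step, ..."""
    if window_size < 1 or step < 1:
        raise ValueError("window_size and step must be positive")
    windows: list[Window] = []
    for chrom, (lo, hi) in snp_map.chrom_slices().items():
        n = hi - lo
        if n < window_size:
            logger.info("chromosome %s has %d SNPs < window size %d; skipped", chrom, n, window_size)
            continue
        for off in range(0, n - window_size + 1, step):
            windows.append(Window(chrom, lo + off, lo + off + window_size - 1))
    return windows


def _phase_codes(geno: PhasedGenotypes, w: Window) -> tuple[np.ndarray, np.ndarray, int]:
    """Integer-encode every phase's haplotype over a window.

    Returns (codes_pat, codes_mat, n_distinct); haplotypes sharing a code
    are identical allele strings. Requires complete biallelic genotypes.
    """
    sl = slice(w.start, w.end + 1)
    pat = geno.pat[:, sl]
    mat = geno.mat[:, sl]
    if (pat == MISSING).any() or (mat == MISSING).any():
        raise ValueError("scan requires complete (imputed) genotypes")
    size = w.end - w.start + 1
    if size <= 62:
        weights = (1 << np.arange(size, dtype=np.uint64))
        raw_p = (pat.astype(np.uint64) * weights).sum(axis=1)
        raw_m = (mat.astype(np.uint64) * weights).sum(axis=1)
    else:  # fall back to row hashing for very wide windows
        both = np.ascontiguousarray(np.vstack([pat, mat]))
        void = both.view([("", both.dtype)] * both.shape[1]).ravel()
        _, inv = np.unique(void, return_inverse=True)
        raw_p, raw_m = inv[: len(pat)], inv[len(pat):]
    uniq, inv = np.unique(np.concatenate([raw_p, raw_m]), return_inverse=True)
    return inv[: len(raw_p)], inv[len(raw_p):], len(uniq)


def _decode_haplotype(geno: PhasedGenotypes, w: Window, codes_pat, codes_mat, code: int) -> np.ndarray:
    """Recover the 0/1 allele vector of a coded haplotype from any carrier."""
    sl = slice(w.start, w.end + 1)
    rows = np.flatnonzero(codes_pat == code)
    if len(rows):
        return geno.pat[rows[0], sl].copy()
    rows = np.flatnonzero(codes_mat == code)
    return geno.mat[rows[0], sl].copy()


def _allele_string(snp_map: SnpMap, start: int, codes: np.ndarray) -> str:
    letters = []
    for off, c in enumerate(codes):
        j = start + off
        letters.append(str(snp_map.alt[j]) if c else str(snp_map.ref[j]))
    return "".join(letters)


def maternal_haplotype_frequencies(geno: PhasedGenotypes, w: Window,
                                   snp_map: SnpMap | None = None) -> dict[str, float]:
    """Frequency of each distinct maternal-phase haplotype in a window.

    Keys are allele strings (letters when a map is given, else '0'/'1'
    codes); values sum to 1 over the window.
    """
    codes_pat, codes_mat, _ = _phase_codes(geno, w)
    counts = np.bincount(codes_mat)
    n = len(codes_mat)
    out: dict[str, float] = {}
    for code in np.flatnonzero(counts):
        vec = _decode_haplotype(geno, w, codes_pat, codes_mat, code)
        key = (_allele_string(snp_map, w.start, vec) if snp_map is not None
               else "".join(map(str, vec)))
        out[key] = counts[code] / n
    return out


# ---------------------------------------------------------------------------
# Expected/observed homozygotes


def _trio_arrays(trios: TrioSet, geno: PhasedGenotypes):
    off = geno.index_of([t.offspring for t in trios])
    sire = geno.index_of([t.sire for t in trios])
    dam = geno.index_of([t.dam_or_mgs for t in trios])
    is_mgs = np.array([t.kind == TrioKind.SIRE_MGS for t in trios], dtype=bool)
    return off, sire, dam, is_mgs


def count_homozygotes(
    trios: TrioSet,
    geno: PhasedGenotypes,
    w: Window,
    k: str,
    *,
    f_k: float | None = None,
    mode: str = DEFAULT_MODE,
    snp_map: SnpMap | None = None,
) -> tuple[int, float]:
    """Observed and expected counts of offspring homozygous for haplotype k.

    ``k`` is an allele string over the window (letters if a map is given,
    else '0'/'1' codes). ``f_k`` defaults to the maternal-phase frequency
    computed from ``geno``.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    codes_pat, codes_mat, _ = _phase_codes(geno, w)
    sl = slice(w.start, w.end + 1)

    def string_of(vec: np.ndarray) -> str:
        return (_allele_string(snp_map, w.start, vec) if snp_map is not None
                else "".join(map(str, vec)))

    # find the code whose allele string equals k
    target = None
    for code in range(codes_pat.max(initial=0) + codes_mat.max(initial=0) + 1):
        rows = np.flatnonzero(codes_pat == code)
        vec = (geno.pat[rows[0], sl] if len(rows)
               else geno.mat[np.flatnonzero(codes_mat == code)[0], sl])
        if string_of(vec) == k:
            target = code
            break
    if target is None:
        return 0, 0.0
    if f_k is None:
        f_k = float((codes_mat == target).sum() / len(codes_mat))
    off, sire, dam, is_mgs = _trio_arrays(trios, geno)
    n_obs, n_exp = _count_homozygotes_coded(
        codes_pat, codes_mat, target, f_k, off, sire, dam, is_mgs, mode
    )
    return n_obs, n_exp


def _count_homozygotes_coded(codes_pat, codes_mat, k, f_k, off, sire, dam, is_mgs, mode):
    g = 1.0 if mode == "frequency-augmented" else 0.0
    cs = (codes_pat[sire] == k).astype(np.float64) + (codes_mat[sire] == k)
    cd = (codes_pat[dam] == k).astype(np.float64) + (codes_mat[dam] == k)
    p_s = cs / 2.0
    p_d = np.where(is_mgs, 0.5 * (cd / 2.0 + g * f_k), cd / 2.0)
    n_exp = float((p_s * p_d).sum())
    n_obs = int(((codes_pat[off] == k) & (codes_mat[off] == k)).sum())
    return n_obs, n_exp


# ---------------------------------------------------------------------------
# The scan


def scan(
    geno: PhasedGenotypes,
    trios: TrioSet,
    snp_map: SnpMap,
    *,
    window_size: int = 20,
    step: int = 1,
    freq_min: float = 0.01,
    p_max: float = 1.9e-4,
    deficit_range: tuple[float, float] = (0.75, 1.0),
    mode: str = DEFAULT_MODE,
    keep_all: bool = True,
) -> ScanResult:
    """Run the sliding-window homozygote-deficiency screen.

    Emits a :class:`WindowResult` for every (window, haplotype) pair with
    maternal frequency strictly above ``freq_min``; pairs with Poisson p
    strictly below ``p_max`` and deficit within ``deficit_range``
    (inclusive) are flagged significant. Iteration order (chromosome in
    map order, start index, haplotype string) is deterministic.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    lo_def, hi_def = deficit_range
    off, sire, dam, is_mgs = _trio_arrays(trios, geno)
    windows = enumerate_windows(snp_map, window_size, step)
    all_results: list[WindowResult] = []
    significant: list[WindowResult] = []
    n_tested = 0
    for w in windows:
        codes_pat, codes_mat, n_codes = _phase_codes(geno, w)
        counts = np.bincount(codes_mat, minlength=n_codes)
        freqs = counts / len(codes_mat)
        cand = np.flatnonzero(freqs > freq_min)
        decoded = []
        for code in cand:
            vec = _decode_haplotype(geno, w, codes_pat, codes_mat, code)
            decoded.append((_allele_string(snp_map, w.start, vec), code, vec))
        decoded.sort()  # lexicographic haplotype order within window
        for alleles, code, vec in decoded:
            f_k = float(freqs[code])
            n_obs, n_exp = _count_homozygotes_coded(
                codes_pat, codes_mat, code, f_k, off, sire, dam, is_mgs, mode
            )
            p = poisson_deficit_test(n_obs, n_exp)
            res = WindowResult(
                chrom=w.chrom, start=w.start, end=w.end, alleles=alleles,
                codes=vec, freq_maternal=f_k, n_obs=n_obs, n_exp=n_exp, p_poisson=p,
            )
            n_tested += 1
            d = res.deficit
            is_sig = p < p_max and d is not None and lo_def <= d <= hi_def
            if is_sig:
                significant.append(res)
            if keep_all or is_sig:
                all_results.append(res)
    return ScanResult(
        results=all_results,
        significant=significant,
        n_windows=len(windows),
        n_tested=n_tested,
        params=dict(
            window_size=window_size, step=step, freq_min=freq_min,
            p_max=p_max, deficit_range=list(deficit_range), mode=mode,
        ),
    )


def bonferroni_p_max(n_tested: int, alpha: float = 0.05) -> float:
    """Alternative significance threshold alpha / number of tested haplotypes."""
    if n_tested < 1:
        raise ValueError("n_tested must be positive")
    return alpha / n_tested


# ---------------------------------------------------------------------------
# Clustering, status, LD


def cluster_regions(sig: Sequence[WindowResult], snp_map: SnpMap) -> list[DHHRegion]:
    """Merge significant windows into regions.

    Two windows join the same region iff their SNP spans overlap or abut
    and their haplotype alleles agree on every shared SNP; the region's
    carrier haplotype is the union of member alleles and its statistics
    come from the member window with minimum p (ties: smallest start).
    The result is invariant to the input order (windows are sorted
    internally).
    """
    ordered = sorted(sig, key=lambda r: (str(r.chrom), r.start, r.alleles))
    regions: list[dict] = []
    open_regions: list[dict] = []
    for wres in ordered:
        placed = False
        still_open = []
        for reg in open_regions:
            if reg["chrom"] != str(wres.chrom) or reg["last"] + 1 < wres.start:
                regions.append(reg)  # closed: no later window can touch it
                continue
            still_open.append(reg)
        open_regions = still_open
        for reg in open_regions:
            consensus = reg["alleles"]
            shared = range(max(wres.start, reg["first"]), min(wres.end, reg["last"]) + 1)
            if all(consensus.get(j, wres.codes[j - wres.start]) == wres.codes[j - wres.start]
                   for j in shared):
                for off, c in enumerate(wres.codes):
                    consensus[wres.start + off] = int(c)
                reg["first"] = min(reg["first"], wres.start)
                reg["last"] = max(reg["last"], wres.end)
                reg["members"].append(wres)
                placed = True
                break
        if not placed:
            open_regions.append(
                {
                    "chrom": str(wres.chrom),
                    "first": wres.start,
                    "last": wres.end,
                    "alleles": {wres.start + off: int(c) for off, c in enumerate(wres.codes)},
                    "members": [wres],
                }
            )
    regions.extend(open_regions)
    regions.sort(key=lambda r: (r["chrom"], r["first"], r["last"]))
    out: list[DHHRegion] = []
    for i, reg in enumerate(regions, start=1):
        first, last = reg["first"], reg["last"]
        codes = np.array([reg["alleles"][j] for j in range(first, last + 1)], dtype=np.int8)
        best = min(reg["members"], key=lambda m: (m.p_poisson, m.start))
        out.append(
            DHHRegion(
                region_id=f"DHH{i}",
                chrom=reg["chrom"],
                first=first,
                last=last,
                carrier_codes=codes,
                carrier_haplotype=_allele_string(snp_map, first, codes),
                member_windows=sorted(reg["members"], key=lambda m: (m.start, m.alleles)),
                n_obs=best.n_obs,
                n_exp=best.n_exp,
                p_poisson=best.p_poisson,
            )
        )
    return out


def assign_status(geno: PhasedGenotypes, region: DHHRegion) -> pd.DataFrame:
    """Carrier status (0/1/2) of every animal for a region.

    Status counts the animal's phases that match the carrier haplotype
    exactly over the whole region span; a phase differing at even one SNP
    (a recombinant) does not count.
    """
    sl = slice(region.first, region.last + 1)
    cons = region.carrier_codes
    hit_p = (geno.pat[:, sl] == cons).all(axis=1)
    hit_m = (geno.mat[:, sl] == cons).all(axis=1)
    status = hit_p.astype(np.int8) + hit_m.astype(np.int8)
    return pd.DataFrame(
        {"animal": geno.animals, "region": region.region_id, "status": status}
    )


def region_ld_r2(status_a: Sequence[int], status_b: Sequence[int]) -> float:
    """Squared Pearson correlation of two carrier-status vectors.

    Returns NaN (flagged not-computable) when either vector is constant.
    """
    a = np.asarray(status_a, dtype=float)
    b = np.asarray(status_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("status vectors must cover the same animals")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def regions_to_frame(regions: Sequence[DHHRegion], snp_map: SnpMap,
                     statuses: dict[str, pd.DataFrame] | None = None) -> pd.DataFrame:
    """Tabular region summary (Table-2 style), one row per region."""
    rows = []
    for reg in regions:
        row = {
            "region": reg.region_id,
            "chrom": reg.chrom,
            "n_markers": reg.last - reg.first + 1,
            "start_bp": int(snp_map.pos[reg.first]),
            "end_bp": int(snp_map.pos[reg.last]),
            "n_exp": reg.n_exp,
            "n_obs": reg.n_obs,
            "deficit_pct": 100.0 * reg.deficit,
            "p_poisson": reg.p_poisson,
            "carrier_haplotype": reg.carrier_haplotype,
        }
        if statuses is not None and reg.region_id in statuses:
            st = statuses[reg.region_id]["status"]
            row["het_carrier_freq_pct"] = 100.0 * float((st == 1).mean())
        rows.append(row)
    return pd.DataFrame(rows)


def regions_to_bed(regions: Sequence[DHHRegion], snp_map: SnpMap) -> str:
    """BED (0-based half-open bp spans of first/last SNP) text for regions."""
    lines = []
    for reg in regions:
        lines.append(
            f"{reg.chrom}\t{int(snp_map.pos[reg.first]) - 1}\t{int(snp_map.pos[reg.last])}\t{reg.region_id}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
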