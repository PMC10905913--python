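"""At-risk-mating classification, fertility outcome coding and trait tests.

A mating between a carrier ram and a ewe born to a carrier sire is
*at-risk*: it is the only mating class that can produce haplotype
homozygotes when ewes themselves are not genotyped. Fertility outcomes:

* AIS (artificial-insemination success): 1 iff a lambing is recorded
  within the gestation window (151 +/- 7 days, inclusive) of the AI date.
* SBR (stillbirth rate): defined only for successful inseminations; 1
  iff at least one lamb in the litter is dead at birth or within 24 h.

AIS and SBR are compared between mating classes with a logit-link
binomial model (fixed effects: mating type, AI season, lactation number,
prolificacy for SBR, herd x year blocks); the reported effect is the
difference of population-averaged predicted probabilities (marginal
standardization), an lsmeans-style estimate. Sire trait deviations
(sDYD) are compared carrier vs non-carrier by OLS with a birth-year
effect, selection indexes by a Wilcoxon rank-sum test, and contingency
tables by an exact Fisher-Freeman-Halton test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import mannwhitneyu

import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "AssocResult",
    "classify_mating",
    "code_outcomes",
    "code_outcome_frame",
    "fit_binary_trait",
    "sdyd_compare",
    "wilcoxon_index",
    "fisher_exact_rxc",
]

logger = logging.getLogger(__name__)

AT_RISK = "at_risk"
SAFE = "safe"


@dataclass
class AssocResult:
    """Effect of carrier status / mating class on one trait."""

    target: str
    trait: str
    effect: float | None  # at_risk - safe (probability scale) or carrier - non-carrier
    p: float | None
    n_per_class: dict[str, int]
    estimable: bool = True
    alpha: float = 0.05
    n_tests: int = 5

    @property
    def significant(self) -> bool:
        return bool(self.estimable and self.p is not None and self.p < self.alpha / self.n_tests)


def classify_mating(ram_status: int, ewe_sire_status: int) -> str:
    """'at_risk' iff both the ram and the ewe's sire carry >= 1 copy."""
    for s in (ram_status, ewe_sire_status):
        if s not in (0, 1, 2):
            raise ValueError("status must be 0, 1 or 2; exclude unknown records upstream")
    return AT_RISK if ram_status >= 1 and ewe_sire_status >= 1 else SAFE


def code_outcomes(
    ai_date: date,
    lambing_date: date | None,
    n_lambs: int,
    n_dead_24h: int,
    *,
    gestation_days: int = 151,
    tolerance_days: int = 7,
) -> tuple[int, int | None]:
    """Code one mating record as (AIS, SBR).

    AIS = 1 iff a lambing date exists and lambing - AI lies within
    [gestation - tolerance, gestation + tolerance] days, bounds
    inclusive. SBR is defined only when AIS = 1 (else None): 1 iff any
    lamb of the litter was stillborn or died within 24 h.
    """
    if lambing_date is None:
        return 0, None
    gap = (lambing_date - ai_date).days
    if gap < 0:
        raise ValueError("lambing date precedes AI date")
    if not (gestation_days - tolerance_days <= gap <= gestation_days + tolerance_days):
        return 0, None
    return 1, int(n_dead_24h > 0)


def code_outcome_frame(matings: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Apply :func:`code_outcomes` to a matings table.

    Expects columns ``ai_date``, ``lambing_date`` (ISO strings or dates;
    empty = no lambing), ``n_lambs``, ``n_dead24h``. Returns a copy with
    ``ais`` and ``sbr`` columns (``sbr`` is NaN where undefined).
    """
    out = matings.copy()
    ais, sbr = [], []
    for _, r in out.iterrows():
        ld = r["lambing_date"]
        if pd.isna(ld) or ld in ("", None):
            ld = None
        else:
            ld = pd.Timestamp(ld).date()
        a, s = code_outcomes(
            pd.Timestamp(r["ai_date"]).date(), ld, int(r["n_lambs"]), int(r["n_dead24h"]),
            **kwargs,
        )
        ais.append(a)
        sbr.append(np.nan if s is None else s)
    out["ais"] = ais
    out["sbr"] = sbr
    return out


def _marginal_means(fit, df: pd.DataFrame, class_col: str) -> dict[str, float]:
    """Population-averaged predicted probability per class (lsmeans-style)."""
    means = {}
    for level in sorted(df[class_col].unique()):
        forced = df.copy()
        forced[class_col] = level
        means[level] = float(fit.predict(forced).mean())
    return means


def fit_binary_trait(
    records: pd.DataFrame,
    trait: str,
    *,
    class_col: str = "mating_type",
    alpha: float = 0.05,
    n_tests: int = 5,
) -> AssocResult:
    """Logit-link binomial comparison of a 0/1 trait across mating classes.

    ``records`` must hold the outcome column (``ais`` or ``sbr``), the
    mating class, and covariates ``season``, ``lactation``, ``herd``,
    ``year`` (+ ``prolificacy`` when trait='sbr'). Herd x year enters as
    fixed-effect blocks. Complete separation within a class (all-0 or
    all-1 outcomes) makes the effect non-estimable and is flagged rather
    than fitted.
    """
    trait = trait.lower()
    if trait not in ("ais", "sbr"):
        raise ValueError("trait must be 'ais' or 'sbr'")
    df = records.dropna(subset=[trait]).copy()
    df[trait] = df[trait].astype(int)
    classes = sorted(df[class_col].unique())
    n_per_class = {c: int((df[class_col] == c).sum()) for c in classes}
    if len(classes) < 2:
        return AssocResult(class_col, trait, None, None, n_per_class,
                           estimable=False, alpha=alpha, n_tests=n_tests)
    for c in classes:
        sub = df.loc[df[class_col] == c, trait]
        if sub.nunique() < 2:
            logger.warning("class %r shows complete separation on %s", c, trait)
            return AssocResult(class_col, trait, None, None, n_per_class,
                               estimable=False, alpha=alpha, n_tests=n_tests)
    df["herd_year"] = df["herd"].astype(str) + ":" + df["year"].astype(str)
    terms = [f"C({class_col}, Treatment('{SAFE}'))", "C(season)", "C(lactation)", "C(herd_year)"]
    if trait == "sbr" and "prolificacy" in df.columns:
        terms.insert(3, "C(prolificacy)")
    formula = f"{trait} ~ " + " + ".join(terms)
    fit = smf.glm(formula, data=df, family=sm.families.Binomial()).fit()
    coef_name = f"C({class_col}, Treatment('{SAFE}'))[T.{AT_RISK}]"
    p = float(fit.pvalues[coef_name]) if coef_name in fit.pvalues.index else None
    means = _marginal_means(fit, df, class_col)
    effect = means.get(AT_RISK, math.nan) - means.get(SAFE, math.nan)
    return AssocResult(class_col, trait, effect, p, n_per_class,
                       estimable=True, alpha=alpha, n_tests=n_tests)


def sdyd_compare(
    traits: pd.DataFrame,
    statuses: pd.DataFrame,
    *,
    min_daughters: int = 20,
    alpha: float = 0.05,
    n_tests: int = 5,
) -> list[AssocResult]:
    """Compare standardized daughter yield deviations carrier vs non-carrier.

    ``traits`` columns: sire, trait, dyd, genetic_sd, n_daughters,
    birth_year; ``statuses``: animal, region, status. Rams with fewer
    than ``min_daughters`` daughters are excluded; the linear model is
    sdyd ~ carrier + C(birth_year) per trait (the year term is dropped,
    with a log message, when only one birth-year level remains).
    """
    st = dict(zip(statuses["animal"], statuses["status"]))
    region = statuses["region"].iloc[0] if len(statuses) else "region"
    df = traits[traits["n_daughters"] >= min_daughters].copy()
    df["status"] = df["sire"].map(st)
    df = df.dropna(subset=["status"])
    df["carrier"] = (df["status"] >= 1).astype(int)
    df["sdyd"] = df["dyd"] / df["genetic_sd"]
    out: list[AssocResult] = []
    for trait in sorted(df["trait"].unique()):
        sub = df[df["trait"] == trait]
        n_per_class = {
            "carrier": int(sub["carrier"].sum()),
            "non_carrier": int((1 - sub["carrier"]).sum()),
        }
        if min(n_per_class.values()) == 0:
            out.append(AssocResult(region, trait, None, None, n_per_class,
                                   estimable=False, alpha=alpha, n_tests=n_tests))
            continue
        if sub["birth_year"].nunique() >= 2:
            formula = "sdyd ~ carrier + C(birth_year)"
        else:
            logger.info("single birth-year level for %s: year term dropped", trait)
            formula = "sdyd ~ carrier"
        fit = smf.ols(formula, data=sub).fit()
        out.append(
            AssocResult(region, trait, float(fit.params["carrier"]),
                        float(fit.pvalues["carrier"]), n_per_class,
                        estimable=True, alpha=alpha, n_tests=n_tests)
        )
    return out


def wilcoxon_index(values_carrier: Sequence[float], values_noncarrier: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p for an index in carriers vs non-carriers.

    Exact for small tie-free samples, normal approximation with tie
    correction otherwise.
    """
    x = np.asarray(values_carrier, dtype=float)
    y = np.asarray(values_noncarrier, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    return float(mannwhitneyu(x, y, alternative="two-sided", method="auto").pvalue)


# ---------------------------------------------------------------------------
# Exact contingency-table test


def _enumerate_tables(row_margins, col_margins):
    """Yield all non-negative integer tables with the given margins."""
    r, c = len(row_margins), len(col_margins)
    table = np.zeros((r, c), dtype=np.int64)
    col_rem = np.array(col_margins, dtype=np.int64)

    def fill_row(i):
        if i == r - 1:
            table[i] = col_rem
            yield table
            return
        def fill_cell(j, remaining):
            if j == c - 1:
                if remaining <= col_rem[j]:
                    table[i, j] = remaining
                    col_rem[j] -= remaining
                    yield from fill_row(i + 1)
                    col_rem[j] += remaining
                return
            # leave enough for later cells: remaining - x <= sum(col_rem[j+1:])
            tail = int(col_rem[j + 1:].sum())
            lo = max(0, remaining - tail)
            hi = min(int(col_rem[j]), remaining)
            for x in range(lo, hi + 1):
                table[i, j] = x
                col_rem[j] -= x
                yield from fill_cell(j + 1, remaining - x)
                col_rem[j] += x
        yield from fill_cell(0, int(row_margins[i]))

    yield from fill_row(0)


def _n_candidate_tables(row_margins, col_margins) -> float:
    """Cheap upper bound on the number of margin-consistent tables."""
    bound = 1.0
    for ri in row_margins[:-1]:
        for cj in col_margins[:-1]:
            bound *= min(ri, cj) + 1
    return bound


def fisher_exact_rxc(
    table,
    *,
    max_enumeration: float = 1e7,
    n_mc: int = 200_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Exact Fisher-Freeman-Halton two-sided p-value for an r x c table.

    Sums the hypergeometric probability of every table with the observed
    margins whose probability does not exceed the observed table's
    (relative tie tolerance 1e-7). Falls back to Monte-Carlo sampling of
    margin-fixed tables (with a logged flag) when the enumeration bound
    exceeds ``max_enumeration``. Zero-margin rows/columns are dropped
    before testing. On 2 x 2 tables this equals the classical two-sided
    Fisher exact test.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or (t < 0).any():
        raise ValueError("table must be a 2-D array of non-negative counts")
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        return 1.0
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    n = int(t.sum())
    log_const = gammaln(rows + 1).sum() + gammaln(cols + 1).sum() - gammaln(n + 1)

    def log_prob(tab) -> float:
        return float(log_const - gammaln(np.asarray(tab) + 1).sum())

    lp_obs = log_prob(t)
    cutoff = lp_obs + math.log1p(1e-7)
    if _n_candidate_tables(rows, cols) <= max_enumeration:
        total = 0.0
        for tab in _enumerate_tables(rows, cols):
            lp = log_prob(tab)
            if lp <= cutoff:
                total += math.exp(lp)
        return min(1.0, total)
    logger.warning("table too large for enumeration; Monte-Carlo p with %d samples", n_mc)
    rng = rng or np.random.default_rng(0)
    from scipy.stats import random_table

    samples = random_table(rows, cols).rvs(n_mc, method="patefield", random_state=rng)
    lps = log_const - gammaln(samples + 1).sum(axis=(1, 2))
    hits = int((lps <= cutoff).sum())
    return (hits + 1) / (n_mc + 1)
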