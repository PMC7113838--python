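"""Carrier counting and 2x2 case-control statistics.

Implements the burden-style contrasts reported for a gene-based dominant
model: carrier contingency tables, the cross-product odds ratio with a Wald
confidence interval and p-value, the equivalent single-predictor logistic
fit, the continuity-adjusted (Yates) chi-square, the two-sided Fisher exact
test, and 1-decimal frequency reporting. Zero cells make the odds ratio
not estimable ("NE") unless the Haldane-Anscombe +0.5 correction is
explicitly requested.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .discover import FilterCriteria, qualifying_mask
from .synth import SyntheticCohort

__all__ = [
    "ContingencyTable",
    "AssociationResult",
    "carrier_table",
    "odds_ratio_wald",
    "logistic_single_predictor",
    "yates_chi2",
    "fisher_exact",
    "frequency_report",
    "round_half_up",
]

Z_975 = 1.959964  # normal 97.5% quantile at the precision used for CIs


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (reporting convention for printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 carrier table: a/b exposed/unexposed cases, c/d likewise controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not float(v).is_integer() or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    def transposed_exposure(self) -> "ContingencyTable":
        return ContingencyTable(self.b, self.a, self.d, self.c)


@dataclass(frozen=True)
class AssociationResult:
    or_estimate: float | None
    ci_low: float | None
    ci_high: float | None
    p_value: float | None
    method: str
    estimable: bool

    def formatted(self, ndigits: int = 1) -> str:
        """Table-style 'OR (low-high)' string, or 'NE' when not estimable."""
        if not self.estimable:
            return "NE"
        return (
            f"{round_half_up(self.or_estimate, ndigits)} "
            f"({round_half_up(self.ci_low, ndigits)}-{round_half_up(self.ci_high, ndigits)})"
        )


def carrier_table(
    cohort: SyntheticCohort,
    gene: str | None = None,
    site_id: str | None = None,
    grouping: str = "group",
    group_pair: tuple[str, str] = ("case", "control"),
    criteria: FilterCriteria | None = None,
) -> ContingencyTable:
    """Distinct-carrier 2x2 table for a gene (or a single site).

    A subject is a carrier when heterozygous at >= 1 qualifying site of the
    gene; carriers are counted once per gene regardless of how many variants
    they hold. ``grouping`` names any binary column of the subject table
    (e.g. ``group`` for case/control, or an age-class column).
    """
    if (gene is None) == (site_id is None):
        raise ValueError("specify exactly one of gene or site_id")
    variants = cohort.variants
    if gene is not None:
        sel = variants["gene"] == gene
        if not sel.any():
            raise KeyError(f"unknown gene {gene!r}")
    else:
        sel = variants["site_id"] == site_id
        if not sel.any():
            raise KeyError(f"unknown site {site_id!r}")
    sub = variants.loc[sel]
    mask = qualifying_mask(sub, criteria or FilterCriteria())
    qual_ids = set(sub.loc[mask, "site_id"])
    order = {sid: j for j, sid in enumerate(cohort.genotypes.site_ids)}
    cols = np.array(sorted(order[s] for s in qual_ids), dtype=int)

    subjects = cohort.subjects
    counts = {}
    for label in group_pair:
        ids = subjects.loc[subjects[grouping] == label, "subject_id"].tolist()
        rows = np.array([cohort.genotypes.subject_index(s) for s in ids], dtype=int)
        if cols.size and rows.size:
            carriers = int(
                np.sum((cohort.genotypes.values[np.ix_(rows, cols)] == 1).any(axis=1))
            )
        else:
            carriers = 0
        counts[label] = (carriers, len(ids) - carriers)
    (a, b), (c, d) = counts[group_pair[0]], counts[group_pair[1]]
    return ContingencyTable(a, b, c, d)


def odds_ratio_wald(
    table: ContingencyTable, alpha: float = 0.05, haldane: bool = False
) -> AssociationResult:
    """Cross-product odds ratio ad/bc with Wald CI and two-sided p.

    A zero cell yields a not-estimable result (printed "NE") unless
    ``haldane`` adds 0.5 to every cell.
    """
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    if haldane and min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        method = "wald_haldane"
    else:
        method = "wald"
    if min(a, b, c, d) == 0:
        return AssociationResult(None, None, None, None, "wald", estimable=False)
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = scipy.stats.norm.ppf(1 - alpha / 2) if alpha != 0.05 else Z_975
    ci = (np.exp(log_or - z * se), np.exp(log_or + z * se))
    p = 2 * scipy.stats.norm.sf(abs(log_or) / se)
    return AssociationResult(float(np.exp(log_or)), ci[0], ci[1], float(p), method, True)


def logistic_single_predictor(
    table: ContingencyTable, alpha: float = 0.05
) -> AssociationResult:
    """Maximum-likelihood logistic fit of case status on the binary exposure.

    For a saturated 2x2 model the exponentiated slope equals the cross-product
    ratio; a zero cell causes separation and mirrors the "NE" policy.
    """
    if min(table.a, table.b, table.c, table.d) == 0:
        return AssociationResult(None, None, None, None, "logistic", estimable=False)
    endog = np.array([1.0, 1.0, 0.0, 0.0])
    exog = sm.add_constant(np.array([1.0, 0.0, 1.0, 0.0]))
    weights = np.array([table.a, table.b, table.c, table.d], dtype=float)
    fit = sm.GLM(endog, exog, family=sm.families.Binomial(), freq_weights=weights).fit(
        tol=1e-12
    )
    beta = fit.params[1]
    se = fit.bse[1]
    z = scipy.stats.norm.ppf(1 - alpha / 2) if alpha != 0.05 else Z_975
    p = 2 * scipy.stats.norm.sf(abs(beta) / se)
    return AssociationResult(
        float(np.exp(beta)),
        float(np.exp(beta - z * se)),
        float(np.exp(beta + z * se)),
        float(p),
        "logistic",
        True,
    )


def yates_chi2(table: ContingencyTable) -> tuple[float, float]:
    """Continuity-adjusted chi-square with the correction truncated at zero.

    chi2 = sum over cells of max(|O - E| - 0.5, 0)^2 / E; when every |O - E|
    is below 0.5 the statistic is exactly 0 and p is 1 (reported as > .99).
    """
    arr = table.as_array()
    if arr.sum(axis=0).min() == 0 or arr.sum(axis=1).min() == 0:
        raise ValueError("zero margin: expected counts undefined")
    stat, p, _, _ = scipy.stats.chi2_contingency(arr, correction=True)
    return float(stat), float(p)


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p (sum of hypergeometric tables <= observed)."""
    _, p = scipy.stats.fisher_exact(table.as_array(), alternative="two-sided")
    return float(p)


def frequency_report(table: ContingencyTable, ndigits: int = 1) -> tuple[float, float]:
    """Carrier percentages (cases, controls), rounded for printed reporting."""
    if table.n_cases == 0 or table.n_controls == 0:
        raise ValueError("group denominators must be positive")
    return (
        round_half_up(100.0 * table.a / table.n_cases, ndigits),
        round_half_up(100.0 * table.c / table.n_controls, ndigits),
    )


def association_report(
    tables: dict[str, ContingencyTable], method: str = "wald"
) -> pd.DataFrame:
    """Table-2-style report: one row per labelled contrast."""
    fit = odds_ratio_wald if method == "wald" else logistic_single_predictor
    rows = []
    for label, t in tables.items():
        res = fit(t)
        pct_case, pct_ctrl = frequency_report(t)
        rows.append(
            {
                "variant": label,
                "case_carriers": t.a,
                "case_n": t.n_cases,
                "case_pct": pct_case,
                "control_carriers": t.c,
                "control_n": t.n_controls,
                "control_pct": pct_ctrl,
                "p_value": "NE" if not res.estimable else f"{res.p_value:.3g}",
                "or_ci": res.formatted(),
            }
        )
    return pd.DataFrame(rows)
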