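"""Genotype-stratified acute vasodilator-response analysis.

Percent change of pulmonary hemodynamics from baseline to post-inhalation,
greedy age/sex matching of non-carrier comparators, and the ANCOVA contrast:
ordinary least squares of the percent change on an intercept, the carrier
indicator and the baseline measurement. The carrier coefficient is the
least-squares-mean difference (carrier minus non-carrier) adjusted to the
common mean baseline; its confidence interval uses t critical values at the
residual degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "HemodynamicRecord",
    "ResponseModelResult",
    "percent_change",
    "match_controls",
    "genotype_response_model",
    "validate_pah_diagnosis",
    "response_table",
]


@dataclass(frozen=True)
class HemodynamicRecord:
    subject_id: str
    phase: str  # baseline / post_iloprost
    mPAP: float | None = None
    PAWP: float | None = None
    PVR: float | None = None
    cardiac_index: float | None = None
    RAP: float | None = None
    SvO2: float | None = None


@dataclass(frozen=True)
class ResponseModelResult:
    outcome: str
    ls_mean_difference: float  # percentage points, carrier - non-carrier
    ci_low: float
    ci_high: float
    p_value: float
    n_carriers: int
    n_noncarriers: int


def percent_change(baseline: float, post: float) -> float:
    """100 * (post - baseline) / baseline; baseline must be positive."""
    b = np.asarray(baseline, dtype=float)
    if np.any(b <= 0):
        raise ValueError("baseline must be positive for a percent change")
    return 100.0 * (np.asarray(post, dtype=float) - b) / b


def match_controls(
    carriers: pd.DataFrame,
    pool: pd.DataFrame,
    ratio: int = 3,
    keys: Sequence[str] = ("age", "sex"),
) -> pd.DataFrame:
    """Greedy nearest-age within-sex matching without replacement.

    Carriers are processed in subject-id order; for each, the ``ratio``
    same-sex pool members with the smallest absolute age difference are
    taken, ties broken by smallest subject id. Raises when the pool cannot
    supply the requested number per sex, reporting the deficit.
    """
    age_key, sex_key = keys
    need = carriers[sex_key].value_counts() * ratio
    have = pool[sex_key].value_counts()
    deficits = {
        s: int(n - have.get(s, 0)) for s, n in need.items() if have.get(s, 0) < n
    }
    if deficits:
        msg = ", ".join(f"{s}: short {d}" for s, d in sorted(deficits.items()))
        raise ValueError(f"insufficient matching pool ({msg})")

    available = pool.sort_values("subject_id").copy()
    matched_rows = []
    for _, carrier in carriers.sort_values("subject_id").iterrows():
        same_sex = available[available[sex_key] == carrier[sex_key]]
        diffs = (same_sex[age_key] - carrier[age_key]).abs()
        order = same_sex.assign(_d=diffs).sort_values(["_d", "subject_id"])
        take = order.head(ratio)
        matched_rows.append(take.drop(columns="_d").assign(matched_to=carrier["subject_id"]))
        available = available.drop(take.index)
    return pd.concat(matched_rows, ignore_index=True)


def genotype_response_model(
    percent_changes: Sequence[float],
    genotype: Sequence[int],
    baselines: Sequence[float],
    outcome: str = "outcome",
    include_baseline: bool = True,
) -> ResponseModelResult:
    """ANCOVA of percent change on {intercept, carrier indicator, baseline}.

    With ``include_baseline=False`` the model reduces to the raw group-mean
    difference. Raises on single-group or collinear input.
    """
    y = np.asarray(percent_changes, dtype=float)
    g = np.asarray(genotype, dtype=float)
    b = np.asarray(baselines, dtype=float)
    if not (y.size == g.size == b.size):
        raise ValueError("inputs must have equal length")
    if len(np.unique(g)) < 2:
        raise ValueError("both genotype groups are required")
    cols = [np.ones_like(y), g] + ([b] if include_baseline else [])
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear design (baseline constant within groups?)")
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)  # t-based at residual df
    return ResponseModelResult(
        outcome=outcome,
        ls_mean_difference=float(fit.params[1]),
        ci_low=float(ci[1, 0]),
        ci_high=float(ci[1, 1]),
        p_value=float(fit.pvalues[1]),
        n_carriers=int(np.sum(g == 1)),
        n_noncarriers=int(np.sum(g == 0)),
    )


_DIAG_FIELDS = ("mPAP", "PAWP", "PVR")


def validate_pah_diagnosis(record: "HemodynamicRecord | Mapping[str, float]") -> bool:
    """Hemodynamic PAH rule: mPAP >= 25 mm Hg, PAWP <= 15 mm Hg, PVR > 3 WU."""
    get = (lambda k: getattr(record, k)) if isinstance(record, HemodynamicRecord) else record.get
    vals = {}
    for k in _DIAG_FIELDS:
        v = get(k)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError(f"missing field {k} in hemodynamic record")
        vals[k] = float(v)
    return vals["mPAP"] >= 25.0 and vals["PAWP"] <= 15.0 and vals["PVR"] > 3.0


def response_table(
    hemodynamics: pd.DataFrame,
    carrier_ids: set[str],
    subject_ids: Sequence[str],
    outcomes: Sequence[str] = ("PVR", "cardiac_index"),
) -> pd.DataFrame:
    """Per-subject percent changes and carrier flags for the listed subjects.

    Expects long-format paired records with a ``phase`` column holding
    ``baseline`` and ``post_iloprost`` rows per subject.
    """
    wanted = hemodynamics[hemodynamics["subject_id"].isin(set(subject_ids))]
    base = wanted[wanted["phase"] == "baseline"].set_index("subject_id")
    post = wanted[wanted["phase"] == "post_iloprost"].set_index("subject_id")
    paired = base.index.intersection(post.index)
    rows = []
    for sid in paired:
        row = {"subject_id": sid, "carrier": int(sid in carrier_ids)}
        for var in outcomes:
            row[f"{var}_baseline"] = float(base.loc[sid, var])
            row[f"{var}_pct_change"] = float(
                percent_change(base.loc[sid, var], post.loc[sid, var])
            )
        rows.append(row)
    return pd.DataFrame(rows)
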