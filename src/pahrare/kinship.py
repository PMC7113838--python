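"""Pairwise relatedness QC with the between-family ("robust") KING estimator.

For two subjects genotyped as alt-allele dosages over shared biallelic SNPs,

    phi_hat = (N_het,het - 2 * N_opposite_hom) / (N_het(i) + N_het(j)),

computed over sites non-missing in both. The estimator is 0.5 for duplicate
samples, 0.25 in expectation for parent-offspring pairs and 0 for unrelated
pairs, without requiring allele-frequency estimates. Degree classes follow
the conventional powers-of-two cutoffs; 2^(-7/2) = 0.0884 separates second-
from third-degree relatives and is the usual unrelatedness screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth import GenotypeMatrix

__all__ = [
    "KinshipResult",
    "RelatednessSummary",
    "DEGREE_THRESHOLDS",
    "king_robust_pair",
    "king_robust_matrix",
    "classify_degree",
    "cohort_relatedness_summary",
]

#: Lower phi bound per degree class, in decreasing order.
DEGREE_THRESHOLDS: tuple[tuple[str, float], ...] = (
    ("duplicate", 2 ** -1.5),   # 0.3536
    ("1st", 2 ** -2.5),         # 0.1768
    ("2nd", 2 ** -3.5),         # 0.0884
    ("3rd", 2 ** -4.5),         # 0.0442
)


@dataclass(frozen=True)
class KinshipResult:
    pair: tuple[str, str]
    phi: float | None
    n_snps_used: int
    degree_class: str  # duplicate / 1st / 2nd / 3rd / unrelated / not_estimable

    @property
    def estimable(self) -> bool:
        return self.phi is not None


@dataclass
class RelatednessSummary:
    n_pairs: int
    fraction_below: float | None
    max_phi: float | None
    max_pair: tuple[str, str] | None
    flagged_pairs: list[tuple[str, str, float]]
    threshold: float


def classify_degree(phi: float | None) -> str:
    if phi is None or np.isnan(phi):
        return "not_estimable"
    for name, cut in DEGREE_THRESHOLDS:
        if phi >= cut:
            return name
    return "unrelated"


def king_robust_pair(
    genotypes_i: np.ndarray,
    genotypes_j: np.ndarray,
    ids: tuple[str, str] = ("i", "j"),
) -> KinshipResult:
    """KING-robust kinship for one pair of 0/1/2 dosage vectors (missing < 0)."""
    gi = np.asarray(genotypes_i)
    gj = np.asarray(genotypes_j)
    if gi.shape != gj.shape:
        raise ValueError("genotype vectors must cover the same site set")
    ok = (gi >= 0) & (gj >= 0)
    gi, gj = gi[ok], gj[ok]
    het_i = gi == 1
    het_j = gj == 1
    n_hethet = int(np.sum(het_i & het_j))
    n_opp = int(np.sum(((gi == 0) & (gj == 2)) | ((gi == 2) & (gj == 0))))
    denom = int(het_i.sum()) + int(het_j.sum())
    if denom == 0:
        return KinshipResult((ids[0], ids[1]), None, int(ok.sum()), "not_estimable")
    phi = (n_hethet - 2.0 * n_opp) / denom
    return KinshipResult((ids[0], ids[1]), phi, int(ok.sum()), classify_degree(phi))


def king_robust_matrix(values: np.ndarray) -> np.ndarray:
    """All-pairs KING-robust phi for an (n_subjects, n_sites) dosage matrix.

    Vectorized through indicator-matrix products; entries with a zero
    denominator (no heterozygous shared sites) are NaN. The diagonal is 0.5
    by construction.
    """
    g = np.asarray(values)
    het = (g == 1).astype(np.float32)
    hom_ref = (g == 0).astype(np.float32)
    hom_alt = (g == 2).astype(np.float32)
    nonmiss = (g >= 0).astype(np.float32)
    n_hethet = het @ het.T
    n_opp = hom_ref @ hom_alt.T
    n_opp = n_opp + n_opp.T
    denom = het @ nonmiss.T
    denom = denom + denom.T
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = (n_hethet - 2.0 * n_opp) / denom
    phi[denom == 0] = np.nan
    return phi


def cohort_relatedness_summary(
    genotypes: GenotypeMatrix,
    group_labels: dict[str, str] | "np.ndarray | list[str]",
    threshold: float = 2 ** -3.5,
    group_pair: tuple[str, str] = ("case", "control"),
) -> RelatednessSummary:
    """Fraction of between-group pairs below the kinship threshold.

    ``group_labels`` maps subject id to group (or gives one label per row of
    the matrix). Returns the fraction of case-control pairs with phi below
    ``threshold``, the maximum phi with its pair, and all offending pairs.
    """
    if isinstance(group_labels, dict):
        labels = np.array([group_labels[s] for s in genotypes.subject_ids])
    else:
        labels = np.asarray(list(group_labels))
        if labels.size != len(genotypes.subject_ids):
            raise ValueError("one group label required per subject")
    a_idx = np.nonzero(labels == group_pair[0])[0]
    b_idx = np.nonzero(labels == group_pair[1])[0]
    if len(genotypes.subject_ids) < 2 or a_idx.size == 0 or b_idx.size == 0:
        return RelatednessSummary(0, None, None, None, [], threshold)

    phi = king_robust_matrix(genotypes.values)
    sub = phi[np.ix_(a_idx, b_idx)]
    finite = np.isfinite(sub)
    n_pairs = int(finite.sum())
    if n_pairs == 0:
        return RelatednessSummary(0, None, None, None, [], threshold)
    below = float(np.sum(sub[finite] < threshold)) / n_pairs
    flat = np.where(finite, sub, -np.inf)
    i, j = np.unravel_index(int(np.argmax(flat)), flat.shape)
    ids = genotypes.subject_ids
    max_pair = (ids[a_idx[i]], ids[b_idx[j]])
    offender_rows, offender_cols = np.nonzero(finite & (sub >= threshold))
    flagged = [
        (ids[a_idx[r]], ids[b_idx[c]], float(sub[r, c]))
        for r, c in zip(offender_rows, offender_cols)
    ]
    flagged.sort(key=lambda t: -t[2])
    return RelatednessSummary(
        n_pairs, below, float(sub[i, j]), max_pair, flagged, threshold
    )
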