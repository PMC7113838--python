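"""Discovery-stage candidate filtering and gene-level prioritization.

A dominant-model rare-variant screen: a site qualifies when it is rare in
every reference panel (minor allele frequency strictly below the cutoff),
absent from the Chinese 1000 Genomes panel, and predicted deleterious; a
subject contributes to a gene when heterozygous at at least one qualifying
site. Genes are then prioritized by the number of distinct carriers and by
abundant expression in the target tissue, and subjects can be screened
against the known PAH risk genes for exclusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .synth import PANEL_COLUMNS, PREDICTOR_COLUMNS, GenotypeMatrix, SyntheticCohort

__all__ = [
    "VariantSite",
    "FilterCriteria",
    "GeneCarrierMap",
    "KNOWN_PAH_GENES",
    "qualify_variant",
    "qualifying_mask",
    "discover_candidates",
    "prioritize_genes",
    "screen_known_pah_genes",
]

logger = logging.getLogger(__name__)

#: The 17 genes with established PAH associations used for the exclusion screen.
KNOWN_PAH_GENES: tuple[str, ...] = (
    "BMPR2", "EIF2AK4", "TBX4", "ATP13A3", "GDF2", "SOX17", "AQP1", "ACVRL1",
    "SMAD9", "ENG", "KCNK3", "CAV1", "SMAD4", "SMAD1", "KLF2", "BMPR1B", "KCNA5",
)


@dataclass(frozen=True)
class VariantSite:
    """One annotated biallelic site."""

    site_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    panel_freqs: Mapping[str, float]
    in_chinese_1kg: bool
    deleterious_flags: Mapping[str, bool]
    consequence: str = "other"  # missense / splice / other

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"{self.site_id}: ref equals alt")
        if not self.panel_freqs:
            raise ValueError(f"{self.site_id}: at least one reference panel required")
        for panel, f in self.panel_freqs.items():
            if f is not None and not np.isnan(f) and not 0.0 <= f <= 1.0:
                raise ValueError(f"{self.site_id}: {panel} frequency {f} outside [0, 1]")

    @classmethod
    def from_row(cls, row: Mapping) -> "VariantSite":
        return cls(
            site_id=row["site_id"],
            gene=row["gene"],
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            ref=row["ref"],
            alt=row["alt"],
            panel_freqs={c: float(row[c]) for c in PANEL_COLUMNS if c in row},
            in_chinese_1kg=bool(row["in_chinese_1kg"]),
            deleterious_flags={c: bool(row[c]) for c in PREDICTOR_COLUMNS if c in row},
            consequence=row.get("consequence", "other"),
        )


@dataclass(frozen=True)
class FilterCriteria:
    """Dominant-model rare-deleterious filter settings.

    ``deleterious_rule`` aggregates the per-predictor flags: ``all`` demands
    unanimity, ``majority`` more than half, ``any`` a single supporting tool.
    Canonical splice variants count as deleterious by consequence class
    regardless of the predictor flags.
    """

    maf_max: float = 0.005
    require_absent_chinese_panel: bool = True
    deleterious_rule: str = "all"
    min_shared_carriers: int = 3
    expression_tissue: str = "lung"

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_max < 1.0:
            raise ValueError("maf_max must lie in [0, 1)")
        if self.min_shared_carriers < 1:
            raise ValueError("min_shared_carriers must be >= 1")
        if self.deleterious_rule not in ("all", "majority", "any"):
            raise ValueError(f"unknown deleterious_rule {self.deleterious_rule!r}")


@dataclass
class GeneCarrierMap:
    """Gene -> qualifying (subject, site) pairs; carriers counted per subject."""

    pairs: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    def add(self, gene: str, subject_id: str, site_id: str) -> None:
        self.pairs.setdefault(gene, set()).add((subject_id, site_id))

    def carriers(self, gene: str) -> set[str]:
        return {s for s, _ in self.pairs.get(gene, set())}

    @property
    def carrier_counts(self) -> dict[str, int]:
        return {g: len({s for s, _ in pairs}) for g, pairs in self.pairs.items()}

    def genes(self) -> list[str]:
        return sorted(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


def _deleterious_ok(flags: np.ndarray, rule: str) -> np.ndarray:
    """Aggregate an (n_sites, n_predictors) boolean array by the consensus rule."""
    if rule == "all":
        return flags.all(axis=1)
    if rule == "majority":
        return flags.sum(axis=1) * 2 > flags.shape[1]
    if rule == "any":
        return flags.any(axis=1)
    raise ValueError(f"unknown deleterious_rule {rule!r}")


def qualifying_mask(variants: pd.DataFrame, criteria: FilterCriteria) -> np.ndarray:
    """Vectorized qualify decision over a variant table; returns a boolean mask."""
    freqs = variants[PANEL_COLUMNS].to_numpy(dtype=float)
    if np.isnan(freqs).any():
        logger.warning(
            "missing panel frequencies at %d sites treated as 0 (absent)",
            int(np.isnan(freqs).any(axis=1).sum()),
        )
        freqs = np.nan_to_num(freqs, nan=0.0)
    rare = (freqs < criteria.maf_max).all(axis=1)
    if criteria.require_absent_chinese_panel:
        rare &= ~variants["in_chinese_1kg"].to_numpy(dtype=bool)
    flags = variants[PREDICTOR_COLUMNS].to_numpy(dtype=bool)
    deleterious = _deleterious_ok(flags, criteria.deleterious_rule)
    deleterious |= variants["consequence"].to_numpy() == "splice"
    return rare & deleterious


def qualify_variant(site: VariantSite, criteria: FilterCriteria) -> bool:
    """True iff one site passes the rare-deleterious dominant-model filter."""
    freqs = []
    for panel, f in site.panel_freqs.items():
        if f is None or np.isnan(f):
            logger.warning("%s: missing frequency in %s treated as 0", site.site_id, panel)
            f = 0.0
        freqs.append(f)
    if not all(f < criteria.maf_max for f in freqs):
        return False
    if criteria.require_absent_chinese_panel and site.in_chinese_1kg:
        return False
    if site.consequence == "splice":
        return True
    flags = np.array([list(site.deleterious_flags.values())], dtype=bool)
    return bool(_deleterious_ok(flags, criteria.deleterious_rule)[0])


def _check_alignment(genotypes: GenotypeMatrix, variants: pd.DataFrame) -> None:
    known = set(variants["site_id"])
    missing = [s for s in genotypes.site_ids if s not in known]
    if missing:
        raise ValueError(
            f"{len(missing)} genotyped sites absent from the variant table "
            f"(first: {missing[0]})"
        )


def discover_candidates(
    cohort: SyntheticCohort,
    criteria: FilterCriteria,
    subjects: Iterable[str] | None = None,
) -> GeneCarrierMap:
    """Collect qualifying heterozygous (subject, site) pairs grouped by gene.

    By default the screen runs over all case subjects; pass ``subjects`` to
    restrict it (e.g. to the whole-genome-sequenced discovery arm).
    """
    variants = cohort.variants
    genotypes = cohort.genotypes
    _check_alignment(genotypes, variants)

    if subjects is None:
        subjects = cohort.subjects.loc[cohort.subjects["group"] == "case", "subject_id"]
    subj_ids = list(subjects)
    subj_idx = [genotypes.subject_index(s) for s in subj_ids]

    order = {sid: j for j, sid in enumerate(genotypes.site_ids)}
    site_mask = qualifying_mask(variants, criteria)
    qual_sites = variants.loc[site_mask, ["site_id", "gene"]]

    gmap = GeneCarrierMap()
    if qual_sites.empty or not subj_idx:
        return gmap
    cols = np.array([order[s] for s in qual_sites["site_id"]])
    het = cohort.genotypes.values[np.ix_(np.array(subj_idx), cols)] == 1
    genes = qual_sites["gene"].to_numpy()
    sids = qual_sites["site_id"].to_numpy()
    for i, j in zip(*np.nonzero(het)):
        gmap.add(genes[j], subj_ids[i], sids[j])
    return gmap


def prioritize_genes(
    gene_map: GeneCarrierMap,
    criteria: FilterCriteria,
    expression: pd.DataFrame,
) -> pd.DataFrame:
    """Rank genes with >= ``min_shared_carriers`` distinct carriers.

    Returns a frame with columns ``gene``, ``n_carriers`` and ``expressed``
    (abundant expression in ``criteria.expression_tissue``), sorted by carrier
    count descending with ties broken by gene symbol. Genes missing from the
    expression table are treated as not expressed and logged.
    """
    if len(gene_map) == 0:
        raise ValueError("empty gene-carrier map")
    tissue_sets = {
        row["gene"]: set(str(row["tissues"]).split(";"))
        for _, row in expression.iterrows()
    }
    counts = gene_map.carrier_counts
    rows = []
    for gene, n in counts.items():
        if n < criteria.min_shared_carriers:
            continue
        if gene not in tissue_sets:
            logger.warning("gene %s missing from expression table; treated as not expressed", gene)
        expressed = criteria.expression_tissue in tissue_sets.get(gene, set())
        rows.append({"gene": gene, "n_carriers": n, "expressed": expressed})
    out = pd.DataFrame(rows, columns=["gene", "n_carriers", "expressed"])
    return out.sort_values(
        ["n_carriers", "gene"], ascending=[False, True], ignore_index=True
    )


def screen_known_pah_genes(
    cohort: SyntheticCohort,
    subjects: Iterable[str],
    criteria: FilterCriteria | None = None,
    gene_list: Iterable[str] = KNOWN_PAH_GENES,
) -> pd.DataFrame:
    """Rare-deleterious hits in known PAH genes per subject (exclusion screen).

    An empty result means every screened subject passes. Returns a frame with
    columns ``subject_id``, ``gene``, ``site_id``.
    """
    genes = list(gene_list)
    if not genes:
        raise ValueError("empty known-gene list")
    criteria = criteria or FilterCriteria()
    restricted = cohort.variants[cohort.variants["gene"].isin(genes)]
    rows: list[dict] = []
    if restricted.empty:
        return pd.DataFrame(rows, columns=["subject_id", "gene", "site_id"])
    mask = qualifying_mask(restricted, criteria)
    qual = restricted.loc[mask]
    order = {sid: j for j, sid in enumerate(cohort.genotypes.site_ids)}
    for subj in subjects:
        gi = cohort.genotypes.row(subj)
        for _, site in qual.iterrows():
            if gi[order[site["site_id"]]] == 1:
                rows.append(
                    {"subject_id": subj, "gene": site["gene"], "site_id": site["site_id"]}
                )
    return pd.DataFrame(rows, columns=["subject_id", "gene", "site_id"])
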