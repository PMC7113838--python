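"""Synthetic two-stage IPAH case-control cohort generator.

Emulates the statistical structure a rare-variant burden study of idiopathic
pulmonary arterial hypertension (IPAH) assumes: a small whole-genome-sequenced
discovery arm, a larger Sanger-genotyped replication arm and a healthy control
panel; heterozygous rare variants planted in one causal gene at different
case/control carrier frequencies; an abundant background of singleton rare
hits in the discovery genomes; common biallelic SNPs in Hardy-Weinberg
equilibrium for relatedness QC; and paired pre/post-vasodilator hemodynamics
with a genotype-dependent percent-change response.

All randomness flows from a single integer seed, so a cohort is a pure
function of its :class:`SimulationConfig`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SimulationConfig",
    "GenotypeMatrix",
    "Truth",
    "SyntheticCohort",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "PANEL_COLUMNS",
    "PREDICTOR_COLUMNS",
]

# Reference-panel frequency columns (four generic panels) and in-silico
# deleteriousness predictor columns carried on every variant record.
PANEL_COLUMNS = ["af_panel1", "af_panel2", "af_panel3", "af_panel4"]
PREDICTOR_COLUMNS = ["pred_sift", "pred_polyphen", "pred_mutation_taster", "pred_cadd"]

#: Baseline hemodynamic means/SDs for cases (pooled two-arm values:
#: mPAP mm Hg, PAWP mm Hg, PVR Wood units, RAP mm Hg, cardiac index
#: L/min/m^2, SvO2 %).
DEFAULT_BASELINES: dict[str, tuple[float, float]] = {
    "mPAP": (60.0, 17.0),
    "PAWP": (8.4, 4.2),
    "PVR": (15.3, 8.5),
    "RAP": (7.6, 6.0),
    "cardiac_index": (2.6, 1.0),
    "SvO2": (63.0, 13.0),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic study; the seed fully determines the cohort."""

    seed: int = 0
    n_discovery_cases: int = 42
    n_replication_cases: int = 188
    n_controls: int = 968
    causal_gene: str = "PTGIS"
    case_carrier_freq: float = 0.061
    control_carrier_freq: float = 0.008
    n_background_genes: int = 8600
    background_hit_rate: float = 47.3  # expected qualifying rare hits per sequenced case genome
    background_deleterious_prob: float = 0.9
    background_lung_expressed_frac: float = 0.25
    n_common_snps: int = 10_000
    common_maf_range: tuple[float, float] = (0.05, 0.5)
    # planted relative pairs among controls, keyed "duplicate"/"first"/"second"
    n_related_pairs: Mapping[str, int] = field(default_factory=dict)
    # percentage-point difference in post-iloprost % change for carriers
    pvr_effect: float = -21.7
    ci_effect: float = 18.3
    pvr_noncarrier_change: float = -10.0
    ci_noncarrier_change: float = 10.0
    pvr_baseline_slope: float = -0.5  # % change per Wood unit above the mean baseline
    ci_baseline_slope: float = -5.0  # % change per L/min/m^2 above the mean baseline
    baseline_means_sds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BASELINES)
    )
    noise_sd: float = 14.5  # residual SD of the % change, percentage points

    def __post_init__(self) -> None:
        for name in ("case_carrier_freq", "control_carrier_freq",
                     "background_deleterious_prob", "background_lung_expressed_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0, 1], got {v}")
        for name in ("n_discovery_cases", "n_replication_cases", "n_controls"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_background_genes < 0 or self.n_common_snps < 0:
            raise ValueError("site counts must be non-negative")
        lo, hi = self.common_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("common_maf_range must satisfy 0 < lo <= hi <= 0.5")
        for degree in self.n_related_pairs:
            if degree not in ("duplicate", "first", "second"):
                raise ValueError(f"unknown relatedness degree {degree!r}")

    @property
    def n_cases(self) -> int:
        return self.n_discovery_cases + self.n_replication_cases

    @property
    def n_subjects(self) -> int:
        return self.n_cases + self.n_controls


@dataclass
class GenotypeMatrix:
    """Subjects-by-sites genotype matrix, coded 0/1/2 alt-allele dosage, -1 missing."""

    values: np.ndarray  # int8, shape (n_subjects, n_sites)
    subject_ids: list[str]
    site_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.subject_ids), len(self.site_ids)):
            raise ValueError(
                f"genotype matrix shape {self.values.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.site_ids)} sites"
            )

    def subject_index(self, subject_id: str) -> int:
        return self.subject_ids.index(subject_id)

    def site_index(self, site_id: str) -> int:
        return self.site_ids.index(site_id)

    def row(self, subject_id: str) -> np.ndarray:
        return self.values[self.subject_index(subject_id)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.subject_ids == other.subject_ids
            and self.site_ids == other.site_ids
            and np.array_equal(self.values, other.values)
        )


@dataclass
class Truth:
    """Planted ground truth: carrier roster and true response effects."""

    carriers: pd.DataFrame  # columns: subject_id, gene, site_id
    pvr_effect: float
    ci_effect: float


@dataclass
class SyntheticCohort:
    subjects: pd.DataFrame
    variants: pd.DataFrame
    genotypes: GenotypeMatrix
    expression: pd.DataFrame  # columns: gene, tissues (semicolon-separated labels)
    hemodynamics: pd.DataFrame
    truth: Truth
    config: SimulationConfig | None = None


# ---------------------------------------------------------------------------
# generation

def _subject_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    specs = [
        # (prefix, n, group, cohort, age_mean, age_sd, female_prob)
        ("D", config.n_discovery_cases, "case", "discovery", 23.0, 10.0, 0.81),
        ("R", config.n_replication_cases, "case", "replication", 37.0, 18.0, 0.69),
        ("C", config.n_controls, "control", "control", 40.0, 12.0, 0.50),
    ]
    for prefix, n, group, cohort, mu, sd, p_female in specs:
        ages = np.clip(np.round(rng.normal(mu, sd, size=n)), 1, 85).astype(int)
        sexes = np.where(rng.random(n) < p_female, "F", "M")
        for i in range(n):
            rows.append(
                {
                    "subject_id": f"{prefix}{i + 1:04d}",
                    "group": group,
                    "cohort": cohort,
                    "age": int(ages[i]),
                    "sex": sexes[i],
                }
            )
    df = pd.DataFrame(rows)
    df["is_pediatric"] = df["age"] < 18
    return df


def _causal_sites(config: SimulationConfig) -> pd.DataFrame:
    """Three causal-gene sites: one canonical splice-donor SNV, two missense."""
    gene = config.causal_gene
    base = [
        (f"{gene}_splice", "splice", 521_000, "G", "A"),
        (f"{gene}_mis1", "missense", 755_000, "G", "A"),
        (f"{gene}_mis2", "missense", 1_339_000, "G", "A"),
    ]
    rows = []
    for site_id, csq, pos, ref, alt in base:
        row = {
            "site_id": site_id,
            "gene": gene,
            "chrom": "20",
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "consequence": csq,
            "in_chinese_1kg": False,
        }
        for col in PANEL_COLUMNS:
            row[col] = 0.0005 if csq == "missense" else 0.0
        for col in PREDICTOR_COLUMNS:
            row[col] = True
        rows.append(row)
    return pd.DataFrame(rows)


def _plant_causal(
    config: SimulationConfig,
    rng: np.random.Generator,
    subjects: pd.DataFrame,
    site_ids: list[str],
) -> pd.DataFrame:
    """Draw carriers binomially per arm and assign each to one causal site.

    Site weights mirror the structure in which the splice variant is
    case-private while missense variants appear in both arms.
    """
    case_w = np.array([1.0, 5.0, 8.0]) / 14.0
    ctrl_w = np.array([0.0, 2.0, 6.0]) / 8.0
    carriers: list[dict] = []
    for group, freq, w in (
        ("case", config.case_carrier_freq, case_w),
        ("control", config.control_carrier_freq, ctrl_w),
    ):
        ids = subjects.loc[subjects["group"] == group, "subject_id"].to_numpy()
        flags = rng.random(ids.size) < freq
        chosen = ids[flags]
        sites = rng.choice(len(site_ids), size=chosen.size, p=w)
        for sid, k in zip(chosen, sites):
            carriers.append(
                {"subject_id": sid, "gene": config.causal_gene, "site_id": site_ids[k]}
            )
    return pd.DataFrame(carriers, columns=["subject_id", "gene", "site_id"])


def _background_sites(
    config: SimulationConfig,
    rng: np.random.Generator,
    discovery_ids: np.ndarray,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Poisson-scatter rare hits over background genes in sequenced (discovery) genomes.

    Each hit is its own biallelic site carried heterozygously by one case, so
    per-gene carrier counts follow the singleton-dominated structure of a
    small-cohort whole-genome screen. Panel frequencies are log-uniform below
    0.5%; a configurable fraction of hits is unanimously flagged deleterious,
    the rest get random predictor flags so the filter has true negatives.
    """
    n_hits = rng.poisson(config.background_hit_rate, size=discovery_ids.size)
    total = int(n_hits.sum())
    if total == 0 or config.n_background_genes == 0:
        return pd.DataFrame(columns=_background_columns()), []
    genes = rng.integers(0, config.n_background_genes, size=total)
    log_lo, log_hi = np.log10(1e-5), np.log10(0.005)
    freqs = 10 ** rng.uniform(log_lo, log_hi, size=(total, len(PANEL_COLUMNS)))
    deleterious = rng.random(total) < config.background_deleterious_prob
    rand_flags = rng.random((total, len(PREDICTOR_COLUMNS))) < 0.5
    csq = rng.choice(["missense", "other"], size=total, p=[0.7, 0.3])
    bases = np.array(["A", "C", "G", "T"])
    refs = bases[rng.integers(0, 4, size=total)]
    alts = np.array([rng.choice([b for b in bases if b != r]) for r in refs])

    rows = []
    carrier_pairs: list[tuple[str, str]] = []
    k = 0
    for subj, n in zip(discovery_ids, n_hits):
        for _ in range(n):
            site_id = f"bg{k + 1:06d}"
            gene = f"GENE{genes[k] + 1:05d}"
            row = {
                "site_id": site_id,
                "gene": gene,
                "chrom": "2",
                "pos": 10_000 + 100 * k,
                "ref": refs[k],
                "alt": alts[k],
                "consequence": csq[k],
                "in_chinese_1kg": False,
            }
            for j, col in enumerate(PANEL_COLUMNS):
                row[col] = float(freqs[k, j])
            for j, col in enumerate(PREDICTOR_COLUMNS):
                row[col] = bool(deleterious[k] or rand_flags[k, j])
            rows.append(row)
            carrier_pairs.append((subj, site_id))
            k += 1
    return pd.DataFrame(rows, columns=_background_columns()), carrier_pairs


def _background_columns() -> list[str]:
    return (
        ["site_id", "gene", "chrom", "pos", "ref", "alt", "consequence", "in_chinese_1kg"]
        + PANEL_COLUMNS
        + PREDICTOR_COLUMNS
    )


def _common_snps(config: SimulationConfig, rng: np.random.Generator,
                 n_subjects: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Common biallelic SNPs in HWE for kinship estimation."""
    m = config.n_common_snps
    lo, hi = config.common_maf_range
    mafs = rng.uniform(lo, hi, size=m)
    geno = rng.binomial(2, mafs[None, :], size=(n_subjects, m)).astype(np.int8)
    rows = {
        "site_id": [f"snp{j + 1:06d}" for j in range(m)],
        "gene": ["." for _ in range(m)],
        "chrom": ["1"] * m,
        "pos": [1000 + 100 * j for j in range(m)],
        "ref": ["A"] * m,
        "alt": ["G"] * m,
        "consequence": ["other"] * m,
        "in_chinese_1kg": [True] * m,
    }
    df = pd.DataFrame(rows)
    for col in PANEL_COLUMNS:
        df[col] = np.round(mafs, 6)
    for col in PREDICTOR_COLUMNS:
        df[col] = False
    return df, geno


def _plant_relatives(config: SimulationConfig, rng: np.random.Generator,
                     common: np.ndarray, mafs: np.ndarray,
                     control_rows: np.ndarray) -> list[tuple[int, int, str]]:
    """Rebuild some control genotype rows so pairs share gametes.

    duplicate: identical vector (expected kinship 0.5); first degree:
    parent-offspring, one allele always transmitted (0.25); second degree:
    the transmitted allele is the relative's with probability 1/2 (0.125).
    """
    pairs: list[tuple[int, int, str]] = []
    needed = sum(self_n for self_n in config.n_related_pairs.values()) * 2
    if needed == 0:
        return pairs
    if needed > control_rows.size:
        raise ValueError("not enough controls to plant the requested related pairs")
    slots = iter(control_rows[: needed])
    m = common.shape[1]
    for degree, n in config.n_related_pairs.items():
        for _ in range(n):
            i, j = next(slots), next(slots)
            if degree == "duplicate":
                common[j] = common[i]
            else:
                # allele transmitted from subject i (random one of its two)
                transmitted = (rng.random(m) < common[i] / 2.0).astype(np.int8)
                if degree == "second":
                    # with prob 1/2 replace by a population allele
                    popl = (rng.random(m) < mafs).astype(np.int8)
                    keep = rng.random(m) < 0.5
                    transmitted = np.where(keep, transmitted, popl).astype(np.int8)
                other = (rng.random(m) < mafs).astype(np.int8)
                common[j] = transmitted + other
            pairs.append((int(i), int(j), degree))
    return pairs


def _expression_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    genes = [config.causal_gene] + [
        f"GENE{g + 1:05d}" for g in range(config.n_background_genes)
    ]
    lung = rng.random(config.n_background_genes) < config.background_lung_expressed_frac
    tissues = ["lung"] + ["lung" if f else "systemic" for f in lung]
    return pd.DataFrame({"gene": genes, "tissues": tissues})


def _hemodynamics(config: SimulationConfig, rng: np.random.Generator,
                  subjects: pd.DataFrame, carrier_ids: set[str]) -> pd.DataFrame:
    """Paired baseline / post-iloprost records for every case subject.

    PVR and cardiac index receive a genotype effect on the percent-change
    scale plus a baseline-linked term and Gaussian noise; the remaining
    variables change by noise only.
    """
    cases = subjects[subjects["group"] == "case"]
    rows = []
    for _, subj in cases.iterrows():
        carrier = subj["subject_id"] in carrier_ids
        baseline: dict[str, float] = {}
        for var, (mu, sd) in config.baseline_means_sds.items():
            v = rng.normal(mu, sd)
            while v <= 0.1:
                v = rng.normal(mu, sd)
            baseline[var] = round(float(v), 3)
        post = {}
        for var in baseline:
            if var == "PVR":
                pct = (
                    config.pvr_noncarrier_change
                    + (config.pvr_effect if carrier else 0.0)
                    + config.pvr_baseline_slope
                    * (baseline["PVR"] - config.baseline_means_sds["PVR"][0])
                    + rng.normal(0.0, config.noise_sd)
                )
            elif var == "cardiac_index":
                pct = (
                    config.ci_noncarrier_change
                    + (config.ci_effect if carrier else 0.0)
                    + config.ci_baseline_slope
                    * (baseline["cardiac_index"] - config.baseline_means_sds["cardiac_index"][0])
                    + rng.normal(0.0, config.noise_sd)
                )
            else:
                pct = rng.normal(0.0, 5.0)
            pct = max(pct, -95.0)
            post[var] = round(baseline[var] * (1.0 + pct / 100.0), 3)
        for phase, vals in (("baseline", baseline), ("post_iloprost", post)):
            rows.append({"subject_id": subj["subject_id"], "phase": phase, **vals})
    cols = ["subject_id", "phase"] + list(config.baseline_means_sds)
    return pd.DataFrame(rows, columns=cols)


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a complete synthetic study from a :class:`SimulationConfig`.

    Raises
    ------
    ValueError
        If the configuration implies zero subjects or zero genotyped sites.
    """
    if config.n_subjects == 0:
        raise ValueError("configuration yields zero subjects")
    rng = np.random.default_rng(config.seed)

    subjects = _subject_table(config, rng)
    n_subj = len(subjects)

    causal = _causal_sites(config)
    truth_carriers = _plant_causal(config, rng, subjects, list(causal["site_id"]))

    discovery_ids = subjects.loc[subjects["cohort"] == "discovery", "subject_id"].to_numpy()
    background, bg_pairs = _background_sites(config, rng, discovery_ids)

    common_df, common_geno = _common_snps(config, rng, n_subj)
    mafs = common_df[PANEL_COLUMNS[0]].to_numpy(dtype=float)
    control_rows = subjects.index[subjects["group"] == "control"].to_numpy()
    if config.n_common_snps > 0:
        _plant_relatives(config, rng, common_geno, mafs, control_rows)

    variants = pd.concat(
        [df for df in (common_df, causal, background) if not df.empty],
        ignore_index=True,
    )
    if len(variants) == 0:
        raise ValueError("configuration yields zero genotyped sites")

    n_sites = len(variants)
    geno = np.zeros((n_subj, n_sites), dtype=np.int8)
    geno[:, : config.n_common_snps] = common_geno
    site_pos = {sid: j for j, sid in enumerate(variants["site_id"])}
    subj_pos = {sid: i for i, sid in enumerate(subjects["subject_id"])}
    for _, row in truth_carriers.iterrows():
        geno[subj_pos[row["subject_id"]], site_pos[row["site_id"]]] = 1
    for subj, site in bg_pairs:
        geno[subj_pos[subj], site_pos[site]] = 1

    genotypes = GenotypeMatrix(geno, list(subjects["subject_id"]), list(variants["site_id"]))
    expression = _expression_table(config, rng)
    hemo = _hemodynamics(config, rng, subjects, set(truth_carriers["subject_id"]))
    truth = Truth(truth_carriers, config.pvr_effect, config.ci_effect)
    return SyntheticCohort(subjects, variants, genotypes, expression, hemo, truth, config)


# ---------------------------------------------------------------------------
# on-disk round trip

_FILES = {
    "subjects": "subjects.tsv",
    "variants": "variants.tsv",
    "genotypes": "genotypes.vcf",
    "expression": "expression.tsv",
    "hemodynamics": "hemodynamics.tsv",
    "truth": "truth_carriers.tsv",
    "config": "config.yaml",
}


class CohortParseError(ValueError):
    """Malformed cohort file; message names the file and line."""


def _write_vcf(path: Path, genotypes: GenotypeMatrix, variants: pd.DataFrame) -> None:
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    var = variants.set_index("site_id")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.subject_ids)
            + "\n"
        )
        for j, sid in enumerate(genotypes.site_ids):
            row = var.loc[sid]
            gts = "\t".join(gt_map[int(g)] for g in genotypes.values[:, j])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{sid}\t{row['ref']}\t{row['alt']}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    site_ids: list[str] = []
    columns: list[np.ndarray] = []
    # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
    remap = np.array([0, 1, -1, 2], dtype=np.int8)
    for rec in vcf:
        site_ids.append(rec.ID)
        columns.append(remap[rec.gt_types])
    vcf.close()
    values = (
        np.stack(columns, axis=1) if columns else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(values, samples, site_ids)


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write a cohort as a directory of plain-text files; returns the paths."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {k: d / v for k, v in _FILES.items()}
    cohort.subjects.to_csv(paths["subjects"], sep="\t", index=False)
    cohort.variants.to_csv(paths["variants"], sep="\t", index=False, float_format="%.10g")
    _write_vcf(paths["genotypes"], cohort.genotypes, cohort.variants)
    cohort.expression.to_csv(paths["expression"], sep="\t", index=False)
    cohort.hemodynamics.to_csv(paths["hemodynamics"], sep="\t", index=False, float_format="%.10g")
    cohort.truth.carriers.to_csv(paths["truth"], sep="\t", index=False)
    meta: dict = {
        "pvr_effect": float(cohort.truth.pvr_effect),
        "ci_effect": float(cohort.truth.ci_effect),
    }
    if cohort.config is not None:
        cfg = dataclasses.asdict(cohort.config)
        cfg["common_maf_range"] = list(cfg["common_maf_range"])
        cfg["n_related_pairs"] = dict(cfg["n_related_pairs"])
        cfg["baseline_means_sds"] = {k: list(v) for k, v in cfg["baseline_means_sds"].items()}
        meta["config"] = cfg
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return paths


def _validate_variants(df: pd.DataFrame, path: Path) -> None:
    for col in PANEL_COLUMNS:
        bad = df.index[(df[col] < 0) | (df[col] > 1)]
        if len(bad):
            # +2: header line and 1-based numbering
            raise CohortParseError(
                f"{path}, line {bad[0] + 2}: panel frequency {col}="
                f"{df.loc[bad[0], col]} outside [0, 1]"
            )
    if (df["ref"] == df["alt"]).any():
        i = df.index[df["ref"] == df["alt"]][0]
        raise CohortParseError(f"{path}, line {i + 2}: ref equals alt")


def read_cohort(directory: str | Path) -> SyntheticCohort:
    """Read a cohort previously written by :func:`write_cohort`.

    Raises :class:`CohortParseError` naming the offending file and line when
    a table violates its invariants.
    """
    d = Path(directory)
    paths = {k: d / v for k, v in _FILES.items()}
    subjects = pd.read_csv(paths["subjects"], sep="\t")
    variants = pd.read_csv(
        paths["variants"], sep="\t", dtype={"chrom": str, "gene": str}
    )
    _validate_variants(variants, paths["variants"])
    genotypes = _read_vcf(paths["genotypes"])
    expression = pd.read_csv(paths["expression"], sep="\t")
    try:
        hemo = pd.read_csv(paths["hemodynamics"], sep="\t")
    except pd.errors.EmptyDataError:
        hemo = pd.DataFrame(columns=["subject_id", "phase"])
    try:
        carriers = pd.read_csv(paths["truth"], sep="\t")
    except pd.errors.EmptyDataError:
        carriers = pd.DataFrame(columns=["subject_id", "gene", "site_id"])
    if carriers.empty:
        carriers = pd.DataFrame(columns=["subject_id", "gene", "site_id"])
    with open(paths["config"]) as fh:
        meta = yaml.safe_load(fh) or {}
    truth = Truth(
        carriers,
        float(meta.get("pvr_effect", 0.0)),
        float(meta.get("ci_effect", 0.0)),
    )
    config = None
    if "config" in meta:
        cfg = dict(meta["config"])
        cfg["common_maf_range"] = tuple(cfg["common_maf_range"])
        cfg["baseline_means_sds"] = {
            k: tuple(v) for k, v in cfg["baseline_means_sds"].items()
        }
        config = SimulationConfig(**cfg)
    return SyntheticCohort(subjects, variants, genotypes, expression, hemo, truth, config)
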