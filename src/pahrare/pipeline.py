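"""End-to-end two-stage study runner.

Orchestrates: known-PAH-gene exclusion screen, kinship QC, discovery-stage
gene prioritization (discovery arm only), replication-stage carrier counting,
pooled case-control association, discovery-vs-replication and pediatric-vs-
adult consistency checks, and the genotype-stratified vasoreactivity ANCOVA.
Each stage writes a headered TSV stamped with the run seed, and the variant
funnel (sites -> qualifying -> genes -> shared -> expressed) is logged.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, discover, kinship, synth, vasoresponse

__all__ = ["RunConfig", "StudyReport", "QCError", "run_study"]

logger = logging.getLogger(__name__)


class QCError(RuntimeError):
    """Raised when cohort-level QC fails (partial outputs are preserved)."""


@dataclass
class RunConfig:
    output_dir: str | Path
    simulation: synth.SimulationConfig | None = None
    input_dir: str | Path | None = None
    criteria: discover.FilterCriteria = field(default_factory=discover.FilterCriteria)
    kinship_threshold: float = 2 ** -3.5
    proceed_on_kinship_failure: bool = False
    haldane: bool = False
    match_ratio: int = 3
    seed: int | None = None
    skip_kinship: bool = False
    skip_response: bool = False

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.input_dir is None):
            raise ValueError("exactly one input source required (simulation xor input_dir)")
        if self.seed is None and self.simulation is not None:
            self.seed = self.simulation.seed


@dataclass
class StudyReport:
    tables: dict[str, pd.DataFrame]
    paths: dict[str, Path]
    funnel: dict[str, int]
    cohort: synth.SyntheticCohort


def _write_table(df: pd.DataFrame, path: Path, seed, stage: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# stage={stage}\tseed={seed}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_study(config: RunConfig) -> StudyReport:
    """Run the full study; returns all tables and writes them under output_dir."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    tables: dict[str, pd.DataFrame] = {}
    paths: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        tables[name] = df
        paths[name] = outdir / f"{name}.tsv"
        _write_table(df, paths[name], seed, name)

    if config.simulation is not None:
        cohort = synth.generate_cohort(config.simulation)
    else:
        cohort = synth.read_cohort(config.input_dir)
    with open(outdir / "run_config.json", "w") as fh:
        cfg = dataclasses.asdict(config)
        cfg["output_dir"] = str(cfg["output_dir"])
        cfg["input_dir"] = str(cfg["input_dir"]) if cfg["input_dir"] else None
        if cfg["simulation"] is not None:
            cfg["simulation"] = {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in cfg["simulation"].items()
                if k != "baseline_means_sds"
            }
        json.dump(cfg, fh, indent=1, sort_keys=True, default=str)

    subjects = cohort.subjects
    discovery_ids = subjects.loc[subjects["cohort"] == "discovery", "subject_id"]
    gene = (cohort.config.causal_gene if cohort.config is not None
            else cohort.truth.carriers["gene"].iloc[0] if len(cohort.truth.carriers)
            else "PTGIS")

    # 1. known-PAH-gene exclusion screen on the sequenced arm
    screen = discover.screen_known_pah_genes(cohort, discovery_ids, config.criteria)
    emit("known_gene_screen", screen)
    logger.info("known-gene screen: %d flagged subjects", screen["subject_id"].nunique())

    # 2. kinship QC between cases and controls
    if not config.skip_kinship:
        summary = kinship.cohort_relatedness_summary(
            cohort.genotypes,
            dict(zip(subjects["subject_id"], subjects["group"])),
            threshold=config.kinship_threshold,
        )
        emit(
            "kinship_summary",
            pd.DataFrame(
                [
                    {
                        "n_pairs": summary.n_pairs,
                        "fraction_below_threshold": summary.fraction_below,
                        "max_phi": summary.max_phi,
                        "max_pair": "|".join(summary.max_pair) if summary.max_pair else "",
                        "n_flagged": len(summary.flagged_pairs),
                        "threshold": summary.threshold,
                    }
                ]
            ),
        )
        if summary.flagged_pairs and not config.proceed_on_kinship_failure:
            raise QCError(
                f"kinship QC: {len(summary.flagged_pairs)} case-control pairs at or above "
                f"phi={config.kinship_threshold:.4f} (max {summary.max_phi:.4f}); "
                f"partial outputs in {outdir}"
            )

    # 3. discovery-stage prioritization (sequenced arm only)
    gmap = discover.discover_candidates(cohort, config.criteria, subjects=discovery_ids)
    counts = gmap.carrier_counts
    singleton = sum(1 for v in counts.values() if v == 1)
    try:
        priority = discover.prioritize_genes(gmap, config.criteria, cohort.expression)
    except ValueError:
        priority = pd.DataFrame(columns=["gene", "n_carriers", "expressed"])
    emit("gene_priority", priority)
    funnel = {
        "sites_total": len(cohort.variants),
        "qualifying_pairs": sum(len(p) for p in gmap.pairs.values()),
        "genes_hit": len(counts),
        "genes_single_carrier": singleton,
        "genes_shared": len(priority),
        "genes_shared_expressed": int(priority["expressed"].sum()) if len(priority) else 0,
    }
    logger.info("discovery funnel: %s", funnel)

    # 4-5. replication carrier counting and pooled association
    crit = config.criteria
    combined = assoc.carrier_table(cohort, gene=gene, criteria=crit)
    per_variant = {
        sid: assoc.carrier_table(cohort, site_id=sid, criteria=crit)
        for sid in cohort.variants.loc[cohort.variants["gene"] == gene, "site_id"]
    }
    per_variant["combined"] = combined
    emit("association", assoc.association_report(per_variant))

    # 6. discovery-vs-replication consistency and pediatric-vs-adult subgroup
    consistency_rows = []
    for label, col, pair in (
        ("discovery_vs_replication", "cohort", ("discovery", "replication")),
        ("pediatric_vs_adult", "age_class", ("pediatric", "adult")),
    ):
        cases = subjects[subjects["group"] == "case"].copy()
        if col == "age_class":
            cases[col] = np.where(cases["is_pediatric"], "pediatric", "adult")
        carriers = set(cohort.truth.carriers["subject_id"]) if len(cohort.truth.carriers) else set()
        sub_tables = []
        for side in pair:
            ids = cases.loc[cases[col] == side, "subject_id"]
            k = sum(1 for s in ids if s in carriers)
            sub_tables.append((k, len(ids) - k))
        t = assoc.ContingencyTable(*sub_tables[0], *sub_tables[1])
        try:
            stat, p = assoc.yates_chi2(t)
            consistency_rows.append(
                {"comparison": label, "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                 "chi2": stat, "p_value": p}
            )
        except ValueError as err:
            consistency_rows.append(
                {"comparison": label, "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                 "chi2": np.nan, "p_value": np.nan}
            )
            logger.warning("consistency %s not computable: %s", label, err)
    emit("consistency", pd.DataFrame(consistency_rows))

    # 7. vasoreactivity ANCOVA on carriers vs matched non-carriers
    if not config.skip_response:
        carrier_ids = set(cohort.truth.carriers.loc[
            cohort.truth.carriers["gene"] == gene, "subject_id"
        ])
        cases = subjects[subjects["group"] == "case"]
        tested = set(cohort.hemodynamics["subject_id"])
        carriers_df = cases[cases["subject_id"].isin(carrier_ids & tested)]
        pool = cases[~cases["subject_id"].isin(carrier_ids) & cases["subject_id"].isin(tested)]
        rows = []
        if len(carriers_df) >= 2:
            matched = None
            for ratio in range(config.match_ratio, 0, -1):
                try:
                    matched = vasoresponse.match_controls(carriers_df, pool, ratio=ratio)
                except ValueError:
                    continue
                if ratio < config.match_ratio:
                    logger.warning("matching pool too small for ratio %d; used %d",
                                   config.match_ratio, ratio)
                break
            if matched is not None:
                comparators = list(matched["subject_id"])
            else:
                logger.warning("matching infeasible even at ratio 1; using the full pool")
                comparators = list(pool["subject_id"])
            analysis_ids = list(carriers_df["subject_id"]) + comparators
            rt = vasoresponse.response_table(cohort.hemodynamics, carrier_ids, analysis_ids)
            for var in ("PVR", "cardiac_index"):
                res = vasoresponse.genotype_response_model(
                    rt[f"{var}_pct_change"], rt["carrier"], rt[f"{var}_baseline"], outcome=var
                )
                rows.append(dataclasses.asdict(res))
        else:
            logger.warning("fewer than 2 tested carriers; vasoreactivity stage skipped")
        emit("vasoreactivity", pd.DataFrame(
            rows, columns=["outcome", "ls_mean_difference", "ci_low", "ci_high",
                           "p_value", "n_carriers", "n_noncarriers"]
        ))

    return StudyReport(tables, paths, funnel, cohort)
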