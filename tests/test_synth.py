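"""Cohort generator: determinism, planted structure, and the disk round trip."""

import filecmp
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from pahrare.synth import (
    CohortParseError,
    SimulationConfig,
    generate_cohort,
    read_cohort,
    write_cohort,
)
from tests.conftest import small_config


def test_config_validation_rejects_bad_values():
    with pytest.raises(ValueError):
        SimulationConfig(case_carrier_freq=1.2)
    with pytest.raises(ValueError):
        SimulationConfig(n_controls=0)
    with pytest.raises(ValueError):
        SimulationConfig(common_maf_range=(0.0, 0.5))
    with pytest.raises(ValueError):
        SimulationConfig(n_related_pairs={"cousin": 1})


def test_cohort_sizes_and_truth_consistency(default_cohort):
    """Arm sizes are forced by the config and the truth roster matches genotypes."""
    c = default_cohort
    counts = c.subjects.groupby("cohort").size()
    assert counts["discovery"] == 42
    assert counts["replication"] == 188
    assert counts["control"] == 968
    assert c.genotypes.values.shape == (len(c.subjects), len(c.variants))

    causal_sites = set(c.variants.loc[c.variants["gene"] == "PTGIS", "site_id"])
    cols = [c.genotypes.site_index(s) for s in sorted(causal_sites)]
    planted = c.truth.carriers
    # every planted carrier is heterozygous at exactly one causal site ...
    for _, row in planted.iterrows():
        dosages = c.genotypes.row(row["subject_id"])[cols]
        assert np.sum(dosages == 1) == 1
        assert np.all(dosages != 2), "homozygous rare genotypes are never planted"
    # ... and nobody else carries a causal-gene variant
    carriers_in_matrix = {
        c.genotypes.subject_ids[i]
        for i in np.nonzero((c.genotypes.values[:, cols] == 1).any(axis=1))[0]
    }
    assert carriers_in_matrix == set(planted["subject_id"])


def test_zero_carrier_config_yields_empty_roster():
    cfg = small_config(case_carrier_freq=0.0, control_carrier_freq=0.0)
    c = generate_cohort(cfg)
    assert len(c.truth.carriers) == 0
    causal_cols = [
        c.genotypes.site_index(s)
        for s in c.variants.loc[c.variants["gene"] == cfg.causal_gene, "site_id"]
    ]
    assert not (c.genotypes.values[:, causal_cols] != 0).any()


def test_determinism_byte_identical(tmp_path):
    """Identical config + seed produce byte-identical cohort directories."""
    cfg = small_config(seed=5)
    for sub in ("a", "b"):
        write_cohort(generate_cohort(cfg), tmp_path / sub)
    files = sorted(p.name for p in (tmp_path / "a").iterdir())
    match, mismatch, errors = filecmp.cmpfiles(
        tmp_path / "a", tmp_path / "b", files, shallow=False
    )
    assert not mismatch and not errors
    assert set(match) == set(files)


def test_carrier_frequency_calibration():
    """Mean planted carrier fractions track the configured frequencies.

    200 replicates at the study's default carrier frequencies and arm sizes
    (background and kinship loads reduced; they do not enter the counts).
    """
    reps = 200
    case_p, ctrl_p = 0.061, 0.008
    n_cases, n_ctrl = 230, 968
    case_fracs, ctrl_fracs = [], []
    for seed in range(reps):
        cfg = SimulationConfig(
            seed=seed,
            n_background_genes=0,
            background_hit_rate=0.0,
            n_common_snps=0,
        )
        c = generate_cohort(cfg)
        carriers = c.truth.carriers["subject_id"]
        is_case = carriers.str[0].isin(["D", "R"])
        case_fracs.append(is_case.sum() / n_cases)
        ctrl_fracs.append((~is_case).sum() / n_ctrl)
    se_case = np.sqrt(case_p * (1 - case_p) / (n_cases * reps))
    se_ctrl = np.sqrt(ctrl_p * (1 - ctrl_p) / (n_ctrl * reps))
    assert abs(np.mean(case_fracs) - case_p) < 3 * se_case
    assert abs(np.mean(ctrl_fracs) - ctrl_p) < 3 * se_ctrl


def test_background_hits_are_singleton_dominated(default_cohort):
    """Most background-hit genes carry a variant in exactly one case genome."""
    c = default_cohort
    bg = c.variants[c.variants["site_id"].str.startswith("bg")]
    cols = [c.genotypes.site_index(s) for s in bg["site_id"]]
    het = c.genotypes.values[:, cols] == 1
    # count distinct carrier subjects per gene
    subj_idx, site_idx = np.nonzero(het)
    per_gene = (
        pd.DataFrame({"gene": bg["gene"].to_numpy()[site_idx], "subject": subj_idx})
        .groupby("gene")["subject"]
        .nunique()
    )
    singleton_frac = (per_gene == 1).mean()
    assert singleton_frac > 0.8


def test_common_snps_in_hwe(default_cohort):
    """Common SNP genotype frequencies follow Hardy-Weinberg expectations."""
    c = default_cohort
    snps = c.variants["site_id"].str.startswith("snp").to_numpy()
    g = c.genotypes.values[:, snps].astype(float)
    p_hat = g.mean(axis=0) / 2.0
    het_obs = (g == 1).mean(axis=0)
    het_exp = 2 * p_hat * (1 - p_hat)
    # averaged over 10^4 sites the HWE excess should be tiny
    assert abs((het_obs - het_exp).mean()) < 0.005


def test_duplicate_pair_has_phi_half_exactly():
    from pahrare.kinship import king_robust_pair

    cfg = SimulationConfig(
        seed=7,
        n_background_genes=0,
        background_hit_rate=0.0,
        n_common_snps=10_000,
        n_related_pairs={"duplicate": 1},
    )
    c = generate_cohort(cfg)
    i = c.genotypes.subject_index("C0001")
    j = c.genotypes.subject_index("C0002")
    res = king_robust_pair(c.genotypes.values[i], c.genotypes.values[j])
    assert res.phi == 0.5
    assert res.degree_class == "duplicate"


def test_roundtrip_identity(tmp_path, small_cohort):
    write_cohort(small_cohort, tmp_path)
    c2 = read_cohort(tmp_path)
    assert c2.genotypes == small_cohort.genotypes
    pd.testing.assert_frame_equal(c2.subjects, small_cohort.subjects)
    pd.testing.assert_frame_equal(
        c2.variants, small_cohort.variants.reset_index(drop=True), check_dtype=False
    )
    pd.testing.assert_frame_equal(
        c2.hemodynamics, small_cohort.hemodynamics, check_dtype=False
    )
    pd.testing.assert_frame_equal(c2.truth.carriers, small_cohort.truth.carriers)
    assert c2.truth.pvr_effect == small_cohort.truth.pvr_effect
    assert c2.config == small_cohort.config


def test_read_rejects_out_of_range_frequency(tmp_path, small_cohort):
    paths = write_cohort(small_cohort, tmp_path)
    var_path = Path(paths["variants"])
    lines = var_path.read_text().splitlines()
    header = lines[0].split("\t")
    fields = lines[1].split("\t")
    fields[header.index("af_panel1")] = "1.2"
    lines[1] = "\t".join(fields)
    var_path.write_text("\n".join(lines) + "\n")
    with pytest.raises(CohortParseError, match=r"line 2"):
        read_cohort(tmp_path)


def test_empty_hemodynamics_file_is_valid(tmp_path, small_cohort):
    paths = write_cohort(small_cohort, tmp_path)
    Path(paths["hemodynamics"]).write_text("")
    c2 = read_cohort(tmp_path)
    assert len(c2.hemodynamics) == 0
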