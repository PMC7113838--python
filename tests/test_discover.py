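"""Rare-deleterious filter, gene aggregation, prioritization and known-gene screen."""

import numpy as np
import pandas as pd
import pytest

from pahrare.discover import (
    KNOWN_PAH_GENES,
    FilterCriteria,
    GeneCarrierMap,
    VariantSite,
    discover_candidates,
    prioritize_genes,
    qualify_variant,
    qualifying_mask,
    screen_known_pah_genes,
)
from pahrare.synth import PANEL_COLUMNS, PREDICTOR_COLUMNS


def make_site(freqs=(0.004,) * 4, chinese=False, flags=(True,) * 4, csq="missense"):
    return VariantSite(
        site_id="s1",
        gene="G1",
        chrom="1",
        pos=100,
        ref="A",
        alt="T",
        panel_freqs=dict(zip(PANEL_COLUMNS, freqs)),
        in_chinese_1kg=chinese,
        deleterious_flags=dict(zip(PREDICTOR_COLUMNS, flags)),
        consequence=csq,
    )


@pytest.mark.parametrize(
    "site, expected",
    [
        # rare in all four panels, absent from the Chinese panel, unanimous flags
        (make_site(), True),
        # one panel at 0.6% violates the <0.5% threshold
        (make_site(freqs=(0.006, 0, 0, 0)), False),
        # present in the Chinese panel while absence is required
        (make_site(freqs=(0,) * 4, chinese=True), False),
        # threshold is strict: exactly 0.5% fails
        (make_site(freqs=(0.005,) * 4), False),
        # one dissenting predictor under the unanimity rule
        (make_site(flags=(True, True, True, False)), False),
        # canonical splice variant is deleterious by consequence class alone
        (make_site(flags=(False,) * 4, csq="splice"), True),
    ],
)
def test_qualify_variant(site, expected):
    assert qualify_variant(site, FilterCriteria()) is expected


def test_qualify_deleterious_rules():
    site = make_site(flags=(True, True, False, False))
    assert not qualify_variant(site, FilterCriteria(deleterious_rule="all"))
    assert not qualify_variant(site, FilterCriteria(deleterious_rule="majority"))
    assert qualify_variant(site, FilterCriteria(deleterious_rule="any"))
    with pytest.raises(ValueError):
        FilterCriteria(deleterious_rule="consensus")


def test_missing_panel_frequency_treated_as_absent(caplog):
    site = make_site(freqs=(np.nan, 0.001, 0.001, 0.001))
    with caplog.at_level("WARNING"):
        assert qualify_variant(site, FilterCriteria())
    assert "missing frequency" in caplog.text


def test_variant_site_invariants():
    with pytest.raises(ValueError, match="ref equals alt"):
        VariantSite("s", "G", "1", 1, "A", "A", {"p": 0.0}, False, {"t": True})
    with pytest.raises(ValueError, match="outside"):
        VariantSite("s", "G", "1", 1, "A", "T", {"p": 1.5}, False, {"t": True})
    with pytest.raises(ValueError, match="panel"):
        VariantSite("s", "G", "1", 1, "A", "T", {}, False, {"t": True})


def brute_force_candidates(cohort, criteria):
    """Exhaustive double loop over all subject x site pairs (oracle)."""
    gmap = GeneCarrierMap()
    cases = set(cohort.subjects.loc[cohort.subjects["group"] == "case", "subject_id"])
    for _, site in cohort.variants.iterrows():
        vs = VariantSite.from_row(site)
        if not qualify_variant(vs, criteria):
            continue
        j = cohort.genotypes.site_index(site["site_id"])
        for i, subj in enumerate(cohort.genotypes.subject_ids):
            if subj in cases and cohort.genotypes.values[i, j] == 1:
                gmap.add(site["gene"], subj, site["site_id"])
    return gmap


def test_discover_matches_brute_force_oracle(small_cohort):
    crit = FilterCriteria()
    fast = discover_candidates(small_cohort, crit)
    slow = brute_force_candidates(small_cohort, crit)
    assert fast.pairs == slow.pairs


def test_maf_zero_gives_empty_map(small_cohort):
    gmap = discover_candidates(small_cohort, FilterCriteria(maf_max=0.0))
    assert len(gmap) == 0


def test_homozygous_alt_subject_excluded(small_cohort):
    import copy

    c = copy.copy(small_cohort)
    c.genotypes = copy.deepcopy(small_cohort.genotypes)
    crit = FilterCriteria()
    gmap = discover_candidates(c, crit)
    gene = c.config.causal_gene
    subj, site = next(iter(gmap.pairs[gene]))
    c.genotypes.values[c.genotypes.subject_index(subj), c.genotypes.site_index(site)] = 2
    gmap2 = discover_candidates(c, crit)
    assert (subj, site) not in gmap2.pairs.get(gene, set())


def test_missing_site_in_variant_table_raises(small_cohort):
    import copy

    c = copy.copy(small_cohort)
    c.variants = small_cohort.variants.iloc[:-1]
    with pytest.raises(ValueError, match="absent from the variant table"):
        discover_candidates(c, FilterCriteria())


def test_filter_monotonicity(small_cohort):
    """Lowering maf_max or strengthening the consensus rule never adds candidates."""
    v = small_cohort.variants

    def qual_set(criteria):
        return set(v.loc[qualifying_mask(v, criteria), "site_id"])

    loose = qual_set(FilterCriteria(maf_max=0.005, deleterious_rule="any"))
    tighter_maf = qual_set(FilterCriteria(maf_max=0.001, deleterious_rule="any"))
    stricter_rule = qual_set(FilterCriteria(maf_max=0.005, deleterious_rule="all"))
    assert tighter_maf <= loose
    assert stricter_rule <= loose


def test_subject_with_two_variants_counts_once():
    gmap = GeneCarrierMap()
    gmap.add("G1", "s1", "v1")
    gmap.add("G1", "s1", "v2")
    gmap.add("G1", "s2", "v3")
    assert gmap.carrier_counts == {"G1": 2}


def test_prioritize_threshold_order_and_expression(caplog):
    gmap = GeneCarrierMap()
    for s in ("a", "b", "c"):
        gmap.add("SHARED3", s, f"v_{s}")
    for s in ("a", "b", "c", "d"):
        gmap.add("SHARED4", s, f"w_{s}")
    gmap.add("SINGLE", "a", "x")
    gmap.add("PAIR", "a", "y1")
    gmap.add("PAIR", "b", "y2")
    expression = pd.DataFrame({"gene": ["SHARED4"], "tissues": ["lung;liver"]})
    with caplog.at_level("WARNING"):
        out = prioritize_genes(gmap, FilterCriteria(), expression)
    assert list(out["gene"]) == ["SHARED4", "SHARED3"]  # count desc, PAIR/SINGLE dropped
    assert list(out["expressed"]) == [True, False]
    assert "SHARED3" in caplog.text  # missing from the expression table, logged

    # all genes below the threshold -> empty list
    below = prioritize_genes(gmap, FilterCriteria(min_shared_carriers=5), expression)
    assert len(below) == 0

    with pytest.raises(ValueError):
        prioritize_genes(GeneCarrierMap(), FilterCriteria(), expression)


def test_known_gene_screen(small_cohort):
    import copy

    c = copy.copy(small_cohort)
    c.variants = small_cohort.variants.copy()
    c.genotypes = copy.deepcopy(small_cohort.genotypes)
    subjects = list(c.subjects.loc[c.subjects["cohort"] == "discovery", "subject_id"])

    # no variants annotated to the 17 known genes -> everyone passes
    assert screen_known_pah_genes(c, subjects).empty

    # plant a rare-deleterious BMPR2 variant in one subject: flagged
    row = {
        "site_id": "bmpr2_1", "gene": "BMPR2", "chrom": "2", "pos": 1, "ref": "C",
        "alt": "T", "consequence": "missense", "in_chinese_1kg": False,
        **{p: 0.0001 for p in PANEL_COLUMNS}, **{p: True for p in PREDICTOR_COLUMNS},
    }
    # and a common (2%) BMPR2 variant in another: not flagged by the rare screen
    common = dict(row, site_id="bmpr2_2", pos=2, **{p: 0.02 for p in PANEL_COLUMNS})
    c.variants = pd.concat([c.variants, pd.DataFrame([row, common])], ignore_index=True)
    g = c.genotypes
    extra = np.zeros((len(g.subject_ids), 2), dtype=np.int8)
    extra[g.subject_index(subjects[0]), 0] = 1
    extra[g.subject_index(subjects[1]), 1] = 1
    from pahrare.synth import GenotypeMatrix

    c.genotypes = GenotypeMatrix(
        np.hstack([g.values, extra]), g.subject_ids, g.site_ids + ["bmpr2_1", "bmpr2_2"]
    )
    hits = screen_known_pah_genes(c, subjects)
    assert list(hits["subject_id"]) == [subjects[0]]
    assert list(hits["gene"]) == ["BMPR2"]

    with pytest.raises(ValueError):
        screen_known_pah_genes(c, subjects, gene_list=[])
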