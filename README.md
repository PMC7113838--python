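# pahrare

Rare-variant discovery and burden-association analysis for idiopathic
pulmonary arterial hypertension (IPAH) cohorts, with relatedness QC,
splice-consequence arithmetic and genotype-stratified vasodilator-response
modelling. Written for statistical geneticists and clinical researchers who
want a tested, seeded, end-to-end implementation of the two-stage
(discovery + replication) rare-variant study design — runnable entirely on a
synthetic cohort generator, so no subject-level data are required.

## What it computes

- **Dominant-model candidate filter**: a variant qualifies when its minor
  allele frequency is < 0.5% in every reference panel, it is absent from the
  Chinese 1000 Genomes panel and predicted deleterious; carriers are
  heterozygous subjects, counted once per gene. Genes with ≥ 3 distinct
  carriers and abundant lung expression are the follow-up candidates, and a
  17-gene known-PAH screen flags subjects for exclusion.
- **KING-robust kinship**: φ = (N_het,het − 2·N_opp.hom) / (N_het(i)+N_het(j))
  over shared SNPs, with the conventional degree cutoffs (0.0884 separating
  2nd from 3rd degree) for case-control unrelatedness QC.
- **2×2 burden statistics**: OR = ad/bc with Wald 95% CI
  exp(ln OR ± 1.959964·SE), SE = √(1/a+1/b+1/c+1/d); the equivalent logistic
  fit; two-sided Fisher exact; continuity-adjusted χ² with the correction
  truncated at zero; "NE" for zero cells.
- **Vasoreactivity ANCOVA**: percent change of PVR and cardiac index after
  inhaled iloprost regressed on {intercept, carrier indicator, baseline};
  the carrier coefficient is the least-squares-mean difference, with a
  t-based 95% CI, on carriers vs 3:1 age/sex-matched non-carriers.
- **Splice arithmetic**: exon-skip frame analysis (deleted nt mod 3),
  HGVS-style protein deletion naming, and cryptic-donor premature-stop
  scanning on a packaged synthetic transcript model.

See `docs/methods.md` for the full model description and design choices.

## Worked example

From printed carrier counts alone (`examples/04_association.py`):

```
        variant  case_carriers  case_n  case_pct  control_carriers  control_n  control_pct  p_value           or_ci
splice donor +1              1     230       0.4                 0        968          0.0       NE              NE
     missense 1              5     230       2.2                 2        968          0.2  0.00472 10.7 (2.1-55.7)
     missense 2              8     230       3.5                 6        968          0.6  0.00129  5.8 (2.0-16.8)
       combined             14     230       6.1                 8        968          0.8 5.05e-06  7.8 (3.2-18.8)

Fisher exact p (combined): 4.8e-06
discovery vs replication consistency: chi2 = 0.0013, p = 0.97
pediatric vs adult carriers:          chi2 = 0.0000, p > .99
```

Reading: 6.1% of cases vs 0.8% of controls carry a qualifying variant, a
7.8-fold odds of disease (95% CI 3.2–18.8); the splice-variant row is not
estimable because no control carries it; and the near-zero χ² statistics say
the carrier rate is consistent between cohorts and between pediatric and
adult cases.

The splice-consequence example (`examples/06_splice_consequences.py`):

```
exon-4 skip: 144 nt removed, frame-preserving = True
  deletes 48 residues -> p.Thr127_Arg174del

cryptic donor +371 nt: retains 371 intronic bases
  premature termination codon: True (codon 176; exon-4 product ends at codon 174)
```

Each script in `examples/` is a short narrative of one capability:
simulation, discovery, kinship QC, association, vasoreactivity, splice
consequences, and the full pipeline (`07_full_study.py`, also available as
the `pahrare run-all` CLI subcommand).

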