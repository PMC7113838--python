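# Methods

`pahrare` implements a two-stage rare-variant discovery and burden-association
analysis for idiopathic pulmonary arterial hypertension (IPAH), together with
the relatedness QC, splice-consequence arithmetic and vasodilator-response
modelling that such a study needs. Because no subject-level data are
distributable, every stage is exercised against a synthetic cohort generator
whose defaults encode the study conditions, plus the printed contingency
counts of the published association table, which are exact inputs in their
own right.

## Study model

Subjects are cases (a small whole-genome-sequenced *discovery* arm and a
larger *replication* arm genotyped only at the candidate gene) and healthy
controls. The genetic model is dominant: a subject is a *carrier* of a gene
when heterozygous at at least one qualifying rare variant in it, counted once
regardless of how many such variants they hold. A variant qualifies when its
minor allele frequency is strictly below `maf_max` (default 0.5%) in every
reference panel, it is absent from the Chinese 1000 Genomes panel, and it is
predicted deleterious. Panels and in-silico predictors are configuration-named
columns (four generic panels, four predictor flags) rather than hard-coded
database identities. The deleteriousness consensus is configurable
(`all`/`majority`/`any`, default `all` — the strictest reading, minimising
false candidates); canonical splice-site variants count as deleterious by
consequence class alone, since a ±1 donor substitution disrupts splicing
regardless of missense-oriented predictor output. Missing panel frequencies
are treated as 0 (absence from a panel is itself evidence of rarity) with a
logged warning.

Discovery-stage prioritization keeps genes with ≥ `min_shared_carriers`
distinct carriers (default 3), ranks by carrier count (ties broken by gene
symbol for determinism) and flags abundant expression in the target tissue
(default lung). A separate screen reports rare-deleterious hits in the 17
established PAH risk genes; any hit marks the subject for exclusion.

## Association statistics

All case-control contrasts reduce to a 2×2 carrier table (a, b; c, d).

- **Odds ratio**: cross-product ad/bc; Wald 95% CI
  `exp(ln OR ± z · sqrt(1/a + 1/b + 1/c + 1/d))` with z = 1.959964; two-sided
  Wald p from `ln OR / SE`. Any zero cell makes the result *not estimable*
  ("NE") unless the Haldane–Anscombe +0.5 correction is explicitly enabled.
- **Logistic fit**: maximum-likelihood logit of status on the exposure
  indicator. For a saturated 2×2 design this equals the cross-product ratio;
  the package keeps both routes and tests their agreement to 1e-6 relative.
  The p-value is the Wald test of the slope; with the published combined
  counts (14/230 vs 8/968) it reproduces the printed 5 × 10⁻⁶.
- **Continuity-adjusted χ²**: Yates correction with the adjustment truncated
  at zero, `Σ max(|O−E|−0.5, 0)² / E`. The truncation matters: in the
  pediatric-vs-adult comparison every |O−E| is below 0.5, so the statistic is
  exactly 0 and p rounds to > .99.
- **Fisher exact**: two-sided hypergeometric summation of tables no more
  probable than the observed one.
- **Reporting**: ORs/CIs and percentages to one decimal with half-up
  rounding; internal values keep full precision.

## Relatedness QC

The between-family ("robust") KING estimator,
`φ = (N_het,het − 2·N_opposite_hom) / (N_het(i) + N_het(j))`, computed over
sites non-missing in both subjects. It needs no allele-frequency estimates
and is the standard case-control QC statistic. Degree classes use the
powers-of-two cutoffs (≥ 2⁻¹·⁵ duplicate, then 1st/2nd/3rd degree halving
down to 2⁻⁴·⁵); the unrelatedness screen uses 2⁻³·⁵ ≈ 0.0884, the boundary
between 2nd- and 3rd-degree relatives. Sites missing in either member are
dropped pairwise, never imputed. A pair with no heterozygous sites has an
undefined φ and is flagged not-estimable. The all-pairs computation is
vectorized through indicator-matrix products and verified against the
pairwise definition.

## Vasoreactivity model

For each tested subject the outcome is the percent change
`100 (post − baseline) / baseline` of pulmonary vascular resistance (PVR,
Wood units) and cardiac index (L/min/m²) after inhaled prostacyclin
(iloprost). Carriers are compared with non-carriers matched greedily within
sex by nearest age, without replacement, at ratio 3:1 (ties broken by
smallest subject id; the matching algorithm is a package choice, tested to be
within 2 years of the exhaustive-optimal assignment on small instances).

The contrast is an ANCOVA: OLS of the percent change on an intercept, the
carrier indicator and the baseline value. The carrier coefficient *is* the
least-squares-mean difference at the common mean baseline — for a two-group
additive model the two readings coincide, which is the only interpretation
consistent with "genotype and baseline as predictors". The 95% CI uses t
critical values at the residual degrees of freedom (at n = 48 the difference
from the normal quantile is within printed rounding). Degenerate inputs
(single group, baseline constant within groups) raise rather than fit.

The hemodynamic PAH diagnostic rule is mPAP ≥ 25 mm Hg, PAWP ≤ 15 mm Hg and
PVR > 3 Wood units (strict on PVR).

## Splice-consequence arithmetic

A transcript is modelled as ordered exon sequences, a CDS offset/length and
intron sequences. Skipping an internal fully coding exon deletes its length
in nucleotides; the frame is preserved iff that length is a multiple of 3,
and the deleted residue interval is located by comparing the translated
products (equal to the exon's codon interval when the exon is codon-aligned).
A cryptic donor at +k retains the first k intronic bases; the resulting frame
is scanned codon-by-codon for the first stop, which is a premature
termination codon (PTC) when it precedes the natural stop's position.
Frame-preserving deletions are named HGVS-style
(`p.Thr127_Arg174del`; single-residue form `p.Xaa10del`).

The packaged transcript model is **synthetic**: a constructed five-exon
prostacyclin-synthase-like minigene (500-residue protein) whose internal
exon 4 is 144 nt and codon-aligned, spanning Thr127–Arg174, with an in-frame
stop placed one codon into intron 4 so a cryptic donor 371 nt downstream
yields a PTC immediately after the exon-4-derived product. Nothing is
downloaded; the fixture exists so that every printed consequence of the +1
donor variant is checkable deterministically. Note the codon-aligned fixture
places the donor after CDS position 522; real donor-site variants of this
kind sit one base into a non-aligned exon boundary, which changes the HGVS
cDNA label but not the arithmetic.

## Synthetic cohort generator

Defaults encode the study conditions: 42 discovery cases, 188 replication
cases, 968 controls; carrier probability 6.1% per case and 0.8% per control,
drawn binomially and planted heterozygously at exactly one of three
causal-gene sites (one splice, two missense; the splice site is case-private
in the site-assignment weights). Homozygous rare genotypes are never planted
— the modelled findings are exclusively heterozygous.

Background rare variants exist only in discovery-arm genomes (only that arm
is whole-genome sequenced): each of the 42 genomes receives Poisson(47.3)
hits scattered uniformly over 8600 background genes, giving a per-gene rate
of ≈ 0.23 over the arm, which reproduces the qualitative funnel of a
small-cohort screen — on the order of 1700–1800 genes hit, ≈ 88–90% by a
single case, and a handful shared by ≥ 3 carriers. These two constants are
the package's calibration of an otherwise unreported background distribution.
Panel frequencies for background hits are log-uniform on [10⁻⁵, 0.005); 90%
of hits are unanimously flagged deleterious, the rest get random predictor
flags so the filter has true negatives to reject. The causal gene is always
lung-expressed; 25% of background genes are, so the expression filter is
discriminative but not trivial.

Kinship SNPs: 10⁴ common biallelic sites with MAF uniform on [0.05, 0.5],
genotypes in Hardy–Weinberg equilibrium. Relative pairs can be planted among
controls by gamete sharing (duplicate: copied vector; 1st degree: one allele
always transmitted; 2nd degree: transmitted with probability ½), giving
expected φ of 0.5 / 0.25 / 0.125.

Hemodynamics: every case gets paired baseline / post-iloprost records.
Baselines are truncated-normal draws around pooled means (mPAP 60 (17) mm Hg,
PAWP 8.4 (4.2) mm Hg, PVR 15.3 (8.5) WU, RAP 7.6 (6.0) mm Hg, cardiac index
2.6 (1.0) L/min/m², SvO₂ 63 (13)%). The percent change of PVR and cardiac
index is group mean (−10 / +10 for non-carriers) plus the planted carrier
effect (−21.7 / +18.3 points), a baseline-linked term (−0.5 %/WU and
−5 %/(L/min/m²) around the mean baseline) and Gaussian noise with SD 14.5
points — the residual scale implied by the published CI width at 12 vs 36
subjects. Noise is Gaussian on the percent-change scale because that is the
scale of the linear model. Other variables change by noise only.

What the generator does **not** emulate: linkage disequilibrium, population
structure/admixture, sequencing error, genotype missingness patterns,
variant-calling artefacts, per-gene mutation-rate heterogeneity, or any
correlation between genotype and demographics beyond the planted effects.
Passing tests therefore demonstrate correctness of the statistical machinery
under the stated model, not robustness to those real-data complications.

## Numerical and design choices

- Determinism everywhere: one integer seed drives the generator; cohort
  directories and pipeline report bundles are byte-identical across runs.
- Frequency threshold comparison is strict (< 0.005), matching "less than
  0.5%".
- Tie-breaks are lexicographic (gene symbols, subject ids) so ranked outputs
  are reproducible.
- The odds-ratio "NE" policy matches published tables; the +0.5 correction is
  opt-in and labelled.
- The published kinship summaries (99.9% below 0.0884, maximum 0.1400) are
  data-dependent quantities of the original cohort; the package treats the
  thresholds as conventions and verifies the estimator's calibration by
  Monte-Carlo instead.
- The logistic p-value is the Wald test (the published table does not state
  Wald/LR/score; Wald reproduces the printed values and is the default).
- Pipeline two-stage logic: gene discovery uses the discovery arm only;
  association pools both case arms against controls.
- When the non-carrier pool cannot supply the requested matching ratio, the
  pipeline steps the ratio down (logging the change) and, as a last resort,
  compares against the whole pool; the standalone `match_controls` operation
  still raises, reporting the per-sex deficit.

## Problem sizes used in the test and acceptance suites

Chosen as the package's own balance of statistical resolution and runtime:
planted-gene recovery over 100 seeds at the default carrier frequencies and
background load (kinship SNPs reduced to 50 there, since kinship does not
enter that property); ANCOVA recovery over 500 replicates of 12 carriers vs
36 matched non-carriers; Fisher type-I calibration from 2000 null draws of
the two binomial carrier counts (230 and 968 subjects at 0.8%); KING
calibration at 10⁴ SNPs with 30–40 Monte-Carlo replicates per degree;
logistic-vs-cross-product agreement on 1000 random tables with cells up to
2000. The carrier-frequency calibration property uses 200 replicates with
the background and kinship loads switched off, which leaves the binomial
planting untouched.

## Known limitations

- Carrier planting is exchangeable across subjects; there is no per-family or
  per-site clustering beyond the three-site assignment weights.
- The expression table is a binary lung/systemic label, not expression
  levels.
- `match_controls` is greedy, not optimal; adversarial age distributions can
  make it worse than the assignment optimum (tests bound the gap on realistic
  instances only).
- The pipeline's known-gene screen is only exercised with injected variants,
  as the generator does not name background genes after real loci.
- Gene-based score/burden tests (SKAT-style), covariate-adjusted association,
  CNV/SV detection and ancestry PCA are out of scope.
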