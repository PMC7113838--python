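"""Generate a synthetic two-stage IPAH study and look at its planted structure.

The generator emulates a 42-case whole-genome discovery arm, a 188-case
replication arm and 968 controls, with heterozygous rare variants planted in
one causal gene at ~6.1% (cases) and ~0.8% (controls) carrier frequency.
"""

import tempfile

from pahrare import SimulationConfig, generate_cohort, write_cohort

config = SimulationConfig(seed=1)
cohort = generate_cohort(config)

print("subjects per arm:")
print(cohort.subjects.groupby("cohort").size().to_string())
print(f"\ngenotyped sites: {len(cohort.variants)}")

carriers = cohort.truth.carriers
groups = cohort.subjects.set_index("subject_id")["group"]
n_case = sum(groups[s] == "case" for s in carriers["subject_id"])
n_ctrl = len(carriers) - n_case
print(f"planted carriers: {n_case} cases ({n_case / 230:.1%}), "
      f"{n_ctrl} controls ({n_ctrl / 968:.1%})")

outdir = tempfile.mkdtemp(prefix="pahrare_cohort_")
paths = write_cohort(cohort, outdir)
print(f"\nwrote {len(paths)} plain-text files (VCF + TSV sidecars) to {outdir}")

# The carrier counts are binomial draws around the configured frequencies,
# so they wobble around 14/230 and 8/968 from seed to seed.
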