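"""Genotype-stratified acute vasodilator response (ANCOVA).

Carriers of the causal-gene variants are compared with age- and sex-matched
non-carriers on the percent change of pulmonary vascular resistance (PVR)
and cardiac index after inhaled prostacyclin, adjusting for the baseline
value. The generator plants a -21.7 point PVR and +18.3 point cardiac-index
carrier effect by default.
"""

from pahrare import SimulationConfig, generate_cohort
from pahrare.vasoresponse import genotype_response_model, match_controls, response_table

cohort = generate_cohort(SimulationConfig(seed=4))
carrier_ids = set(cohort.truth.carriers["subject_id"])
cases = cohort.subjects[cohort.subjects["group"] == "case"]
carriers = cases[cases["subject_id"].isin(carrier_ids)]
pool = cases[~cases["subject_id"].isin(carrier_ids)]

matched = match_controls(carriers, pool, ratio=3)
print(f"{len(carriers)} carriers matched to {len(matched)} non-carriers (3:1, age/sex)")

ids = list(carriers["subject_id"]) + list(matched["subject_id"])
rt = response_table(cohort.hemodynamics, carrier_ids, ids)
for outcome in ("PVR", "cardiac_index"):
    res = genotype_response_model(
        rt[f"{outcome}_pct_change"], rt["carrier"], rt[f"{outcome}_baseline"],
        outcome=outcome,
    )
    print(f"{outcome:14s} LS-mean difference = {res.ls_mean_difference:+6.1f} points "
          f"(95% CI {res.ci_low:+.1f} to {res.ci_high:+.1f}), p = {res.p_value:.2g}")

# The carrier coefficient is the baseline-adjusted difference in mean percent
# change; with the default planted effects it lands near -21.7 (PVR) and
# +18.3 (cardiac index), within its CI.
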