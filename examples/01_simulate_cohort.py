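"""Simulate a synthetic resting-state cohort and inspect its structure.

The generator emulates a two-group elderly cohort (subjective cognitive
decline vs normal controls): band-limited BOLD-like ROI time series on a
300-ROI parcellation, demographic covariates, motion summaries and clinical
rating scales.
"""

from dynconn import SimulationSpec, filter_defined_networks, simulate_cohort

spec = SimulationSpec(seed=42)
cohort = simulate_cohort(spec, rng=42, update_scores=False)

print(f"subjects: {cohort.n_subjects} {cohort.group_sizes()}")
print(f"atlas ROIs: {cohort.atlas.n_roi} "
      f"({filter_defined_networks(cohort.atlas).n_roi} in named networks)")

first = next(iter(cohort.series.values()))
print(f"series shape per subject: {first.data.shape} at TR {first.tr} s")

pheno = cohort.phenotypes
print("\nAD8 (subjective complaints) by group — the score that defines SCD:")
print(pheno.groupby("group")["AD8"].agg(["mean", "std"]).round(2))
# SCD subjects report complaints (AD8 >= 2); controls score 0-1.
print("\nage by group — balanced by design, so the GLM covariate carries "
      "no group signal:")
print(pheno.groupby("group")["age"].agg(["mean", "std"]).round(2))
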