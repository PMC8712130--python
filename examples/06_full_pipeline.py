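"""Run the complete analysis on a simulated cohort in one call.

Simulates the cohort, preprocesses every session, computes cluster band
powers and the engagement index, scores behavior, and prints the behavioral
and neurophysiological ANOVA tables plus the EI-RT correlation.

A 5-subject cohort keeps this example quick; the study-sized default is
11 subjects (RunConfig()).
"""

from vwm.pipeline import RunConfig, run_pipeline

report = run_pipeline(RunConfig(seed=1, n_subjects=5))

print("behavioral ANOVA:")
print(report.anova_behavior[["measure", "effect", "F", "p",
                             "partial_eta_sq"]].round(4).to_string(index=False))
print("\nneurophysiological ANOVA (selected cluster/band combos + EI):")
print(report.anova_eeg[["cluster", "band", "effect", "F", "p",
                        "partial_eta_sq"]].round(4).to_string(index=False))
print("\nengagement-RT correlation across subject x condition cells:")
print(report.correlation.round(4).to_string(index=False))
print("\nepoch rejection QC:")
print(report.qc.to_string(index=False))
# expected pattern: load effects on RT/ACC/IES and on frontal/midline/left
# theta; a load-by-modality interaction on parietal gamma; EI varying with
# load and correlating negatively with RT
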