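"""Full cohort analysis on a synthetic two-group cohort.

Synthesizes 8 controls and 8 patients (pathology in noise level and
voice-break rate only), extracts all measures, compares the groups with
effect sizes, classifies each subject's affected phonatory dimensions,
and searches feature combinations with the RBF-SVM.

Run:  python examples/cohort_analysis.py     (~1 minute)
"""

import dysphonia as dp
from dysphonia.classify import CvConfig

cv = CvConfig(repeats=5, max_subset_size=2, seed=0,
              c_grid=(1.0, 10.0, 100.0), gamma_grid=(1.0,), inner_folds=2)
result = dp.demo_end_to_end(seed=1, n_per_group=8, cv_config=cv)

report = result["report"]
cols = ["measure", "mean_prehd", "mean_control", "test", "p", "significant", "cohens_d"]
print(report[cols].round(3).to_string(index=False))

print("\npercent of subjects with each phonatory dimension affected:")
print(result["wald"]["percent_affected"].round(1))

best = result["svm"][0]
print(
    f"\nbest marker combination: {'+'.join(best.features)} — "
    f"sensitivity {best.sensitivity_mean:.1f}±{best.sensitivity_sd:.1f} %, "
    f"specificity {best.specificity_mean:.1f}±{best.specificity_sd:.1f} %"
)
print(
    "\nthe injected pathology (noise + breaks) surfaces as higher NVB, DPB\n"
    "and DFA and lower HNR in the patient group; the winning marker\n"
    "combination is built on break- and noise-sensitive measures, which\n"
    "in audio inevitably co-vary (breaks also shorten FOVB, noise also\n"
    "raises RPDE and the MFCC indices)."
)
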