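"""ROC threshold selection for the two clinical contrasts.

Builds a synthetic cohort (200 region means per side, matched to the
published class distributions) and selects Youden operating thresholds
for cancer-vs-non-tumorous and precancer(EIN)-vs-benign contrasts, per
modality.  Sensitivity/specificity are reported in percent.
"""

from mmoct import ContrastSpec, roc, select_threshold, synthetic_measurement_table
from mmoct.diagnostics import ec_vs_non_tumorous, ein_vs_benign
from mmoct.reference import split_n_across

counts = split_n_across(
    ("proliferative", "secretory", "atrophic", "non_atypical", "EIN",
     "EC_low", "EC_high", "EC_clear", "EC_serous"), 400)
table = synthetic_measurement_table(counts, seed=11)

for name, make in (("EC vs non-tumorous", ec_vs_non_tumorous),
                   ("EIN vs benign", ein_vs_benign)):
    print(name)
    for modality in ("att_co", "att_cross", "stiffness"):
        unit = "kPa" if modality == "stiffness" else "mm^-1"
        result = select_threshold(roc(table, make(modality)), policy="youden")
        print(f"  {modality:>9}: AUC {result.auc:.3f}  "
              f"threshold {result.chosen_threshold:.3g} {unit}  "
              f"Se {result.se:.1f}%  Sp {result.sp:.1f}%")
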