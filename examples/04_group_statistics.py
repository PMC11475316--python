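"""Group statistics on a synthetic measurement cohort.

Draws region-mean measurements for four tissue classes from log-normal
distributions matched to the published Me [Q1; Q3] values, prints the
descriptives in the same format, and runs the pairwise Mann-Whitney
comparison matrix with Bonferroni correction.
"""

from mmoct import pairwise_mann_whitney, synthetic_measurement_table
from mmoct.roi_stats import describe

table = synthetic_measurement_table(
    {"proliferative": 30, "non_atypical": 30, "EIN": 30, "EC_low": 30}, seed=4
)

print("descriptives (stiffness, kPa):")
stiff = table[table.modality == "stiffness"]
for cls, group in stiff.groupby("tissue_class"):
    print(f"  {cls:>14}: {describe(group['value'], unit='kPa')['formatted']}")

matrix = pairwise_mann_whitney(table, alpha=0.05)
stiff_matrix = matrix[matrix.modality == "stiffness"]
print("\npairwise Mann-Whitney (stiffness), Bonferroni-adjusted:")
for _, row in stiff_matrix.iterrows():
    flag = "significant" if row.significant else "n.s."
    print(f"  {row.class_a:>14} vs {row.class_b:<14} "
          f"p_adj = {row.p_adjusted:.2e}  {flag}")
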