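"""Atlas region report, selection, and hierarchical ROI regression.

Projects the VLSM significance maps onto the toy atlas, selects regions
with >= 100 significant voxels, and asks — per region — whether lesion
volume inside it (ml) explains behavioral variance beyond demographics
(and beyond total lesion volume).
"""

from fluencymap import SEMANTIC, PHONEMIC, RunConfig, make_cohort, run_full_analysis
from fluencymap.synthetic import default_norms

cohort = make_cohort(seed=1)
result = run_full_analysis(cohort, RunConfig(), norms=default_norms())

cols = ["region", "tested_voxels", f"sig_{SEMANTIC}", f"sig_{PHONEMIC}"]
print(result.region_report.table[cols].to_string(index=False))

names = cohort.atlas.region_table
print("\nselected (>=100 significant voxels):")
for outcome, labels in result.roi_selection.selected.items():
    print(f"  {outcome}: {[names[l] for l in labels]}")

rm = result.roi_models
show = rm[~rm.adjusted_for_total_volume][
    ["outcome", "region", "r2_base", "r2_full", "p_delta_r2", "B_per_ml", "ci95_low", "ci95_high"]
]
print("\nhierarchical regressions (unadjusted for total volume):")
print(show.round(3).to_string(index=False))
# B is the change in z score per 1 ml of regional infarct; p_delta_r2 is
# the partial-F p value for the gain in explained variance when the
# regional volume is added to the demographic base model.
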