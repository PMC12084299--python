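"""Generate a synthetic two-group salivary-gland cohort with ground truth.

The default spec mirrors a small clinical IMC study: 3 control and 15 case
samples, 2 ROIs each, ~500 cells per 300x300 px ROI, 12 cell types with a
higher immune fraction in the case group. Every cell's true type is known,
so downstream analyses can be validated exactly.
"""

import imcspace as m

spec = m.SyntheticCohortSpec(seed=1)
rois, cells, truth = m.generate_cohort(spec)

print(f"ROIs generated:   {len(rois)}")
print(f"cells generated:  {len(cells)}")
immune = truth.cells["true_type"].isin(m.IMMUNE_TYPES)
for group in spec.n_samples_per_group:
    sel = cells["group"] == group
    frac = immune[sel.to_numpy()].mean()
    print(f"immune fraction in {group:8s}: {100 * frac:.1f}%")
# The case group should show roughly twice the immune infiltration of the
# control group (the planted compositions are ~26% vs ~14.5%).
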