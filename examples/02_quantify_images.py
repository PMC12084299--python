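"""Preprocess a rendered ROI and quantify per-cell marker intensities.

The rendered image stack carries background, channel spillover and Poisson
counting noise; the preprocessing chain (spillover unmixing -> median
denoise -> linear intensity adjustment) is applied before averaging pixels
within each segmentation label.
"""

import numpy as np

import imcspace as m

# plant a mild off-diagonal spillover between adjacent channels
n_ch = len(m.default_panel())
s = np.eye(n_ch)
for i in range(n_ch - 1):
    s[i, i + 1] = 0.05
spec = m.SyntheticCohortSpec(
    n_samples_per_group={"g": 1},
    rois_per_sample=1,
    proportions={"g": dict(m.synthetic.DEFAULT_PROPORTIONS["pSS"])},
    spillover=m.SpilloverMatrix(s),
)

roi, true_cells, _ = m.generate_roi(spec, "g", seed=2)
quant = m.preprocess_and_quantify(roi, spillover=spec.spillover, adjust=None)

print(f"quantified {len(quant)} cells from a "
      f"{roi.shape[1]}x{roi.shape[0]} px ROI with {roi.n_channels} channels")
for marker in ("E-cadherin", "CD8a", "CD45"):
    r = np.corrcoef(quant[marker], true_cells[marker])[0, 1]
    print(f"correlation of quantified vs true {marker:10s}: r = {r:.3f}")
# r close to 1 means spillover compensation + denoising recovered the
# drawn per-cell signal despite background and counting noise.
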