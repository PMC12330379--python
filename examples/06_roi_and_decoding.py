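"""ROI extraction from cluster masks and meta-analytic decoding.

A significant-cluster mask is just a binary vector: multiplying it into
the cohort matrix gives each subject's total (or mean) measure inside the
ROI, and correlating it against a database of keyword-labelled maps ranks
the keywords most associated with the region.
"""

import numpy as np

from vertexstats import (
    SimulationConfig,
    decode_roi,
    hemisphere_pair,
    roi_extract,
    simulate_cohort,
    simulate_decoding_db,
)
from vertexstats.simulate import effect_region

pair = hemisphere_pair(2)
cfg = SimulationConfig(n_subjects=12, space_tag="synthetic-ico2", seed=3)
cohort, sheet, _ = simulate_cohort(cfg, meshes=pair)

mask = effect_region(pair, center=9, hops=3).astype(float)
print(f"ROI mask: {int(mask.sum())} vertices")

totals = roi_extract(cohort, mask)
means = roi_extract(cohort, mask, average=True)
print(f"subject ROI means (mm): min {means.min():.2f}, max {means.max():.2f} "
      f"(totals are means x {int(mask.sum())})")
assert np.allclose(totals / mask.sum(), means)

db = simulate_decoding_db(30, pair, planted_support=mask, seed=4, smooth_fwhm=40.0)
table = decode_roi(mask, db, exclude=["kw_003"])
print(table.head(5).to_string(index=False))
# Keywords are sorted by |r|; the planted keyword's map equals the ROI
# support, so it must top the list with r = 1.
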