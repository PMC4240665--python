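"""Detect percussive damage on one simulated stone surface.

Generates a synthetic anthropogenic (hammerstone-like) surface, runs the
DEM -> TPI -> Gi* -> polygon pipeline and prints the per-specimen summary.
"""

import numpy as np

from percmorph import (
    PipelineConfig,
    SyntheticSurfaceParams,
    generate_surface,
    run_specimen,
)

params = SyntheticSurfaceParams(damage_class="anthropogenic", seed=7)
raster, truth_mask = generate_surface(params)

result = run_specimen(
    raster, PipelineConfig(), specimen_id="demo", group_label="anthropogenic"
)

print("cells analysed:        ", result.counts["cells_tpi_valid"])
print("significant hot cells: ", result.counts["cells_hot"])
print("significant cold cells:", result.counts["cells_cold"])
print("hot polygons:          ", result.summary.n_hot)
print("cold polygons:         ", result.summary.n_cold)
print("hot/cold area ratio:   ", round(result.summary.hot_cold_area_ratio, 3))

hot_p2v = [p.p2v for p in result.polygons if p.cls == "hot" and p.p2v]
print("median hot perimeter^2/volume: %.0f mm^-1" % np.median(hot_p2v))

flagged = np.zeros(truth_mask.shape, dtype=bool)
for poly in result.polygons:
    flagged[poly.cells[:, 0], poly.cells[:, 1]] = True
print(
    "fraction of truly damaged cells flagged: %.2f"
    % flagged[truth_mask].mean()
)

# The hot/cold ratio near or above 1 and the high perimeter^2/volume of the
# hot polygons are the two signatures of crushed (percussive) texture; on a
# naturally abraded surface both numbers come out much lower.
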