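"""Topographic map of a band-power change on the rat montage.

Per-electrode alpha-power change rates are interpolated over the planar
electrode layout (barycentric linear on the Delaunay triangulation) with
significant electrodes drawn filled. The figure is saved as a PNG.
"""

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

import eegbico as eb
from eegbico.topo import plot_map

montage = eb.load_default_montage()
rng = np.random.default_rng(0)

# synthetic change rates: frontal increase fading posteriorly
values = {lab: 30.0 - 4.0 * abs(xy[0] - 3.0) + rng.normal(0, 2)
          for lab, xy in montage.positions.items() if lab in montage.scalp_labels}
significance = {lab: v > 25 for lab, v in values.items()}

tmap = eb.interpolate_map(values, montage, resolution=96,
                          significance=significance)
ax = plot_map(tmap, title="alpha power change (%)")
plt.savefig("scratch/topomap.png", dpi=120, bbox_inches="tight")

print(f"map over {len(tmap.labels)} electrodes; "
      f"range {np.nanmin(tmap.grid):.1f} to {np.nanmax(tmap.grid):.1f} %")
print("significant electrodes:",
      [lab for lab, s in significance.items() if s])
print("figure written to scratch/topomap.png")
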