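"""FFT-filtered colocalization score versus true co-occupancy.

Simulates scenes in which a known fraction of channel-2 signal shares
channel 1's filaments, then scores each with the high-pass-filtered Spearman
correlation (features larger than 2 um are discarded before correlating).
"""

import numpy as np

from mtllps import Roi, SimulationSpec, coloc_score, make_coloc_scene

print("true co-occupancy -> spearman rho")
for i, f in enumerate([0.0, 0.25, 0.5, 0.75, 1.0]):
    spec = SimulationSpec(seed=300 + i, background_level=50.0)
    image, truth = make_coloc_scene(f, spec)
    roi = Roi(np.ones(image.shape, dtype=bool), label="full-frame")
    res = coloc_score(image.ch1, image.ch2, roi, image.pixel_size_nm)
    print(f"  {truth.true_coloc_fraction:4.2f} -> {res.spearman_rho:+.3f} "
          f"({res.n_pixels} px, expression {res.expression_level:.1f} a.u.)")
# rho rises monotonically with the planted co-occupancy: near 0 for
# independent networks, toward 1 when every channel-2 filament lies on a
# channel-1 filament.
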