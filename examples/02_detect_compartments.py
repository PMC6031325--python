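"""Detect sub-compartments along filaments from a rendered scene.

Re-creates the scene of example 01, extracts paired 120-nm-thick line
profiles along the ground-truth paths, and runs the ratio-based detector:
a compartment is a contiguous stretch where the mean-normalized I_RBP1/I_RBP2
ratio deviates from 1 by more than 20%.
"""

from mtllps import PlantedCompartment, SimulationSpec, make_network, render_scene, sample_profile
from mtllps.compartments import analyze_cell

spec = SimulationSpec(n_paths=4, seed=42, background_level=20.0)
paths = make_network(spec)
planted = [PlantedCompartment(0, 3.0, 6.0, "enrich_ch1", 2.5)]
image, truth = render_scene(paths, planted, spec)

profiles = [sample_profile(image, p) for p in paths]
cell = analyze_cell("demo", profiles, min_total_length_um=40.0)

print(f"analyzed {cell.total_analyzed_length_um:.1f} um of network")
print(f"detected {len(cell.compartments)} compartment(s):")
for c in cell.compartments:
    print(f"  path {c.path_id}: {c.dominant_channel}-dominant, "
          f"[{c.start_um:.2f}, {c.end_um:.2f}] um (L={c.length_um:.2f} um), "
          f"enrichment {c.enrichment_pct:.0f}%, {c.attribution}")
# The detected interval matches the planted [3, 6] um segment to within a
# couple of samples.  The 2.5-fold plant corresponds to a 150% ratio excess;
# the ~130% measured here is attenuated by the unsubtracted 20-photon
# background and by the compartment's own contribution to the mean ratio.
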