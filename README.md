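# mtllps

Quantifying liquid–liquid phase separation (LLPS) of RNA-binding proteins
(RBPs) confined on microtubules.

## The problem

Many RBPs — TDP-43, FUS, HuR, G3BP1 — demix into liquid-like, mRNA-rich
compartments. A powerful cell-based assay for probing whether two such
proteins mix or demix is to confine both on the microtubule network (via
fusion to the microtubule-associated protein tau, one tagged with GFP and one
with RFP) and measure their spatial segregation *along* the filaments. The
filament geometry turns a hard 3D colocalization problem into a 1D one: each
microtubule becomes a line along which two fluorescence intensity vectors,
I_RBP1 and I_RBP2, are recorded.

`mtllps` implements the quantitative analysis of that assay for two-channel
fluorescence images, plus a synthetic-scene simulator with exact ground truth
so every stage is testable without microscopy data. It is aimed at
microscopists and quantitative cell biologists analyzing ratiometric
segregation along filamentous structures.

## The statistics

**Sub-compartment detection.** Along each filament path, intensities are
sampled on a uniform arc grid with a 120 nm perpendicular averaging band
(4 pixels at 30 nm/px). The ratio r_i = I_RBP1,i / I_RBP2,i (epsilon-guarded)
is normalized by its geometric mean over the cell's pooled network,
n_i = r_i / gmean(r). A **compartment** is a maximal contiguous run where the
(geometrically smoothed) normalized ratio deviates from 1 by more than a
threshold θ = 20%:

- RBP1-dominant: n_i > 1 + θ;  RBP2-dominant: n_i < 1/(1 + θ),

so channel swap is an exact symmetry. Each compartment reports its length L
and its **relative enrichment**, 100·(max over L of the dominant-over-other
normalized ratio − 1), in percent.

**Attribution.** At the position of the maximal ratio, the signed log
deviations of both channels from their network means are summed:

    log[I_dom / mean(I_dom)] + log[I_other / mean(I_other)] > 0

→ the compartment is caused by *enrichment of the dominant* protein;
otherwise by *exclusion of the coexisting* one.

**Colocalization score.** Both channels are FFT high-pass filtered
(features larger than 2 µm discarded, Gaussian-edged rolloff with half-power
at the cutoff), then the Spearman rank correlation ρ (and Pearson r) is
computed over the cytoplasmic ROI pixels and reported against the cell's
expression level.

## Worked example

```python
from mtllps import (PlantedCompartment, SimulationSpec, make_network,
                    render_scene, sample_profile)
from mtllps.compartments import analyze_cell

spec = SimulationSpec(n_paths=4, seed=42, background_level=20.0)
paths = make_network(spec)
planted = [PlantedCompartment(0, 3.0, 6.0, "enrich_ch1", 2.5)]
image, truth = render_scene(paths, planted, spec)

profiles = [sample_profile(image, p) for p in paths]
cell = analyze_cell("demo", profiles, min_total_length_um=40.0)
for c in cell.compartments:
    print(f"path {c.path_id}: {c.dominant_channel}-dominant, "
          f"[{c.start_um:.2f}, {c.end_um:.2f}] um (L={c.length_um:.2f} um), "
          f"enrichment {c.enrichment_pct:.0f}%, {c.attribution}")
```

prints

```
path 0: RBP1-dominant, [2.93, 6.08] um (L=3.15 um), enrichment 132%, enrichment_of_dominant
```

— the planted 2.5-fold segment on [3, 6] µm is recovered to within a few
samples; its measured enrichment (132%, vs the nominal 150% excess of a
2.5-fold ratio) is slightly attenuated by the unsubtracted background and by
the segment's own contribution to the mean ratio, and the deviation is
correctly attributed to accumulation of RBP1 rather than loss of RBP2.

The `examples/` directory holds one short narrative script per capability
(scene simulation, detection, attribution, colocalization, scenario presets);
each prints the numbers it computes and what they mean. A thin CLI wraps the
same pipeline: `mtllps simulate|analyze|coloc|report`.

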