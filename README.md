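# mvnquant

Quantification of self-assembled 3D microvascular networks (MVNs) in
microphysiological barrier models — the kind grown from endothelial cells,
pericytes and astrocytes in a microfluidic fibrin-gel channel to model the
inner blood-retinal barrier and its degeneration under chronic diabetic
stimulation.

It is written for imaging scientists who have multi-channel confocal stacks
(endothelium, pericyte, astrocyte, collagen-IV basement membrane, nuclei,
apoptosis reporter, dextran tracer) and want reproducible, scriptable
versions of the standard readouts:

- **MIP morphology** — marker region areas by fractional thresholding
  (endothelium 0.25, pericyte/astrocyte/basement membrane 0.40 of the
  clipped range), nuclei segmentation and border-based assignment to
  regions, **pericyte coverage** = area(pericyte ∩ endothelium ⊕ 5 µm), and
  the **ghost-vessel fraction**

      F_ghost = area(COL IV \ endothelium) / area(COL IV),

  the fraction of basement-membrane sleeves lacking endothelium — a
  hallmark of vascular regression.
- **3D analysis** — rolling-ball + Gaussian denoising, three-class
  multi-Otsu object segmentation with watershed splitting, random-walker
  vascular segmentation with skeleton-based mean diameter
  d̄ = 2·√(V/(πL)), optional random-forest pixel-classifier refinement, and
  object-to-vessel proximity (3-voxel dilation overlap; marching-cubes
  surface distances via k-d tree).
- **Barrier function** — perfusability (% of vessel area reached by tracer)
  and the apparent permeability coefficient

      P_app = (Ī_t(t₂) − Ī_t(t₁)) / (Ī_v(t₁) − I_bg) · 1/(t₂−t₁) · d̄/4   [cm/s]

  from tracer intensities inside/outside the vessel mask at t₁ = 5 and
  t₂ = 15 min.
- **Statistics** — per-group mean ± s.d., one-way ANOVA with Šidák-adjusted
  pairwise comparisons, and percent-of-control normalization.
- **Synthetic scenes** — a seeded generator that renders MVN-like
  six-channel stacks with full ground truth (vessel graph, ghost sleeves,
  pericyte coverage, nuclei, tracer leak at a prescribed permeability,
  Poisson+Gaussian noise). Condition presets encode the effect sizes of a
  chronic diabetic-stimulation experiment, so every stage of the pipeline is
  verifiable by parameter recovery. See `docs/methods.md` for the model.

## Worked example

```python
from mvnquant import (GridSpec, generate_scene, max_projection,
                      normalize_and_smooth, build_region_masks,
                      pericyte_coverage, ghost_vessel_fraction,
                      estimate_permeability)
from mvnquant.mip import ROLE_TO_MARKER
from mvnquant.synthetic import simulate_perfusion

grid = GridSpec(shape=(24, 128, 256), voxel_size=(0.6, 0.6, 5.0))  # µm

for name in ("control_D7", "diabetic_D28"):
    scene = generate_scene(name, seed=1, grid=grid)
    images01, px = {}, scene.grid.pixel_size
    for role in ("endothelium", "pericyte", "colIV"):
        img, px = max_projection(scene.stack, role)
        images01[ROLE_TO_MARKER[role]] = normalize_and_smooth(img, clip_max=1.0)
    regions = build_region_masks(images01, px)
    vascular = regions.area_um2("EC")
    coverage = pericyte_coverage(regions)
    ghost = ghost_vessel_fraction(regions)
    print(f"{name}: vascular {vascular:.0f} um^2, "
          f"coverage {coverage / vascular:.2f}, ghost {ghost:.3f}")

series = simulate_perfusion(generate_scene("untreated", seed=1, grid=grid))
print(f"untreated P_app = {estimate_permeability(series).p_app:.2e} cm/s")
```

prints

```
control_D7: vascular 3540 um^2, coverage 0.60, ghost 0.238
diabetic_D28: vascular 1058 um^2, coverage 0.19, ghost 0.369
untreated P_app = 1.02e-07 cm/s
```

Read: by day 28 of diabetic stimulation the vascular area has regressed to
~30 % of the day-7 control, pericyte coverage has fallen 3-fold, and the
ghost-vessel fraction has climbed from ~0.25 toward 0.40 — the encoded
disease phenotype, recovered here through the full measurement chain
(rendering, noise, projection, thresholding, mask arithmetic) rather than
read off the ground truth. The permeability estimate inverts a tracer
time-lapse back to the preset 1×10⁻⁷ cm/s.

For instrument data, `read_stack` loads plain multi-page TIFF with a YAML
sidecar (voxel size, channel roles) or OME-TIFF, and `run_pipeline` /
the `mvnquant` CLI (`simulate`, `quantify-mip`, `quantify-3d`, `perfusion`,
`report`, `all`) orchestrate multi-condition studies into CSV tables with a
JSON run manifest that reproduces the outputs byte for byte.

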