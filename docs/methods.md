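# Methods

## Scope and model system

`mvnquant` quantifies morphology and barrier function of self-assembled 3D
microvascular networks (MVNs) of the kind grown in microfluidic fibrin-gel
channels to model the inner blood-retinal barrier: endothelial tubes
(UEA I/CD31), mural pericytes (PDGFRβ), astrocytes (S100b), a collagen-IV
basement membrane, nuclei (DAPI), an apoptosis reporter (Caspase-3/7) and a
fluorescent dextran tracer. Because raw imaging of such experiments is rarely
shareable, the package pairs every quantification stage with a synthetic
scene generator whose ground truth encodes the condition effect sizes of a
chronic diabetic-stimulation experiment, so the whole pipeline is validated
by parameter recovery with no external data.

## MIP quantification

Projections are quantified with a high-content-screening-style chain:

1. **Normalization** — intensities clipped to a fixed ceiling (20 000 counts
   for instrument data; 1.0 for the generator's normalized units), scaled to
   [0, 1], median-filtered (square window, radius 3 px; the basement-membrane
   channel gets an additional radius-10 median before thresholding).
2. **Region masks** — fractional thresholds of the clipped range:
   endothelium 0.25, pericyte 0.40, astrocyte 0.40, basement membrane 0.40.
3. **Nuclei** — Gaussian smoothing (σ 2 px) → global Otsu → hole filling →
   distance-transform watershed → area floor 20 µm². Watershed seeds are
   local EDT maxima with a 3 px minimum separation; a flat plateau forms a
   single connected seed, and every foreground component is guaranteed one
   seed (a component whose maxima are all suppressed would otherwise vanish).
4. **Assignment** — a nucleus counts for a marker when its mask intersects
   the marker region dilated by an outer border (endothelium 3 µm,
   pericyte 2 µm, astrocyte 2 µm, basement membrane 3 µm). Borders convert
   to pixels by rounding up and dilate with a Euclidean disk. Assignment is
   deliberately non-exclusive: each selection is defined independently.
5. **Derived metrics** —
   *pericyte coverage* = area(pericyte ∩ dilate(endothelium, 5 µm));
   *ghost-vessel fraction* = area(basement membrane \ endothelium) /
   area(basement membrane), clamped to [0, 1] against mask-arithmetic noise;
   *viability* = 1 − apoptotic/total nuclei, with apoptotic flags taken from
   the reporter channel (mean in-nucleus intensity above 0.25).

## 3D quantification

Stacks are denoised by Gaussian smoothing and slice-wise rolling-ball
background subtraction (a 3D ball is ill-posed at a 5 µm Z step; the ball's
intensity semi-axis is scaled to the image's dynamic range so the subtraction
geometry is unit-independent). Cell bodies are segmented by three-class
multi-Otsu thresholding with the top class as foreground (markers are bright
on dark), regularized by radius-1 closing/opening applied in-plane (a 3D
radius-1 erosion at 5 µm Z step deletes bodies one slice thick), and split
by the same plateau-merged distance-transform watershed, with EDT computed
under the physical anisotropy and a suppression window of ±3 px in-plane and
±1 slice in Z. Vasculature is segmented by random-walker label propagation
seeded from the upper (vessel) and lower (background) multi-Otsu cuts. Mean
vessel diameter derives from the mask volume V and 3D skeleton length L as
d̄ = 2·sqrt(V/(πL)) (area-equivalent circular cross-section); skeleton
length sums physical distances between 26-connected skeleton voxel pairs.

An optional refinement stage trains a seeded random forest on per-voxel
features (raw intensity plus Gaussian intensity, gradient magnitude and
Laplacian at σ ∈ {1, 2, 4} px) from curated masks and applies it to unseen
stacks; the pipeline runs without it.

Proximity of pericytes/astrocytes to vessels is reported two ways: the
overlap volume after dilating both object and vessel mask by 3 voxels
(cubic structuring element), and the shortest distance between
marching-cubes surfaces (anisotropy applied before extraction) found with a
k-d tree, averaged per ROI.

## Perfusion

Perfusability is the percent of the endothelial mask area reached by
thresholded tracer (threshold 0.25 of the clipped range, mirroring the
endothelial threshold), with the tracer image nearest-neighbour-resampled to
the vessel-mask grid (centred alignment) when magnifications differ.

The apparent permeability coefficient uses the cylindrical-lumen convention

    P_app = (Ī_t(t₂) − Ī_t(t₁)) / (Ī_v(t₁) − I_bg) · 1/(t₂ − t₁) · d̄/4

with Ī_t the mean tracer intensity outside the vessel mask, Ī_v the mean
inside, t₁ = 5 min, t₂ = 15 min (converted to seconds), d̄ in cm, and I_bg
the mean of the t = 0 frame outside the mask dilated by 10 px. d̄/4 is the
volume-to-surface ratio of a circular lumen; `lumen_volume_to_surface_cm`
supplies a mask-measured V/S as a drop-in alternative. A negative intensity
rise clamps the estimate to zero with a flag. The forward simulator uses the
identical linear leak model, so noise-free recovery is exact by construction
— the noise-free round trip validates unit handling, not model adequacy.

## Synthetic scenes

**Geometry.** Vessels are grown on a jittered lattice (spacing ≈ 45 µm,
Z scatter ≈ 15 µm s.d. about the mid-plane — planar-biased, as in a gel
channel). Edges join a random connected frontier until the rendered MIP area
fraction crosses the preset target; the final edge's length (degenerately,
radius) is bisected to land within the calibration band. Radii are
log-normal, median 12 µm, clipped to [5, 45] µm. Every edge carries a
basement-membrane sleeve 2.5 µm beyond its radius; ghost vessels are
additional sleeve-only tubes appended until the ground-truth ghost-vessel
fraction (avascular sleeve MIP area over sleeve MIP area) matches the
preset, the last tube scaled in length and radius jointly by bisection. A
target at or below the bare rim fraction of the lumenized sleeves adds no
ghost tubes (the rim is irreducible). Spherical pericyte bodies (log-normal
radius, median 7.5 µm) are placed on vessel surfaces until the coverage
fraction is met, with a body-separation constraint that relaxes as placement
saturates (wrapping pericytes overlap in crowded networks); astrocytes
(median 6.5 µm) scatter through the gel, half biased near vessels. Each cell
body gets one nucleus (ellipsoid 4.5×4.5×3.2 µm); endothelial nuclei are
strung along edges every ~28 µm on the tube wall. Apoptotic nuclei are an
exact-count draw per cell type (round(fraction × n)).

**Rendering.** Default grid 512×256×40 voxels at 0.6×0.6×5.0 µm — 20×-like
in-plane sampling with a deliberately anisotropic, shortened Z extent so 3D
operations face realistic anisotropy at desk scale. Each marker's plateau
intensity is set to twice its segmentation threshold (endothelium 0.5,
others 0.8) so the symmetric point-spread blur (Gaussian, σ 0.8 px in-plane)
does not bias thresholded boundaries; base background 0.02 plus a linear
ramp (slope 0.03 across the field). Noise: Poisson shot noise at 200
effective photons per intensity unit, then additive Gaussian read noise
(s.d. 0.02 of the dynamic range). All fractions realized in the ground truth
are re-checked against the preset within ±5 % relative (resampled up to 20
times, else an explicit infeasibility error — never a silent miss).

**Presets.** Absolute baselines are free choices (the source experiment
reports relative changes): control D7 vascular MIP fraction 0.30, coverage
fraction 0.60, ghost fraction 0.25, leak 1×10⁻⁷ cm/s. Condition ratios
encode the published effect sizes: vascular area 70 % of the D7 control at
D14 and 30 % under diabetic treatment at D28; 3-fold coverage loss over the
diabetic time course; ghost fraction ×1.6 over the diabetic time course and
×1.3 versus the D28 control (hence control D28 ghost = 0.40/1.3 ≈ 0.31);
TNF-α leak ×4.7. Diabetic D14 sits at the log-midpoint of its D7 and D28
values, reflecting that the major changes appear between D14 and D28.
"Coverage" is compared across conditions as the vascular-area-normalized
coverage fraction — with vascular area itself regressing 3.3-fold, raw
coverage areas conflate the two effects.

**What the generator does not emulate.** Real acquisitions have curved,
tapering, anastomosing lumens, textured cytoplasmic staining, depth-dependent
attenuation, optical sectioning cross-talk and stitching seams; pericytes are
flattened processes rather than spheres. Recovery of the encoded effect
sizes therefore demonstrates that the measurement chain is unbiased under a
controlled forward model with realistic noise and anisotropy — not that
segmentation accuracy transfers to arbitrary real-world image quality.

## Statistics

Group readouts are summarized as mean ± s.d. per group; a one-way ANOVA is
followed by pairwise comparisons using pooled-MSE t statistics with Šidák
adjustment (1 − (1 − p)^m). With two groups the adjusted p equals the raw p.
A simulated-null check (1000 replicates) keeps the adjusted type-I error
within [3 %, 7 %] at α = 0.05. ROIs within a channel are treated as
technical-replicate rows; per-channel means are also available so either
aggregation level can be reported.

## Numerical and design notes

- Voxel rasterization is centre-in-capsule: a voxel belongs to a tube when
  its centre is within the radius of the axis segment; MIP footprints are
  the Z-projection of the same 3D rasterization, so 2D calibration and 3D
  rendering agree exactly.
- Determinism: every stochastic step draws from `numpy.random.default_rng`
  streams keyed on (seed, preset name, stage tag); identical inputs give
  bit-identical scenes, masks and CSV outputs.
- Ghost-fraction mask arithmetic clamps tiny negatives at 0; empty
  denominators (no basement-membrane area, no nuclei, no vessel mask) raise
  explicit errors rather than returning NaN.
- Desk-scale problem sizes: the bundled tests run conditions at
  256×128×24 voxels (same voxel calibration); the acceptance script uses the
  full default grid with 5 seeds per condition.
- Degenerate inputs: constant images fail multi-Otsu with an explicit
  degenerate-histogram error; blank nuclei images yield an empty (not
  erroneous) label set; a constant tracer series estimates P_app = 0.
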