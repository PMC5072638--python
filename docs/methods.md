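# Methods

## The asymmetry analysis

Healthy retinas are markedly symmetric, both between fellow eyes and
between the superior and inferior halves of the macula, while glaucomatous
damage is typically focal and asymmetric at diagnosis. `macusym` exploits
this by differencing macular layer-thickness maps superpixel by
superpixel. Each map is a fovea-centered 31×31 grid of 200×200 μm
superpixels (a 6.2×6.2 mm macular area), for four layers: the retinal
nerve fiber layer (RNFL), the ganglion cell–inner plexiform layer (GCIPL),
the ganglion cell complex (GCC = RNFL + GCIPL), and the total retina.

**Inter-ocular mode.** For the target eye *T* and its fellow *F*, the
anatomically corresponding superpixel of a fellow eye is the horizontal
mirror image (fellow eyes are mirror-symmetric about the vertical
midline):

```
d(r, c) = T(r, c) − F(r, ncols − 1 − c)
```

**Inter-hemispheric mode.** Within one eye, superpixels are paired across
the horizontal line through the foveal pit, i.e. across the central grid
row:

```
d(r, c) = G(r, c) − G(nrows − 1 − r, c),   r ≠ center
```

The center row lies on the symmetry axis, has no mirror partner, and is
excluded (rendered neutral). Because the map is antisymmetric by
construction, each mirrored pair contributes exactly one negative and one
positive value unless it ties at zero.

**Negative selection and indices.** Only negative differences — relative
thinning of the target superpixel — are retained; positive values carry no
evidence of damage in the target cell and are excluded. Two summary
indices are computed per map:

* *average negative difference* (μm): the mean over retained cells only
  (0 with an explicit flag when nothing is retained, so group statistics
  stay total);
* *black superpixel count*: retained cells whose thinning is over the
  layer cut-off — 20 μm for GCIPL and 40 μm for RNFL, GCC and total
  retina, chosen conservatively from the reported normal-vs-glaucoma
  thickness gaps of these layers. "Over" is implemented strictly
  (`d < −cutoff`); a `cutoff_inclusive` switch provides the `≤` variant,
  since ties must be handled deterministically even though they are
  measure-zero in real data.

Missing superpixels (local segmentation failure) propagate as missing,
never imputed, and are excluded from every average and count; their number
is reported alongside the indices.

### Conventions

* Grids are stored fundus-view as displayed: row 0 superior, columns left
  to right of the displayed image. No nasal/temporal column convention is
  assumed anywhere; inter-ocular correspondence is defined purely by the
  horizontal mirror, which is correct for fellow eyes on either display
  convention.
* Coordinates are 0-based `(row, col)`; windows inclusive.
* Fovea localization is an input (wide-scan grids carry a `fovea_rc`
  field); it is not computed from image content.
* The macular window is extracted from a 12×9 mm wide scan (45×60 cells of
  0.2 mm) as the 31×31 block centered on the fovea superpixel.

## Diagnostic evaluation

Group comparison uses the two-sided Mann-Whitney test (exact enumeration
when `n_a·n_b ≤ 400` without ties, otherwise the normal approximation with
tie and continuity correction). Diagnostic scores are oriented so larger =
more glaucoma-like: the magnitude of the average negative difference, and
the black-superpixel count. AUROC is computed by the Mann-Whitney
pair-count identity, so `AUROC = U/(n_pos·n_neg)` holds exactly.

Confidence intervals use DeLong's structural-components variance with a
Wald 95% interval clipped to [0, 1]; DeLong is the field standard when no
CI procedure is otherwise specified, and a stratified percentile bootstrap
is provided as an alternative (`auroc_ci_bootstrap`). Two ROC curves on
the same subjects are compared with the paired DeLong z-test. Evaluation
runs two contrasts: all glaucoma vs normal, and bilateral glaucoma vs
normal with the same target eyes. No multiple-testing correction is
applied across the 16 indices, matching common practice for this kind of
descriptive table; p-values should be read accordingly.

## The synthetic cohort generator

No raw patient grids ship with the package; the simulator provides cohorts
with the statistical structure the analysis assumes, so the full pipeline
is testable end to end.

Per subject and source layer (RNFL, GCIPL, and outer retina = total −
GCC), thickness is

```
base(d) + subject effect + eye effect + superpixel field (+ defect)
```

* **Base profile**: radially symmetric — peripheral plateau, perifoveal
  ring (Gaussian bump at the ganglion-cell ring radius), central foveal
  dip. Defaults give grid means of ≈49 μm (RNFL), ≈81 μm (GCIPL, anchored
  to the reported normal macular GCIPL average of ~80 μm) and ≈325 μm
  total retina.
* **Variance components**: subject SD 5 μm (shared across eyes and cells),
  eye SD 0.8 μm, and a unit-variance superpixel field scaled per layer.
  The field mixes a vertically symmetric component (weight
  `inter_hemi_corr`) and, between eyes, a column-mirrored shared component
  (weight `inter_eye_corr`), then is smoothed by a moving-average kernel
  (radius 2 superpixels by default) and rescaled — real 200 μm superpixels
  are spatially correlated, and a moving average is the simplest seedable
  smooth field.
* **Calibration**: with mirrored-pair difference SD σ_d, the expected
  average negative difference of a null map is −σ_d·√(2/π) (mean of the
  negative half-normal). The per-layer defaults
  (`superpixel_sd_um`, `inter_eye_corr`, `inter_hemi_corr` = 3.24/0.655/0.04
  RNFL, 3.10/0.41/0.04 GCIPL, 1.5/0.5/0.5 outer) were solved once from
  this identity against the reported normal-group index magnitudes
  (≈ −2.2 to −3.6 μm). Because GCC and total retina are sums of source
  layers, their null asymmetry comes out some 20–30% larger in magnitude
  than the clinical values — the real layers are not independent sums —
  and exact matching is not claimed.
* **Defect**: glaucomatous eyes get a fovea-anchored angular wedge
  (default half-angle 22.5° about a 45° arcuate direction, annulus
  0.6–3.0 mm) confined to one hemifield, mimicking arcuate bundle loss,
  with depth tapering linearly over 1 superpixel at the border. Peak
  depths default to 55 μm (RNFL) and 25 μm (GCIPL); GCC and total inherit
  the sum. Each patient's depth is scaled by a severity multiplier
  U(0.3, 1.1), reflecting the early-to-severe mix of real cohorts. With
  probability `bilateral_fraction` (default 52/62) the fellow eye receives
  its own wedge — independent hemifield and side, severity further scaled
  by U(0.2, 0.8) — because bilateral glaucoma is typically asymmetric and
  an identical mirrored defect would be invisible to inter-ocular
  comparison.
* **Randomness**: one integer seed; each subject uses a substream keyed by
  (seed, subject counter), so cohorts are reproducible and adding subjects
  never perturbs earlier ones.

### What the simulator does *not* emulate

Real normal eyes show heavy-tailed focal asymmetries (epiretinal traction,
vascular shadows, segmentation slips) that produce black superpixels even
in health — clinically, normals average ~12–18 black GCIPL superpixels.
Gaussian fields at the calibrated SDs produce essentially none, so
simulated group separation is cleaner than clinical separation: AUROCs on
synthetic cohorts run ~0.95–1.0 where the clinical range is ~0.75–0.89.
Passing tests therefore demonstrate correctness of the computation and
calibration of the first moments, not clinical diagnostic accuracy. Axial
length/magnification effects, anisometropia, fovea-disc-axis tilt and
B-scan-level physics are likewise out of scope.

## Rendering

Retained differences map to a linear gray ramp: white (255) at zero
difference to black (0) at the cut-off, `g = round(255·(1 −
min(|d|, cutoff)/cutoff))`. Linearity is the minimal assumption and makes
the count of pure-black rendered superpixels coincide with the black-
superpixel index away from exact cut-off ties. Excluded and centerline
cells render white; missing cells render a configurable sentinel gray
(128). The subject panel arrays 16 maps in 4×4: rows RNFL, GCIPL, GCC,
total retina; columns inter-hemispheric right, inter-ocular right,
inter-ocular left, inter-hemispheric left. Output is PGM (plain text,
bit-reproducible) or PNG.

## Numerical choices and degenerate inputs

* Zero retained cells → average reported as 0.0 with `no_negative_cells`
  set.
* Even-row grids have no defined centerline and are rejected for
  inter-hemispheric analysis.
* Paired DeLong with zero variance of the difference returns p = 1 for
  equal areas, p = 0 otherwise.
* Grid CSV output uses shortest round-trip decimal formatting, so
  write → read → write is byte-identical.
* All thicknesses are clipped at 0 μm in the simulator; validation rejects
  negative and infinite thickness on input.

## Problem sizes used in the test suite

Null-calibration checks run 200-subject defect-free cohorts;
separation/power checks run 100 cohorts of 70 + 62 subjects; DeLong
coverage uses 500 binormal cohorts of 60 + 60; oracle equivalence uses 200
random grids up to 31×31. These sizes give stable acceptance statistics
(3-SE bands, binomial tests at α = 0.01) while keeping the whole suite
under a minute of compute for the statistical parts.
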