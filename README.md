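# macusym

Superpixel asymmetry analysis of macular inner retinal layer thickness
maps for glaucoma structural diagnostics.

Glaucoma thins the inner retina focally and asymmetrically, while healthy
maculas are strongly symmetric between fellow eyes and between the
superior and inferior hemifields. `macusym` turns that observation into a
quantitative analysis of OCT thickness maps: on a fovea-centered 31×31
grid of 200×200 μm superpixels (6.2×6.2 mm of macula), for each of four
layers — RNFL, GCIPL, ganglion cell complex (GCC) and total retina — it
computes

* **inter-ocular difference maps**: `d(r,c) = target(r,c) −
  fellow(r, mirrored c)`, fellow eyes being horizontal mirror images, and
* **inter-hemispheric difference maps**: `d(r,c) = G(r,c) −
  G(mirrored r, c)` across the horizontal through the foveal pit,

retains only the negative differences (relative thinning), and summarizes
each map by the **average negative difference** (μm) and the number of
**black superpixels** — cells thinned beyond the layer cut-off (20 μm for
GCIPL, 40 μm for the others). Maps render as white-to-black gray-scale
images; cohorts are evaluated by Mann-Whitney group comparison and DeLong
AUROC (the identity `AUROC = U/(n_pos·n_neg)` is used and tested). A
synthetic paired-eye cohort simulator with calibrated symmetry structure
and arcuate wedge defects makes the full pipeline runnable without
patient data. See `docs/methods.md` for the model details.

Intended users: ophthalmic imaging researchers prototyping asymmetry-based
structural indices, and anyone needing a tested reference implementation
of superpixel-level hemifield/fellow-eye differencing.

## Worked example

```python
from macusym import *

cfg = SimulationConfig(n_normal=70, n_glaucoma=62, seed=1)
records = simulate_records(cfg)

rec = records[70]                      # first glaucoma subject
idx = analyze_subject(rec)
gcipl_ih = idx[(Layer.GCIPL, Mode.INTERHEMISPHERIC)]
print(f"{rec.subject_id}: target eye {rec.target_eye.value}, {rec.disease_laterality.value}")
print(f"GCIPL inter-hemispheric: avg negative diff = {gcipl_ih.avg_negative_diff_um:.2f} um, "
      f"black superpixels = {gcipl_ih.n_black}")

table = run_study(records)
row = table[(table.layer == "GCIPL") & (table["mode"] == "INTERHEMISPHERIC")
            & (table["index"] == "avg_negative_diff")].iloc[0]
print(f"cohort GCIPL inter-hemispheric avg negative diff: "
      f"normal {row.normal_mean:.2f} +/- {row.normal_sd:.2f} um, "
      f"glaucoma {row.glaucoma_mean:.2f} +/- {row.glaucoma_sd:.2f} um, "
      f"Mann-Whitney p = {row.mann_whitney_p:.2e}")
print(f"AUROC {row.total_auroc:.3f} (95% CI {row.total_ci_lo:.3f}-{row.total_ci_hi:.3f})")
```

prints

```
S070: target eye OD, BILATERAL
GCIPL inter-hemispheric: avg negative diff = -5.78 um, black superpixels = 34
cohort GCIPL inter-hemispheric avg negative diff: normal -3.64 +/- 0.44 um, glaucoma -5.51 +/- 0.98 um, Mann-Whitney p = 3.05e-20
AUROC 0.966 (95% CI 0.938-0.994)
```

This one patient's superior/inferior GCIPL comparison shows a mean
retained thinning of 5.8 μm with 34 superpixels beyond the 20 μm cut-off —
a focal hemifield defect. At cohort level the glaucoma group's retained
thinning is ~1.9 μm deeper than the normals' baseline asymmetry, a highly
significant separation with AUROC 0.97 on this synthetic cohort (clinical
cohorts separate less cleanly; see `docs/methods.md`).

## Command line

```sh
macusym simulate --out cohort/ --seed 7          # grids + manifest.csv
macusym analyze  --manifest cohort/manifest.csv --out indices/
macusym evaluate --manifest cohort/manifest.csv --out report/
macusym render   --manifest cohort/manifest.csv --subject S070 --out panel.png
```

`evaluate` writes the 16-index evaluation table (group stats,
Mann-Whitney p, AUROC with DeLong 95% CI for the total and
bilateral-glaucoma contrasts) as CSV/JSON plus ROC curve coordinates;
`render` draws the 4×4 asymmetry-map panel (rows RNFL, GCIPL, GCC, total
retina; columns inter-hemispheric/inter-ocular for each eye).

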