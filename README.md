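# spectromics3d

Quantitative 3D infrared (IR) spectro-microscopy of serial tissue sections.

Discrete-wavelength IR microscopes record, for every 20 µm pixel of a tissue
section, an absorbance spectrum A(ν) on a fixed wavenumber grid
(1800–900 cm⁻¹ every 4 cm⁻¹, 225 channels).  Cutting a whole organ — here a
mouse brain bearing a glioma — into hundreds of serial cryosections and
imaging alternate sections by IR and by fluorescence histology yields the raw
material for a *3D chemical image*.  The obstacle is that every section is
individually shrunken, bent or torn by cryomicrotomy.  This package
implements the full processing chain that turns such a section series into
calibrated 3D metabolite maps:

1. **Virtual 2D masks** — per-section silhouettes extracted from a 3D binary
   reference volume of the organ (e.g. an X-ray tomogram), completed between
   sparse atlas planes by signed-distance interpolation.
2. **Shape correction** — label images are warped onto their masks
   (moment affine + distance-transform refinement); hyperspectral images are
   *re-pixelated*: every pixel's spectrum is redistributed over the mask grid
   with bilinear weights and the total spectral absorbance
   Σ_pixels ∫ A(ν) dν is conserved exactly (enforced by a single global
   renormalisation and validated per section).
3. **3D reconstruction** — corrected sections are centre-aligned into a
   spectral cube; alternating series keep the z of their physical section.
4. **Chemical segmentation** — the tumor is protein-rich and lipid-poor, so
   a band-ratio map, protein (1700–1480 cm⁻¹) over lipid ester
   (1760–1710 cm⁻¹), thresholded by Otsu and reduced to its largest
   connected component, isolates it.  The fluorescent (green-channel)
   histology segmentation is the independent reference; volumes are compared
   by percent difference (both denominator conventions) and by the symmetric
   Hausdorff distance between marching-cubes surfaces.
5. **Metabolite quantification** — Savitzky–Golay second derivatives sharpen
   the carbohydrate-region bands; band areas are the negative-lobe integrals
   ∫ max(−A''(ν), 0) dν over glucose 1040–1027, glycogen 1027–1018 +
   1167–1157, lactate 1135–1114 cm⁻¹.  Exact zeros and values outside
   mean ± 3 SD are rejected, and a linear calibration anchors the mean
   healthy-hemisphere band area to enzymatic-assay reference concentrations
   (glucose 2.2, glycogen 5.1, lactate 1.2 µmol g⁻¹), producing 3D
   concentration maps and per-region mean ± SD with Welch t-tests.

A ground-truthed digital phantom (`spectromics3d.phantom`) emulates the
entire experiment — organ geometry, per-class Gaussian-band spectra,
sectioning, distortions, noise — so every stage is testable end to end.

## Worked example

```python
from spectromics3d import phantom as ph, pipeline as pl

spec = ph.PhantomSpec(seed=1)                       # the default digital brain
volume, truth = ph.generate_reference_volume(spec)
ir, labels, truth = ph.generate_section_series(volume, truth, spec)
res = pl.run_analysis(ir, labels, truth.label_planes, volume,
                      pl.PipelineConfig(seed=1))

print(res.comparison)
for met, s in res.region_stats.items():
    print(met, s["healthy"]["mean"], s["tumor"]["mean"], s["welch_p"])
```

This cuts the phantom into 52 sections (26 IR, 26 histology), distorts each
(mean shrinkage 11 % in height, 8 % in width, plus jitter and occasional
tears), corrects, reconstructs and quantifies.  Output for seed 1:

```
volume_ir_mm3                 0.013
volume_ihc_mm3                0.014
percent_difference_of_reference   4.65   # |IHC−IR| / IHC × 100
percent_difference_of_other       4.88   # |IHC−IR| / IR × 100
hausdorff_um                 41.2
hausdorff_p95_um             30.6

glucose    healthy 2.20 ± 0.27   tumor 0.77 ± 0.19   p < 1e-300
glycogen   healthy 5.10 ± 0.57   tumor 1.20 ± 0.36   p < 1e-186
lactate    healthy 1.20 ± 0.22   tumor 2.52 ± 0.24   p < 1e-200
```

The healthy means equal the assay anchors by construction (calibration
closure); the tumor means recover the constructed Warburg-effect ground
truth (0.8 / 1.2 / 2.4 µmol g⁻¹) within a few percent — the residual bias is
the documented glucose–glycogen spectral overlap, not noise.  Every
corrected section conserves its total spectral absorbance to better than
1e-15 relative.

The same run is available from the shell:

```sh
spectromics3d phantom --out phantom/ --seed 1
spectromics3d all --config cfg.yaml --out results/
```

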