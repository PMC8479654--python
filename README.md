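# frcqe — Fourier ring correlation quality estimation for 3D microscopy

`frcqe` scores the per-slice image quality of 3D fluorescence microscopy
z-stacks without any reference image. It targets the everyday problem of
cleared-tissue imaging — which optical clearing protocol actually keeps a
nuclear-stained organoid sharp all the way to its center? — where the usual
proxy, raw image intensity, is misleading: scattered haze can *raise*
intensity exactly where quality falls.

## The metric

Fourier ring correlation (FRC) measures, per concentric ring of spatial
frequency `r`, the normalized cross-correlation of two images' spectra:

```
FRC(r) = Re[ Σ_{f∈r} F₁(f) · F₂*(f) ] / sqrt( Σ_{f∈r} |F₁(f)|² · Σ_{f∈r} |F₂(f)|² )
```

Classical FRC needs two independent acquisitions of the same object. In a
densely sampled z-stack, adjacent slices approximate such a pair. The FRC-QE
score of slice `z` is built from the **relative FRC curve**

```
FRC_rel(r) = FRC(I_z, I_{z+dz_adj})(r) − mean± FRC(I_z, I_{z±dz_dist})(r)
```

where the distant slices (default `dz_dist = 10`) share only coarse structure
and artifacts, so subtracting their curve suppresses frequency content that is
not genuine in-focus signal. The curve is smoothed with a centered moving
average over rings (default width 5) and reduced to a scalar by a trapezoidal
integral over ring radius. Scores are **arbitrary units**: they do not convert
to a physical resolution, and they are comparable only between stacks scored
with identical parameters (block, ring width, z offsets, smoothing,
aggregation) — every output profile carries a verbatim parameter audit for
this reason.

Two standard baselines are included for comparison: the DCT Shannon entropy
focus metric (entropy of the L1-normalized magnitudes of the type-II DCT) and
plain mean intensity.

A seeded synthetic generator renders nuclear-stained spherical organoid
stacks whose quality either stays constant with depth ("well cleared") or
degrades toward the central slices through depth-ramped blur plus an additive
haze background ("poorly cleared") — reproducing, at desk scale, the
characteristic U-shaped quality profile and the intensity inversion seen in
real cleared-organoid acquisitions.

## Worked example

```python
import frcqe

spec = frcqe.SyntheticSpec(degradation_mode="poorly_cleared", seed=7)
stack = frcqe.generate_organoid_stack(spec)          # 64 x 128 x 128 voxels
profile = frcqe.frc_qe_profile(stack, frcqe.QEParams())
df = profile.to_dataframe()
print(df.iloc[[0, 15, 31, 47, 62]].round(3).to_string(index=False))
```

prints

```
 z_index  frc_qe  dct_entropy  mean_intensity  n_undefined_rings
       0  22.900       11.834           2.690                  0
      15  16.316       11.570           8.957                  0
      31  11.798       10.745          17.845                  0
      47  20.608       11.574           9.558                  0
      62  26.002       11.837           2.950                  0
```

Read the table vertically: FRC-QE is highest at the stack faces (z = 0, 62)
and dips to its minimum at the central slice (z = 31) where the simulated
clearing failure blurs the image — while mean intensity moves the *opposite*
way, peaking at the center because of the haze background. DCT entropy shows
the same dip as FRC-QE. A matched-seed `well_cleared` stack scores a flat
profile (interior coefficient of variation ≈ 0.07) at a higher mean.

The same pipeline from a shell:

```bash
frcqe simulate --spec-file organoid.spec --seed 7 --output sim.tif
frcqe score --input sim.tif --output profile.csv --dz-distant 10
```

`score` writes the CSV above plus `profile.csv.params.json` recording every
effective parameter. `organoid.spec` is a plain-text `key = value` file (see
`frcqe.spec_to_text` for the full key list).

## Scope

`frcqe` scores image quality only. It does not perform multi-view fusion or
deconvolution, does not model the microscope PSF, and deliberately excludes
learned no-reference metrics (e.g. BRISQUE), whose pretrained weights do not
transfer predictably to fluorescence data. See `docs/methods.md` for the full
model description, parameter reference, and known limitations.
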