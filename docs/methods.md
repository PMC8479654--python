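# Methods

## The FRC-QE model

FRC-QE treats adjacent z-slices of a densely sampled fluorescence stack as a
surrogate for the two independent realizations that classical Fourier ring
correlation requires. The assumptions this rests on:

- **z-spacing small relative to axial structure.** Slices `z` and
  `z + dz_adjacent` must image essentially the same object plane, differing
  mainly in noise; if the z-step is coarse, adjacent-slice FRC measures axial
  structure change, not quality.
- **distant slices decorrelated.** Slices `dz_distant` steps away must share
  only coarse structure (sample envelope, stripes, fixed-pattern artifacts).
  Subtracting their FRC curve from the adjacent-slice curve removes the
  contribution of such artifacts to apparent correlation. `dz_distant` must be
  large relative to the axial extent of the stained structures: with nuclear
  blobs of axial width σ voxels, slice pairs `dz` apart retain a structural
  correlation of roughly `exp(−dz²/4σ²)`, so `dz_distant ≳ 4σ` is needed for
  the normalization to measure artifacts rather than signal.
- **fixed parameters within a comparison.** The score scale depends on the
  block, ring width, z offsets, smoothing, aggregation rule, image content,
  and PSF. Scores are arbitrary units for *relative* comparison only; every
  profile embeds its parameter set and the CSV writer emits a
  `.params.json` audit file so mismatched comparisons are detectable.

### Computation per slice

1. Crop the block from slices `z`, `z + dz_adjacent`, `z ± dz_distant`
   (promoting to float64), optionally apodize all with the same raised-cosine
   (Hann) window.
2. Full two-sided centered FFT of each block; partition the frequency plane
   into rings of width `ring_width` (default 1 frequency sample) by Euclidean
   distance from the DC bin. Non-square and odd blocks are supported without
   padding; the outermost ring reaches the farthest grid corner.
3. Per ring: `FRC = Re[Σ F₁F₂*] / sqrt(Σ|F₁|² · Σ|F₂|²)`. The numerator uses
   the real part of the complex cross-spectrum sum (the standard FRC
   definition). A ring is **undefined** when either power sum falls below
   `1e-20` of the image's total spectral power — this catches constant blocks
   and FFT round-off leakage explicitly instead of imputing a silent 0, which
   would bias scores downward in background regions.
4. Relative curve: adjacent-slice FRC minus the mean of the two distant-slice
   curves (one-sided near the stack faces by default; a strict two-sided mode
   shrinks the scoreable z-range). Undefined rings propagate.
5. Smooth the defined values with a centered moving average of
   `smooth_window` rings (default 5; the window shrinks symmetrically at the
   curve ends), then reduce with the `integrate` rule. Default is the
   trapezoidal integral over ring radius with undefined rings skipped by
   joining their defined neighbours; `mean` and `clip` (negatives clipped to 0
   before integrating) are provided as alternatives. Negative relative values
   are *retained* by default — clipping is an extra nonlinearity and is
   opt-in.

A brute-force FRC implementation (`frc_curve_bruteforce`) that loops over
every frequency sample in scalar arithmetic ships with the package and is
exercised by the test suite as a permanent definitional oracle for the
vectorized path (agreement ≤ 1e-9 over randomized shapes including odd
dimensions).

### Parameters

| parameter | default | units | notes |
|---|---|---|---|
| `block` | largest centered square | voxels | FRC rings are cleanest on squares; any fixed choice is valid if held constant |
| `dz_adjacent` | 1 | slices | the "independent realization" offset |
| `dz_distant` | 10 | slices | normalization offset; must exceed the axial structure extent |
| `ring_width` | 1 | frequency samples | finest stable binning |
| `smooth_window` | 5 | rings | centered moving average |
| `integrate` | `trapz` | — | also `mean`, `clip` |
| `window` | off | — | Hann apodization of both images; off so the brute-force definition holds exactly |
| `boundary` | `one_sided` | — | distant-partner fallback at stack faces |

Numerical tolerances: defined FRC values are asserted within
`[−1 − 1e−9, 1 + 1e−9]`; the undefined-ring power threshold is `1e-20`
relative. All metrics for a slice are computed on the same float64 block.

### Baselines

- **DCT Shannon entropy**: `d = |DCT-II(block)|`, `p = d / Σd`,
  `H = −Σ p log₂ p` with `0·log 0 = 0`. Base-2 logarithm and L1-normalized
  absolute coefficients; literature variants differ, so the formula is fixed
  and documented here. Constant and all-zero blocks score 0; the metric is
  invariant under positive scaling and bounded by `log₂(H·W)`.
- **Mean intensity**: arithmetic mean of the block, the conventional (and, on
  hazy samples, misleading) clearing-quality proxy.

## Synthetic organoid stacks

The generator renders the study conditions under which the behavioral claims
are tested: a sphere of radius 48 voxels filled with 300 nuclei (isotropic
Gaussian blobs, σ = 2 voxels, peak ≈ 100 counts) inside a 64×128×128 stack,
with Gaussian read noise σ = 2 added last. The sphere must fit in-plane but
may be truncated by the z faces — as when the imaged slab is thinner than the
organoid; with radius 48 and 64 slices every slice intersects the sphere.
The read-noise level (2% of blob peak) was fixed once as a realistic
camera-noise scale for this intensity range.

Degradation is driven by normalized depth from the nearer z-face,
`d(z) ∈ [0, 1]` (0 at the faces, ~1 at the central slice), through a gain
`g(d)`: identity ramp for `poorly_cleared`, 0 for `well_cleared`, 1 for
`uniform_blur`. Per slice the generator applies a 2D Gaussian blur of width
`blur_sigma_max · g(d)` (default max 3 px) and adds a haze background
`haze_max · g(d)` (default max 50 counts, i.e. half the blob peak) shaped by
a wide (5·σ_nucleus) blur of the slice, so haze raises mean intensity without
contributing high-frequency structure. Noise is drawn after degradation from
a generator state independent of the degradation mode, so matched-seed
well/poor stacks are voxelwise identical at the zero-degradation faces.

**Why blur lowers the score here.** FRC is invariant under applying the same
linear filter to both images of a pair — each ring's numerator and denominator
scale identically. Blur therefore reduces FRC-QE only through noise added
*after* the blur (physically: optics degrade the signal before the detector
adds read noise), which leaves high-frequency rings noise-dominated and
decorrelated. The generator and the blur-response tests follow this order
deliberately.

**What the generator does not emulate:** optics-accurate PSFs and 3D light
propagation (degradation is per-slice 2D), scattering anisotropy, shot noise
(noise is additive Gaussian, not Poisson), photobleaching, and multi-view
fusion seams. Passing tests therefore demonstrate the metric's response to
depth-dependent blur/haze/noise of the modelled kind, not performance on any
particular instrument's data.

## Problem sizes and test design

Behavioral checks run on the full 64×128×128 study stacks (a profile takes
~1 s: spectra are computed once per slice and reused across the adjacent and
distant pairings). Unit tests use compact stacks (e.g. 12×48×48, 16×96×96)
chosen so that `dz_distant` still exceeds the nuclear axial decorrelation
length — at `dz_distant = 3` with σ = 2 blobs, "distant" slices still share
~57% structural correlation and the normalization term confounds blur
comparisons, so blur-response tests use 16-slice stacks with `dz_distant = 4`
and σ = 2. The oracle parity sweep uses 100 randomized pairs with sizes 4–64,
odd and even.

## Design choices where the design was open

- **Distant-curve combiner**: mean of the ±`dz_distant` curves, symmetric in
  z; one-sided fallback at the faces maximizes usable depth and is the
  default, with strict two-sided available when a uniform normalization
  matters more than coverage.
- **Aggregation**: trapezoidal integration over ring radius rather than a
  plain ring mean, so coarser `ring_width` choices reweight consistently; the
  rule is pluggable and recorded in the params audit.
- **Degradation depth coordinate**: depth from the nearer z-face (not radial
  distance), giving the simple U-shaped axial profile the metric is meant to
  resolve.
- **Undefined rings**: flagged and excluded from smoothing/integration, never
  imputed; the per-slice count is reported in the profile
  (`n_undefined_rings`) so heavily degenerate blocks are visible.
- **Noise model of the relative curve**: for white-noise inputs each ring's
  FRC estimate fluctuates with standard deviation ~`n_ring^{-1/2}`; tests
  bound the relative curve per ring by `6/√n_ring` rather than a flat
  constant, since innermost rings hold only a handful of samples.

## Known limitations

- Scores are not comparable across different `z_spacing`, PSFs, staining, or
  any parameter change; the package records parameters but cannot normalize
  across them.
- The exact smoothing/aggregation used by other FRC-QE implementations is not
  claimed to match bit-for-bit; this implementation fixes and documents its
  own defaults and reproduces the method's qualitative behavior.
- Very small blocks (≲16 px) leave few rings; scores become noisy and the
  smoothing window dominates.
- TIFF is the only supported container (single grayscale channel); no HDF5 /
  Zarr streaming, no tile-based processing of terabyte volumes.
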