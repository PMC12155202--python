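# Methods

`widefield3d` restores thick-tissue widefield fluorescence z-stacks by
combining four stages: depth-variant theoretical PSF generation, background
prefiltering, brick-wise maximum-likelihood deconvolution, and 3D mosaic
stitching. This note documents the models, the numerical choices, and what
the synthetic tests do and do not demonstrate.

## Optical model

The PSF is a scalar-diffraction (Gibson–Lanni-class) pupil integral. With
normalized pupil radius ρ ∈ [0, 1], immersion index `n_i`, sample index
`n_s`, numerical aperture `NA`, emission wavelength λ and `k₀ = 2π/λ`:

    sin θ_i = NA ρ / n_i,    sin θ_s = NA ρ / n_s
    OPD(ρ; d) = d (n_s cos θ_s − n_i cos θ_i)
    U(z, r)  = ∫₀¹ J₀(k₀ NA r ρ) exp[i k₀ (z n_i cos θ_i + OPD)] ρ dρ
    PSF(z, r) = |U(z, r)|²

Three quantities beyond the objective drive the depth dependence: `n_i`
(water, 1.33), `n_s` (cleared tissue, 1.50), and the nominal depth `d` below
the coverslip, reckoned as `coverslip_distance + z_index · dz` for downward
imaging. When `n_s = n_i` the OPD vanishes identically and the PSF is
depth-invariant — a property asserted to 1e-8 in the tests.

The integral is evaluated with 256-node Gauss–Legendre quadrature over the
pupil radius, on a fine radial grid, then interpolated onto the voxel
lattice; the kernel is therefore radially symmetric by construction.
Apodization is uniform; the model is scalar (no polarization), and
excitation-side blur is ignored — epi-illumination is near-uniform across
the field. These simplifications matter for absolute Strehl ratios but not
for the depth trends the pipeline relies on (axial FWHM growing from
~1.0 µm at the coverslip to ~5.8 µm at 500 µm for NA 1.0 / 520 nm, and a
spherical-aberration focal shift of roughly 0.12–0.13 · depth).

**Kernel z-orientation.** With `n_s > n_i` the true focus lies deeper than
the nominal plane, so an emitter's in-focus image appears at a *shallower*
nominal index. The kernel's defocus coordinate therefore runs opposite to
the stack index; the simulator and the deconvolver share this convention.

**Support selection.** A widefield PSF conserves energy per defocus plane
(no optical sectioning), and within any finite lateral box the axial tail
decays only ~1/z², so no box captures "all" of the PSF. Support is an
explicit truncation rule: lateral half-width = 3× the 99%-energy radius of
the in-focus plane; axial half-width = focal shift + 4 axial FWHM; both are
capped (default 161×61×61 voxels) and the kernel is renormalized to unit
sum. A warning reports when the border shell still holds >1% of in-box
energy. Restoration tests fix a shared support of 81×41×41 voxels for the
simulator and the deconvolver so both use the identical forward kernel.

**Axial Nyquist.** The sampling utility implements
λ / (4 n_i (1 − cos(asin(NA/n_i)))): 0.287 µm at 520 nm and at most
0.386 µm over 450–700 nm for NA 1.0 in water, comfortably below the ~1 µm
z-steps of typical acquisitions; the pipeline logs a warning when the
configured z-step exceeds the bound.

## Background prefiltering

The background estimate is Gaussian blur (σ = `gaussian_sigma_um`) →
grayscale minimum filter (disk/ellipsoid radius = `min_radius_um`) →
Gaussian smooth (σ = `post_smooth_sigma_um`, truncated near the
minimum-filter radius and clipped to the blurred image so the estimate never
exceeds what the blur sees). The default mode filters each x-y plane
independently, because the dominant artifact driver in thick stacks is
plane-to-plane background variability. Subtraction clamps at zero: the
image reaching the deconvolver is assumed background-free, so the
deconvolver's own background term is zero for filtered images.

The minimum-filter radius must exceed both the PSF lateral extent and the
radius of real image features; `auto_settings` derives
(σ, radius, post) = (0.5, 3, 1.5) × the PSF's 95%-energy lateral radius,
with a one-voxel floor for delta-like kernels. For nuclei-scale objects the
defaults in the test pipeline are σ = 1 µm, radius = 8 µm, post = 4 µm —
the radius sits above the nucleus radius (2–4 µm) so the minimum filter
always reaches past a nucleus into true background.

Rationale for the trailing smooth: the raw minimum filter produces blocky
plateaus whose own edges would be sharpened by deconvolution; smoothing at
sub-radius scale removes them without re-admitting features.

## Maximum-likelihood deconvolution

Restoration is Richardson–Lucy (the Poisson MLE iteration):
`e ← e · K†(obs / (K e + ε))`, ε = 1e-12 · max(obs). `qmle_accelerated`
raises the multiplicative correction to power 1.5 — an exponent-accelerated
variant reaching a comparable likelihood in ~2/3 the iterations; it is an
analog of commercial "quick MLE" modes, not a reimplementation of any
proprietary algorithm. The user-facing `snr` knob maps to an iteration
budget, `round(base_iterations · snr / 20)`, so low-SNR data is regularized
by early stopping; `acuity` multiplies the budget for fine-structured
images. Iterations run in float32 by default (float64 available via
`precision`), with cached kernel FFTs.

Boundary handling: `circular` and `zero_pad` form exact forward/adjoint
transpose pairs (circular conserves total flux exactly for a unit-sum
kernel; likelihood monotonicity is guaranteed and tested under these).
`reflect` — the default for real data — extends the stack by mirror
reflection and approximates the adjoint by flipped-kernel correlation,
standard practice that suppresses boundary ringing.

**Bricking.** The stack is split along z into near-equal cores (sizes
differ by ≤1); each brick is padded by half the PSF axial support, given a
PSF generated at its core-center depth, deconvolved independently, and
written back. The pad exists to give the iteration context; the write-back
cross-fades linearly over only a *narrow seam* (3 planes beyond each core by
default). A pad-wide cross-fade was measured to be harmful: it lets a
neighbouring brick's estimate — computed with the wrong depth's PSF — bleed
deep into the core and bias axial positions by 1–2 voxels.

## Mosaic stitching

Tiles are flat-field corrected (division by the vignetting reference
normalized to unit mean), registered pairwise over their expected overlap
strips, placed globally, and fused. Offset estimation proposes an integer
shift by phase correlation, then scores candidate shifts (the proposal, the
nominal grid offset, and search windows around both derived from the overlap
width) by Pearson correlation of the implied full-tile overlap, breaking
ties toward the nominal offset; featureless strips return the nominal offset
with score 0 and a low-confidence flag. Offsets are integer-voxel only —
z-steps of 0.8 µm and pixels of 0.34 µm make subvoxel refinement
unnecessary at nuclear scale. Multi-channel estimates merge by
score-weighted consensus. Global placement solves the grid-graph least
squares problem anchored at tile (0,0); fusion uses separable pyramid
feather weights normalized to a partition of unity over the covered canvas;
uncovered voxels are zero.

A caveat the tests document deliberately: a pure linear intensity ramp is
shift-ambiguous (a translated ramp correlates perfectly with itself), so
registration fixtures must contain texture; featureless fixtures exercise
the low-confidence path instead.

## Synthetic phantoms

The generator emulates what the pipeline assumes about cleared-tissue
stacks: antialiased spheres/ellipsoids ("nuclei") with non-overlapping
placement (rejection sampling, separation > sum of radii + 2 µm), a
low-frequency background (linear ramp, or a field smooth within planes but
weakly correlated along z to mimic plane-to-plane background variability),
optional abrupt glare over the deepest planes (an out-of-focus bright layer
no axial blur model can explain — the edge-artifact trigger), Poisson shot
noise with optional Gaussian read noise, and radial vignetting. Depth
variance is applied slab-wise with the same even z-partition the brick
planner uses, so the simulator and the restoration share the forward model
they claim to invert; a finer slab count probes model mismatch. Everything
is deterministic under the seed; changing only the seed changes noise, not
explicitly placed geometry.

Default study conditions (the restoration acceptance phantom): 200×256×256
voxels at (0.8, 0.34, 0.34) µm, 150 nuclei of radius 2–4 µm at intensity
500 counts, ramp background at 20% of peak, Poisson noise, NA 1.0,
n 1.33/1.50, depth 0–160 µm. Smaller problem sizes (e.g. 64×128×128 for
the background ablation, 2×2 grids of 16×96×96 tiles for determinism) are
used where the property under test does not depend on full scale.

What passing these tests shows — and does not. The phantoms share the
forward model with the restoration (the "inverse crime"), so the tests
verify correctness and internal consistency of the implementation:
depth-matched kernels recover positions and deep-slab flux where a single
mid-depth kernel demonstrably does not. They do not measure robustness to
PSF model error, tissue scattering, refractive inhomogeneity, or spectral
mixing in real cleared tissue; a finer simulation slab count than brick
count probes the first of these only coarsely.

## Measured behaviour at the default conditions

Numbers the acceptance suite computes at the conditions above (seeded, so
reproducible): ≥95% of nuclei localized within 1 voxel after 7-brick
restoration (the blurred input fails the same test); deepest-core flux
around the nuclei recovered within 20% of truth with 7 bricks and strictly
worse with 1; edge-plane pile-up exceeding 3× interior without background
subtraction and below it with; planted mosaic shifts recovered exactly in
≥99% of 200 noisy trials and a 3×3 mosaic reassembled to <2% relative RMS;
bit-identical reruns under a fixed seed.

## Known limitations

- Scalar, emission-only PSF; no vectorial high-NA corrections, no measured
  (bead-derived) PSFs.
- One PSF per brick (core-center depth); per-slice PSF interpolation is a
  natural extension.
- The `snr`/`acuity` mappings to an iteration budget are this package's own
  semantics for those user-facing knobs; other tools' identically named
  settings need not agree quantitatively.
- Stitching is rigid and integer-voxel; no affine/non-rigid registration,
  no illumination harmonization beyond flat-field.
- No GPU path; runtimes are FFT-bound on CPU.
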