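# widefield3d

Depth-variant deconvolution for thick-tissue widefield fluorescence
microscopy: theoretical PSF generation, background prefiltering, brick-wise
maximum-likelihood restoration along z, and 3D mosaic stitching.

Classical widefield epifluorescence collects *all* emitted light — in-focus
and out-of-focus — so a z-stack through hundreds of micrometers of cleared
tissue is a superposition of every plane's blur. With refractive-index
matched (cleared) tissue under a water-immersion objective, the blur kernel
is not even constant: the index mismatch between immersion water
(n ≈ 1.33) and the embedding medium (n ≈ 1.50) accumulates spherical
aberration linearly with depth, broadening and displacing the PSF. This
package restores such stacks for researchers and imaging-core staff who
want confocal-like axial resolution from a fast, accessible camera-based
microscope:

- **`widefield3d.optics`** — scalar Gibson–Lanni-class PSFs
  `PSF(z, r) = |∫₀¹ J₀(k₀ NA r ρ) e^{i k₀ (z n_i cosθ_i + OPD(ρ; d))} ρ dρ|²`
  with the depth-aberration term `OPD = d (n_s cosθ_s − n_i cosθ_i)`, plus
  the axial Nyquist rule `λ/(4 n_i (1 − cos asin(NA/n_i)))`.
- **`widefield3d.background`** — pre-deconvolution background estimation
  (small Gaussian blur → local minimum filter → smooth) and subtraction;
  scales sit below the PSF and feature frequencies so only true background
  is removed. This prevents maximum-likelihood restoration from projecting
  unexplainable background shifts onto the volume edges.
- **`widefield3d.deconv`** — Richardson–Lucy (Poisson MLE) and an
  exponent-accelerated quick variant, applied brick-wise along z with a
  depth-matched PSF per brick and seamless reassembly.
- **`widefield3d.stitch`** — flat-field correction, pairwise 3D offset
  estimation per channel, least-squares global placement, feathered fusion.
- **`widefield3d.phantom`** — seeded synthetic phantoms (nuclei, depth-
  variant blur, structured background, Poisson noise, vignetting, tile
  grids with planted offsets) so the whole pipeline is testable end-to-end
  without any data download.
- **`widefield3d.pipeline` / CLI** — the end-to-end flow
  (background-subtract → brick-wise deconvolve → stitch) driven by a YAML
  parameter template.

## Worked example

Simulate a small depth-variant acquisition, restore it, and check the
axial sampling rule:

```python
import numpy as np
from widefield3d import (OpticalConfig, DeconvSettings, nyquist_axial_um,
                         plan_bricks, deconvolve_depth_variant)
from widefield3d.phantom import nuclei_spec, simulate_widefield, render_ground_truth

cfg = OpticalConfig(na=1.0, n_immersion=1.33, n_sample=1.50,
                    em_wavelength_nm=520.0, voxel_size=(0.8, 0.34, 0.34))
print(f"axial Nyquist interval: {nyquist_axial_um(cfg):.3f} um")

spec = nuclei_spec(shape=(60, 96, 96), n_objects=10, radius_range_um=(2.0, 3.0),
                   background="none", noise="poisson", seed=7, margin_um=8.0)
observed = simulate_widefield(spec, cfg, n_depth_slabs=5, psf_support=(61, 31, 31))
truth = render_ground_truth(spec)

settings = DeconvSettings(algorithm="qmle_accelerated", snr=20.0,
                          max_iterations=40, base_iterations=40)
plan = plan_bricks(60, 5, psf_axial_support=61)
restored = deconvolve_depth_variant(observed, cfg, settings, plan,
                                    psf_support=(61, 31, 31))
peak_gain = restored.data.max() / observed.data.max()
print(f"peak intensity gain after restoration: {peak_gain:.1f}x")
```

Output:

```
axial Nyquist interval: 0.287 um
peak intensity gain after restoration: 5.7x
```

The 0.287 µm interval says a 20×/NA 1.0 water-immersion objective supports
lossless axial sampling well below 1 µm z-steps at green emission. The
restored stack concentrates each nucleus's light back to its origin — the
peak gain reflects out-of-focus light returned to the in-focus voxels. On
the full-scale acceptance phantom (200×256×256, 150 nuclei), the suite in
`tests/test_acceptance.py` verifies that ≥95% of nuclei land within one
voxel of their true centers, while the blurred input fails the same check.

The same stages are available from the shell:

```sh
widefield3d simulate --preset tiles --seed 1 --out fixtures/
widefield3d bgsub observed.ome.tif filtered.ome.tif --sigma-um 1 --min-radius-um 8
widefield3d deconv filtered.ome.tif restored.ome.tif --bricks 7 --snr 20
widefield3d stitch tiles/ mosaic.ome.tif --grid 3x3 --overlap 0.10
widefield3d pipeline config.yaml tiles/ mosaic.ome.tif
```

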