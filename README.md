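# scatmap

Scanning SAXS/WAXS structural mapping for biological tissues: detector
geometry and azimuthal reduction, SAXS/WAXS profile merging and
transmission-normalized background subtraction, raster-scan structural
maps, scattering-contrast tomography by filtered backprojection, and a
thin-lens model of the beryllium CRL transfocator that focuses the beam.
Everything is exercised end to end on synthetic phantoms with known
ground truth, so the full pipeline is testable on a laptop with no
beamtime and no downloads.

## Who this is for

Beamline staff and users of scanning scattering instruments who need a
self-contained, inspectable implementation of the standard processing
chain: raw 2D detector frames → (q, φ) maps → azimuthally averaged
1D profiles → scalar features → structural maps and tomograms. The
synthetic module doubles as a simulator for planning measurements and as
a fixture generator for testing analysis code.

## The computation in brief

- **Reciprocal-space mapping.** A flat detector pixel at radial offset
  *r* from the beam center sees scattering angle 2θ = atan(*r*/*L*) and
  scattering vector *q* = 4π sin θ/λ; azimuth φ is measured
  counter-clockwise from +columns. Frames are regridded into (q, φ)
  intensity maps ("caking") and averaged over φ into I(q), with Poisson
  errors and per-bin pixel counts retained.
- **Calibration.** Powder rings of a known d-spacing (silver behenate,
  d = 58.380 Å, q_n = 2πn/d) refine the sample–detector distance and
  beam center by least squares on per-sector ring-arc centroids.
- **Merging and background.** The WAXS profile is scaled onto the SAXS
  profile by the median intensity ratio over their q overlap and the two
  are stitched into one profile spanning ~0.006–3 Å⁻¹. Thin-sample
  background (windows, residual air) scales with the transmitted beam:
  I_corr = (I_s/M_s − I_b/M_b)·M_s with M the transmitted monitor.
- **Structural maps.** Any scalar feature of the per-point profile — the
  integrated intensity above q = 0.1 Å⁻¹, the cellulose (200) peak area
  at q = 1.58 Å⁻¹, the amorphous band near 2.27 Å⁻¹ — placed on the
  (unscrambled, snake-aware) scan grid.
- **Tomography.** Voxel-linear attributes (peak areas, band integrals,
  −ln T absorption) form parallel-beam sinograms reconstructed by
  Ram-Lak-filtered backprojection; the cellulose crystallinity index is
  the *ratio of two reconstructed tomograms* (crystalline peak over
  amorphous band), never a ratio sinogram.
- **CRL optics.** N lenses of apex radius R give f = R/(2Nδ) with
  δ = r_e λ² ρ_e/2π for beryllium; the transfocator search picks the
  lens-group state (and optionally the position along the beam) that
  best satisfies the imaging condition f = pq/(p+q) for the 8 m
  SSA-to-sample layout.

## Worked example

Solve the transfocator for 12.4 keV with the lenses 0.5 m from the
sample:

```
$ scatmap lenses --energy 12.4 --lens-to-sample 0.5
demagnification 15.00:1, f_required = 0.4688 m
best state (1, 1, 1, 1, 1, 1, 1) (47 lenses): f = 0.5154 m, residual = 0.04667 m
```

At the closest approach the 7.5 m object arm and 0.5 m image arm demand
f = 7.5·0.5/8 = 0.4688 m and demagnify the secondary source 15:1; even
the full stack (43 lenses of 0.1 mm radius plus four of 0.5 mm) only
reaches 0.515 m at this energy, so in practice the transfocator is moved
along the beam to close the residual — `scatmap lenses` with
`--scan-energies 7:18:1` tabulates focal lengths across the operating
range.

A complete synthetic mapping run from the shell:

```
$ scatmap simulate scan --seed 3 --out scan.h5
wrote scan -> scan.h5
$ scatmap map --scan scan.h5 --feature peak:1.58:0.1 --out map.tif
peak:1.58:0.1: 32x32 map, range [0, 58.27] -> map.tif
```

The map is the cellulose (200) peak area per scan point of a two-phase
stem-like phantom (crystalline-rich ring around an amorphous-rich pith);
thresholding it at the midpoint reproduces the phantom's crystalline
region essentially exactly (Jaccard > 0.95 in the test suite).

The same works from Python, including tomography:

```python
import numpy as np, scatmap as sm
from scatmap.tomo import make_peak_attribute, build_sinogram, reconstruct_fbp

geom = sm.ExperimentGeometry(wavelength=1.0, det_distance=30.0,
                             beam_center=(32, 32), pixel_pitch=0.5,
                             det_shape=(64, 64), detector_name="waxs")
phantom = sm.two_phase_disk_phantom(64, pixel_size=0.005)   # 5 um voxels
series = sm.simulate_tomo(phantom, {"waxs": geom},
                          angles=np.arange(-90, 90.1, 1.5), seed=7)
sino = build_sinogram(series, make_peak_attribute(1.58, 0.1))
tomogram = reconstruct_fbp(sino)
```

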