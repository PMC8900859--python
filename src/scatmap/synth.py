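"""Synthetic calibrants, tissue-like scattering and scan/tomo phantoms.

Everything downstream of the beamline is testable without measured data:
this module renders detector frames from analytic material models
(power-law decay plus Gaussian diffraction peaks, the phenomenology of
plant cell-wall scattering), generates silver-behenate-like calibration
rings, raster-scan bundles over 2D phantoms, and tomographic projection
series — all seed-deterministic and carrying their ground truth alongside.

The material models are phenomenological stand-ins, not physical
fibre-diffraction simulations: a power law (default exponent 3) mimics the
multi-scale low-q decay of cell-wall tissue, a sharp Gaussian at
1.58 1/A stands for the cellulose (200) reflection, and a broad hump near
2.27 1/A for amorphous (non-crystalline) scattering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (DetectorFrame, ExperimentGeometry, pixel_to_qphi,
                       qphi_to_radius)
from .mapping import ScanBundle
from .tomo import project_map

__all__ = [
    "MaterialModel", "Phantom2D", "make_cellwall_materials",
    "render_pattern", "make_agbeh", "pilatus_mask", "detector_template",
    "disk_phantom", "two_phase_disk_phantom", "simulate_scan",
    "simulate_tomo", "AGBEH_D_SPACING",
]

#: silver behenate lamellar period, Angstrom (standard calibrant value)
AGBEH_D_SPACING = 58.380


@dataclass(frozen=True)
class MaterialModel:
    """Analytic scattering model: I(q) = flat + A*q^-p + sum of Gaussians.

    ``peaks`` is a list of (q0 [1/A], sigma [1/A], amplitude) tuples.
    ``mu_mm`` is the attenuation coefficient per unit material weight per
    mm of path, used for monitor simulation.  q below ``q_floor`` is
    clipped so the power law stays finite at the beam center.
    """

    name: str
    power_law_amplitude: float = 0.0
    power_law_exponent: float = 3.0
    peaks: tuple = ()
    flat: float = 0.0
    is_centrosymmetric: bool = True
    mu_mm: float = 0.1
    q_floor: float = 5e-3

    def intensity(self, q):
        q = np.asarray(q, dtype=float)
        qc = np.maximum(q, self.q_floor)
        out = np.full(qc.shape, float(self.flat))
        if self.power_law_amplitude:
            out = out + self.power_law_amplitude * qc ** (-self.power_law_exponent)
        for q0, sigma, amp in self.peaks:
            out = out + amp * np.exp(-0.5 * ((q - q0) / sigma) ** 2)
        return out


def make_cellwall_materials():
    """(crystalline, amorphous, blank) material models for cell-wall tissue.

    * crystalline: power-law decay + sharp cellulose (200) peak at
      1.58 1/A + a smooth wide-angle hump;
    * amorphous: power-law decay + broad hump centred near 2.27 1/A,
      nothing sharper than ~0.05 1/A FWHM;
    * blank: weak flat term + residual-air-like low-q scattering, far
      below the sample everywhere that matters.
    """
    crystalline = MaterialModel(
        "crystalline", power_law_amplitude=0.10, power_law_exponent=3.0,
        peaks=((1.58, 0.03, 1.0), (1.1, 0.45, 0.15)), mu_mm=0.15)
    amorphous = MaterialModel(
        "amorphous", power_law_amplitude=0.10, power_law_exponent=3.0,
        peaks=((2.27, 0.30, 0.6),), mu_mm=0.10)
    blank = MaterialModel(
        "blank", power_law_amplitude=0.001, power_law_exponent=3.0,
        flat=0.002, mu_mm=0.01)
    return crystalline, amorphous, blank


# ---------------------------------------------------------------------------
# detector templates
# ---------------------------------------------------------------------------

def pilatus_mask(det_shape, module_shape=(195, 487), gap=(17, 7),
                 dead_module_rows=()) -> np.ndarray:
    """True = valid pixel; False in inter-module gaps and dead module rows.

    The default module/gap sizes tile a (1043, 981) hybrid pixel detector
    as 5 x 2 modules; ``dead_module_rows`` removes whole module rows (the
    wide-angle unit used here is such a detector with the center module
    row absent so small-angle photons pass through).
    """
    rows, cols = det_shape
    mask = np.ones(det_shape, dtype=bool)
    mh, mw = module_shape
    gh, gw = gap
    r = mh
    mod_row = 0
    row_band = np.zeros(rows, dtype=int)   # module-row index per pixel row
    rr = 0
    while rr < rows:
        band_end = min(rr + mh, rows)
        row_band[rr:band_end] = mod_row
        if band_end < rows:
            mask[band_end:min(band_end + gh, rows), :] = False
            row_band[band_end:min(band_end + gh, rows)] = -1
        rr = band_end + gh
        mod_row += 1
    cc = 0
    while cc < cols:
        band_end = min(cc + mw, cols)
        if band_end < cols:
            mask[:, band_end:min(band_end + gw, cols)] = False
        cc = band_end + gw
    for dead in dead_module_rows:
        mask[row_band == dead, :] = False
    return mask


def detector_template(name: str):
    """(det_shape, mask) for the built-in detector layouts.

    ``"saxs"``: full 5x2-module detector, (1043, 981) px.
    ``"waxs"``: same layout with the center module row removed.
    """
    shape = (1043, 981)
    if name == "saxs":
        return shape, pilatus_mask(shape)
    if name == "waxs":
        return shape, pilatus_mask(shape, dead_module_rows=(2,))
    raise ValueError(f"unknown detector template {name!r}")


# ---------------------------------------------------------------------------
# pattern rendering
# ---------------------------------------------------------------------------

_Q_CACHE: dict = {}


def _pixel_q(geom: ExperimentGeometry) -> np.ndarray:
    key = (geom.wavelength, geom.det_distance, geom.beam_center,
           geom.pixel_pitch, geom.det_shape)
    if key not in _Q_CACHE:
        rows, cols = np.indices(geom.det_shape)
        q, _ = pixel_to_qphi(geom, (rows.ravel(), cols.ravel()))
        _Q_CACHE[key] = q.reshape(geom.det_shape)
    return _Q_CACHE[key]


def render_pattern(material_mix, geom: ExperimentGeometry, exposure: float,
                   noise_seed: int | None = None, mask=None) -> DetectorFrame:
    """Render one detector frame from a weighted mix of materials.

    ``material_mix`` is a sequence of (MaterialModel, weight) pairs.  The
    expected count per pixel is ``exposure * sum(w * I_m(q))``; Poisson
    noise is applied when ``noise_seed`` is given (None = noise-free
    expected values).  The seed is recorded in the frame metadata.
    """
    q = _pixel_q(geom)
    expected = np.zeros(geom.det_shape)
    for material, weight in material_mix:
        if weight != 0.0:
            expected += weight * material.intensity(q)
    expected *= exposure
    if noise_seed is not None:
        rng = np.random.default_rng(noise_seed)
        counts = rng.poisson(np.maximum(expected, 0.0)).astype(float)
    else:
        counts = expected
    if mask is None:
        mask = np.ones(geom.det_shape, dtype=bool)
    return DetectorFrame(counts, mask, geom.detector_name,
                         metadata={"noise_seed": noise_seed,
                                   "exposure": exposure})


def make_agbeh(geom: ExperimentGeometry, d_spacing: float = AGBEH_D_SPACING,
               n_orders: int = 3, exposure: float = 1000.0,
               seed: int | None = None, ring_sigma_q: float | None = None,
               mask=None) -> DetectorFrame:
    """Silver-behenate-like calibration frame: rings at q_n = 2*pi*n/d.

    Ring widths default to 2% of the fundamental ring q.  Orders falling
    outside the detector's angular range are silently absent.
    """
    q1 = 2.0 * np.pi / d_spacing
    sigma = ring_sigma_q if ring_sigma_q is not None else 0.02 * q1
    peaks = []
    for order in range(1, n_orders + 1):
        try:
            qphi_to_radius(geom, order * q1)
        except ValueError:
            break
        peaks.append((order * q1, sigma, 1.0 / order))
    model = MaterialModel("agbeh", flat=0.01, peaks=tuple(peaks))
    frame = render_pattern([(model, 1.0)], geom, exposure, seed, mask=mask)
    frame.metadata.update({"d_spacing": d_spacing, "n_orders": len(peaks)})
    return frame


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------

@dataclass
class Phantom2D:
    """Per-pixel material weights on a square grid.

    ``weights`` has shape (n, n, n_materials), aligned with ``materials``;
    ``pixel_size`` is in mm.  For raster scans a phantom pixel is one scan
    point (a thin flat sample); for tomography it is one voxel of the
    rotated slice.
    """

    weights: np.ndarray
    materials: tuple
    pixel_size: float = 0.005          # 5 um, the typical scanning step

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 3 or self.weights.shape[2] != len(self.materials):
            raise ValueError("weights must be (n, n, n_materials)")
        if np.any(self.weights < 0):
            raise ValueError("material weights must be non-negative")

    @property
    def shape(self):
        return self.weights.shape[:2]


def disk_phantom(n: int, materials, weights_inside, radius_frac: float = 0.4,
                 pixel_size: float = 0.005) -> Phantom2D:
    """Uniform disk of the given material weights on an empty background."""
    yy, xx = np.indices((n, n)) - (n - 1) / 2.0
    inside = np.hypot(xx, yy) <= radius_frac * n
    w = np.zeros((n, n, len(materials)))
    for m, wi in enumerate(weights_inside):
        w[inside, m] = wi
    return Phantom2D(w, tuple(materials), pixel_size)


def two_phase_disk_phantom(n: int, materials=None, pixel_size: float = 0.005,
                           r_outer_frac: float = 0.42,
                           r_pith_frac: float = 0.22,
                           crystalline_ring: float = 0.8,
                           crystalline_pith: float = 0.2) -> Phantom2D:
    """Stem-like phantom: an outer ring rich in crystalline material and an
    inner pith poor in it, total material density constant on the disk.

    Ground-truth crystalline fractions default to 0.8 (ring) / 0.2 (pith).
    """
    if materials is None:
        crystalline, amorphous, _ = make_cellwall_materials()
        materials = (crystalline, amorphous)
    yy, xx = np.indices((n, n)) - (n - 1) / 2.0
    rho = np.hypot(xx, yy)
    disk = rho <= r_outer_frac * n
    pith = rho <= r_pith_frac * n
    w = np.zeros((n, n, len(materials)))
    w[disk, 0] = crystalline_ring
    w[disk, 1] = 1.0 - crystalline_ring
    w[pith, 0] = crystalline_pith
    w[pith, 1] = 1.0 - crystalline_pith
    return Phantom2D(w, tuple(materials), pixel_size)


# ---------------------------------------------------------------------------
# scan / tomography simulation
# ---------------------------------------------------------------------------

def _monitors_from_mu(path_mu, incident: float = 1.0e6):
    incident_arr = np.full(len(path_mu), float(incident))
    transmitted = incident_arr * np.exp(-np.asarray(path_mu, dtype=float))
    return incident_arr, transmitted


def simulate_scan(phantom: Phantom2D, geom_set, step: float | None = None,
                  snake: bool = False, seed: int = 0,
                  exposure: float = 1000.0, masks=None) -> ScanBundle:
    """Raster-scan a thin flat phantom: one frame per detector per point.

    ``geom_set`` maps detector names to geometries.  The per-point material
    mix is the phantom pixel under the beam; monitors encode transmittance
    ``exp(-sum(w * mu))``.  Ground-truth per-material weight maps are
    stored in the bundle's ``truth`` dict (and in ``/truth`` on write).
    Snake scans reverse the traversal of odd rows; the recorded positions
    always tell the truth about where each frame was taken.
    """
    step = phantom.pixel_size if step is None else float(step)
    nrows, ncols = phantom.shape
    n = nrows * ncols
    rng = np.random.default_rng(seed)
    masks = masks or {}

    # one noise seed per *grid cell* (row-major), so snake and raster
    # traversals of the same phantom record identical physics per cell
    cell_seeds = rng.integers(2 ** 31, size=n)
    positions = np.empty((n, 2))
    point_weights = np.empty((n, phantom.weights.shape[2]))
    grid_flat = np.empty(n, dtype=int)
    for k in range(n):
        row, col = divmod(k, ncols)
        gc = ncols - 1 - col if (snake and row % 2 == 1) else col
        positions[k] = (gc * step, row * step)
        point_weights[k] = phantom.weights[row, gc]
        grid_flat[k] = row * ncols + gc

    frames = {}
    out_masks = {}
    geoms = {}
    for name, geom in geom_set.items():
        mask = masks.get(name)
        stack = np.empty((n,) + geom.det_shape, dtype=np.float32)
        for k in range(n):
            mix = list(zip(phantom.materials, point_weights[k]))
            frame = render_pattern(mix, geom, exposure,
                                   noise_seed=int(cell_seeds[grid_flat[k]]),
                                   mask=mask)
            stack[k] = frame.counts
        frames[name] = stack
        out_masks[name] = (mask if mask is not None
                           else np.ones(geom.det_shape, dtype=bool))
        geoms[name] = geom

    mu = np.array([m.mu_mm for m in phantom.materials])
    incident, transmitted = _monitors_from_mu(point_weights @ mu)

    truth = {f"weight_{m.name}": phantom.weights[:, :, i]
             for i, m in enumerate(phantom.materials)}
    truth["pixel_size_mm"] = np.array([phantom.pixel_size])
    return ScanBundle(positions, frames, out_masks, geoms, incident,
                      transmitted, (nrows, ncols), snake, truth)


def path_weights(phantom: Phantom2D, angle_deg: float) -> np.ndarray:
    """Line-integrated material weights (n_translations, n_materials) of the
    phantom rotated to ``angle_deg``; units weight * mm.  This is the
    per-material ground truth of one tomographic projection."""
    n = phantom.shape[0]
    out = np.empty((n, phantom.weights.shape[2]))
    for m in range(phantom.weights.shape[2]):
        out[:, m] = project_map(phantom.weights[:, :, m], [angle_deg],
                                phantom.pixel_size)[0]
    return out


def simulate_tomo(phantom: Phantom2D, geom_set,
                  angles=None, seed: int = 0, exposure: float = 1000.0,
                  masks=None):
    """Tomographic projection series over a slice phantom.

    Yields (angle_deg, ScanBundle) lazily, one single-row line scan per
    projection angle (so long series stream through without holding every
    frame in memory).  Angles default to -90..90 deg inclusive at 1.5 deg
    steps; the translation step equals the phantom pixel size.  Monitors
    encode the attenuation line integral, so the absorption attribute
    reconstructs the local attenuation coefficient.
    """
    if angles is None:
        angles = np.arange(-90.0, 90.0 + 1e-9, 1.5)
    step = phantom.pixel_size
    n = phantom.shape[0]
    rng = np.random.default_rng(seed)
    masks = masks or {}
    mu = np.array([m.mu_mm for m in phantom.materials])
    x = np.arange(n) * step

    for angle in np.asarray(angles, dtype=float):
        w_path = path_weights(phantom, angle)       # (n, n_materials), w*mm
        frames = {}
        out_masks = {}
        geoms = {}
        for name, geom in geom_set.items():
            mask = masks.get(name)
            stack = np.empty((n,) + geom.det_shape, dtype=np.float32)
            for k in range(n):
                mix = list(zip(phantom.materials, w_path[k]))
                stack[k] = render_pattern(
                    mix, geom, exposure,
                    noise_seed=int(rng.integers(2 ** 31)), mask=mask).counts
            frames[name] = stack
            out_masks[name] = (mask if mask is not None
                               else np.ones(geom.det_shape, dtype=bool))
            geoms[name] = geom
        incident, transmitted = _monitors_from_mu(w_path @ mu)
        positions = np.column_stack([x, np.zeros(n)])
        truth = {f"path_weight_{m.name}": w_path[:, i]
                 for i, m in enumerate(phantom.materials)}
        yield float(angle), ScanBundle(positions, frames, out_masks, geoms,
                                       incident, transmitted, (1, n),
                                       False, truth)
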