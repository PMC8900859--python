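"""Detector geometry, reciprocal-space mapping and azimuthal reduction.

A flat area detector at normal incidence records photons scattered by the
sample.  Each pixel maps to a point in the plane of reciprocal space
perpendicular to the incident beam, described by the scattering-vector
magnitude q = 4*pi*sin(theta)/lambda (2*theta being the scattering angle)
and the azimuthal angle phi around the beam axis.  This module provides
that mapping, its inverse, geometry refinement from powder rings, and the
two standard reductions: the (q, phi) intensity map ("caked" image) and the
azimuthally averaged 1D profile.

Conventions
-----------
* pixels are 0-based (row, col); the beam center may lie off the detector;
* phi = 0 points along +columns and increases counter-clockwise when the
  image is displayed with row 0 at the top (rows increase downward), range
  (-180, 180] degrees;
* bin edges are half-open [lo, hi) except the last bin, which is closed;
* bin statistic is the mean of contributing pixels (exposure-comparable),
  with the contributing pixel count kept alongside so totals can be
  recovered.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .exceptions import CalibrationError

#: hc in keV * Angstrom (CODATA)
HC_KEV_A = 12.3984


def energy_to_wavelength(energy: float) -> float:
    """Convert photon energy in keV to wavelength in Angstrom.

    Parameters
    ----------
    energy : float
        Photon energy in keV; must be positive.
    """
    energy = float(energy)
    if energy <= 0:
        raise ValueError(f"photon energy must be positive, got {energy} keV")
    return HC_KEV_A / energy


@dataclass(frozen=True)
class ExperimentGeometry:
    """Scattering geometry of one flat, normal-incidence detector.

    Attributes
    ----------
    wavelength : float
        X-ray wavelength, Angstrom.
    det_distance : float
        Sample-to-detector distance along the beam, mm.
    beam_center : tuple of float
        (row, col) of the direct-beam position in fractional pixels.  May
        lie outside the detector (typical for off-axis WAXS modules).
    pixel_pitch : float
        Pixel size, mm (square pixels).
    det_shape : tuple of int
        (rows, cols) of the detector.
    detector_name : str
        Label used to tie frames to their geometry.
    """

    wavelength: float
    det_distance: float
    beam_center: tuple[float, float]
    pixel_pitch: float
    det_shape: tuple[int, int]
    detector_name: str = "det"

    def __post_init__(self):
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.det_distance <= 0:
            raise ValueError("det_distance must be positive")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        object.__setattr__(self, "beam_center",
                           (float(self.beam_center[0]), float(self.beam_center[1])))
        object.__setattr__(self, "det_shape",
                           (int(self.det_shape[0]), int(self.det_shape[1])))


@dataclass
class DetectorFrame:
    """One 2D detector exposure: photon counts plus a validity mask."""

    counts: np.ndarray
    mask: np.ndarray
    geometry_ref: str = "det"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.counts.shape != self.mask.shape:
            raise ValueError("counts and mask must share a shape")

    @property
    def shape(self):
        return self.counts.shape


@dataclass
class QPhiMap:
    """Intensity regridded onto (q, phi) bins.

    ``intensity[i, j]`` is the mean count of the pixels falling in q bin i
    and phi bin j; NaN exactly where ``counts_per_bin == 0`` (bins filled
    synthetically by gap interpolation keep ``counts_per_bin == 0`` as a
    marker).
    """

    q_edges: np.ndarray
    phi_edges: np.ndarray
    intensity: np.ndarray
    counts_per_bin: np.ndarray

    def __post_init__(self):
        self.q_edges = np.asarray(self.q_edges, dtype=float)
        self.phi_edges = np.asarray(self.phi_edges, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.counts_per_bin = np.asarray(self.counts_per_bin)
        if np.any(np.diff(self.q_edges) <= 0) or np.any(np.diff(self.phi_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        expect = (len(self.q_edges) - 1, len(self.phi_edges) - 1)
        if self.intensity.shape != expect or self.counts_per_bin.shape != expect:
            raise ValueError("intensity/counts_per_bin shape mismatch with edges")

    @property
    def q_centers(self):
        return 0.5 * (self.q_edges[:-1] + self.q_edges[1:])

    @property
    def phi_centers(self):
        return 0.5 * (self.phi_edges[:-1] + self.phi_edges[1:])


@dataclass
class Profile1D:
    """Azimuthally averaged 1D intensity profile I(q).

    ``error`` is the Poisson-propagated standard error of the bin mean;
    ``n_pixels`` the number of contributing detector pixels per bin.  Bins
    with no contributing pixels carry NaN intensity.
    """

    q: np.ndarray
    intensity: np.ndarray
    error: np.ndarray
    n_pixels: np.ndarray

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.error = np.asarray(self.error, dtype=float)
        self.n_pixels = np.asarray(self.n_pixels)
        n = len(self.q)
        if not (len(self.intensity) == len(self.error) == len(self.n_pixels) == n):
            raise ValueError("q, intensity, error, n_pixels must share a length")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q grid must be strictly increasing")

    def copy(self) -> "Profile1D":
        return Profile1D(self.q.copy(), self.intensity.copy(),
                         self.error.copy(), self.n_pixels.copy())


# ---------------------------------------------------------------------------
# pixel <-> reciprocal space
# ---------------------------------------------------------------------------

def pixel_to_qphi(geom: ExperimentGeometry, pixel):
    """Map fractional pixel coordinates to (q, phi).

    Parameters
    ----------
    geom : ExperimentGeometry
    pixel : array-like
        ``(row, col)`` pair; row/col may be arrays of any (broadcastable)
        shape.

    Returns
    -------
    q : ndarray or float
        Scattering-vector magnitude, 1/Angstrom.
    phi : ndarray or float
        Azimuth in degrees, (-180, 180]; 0 by convention at zero radius.
    """
    row = np.asarray(pixel[0], dtype=float)
    col = np.asarray(pixel[1], dtype=float)
    cr, cc = geom.beam_center
    drow_up = -(row - cr)          # rows grow downward on screen
    dcol = col - cc
    r = geom.pixel_pitch * np.hypot(drow_up, dcol)
    two_theta = np.arctan2(r, geom.det_distance)
    q = (4.0 * np.pi / geom.wavelength) * np.sin(0.5 * two_theta)
    phi = np.degrees(np.arctan2(drow_up, dcol))
    # atan2 returns [-180, 180]; fold -180 onto +180, and pin phi=0 at r=0
    phi = np.where(phi <= -180.0, phi + 360.0, phi)
    phi = np.where(r == 0.0, 0.0, phi)
    if np.isscalar(pixel[0]) or np.ndim(pixel[0]) == 0:
        return float(q), float(phi)
    return q, phi


def qphi_to_radius(geom: ExperimentGeometry, q):
    """Radial distance on the detector (mm) at which |q| is observed.

    Exact inverse of the radial part of :func:`pixel_to_qphi`.  Raises
    ``ValueError`` for q mapping to a scattering angle 2*theta >= 90 deg,
    which a normal-incidence flat detector cannot intercept.
    """
    q = np.asarray(q, dtype=float)
    s = q * geom.wavelength / (4.0 * np.pi)
    if np.any(s < 0) or np.any(s >= 1.0):
        raise ValueError("q outside the physical range for this wavelength")
    two_theta = 2.0 * np.arcsin(s)
    if np.any(two_theta >= 0.5 * np.pi):
        raise ValueError("q maps to a scattering angle >= 90 deg: "
                         "not interceptable by a flat normal-incidence detector")
    r = geom.det_distance * np.tan(two_theta)
    return float(r) if q.ndim == 0 else r


def qphi_to_pixel(geom: ExperimentGeometry, q, phi):
    """Inverse of :func:`pixel_to_qphi`: fractional (row, col) for (q, phi deg)."""
    r_px = np.asarray(qphi_to_radius(geom, q)) / geom.pixel_pitch
    phi_r = np.radians(np.asarray(phi, dtype=float))
    row = geom.beam_center[0] - r_px * np.sin(phi_r)
    col = geom.beam_center[1] + r_px * np.cos(phi_r)
    return row, col


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def _bin_index(values, edges):
    """Half-open [lo, hi) binning with the last bin closed (histogram rule)."""
    idx = np.searchsorted(edges, values, side="right") - 1
    nb = len(edges) - 1
    idx[values == edges[-1]] = nb - 1
    idx[(values < edges[0]) | (values > edges[-1])] = -1
    return idx


class QPhiBinner:
    """Precomputed pixel -> (q, phi) bin assignment for one geometry.

    Building the assignment is the costly step; once cached, regridding a
    frame is a pair of ``bincount`` calls, which is what makes per-point
    reduction of raster scans and tomographic line scans cheap.
    """

    def __init__(self, geom: ExperimentGeometry, q_edges, phi_edges, mask=None):
        self.geom = geom
        self.q_edges = np.asarray(q_edges, dtype=float)
        self.phi_edges = np.asarray(phi_edges, dtype=float)
        if np.any(np.diff(self.q_edges) <= 0) or np.any(np.diff(self.phi_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        rows, cols = np.indices(geom.det_shape)
        q, phi = pixel_to_qphi(geom, (rows.ravel(), cols.ravel()))
        qi = _bin_index(q, self.q_edges)
        pi = _bin_index(phi, self.phi_edges)
        self.n_q = len(self.q_edges) - 1
        self.n_phi = len(self.phi_edges) - 1
        inside = (qi >= 0) & (pi >= 0)
        if mask is not None:
            inside &= np.asarray(mask, dtype=bool).ravel()
        self._inside = inside
        self._flat = (qi * self.n_phi + pi)[inside]
        self._base_n = np.bincount(self._flat, minlength=self.n_q * self.n_phi)

    def regrid(self, counts, mask=None) -> QPhiMap:
        """Bin one frame's counts into a :class:`QPhiMap`."""
        c = np.asarray(counts, dtype=float).ravel()
        if mask is None:
            sums = np.bincount(self._flat, weights=c[self._inside],
                               minlength=self.n_q * self.n_phi)
            return self._assemble(sums, self._base_n)
        full = np.full(c.shape, -1, dtype=np.int64)
        full[self._inside] = self._flat
        sel = (full >= 0) & np.asarray(mask, dtype=bool).ravel()
        flat = full[sel]
        sums = np.bincount(flat, weights=c[sel], minlength=self.n_q * self.n_phi)
        n = np.bincount(flat, minlength=self.n_q * self.n_phi)
        return self._assemble(sums, n)

    def _assemble(self, sums, n):
        with np.errstate(invalid="ignore", divide="ignore"):
            intensity = np.where(n > 0, sums / np.maximum(n, 1), np.nan)
        return QPhiMap(self.q_edges, self.phi_edges,
                       intensity.reshape(self.n_q, self.n_phi),
                       n.reshape(self.n_q, self.n_phi))


def make_qphi_map(frame: DetectorFrame, geom: ExperimentGeometry,
                  q_edges, phi_edges) -> QPhiMap:
    """Regrid a detector frame onto (q, phi) bins.

    Each unmasked pixel contributes its count to the bin holding its
    (q, phi); bin intensity is the mean over contributing pixels and
    ``counts_per_bin`` records their number.  Pixels outside the edge
    ranges are dropped; an all-masked frame yields an all-NaN map.
    """
    binner = QPhiBinner(geom, q_edges, phi_edges, mask=frame.mask)
    return binner.regrid(frame.counts)


def azimuthal_average(qphi: QPhiMap, phi_range=None) -> Profile1D:
    """Average a (q, phi) map over phi into a 1D profile.

    The mean per q bin is weighted by the pixel count of each phi bin, so
    it equals the plain mean over contributing pixels.  The Poisson error
    is sqrt(total counts)/n_pixels per bin.

    Parameters
    ----------
    phi_range : tuple (lo, hi) in degrees, optional
        Restrict the average to phi-bin centers inside [lo, hi]; if
        lo > hi the interval wraps through 180/-180.  Default: all phi.
    """
    centers = qphi.phi_centers
    if phi_range is None:
        cols = np.ones(len(centers), dtype=bool)
    else:
        lo, hi = float(phi_range[0]), float(phi_range[1])
        if lo <= hi:
            cols = (centers >= lo) & (centers <= hi)
        else:
            cols = (centers >= lo) | (centers <= hi)
    n = qphi.counts_per_bin[:, cols].astype(float)
    inten = np.where(np.isfinite(qphi.intensity[:, cols]),
                     qphi.intensity[:, cols], 0.0)
    totals = (inten * n).sum(axis=1)
    n_tot = n.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n_tot > 0, totals / np.maximum(n_tot, 1), np.nan)
        err = np.where(n_tot > 0, np.sqrt(np.maximum(totals, 0.0)) /
                       np.maximum(n_tot, 1), np.nan)
    return Profile1D(qphi.q_centers, mean, err, n_tot.astype(int))


# ---------------------------------------------------------------------------
# calibration from powder rings
# ---------------------------------------------------------------------------

@dataclass
class CalibrationResult:
    """Refined geometry plus fit quality from a powder-ring calibration."""

    geometry: ExperimentGeometry
    rms_pixels: float
    ring_q: np.ndarray
    n_points: int
    diagnostics: dict = field(default_factory=dict)


def d_spacing_orders(d0: float, n_orders: int) -> list[float]:
    """Effective d-spacings of the first ``n_orders`` rings of a lamellar
    calibrant with fundamental period ``d0`` (q_n = 2*pi*n/d0)."""
    return [d0 / n for n in range(1, n_orders + 1)]


def _radial_profile(counts, mask, center, bin_px=1.0):
    rows, cols = np.indices(counts.shape)
    rho = np.hypot(rows - center[0], cols - center[1]).ravel()
    c = counts.ravel()
    m = mask.ravel()
    idx = (rho[m] / bin_px).astype(int)
    nb = idx.max() + 1 if idx.size else 1
    s = np.bincount(idx, weights=c[m], minlength=nb)
    n = np.bincount(idx, minlength=nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        prof = np.where(n > 0, s / np.maximum(n, 1), 0.0)
    return prof


def _find_radial_peaks(prof, snr=5.0):
    """Local maxima above median + snr*MAD of a lightly smoothed profile."""
    k = np.ones(3) / 3.0
    sm = np.convolve(prof, k, mode="same")
    med = np.median(sm)
    mad = np.median(np.abs(sm - med))
    thr = med + snr * max(mad, 1e-12)
    peaks = []
    for i in range(2, len(sm) - 2):
        if sm[i] > thr and sm[i] >= sm[i - 1] and sm[i] >= sm[i + 1] \
                and sm[i] >= sm[i - 2] and sm[i] >= sm[i + 2]:
            # sub-bin parabolic centroid
            a, b, c = sm[i - 1], sm[i], sm[i + 1]
            denom = a - 2 * b + c
            off = 0.5 * (a - c) / denom if denom != 0 else 0.0
            peaks.append(i + off)
    # merge maxima closer than 3 bins (plateaus)
    merged = []
    for p in peaks:
        if merged and p - merged[-1] < 3:
            merged[-1] = 0.5 * (merged[-1] + p)
        else:
            merged.append(p)
    return merged, {"median": float(med), "mad": float(mad),
                    "max": float(sm.max())}


def calibrate_from_rings(frame: DetectorFrame, ring_d_spacings, wavelength,
                         initial: ExperimentGeometry, *, n_sectors: int = 36,
                         max_iter: int = 6) -> CalibrationResult:
    """Refine detector distance and beam center from powder rings.

    Rings at q = 2*pi/d for each d-spacing are located in the frame; the
    (det_distance, beam_center) pair minimizing the squared radial residual
    of ring-arc centroids against the predicted ring radii is returned.
    The initial guess must be within roughly +-20% in distance and
    +-50 px in center.

    Procedure: radial histogram around the initial center -> peaks above
    5x the median absolute deviation -> match to predicted rings (with a
    one-parameter distance rescale) -> iterate {per-sector intensity
    centroids in a shrinking radial window, linearized least-squares for
    (L, center)}.
    """
    q_rings = np.array(sorted(2.0 * np.pi / np.asarray(ring_d_spacings, float)))
    geom = replace(initial, wavelength=float(wavelength))
    counts = frame.counts
    mask = frame.mask

    prof = _radial_profile(counts, mask, geom.beam_center)
    peaks, diag = _find_radial_peaks(prof)
    if not peaks:
        raise CalibrationError("no powder ring found above noise", diag)

    # --- match detected peak radii to predicted rings via a distance rescale
    r_pred0 = np.array([qphi_to_radius(geom, q) for q in q_rings]) / geom.pixel_pitch
    best = None
    for p in peaks:
        for r0 in r_pred0:
            s = p / r0
            if not 0.6 <= s <= 1.6:
                continue
            matched = sum(1 for pp in peaks
                          if np.min(np.abs(pp - s * r_pred0) / (s * r_pred0)) < 0.05)
            if best is None or matched > best[1]:
                best = (s, matched)
    if best is None:
        raise CalibrationError("detected peaks match no predicted ring", diag)
    L = geom.det_distance * best[0]
    cr, cc = geom.beam_center

    rows, cols = np.indices(counts.shape)
    lam = geom.wavelength
    pitch = geom.pixel_pitch
    half_angle = np.arcsin(q_rings * lam / (4 * np.pi))

    def r_pred_px(L_mm):
        return L_mm * np.tan(2 * half_angle) / pitch

    resid = np.array([np.nan])
    ring_sigma = None          # per-ring radial width estimate, px
    for it in range(max_iter):
        rho = np.hypot(rows - cr, cols - cc)
        psi = np.arctan2(rows - cr, cols - cc)
        sector = np.minimum(((psi + np.pi) / (2 * np.pi) * n_sectors).astype(int),
                            n_sectors - 1)
        meas_rho, meas_psi, meas_ring = [], [], []
        sigma_est = []
        rp = r_pred_px(L)
        bg = float(np.median(counts[mask])) if mask.any() else 0.0
        for k, rk in enumerate(rp):
            if ring_sigma is None:
                window = 50.0 if it == 0 else 30.0
            else:
                # keep the window wide enough to hold the whole ring:
                # a window narrower than the ring anchors the centroid to
                # the current (possibly wrong) predicted radius
                window = float(np.clip(4.0 * ring_sigma[k], 8.0, 60.0))
            sel = mask & (np.abs(rho - rk) < window)
            if not sel.any():
                sigma_est.append(np.nan)
                continue
            w = np.maximum(counts[sel] - bg, 0.0)
            sec = sector[sel]
            rr = rho[sel]
            pp = psi[sel]
            wtot = w.sum()
            if wtot > 0:
                mu = (w * rr).sum() / wtot
                sigma_est.append(np.sqrt((w * (rr - mu) ** 2).sum() / wtot))
            else:
                sigma_est.append(np.nan)
            wsum = np.bincount(sec, weights=w, minlength=n_sectors)
            rsum = np.bincount(sec, weights=w * rr, minlength=n_sectors)
            csum = np.bincount(sec, weights=w * np.cos(pp), minlength=n_sectors)
            ssum = np.bincount(sec, weights=w * np.sin(pp), minlength=n_sectors)
            npix = np.bincount(sec, minlength=n_sectors)
            # sectors clipped by a detector edge or module gap see only
            # part of the ring profile and give centroids biased by
            # several px; keep only (nearly) complete annulus sectors
            expected_px = 2.0 * window * (2.0 * np.pi * rk / n_sectors)
            ok = (wsum > 10.0) & (npix > 0.9 * expected_px)
            if not ok.any():
                continue
            meas_rho.append(rsum[ok] / wsum[ok])
            meas_psi.append(np.arctan2(ssum[ok], csum[ok]))
            meas_ring.append(np.full(ok.sum(), k))
        if not meas_rho:
            raise CalibrationError("rings vanished during refinement", diag)
        if it >= 1:
            sig = np.asarray(sigma_est)
            fallback = np.nanmedian(sig) if np.isfinite(sig).any() else 10.0
            ring_sigma = np.where(np.isfinite(sig), sig, fallback)
        mrho = np.concatenate(meas_rho)
        mpsi = np.concatenate(meas_psi)
        mring = np.concatenate(meas_ring).astype(int)

        def residuals(p):
            L_, dr, dc = p
            return (mrho - r_pred_px(L_)[mring]
                    - dr * np.sin(mpsi) - dc * np.cos(mpsi))

        sol = least_squares(residuals, x0=[L, 0.0, 0.0],
                            loss="soft_l1", f_scale=1.0)
        dL = sol.x[0] - L
        L = sol.x[0]
        cr += sol.x[1]
        cc += sol.x[2]
        resid = sol.fun
        if it >= 2 and abs(dL) / L < 1e-6 and np.hypot(sol.x[1], sol.x[2]) < 5e-3:
            break

    rms = float(np.sqrt(np.mean(resid ** 2)))
    refined = replace(geom, det_distance=float(L), beam_center=(float(cr), float(cc)))
    return CalibrationResult(refined, rms, q_rings, len(resid), diag)
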