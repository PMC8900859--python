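"""Merging, gap filling, background subtraction and scalar features.

The SAXS and WAXS detectors see the same sample through different
geometries and efficiencies; their azimuthally averaged profiles overlap
in q and are stitched into one continuous profile after a robust
inter-detector scale is estimated on the overlap.  Thin-sample background
(entrance window, residual air in the flight path) scales with the
transmitted beam and is removed by monitor-normalized subtraction.
Scalar features — band integrals and diffraction-peak areas — turn
profiles into the per-point attributes from which structural maps and
sinograms are assembled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import MergeError
from .geometry import Profile1D, QPhiMap

__all__ = [
    "TransmissionPair", "MergeResult", "merge_profiles", "auto_overlap_window",
    "fill_gaps", "subtract_background", "smooth_profile",
    "integrate_intensity", "peak_intensity",
]


@dataclass(frozen=True)
class TransmissionPair:
    """Beam-monitor readings upstream (incident) and downstream
    (transmitted) of the sample for one exposure."""

    incident: float
    transmitted: float

    @property
    def transmittance(self) -> float:
        if self.incident <= 0 or self.transmitted <= 0:
            raise ValueError("monitor counts must be positive")
        return self.transmitted / self.incident


@dataclass
class MergeResult:
    """Outcome of stitching a SAXS and a WAXS profile."""

    merged: Profile1D
    scale_factor: float
    overlap_q_window: tuple[float, float]
    n_overlap_bins: int


def _filled(p: Profile1D):
    return np.isfinite(p.intensity) & (np.asarray(p.n_pixels) > 0)


def auto_overlap_window(saxs: Profile1D, waxs: Profile1D) -> tuple[float, float]:
    """Central 80% of the mutual q overlap of two profiles' filled bins."""
    fs, fw = _filled(saxs), _filled(waxs)
    if not fs.any() or not fw.any():
        raise MergeError("a profile has no filled bins")
    lo = max(saxs.q[fs].min(), waxs.q[fw].min())
    hi = min(saxs.q[fs].max(), waxs.q[fw].max())
    if hi <= lo:
        raise MergeError("profiles have disjoint q ranges")
    pad = 0.1 * (hi - lo)
    return (lo + pad, hi - pad)


def merge_profiles(saxs: Profile1D, waxs: Profile1D,
                   overlap_q_window=None) -> MergeResult:
    """Stitch a SAXS and a WAXS azimuthal average into one profile.

    The WAXS profile is interpolated onto the SAXS q grid inside the
    overlap window; the scale factor applied to WAXS is the median of
    I_saxs/I_waxs there (robust against gap artifacts).  The merged grid
    keeps SAXS bins up to the window, the count-weighted average of both
    inside it, and scaled WAXS bins above.

    Raises
    ------
    MergeError
        Fewer than 3 overlap bins, or no positive intensities in overlap.
    """
    if overlap_q_window is None:
        overlap_q_window = auto_overlap_window(saxs, waxs)
    lo, hi = map(float, overlap_q_window)

    fs, fw = _filled(saxs), _filled(waxs)
    in_win = fs & (saxs.q >= lo) & (saxs.q <= hi)
    waxs_cov = in_win & (saxs.q >= waxs.q[fw].min()) & (saxs.q <= waxs.q[fw].max())
    if waxs_cov.sum() < 3 or (fw & (waxs.q >= lo) & (waxs.q <= hi)).sum() < 3:
        raise MergeError(f"fewer than 3 filled overlap bins in [{lo:g}, {hi:g}]")

    qi = saxs.q[waxs_cov]
    wi = np.interp(qi, waxs.q[fw], waxs.intensity[fw])
    we = np.interp(qi, waxs.q[fw], waxs.error[fw])
    wn = np.interp(qi, waxs.q[fw], np.asarray(waxs.n_pixels, float)[fw])
    si = saxs.intensity[waxs_cov]
    pos = (si > 0) & (wi > 0)
    if not pos.any():
        raise MergeError("no positive intensities in the overlap window")
    scale = float(np.median(si[pos] / wi[pos]))
    if scale <= 0:
        raise MergeError("non-positive inter-detector scale")

    # --- assemble merged grid
    below = fs & (saxs.q < lo)
    above = fw & (waxs.q > hi)

    q_mid = qi
    n_s = np.asarray(saxs.n_pixels, float)[waxs_cov]
    n_w = wn
    wsum = n_s + n_w
    i_mid = (n_s * si + n_w * scale * wi) / np.maximum(wsum, 1e-300)
    e_mid = np.sqrt((n_s * saxs.error[waxs_cov]) ** 2
                    + (n_w * scale * we) ** 2) / np.maximum(wsum, 1e-300)

    q = np.concatenate([saxs.q[below], q_mid, waxs.q[above]])
    i = np.concatenate([saxs.intensity[below], i_mid,
                        scale * waxs.intensity[above]])
    e = np.concatenate([saxs.error[below], e_mid, scale * waxs.error[above]])
    n = np.concatenate([np.asarray(saxs.n_pixels, float)[below], wsum,
                        np.asarray(waxs.n_pixels, float)[above]])
    order = np.argsort(q, kind="stable")
    q, i, e, n = q[order], i[order], e[order], n[order]
    keep = np.concatenate([[True], np.diff(q) > 0])
    merged = Profile1D(q[keep], i[keep], e[keep], n[keep])
    return MergeResult(merged, scale, (lo, hi), int(waxs_cov.sum()))


def fill_gaps(qphi: QPhiMap, assume_centrosymmetry: bool = False) -> QPhiMap:
    """Fill empty (q, phi) bins left by detector gaps.

    If ``assume_centrosymmetry``, each empty bin first takes the value of
    its (q, phi +- 180 deg) partner when that bin is filled (Friedel-pair
    copy).  Remaining empty bins are filled by linear interpolation along
    phi at fixed q between the nearest filled neighbors, wrapping around
    the circle.  q rows with no filled bin stay NaN.  Synthetic bins keep
    ``counts_per_bin == 0`` so downstream code can exclude them; already
    filled bins are never modified.  Idempotent.
    """
    inten = qphi.intensity.copy()
    centers = qphi.phi_centers
    nphi = len(centers)

    if assume_centrosymmetry:
        width = np.diff(qphi.phi_edges)
        partner = np.full(nphi, -1, dtype=int)
        for j, c in enumerate(centers):
            target = c - 180.0 if c > 0 else c + 180.0
            d = np.abs((centers - target + 180.0) % 360.0 - 180.0)
            k = int(np.argmin(d))
            if d[k] <= 0.5 * width[k]:
                partner[j] = k
        for j in range(nphi):
            k = partner[j]
            if k < 0:
                continue
            empty = ~np.isfinite(inten[:, j]) & np.isfinite(inten[:, k])
            inten[empty, j] = inten[empty, k]

    for irow in range(inten.shape[0]):
        row = inten[irow]
        good = np.isfinite(row)
        if not good.any() or good.all():
            continue
        row[~good] = np.interp(centers[~good], centers[good], row[good],
                               period=360.0)
    return QPhiMap(qphi.q_edges, qphi.phi_edges, inten,
                   qphi.counts_per_bin.copy())


def subtract_background(sample: Profile1D, blank: Profile1D,
                        sample_T: TransmissionPair, blank_T: TransmissionPair,
                        *, use_incident: bool = False) -> Profile1D:
    """Transmission-normalized background subtraction.

    Each profile is divided by its transmitted-monitor counts (the blank's
    contribution scales with the beam actually reaching the detector), the
    blank is subtracted, and the result is rescaled by the sample's
    monitor so the sample's exposure scale is retained:

        I_corr = (I_s / M_s - I_b / M_b) * M_s

    Errors propagate in quadrature.  Set ``use_incident`` to normalize by
    the upstream monitor instead.
    """
    if len(sample.q) != len(blank.q) or not np.allclose(sample.q, blank.q):
        raise ValueError("sample and blank must share a q grid")
    m_s = sample_T.incident if use_incident else sample_T.transmitted
    m_b = blank_T.incident if use_incident else blank_T.transmitted
    if m_s <= 0 or m_b <= 0:
        raise ValueError("monitor counts must be positive")
    ratio = m_s / m_b
    inten = sample.intensity - ratio * blank.intensity
    err = np.sqrt(sample.error ** 2 + (ratio * blank.error) ** 2)
    return Profile1D(sample.q.copy(), inten, err, sample.n_pixels.copy())


def smooth_profile(profile: Profile1D, window_bins: int = 11) -> Profile1D:
    """Rolling-median smoothing (window shrinks at the edges).

    Removes narrow spikes — e.g. mineral diffraction peaks riding on a
    broad cell-wall signal — while leaving broad features almost
    untouched.  ``window_bins`` must be odd, >= 3 and <= len(q).
    """
    w = int(window_bins)
    n = len(profile.q)
    if w % 2 == 0 or w < 3 or w > n:
        raise ValueError("window_bins must be odd, >= 3 and <= the profile length")
    h = w // 2
    out = np.empty(n)
    inten = profile.intensity
    for i in range(n):
        seg = inten[max(0, i - h):min(n, i + h + 1)]
        seg = seg[np.isfinite(seg)]
        out[i] = np.median(seg) if seg.size else np.nan
    out[~np.isfinite(inten)] = np.nan
    return Profile1D(profile.q.copy(), out, profile.error.copy(),
                     profile.n_pixels.copy())


def _integration_nodes(profile: Profile1D, q_min: float, q_max: float):
    good = _filled(profile) & np.isfinite(profile.intensity)
    qg, ig = profile.q[good], profile.intensity[good]
    inside = (qg >= q_min) & (qg <= q_max)
    if not inside.any():
        return None, None
    q_nodes = qg[inside]
    i_nodes = ig[inside]
    # extend to the exact limits where the filled grid covers them
    if q_nodes[0] > q_min and qg.min() <= q_min:
        q_nodes = np.concatenate([[q_min], q_nodes])
        i_nodes = np.concatenate([[np.interp(q_min, qg, ig)], i_nodes])
    if q_nodes[-1] < q_max and qg.max() >= q_max:
        q_nodes = np.concatenate([q_nodes, [q_max]])
        i_nodes = np.concatenate([i_nodes, [np.interp(q_max, qg, ig)]])
    return q_nodes, i_nodes


def integrate_intensity(profile: Profile1D, q_min: float, q_max: float) -> float:
    """Trapezoidal integral of I(q) over [q_min, q_max], skipping empty bins.

    Returns NaN when no filled bin falls in the range.
    """
    if not q_min < q_max:
        raise ValueError("q_min must be < q_max")
    q_nodes, i_nodes = _integration_nodes(profile, q_min, q_max)
    if q_nodes is None:
        return float("nan")
    return float(np.trapezoid(i_nodes, q_nodes))


def peak_intensity(profile: Profile1D, q_center: float, q_halfwidth: float,
                   baseline_mode: str = "linear") -> float:
    """Integrated intensity in a window around a diffraction peak.

    ``baseline_mode="linear"`` subtracts the trapezoid under the straight
    line joining the window endpoints (background under a sharp peak);
    ``"none"`` returns the plain integral (used for the smooth amorphous
    band where no peak sits on the baseline).  Both are linear functionals
    of the profile and hence sinogram-safe.
    """
    if baseline_mode not in ("linear", "none"):
        raise ValueError(f"unknown baseline_mode {baseline_mode!r}")
    lo, hi = q_center - q_halfwidth, q_center + q_halfwidth
    q_nodes, i_nodes = _integration_nodes(profile, lo, hi)
    if q_nodes is None:
        return float("nan")
    area = float(np.trapezoid(i_nodes, q_nodes))
    if baseline_mode == "none":
        return area
    base = 0.5 * (i_nodes[0] + i_nodes[-1]) * (q_nodes[-1] - q_nodes[0])
    return area - base
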