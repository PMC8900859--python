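"""Raster-scan bundles, structural maps and on-axis camera mosaics.

A scanning measurement yields, per grid point, one frame per detector plus
beam-monitor readings; this module defines the HDF5 bundle holding that
record, turns bundles into 2D structural maps by scoring each point with a
scalar feature, and handles the optical side: calibrating the on-axis
camera's pixel scale from a moved straight edge, tiling camera images into
a full-field mosaic by motor position, and converting mosaic ROIs back to
motor targets.

Scan-file schema (one file per scan)::

    /scan/positions/x, /scan/positions/y          [N]  mm
    /scan/detectors/<name>/data                   [N, H, W]
    /scan/detectors/<name>/mask                   [H, W]
    /scan/detectors/<name>  attrs: geometry (text serialization)
    /scan/monitors/incident, /scan/monitors/transmitted  [N]
    root attrs: scan_shape [2], snake (0/1)
    /truth/<name>                                 optional ground-truth maps

Snake scans traverse alternate rows in reverse; all map assembly
unscrambles point order first, so raster and snake recordings of the same
sample produce identical maps.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import h5py

from .exceptions import CalibrationError, SchemaError
from .geometry import (ExperimentGeometry, QPhiBinner, azimuthal_average)
from .io import geometry_from_text, geometry_to_text
from .reduce import TransmissionPair, smooth_profile

__all__ = [
    "ScanBundle", "FeatureMap", "MosaicCalibration", "Mosaic",
    "ReductionConfig", "read_scan", "write_scan", "build_feature_map",
    "calibrate_mosaic", "tile_mosaic", "mosaic_roi_to_motor",
]


@dataclass
class ScanBundle:
    """In-memory image of one raster scan's HDF5 record."""

    positions: np.ndarray                   # (N, 2) -> (x, y) mm
    frames: dict                            # detector -> (N, H, W)
    masks: dict                             # detector -> (H, W) bool
    geometries: dict                        # detector -> ExperimentGeometry
    incident: np.ndarray                    # (N,)
    transmitted: np.ndarray                 # (N,)
    scan_shape: tuple[int, int]
    snake: bool = False
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.incident = np.asarray(self.incident, dtype=float)
        self.transmitted = np.asarray(self.transmitted, dtype=float)
        n = self.scan_shape[0] * self.scan_shape[1]
        if self.positions.shape != (n, 2):
            raise ValueError("positions must be (n_rows*n_cols, 2)")
        for name, stack in self.frames.items():
            if stack.shape[0] != n:
                raise ValueError(f"detector {name!r} has {stack.shape[0]} frames, "
                                 f"expected {n}")
        if len(self.incident) != n or len(self.transmitted) != n:
            raise ValueError("monitor arrays must have one entry per point")

    @property
    def n_points(self) -> int:
        return len(self.positions)

    def monitors(self, k: int) -> TransmissionPair:
        return TransmissionPair(float(self.incident[k]), float(self.transmitted[k]))

    def grid_index(self, k: int) -> tuple[int, int]:
        """(row, col) of acquisition point k after snake unscrambling."""
        ncols = self.scan_shape[1]
        row, col = divmod(k, ncols)
        if self.snake and row % 2 == 1:
            col = ncols - 1 - col
        return row, col


@dataclass
class FeatureMap:
    """A scalar feature on the scan grid, with physical axes in mm."""

    values: np.ndarray
    x_coords: np.ndarray
    y_coords: np.ndarray
    feature_name: str = "feature"
    units: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.x_coords = np.asarray(self.x_coords, dtype=float)
        self.y_coords = np.asarray(self.y_coords, dtype=float)
        if self.values.shape != (len(self.y_coords), len(self.x_coords)):
            raise ValueError("values shape must be (n_rows, n_cols)")


# ---------------------------------------------------------------------------
# HDF5 round trip
# ---------------------------------------------------------------------------

def _require(fh, path):
    if path not in fh:
        raise SchemaError(f"scan file missing required dataset {path!r}")
    return fh[path]


def write_scan(path, bundle: ScanBundle) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["scan_shape"] = np.asarray(bundle.scan_shape, dtype=np.int64)
        fh.attrs["snake"] = int(bundle.snake)
        g = fh.create_group("scan")
        gp = g.create_group("positions")
        gp.create_dataset("x", data=bundle.positions[:, 0])
        gp.create_dataset("y", data=bundle.positions[:, 1])
        gm = g.create_group("monitors")
        gm.create_dataset("incident", data=bundle.incident)
        gm.create_dataset("transmitted", data=bundle.transmitted)
        gd = g.create_group("detectors")
        for name, stack in bundle.frames.items():
            det = gd.create_group(name)
            det.create_dataset("data", data=np.asarray(stack))
            det.create_dataset("mask", data=np.asarray(bundle.masks[name], dtype=bool))
            det.attrs["geometry"] = geometry_to_text(bundle.geometries[name])
        if bundle.truth:
            gt = fh.create_group("truth")
            for name, arr in bundle.truth.items():
                gt.create_dataset(name, data=np.asarray(arr))


def read_scan(path) -> ScanBundle:
    with h5py.File(path, "r") as fh:
        x = _require(fh, "scan/positions/x")[()]
        y = _require(fh, "scan/positions/y")[()]
        incident = _require(fh, "scan/monitors/incident")[()]
        transmitted = _require(fh, "scan/monitors/transmitted")[()]
        dets = _require(fh, "scan/detectors")
        frames, masks, geoms = {}, {}, {}
        for name in dets:
            frames[name] = _require(fh, f"scan/detectors/{name}/data")[()]
            masks[name] = _require(fh, f"scan/detectors/{name}/mask")[()].astype(bool)
            geoms[name] = geometry_from_text(dets[name].attrs["geometry"])
        if "scan_shape" not in fh.attrs:
            raise SchemaError("scan file missing required attribute 'scan_shape'")
        shape = tuple(int(v) for v in fh.attrs["scan_shape"])
        snake = bool(fh.attrs.get("snake", 0))
        truth = {}
        if "truth" in fh:
            for name in fh["truth"]:
                truth[name] = fh["truth"][name][()]
    return ScanBundle(np.column_stack([x, y]), frames, masks, geoms,
                      incident, transmitted, shape, snake, truth)


# ---------------------------------------------------------------------------
# structural maps
# ---------------------------------------------------------------------------

@dataclass
class ReductionConfig:
    """How each scan point is reduced before feature scoring."""

    q_edges: np.ndarray = None
    phi_edges: np.ndarray = None
    detector: str | None = None       # default: sole/first detector
    phi_range: tuple | None = None
    smooth_window: int | None = None  # odd rolling-median width, None = off

    def resolved_edges(self, geom: ExperimentGeometry, mask):
        if self.q_edges is not None and self.phi_edges is not None:
            return np.asarray(self.q_edges, float), np.asarray(self.phi_edges, float)
        from .geometry import pixel_to_qphi
        rows, cols = np.indices(geom.det_shape)
        q, _ = pixel_to_qphi(geom, (rows.ravel(), cols.ravel()))
        if mask is not None:
            q = q[np.asarray(mask, bool).ravel()]
        q_edges = (np.linspace(0.0, float(q.max()), 201)
                   if self.q_edges is None else np.asarray(self.q_edges, float))
        phi_edges = (np.linspace(-180.0, 180.0, 61)
                     if self.phi_edges is None else np.asarray(self.phi_edges, float))
        return q_edges, phi_edges


def point_profiles(scan: ScanBundle, config: ReductionConfig | None = None):
    """Yield (index, Profile1D) for every scan point, using a cached binner."""
    config = config or ReductionConfig()
    det = config.detector or next(iter(scan.frames))
    geom = scan.geometries[det]
    mask = scan.masks[det]
    q_edges, phi_edges = config.resolved_edges(geom, mask)
    binner = QPhiBinner(geom, q_edges, phi_edges, mask=mask)
    for k in range(scan.n_points):
        prof = azimuthal_average(binner.regrid(scan.frames[det][k]),
                                 phi_range=config.phi_range)
        if config.smooth_window:
            prof = smooth_profile(prof, config.smooth_window)
        yield k, prof


def build_feature_map(scan: ScanBundle, feature_fn,
                      reduction_config: ReductionConfig | None = None,
                      feature_name: str | None = None,
                      units: str = "") -> FeatureMap:
    """Score every scan point with a scalar feature and assemble the map.

    ``feature_fn`` maps a reduced :class:`Profile1D` to a scalar by
    default; set ``feature_fn.input_kind = "frame"`` to receive the raw
    frame, or ``"monitors"`` to receive the point's
    :class:`TransmissionPair`.  Points whose reduction or scoring fails
    become NaN cells (a long scan is never aborted by one bad point).
    """
    kind = getattr(feature_fn, "input_kind", "profile")
    values = np.full(scan.scan_shape, np.nan)

    def score(k, payload):
        try:
            return float(feature_fn(payload))
        except Exception as exc:       # noqa: BLE001 - per-point isolation
            warnings.warn(f"feature failed at point {k}: {exc}")
            return np.nan

    if kind == "profile":
        for k, prof in point_profiles(scan, reduction_config):
            values[scan.grid_index(k)] = score(k, prof)
    elif kind == "frame":
        det = (reduction_config.detector if reduction_config and
               reduction_config.detector else next(iter(scan.frames)))
        for k in range(scan.n_points):
            values[scan.grid_index(k)] = score(k, scan.frames[det][k])
    elif kind == "monitors":
        for k in range(scan.n_points):
            values[scan.grid_index(k)] = score(k, scan.monitors(k))
    else:
        raise ValueError(f"unknown feature input kind {kind!r}")

    # physical axes from unscrambled positions
    nrows, ncols = scan.scan_shape
    xs = np.full(scan.scan_shape, np.nan)
    ys = np.full(scan.scan_shape, np.nan)
    for k in range(scan.n_points):
        r, c = scan.grid_index(k)
        xs[r, c] = scan.positions[k, 0]
        ys[r, c] = scan.positions[k, 1]
    x_coords = np.nanmean(xs, axis=0)
    y_coords = np.nanmean(ys, axis=1)
    name = feature_name or getattr(feature_fn, "__name__", "feature")
    return FeatureMap(values, x_coords, y_coords, name, units)


# ---------------------------------------------------------------------------
# on-axis camera: pixel scale, mosaics, ROI -> motor
# ---------------------------------------------------------------------------

@dataclass
class MosaicCalibration:
    """Pixel <-> motor conversion for the on-axis camera.

    ``mm_per_px`` and ``axis_sign`` are (row, col) pairs; NaN marks an axis
    not yet calibrated.  ``beam_pixel`` is where the X-ray beam appears in
    the camera view (from a scintillator image) and is required to turn
    ROIs into motor targets.
    """

    mm_per_px: tuple = (float("nan"), float("nan"))
    beam_pixel: tuple | None = None
    axis_sign: tuple = (1, 1)


@dataclass
class Mosaic:
    """Tiled full-field view plus the offset making pixel->motor invertible."""

    image: np.ndarray
    canvas_offset: tuple    # (row, col) pixel of motor origin... see tile_mosaic


def _edge_position(image: np.ndarray, axis: int, min_snr: float = 5.0) -> float:
    """Locate a dominant straight edge along ``axis`` (0=row coord, 1=col).

    The gradient magnitude along that axis is projected (summed) over the
    other axis; the peak of the projection is the edge, refined to
    sub-pixel precision by a parabolic fit.
    """
    img = np.asarray(image, dtype=float)
    grad = np.abs(np.gradient(img, axis=axis))
    proj = grad.sum(axis=1 - axis)
    med = np.median(proj)
    mad = np.median(np.abs(proj - med))
    i = int(np.argmax(proj))
    if proj[i] <= med + min_snr * max(mad, 1e-12):
        raise CalibrationError("no edge above contrast threshold",
                               {"peak": float(proj[i]), "median": float(med),
                                "mad": float(mad)})
    if 0 < i < len(proj) - 1:
        a, b, c = proj[i - 1], proj[i], proj[i + 1]
        denom = a - 2 * b + c
        if denom != 0:
            return i + 0.5 * (a - c) / denom
    return float(i)


def calibrate_mosaic(before_img, after_img, motor_displacement,
                     base: MosaicCalibration | None = None) -> MosaicCalibration:
    """Pixel scale and sign of one motor axis from a moved straight edge.

    ``motor_displacement = (dx, dy)`` mm must be along a single motor axis;
    x moves the image along columns, y along rows.  Call once per axis,
    passing the first result as ``base`` the second time.
    """
    dx, dy = float(motor_displacement[0]), float(motor_displacement[1])
    if abs(dx) >= abs(dy):
        axis, d = 1, dx     # column-coordinate edge motion
    else:
        axis, d = 0, dy
    if d == 0:
        raise ValueError("motor displacement must be non-zero on one axis")
    p0 = _edge_position(before_img, axis)
    p1 = _edge_position(after_img, axis)
    dp = p1 - p0
    if abs(dp) < 1e-6:
        raise CalibrationError("edge did not move between images",
                               {"before_px": p0, "after_px": p1})
    scale = abs(d) / abs(dp)
    sign = int(math.copysign(1, dp * d))
    mmpp = list(base.mm_per_px) if base else [float("nan"), float("nan")]
    signs = list(base.axis_sign) if base else [1, 1]
    mmpp[axis] = scale
    signs[axis] = sign
    beam = base.beam_pixel if base else None
    return MosaicCalibration(tuple(mmpp), beam, tuple(signs))


def _motor_to_pixel(x_mm, y_mm, cal: MosaicCalibration):
    """Pixel offset (row, col) at which an image taken at (x, y) is placed."""
    r = cal.axis_sign[0] * y_mm / cal.mm_per_px[0]
    c = cal.axis_sign[1] * x_mm / cal.mm_per_px[1]
    return r, c


def tile_mosaic(images, motor_positions, cal: MosaicCalibration) -> Mosaic:
    """Paste camera images into one canvas by motor position.

    Placement is ``round(position / mm_per_px)`` per axis; later images
    overwrite earlier ones on overlap.  The returned ``canvas_offset`` is
    the (row, col) placement that was subtracted so the canvas starts at
    (0, 0); it makes mosaic pixel -> motor conversion invertible.
    """
    shapes = {np.asarray(im).shape for im in images}
    if len(shapes) != 1:
        raise ValueError(f"all images must share a shape, got {shapes}")
    h, w = shapes.pop()
    offs = []
    for (x, y) in motor_positions:
        r, c = _motor_to_pixel(float(x), float(y), cal)
        offs.append((int(round(r)), int(round(c))))
    offs = np.asarray(offs)
    origin = offs.min(axis=0)
    offs = offs - origin
    extent = offs.max(axis=0) + (h, w)
    canvas = np.zeros(tuple(extent), dtype=np.asarray(images[0]).dtype)
    for im, (r, c) in zip(images, offs):
        canvas[r:r + h, c:c + w] = im
    return Mosaic(canvas, (int(origin[0]), int(origin[1])))


def mosaic_roi_to_motor(roi_pixels, cal: MosaicCalibration, canvas_offset):
    """Motor target (x, y) mm that brings a mosaic ROI onto the beam.

    ``roi_pixels`` is one (row, col) or an (N, 2) array of them; requires
    ``cal.beam_pixel`` (measured with a scintillator image).
    """
    if cal.beam_pixel is None:
        raise ValueError("calibration lacks beam_pixel; "
                         "image the beam on a scintillator first")
    pts = np.atleast_2d(np.asarray(roi_pixels, dtype=float))
    abs_r = pts[:, 0] + canvas_offset[0] - cal.beam_pixel[0]
    abs_c = pts[:, 1] + canvas_offset[1] - cal.beam_pixel[1]
    y = cal.axis_sign[0] * abs_r * cal.mm_per_px[0]
    x = cal.axis_sign[1] * abs_c * cal.mm_per_px[1]
    out = np.column_stack([x, y])
    return out[0] if np.ndim(roi_pixels) == 1 else out
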