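"""Serialization: geometry text files, ASCII profiles, TIFF frames, HDF5.

Formats are deliberately plain so that reduced data stay inspectable with
generic tools: geometries are flat ``key: value`` text, profiles are
4-column ASCII with ``#`` headers, frames are single-image TIFFs or HDF5
stacks, sinograms/tomograms live under ``/tomo`` in HDF5.
"""

from __future__ import annotations

import numpy as np
import h5py
import tifffile

from .geometry import ExperimentGeometry, Profile1D

_GEOM_KEYS = ("wavelength_A", "det_distance_mm", "beam_center_row",
              "beam_center_col", "pixel_pitch_mm", "det_rows", "det_cols",
              "detector_name")


def geometry_to_text(geom: ExperimentGeometry) -> str:
    return "\n".join([
        f"wavelength_A: {geom.wavelength!r}",
        f"det_distance_mm: {geom.det_distance!r}",
        f"beam_center_row: {geom.beam_center[0]!r}",
        f"beam_center_col: {geom.beam_center[1]!r}",
        f"pixel_pitch_mm: {geom.pixel_pitch!r}",
        f"det_rows: {geom.det_shape[0]}",
        f"det_cols: {geom.det_shape[1]}",
        f"detector_name: {geom.detector_name}",
    ]) + "\n"


def geometry_from_text(text: str) -> ExperimentGeometry:
    kv = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition(":")
        kv[key.strip()] = val.strip()
    missing = [k for k in _GEOM_KEYS if k not in kv]
    if missing:
        raise ValueError(f"geometry file missing keys: {missing}")
    return ExperimentGeometry(
        wavelength=float(kv["wavelength_A"]),
        det_distance=float(kv["det_distance_mm"]),
        beam_center=(float(kv["beam_center_row"]), float(kv["beam_center_col"])),
        pixel_pitch=float(kv["pixel_pitch_mm"]),
        det_shape=(int(kv["det_rows"]), int(kv["det_cols"])),
        detector_name=kv["detector_name"],
    )


def write_geometry(path, geom: ExperimentGeometry) -> None:
    with open(path, "w") as fh:
        fh.write(geometry_to_text(geom))


def read_geometry(path) -> ExperimentGeometry:
    with open(path) as fh:
        return geometry_from_text(fh.read())


def write_profile(path, profile: Profile1D, header: str = "") -> None:
    """4-column ASCII: q (1/A), intensity, error, n_pixels."""
    with open(path, "w") as fh:
        for line in header.splitlines():
            fh.write(f"# {line}\n")
        fh.write("# q_A^-1 intensity error n_pixels\n")
        for q, i, e, n in zip(profile.q, profile.intensity,
                              profile.error, profile.n_pixels):
            fh.write(f"{q:.8g} {i:.8g} {e:.8g} {int(n)}\n")


def read_profile(path) -> Profile1D:
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] != 4:
        raise ValueError("profile files carry exactly 4 columns")
    return Profile1D(data[:, 0], data[:, 1], data[:, 2],
                     data[:, 3].astype(int))


def profile_to_hdf5(group: h5py.Group, profile: Profile1D) -> None:
    for name, arr in (("q", profile.q), ("intensity", profile.intensity),
                      ("error", profile.error), ("n_pixels", profile.n_pixels)):
        if name in group:
            del group[name]
        group.create_dataset(name, data=np.asarray(arr))


def profile_from_hdf5(group: h5py.Group) -> Profile1D:
    return Profile1D(group["q"][()], group["intensity"][()],
                     group["error"][()], group["n_pixels"][()])


def write_image_tiff(path, image: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(image))


def read_image_tiff(path) -> np.ndarray:
    return tifffile.imread(path)


def write_frame_stack(path, frames: np.ndarray, dataset: str = "frames") -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset(dataset, data=np.asarray(frames))


def read_frame_stack(path, dataset: str = "frames") -> np.ndarray:
    with h5py.File(path, "r") as fh:
        return fh[dataset][()]


def write_feature_map_ascii(path, fmap) -> None:
    """FeatureMap as a plain-text grid with axis headers."""
    with open(path, "w") as fh:
        fh.write(f"# feature: {fmap.feature_name}"
                 + (f" [{fmap.units}]" if fmap.units else "") + "\n")
        fh.write("# x_mm: " + " ".join(f"{x:.6g}" for x in fmap.x_coords) + "\n")
        fh.write("# y_mm: " + " ".join(f"{y:.6g}" for y in fmap.y_coords) + "\n")
        np.savetxt(fh, fmap.values, fmt="%.8g")


def feature_map_to_hdf5(group: h5py.Group, fmap) -> None:
    group.create_dataset("values", data=fmap.values)
    group.create_dataset("x_mm", data=fmap.x_coords)
    group.create_dataset("y_mm", data=fmap.y_coords)
    group.attrs["feature_name"] = fmap.feature_name
    group.attrs["units"] = fmap.units


def feature_map_from_hdf5(group: h5py.Group):
    from .mapping import FeatureMap
    return FeatureMap(group["values"][()], group["x_mm"][()],
                      group["y_mm"][()], str(group.attrs["feature_name"]),
                      str(group.attrs["units"]))
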