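"""Reading and writing of serial-section MSI data.

Serial sections arrive as one centroid imzML file each (the "processed"
flavour of the format: a peak list per pixel).  On read, every centroid
peak is snapped onto a shared :class:`FeatureAxis` so that all sections of
a sample live on one common feature grid; downstream modules then treat a
section as a dense ``(n_pixels, n_features)`` intensity matrix plus a
foreground mask.

Volumes are exchanged as NRRD (raw little-endian encoding) so that label
maps and feature stacks can be handed to external 3D renderers.  Sample
sheets (manifests) and result tables are plain delimited text.

Conventions
-----------
* In-plane pixel coordinates are 0-based row-major ``(y, x)``; imzML's
  1-based coordinates are shifted on read.
* ``z_index`` increases with cutting order and comes from an explicit
  manifest, never from filename order.
* Two centroid peaks that snap to the same axis entry have their
  intensities summed (ion counts are conserved).
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyimzml.ImzMLParser import ImzMLParser
from pyimzml.ImzMLWriter import ImzMLWriter

__all__ = [
    "FeatureAxis",
    "SectionImage",
    "SerialSectionDataset",
    "read_section_imzml",
    "write_section_imzml",
    "read_manifest",
    "write_manifest",
    "read_dataset",
    "write_volume_nrrd",
    "read_volume_nrrd",
]


class EmptySectionError(ValueError):
    """No peak in the file matched any feature-axis entry."""


class ImzMLFormatError(ValueError):
    """The imzML file violates the expected centroid-grid structure."""


# --------------------------------------------------------------------------
# feature axis
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureAxis:
    """Shared m/z grid onto which centroid peaks are binned.

    Parameters
    ----------
    mz_values
        Strictly ascending m/z values in Da, all positive.
    tolerance_ppm
        Half-width of the match window in parts per million.  Entries must
        be farther apart than the mutual tolerance so a peak can match at
        most one entry.
    """

    mz_values: tuple[float, ...]
    tolerance_ppm: float = 10.0

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz_values, dtype=float)
        if mz.size == 0:
            raise ValueError("feature axis is empty")
        if np.any(mz <= 0):
            raise ValueError("m/z values must be positive")
        if np.any(np.diff(mz) <= 0):
            raise ValueError("m/z values must be strictly ascending")
        # adjacent entries must not fall inside each other's ppm window
        tol = mz * self.tolerance_ppm * 1e-6
        if np.any(np.diff(mz) <= tol[:-1] + tol[1:]):
            raise ValueError(
                "adjacent m/z entries are within mutual ppm tolerance; "
                "increase spacing or reduce tolerance_ppm"
            )
        object.__setattr__(self, "mz_values", tuple(float(v) for v in mz))

    def __len__(self) -> int:
        return len(self.mz_values)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.mz_values, dtype=float)

    def index_of(self, mz: float, tol_ppm: float | None = None) -> int:
        """Index of the axis entry matching *mz* within tolerance.

        Raises ``KeyError`` (listing the nearest entries) if no entry
        matches.
        """
        tol = self.tolerance_ppm if tol_ppm is None else tol_ppm
        arr = self.array
        i = int(np.argmin(np.abs(arr - mz)))
        if abs(arr[i] - mz) <= arr[i] * tol * 1e-6:
            return i
        near = arr[max(0, i - 1): i + 2]
        raise KeyError(
            f"m/z {mz} matches no axis entry within {tol} ppm; "
            f"nearest entries: {list(near)}"
        )

    def bin_peaks(self, mzs: np.ndarray, intensities: np.ndarray) -> np.ndarray:
        """Bin centroid peaks onto the axis; colliding peaks are summed.

        Peaks outside every entry's ppm window are dropped.  Returns a
        dense vector of length ``len(self)``.
        """
        out = np.zeros(len(self), dtype=np.float64)
        if len(mzs) == 0:
            return out
        mzs = np.asarray(mzs, dtype=float)
        arr = self.array
        idx = np.clip(np.searchsorted(arr, mzs), 0, len(arr) - 1)
        left = np.clip(idx - 1, 0, len(arr) - 1)
        pick_left = np.abs(arr[left] - mzs) < np.abs(arr[idx] - mzs)
        idx = np.where(pick_left, left, idx)
        ok = np.abs(arr[idx] - mzs) <= arr[idx] * self.tolerance_ppm * 1e-6
        np.add.at(out, idx[ok], np.asarray(intensities, dtype=float)[ok])
        return out


# --------------------------------------------------------------------------
# section / dataset containers
# --------------------------------------------------------------------------

@dataclass
class SectionImage:
    """One tissue section on the common feature axis.

    ``intensities`` has shape ``(height, width, n_features)`` and is
    non-negative; ``foreground_mask`` is boolean ``(height, width)``.
    Background pixels carry zero intensity.
    """

    intensities: np.ndarray
    foreground_mask: np.ndarray
    pixel_size_um: float
    thickness_um: float
    z_index: int

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        self.foreground_mask = np.asarray(self.foreground_mask, dtype=bool)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be (height, width, n_features)")
        if self.foreground_mask.shape != self.intensities.shape[:2]:
            raise ValueError("mask shape does not match intensity grid")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def height(self) -> int:
        return self.intensities.shape[0]

    @property
    def width(self) -> int:
        return self.intensities.shape[1]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[2]

    def copy(self) -> "SectionImage":
        return SectionImage(
            self.intensities.copy(), self.foreground_mask.copy(),
            self.pixel_size_um, self.thickness_um, self.z_index,
        )


@dataclass
class SerialSectionDataset:
    """z-ordered serial sections of one sample on one feature axis."""

    sections: list[SectionImage]
    feature_axis: FeatureAxis
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        if not self.sections:
            raise ValueError("dataset has no sections")
        z = [s.z_index for s in self.sections]
        if sorted(z) != list(range(len(z))):
            raise ValueError("z_index values must be consecutive from 0")
        self.sections = sorted(self.sections, key=lambda s: s.z_index)
        first = self.sections[0]
        for s in self.sections:
            if (s.pixel_size_um, s.thickness_um) != (first.pixel_size_um,
                                                     first.thickness_um):
                raise ValueError("sections disagree on voxel geometry")
            if s.n_features != len(self.feature_axis):
                raise ValueError("section feature count does not match axis")

    @property
    def n_sections(self) -> int:
        return len(self.sections)

    @property
    def pixel_size_um(self) -> float:
        return self.sections[0].pixel_size_um

    @property
    def thickness_um(self) -> float:
        return self.sections[0].thickness_um

    @property
    def voxel_um(self) -> tuple[float, float, float]:
        """(thickness, pixel, pixel) in µm, i.e. (z, y, x) spacing."""
        return (self.thickness_um, self.pixel_size_um, self.pixel_size_um)


# --------------------------------------------------------------------------
# imzML
# --------------------------------------------------------------------------

def read_section_imzml(
    path: str | os.PathLike,
    axis: FeatureAxis,
    z_index: int = 0,
    pixel_size_um: float = 20.0,
    thickness_um: float = 20.0,
) -> SectionImage:
    """Read one centroid imzML file into a :class:`SectionImage`.

    Every pixel's peaks are snapped to the nearest axis entry within the
    axis ppm tolerance (colliding peaks summed).  Pixels absent from the
    file are background.  Coordinates are shifted so the minimum imzML
    coordinate maps to row/column 0.
    """
    try:
        parser = ImzMLParser(str(path))
    except Exception as exc:  # pragma: no cover - error text from lxml varies
        raise ImzMLFormatError(f"cannot parse imzML file {path}: {exc}") from exc
    coords = np.asarray([(c[0], c[1]) for c in parser.coordinates], dtype=int)
    if coords.size == 0:
        raise ImzMLFormatError(f"{path}: file contains no spectra")
    xmin, ymin = coords.min(axis=0)
    xs = coords[:, 0] - xmin
    ys = coords[:, 1] - ymin
    width = int(xs.max()) + 1
    height = int(ys.max()) + 1
    inten = np.zeros((height, width, len(axis)), dtype=np.float64)
    mask = np.zeros((height, width), dtype=bool)
    any_match = False
    for i in range(len(coords)):
        mzs, ints = parser.getspectrum(i)
        vec = axis.bin_peaks(np.asarray(mzs), np.asarray(ints))
        if vec.any():
            any_match = True
        inten[ys[i], xs[i]] += vec
        mask[ys[i], xs[i]] = True
    if not any_match:
        raise EmptySectionError(
            f"{path}: no peak matched any of the {len(axis)} axis entries "
            f"at {axis.tolerance_ppm} ppm"
        )
    return SectionImage(inten, mask, pixel_size_um, thickness_um, z_index)


def write_section_imzml(
    section: SectionImage, axis: FeatureAxis, path: str | os.PathLike
) -> None:
    """Write a section as centroid imzML: one spectrum per foreground pixel.

    Zero-intensity features are omitted from each peak list, so the file
    round-trips through :func:`read_section_imzml` bit-exactly.
    """
    ys, xs = np.nonzero(section.foreground_mask)
    if len(ys) == 0:
        raise ValueError("section has no foreground pixels; nothing to write")
    mz = axis.array
    with ImzMLWriter(str(path), intensity_dtype=np.float64,
                     mode="processed") as writer:
        for y, x in zip(ys, xs):
            vec = section.intensities[y, x]
            keep = vec > 0
            if not keep.any():
                # keep the pixel in the file so the mask round-trips; a
                # single zero peak at the first axis entry marks presence
                writer.addSpectrum(mz[:1], np.zeros(1), (int(x) + 1, int(y) + 1))
                continue
            writer.addSpectrum(mz[keep], vec[keep], (int(x) + 1, int(y) + 1))


# --------------------------------------------------------------------------
# manifest (sample sheet)
# --------------------------------------------------------------------------

def write_manifest(path: str | os.PathLike, rows: list[dict]) -> None:
    """Write a sample sheet (columns sample_id, z_index, path) as TSV."""
    pd.DataFrame(rows, columns=["sample_id", "z_index", "path"]).to_csv(
        path, sep="\t", index=False
    )


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"sample_id", "z_index", "path"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    return df


def read_dataset(
    manifest_path: str | os.PathLike,
    axis: FeatureAxis,
    sample_id: str | None = None,
    pixel_size_um: float = 20.0,
    thickness_um: float = 20.0,
) -> SerialSectionDataset:
    """Read all sections of one sample listed in a manifest.

    Sections may have different grid extents in their files; they are
    padded (top-left anchored) onto the common maximal grid.
    """
    df = read_manifest(manifest_path)
    if sample_id is not None:
        df = df[df["sample_id"] == sample_id]
    if df.empty:
        raise ValueError("manifest selects no sections")
    base = os.path.dirname(os.fspath(manifest_path))
    sections = []
    for _, row in df.sort_values("z_index").iterrows():
        p = row["path"]
        if not os.path.isabs(p):
            p = os.path.join(base, p)
        sections.append(
            read_section_imzml(p, axis, int(row["z_index"]),
                               pixel_size_um, thickness_um)
        )
    h = max(s.height for s in sections)
    w = max(s.width for s in sections)
    for i, s in enumerate(sections):
        if (s.height, s.width) != (h, w):
            inten = np.zeros((h, w, s.n_features))
            mask = np.zeros((h, w), dtype=bool)
            inten[: s.height, : s.width] = s.intensities
            mask[: s.height, : s.width] = s.foreground_mask
            sections[i] = SectionImage(inten, mask, s.pixel_size_um,
                                       s.thickness_um, s.z_index)
    sid = sample_id if sample_id is not None else str(df["sample_id"].iloc[0])
    return SerialSectionDataset(sections, axis, sid)


# --------------------------------------------------------------------------
# NRRD (raw little-endian encoding)
# --------------------------------------------------------------------------

_NRRD_TYPES = {
    "uint8": np.uint8, "int16": np.int16, "uint16": np.uint16,
    "int32": np.int32, "uint32": np.uint32, "int64": np.int64,
    "float": np.float32, "double": np.float64,
}
_NP_TO_NRRD = {np.dtype(v): k for k, v in _NRRD_TYPES.items()}


def write_volume_nrrd(
    volume: np.ndarray,
    path: str | os.PathLike,
    voxel_um: tuple[float, float, float] = (20.0, 20.0, 20.0),
) -> None:
    """Write a (z, y, x) volume as single-file NRRD, raw little-endian.

    ``voxel_um`` is (thickness, pixel, pixel).  The sizes field lists the
    fastest-varying axis first (x y z), matching the C-ordered buffer.
    Integer volumes (label maps) round-trip losslessly.
    """
    vol = np.ascontiguousarray(volume)
    if vol.ndim != 3 or vol.size == 0:
        raise ValueError("volume must be a non-empty 3D (z, y, x) array")
    dt = vol.dtype
    if dt not in _NP_TO_NRRD:
        vol = vol.astype(np.float64)
        dt = vol.dtype
    nz, ny, nx = vol.shape
    tz, ty, tx = voxel_um
    header = (
        "NRRD0004\n"
        f"type: {_NP_TO_NRRD[dt]}\n"
        "dimension: 3\n"
        f"sizes: {nx} {ny} {nz}\n"
        f"spacings: {tx} {ty} {tz}\n"
        "encoding: raw\n"
        "endian: little\n"
        "\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(vol.astype(dt.newbyteorder("<"), copy=False).tobytes())


def read_volume_nrrd(path: str | os.PathLike) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a single-file raw NRRD written by :func:`write_volume_nrrd`.

    Returns ``(volume (z, y, x), voxel_um (z, y, x))``.
    """
    with open(path, "rb") as fh:
        magic = fh.readline().decode("ascii").strip()
        if not magic.startswith("NRRD"):
            raise ValueError(f"{path}: not an NRRD file")
        fields: dict[str, str] = {}
        while True:
            line = fh.readline().decode("ascii")
            if line in ("\n", "\r\n", ""):
                break
            if line.startswith("#") or ":" not in line:
                continue
            key, val = line.split(":", 1)
            fields[key.strip()] = val.strip()
        if fields.get("encoding") != "raw":
            raise ValueError("only raw encoding is supported")
        dtype = np.dtype(_NRRD_TYPES[fields["type"]]).newbyteorder(
            "<" if fields.get("endian", "little") == "little" else ">"
        )
        nx, ny, nz = (int(v) for v in fields["sizes"].split())
        spac = fields.get("spacings", "1 1 1").split()
        tx, ty, tz = (float(v) for v in spac)
        buf = fh.read(nx * ny * nz * dtype.itemsize)
    vol = np.frombuffer(buf, dtype=dtype).reshape(nz, ny, nx)
    return vol.astype(dtype.newbyteorder("=")), (tz, ty, tx)
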