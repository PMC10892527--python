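"""Hyperspectral cubes, label rasters and the ENVI on-disk format.

A scene is a reflectance cube of shape ``(lines, samples, bands)`` — the ENVI
``lines``/``samples`` convention, 0-based and line-major throughout — paired
with an integer label raster of the same spatial shape in which 0 marks
unlabeled background and 1..K the land-cover classes.

ENVI storage is a plain-text ``.hdr`` file next to a flat binary block in
band-sequential (BSQ), band-interleaved-by-line (BIL) or
band-interleaved-by-pixel (BIP) order; all three interleaves are read, BSQ is
written.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import yaml
from PIL import Image

from .exceptions import EnviFormatError, SizeError

__all__ = [
    "HyperspectralCube",
    "LabelMap",
    "Spectrum",
    "read_envi_cube",
    "write_envi_cube",
    "read_label_raster",
    "write_label_raster",
    "read_class_table",
    "write_class_table",
    "center_crop",
    "stitch_quadrats",
    "roi_mean_spectrum",
]

# ENVI numeric data-type codes -> numpy dtypes
_ENVI_DTYPES = {
    1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32, 5: np.float64,
    12: np.uint16, 13: np.uint32, 14: np.int64, 15: np.uint64,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


@dataclass
class HyperspectralCube:
    """Reflectance cube ``values[line, sample, band]`` with band wavelengths in nm."""

    values: np.ndarray
    wavelengths: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.ndim != 3:
            raise SizeError(f"cube must be 3-D (lines, samples, bands), got {self.values.shape}")
        h, w, c = self.values.shape
        if min(h, w, c) < 1:
            raise SizeError("all cube dimensions must be >= 1")
        if self.wavelengths.shape != (c,):
            raise EnviFormatError(
                f"wavelength count {self.wavelengths.size} != band count {c}")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise EnviFormatError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise EnviFormatError("cube contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]


@dataclass
class LabelMap:
    """Integer class raster aligned to a cube; 0 = unlabeled background."""

    codes: np.ndarray
    class_table: dict = field(default_factory=dict)  # id -> {"name", "color"}

    def __post_init__(self):
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2:
            raise SizeError(f"label raster must be 2-D, got {self.codes.shape}")
        if not np.issubdtype(self.codes.dtype, np.integer):
            raise EnviFormatError("label codes must be integers")
        if self.codes.min(initial=0) < 0:
            raise EnviFormatError("label codes must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    @property
    def n_labeled(self) -> int:
        return int(np.count_nonzero(self.codes))

    def class_ids(self) -> np.ndarray:
        ids = np.unique(self.codes)
        return ids[ids > 0]


@dataclass
class Spectrum:
    """A single reflectance spectrum with its wavelength axis."""

    reflectance: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self):
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.reflectance.shape != self.wavelengths.shape:
            raise SizeError("reflectance and wavelength lengths differ")
        if not np.all(np.isfinite(self.reflectance)):
            raise EnviFormatError("spectrum contains non-finite values")


# ---------------------------------------------------------------------------
# ENVI I/O
# ---------------------------------------------------------------------------

def _header_path(path: str) -> tuple[str, str]:
    """Resolve (header, data) paths from any of base / .hdr / .img."""
    if path.endswith(".hdr"):
        base = path[:-4]
        hdr = path
    elif path.endswith(".img"):
        base = path[:-4]
        hdr = base + ".hdr"
    else:
        base = path
        hdr = path + ".hdr"
    for cand in (base + ".img", base):
        if os.path.exists(cand):
            return hdr, cand
    return hdr, base + ".img"


def _parse_envi_header(text: str) -> dict:
    if not text.lstrip().lower().startswith("envi"):
        raise EnviFormatError("not an ENVI header (missing ENVI magic)")
    fields: dict = {}
    lines = text.splitlines()[1:]
    i = 0
    while i < len(lines):
        line = lines[i]
        i += 1
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        key = key.strip().lower()
        val = val.strip()
        if val.startswith("{"):
            while "}" not in val and i < len(lines):
                val += " " + lines[i].strip()
                i += 1
            val = val.strip("{} ").strip()
            fields[key] = [v.strip() for v in val.split(",") if v.strip()]
        else:
            fields[key] = val
    return fields


def read_envi_cube(path: str) -> HyperspectralCube:
    """Read an ENVI header/data pair into a :class:`HyperspectralCube`.

    Accepts the base path, the ``.hdr`` path or the data-file path; BSQ, BIL
    and BIP interleaves and both byte orders are supported.
    """
    hdr_path, data_path = _header_path(path)
    with open(hdr_path) as fh:
        hdr = _parse_envi_header(fh.read())

    try:
        lines = int(hdr["lines"])
        samples = int(hdr["samples"])
        bands = int(hdr["bands"])
    except KeyError as exc:
        raise EnviFormatError(f"header missing required field: {exc}") from exc
    code = int(hdr.get("data type", 4))
    if code not in _ENVI_DTYPES:
        raise EnviFormatError(f"unsupported ENVI data type code {code}")
    dtype = np.dtype(_ENVI_DTYPES[code])
    if int(hdr.get("byte order", 0)) == 1:
        dtype = dtype.newbyteorder(">")
    interleave = str(hdr.get("interleave", "bsq")).lower()
    offset = int(hdr.get("header offset", 0))

    n = lines * samples * bands
    raw = np.fromfile(data_path, dtype=dtype, count=n, offset=offset)
    if raw.size != n:
        raise EnviFormatError(
            f"data file holds {raw.size} values, header declares {n}")
    if interleave == "bsq":
        values = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        values = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        values = raw.reshape(lines, samples, bands)
    else:
        raise EnviFormatError(f"unknown interleave {interleave!r}")

    if "wavelength" in hdr:
        wl = np.array([float(v) for v in hdr["wavelength"]])
        if wl.size != bands:
            raise EnviFormatError(
                f"header lists {wl.size} wavelengths for {bands} bands")
    else:
        wl = np.arange(bands, dtype=float)
    meta = {k: v for k, v in hdr.items()
            if k not in {"lines", "samples", "bands", "data type", "interleave",
                         "byte order", "header offset", "wavelength"}}
    return HyperspectralCube(values.astype(np.float64, copy=False), wl, meta)


def write_envi_cube(cube: HyperspectralCube, path: str,
                    interleave: str = "bsq") -> str:
    """Write ``cube`` as an ENVI header + binary pair; returns the data path."""
    interleave = interleave.lower()
    if interleave not in {"bsq", "bil", "bip"}:
        raise EnviFormatError(f"unknown interleave {interleave!r}")
    hdr_path, data_path = _header_path(path)
    h, w, c = cube.shape
    values = np.ascontiguousarray(cube.values, dtype=np.float64)
    if interleave == "bsq":
        out = values.transpose(2, 0, 1)
    elif interleave == "bil":
        out = values.transpose(0, 2, 1)
    else:
        out = values
    np.ascontiguousarray(out).tofile(data_path)
    wl = ", ".join(f"{v:.17g}" for v in cube.wavelengths)
    header = (
        "ENVI\n"
        "description = {hsiclass reflectance cube}\n"
        f"samples = {w}\n"
        f"lines = {h}\n"
        f"bands = {c}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[np.dtype(np.float64)]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    with open(hdr_path, "w") as fh:
        fh.write(header)
    return data_path


def write_label_raster(labels: LabelMap, path: str) -> str:
    """Write a label raster: paletted PNG if ``path`` ends in .png, else ENVI int32."""
    if path.endswith(".png"):
        codes = labels.codes
        if codes.max(initial=0) > 255:
            raise EnviFormatError("PNG palette rasters support at most 255 classes")
        img = Image.fromarray(codes.astype(np.uint8), mode="P")
        palette = [0] * 768
        for cid, entry in labels.class_table.items():
            color = entry.get("color", "#000000").lstrip("#")
            r, g, b = (int(color[i:i + 2], 16) for i in (0, 2, 4))
            palette[3 * cid: 3 * cid + 3] = [r, g, b]
        img.putpalette(palette)
        img.save(path)
        return path
    hdr_path, data_path = _header_path(path)
    h, w = labels.shape
    labels.codes.astype(np.int32).tofile(data_path)
    with open(hdr_path, "w") as fh:
        fh.write(
            "ENVI\ndescription = {hsiclass label raster}\n"
            f"samples = {w}\nlines = {h}\nbands = 1\n"
            "header offset = 0\nfile type = ENVI Classification\n"
            "data type = 3\ninterleave = bsq\nbyte order = 0\n")
    return data_path


def read_label_raster(path: str, class_table: dict | None = None) -> LabelMap:
    if path.endswith(".png"):
        codes = np.asarray(Image.open(path), dtype=np.int32)
        return LabelMap(codes, class_table or {})
    hdr_path, data_path = _header_path(path)
    with open(hdr_path) as fh:
        hdr = _parse_envi_header(fh.read())
    h, w = int(hdr["lines"]), int(hdr["samples"])
    code = int(hdr.get("data type", 3))
    codes = np.fromfile(data_path, dtype=_ENVI_DTYPES[code], count=h * w)
    if codes.size != h * w:
        raise EnviFormatError("label data file truncated")
    return LabelMap(codes.reshape(h, w).astype(np.int32), class_table or {})


def write_class_table(class_table: dict, path: str) -> str:
    with open(path, "w") as fh:
        yaml.safe_dump({int(k): dict(v) for k, v in class_table.items()}, fh)
    return path


def read_class_table(path: str) -> dict:
    with open(path) as fh:
        return {int(k): v for k, v in yaml.safe_load(fh).items()}


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

def center_crop(cube: HyperspectralCube, labels: LabelMap | None,
                h: int, w: int) -> tuple[HyperspectralCube, LabelMap | None]:
    """Crop the centered ``h x w`` window; ties break toward the top-left."""
    H, W, _ = cube.shape
    if h > H or w > W:
        raise SizeError(f"crop {h}x{w} exceeds cube {H}x{W}")
    if h < 1 or w < 1:
        raise SizeError("crop dimensions must be >= 1")
    r0 = (H - h) // 2
    c0 = (W - w) // 2
    out = HyperspectralCube(cube.values[r0:r0 + h, c0:c0 + w].copy(),
                            cube.wavelengths.copy(), dict(cube.meta))
    if labels is None:
        return out, None
    if labels.shape != (H, W):
        raise SizeError("label raster shape differs from cube")
    lab = LabelMap(labels.codes[r0:r0 + h, c0:c0 + w].copy(), dict(labels.class_table))
    return out, lab


def stitch_quadrats(cubes: list[HyperspectralCube], labels: list[LabelMap],
                    rows: int, cols: int) -> tuple[HyperspectralCube, LabelMap]:
    """Mosaic equally sized quadrat tiles row-major into one scene.

    Tile ``k`` in the input list occupies block row ``k // cols`` and block
    column ``k % cols``; values are copied unchanged.
    """
    if rows * cols != len(cubes):
        raise SizeError(f"{len(cubes)} tiles cannot fill a {rows}x{cols} grid")
    if len(labels) != len(cubes):
        raise SizeError("need one label raster per tile")
    ref = cubes[0]
    for c in cubes[1:]:
        if c.shape != ref.shape:
            raise SizeError(f"tile shape mismatch: {c.shape} vs {ref.shape}")
        if not np.array_equal(c.wavelengths, ref.wavelengths):
            raise EnviFormatError("tile wavelength axes differ")
    for lab, c in zip(labels, cubes):
        if lab.shape != c.shape[:2]:
            raise SizeError("label raster shape differs from its tile")
    h, w, _ = ref.shape
    values = np.concatenate(
        [np.concatenate([cubes[i * cols + j].values for j in range(cols)], axis=1)
         for i in range(rows)], axis=0)
    codes = np.concatenate(
        [np.concatenate([labels[i * cols + j].codes for j in range(cols)], axis=1)
         for i in range(rows)], axis=0)
    table: dict = {}
    for lab in labels:
        table.update(lab.class_table)
    return (HyperspectralCube(values, ref.wavelengths.copy(), dict(ref.meta)),
            LabelMap(codes, table))


def roi_mean_spectrum(cube: HyperspectralCube, mask: np.ndarray) -> Spectrum:
    """Per-band arithmetic mean over the pixels selected by a boolean mask.

    This is the region-of-interest averaging used to derive reference
    endmember spectra from pure pixels of one land-cover class.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.shape[:2]:
        raise SizeError("mask shape differs from cube spatial shape")
    if not mask.any():
        raise EmptyMaskError("mask selects no pixels")
    mean = cube.values[mask].mean(axis=0)
    return Spectrum(mean, cube.wavelengths.copy())


class EmptyMaskError(SizeError):
    """ROI mask selects zero pixels."""
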