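"""Hypercube container, cube I/O, transmittance calibration, tiling and display RGB.

A microscopic hyperspectral frame is an ``H x W x B`` array of per-pixel
spectra sampled at ``B`` narrow wavelength bands (nanometres).  Raw sensor
counts are converted to transmittance with a white-reference frame (blank
slide area) and a dark-current frame (shutter closed):

    T(lambda) = (I_raw - I_dark) / (I_white - I_dark)

Whole frames are tiled into non-overlapping square patches for
classification, and patches are resized with anti-aliased interpolation to
the network input size.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field

import h5py
import numpy as np
from skimage.transform import resize as _sk_resize

logger = logging.getLogger(__name__)

RAW_COUNTS = "raw_counts"
TRANSMITTANCE = "transmittance"


@dataclass
class Hypercube:
    """An ``H x W x B`` hyperspectral image with its wavelength axis.

    Parameters
    ----------
    data : ndarray, shape (H, W, B)
        Nonnegative intensities; after calibration on a normalized 0-1
        transmittance scale (values slightly above 1 can occur where the
        tissue is brighter than the blank-slide reference).
    wavelengths : ndarray, shape (B,)
        Band-centre wavelengths in nm, strictly increasing.
    kind : {"raw_counts", "transmittance"}
    """

    data: np.ndarray
    wavelengths: np.ndarray
    kind: str = RAW_COUNTS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be H x W x B, got shape {self.data.shape}")
        if self.wavelengths.ndim != 1 or self.wavelengths.size != self.data.shape[2]:
            raise ValueError(
                f"wavelength vector length {self.wavelengths.size} does not match "
                f"band count {self.data.shape[2]}"
            )
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.kind not in (RAW_COUNTS, TRANSMITTANCE):
            raise ValueError(f"unknown cube kind {self.kind!r}")
        if self.kind == TRANSMITTANCE and np.any(self.data < 0):
            raise ValueError("transmittance cubes must be nonnegative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def copy(self) -> "Hypercube":
        return Hypercube(self.data.copy(), self.wavelengths.copy(), self.kind)

    def with_data(self, data: np.ndarray, kind: str | None = None) -> "Hypercube":
        """New cube sharing this cube's wavelength axis."""
        return Hypercube(data, self.wavelengths, self.kind if kind is None else kind)


@dataclass
class CalibrationFrames:
    """Raw / white-reference / dark-current triplet for one slide."""

    raw: Hypercube
    white: Hypercube
    dark: Hypercube

    def __post_init__(self) -> None:
        shapes = {self.raw.shape, self.white.shape, self.dark.shape}
        if len(shapes) != 1:
            raise ValueError(f"calibration frames disagree in shape: {shapes}")
        if not (
            np.array_equal(self.raw.wavelengths, self.white.wavelengths)
            and np.array_equal(self.raw.wavelengths, self.dark.wavelengths)
        ):
            raise ValueError("calibration frames disagree in wavelengths")


@dataclass
class PatchRecord:
    """One tile cut from a whole frame, with its grid position and label."""

    cube: Hypercube
    grid_row: int
    grid_col: int
    slide_id: str = ""
    patient_id: str = ""
    label: str = "unknown"

    def __post_init__(self) -> None:
        if self.grid_row < 0 or self.grid_col < 0:
            raise ValueError("grid indices must be nonnegative")


# ---------------------------------------------------------------------------
# I/O: HDF5 (native) and ENVI (interoperability)
# ---------------------------------------------------------------------------

def write_cube(path: str | os.PathLike, cube: Hypercube, format: str = "hdf5") -> None:
    """Write a cube to ``path`` as HDF5 (datasets ``data``/``wavelengths``) or ENVI."""
    if format == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=cube.data)
            f.create_dataset("wavelengths", data=cube.wavelengths)
            f.attrs["kind"] = cube.kind
    elif format == "envi":
        _write_envi(str(path), cube)
    else:
        raise ValueError(f"unknown cube format {format!r}")


def read_cube(path: str | os.PathLike, format: str = "hdf5") -> Hypercube:
    """Read a cube written by :func:`write_cube` (or third-party ENVI files).

    Raises
    ------
    ValueError
        If wavelength metadata is missing or inconsistent with the array.
    """
    if format == "hdf5":
        with h5py.File(path, "r") as f:
            if "data" not in f:
                raise ValueError(f"{path}: missing dataset 'data'")
            if "wavelengths" not in f:
                raise ValueError(f"{path}: missing dataset 'wavelengths'")
            data = f["data"][...]
            wl = f["wavelengths"][...]
            kind = f.attrs.get("kind", RAW_COUNTS)
        return Hypercube(data, wl, str(kind))
    if format == "envi":
        return _read_envi(str(path))
    raise ValueError(f"unknown cube format {format!r}")


_ENVI_DTYPES = {4: np.float32, 5: np.float64, 12: np.uint16, 2: np.int16}
_ENVI_CODES = {np.dtype(v).name: k for k, v in _ENVI_DTYPES.items()}


def _write_envi(path: str, cube: Hypercube) -> None:
    """Minimal ENVI writer: ASCII ``.hdr`` next to a BSQ binary file."""
    base = path[:-4] if path.endswith(".hdr") else path
    hdr, raw = base + ".hdr", base + ".raw"
    data = cube.data
    code = _ENVI_CODES[data.dtype.name]
    wl = ", ".join(f"{w:.17g}" for w in cube.wavelengths)
    lines = [
        "ENVI",
        "description = {hsipath hypercube}",
        f"samples = {data.shape[1]}",
        f"lines = {data.shape[0]}",
        f"bands = {data.shape[2]}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {code}",
        "interleave = bsq",
        "byte order = 0",
        f"cube kind = {cube.kind}",
        "wavelength units = Nanometers",
        "wavelength = {" + wl + "}",
    ]
    with open(hdr, "w") as f:
        f.write("\n".join(lines) + "\n")
    # BSQ: band-sequential, each band a lines x samples plane
    np.ascontiguousarray(np.moveaxis(data, 2, 0)).astype("<" + data.dtype.str[1:]).tofile(raw)


def _parse_envi_header(hdr: str) -> dict:
    with open(hdr) as f:
        text = f.read()
    fields: dict[str, str] = {}
    key, buf, in_brace = None, [], False
    for line in text.splitlines():
        if in_brace:
            buf.append(line)
            if "}" in line:
                fields[key] = " ".join(buf)
                in_brace = False
            continue
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        key, val = key.strip().lower(), val.strip()
        if val.startswith("{") and "}" not in val:
            buf, in_brace = [val], True
        else:
            fields[key] = val
    return fields


def _read_envi(path: str) -> Hypercube:
    base = path[:-4] if path.endswith(".hdr") else path
    hdr = base + ".hdr"
    fields = _parse_envi_header(hdr)
    for req in ("samples", "lines", "bands", "data type"):
        if req not in fields:
            raise ValueError(f"{hdr}: ENVI header missing field '{req}'")
    if "wavelength" not in fields:
        raise ValueError(f"{hdr}: ENVI header missing field 'wavelength'")
    samples, nlines, bands = (int(fields[k]) for k in ("samples", "lines", "bands"))
    dtype = _ENVI_DTYPES.get(int(fields["data type"]))
    if dtype is None:
        raise ValueError(f"{hdr}: unsupported ENVI data type {fields['data type']}")
    wl = np.array(
        [float(tok) for tok in fields["wavelength"].strip("{} ").split(",") if tok.strip()]
    )
    if wl.size != bands:
        raise ValueError(f"{hdr}: {wl.size} wavelengths for {bands} bands")
    raw_path = base + ".raw" if os.path.exists(base + ".raw") else base
    arr = np.fromfile(raw_path, dtype=np.dtype(dtype).newbyteorder("<"))
    expect = samples * nlines * bands
    if arr.size != expect:
        raise ValueError(f"{raw_path}: expected {expect} values, found {arr.size}")
    interleave = fields.get("interleave", "bsq").lower()
    if interleave == "bsq":
        data = np.moveaxis(arr.reshape(bands, nlines, samples), 0, 2)
    elif interleave == "bil":
        data = np.moveaxis(arr.reshape(nlines, bands, samples), 1, 2)
    elif interleave == "bip":
        data = arr.reshape(nlines, samples, bands)
    else:
        raise ValueError(f"{hdr}: unsupported interleave {interleave!r}")
    kind = fields.get("cube kind", RAW_COUNTS)
    return Hypercube(data, wl, kind)


# ---------------------------------------------------------------------------
# Calibration, tiling, resizing
# ---------------------------------------------------------------------------

def calibrate_transmittance(
    frames: CalibrationFrames, denom_floor: float = 1e-6
) -> Hypercube:
    """Per-pixel, per-band ``(raw - dark) / (white - dark)`` transmittance.

    The denominator is clamped below at ``denom_floor`` and negative results
    (sensor noise below dark level) are clamped to 0.  Values above 1 are
    kept: tissue can transmit more than the blank reference area.
    """
    num = frames.raw.data - frames.dark.data
    den = np.maximum(frames.white.data - frames.dark.data, denom_floor)
    t = np.maximum(num / den, 0.0)
    return Hypercube(t, frames.raw.wavelengths, TRANSMITTANCE)


def tile_patches(
    frame: Hypercube,
    patch_px: int,
    slide_id: str = "",
    patient_id: str = "",
    label: str = "unknown",
) -> list[PatchRecord]:
    """Cut a frame into non-overlapping ``patch_px`` square tiles, row-major.

    Partial tiles at the bottom/right edge are dropped, so the count is
    ``floor(H/patch_px) * floor(W/patch_px)``.
    """
    if patch_px < 1:
        raise ValueError("patch_px must be >= 1")
    H, W, _ = frame.shape
    nr, nc = H // patch_px, W // patch_px
    if nr == 0 or nc == 0:
        logger.warning(
            "patch size %d exceeds frame size %dx%d; no tiles produced", patch_px, H, W
        )
        return []
    out = []
    for r in range(nr):
        for c in range(nc):
            sub = frame.data[
                r * patch_px : (r + 1) * patch_px, c * patch_px : (c + 1) * patch_px
            ]
            out.append(
                PatchRecord(
                    cube=Hypercube(sub.copy(), frame.wavelengths, frame.kind),
                    grid_row=r,
                    grid_col=c,
                    slide_id=slide_id,
                    patient_id=patient_id,
                    label=label,
                )
            )
    return out


def mean_intensity_filter(
    patches: list[PatchRecord], lo: float = 0.0, hi: float = 1.0
) -> list[PatchRecord]:
    """Optional background/QC filter: keep patches whose mean intensity lies in [lo, hi].

    Mostly-blank tiles on a transmittance slide have mean near 1; a typical
    use is ``hi=0.95`` to drop background-only tiles.
    """
    return [p for p in patches if lo <= float(p.cube.data.mean()) <= hi]


def resize_patch(patch: Hypercube, out_px: int) -> Hypercube:
    """Resize each band to ``out_px`` square with anti-aliased interpolation.

    The band axis is untouched (no cross-band smoothing) and the output is
    clipped to ``[0, max(input)]`` so interpolation overshoot cannot create
    out-of-range intensities.
    """
    if out_px <= 0:
        raise ValueError("out_px must be positive")
    H, W, B = patch.shape
    if H != W:
        raise ValueError(f"patch must be square, got {H}x{W}")
    out = _sk_resize(
        patch.data,
        (out_px, out_px, B),
        order=1,
        mode="edge",
        anti_aliasing=(out_px < H),
        preserve_range=True,
    )
    hi = float(patch.data.max()) if patch.data.size else 0.0
    return Hypercube(np.clip(out, 0.0, hi), patch.wavelengths, patch.kind)


def reassemble(patches: list[PatchRecord], wavelengths: np.ndarray, kind: str) -> Hypercube:
    """Stitch tiles back into the cropped frame (inverse of :func:`tile_patches`)."""
    if not patches:
        raise ValueError("no patches to assemble")
    p = patches[0].cube.shape[0]
    nr = max(rec.grid_row for rec in patches) + 1
    nc = max(rec.grid_col for rec in patches) + 1
    B = patches[0].cube.n_bands
    out = np.zeros((nr * p, nc * p, B))
    for rec in patches:
        out[
            rec.grid_row * p : (rec.grid_row + 1) * p,
            rec.grid_col * p : (rec.grid_col + 1) * p,
        ] = rec.cube.data
    return Hypercube(out, wavelengths, kind)


# ---------------------------------------------------------------------------
# Display RGB synthesis
# ---------------------------------------------------------------------------

def _cmf_lobe(wl: np.ndarray, mu: float, s1: float, s2: float) -> np.ndarray:
    # piecewise-Gaussian lobe of the CIE 1931 colour-matching fit
    s = np.where(wl < mu, s1, s2)
    return np.exp(-0.5 * ((wl - mu) / s) ** 2)


def color_matching_functions(wavelengths: np.ndarray) -> np.ndarray:
    """CIE-1931-style x̄, ȳ, z̄ sampled at the given wavelengths (nm).

    Multi-lobe Gaussian analytic approximation; adequate for display RGB.
    Returns an array of shape (B, 3).
    """
    wl = np.asarray(wavelengths, dtype=float)
    x = (
        1.056 * _cmf_lobe(wl, 599.8, 37.9, 31.0)
        + 0.362 * _cmf_lobe(wl, 442.0, 16.0, 26.7)
        - 0.065 * _cmf_lobe(wl, 501.1, 20.4, 26.2)
    )
    y = 0.821 * _cmf_lobe(wl, 568.8, 46.9, 40.5) + 0.286 * _cmf_lobe(wl, 530.9, 16.3, 31.1)
    z = 1.217 * _cmf_lobe(wl, 437.0, 11.8, 36.0) + 0.681 * _cmf_lobe(wl, 459.0, 26.0, 13.8)
    return np.stack([x, y, z], axis=1)


_XYZ_TO_RGB = np.array(
    [
        [3.2406, -1.5372, -0.4986],
        [-0.9689, 1.8758, 0.0415],
        [0.0557, -0.2040, 1.0570],
    ]
)


def hsi_to_rgb(cube: Hypercube) -> np.ndarray:
    """Project a transmittance cube onto a display RGB image in [0, 1].

    Spectra are integrated against colour-matching weights over the cube's
    wavelength support, converted with the linear sRGB matrix, and
    normalized per channel by the response to a flat unit spectrum, so a
    spectrally uniform cube maps to a neutral grey.
    """
    if cube.kind != TRANSMITTANCE:
        raise ValueError("hsi_to_rgb expects a transmittance cube")
    wl = cube.wavelengths
    if wl.max() < 400.0 or wl.min() > 720.0:
        raise ValueError(
            f"wavelength support {wl.min():.0f}-{wl.max():.0f} nm lies outside the "
            "visible display range 400-720 nm"
        )
    cmf = color_matching_functions(wl)  # (B, 3)
    # trapezoid quadrature weights over the wavelength grid
    if wl.size > 1:
        qw = np.gradient(wl)
    else:
        qw = np.ones(1)
    weights = cmf * qw[:, None]  # (B, 3)
    xyz = cube.data @ weights  # (H, W, 3)
    rgb = xyz @ _XYZ_TO_RGB.T
    white = (np.ones(wl.size) @ weights) @ _XYZ_TO_RGB.T  # flat-spectrum response
    rgb = rgb / white
    rgb = np.clip(rgb, 0.0, 1.0)
    # sRGB transfer curve for display
    out = np.where(rgb <= 0.0031308, 12.92 * rgb, 1.055 * rgb ** (1 / 2.4) - 0.055)
    return np.clip(out, 0.0, 1.0)
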