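"""Seed-reproducible synthetic H&E-like hyperspectral data.

Real microscopic hyperspectral slides of stained tissue are modelled with a
three-stain Beer-Lambert transmittance law

    T(x, y, lambda) = 10 ** ( - sum_i c_i(x, y) * eps_i(lambda) )

where ``c_i`` are spatial stain abundance maps and ``eps_i`` absorbance
endmember spectra for a hematoxylin-like, an eosin-like and a
hemoglobin-like component.  Two tissue classes are rendered:

* ``cancer`` — many small, densely packed hematoxylin-rich nuclei over an
  eosin-stained stroma (carcinoma-like crowded-nucleus texture);
* ``normal`` — thyroid-follicle-like rings of moderately stained epithelium
  around a nearly transparent colloid lumen.

The two classes differ both spatially (disks vs. rings) and spectrally
(mean hematoxylin abundance is higher in cancer patches), so they are
separable by construction.  The generator also produces white-reference and
dark-current count frames so the calibration pipeline can be exercised
end to end without any real acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .cube import RAW_COUNTS, TRANSMITTANCE, CalibrationFrames, Hypercube, write_cube

DEFAULT_WL_RANGE = (467.0, 721.0)


@dataclass
class StainBasis:
    """Three unit-peak absorbance endmembers on a common wavelength grid."""

    wavelengths: np.ndarray
    spectra: np.ndarray  # (3, B), rows: hematoxylin-, eosin-, hemoglobin-like
    names: tuple[str, str, str] = ("hematoxylin", "eosin", "hemoglobin")
    peaks_nm: tuple[float, float, float] = (590.0, 520.0, 575.0)

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        if self.spectra.shape != (3, self.wavelengths.size):
            raise ValueError("basis must be 3 x B")
        if np.any(self.spectra < 0):
            raise ValueError("absorbance endmembers must be nonnegative")


def make_stain_basis(
    wavelengths: np.ndarray,
    peaks_nm: tuple[float, float, float] = (590.0, 520.0, 575.0),
    widths_nm: tuple[float, float, float] = (45.0, 25.0, 12.0),
) -> StainBasis:
    """Gaussian-bump absorbance endmembers, unit peak after sampling.

    Default peaks sit at 590 nm (hematoxylin-like: the hematein-aluminium
    complex absorbs around 590 nm), 520 nm (eosin-like) and 575 nm
    (hemoglobin-like, oxyhemoglobin Q band); widths are broad for the dyes
    and narrow for hemoglobin, as in real absorbance spectra, and keep the
    sampled curves pairwise distinguishable (cosine similarity < 0.9) and
    rank-3 identifiable even on a coarse 8-band grid.
    """
    wl = np.asarray(wavelengths, dtype=float)
    if wl.size > 1 and not np.all(np.diff(wl) > 0):
        raise ValueError("wavelengths must be increasing")
    spectra = np.stack(
        [np.exp(-0.5 * ((wl - p) / w) ** 2) for p, w in zip(peaks_nm, widths_nm)]
    )
    spectra /= spectra.max(axis=1, keepdims=True)
    return StainBasis(wl, spectra, peaks_nm=peaks_nm)


@dataclass
class SceneConfig:
    """Geometry, optics and noise for one rendered patch."""

    patch_px: int = 56
    n_bands: int = 8
    wl_range: tuple[float, float] = DEFAULT_WL_RANGE
    tissue_class: str = "cancer"  # {"cancer", "normal"}
    nucleus_density: float = 0.25  # fraction of area covered by nuclei (cancer)
    nucleus_radius_px: tuple[float, float] = (2.0, 4.5)
    follicle_radius_frac: tuple[float, float] = (0.22, 0.42)  # of patch size (normal)
    follicle_wall_frac: float = 0.3  # wall thickness as fraction of outer radius
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patch_px < 8 or self.n_bands < 1:
            raise ValueError("degenerate scene geometry")
        if not 0.0 <= self.nucleus_density <= 1.0:
            raise ValueError("nucleus_density must be in [0, 1]")
        if self.tissue_class not in ("cancer", "normal"):
            raise ValueError(f"unknown tissue class {self.tissue_class!r}")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.wl_range[0], self.wl_range[1], self.n_bands)


def _disk(grid_r: np.ndarray, grid_c: np.ndarray, r0: float, c0: float, rad: float) -> np.ndarray:
    return (grid_r - r0) ** 2 + (grid_c - c0) ** 2 <= rad**2


def _smooth_field(rng: np.random.Generator, n: int, lo: float, hi: float, scale: float = 6.0) -> np.ndarray:
    f = gaussian_filter(rng.standard_normal((n, n)), scale, mode="reflect")
    f = (f - f.min()) / max(np.ptp(f), 1e-12)
    return lo + (hi - lo) * f


def render_abundances(cfg: SceneConfig) -> np.ndarray:
    """Draw the (3, H, W) stain abundance maps for one patch."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.patch_px
    rr, cc = np.mgrid[0:n, 0:n].astype(float)
    c_h = np.full((n, n), 0.05)
    c_e = _smooth_field(rng, n, 0.15, 0.45)
    c_b = np.zeros((n, n))

    if cfg.tissue_class == "cancer":
        r_lo, r_hi = cfg.nucleus_radius_px
        mean_area = np.pi * ((r_lo + r_hi) / 2) ** 2
        n_nuclei = max(1, int(round(cfg.nucleus_density * n * n / mean_area)))
        for _ in range(n_nuclei):
            rad = rng.uniform(r_lo, r_hi)
            r0, c0 = rng.uniform(0, n, size=2)
            mask = _disk(rr, cc, r0, c0, rad)
            c_h[mask] = rng.uniform(0.7, 1.0)
            c_e[mask] *= 0.15  # nuclei displace cytoplasm stain
        # small vessels: hemoglobin-rich blobs (carcinoma is vascularized)
        for _ in range(rng.integers(2, 5)):
            mask = _disk(rr, cc, *rng.uniform(0, n, size=2), rng.uniform(2.5, 5.0))
            c_b[mask] = rng.uniform(0.5, 0.9)
            c_h[mask] = 0.02
            c_e[mask] = 0.02
    else:
        n_follicles = rng.integers(1, 3)
        for _ in range(n_follicles):
            r_out = rng.uniform(*cfg.follicle_radius_frac) * n
            wall = cfg.follicle_wall_frac * r_out
            r0 = rng.uniform(r_out, n - r_out) if n > 2 * r_out else n / 2
            c0 = rng.uniform(r_out, n - r_out) if n > 2 * r_out else n / 2
            outer = _disk(rr, cc, r0, c0, r_out)
            lumen = _disk(rr, cc, r0, c0, r_out - wall)
            ring = outer & ~lumen
            c_e[ring] = rng.uniform(0.45, 0.7)
            c_h[ring] = rng.uniform(0.12, 0.2)
            # colloid lumen: almost transparent, faint hemoglobin tint
            c_e[lumen] = 0.02
            c_h[lumen] = 0.01
            c_b[lumen] = rng.uniform(0.03, 0.08)
        # sparse epithelial nuclei outside follicles
        for _ in range(rng.integers(3, 8)):
            mask = _disk(rr, cc, *rng.uniform(0, n, size=2), rng.uniform(1.5, 2.5))
            c_h[mask] = rng.uniform(0.3, 0.5)
    return np.stack([c_h, c_e, c_b])


def render_patch(
    cfg: SceneConfig, basis: StainBasis | None = None
) -> tuple[Hypercube, np.ndarray]:
    """Render one labelled patch; returns (transmittance cube, abundance maps).

    Ground-truth abundances are returned so decomposition methods can be
    scored against the generator.
    """
    if basis is None:
        basis = make_stain_basis(cfg.wavelengths)
    if basis.wavelengths.size != cfg.n_bands:
        raise ValueError("basis wavelength grid does not match scene config")
    ab = render_abundances(cfg)  # (3, H, W)
    od = np.einsum("ihw,ib->hwb", ab, basis.spectra)
    t = 10.0 ** (-od)
    if cfg.noise_sd > 0:
        rng = np.random.default_rng((cfg.seed, 0xBEEF))
        t = t + rng.normal(0.0, cfg.noise_sd, size=t.shape)
    t = np.clip(t, 0.0, 1.0)
    return Hypercube(t, basis.wavelengths, TRANSMITTANCE), ab


def make_dataset(
    n_per_class: int,
    cfg: SceneConfig | None = None,
    seed: int = 0,
    patient_block: int = 10,
    out_dir: str | None = None,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Render a balanced labelled patch set with blocked synthetic patients.

    Patches are assigned to synthetic patients in blocks of ``patient_block``
    consecutive patches of the same class, so patient-stratified splitting
    has real structure to respect.  Returns ``(X, y, manifest)`` where X is
    ``(2*n_per_class, H, W, B)``, y is 0 for normal / 1 for cancer, and the
    manifest carries slide/patient/label columns (with file paths when
    ``out_dir`` is given).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    base = cfg if cfg is not None else SceneConfig()
    root = np.random.default_rng(seed)
    rows, cubes, labels = [], [], []
    idx = 0
    for label_ix, cls in enumerate(["normal", "cancer"]):
        for j in range(n_per_class):
            scene = replace(
                base,
                tissue_class=cls,
                seed=int(root.integers(0, 2**31 - 1)),
            )
            cube, _ = render_patch(scene)
            patient = f"P{label_ix}{j // patient_block:03d}"
            slide = f"S{label_ix}{j // patient_block:03d}"
            path = ""
            if out_dir is not None:
                import os

                os.makedirs(out_dir, exist_ok=True)
                path = os.path.join(out_dir, f"patch_{idx:05d}.h5")
                write_cube(path, cube)
            rows.append(
                dict(
                    slide_id=slide,
                    patient_id=patient,
                    grid_row=j // patient_block,
                    grid_col=j % patient_block,
                    label=cls,
                    path=path,
                )
            )
            cubes.append(cube.data)
            labels.append(label_ix)
            idx += 1
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        import os

        manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return np.stack(cubes), np.array(labels), manifest


def make_reference_frames(cfg: SceneConfig | None = None) -> tuple[CalibrationFrames, Hypercube]:
    """Raw/white/dark count frames for a rendered scene.

    The white frame carries a smooth spectral lamp profile around 4000
    counts, the dark frame a small offset near 100 counts, and the raw frame
    is ``dark + (white - dark) * T`` plus sensor noise, so transmittance
    calibration recovers the rendered T up to noise.  Returns the frames and
    the ground-truth transmittance cube.
    """
    scene = cfg if cfg is not None else SceneConfig()
    truth, _ = render_patch(replace(scene, noise_sd=0.0))
    rng = np.random.default_rng((scene.seed, 0xCAFE))
    wl = truth.wavelengths
    lamp = 4000.0 * (0.75 + 0.25 * np.sin((wl - wl[0]) / max(wl[-1] - wl[0], 1.0) * np.pi))
    shape = truth.shape
    white = np.broadcast_to(lamp, shape) + rng.normal(0, 5.0, shape)
    dark = 100.0 + rng.normal(0, 2.0, shape)
    raw = dark + (white - dark) * truth.data
    if scene.noise_sd > 0:
        raw = raw + rng.normal(0, scene.noise_sd * 3900.0, shape)
    frames = CalibrationFrames(
        raw=Hypercube(np.maximum(raw, 0), wl, RAW_COUNTS),
        white=Hypercube(np.maximum(white, 0), wl, RAW_COUNTS),
        dark=Hypercube(np.maximum(dark, 0), wl, RAW_COUNTS),
    )
    return frames, truth
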