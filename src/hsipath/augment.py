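"""Hyperspectral RandAugment: 3 random transforms per cube from a 13-entry set.

Each augmented cube receives three transforms drawn uniformly with
replacement from {identity, rotate, shearX, shearY, translateX, translateY,
brightness, contrast, sharpen, spectral noise, shifting, zeroing, NMF stain
gamma}, each with a strength drawn uniformly from its configured range.
Geometric transforms act identically on every band; spectral transforms act
on the wavelength axis.  The NMF transform perturbs stain concentrations:
the cube is decomposed in optical-density space into three nonnegative
components (hematoxylin-, eosin- and hemoglobin-like), the abundance maps
are gamma-corrected, and the cube is reconstructed.

All transforms are deterministic given (input, plan); stochastic choices
are made when the plan is sampled, not when it is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.decomposition import NMF

from .cube import TRANSMITTANCE, Hypercube

TRANSFORMS = (
    "identity",
    "rotate",
    "shearX",
    "shearY",
    "translateX",
    "translateY",
    "brightness",
    "contrast",
    "sharpen",
    "spectral_noise",
    "shifting",
    "zeroing",
    "nmf",
)

GEOMETRIC_KINDS = ("rotate", "shearX", "shearY", "translateX", "translateY")

#: Denominator clamp for the contrast map: the published formula
#: 1.0157(C+1)(I-0.5)/(1.0157-C)+0.5 has a pole at C=1.0157 inside the
#: sampled range [0, 2]; the denominator is kept >= this floor.
CONTRAST_DENOM_FLOOR = 0.01


@dataclass(frozen=True)
class TransformRanges:
    """Per-transform [lo, hi] strength bounds (units as documented per field)."""

    rotate: tuple[float, float] = (0.0, np.pi / 2)  # radians, clockwise
    translate: tuple[float, float] = (0.0, 0.5)  # fraction of image length
    shear: tuple[float, float] = (0.0, 0.5)  # fraction of image length
    contrast: tuple[float, float] = (0.0, 2.0)  # contrast score C
    sharpen: tuple[float, float] = (0.0, 5.0)  # unsharp-mask multiplier
    spectral_noise: tuple[float, float] = (0.0, 0.5)  # fraction of max intensity
    shifting: tuple[float, float] = (0.0, 2.0)  # spectral ramp strength A
    zeroing: tuple[int, int] = (0, 3)  # number of zeroed channels
    brightness: tuple[float, float] = (0.0, 1.0)  # fraction of max intensity
    nmf_gamma: tuple[float, float] = (0.5, 1.5)  # abundance gamma

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: lo {lo} > hi {hi}")
        zlo, zhi = self.zeroing
        if int(zlo) != zlo or int(zhi) != zhi:
            raise ValueError("zeroing bounds must be integers")

    def bounds_for(self, transform: str) -> tuple[float, float]:
        key = {
            "rotate": "rotate",
            "shearX": "shear",
            "shearY": "shear",
            "translateX": "translate",
            "translateY": "translate",
            "brightness": "brightness",
            "contrast": "contrast",
            "sharpen": "sharpen",
            "spectral_noise": "spectral_noise",
            "shifting": "shifting",
            "zeroing": "zeroing",
            "nmf": "nmf_gamma",
        }.get(transform)
        if key is None:  # identity
            return (0.0, 0.0)
        return getattr(self, key)


@dataclass
class AugmentPlan:
    """Three sampled (transform, strength, aux) steps plus the seed that drew them."""

    steps: list[tuple[str, float, dict]]
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.steps) != 3:
            raise ValueError("a plan holds exactly 3 transforms")
        for name, _, _ in self.steps:
            if name not in TRANSFORMS:
                raise ValueError(f"unknown transform {name!r}")


def sample_plan(
    ranges: TransformRanges, rng: np.random.Generator, seed_label: int | None = None
) -> AugmentPlan:
    """Draw 3 transforms uniformly with replacement, strengths uniform in range."""
    steps: list[tuple[str, float, dict]] = []
    for _ in range(3):
        name = TRANSFORMS[int(rng.integers(0, len(TRANSFORMS)))]
        lo, hi = ranges.bounds_for(name)
        aux: dict = {}
        if name == "zeroing":
            strength = float(rng.integers(int(lo), int(hi) + 1))
            aux["seed"] = int(rng.integers(0, 2**31 - 1))
        else:
            strength = float(rng.uniform(lo, hi))
        if name in ("shearX", "shearY", "translateX", "translateY"):
            aux["direction"] = int(rng.choice([-1, 1]))
        if name == "spectral_noise":
            aux["seed"] = int(rng.integers(0, 2**31 - 1))
        if name == "nmf":
            aux["seed"] = int(rng.integers(0, 2**31 - 1))
        steps.append((name, strength, aux))
    return AugmentPlan(steps, rng_seed=seed_label)


# ---------------------------------------------------------------------------
# Individual transforms
# ---------------------------------------------------------------------------

def apply_geometric(
    cube: Hypercube, kind: str, strength: float, fill: float = 1.0, direction: int = 1
) -> Hypercube:
    """Rotate / shear / translate every band with the same bilinear map.

    Out-of-frame regions are set to ``fill`` (default 1.0: bright slide
    background in transmittance).  Rotation is about the image centre,
    clockwise; shear and translation strengths are fractions of the image
    side length, with ``direction`` choosing the sign.
    """
    if kind not in GEOMETRIC_KINDS:
        raise ValueError(f"unknown geometric transform {kind!r}")
    H, W, _ = cube.shape
    cm = np.array([(H - 1) / 2.0, (W - 1) / 2.0])
    if kind == "rotate":
        th = strength
        A = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        # snap quarter-turn roundoff (cos(pi/2) ~ 6e-17) so exact grid
        # rotations stay exact index permutations
        A[np.abs(A) < 1e-12] = 0.0
        offset = cm - A @ cm
        near_int = np.round(offset)
        offset[np.abs(offset - near_int) < 1e-9] = near_int[np.abs(offset - near_int) < 1e-9]
    elif kind in ("shearX", "shearY"):
        s = direction * strength
        if kind == "shearX":  # horizontal displacement proportional to row
            A = np.array([[1.0, 0.0], [s, 1.0]])
        else:
            A = np.array([[1.0, s], [0.0, 1.0]])
        offset = cm - A @ cm
    else:  # translate
        A = np.eye(2)
        t = direction * strength
        offset = np.array([-t * H, 0.0]) if kind == "translateY" else np.array([0.0, -t * W])
    out = np.empty_like(cube.data)
    for b in range(cube.n_bands):
        out[:, :, b] = ndimage.affine_transform(
            cube.data[:, :, b], A, offset=offset, order=1, mode="constant", cval=fill
        )
    return cube.with_data(np.clip(out, 0.0, 1.0))


def adjust_brightness(cube: Hypercube, s: float) -> Hypercube:
    """Additive brightening by ``s`` times the cube's maximum intensity."""
    out = cube.data + s * float(cube.data.max())
    return cube.with_data(np.clip(out, 0.0, 1.0))


def contrast_formula(I: np.ndarray | float, C: float) -> np.ndarray | float:
    """The published contrast map, before clipping.

    ``I' = 1.0157 (C+1) (I - 0.5) / (1.0157 - C) + 0.5``; the denominator is
    clamped to :data:`CONTRAST_DENOM_FLOOR` to keep the map finite for
    C >= 1.0157 within the sampled range.
    """
    den = max(1.0157 - C, CONTRAST_DENOM_FLOOR)
    return 1.0157 * (C + 1.0) * (np.asarray(I) - 0.5) / den + 0.5


def adjust_contrast(cube: Hypercube, C: float) -> Hypercube:
    out = contrast_formula(cube.data, C)
    return cube.with_data(np.clip(out, 0.0, 1.0))


def sharpen_bands(cube: Hypercube, s: float) -> Hypercube:
    """Unsharp masking per band: ``I + s (I - blur(I))`` with a 3x3 mean blur."""
    blur = ndimage.uniform_filter(cube.data, size=(3, 3, 1), mode="nearest")
    out = cube.data + s * (cube.data - blur)
    return cube.with_data(np.clip(out, 0.0, 1.0))


def add_spectral_noise(
    cube: Hypercube, s: float, rng: np.random.Generator
) -> tuple[Hypercube, np.ndarray]:
    """Add one uniform random offset per band, in [0, s * max(I)].

    Returns the new cube and the per-band offsets actually drawn.
    """
    delta = rng.uniform(0.0, s * float(cube.data.max()), size=cube.n_bands)
    out = cube.data + delta[None, None, :]
    return cube.with_data(np.clip(out, 0.0, 1.0)), delta


def spectral_ramp_factor(wavelengths: np.ndarray, A: float) -> np.ndarray:
    """Unit-gain-at-600 nm multiplicative ramp, clamped nonnegative.

    ``f(lambda) = max(0, 1 + A (lambda - 600) / (lambda_max - lambda_min))``.
    A linear spectral tilt anchored so the 600 nm band is unchanged.
    """
    wl = np.asarray(wavelengths, dtype=float)
    span = max(float(wl.max() - wl.min()), 1e-12)
    return np.maximum(0.0, 1.0 + A * (wl - 600.0) / span)


def apply_spectral_ramp(cube: Hypercube, A: float) -> Hypercube:
    factor = spectral_ramp_factor(cube.wavelengths, A)
    out = cube.data * factor[None, None, :]
    return cube.with_data(np.clip(out, 0.0, 1.0))


def zero_bands(cube: Hypercube, k: int, rng: np.random.Generator) -> Hypercube:
    """Blacken ``k`` distinct randomly chosen bands; others are untouched."""
    k = int(k)
    if k < 0 or k > cube.n_bands:
        raise ValueError(f"cannot zero {k} of {cube.n_bands} bands")
    out = cube.data.copy()
    if k:
        bands = rng.choice(cube.n_bands, size=k, replace=False)
        out[:, :, bands] = 0.0
    return cube.with_data(out)


@dataclass(frozen=True)
class NMFConfig:
    """Rank-3 optical-density factorization settings for the stain transform.

    The default init is NNDSVDA (deterministic, SVD-seeded): purely random
    init occasionally lands the multiplicative-update solver in a local
    minimum that mixes the overlapping dye endmembers.
    """

    n_components: int = 3
    max_iter: int = 200
    tol: float = 1e-4
    eps: float = 1e-4  # transmittance floor before the log
    init: str = "nndsvda"


def od_nmf(
    cube: Hypercube, cfg: NMFConfig, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Factor the cube's optical density as W @ S (pixels x k, k x bands).

    OD = -log10(max(T, eps)) is additive across stains under Beer-Lambert,
    so a nonnegative rank-3 factorization recovers abundance maps (W) and
    absorbance endmembers (S).  Multiplicative-update solver, seeded random
    init; if the iteration cap is reached the best iterate is returned.
    """
    H, W_, B = cube.shape
    # transmittance above 1 (tissue brighter than the blank reference) maps
    # to negative OD; clamp to zero absorbance so the factorization stays
    # nonnegative
    od = -np.log10(np.clip(cube.data, cfg.eps, 1.0)).reshape(H * W_, B)
    model = NMF(
        n_components=cfg.n_components,
        solver="mu",
        init=cfg.init,
        max_iter=cfg.max_iter,
        tol=cfg.tol,
        random_state=int(seed) % (2**32),
    )
    import warnings

    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        w = model.fit_transform(od)
    return w, model.components_, od


def nmf_stain_augment(
    cube: Hypercube,
    gamma: float,
    nmf_cfg: NMFConfig | None = None,
    seed: int = 0,
) -> Hypercube:
    """Stain-concentration perturbation via gamma on NMF abundance maps.

    The abundance columns are normalized to [0, 1], raised to ``gamma``,
    restored to their original scale, and the cube is reconstructed as
    ``10 ** -(W' @ S)``.  gamma = 1 returns the plain rank-3 reconstruction.
    """
    if cube.kind != TRANSMITTANCE:
        raise ValueError("nmf_stain_augment expects a transmittance cube")
    cfg = nmf_cfg or NMFConfig()
    w, s, _ = od_nmf(cube, cfg, seed)
    scale = np.maximum(w.max(axis=0, keepdims=True), 1e-12)
    w_gamma = ((w / scale) ** gamma) * scale
    od_new = w_gamma @ s
    H, W_, B = cube.shape
    out = 10.0 ** (-od_new.reshape(H, W_, B))
    return cube.with_data(np.clip(out, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Plan application
# ---------------------------------------------------------------------------

def apply_plan(cube: Hypercube, plan: AugmentPlan, fill: float = 1.0) -> Hypercube:
    """Apply a sampled plan's three transforms in order."""
    out = cube
    for name, strength, aux in plan.steps:
        if name == "identity":
            continue
        elif name in GEOMETRIC_KINDS:
            out = apply_geometric(
                out, name, strength, fill=fill, direction=aux.get("direction", 1)
            )
        elif name == "brightness":
            out = adjust_brightness(out, strength)
        elif name == "contrast":
            out = adjust_contrast(out, strength)
        elif name == "sharpen":
            out = sharpen_bands(out, strength)
        elif name == "spectral_noise":
            out, _ = add_spectral_noise(
                out, strength, np.random.default_rng(aux["seed"])
            )
        elif name == "shifting":
            out = apply_spectral_ramp(out, strength)
        elif name == "zeroing":
            out = zero_bands(out, int(strength), np.random.default_rng(aux["seed"]))
        elif name == "nmf":
            out = nmf_stain_augment(out, strength, seed=aux["seed"])
    return out


def rand_augment(
    cube: Hypercube, ranges: TransformRanges | None = None, rng: np.random.Generator | int = 0
) -> Hypercube:
    """Sample a 3-transform plan and apply it; shape-preserving, output in [0, 1]."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    plan = sample_plan(ranges or TransformRanges(), rng)
    return apply_plan(cube, plan)


class HyperspectralRandAugment:
    """Stateless transformer wrapper around :func:`rand_augment`.

    scikit-learn-style surface: ``get_params``/``set_params`` plus a
    ``transform(X)`` that augments a batch of cubes given as an
    ``(n, H, W, B)`` array with a shared wavelength axis.  Each sample's
    draws come from a per-sample child seed of ``random_state``, so a batch
    is reproducible regardless of ordering of the augment calls.
    """

    def __init__(
        self,
        ranges: TransformRanges | None = None,
        wavelengths: np.ndarray | None = None,
        fill: float = 1.0,
        random_state: int = 0,
    ):
        self.ranges = ranges
        self.wavelengths = wavelengths
        self.fill = fill
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "ranges": self.ranges,
            "wavelengths": self.wavelengths,
            "fill": self.fill,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "HyperspectralRandAugment":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None) -> "HyperspectralRandAugment":
        return self  # stateless

    def transform(self, X: np.ndarray, sample_ids: np.ndarray | None = None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 4:
            raise ValueError("expected a batch of cubes, shape (n, H, W, B)")
        wl = (
            np.asarray(self.wavelengths)
            if self.wavelengths is not None
            else np.linspace(467.0, 721.0, X.shape[3])
        )
        ranges = self.ranges or TransformRanges()
        ids = np.arange(X.shape[0]) if sample_ids is None else np.asarray(sample_ids)
        out = np.empty_like(X)
        for i, sid in enumerate(ids):
            child = np.random.default_rng((int(self.random_state), int(sid)))
            cube = Hypercube(X[i], wl, TRANSMITTANCE)
            plan = sample_plan(ranges, child, seed_label=int(sid))
            out[i] = apply_plan(cube, plan, fill=self.fill).data
        return out
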