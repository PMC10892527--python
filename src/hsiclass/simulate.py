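"""Synthetic desert-grassland hyperspectral scenes.

The generator emulates the statistical structure of a drone-borne
hyperspectral survey of degraded desert grassland: three land-cover classes
(a dominant grass community, a drought-stressed degradation-indicator
community with a flattened spectrum, and non-vegetation), low vegetation
reflectance over 400-1000 nm, sparse patchy spatial distribution, linearly
mixed pixels at community boundaries, additive sensor noise, and a large
unlabeled background fraction.

Endmember model
---------------
Vegetation classes follow a logistic red-edge curve,

    r(lambda) = base + (1 - flatness) * amplitude * sigmoid((lambda - edge)/steepness),

so ``flatness`` in [0, 1] interpolates between a healthy red-edge spectrum
and the flat, featureless curve of drought-stressed canopies.  The
non-vegetation class (withered grass / bare soil) is an affine ramp in
wavelength.  All endmembers are clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .data import HyperspectralCube, LabelMap, Spectrum
from .exceptions import SizeError

__all__ = [
    "ClassParams",
    "SceneConfig",
    "Scene",
    "endmember_spectrum",
    "generate_scene",
    "difficulty_report",
    "default_config",
    "intermediate_config",
]


@dataclass(frozen=True)
class ClassParams:
    """Parametric endmember for one land-cover class.

    ``kind`` is "vegetation" (logistic red edge) or "soil" (affine ramp, in
    which case ``amplitude`` is the total rise over the wavelength range).
    """

    name: str
    kind: str = "vegetation"
    base: float = 0.08
    amplitude: float = 0.25
    red_edge: float = 715.0       # nm
    steepness: float = 18.0       # nm
    flatness: float = 0.0         # 0 = healthy, 1 = fully flattened

    def __post_init__(self):
        if not 0.0 <= self.flatness <= 1.0:
            raise SizeError("flatness must lie in [0, 1]")


@dataclass(frozen=True)
class SceneConfig:
    """Stated world for the simulator.

    Defaults mirror the study scene: class priors proportional to the
    labeled-sample composition (21.5% dominant grass, 40.8% indicator
    community, 37.7% non-vegetation), 75% of pixels left unlabeled, 64 bands
    across 400-1000 nm, patchiness at an 8-pixel correlation length,
    one-pixel mixed borders and 0.01 reflectance units of sensor noise.
    """

    height: int = 120
    width: int = 120
    n_bands: int = 64
    wavelength_range: tuple[float, float] = (400.0, 1000.0)
    classes: tuple[ClassParams, ...] = (
        ClassParams("S. breviflora", "vegetation", base=0.06, amplitude=0.28,
                    red_edge=715.0, steepness=18.0, flatness=0.10),
        ClassParams("A. frigida", "vegetation", base=0.10, amplitude=0.20,
                    red_edge=705.0, steepness=25.0, flatness=0.55),
        ClassParams("non-vegetation", "soil", base=0.16, amplitude=0.18),
    )
    priors: tuple[float, ...] = (0.215, 0.408, 0.377)
    correlation_length: float = 8.0
    border_width: float = 1.0
    noise_sd: float = 0.01
    unlabeled_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self):
        if len(self.priors) != len(self.classes):
            raise SizeError("one prior per class required")
        if abs(sum(self.priors) - 1.0) > 1e-9:
            raise SizeError("class priors must sum to 1")
        if self.noise_sd < 0:
            raise SizeError("noise sd must be >= 0")
        if self.border_width < 0:
            raise SizeError("border width must be >= 0")
        if not 0.0 <= self.unlabeled_fraction < 1.0:
            raise SizeError("unlabeled fraction must lie in [0, 1)")

    @property
    def wavelengths(self) -> np.ndarray:
        lo, hi = self.wavelength_range
        return np.linspace(lo, hi, self.n_bands)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def class_table(self) -> dict:
        palette = ["#2e8b57", "#d2b48c", "#8b4513", "#4682b4", "#9932cc"]
        return {i + 1: {"name": p.name, "color": palette[i % len(palette)]}
                for i, p in enumerate(self.classes)}


class Scene(NamedTuple):
    """A generated scene: noisy cube, public labels, full ground truth, clean cube."""

    cube: HyperspectralCube
    labels: LabelMap          # unlabeled fraction zeroed out
    truth: LabelMap           # ground-truth sidecar, no unlabeled pixels
    clean: np.ndarray         # pre-noise reflectance (H, W, C)


def default_config(**overrides) -> SceneConfig:
    """The separable stated-world configuration."""
    return replace(SceneConfig(), **overrides) if overrides else SceneConfig()


def intermediate_config(**overrides) -> SceneConfig:
    """Harder variant: five-fold noise, flatter indicator spectrum, wider borders.

    Used for experiments whose point is a ranking between models rather than
    near-perfect accuracy.
    """
    base = SceneConfig()
    classes = list(base.classes)
    classes[1] = replace(classes[1], flatness=0.85, base=0.075)
    classes[0] = replace(classes[0], flatness=0.45)
    cfg = replace(base, classes=tuple(classes), noise_sd=0.05, border_width=2.0)
    return replace(cfg, **overrides) if overrides else cfg


def endmember_spectrum(params: ClassParams, wavelengths: np.ndarray) -> Spectrum:
    """Evaluate a parametric endmember on a wavelength axis."""
    wl = np.asarray(wavelengths, dtype=float)
    if np.any(np.diff(wl) <= 0):
        raise SizeError("wavelengths must be strictly increasing")
    if params.kind == "soil":
        span = wl[-1] - wl[0] if wl.size > 1 else 1.0
        r = params.base + params.amplitude * (wl - wl[0]) / span
    else:
        z = (wl - params.red_edge) / params.steepness
        sigmoid = 1.0 / (1.0 + np.exp(-z))
        r = params.base + (1.0 - params.flatness) * params.amplitude * sigmoid
    return Spectrum(np.clip(r, 0.0, 1.0), wl)


def _latent_fields(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-class smooth Gaussian fields, unit variance, shape (K, H, W)."""
    fields = rng.standard_normal((cfg.n_classes, cfg.height, cfg.width))
    if cfg.correlation_length > 0:
        sigma = cfg.correlation_length / 2.0
        fields = np.stack([ndimage.gaussian_filter(f, sigma, mode="reflect")
                           for f in fields])
    sd = fields.std(axis=(1, 2), keepdims=True)
    sd[sd == 0] = 1.0
    return (fields - fields.mean(axis=(1, 2), keepdims=True)) / sd


def _calibrate_offsets(fields: np.ndarray, priors: np.ndarray,
                       n_iter: int = 60) -> np.ndarray:
    """Fixed-point offsets so argmax class fractions track the priors."""
    k = fields.shape[0]
    offsets = np.zeros(k)
    n = fields[0].size
    for _ in range(n_iter):
        lab = np.argmax(fields + offsets[:, None, None], axis=0)
        frac = np.bincount(lab.ravel(), minlength=k) / n
        err = priors - frac
        if np.abs(err).max() < 2e-3:
            break
        offsets += 3.0 * err  # fields have unit variance: step ~ O(1)
    return offsets


def generate_scene(cfg: SceneConfig, seed: int | None = None) -> Scene:
    """Draw one synthetic scene. Deterministic for a given config + seed.

    Pipeline: smooth per-class latent fields -> argmax labels calibrated to
    the priors -> endmember spectra with distance-weighted two-endmember
    linear mixing inside the border band -> i.i.d. Gaussian noise, clipped to
    [0, 1] -> a seeded fraction of pixels hidden (label 0) in the public
    raster while the sidecar keeps full ground truth.
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    K = cfg.n_classes
    priors = np.asarray(cfg.priors, dtype=float)

    fields = _latent_fields(cfg, rng)
    offsets = _calibrate_offsets(fields, priors)
    truth = np.argmax(fields + offsets[:, None, None], axis=0) + 1  # 1..K

    wl = cfg.wavelengths
    endmembers = np.stack([endmember_spectrum(p, wl).reflectance
                           for p in cfg.classes])  # (K, C)

    clean = endmembers[truth - 1].astype(np.float64)  # (H, W, C)
    if cfg.border_width > 0:
        # Distance from each pixel to the nearest pixel of another class, and
        # that pixel's class: drives the two-endmember convex mixture.
        dist = np.zeros(truth.shape)
        neighbor = np.zeros(truth.shape, dtype=np.int32)
        for c in range(1, K + 1):
            mask = truth == c
            if not mask.any():
                continue
            d, (inds_r, inds_c) = ndimage.distance_transform_edt(
                mask, return_indices=True)
            dist[mask] = d[mask]
            neighbor[mask] = truth[inds_r[mask], inds_c[mask]]
        mixed = (dist <= cfg.border_width) & (neighbor > 0) & (neighbor != truth)
        if mixed.any():
            # weight 0.5 at the boundary rising to 1 at the border width
            w_own = 0.5 + 0.5 * np.clip(
                (dist[mixed] - 0.5) / max(cfg.border_width, 1e-9), 0.0, 1.0)
            own = endmembers[truth[mixed] - 1]
            other = endmembers[neighbor[mixed] - 1]
            clean[mixed] = w_own[:, None] * own + (1 - w_own[:, None]) * other

    noisy = clean + rng.normal(0.0, cfg.noise_sd, clean.shape) if cfg.noise_sd > 0 \
        else clean.copy()
    noisy = np.clip(noisy, 0.0, 1.0)

    codes = truth.astype(np.int32).copy()
    n_pixels = codes.size
    n_hidden = int(round(cfg.unlabeled_fraction * n_pixels))
    hidden = rng.permutation(n_pixels)[:n_hidden]
    codes.ravel()[hidden] = 0

    table = cfg.class_table()
    cube = HyperspectralCube(noisy, wl, {"generator": "hsiclass.simulate",
                                         "seed": seed})
    return Scene(cube, LabelMap(codes, table),
                 LabelMap(truth.astype(np.int32), table), clean)


@dataclass
class DifficultyReport:
    """Separability summary of a scene configuration."""

    endmember_distances: np.ndarray   # (K, K) pairwise L2 over bands
    distance_noise_ratio: np.ndarray  # (K, K), distances / (noise_sd * sqrt(C))
    oracle_accuracy: float            # nearest-centroid accuracy, percent
    class_fractions: np.ndarray

    def summary(self) -> str:
        lines = ["Scene difficulty report",
                 f"  nearest-centroid oracle accuracy: {self.oracle_accuracy:.2f}%",
                 f"  class fractions: {np.round(self.class_fractions, 3)}",
                 "  pairwise endmember L2 distances:"]
        for row in self.endmember_distances:
            lines.append("    " + "  ".join(f"{v:6.3f}" for v in row))
        return "\n".join(lines)


def nearest_centroid_accuracy(cube: HyperspectralCube, truth: LabelMap) -> float:
    """Accuracy (%) of a per-class mean-spectrum nearest-centroid classifier.

    The reference yardstick for the trained networks: it only sees raw band
    space and class means, so a correct deep model on a separable scene
    should approach (not necessarily beat) this number.
    """
    X = cube.values.reshape(-1, cube.n_bands)
    y = truth.codes.ravel()
    ids = np.unique(y[y > 0])
    centroids = np.stack([X[y == c].mean(axis=0) for c in ids])
    d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    pred = ids[np.argmin(d2, axis=1)]
    keep = y > 0
    return 100.0 * float(np.mean(pred[keep] == y[keep]))


def difficulty_report(cfg: SceneConfig, seed: int | None = None) -> DifficultyReport:
    """Quantify how separable the configured scene is."""
    wl = cfg.wavelengths
    E = np.stack([endmember_spectrum(p, wl).reflectance for p in cfg.classes])
    K = E.shape[0]
    dist = np.sqrt(((E[:, None, :] - E[None, :, :]) ** 2).sum(axis=2))
    noise_norm = cfg.noise_sd * np.sqrt(cfg.n_bands)
    ratio = dist / noise_norm if noise_norm > 0 else np.full_like(dist, np.inf)
    np.fill_diagonal(ratio, 0.0)
    scene = generate_scene(cfg, seed=seed)
    acc = nearest_centroid_accuracy(scene.cube, scene.truth)
    frac = np.bincount(scene.truth.codes.ravel(), minlength=K + 1)[1:] / scene.truth.codes.size
    return DifficultyReport(dist, ratio, acc, frac)
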