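"""PCA band reduction, 3D patch extraction and stratified splitting.

The pipeline order follows the usual spectral-spatial classification recipe:
the full scene (labeled and unlabeled pixels alike) is reduced to B principal
components retaining a target fraction of spectral variance, S x S x B
neighborhoods are cut around every labeled pixel, and patches are split per
class into train/validation/test by a seeded shuffle with floor rounding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.decomposition import PCA as _SkPCA

from .data import HyperspectralCube, LabelMap
from .exceptions import DegeneracyError, EmptyDatasetError, SizeError

__all__ = [
    "PCAModel",
    "PatchDataset",
    "SplitSpec",
    "Standardizer",
    "pca_reduce",
    "extract_patches",
    "stratified_split",
    "standardize",
]


@dataclass
class PCAModel:
    """Fitted PCA: band means, orthonormal loadings and the retained count B.

    ``loadings`` holds all computed components (columns); the first
    ``n_retained`` are the ones used for the reduced scene. Column signs are
    fixed so the largest-magnitude element of each component is positive,
    which makes scores reproducible across runs and BLAS builds.
    """

    means: np.ndarray                   # (C,)
    loadings: np.ndarray                # (C, n_components), orthonormal columns
    explained_variance_ratio: np.ndarray  # descending, sums to 1
    n_retained: int                     # B
    variance_threshold: float

    @property
    def B(self) -> int:
        return self.n_retained

    def transform(self, cube: HyperspectralCube, n_components: int | None = None) -> np.ndarray:
        """Project a cube onto the top components; returns (H, W, B) scores."""
        b = self.n_retained if n_components is None else n_components
        h, w, c = cube.shape
        X = cube.values.reshape(-1, c) - self.means
        return (X @ self.loadings[:, :b]).reshape(h, w, b)

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        """Reconstruct reflectance from (H, W, b) scores."""
        b = scores.shape[-1]
        flat = scores.reshape(-1, b) @ self.loadings[:, :b].T + self.means
        return flat.reshape(*scores.shape[:-1], self.means.size)


def pca_reduce(cube: HyperspectralCube,
               variance_threshold: float = 0.98) -> tuple[np.ndarray, PCAModel]:
    """Reduce a scene's spectral axis by PCA on all pixels.

    B is the smallest component count whose cumulative explained-variance
    ratio reaches ``variance_threshold``; the returned scores are the centered
    projections of every pixel onto those B loadings, shape (H, W, B).
    """
    if not 0.0 < variance_threshold <= 1.0:
        raise SizeError("variance threshold must lie in (0, 1]")
    h, w, c = cube.shape
    X = cube.values.reshape(-1, c).astype(np.float64)
    if np.allclose(X.var(axis=0).sum(), 0.0, atol=1e-15):
        raise DegeneracyError("cube has zero spectral variance (constant scene)")

    pca = _SkPCA(n_components=min(c, X.shape[0]), svd_solver="full")
    pca.fit(X)
    loadings = pca.components_.T.copy()           # (C, n_components)
    # deterministic sign: largest-magnitude loading element positive
    flip = loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])] < 0
    loadings[:, flip] *= -1.0
    evr = pca.explained_variance_ratio_

    cum = np.cumsum(evr)
    b = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    b = min(b, loadings.shape[1])
    model = PCAModel(pca.mean_.copy(), loadings, evr, b, variance_threshold)
    scores = ((X - model.means) @ loadings[:, :b]).reshape(h, w, b)
    return scores, model


@dataclass
class PatchDataset:
    """S x S x B neighborhoods with center-pixel labels and source coordinates."""

    patches: np.ndarray   # (N, S, S, B) float32
    labels: np.ndarray    # (N,) int, values in 1..K
    coords: np.ndarray    # (N, 2) (line, sample)
    S: int
    B: int
    standardized: bool = False

    def __post_init__(self):
        n = len(self.labels)
        if self.patches.shape != (n, self.S, self.S, self.B):
            raise SizeError(
                f"patches shape {self.patches.shape} inconsistent with "
                f"N={n}, S={self.S}, B={self.B}")
        if self.coords.shape != (n, 2):
            raise SizeError("coords must be (N, 2)")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_classes(self) -> int:
        return int(self.labels.max(initial=0))

    def subset(self, idx: np.ndarray) -> "PatchDataset":
        idx = np.asarray(idx)
        return PatchDataset(self.patches[idx], self.labels[idx],
                            self.coords[idx], self.S, self.B,
                            self.standardized)

    def label_histogram(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels, return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}


def extract_patches(scores: np.ndarray, labels: LabelMap, S: int,
                    pad_mode: str = "reflect") -> PatchDataset:
    """Cut one S x S x B block around every labeled (nonzero) pixel.

    Scene borders are padded with ``pad_mode`` (numpy.pad semantics; default
    reflect, which avoids injecting artificial zero spectra at the edges of
    sparse-vegetation scenes).
    """
    if S % 2 == 0 or S < 1:
        raise SizeError(f"patch side S must be odd and >= 1, got {S}")
    scores = np.asarray(scores)
    if scores.ndim != 3:
        raise SizeError("scores must be (H, W, B)")
    h, w, b = scores.shape
    if labels.shape != (h, w):
        raise SizeError("label raster shape differs from score array")
    lines, samples = np.nonzero(labels.codes)
    if lines.size == 0:
        raise EmptyDatasetError("no labeled pixels to extract patches from")

    r = S // 2
    padded = np.pad(scores, ((r, r), (r, r), (0, 0)), mode=pad_mode)
    if S == 1:
        windows = padded[:, :, None, None, :].transpose(0, 1, 4, 2, 3)
    else:
        windows = np.lib.stride_tricks.sliding_window_view(
            padded, (S, S), axis=(0, 1))          # (H, W, B, S, S)
    patches = windows[lines, samples]              # (N, B, S, S)
    patches = np.ascontiguousarray(
        patches.transpose(0, 2, 3, 1), dtype=np.float32)  # (N, S, S, B)
    y = labels.codes[lines, samples].astype(np.int64)
    coords = np.stack([lines, samples], axis=1)
    return PatchDataset(patches, y, coords, S, b)


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test fractions (summing to 1) plus shuffle seed."""

    train: float = 0.7
    validation: float = 0.0
    test: float = 0.3
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        for f in (self.train, self.validation, self.test):
            if not 0.0 <= f <= 1.0:
                raise SizeError("split fractions must lie in [0, 1]")
        if abs(self.train + self.validation + self.test - 1.0) > 1e-12:
            raise SizeError("split fractions must sum to 1")


def stratified_split(ds: PatchDataset, spec: SplitSpec
                     ) -> tuple[PatchDataset, PatchDataset, PatchDataset]:
    """Deterministic per-class split by seeded shuffle.

    Per class, floor(train * n) samples go to train and floor(validation * n)
    to validation; the remainder is the test set.  Sample order inside a
    class is canonicalized by (line, sample) before shuffling, so the split
    depends only on the seed and the sample identities, not on input order.
    """
    rng = np.random.default_rng(spec.seed)
    tr_idx, va_idx, te_idx = [], [], []
    classes = np.unique(ds.labels)
    for c in classes:
        idx = np.nonzero(ds.labels == c)[0]
        order = np.lexsort((ds.coords[idx, 1], ds.coords[idx, 0]))
        idx = idx[order]
        perm = idx[rng.permutation(idx.size)] if spec.stratified else idx
        n = idx.size
        n_tr = int(np.floor(spec.train * n))
        n_va = int(np.floor(spec.validation * n))
        if spec.train > 0 and n_tr == 0:
            warnings.warn(f"class {c}: training fraction {spec.train} leaves "
                          "no training samples", stacklevel=2)
        tr_idx.append(perm[:n_tr])
        va_idx.append(perm[n_tr:n_tr + n_va])
        te_idx.append(perm[n_tr + n_va:])
    cat = lambda parts: np.sort(np.concatenate(parts)) if parts else np.array([], int)
    return (ds.subset(cat(tr_idx)), ds.subset(cat(va_idx)), ds.subset(cat(te_idx)))


@dataclass
class Standardizer:
    """Per-band standardization fitted on the training split only.

    Bands with zero spread are centered but not divided.  A fitted flag
    guards against accidentally re-standardizing already transformed data.
    """

    means: np.ndarray | None = None   # (B,)
    sds: np.ndarray | None = None     # (B,), zeros kept as recorded

    @property
    def fitted(self) -> bool:
        return self.means is not None

    def fit(self, train: PatchDataset) -> "Standardizer":
        if len(train) == 0:
            raise EmptyDatasetError("cannot fit a standardizer on an empty split")
        flat = train.patches.reshape(-1, train.B).astype(np.float64)
        self.means = flat.mean(axis=0)
        self.sds = flat.std(axis=0)
        return self

    def apply(self, ds: PatchDataset) -> PatchDataset:
        if not self.fitted:
            raise RuntimeError("standardizer not fitted")
        if ds.standardized:
            raise RuntimeError("dataset is already standardized")
        denom = np.where(self.sds == 0, 1.0, self.sds)
        patches = ((ds.patches - self.means) / denom).astype(np.float32)
        return PatchDataset(patches, ds.labels.copy(), ds.coords.copy(),
                            ds.S, ds.B, standardized=True)


def standardize(train: PatchDataset, *others: PatchDataset
                ) -> tuple[list[PatchDataset], Standardizer]:
    """Fit per-band scaling on ``train`` and apply it to train and all others."""
    scaler = Standardizer().fit(train)
    out = [scaler.apply(train)] + [scaler.apply(o) for o in others]
    return out, scaler
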