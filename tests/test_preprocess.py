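"""PCA reduction, patch extraction, splitting and standardization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hsiclass as h
from hsiclass.exceptions import DegeneracyError, EmptyDatasetError, SizeError

WL8 = np.linspace(400, 1000, 8)


def rank2_cube(seed=0):
    """Cube whose pixel spectra span an exactly 2-D affine subspace."""
    rng = np.random.default_rng(seed)
    v1 = rng.normal(size=8)
    v2 = rng.normal(size=8)
    a = rng.normal(size=(10, 12))
    b = rng.normal(size=(10, 12))
    values = 0.5 + a[..., None] * v1 + b[..., None] * v2
    return h.HyperspectralCube(values, WL8)


def test_pca_rank2_retains_two_components():
    """Brute-force eigendecomposition confirms exactly two nonzero modes."""
    cube = rank2_cube()
    X = cube.values.reshape(-1, 8)
    eigvals = np.linalg.eigvalsh(np.cov(X.T))[::-1]
    assert (eigvals > 1e-10 * eigvals[0]).sum() == 2  # oracle
    scores, model = h.pca_reduce(cube, 0.98)
    assert model.B == 2
    assert scores.shape == (10, 12, 2)


def test_pca_constant_cube_degenerate():
    cube = h.HyperspectralCube(np.full((4, 4, 8), 0.3), WL8)
    with pytest.raises(DegeneracyError):
        h.pca_reduce(cube, 0.98)


def test_pca_component_count_monotone_in_threshold(small_cube):
    thresholds = [0.5, 0.8, 0.9, 0.98, 0.999, 1.0]
    bs = [h.pca_reduce(small_cube, t)[1].B for t in thresholds]
    assert all(b1 <= b2 for b1, b2 in zip(bs, bs[1:]))


def test_pca_orthonormal_loadings_and_ratios(small_cube):
    _, model = h.pca_reduce(small_cube, 0.98)
    gram = model.loadings.T @ model.loadings
    np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-8)
    assert abs(model.explained_variance_ratio.sum() - 1.0) < 1e-8
    assert np.all(np.diff(model.explained_variance_ratio) <= 1e-12)
    # sign convention: dominant element of each column is positive
    dom = np.abs(model.loadings).argmax(axis=0)
    assert np.all(model.loadings[dom, np.arange(model.loadings.shape[1])] > 0)


def test_pca_reconstruction_error_non_increasing(small_cube):
    _, model = h.pca_reduce(small_cube, 1.0)
    X = small_cube.values
    errs = []
    for b in range(1, model.loadings.shape[1] + 1):
        scores = model.transform(small_cube, b)
        recon = model.inverse_transform(scores)
        errs.append(np.linalg.norm(recon - X) / np.linalg.norm(X))
    assert all(e1 >= e2 - 1e-12 for e1, e2 in zip(errs, errs[1:]))
    assert errs[-1] <= 1e-6


def test_extract_patches_centers_and_conservation(rng):
    scores = rng.normal(size=(5, 5, 3))
    labels = h.LabelMap(rng.integers(1, 4, (5, 5)).astype(np.int32))
    ds = h.extract_patches(scores, labels, 3)
    assert len(ds) == 25
    for i in range(len(ds)):
        line, sample = ds.coords[i]
        np.testing.assert_array_equal(ds.patches[i, 1, 1],
                                      scores[line, sample].astype(np.float32))
        assert ds.labels[i] == labels.codes[line, sample]
    # label conservation: patch histogram == nonzero label histogram
    ids, counts = np.unique(labels.codes[labels.codes > 0], return_counts=True)
    assert ds.label_histogram() == {int(i): int(c) for i, c in zip(ids, counts)}


def test_extract_patches_reflect_padding(rng):
    """Corner patch rows/cols reflect: index -1 maps to index 1."""
    scores = rng.normal(size=(4, 4, 2))
    codes = np.zeros((4, 4), dtype=np.int32)
    codes[0, 0] = 1
    ds = h.extract_patches(scores, h.LabelMap(codes), 3, pad_mode="reflect")
    patch = ds.patches[0]
    np.testing.assert_array_equal(patch[0, 0], scores[1, 1].astype(np.float32))
    np.testing.assert_array_equal(patch[0, 1], scores[1, 0].astype(np.float32))
    np.testing.assert_array_equal(patch[1, 0], scores[0, 1].astype(np.float32))


def test_extract_patches_default_patch_size(rng):
    """The working 9 x 9 neighborhood applies everywhere on a 20 x 20 scene."""
    scores = rng.normal(size=(20, 20, 4))
    labels = h.LabelMap(np.ones((20, 20), dtype=np.int32))
    ds = h.extract_patches(scores, labels, 9)
    assert ds.patches.shape == (400, 9, 9, 4)


def test_extract_patches_errors(rng):
    scores = rng.normal(size=(4, 4, 2))
    with pytest.raises(SizeError):
        h.extract_patches(scores, h.LabelMap(np.ones((4, 4), np.int32)), 4)
    with pytest.raises(EmptyDatasetError):
        h.extract_patches(scores, h.LabelMap(np.zeros((4, 4), np.int32)), 3)


def _dataset_of(counts, S=1, B=2, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.concatenate([np.full(n, c + 1) for c, n in enumerate(counts)])
    n = labels.size
    coords = np.stack([np.arange(n), np.arange(n)], axis=1)
    return h.PatchDataset(rng.normal(size=(n, S, S, B)).astype(np.float32),
                          labels.astype(np.int64), coords, S, B)


def test_split_floor_rule_small():
    ds = _dataset_of([10, 10])
    tr, va, te = h.stratified_split(ds, h.SplitSpec(0.7, 0.0, 0.3, seed=0))
    assert tr.label_histogram() == {1: 7, 2: 7}
    assert te.label_histogram() == {1: 3, 2: 3}
    assert len(va) == 0


def test_split_floor_rule_study_counts():
    """A 7,224-sample class yields 5,056 training samples at 70% (floor)."""
    ds = _dataset_of([7224])
    tr, _, te = h.stratified_split(ds, h.SplitSpec(0.7, 0.0, 0.3, seed=3))
    assert len(tr) == 5056
    assert len(te) == 7224 - 5056


def test_split_partition_and_determinism():
    ds = _dataset_of([40, 25, 35])
    spec = h.SplitSpec(0.6, 0.1, 0.3, seed=11)
    tr1, va1, te1 = h.stratified_split(ds, spec)
    tr2, va2, te2 = h.stratified_split(ds, spec)
    for a, b in ((tr1, tr2), (va1, va2), (te1, te2)):
        np.testing.assert_array_equal(a.coords, b.coords)
    # exact partition
    all_coords = np.concatenate([tr1.coords, va1.coords, te1.coords])
    assert len(all_coords) == len(ds)
    assert len(np.unique(all_coords[:, 0])) == len(ds)
    # different seed: same counts, different membership
    tr3, _, _ = h.stratified_split(ds, h.SplitSpec(0.6, 0.1, 0.3, seed=12))
    assert tr3.label_histogram() == tr1.label_histogram()
    assert not np.array_equal(np.sort(tr3.coords[:, 0]),
                              np.sort(tr1.coords[:, 0]))


def test_split_invariant_to_input_order():
    """Membership depends on sample identity + seed, not array order."""
    ds = _dataset_of([40, 25, 35], seed=5)
    perm = np.random.default_rng(99).permutation(len(ds))
    shuffled = ds.subset(perm)
    spec = h.SplitSpec(0.7, 0.0, 0.3, seed=2)
    tr1, _, _ = h.stratified_split(ds, spec)
    tr2, _, _ = h.stratified_split(shuffled, spec)
    assert set(map(tuple, tr1.coords)) == set(map(tuple, tr2.coords))


@settings(deadline=None, max_examples=25, derandomize=True)
@given(n1=st.integers(2, 60), n2=st.integers(2, 60),
       frac=st.sampled_from([0.2, 0.5, 0.7, 0.8]), seed=st.integers(0, 2**20))
def test_split_floor_property(n1, n2, frac, seed):
    ds = _dataset_of([n1, n2], seed=1)
    tr, _, te = h.stratified_split(
        ds, h.SplitSpec(frac, 0.0, round(1 - frac, 12), seed=seed))
    hist = tr.label_histogram()
    assert hist.get(1, 0) == int(np.floor(frac * n1))
    assert hist.get(2, 0) == int(np.floor(frac * n2))
    assert len(tr) + len(te) == n1 + n2


def test_standardize_train_statistics_applied_to_test():
    tr = _dataset_of([50])
    te = _dataset_of([20], seed=9)
    (tr_s, te_s), scaler = h.standardize(tr, te)
    flat = tr_s.patches.reshape(-1, tr_s.B)
    np.testing.assert_allclose(flat.mean(axis=0), 0.0, atol=1e-5)
    np.testing.assert_allclose(flat.std(axis=0), 1.0, atol=1e-5)
    np.testing.assert_allclose(
        te_s.patches, (te.patches - scaler.means) / scaler.sds, atol=1e-5)


def test_standardize_constant_band_and_refit_guard():
    ds = _dataset_of([30])
    ds.patches[..., 1] = 4.0
    (ds_s,), scaler = h.standardize(ds)
    np.testing.assert_allclose(ds_s.patches[..., 1], 0.0, atol=1e-6)
    with pytest.raises(RuntimeError, match="already standardized"):
        scaler.apply(ds_s)
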