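import numpy as np
import pytest
from scipy import stats

from spadspec import (
    DataError,
    DiffSpectraSet,
    IndexFeature,
    IndexMaskError,
    best_pairs,
    compute_index,
    correlation_map,
)

KIND_FORMULAS = {
    "FDI": lambda a, b: a - b,
    "FRI": lambda a, b: a / b,
    "FNDI": lambda a, b: (a - b) / (a + b),
}


def _dset(D, alpha=0.3, wl=None, trim=0):
    D = np.asarray(D, dtype=float)
    wl = np.arange(D.shape[1], dtype=float) if wl is None else wl
    return DiffSpectraSet(alpha=alpha, wavelengths_nm=wl, diff_reflectance=D, edge_trim=trim)


def test_index_arithmetic():
    d = _dset([[0.5, 0.2]])
    for kind, expect in [("FDI", 0.3), ("FRI", 2.5), ("FNDI", 0.3 / 0.7)]:
        f = IndexFeature(kind, 0.3, 0.0, 1.0)
        assert compute_index(d, f)[0] == pytest.approx(expect, abs=1e-12)


def test_fndi_masks_zero_denominator_sample():
    d = _dset([[0.4, -0.4], [0.5, 0.2], [0.3, 0.1], [0.2, 0.1], [0.6, 0.2]])
    v = compute_index(d, IndexFeature("FNDI", 0.3, 0.0, 1.0))
    assert np.isnan(v[0]) and np.all(np.isfinite(v[1:]))


def test_feature_invalid_when_over_20pct_masked():
    D = np.array([[0.4, -0.4], [0.5, -0.5], [0.3, 0.1], [0.2, 0.1]])
    with pytest.raises(IndexMaskError, match="masked"):
        compute_index(_dset(D), IndexFeature("FNDI", 0.3, 0.0, 1.0))


def test_fndi_bounded_on_positive_rows(rng):
    a, b = rng.uniform(0.01, 1.0, size=(2, 1000))
    v = KIND_FORMULAS["FNDI"](a, b)
    assert np.all((v > -1) & (v < 1))
    d = _dset(np.column_stack([a, b]))
    out = compute_index(d, IndexFeature("FNDI", 0.3, 0.0, 1.0))
    assert np.all((out > -1) & (out < 1))


def test_same_band_pair_rejected():
    with pytest.raises(ValueError, match="differ"):
        IndexFeature("FDI", 0.3, 500.0, 500.0)


@pytest.mark.parametrize("kind", ["FDI", "FRI", "FNDI"])
def test_map_matches_naive_loop_oracle(kind, rng):
    """Vectorized maps against a per-pair Pearson loop; the load-bearing check."""
    D = rng.normal(size=(15, 10)) + 2.0
    y = rng.normal(size=15)
    d = _dset(D, wl=np.arange(10.0))
    cmap = correlation_map(d, y, kind, resample_step_nm=1.0)
    for i in range(10):
        for j in range(10):
            if i == j:
                assert np.isnan(cmap.r[i, j])
                continue
            v = KIND_FORMULAS[kind](D[:, i], D[:, j])
            r_oracle = stats.pearsonr(v, y)[0]
            assert abs(cmap.r[i, j] - r_oracle) < 1e-10


def test_map_shape_and_nan_diagonal(rng):
    D = rng.normal(size=(12, 60))
    d = _dset(D, wl=np.linspace(400, 1000, 60))
    cmap = correlation_map(d, rng.normal(size=12), "FDI", resample_step_nm=20.0)
    B = cmap.band_grid_nm.size
    assert cmap.r.shape == (B, B)
    assert np.all(np.isnan(np.diag(cmap.r)))
    finite = cmap.r[np.isfinite(cmap.r)]
    assert np.all((finite >= -1) & (finite <= 1))


@pytest.mark.parametrize("kind", ["FDI", "FNDI"])
def test_antisymmetry_under_band_swap(kind, rng):
    D = rng.normal(size=(20, 8)) + 3.0
    d = _dset(D, wl=np.arange(8.0))
    cmap = correlation_map(d, rng.normal(size=20), kind, resample_step_nm=1.0)
    off = ~np.eye(8, dtype=bool)
    np.testing.assert_allclose(cmap.r[off], -cmap.r.T[off], atol=1e-12)


def test_fri_values_reciprocal_under_swap(rng):
    a, b = rng.uniform(0.1, 1.0, size=(2, 50))
    np.testing.assert_allclose(
        KIND_FORMULAS["FRI"](a, b), 1.0 / KIND_FORMULAS["FRI"](b, a), atol=1e-12
    )


def test_perfect_pair_scores_r_one(rng):
    D = rng.normal(size=(20, 5)) + 2.0
    spad = D[:, 1] - D[:, 3]  # SPAD equals the FDI of pair (1, 3)
    d = _dset(D, wl=np.arange(5.0))
    cmap = correlation_map(d, spad, "FDI", resample_step_nm=1.0)
    assert cmap.r[1, 3] == pytest.approx(1.0, abs=1e-12)
    top, r = best_pairs(cmap, 1)[0]
    assert {top.band_i_nm, top.band_j_nm} == {1.0, 3.0}
    assert abs(r) == pytest.approx(1.0, abs=1e-12)


def test_best_pairs_match_loop_oracle(rng):
    D = rng.normal(size=(15, 10)) + 2.0
    y = rng.normal(size=15)
    d = _dset(D, wl=np.arange(10.0))
    cmap = correlation_map(d, y, "FRI", resample_step_nm=1.0)
    got = [(f.band_i_nm, f.band_j_nm) for f, _ in best_pairs(cmap, 3)]
    cells = []
    for i in range(10):
        for j in range(10):
            if i != j and np.isfinite(cmap.r[i, j]):
                cells.append((-abs(cmap.r[i, j]), float(i), float(j)))
    cells.sort()
    assert got == [(i, j) for _, i, j in cells[:3]]


def test_best_pairs_ranking_and_orientation(rng):
    D = rng.normal(size=(25, 8)) + 2.0
    d = _dset(D, wl=np.arange(8.0))
    cmap = correlation_map(d, rng.normal(size=25), "FNDI", resample_step_nm=1.0)
    ranked = best_pairs(cmap, 5)
    rs = [abs(r) for _, r in ranked]
    assert rs == sorted(rs, reverse=True)
    # antisymmetric kind reports one orientation per unordered pair, r >= 0
    assert all(r >= 0 for _, r in ranked)
    pairs = [frozenset((f.band_i_nm, f.band_j_nm)) for f, _ in ranked]
    assert len(set(pairs)) == len(pairs)


def test_single_finite_cell_and_all_nan_map():
    r = np.full((3, 3), np.nan)
    r[0, 2] = -0.5
    cmap_single = _cmap_with(r)
    f, rv = best_pairs(cmap_single, 1)[0]
    assert (f.band_i_nm, f.band_j_nm, rv) == (0.0, 2.0, -0.5)
    with pytest.raises(DataError, match="all-NaN"):
        best_pairs(_cmap_with(np.full((3, 3), np.nan)), 1)


def _cmap_with(r):
    from spadspec import CorrelationMap

    return CorrelationMap(
        kind="FRI", alpha=0.2, band_grid_nm=np.arange(3.0), r=r, n_samples=10
    )


def test_map_requires_three_samples():
    d = _dset(np.array([[0.1, 0.2], [0.2, 0.3]]))
    with pytest.raises(DataError, match="3 samples"):
        correlation_map(d, np.array([1.0, 2.0]), "FDI", resample_step_nm=1.0)
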