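"""Two-band fractional-order differential spectral indices and their maps.

Three index families are built from a pair of fractionally differentiated
reflectance bands R_i^a, R_j^a (i != j):

* FDI, the difference index  R_i^a - R_j^a
* FRI, the ratio index       R_i^a / R_j^a
* FNDI, the normalized-difference index (R_i^a - R_j^a)/(R_i^a + R_j^a)

For each family and each order the exhaustive band-pair grid of Pearson
correlations with SPAD forms a :class:`CorrelationMap`; the strongest cells
become candidate model features.  Differentiated spectra can be negative,
so FRI/FNDI singularities (zero denominator) are handled by masking the
offending sample rather than jittering the value — jitter would corrupt the
correlation invisibly.  A feature with more than 20 % of samples masked is
rejected outright.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import DataError
from .fracdiff import DiffSpectraSet

__all__ = [
    "KINDS",
    "IndexFeature",
    "CorrelationMap",
    "IndexMaskError",
    "compute_index",
    "correlation_map",
    "best_pairs",
]

KINDS = ("FDI", "FRI", "FNDI")

#: features with more than this fraction of masked samples are invalid
MAX_MASKED_FRACTION = 0.20


class IndexMaskError(ValueError):
    """Too many samples masked by singular denominators for one feature."""


@dataclass(frozen=True)
class IndexFeature:
    """One candidate two-band predictor: (kind, order, band pair)."""

    kind: str
    alpha: float
    band_i_nm: float
    band_j_nm: float

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown index kind {self.kind!r}")
        if self.band_i_nm == self.band_j_nm:
            raise ValueError("band_i_nm must differ from band_j_nm")


@dataclass
class CorrelationMap:
    """Band-pair grid of Pearson r against SPAD for one (kind, order).

    ``r[i, j]`` correlates index(band i, band j) with SPAD; the diagonal is
    NaN, as are pairs invalidated by the masking policy.
    """

    kind: str
    alpha: float
    band_grid_nm: np.ndarray
    r: np.ndarray
    n_samples: int


def _nearest_band(wl: np.ndarray, target: float) -> int:
    return int(np.argmin(np.abs(wl - target)))


def _index_values(kind: str, Ri: np.ndarray, Rj: np.ndarray) -> np.ndarray:
    """Elementwise index with NaN at singular samples."""
    if kind == "FDI":
        return Ri - Rj
    with np.errstate(divide="ignore", invalid="ignore"):
        if kind == "FRI":
            v = Ri / Rj
        elif kind == "FNDI":
            v = (Ri - Rj) / (Ri + Rj)
        else:
            raise ValueError(f"unknown index kind {kind!r}")
    v = np.where(np.isfinite(v), v, np.nan)
    return v


def compute_index(d: DiffSpectraSet, feat: IndexFeature) -> np.ndarray:
    """Index values per sample; singular samples are NaN ("masked").

    Raises :class:`IndexMaskError` when more than 20 % of samples are
    masked — such a feature is unusable as a predictor.
    """
    if feat.alpha != d.alpha:
        raise ValueError(f"feature order {feat.alpha} != spectra order {d.alpha}")
    wl = d.wavelengths_nm
    i = _nearest_band(wl, feat.band_i_nm)
    j = _nearest_band(wl, feat.band_j_nm)
    if abs(wl[i] - feat.band_i_nm) > 1.0 or abs(wl[j] - feat.band_j_nm) > 1.0:
        raise DataError("requested band more than 1 nm from the spectral grid")
    v = _index_values(feat.kind, d.diff_reflectance[:, i], d.diff_reflectance[:, j])
    frac = np.mean(~np.isfinite(v))
    if frac > MAX_MASKED_FRACTION:
        raise IndexMaskError(
            f"{feat.kind}({feat.band_i_nm}, {feat.band_j_nm}) at order {feat.alpha}: "
            f"{frac:.0%} of samples masked (> {MAX_MASKED_FRACTION:.0%})"
        )
    return v


def resample_grid(d: DiffSpectraSet, step_nm: float) -> np.ndarray:
    """Indices of native bands nearest to a coarser regular grid.

    Edge-trimmed bands are excluded.  Requires ``step_nm`` at least the
    native spacing.
    """
    wl = d.wavelengths_nm
    native = float(np.min(np.diff(wl)))
    if step_nm < native:
        raise ValueError(f"resample step {step_nm} below native spacing {native:.4g}")
    lo = wl[d.edge_trim]
    targets = np.arange(lo, wl[-1] + step_nm * 0.5, step_nm)
    idx = np.searchsorted(wl, targets)
    idx = np.clip(idx, d.edge_trim + 1, wl.size - 1)
    left = np.abs(wl[idx - 1] - targets) <= np.abs(wl[idx] - targets)
    idx = np.where((idx - 1 >= d.edge_trim) & left, idx - 1, idx)
    return np.unique(idx)


def correlation_map(
    d: DiffSpectraSet,
    spad: np.ndarray,
    kind: str,
    resample_step_nm: float = 2.0,
    _block: int = 48,
) -> CorrelationMap:
    """Pearson r against SPAD for every ordered band pair of one index kind.

    Bands are taken on a regular grid of ``resample_step_nm`` (nearest
    native band).  Masked samples are dropped pair-wise; a pair is NaN when
    fewer than 3 samples survive, more than 20 % are masked, or the index
    is constant.
    """
    y = np.asarray(spad, dtype=float)
    if y.size < 3:
        raise DataError("correlation_map: need at least 3 samples")
    if kind not in KINDS:
        raise ValueError(f"unknown index kind {kind!r}")
    keep = resample_grid(d, resample_step_nm)
    D = d.diff_reflectance[:, keep]
    n, B = D.shape
    r = np.full((B, B), np.nan)
    min_used = max(3, int(np.ceil(n * (1.0 - MAX_MASKED_FRACTION))))
    for j0 in range(0, B, _block):
        j1 = min(j0 + _block, B)
        V = _index_values(kind, D[:, :, None], D[:, None, j0:j1])  # n x B x w
        M = np.isfinite(V)
        nu = M.sum(axis=0)
        Vz = np.where(M, V, 0.0)
        yc = y[:, None, None]
        s1 = Vz.sum(axis=0)
        s2 = (Vz * Vz).sum(axis=0)
        sy = (M * yc).sum(axis=0)
        syy = (M * yc * yc).sum(axis=0)
        sxy = (Vz * yc).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            num = nu * sxy - s1 * sy
            den = np.sqrt((nu * s2 - s1 * s1) * (nu * syy - sy * sy))
            blk = num / den
        blk[nu < min_used] = np.nan
        r[:, j0:j1] = blk
    np.fill_diagonal(r, np.nan)
    r = np.clip(r, -1.0, 1.0)
    return CorrelationMap(
        kind=kind, alpha=d.alpha, band_grid_nm=d.wavelengths_nm[keep], r=r, n_samples=n
    )


def best_pairs(cmap: CorrelationMap, top_k: int) -> list[tuple[IndexFeature, float]]:
    """Top band pairs of one map, ranked by |r| descending.

    FDI and FNDI maps are antisymmetric under (i, j) swap, so only one
    orientation per unordered pair is reported — the one with r >= 0
    (band_i < band_j on the r == 0 tie).  FRI values at swapped pairs are
    reciprocals, not negations, so both orientations remain candidates.
    Remaining ties break on (smaller band_i_nm, smaller band_j_nm).
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    R = cmap.r
    finite = np.argwhere(np.isfinite(R))
    if finite.size == 0:
        raise DataError("best_pairs: all-NaN correlation map")
    wl = cmap.band_grid_nm
    rows = []
    for i, j in finite:
        rv = R[i, j]
        if cmap.kind in ("FDI", "FNDI"):
            if rv < 0.0 or (rv == 0.0 and i > j):
                continue  # the swapped orientation represents this pair
        rows.append((-abs(rv), wl[i], wl[j], float(rv), int(i), int(j)))
    rows.sort()
    out = []
    for _, wi, wj, rv, i, j in rows[:top_k]:
        out.append(
            (IndexFeature(cmap.kind, cmap.alpha, float(wi), float(wj)), rv)
        )
    return out
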