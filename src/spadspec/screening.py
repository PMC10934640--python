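"""Pearson screening of differentiated bands and joint feature ranking.

For every differentiation order the band most correlated with SPAD is
extracted (signed r preserved, ranking by |r|), with two-sided significance
stars: ``**`` for p < 0.01, ``*`` for p < 0.05.  Single-band and two-band
index features are then merged into one list ordered by correlation
strength — the order in which they are fed to the regression models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import DataError
from .fracdiff import DiffSpectraSet
from .indices import IndexFeature

__all__ = [
    "SingleBandFeature",
    "ScreeningReport",
    "pearson_with_sig",
    "significance_star",
    "screen_orders",
    "rank_features",
]


@dataclass(frozen=True)
class SingleBandFeature:
    """One differentiated reflectance band used directly as a predictor."""

    alpha: float
    band_nm: float


def significance_star(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def pearson_with_sig(x: np.ndarray, y: np.ndarray) -> tuple[float, float, str]:
    """Pearson r with a two-sided t-test p-value and significance star."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DataError("pearson_with_sig: need equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("pearson_with_sig: constant input has undefined correlation")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), significance_star(p)


@dataclass
class ScreeningReport:
    """Per-order best-band table plus the full per-band correlations."""

    per_order: pd.DataFrame  # columns: alpha, wavelength_nm, r, p, star
    features: list[SingleBandFeature]

    def ranked(self) -> pd.DataFrame:
        return self.per_order.reindex(
            self.per_order["r"].abs().sort_values(ascending=False, kind="stable").index
        )


def _pearson_columns(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of every column of X against y (NaN for constant columns)."""
    n = y.size
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    num = yc @ Xc
    den = np.sqrt((Xc * Xc).sum(axis=0) * (yc @ yc))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den > 0, num / den, np.nan)


def screen_orders(diffs: list[DiffSpectraSet], spad: np.ndarray) -> ScreeningReport:
    """Best band per differentiation order (edge-trimmed bands excluded).

    Ties on |r| resolve to the smallest wavelength.  The report preserves
    the signed correlation; downstream ranking uses |r|.
    """
    if not diffs:
        raise DataError("screen_orders: need at least one differentiated set")
    y = np.asarray(spad, dtype=float)
    rows = []
    feats = []
    n = y.size
    for d in diffs:
        lo = d.edge_trim
        r = _pearson_columns(d.diff_reflectance[:, lo:], y)
        if not np.any(np.isfinite(r)):
            raise DataError(f"screen_orders: no usable band at order {d.alpha}")
        k = int(np.nanargmax(np.abs(r)))
        rv = float(r[k])
        # two-sided t test on the winning band
        t = rv * np.sqrt((n - 2) / max(1e-300, 1.0 - rv * rv))
        p = float(2 * stats.t.sf(abs(t), n - 2))
        wl = float(d.wavelengths_nm[lo + k])
        rows.append(
            {"alpha": d.alpha, "wavelength_nm": wl, "r": rv, "p": p,
             "star": significance_star(p)}
        )
        feats.append(SingleBandFeature(alpha=d.alpha, band_nm=wl))
    report = ScreeningReport(per_order=pd.DataFrame(rows), features=feats)
    return report


def rank_features(
    report: ScreeningReport | None,
    index_pairs: list[tuple[IndexFeature, float]] | None,
    k: int,
):
    """Merge single-band and index features into one |r|-ranked list.

    Returns ``[(feature, r), ...]`` of length ``k``; features may be
    :class:`SingleBandFeature` or :class:`IndexFeature`.  Deterministic
    tie-break: smaller first band, then smaller second band, then order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    pool: list[tuple[tuple, object, float]] = []
    if report is not None:
        for f, row in zip(report.features, report.per_order.itertuples()):
            key = (-abs(row.r), f.band_nm, -1.0, f.alpha, 0)
            pool.append((key, f, float(row.r)))
    if index_pairs:
        for f, r in index_pairs:
            key = (-abs(r), f.band_i_nm, f.band_j_nm, f.alpha, 1)
            pool.append((key, f, float(r)))
    if k > len(pool):
        raise ValueError(f"k={k} exceeds the {len(pool)} available features")
    pool.sort(key=lambda t: t[0])
    return [(f, r) for _, f, r in pool[:k]]
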