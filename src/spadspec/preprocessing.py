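"""Scatter correction and wavelength selection.

Two standard chemometric steps sit in front of the screening stages:

* **SNV** (standard normal variate): each spectrum is centred and scaled to
  unit sample standard deviation, removing multiplicative scatter
  differences between samples.
* **SPA** (successive projections algorithm): forward selection of
  minimally collinear wavelengths.  Starting from each candidate band, the
  chain repeatedly appends the band whose column has the largest norm after
  projection onto the orthogonal complement of the span of the bands
  already chosen.  Every chain prefix within the requested size range is
  scored by cross-validated RMSE of an ordinary least-squares fit, and the
  subset size is fixed where that RMSE is minimal (first minimum on ties).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold

from .dataset import DataError

__all__ = ["SPAResult", "snv", "snv_matrix", "spa_select"]


class SelectionError(RuntimeError):
    """SPA could not build a chain of the requested minimum size."""


def snv(row: np.ndarray) -> np.ndarray:
    """Standard normal variate transform of one spectrum.

    Output has mean 0 and sample standard deviation 1 (n-1 denominator).
    """
    x = np.asarray(row, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise DataError("snv: need a 1-D row of length >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DataError("snv: constant row has no dispersion to normalize")
    return (x - x.mean()) / sd


def snv_matrix(X: np.ndarray) -> np.ndarray:
    """Row-wise SNV of a sample-by-band matrix."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        i = int(np.argwhere(sd[:, 0] == 0)[0, 0])
        raise DataError(f"snv: constant spectrum in row {i}")
    return (X - mu) / sd


@dataclass
class SPAResult:
    """Outcome of SPA band selection with RMSE-minimum subset sizing."""

    selected_band_indices: list[int]
    selected_wavelengths_nm: list[float]
    rmse_by_subset_size: np.ndarray  # aligned with `sizes`
    sizes: np.ndarray
    chosen_size: int
    folds: int = 5
    seed: int = 0
    start_band: int = field(default=0)


def _chain(Xn: np.ndarray, start: int, size_max: int, tol: float = 1e-12) -> list[int]:
    """SPA projection chain from one starting band (may stop early)."""
    P = Xn.copy()
    chain = [start]
    for _ in range(size_max - 1):
        v = P[:, chain[-1]]
        vv = v @ v
        if vv < tol:
            break
        P = P - np.outer(v, v @ P) / vv
        norms = np.einsum("ij,ij->j", P, P)
        norms[chain] = -1.0
        j = int(np.argmax(norms))
        if norms[j] < tol:
            break
        chain.append(j)
    return chain


def spa_select(
    X: np.ndarray,
    y: np.ndarray,
    size_min: int = 5,
    size_max: int = 40,
    eval_folds: int = 5,
    seed: int = 0,
    wavelengths_nm: np.ndarray | None = None,
) -> SPAResult:
    """Successive projections algorithm with CV-RMSE subset sizing.

    Each of the ``n_bands`` starting bands spawns a projection chain of up
    to ``size_max`` bands; every prefix of size in ``[size_min, size_max]``
    is scored by k-fold cross-validated RMSE of OLS (with intercept) on the
    selected columns, and the globally RMSE-minimal prefix wins.  Fold
    assignment is a seeded shuffle, so the whole selection is reproducible
    from ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, b = X.shape
    if not 1 <= size_min <= size_max < b:
        raise ValueError(f"need 1 <= size_min <= size_max < n_bands, got {size_min}..{size_max} of {b}")
    if n <= eval_folds:
        raise ValueError(f"need n_samples > eval_folds, got {n} <= {eval_folds}")
    # unit-norm columns: projections compare direction, not scale
    norms = np.linalg.norm(X, axis=0)
    if np.any(norms == 0):
        raise SelectionError("zero-variance band present; cannot project")
    Xn = X / norms

    folds = list(KFold(n_splits=eval_folds, shuffle=True, random_state=seed).split(X))
    sizes = np.arange(size_min, size_max + 1)
    best_by_size = np.full(sizes.size, np.inf)
    best_chain_by_size: list[tuple[list[int], int] | None] = [None] * sizes.size
    for start in range(b):
        chain = _chain(Xn, start, size_max)
        if len(chain) < size_min:
            continue
        rmses = _cv_rmse_prefixes(X, y, chain, sizes, folds)
        for si, rm in enumerate(rmses):
            if np.isfinite(rm) and rm < best_by_size[si]:
                best_by_size[si] = rm
                best_chain_by_size[si] = (chain[: sizes[si]], start)
    if not np.any(np.isfinite(best_by_size)):
        raise SelectionError(
            f"no projection chain reached the minimum size {size_min} "
            "(degenerate/collinear design)"
        )
    si = int(np.argmin(best_by_size))  # first minimum on ties
    chosen, start_band = best_chain_by_size[si]
    wl = (
        [float(wavelengths_nm[i]) for i in chosen]
        if wavelengths_nm is not None
        else [float(i) for i in chosen]
    )
    return SPAResult(
        selected_band_indices=list(map(int, chosen)),
        selected_wavelengths_nm=wl,
        rmse_by_subset_size=best_by_size,
        sizes=sizes,
        chosen_size=len(chosen),
        folds=eval_folds,
        seed=seed,
        start_band=int(start_band),
    )


def _cv_rmse_prefixes(X, y, chain, sizes, folds) -> np.ndarray:
    """CV RMSE of OLS on each chain prefix whose size is in `sizes`."""
    usable = sizes[sizes <= len(chain)]
    sq = np.zeros(usable.size)
    cnt = 0
    for tr, te in folds:
        A = np.column_stack([np.ones(tr.size), X[np.ix_(tr, chain)]])
        At = np.column_stack([np.ones(te.size), X[np.ix_(te, chain)]])
        G = A.T @ A
        g = A.T @ y[tr]
        for si, k in enumerate(usable):
            m = k + 1  # intercept + k bands
            try:
                beta = np.linalg.solve(G[:m, :m], g[:m])
            except np.linalg.LinAlgError:
                sq[si] = np.inf
                continue
            r = At[:, :m] @ beta - y[te]
            sq[si] += r @ r
        cnt += te.size
    out = np.full(sizes.size, np.inf)
    out[: usable.size] = np.sqrt(sq / cnt)
    return out
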