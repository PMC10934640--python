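"""Spectral dataset container and its on-disk CSV dialect.

A :class:`SpectraSet` is the pipeline's universal currency: a sample-by-
wavelength reflectance matrix with an aligned SPAD vector.  The CSV dialect
is ``sample_id, spad, <wavelength headers in nm>`` with wavelengths printed
to two decimals, UTF-8, '.' decimal separator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ConfigError(ValueError):
    """A configuration field violates its contract."""


class DataError(ValueError):
    """Input data violate a structural contract (shape, monotonicity, NaN)."""


@dataclass
class SpectraSet:
    """Reflectance spectra with aligned SPAD readings.

    Parameters
    ----------
    wavelengths_nm : array of float
        Strictly increasing band centres in nanometres.
    reflectance : array, shape (n_samples, n_bands)
        Unitless reflectance, one row per sample.
    spad : array, shape (n_samples,)
        SPAD readings (unitless relative chlorophyll content).
    sample_ids : list of str
        One label per sample.
    """

    wavelengths_nm: np.ndarray
    reflectance: np.ndarray
    spad: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.reflectance = np.atleast_2d(np.asarray(self.reflectance, dtype=float))
        self.spad = np.asarray(self.spad, dtype=float)
        if self.wavelengths_nm.ndim != 1:
            raise DataError("wavelengths_nm must be one-dimensional")
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise DataError("wavelengths_nm must be strictly increasing")
        n, b = self.reflectance.shape
        if b != self.wavelengths_nm.size:
            raise DataError(
                f"reflectance has {b} columns but {self.wavelengths_nm.size} wavelengths given"
            )
        if self.spad.shape != (n,):
            raise DataError(f"spad has length {self.spad.size}, expected {n}")
        if not self.sample_ids:
            self.sample_ids = [f"S{i + 1:03d}" for i in range(n)]
        if len(self.sample_ids) != n:
            raise DataError("sample_ids length mismatch")

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[1]

    def to_csv(self, path) -> None:
        """Write the set in the pipeline's CSV dialect."""
        cols = [f"{w:.2f}" for w in self.wavelengths_nm]
        df = pd.DataFrame(self.reflectance, columns=cols)
        df.insert(0, "spad", self.spad)
        df.insert(0, "sample_id", self.sample_ids)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpectraSet":
        return read_spectra_csv(path)


def read_spectra_csv(path) -> SpectraSet:
    """Read a SpectraSet from the pipeline CSV dialect.

    The ``spad`` header is matched case-insensitively; all remaining
    numeric headers are parsed as wavelengths in nm and must be strictly
    increasing.  NaN or non-numeric cells are reported with their row and
    column.
    """
    df = pd.read_csv(path)
    spad_col = None
    id_col = None
    for c in df.columns:
        lc = str(c).strip().lower()
        if lc == "spad":
            spad_col = c
        elif lc == "sample_id":
            id_col = c
    if spad_col is None:
        raise DataError("missing 'spad' column (matched case-insensitively)")
    wl_cols = [c for c in df.columns if c not in (spad_col, id_col)]
    try:
        wl = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise DataError(f"non-numeric wavelength header: {exc}") from exc
    if np.any(np.diff(wl) <= 0):
        raise DataError("wavelength headers are not strictly increasing")
    sub = df[wl_cols].apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(~np.isfinite(sub.to_numpy()))
    if bad.size:
        i, j = bad[0]
        raise DataError(
            f"non-numeric or NaN reflectance cell at row {i}, column '{wl_cols[j]}'"
        )
    spad = pd.to_numeric(df[spad_col], errors="coerce").to_numpy(dtype=float)
    if not np.all(np.isfinite(spad)):
        i = int(np.argwhere(~np.isfinite(spad))[0])
        raise DataError(f"non-numeric or NaN SPAD cell at row {i}")
    ids = (
        [str(v) for v in df[id_col]]
        if id_col is not None
        else [f"S{i + 1:03d}" for i in range(len(df))]
    )
    return SpectraSet(
        wavelengths_nm=wl,
        reflectance=sub.to_numpy(dtype=float),
        spad=spad,
        sample_ids=ids,
    )
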