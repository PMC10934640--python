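"""Seeded synthetic canopy-reflectance generator with a known SPAD link.

The generator is phenomenological, not radiative-transfer: each spectrum is
a smooth visible baseline with SPAD-scaled Gaussian chlorophyll absorption
troughs near 450 nm (blue) and 670 nm (red), a logistic red-edge rise whose
inflection shifts with SPAD, and a NIR plateau around 0.4-0.5 that rises
with SPAD, plus additive Gaussian noise.  Larger SPAD means deeper blue/red
absorption (negative correlation in the troughs) and a brighter NIR plateau
(positive correlation) — the sign structure a chlorophyll-driven canopy
spectrum shows in the field.

The default configuration emulates the study conditions the pipeline is
built around: 46 samples, 400-1000 nm at 0.22 nm spacing (2728 bands),
canopy-leaf SPAD uniform on [26.8, 46.9].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import ConfigError, SpectraSet

__all__ = ["SynthConfig", "generate_dataset", "spectrum_model"]


@dataclass
class SynthConfig:
    """Configuration of one synthetic spectra-SPAD dataset.

    Defaults reproduce the reference conditions: n=46 samples on a
    400-1000 nm grid at 0.22 nm, SPAD uniform in [26.8, 46.9], reflectance
    noise sd 0.002.
    """

    n_samples: int = 46
    wl_start: float = 400.0
    wl_end: float = 1000.0
    wl_step: float = 0.22
    spad_min: float = 26.8
    spad_max: float = 46.9
    noise_sd: float = 0.002
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ConfigError(f"n_samples must be >= 1, got {self.n_samples}")
        if self.wl_step <= 0:
            raise ConfigError(f"wl_step must be > 0, got {self.wl_step}")
        if self.wl_end <= self.wl_start:
            raise ConfigError(
                f"wl_end ({self.wl_end}) must exceed wl_start ({self.wl_start})"
            )
        if not self.spad_min < self.spad_max:
            raise ConfigError(
                f"spad_min ({self.spad_min}) must be < spad_max ({self.spad_max})"
            )
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")


def _gauss(wl: np.ndarray, centre: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - centre) / width) ** 2)


def spectrum_model(wavelengths_nm: np.ndarray, spad) -> np.ndarray:
    """Noise-free reflectance for given SPAD value(s).

    Pure deterministic map SPAD -> spectrum; broadcasting over a vector of
    SPAD values returns one row per value.  SPAD enters through a scaled
    variable u = SPAD/50 so the shape parameters are stable across SPAD
    ranges:

    * blue trough at 450 nm, depth 0.02 + 0.055*u
    * red trough at 670 nm, depth 0.03 + 0.060*u
    * red-edge logistic inflection at 712 + 10*u nm (width 9 nm)
    * NIR plateau 0.40 + 0.10*u
    """
    wl = np.asarray(wavelengths_nm, dtype=float)
    u = np.asarray(spad, dtype=float)[..., None] / 50.0
    vis = 0.10 + 0.05 * _gauss(wl, 550.0, 40.0)  # green bump baseline
    vis = vis - (0.02 + 0.055 * u) * _gauss(wl, 450.0, 28.0)
    vis = vis - (0.03 + 0.060 * u) * _gauss(wl, 670.0, 32.0)
    nir = 0.40 + 0.10 * u
    edge = 1.0 / (1.0 + np.exp(-(wl - (712.0 + 10.0 * u)) / 9.0))
    out = vis * (1.0 - edge) + nir * edge
    return out if np.asarray(spad).ndim else out[0]


def generate_dataset(cfg: SynthConfig) -> SpectraSet:
    """Generate one seeded spectra-SPAD dataset.

    Deterministic for a fixed seed.  The seed is split into two independent
    child streams — one for the SPAD draws, one for the reflectance noise —
    so regenerating with a different noise level leaves the SPAD values
    untouched.
    """
    cfg.validate()
    wl = np.arange(cfg.wl_start, cfg.wl_end + cfg.wl_step * 0.5, cfg.wl_step)
    ss = np.random.SeedSequence(cfg.seed)
    rng_spad, rng_noise = (np.random.default_rng(c) for c in ss.spawn(2))
    spad = rng_spad.uniform(cfg.spad_min, cfg.spad_max, size=cfg.n_samples)
    refl = spectrum_model(wl, spad)
    if cfg.noise_sd > 0:
        refl = refl + rng_noise.normal(0.0, cfg.noise_sd, size=refl.shape)
    return SpectraSet(wavelengths_nm=wl, reflectance=refl, spad=spad)
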