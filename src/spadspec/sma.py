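"""Slime mold algorithm (SMA) for bound-constrained minimization.

Population metaheuristic modelling the oscillatory foraging of slime
molds.  Each iteration evaluates the population, ranks it by fitness
("smell index"), and moves every individual by one of three rules:

* with probability ``z``: uniform random restart in the box;
* with probability ``p = tanh|s(i) - DF|``: a step around the best
  position, ``x_b + v_b * (w * x_A - x_B)`` with ``v_b ~ U(-a, a)``,
  ``a = arctanh(1 - t/T)``, and rank-dependent weights
  ``w = 1 ± r * log10((bF - s)/(bF - wF) + 1)`` (+ for the better half);
* otherwise a contraction ``v_c * x`` with ``v_c ~ U(-b, b)``,
  ``b = 1 - t/T`` (envelope decaying linearly 1 -> 0).

``DF`` is the best fitness seen so far (elitist, so its trace is monotone
non-increasing); positions are repaired to the box by clipping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SMAConfig", "SMAResult", "sma_minimize"]

_EPS = 1e-12


@dataclass
class SMAConfig:
    """SMA hyperparameters and search box."""

    lb: np.ndarray
    ub: np.ndarray
    pop_size: int = 30
    max_iter: int = 500
    z: float = 0.03
    seed: int = 0

    def __post_init__(self):
        self.lb = np.atleast_1d(np.asarray(self.lb, dtype=float))
        self.ub = np.atleast_1d(np.asarray(self.ub, dtype=float))
        if self.pop_size < 2:
            raise ValueError(f"pop_size must be >= 2, got {self.pop_size}")
        if not 0.0 <= self.z <= 1.0:
            raise ValueError(f"z must be in [0, 1], got {self.z}")
        if self.lb.shape != self.ub.shape or np.any(self.lb >= self.ub):
            raise ValueError("need lb < ub elementwise with matching shapes")

    @property
    def dim(self) -> int:
        return self.lb.size


@dataclass
class SMAResult:
    x_best: np.ndarray
    f_best: float
    trace: np.ndarray = field(repr=False)  # DF after each iteration
    n_evals: int = 0


def sma_minimize(objective, cfg: SMAConfig) -> SMAResult:
    """Minimize ``objective`` over the box [lb, ub] with SMA.

    The objective receives one position vector and must return a finite
    scalar; a non-finite value aborts with the offending position.  Fixed
    seed gives a bitwise-reproducible trajectory.
    """
    rng = np.random.default_rng(cfg.seed)
    N, d, T = cfg.pop_size, cfg.dim, cfg.max_iter
    lb, ub = cfg.lb, cfg.ub
    span = ub - lb

    def _eval(pop: np.ndarray) -> np.ndarray:
        s = np.empty(pop.shape[0])
        for i, x in enumerate(pop):
            v = float(objective(x))
            if not np.isfinite(v):
                raise ValueError(f"objective returned non-finite value {v} at x={x}")
            s[i] = v
        return s

    X = lb + rng.random((N, d)) * span
    DF = np.inf
    x_b = X[0].copy()
    trace = np.empty(T)
    n_evals = 0

    for t in range(1, T + 1):
        S = _eval(X)
        n_evals += N
        order = np.argsort(S, kind="stable")  # smell index: ascending fitness
        bF, wF = S[order[0]], S[order[-1]]
        if bF < DF:
            DF = bF
            x_b = X[order[0]].copy()
        trace[t - 1] = DF

        # rank weights, +branch for the better half
        r1 = rng.random((N, d))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = (bF - S[order]) / (bF - wF + _EPS)
        ratio = np.clip(ratio, 0.0, 1.0)  # exact-arithmetic range; guards bF ~ wF
        term = r1 * np.log10(ratio[:, None] + 1.0)
        W = np.empty((N, d))
        half = N // 2
        W[order[:half]] = 1.0 + term[:half]
        W[order[half:]] = 1.0 - term[half:]

        a = np.arctanh(np.clip(1.0 - t / T, -1.0 + _EPS, 1.0 - _EPS))
        b = 1.0 - t / T
        p = np.tanh(np.abs(S - DF))

        # draw every random tensor unconditionally: reproducible trajectories
        restart = rng.random(N) < cfg.z
        r2 = rng.random(N)
        vb = rng.uniform(-a, a, (N, d))
        vc = rng.uniform(-b, b, (N, d)) if b > 0 else np.zeros((N, d))
        A = rng.integers(0, N, N)
        B = rng.integers(0, N, N)
        Xrand = lb + rng.random((N, d)) * span

        approach = x_b + vb * (W * X[A] - X[B])
        contract = vc * X
        X = np.where((r2 < p)[:, None], approach, contract)
        X[restart] = Xrand[restart]
        X = np.clip(X, lb, ub)

    # final population would otherwise go unevaluated
    S = _eval(X)
    n_evals += N
    i = int(np.argmin(S))
    if S[i] < DF:
        DF = float(S[i])
        x_b = X[i].copy()
    return SMAResult(x_best=x_b, f_best=float(DF), trace=trace, n_evals=n_evals)
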