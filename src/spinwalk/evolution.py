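"""Coin matrices and one-step propagation of pure and mixed walk states.

One walk step is U = S · (C ⊗ I): the coin acts on the spin at each site,
then the shift moves the left component one site left and the right
component one site right.  In amplitude form, with a (possibly site
dependent) coin C_x = [[a_x, b_x], [c_x, d_x]],

    psi_L(x, t) = a_{x+1} psi_L(x+1, t-1) + b_{x+1} psi_R(x+1, t-1)
    psi_R(x, t) = c_{x-1} psi_L(x-1, t-1) + d_{x-1} psi_R(x-1, t-1)

On the unbounded line the window grows by one site per step (exact, since
one step moves amplitude at most one site).  On a fixed window, amplitude
that would shift past the edges is dropped; this is exact whenever the
edge sites carry boundary coins (reflecting rho=0 keeps the outgoing
component identically zero, absorbing rho=1 boundary mass is harvested by
the boundary bookkeeping before it can pile up).
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .states import CoinParams, DensityState, SpinorField

__all__ = ["coin_matrix", "StepOperator", "step", "evolve", "density_step"]


def coin_matrix(params: CoinParams) -> np.ndarray:
    """2x2 unitary [[e^{i xi}√ρ, e^{i zeta}√(1−ρ)], [e^{−i zeta}√(1−ρ), −e^{−i xi}√ρ]]."""
    sr = np.sqrt(params.rho)
    sq = np.sqrt(1.0 - params.rho)
    return np.array(
        [
            [np.exp(1j * params.xi) * sr, np.exp(1j * params.zeta) * sq],
            [np.exp(-1j * params.zeta) * sq, -np.exp(-1j * params.xi) * sr],
        ]
    )


CoinMap = Callable[[int], CoinParams]


class StepOperator:
    """Shift-after-coin update with a uniform or per-site coin.

    ``coin`` may be a single :class:`CoinParams` or a callable mapping a
    lattice site to one.  ``grow`` controls whether the window expands by
    one site per step (unbounded line) or stays fixed (segments).
    """

    def __init__(self, coin: CoinParams | CoinMap, grow: bool = True):
        if isinstance(coin, CoinParams):
            self._coin_at: CoinMap = lambda x, c=coin: c
            self.uniform: CoinParams | None = coin
        else:
            self._coin_at = coin
            self.uniform = None
        self.grow = grow

    def coin_at(self, x: int) -> CoinParams:
        return self._coin_at(int(x))

    def coin_entries(self, sites: np.ndarray) -> tuple[np.ndarray, ...]:
        """Arrays (a, b, c, d) of coin-matrix entries over ``sites``."""
        if self.uniform is not None:
            m = coin_matrix(self.uniform)
            ones = np.ones(len(sites))
            return m[0, 0] * ones, m[0, 1] * ones, m[1, 0] * ones, m[1, 1] * ones
        mats = np.array([coin_matrix(self._coin_at(int(x))) for x in sites])
        return mats[:, 0, 0], mats[:, 0, 1], mats[:, 1, 0], mats[:, 1, 1]

    def unitary(self, xmin: int, n_sites: int) -> np.ndarray:
        """Dense matrix of U = S·(C⊗I) on the window, spin-major ordering.

        Shifts that leave the window are dropped (see module docstring for
        when this is exact).
        """
        sites = np.arange(xmin, xmin + n_sites)
        a, b, c, d = self.coin_entries(sites)
        dim = 2 * n_sites
        u = np.zeros((dim, dim), dtype=complex)
        idx = np.arange(n_sites)
        # L component at site i lands at i-1; R component lands at i+1.
        src_l, src_r = idx, idx + n_sites
        keep = idx >= 1
        u[src_l[keep] - 1, src_l[keep]] += a[keep]
        u[src_l[keep] - 1, src_r[keep]] += b[keep]
        keep = idx <= n_sites - 2
        u[src_r[keep] + 1, src_l[keep]] += c[keep]
        u[src_r[keep] + 1, src_r[keep]] += d[keep]
        return u


def step(state: SpinorField, op: StepOperator) -> SpinorField:
    """Apply one coin-then-shift update to a pure state."""
    sites = state.sites
    a, b, c, d = op.coin_entries(sites)
    new_l_src = a * state.psi_l + b * state.psi_r  # L component after coin, at site x
    new_r_src = c * state.psi_l + d * state.psi_r
    n = len(sites)
    if op.grow:
        out_l = np.zeros(n + 2, dtype=complex)
        out_r = np.zeros(n + 2, dtype=complex)
        out_l[0:n] = new_l_src  # site x -> x-1, window shifted left by one
        out_r[2 : n + 2] = new_r_src
        return SpinorField(state.xmin - 1, out_l, out_r)
    out_l = np.zeros(n, dtype=complex)
    out_r = np.zeros(n, dtype=complex)
    out_l[: n - 1] = new_l_src[1:]
    out_r[1:] = new_r_src[: n - 1]
    return SpinorField(state.xmin, out_l, out_r)


def evolve(state: SpinorField, op: StepOperator, t: int) -> SpinorField:
    """t-fold composition of :func:`step`; t=0 returns a copy."""
    if t < 0:
        raise ValueError(f"number of steps must be non-negative, got {t}")
    out = state.copy()
    for _ in range(t):
        out = step(out, op)
    return out


def density_step(state: DensityState, op: StepOperator) -> DensityState:
    """One unitary update rho -> U rho U† of a mixed state."""
    if op.grow:
        n = state.n_sites
        big = np.zeros((2 * (n + 2), 2 * (n + 2)), dtype=complex)
        # embed with one empty site on each side, spin-major blocks
        for si in range(2):
            for sj in range(2):
                big[
                    si * (n + 2) + 1 : si * (n + 2) + 1 + n,
                    sj * (n + 2) + 1 : sj * (n + 2) + 1 + n,
                ] = state.matrix[si * n : (si + 1) * n, sj * n : (sj + 1) * n]
        u = op.unitary(state.xmin - 1, n + 2)
        return DensityState(state.xmin - 1, u @ big @ u.conj().T)
    u = op.unitary(state.xmin, state.n_sites)
    return DensityState(state.xmin, u @ state.matrix @ u.conj().T)
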