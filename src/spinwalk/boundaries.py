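"""Absorbing and reflecting boundaries with absorbed-mass bookkeeping.

Two equivalent absorbing mechanisms are provided:

* **coin-based** — the boundary site (and everything beyond) carries a
  rho=1 coin, so amplitude that reaches it streams outward and never
  returns.  Absorbed mass is the probability arriving at or beyond the
  boundary site, harvested once per step and pruned from the active
  window (exact: with rho=1 the left boundary site can only ever hold a
  left-moving component, so pruning never touches amplitude that could
  re-enter the interior).

* **measurement-based** — after each unitary step the boundary sites are
  measured (projectors I_s ⊗ |b><b|) on a density matrix; the projected
  mass is logged and removed from the live state.

Both produce the same cumulative absorption series, which the test suite
checks to 1e-8.  A reflecting boundary is the rho=0 swap coin at the wall
site, which inverts the incoming movement direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evolution import StepOperator, density_step
from .measurement import kraus_set
from .states import (
    ABSORBING_COIN,
    REFLECTING_COIN,
    CoinParams,
    DensityState,
    InitialSpec,
    SpinorField,
    WalkConfig,
    make_point_state,
)

__all__ = [
    "AbsorptionRecord",
    "absorbing_coin_map",
    "reflecting_coin_map",
    "measured_boundary_step",
    "absorption_series",
]

#: early-stop rule: stop once the per-step absorbed mass has stayed below
#: this threshold for STALL_PATIENCE consecutive steps.
STALL_THRESHOLD = 1e-12
STALL_PATIENCE = 50


@dataclass
class AbsorptionRecord:
    """Per-step and cumulative absorbed mass at the two boundaries."""

    left_increments: np.ndarray
    right_increments: np.ndarray
    residual: float
    truncated_at: int

    @property
    def cumulative_left(self) -> np.ndarray:
        return np.cumsum(self.left_increments)

    @property
    def cumulative_right(self) -> np.ndarray:
        return np.cumsum(self.right_increments)

    @property
    def total_left(self) -> float:
        return float(self.left_increments.sum())

    @property
    def total_right(self) -> float:
        return float(self.right_increments.sum())

    def conditional_left(self, mode: str = "cumulative") -> np.ndarray:
        """π(t) = p_L / (p_L + p_R); ``mode`` selects cumulative-up-to-t
        (default) or instantaneous-at-t masses.  NaN where nothing has been
        absorbed yet."""
        if mode == "cumulative":
            num, den = self.cumulative_left, self.cumulative_left + self.cumulative_right
        elif mode == "instant":
            num, den = self.left_increments, self.left_increments + self.right_increments
        else:
            raise ValueError(f"unknown conditional mode {mode!r}")
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)


def absorbing_coin_map(interior: CoinParams, left_at: int | None, right_at: int | None):
    """Coin map with rho=1 coins at/beyond each absorbing site.

    Returned as a callable site -> CoinParams suitable for a
    :class:`~spinwalk.evolution.StepOperator`.
    """
    if left_at is not None and right_at is not None and left_at >= right_at:
        raise ValueError(f"absorbing boundaries overlap: left {left_at} >= right {right_at}")

    def coin_at(x: int) -> CoinParams:
        if left_at is not None and x <= left_at:
            return ABSORBING_COIN
        if right_at is not None and x >= right_at:
            return ABSORBING_COIN
        return interior

    return coin_at


def reflecting_coin_map(interior, left_at: int | None, right_at: int | None):
    """Coin map with rho=0 swap coins at the wall sites.

    ``interior`` may be a CoinParams or a callable site -> CoinParams (the
    confidence-task drift coin is site dependent).
    """
    base = interior if callable(interior) else (lambda x, c=interior: c)

    def coin_at(x: int) -> CoinParams:
        if (left_at is not None and x == left_at) or (right_at is not None and x == right_at):
            return REFLECTING_COIN
        return base(x)

    return coin_at


def measured_boundary_step(
    state: DensityState,
    op: StepOperator,
    boundaries: tuple[int | None, int | None],
    interior_mset=None,
) -> tuple[DensityState, float, float]:
    """One step of the measurement-based absorber.

    Evolves one unitary step, projects out the boundary sites b1, b2 (the
    absorbed masses are returned), and optionally applies an interior
    decoherence channel.  Returns (new live state, left mass, right mass).
    """
    state = density_step(state, op)
    n = state.n_sites
    m = state.matrix
    absorbed = [0.0, 0.0]
    for k, b in enumerate(boundaries):
        if b is None:
            continue
        i = b - state.xmin
        if i < 0 or i >= n:
            continue
        for j in (i, n + i):
            absorbed[k] += float(np.real(m[j, j]))
            m[j, :] = 0.0
            m[:, j] = 0.0
    out = DensityState(state.xmin, m)
    if interior_mset is not None:
        out = interior_mset.apply(out)
    return out, absorbed[0], absorbed[1]


def absorption_series(config: WalkConfig, T: int | None = None) -> AbsorptionRecord:
    """Run the configured absorbing walk for T steps and record absorption.

    Dispatches on ``config.mechanism``: "coin" runs the pure-state rho=1
    construction, "measurement" the density-matrix boundary-measurement
    construction (which also honours ``config.p_m`` as interior
    decoherence).  Stops early once per-step absorption has stalled.
    """
    T = config.T if T is None else T
    left_b, right_b = _absorbing_sites(config)
    if left_b is None and right_b is None:
        raise ValueError("absorption_series requires at least one absorbing boundary")
    if config.mechanism == "coin" and config.p_m == 0.0:
        return _coin_absorption(config, T, left_b, right_b)
    return _measured_absorption(config, T, left_b, right_b)


def _absorbing_sites(config: WalkConfig) -> tuple[int | None, int | None]:
    left = 0 if config.boundaries.get("left") == "absorbing" else None
    if config.boundaries.get("right") == "absorbing":
        if config.domain[0] != "segment":
            raise ValueError("a right absorbing boundary requires a segment domain")
        right = config.domain[1]
    else:
        right = None
    return left, right


def _coin_absorption(
    config: WalkConfig, T: int, left_b: int | None, right_b: int | None
) -> AbsorptionRecord:
    """Pure-state absorber: harvest boundary arrivals each step, prune them."""
    interior_op = StepOperator(
        config.coin_at if config.coin_overrides else config.coin, grow=False
    )
    state = make_point_state(config.initial, config.domain)
    # active window spans the interior plus the boundary sites themselves,
    # so one step can deposit amplitude onto a boundary site.
    lo = left_b if left_b is not None else state.xmin - T - 1
    hi = right_b if right_b is not None else state.xmin + T + 1
    psi_l = np.zeros(hi - lo + 1, dtype=complex)
    psi_r = np.zeros(hi - lo + 1, dtype=complex)
    i0 = config.initial.x0 - lo
    l0, r0 = config.initial.spin_amplitudes
    psi_l[i0], psi_r[i0] = l0, r0
    field = SpinorField(lo, psi_l, psi_r)

    inc_l = np.zeros(T)
    inc_r = np.zeros(T)
    stall = 0
    truncated_at = T
    from .evolution import step as _step

    for k in range(T):
        field = _step(field, interior_op)
        got = 0.0
        if left_b is not None:
            i = left_b - field.xmin
            got_l = float(np.abs(field.psi_l[i]) ** 2 + np.abs(field.psi_r[i]) ** 2)
            inc_l[k] = got_l
            field.psi_l[i] = 0.0
            field.psi_r[i] = 0.0
            got += got_l
        if right_b is not None:
            i = right_b - field.xmin
            got_r = float(np.abs(field.psi_l[i]) ** 2 + np.abs(field.psi_r[i]) ** 2)
            inc_r[k] = got_r
            field.psi_l[i] = 0.0
            field.psi_r[i] = 0.0
            got += got_r
        stall = stall + 1 if got < STALL_THRESHOLD else 0
        if stall >= STALL_PATIENCE:
            truncated_at = k + 1
            inc_l, inc_r = inc_l[: k + 1], inc_r[: k + 1]
            break
    return AbsorptionRecord(inc_l, inc_r, residual=field.norm_sq(), truncated_at=truncated_at)


def _measured_absorption(
    config: WalkConfig, T: int, left_b: int | None, right_b: int | None
) -> AbsorptionRecord:
    """Density-matrix absorber: boundary measurement (plus optional interior
    decoherence) after every unitary step."""
    if config.domain[0] != "segment":
        raise ValueError("the measurement-based absorber requires a segment domain")
    n_seg = config.domain[1]
    coin_at = absorbing_coin_map(config.coin, left_b, right_b)
    if config.coin_overrides:
        base = coin_at
        coin_at = lambda x: config.coin_overrides.get(x, base(x))  # noqa: E731
    op = StepOperator(coin_at, grow=False)
    # initial pure state embedded on the full fixed segment window
    i0 = config.initial.x0
    l0, r0 = config.initial.spin_amplitudes
    vec = np.zeros(2 * (n_seg + 1), dtype=complex)
    vec[i0] = l0
    vec[n_seg + 1 + i0] = r0
    state = DensityState(0, np.outer(vec, vec.conj()))
    mset = kraus_set(config.basis, config.p_m) if config.p_m > 0 else None

    inc_l = np.zeros(T)
    inc_r = np.zeros(T)
    stall = 0
    truncated_at = T
    for k in range(T):
        state, got_l, got_r = measured_boundary_step(
            state, op, (left_b, right_b), interior_mset=mset
        )
        inc_l[k], inc_r[k] = got_l, got_r
        stall = stall + 1 if got_l + got_r < STALL_THRESHOLD else 0
        if stall >= STALL_PATIENCE:
            truncated_at = k + 1
            inc_l, inc_r = inc_l[: k + 1], inc_r[: k + 1]
            break
    return AbsorptionRecord(inc_l, inc_r, residual=state.trace(), truncated_at=truncated_at)
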