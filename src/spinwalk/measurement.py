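"""Projective measurements, decoherence channels, and trajectory unraveling.

Decoherence is modelled by a probabilistic projective measurement: at each
step, with probability p_m, the walker is measured in the position basis,
the spin basis, or both.  The corresponding Kraus families are

    {M_p}   = { √p_m · I_s ⊗ |x><x| } ∪ { √(1−p_m) · I }
    {M_s}   = { √p_m · |s><s| ⊗ I_p : s ∈ {L, R} } ∪ { √(1−p_m) · I }
    {M_p,s} = { √p_m · |s><s| ⊗ |x><x| } ∪ { √(1−p_m) · I }

(the √ on p_m is forced by the completeness relation Σ M†M = I).  Applied
to a density matrix the channel mixes the unmeasured state with its
block-diagonal restriction, which is how it is implemented here; the full
operator family is also materialisable for completeness checks.

For p_m = 1 with the both-bases family the state is diagonal after every
step and the walk reduces exactly to a classical Markov chain with kernel
|C_ij|^2; :func:`fully_decohered_walk` implements that reduction directly
so the classical limit can be followed to large times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evolution import StepOperator, coin_matrix, density_step, step
from .states import CoinParams, DensityState, InitialSpec, SpinorField, WalkConfig, make_point_state

__all__ = [
    "MeasurementSet",
    "kraus_set",
    "position_distribution",
    "spin_probabilities",
    "decohere_step",
    "decohere_evolve",
    "sample_trajectory",
    "trajectory_position_distribution",
    "fully_decohered_walk",
]

BASES = ("position", "spin", "both")


def position_distribution(state: SpinorField | DensityState) -> tuple[np.ndarray, np.ndarray]:
    """(sites, p(x)) with p(x) = |psi_L(x)|² + |psi_R(x)|² (pure) or the
    position-diagonal marginal (mixed).  Sums to the state's live mass."""
    if isinstance(state, SpinorField):
        return state.sites, np.abs(state.psi_l) ** 2 + np.abs(state.psi_r) ** 2
    n = state.n_sites
    diag = np.real(np.diag(state.matrix))
    return state.sites, diag[:n] + diag[n:]


def spin_probabilities(state: SpinorField | DensityState) -> tuple[float, float]:
    """(p(L), p(R)) from the global spin measurement; sums to the live mass."""
    if isinstance(state, SpinorField):
        return (
            float(np.sum(np.abs(state.psi_l) ** 2)),
            float(np.sum(np.abs(state.psi_r) ** 2)),
        )
    n = state.n_sites
    diag = np.real(np.diag(state.matrix))
    return float(diag[:n].sum()), float(diag[n:].sum())


@dataclass(frozen=True)
class MeasurementSet:
    """A complete Kraus family: basis projectors scaled by √p_m plus √(1−p_m)·I."""

    basis: str
    p_m: float

    def __post_init__(self) -> None:
        if self.basis not in BASES:
            raise ValueError(f"unknown measurement basis {self.basis!r}")
        if not 0.0 <= self.p_m <= 1.0:
            raise ValueError(f"p_m must lie in [0, 1], got {self.p_m}")

    def apply(self, state: DensityState) -> DensityState:
        """Channel action rho -> Σ_i M_i rho M_i† (block-diagonal mixing)."""
        if self.p_m == 0.0:
            return state.copy()
        n = state.n_sites
        r = state.matrix.reshape(2, n, 2, n)
        measured = np.zeros_like(r)
        if self.basis == "position":
            ix = np.arange(n)
            measured[:, ix, :, ix] = r[:, ix, :, ix]
        elif self.basis == "spin":
            for s in range(2):
                measured[s, :, s, :] = r[s, :, s, :]
        else:  # both
            ix = np.arange(n)
            for s in range(2):
                measured[s, ix, s, ix] = r[s, ix, s, ix]
        out = (1.0 - self.p_m) * r + self.p_m * measured
        return DensityState(state.xmin, out.reshape(2 * n, 2 * n))

    def operators(self, n_sites: int) -> list[np.ndarray]:
        """Materialise the full operator family on a window (for small windows)."""
        dim = 2 * n_sites
        sp = np.sqrt(self.p_m)
        ops: list[np.ndarray] = []
        if self.basis == "position":
            for i in range(n_sites):
                m = np.zeros((dim, dim))
                m[i, i] = sp
                m[n_sites + i, n_sites + i] = sp
                ops.append(m)
        elif self.basis == "spin":
            for s in range(2):
                m = np.zeros((dim, dim))
                block = slice(s * n_sites, (s + 1) * n_sites)
                m[block, block] = sp * np.eye(n_sites)
                ops.append(m)
        else:
            for s in range(2):
                for i in range(n_sites):
                    m = np.zeros((dim, dim))
                    j = s * n_sites + i
                    m[j, j] = sp
                    ops.append(m)
        ops.append(np.sqrt(1.0 - self.p_m) * np.eye(dim))
        return ops


def kraus_set(basis: str, p_m: float) -> MeasurementSet:
    """Build the measurement family for a basis tag and occurrence probability."""
    return MeasurementSet(basis=basis, p_m=p_m)


def decohere_step(state: DensityState, op: StepOperator, mset: MeasurementSet) -> DensityState:
    """One unitary step followed by the measurement channel; trace preserving."""
    return mset.apply(density_step(state, op))


def decohere_evolve(
    state: DensityState, op: StepOperator, mset: MeasurementSet, t: int
) -> DensityState:
    if t < 0:
        raise ValueError(f"number of steps must be non-negative, got {t}")
    out = state.copy()
    for _ in range(t):
        out = decohere_step(out, op, mset)
    return out


def fully_decohered_walk(
    coin: CoinParams, initial: InitialSpec, t: int
) -> tuple[np.ndarray, np.ndarray]:
    """Exact p_m=1 both-bases walk on the line: (sites, p(x)) after t steps.

    A full measurement after every step keeps the density matrix diagonal,
    and the composed step reduces to the classical kernel

        p_L(x, t) = ρ p_L(x+1) + (1−ρ) p_R(x+1)
        p_R(x, t) = (1−ρ) p_L(x−1) + ρ p_R(x−1)

    starting from the measured initial occupations (η, 1−η).  Phases xi,
    zeta drop out of |C_ij|².  Cross-validated against the full channel in
    the test suite.
    """
    if t < 0:
        raise ValueError(f"number of steps must be non-negative, got {t}")
    rho = coin.rho
    p_l = np.array([initial.eta])
    p_r = np.array([1.0 - initial.eta])
    xmin = initial.x0
    for _ in range(t):
        n = len(p_l)
        nl = np.zeros(n + 2)
        nr = np.zeros(n + 2)
        nl[0:n] = rho * p_l + (1.0 - rho) * p_r
        nr[2 : n + 2] = (1.0 - rho) * p_l + rho * p_r
        p_l, p_r = nl, nr
        xmin -= 1
    return np.arange(xmin, xmin + len(p_l)), p_l + p_r


def sample_trajectory(
    config: WalkConfig, t: int, seed: int | None = None
) -> tuple[list[tuple[int, str, object]], SpinorField]:
    """One stochastic unraveling of the decoherence channel.

    At each step, after the unitary update, a measurement of the configured
    basis occurs with probability p_m and the pure state collapses onto the
    sampled outcome.  Returns the list of (step, basis, outcome) events and
    the final pure state.  Averaging many trajectories reproduces the
    density-matrix channel.
    """
    if t < 0:
        raise ValueError(f"number of steps must be non-negative, got {t}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    op = StepOperator(config.coin_at if config.coin_overrides else config.coin, grow=True)
    state = make_point_state(config.initial, config.domain)
    events: list[tuple[int, str, object]] = []
    for k in range(1, t + 1):
        state = step(state, op)
        if config.p_m > 0.0 and rng.random() < config.p_m:
            outcome = _collapse(state, config.basis, rng)
            events.append((k, config.basis, outcome))
    return events, state


def _collapse(state: SpinorField, basis: str, rng: np.random.Generator) -> object:
    if basis in ("position", "both"):
        _, p = position_distribution(state)
        i = rng.choice(len(p), p=p / p.sum())
        keep_l = np.zeros_like(state.psi_l)
        keep_r = np.zeros_like(state.psi_r)
        keep_l[i], keep_r[i] = state.psi_l[i], state.psi_r[i]
        state.psi_l, state.psi_r = keep_l, keep_r
        site = int(state.xmin + i)
    if basis in ("spin", "both"):
        pl, pr = spin_probabilities(state)
        tot = pl + pr
        s = "L" if rng.random() < pl / tot else "R"
        if s == "L":
            state.psi_r = np.zeros_like(state.psi_r)
        else:
            state.psi_l = np.zeros_like(state.psi_l)
    nrm = np.sqrt(state.norm_sq())
    state.psi_l /= nrm
    state.psi_r /= nrm
    if basis == "position":
        return site
    if basis == "spin":
        return s
    return (site, s)


def trajectory_position_distribution(
    config: WalkConfig, t: int, n_traj: int, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo estimate of the channel's position marginal at time t."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    x0 = config.initial.x0
    sites = np.arange(x0 - t, x0 + t + 1)
    acc = np.zeros(len(sites))
    for _ in range(n_traj):
        _, state = sample_trajectory(config, t, seed=int(rng.integers(2**31)))
        s, p = position_distribution(state)
        acc[s - (x0 - t)] += p
    return sites, acc / n_traj
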