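"""State containers and initial-state constructors for coined quantum walks.

A discrete-time quantum walk lives on the Hilbert space H_s ⊗ H_p, where
H_s = span{|L>, |R>} is a two-level "spin" (the movement direction, used by
the decision models as the *choice* basis) and H_p = span{|x>, x ∈ Z} is the
lattice position (the *confidence*/evidence basis).

Pure states are stored as a :class:`SpinorField`: two complex amplitude
arrays psi_l, psi_r over an integer window; amplitudes outside the window
are implicitly zero.  Mixed states are stored as a :class:`DensityState`
holding the full spin-major density matrix over the window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CoinParams",
    "HADAMARD",
    "InitialSpec",
    "SpinorField",
    "DensityState",
    "WalkConfig",
    "make_point_state",
    "make_gaussian_state",
]


@dataclass(frozen=True)
class CoinParams:
    """Parameters (rho, xi, zeta) of one 2x2 quantum coin.

    rho in [0, 1] controls the spread (rho=0.5, xi=zeta=0 is the Hadamard
    coin; rho=1 propagates without deformation, rho=0 swaps the spin
    components).  xi and zeta are phase biases in radians; zeta defaults to
    0, which loses no generality for the walks considered here.
    """

    rho: float
    xi: float = 0.0
    zeta: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"coin parameter rho must lie in [0, 1], got {self.rho}")


HADAMARD = CoinParams(rho=0.5, xi=0.0, zeta=0.0)

#: coins implementing boundaries: rho=1 absorbs (no direction change, mass
#: streams outward), rho=0 reflects (swap coin inverts the direction).
ABSORBING_COIN = CoinParams(rho=1.0)
REFLECTING_COIN = CoinParams(rho=0.0)


@dataclass(frozen=True)
class InitialSpec:
    """Initial condition: spin weights and a point or Gaussian position profile.

    The spin amplitudes are (e^{i alpha} sqrt(eta), e^{i beta} sqrt(1-eta));
    the defaults alpha=0, beta=pi/2 give the conventional (sqrt(eta),
    i sqrt(1-eta)) spin.  ``sigma=None`` selects a point state at ``x0``,
    otherwise a truncated Gaussian of width sigma centred at x0.
    """

    eta: float = 0.5
    alpha: float = 0.0
    beta: float = math.pi / 2
    x0: int = 0
    sigma: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError(f"initial spin weight eta must lie in [0, 1], got {self.eta}")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError(f"gaussian width sigma must be positive, got {self.sigma}")

    @property
    def spin_amplitudes(self) -> tuple[complex, complex]:
        return (
            np.exp(1j * self.alpha) * math.sqrt(self.eta),
            np.exp(1j * self.beta) * math.sqrt(1.0 - self.eta),
        )


class SpinorField:
    """Pure walk state: left/right complex amplitudes over an integer window."""

    __slots__ = ("xmin", "psi_l", "psi_r")

    def __init__(self, xmin: int, psi_l: np.ndarray, psi_r: np.ndarray):
        psi_l = np.asarray(psi_l, dtype=complex)
        psi_r = np.asarray(psi_r, dtype=complex)
        if psi_l.shape != psi_r.shape or psi_l.ndim != 1:
            raise ValueError("psi_l and psi_r must be 1-d arrays of equal length")
        self.xmin = int(xmin)
        self.psi_l = psi_l
        self.psi_r = psi_r

    @property
    def xmax(self) -> int:
        return self.xmin + len(self.psi_l) - 1

    @property
    def sites(self) -> np.ndarray:
        return np.arange(self.xmin, self.xmax + 1)

    def norm_sq(self) -> float:
        return float(np.sum(np.abs(self.psi_l) ** 2 + np.abs(self.psi_r) ** 2))

    def copy(self) -> "SpinorField":
        return SpinorField(self.xmin, self.psi_l.copy(), self.psi_r.copy())

    def amplitude_at(self, x: int) -> tuple[complex, complex]:
        """(psi_L(x), psi_R(x)); zero outside the window."""
        if x < self.xmin or x > self.xmax:
            return 0.0 + 0.0j, 0.0 + 0.0j
        i = x - self.xmin
        return complex(self.psi_l[i]), complex(self.psi_r[i])

    def to_vector(self) -> np.ndarray:
        """Spin-major flat vector (all L amplitudes, then all R amplitudes)."""
        return np.concatenate([self.psi_l, self.psi_r])

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"SpinorField(window=[{self.xmin}, {self.xmax}], "
            f"norm={self.norm_sq():.6f})"
        )


class DensityState:
    """Mixed walk state: spin-major density matrix over an integer window.

    Basis ordering is spin-major: index s * n_sites + i for spin s in {L=0,
    R=1} and site offset i.  The trace may be below one while absorbed mass
    is tracked separately by the boundary bookkeeping.
    """

    __slots__ = ("xmin", "matrix")

    def __init__(self, xmin: int, matrix: np.ndarray):
        matrix = np.asarray(matrix, dtype=complex)
        if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1] or matrix.shape[0] % 2:
            raise ValueError("density matrix must be square with even dimension")
        self.xmin = int(xmin)
        self.matrix = matrix

    @classmethod
    def from_pure(cls, state: SpinorField) -> "DensityState":
        v = state.to_vector()
        return cls(state.xmin, np.outer(v, v.conj()))

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[0] // 2

    @property
    def xmax(self) -> int:
        return self.xmin + self.n_sites - 1

    @property
    def sites(self) -> np.ndarray:
        return np.arange(self.xmin, self.xmax + 1)

    def trace(self) -> float:
        return float(np.real(np.trace(self.matrix)))

    def copy(self) -> "DensityState":
        return DensityState(self.xmin, self.matrix.copy())

    def validate(self, atol: float = 1e-10) -> None:
        """Check Hermiticity and positivity (used in tests and debugging)."""
        m = self.matrix
        if not np.allclose(m, m.conj().T, atol=atol):
            raise ValueError("density matrix is not Hermitian")
        eigs = np.linalg.eigvalsh(m)
        if eigs.min() < -atol:
            raise ValueError(f"density matrix has negative eigenvalue {eigs.min()}")

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"DensityState(window=[{self.xmin}, {self.xmax}], "
            f"trace={self.trace():.6f})"
        )


@dataclass
class WalkConfig:
    """Full walk configuration used by the drivers and the CLI.

    ``domain`` is either ``("line",)`` for the unbounded lattice or
    ``("segment", N)`` for sites 0..N.  ``boundaries`` maps "left"/"right"
    to None, "absorbing" or "reflecting"; ``mechanism`` selects how an
    absorbing boundary is realised ("coin" for the rho=1 coin construction,
    "measurement" for per-step boundary measurement of a density matrix).
    """

    coin: CoinParams = HADAMARD
    coin_overrides: dict[int, CoinParams] = field(default_factory=dict)
    domain: tuple = ("line",)
    boundaries: dict[str, str | None] = field(
        default_factory=lambda: {"left": None, "right": None}
    )
    mechanism: str = "coin"
    initial: InitialSpec = field(default_factory=InitialSpec)
    p_m: float = 0.0
    basis: str = "position"
    T: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_m <= 1.0:
            raise ValueError(f"measurement probability p_m must lie in [0, 1], got {self.p_m}")
        if self.basis not in ("position", "spin", "both"):
            raise ValueError(f"unknown measurement basis {self.basis!r}")
        if self.mechanism not in ("coin", "measurement"):
            raise ValueError(f"unknown boundary mechanism {self.mechanism!r}")
        if self.domain[0] not in ("line", "segment"):
            raise ValueError(f"unknown domain type {self.domain[0]!r}")
        if self.domain[0] == "segment" and (len(self.domain) < 2 or self.domain[1] < 2):
            raise ValueError("segment domain needs a length N >= 2")
        if self.T < 0:
            raise ValueError("step budget T must be non-negative")
        for side, kind in self.boundaries.items():
            if side not in ("left", "right"):
                raise ValueError(f"unknown boundary side {side!r}")
            if kind not in (None, "absorbing", "reflecting"):
                raise ValueError(f"unknown boundary type {kind!r} for side {side!r}")

    def coin_at(self, x: int) -> CoinParams:
        return self.coin_overrides.get(x, self.coin)


def make_point_state(spec: InitialSpec, domain: tuple = ("line",)) -> SpinorField:
    """Point initial state: spin (e^{ia}√η, e^{ib}√(1−η)) localised at x0."""
    if spec.sigma is not None:
        raise ValueError("make_point_state requires a point position (sigma=None)")
    if domain[0] == "segment":
        n = domain[1]
        if not 0 <= spec.x0 <= n:
            raise ValueError(f"initial position x0={spec.x0} outside segment [0, {n}]")
    l0, r0 = spec.spin_amplitudes
    return SpinorField(spec.x0, np.array([l0]), np.array([r0]))


def make_gaussian_state(spec: InitialSpec, n: int) -> SpinorField:
    """Gaussian wave packet on the segment [0, n] with uniform spin factor.

    Position amplitudes follow exp(-((x-x0)/sigma)^2 / 2) truncated to the
    segment and renormalised to unit total norm; the spin factor at every
    site is (e^{ia}√η, e^{ib}√(1−η)) (the default spec gives the unbiased
    (1, i)/√2 spin).
    """
    if spec.sigma is None:
        raise ValueError("make_gaussian_state requires a gaussian position (sigma set)")
    if not 0 <= spec.x0 <= n:
        raise ValueError(f"gaussian centre x0={spec.x0} outside segment [0, {n}]")
    x = np.arange(n + 1)
    profile = np.exp(-0.5 * ((x - spec.x0) / spec.sigma) ** 2)
    profile = profile / np.sqrt(np.sum(profile**2))
    l0, r0 = spec.spin_amplitudes
    return SpinorField(0, l0 * profile, r0 * profile)
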