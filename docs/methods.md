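# Methods

## Model

The walker lives on H_s ⊗ H_p with H_s = span{|L⟩, |R⟩} and H_p the
integer lattice. A pure state is ψ(t) = Σ_x (ψ_L(x,t), ψ_R(x,t))ᵀ ⊗ |x⟩;
mixed states are spin-major density matrices over a finite window. One
step applies the coin

    C(ρ, ξ, ζ) = [[ e^{iξ}√ρ,      e^{iζ}√(1−ρ) ],
                  [ e^{−iζ}√(1−ρ), −e^{−iξ}√ρ   ]]

to the spin at every site, then shifts the L component one site left and
the R one site right. The default initial spin is
(e^{iα}√η, e^{iβ}√(1−η)) with α = 0, β = π/2; together with ζ = 0 this
parameter convention loses no generality for the family of walks the
package targets (a global-phase/relabelling degeneracy), while all five
angles remain settable.

### Parameters

| parameter | meaning | range / default |
|---|---|---|
| ρ | coin spread control; 0.5 = Hadamard, 1 = deformation-free transport, 0 = swap/reflect | [0, 1], default 0.5 |
| ξ, ζ | coin phase biases (radians); ξ biases direction, ζ fixed at 0 by convention | default 0 |
| η | initial left-spin weight; 0.5 = unbiased | [0, 1], default 0.5 |
| p_m | per-step probability of a projective measurement (decoherence level) | [0, 1], default 0 |
| basis | measured basis: position, spin, or both | default position |
| N, x0, σ | segment length, start site, Gaussian width | model-specific |

## Propagation and windows

Pure states on the unbounded line use a window grown by one site per step
— exact, since the shift moves amplitude at most one site. Density
matrices grow the same way, so a t-step unbounded channel evolution costs
O(Σ_{s≤t} s³) rather than t·(final window)³. On fixed segments the shift
simply drops amplitude that would leave the window; this is exact for the
states the segment drivers produce, because the outgoing sectors (a right
mover on the left wall, a left mover on the right wall) are dynamically
empty: nothing can arrive at a wall moving outward when there is no
lattice beyond it. The one exception is a generic *initial* state with
support on the wall sites (see Limitations).

## Decoherence

The per-step channel is Σ_i M_i ρ M_i† with √p_m-scaled projectors of the
chosen basis plus √(1−p_m)·I (the √ is forced by Σ M_i†M_i = I). In
matrix form the channel is (1−p_m)ρ + p_m·Π(ρ), where Π keeps the
position-diagonal, spin-diagonal, or fully diagonal part — implemented
that way rather than by materialising operators, which are only built
explicitly for completeness tests on small windows.

Two backends are exposed and cross-validated: exact density-matrix
propagation, and a seeded Monte-Carlo trajectory unraveling (with
probability p_m per step, sample an outcome and collapse), whose ensemble
average reproduces the channel to sampling error.

At p_m = 1 with the joint (both-bases) measurement the state is diagonal
after every step and the composed step reduces to the classical Markov
kernel |C_ij|²: p_L(x,t) = ρ p_L(x+1) + (1−ρ) p_R(x+1), and symmetrically
for p_R. `fully_decohered_walk` implements this reduction directly so the
classical limit can be followed to large t at O(t²) total cost; it agrees
with the full channel to 1e−10 where both are run. The same diagonal
reduction makes the position-only p_m = 1 channel classical as well for
the symmetric (1, i)/√2 initial spin (the only configuration for which
the package asserts it): the initial spin coherence enters the kernel only
through Re(e^{i(ξ+ζ)}√(ρ(1−ρ)) L R̄), which vanishes there.

## Boundaries and absorption

Absorbing boundaries are realised two equivalent ways:

* **coin-based** — ρ = 1 coins at and beyond the boundary site. With ρ = 1
  the boundary site can only ever hold an inward-arrived component moving
  outward, so arrivals stream away and never return. Absorbed mass is the
  probability arriving at/beyond the boundary, harvested once per step and
  pruned from the window (this keeps single-boundary windows from growing
  without bound and is exact by the no-return property).
* **measurement-based** — after each unitary step the boundary sites are
  projected out of the density matrix (I_s ⊗ |b⟩⟨b|), the projected mass
  logged. Interior decoherence (p_m > 0) composes with this, which is how
  the decohered judgment curves are computed.

The two cumulative series agree to machine precision; the suite asserts
1e−8. Reflecting boundaries are ρ = 0 swap coins: the wall inverts the
incoming component (ψ_L(x−1,t+1) = e^{iζ}ψ_R(x,t)).

Absorption runs stop early once the per-step absorbed mass has stayed
below 1e−12 for 50 consecutive steps; the residual live mass is always
reported, so truncation error is visible rather than silent. The
conditional absorption probability π(t) = p_L/(p_L+p_R) uses cumulative
masses up to t by default — the time-dependent judgment curves are only
meaningful cumulatively — with an `instant` mode exposed for the
per-step reading.

## Observables

Mean, variance, and standardized skewness are computed from the
live-mass-renormalised position marginal, and analogously on the
two-point spin distribution with values L = 0, R = 1. A directional
caveat worth stating: a walk drifting right (mean displacement > 0) has a
dominant peak ahead and a long tail behind, hence *negative* third-moment
skewness. Directional claims in the test suite are therefore asserted on
the sign of the mean displacement, with the skewness computed and checked
for sign-consistency between the spin and position spaces (the two
correlate positively across the ξ range).

## Decision models

* **Subjective probability** — objective p encoded as x0 = round(N(1−p))
  on a two-absorbing-wall segment, N = 50 by default; π(t) read from the
  absorption record. ρ = 1 gives π = 1/2 identically (the packet splits
  (η, 1−η) and both halves absorb after a light-cone delay); p_m = 1
  recovers the gambler's-ruin diagonal π → p. Coherent finite-t walks
  give inverse-S weighting curves with π(p) + π(1−p) = 1 for unbiased
  parameters.
* **Conjunction demo** — Hadamard walk from x = 1; left absorption with
  one wall (2/π) vs. with a second wall at n = 100 (≈ 0.7068 at T = 5000,
  an ≈ 11% increase). The classical engine never shows an increase.
* **Confidence task** — segment [0, 100], reflecting walls, interior coin
  ρ(x) = x/(N−1) (larger ρ to the right drifts the packet left), Gaussian
  start at N/2 with σ = N/6. Expected position is the confidence proxy;
  the global spin probabilities, read at the prior-decision time and
  renormalised by live mass, are the choice probabilities. A prior
  decision is one full position ⊗ spin measurement applied at that step;
  in simulation the undisturbed packet drifts from 50 down to ≈ 10 by
  t ≈ 200 (dipping below N/2 from t ≈ 68 after a small initial transient
  toward the right) and bounces, while the measured walk visibly departs
  from it after the intervention.

## Problem sizes used in the shipped checks

Headline quantities are recomputed at the configurations above (T = 5000
absorption horizons; variance exponents fitted over t ∈ {50, 100, 200,
400}). Structural properties use smaller instances chosen to exercise the
same code paths exactly: mechanism equivalence on 21- and 51-site
segments over 300 steps, channel identities at t ≤ 14, trajectory/channel
agreement with 10,000 samples at t = 20, decoherence variance sweeps at
t = 50, and the classical-limit judgment on a 21-site segment.

## Limitations

* One-dimensional lattices, unit steps, two-level coins only; no
  continuous-time or continuous-space variants.
* No leaky (partially absorbing) boundaries and no spin-basis boundaries.
* The truncated-Gaussian initial state overlaps the wall sites; its
  outward-moving tail (≈ 1e−5 of mass for σ = N/6) leaks on the first
  steps of the reflecting-segment task. Records renormalise by live mass;
  the loss is reported via the trace.
* Decoherence is the probabilistic-projective-measurement channel only —
  amplitude-damping and quantum/classical mixture schemes are different
  mechanisms and are out of scope.
* The synthetic configurations are idealised study conditions: point or
  Gaussian starts, stationary coins, exact unitarity. Passing tests show
  the engine reproduces the mathematical structure (interference,
  incomplete absorption, decoherence limits), not that the models fit any
  behavioural data set.
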