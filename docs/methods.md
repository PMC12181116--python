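# Methods

This note records the model assumptions, numerical schemes, parameter
conventions and design choices behind `cortexfield`, and what the test suite
does and does not establish.

## Model summary

The neural field φ is one complex amplitude per excitatory/inhibitory
bi-layer of the cortical sheet, evolving near an oscillatory equilibrium.
Lateral (extrinsic) connections act through a disc-shaped kernel of gain U
and radius R; expanding the disc integral to second order in the distance
(the long-wavelength approximation) turns the integral dynamics into a
Klein-Gordon equation with

    m²c⁴ = 1 − U·a − b·∂²U,   c² = U·b,   a = πR²,  b = πR⁴/4.

The integro-differential (retarded-time) form is never time-stepped; the PDE
reduction is the computational object, and the Taylor reduction is treated
as exact at the working wavelengths.  First-derivative connectivity terms
(directional connections) are excluded: the sheet is assumed to have no
intrinsic directionality.

Two connectivity regimes are covered.  The *weak* branch perturbs around
φ = 0 and carries the mass term above.  The *strong intrinsic* branch adds a
point-like intrinsic connection with sigmoid-expansion coefficients
(α, β, γ); its uniform stationary states satisfy 1 − α + aγ + β|φ₀|² = 0 and
perturbations around a nontrivial state propagate as massless waves with
c² = 2Wβγb|φ₀|².  Only stationarity of these states is verified — their
dynamical stability is assumed, not proven.

### Units and signature

All quantities are in model units; the coefficient of φ in the wave equation
is normalized to 1 (no physical unit conversion).  The 2+1 pseudo-metric is
diagonal with g_tt = +1 and negative spatial entries (mostly-minus).  The
discrete spatial Laplace-Beltrami operator is defined with the magnitudes of
the spatial components, Δ_g = (1/√|g|)∂_i(√|g| |g^{ii}|∂_i·), which fixes
the d'Alembertian sign so that the flat metric reproduces ∂²_t φ = −m²c⁴φ +
c²∇²φ.  Index convention: Greek 0–2 with 0 = time, Roman 1–2 spatial.

## Numerical schemes

**Grid.** Uniform rectangular, periodic boundaries by default (they preserve
the discrete conservation laws the tests assert; the sheet in the theory is
unbounded).  Dirichlet boundaries are available via a flag.

**Wave integrator.** Leapfrog / velocity Verlet.  For the linear system the
map conserves the shadow energy
E = Σ√|g|[|φ̇|² + Re(φ*Mφ) − (dt²/4)|Mφ|²]dx² exactly (M = m²c⁴ − c²Δ_g is
self-adjoint in the √|g|-weighted inner product), which is the quantity
`discrete_energy` reports; the ≤1e-6 conservation checks therefore pass at
rounding level for any stable step.  Stability is enforced with a 0.5 margin
on dt ≤ dx/√c² plus a 1/ω_max bound from the mass term.  Leapfrog was chosen
over RK4 precisely because this symplectic energy behaviour is the test
surface.

**Gauge sector.**  The coupled integrator uses compact link variables
U_i = e^{−iε dx A_i} (the standard lattice-gauge discretization), with A_i
stored on forward links.  Consequences, all exact up to float rounding:

* gauge covariance — a lattice gauge transformation (φ → e^{iθ}φ, link shift
  A_i → A_i + Δ⁺θ/(ε dx)) commutes with the update map, so gauge-equivalent
  initial data give identical |φ| trajectories;
* charge conservation — the midpoint charge Σ Im(φⁿ*φⁿ⁺¹)/dt·dx² is an exact
  invariant because the covariant lattice Laplacian is Hermitian;
* a discrete continuity equation with the link current
  J_i = −c² Im(φ*U_iφ(x+î))/dx.

The exposed `covariant_derivative` keeps the centered-difference convention
(plane waves with constant A have the closed-form eigenvalue
i(sin(k dx)/dx − εA)); `scheme="link"` gives the exactly covariant forward
difference.  The gauge-shift sign follows from requiring covariance of
D = ∂ − iεA (the opposite sign convention exists in the literature; the
covariance contract is what the tests pin down).  Temporal gauge is used in
the dynamics (A_t does not propagate; the Gauss-law potential is computed
separately).  The A components obey ∂²_t A_i = c²(∇²A_i − ∂_i∇·A) + εJ_i:
gradient modes are exactly annihilated by the circulant operator pair, and
the connectivity field evolves even when φ = 0.

**Current normalization.**  J_μ = −(i/2)(φ*∂_μφ − ∂_μφ*φ) − εA_μ|φ|², so a
uniform oscillation φ = ρe^{−it} carries J_t = −|φ|².  (The unnormalized
convention gives −2|φ|²; the ½ makes the temporal component equal the
Hebbian source used throughout the learning sector.  Conservation is
unaffected.)

**Gauss law.**  ∂²_i A_t = −|φ|² is solved by default as a Dirichlet sparse
direct solve, so the discrete Laplacian identity holds at every node to
rounding; an independent DST solver of the identical problem serves as the
dual route in the tests, and a free-space −log(r)/(2π) kernel convolution is
available (`method="greens"`, self-cell assigned the kernel cell average).
The 2-D Green's function carries the 1/(2π) normalization so that
∂²A_t = −source holds exactly; an `absorb_two_pi` flag rescales to the
−q·log(r) convention that absorbs the 2π.  Interior potential differences
of a point source follow −(q/2π)log(r/r_ref) to a few percent on a 128²
grid (lattice and boundary corrections at small and large r respectively).

**Geometry.**  Only diagonal metrics are implemented (every metric used by
the theory is diagonal).  Christoffel symbols and the Ricci scalar are
computed symbolically (sympy) for analytically specified metrics — exact up
to rounding — with a second-order finite-difference path for metrics given
only as callables (its h² convergence is itself tested on the 2-sphere).
On the Cartesian grid the Robertson-Walker metric is supported for k = 0
(spatial part −a²δ_ij); curved-k analytics are closed-form
(`einstein_tensor_rw`).

**Expansion dynamics.**  `evolve_expansion` steps the first-order density
equation a′ = ±√(ρa² − k) with RK4 and cross-checks the acceleration
equation a″ = −p·a and the conservation law d(a²ρ)/dt + p·d(a²)/dt = 0 by
centered differences along the run; for (ρ, p) pairs consistent with the
conservation law all residuals sit at integration accuracy.  The packaged
consistency families are the coasting matter-like pair (ρ = ρ₀/a², p = 0;
linear a(t)) and the constant-density pair (ρ = A₀, p = −A₀; exponential
a(t)).  Parameter recovery uses the stiff pair (p = ρ, hence ρ = ρ₀/a⁴):
under the matter-like law a(t) is linear and only ρ₀ − k is identifiable,
while the stiff law separates ρ₀ from k.  The curvature-stress coupling
κ (`kappa_coupling`) is 1 in model units and is distinct from the spatial
curvature constant k (`k_curv`).  The sign branch of da/dt = ±m|φ| defaults
to + and is configurable.

**Delta-response experiment.**  The "delta" perturbation is a Gaussian
velocity kick of width 2·dx (grid-representable; converges to the impulse
response), probed at the kick centre.  Defaults: 64×64 grid, dx = 1, the
weak-branch parameters of U = 0.1, R = 1, dt = 0.25, 240 steps,
a_before = 1, a_after = 1.5.  Learning (larger a) lowers the effective
propagation speed c/a, so activity lingers near the perturbation: both the
peak and the time-integrated probe response increase.  This direction is
asserted only for the packaged defaults and the packaged sweep
(a_after ∈ {1.2, 1.5, 2.0}, monotone); it is not claimed for all parameter
regimes.

**SU(2) sector.**  The generators are used exactly in their printed 2×2 form
(full Pauli matrices, not σ/2); the structure constants are computed from
commutators, giving f^{abc} = 2ε_abc for this normalization.  The
approximate solution factorizes into carrier × unitary rotation,
φ(t) = e^{±imt}exp(∓iΣα^aT^at)φ₀, with the α coefficients taken as inputs
(they stand for g∂_tA^a_t/(2m)).  The independent oracle integrates
∂²φ = −(m²I − 2mα^aT^a)φ — the final approximation of the layer dynamics
with the rotation read as unitary — and the comparison is made on the
gauge-invariant layer moduli |φ_i(t)|, where the genuinely dropped α²
term (a common phase for a single generator) cancels; agreement is ≈0.13%
over a full rotation period at α = m/50.  The complex values themselves
drift in common phase by O(πα/m) per rotation period, which the
approximation does not claim to control.  The quadratic 3g²(A_t)² term can
be reinstated in the oracle as a constant mass shift (`quadratic_shift`).
Cross-generator couplings between the three conserved currents are not
modelled.

**LFP forward model.**  The printed Green's function
g(t) = H(t)(1/m)e^{imt}e^{−Ct/2} keeps the decaying carrier branch of the
complex-damped oscillator; the exact roots of s² + m² + iC give decay
C/(2m), which coincides with C/2 at m = 1.  The oracle test therefore
integrates the damped oscillator (∂²_t + C∂_t + m²)φ = δ(t) — whose envelope
is e^{−Ct/2} exactly — at m = 1 with C = 0.01 ≪ m (the regime the model
assumes), where the residual frequency mismatch O(C²/8) stays within 1e-3
over ten carrier periods.  The delta stimulus is realized as unit initial
velocity (the Green's-function convention giving the 1/m prefactor), and the
LFP channel is the real part of the complex layer field by default.

The three-layer forward model uses the three real antisymmetric rotation
generators (amplitude transfer between each layer pair, the behaviour
reported in laminar recordings); complex phase-type generators are excluded
from the default model to keep it identifiable.  Inversion is
Levenberg-Marquardt-style damped least squares with 5 restarts from jittered
initial points (fixed RNG stream per fit) to escape carrier-phase local
minima, optional Gaussian priors as ridge residuals, and Gauss-Newton
standard errors; full posterior sampling is out of scope.

## Synthetic data

`make_synthetic_lfp` adds independent Gaussian noise of a stated sd to the
real part (or to both quadratures) of the closed-form forward response, with
everything recorded in the metadata and reproducible from the seed.  This
emulates the amplitude scale and additive-noise character of evoked laminar
recordings, but none of their confounds: no 1/f background activity, no
volume conduction or electrode forward physics, no trial-to-trial parameter
drift, no model mismatch.  Passing recovery tests therefore demonstrates
that the estimator is correct and well-calibrated *under the model*, not
that the model fits real cortical data.

## Problem sizes

Dispersion runs use a 128×128 sheet with 5 wavenumbers per branch (4
oscillation periods each, dt = 0.02); conservation runs use a 48² sheet for
10⁴ steps; Poisson/profile checks a 128² grid; the inversion study 20
noisy records of 800 samples each.  These sizes were chosen so that every
property sits well inside its tolerance while the full suite runs in well
under a minute per sector on one CPU.

## Known limitations

* No torsion connections, no off-diagonal metrics, no full 2+1-D
  Einstein-equation evolution beyond the Robertson-Walker ansatz.
* No non-abelian Yang-Mills PDE evolution (the F·F self-interaction as
  dynamics); SU(3) appears only through the minimal 3-layer rotation model.
* The complex-parameter generalization of the connection modulation enters
  only through gradient-type potentials; solenoidal components are exercised
  via the field strength, not evolved.
* Stability (vs stationarity) of the strong-branch states is not analysed.
* No neuroimaging formats and no volume-conduction modelling; traces are
  CSV/HDF5 in model units.
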