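# Methods

## The model

`drypatch` studies strongly localised vegetation patterns in drylands with
the extended Klausmeier model, a two-component reaction–advection–diffusion
system for water `w` and plant biomass `v` on a 1D transect.  In
non-dimensional form,

    w_t = w_xx + (s w)_x + a − w − w v²
    v_t = D² v_xx − m v + w v²

with rainfall `a`, evaporation `−w`, uptake/growth `∓ w v²`, mortality
`m`, downhill water advection `s` (constant slope) and diffusion ratio
`D = sqrt(D_V/D_W) ≪ 1` expressing that water redistributes far faster
than plants disperse.  `params.nondimensionalize` maps the dimensional
parameter set (A, L, R, J, M, S, D_W, D_V) onto (a, m, s, D) via
`a = √R·J·A·L^(−3/2)`, `m = M/L`, `s = S/√(L·D_W)`, with space scale
`√(D_W/L)` and time scale `1/L`; the inverse map reproduces the inputs to
rounding.

In the arid regime the attractor consists of isolated vegetation pulses.
Each pulse has the sech² profile

    v_j(x) = (3m / 2w_j) · sech²( √m (x − p_j) / 2D ),

where `w_j` is the (small) water level at the patch, so the state of an
N-patch ecosystem is just the ordered positions p_1 < … < p_N — the
N-patch phase portrait.

## The pulse-interaction reduction

Between patches vegetation is absent and water is quasi-steady:

    0 = w_xx + s w_x + a − w,   w = 0 at the patch positions,

solved in closed form on every gap (`solve_interpatch`; the two
exponents are the roots of μ² + sμ − 1 = 0, and for s = 0 the profile is
`a(1 − cosh(x−c)/cosh(g/2))`).  The boundary slopes w_x(p_j±) of the two
adjacent gaps drive patch motion:

    dp_j/dt = c · (D/m^{3/2}) · [ w_x(p_j⁺)² − w_x(p_j⁻)² ].

**The prefactor constant.**  The printed source of this equation is
corrupted, so the constant is fixed here by an independent derivation:
projecting the quasi-steady pulse equation onto its translation mode and
using the flux balance below gives the patch velocity
`2 D² w̄_x / w_j` with `w̄_x` the mean of the two boundary slopes, i.e.
`c = 1/6`.  The constant lives in exactly one place
(`params.PULSE_PREFACTOR_COEF`), and the full-PDE drift oracle in the
test suite arbitrates it: at D = 0.01, m = 0.45, a = 0.5 the measured
PDE drift of irregular 2-patch states is 0.90–0.99 of the ODE
prediction across random geometries, whereas `c = 1` would overpredict
the drift six-fold.

Per patch, the absorbed water flux `F_j = w_x(p_j⁺) − w_x(p_j⁻)` must
balance the uptake integrated over the pulse, which gives

    w_j = 6 D m^{3/2} / F_j,     B_j = ∫ v_j dx = F_j / m.

Patches therefore drift toward their wider gap; the equidistant
("regular") configuration is the unique attractor on constant slopes,
and the regular configuration maximises biomass at fixed N.  The gap
coefficient of variation (cv) quantifies distance from regularity.

The reduction's only systematic bias is the bare-soil boundary condition
`w = 0` at the patches: the true boundary value is `w_j = O(D)`, so
fluxes, biomass and drift speeds carry an O(w_j/a) ≈ 5% overestimate at
the reference parameters.  This is deliberate — it keeps every formula
closed-form — and all cross-checks against the PDE use 5–20% tolerances
sized to this bias.

## The PDE engine

`pde.simulate` integrates the full system by a linearly implicit IMEX
step.  At frozen v the water equation is *linear* in w, so diffusion,
advection, evaporation and uptake are all implicit (a cyclic-tridiagonal
solve whose diagonal carries `1 + v²`); for vegetation, diffusion and
mortality are implicit with a prefactored constant matrix, and only the
mild growth term `+ w v²` is explicit.  Both matrices are M-matrices
acting on non-negative data, so the scheme preserves positivity and the
bare-desert equilibrium (w = a, v = 0) exactly; dt (default 0.05) is an
accuracy knob, not a stability constraint.  An earlier design — Strang
splitting with exact pointwise reaction substeps — was abandoned because
the vegetation substep at frozen water has finite-time blow-up near
pulse edges at any practical dt.

Grid: `dx = (2D/√m)/10` by default (≈ 0.003 at the reference
parameters, ~10 nodes across a pulse core); constructors refuse grids
coarser than 1/8 of the pulse width.  Halving dx moves the rainfall
values of a 5-patch desertification cascade's loss events by < 0.3%.

Patches are detected as parabolically interpolated maxima of v above
θ_v = 1.0 (healthy peaks are 20–30, numerical ripple ≪ 1), with peaks
closer than the collision floor 4·(2D/√m) merged.  Count drops within a
coalescence window Δt_c = 5/m are one event (loss eigenvalues are O(m),
so a period-doubling sheds its patches essentially simultaneously);
events are classified halving / near-halving / single / collapse /
other by their size relative to N/2, with small-N ties (N ≤ 3 losing
one patch) resolved toward halving.  Symmetry-breaking for instability
studies uses a seeded multiplicative perturbation built from 16 random
Fourier modes, making it a grid-independent function of x.

## Feasibility and resilience

A configuration is feasible when every patch can be sustained.
`quasi_steady_state` builds the closed-form field, relaxes it under the
PDE at frozen rainfall (t = 80), and Newton-polishes the discrete steady
state when one exists; a patch dying during relaxation is itself an
infeasibility verdict.  `linear_stability` assembles the sparse Jacobian
of the discretised right-hand side and computes the 4N+6 eigenvalues of
largest real part by shift-inverted Arnoldi (shift 0.1·m).  Modes with
|λ| < 0.05·m and dominant overlap with per-patch translation templates
(the windowed spatial derivative of the state) are translations — one
per patch, near zero by construction; everything else is an amplitude
mode, and feasibility requires every amplitude eigenvalue to satisfy
Re λ < ε_eig = 1e−4 (above discretisation noise, far below the O(m)
loss-mode scale).

`critical_rainfall` bisects this feasibility verdict in `a` for the
regular N-pattern (tolerance δ_a = 1e−3).  Because patterns also
destabilise from *above* — pulse self-replication at high rainfall — the
bisection first scans a candidate list for a feasible anchor rather than
ratcheting upward.  On the default sweep domain (length 6) the values
are ordered a_c,1 < … < a_c,6 with ≥ 5% separation; the domain is kept
short so that the regular gap l/N, and hence a_c, changes appreciably
between consecutive N.

Resilience of an N-patch state is reported as the pair: *ecological*
margin `a − a_c,N` (how much drying the state can absorb) and
*engineering* margin `−max Re λ` over amplitude modes (how fast the
weakest patch recovers from disturbance).  The engineering margin shows
critical slowing down, falling monotonically to zero as `a ↓ a_c,N`,
and is smaller for irregular states than for the regular state at the
same N and a.

`predict_transition` encodes which patches an infeasible state loses:
if gap cv < θ_reg = 0.05 the pattern counts as regular and loses the
alternating set (⌈N/2⌉ patches, anchored at the patch with least
biomass); otherwise it loses the single argmin-biomass patch
(lowest-index tie-break).  θ_reg is a free calibration; only clearly
regular (cv ≈ 0) and clearly irregular (cv > 0.2) cases are treated as
ground truth in tests.

## Scenario engines

`run_scenario` executes a drying ramp `a(t) = a_start + (a_end −
a_start)·t/T` (clamped) with either engine:

* **pde** — the full solver, with events extracted from the simulation;
* **hybrid** — the pulse-location ODE between events; when feasibility
  fails, the predicted patches are dropped instantaneously (losses occur
  at rate O(m), effectively instantaneous whenever |da/dt| ≪ m).  The
  hybrid feasibility test is a per-patch water threshold: patch j is
  lost when `w_j = 6Dm^{3/2}/F_j` exceeds a critical level w_* obtained
  once per parameter set by converting a bisected a_c.  Empirically w_*
  is nearly gap-independent (0.048–0.055 across gaps 1–6 at the
  reference parameters, ±7%), which is what makes the one-number
  calibration defensible; the same proxy provides the "margin" trigger
  for removal policies, as `m·(1 − max_j w_j / w_*)`.

Removal policies: `early_one` (at a fixed rainfall, default a ≈ 0.35),
`just_before_one` (at margin < 0.02·m), and `every_kth` (remove
round(N/k) patches at stride k from a regular pattern; k = 3 trades the
natural halving for a deliberate one-third loss).  Field-level removal
zeroes v in a window of 8 pulse widths and leaves w untouched.

### Study conditions

The reference parameters are D = 0.01, m = 0.45, s = 0 with rainfall
ramped 0.5 → 0 — the regime where pulses are well separated, feasible at
a = 0.5, and the reduction is quantitatively accurate.  Scenario runs
use 8–10 patches at a target gap g₀ = 2.0 (domain l = N·g₀) —
feasible at a ≈ 0.5 with comfortable margin; random starts draw gaps
uniformly subject to a minimum gap 0.4·g₀ (visibly irregular, still
well separated).  The slow ramp lasts T = 10⁵ and the fast ramp
T = 2·10³: with the verified prefactor c = 1/6 the migration timescale
of an 8-patch train at g₀ = 2 is ~10³–10⁴ time units, so T = 10⁵ sits
deep in the slow regime (the state regularises to cv < 10⁻³ before its
first loss) while T = 2·10³ freezes the initial irregularity.
Intermediate durations (e.g. T = 2·10⁴) are genuinely marginal: the cv
reaches only ~0.08 and first losses go single — the dichotomy is a
limit statement, not a binary.

The slow/fast classifier (`classify_rate`) operationalises the
asymptotic inequality |da/dt| ≪ D a³ m^{−3/2} with ε_slow = 0.1
(slow below ε·threshold, fast above the threshold, marginal in the
decade between, evaluated at the ramp midpoint by default).  It is a
heuristic: it ignores domain geometry, which modulates the migration
rate through tanh-saturation factors of the gap sizes.

### What the generator does and does not emulate

Synthetic initial states reproduce the study's *class* of conditions —
regular trains and seeded uniform-random placements with a separation
floor — not any empirical landscape.  Real dryland transects have
heterogeneous soils, non-constant slopes, stochastic rainfall and
patch-size variability, none of which is modelled; a passing suite
shows the pulse-interaction framework is internally consistent and that
its qualitative predictions (regularisation, ordered thresholds, the
rate dichotomy, the weakest-patch rule, the conservation trade-off) are
robust at desk scale, not that any specific ecosystem follows them
quantitatively.

## Numerical choices and degenerate inputs

* Adaptive LSODA with rtol 1e−8/atol 1e−10 for the pulse ODE; positions
  are never re-sorted (sortedness is dynamically invariant: the minimum
  gap obeys a discrete maximum principle and grows under s = 0
  migration, so collisions cannot occur; the collision event handler
  remains as a guard and terminates integration rather than raising).
* N = 0 is the desert state everywhere (w ≡ a, v ≡ 0, zero biomass);
  N = 1 under periodic bc is stationary by symmetry; a = 0 makes every
  patch budget degenerate and is reported as infeasibility.
* Neumann walls use mirror ghosts for the field solver, a zero-total-flux
  wall condition for the gap profiles, and a virtual-mirror convention
  for gap statistics (a patch at distance d from the wall counts a gap
  2d); advection requires periodic bc.
* Event extraction raises on patch-count increases by default (patch
  birth is outside the drying regime), but the simulator tolerates them
  because pulse self-replication is real at high rainfall.

## Scales used in the shipped experiments

Desk-scale sizes keep the full check suite in minutes: drift probes use
2 patches on domains of length 5–8 for 150 time units; budget and
spectrum checks use N = 3–4; critical-rainfall sweeps use N ≤ 6 on
length 6; period-doubling runs use N = 8 on length 16; scenario runs
use N = 8–9 with the hybrid engine at full ramp durations (T up to
10⁵), and the PDE engine for the fast ramps (T = 2·10³).  The paper-size
configurations (N ≈ 88–100, domains of ~200) are available through the
same API and the `paper` profile; the hybrid engine handles them in
seconds, the PDE engine in hours.

## Known limitations

* One spatial dimension, constant slope, deterministic rainfall.
* The hybrid engine's one-number calibration transfers a_c across gap
  geometries with ~5–7% error; its event rainfall values inherit that.
* The w = 0 patch boundary condition biases reduced-order fluxes and
  biomass ~5% high at the reference parameters.
* Stability is computed on the discretised operator; no analytic
  eigenvalue machinery (NLEP/Evans) is included, and eigenvalues within
  ~1e−4 of zero are resolution-limited.
* `classify_rate` knows nothing of domain geometry and should be read
  as an order-of-magnitude guide.
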