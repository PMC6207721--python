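# Methods

This note documents the models and algorithms implemented in `redivsys`,
their assumptions, the default parameters, and the design decisions taken
where several constructions were defensible.

## Reaction–division systems

A cell carries N molecular species with counts **x**; its mass is
`M = mᵀx` with **m** the per-molecule masses (amino-acid units), and
concentrations are `X = x/M`, so `mᵀX = 1` identically.  Reactions are
specified *intensively*: `f_r(X)` is the rate per unit mass per minute,
and the propensity in a cell of mass M is `M·f_r(X)`.  This single
convention reproduces both extensive transcription propensities and
intensive first-order rates, and makes the noise scale as `1/√M`.  The
growth rate is not a parameter but the network's mass production,
`λ(X) = mᵀν f(X)`; concentration dynamics follow
`dX/dt = νf(X) − λ(X)X` between divisions, and the mass-flux identity
`mᵀ(νf − λX) = λ(1 − mᵀX)` keeps trajectories on the simplex.

Rate laws are declarative templates (constant, linear, mass action, Hill
activation with optional Hill repression, Michaelis–Menten catalysis,
resource-gated translation).  Templates make networks serialisable to
JSON, analytically differentiable (exact Jacobians for the steady-state
and covariance solvers) and compilable for the simulator; ad-hoc networks
may instead pass an arbitrary rate callable and lose only those three
conveniences.

## The coarse-grained cell model

Four proteome sectors y ∈ {t, e, r, q} — transporters, catabolic enzymes,
ribosomes, housekeeping — each have an mRNA `m_y`, a translating complex
`c_y`, and a protein `p_y` (`p_r` is the ribosome itself).  Transcription
is resource-gated, `w_y X_a/(X_a+θ_y)`, with a fourth-power negative
autoregulation on the q sector; mRNAs degrade first order; ribosomes bind
and unbind mRNAs by mass action; translation of a length-`n_y` protein
consumes `n_y` resource units at rate `(X_c/n_y)·γ_max X_a/(X_a+K_γ)`;
transporters import an external nutrient held at constant level, and
enzymes catabolise it into `n_s` resource units per molecule — the
nutrient quality `n_s` is the growth-condition dial.  Mass is carried by
proteins and ribosome complexes only (protein dominates biomass), so
`λ = γ_max X_a/(X_a+K_γ) · Σ_y X_{c_y}`: elongation rate times translating
ribosomes.  Ribosome translation (`y = r`) produces two ribosomes — the
translating one released plus the new one made.

Variants: the operon model co-expresses t and e from one bicistronic mRNA
(12 species, 17 reactions; each translation adds mass `n_t+n_e` while
consuming `n_e` resources, exactly as the reaction is written — the
asymmetry is deliberate bookkeeping of the printed scheme); the
chloramphenicol extension adds `c_y → z_y` at rate `k_cm·X_cm·X_{c_y}`,
sequestering ribosome mass into translation-inactive complexes that are
only diluted and partitioned.

### Default parameters (synthetic fixture)

Supplementary calibration data for the published parameterisation were
not available, so the packaged fixture is a **synthetic reconstruction**,
assembled once and then frozen.  Literature anchors: `γ_max = 1260`
aa/min, `n_r = 7459` aa, `n_t = n_e = n_q = 300` aa, mRNA decay 0.1/min,
import and catabolic turnovers 726 and 5800/min (uptake-limited by
construction).  The free transcription capacities/thresholds, binding
rate, resource thresholds and cell-cycle constants (`O_c = 2×10⁻⁹`/aa,
i.e. unit size 3.5×10⁸ aa ≈ 0.3 μm³ at protein density ~1.2×10⁹ aa/μm³;
`τ_CD = 60` min) were chosen so that the model reproduces reported
observables: saturated growth ≤ 3.75 dbl/hr, 3–9 free t/e-mRNAs and
~9000 t/e proteins per cell, r-mRNA in the 10²–10³ range, ribosomal mass
fraction rising with growth rate, CV[λ] falling from ~0.3 (0.3 dbl/hr)
to ~0.03 (3 dbl/hr), and resource fluctuations below 80%.  One reported
band could not be met simultaneously with the copy-number anchors: the
ribosomal-mass-fraction CV stays at 2–4% across conditions (simulation
confirms the analytic value), whereas ~10–20% would require cells roughly
ten times smaller than the size and copy-number anchors permit.  The
catabolism Michaelis constant is set to `3×10⁻⁴`/aa, giving an internal
nutrient pool relaxing at ~10²/min; much smaller values make the pool a
stiff fast variable without affecting steady-state fluxes.

## Small-noise approximation

Expanding the concentration dynamics around the growing steady state (the
large-M limit) yields:

* **Means** from `νf(X̄) = λ(X̄)X̄` on the simplex.
* **Cell cycle**: `M₀ = e^{λτ_CD}/(2O_c)`, `O₀ = e^{λτ_CD}/(2 ln2)`,
  unit size `ln2/O_c` independent of conditions; bulk (population-average)
  mass `M_bulk = 2M₀ ln2`, neglecting the small birth/division size spread.
* **Covariance** from `0 = JΣ + ΣJᵀ + (λΓ + Σ_r D_r)/(2M₀ ln2)`.
  `1/(2M₀ ln2)` is the cycle-average of `1/M(t)`; the division frequency
  `λ/ln2` is absorbed into the Γ prefactor.  Reaction noise enters through
  the projected stoichiometries `ν̃_r = ν_r − X̄(mᵀν_r)`,
  `D_r = ν̃_r ν̃_rᵀ f_r(X̄)`: the direct stoichiometric kick and the
  dilution kick from the mass the same event adds share one noise source,
  so their covariance is the rank-1 outer product of the summed
  coefficient.
* **Growth noise** `CV²[λ] = ∇λᵀ Σ ∇λ / λ²` (equivalently the
  log-sensitivity quadratic form), gradients by central differences with
  relative step 10⁻⁶.
* **Decomposition**: the Lyapunov equation is linear in its inhomogeneity,
  so re-solving with one group's share of `λΓ + Σ D_r` gives that group's
  exact additive contribution to Σ and to CV²[λ].

### Partitioning noise

Binomial partitioning acts on counts, but concentrations are counts over
the *fluctuating* daughter mass `mᵀx'`.  Propagating both gives the
simplex-projected per-division covariance

    Γ = P diag(X̄) Pᵀ,   P = I − X̄mᵀ,

which we verified directly against simulated division kicks (1470 kicks
of the two-species test model: sample variance 5.02×10⁻⁵ vs 5.00×10⁻⁵
predicted).  A simpler diagonal-mass expression that subtracts the mass
correlation only pairwise is available as
`division_noise(form="diagonal-mass")`; it overestimates the kick of
abundant mass-carrying species (3.09×10⁻⁵ in the same test) while
agreeing for the low-copy massless mRNAs that dominate the cell model's
growth noise.  Variability of the inherited volume fraction adds a
further ≈1–2% to CV[λ] (measured); it is excluded from the default Γ and
from theory–simulation comparisons, which therefore simulate an even
split.

### Numerics

The steady-state system is singular along the conserved mass direction
and possesses a degenerate *washout* manifold (no growth, arbitrary
protein composition) that attracts naive root finding.  The solver
therefore (i) builds an initial point by an exact physiological reduction
of the cell model to nested, monotone 1-D bracketed problems —
q-autoregulation fixed point inside the mass-normalisation closure inside
the growth-rate identity inside the resource balance — which reliably
selects the fastest-growing root when one exists; (ii) polishes it with a
MINPACK dogleg iteration on the turnover-scaled log-concentration system,
the dominant-mass species' equation replaced by the simplex constraint
(row scaling keeps the condition number ~10⁴ instead of ~10¹⁵); and
(iii) rejects converged states with λ < 10⁻⁹/min, falling back to ODE
relaxation and seeded restarts.  Residual tolerance is 10⁻¹⁰ in the
drift infinity-norm.  The Lyapunov equation is solved in an orthonormal
basis of the hyperplane `mᵀX = 0` (where J is well conditioned; its
mass-direction eigenvalue is −λ) and embedded back; residuals are
accepted at 10⁻⁸·‖Q‖ or at the double-precision evaluation floor
`100·ε·N·‖J‖·‖Σ‖`, whichever is larger — at stiff fast-growth corners
`‖Q‖ ≪ ε‖J‖‖Σ‖` makes the relative criterion unattainable for any
solver.  Grid sweeps and MCMC warm-start each solve from the previous
solution.

## Hybrid simulation

Only the lowly abundant species need discrete treatment — by default the
t/e mRNAs and their complexes (the bicistronic pair in the operon model).
Reactions touching them fire via the modified next-reaction method with
unit-exponential clocks; propensities are frozen over 0.05-min refresh
windows (and refreshed after every firing and division), which handles
the non-exponential waiting times induced by the drifting ODE background.
All other counts integrate `dx/dt = M·ν_det f(X)` with fixed-step RK4
(default 0.005 min, set by the internal-nutrient relaxation rate;
negative excursions are clamped and counted).  Replication initiation is
detected on the continuous mass trajectory; the step is re-integrated to
land exactly on the crossing, the origin count doubles and a division is
queued `τ_CD` later — the sorted queue holds overlapping rounds at fast
growth.  At division the tracked daughter inherits a volume fraction ρ
(truncated normal, mean 0.5, sd 0.05 on [0.3, 0.7]; the complementary
daughter by flag), integer species draw Binomial(x, ρ), continuous ones
ρx plus matched Gaussian noise truncated to [0, x], origins halve
exactly, and `M = mᵀx` is recomputed — mass bookkeeping is exact by
construction rather than via an approximate log-mass jump.  In
deterministic mode (no discrete reactions, exact halving) the lineage
reproduces the analytic steady state to integration tolerance and the
doubling time `ln2/λ̄` to <10⁻⁶ relative, which is the strongest check
that the two engines share one model.

One master seed drives everything; per-lineage streams are derived
through `numpy.random.SeedSequence`.  Initial states take the analytic
concentrations at a mass just below the first initiation with one origin;
the first ten divisions are discarded as burn-in.  At strongly reduced
cell mass (the 10× mass-reduction used for noise-amplified validation)
roughly 0.5% of lineages are absorbed by the non-growing state when the
sub-copy free mRNAs dwell at zero; stationary comparisons condition on
surviving lineages and report the count.

### What the theory–simulation comparison shows

With matched noise sources the toy birth/death/synthesis model agrees
with the analytic solver in means and CV[λ] to within Monte-Carlo
precision (200 lineages × 50 divisions, bootstrap SEs over lineages;
per-lineage CV estimates carry O(1/n_cycles) bias, so pooled ensemble
moments are used).  For the 10× mass-reduced cell model the CV[λ]
agrees, while the *means* show the expected leading-order expansion error
(λ low by ~3%, the heavy-tailed resource mean larger) — corrections are
O(CV²) and become resolvable at that precision.  At physiological mass
the same deviations are ~1%.

## Trajectory analysis

Macrovariables are weighted sums of concentrations (ribosomes = free +
translating + drug-bound; mRNA groups include ribosome-bound copies).
Cross-correlations `r_AB(τ) = corr(A(t), B(t+τ))` are estimated per
lineage (division discontinuities retained; linear scale by default, log
optional) and averaged across lineages; the delay is the lag of maximal
|r|, ties broken toward the smallest then the negative lag.  The
minimal-delay graph draws a dark edge from each node to its
smallest-positive-delay target and a light edge to the second-smallest
when that target is not already reached through dark steps; edges with
|r| below 0.1 (configurable — no published threshold exists) are
omitted.  These graphs order noise propagation; they are not causal
claims.  In the uptake-limited default the t-mRNA node is a source, the
autoregulated q-mRNA a sink, ribosomes trail growth (positive r at
negative lag) and q-protein is diluted (negative r at negative lag).

## Inference

The likelihood treats the bulk ribosomal-fraction curve and the
single-cell CV²[λ] curve as independent Gaussians around the analytic
predictions on the observation grid, with a hard prior truncation at a
saturated growth of 3.75 dbl/hr.  Parameters are sampled in log space
under bounded log-uniform priors (default one decade either side) with
`emcee`; failed analytic solves count as rejected proposals and are
reported.  A synthetic-observation generator emulates the two calibration
curves with declared Gaussian noise so the machinery runs without
external data; it reproduces the noise-free predictions exactly at zero
sd and its standardised residuals are unit normal.  Only low-dimensional
refits are exercised (2–4 transcription parameters): recovery at
vanishing noise is exact to ~10⁻⁵ relative and 90% credible intervals
cover the truth in ≈88% of seeded repeats at moderate noise.  What the
synthetic curves do **not** emulate: correlated errors between
conditions, growth-rate measurement error on the abscissa, and model
misspecification — recovery results bound algorithmic, not systematic,
error.

## Problem sizes

Default test and reproduction runs use 200 lineages × 50 post-burn-in
divisions for theory–simulation validation, 9-point nutrient grids for
sweeps, a 2×6 nutrient×dose scan, and 8-walker, 150-step ensemble chains
for the inference checks; all are package defaults chosen to give
Monte-Carlo errors well below the effects being measured.

## Known limitations

* The analytic solver is a leading-order small-noise theory: covariances
  are exact only as M → ∞, and means carry O(CV²) corrections that are
  visible at artificially reduced mass.
* One ribosome per mRNA (no polysomes), lumped single transporter/enzyme
  species, no explicit (p)ppGpp/cAMP regulation, constant environment
  within a run, protein-dominated mass with no volume/density model.
* The hybrid split treats r/q mRNAs as continuous; at strongly reduced
  mass their discreteness is real but unmodelled.
* The washout state is absorbing in the stochastic model; survival
  conditioning is the user's responsibility at extreme noise.
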