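# Methods

## Model

The community is a chemostat food web: one dissolved nutrient pool `N`, two
bacterial competitors `B1` (fast, metabolic scaling `y1 = 7.5`) and `B2`
(slow, `y2 = 4`), their phage-infected compartments `I1`, `I2`, and two
species-specific phage populations `P1`, `P2`.  All state variables are
biovolume densities normalized by the bacterial half-saturation biovolume,
so the half-saturation density is exactly 1 and laboratory abundances map
back through `phagestrat.units` (bacteria: ÷10⁷ particles mL⁻¹; phages carry
an extra biovolume factor `c = 3.14·10⁻⁴` per particle).

Growth follows a Type-2 (Monod) functional response `G_k(N) = x y_k N/(N+1)`
with a shared metabolic rate `x = 0.0206 h⁻¹` that also sets the metabolic
loss of every bacterial compartment.  Phage adsorption is mass action,
`i B_k P_k`, with `i = 5.23 h⁻¹` (the normalized form of 1.64·10⁻¹⁰ mL h⁻¹;
the conversion multiplies by the half-saturation abundance and divides by
the phage/bacterium volume ratio, and the code computes 5.2229 rather than
storing the rounded table entry).  An infected cell's biovolume grows by the
adsorbed phage's share, hence the `(1+c)` gain factor; the phage pool loses
the corresponding `c i B_k P_k`.

Lysis converts infected biovolume at the strategy-dependent rate `s_k`: a
fraction `n = 0.02` becomes phage particles and, with the viral shunt
enabled (the default), the remaining `1 − n` returns to the nutrient pool.
The nutrient pool is shared, so consumption and shunt terms sum over both
species.  Nutrient enters by chemostat turnover `D (N0 − N)` with
`D = 1/24 h⁻¹`; environmental variability multiplies the turnover by
`1 + a sin(2πt/T)` with relative amplitude `a < 1` (positivity) and period
`T`.

### Phage strategies and the lysogenic switch

The three strategies differ only in the lysis law: constant `s = 0.33 h⁻¹`
(lytic), increasing sigmoid in total host density `B_k + I_k` with
half-saturation constant `SH = 4` (PtL), and a decreasing function with
correction parameters `r = 0.5`, `H = 1` (PtW).  A single switching rule
encodes lysogeny: infected cells grow and consume nutrient exactly while
their current lysis rate is ≤ `s_switch = 0.0033 h⁻¹` (1% of the maximum;
0.001 and 0.165 are available for the sensitivity presets).  Because the PtL
rate is small at low density and the PtW rate is small at high density, the
one rule produces lysogeny-when-rare (PtL) and lysogeny-when-abundant (PtW).
The equivalent density thresholds, obtained by inverting the lysis laws, are
`sqrt(s_switch·SH/(s − s_switch)) = 0.2010076` and
`sqrt(s/s_switch − H)/r = 2√99 = 19.89975`.

With the `NONE` strategy the infected and phage compartments are pinned at
zero and the model reduces to pure resource competition, where the fast
grower always excludes the slow one — the baseline against which
phage-mediated coexistence is measured.

## Numerical integration

The right-hand side is discontinuous at the switching density.  We evaluate
the lysogenic boolean inside every RHS call and let adaptive step-size
control resolve the discontinuity, keeping the RHS pure (no event location).
The integrator is an embedded Cash–Karp 5(4) pair with standard
proportional error control (RMS norm over `atol + rtol·|y|`, growth capped
at 5×, shrink floored at 0.1×, minimum step 10⁻¹⁰ h), compiled with numba;
it steps exactly onto each requested output time.  Defaults:
`rel_tol = abs_tol = 10⁻⁸`, output every 1 h, `t_end = 43 800 h` (5 years)
with the leading 80% discarded as transient — long enough for several
cycles of the slowest forcing period studied (1 year).  The pure-Python
reference RHS and the compiled kernel are asserted equal to machine
precision in the test suite, and short trajectories are cross-checked
against scipy's independent RK 5(4) implementation.

Components that round off marginally below zero are clamped to zero for
rate evaluation only; no floor is imposed on the solution, so extinction is
asymptotic decay and is judged at classification time, not in the dynamics.

A practical note: when a host density slides along the switching manifold
(notably PtL at supply concentrations above ≈10), the step controller
chatters against the discontinuity and single trajectories can take orders
of magnitude longer than typical.  The analysis presets therefore keep
their supply grids where the dynamics are well behaved unless a user asks
otherwise.

## Classification and analyses

A component survives a run when its **maximum** over the post-transient
window is at or above the extinction threshold, default 10⁻⁶ normalized
(≈10 bacteria mL⁻¹) — far below every attractor scale, far above solver
noise; the maximum (rather than the final value) keeps oscillating
populations that dip low from being misclassified.  Phage and its infected
compartment count as one "infection" state; the persistence code is the
number of surviving states among {B1, infection 1, B2, infection 2}, 0–4.
Off-ladder flag combinations (e.g. PtW at high supply, where the uninfected
fast grower dies while its lysogenic infected line persists) keep their
full flag vector.

Oscillation extrema for bifurcation diagrams come from a plain
post-transient extrema detector: a series whose relative amplitude is
≤ 10⁻³ is steady and reports its mean; otherwise interior local extrema are
found by sign changes of the discrete differences (plateaus carry the
previous slope; a still-monotone series falls back to its overall range).

- **Bifurcation scans** run one simulation per supply concentration
  (`N0` ∈ [0.6, 30]); the fluctuating variant uses `a = 0.5`, `T = 7 d`.
- **2-D sweeps** classify persistence on amplitude × supply grids
  (period fixed at 30 d) or period × supply grids (log-spaced 1 d–1 yr,
  amplitude fixed at 0.9), with supply in [0.6, 8].
- **Critical supply levels** (e.g. the PtW fast-grower extinction
  threshold) come from bisection of the survival predicate, each predicate
  evaluation being a full simulation.

Default grid resolutions (60 supply points, 25 amplitude, 25 period) are a
desk-scale choice that resolves the region boundaries; the acceptance
checks use 15×15 grids and 2-h output sampling, which classification is
insensitive to since the relevant dynamics are on day scales.  Scans record
per-cell integration failures instead of aborting.

## Scenario configuration

Scenarios are YAML files validated against a strict schema (unknown keys
rejected, `a < 1`, `y1 > y2 > 1`, `s_switch < s_max`, grids confined to the
studied ranges unless extrapolation is explicitly allowed) that round-trip
exactly through load → save → load.  Thirty-one bundled presets name the
study's scenarios: the four baseline time series at `N0 = 2`, constant and
fluctuating bifurcation scans per strategy, amplitude and period sweeps per
strategy, low/high growth-rate variants (`y1, y2` ∈ {3.75, 2} and {15, 8}),
switching-point and lysis-rate sensitivity runs, and shunt-disabled scans.

## Design choices where the design was open

- Initial conditions are fixed for all runs: `B_k = 0.83`, `I_k = 0.17`,
  `P_k = 3.10·10⁻⁴` normalized, `N(0) = N0`.  The phage initial density uses
  the tabulated normalized value verbatim even though the volume-ratio
  conversion of 10⁷ particles mL⁻¹ would give 3.14·10⁻⁴; the reference
  values disagree at the third digit and we use each in its own role rather
  than force a consistency they lack.
- The metabolic rate `x = 0.0206 h⁻¹` is taken as a given constant; the
  body-mass conversion chain behind it is outside scope.
- Whether a non-growing (lytic-phase) infected cell still consumes nutrient
  is ambiguous in a single-equation statement of the nutrient balance; we
  couple consumption to the growth switch (a compartment that cannot grow
  does not take up nutrient), conserving the growth/uptake pairing.
  Re-infection of infected cells is excluded.
- Total simulated time and sampling are not externally fixed; 5 years with
  an 80% transient is long enough that halving the solver tolerances moves
  the baseline endpoints by less than 10⁻⁴ relative, and the closed-form
  single-species equilibrium (`N* = 1/(y−1)`, `B* = D(N0−N*)/x`) is
  recovered to 10⁻⁶ relative.

## What the simulations do and do not show

All results are properties of this deterministic ODE model under the stated
parameterization: two species, one nutrient, species-specific phages, no
stochasticity in lysogeny induction, no latent period or explicit burst
size, no resistance evolution, no spatial structure, and no stoichiometric
(C/N/P) accounting of the lysate.  Passing tests demonstrate faithful
reproduction of the model's dynamics — competitive exclusion without
phages, phage-mediated coexistence under all three strategies, shunt-driven
enrichment shifting coexistence onsets to lower supply, robustness of
coexistence to ≤50% supply fluctuations, PtL's broader coexistence range
than PtW's, and the growth-rate resilience effect — not predictions about
any particular natural community.

## Known limitations

- The discontinuous lysis switch makes some high-supply PtL trajectories
  expensive (sliding-mode chattering); an event-locating or regularized
  integrator would help if those regimes become a focus.
- The extinction threshold is a classification convention; codes near
  region boundaries can shift by one cell on coarse grids when the
  threshold moves by ±2 orders of magnitude, which the test suite probes
  only at its default.
- Under PtW with constant supply the uninfected fast grower's extinction
  threshold computes to `N0 = 10.05` here (bisection, insensitive to solver
  tolerance, horizon, and threshold); disabling the viral shunt moves it to
  11.60.
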