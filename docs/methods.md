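# Methods

## Models

All oscillators are autonomous ODE systems integrated in hours.

**Harmonic / Duffing.** `x'' + (k/m) x + (β/m) x³ = 0`, integrated as the
first-order pair `(x, v)`.  These conservative systems carry no limit
cycle: amplitude is set by the initial condition, so twist is probed by a
sweep of initial displacements (at rest, `(x₀, 0)`).  The defaults
`m = k = 1`, `|β| = 1` are package conventions — the models are
dimensionless and no canonical values exist for them; `β = +1` (hard
spring) is the default, `β = −1` the soft variant.  For `β = −1` the
potential barrier sits at `|x| = 1`, so displacement sweeps stay at or
below 0.6.

**Goodwin / Gonze.** Three-stage delayed negative feedback (mRNA x →
protein y → repressor z ⊣ x) with Hill repression
`k1·K1ⁿ/(K1ⁿ + zⁿ)`.  Goodwin degrades linearly and needs a steep Hill
exponent (default n = 9.5, with k4 = 0.15 h⁻¹, adapted so the defaults
oscillate rather than ring down); Gonze degrades through saturating
Michaelis–Menten terms, which lets n = 4 suffice.  Gonze defaults:
k1=k3=k5=0.7, k2=k4=k6=0.35, all Michaelis constants 1.

**Almeida.** Eight clock proteins coupled through three
clock-controlled-element activities,

    Ebox = VE·B/(kE + B + kEr·B·CRY)          (competitive CRY inhibition)
    RORE = VR·ROR/(kR+ROR) · kRr²/(kRr²+REV²)
    Dbox = VD·DBP/(kD+DBP) · kDr/(kDr+E4BP4)

with the R-box activity in the E4BP4 and CRY equations identical to RORE
(no separate element exists in this model).  `γ_PC` multiplies `PER·CRY`
(complex association) and `γ_CP` multiplies `PERCRY` (dissociation), as
the equations are wired.  With the default 18-parameter table the model
oscillates with a ≈20.0 h period and no period doubling.  The competitive
E-box form was selected over a multiplicative
`VE·B/(kE+B) · kEr/(kEr+CRY)` variant because only it reproduces the
variable-dependent twist fingerprint this package tests (VD heterogeneity:
negative twist read on BMAL1, none on PER, positive on PER:CRY) and a
circadian-range period (the multiplicative variant runs at ≈50 h).

**Poincaré with twist.** `r' = λr(A−r)`, `φ' = ω + ε(A−r)`; Cartesian
form used for all forced experiments, with zeitgeber, mean field and
pulse added to `x'` only.  Defaults A = 1 a.u., λ = 0.05 h⁻¹, τ = 24 h,
ε ∈ {0, ±0.1} h⁻¹.

## Numerics

ODEs are solved with `scipy.integrate.solve_ivp` at `rtol 1e-8`,
`atol 1e-10`, output step 0.05 h: LSODA for single kinetic-model runs,
the explicit high-order DOP853 for the smooth mechanical/amplitude-phase
models (conservative energy drift < 1e-6 relative over 500 time units)
and for all *batched* runs.  Ensembles, bifurcation-branch simulations
and zeitgeber grids are integrated as one stacked ODE system with a
vectorised right-hand side — numerically identical to per-member
integration (checked in the tests) and an order of magnitude faster.
Square pulses and the coupling switch-on are handled by segmenting the
integration at the discontinuity, never by stepping across it.

Periods: post-transient signal normalised to its mean, centred, zeros by
sign change + linear interpolation; the period is the mean spacing of
consecutive downward zeros.  Amplitudes: mean peak-to-trough of the last
5 cycles (configurable), peaks refined by quadratic interpolation through
the three samples around each discrete extremum; computed on the
mean-normalised signal (relative amplitude) except for near-zero-mean
signals such as the Poincaré `x`, where division by the mean is
meaningless and the raw distance is used.

Classification rules (the sources state none, so these are package
choices): a signal is *oscillatory* if its relative amplitude exceeds
1e-3 **and** the coefficient of variation of its last five peak heights is
below 1e-2 (damped rhythms fail the latter); *period doubling* is flagged
when successive peak heights alternate in sign of change with an
odd/even split above 5 % of the amplitude.

Transient discards: 500 h for the kinetic models, except the Gonze model,
whose limit cycle attracts on a ≈800 h Floquet timescale — its ensembles
discard 1000 h so that slowly-settling members are not misread as damped.
Poincaré experiments discard 40 cycles unless stated.

## Parametric twist protocol

Heterogeneity: each varied parameter is multiplied by an independent
uniform factor on `[1−f, 1+f]` (f = 0.1 or 0.2).  Uniform was chosen
because the stated heterogeneity is a bounded percentage range; the
distribution is isolated in `draw_ensemble` and swappable.  Joint
heterogeneity draws each parameter's factor independently.  One seeded
generator drives all draws.

Members are filtered before correlating: non-oscillatory members,
relative amplitude < 0.1, and (for the Almeida model) period-doubled
members are removed.  The correlation is Spearman's rank statistic,
two-sided; for fewer than 20 retained members the p-value comes from a
seeded randomised permutation test (9999 resamples) instead of the
asymptotic approximation — full enumeration is infeasible beyond n ≈ 12.
Labels: *positive*/*negative* when p < 0.001, else *none*.  In
amplitude-ratio mode (Almeida protocol: member amplitude divided by the
unperturbed model's amplitude) an ensemble whose ratio range is below 0.1
is *no twist* regardless of ρ, since a rank statistic is blind to effect
size.

## Bifurcation scans

Steady states of the Goodwin/Gonze loops reduce to a scalar fixed-point
equation in the repressor, solved by bracketed bisection (for Gonze the
bracket is grown from the feasible side of the Michaelis–Menten flux
ceilings); other families use a Newton-type solve.  Jacobians are central
differences (relative step 1e-6).  A scan walks a 100-point grid with
steady-state continuation, records the leading eigenvalue real part, and
refines each sign change by bisection to 1e-3 in the parameter — a
deliberate replacement for pseudo-arclength continuation, adequate for
one-parameter Hopf pairs.  Branch oscillation profiles are simulated by
*cycle continuation*: settle once at the most unstable grid point, then
walk outward restarting each member from its neighbour's final state,
which sidesteps the critical slowing down near the Hopf points; residual
finite-settling bias remains visible as small nonzero amplitudes at the
outermost oscillatory grid points.

## Pulses, isochrones, entrainment, coupling

Conventions: the oscillator starts on its cycle with φ(0) = 0; **CT0 is
the x-maximum** (this anchor shifts PRCs horizontally and is stated
wherever phases are reported); phase shifts are in hours, **advances
positive**, wrapped to (−12, 12].  Pulses are additive in x;
"amplitude-increasing" is achieved by timing (+x at CT3).

Latent phases are computed two independent ways: the closed form
Φ = φ − (ε/λ) ln(r/A), and stroboscopic integration of the polar flow
(footprints every τ, convergence 1e-4 rad, ≤200 cycles).  Their agreement
to <1e-3 rad over a (φ, r, ε, λ) grid is the package's central oracle.

Transient cycle lengths after a pulse (`transient_twist`) are delimited
by downward mean-crossings of x rather than x-maxima: the peak condition
of a radially relaxing orbit mixes `dr/dt` into the projection and
displaces peaks by ≈0.1 h even with ε = 0, whereas x = 0 occurs at fixed
phase for any radius, so crossings read the phase dynamics exactly (a
`peaks` mode is available for comparison).

Entrainment criterion (package choice; cheap and robust): after
discarding 80 zeitgeber cycles, locked iff the mean x-peak spacing over
the last 10 cycles is within 0.05 h of T and the stroboscopic drift of
peak times is below 0.05 h/cycle; the F = 0 column is not entrained by
definition.  Resonance curves report the mean peak-to-trough amplitude
for every cell and a masked copy restricted to entrained cells (whether
off-tongue cells belong in such curves is a presentation choice, so both
are emitted).  The phase of entrainment is the x-maximum relative to the
zeitgeber maximum (positive = clock peaks after the zeitgeber).

Coupling: 2N equations integrated jointly with the mean field inside the
right-hand side; the field is zero before the switch-on time (default
240 h).  Initial phases are seeded-uniform or all-zero (the overlap
protocol).  *Synchronization is frequency locking* — each member's peak
spacing matches the mean field's within 0.05 h with spacing variability
below the same bound.  The Kuramoto order parameter is kept as a
diagnostic only: a locked mixed-twist network retains ±4 h lags and an
order parameter near 0.6, so an alignment threshold would misclassify
exactly the regime of interest.

## Problem sizes and known limitations

Ensembles use n = 100 (Goodwin/Gonze) and n = 40 (Almeida) members, the
stated heterogeneities, and 5 seeds in the sign suites; tongue/resonance
scans use T ∈ [16, 32] h at 0.25 h steps, F ∈ [0, 0.4] at 0.02; PRCs in
the ordering suite use 12 pulse phases.  These are the sizes at which all
reported statistics were computed.

Findings that qualify the headline claims, measured with this code:

* The zero-twist resonance maximum falls at T = 23.75 h on the 0.25-h
  grid — one grid step shy of the intrinsic 24 h, a genuine small skew of
  the peak-to-trough readout at F_Z = 0.05, not a transient artifact.
* The driven single oscillator at zero detuning entrains robustly up to
  |ε| = 2 h⁻¹ (the forced orbit hugs r = A, where twist is inert);
  entrainment failure appears from |ε| ≈ 3 h⁻¹.  Likewise a mixed
  network's large-twist member desynchronizes the network from ε ≈ 2 h⁻¹.
* Identical-pair coupling at λ = 0.05 leaves the locked oscillatory
  regime near K = 0.2 for ε = +0.1 (the inflated radius drives
  ω + ε(A−r) through zero), so coupled-period trends are only meaningful
  on the locked K range.
* The equal-degradation Goodwin instability threshold is n = 8 only as an
  infimum: the self-consistent secant condition gives 8.06–8.21 for
  transcription rates and repression constants of order one, and the scan
  reproduces those values, not 8.0 exactly.

What the synthetic experiments do *not* emulate: molecular noise,
cell-to-cell coupling heterogeneity beyond the mean field, delays,
nuclear transport, or any data-derived waveforms.  Passing tests show the
deterministic models behave as analysed; they say nothing about
inference from noisy experimental rhythms.
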