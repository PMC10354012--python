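# Methods

This note documents the models behind `treskit`, the defaults they run with,
the numerical choices in the analysis code, and what the synthetic
generators do and do not emulate.

## Single-file permeation surrogate

The ion-conduction surrogate (`treskit.simulate.permeation`) is a
continuous-time Markov jump process over the ladder

    intracellular bulk <-> cavity <-> S4 <-> S3 <-> S2 <-> S1 <-> extracellular

with hard single-file exclusion: every in-filter station holds at most one
ion. Four labelled ions start stacked in the filter (role 1 at S1 through
role 4 at S4, matching the fully occupied initial condition of conduction
simulations); an unlimited intracellular reservoir feeds the cavity, and
ions that leave either end are parked in a bulk pool from which they may
re-enter last-in-first-out. A `voltage_bias` factor multiplies all outward
rates, emulating a constant outward electrostatic field; bias 1 with
symmetric rates gives zero net flux (tested by a sign test on completed
boundary crossings), bias > 1 drives net outward permeation.

**Rates are free parameters.** No quantitative hop rates exist for the
channel variants, so the surrogate makes no claim of physical fidelity; it
reproduces the *statistical structure* the analyses assume. Two regimes are
preconfigured:

* `wt_config` / `t322a_config` — occupancy regime (150 ns, 0.1 ns sampling,
  3 replicates): dwell-dominated rates (0.6–1.2 ns⁻¹ in-filter, slow
  0.04 ns⁻¹ exit) so ions mostly sit at sites, as in field-free runs. The
  inner-filter-impaired variant scales the S3↔S2 and S2↔S1 rates by 0.25
  (configurable) — the qualitative, not quantitative, phenotype of the
  conduction-impairing filter mutation.
* `esf_config` — conduction regime (100 ns, outward bias 2.5, fast
  0.5 ns⁻¹ exit): here the inner-filter hops are rate-limiting, so slowing
  them visibly prolongs the 3rd/4th first-passage steps. With the slow
  default exit rate the exit step dominates both variants equally and the
  contrast would be masked; this is a regime choice, fixed before use as
  the transition-timing condition.
* `rb_config` — Rb⁺ emulation: strongly elevated S1→out rate (quick loss of
  the outermost ion) and mildly rebalanced inner rates, giving the
  species-dependent occupancy shift at S2/S3.

**Emitted observable.** Each labelled ion emits its distance to the
S1-forming reference on the sampling grid: the canonical site distance
(S1 = 1.5, S2 = 4.5, S3 = 7.5, S4 = 10.5 Å, cavity = 14 Å — spread across
the 0–16 Å histogram axis) plus Gaussian jitter (SD 0.4 Å), with a 0.2 ns
linear transit ramp after each in-filter hop. The ramp matters: without it
a jump process shows no between-site presence at all, and slowing hop rates
could not deplete the between-peak occupancy density the way an impaired
filter does. Exited ions are parked at 16.5 Å (extracellular) or 18 Å
(intracellular bulk) — sentinels just past the cavity end of the axis, a
deliberate convention rather than a geometric claim. A physically literal
extracellular distance (6–8 Å from the reference) would alias with S3 on
the shared axis; the sentinel keeps the assignment ladder monotone while
the role-based exclusion rule below behaves exactly as for real data.
Replicate *r* uses the deterministic child seed `seed + r`, so replicate
counts can grow without reshuffling earlier replicates.

## Trajectory post-analysis

* **Exclusion rule.** The outermost ion is excluded record-wise when its
  distance to the S1 reference exceeds 5 Å (it has left the filter); the
  innermost ion when its derived distance to the S4-forming residue,
  `|d − 10.5 Å|`, exceeds 5 Å. Only the single shared distance column
  exists, hence the derivation; the offset is configurable. Individual
  records are removed, never whole frames, and intermediate-role ions are
  never excluded.
* **Histograms.** 50 equal bins over 0–16 Å, left-closed/right-open with the
  final bin closed; out-of-range records are tallied as overflow, never
  silently dropped, so `binned + overflow = retained` holds exactly.
  Relative counts are normalized over binned records; difference profiles
  (`mutant − wild-type` per bin) therefore sum to zero.
* **Site assignment.** Nearest-site assignment with a hysteresis dead band
  (default 0.5 Å) around the midpoints between adjacent sites: a new site is
  adopted only when the distance penetrates the neighbouring core by more
  than half the band, which suppresses jitter flicker at boundaries. Site
  maps whose spacing does not exceed the band are rejected.
* **First-passage transitions.** Transition *k* of the tracked (innermost)
  ion is the first time its assigned site reaches the *k*-th station above
  S4 in conduction order (S3, S2, S1, out). Stations skipped between
  samples are credited at the time the farther station is first seen;
  back-steps never erase an achieved transition. The exit station counts
  only when the last in-filter assignment was S3 or above, so an inward
  tumble into the cavity bulk (whose sentinel also lies past the axis end)
  is not mistaken for a permeation; a fast inward passage from S3 through
  the cavity within one 0.1 ns sampling interval would evade this guard,
  but requires three against-gradient hops in 0.1 ns and is negligible at
  the configured rates. Transitions not reached by the end of a run are
  censored; replicate summaries report mean ± SEM (n−1 denominator, n ≥ 2)
  over achieving replicates with censored counts alongside, never imputed.

## Residue-motion coupling

Displacements follow a latent-factor model `x_i(t) = Σ_k L_ik f_k(t) + ε_i(t)`
with independent standard-normal 3-vector factors per frame. The implied
motion correlation between residues is the cosine of their loading rows
attenuated by noise (`implied_correlation` gives the closed form); the
block-structured demo couples each M4 helix to its neighbouring filter
loops through one factor per channel half, leaving cross-half blocks at
zero. The DCCM uses the isotropic (dot-product) definition. Replicates are
accumulated by mean-centering each independently and concatenating — the
result is the correlation of the pooled centered series, *not* the average
of per-replicate matrices, and inter-replicate drift cannot masquerade as
correlation. Zero-variance residues yield flagged NaN rows, never silent
zeros. Finite-sample matrices recover the implied correlation statistically
(≈ 1/√frames); only degenerate loadings (ρ = ±1, noise 0) are recovered to
machine precision, which is what the exactness tests assert.

## TEVC surrogate and analysis

Sweep currents follow
`I(t) = g · r(V) · (V − E_rev) · P(t) · A(t) + I_cap(t) + noise` with

* `E_rev` from the Nernst relation per solution block (default 100 mM
  internal K⁺, 20 °C; 2 mM bath gives −98.8 mV),
* rectification `r = 2` applied above `E_rev` (outward asymmetry),
* wash-in `P(t)`: a fast saturating component (τ = 5 s) plus a slow one
  whose onset is delayed (τ = 30 s, delay 15 s). A plain sum of two
  saturating exponentials has a strictly decreasing slope and cannot show
  the temporary plateau seen 10–20 s into compound application; the onset
  delay produces the interior slope minimum that defines the biphasic
  shape. Washout relaxes back through the same components. When a
  dose-response model is attached, the saturated amplitude of each
  compound block is the closed-form activity at that concentration.
* inactivation `A(t)`: during hyperpolarizing segments the current decays
  exponentially (τ = 50 ms) toward `1 − F_I/100`, with
  `F_I = a − b·cˣ` of the preceding depolarization duration *x*
  (defaults a = b = 15.9 %, c = 0.98 ms⁻¹-scale). The compound reduces
  `F_I` by a factor 0.7 at full receptor occupancy, scaled by the Hill
  occupancy at the block concentration — so activity measured from sweeps
  carries a small realistic upward bias relative to the attached
  dose-response model (visible in the README example).
* a 1 ms capacitive transient at every voltage-step edge, so that the
  2 ms-delayed tail window is meaningfully exercised.

**Measurement windows** are not dictated by any protocol standard and are
configurable: steady state averages the final 50 ms of a segment; the tail
averages 5 ms starting 2 ms after the step edge, skipping the simulated
transient (residual contamination < 2 % of the step amplitude).
Dose-response activities use the mean of the last three sweeps of each
application block (quasi-steady state).

**Fits.** All nonlinear fits run through lmfit with analytic-free
covariance SEs and explicit convergence flags. The Hill fit fixes the
minimal activity at zero and initializes E_max at the observed maximum,
EC50 at the geometric mean of the concentration range, h = 1 (h is left
free). The asymptotic growth fit constrains 0 < c < 1 and seeds the
optimizer from a grid over c with amplitudes solved linearly, which makes
degenerate (constant) inputs land on b ≈ 0 instead of diverging. The
single-exponential fit flags flat traces as non-identifiable rather than
reporting a meaningless τ.

**Classification logic.** Stoichiometry and antagonism decisions use
z-tests on fitted parameters at α = 0.05 with propagated ratio SEs (a
vanishing SE degenerates to an exact comparison): E_max ratio ≈ 0.5 with
EC50 ratio ≈ 1 ⇒ proportional two-site occupancy; E_max ratio ≈ 1 ⇒ a
single site suffices. Across antagonist levels, a significant monotone
E_max decrease with stable EC50 ⇒ noncompetitive (allosteric), the reverse
⇒ competitive, anything else ⇒ indeterminate; K_b is additionally
estimated by fitting the apparent-parameter relations
`E_max/(1 + [B]/K_b)` and `EC50·(1 + [B]/K_b)`.

**Group statistics** use one-way ANOVA with Tukey HSD (scipy), the
pooled-variance two-sided t-test, per-group SEM (n−1), and the
conventional star thresholds (ns > 0.05, * < 0.05, ** < 0.01, *** < 0.001).

## Problem sizes and noisy-recovery tolerances

Recovery studies run 100 seeded noise realizations: Hill fits at 10
replicates × 6 concentrations with additive noise of 10 percentage points,
growth fits with 2-point noise on 8 inter-pulse durations, exponential
fits at SNR ≈ 10. The stated tolerances (EC50 within 15 %, steady-state
F_I within 20 %, τ within 10 %) hold at the distribution level (median
over seeds); individual seeds can stray further — the additive noise is
proportionally enormous at sub-µM concentrations, which occasionally drags
a single EC50 estimate beyond 20 %. Variant-emulation comparisons use 50
replicates per arm for first-passage times and 25 single-replicate 50 ns
runs per arm for between-site density, both evaluated by one-sided
Mann-Whitney tests; demo pipelines default to 10–30 ns runs so the whole
suite and the acceptance script finish in seconds.

## What the generators do not emulate

The hopping surrogate has no energetics, no force field, no membrane and
no water: rates are phenomenological, jitter is Gaussian and uncorrelated,
and exit geometry is a bookkeeping convention. The motion generator has no
time correlation between frames (each frame is i.i.d.), so it validates
correlation *structure*, not kinetics. The sweep generator is an ohmic
conductor with multiplicative gating states; it has no leak, no series
resistance, no liquid-junction offsets, and its noise is white. Passing
tests therefore demonstrate that the analysis chain measures what it
claims to measure on data with the assumed structure — not that real
trajectories or oocytes satisfy those assumptions.

## Known limitations

* The exclusion rule judges the innermost ion against a derived S4 distance
  and will also exclude it if it ever crosses to S1/S2 territory; in the
  occupancy regime this is vanishingly rare, in strongly biased runs the
  exclusion step is not used.
* Retained-record counts depend on the stochastic boundary-ion excursions
  and are therefore reported, not asserted.
* The antagonism trend test requires monotone, individually significant
  parameter shifts; shallow antagonist series with large SEs will return
  "indeterminate" rather than guessing.
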