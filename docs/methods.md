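# Methods

This note documents the models and procedures implemented in `wheatsa`:
what each component assumes, which knobs matter, which design choices
were genuinely open and how they were resolved, and what the synthetic
test bed can and cannot demonstrate.

## The synthetic environment

`wheatsa.synthetic_env` generates the three kinds of input a crop-model
sensitivity study consumes: daily weather, a soil store, and irrigation
treatment plans.

**Weather.** One season of daily (Tmax, Tmin, precipitation, solar
radiation) starting at sowing in mid-September. The mean-temperature
cycle is a two-harmonic annual wave (mean 6.5 °C, fundamental amplitude
19 °C, second harmonic 5.5 °C); the second harmonic deepens the winter
and broadens the warm season, which is characteristic of the arid
continental target climate (~−18 °C in mid-January, ~+20 °C in July).
Precipitation is a Bernoulli–exponential process tuned to ≈190 mm
annually; radiation follows a clear-sky seasonal curve (16.5 ± 10.5
MJ·m⁻²·d⁻¹). All noise is seeded; generation is pure in
`(seed, season_days, climate)`. The default series length is a full
sowing-to-sowing year (365 d): harvest happens at simulated maturity
(typically day 260–290, early July), but the ±50% phenology bounds
include corners needing ≈2,600 °C·d of development thermal time, which a
290-day window cannot supply under this climate — the worst corner
matures around day 333, and truncating it is treated as an error, never
silently. The generator emulates the *seasonal structure* of the site;
it does not reproduce inter-annual persistence, dew/frost timing or any
real station record, so passing tests say nothing about fidelity to a
particular year's weather.

**Soil and treatments.** A single-bucket store over 600 mm of rooting
depth at 26.15% volumetric field capacity (157 mm). The six treatments
W1–W6 set phase-wise lower irrigation limits at 50/65/80% of field
capacity over seven growth phases (seedling, wintering, greening,
jointing, heading, grain filling, maturity); allowable depletion is
FC × (1 − limit). A higher lower limit is a wetter regime.

**Observations.** Emulator truth plus seeded additive Gaussian noise
(default SD 300 kg·ha⁻¹ — a design choice matching the Gaussian
calibration likelihood; no published value exists), tagged by
(treatment, year, variable).

## The wheat emulator

`wheatsa.emulator` is a deterministic daily-step *emulator*, not a
mechanistic crop model. Its purpose is to give every driver in the
package a realistic 21-parameter target whose **global sensitivity
structure** matches what has been reported for a full wheat simulator
under ±50% parameter perturbations: biomass (WAGT) dominated by the
thermal-time targets T1, T2, T4 and water demand E1; yield additionally
by grain number G1, the grain-set window T3, the filling rate P1 and
the extinction coefficient K; everything else below the influence
thresholds. The constants in `EmulatorConstants` were fixed once against
that structure and ship frozen with regression tests.

Stages (per day, vectorized over parameter sets):

1. **Phenology.** Development thermal time min(20, max(0, Tmean − 2.5))
   accumulates through stage boundaries at T1 (jointing), +T2
   (flowering), +T3 (grain-fill onset), +T4 (maturity); pre-jointing
   development is slowed by 1/(1 + 0.02(P4 + V1)). The development base
   temperature sits above the growth base (0 °C) and hot days saturate
   at the cap, so boundary dates spread widely across the spring
   calendar — this is what makes the early windows expensive in days
   and gives T1 its leading role. The final day of the season is
   weighted by the fraction of thermal time actually needed, so outputs
   vary smoothly with the thermal-time targets.
2. **Canopy.** Leaf area starts from I1 × plant density and expands at a
   thermal-time-paced rate (leaf appearance is temperature-driven),
   weakly modulated by (Y1/33500)^0.25 and (I1/200)^0.15, slower after
   jointing, capped at I2, senescing under water stress at rate ∝ S1.
   Expansion is deliberately *not* assimilate-driven: feeding the
   biomass increment back into leaf growth creates an exponential early
   phase that amplifies Y1, I1 and K far beyond their reported roles.
3. **Biomass.** dW = R1 × radiation × f × Wfac × Nfac × Tgrow with
   interception f = 1 − exp(−(0.48 + 0.12·K)·LAI_green): the floor is
   stem/ear interception, so K's vegetative influence is modest, as
   reported. The nitrogen factor blends clamp(2 − 0.5·N1, 0.5, 1.25)
   with a baseline at weight 0.55 — the site is fertilized to local
   practice, so nitrogen-response parameters express only partially.
   Tgrow ramps from 0 at 0 °C to 1 at 8 °C: no winter assimilation.
   Stress sensitivity is stage-dependent: Wstress^0.5 before flowering
   (osmotic adjustment), Wstress through flowering, Wstress^2.4 during
   grain fill (the drought-critical phase).
4. **Water.** Demand = E1 × reference demand (radiation- and
   temperature-driven, gated by the growth ramp, capped at 12 mm·d⁻¹ as
   an atmospheric ceiling); extraction is capped at 7.2% of stored
   water per day; Wstress = supply/demand ∈ [0, 1]. Irrigation is a
   proportional drip controller: daily inflow closes half the deficit
   to the phase's moisture setpoint (halfway from the treatment's lower
   limit to field capacity). The controller is smooth and monotone in
   the lower limit — instantaneous refill-to-FC events inject
   discontinuities whose broadband spectral leakage corrupts the
   small-sample FAST estimator, and the drip protocol being emulated is
   itself continuously regulated.
5. **Grain.** Grain number = G1 × (anthesis-window growth + 0.2 × shoot
   mass) × duration windows (T1/600)^0.75 · (T2/800)^0.45 · (T3/180)^0.75
   — the classic growth-around-anthesis grain-number model with
   tillering, spike-growth and grain-set windows; grain number in wheat
   integrates these phase durations. Lag filling at 0.25·P2 per day;
   main filling co-limited between the sink rate 0.2·P1·(1 − X1 ×
   cold penalty) and the per-grain source (the exportable share of
   current assimilate — green-leaf interception with extinction
   0.03 + 1.25·K — plus a stem-reserve flow) through a q-norm blend
   rate = (sink^−q + source^−q)^(−1/q), q = 2.3. The smooth co-limitation
   keeps both the sink parameter P1 and the source parameters (K, E1)
   influential, where a hard minimum silences whichever side is
   momentarily slack. Per-grain mass is capped at M2; grain-N
   accumulation (M1, P3) drains reserves; yield = grains × grain mass,
   capped at 0.55 × WAGT.

**What the emulator does and does not show.** Passing the structure
tests shows the screening/concordance/calibration machinery behaves
correctly on a nontrivial, interaction-rich, 21-parameter crop-like
response with the reported influence pattern. It does *not* validate
agronomic predictions: absolute yields (≈1.5–4 t·ha⁻¹, harvest index
≈0.1–0.2) are on the low side of deficit-irrigated winter wheat, several
mechanisms (grain-fill export share, the duration windows, the nitrogen
blend) are phenomenological devices chosen for their sensitivity
signature, and no nitrogen cycle, salinity or multi-layer soil exists.
Quantitative index values from the real simulator are not reproducible
without it; only the qualitative structure is.

## Screening engines

**Morris.** Randomized trajectories on a p = 4 level grid with
Δ = p/(2(p−1)) = 2/3 (the standard choice; only the admissible interval
for Δ is prescribed by the method), t = 10 repetitions by default;
effects are computed in unit-hypercube coordinates so μ\* compares
across parameters with different units. The influence rule is
μ\* > mean(μ\*); the strict reading "μ\* < μ\*max" would exclude the
single most influential parameter and contradicts the reported results,
so the maximum is retained. Two factor groupings exist: the default
treats the 21 parameters as factors and averages the year outputs per
design point; the published grouping (one factor per parameter × year,
n = 63, hence 10 × 64 = 640 runs) is available as
`morris_per_year_factors`.

**Extended FAST.** Per factor of interest, one block of Ns samples with
the factor at ω_max = ⌊(Ns − 1)/(2M)⌋, M = 4 harmonics, complementary
factors cycling over [1, max(1, ω_max/(2M))] with random phases. At the
study size (Ns = 70, so ω_max = 8) every complementary factor carries
frequency 1 — along a single curve they are mutually *deterministic*,
which inflates block variance severalfold and distorts main effects.
The design therefore supports Nr random-phase resample curves whose
spectra are pooled (Saltelli's resampling); the study runs one curve per
season (Nr = 3), reproducing the 21 × 3 × 70 = 4410 sample arithmetic.
The Si estimator additionally subtracts the local non-harmonic noise
floor around each harmonic — a no-op for well-separated designs
(validated against the g-function closed form at Ns = 1027, agreement
within ±0.05) but a necessary debias at Ns = 70. Even Ns is accepted:
the classical odd-Ns convention stems from symmetric-grid sampling that
the FFT-based estimator does not require, and the published sample
count uses 70. Constant-output blocks report zero indices with a
degenerate flag rather than NaN so batch pipelines never halt.

## Concordance

Savage scores with tie-averaging (tied items share the mean of the
scores their positions span, preserving Σss = n exactly); the
concordance coefficient uses the standard top-down form (squares of
item-wise score sums), the only parenthesization under which identical
rankings give C_T = 1 identically. Two groupings for the published
table layout are provided, because the original per-treatment columns
are ambiguous: `columns` (all treatments in one matrix, one C_T per
year × variable) and `consensus` (each treatment against the
leave-one-out consensus ranking, one C_T per treatment).

Two small-sample facts worth knowing when reading p-values: under
unrelated rankings E[C_T] = 1/m exactly (not 0), and the χ²(n−1)
reference for T = m(n−1)·C_T is asymptotic and *conservative* — at
n = 6, m = 3 the exact permutation tail at the nominal 0.05 point is
≈0.028, and the effect persists mildly at n = 21, m = 6. Significance
calls are therefore never overstated; both facts are asserted by
simulation in the test suite.

## Calibration

Uniform priors on the published bounds (sampling in the unit
hypercube), Gaussian likelihood with per-observation residuals matched
by (treatment, year, variable) — a mean-level residual cannot drive
per-treatment calibration — and σ_o fixed in the config (default 300
kg·ha⁻¹, matching the generator). The sampler is adaptive random-walk
Metropolis: per-chain step size tuned toward 0.25 acceptance and the
proposal covariance learned from the chain history with diminishing
adaptation (ergodicity-preserving), chains started at the prior
midpoint. The adaptation is not optional decoration: the posterior
under the study layout (8 free parameters, 36 observations, six
near-collinear treatments) is a long compensation ridge — e.g. a larger
T1 with a smaller T2 and a higher K predicts almost identically — and a
fixed-scale isotropic walk reaches roughly half the nominal interval
coverage at any desk-scale run length. With adaptation, 95% credible
intervals cover the generating values in ≈94% of
(replicate × parameter) cases at chain length 6000 (twenty replicates
run in lockstep through one vectorized emulator call per step).
Equifinality is real and visible: single-replicate intervals for
individual thermal-time targets can exclude the truth while the fit is
excellent; this is a property of the inference problem, not the
sampler. Only the eight yield-influential parameters are free by
default; the rest stay pinned (midpoints unless supplied).

## Evaluation

Population (divide-by-n) variance throughout, making RSR² = 1 − NSE an
exact internal identity (asserted to 1e−12). Grade bands are data, not
logic: Excellent (NSE > 0.75, RSR ≤ 0.50), Good (NSE > 0.65,
RSR ≤ 0.60), Satisfactory (NSE > 0.50, RSR ≤ 0.70), else Unacceptable;
a row must pass both limits, so the worse band wins, and all six
published grade rows reproduce under these bands. NSE within a year is
measured across treatments: it only rewards a model that resolves the
irrigation contrast, which is why an uncalibrated default can show small
RMSE yet deeply negative NSE.

## Problem sizes and determinism

Defaults mirror the published study arithmetic: Morris t = 10, p = 4
(640 runs in the 63-factor grouping; 220 per treatment × year in the
default grouping), extended FAST 21 × 70 × 3 = 4410 runs per treatment,
TDCC over the six treatments per (variable, year), calibration on
6 × 3 × 2 = 36 synthetic observations. Every stochastic stage takes an
explicit seed recorded in the run manifest; identical configs produce
byte-identical artifacts. The recovery experiment (20 replicates ×
chain 6000) and the full default study each run in minutes on one CPU,
which is the intended scale for a screening test bed.
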