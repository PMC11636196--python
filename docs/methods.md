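# Methods

This note documents the models implemented in `gbmrisk`, the defaults
and their rationale, what the synthetic generators do and do not
emulate, and the numerical conventions that fix reproducibility.

## Form disaggregation

Market shares are represented as row-stochastic `ShareMatrix` objects
(every row sums to 1 within 1e-9; entries in [0, 1]). For years *m*,
product categories *n* and forms *z*:

- form shares per year: `g_mz = Σ_n e_mn f_nz` (matrix product G = E·F,
  which is row-stochastic whenever E and F are);
- per-form production: `P_m · g_mz`, conserving the total sample-wise;
- per-form category allocation: `e_mn · f_nz / g_mz`. A year in which a
  form has zero total share has no meaningful allocation, so it raises
  instead of emitting a zero row.

The shipped GBM split table covers 14 product categories over
(pG, GO, rGO). Printed references round these splits to integer
percentages, which would make several rows sum to 0.99–1.01; the
package stores exact fractions consistent with the printed values and
with the construction rules behind them (equal splits are thirds; a
two-way pristine/oxide market split has its oxide share halved between
GO and rGO, e.g. the composite row is 0.81/0.095/0.095). The printed
convention is reproduced by a separate formatter (`format_split_percent`,
integer percent, half-up), never by the stored data. Declarative split
rules (`explicit`, `equal`, `go_halving`, `mixture`) build custom rows;
`combine_market_matrices` derives application × form distributions for
users who have form market fractions A and a form × application
matrix B. Form labels are an ordered, user-extensible list — three-form
GBM is a default, not a limit.

## Material-flow engine

Compartments have kinds: `technical`, `environmental`, `transfer`,
`sink`, `elimination`. Sinks and elimination have no outgoing edges and
accumulate; a transfer compartment (air) must have outgoing edges and
ends every year with zero stock; any compartment without outgoing edges
accumulates like a sink (e.g. subsurface, soils). The graph of
non-terminal compartments must be acyclic: one topological pass moves
mass through arbitrarily many compartments within a year, because the
model's time step is one year and multi-hop transport (production →
air → soil) completes well within it.

Transfer coefficients (TCs) are uncertain: per edge a `point`,
`uniform(lo, hi)` or `triangular(lo, mode, hi)` prior on [0, 1]. Per
Monte-Carlo run, each source's outgoing coefficients are drawn and then
renormalised to sum to exactly 1 (draw-then-renormalise, the standard
probabilistic-MFA device; a Dirichlet alternative was not chosen
because priors are specified per edge). TCs are sampled **once per run
and held fixed across years** — they encode parameter uncertainty, not
year-to-year process noise. This is a modelling choice, exposed by
re-running with per-year scenarios if needed.

In-use compartments may carry a `ReleaseSchedule`: fractions of
entering mass released 0, 1, 2, … years after entry (cumulative ≤ 1;
the remainder stays in stock). Cohorts are tracked by entry year, so
arbitrary schedules (geometric, box, delayed) are exact. A compartment
without a schedule passes its whole throughput downstream the same year
— the conservative, explicit default when lifetimes are unknown.

Invariants enforced by tests: mass conservation (cumulative external
inflow = sinks + elimination + stocks) within 1e-9 relative for every
run and year; zero end-of-year stock in transfer compartments;
linearity (scaling production scales everything); bit-identical
ensembles under a fixed seed; exact agreement with an independent
hand-propagation oracle on small point-TC graphs.

## Exposure

`pec_freshwater` supports two modes. `annual_dilution` (default):
C = annual release mass / freshwater volume, converted to ng/L
(1 t = 1e15 ng exactly). `residence_scaled` additionally multiplies by
residence_days/365 (default 40 days, the regulatory recommendation for
the water residence time). The default was chosen because published
form-specific freshwater concentrations for this material family are
plain release/volume dilutions — their sum reproduces the aggregate
release concentration — while the residence-time formulation describes
a different (steady-state) quantity; both are first-class and the mode
is logged with every run. Soil PECs divide by the receiving soil mass;
whether the numerator is an annual inflow or an accumulated sink mass
is the caller's choice (both appear in practice; the package does not
silently pick one).

Freshwater volume and soil masses are required configuration — there
are no baked-in continental defaults.

Summaries report mean, SD (ddof = 1) and Q5/Q25/Q75/Q95 with
linear-interpolation quantiles (NumPy's default, the "type 7"
convention) — fixed for reproducibility, configurable in principle.
The reporting layer rounds to 2 significant figures below 100 and 3 at
or above 100, half-up; rounding lives only in formatters.

## Hazard

Endpoints are converted to chronic NOECs by dividing by UF_t (exposure
duration) × UF_dd (dose descriptor). The shipped defaults —
acute → chronic 10; ECx/LCx → NOEC 10; LOEC → NOEC 2.5; HONEC → NOEC 1;
chronic NOEC fixed at 1×1 — follow common regulatory extrapolation
practice and are an editable table, logged whenever used: they are the
package's defaults, not constants of nature.

Each species' sensitivity is the **discrete uniform distribution over
its converted endpoints** — endpoint resampling embraces within-species
variability without asserting a parametric form. Per PSSD iteration one
endpoint per species is drawn and the 5th percentile (linear
interpolation) of the drawn values is the iteration's HC5; over 10,000
iterations (default) the PNEC point value is the mean of the HC5
samples (the median is also reported; the mean is the conventional
headline). An alternative `most_sensitive` mode collapses each species
to its minimum endpoint, giving the deterministic most-sensitive-point
SSD.

Strategy selection: the PSSD route requires at least 8 species
(configurable) covering fish, daphnids and algae; otherwise the
assessment-factor route divides the lowest raw endpoint by AF
(default 1,000). The raw (unconverted) minimum is used by default
because the assessment factor itself covers the extrapolation;
`convert=True` applies the UF table first. Every decision is returned
with its rationale and logged.

## Risk

RCR = PEC/PNEC after exact power-of-ten unit reconciliation (per-volume
and per-mass families are never mixed). Distribution ÷ distribution
divides **independently resampled** (seeded) draws — the exposure and
hazard Monte-Carlo chains share no randomness, so pairing samples would
be arbitrary. Distribution ÷ point divides element-wise, so
mean(RCR) = mean(PEC)/PNEC exactly. Headlines: mean, interquartile
range, P(RCR > 1), and floor(−log10(mean)) as "orders of magnitude
below 1" (an epsilon of 1e-9 in the log guards against 1e-5 evaluating
to 4.999…; a mean above 1 reports 0 with a warning). Unit choice
cancels out of RCR up to IEEE rounding of the rescalings (~1 ulp);
bit-exactness across different conversion paths is not a meaningful
target in floating point.

## Synthetic data: what it does and does not emulate

`make_scenario` builds Dirichlet(1, …, 1) share matrices (uniform on
the simplex — maximally uninformative while valid), lognormal yearly
production (median 1,000 t/yr, CV 0.5 by default: the order of
magnitude and spread typical of an emerging-material forecast),
triangular TC priors around a 9-compartment toy graph's nominal splits,
and an optional geometric in-use release. The toy graph's expected
terminal masses have a closed form (documented in
`expected_sink_masses`), giving the engine an analytic oracle. When the
category count is 14 the synthetic E matrix reuses the shipped category
vocabulary so it composes with the default split table.

`make_hazard_dataset` draws species sensitivities from
lognormal(μ, σ) in mg/L; the analytic true HC5 is
exp(μ + σ·Φ⁻¹(0.05)), independent of the seed. Endpoints scatter
lognormally (σ_within = 0.3) around each species and are emitted as a
mix of chronic NOECs and acute ECx/LCx records pre-multiplied by the
UF product, so conversion recovers the intended values exactly. The
default spread is σ = 0.5: the empirical 5th percentile over 26
species is a convex, small-sample statistic whose intrinsic upward
bias grows with σ (≈ +16% at σ = 1 on top of ±40% per-replicate
noise), and the default keeps that estimator-intrinsic bias near 3% so
recovery tests measure the implementation, not the estimator's
asymptotics. Raising σ emulates the multi-order-of-magnitude spread of
real inventories. `make_form_hazard_datasets` reproduces a realistic
per-form inventory shape — 26 pG records over 9 species, 82 GO records
over 18 species, and 5 single-species rGO records with no fish or
daphnids, 113 records in total — so the strategy-selection logic is
exercised end to end.

What passing synthetic tests do **not** show: real toxicity data are
not lognormal with independent within-species scatter, real transfer
coefficients are not symmetric triangles around known nominals, and the
toy graph is far smaller than a full continental system. The synthetic
results validate the arithmetic and the statistical machinery, not any
real-world concentration.

## Problem sizes and determinism

Default Monte-Carlo sizes are 10,000 runs (flows) and 10,000 iterations
(PSSD), matching standard practice for these pipelines; the test suite
uses 200–10,000 depending on what the assertion needs. All randomness
flows from `numpy.random.default_rng` seeds; the pipeline expands one
root seed into per-stage substreams (production, per-form simulation,
SSD, RCR) so a stage can be re-run in isolation. Identical config +
seed reproduces every output file byte for byte.

## Known limitations

- No environmental fate (agglomeration, sedimentation, degradation):
  PECs are release concentrations at the point of entry, upper bounds
  on the suspended concentration.
- Regional averages only; local or accidental releases can exceed them.
- Soil hazard/PNEC (and hence soil RCR) is out of scope; only soil
  exposure is computed.
- Release schedules must be supplied; the default of immediate release
  is conservative for surface-water exposure but understates stocks.
- The full continental compartment list and its calibrated transfer
  coefficients are scenario *inputs* (YAML/CSV), not built-in truth.
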