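# Methods

## The release mechanism

A daily O-D matrix is released in three steps. Step 1 counts
inter-region trips (a trip is two consecutive phone events by the same
subscriber in different regions, dated by the arrival event). Step 2
adds independent zero-mean Laplace noise with scale λ = T/ε to every
off-diagonal cell. Step 3 suppresses any noisy value strictly below the
threshold τ (released as 0, flagged) and otherwise rounds half-up and
clamps to ≥ τ.

The sensitivity parameter T has two readings. At T = 1 the protected
unit is a single trip: adding or removing one trip changes exactly one
cell by 1, and Laplace(1/ε) noise gives ε-differential privacy per
matrix. For individual-level protection the input is first censored so
no subscriber contributes more than T trips (extras dropped uniformly at
random); one person then changes the counts by at most T in total, and
Laplace(T/ε) noise again yields ε per release. Thresholding and
rounding are post-processing and cost no additional privacy.

Design choices in step 3 that the mathematics does not force:

- Suppression is *strict* (`noisy < τ`); a noisy value exactly at τ is
  released. With continuous noise the boundary has probability zero, so
  this only fixes a convention.
- Suppressed cells are released as 0 *and* carry a flag, so consumers
  can distinguish "no observed trips" from "withheld"; all sums treat
  both as zero, which biases private totals downward.
- Released values are integers via round-half-up, then clamped to ≥ τ,
  so every non-suppressed count is a plausible (≥ τ) integer count. The
  0.5 rounding allowance is what puts the `α + 0.5` in the tail-bound
  calculator below.
- Noise is drawn independently per cell per day; one seed per release
  makes the whole matrix reproducible.

## Choosing ε and τ

`heuristic_epsilon_for_error(α, T)` returns √2·T/α: the smallest ε whose
noise standard deviation T√2/ε does not exceed the tolerated typical
error α. It uses only the second moment and ignores thresholding.

`epsilon_for_error_bound(α, δ, T)` returns −T·ln(δ)/(α + 0.5). For a
non-suppressed cell the released error exceeds the integer α only when
the Laplace sample exceeds α + 0.5 in magnitude (the 0.5 absorbs
rounding), and P(|Laplace(T/ε)| > a) = exp(−εa/T); solving for ε at tail
mass δ gives the formula. The suite validates the calibration by Monte
Carlo: at the returned ε the fraction of rounded errors above α is
statistically indistinguishable from (or below) δ. Because the tail
bound uses the whole distribution rather than just its spread, it
permits a larger ε — hence a more accurate release — than the heuristic
for the same α (0.285 vs 0.14 at α = 10, δ = 0.05).

`tau_from_standard(s, ε, direction)` adapts an existing organizational
suppression standard s: unchanged (τ = s, since the noise is zero-mean),
or shifted by one noise standard deviation √2/ε downward (fewer cells
suppressed, when intervention accuracy depends on small flows) or upward
(more protection, when noise might surface small sub-populations).
Results are rounded to the nearest non-negative integer since τ ∈ ℤ≥0.

`suppression_probability(c, τ, ε, T)` is the Laplace CDF at τ with
location c and scale T/ε — the exact probability that a cell with true
count c is withheld. One counterintuitive consequence, verified
numerically in the suite: a below-threshold cell is *more* likely to be
released at smaller ε, because heavier noise more often lifts it above
τ. Private totals can therefore be more accurate at ε = 0.1 than at
ε = 1 when many true counts sit just below τ.

## Privacy-loss accounting

Losses compose linearly. Trip-level: an individual with n_j trips in
release j incurs ε·Σn_j over the window. Individual-level: censoring
caps the per-release contribution, so each release costs exactly ε and J
releases cost ε·J. `PrivacyLedger` stores the regime, the per-release
contributions, and is additive under concatenation; worst-case loss uses
the maximum per-individual trip counts, expected loss
(`expected_privacy_loss`) uses the population mean. Whether the
privatized population vector (see below) is budgeted on top of the O-D
releases is an open deployment question; the ledger records population
releases separately so either convention can be reported.

## Empirical DP audit

`empirical_dp_audit` runs the single-cell release rule ~10⁶ times on two
neighboring counts (differing by T), histograms the integer outputs, and
compares log probability ratios against the ε bound. Bins observed
fewer than 100 times in either histogram are excluded, and the bound is
checked up to a 3σ binomial tolerance on the log ratio. This is an
outside-in check of the implementation (it would catch, e.g., a wrong
noise scale or a data-dependent threshold), not a proof.

## Mobility-informed SIR model

Each region i carries S_i, I_i, R_i with fixed population
N_i = S_i + I_i + R_i. The force of infection has an intra-region term
β·S_i·I_i/N_i and an inter-region term
α·β·S_i·(Σ_j M_ij·I_j/N_j)/(N_i + Σ_j M_ij), where M is the day's O-D
matrix: the prevalence at the destinations a region's travelers visit,
trip-weighted and normalized by the region's effective (resident plus
traveling) population. Defaults β = 0.10, μ = 0.04, α = 1 are in the
range of SIR fits to early-COVID-19 national data; simulations seed 1%
of one region's population as infected and trigger intervention
decisions at 20% estimated prevalence (boundary inclusive).

Two deliberate deviations from a naive transcription of the model's
usual presentation:

- dI is computed as −dS − dR, not dS − dR. A literal dS − dR with
  dS ≤ 0 and dR ≥ 0 would force dI ≤ 0 always and cannot conserve
  population; defining dI as the negative sum conserves
  S + I + R = N exactly by construction (asserted to 10⁻⁹ relative in
  the suite).
- The recovery term is selectable: `as-printed` uses dR = μ·I/N (the
  form stated alongside the mobility model, in which recovery slows in
  large regions), `classic` uses dR = μ·I (the standard SIR reading of μ
  as the fraction of infected individuals recovering per day). The
  default is `as-printed`; with it, μ's effective timescale depends on
  N, so prevalence decay in large regions is dominated by susceptible
  depletion rather than recovery.

Integration is forward Euler with a one-day step, matching the daily
matrix cadence; compartments are floored at zero after each step. With
all-zero matrices the system decouples into k independent scalar SIR
models, which an independent scalar integrator cross-checks in the
suite. When private matrices drive the simulation, suppressed cells
contribute zero flow, and the population vector is itself privatized
(Laplace(1/ε), rounded, clamped to ≥ 1 so denominators stay positive).

## Aid targeting

Out-migration from an affected region over a response window (typically
7 daily matrices) is the sum of the region's matrix row across days;
grand totals sum everything. Top-k selection ranks regions by flow
received from the affected region (mode `destinations`, the default —
where the migrants went) or by total out-flow (mode `origins`), ties
broken by region id so rankings are deterministic. Top-k accuracy is
computed per day — the overlap fraction between private and non-private
daily top-k sets — and averaged over the window; with 7 days and k = 3
each day contributes 3 selections, so one daily disagreement in two days
gives 19/21 ≈ 90.48%.

## Error metrics

Per-cell absolute error is |private − nonprivate| with suppressed cells
read as 0. Relative error is symmetric: 2·abs/(private + nonprivate),
which lies in [0, 2] and is defined as 0 when both counts are 0 (a
suppressed cell against a positive true count hits the ceiling of 2).
Medians are over off-diagonal cells. Decision metrics score the private
intervention grid against the non-private grid per region across days:
accuracy (fraction of agreeing days), precision and recall with
non-private positives as ground truth, then mean ± std across regions
with equal weights. Degenerate conventions: a region with no true
positives scores recall 1, and precision 1 exactly when it also predicts
none; a region predicting nothing while true positives exist scores
precision 0.

## Synthetic scenario generator

Real CDR are proprietary, so the generator emulates their structure:

- **Regions**: k (default 30) regions with log-uniform populations on
  [10³, 10⁶] and uniform planar coordinates (Euclidean distances).
- **Subscribers**: homed proportionally to population; each draws a
  personal daily trip rate from a gamma distribution with mean
  `mean_daily_trips` (default 0.05/day — weekly means of a few tenths
  of a trip, the scale seen in sparse telecom panels) and shape 0.3, so
  daily counts are marginally negative binomial: the 5th percentile of
  per-subscriber trips is 0 while the 95th percentile sits an order of
  magnitude above the mean.
- **Trips**: per day a Poisson count of trips chains gravity-sampled
  destinations (weight ∝ N_j/d_ij^γ, default γ = 1) starting from home.
- **Shock**: from its start day, a shock multiplies the trip rate of
  subscribers homed in the affected region (default 5×), producing the
  out-migration surge the targeting analysis looks for.
- **Events**: optionally each trip chain is realized as a CDR stream —
  one nighttime event at home (02:00, anchoring home inference) plus one
  daytime event per visited location. Within-day trip extraction
  recovers the generated trips exactly; default (cross-day) extraction
  additionally observes the overnight return home.

What the generator does *not* emulate: road networks and travel times,
multi-day displacement trajectories, tower-level spatial noise,
day-of-week seasonality, or coverage gaps. Passing tests on synthetic
data therefore demonstrate the correctness of the mechanism and the
decision harnesses under controlled conditions, not the empirical
accuracy figures any particular real deployment would see.

## Problem sizes and numerical choices

The suite runs its large simulation at 305 days × 34 regions with 3,000
subscribers, Monte-Carlo checks at 10⁵–10⁶ replicates, and the DP audit
at 10⁶ replicates per ε — sizes chosen so every check carries
statistical weight while the whole suite stays fast. Home-inference
ties break toward the smallest tower id; the nighttime window is
half-open [20:00, 24:00) ∪ [00:00, 06:00). Trip days use the arrival
event's date; cross-day event pairs count as trips unless within-day
extraction is requested. All randomness flows through seeded numpy
generators, and every CLI run is bit-reproducible given its seed.
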