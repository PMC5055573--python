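# Methods

## Thermal accounting

Decomposition progress is indexed by accumulated degree-days,
`ADD(t) = Σ max(Tᵢ, 0) · Δtᵢ / 24` over the chronological
constant-temperature segments of a case's postmortem history. Durations are
kept in hours at every interface (forensic records are hourly) and divided
by 24 at accumulation time; the floor at 0 °C is applied per segment before
multiplication, never to the final sum, so sub-zero phases contribute
exactly zero rather than negative degree-days.

`invert_add` returns the earliest time at which a target ADD is reached
and, when accumulation stalls at the target (segments at or below 0 °C),
also the latest time still at that value — an interval, because the map is
non-invertible on plateaus and the method is a delimitation, not a point
estimate. The profile is never extrapolated: a target beyond the profile's
total accumulation comes back flagged `unreached` with the total, and
callers wanting open-ended bounds must append an explicit trailing segment.
Plateau and boundary comparisons use an absolute tolerance of 1e-9 °d.

## Band calling

Lane traces are 1-D position/intensity profiles as exported by standard gel
software. Molecular weights are interpolated log-linearly against the
ladder (migration distance is approximately linear in log10 MW on
SDS-PAGE); positions outside the ladder span are extrapolated from the edge
slope and flagged with a warning rather than trusted silently.

The baseline is a rolling minimum over a window three times the widest band
window. The minimum is taken on a lightly smoothed copy of the trace
(Gaussian, σ = 0.5 position units) so that additive noise does not bias the
baseline downward, but it is subtracted from the *raw* trace so band areas
are not blurred; the residual is clipped at zero and integrated by the
trapezoid rule inside each band window. Band windows default to ±1.5 kDa
around nominal weights, which are approximate by nature, and are
configurable per panel. The zymogram carries no ladder, so its windows
(native calpain 1 and 2, and the autolyzed calpain 1 band between them) are
defined directly in lane-position units.

Presence is decided by the background rule: a band's area relative to the
largest-area band *of the same lane* must reach 1 % ("less than 1 %" is
background, so exactly 1 % is a band; the comparison is `≥ 0.01`). The
dominant-band denominator is scoped per lane because blots of different
proteins are separate images. Area, not peak height, is the measured
quantity. Because the rule is a ratio, calls are invariant to global
intensity scaling of a lane. Windows that cannot be placed (a molecular-
weight window without ladder coverage) yield an `uncallable` status and a
missing call, never a crash; violations of the degradation-product nesting
order are logged as warnings, since they indicate either a calling problem
or a genuinely unusual sample.

## Calibration

For each product and subgroup the pipeline first asks whether presence is
random over the observed ADD range: Spearman's ρ, computed as the Pearson
correlation of average-tied ranks. With fewer than 10 cases the two-sided
p-value is an exact permutation test (enumeration over presence-label
assignments; each assignment carries equal permutation weight); otherwise
the classical t approximation with n − 2 degrees of freedom. Products with
fewer than 4 cases in the rarer class are reported as "few cases" and not
correlated at all — a correlation on a nearly constant variable is
meaningless. Displayed p-values print as `0.000` below 5e-4; stored values
keep full precision.

Products passing the significance gate (p ≤ 0.01) get a binomial logistic
regression of presence on ADD, fitted by Newton/IRLS with step-halving so
the log-likelihood is non-decreasing across iterations (the history is
retained on the results object). Convergence requires a maximum absolute
score below 1e-8 or a parameter update below 1e-10, within 100 iterations.
The fit is hand-authored and package-independent; it agrees with an
off-the-shelf MLE to machine precision in the test suite.

Quasi-complete separation (the two presence classes split monotonically in
ADD) makes the MLE diverge; it is detected up front and flagged. Without
the Firth option the flagged result carries no thresholds — a huge slope
would be noise, not information. With `firth=True` the Jeffreys-prior
penalized fit is used instead, which is finite under separation. Fits whose
slope is not significantly different from zero are additionally marked
`wide`: their thresholds are orders of magnitude, not estimates.

Thresholds follow from the fitted curve: `ADD(p) = (logit(p) − β₀)/β₁`,
with P50 the inflection point and P95 the level at which presence is
expected in at least 95 % of cases (logit 0.95 = ln 19).

Demographic subgroups use strict boundaries: the age-corrected group keeps
18 < age < 80 years (excluding possible developmental protein isoforms in
the young and severe sarcopenia in the very old), the BMI-corrected group
19 < BMI < 30 kg/m² (excluding underweight/cachectic and obese), plus
female/male restrictions. Subgroup rows with a single presence class,
too-small minorities, or empty membership are reported with the
corresponding status rather than numbers.

## Delimitation

Given calibrated curves and one case's binary marker vector, the combined
evidence over ADD is an independent-Bernoulli likelihood
`L(a) ∝ Π Pₖ(a)^yₖ (1−Pₖ(a))^(1−yₖ)` evaluated on a grid of step ≤ 0.1 °d
from 0 to 1.5× the largest calibrated P95. Missing calls contribute a
constant factor. Normalized over the grid this is a posterior under a
uniform ADD prior, and the reported bounds are its highest-density region
at the requested level; each factor is log-concave in ADD, so the product
is unimodal and the region is a single interval. Time bounds follow by
inverting the ADD bounds through the case's temperature profile, taking the
conservative ends of plateau intervals. An upper bound beyond the
calibrated observation window (36 °d by default) is flagged as
extrapolated; a profile that cannot even accumulate the lower bound flags
the interval as profile-inconsistent.

The interval-combination rule is this package's formalization — the
underlying calibration style publishes one-sided "significantly present
from X °d onward" statements per marker, which are retained verbatim in
`per_marker_support`. Marker independence is assumed; because the desmin
degradation chain is strongly dependent (products appear consecutively),
the chain is collapsed by default to its most advanced observed product
(or, with all members absent, to the earliest product's absence, the most
informative negative), avoiding double-counted evidence. The collapse is
configurable.

`coverage_experiment` validates the construction: drawing true ADD
uniformly over the grid and presence from the calibrated curves, the
nominal 95 % interval covers the truth at its nominal rate (the discrete
grid gives slight over-coverage). This holds by design only under the
uniform prior and correct curves; on real cases the interval inherits any
calibration error.

## Synthetic cohort generator

The generator emulates the structure of the 40-case calibration cohort:
ages from a truncated normal (69.1 ± 19.5, range 2–90 years), BMI
(26.2 ± 6.1, range 10.7–50.4), 23 F : 17 M, PMI 37.7 ± 27.8 h truncated to
4–92.8 h, ambient temperature 19.8 ± 4.6 °C truncated to −7 to 21 °C (the
printed upper truncation sits close to the mean, so the realized average is
lower), and 28/40 cases transferred to 4 °C cooling for a truncated-normal
39.1 ± 26.3 h. Two couplings keep the emergent ADD distribution inside the
observed 2.6–36 °d span, because fully independent draws would let
long-PMI cases sit at warm ambient for days: scene time before cooling is
capped at 24 h (cooling begins at discovery), and never-cooled cases draw
their PMI truncated at 36 h (they were sampled straight from the scene).
With these defaults the realized ADD distribution is ≈ 12.7 ± 8.1 °d with
maximum near 32 °d.

Marker presence is Bernoulli in the case's true ADD under logistic curves
reconstructed through the published (P50, P95) pairs,
β₁ = ln 19/(P95 − P50), β₀ = −β₁·P50: cTnT dp2 (9.4, 28.2), desmin dp1
(6.7, 28.1), calpain 1 dp (15.0, 39.6). The desmin chain is drawn
sequentially — dp2 only where dp1 is present, dp3 only where dp2 is — so
nesting holds by construction; the conditional curve of dp2 uses the only
published regression available for it (9.0, 23.3), and dp3's conditional
curve (18.0, 36.0) encodes its late, last-in-chain appearance (≈ 8/40
present). cTnT dp1 has no published regression either; its curve
(2.0, 6.0) encodes its emergence soon after death, leaving ~2–3 of 40
cases without the band at the low end of the ADD range. Because later
chain members are conditional draws, only chain heads and independent
markers have marginal curves equal to their generating logistic; recovery
tests fit conditional products on the parent-present subset.

An optional `extreme_slope_factor` < 1 flattens every marker's curve
(around an unchanged P50) for demographically extreme cases — age outside
(18, 80) or BMI outside (19, 30) — emulating the noisier degradation
reported in those groups; with it enabled, restricted recalibration yields
visibly steeper curves (smaller P95 − P50) than the total group. The
default is 1.0 (off), so the standard cohort is generated from the clean
curves.

Lane traces render each case's marker vector as Gaussian peaks (σ = 0.35
position units) at nominal band positions via a conventional 10-point
ladder laid out log-linearly across the lane: native bands always present
with total area 1000 split over their multiplets, present products at a
uniform 5–80 % of the dominant area, plus a slow sinusoidal baseline drift
and additive Gaussian noise. The signal-to-noise ratio is defined as the
weakest allowed product peak height over the noise SD. Deterministic
per-case substreams make trace generation order-independent and
byte-reproducible.

What the generator does *not* emulate: real densitometric artifacts (lane
smiles, saturation, overlapping bands of unrelated proteins), continuous
temperature records, dependence between markers beyond the desmin chain,
cause-of-death effects (confounded with age in cohorts of this kind), and
any mechanistic proteolysis kinetics. Passing tests therefore demonstrate
internal consistency of the pipeline under the stated statistical model,
not field performance on real casework.

## Numerical choices and problem sizes

Logistic fitting tolerances are stated above; Spearman agreement with the
brute-force oracle is checked to 1e-12 and degree-day accumulation against
a 0.01 h Riemann sum to 1e-9 °d. The validation suite uses cohorts of
40–800 cases, simulate-and-refit at n = 2000 over 10–20 seeds, 500
delimitation replicates for coverage, and 100 lanes for call accuracy —
sizes at which every multi-seed mean is stable while the full suite runs in
about a minute. The 1 % presence comparison carries a 1e-12 epsilon so the
boundary case lands on the "band" side, and zero-length temperature
segments are dropped at profile construction.

## Known limitations

* The calibration anchors are reconstructed from printed thresholds, not
  refitted from case data; real per-case calibration data would supersede
  them.
* The independent-Bernoulli combination ignores residual dependence among
  markers from different assays; the desmin collapse removes only the
  strongest known dependence.
* ADD treats degradation as exchangeable in time and temperature with a
  hard 0 °C floor; freeze–thaw damage and body-core cooling lags (algor
  mortis) are outside the model.
* Subgroup recalibration reduces sample size sharply (40 → 24 in the
  motivating design); "few cases" and separation flags are common at such
  sizes and must be respected downstream.
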