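# Methods

## Model

A patient undergoing right-heart catheterisation with mPAP > 20 mmHg and
PAWP ≤ 15 mmHg is classified by the pulmonary vascular resistance
PVR = TPG / CO (TPG = mPAP − PAWP): precapillary pulmonary hypertension
(PcPH) when PVR > 2 WU, unclassified PH when PVR ≤ 2 WU. The CO entering
this ratio is usually the thermodilution value CO_TD; the reference
method is direct Fick (CO_DF). The model treats the method difference as
a normal random variable,

    X = CO_TD − CO_DF ~ N(μ, σ),   σ = LoA / 1.96,

with μ the Bland–Altman bias and LoA the 1.96·SD limits-of-agreement
half-width, and conditions on the event B that the implied direct-Fick
value CO_DF = CO_TD − X lies in a physiological interval [a, b] — an
aberrant CO would be rejected at the bench, so the conditioning mirrors
clinical practice. Because the diagnosis under DF flips exactly when
TPG / (CO_TD − X) crosses the threshold r, the flip probability is a
one-dimensional truncated-normal interval probability; both directional
joint events partition B up to the measure-zero boundary
X = CO_TD − TPG/r, an identity the test suite asserts to 1e−12.

Assumptions worth stating explicitly: the difference distribution is
normal with no proportional bias (true of published resting comparisons;
false during exercise, where the model must not be used); μ, σ are known
constants rather than estimates with their own uncertainty; mPAP and
PAWP are treated as exact, so all diagnostic uncertainty is attributed
to CO.

## Parameters

| parameter | meaning | unit | default |
|---|---|---|---|
| `bias` (μ) | mean CO_TD − CO_DF | L/min | 0.0 |
| `loa` (1.96 σ) | limits-of-agreement half-width | L/min | 2.0 |
| `co_min`, `co_max` ([a, b]) | physiological resting CO interval | L/min | 1.3, 10.2 |
| `pvr_threshold` (r) | PcPH resistance cut-off | WU | 2.0 |
| `mpap_threshold`, `pawp_threshold` | pressure entry criteria | mmHg | 20, 15 |

The agreement defaults summarise the three published resting TD-vs-DF
comparisons in PcPH (biases 0.01–0.45 L/min, LoA 1.10–2.48 L/min); the
CO interval is the observed range of mean CO (1.6–8.5 L/min) widened by
a 20 % safety margin. All are configurable because the evidence base is
small (134 patients) and may move. Note the pressure criteria imply
TPG > 5 mmHg: no mPAP/PAWP split can place a lower TPG inside the
model's domain.

Convention at the threshold: PVR exactly at r is classified unclassified
PH (the PcPH definition's "> 2 WU" is strict). The flip events use the
complementary closed/open convention, which is measure-zero under the
continuous difference distribution and therefore does not affect any
probability.

## Numerical choices

- Φ is evaluated with `scipy.special.ndtr` (erf-based, double-precision
  accurate); probabilities are carried at full precision and rounded
  only for display (one decimal percent by default).
- Empty flip intervals (threshold outside [CO_TD − b, CO_TD − a]) give
  probability 0 rather than an error.
- An observed CO_TD outside [a, b] is a domain error, not a clamp: the
  conditioning presumes the observed value itself is physiological.
- Iso-probability lines are extracted per CO by bracketed Brent root
  finding on TPG (tolerance 1e−10 mmHg), bracketing each branch between
  the PVR-threshold line and the domain edge; the field is monotone in
  TPG on each branch, which makes this robust. The solver evaluates the
  branch-specific probability (joint/P(B)), which is continuous across
  the threshold line, rather than the direction-dispatched one, which
  jumps there. CO values where the level is unattainable — near the CO
  limits the truncation caps the attainable probability — are reported
  as gaps, never extrapolated. In the central region the lines reduce to
  the straight form TPG/r = CO ∓ z(level)·σ, verified to 1e−6 where the
  truncation is numerically inactive (≥ 7 σ from both CO limits).
- The Monte-Carlo check conditions on B by exact rejection (no
  importance weighting): draw X, keep draws with CO_TD − X in [a, b],
  count diagnostic flips. Agreement with the closed form is asserted
  within 3 binomial standard errors at 10⁶ draws on a 24-point
  (TPG, CO_TD) grid; the standard error is computed under the analytic
  value so the check remains meaningful when the expected flip count is
  near zero.

## Synthetic paired data

The generator emulates a Bland–Altman dataset of fictive (CO_TD, CO_DF)
pairs. It draws the difference d ~ N(μ, σ) first, then the pair mean
uniformly over [a + |d|/2, b − |d|/2] — the exact set of means for which
both individual CO values are physiological; differences wider than the
interval itself (an ~8.7 σ event at the defaults) are rejected, and a
grossly infeasible configuration (LoA large relative to b − a, acceptance
below 1 %) raises a stall error instead of looping. Drawing the
difference first keeps its marginal distribution exactly normal, so a
Bland–Altman analysis of the output recovers the configured bias and LoA
within sampling error (asserted within 3 analytic SE at 10⁵ pairs). The
alternative — drawing the mean uniformly over all of [a, b] and rejecting
out-of-range pairs — thins large differences near the boundaries, which
at the defaults shrinks the SD of the accepted differences by ~3.5 % and
would make parameter recovery systematically biased; that is why it was
not used. The price is that the pair means are not exactly uniform
(their density tapers within ~σ/2 of the limits).

What the generator does not emulate: replicate measurements per patient,
exercise-induced proportional bias, heavy-tailed or skewed difference
distributions, and any correlation between CO level and measurement
error. Passing parameter-recovery tests therefore shows the estimators
and the generator are mutually consistent, not that real TD/DF data meet
the normality assumption.

## Validation scale

The test suite runs the closed form against 50-digit frozen oracle
values (22 worked-example patients, two P(B) values), a 50×50 partition
grid, 24 Monte-Carlo points at 10⁶ draws, 10⁵-pair generator recovery,
and 50-point iso-line round-trips — a few seconds in total. The
published worked-example tables contain several cells (notably at low
CO) that deviate from the closed-form evaluation of the model's own
formulas by 0.2–10 percentage points; `dgdis table --compare` lists
every cell with its deviation, and the package reproduces the formulas,
not those cells.

## Limitations

Resting haemodynamics only; the agreement parameters are point
estimates from a small literature; the model propagates CO uncertainty
only, so a patient near the pressure criteria may carry additional
diagnostic uncertainty the model does not see; and the tier cut-offs
(10 %, 20 %) are pragmatic conventions, not decision-theoretic optima.
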