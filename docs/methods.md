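# Methods

This note records the scientific and numerical choices behind `obcode`: the
imaging-analysis pipeline, the circuit model, the discriminability theory,
and what the synthetic-data generator does and does not emulate.

## Imaging-trace pipeline

**Input contract.** An `ImagingSession` is a dense tensor of raw
fluorescence, cells × odors × trials × frames, with a fixed odor-onset
frame and at least 6 s of pre-stimulus and 5 s of post-onset recording per
trial. Segmentation, motion correction, and neuropil handling are upstream
of this contract and out of scope.

**dF/F.** Baseline f0 is computed per cell and trial as the mean raw
fluorescence 5–2 s before odor onset; dF/F = (f − f0)/f0. Non-positive f0
is an error naming the offending cell/trial. dF/F is exactly invariant to
scaling a cell's raw trace by a positive constant.

**Smoothing.** Per-trial traces are smoothed with a span-5 centered moving
average before any analysis; near the edges the window shrinks to the
largest centered odd window that fits (first point unsmoothed, second
averaged over 3, ...), so output length equals input length and a linear
ramp is a fixed point. The trial-averaged trace used for detection is the
mean of the smoothed trials.

**Response detection.** The response window is 0–4 s post onset. The sign
of the trace integral over that window — measured relative to the mean of
the 6–2 s pre-stimulus baseline window so that the decision is invariant
to a constant offset; on a genuine dF/F trace the baseline mean is ~0 and
the two readings coincide — selects a maximum (excited) or minimum
(suppressed) search. The extremum and its three neighbors on each side
form the response sample; the same-type extremum within the baseline
window, with its six neighbors, forms the baseline sample. This "parallel
point" construction is the one self-consistent reading of picking a
baseline point "similarly" to the response point. The effect size is the
difference of sample means over the mean of the two sample standard
deviations (n−1 convention throughout); |ES| > 5 defines a significant
response. Ties in the extremum search break to the earliest frame.
Neighbors truncated at a recording edge are flagged on the call; a pooled
standard deviation at zero (to within 1e-12 of the sample scale — exact
zeros do not survive floating-point averaging) yields ±infinity with a
degenerate flag. Integrals within 1e-9 (relative) of zero are classified
as no response for the same round-off reason.

**Magnitude.** The response magnitude is the Riemann sum of the mean trace
over 0–5 s post onset times the frame interval (dF/F·s), signed.

**Permutation comparison.** Before/after comparison of a cell-odor pair
uses the per-trial mean smoothed dF/F over the response window, five
values per condition, and enumerates all C(10,5) = 252 equal-split
relabelings of the pooled ten values with the absolute difference of
sample means as statistic. P-values are therefore exact multiples of
1/252 and symmetric in the two samples; p < 0.05 (i.e. at most 12/252)
marks a changed pair, giving a guaranteed type-I level of 4.76% under
exchangeability. The window defaults to the 0–4 s response window rather
than the 0–5 s magnitude window; this is configurable because the choice
is not forced by the procedure's description.

**Pools.** Every cell-odor pair with a significant excited (suppressed)
call in either condition enters the excited (suppressed) pool together
with its partner call regardless of the partner's classification; a pair
flipping sign between conditions appears in both pools, and such double
counting is reported rather than suppressed.

**Tuning and sharpening.** A cell's tuning curve is its ranked vector of
response magnitudes over all odors, significant or not; its tuning width
is the sample standard deviation of those magnitudes. The population
sharpening ratio is mean tuning width before over mean tuning width
after, with confidence borders taken as the extrema of
(Avg ± SEM)_before / (Avg ∓ SEM)_after. The point estimate always lies
inside these borders; on synthetic data with amplitudes scaled by q the
estimate recovers 1/q (exactly at zero noise, within the borders at low
noise — frame noise inflates both widths and biases the ratio slightly
toward 1, second-order in noise/width).

**Baseline activity.** Spontaneous-activity changes are estimated from
each cell's fluorescence divided by a cell-free background trace,
averaged over 60 pre-stimulus time points collected from the 5–3 s
pre-onset window of successive stimulus presentations; the shift is the
after-minus-before difference, flagged when fewer than 60 points exist.

## Population discriminability

For odors p and q, each a cells × trials matrix of per-trial mean dF/F
over the response window (all imaged cells, regardless of significance),

d′ = ‖mean(p) − mean(q)‖ / mean(inner_p, inner_q),

with each inner distance the mean Euclidean distance of single trials
from their own centroid. Both terms scale as √n_cells, so d′ is
dimensionless, and it is exactly invariant under global translation,
global positive scaling, and duplication of the cell dimension. The
pairwise d′ matrix stores 0 on the diagonal; entries where both inner
distances vanish are undefined and flagged. Cross-animal aggregation is
an entrywise mean weighted by cell count.

DCI = (d′_after − d′_before)/(d′_after + d′_before) per entry, bounded in
[−1, 1] and antisymmetric under swapping conditions; entries with zero
denominator are excluded and counted. Significance of the mean DCI is
assessed by a two-sided one-sample t-test over the unique entries (with
an optional Bonferroni factor when several conditions are tested
together). **Limitation:** the entries share odors and are positively
correlated, so the nominal test level is not attained — on null synthetic
sessions the t-test rejects far above 5% even though the mean DCI is
unbiased at 0. The test is reported as-is rather than corrected, and
inference should lean on effect size and cross-animal reproducibility
rather than this single p-value.

## Circuit model

Linear firing-rate populations on a ring, θ uniform on [0, 2π) (an even
grid; angular distance wraps as min(|Δ|, 2π − |Δ|), the natural metric on
a ring). Connection strength from neuron j (population Y) to neuron i
(population X) is J_XY exp(−d(θ_j, θ_i)²/2σ_XY²) with a common peak
J = 10 and width σ = 0.5 rad for the MC↔GC loop; the ring average is
J0 = Jσ/√(2π) ≈ 1.995. abGCs share mature-GC output width but have input
width b·σ (b = 3) and gain g = 5 on a linear input–output function;
mature GC rate equals its input. MCs receive I0 = 1 baseline and I1·z
odor input (z i.i.d. standard normal per MC per odor, so odor tuning
with no circuit is I1/I0 = 0.1) minus granule inhibition normalized by
the total granule count.

**Solution.** Substituting the granule responses into the MC equation
gives one linear system (I + W) r = I0 + I1 z, with W the effective
MC→MC inhibition formed from the product of the in- and out-matrices of
each granule population (accumulated over blocks of granule cells to
bound memory at large scale). Only the self-consistent rates are defined,
so the fixed point is solved directly; no dynamics are integrated. Rates
are not rectified — the model is strictly linear, negative rates are
reported with a warning, and clipping happens only where Poisson sampling
requires non-negative means. The baseline solution uses z = 0 and defines
the normalized response R = (r(odor) − r(0))/r(0), the model analogue of
dF/F.

**Silencing.** A silenced subpopulation keeps its place in the normalizer
but emits zero rate (chemogenetic silencing, not ablation). Partial
silencing picks evenly spaced indices along the ring — deterministic and
spatially unbiased.

**Sizes.** Desk-scale defaults are 500 MCs and a 20,000-cell granule
population split 19,500 mature + 500 adult-born, preserving both the
1:40 MC:granule ratio and f = 0.025 exactly; these sizes keep a full
solve-plus-silencing comparison under a few seconds on one core while
finite-size effects stay within a few percent of the closed forms (the
reduced parameters are size-independent). Larger networks (e.g. 1000 MCs,
100,000 granule cells) are supported through the blocked construction.

**Closed forms.** The model reduces to f (abGC fraction),
g_eff = b·g (efficacy), and J_eff = J0_out · J0_in ≈ 3.979. Mean MC
tuning is (I1/I0)(1 + J_eff(1 + (g_eff − 1)f)) intact and
(I1/I0)(1 + J_eff(1 − f)) with all abGCs silenced; their ratio is the
abGC sharpening, ≈ 1.306 at defaults. The simulated population tuning
matches these within a few percent at desk scale (the finite-width
Gaussian kernel suppresses only the lowest spatial-frequency modes of
the white odor input, which carry a vanishing fraction of its power).
Inverting the sharpening relation for g_eff at fixed measured sharpening
gives a strictly decreasing constraint curve in J_eff whose J_eff → ∞
limit is 1 + (S(1 − f) − 1)/f ≈ 11.93 at defaults; the confidence
borders of the sharpening estimate induce a band around the curve.

## Chernoff discriminability and the neurogenesis tradeoff

Single-trial MC spike counts are modelled as Poisson at the evoked rate.
For two Poisson means the Chernoff distance has the closed form
max_α [αλ1 + (1 − α)λ2 − λ1^α λ2^{1−α}], maximized analytically
(α* = log(m/λ2)/log(λ1/λ2) with m = (λ1 − λ2)/log(λ1/λ2)); equal rates
give 0, one zero rate gives the other rate, both zero is defined as 0 and
flagged. It is symmetric and additive over independent neurons.

In the small-signal regime the expected per-MC distance between two
random odors is (I1²/4I0)(1 + J_eff(1 + (g_eff − 1)f)) — the same factor
that amplifies tuning, so the before/after-silencing ratio of expected
discriminability equals the sharpening ratio as an exact identity of the
closed forms. The Monte-Carlo estimate (network solve, rates clipped at
zero, Chernoff averaged over MCs and odor pairs) confirms the closed
form to ~2% when odor-evoked excursions are small relative to baseline
(I1 ≲ 0.02 at the default I0); at the full default I1 = 0.1 the
excursions are comparable to the baseline rate, ~5% of rates clip, and
the small-signal form underestimates the simulated value substantially —
the closed form is an approximation, and the package treats it as such.

Total discrimination is n_mc times the per-MC expectation (independent
neurons). Holding it at the reference value (1000 MCs, f = 0.025) gives
the iso-discrimination curve n_mc(f), strictly decreasing for
g_eff > 1 and flat (flagged, no midpoint) when abGCs are ordinary. Half
of the total potential MC-count reduction — defined between the f = 0
and f = 1 endpoints, the only reading that produces a fixed interior
fraction — is reached at f_half = 1/(2 + ρ), ρ = J_eff(g_eff − 1)/
(1 + J_eff) ≈ 7.6% at defaults; the closed form is cross-checked against
a bracketed numeric solve on the curve and is exactly independent of I0
and I1 and insensitive (< 1 percentage point for ±20% peak-strength
changes) to the remaining free parameter.

## Synthetic-data generator

The generator emulates the *structure* of the paired experiments: 7 Hz
frames, 6 s pre-stimulus, 2 s stimulus, 8 s post window (covering every
analysis window with margin), 11 odors × 5 trials, excited and
suppressed cell-odor pairs drawn with probabilities 0.3/0.2 (≈ 40% of
responsive pairs suppressed, as in awake recordings), unit-peak
difference-of-exponentials transients (rise 0.15 s, decay 0.8 s —
GCaMP6f-like) scaled by amplitudes ~N(0.6, 0.2²) dF/F clipped to
[0.05, 0.9], i.i.d. Gaussian frame noise (default 0.05 dF/F), a
multiplicative quench factor on "after" amplitudes, and an additive raw
baseline shift. Raw traces are f0·(1 + dF/F) with per-cell f0 uniform in
[100, 1000] a.u. and a constant 50 a.u. background trace, so the dF/F
and background-normalization stages do real work. Response identities
and amplitudes come from a stream keyed by the seed alone; frame noise
from streams keyed by (seed, condition) — before/after share responders
but not noise, and identical configs reproduce sessions bit-exactly.

It does **not** model spike-to-calcium dynamics, sniff coupling,
trial-to-trial amplitude variability, motion artifacts, neuropil
contamination, or correlated noise across cells. Passing tests therefore
demonstrate correctness of the analysis operations and their
calibration under idealized noise, not robustness to those real-data
nuisances.

## Degenerate inputs and tolerances

- Window endpoints in seconds are converted to frames by rounding, with
  half-open [start, end) intervals (at 7 Hz the 0–4 s window is exactly
  28 frames).
- The linear solver raises on a singular (I + W); this occurs only if
  inhibition exactly cancels the identity.
- Chernoff optimization uses the analytic optimizer (no numeric search),
  so the only truncation error lives in the joint-distribution oracle
  used by tests.
- Permutation enumeration compares statistics with a 1e-12 slack so that
  ties arising from exact arithmetic count as at-least-as-extreme.
- CSV payloads are written with 17 significant digits and parsed with
  round-trip float precision.
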