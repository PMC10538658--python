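# Methods

## The design and its conventions

All analyses assume the two-condition circadian time course: plants
under free-running conditions receive identical acute cold treatments
whose 3 h windows end at ZT28, 32, 36, 40, 44 and 48, with
contemporaneous controls and (by default) three biological replicates
per condition × timepoint. A sample's ZT label marks the **end** of its
treatment window. Subjective dawn under free run is ZT24, so internal
phases are h = (ZT − 24) mod 24; the six sampled timepoints sit at
phases 4, 8, 12, 16, 20 and 0. ETMR bins are half-open 4 h intervals of
phase: [0,4) → "<4 h" … [20,24) → ">20 h".

Designs with a timepoint count other than six are accepted with a
warning (the ETMR bins presuppose a 24 h span at 4 h resolution);
fewer than two timepoints is an error.

## Expression and differential expression

CPM is plain library-size normalization (10⁶ · count / column sum); a
`norm_factors` hook exists for composition corrections such as TMM but
defaults off. The low-expression filter retains genes with
CPM > k in ≥ n samples, k = 10⁶ · min_count / median library size
(min_count 10) and n = the smallest condition × timepoint group size.

Cold vs control is tested per timepoint on log₂(CPM + 0.5) with a
moderated two-sample t-statistic. Gene-wise pooled variances (4
residual df at 3+3 replicates) are shrunk toward a prior fitted by
empirical Bayes under the scaled-F hierarchical model; the prior
(d₀, s₀²) is estimated from the moments of log s² (digamma/trigamma
moment matching) jointly across all genes and timepoints, so the six
contrasts share one global variance prior. The moderated t has
d + d₀ df. With `moderate=False` the test reduces exactly to the
ordinary pooled two-sample t-test (verified against
`scipy.stats.ttest_ind`). BH adjustment is applied within each
timepoint's contrast by default (`fdr_scope="global"` pools all six); a
DEG is FDR < 0.05 and |log₂FC| > 0.5. Cells with a single replicate
trigger a logged fallback to a variance pooled across timepoints.

## Rhythmicity on six points

The default backend is a grid cosinor: y = m + a·cos(2πt/T) +
b·sin(2πt/T) fitted at trial periods T ∈ {20, 20.5, …, 28} h, the
best period chosen by least residual error (ties to the smaller
period), amplitude √(a²+b²), and phase the peak time of the fitted
cosine within the sampled cycle, mod 24.

Selecting the best-fitting period before testing invalidates the naive
F(2, n−3) tail: on this design it rejects ~9% of flat Gaussian profiles
at a nominal 0.05. Because the max-F statistic is scale- and
location-free under that null, its distribution depends only on the
sampling and period grids; it is tabulated once per grid pair by Monte
Carlo (10⁵ draws, fixed internal seed, cached) and the reported p-value
is the empirical tail probability. Measured null rejection is 0.050 at
0.05 and the p-distribution is uniform to Monte-Carlo resolution; the
smallest reportable p is ~10⁻⁵, ample for thresholding at 0.05. An
optional `method="fisher"` combines this p with a Lomb–Scargle p over
the same window by Fisher's method; the two statistics are computed
from the same six points and are strongly dependent, so the combination
is anti-conservative and is not the default.

Replicate-level series (used for the per-condition rhythmicity
prefilter of the displacement analysis) are tested separately and
combined by Fisher's method — replicates are independent plants, so
independence holds there — with amplitude-weighted circular-mean
phases. A means-based variant is available via `use_replicates=False`.

Consequences of n = 6 worth knowing: the test needs R² ≳ 0.92 at the
best period to reach p < 0.05, so only near-sinusoidal profiles are
detectable, and power against NB noise plateaus below 1 (the noise is
multiplicative, so signal-to-noise does not grow with response
magnitude). Both behaviours match the intuition that short-series
rhythm detection is conservative.

## Gating calls

Filters run in the order expression → DEG → rhythm → direction →
anomaly, and every gene's booleans are retained for audit. Direction
uses mean Δmean-normCPM with thresholds ±0.5; a value exactly at a
threshold is assigned displacement (logged tie-break). The printed
description of the reduction threshold is ambiguous between "> −0.5"
and "< −0.5"; only < −0.5 makes the three classes partition the line,
so that is implemented. ΔCPM is cold − control, making inductions
positive and consistent with the +0.5 induction cut.

ETMR is the cosinor phase of ΔCPM (of −ΔCPM for reductions, giving the
trough). The anomaly filter applies to the two edge bins ("<4 h",
">20 h") for inductions and displacements: the gene is removed when
|ΔCPM| at the sampled timepoint circularly nearest phase+12 exceeds
|ΔCPM| at the timepoint nearest the phase itself. "Nearest" breaks
ties toward the earlier timepoint.

## Displacement

Adj.ΔCPM(ZTx) = cold(ZTx+4) − control(ZTx) for x ∈ {28…44}; both the
mean |ΔCPM| and mean |Adj.ΔCPM| average absolute values over those five
timepoints, and the ratio of the two classifies genes at 1 and 0.5. A
zero mean |ΔCPM| leaves the ratio undefined (logged, excluded from
classes). Two cohorts are summarized: genes with rhythmic ΔCPM minus
gated inductions/reductions (a flag switches to excluding all gated
calls, since the published cohort size cannot be reconstructed from the
stated filters alone), and genes rhythmic in both condition CPM
profiles.

## Subgenomes and triads

Subgenome is parsed from the identifier (TraesCS⟨chr⟩⟨A|B|D⟩…;
TraesCSU… is unplaced). Unparseable identifiers stay in the expression
and gating analyses but never enter subgenome denominators. ΔCPM_ETMR
averages ΔCPM at a group's two endpoint timepoints; ZT24 was not
sampled, so the "<4 h" group wraps circularly to ZT48 as its lower
endpoint (the subjective dawn of the following cycle). Relative
contributions are shares of the summed member ΔCPM_ETMR; triads whose
members disagree in sign are flagged "mixed-sign" (shares are computed
but are not proportions) and excluded from default summaries, and
zero-sum triads are undefined. Dominance means one share > 0.5
(configurable). A triad joins an ETMR group if any member is gated in
it.

## The synthetic-data generator

The generator is first-class, tested code: it defines the study
conditions under which the pipeline's operating characteristics are
measured. Per gene it draws a rhythmic baseline
CPM·(1 + amp·cos(2π(t−24−φ)/24)) and layers one of five cold-response
archetypes; counts are NB with variance μ + φμ² (φ default 0.05 — the
replicate noise of the motivating data is uncharacterized, so this is
an explicit stand-in, exposed in config), library sizes log-uniform
±20% around 5·10⁶ reads.

Choices that matter, with reasoning:

* **Gate shape and width.** Gated responses follow a raised-cosine
  sensitivity gate centred on the true ETMR. The default width is
  20 h — graded gating, a near-sinusoidal modulation of responsiveness
  across the cycle. Narrow all-or-none gates (e.g. 8 h) remain
  available, but sampled every 4 h they produce one- or two-point
  spikes whose noiseless cosinor p is ~0.15: they are invisible to any
  6-point harmonic test, which is a property of the sampling, not a
  bug.
* **Induction archetype.** Cold-induced genes start from low baselines
  (lognormal, median 8 CPM) and induce 5–20-fold. Both halves matter:
  the fold range is what carries the true time-course average past the
  +0.5 normalized threshold, and low baselines keep the induced read
  mass a small share of the library. Giving induced genes average
  baselines makes cold libraries visibly larger, and CPM's
  compositional normalization then drags every other gene's apparent
  cold expression down — a real artifact of CPM that the default mix
  (responsive genes a minority: 900/420/80/240/120/240 across the six
  classes) keeps at the few-percent level seen in real data.
* **Reduction archetype.** Reductions are bounded by the control level,
  so only deep (1.0–1.4 × baseline, expectation clamped at zero),
  wide-window repression can move the time-course average below −0.5.
* **Stabilized archetype.** The cold expectation at ZTx equals the
  control expectation at ZTx − 3 (the treatment start), evaluated in
  continuous time from the cosine model; baseline amplitudes are
  U(0.3, 0.8). The implied true displacement ratio is
  sin(π/24)/sin(3π/24) ≈ 0.34.
* **Triads and bias.** A configurable fraction of genes is organized
  into A/B/D triads whose members share generative parameters, so
  unbiased triads have mean shares of exactly 1/3 and any recovered
  asymmetry is attributable to the injected `subgenome_bias`
  (per-subgenome magnitude multipliers, optionally restricted to an
  ETMR window). Because NB noise is multiplicative, a magnitude
  multiplier is invisible once responses are far above the detection
  margin; the packaged bias experiment (`subgenome_bias_config`)
  therefore draws induction folds log-uniform over 1.2–6× so the ×2
  night-time D multiplier genuinely changes which genes are recovered.
* **Scaling.** Baselines are rescaled so each sample's expected CPM
  total is ~10⁶, keeping generative CPM units commensurate with
  realized CPM (a few percent of compositional jitter remains, as in
  real CPM data). One RNG stream seeded once; gene order is derivation
  order, so truth and counts align positionally.

What the generator does **not** emulate: read-level artifacts
(mapping, GC, length biases), batch effects, isoform structure,
non-sinusoidal baseline waveforms, inter-gene correlation, and
vernalization/photoperiod history. Passing recovery tests therefore
demonstrate correctness of the pipeline's logic and its operating
characteristics under idealized NB noise, not performance guarantees
on real libraries.

## Numerical choices

Cosinor ties on the period grid go to the smallest period; phases are
rounded at 10⁻⁹ h before ETMR binning so bin-edge phases (a cosine
peaking exactly at ZT40 → phase 16) land in the intended bin; the
empirical-null table uses 10⁵ draws (p resolution 10⁻⁵); BH is
statsmodels' `fdr_bh` (tested for exact equality against an independent
sort-and-cummin implementation); float comparisons in tests use 10⁻⁹
where exactness is claimed. All-constant profiles get p = 1 and
amplitude 0. Output tables print floats at 6 significant digits, and
`summary.json` is written with sorted keys so identical runs are
byte-identical.

## Known limitations

* The rhythm backend is a cosinor/Lomb–Scargle contract, not a
  re-implementation of ensemble detectors (meta2d/ARSER/JTK); p-values
  and phases near bin edges can disagree with ensemble estimates, so
  published group sizes should not be expected to reproduce exactly.
* Whether BH should pool timepoints is exposed as `fdr_scope` rather
  than decided; the per-timepoint default is the standard per-contrast
  reading.
* The displacement ratio is biased upward for genes whose adjusted
  profile is below the noise floor (mean |noise| dominates the
  numerator); cohort membership does not guarantee adjusted-signal
  detectability, so a noise-dominated minority of genuinely stabilized
  genes reports ratios near or above 1.
* Displacement cannot distinguish a held abundance from a phase shift
  of the underlying oscillator; the analysis makes no claim about the
  clock itself.
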