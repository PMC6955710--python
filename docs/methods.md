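# Methods

## Signal model and connectivity estimator

Epochs are modelled as stationary MVAR processes
`x(t) = Σ_{r=1..p} A(r) x(t−r) + e(t)` with i.i.d. Gaussian innovations.
Coefficients are estimated per epoch by least squares on the stacked
lag design; the residual covariance is normalized by the residual count
(n − p). With ridge = 0 the solver is SVD-based least squares with an
explicit rank check; a rank-deficient design raises an error advising
ridge > 0. The ridge penalty is *relative* — scaled by the mean
diagonal of the Gram matrix — so that the effective regularization does
not depend on signal units and canonical PDC's invariance to a uniform
channel gain survives regularization.

Partial directed coherence is computed in its canonical form,
`Ā(f) = I − Σ_r A(r) e^{−i2πfr/fs}` and
`PDC_ij(f) = |Ā_ij(f)| / ‖ā_j(f)‖₂`. Only this form guarantees the
column-normalization identity `Σ_i PDC_ij(f)² = 1` and entries in
[0, 1], which the thresholding grid (0–0.3) presumes. Frequencies are
interpreted in Hz with the lag index divided by the sampling rate in
the exponent. Note that canonical PDC is invariant to a *uniform*
rescaling of all channels but not to per-channel gains; the
variance-normalized (generalized) variant that has the latter property
is deliberately out of scope.

Per-epoch band averages (arithmetic mean of |PDC| over 0.5–30 Hz on a
0.5 Hz grid, 60 bins) are averaged entrywise across an epoch set's kept
epochs to give one m×m weighted directed network per time-on-task
block; the diagonal is zeroed for graph use. Windows are non-overlapping
(one per 1200 ms epoch); a concatenated-fit alternative is available via
`block_connectivity(..., concatenate=True)`. Orientation is fixed
package-wide: `W[i, j]` is the flow j → i (row = receiver).

Model order defaults to 7 for protocol-scale data; `select_order_aic`
implements `AIC(p) = ln det Σ̂_p + 2pm²/N_eff` over 1 ≤ p ≤ p_max and
returns the full curve for audit alongside the argmin.

## Preprocessing

The chain is common average reference → zero-phase FIR band-pass →
target-locked epoching with per-epoch mean (baseline/DC) removal →
absolute-amplitude epoch rejection.

* The band-pass (default 0.1–30 Hz) uses a Hamming-window linear-phase
  design, default length min(3·fs/lo, 8449) taps forced odd. Because
  the low cut-off sits inside the transition band, the raw windowed
  design leaks at 0 Hz; the taps are mean-adjusted so that the DC gain
  is exactly zero. The symmetric kernel is applied twice by centered
  FFT convolution with odd-reflection padding — the forward–backward
  scheme for a symmetric filter — so the magnitude response is squared
  and group delay cancels (epoch timing is not shifted).
* Epochs start at the event sample (half-open windows,
  round(epoch_ms·fs/1000) samples; 600 at the 500 Hz / 1200 ms
  defaults) and are labelled with the time-on-task block containing
  their event (default three 20-min blocks). Events too close to the
  recording end are skipped with a logged warning.
* Rejection drops any epoch whose absolute amplitude exceeds 100 µV on
  any channel. This automated criterion stands in for manual/ICA
  artifact screening, which cannot be specified as a reproducible
  contract; it catches the same gross artifacts on synthetic data with
  injected spikes.

## Graph indices

Thresholding is either absolute (entries < T zeroed; grid
{0, 0.1, 0.15, 0.2, 0.25, 0.3}) or proportional (the
floor(s·m·(m−1)) largest off-diagonal weights kept, s ∈ {0.10, …,
0.30}; ties at the cut broken by (row, column) index order so repeated
runs are identical). Degree/strength are computed on the thresholded
weights. The clustering coefficient is Fagiolo's weighted directed
form with the canonical factor-2 denominator and the reciprocal-pair
correction `2d_i^↔`; it is homogeneous of degree 1 in the weights and
bounded by 1 for weights in [0, 1]. C_i is defined as 0 where the
denominator vanishes. The global CC is the arithmetic mean of local
values. Path length uses edge length = 1/weight and Dijkstra's
algorithm; PL is the mean over *finite* ordered pairs, with the
unreachable-pair fraction reported alongside, because proportional
thresholding routinely disconnects the graph and silently averaging
infinities would be meaningless. Metric integrals over the sparsity
range use the trapezoid rule. Normalized degree divides d_tot by its
maximum 2(m−1).

All metrics are verified against brute-force enumeration oracles
(loop-based degree counts, triangle enumeration, Floyd–Warshall) on
random graphs up to m = 8, at 1e−10.

## Hemispheric information flow

The default montage is the standard 10–20 64-electrode layout minus the
mastoids: 27 left, 27 right, 8 midline (Fpz, Fz, FCz, Cz, CPz, Pz, POz,
Oz). Midline electrodes are dropped and the remaining matrix split into
four sub-networks by (sender hemisphere → receiver hemisphere).
"Information flow" of a node is its summed outflow across receivers
(the inflow summary is also available, since either reading of a
per-node flow total is defensible). The nonstandard label "PT8" seen in
some montage listings is mapped to TP8. Reduced desk-scale montages use
homologous left/right electrode pairs so the hemispheric stage remains
exercised at any even channel count up to 54.

## Statistics

Within-cohort level contrasts are paired t-tests (the same subjects
contribute all three blocks); vigilance-versus-enhancement contrasts
are Welch two-sample tests (different participants). All tests are
two-sided. Families of p-values are corrected with Bonferroni–Holm
(step-down; the implementation is backed by
`statsmodels.stats.multitest.multipletests(method="holm")` and verified
against the explicit step-down rule). Zero-variance situations raise a
degenerate-test error rather than returning an infinite statistic.
Electrode t-maps flag |t| ≥ 2.5 by default (configurable); electrodes
with exactly constant metrics yield an undefined t and are excluded
from the mask. The one-vs-all Δ construction subtracts a weighted sum
of the vigilance (control) cohort from each enhancement subject;
weights default to uniform (Δ = value − control mean) because no
specific weighting is prescribed, and are exposed as a parameter.

## Synthetic sessions: what they emulate, and what they do not

`CouplingSpec` places ground-truth directed coupling at lag 1 only —
the simplest structure whose PDC is analytically computable — with a
per-channel AR(1) self-term (default 0.5) and per-block multipliers on
all edge strengths: (1.0, 0.7, 0.4) for vigilance decrement,
(1.0, 1.0, 0.95) for enhancement (the small final-block dip mirrors the
non-significant late decrease seen under stimulation). Stability is
enforced by uniform coefficient shrinkage to companion spectral radius
0.95, which preserves topology. Innovations are i.i.d. Gaussian,
default 5 µV, giving realistic ~10 µV signals comfortably inside the
100 µV rejection limit.

The default truth network has in-degree ≤ 1 (one incoming edge per
channel, sources random, strengths U(0.35, 0.55), topology drawn once
from a fixed seed). Unconstrained random placement creates receiving
hubs whose variance explodes near the stability boundary and would be
blanket-rejected by the amplitude criterion; the in-degree cap keeps
per-channel variance homogeneous.

Two variance components make the cohorts statistically realistic:
a between-subject strength factor (uniform ±10 %) and a per-block
session-variability factor (uniform ±10 %). The block factor matters:
without any within-subject, between-block variance beyond Monte-Carlo
epoch noise, paired tests at n = 12 would flag even the trivial 5 %
enhancement drift as a significant decline, which real
sessions — and the maintenance finding the generator is built to
emulate — do not show. Subjects with a stronger coupling factor get a
proportionally faster baseline reaction time, reproducing the observed
association between connectivity enhancement and performance.
Behavioral series are linear trends plus Gaussian noise per 3-min bin
(vigilance: RT +0.30 s and accuracy −0.12 over the session from bases
0.85 s / 0.95; enhancement: RT −0.12 s, accuracy flat), with matching
omission/commission-rate trends.

Not emulated: volume conduction and a head model, non-Gaussian/1-f
background spectra (a surrogate-noise flag is reserved but off),
ocular/muscle artifacts beyond optional amplitude spikes, higher-lag or
time-varying coupling within a block, and event-locked evoked
responses. Passing tests therefore demonstrate correctness of the
estimation/statistics machinery on a known directed system — not
robustness to the full physiology of scalp EEG.

## Scale choices

The cohort studies shipped in `analysis/` and exercised by the
acceptance script run at a desk scale chosen to finish in minutes on
one CPU: 16 channels, 12 subjects per cohort, three 2-min blocks with
40 target epochs each (event every 3 s, as at protocol scale, where
20-min blocks hold 400 epochs). Two estimator settings differ from the
protocol defaults at this scale, both for cause:

* **No common average reference.** CAR removes a shared physical
  reference; the synthetic sessions are generated reference-free, so
  CAR only injects −1/m of every channel into each channel. At m = 62
  that contamination is mild; at m = 16 it destroys directional
  structure (measured true-edge vs null-pair band-averaged PDC:
  0.15 vs 0.22 with CAR, 0.33 vs 0.13 without). CAR also makes the
  MVAR design exactly rank-deficient (channels sum to zero), which is
  why the protocol-scale default pairs CAR with a small relative ridge
  (1e−3).
* **Order 1, not 7.** The generator couples at lag 1, and AIC on raw
  synthetic epochs selects order 1; on band-passed epochs AIC instead
  chases the filter-induced autocorrelation. Order 7 on 600-sample
  windows spreads the coupling over collinear lags and buries it in
  estimation noise (true-edge PDC ≈ null ≈ 0.22).

## Known limitations

* Canonical PDC is sensitive to per-channel gain differences; recordings
  with severely unbalanced channel variances should be standardized
  upstream, or interpreted accordingly.
* At protocol scale (62 channels, p = 7, 600-sample windows) the
  per-epoch regression is near-saturated; the ridge default stabilizes
  it, but per-epoch estimates are strongly regularized and block
  averages should be interpreted as shrunken effect sizes.
* PL's unreachable-pair exclusion makes PL non-monotone in pathological
  cases where thresholding removes the only long path; the reported
  unreachable fraction should be checked alongside.
* No EDF writer is provided (only reading, via the optional `mne`
  dependency); sessions are persisted in the package's delimited
  text container.
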