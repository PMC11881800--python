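# Methods

This note records the models, the defaults and why they are set where they
are, what the synthetic generator does and does not emulate, and the places
where the design was genuinely open.

## Signal model and preprocessing

Channel intensities at 760/850 nm are converted to delta optical density
ΔOD(t) = ln(Φ_ref/Φ(t)). The reference Φ_ref is the channel's temporal mean
(robust to startup transients; `reference="first"` is available). A
consequence worth stating: ΔOD only identifies *changes* in chromophore
concentration — any per-channel DC offset is absorbed into the reference, so
round-trip comparisons are made after mean-centering; on centered data the
optical forward/inverse maps are exact to machine precision.

Motion artifacts are detected on the first-difference series: haemodynamics
are smooth, so spikes and baseline shifts stand out against the robust
derivative scale (1.4826·MAD). Defaults: 1 s moving-SD window, moving-SD
factor 13.5, jump factor 5, flag dilation of half a window. Flagged segments
are refit with a near-interpolating smoothing spline (p = 0.99); the residual
is re-anchored to the preceding baseline and the tail rejoined continuously,
which removes both spikes and step shifts. A wavelet stage (db2, 4 levels)
then zeroes detail coefficients beyond the two-sided Gaussian tail at
α = 0.1 per level (robust σ from the MAD). Signals confined below ~0.24 Hz
pass this stage essentially unchanged; broad-band content is attenuated.

The modified Beer–Lambert inversion solves the per-channel 2×2 system with a
standard compiled extinction table (decadic ε, converted to natural-log
units) at source–detector distance 3 cm and DPF(age) = 4.99 + 0.067·Age^0.814
(so DPF(0) = 4.99). Channels are then linearly detrended and centered. No
temporal band-pass filtering is applied at any stage — frequency selection
happens only by band-averaging the spectral estimates later, which avoids
filter-induced spurious connectivity.

Systemic physiology (Mayer waves near 0.1 Hz, scalp/global haemodynamics) is
removed by spatial regression: each channel's regressor is the mean of all
channels *outside its own ROI* (leave-self-out when no channel→ROI map is
supplied). Residuals are exactly orthogonal to their own regressor.
Excluding the channel's own region keeps regional activity from being
subtracted out of the very channels that carry it; the estimate of the
global component comes mostly from the ~80 montage channels outside the
seven reading ROIs. Finally the 40 mapped channels are pooled (plain mean)
into 7 ROIs per hemisphere (8 IFG, 6 STG, 8 MTG, 6 FFG, 4 SMG, 4 IPL, 4 ANG).

Measured fidelity of the whole chain on synthetic data (7-min recordings,
default artifact levels): each artifact class at its default level is
handled with recovery correlation > 0.95 per ROI; with *all* classes active
simultaneously the per-ROI correlation is ~0.91–0.94. The residual loss is
not a bug in any stage: regressing one slow (~0.009–0.08 Hz) signal on
another over 7 minutes has only a few dozen effective samples, so the
spatial-regression stage unavoidably removes a chance-correlated slice of
genuine activity, on top of a small residue of uncorrected motion energy.
This matches the accuracy range reported for short-channel-free spatial
filtering against reference corrections in the validation literature, and it
bounds what a passing test demonstrates about real recordings.

## Time-varying MVAR and TPDC

The adaptive model is x(t) = Σ_{r=1..P} A_r(t) x(t−r) + η(t). Two coupled
predictor–corrector filters estimate it: a *state filter* on the stacked lag
state (companion transition built from the current coefficient estimate,
observation = the measured sample plus noise) and a *weight filter* that
treats each target row's coefficients as a random walk and corrects them
against the one-step prediction error using the state filter's estimate.
Numerical choices that matter:

- **State process noise.** The MVAR innovation η *is* the state process
  noise, so its per-channel variance is tracked online from the prediction
  errors (exponential forgetting 0.99) and fed to both filters (as the state
  filter's process noise and the weight filter's observation noise). A small
  fixed value here over-smooths the state and systematically inflates
  coefficients; a fixed override remains available.
- **Initialization.** The weight filter warm-starts from a stationary
  least-squares (ARfit-style) fit of the leading segment. Haemodynamic-band
  signals are strongly autocorrelated, so the lagged regressors are nearly
  collinear and information accrues slowly; from a zero start the
  convergence transient lasts thousands of samples and corrupts
  time-averaged coefficients. `init="zero"` is available for studying that
  transient. Weight covariance starts at `init_scale`·I (default 1); weight
  random-walk variance 1e−4; state observation noise 1% of the sample
  variance; burn-in 10·P samples.
- **Model order** is selected by Schwarz's Bayesian criterion over a common
  effective sample (default range 1–8). An augmented Dickey–Fuller test per
  channel warns (never aborts) on unit-root behaviour.

PDC is evaluated from the coefficient polynomial
Ā(f,t) = I − Σ_r A_r(t)e^(−i2πfr/fs) with the standard column-root
normalization, so Σ_i |π_{i←j}|² = 1 exactly per source column. The grid is
64 evenly spaced frequencies on (0, fs/2]; at fs = 7.8125 Hz exactly one
grid point falls inside 0.009–0.08 Hz, so the band average is effectively
the PDC at ~0.06 Hz (raise `n_freq` for a denser in-band average). The
stored time–frequency tensor is decimated to ≤ 512 time points; the
band/time average uses those points. Hemisphere averaging operates on the
band/time-averaged matrices (element-wise mean), preserving within-
hemisphere dynamics.

## Significance: windowed-shuffle bootstrap and time reversal

Each subject's series is cut into K = 20 nonoverlapping windows (N = KV,
trailing remainder truncated) and the window order is permuted
*independently per channel* — this preserves each channel's spectrum and
short-range autocorrelation while destroying the cross-channel alignment
that carries directed coupling. (Permuting all channels jointly leaves the
causal structure intact and is not a null.) A stationary MVAR is refit to
each surrogate and its band-averaged PDC recorded; the 99th percentile over
1000 iterations (100–200 in reduced test mode, with correspondingly wider
Monte-Carlo tolerance) is the per-connection threshold. The same statistic
is used for the observed value and the nulls by default, which makes the
percentile rule exchangeable and hence calibrated; a DEKF-based observed
matrix can be thresholded instead via the `observed` argument, at the cost
of an estimator mismatch between observed and null.

The time-reversal test uses the *directional asymmetry*
d(j→i) = π(i←j) − π(j←i). For genuine lagged coupling this asymmetry
inverts when the time axis is reversed (time reversal transposes the lagged
cross-covariances), while instantaneous common-input artifacts are symmetric
under reversal. A connection passes when the forward-minus-reversed
asymmetry exceeds the 95th percentile of its |distribution| over the same
shuffled surrogates. The asymmetry form is deliberately insensitive to the
saturation of strong connections (a 0.99 forward PDC can still have a 0.90
reversed PDC; the raw difference carries almost no signal, the asymmetry
flip does). Only bootstrap-significant connections can pass the final mask.

## Cohort statistics

PCA standardizes the 10 clinical variables (CI group only), decomposes the
correlation matrix, retains components with eigenvalue > 1, and reports a
promax (power 4) pattern matrix — a pattern matrix implies an oblique
rotation. Scores are unrotated component scores (exactly uncorrelated).

Each mediation is the saturated linear path model m = a·x + e₁,
y = b·m + c′·x + e₂, estimated by OLS (maximum likelihood for this model);
total = direct + indirect holds as an algebraic identity. The indirect
effect a·b gets a percentile bootstrap over subjects (5000 draws by default)
and a two-sided p from the sign balance of the bootstrap distribution.
Variables are z-scored inside the battery so effects are standardized. BH
correction is applied within each component's family of 252 tests
(42 connections × 6 subtests), matching the bookkeeping of the analysis it
reimplements; no covariates are included by default. Group comparisons use
Welch's t (Satterthwaite df) and the Mann–Whitney U with tie correction;
reading regressions are plain OLS with R², overall F and slopes, rejecting
designs with condition number above 1e10.

## The synthetic generator

**Networks.** Self-dynamics are a double real pole at ρ = 0.94 (lag-1
coefficient 2ρ, lag-2 −ρ²), which places >80% of spectral power below
0.08 Hz at fs = 7.8125 Hz — the band the analysis averages. Directed edges
are plain lag-1 coefficients drawn from (0.15, 0.35). Because feedback
between such strongly resonant nodes diverges at any detectable coupling,
the default generator samples acyclic edge patterns (block-triangular ⇒
stable at full coupling strength); cyclic patterns are available
(`acyclic=False`) and are stabilized by shrinking couplings 30% per retry,
which necessarily leaves them weak. Stability is always verified on the
companion matrix spectrum. A by-product of acyclic cascades of resonant
nodes is a wide dynamic range across ROIs; amplitudes are re-normalized per
channel in the optical forward model, and PDC is scale-invariant.

**Recordings.** Each mapped channel gets its ROI's latent series (0.3 µM per
latent SD) plus white channel noise (0.2×), a shared slow systemic component
(0.5×), a shared 0.1 Hz Mayer oscillation (0.5×), and Poisson spike
(0.5/min, 8× SD, ~0.25 s decay) and baseline-shift (0.2/min, 4× SD)
artifacts; HbR mirrors HbO at −0.33. Forty-two unmapped background channels
carry independent slow haemodynamics plus the shared confounds, completing a
122-channel whole-head montage (2×40 mapped + 42) and giving the spatial-
regression stage a realistic, mostly non-network global estimate. The
forward Beer–Lambert map then produces strictly positive two-wavelength
intensities. Not emulated: photon transport/partial-volume effects, probe
geometry, CI device artifacts, heart-rate/respiratory bands, and
channel-specific systemic gains — so passing tests certify the algorithmic
chain, not device physics.

**Cohorts.** Clinical variables are drawn in three correlated blocks
(primary intervention: age at first CI 1.98 ± 0.98 y, age at hearing-aid fit
1.00 ± 0.85 y, deafness durations; secondary intervention: bilateral-implant
timing, age at bilateral CI 3.4 ± 2.6 y; development: age at testing
12.2 ± 2.9 y, head size), with hearing age = age at testing − first hearing
intervention enforced as an exact identity and small reporting jitter
keeping the table full rank. Planted mediation routes factor → connection
strength → reading score with configurable (a, b, direct) paths; the
default plants a timing-of-intervention effect (a = −0.5, b = 0.4,
c′ = −0.15) through SMG→IPL on all six subtests. Reading scores share a
general-ability factor (0.5) and a development loading (0.3); TH children's
scores rise with age (0.55) and sit ~0.8 SD above CI scores, with the 2:1
group mix keeping the population mean at 250 and the within-group variance
shrunk so the population SD is 15 before clamping to [190, 310]. All
variance bookkeeping is explicit; infeasible effect combinations (implied
residual variance < 0) raise immediately.

## Problem sizes used in the test suite

Simulations in the shipped tests use 1.5–10 k samples per series, 10–50
seeds per Monte-Carlo claim, 100–200 bootstrap iterations (the reduced mode
documented above), and cohorts of 50–5000 subjects — sizes at which every
stochastic assertion has comfortable margin while the whole suite stays
fast on a single CPU.

## Known limitations

- The exact spatial-domain filtering algorithm of the original analysis is
  not published as equations; leave-ROI-out mean regression is this
  package's documented stand-in.
- The time-reversal acceptance rule is an operationalization (asymmetry
  exceedance against the shuffled-null spread); other TRT variants exist.
- With the default 64-point grid the 0.009–0.08 Hz average rests on a
  single frequency; set `n_freq ≥ 256` for a genuine band average.
- Bootstrap nulls refit a stationary MVAR rather than rerunning the dual
  EKF (the fidelity/speed trade described above); thresholding a DEKF-based
  observed value against stationary nulls mixes estimators and is not
  calibrated at the nominal 1%.
- Mediation models are single-mediator linear path models; no latent
  variables, no longitudinal structure, no covariate adjustment by default.
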