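# Methods

## Model

The system comprises the four cyclins CLN3, CLN2, CLB5 and CLB2 and the
transcription-factor subunits SWI4, NDD1 and SWI5 (variants 2-4 add HCM1,
variants 3-4 add YOX1).  Each gene contributes two state variables, its
transcript and its protein, both in micromolar; time is in seconds.  The
rate laws are mass action with a single nonlinearity for repression:

    dm_i/dt = (beta_i + alpha_i * P_act(i)) * f_i  -  deltam * m_i
    dP_i/dt = kappa * m_i  -  deltap_i * P_i * g_i

Each transcript has exactly one activating factor and at most one
repressor.  The repression factor is Hill-type, `f = 1/(1 + (x/K)^h)`,
applied multiplicatively to the transcription term (and, for NDD1 in
variant 4, to the protein degradation term).  The Hill exponent is a free
parameter per repression edge with a linear-uniform prior on [1, 4],
spanning gentle to switch-like repression without fixing the cooperativity;
the functional form itself is a modeling choice — only "a nonlinear
inhibition term" is demanded by the biology, and Hill repression is the
field's default.  `deltam` and `kappa` are shared across genes; attempting
gene-specific values would leave most of them unidentifiable from the data
channels used here.  Post-translational modification, complex formation and
localization are deliberately out of scope: the aim is the smallest model
that can express cyclic transcription, not a comprehensive cell-cycle model.

Initial conditions at the synchronization release (t = 0) are free
parameters with log10-uniform priors, because the released population's
state is not measured directly.

Wiring of the variants: CLN3 -> SWI4 -> {CLN2, CLB5}; NDD1 -> {CLB2, SWI5};
SWI5 -> CLN3; NDD1 is activated by SWI4 (variant 1) or by SWI4 -> HCM1
(variants 2-4); variant 3 adds SWI4 -> YOX1 with YOX1 repressing
transcription of SWI4 and CLN3; variant 4 adds inhibition of NDD1 protein
degradation by CLN2.  CLB5 activation is wired through SWI4 (as the SBF/MBF
representative in this reduced network).

## Parameters, units and priors

Per gene: basal transcription `beta` (uM/s), induced transcription `alpha`
(1/s per uM of activator), protein degradation `deltap` (1/s), initial
concentrations `m0`, `p0` (uM).  Shared: `deltam`, `kappa` (1/s).  Per
repression edge: `K` (uM) and `h`.  Channel error scales `sigma_tc`,
`sigma_ss` (dimensionless, log-ratio / log10 units) are inferred alongside
the kinetics.  All parameters except the Hill exponents are sampled on
log10 scale with independent uniform box priors; the defaults are

| class | bounds (linear) |
| --- | --- |
| rates (`beta`, `alpha`, `deltam`, `deltap`, `kappa`) | 1e-6 .. 10 |
| concentrations (`m0`, `p0`, `K`) | 1e-5 .. 10 uM |
| error scales | 1e-2 .. 10 |
| Hill exponents | 1 .. 4 (linear) |

all overridable per parameter or per class in the run configuration.  The
bounds are intentionally generous — several orders of magnitude around
plausible yeast values — so that "the data constrain a parameter" is a
statement about the likelihood, not the prior.

## Likelihood

The cell-cycle period is fixed at T = 4800 s (80 min); trajectories are
integrated over exactly two periods starting at t = 0, and the *time
average* of a species is its trapezoidal mean over [0, 2T].  Averaging
starts at t = 0 rather than after a transient because the data themselves
start at the synchronization release.

Relative time-course records (experiment, gene, time, log-ratio) are
centered on `log(m_g(t) / mbar_g)`, the log-ratio of the modeled transcript
to its own time average — the model analogue of synchronized-over-
unsynchronized expression.  Natural log is the internal convention; a
configuration switch accepts log2-ratio input (microarray convention).
Times are on the common 80-min frame; measurements from experiments with
other native doubling times are mapped linearly
(`t' = t * 80 / native_period`).  Absolute steady-state records are
centered on `log10` of the time average of the corresponding species;
multiple sources for the same species enter as independent records.

Both channels use a location-scale Student-t density with 3 degrees of
freedom — a robust error model under which outlying measurements are
penalized logarithmically rather than quadratically — with one inferred
scale per channel.  This is the minimal error-scale structure; per-source
or per-gene scales would multiply weakly-identified parameters.

A failed ODE solve, or a non-positive concentration where a log is needed,
contributes -inf: the posterior simply excludes that parameter point, and
the sampler rejects the proposal.  NaN from the posterior is a hard error,
never silently absorbed.

## Sampling

The tempered target is `log prior + beta * log likelihood`.  Tempering the
likelihood only (rather than the full posterior) makes the beta = 0 chain
sample the prior exactly, which is what gives "round trips between prior
and posterior" their meaning.  The ladder is quadratic,
`beta_i = (i/(n-1))^2` with n = 32 chains by default.

Each iteration draws between two moves: with probability 0.99 a swap of a
uniformly chosen adjacent chain pair (Metropolis acceptance
`exp((beta_i - beta_j)(l_j - l_i))` on the untempered log-likelihoods,
replica labels traveling with the states), otherwise five
Metropolis-Hastings steps applied to every chain.  "Samples" counts
iterations of this choose-swap-or-update loop.

MH proposals are blockwise multivariate normal.  Blocks are rebuilt every
10,000 burn-in iterations by single-linkage clustering of the cold chain's
recent draws at |correlation| >= 0.5 (parameters below 100 available draws
fall back to a single joint block; zero-variance parameters get singleton
unit-variance blocks).  The proposal covariance of each block is the
empirical covariance of each chain's *own* recent draws plus 1e-8 jitter —
per-chain covariances matter because hot chains have near-prior geometry
that the cold chain's covariance misrepresents.  A scalar per chain and
block is adapted every 25 update iterations by the diminishing rule
`log s <- log s + t^-0.6 (acc - 0.23)`, clamped to [1e-6, 1e3]; learned
scale multipliers are carried across re-blocking events so adaptation
resumes near its fixed point.  All adaptation freezes at the end of
burn-in.  Posterior draws are the cold chain's states subsampled at a
configurable stride, stored with their log-prior and log-likelihood so the
MAP draw can be extracted later.

Replica labels are recorded every iteration; a round trip is one complete
label cycle chain 0 -> chain n-1 -> chain 0.  Trace diagnostics (ESS,
autocorrelation, degenerate-chain flags) are computed with ArviZ.

## Synthetic data

The generator emulates the statistical structure of the real study
designs: three synchronization time courses with native doubling times of
60, 80 and 100 min and 25/15/12 points over two native cycles, rescaled to
the 80-min frame, with `sigma_tc * t(3)` noise on the log-ratios
(sigma_tc = 0.2, typical microarray log-ratio scatter); absolute records
from two transcript sources and three protein sources per species with
`sigma_ss * t(3)` noise on the log10 concentrations (sigma_ss = 0.2,
the order of cross-study disagreement in absolute quantification); and
validation rates as log10-normal perturbations (SD 0.2) of the true model
rates — the shared degradation and translation rates reported gene-wise,
plus per-gene time-averaged transcription rates.  Noise scales default to
the truth's own `sigma` parameters so generated data match the likelihood
model exactly, which is what simulation-based calibration requires.

It does *not* emulate probe-level microarray noise, synchronization decay
over the second cycle, cross-platform batch effects, or cell-to-cell
variability; passing tests therefore demonstrate correctness of the
inference machinery under the assumed error model, not robustness to
real-data artifacts beyond what the t(3) tails absorb.

The variant-4 ground-truth preset was hand-tuned once and committed: all
rates sit at realistic yeast scales (7-min mRNA and protein half-lives,
kappa = 0.05/s, transcripts at 1e-3..1e-1 uM), and the YOX1 feedback loop
with h = 4, K = 0.02 uM sustains an ~80-min oscillation (every transcript
shows two maxima over the two-cycle window).  The preset is a fixture:
it is never regenerated silently.

### Reduced benchmark

Sampler benchmarking, parameter recovery and calibration use a single-gene
model with basal transcription only — linear, with closed-form
trajectories that are cross-checked against the ODE solver.  Its preset
truth is a typical yeast transcript (beta = 2e-6 uM/s, deltam = 1e-3/s,
steady state 2 nM) with a moderately stable protein (deltap = 2e-4/s,
kappa = 0.05/s) released below steady state (m0 = 0.2 nM, p0 = 0.05 uM).
Four parameters are free — `beta`, `deltam`, `kappa`, `m0` — while
`deltap`, `p0` and the noise scales are conditioned on their true values.
The protein quantities need this: with no protein *time-course* channel,
the initial protein concentration trades off freely against the
translation rate through the protein time average, so leaving both free
makes `kappa` unidentifiable by construction.  Conditioning on the release
state and degradation rate makes `kappa` exactly the quantity the
steady-state channel should determine — mirroring, at benchmark scale, the
full study's finding that the translation rate is constrained only when
relative and absolute data are combined.

## Model checking

* **Predictive bands** are pointwise 5/50/95% quantiles of the *modeled
  mean* log-ratios over posterior draws (no observation noise re-added);
  an option adds t(3) noise for full predictive checks.  Draws whose
  simulation fails are dropped and counted.
* **R²** uses a null model with a separate mean per experiment —
  appropriate because each synchronization series has its own baseline —
  and is reported as a posterior distribution (median and central 90%
  interval over draws).
* The **spline reference R²** bounds what any smooth curve could achieve:
  a natural cubic smoothing spline per gene and experiment, smoothing
  parameter chosen by leave-one-out CV over a fixed grid of 25 log-spaced
  values with the one-standard-error rule (the smoothest value within one
  SE of the CV minimum).  The 1-SE rule is essential at a dozen points per
  series: raw LOO minima occasionally select near-interpolating fits whose
  in-sample R² is meaningless.  The procedure has no random element, so
  identical input gives identical output.
* **CI-width accounting**: per-parameter central 90% interval width on the
  sampling scale, its ratio to the prior range, and the count of
  parameters with ratio < 0.5.

## Validation comparison

The comparable transcription quantity is the *time-averaged total*
transcription rate `mean_t[(beta + alpha P_act(t)) f(t)]`, because
measured rates are population averages over unsynchronized cells.  The
shared `deltam` and `kappa` are compared against gene-wise measurements
(one model rate, several measured values).  Estimates use the MAP draw
(maximal recorded log-posterior; ties broken by first occurrence);
agreement is `|log10(measured) - log10(estimate)| < 0.5` (same order of
magnitude), with an additional flag for containment in the 90% credible
interval.

## Numerical choices

* Integration: LSODA (stiff-capable) with rtol 1e-6, atol 1e-9 uM on a
  481-point dense grid (10-s spacing over two cycles) merged with the
  exact data times; decoupled linear models use the closed form (with the
  `deltap -> deltam` limit handled analytically).  Solver failure is an
  explicit flag consumed as -inf likelihood.
* Time averages are trapezoidal on that grid; the default 481-point grid
  is within ~3e-6 relative of the fully refined value even for the
  oscillatory variant-4 trajectories (the worst case), and doubling a
  2001-point grid changes averages by ~1e-7.
* Degenerate inputs: empty draw sets, too-few diagnostics draws, zero null
  sums of squares and sub-minimum spline series are reported as errors or
  NaN "missing", never silently imputed.

### Problem sizes in the shipped studies

The test suite and the acceptance script run desk-scale versions of each
study, sized so the full suite completes in minutes on one CPU while every
statistical check retains power: the adaptive-scaling study uses 30k
adaptation + 20k measurement proposals on a 10-d Gaussian with condition
number 100; ladder-traffic runs use the full 32-chain ladder for 200k-600k
iterations of the reduced problem; simulation-based calibration pools 50
prior-drawn replicates (4 indicators each) with 8-chain PT runs of 12k
iterations; recovery runs use 16 chains for 40k iterations.  These sizes
are the package's chosen benchmark conditions and are recorded in the
respective entry points.

## Known limitations

* The full 55-parameter variant-4 posterior is not explored at
  publication scale by the shipped studies; the committed settings
  (32 chains, 1.25M + 5M iterations) reproduce the method but need hours
  of compute.
* Absolute-channel identifiability of protein-side parameters is limited
  by design when no protein dynamics are measured (see the reduced
  benchmark discussion above).
* The SBML export targets Level 3 core with a small custom annotation for
  the regulatory-edge roles; it round-trips through the package's own
  importer and standard structural checks, but full XSD validation is not
  performed.
* Real-data use of the validation channel requires a unit-conversion
  constant (molecules/min per cell to uM/s via cell volume) supplied in
  configuration; the synthetic channel sidesteps this conversion.
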