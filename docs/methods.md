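# Methods

## The measurement being emulated

A TCSPC experiment excites the sample with a picosecond laser pulse and
histograms single-photon arrival times.  The emulated acquisition uses a
25 ps bin width over 500 bins (12.5 ns, ≥ 4× the longest default
lifetime, capturing > 98% of a 3 ns decay), a Gaussian instrument
response of 50 ps FWHM, and an acquisition stop criterion of 3×10⁴
counts in the peak channel.  One decay is recorded per (sequence, pH,
emission wavelength): seven wavelengths from 560 to 610 nm at pH 7, 6,
5, 4 (three wavelengths for the unstructured control strand).

## Synthetic-data generator

Each conformer ("species") is a sum-of-exponentials decay law plus a
relative abundance per pH.  A trace's expected curve is the
abundance-weighted sum of the reconvolved species decays, rescaled so
its maximum equals the stop level, then multiplied by an optional
per-wavelength intensity factor; counts are drawn per bin from
independent Poisson laws.  Per-trace random streams derive
deterministically from (scenario seed, pH index, wavelength index), so
results never depend on iteration order.

Choices where the emulated experiment dictates no value:

- **IRF shape** — Gaussian parameterised by the quoted 50 ps FWHM
  (instruments report scatter-peak FWHM only); peak placed at 0.5 ns so
  the axis holds the full rise.
- **Acquisition model** — scaling the expected curve to the stop level
  and adding Poisson noise has the same marginal statistics as
  event-by-event accumulation at far lower cost.
- **Concentration-vs-pH profiles** — logistic
  (Henderson–Hasselbalch-like) transitions with Hill slope 2, midpoints
  pH 6.5 (open ↔ folded) and pH 4.5 (between the two folded forms of the
  short-sequence preset).  These are plausible stand-ins for cooperative
  proton-driven folding, chosen for their sequential, monotone shape;
  they are *not* fitted to any measurement.  At each recorded pH the
  dominant species carries ~91% of the population and its neighbour ~9%.
- **Species decay laws** — the published global-fit parameter sets for
  the cyanine/dabcyl beacon sequences (per sequence and pH group) are
  used verbatim as inputs: open forms are three-term models
  (τ ≈ 2.3–2.6, ~1.1, ~0.3 ns), folded forms four-term models adding the
  dominant ~0.03 ns quenched component.  The control strand uses
  lifetimes 1.88/0.80/0.20 ns with an amplitude split (20/30/50%) chosen
  so its amplitude-weighted mean lifetime sits at the ~0.72 ns plateau a
  control shows across the pH range.
- **Wavelength factors** — default all ones, matching an acquisition
  that stops every trace at the same peak count; the factors exist so
  intensity variation across the emission band can be simulated.
- **Background** — zero by default; the generator is deliberately
  minimal (no pile-up, afterpulsing, dead time or anisotropy effects).

What passing tests on these data do *not* show: real decays carry
instrument artefacts (IRF drift, afterpulsing, background), the true
concentration profiles are unknown, and real conformer decay laws need
not be exact finite sums of exponentials.  The simulations validate the
statistical machinery at matched counting statistics, not the chemistry.

## Global reconvolution fitting

The discrete forward model convolves the unit-sum (optionally
fractionally shifted, linear-interpolation) IRF histogram with the decay
law sampled at bin offsets.  Lifetimes below bin_width/100 are rejected
as ill-conditioned.

- **Weights** — Poisson (Neyman) weights 1/√max(counts, 1); the unit
  floor guards empty channels.  These weights are biased upward for
  channels under ~50 counts (≈ +5% on the pooled reduced χ² at the
  default window), which is visible but small at the simulated counting
  depth.
- **Fitting window** — from the first channel where the IRF exceeds
  10⁻⁴ of its peak to the last channel with ≥ 10 counts (configurable);
  this avoids giving weight to essentially empty tail channels.
- **Optimisation** — lifetimes on a log scale (positivity), per-trace
  amplitudes solved exactly by non-negative least squares inside every
  objective evaluation (variable projection), IRF shift bounded at ±2
  bins.  The fit is staged: lifetimes first with the shift pinned at 0,
  then all parameters from that optimum — the shift direction is nearly
  degenerate early on and otherwise attracts local minima.  Three
  geometric-jitter restarts run if the first start fails to converge.
- **Degrees of freedom** — total fitted channels minus (shared lifetimes
  + shift + all per-trace amplitudes).
- **Standard errors** — Gauss–Newton covariance from the full-parameter
  finite-difference Jacobian at the optimum, scaled by reduced χ².
  A condition number above 10⁸ triggers an over-parameterisation
  warning; fitted neighbour lifetimes closer than ratio 1.2 set an
  `overparameterized` flag.
- **Model order** — smallest term count with reduced χ² < 1.1 and at
  most 10% of residual-autocorrelation lags outside ±2/√N; all per-order
  diagnostics are returned so the choice is auditable.

## Matrix construction and PCA

Rows are sorted by pH, then wavelength, then sequence id, making the
matrix independent of input order.  Autoscaling uses the sample standard
deviation (ddof = 1) by default with a switch for the population
convention; zero-variance columns are centred only and flagged, and the
stored parameters invert the transform exactly.  PCA is computed by SVD
of the autoscaled matrix; component signs follow the
largest-|loading|-positive convention; explained variance is relative to
the total sum of squares.  The suggested component count is the smallest
reaching 95% cumulative variance — a default, not a rule; the
cumulative-variance table is always available.  Local models re-autoscale
the row subset on its own statistics.  MCR, by contrast, operates on raw
counts: non-negativity constraints are meaningless after autoscaling.

## EFA and MCR-ALS

EFA computes singular values of submatrices growing from the acidic end
(forward) and the neutral end (backward).  Because the wavelength
replicates within one pH share a composition, windows are computed per
pH block and replicated across the block's rows.  The initial
concentration estimate for component j is the classical sequential
construction min(forward_j, backward_{p−j+1}), with singular values
below 3× the median trailing (noise) singular value treated as absent.
The factor 3 sits just above the Poisson noise plateau: in the
three-species preset the weakest component's singular value is only
~3.5× the noise level (the two folded conformers' decay laws are nearly
collinear), so a much larger factor would erase a real window.  If
flooring empties a window entirely, the unfloored profile is kept.

ALS alternates exact non-negative least squares for Sᵀ (given C) and C
(given Sᵀ), renormalising each pure trace to unit maximum every cycle
(the scale moves into C, fixing the intensity ambiguity).  The objective
is non-increasing by construction.  Convergence is |ΔLOF| < 10⁻⁴
percentage points or 500 iterations; the tolerance is deliberately tight
because with nearly collinear factors the per-iteration LOF change
becomes tiny long before the factors stop rotating — a loose threshold
freezes them mid-rotation.  Empty components are dropped with a warning.
Components are reported ordered by the pH of their maximal mean
concentration, most acidic first.

**Known limitation** — with overlapping concentration windows and
strictly positive pure traces, the rotational ambiguity between the two
folded conformers of the short-sequence preset is only weakly
constrained: their recovered pure traces typically match the generators
at r ≈ 0.98–1.00 (the weaker conformer around 0.984), while the open
form and the well-separated two-species case recover at r > 0.997.
Lack of fit and reconstruction quality are reliable throughout;
factor uniqueness is not guaranteed on overlapping designs.

## Tail fitting

The resolved pure traces are trimmed past their maximum (peak channel
plus a 2-bin offset by default) and fitted, without any IRF, with
n = 1…4 exponential terms by nonlinear least squares (lifetimes on a log
scale, log-spaced starts).  The selected order is the smallest with
R² > 0.999, every lifetime passing a two-sided t-test (α = 0.05,
dof = points − parameters), and a well-formed term set (no neighbour
lifetime ratio below 1.2, no term under 0.1% of the amplitude — the
minimum-terms rule made operational).  If nothing qualifies, the best
well-formed fit is returned flagged unsatisfied.  Ignoring the IRF
biases sub-100 ps components toward longer apparent lifetimes; the bias
is inherent to the procedure and left uncorrected deliberately.

## Problem sizes used by the test suite and acceptance script

Simulations run at the acquisition geometry above (500 bins, 3×10⁴ peak
counts).  Recovery statistics use 20 repeated simulations for the
four-term global fit and 10 for model-order selection, MCR factor
matching and noisy tail fits; these sizes give stable medians and rates
while keeping a full run in tens of seconds.
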