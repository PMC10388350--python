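# Methods

`photonhmm` analyses diffusion-based single-molecule FRET experiments in
which individual protein complexes — here a GroEL/SR1 chaperonin ring
carrying one donor/acceptor-labeled subunit — drift through a confocal spot
and emit short bursts of photons.  The conformational state of the labeled
subunit modulates the FRET efficiency and therefore the color statistics of
the photons; because the states exchange on the submillisecond timescale,
comparable to the ~1 ms transit itself, burst-averaged FRET histograms blur
the states together and the analysis must operate photon by photon.

## The model

A continuous-time Markov chain over K conformational microstates with
generator Q (s^-1; rows sum to zero) underlies each burst.  Detected
donor-excitation photons arrive as a Poisson process whose rate does not
depend on the state; the photon detected at time t is acceptor-colored with
probability E_i, the FRET efficiency of the state occupied at t.  The
likelihood of a burst with colors c_1..c_N and inter-photon gaps tau_t is

    L = p0 diag(b_1) prod_{t=2..N} [ exp(Q tau_t) diag(b_t) ] 1,

where b_t(i) = E_i or 1-E_i according to the color and p0 is the state
distribution at the first photon.  Because the photon arrival times carry no
state information under the state-independent-rate assumption, they enter
only through the propagators exp(Q tau_t).  Acceptor-excitation (PIE)
photons are excluded from the likelihood; they serve stoichiometry only.

### Fitting

Parameters (Q per dataset, shared E across datasets in the global mode, p0
per dataset) are estimated by EM:

* E step — scaled forward/backward recursions over each burst give the
  log-likelihood, per-photon posteriors, and, per inter-photon gap, the
  endpoint-conditioned expectations of the hidden chain's sufficient
  statistics: occupation times R_i and jump counts N_ij.  Both come from a
  single eigendecomposition Q = U diag(q) U^-1 per iteration: the gap
  integrals reduce to J_pq(tau) = (e^{q_p tau} - e^{q_q tau})/(q_p - q_q),
  with the limit tau e^{q_p tau} taken whenever |q_p - q_q| tau < 1e-4
  (which is also the numerically stable branch).  All per-photon work
  factorises into three (n_photons x K) -> (K x K) matrix products plus a
  compiled forward/backward kernel, so an iteration over 5 x 10^5 photons
  takes ~0.3 s on one core.
* M step — closed form: k_ij = N_ij / R_i, E_i = (posterior-weighted
  acceptor photons)/(posterior-weighted photons), p0 = mean first-photon
  posterior.  This is exact EM, so the log-likelihood never decreases; the
  trace is exposed on every results object and asserted in the tests.

Numerical choices: off-diagonal rates are floored at 1e-4 s^-1 (EM can
drive unused transitions to exactly zero, which would freeze them);
efficiencies are kept in [1e-6, 1-1e-6]; a nearly defective Q (eigenbasis
condition number > 1e8) receives a deterministic relative jitter of 1e-7 on
its rates before decomposition.  States are reported sorted by descending
efficiency, the field's labeling convention.

Initialisation places the K efficiencies on a uniform grid between the 5th
and 95th percentiles of the burst proximity-ratio distribution and all
exchange rates at 1000 s^-1.  Restarts jitter the efficiencies by ±0.06 and
the rates by a log-normal factor (sigma = 0.5).  Each restart runs a short
exploratory phase (default 20-25 iterations); the best log-likelihood is
then polished to convergence (default |Delta loglik|/photon < 1e-8, at most
200 iterations).  Ties go to the candidate that needed fewer iterations.
Model-size selection is deliberately manual: `k_scan` reports
log-likelihood and BIC for K = 2..5 and leaves the choice to the user.

Timestamps are integers in sync-clock ticks (12.5 ns default, 80 MHz);
gaps are converted to seconds inside the likelihood.  The tick transition
matrix exp(Q * clock_period) and the logm-based inverse are available for
interoperability, but Q in s^-1 is the native parameter.

## Synthetic data generator

The generator is first-class, tested code: it produces the study conditions
under which every recovery claim is evaluated.

* Four condition fixtures (apo, ATP, ADP, ATP+GroES) share the microstate
  efficiencies (0.850, 0.608, 0.419, 0.213) and differ in their stationary
  populations pi.  Rates are constructed as k_ij = c pi_j with
  c = 3000 s^-1, which makes pi the exact stationary distribution, is
  reversible, and gives a single relaxation time 1/c ~ 333 us — inside the
  observed 300-500 us exchange window.  The apo populations print as
  8.4/55.1/29.6/7.0 %, which sum to 100.1 %; they are stored normalised to
  sum to one (a relative change < 1e-3).  Populations not individually
  printed are completed by the remainder: ATP state 1 = 0.048; ADP states
  1 and 4 split 0.17 equally; ATP+GroES states 1 and 2 split 0.094 equally.
* Per burst: duration ~ Exp(1 ms); donor-excitation photons Poisson at
  100 kHz, colored by the state occupied at their arrival (hidden path by
  exact Gillespie simulation, initial state stationary); acceptor-excitation
  photons Poisson at 100 kHz, all acceptor-colored; optional per-channel
  uniform background (default 0 for recovery runs, 1 kHz for robustness
  checks).  Bursts are separated by at least 10x the mean duration.  Photon
  times are rounded to clock ticks and forced strictly increasing (minimum
  1-tick steps).
* The titration generator draws each burst from the ATP fixture with
  probability Y(c) = c^n/(K^n + c^n) (n = 2.9, K = 1.7 uM — the generating
  parameters of the saturation curve) and from the apo fixture otherwise,
  storing per-burst labels as ground truth.

What the generator does **not** emulate: diffusion through a 3-D Gaussian
excitation profile (intensity is constant during a burst), dye photophysics
(blinking, bleaching), detector dead time and afterpulsing, donor leakage
and direct acceptor excitation (corrections default to l = d = 0, gamma = 1,
so analyses run in the proximity-ratio domain).  Passing recovery tests
therefore demonstrate correctness of the inference machinery under the
model's own assumptions, not robustness to every instrumental artifact of
real data.

## Validation procedures

* **Recoloring** keeps every measured arrival time, samples a fresh hidden
  path from the fitted model (p0 at the first photon, exp(Q tau) between
  photons) and redraws colors.  Burst-E histograms of recolored vs measured
  data are compared by eye in figures and by a Poisson chi-square in tests.
* **Dwell times** are computed from a posterior path sample
  (forward-filter backward-sample) rather than the Viterbi path: marginally
  over data generated by the model, sampled paths follow the chain's own
  law, whereas the Viterbi path systematically merges fast excursions when
  neighbouring states overlap in efficiency (at fixture scale this inflates
  apparent dwells by 50-130 %).  Segment boundaries sit at inter-photon gap
  midpoints.  The monoexponential mean is the right-censoring-aware maximum
  likelihood estimate tau_i = (time in state) / (observed exits): segments
  touching a burst edge contribute exposure but no exit event, the standard
  survival treatment, without which burst-length selection biases tau.
  Segments also carry their mean posterior probability as a likelihood
  weight for the returned dwell histograms.  At fixture scale this
  estimator agrees with 1/(-Q_ii) to within ~8 %.
* **Segmentation histograms** select bursts whose Viterbi path occupies a
  single state and histogram their burst E per state.  At fixture-scale
  exchange (3000 s^-1) such bursts are rare and somewhat impure, so the
  group means separate in state order but sit within ~0.05 of E_i; at
  slower exchange (~400 s^-1) they match E_i within 0.03 (the conditional
  binomial mean), and the tests check exactly these two regimes.
* **Burst-wise correlation** counts photon pairs inside each burst over a
  logarithmic lag grid (8 points/decade, 10 us - 10 ms) and divides by the
  pair count expected for a rate-matched Poisson burst.  The burst's first
  and last photons define its span and are excluded from counting —
  conditioned on the span the interior photons of a Poisson burst are
  exactly iid uniform, making the estimator unbiased at all lags.  Lag bins
  sampled by fewer than 500 expected pairs or covered by fewer than 25
  bursts are dropped (a single long burst would otherwise dominate), and
  the curve is normalised to 1 at the largest surviving lag.  For two-state
  exchange the autocorrelations rise toward short lags and the
  donor-acceptor cross-correlation dips, both with relaxation time
  1/k_total.

## Macrostate thermodynamics

Stationary populations come from the left null space of the fitted Q
(equivalently its diagonalization).  Equilibrium constants along the
microstate ladder are rate ratios K(i->i+1) = k_{i,i+1}/k_{i+1,i}; for a
reversible chain these equal pi_{i+1}/pi_i, and that identity is reported
as a diagnostic rather than enforced, since fitted matrices need not obey
detailed balance.  The apo (T) and ATP (R) macrostates close a
thermodynamic cycle: vertical T->R constants relative to microstate 1 are
alpha_i/alpha_1 = prod_{j<i} K_R(j)/K_T(j), and free-energy differences are
-R_gas T ln(alpha_i/alpha_j) with R_gas = 1.9872e-3 kcal/(mol K) and
T = 295.15 K (~22 C) by default.  The cycle is invariant under a common
rescaling of all rates.

## Titration analysis

Each burst receives the posterior score L_ATP/(L_apo + L_ATP) with equal
priors, computed from whole-burst likelihoods under the two macrostate
models (which share efficiencies by construction of the global fit).  Mean
scores per concentration are linearly calibrated so the 0-concentration
endpoint maps to 0 and the saturating endpoint to 1; under the two-state
mixture model the scaled mean is then an unbiased estimator of the
ATP-macrostate burst fraction regardless of how weak single-burst
discrimination is (at 1 ms transits individual bursts classify correctly
only ~65-70 % of the time; bursts longer than ~800 photons exceed 90 %).
Standard errors come from a 1000-resample burst-level bootstrap.  The Hill
fit Y(c) = Y0 + A c^n/(K^n + c^n) uses inverse-variance weights (errors
floored at 1e-4 of the response range), multistart over n in {1, 2, 3, 4},
and reports the covariance from weighted least squares.

## Design calculations

For reassembly at labeled:unlabeled ratio 1:N over n-subunit rings, the
number of labeled subunits per complex is Binomial(n, 1/(N+1)); the
fraction of labeled complexes with exactly one label, P(X=1)/P(X>=1), is
0.9704 for 1:100 and n = 7.  The Foerster relation E = 1/(1+(R/R0)^6) and
its inverse convert between distances and efficiencies; note that
ensemble-averaged (R, E) pairs from dye-cloud simulations are not
reproducible from the point relation with a single R0 (mean-of-E vs
E-of-mean), so such pairs are treated as qualitative references only.

## Simulation scales

Recovery runs use scales at which parameter standard errors sit well below
the documented tolerances while keeping the full suite fast on one core:
efficiency recovery fits 1,500-2,500 bursts per condition (the efficiency
SEs are ~0.005, tolerance 0.02); stationary-population fits use
8,000 bursts (population SEs ~1 percentage point, tolerance 3 points); the
titration uses 9,000-12,000 bursts at each of nine concentrations between
0 and 10 uM.  The titration scale is set by the weak per-burst
discrimination of the two macrostates at 1 ms transits: the mean score
span between the pure conditions is only ~0.17, so per-point noise is
amplified ~6x by the endpoint calibration, and a Monte-Carlo calibration
of the full estimator chain gives a Hill-coefficient standard deviation of
~0.13 at 8,000 bursts per point (unbiased), scaling as the inverse square
root of the burst count.
The acceptance script accepts `--n-bursts-*` flags to rerun any stage at
other scales.

## Known limitations

* Background photons are not part of the emission model; recovery runs use
  background-free data, and ~1 kHz backgrounds mildly bias the lowest- and
  highest-efficiency states toward the center.
* The likelihood assumes state-independent detection rates; true
  brightness differences between conformations (e.g. acceptor quantum-yield
  changes) would bias populations.
* p0 is a free per-dataset parameter rather than tied to the stationary
  distribution; for equilibrium data the two coincide asymptotically.
* Viterbi-based segmentation under fast exchange under-reports transitions;
  use the posterior-sampling dwell machinery for kinetics.
* The Hill analysis treats the macrostate mixture as two-state; nested or
  multi-ring cooperativity models are out of scope.
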