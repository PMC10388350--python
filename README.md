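# photonhmm

Photon-by-photon hidden Markov analysis of single-molecule FRET bursts,
built around the conformational dynamics of the chaperonin GroEL: a single
donor/acceptor-labeled subunit inside an SR1 ring samples four
conformational microstates that exchange on the submillisecond timescale —
faster than the ~1 ms diffusion transit through the confocal spot — so
burst-averaged FRET histograms blur the states together and the analysis
must use the arrival time and color of every photon.

The package provides, end to end:

* **Photon data** — photon streams (Photon-HDF5-style HDF5 or columnar
  text), all-photon sliding-window burst search, per-burst FRET efficiency
  E and PIE stoichiometry S, histograms.
* **Synthetic data** — a tested generator producing bursts whose hidden
  continuous-time Markov chain, photon statistics and condition fixtures
  (apo, ATP, ADP, ATP+GroES; shared efficiencies 0.850/0.608/0.419/0.213)
  emulate the experiment, plus a concentration-dependent two-macrostate
  titration generator.
* **Inference** — maximum-likelihood multi-state fitting of photon streams
  (`PhotonHMM`, statsmodels-style: model object, `.fit()`, results object
  with `.summary()`), including global fits of several conditions with
  shared FRET efficiencies (`GlobalPhotonHMM`), exact EM with monotone
  log-likelihood, Viterbi decoding, per-burst likelihoods.
* **Validation** — photon recoloring, posterior-sampled likelihood-weighted
  dwell-time analysis, single-state-burst segmentation histograms, and
  burst-wise fluorescence correlation.
* **Kinetics & thermodynamics** — stationary populations by diagonalizing
  fitted rate matrices, inter-microstate equilibrium constants, and the
  closed apo/ATP (T/R) thermodynamic cycle with free-energy differences.
* **Titration** — per-burst macrostate likelihood scoring, endpoint-
  calibrated saturation curves, Hill fits (cooperativity n_H and apparent
  binding constant K_app).
* **Design** — reassembly labeling statistics (fraction of single-labeled
  complexes) and the Foerster distance/efficiency relation.

The model in brief: a hidden chain with generator Q (s^-1) over K states;
each detected donor-excitation photon is acceptor-colored with the occupied
state's efficiency E_i; the burst likelihood is
`p0 diag(b_1) prod_t [exp(Q tau_t) diag(b_t)] 1` over inter-photon gaps
tau_t.  EM uses the exact endpoint-conditioned sufficient statistics of the
chain, so rates come out directly in s^-1.  See `docs/methods.md` for the
full account.

## Worked example

Simulate an apo-like dataset and fit a 4-state model:

```python
import numpy as np
from photonhmm import simulate, PhotonHMM, PhotonRecords

model = simulate.make_macrostate_fixture("apo")   # ground truth
stream, bursts, truth = simulate.simulate_dataset(model, 1000, seed=12)
records = PhotonRecords.from_stream(stream, bursts)
result = PhotonHMM(records, k_states=4).fit(restarts=4, seed=0, tol=1e-7)
print(result.summary())
```

```
Photon-by-photon HMM fit
============================================================
states: 4   bursts: 953   photons: 100106
log-likelihood: -66679.72   iterations: 107   converged: True

state        E       pi       p0   tau_ms
    1    0.851    0.093    0.089    0.349
    2    0.610    0.557    0.534    0.663
    3    0.417    0.269    0.322    0.445
    4    0.225    0.081    0.055    0.405

rate matrix (s^-1):
     -2865.2     1680.5     1112.5       72.1
       318.9    -1509.1      880.3      310.0
       306.7     1863.2    -2246.3       76.4
        91.3     2241.1      136.0    -2468.3
```

The fitted efficiencies (column `E`) recover the generating values
(0.850, 0.608, 0.419, 0.213) to within ~0.01 at this data size, and the
stationary populations `pi` (from diagonalizing the fitted rate matrix)
recover the apo fingerprint (8.4 / 55.1 / 29.6 / 7.0 %) to within ~3
percentage points; `tau_ms` is each state's mean dwell time, in the
300-700 us range that makes the exchange submillisecond.  Validation
(recoloring, dwell times, segmentation, correlation) hangs off the same
results object, e.g. `result.dwell_times().to_frame()`.

The command line mirrors the library:

```bash
photonhmm simulate --fixture apo --n-bursts 5000 --seed 1 --out apo.h5
photonhmm fit --in apo.h5 --k 4 --restarts 8 --out apo_model.json
photonhmm thermo --model-apo apo_model.json --model-atp atp_model.json --out cycle.csv
photonhmm design single-label --ratio 1:100 --subunits 7
photonhmm run-suite --seed 1 --out report/
```

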