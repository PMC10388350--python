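"""Likelihood-based macrostate assignment and ligand-titration analysis.

Each burst is scored against two fitted macrostate models (apo vs ATP) that
share emission efficiencies; the posterior score with equal priors,
L_atp / (L_apo + L_atp), estimates the probability the molecule was in the
ATP macrostate during its transit.  Mean scores per ligand concentration,
linearly calibrated between the 0-concentration and saturating endpoints,
give an unbiased estimate of the ATP-macrostate burst fraction, which is
fitted with the Hill equation Y(c) = Y0 + A c^n / (K^n + c^n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .hmm import H2MMModel, PhotonRecords, burst_logliks

__all__ = [
    "macrostate_score",
    "saturation_curve",
    "hill_fit",
    "HillFit",
    "SaturationPoint",
]


def macrostate_score(records: PhotonRecords, model_apo: H2MMModel,
                     model_atp: H2MMModel) -> np.ndarray:
    """Per-burst posterior score of the ATP macrostate (equal priors).

    score = L_atp / (L_apo + L_atp), computed in the log domain
    (log-sum-exp stabilised).  Bursts for which both likelihoods vanish are
    returned as NaN and should be excluded downstream.
    """
    ll_apo = burst_logliks(model_apo, records)
    ll_atp = burst_logliks(model_atp, records)
    both_dead = ~np.isfinite(ll_apo) & ~np.isfinite(ll_atp)
    d = np.clip(ll_apo - ll_atp, -700, 700)
    score = 1.0 / (1.0 + np.exp(d))
    score[both_dead] = np.nan
    return score


@dataclass
class SaturationPoint:
    concentration: float  # uM
    score: float  # mean scaled score
    se: float  # bootstrap standard error
    n_bursts: int


def saturation_curve(datasets: dict, model_apo: H2MMModel, model_atp: H2MMModel,
                     n_boot: int = 1000, seed=0,
                     calibration: tuple | None = None) -> list[SaturationPoint]:
    """Endpoint-calibrated saturation curve over ligand concentrations.

    ``datasets`` maps concentration (uM) to PhotonRecords (or to a
    precomputed per-burst score array).  Raw per-concentration mean scores
    are scaled linearly so the 0-concentration endpoint maps to 0 and the
    highest-concentration (saturating) endpoint to 1; under the two-state
    mixture model the scaled mean is then an unbiased estimator of the
    ATP-macrostate burst fraction.  Standard errors come from a burst-level
    bootstrap.  Without both endpoints, explicit ``calibration`` = (raw mean
    at 0, raw mean at saturation) must be supplied.
    """
    concs = sorted(datasets)
    scores = {}
    for c in concs:
        v = datasets[c]
        s = v if isinstance(v, np.ndarray) else macrostate_score(v, model_apo, model_atp)
        s = s[np.isfinite(s)]
        if s.size == 0:
            raise ValueError(f"no scorable bursts at concentration {c}")
        scores[c] = s
    if calibration is None:
        if 0.0 not in scores or len(concs) < 2:
            raise ValueError(
                "calibration endpoints missing: need a 0-concentration and a "
                "saturating dataset, or pass calibration=(m0, m_sat) explicitly")
        m0 = float(scores[0.0].mean())
        m1 = float(scores[concs[-1]].mean())
    else:
        m0, m1 = calibration
    span = m1 - m0
    if span <= 0:
        raise ValueError("calibration endpoints do not separate the macrostates")
    rng = np.random.default_rng(seed)
    points = []
    for c in concs:
        s = scores[c]
        mean = (s.mean() - m0) / span
        idx = rng.integers(0, s.size, size=(n_boot, s.size))
        boot = s[idx].mean(axis=1) / span
        points.append(SaturationPoint(float(c), float(mean), float(boot.std(ddof=1)),
                                      int(s.size)))
    return points


@dataclass
class HillFit:
    """Fitted Hill saturation curve."""

    n_hill: float
    k_app: float  # uM
    amplitude: float
    baseline: float
    cov: np.ndarray  # parameter covariance, order (n, K, A, Y0)
    residuals: np.ndarray
    concentrations: np.ndarray
    warnings: list

    @property
    def n_hill_se(self) -> float:
        return float(np.sqrt(self.cov[0, 0]))

    @property
    def k_app_se(self) -> float:
        return float(np.sqrt(self.cov[1, 1]))

    def predict(self, conc) -> np.ndarray:
        return _hill(np.asarray(conc, float), self.n_hill, self.k_app,
                     self.amplitude, self.baseline)

    def summary(self) -> str:
        lines = [
            "Hill fit: Y(c) = Y0 + A c^n / (K^n + c^n)",
            f"  n_H   = {self.n_hill:.3f} +/- {self.n_hill_se:.3f}",
            f"  K_app = {self.k_app:.3f} +/- {self.k_app_se:.3f} uM",
            f"  A     = {self.amplitude:.3f}   Y0 = {self.baseline:.3f}",
        ]
        lines += [f"  warning: {w}" for w in self.warnings]
        return "\n".join(lines)


def _hill(c, n, K, A, Y0):
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        y = np.where(c > 0, 1.0 / (1.0 + (K / np.maximum(c, 1e-300)) ** n), 0.0)
    return Y0 + A * y


def hill_fit(points) -> HillFit:
    """Weighted least-squares Hill fit with multistart over n in {1, 2, 3, 4}.

    ``points`` is a list of SaturationPoint or a DataFrame with columns
    conc_uM, score, se.  Weights are inverse bootstrap variances (se floored
    at 1e-4 of the response range to avoid infinite weight on noiseless
    endpoints).
    """
    if isinstance(points, pd.DataFrame):
        conc = points["conc_uM"].to_numpy(float)
        y = points["score"].to_numpy(float)
        se = points["se"].to_numpy(float) if "se" in points else np.ones_like(y)
    else:
        conc = np.array([p.concentration for p in points], float)
        y = np.array([p.score for p in points], float)
        se = np.array([p.se for p in points], float)
    if conc.size < 4:
        raise ValueError("need >= 4 concentrations for a Hill fit")
    warnings_ = []
    span = y.max() - y.min()
    se = np.maximum(se, 1e-4 * max(span, 1e-12))
    pos = conc[conc > 0]
    K0 = np.sqrt(pos.min() * pos.max())
    best = None
    for n0 in (1.0, 2.0, 3.0, 4.0):
        try:
            popt, pcov = curve_fit(
                _hill, conc, y, p0=[n0, K0, max(span, 0.1), float(y.min())],
                sigma=se, absolute_sigma=False, maxfev=20000,
                bounds=([0.05, 1e-6, 1e-6, -0.5], [20.0, 1e6, 2.0, 0.5]),
            )
        except RuntimeError:
            continue
        r = (y - _hill(conc, *popt)) / se
        chi2 = float(np.sum(r * r))
        if best is None or chi2 < best[0]:
            best = (chi2, popt, pcov)
    if best is None:
        raise RuntimeError("Hill fit failed for all starting values")
    _, popt, pcov = best
    n_H, K_app = popt[0], popt[1]
    if not (pos.min() < K_app < pos.max()):
        warnings_.append(
            "fitted K_app lies outside the sampled concentration range; "
            "confidence intervals are unreliable")
    resid = y - _hill(conc, *popt)
    return HillFit(float(n_H), float(K_app), float(popt[2]), float(popt[3]),
                   pcov, resid, conc, warnings_)


def saturation_table(points: list[SaturationPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "conc_uM": [p.concentration for p in points],
            "score": [p.score for p in points],
            "se": [p.se for p in points],
            "n_bursts": [p.n_bursts for p in points],
        }
    )
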