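"""Estimation of the OU correlation-decay parameter and cross-correlation.

The autocorrelation of the standardized scan track is assumed to decay as
``exp(-theta * d)`` with genetic distance ``d`` in Morgans.  ``theta`` is
estimated by regressing log autocovariances on lag through the origin:
autocovariances are taken at lags ``step, 2*step, ...`` up to 4 cM, within
chromosomes only and skipping any pair that touches a masked position, and
the no-intercept OLS slope of ``log(acov)`` on lag (Morgans) gives
``-theta``.  The regression requires a variance-1 standardized track — on
any other scale the no-intercept log-linear model is misspecified.

Typical values in large human cohorts run from ~25 (founder populations,
long-range sharing) to ~70 (outbred cohorts, faster decay).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np


class EstimationError(ValueError):
    pass


@dataclass
class OuModel:
    """Fitted OU decay parameters for a scan track."""

    theta: float                 # per Morgan, for the test (difference) track
    step_cm: float
    lags_used: list              # (lag_cm, autocovariance) pairs entering the fit
    rho: Optional[float] = None  # case/control same-position cross-correlation
    theta_case: Optional[float] = None
    theta_control: Optional[float] = None

    def to_dict(self) -> dict:
        out = {"theta": self.theta, "step_cm": self.step_cm,
               "lags_used": [[float(l), float(a)] for l, a in self.lags_used]}
        for key in ("rho", "theta_case", "theta_control"):
            if getattr(self, key) is not None:
                out[key] = getattr(self, key)
        return out


def autocovariances_arrays(values_by_chrom, step_cm: float,
                           max_lag_cm: float = 4.0, masks_by_chrom=None):
    """Autocovariances of a standardized track at integer multiples of the step.

    ``values_by_chrom`` is a sequence of per-chromosome arrays; pairs never
    straddle chromosomes.  The mean-zero product form ``mean(z_m * z_{m+k})``
    is used (the track is already centred).  Lags with no valid pair are
    omitted.  Returns a list of ``(lag_cm, acov)`` pairs.
    """
    if step_cm <= 0:
        raise EstimationError("step_cm must be positive")
    n_lags = int(np.floor(max_lag_cm / step_cm + 1e-9))
    if n_lags < 1:
        raise EstimationError("max_lag_cm must cover at least one step")
    if masks_by_chrom is None:
        masks_by_chrom = [None] * len(values_by_chrom)
    sums = np.zeros(n_lags + 1)
    counts = np.zeros(n_lags + 1, dtype=np.int64)
    for z, excluded in zip(values_by_chrom, masks_by_chrom):
        z = np.asarray(z, dtype=float)
        ok = np.ones(len(z), dtype=bool) if excluded is None else ~np.asarray(excluded)
        for k in range(1, min(n_lags, len(z) - 1) + 1):
            valid = ok[:-k] & ok[k:]
            if valid.any():
                sums[k] += float((z[:-k] * z[k:])[valid].sum())
                counts[k] += int(valid.sum())
    out = [(k * step_cm, sums[k] / counts[k])
           for k in range(1, n_lags + 1) if counts[k] > 0]
    if not out:
        raise EstimationError("no valid position pairs at any lag")
    return out


def autocovariances(track, max_lag_cm: float = 4.0):
    """Autocovariances of a scan track's test statistic, masked positions skipped."""
    return autocovariances_arrays(
        track.per_chrom(), track.grid.step_cm, max_lag_cm,
        masks_by_chrom=track.per_chrom(track.excluded))


def estimate_theta(acovs) -> float:
    """No-intercept log-linear fit of autocovariance decay.

    ``acovs`` is a sequence of ``(lag_cm, acov)`` pairs.  Non-positive
    autocovariances are dropped before taking logs (the log-linear model has
    no image for them).  The OLS-through-origin slope of ``log(acov)`` on
    lag in Morgans is ``-theta``.
    """
    acovs = list(acovs)
    lags_m = np.array([l for l, _ in acovs], dtype=float) / 100.0
    vals = np.array([a for _, a in acovs], dtype=float)
    pos = vals > 0
    if not pos.any():
        raise EstimationError("all autocovariances are non-positive")
    x, y = lags_m[pos], np.log(vals[pos])
    theta = -float(x @ y) / float(x @ x)
    if theta <= 0:
        raise EstimationError(
            f"estimated decay parameter is non-positive ({theta:.3g}); "
            "autocovariances do not decay"
        )
    return theta


def estimate_rho(track) -> float:
    """Sample correlation of the standardized case and control tracks."""
    if track.z_case is None or track.z_control is None:
        raise EstimationError("cross-correlation needs a two-sample track")
    ok = ~track.excluded
    if ok.sum() < 3:
        raise EstimationError("need at least 3 non-excluded positions")
    return float(np.corrcoef(track.z_case[ok], track.z_control[ok])[0, 1])


def fit_ou_model(track, max_lag_cm: float = 4.0) -> OuModel:
    """Fit theta (and, for two-sample tracks, rho and per-group thetas)."""
    lags = autocovariances(track, max_lag_cm=max_lag_cm)
    theta = estimate_theta(lags)
    rho = theta1 = theta0 = None
    if track.two_sample:
        rho = estimate_rho(track)
        masks = track.per_chrom(track.excluded)
        step = track.grid.step_cm
        try:
            theta1 = estimate_theta(autocovariances_arrays(
                track.per_chrom(track.z_case), step, max_lag_cm, masks))
            theta0 = estimate_theta(autocovariances_arrays(
                track.per_chrom(track.z_control), step, max_lag_cm, masks))
        except EstimationError:
            pass  # per-group decay is diagnostic only; the test track drives thresholds
    return OuModel(theta=theta, step_cm=track.grid.step_cm, lags_used=lags,
                   rho=rho, theta_case=theta1, theta_control=theta0)
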