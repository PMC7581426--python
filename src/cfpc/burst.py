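"""Burst-size calibration and spike-count inference.

Climbing fibers fire brief 400 Hz bursts of 1-9 spikes; the evoked axonal calcium
transient grows with the number of spikes and saturates around seven. This module
models that transfer with a two-parameter saturating exponential

    a(n) = a_max * (1 - exp(-n / kappa)),

fits it to (spike count, amplitude) calibration points, and inverts measured
first-peak amplitude distributions into discrete spike-count estimates, either by
nearest-calibration-point assignment or by a one-dimensional Gaussian mixture on
median-normalized amplitudes (amplitude clusters <-> burst sizes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "CalibrationCurve",
    "forward_amplitude",
    "fit_calibration",
    "infer_spike_counts",
    "SpikeCountPosterior",
]


@dataclass
class CalibrationCurve:
    """Fitted saturating spike-count -> amplitude transfer.

    Attributes
    ----------
    a_max : float
        Asymptotic amplitude (SD units), > 0.
    kappa : float
        Saturation constant in spikes; at the default kappa = 2,
        a(7) ~ 0.97 a_max, i.e. seven spikes effectively saturate the response.
    fit_rss : float
        Residual sum of squares of the fit (0 for a curve set by hand).
    n_points : int
        Number of calibration points used.
    """

    a_max: float
    kappa: float
    fit_rss: float = 0.0
    n_points: int = 0

    def __post_init__(self) -> None:
        if not (self.a_max > 0 and self.kappa > 0):
            raise ValueError("a_max and kappa must be > 0")

    def __call__(self, n) -> np.ndarray:
        return forward_amplitude(n, self)

    def summary(self) -> str:
        return (
            "Saturating calibration a(n) = a_max (1 - exp(-n/kappa))\n"
            f"  a_max = {self.a_max:.4f} SD\n"
            f"  kappa = {self.kappa:.4f} spikes\n"
            f"  a(7)/a_max = {1 - np.exp(-7 / self.kappa):.4f}\n"
            f"  rss = {self.fit_rss:.4g} over n_points = {self.n_points}"
        )


def forward_amplitude(n, cc: CalibrationCurve) -> np.ndarray:
    """Predicted transient amplitude (SD units) for burst spike count ``n``.

    ``a(0) = 0``; strictly increasing in ``n`` and bounded by ``a_max``.
    """
    n_arr = np.asarray(n)
    if np.any(n_arr < 0):
        raise ValueError("spike count must be >= 0")
    out = cc.a_max * (1.0 - np.exp(-np.asarray(n_arr, dtype=float) / cc.kappa))
    if np.isscalar(n) or n_arr.ndim == 0:
        return float(out)
    return out


def fit_calibration(points) -> CalibrationCurve:
    """Least-squares fit of (a_max, kappa) to (spike count, amplitude) pairs.

    A deterministic coarse grid over (a_max, kappa) seeds a trust-region local
    refinement, so the result does not depend on a random initializer.

    Parameters
    ----------
    points : array-like of shape (m, 2) or pair of arrays
        Spike counts and measured amplitudes. At least 3 distinct counts needed.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 2 and pts.shape[1] == 2:
        n, a = pts[:, 0], pts[:, 1]
    else:
        n, a = np.asarray(points[0], float), np.asarray(points[1], float)
    if np.unique(n).size < 3:
        raise ValueError("fit_calibration needs >= 3 distinct spike counts")
    if np.any(n < 0):
        raise ValueError("spike counts must be >= 0")

    # warn (but proceed) when group means are non-monotone beyond noise
    order = np.argsort(n)
    uniq, idx = np.unique(n[order], return_index=True)
    means = np.array([a[n == u].mean() for u in uniq])
    resid_sd = np.std(a - np.interp(n, uniq, means)) + 1e-12
    if np.any(np.diff(means) < -2 * resid_sd):
        warnings.warn("calibration point means are non-monotone in spike count")

    amax_grid = np.max(a) * np.array([0.8, 1.0, 1.2, 1.6, 2.2, 3.0])
    kappa_grid = np.array([0.5, 1.0, 1.5, 2.0, 3.0, 5.0, 8.0])

    def resid(theta):
        am, ka = theta
        return am * (1.0 - np.exp(-n / ka)) - a

    best = None
    for am in amax_grid:
        for ka in kappa_grid:
            rss = float(np.sum(resid((am, ka)) ** 2))
            if best is None or rss < best[0]:
                best = (rss, am, ka)
    sol = least_squares(
        resid,
        x0=[best[1], best[2]],
        bounds=([1e-9, 1e-3], [np.inf, 1e3]),
        method="trf",
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    am, ka = sol.x
    return CalibrationCurve(
        a_max=float(am), kappa=float(ka), fit_rss=float(np.sum(sol.fun**2)), n_points=int(n.size)
    )


@dataclass
class SpikeCountPosterior:
    """Per-event spike-count responsibilities over candidate counts 1..n_max.

    ``responsibilities[i, k]`` is the posterior weight of count ``counts[k]`` for
    event ``i``; rows sum to one. ``assignments`` is the argmax (hard) estimate.
    """

    counts: np.ndarray
    responsibilities: np.ndarray
    assignments: np.ndarray
    mode: str
    n_components: int

    def summary(self) -> str:
        vals, freq = np.unique(self.assignments, return_counts=True)
        lines = [f"Spike-count inference ({self.mode} mode, {self.n_components} components)"]
        for v, f in zip(vals, freq):
            lines.append(f"  n={int(v)}: {int(f)} events")
        return "\n".join(lines)


def _gmm_1d(x: np.ndarray, n_max: int, random_state: int = 0):
    """Select a 1-D Gaussian mixture over 1..n_max components by corrected AIC."""
    from sklearn.mixture import GaussianMixture

    X = x[:, None]
    n = x.size
    best = None
    for k in range(1, n_max + 1):
        n_params = 3 * k - 1  # k means, k variances, k-1 weights
        if n - n_params - 1 <= 1:
            break
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=3,
            random_state=random_state,
            reg_covar=1e-6,
        )
        try:
            gm.fit(X)
        except Exception:
            continue
        if not gm.converged_:
            continue
        aic = gm.aic(X)
        # small-sample correction (AICc); ties resolved toward fewer components
        aicc = aic + 2.0 * n_params * (n_params + 1) / max(n - n_params - 1, 1)
        if best is None or aicc < best[0] - 1e-9:
            best = (aicc, k, gm)
    if best is None:
        raise RuntimeError("Gaussian mixture failed to converge for any component count")
    return best[1], best[2]


def infer_spike_counts(
    events: pd.DataFrame,
    n_max: int = 7,
    mode: str = "mixture",
    cc: CalibrationCurve | None = None,
    amplitude_noise_sd: float | None = None,
    random_state: int = 0,
) -> tuple[SpikeCountPosterior, pd.DataFrame]:
    """Invert first-peak amplitudes into discrete spike-count estimates.

    mixture mode
        Fits a 1-D Gaussian mixture to median-normalized first-peak amplitudes
        pooled across ROIs; the component count (1..n_max) is chosen by a
        small-sample-corrected information criterion; components sorted by mean
        are read as spike counts 1, 2, ... If the mixture fails and a calibration
        curve is supplied, falls back to calibration mode.
    calibration mode
        Assigns each amplitude to the nearest ``forward_amplitude(n, cc)`` for
        n = 1..n_max, with Gaussian responsibilities at ``amplitude_noise_sd``.

    Returns the posterior plus a copy of ``events`` with ``spike_count_est`` set
    on the first-peak rows that were inferred.
    """
    if mode not in ("mixture", "calibration"):
        raise ValueError("mode must be 'mixture' or 'calibration'")
    ev = events[events["first_peak"].astype(bool)].copy()
    if len(ev) == 0:
        raise ValueError("no first-peak events to infer from")
    amps = ev["amplitude_sd"].to_numpy(float)

    if mode == "mixture":
        per_roi_counts = ev.groupby("roi_id").size()
        if (per_roi_counts < 10).any():
            warnings.warn(
                "fewer than 10 first-peak events in some ROIs; mixture fit is pooled "
                "and may be unstable"
            )
        med = np.median(amps)
        x = amps / med
        if np.ptp(x) < 1e-12:
            counts = np.array([1])
            resp = np.ones((x.size, 1))
            assign = np.ones(x.size, dtype=int)
            post = SpikeCountPosterior(counts, resp, assign, "mixture", 1)
        else:
            try:
                k, gm = _gmm_1d(x, n_max, random_state)
            except RuntimeError:
                if cc is None:
                    raise
                return infer_spike_counts(
                    events, n_max, "calibration", cc, amplitude_noise_sd, random_state
                )
            order = np.argsort(gm.means_.ravel())
            resp = gm.predict_proba(x[:, None])[:, order]
            counts = np.arange(1, k + 1)
            assign = counts[np.argmax(resp, axis=1)]
            post = SpikeCountPosterior(counts, resp, assign, "mixture", k)
    else:
        if cc is None:
            raise ValueError("calibration mode requires a CalibrationCurve")
        counts = np.arange(1, n_max + 1)
        centers = forward_amplitude(counts, cc)
        if amplitude_noise_sd is None or amplitude_noise_sd <= 0:
            # noiseless limit: hard nearest-center assignment
            d = np.abs(amps[:, None] - centers[None, :])
            resp = np.zeros_like(d)
            resp[np.arange(len(amps)), np.argmin(d, axis=1)] = 1.0
        else:
            logp = -0.5 * ((amps[:, None] - centers[None, :]) / amplitude_noise_sd) ** 2
            logp -= logp.max(axis=1, keepdims=True)
            resp = np.exp(logp)
            resp /= resp.sum(axis=1, keepdims=True)
        assign = counts[np.argmax(resp, axis=1)]
        post = SpikeCountPosterior(counts, resp, assign, "calibration", len(counts))

    out = events.copy()
    out.loc[ev.index, "spike_count_est"] = post.assignments
    out["spike_count_est"] = out["spike_count_est"].astype("Int64")
    return post, out
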