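"""Analytic reference methods for respiration -> CO2/PETCO2 prediction.

Two baselines:

* **RVTRRF** — respiratory volume per time (breath-wise peak-trough
  amplitude over breath period) convolved with the canonical respiratory
  response function, then lag-aligned (within +/-120 s), sign-aligned and
  rescaled to the ground-truth PETCO2's mean and SD. Because alignment
  and rescaling use the ground truth, this baseline is evaluation-only.
* **LR** — a single affine map CO2'(t) = beta * Resp(t) + eps with one
  slope and intercept pooled over the training recordings. Being affine,
  it cannot change the magnitude of the Pearson correlation between
  respiration and CO2 — a useful floor for judging the networks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .endtidal import EndTidalTrace
from .fcn import Adam
from .io import PhysioRecording, WaveformSeries

RRF_KERNEL_DURATION_S = 60.0
DEFAULT_MAX_LAG_S = 120.0


# ---------------------------------------------------------------------------
# RVT
# ---------------------------------------------------------------------------

def compute_rvt(resp: WaveformSeries, min_breath_distance_s: float = 2.0
                ) -> WaveformSeries:
    """Respiratory volume per time on the respiration grid.

    Breath-wise (inspiratory peak minus preceding trough) divided by the
    breath period (time to the next peak), assigned at peak times and
    linearly interpolated to the uniform grid. Sign-agnostic trough
    detection; invariant to constant offsets of the belt signal.
    """
    distance = max(1, int(round(min_breath_distance_s * resp.fs)))
    peaks, _ = signal.find_peaks(resp.values, distance=distance)
    troughs, _ = signal.find_peaks(-resp.values, distance=distance)
    if peaks.size < 2 or troughs.size < 1:
        raise ValueError("need >= 2 breaths to compute RVT")
    t = resp.times
    rvt_t, rvt_v = [], []
    for i, p in enumerate(peaks[:-1]):
        prev = troughs[troughs < p]
        if prev.size == 0:
            continue
        amplitude = resp.values[p] - resp.values[prev[-1]]
        period = t[peaks[i + 1]] - t[p]
        rvt_t.append(t[p])
        rvt_v.append(amplitude / period)
    if len(rvt_t) < 2:
        raise ValueError("need >= 2 breaths with a preceding trough for RVT")
    vals = np.interp(t, np.array(rvt_t), np.array(rvt_v))
    return WaveformSeries(vals, resp.fs, resp.t0)


def rrf(t) -> np.ndarray:
    """Respiratory response function.

    RRF(t) = 0.6 t^2.1 e^(-t/1.6) - 0.0023 t^3.54 e^(-t/4.25), t in
    seconds: an early positive lobe (~seconds) followed by a long shallow
    undershoot, modelling the delayed effect of a change in ventilation.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("RRF is defined for t >= 0")
    return 0.6 * t ** 2.1 * np.exp(-t / 1.6) - 0.0023 * t ** 3.54 * np.exp(-t / 4.25)


def rvtrrf_predict(resp: WaveformSeries, petco2_truth: EndTidalTrace,
                   max_lag_s: float = DEFAULT_MAX_LAG_S) -> EndTidalTrace:
    """Eq.-style PETCO2 estimate: RVT convolved with the RRF kernel,
    lag/sign-aligned against the ground truth within +/-``max_lag_s`` and
    rescaled to the truth's mean and SD."""
    if petco2_truth is None:
        raise ValueError("RVTRRF requires the ground-truth PETCO2 for alignment; "
                         "this baseline is evaluation-only")
    rvt = compute_rvt(resp)
    kernel_t = np.arange(0, RRF_KERNEL_DURATION_S, 1.0 / resp.fs)
    kernel = rrf(kernel_t) / resp.fs
    pred = signal.fftconvolve(rvt.values - rvt.values.mean(), kernel)[: rvt.values.size]

    truth = petco2_truth.series.values
    n = min(pred.size, truth.size)
    pred, truth = pred[:n], truth[:n]
    max_k = min(int(round(max_lag_s * resp.fs)), n - 2)
    best = (0, 0.0)
    for k in range(-max_k, max_k + 1):
        if k >= 0:
            a, b = pred[k:], truth[: n - k]
        else:
            a, b = pred[: n + k], truth[-k:]
        r = _pearson(a, b)
        if np.isfinite(r) and abs(r) > abs(best[1]):
            best = (k, r)
    k, r_best = best
    aligned = np.empty(n)
    if k >= 0:
        aligned[: n - k] = pred[k:]
        aligned[n - k :] = pred[-1]
    else:
        aligned[-k:] = pred[: n + k]
        aligned[: -k] = pred[0]
    if r_best < 0:
        aligned = -aligned
    sd = aligned.std()
    if sd == 0:
        raise ValueError("degenerate RVTRRF prediction (zero variance)")
    aligned = (aligned - aligned.mean()) / sd * truth.std() + truth.mean()
    out = np.full(petco2_truth.series.n, aligned[-1])
    out[:n] = aligned
    return EndTidalTrace(WaveformSeries(out, petco2_truth.series.fs,
                                        petco2_truth.series.t0))


def _pearson(a, b):
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    return float(a @ b / denom) if denom > 0 else np.nan


# ---------------------------------------------------------------------------
# linear regression
# ---------------------------------------------------------------------------

@dataclass
class LRModel:
    """Pointwise affine respiration -> CO2 map."""

    beta: float
    intercept: float


def lr_fit(train: list[PhysioRecording], method: str = "exact",
           lr: float = 0.05, epochs: int = 200) -> LRModel:
    """Fit the pooled slope/intercept minimizing MSE over the training set.

    ``exact`` solves the pooled least-squares normal equations;
    ``adam`` runs full-batch Adam on the same objective (both converge to
    the same optimum on these convex fits).
    """
    if not train:
        raise ValueError("empty training set")
    x = np.concatenate([rec.resp.values for rec in train])
    y = np.concatenate([rec.co2.values for rec in train])
    var = x.var()
    if var == 0:
        raise ValueError("degenerate training data: respiration has zero variance")
    if method == "exact":
        beta = float(np.cov(x, y, bias=True)[0, 1] / var)
        intercept = float(y.mean() - beta * x.mean())
        return LRModel(beta, intercept)
    if method == "adam":
        w = np.zeros(1)
        b = np.zeros(1)
        gw, gb = np.zeros(1), np.zeros(1)
        opt = Adam([(w, gw), (b, gb)], lr=lr)
        for _ in range(epochs):
            resid = w[0] * x + b[0] - y
            gw[0] = 2.0 * np.mean(resid * x)
            gb[0] = 2.0 * np.mean(resid)
            opt.step()
        return LRModel(float(w[0]), float(b[0]))
    raise ValueError(f"unknown method {method!r}")


def lr_predict(model: LRModel, resp: WaveformSeries) -> WaveformSeries:
    return WaveformSeries(model.beta * resp.values + model.intercept,
                          resp.fs, resp.t0)
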