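"""Subject-level cross-validated training and evaluation.

Folds are made over subjects, never recordings, so the train and test
partitions of a fold share no individual. Two training regimes are
supported: fixed 90 s chunks batched together (cheap, but each chunk
boundary adds convolution edge effects) and whole variable-length
recordings one at a time (no segmentation artifacts). Metrics follow the
standard set — Pearson r, MSE, MAE for both the CO2 waveform and the
PETCO2 trace, plus MAPE for PETCO2 only (MAPE is undefined near the zero
crossings that the full CO2 waveform necessarily has). Methods are
compared with Kruskal-Wallis omnibus tests and Benjamini-Hochberg
corrected pairwise tests against a designated reference method.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import endtidal
from .fcn import Adam, FCNModel, loss_and_grad
from .io import PhysioRecording, WaveformSeries

logger = logging.getLogger(__name__)

CHUNK_S = 90.0
BATCH_SIZE = 256
MAPE_EPS = 1e-6


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

@dataclass
class FoldSplit:
    k: int
    assignment: dict  # subject_id -> fold index

    def test_subjects(self, fold: int) -> list:
        return sorted(s for s, f in self.assignment.items() if f == fold)

    def train_subjects(self, fold: int) -> list:
        return sorted(s for s, f in self.assignment.items() if f != fold)


def kfold_split(subject_ids, k: int = 5, seed: int = 0) -> FoldSplit:
    """Near-balanced deterministic partition of subjects into k folds."""
    subjects = sorted(set(subject_ids))
    if len(subjects) < k:
        raise ValueError(f"need >= {k} subjects for {k}-fold CV, got {len(subjects)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    assignment = {subjects[j]: int(i % k) for i, j in enumerate(order)}
    return FoldSplit(k=k, assignment=assignment)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    method: str = "variable"   # "variable" | "chunked"
    chunk_s: float = CHUNK_S
    batch_size: int = BATCH_SIZE
    shuffle_seed: int = 0


def _chunks(recordings, chunk_s):
    """Segment recordings into equal chunks, dropping the partial tail."""
    out = []
    for rec in recordings:
        n = int(round(chunk_s * rec.resp.fs))
        m = min(rec.resp.n, rec.co2.n)
        for start in range(0, m - n + 1, n):
            out.append((rec.resp.values[start : start + n],
                        rec.co2.values[start : start + n]))
    return out


def n_chunks(duration_s: float, chunk_s: float = CHUNK_S) -> int:
    """Number of full chunks a recording of the given duration yields."""
    return int(duration_s // chunk_s)


def train(model: FCNModel, recordings: list[PhysioRecording],
          cfg: TrainConfig | None = None) -> FCNModel:
    """Train an FCN with Adam for ``model.spec.epochs`` epochs.

    ``variable``: each recording is one full-length training sample.
    ``chunked``: 90 s segments batched up to 256 at a time.
    Per-epoch mean training loss is appended to ``model.training_log``.
    """
    if not recordings:
        raise ValueError("empty training set")
    cfg = cfg or TrainConfig()
    rng = np.random.default_rng(cfg.shuffle_seed)
    opt = Adam(model.parameters(), lr=model.spec.lr)

    if cfg.method == "chunked":
        samples = _chunks(recordings, cfg.chunk_s)
        if not samples:
            raise ValueError("no full chunks available; recordings too short")
        for _ in range(model.spec.epochs):
            order = rng.permutation(len(samples))
            losses = []
            for lo in range(0, len(order), cfg.batch_size):
                batch = [samples[i] for i in order[lo : lo + cfg.batch_size]]
                x = np.stack([b[0] for b in batch])[:, None, :]
                y = np.stack([b[1] for b in batch])[:, None, :]
                pred = model.forward_batch(x)
                value, grad = loss_and_grad(pred, y, model.spec)
                model.zero_grad()
                model.backward_batch(grad)
                opt.step()
                losses.append(value)
            model.training_log.append(float(np.mean(losses)))
        return model

    if cfg.method != "variable":
        raise ValueError(f"unknown training method {cfg.method!r}")
    for _ in range(model.spec.epochs):
        order = rng.permutation(len(recordings))
        losses = []
        for i in order:
            rec = recordings[i]
            m = min(rec.resp.n, rec.co2.n)
            x = rec.resp.values[None, None, :m]
            y = rec.co2.values[None, None, :m]
            pred = model.forward_batch(x)
            value, grad = loss_and_grad(pred, y, model.spec)
            model.zero_grad()
            model.backward_batch(grad)
            opt.step()
            losses.append(value)
        model.training_log.append(float(np.mean(losses)))
    return model


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def pearson_r(a, b) -> float:
    """Pearson correlation; NaN (with a warning) for constant inputs."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        warnings.warn("Pearson r undefined for constant input; recording as NaN",
                      RuntimeWarning, stacklevel=2)
        return np.nan
    return float(np.clip((a @ b) / denom, -1.0, 1.0))


def mse(pred, truth) -> float:
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("length mismatch")
    return float(np.mean((truth - pred) ** 2))


def mae(pred, truth) -> float:
    """Mean absolute error (1/L) sum |y - yhat|."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("length mismatch")
    return float(np.mean(np.abs(truth - pred)))


def mape(pred, truth, eps: float = MAPE_EPS) -> float:
    """Mean absolute percent error (1/L) sum |(y - yhat)/y|.

    Hard-errors if the truth approaches zero: MAPE is meaningful for the
    PETCO2 trace (bounded away from zero by the peak amplitude floor),
    not for the zero-crossing CO2 waveform.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("length mismatch")
    if np.any(np.abs(truth) < eps):
        raise ValueError("MAPE undefined near zero truth values; "
                         "apply it to PETCO2 traces only")
    return float(np.mean(np.abs((truth - pred) / truth)))


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalResult:
    recording_id: str
    method: str
    r_co2: float = np.nan
    r_petco2: float = np.nan
    mse_co2: float = np.nan
    mse_petco2: float = np.nan
    mae_co2: float = np.nan
    mae_petco2: float = np.nan
    mape_petco2: float = np.nan
    extra: dict = field(default_factory=dict)


def evaluate_recording(recording_id: str, method: str,
                       pred_co2: WaveformSeries | None,
                       truth_co2: WaveformSeries,
                       pred_petco2: WaveformSeries | None = None,
                       truth_petco2: WaveformSeries | None = None) -> EvalResult:
    """Full metric set for one recording.

    If ``pred_petco2`` is not supplied it is extracted from the predicted
    CO2 with the same extractor used for the ground truth. MAPE for the
    PETCO2 pair only. Degenerate predictions yield NaN metrics with a
    warning rather than an error.
    """
    res = EvalResult(recording_id=recording_id, method=method)
    if pred_co2 is not None:
        n = min(pred_co2.n, truth_co2.n)
        p, t = pred_co2.values[:n], truth_co2.values[:n]
        res.r_co2 = pearson_r(p, t)
        res.mse_co2 = mse(p, t)
        res.mae_co2 = mae(p, t)
        if pred_petco2 is None:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    pred_petco2 = endtidal.extract_petco2(pred_co2).series
            except ValueError:
                logger.warning("%s/%s: PETCO2 extraction failed on prediction",
                               recording_id, method)
    if truth_petco2 is None:
        truth_petco2 = endtidal.extract_petco2(truth_co2).series
    if pred_petco2 is not None:
        n = min(pred_petco2.n, truth_petco2.n)
        p, t = pred_petco2.values[:n], truth_petco2.values[:n]
        res.r_petco2 = pearson_r(p, t)
        res.mse_petco2 = mse(p, t)
        res.mae_petco2 = mae(p, t)
        try:
            res.mape_petco2 = mape(p, t)
        except ValueError:
            logger.warning("%s/%s: MAPE undefined (truth crosses zero)",
                           recording_id, method)
    return res


METRIC_COLUMNS = ["r_co2", "r_petco2", "mse_co2", "mse_petco2",
                  "mae_co2", "mae_petco2", "mape_petco2"]


def results_frame(results: list[EvalResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        d = asdict(r)
        d.pop("extra")
        rows.append(d)
    return pd.DataFrame(rows)


def summarize(results: list[EvalResult]) -> pd.DataFrame:
    """Mean +/- SD of each metric per method, pooled over recordings."""
    df = results_frame(results)
    agg = df.groupby("method")[METRIC_COLUMNS].agg(["mean", "std", "count"])
    return agg


def run_crossval(recordings: list[PhysioRecording], spec,
                 k: int = 5, seed: int = 0,
                 include_lr: bool = True, include_rvtrrf: bool = False,
                 train_cfg: TrainConfig | None = None) -> list[EvalResult]:
    """Subject-level k-fold cross-validation of an FCN against baselines.

    Each fold trains on all other folds' recordings and is evaluated on
    its own; ground-truth PETCO2 is extracted from the measured CO2 with
    the same extractor applied to predictions. Returns one
    :class:`EvalResult` per recording and method.
    """
    from . import baselines as _bl
    from .fcn import build_model, forward as fcn_forward

    split = kfold_split([r.subject_id for r in recordings], k=k, seed=seed)
    method_name = f"FCN-{spec.depth}" + ("-Wgt" if spec.loss == "weighted_mse" else "")
    results: list[EvalResult] = []
    for fold in range(k):
        test_subj = set(split.test_subjects(fold))
        train_recs = [r for r in recordings if r.subject_id not in test_subj]
        test_recs = [r for r in recordings if r.subject_id in test_subj]
        if not train_recs or not test_recs:
            continue
        cfg = train_cfg or TrainConfig()
        cfg = TrainConfig(method=cfg.method, chunk_s=cfg.chunk_s,
                          batch_size=cfg.batch_size,
                          shuffle_seed=seed * 1000 + fold)
        model = train(build_model(spec, seed=seed * 100 + fold), train_recs, cfg)
        lr_model = _bl.lr_fit(train_recs) if include_lr else None
        for rec in test_recs:
            truth_petco2 = endtidal.extract_petco2(rec.co2).series
            pred = WaveformSeries(fcn_forward(model, rec.resp.values),
                                  rec.resp.fs, rec.resp.t0)
            results.append(evaluate_recording(
                rec.recording_id, method_name, pred, rec.co2,
                truth_petco2=truth_petco2))
            if lr_model is not None:
                results.append(evaluate_recording(
                    rec.recording_id, "LR", _bl.lr_predict(lr_model, rec.resp),
                    rec.co2, truth_petco2=truth_petco2))
            if include_rvtrrf:
                trace = _bl.rvtrrf_predict(
                    rec.resp, endtidal.EndTidalTrace(
                        WaveformSeries(truth_petco2.values, truth_petco2.fs,
                                       truth_petco2.t0)))
                results.append(evaluate_recording(
                    rec.recording_id, "RVTRRF", None, rec.co2,
                    pred_petco2=trace.series, truth_petco2=truth_petco2))
    return results


def compare_methods(results: list[EvalResult], metric: str,
                    reference: str, alpha: float = 0.05) -> pd.DataFrame:
    """Kruskal-Wallis omnibus across methods plus BH-corrected pairwise
    tests of each method against ``reference``, paired by recording."""
    df = results_frame(results).pivot(index="recording_id", columns="method",
                                      values=metric).dropna()
    methods = list(df.columns)
    if reference not in methods:
        raise ValueError(f"reference method {reference!r} not in results")
    if len(methods) < 2:
        raise ValueError("need >= 2 methods to compare")
    if len(df) < 3:
        raise ValueError("need >= 3 recordings for a meaningful comparison")
    groups = [df[m].to_numpy() for m in methods]
    try:
        omnibus = float(stats.kruskal(*groups).pvalue)
    except ValueError:  # all values identical
        omnibus = 1.0
    others = [m for m in methods if m != reference]
    raw = []
    for m in others:
        try:
            raw.append(float(stats.kruskal(df[reference].to_numpy(),
                                           df[m].to_numpy()).pvalue))
        except ValueError:
            raw.append(1.0)
    if raw:
        reject, adj, _, _ = multipletests(raw, alpha=alpha, method="fdr_bh")
    else:
        reject, adj = np.array([]), np.array([])
    out = pd.DataFrame({
        "method": others,
        "p_raw": raw,
        "p_fdr": adj,
        "significant": reject.astype(bool),
    })
    out.attrs["omnibus_p"] = omnibus
    out.attrs["metric"] = metric
    out.attrs["reference"] = reference
    return out
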