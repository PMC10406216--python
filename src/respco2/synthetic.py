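"""Synthetic paired respiration/CO2 recordings with known ground truth.

The generator produces the qualitative structure the translation method
relies on, with every latent quantity exposed for closed-loop testing:

* respiration is a train of raised-cosine breaths with per-breath period
  jitter (around a mean rate in the 0.2-0.4 Hz band) and amplitude
  (depth) modulation;
* the capnogram is a breath-synchronous waveform whose exhalation-end
  value (the PETCO2 of that breath) varies inversely with a leaky
  integrator of recent breathing depth (~20 s time constant), giving the
  negative respiration-CO2 coupling seen in real recordings;
* the measured CO2 channel lags respiration by a configurable delay
  (default 8.5 s) emulating gas-line transit time;
* additive white noise on both channels and an optional sub-0.2 Hz drift
  artifact on the respiration belt emulate the failure modes the QA
  gates screen for.

It is deliberately not a quantitative gas-exchange model: amplitudes are
in arbitrary (pre-normalization) units, like real belt voltages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .endtidal import EndTidalTrace, PeakSeries, peaks_to_trace
from .io import PhysioRecording, WaveformSeries

#: envelope time constant (s) for the ventilation -> PETCO2 coupling
ENVELOPE_TAU_S = 20.0


@dataclass
class SimParams:
    """Parameters of one simulated recording."""

    duration_s: float = 600.0
    fs: float = 25.0
    breath_rate_hz: float = 0.3
    rate_jitter: float = 0.12       # fractional SD of per-breath period
    depth_modulation: float = 0.40  # fractional SD of per-breath amplitude (incl. sighs)
    coupling_gain: float = 0.65     # depth-envelope -> PETCO2 negative coupling
    osc_gain: float = 0.6           # breath-synchronous CO2 dilution depth
    delay_s: float = 8.5            # CO2 lags respiration (gas-line transit)
    noise_sd_resp: float = 0.03
    noise_sd_co2: float = 0.015
    belt_artifact_sd: float = 0.20  # in-band (0.15-0.5 Hz) belt-only artifact
    petco2_wander_sd: float = 0.015  # slow (0.01-0.05 Hz) spontaneous PETCO2 drift
    drift_amp: float = 0.0          # sub-0.2 Hz belt drift artifact
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ValueError("duration_s must be > 0")
        if not self.fs > 0:
            raise ValueError("fs must be > 0")
        if not self.breath_rate_hz > 0:
            raise ValueError("breath_rate_hz must be > 0")


@dataclass
class SimOutput:
    """A simulated recording plus its ground truth."""

    recording: PhysioRecording
    true_petco2: EndTidalTrace
    true_peaks: PeakSeries
    true_delay_s: float
    params: SimParams


def _breath_train(params: SimParams, rng: np.random.Generator,
                  t_start: float, t_stop: float):
    """Draw breath onset times, periods, depths and PETCO2 values."""
    mean_period = 1.0 / params.breath_rate_hz
    onsets, periods, depths = [], [], []
    t = t_start
    while t < t_stop:
        period = mean_period * (1.0 + params.rate_jitter * rng.standard_normal())
        period = float(np.clip(period, 0.5 * mean_period, 2.0 * mean_period))
        depth = 1.0 + params.depth_modulation * rng.standard_normal()
        depth = float(np.clip(depth, 0.2, None))
        onsets.append(t)
        periods.append(period)
        depths.append(depth)
        t += period
    onsets = np.array(onsets)
    periods = np.array(periods)
    depths = np.array(depths)

    # leaky integrator of breathing depth; deeper recent breathing -> lower PETCO2
    env = np.empty_like(depths)
    acc = 1.0
    for i, (T, d) in enumerate(zip(periods, depths)):
        alpha = np.exp(-T / ENVELOPE_TAU_S)
        acc = alpha * acc + (1.0 - alpha) * d
        env[i] = acc
    petco2 = 1.0 - params.coupling_gain * (env - 1.0)

    if params.petco2_wander_sd > 0:
        # spontaneous slow arterial-CO2 variability, independent of the
        # breath train: a random sum of 0.01-0.05 Hz sinusoids evaluated
        # at each breath's end (where its PETCO2 is attained)
        ends = onsets + periods
        amp = params.petco2_wander_sd * np.sqrt(2.0 / 3.0)
        for _ in range(3):
            f = rng.uniform(0.01, 0.05)
            ph = rng.uniform(0, 2 * np.pi)
            petco2 = petco2 + amp * np.sin(2 * np.pi * f * ends + ph)
    return onsets, periods, depths, petco2


def _render(onsets, periods, depths, petco2, osc_gain, t):
    """Sample respiration and ideal CO2 on grid ``t`` from the breath train.

    Respiration is a smooth raised-cosine bump per breath. The capnogram
    is a slowly varying end-tidal envelope (linear between the per-breath
    PETCO2 values, attained at each breath's end) minus a plateau-shaped
    breath-synchronous dilution dip: CO2 sits on its exhalation plateau
    around the breath boundaries (peaking exactly at exhalation end) and
    drops steeply to a low plateau while fresh air passes the sensor
    mid-breath. Both waveshapes are symmetric about mid-breath, so their
    cross-correlation extremum falls exactly at the injected delay; the
    square-vs-sinusoid shape difference mirrors real capnogram/belt
    morphology and is what a pointwise affine map cannot reproduce.
    """
    # index of the breath covering each time point
    i = np.clip(np.searchsorted(onsets, t, side="right") - 1, 0, len(onsets) - 1)
    phase = np.clip((t - onsets[i]) / periods[i], 0.0, 1.0)
    resp = depths[i] * np.sin(np.pi * phase) ** 2
    envelope = np.interp(t, onsets + periods, petco2)
    dip = 0.5 * (np.tanh((phase - 0.28) / 0.09) - np.tanh((phase - 0.72) / 0.09))
    co2 = envelope - osc_gain * depths[i] * dip
    return resp, co2


def simulate_recording(params: SimParams | None = None, *,
                       subject_id: str = "sim", recording_id: str = "sim-000",
                       _co2_params: SimParams | None = None) -> SimOutput:
    """Simulate one paired recording.

    ``_co2_params`` replaces the breath train driving the CO2 channel with
    an independent one (used to build decoupled QA-failure fixtures).
    """
    params = params or SimParams()
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration_s * params.fs))
    t = np.arange(n) / params.fs

    margin = 3.0 / params.breath_rate_hz
    onsets, periods, depths, petco2 = _breath_train(
        params, rng, -params.delay_s - margin, params.duration_s + margin)
    resp, _ = _render(onsets, periods, depths, petco2, params.osc_gain, t)

    if _co2_params is not None:
        rng2 = np.random.default_rng(_co2_params.seed)
        onsets, periods, depths, petco2 = _breath_train(
            _co2_params, rng2, -params.delay_s - margin, params.duration_s + margin)
    # measured CO2 at time t reflects ideal CO2 at t - delay
    _, co2_meas = _render(onsets, periods, depths, petco2, params.osc_gain,
                          t - params.delay_s)

    if params.drift_amp > 0:
        f1, f2 = rng.uniform(0.02, 0.12, size=2)
        p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
        resp = resp + params.drift_amp * (np.sin(2 * np.pi * f1 * t + p1)
                                          + 0.6 * np.sin(2 * np.pi * f2 * t + p2))
    if params.belt_artifact_sd > 0:
        # motion / non-abdominal-breathing artifact: band-limited to the
        # breathing band so filtering cannot remove it (belt channel only)
        from scipy import signal as _sg
        sos = _sg.butter(2, (0.15, 0.5), btype="bandpass", fs=params.fs,
                         output="sos")
        art = _sg.sosfiltfilt(sos, rng.standard_normal(n))
        sd = art.std()
        if sd > 0:
            resp = resp + params.belt_artifact_sd * art / sd
    resp = resp + params.noise_sd_resp * rng.standard_normal(n)
    co2_meas = co2_meas + params.noise_sd_co2 * rng.standard_normal(n)

    rec = PhysioRecording(
        subject_id=subject_id, recording_id=recording_id,
        resp=WaveformSeries(resp, params.fs),
        co2=WaveformSeries(co2_meas, params.fs),
    )

    # ground-truth PETCO2 in the measured (delayed) time frame: noiseless
    # per-breath values at end-of-exhalation times (= breath ends)
    peak_t = onsets + periods + params.delay_s
    keep = (peak_t >= 0) & (peak_t < params.duration_s)
    true_peaks = PeakSeries(peak_t[keep], petco2[keep])
    true_trace = peaks_to_trace(true_peaks, rec.co2)
    return SimOutput(rec, true_trace, true_peaks, params.delay_s, params)


def make_qa_failure_fixture(kind: str, seed: int = 0) -> SimOutput:
    """Build a recording that fails exactly one QA gate.

    ``too_short``: 120 s recording, tripping the 3-min length gate.
    ``weak_coupling``: CO2 driven by an independent breath train, so the
    delay-corrected correlation stays above the -0.4 threshold.
    ``lf_noise``: strong sub-0.2 Hz belt drift, tripping the low-frequency
    spectral-mismatch flag while duration and correlation gates pass.
    """
    if kind == "too_short":
        params = SimParams(duration_s=120.0, seed=seed)
        return simulate_recording(params, recording_id=f"qa-short-{seed}")
    if kind == "weak_coupling":
        params = SimParams(seed=seed)
        decoupled = replace(params, seed=seed + 104729)  # independent breath train
        return simulate_recording(params, recording_id=f"qa-weak-{seed}",
                                  _co2_params=decoupled)
    if kind == "lf_noise":
        params = SimParams(drift_amp=0.45, seed=seed)
        return simulate_recording(params, recording_id=f"qa-lf-{seed}")
    raise ValueError(f"unknown QA failure kind: {kind!r}")


@dataclass
class CohortParams:
    """Population-level ranges for :func:`simulate_cohort`.

    Per-subject traits (breathing rate, depth modulation, coupling,
    noise) are drawn once per subject; recording durations are drawn per
    recording from a clipped normal emulating a resting-state session
    pool averaging ~10.8 min within 7.2-16.1 min.
    """

    mean_duration_s: float = 648.0
    sd_duration_s: float = 150.0
    min_duration_s: float = 432.0
    max_duration_s: float = 966.0
    breath_rate_range: tuple = (0.22, 0.38)
    depth_mod_range: tuple = (0.3, 0.5)
    coupling_range: tuple = (0.5, 0.8)
    noise_resp_range: tuple = (0.02, 0.06)
    noise_co2_range: tuple = (0.01, 0.03)
    belt_artifact_range: tuple = (0.10, 0.50)
    base: SimParams = field(default_factory=SimParams)


def simulate_cohort(n_subjects: int = 18, recs_per_subject: int = 8,
                    cohort: CohortParams | None = None, seed: int = 0) -> list[SimOutput]:
    """Simulate a cohort with stable per-subject physiology.

    Subject traits are drawn once per subject so recordings from the same
    subject are statistically alike (the property subject-level folding
    guards against); the spread of noise levels across subjects yields a
    cohort-level spread of respiration-CO2 correlations.
    """
    if n_subjects < 1 or recs_per_subject < 1:
        raise ValueError("counts must be >= 1")
    cohort = cohort or CohortParams()
    ss = np.random.SeedSequence(seed)
    out: list[SimOutput] = []
    for s in range(n_subjects):
        sub_ss = ss.spawn(1)[0]
        rng = np.random.default_rng(sub_ss)
        rate = rng.uniform(*cohort.breath_rate_range)
        depth_mod = rng.uniform(*cohort.depth_mod_range)
        coupling = rng.uniform(*cohort.coupling_range)
        noise_r = rng.uniform(*cohort.noise_resp_range)
        noise_c = rng.uniform(*cohort.noise_co2_range)
        # square-law draw: most subjects have clean belts, a minority carry
        # strong artifact, concentrating the cohort correlation near -0.85
        # with a tail towards the -0.5 acceptance region
        lo, hi = cohort.belt_artifact_range
        artifact = lo + (hi - lo) * rng.uniform() ** 2
        delay = float(np.clip(rng.normal(8.5, 1.5), 4.0, 15.0))
        for r in range(recs_per_subject):
            dur = float(np.clip(rng.normal(cohort.mean_duration_s, cohort.sd_duration_s),
                                cohort.min_duration_s, cohort.max_duration_s))
            rec_seed = int(rng.integers(0, 2**31 - 1))
            params = replace(
                cohort.base, duration_s=dur, breath_rate_hz=rate,
                depth_modulation=depth_mod, coupling_gain=coupling,
                noise_sd_resp=noise_r, noise_sd_co2=noise_c,
                belt_artifact_sd=artifact, delay_s=delay, seed=rec_seed)
            out.append(simulate_recording(
                params, subject_id=f"sub-{s:02d}",
                recording_id=f"sub-{s:02d}_rec-{r:02d}"))
    return out
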