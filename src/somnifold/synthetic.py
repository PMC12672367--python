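"""Synthetic ground-truth inputs for the falling-asleep analysis.

Two generators are provided:

* :func:`simulate_bifurcation_series` integrates the fold-bifurcation ODE
  with a linear control ramp and additive Gaussian observation noise,
  returning the clean and noisy state together with the true tipping time —
  the ground truth for model-fitting and early-warning-signal tests.

* :func:`simulate_eeg_night` builds a multichannel EEG night with a staged
  wake -> N1 -> N2 spectral transition: a 1/f (pink) background whose
  exponent steepens into sleep, band-limited alpha/beta activity that fades
  after lights-out wakefulness, rising theta/delta power, sleep-spindle
  bursts (12-16 Hz) after the transition, optional ECG contamination on all
  channels, and a hypnogram matching the stage plan exactly.  EEG components
  are band-limited filtered noise plus deterministic bursts; this matches
  the spectral phenomenology of falling asleep without claiming
  neural-mass realism.

:func:`simulate_cohort` draws multi-night cohorts in which each subject's
sleep (N2) spectral profile is fixed by a per-subject seed, so sleep-onset
feature centroids cluster by subject across nights while bedtime wake
profiles vary freely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .bifurcation import BifurcationParams, bifurcation_diagram, simulate_model
from .io import EEGRecording, Hypnogram, EPOCH_LEN_S

__all__ = [
    "SimulationSpec", "BifurcationSeries", "simulate_bifurcation_series",
    "NightSpec", "simulate_eeg_night", "simulate_cohort",
]


# ---------------------------------------------------------------------------
# Fold-bifurcation time series
# ---------------------------------------------------------------------------

@dataclass
class SimulationSpec:
    """Ground-truth parameters for a simulated sleep-distance series."""

    r: float = 1.0
    K: float = 10.0
    h: float = 1.0
    m: float = 0.01
    c0: float = 1.0
    x0: float | None = None
    noise_sd: float = 0.0          # additive observation noise on s(t)
    process_noise_sd: float = 0.0  # dynamic (state) noise, per sqrt(min)
    dt: float = 0.05  # minutes, the 3-s feature hop
    duration: float = 30.0  # minutes
    seed: int = 0

    def __post_init__(self):
        if not (self.r > 0 and self.K > 0 and self.h > 0 and self.m >= 0):
            raise ValueError("require r, K, h > 0 and m >= 0")
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")


@dataclass
class BifurcationSeries:
    t: np.ndarray        # minutes
    clean: np.ndarray    # noiseless state x(t)
    noisy: np.ndarray    # clean + N(0, noise_sd^2)
    control: np.ndarray  # c(t) = c0 + m t
    tipping_time: float  # minutes; solves c(t*) = c_fold (inf if never)
    c_fold: float
    seed: int


def simulate_bifurcation_series(spec: SimulationSpec) -> BifurcationSeries:
    """Integrate the fold model and add observation noise.

    Raises ``ValueError`` if the parameters admit no fold (no
    three-equilibrium zone) anywhere in ``c >= c0``.
    """
    params = BifurcationParams(spec.r, spec.K, spec.h, spec.m, spec.c0,
                               spec.K if spec.x0 is None else spec.x0)
    c_max = spec.c0 + spec.m * spec.duration
    dia = bifurcation_diagram(params, c_range=(0.0, max(4 * spec.r * 2, 2 * c_max)),
                              c_step=1e-2)
    if not dia.has_fold or dia.fold[0] < spec.c0:
        raise ValueError(
            f"no fold bifurcation for r={spec.r}, K={spec.K}, h={spec.h} "
            f"in c >= c0={spec.c0}; choose parameters with a bistable zone")
    c_fold = dia.fold[0]
    t = np.arange(0.0, spec.duration + spec.dt / 2, spec.dt)
    clean = simulate_model(params, t)
    rng = np.random.default_rng(spec.seed)
    if spec.process_noise_sd > 0:
        # Euler-Maruyama: dynamic noise relaxes through the drift, so the
        # series exhibits genuine critical slowing down near the fold
        sub = 5
        h_int = spec.dt / sub
        x = params.x0 if params.x0 is not None else spec.K
        path = np.empty(len(t))
        path[0] = x
        sq = spec.process_noise_sd * np.sqrt(h_int)
        from .bifurcation import rhs as _rhs
        for i in range(1, len(t)):
            for _ in range(sub):
                c = spec.c0 + spec.m * (t[i - 1])
                x = x + _rhs(x, c, params) * h_int + sq * rng.standard_normal()
                x = max(x, 0.0)
            path[i] = x
        noisy = path + rng.normal(0.0, spec.noise_sd, size=len(t))
    else:
        noisy = clean + rng.normal(0.0, spec.noise_sd, size=len(t))
    control = spec.c0 + spec.m * t
    tipping = (c_fold - spec.c0) / spec.m if spec.m > 0 else np.inf
    return BifurcationSeries(t, clean, noisy, control, tipping, c_fold,
                             spec.seed)


# ---------------------------------------------------------------------------
# EEG night
# ---------------------------------------------------------------------------

#: per-stage RMS amplitude (µV) of each band-limited component; the wake
#: entries are overwritten per night from `wake_amp_jitter`, the N2 entries
#: per subject from `subject_centroid_seed`.
_DEFAULT_STAGE_AMPS = {
    "W":  {"delta": 4.0, "theta": 3.0, "alpha": 12.0, "beta": 6.0},
    "N1": {"delta": 6.0, "theta": 7.0, "alpha": 5.0, "beta": 4.0},
    "N2": {"delta": 14.0, "theta": 10.0, "alpha": 3.0, "beta": 2.5},
    "N3": {"delta": 20.0, "theta": 9.0, "alpha": 2.0, "beta": 2.0},
    "REM": {"delta": 5.0, "theta": 6.0, "alpha": 4.0, "beta": 5.0},
}
_BAND_EDGES = {"delta": (1.0, 4.0), "theta": (4.0, 8.0),
               "alpha": (8.0, 12.0), "beta": (18.0, 24.0)}


@dataclass
class NightSpec:
    """Recipe for one simulated night."""

    fs: float = 256.0
    stage_plan: list[tuple[str, float]] = field(
        default_factory=lambda: [("W", 1200.0), ("N1", 240.0), ("N2", 720.0)])
    stage_amps: dict | None = None       # per-stage band RMS (µV); default above
    pink_rms: float = 10.0               # broadband 1/f background RMS (µV)
    pink_exp_wake: float = 1.0           # aperiodic exponent in wake
    pink_exp_sleep: float = 1.8          # steeper exponent after transition
    spindle_rate: float = 6.0            # bursts/min post-transition
    spindle_amp: float = 10.0            # burst RMS (µV)
    ramp_s: float = 45.0                 # raised-cosine stage-transition ramp
    ecg_rate: float = 60.0               # bpm; 0 disables ECG
    ecg_amp: float = 6.0                 # cardiac artifact amplitude on EEG (µV)
    n_channels: int = 3
    channel_names: tuple = ("F3", "C3", "O1")
    subject_centroid_seed: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.fs < 128:
            raise ValueError("fs must be >= 128 Hz")
        if any(d <= 0 for _, d in self.stage_plan):
            raise ValueError("stage durations must be positive")


def _band_noise(rng, n, fs, band):
    lo, hi = band
    x = rng.standard_normal(n)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x)
    return y / (np.std(y) + 1e-12)


def _pink_noise(rng, n, fs, exponent):
    """1/f^exponent noise via FFT spectral shaping, unit RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1 / fs)
    shaping = np.ones_like(f)
    nz = f > 0
    shaping[nz] = f[nz] ** (-exponent / 2.0)
    shaping[0] = 0.0
    y = np.fft.irfft(spec * shaping, n)
    return y / (np.std(y) + 1e-12)


def _stage_envelope(plan, fs, n, ramp_s, values):
    """Piecewise-constant per-stage values with raised-cosine ramps.

    Built at a coarse 8-Hz grid and linearly interpolated to ``fs``; the
    ramps are much longer than the grid step so no detail is lost.
    """
    coarse_fs = 8.0
    nc = int(np.ceil(n / fs * coarse_fs)) + 1
    env = np.empty(nc)
    pos = 0
    for stage, dur in plan:
        ns = int(round(dur * coarse_fs))
        env[pos:pos + ns] = values[stage]
        pos += ns
    env[pos:] = values[plan[-1][0]]
    ramp = int(ramp_s * coarse_fs)
    if ramp > 1:
        win = np.hanning(2 * ramp + 1)
        win /= win.sum()
        env = np.convolve(env, win, mode="same")
        env[:ramp] = env[ramp]          # undo edge shrinkage
        env[-ramp:] = env[-ramp - 1]
    t_c = np.arange(nc) / coarse_fs
    return np.interp(np.arange(n) / fs, t_c, env)


def _ecg_template(fs):
    """One synthetic PQRST complex (unit R amplitude), 0.6 s long."""
    t = np.arange(int(0.6 * fs)) / fs - 0.3
    g = lambda mu, sd, a: a * np.exp(-0.5 * ((t - mu) / sd) ** 2)
    return (g(-0.2, 0.025, 0.15) + g(-0.025, 0.01, -0.1) + g(0.0, 0.008, 1.0)
            + g(0.025, 0.01, -0.15) + g(0.22, 0.04, 0.25))


def simulate_eeg_night(spec: NightSpec) -> tuple[EEGRecording, Hypnogram]:
    """Render one night of multichannel EEG plus its hypnogram.

    The hypnogram matches ``spec.stage_plan`` exactly (durations rounded to
    30-s epochs).  Raises if the plan has no two consecutive N2 epochs, as
    no sleep onset would be definable.
    """
    plan = [(s, round(d / EPOCH_LEN_S) * EPOCH_LEN_S)
            for s, d in spec.stage_plan]
    stages: list[str] = []
    for stage, dur in plan:
        stages.extend([stage] * int(dur / EPOCH_LEN_S))
    if not any(stages[i] == stages[i + 1] == "N2"
               for i in range(len(stages) - 1)):
        raise ValueError("stage plan has no two consecutive N2 epochs; "
                         "sleep onset undefined")
    fs = spec.fs
    n = int(sum(d for _, d in plan) * fs)
    rng = np.random.default_rng(spec.seed)

    amps = {k: dict(v) for k, v in _DEFAULT_STAGE_AMPS.items()}
    if spec.stage_amps:
        for st, bands in spec.stage_amps.items():
            amps.setdefault(st, {}).update(bands)
    # subject-specific sleep spectral profile: fixes the sleep-onset centroid
    if spec.subject_centroid_seed is not None:
        srng = np.random.default_rng(spec.subject_centroid_seed)
        for band in ("delta", "theta", "alpha", "beta"):
            amps["N2"][band] *= srng.uniform(0.6, 1.6)
        spindle_freq = srng.uniform(12.5, 15.5)
        sleep_exp = srng.uniform(1.5, 2.1)
    else:
        spindle_freq = 13.5
        sleep_exp = spec.pink_exp_sleep

    # sleep-weight envelope: 0 in W, 0.5 in N1, 1 from N2 on
    sleep_w = _stage_envelope(plan, fs, n, spec.ramp_s,
                              {"W": 0.0, "N1": 0.5, "N2": 1.0, "N3": 1.0,
                               "REM": 0.8})
    # spindle burst train, shared timing across channels
    t_first_n2 = 0.0
    for stage, dur in plan:
        if stage == "N2":
            break
        t_first_n2 += dur
    spindles = np.zeros(n)
    n_burst = int(0.75 * fs)
    burst_win = np.hanning(n_burst)
    t_cursor = t_first_n2 + rng.exponential(60.0 / max(spec.spindle_rate, 1e-6))
    while t_cursor * fs + n_burst < n:
        i0 = int(t_cursor * fs)
        tt = np.arange(n_burst) / fs
        phase = rng.uniform(0, 2 * np.pi)
        spindles[i0:i0 + n_burst] += burst_win * np.sin(
            2 * np.pi * spindle_freq * tt + phase)
        t_cursor += rng.exponential(60.0 / max(spec.spindle_rate, 1e-6))
    spindles *= spec.spindle_amp * np.sqrt(2.0)

    ecg_chan = None
    cardiac = None
    if spec.ecg_rate > 0:
        template = _ecg_template(fs)
        ecg_chan = np.zeros(n)
        rr = 60.0 / spec.ecg_rate
        beat = 0.5
        while beat * fs + len(template) < n:
            i0 = int(beat * fs)
            ecg_chan[i0:i0 + len(template)] += template
            beat += rr * (1.0 + 0.02 * rng.standard_normal())
        cardiac = ecg_chan * spec.ecg_amp  # µV leakage into EEG
        ecg_chan = ecg_chan * 1000.0 + rng.normal(0, 5.0, n)  # ~1 mV R peak

    data = np.empty((spec.n_channels, n))
    for ch in range(spec.n_channels):
        pink = (_pink_noise(rng, n, fs, spec.pink_exp_wake) * (1 - sleep_w)
                + _pink_noise(rng, n, fs, sleep_exp) * sleep_w) * spec.pink_rms
        x = pink + spindles * sleep_w
        for band, edges in _BAND_EDGES.items():
            env = _stage_envelope(plan, fs, n, spec.ramp_s,
                                  {st: amps.get(st, amps["W"]).get(band, 0.0)
                                   for st in ("W", "N1", "N2", "N3", "REM")})
            x += _band_noise(rng, n, fs, edges) * env
        if cardiac is not None:
            x += cardiac
        data[ch] = x

    names = list(spec.channel_names[:spec.n_channels])
    while len(names) < spec.n_channels:
        names.append(f"EEG{len(names) + 1}")
    rec = EEGRecording(channels=names, data=data, fs=fs, ecg=ecg_chan)
    return rec, Hypnogram(stages=stages)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def simulate_cohort(n_subjects: int = 4, nights_per_subject: int = 4,
                    between_night_jitter: float = 0.15, seed: int = 0,
                    latency_range: tuple[float, float] = (3.0, 90.0),
                    n1_minutes: float = 3.0, post_onset_minutes: float = 12.0,
                    fs: float = 256.0, ecg_rate: float = 60.0,
                    ) -> list[tuple[str, str, EEGRecording, Hypnogram]]:
    """Simulate a multi-night cohort with subject-consistent sleep centroids.

    Each subject's nights share one ``subject_centroid_seed`` (so their
    sleep-onset spectral profiles cluster), perturbed multiplicatively by
    ``between_night_jitter``; bedtime wake amplitudes vary freely per night.
    Sleep latencies are drawn log-uniformly within ``latency_range``
    (minutes, bounded by the [3, 90]-min inclusion window of the analysis).

    Returns ``(subject_id, night_id, recording, hypnogram)`` tuples.
    """
    if n_subjects < 2 or nights_per_subject < 2:
        raise ValueError("need >= 2 subjects and >= 2 nights per subject")
    lo, hi = latency_range
    if not (3.0 <= lo <= hi <= 90.0):
        raise ValueError("latency_range must lie within [3, 90] minutes")
    master = np.random.default_rng(seed)
    out = []
    for si in range(n_subjects):
        subject_seed = int(master.integers(2**31 - 1))
        for ni in range(nights_per_subject):
            night_rng = np.random.default_rng(int(master.integers(2**31 - 1)))
            latency = float(np.exp(night_rng.uniform(np.log(lo), np.log(hi))))
            n1 = min(n1_minutes, max(latency - 1.0, 0.5))
            w = max(latency - n1, 0.5)
            plan = [("W", w * 60.0), ("N1", n1 * 60.0),
                    ("N2", post_onset_minutes * 60.0)]
            # wake profile varies freely per night
            wake_amps = {"W": {b: a * night_rng.uniform(0.5, 1.5)
                               for b, a in _DEFAULT_STAGE_AMPS["W"].items()}}
            jitter_seed = subject_seed
            if between_night_jitter > 0:
                wake_amps["N2"] = {
                    b: a * (1.0 + between_night_jitter
                            * night_rng.standard_normal())
                    for b, a in _DEFAULT_STAGE_AMPS["N2"].items()}
            spec = NightSpec(fs=fs, stage_plan=plan, stage_amps=wake_amps,
                             ecg_rate=ecg_rate,
                             subject_centroid_seed=jitter_seed,
                             seed=int(night_rng.integers(2**31 - 1)))
            rec, hyp = simulate_eeg_night(spec)
            out.append((f"S{si + 1:02d}", f"N{ni + 1:02d}", rec, hyp))
    return out
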