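"""Seeded synthetic task-session generator.

Produces continuous multichannel LFP-like signals plus a movement trace
with the statistical structure the downstream analysis assumes:

* 1/f background noise and a 50 Hz line component,
* a tonic beta (13-30 Hz) oscillation that desynchronises around movement,
* a theta (2-8 Hz) synchronisation around movement,
* transient gamma bursts (windowed sinusoids at a fixed centre frequency
  in 62-81 Hz, ~1-3 cycles long) injected as an inhomogeneous Poisson
  process whose *rate* -- not amplitude or duration -- increases in the
  0.5 s after movement onset, scales across the three movement
  conditions, and is damped in the simulated OFF state,
* a movement trace with minimum-jerk (bell-shaped velocity) rotations to
  the target angle, trial-to-trial velocity variability, and, on the
  "contra" electrode only, coupling between trial velocity and burst rate.

Everything injected is recorded in a :class:`GroundTruth` object so that
parameter-recovery tests can score the pipeline against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import SimConfig

CONDITION_LABELS = ("small", "medium", "large")


@dataclass
class SessionRecording:
    """Continuous recording of one hand/side of one simulated subject."""

    lfp: np.ndarray                 # channels x samples, a.u.
    channel_table: pd.DataFrame     # name, electrode, hemisphere, role
    movement_trace: np.ndarray      # samples, degrees
    cue_times: np.ndarray           # s
    condition_labels: np.ndarray    # target angle (deg) per trial
    sampling_rate: float
    state: str

    @property
    def n_channels(self) -> int:
        return self.lfp.shape[0]

    @property
    def duration(self) -> float:
        return self.lfp.shape[1] / self.sampling_rate

    def events_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "trial": np.arange(len(self.cue_times)),
            "cue_time_s": self.cue_times,
            "condition": self.condition_labels,
            "state": self.state,
        })

    def validate(self) -> None:
        if self.lfp.ndim != 2 or self.lfp.shape[0] == 0:
            raise ValueError("lfp must be a non-empty channels x samples array")
        if self.lfp.shape[1] != self.movement_trace.shape[0]:
            raise ValueError("lfp and movement trace must share the time axis")
        if len(self.channel_table) != self.lfp.shape[0]:
            raise ValueError("channel table does not match lfp channel count")
        for _, grp in self.channel_table.groupby("electrode"):
            if len(grp) != 3:
                raise ValueError("each electrode must carry exactly 3 bipolar channels")
        if np.any(np.diff(self.cue_times) <= 0):
            raise ValueError("cue_times must be strictly increasing")
        if len(self.cue_times) != len(self.condition_labels):
            raise ValueError("one condition label per cue required")


@dataclass
class GroundTruth:
    """Record of everything the generator injected."""

    burst_events: dict                    # channel name -> DataFrame
    true_onset_times: np.ndarray          # s per trial
    true_peak_velocities: np.ndarray      # deg/s per trial
    true_peak_times: np.ndarray           # s per trial, time of peak velocity
    true_end_times: np.ndarray            # s per trial, end of outward movement
    injected_effect_sizes: dict           # condition/state gains actually used


def powerlaw_noise(n: int, exponent: float, rng: np.random.Generator,
                   sampling_rate: float = 1000.0) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f**exponent, unit variance."""
    from scipy import fft as sp_fft
    n_fft = sp_fft.next_fast_len(n, real=True)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / sampling_rate)
    spectrum = np.zeros(len(freqs))
    spectrum[1:] = freqs[1:] ** (-exponent / 2.0)
    phases = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    x = sp_fft.irfft(spectrum * phases, n=n_fft)[:n]
    sd = x.std()
    return x / sd if sd > 0 else x


def minimum_jerk(t: np.ndarray, amplitude: float, duration: float) -> np.ndarray:
    """Minimum-jerk position profile: 0 at t=0, `amplitude` at t=duration."""
    tau = np.clip(t / duration, 0.0, 1.0)
    return amplitude * (10 * tau ** 3 - 15 * tau ** 4 + 6 * tau ** 5)


def minimum_jerk_peak_velocity(amplitude: float, duration: float) -> float:
    """Peak velocity of the minimum-jerk profile: 15/8 * A / T."""
    return 1.875 * amplitude / duration


def _smooth_window(n: int, i0: int, i1: int, ramp: int) -> np.ndarray:
    """Boxcar on [i0, i1) with raised-cosine ramps of `ramp` samples."""
    w = np.zeros(n)
    i0c, i1c = max(i0, 0), min(i1, n)
    if i1c <= i0c:
        return w
    w[i0c:i1c] = 1.0
    up = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
    a0 = i0c - ramp
    for k in range(ramp):
        idx = a0 + k
        if 0 <= idx < n:
            w[idx] = max(w[idx], up[k])
        idx2 = i1c + ramp - 1 - k
        if 0 <= idx2 < n:
            w[idx2] = max(w[idx2], up[k])
    return w


def _sample_bursts(rng: np.random.Generator, duration_s: float,
                   rate_hz_fn, max_rate_hz: float, cfg: SimConfig) -> list[dict]:
    """Inhomogeneous Poisson burst times by thinning, with a refractory gap
    of one burst duration after each accepted burst (prevents overlap)."""
    b = cfg.bursts
    lo, hi = b.duration_cycles_range
    events = []
    t = 0.0
    while True:
        t += rng.exponential(1.0 / max_rate_hz)
        if t >= duration_s:
            break
        if rng.random() * max_rate_hz > rate_hz_fn(t):
            continue
        cycles = np.clip(rng.normal(b.duration_cycles_mean, b.duration_cycles_sd),
                         lo, hi)
        dur = cycles / b.center_hz
        if t + dur >= duration_s:
            continue
        amp = b.amplitude_mean * rng.lognormal(0.0, b.amplitude_sigma)
        events.append({"onset_s": t, "offset_s": t + dur,
                       "center_hz": b.center_hz, "amplitude": amp})
        t += 2.0 * dur   # refractory gap >= one burst duration
    return events


def generate_session(config: SimConfig, seed: int | None = None,
                     include_lfp: bool = True) -> tuple[SessionRecording, GroundTruth]:
    """Generate one synthetic session.

    Parameters
    ----------
    config
        Validated :class:`SimConfig`; ``config.seed`` drives all randomness
        unless `seed` overrides it.
    include_lfp
        When False only the movement trace and ground truth are produced
        (the LFP array is all zeros); useful for kinematics-only tests.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    fs = config.sampling_rate
    n_cond = len(config.conditions)
    n_trials = n_cond * config.n_trials_per_condition

    # --- trial schedule: balanced, randomised condition order -------------
    cond_idx = rng.permutation(np.repeat(np.arange(n_cond), config.n_trials_per_condition))
    rt = np.maximum(rng.normal(config.reaction_time_mean, config.reaction_time_sd,
                               n_trials), 0.2)
    speed_factor = rng.lognormal(0.0, config.velocity_variability, n_trials)

    cue_times = np.empty(n_trials)
    onset_times = np.empty(n_trials)
    durations = np.empty(n_trials)
    t_cursor = config.edge_padding
    for k in range(n_trials):
        c = cond_idx[k]
        cue_times[k] = t_cursor
        onset_times[k] = t_cursor + rt[k]
        durations[k] = config.movement_duration_by_condition[c] / speed_factor[k]
        trial_end = onset_times[k] + durations[k] + config.hold_time + durations[k]
        t_cursor = trial_end + config.inter_trial_interval
    total_s = t_cursor + config.edge_padding
    n_samples = int(round(total_s * fs))
    time = np.arange(n_samples) / fs

    # --- movement trace ----------------------------------------------------
    trace = np.zeros(n_samples)
    peak_velocities = np.empty(n_trials)
    peak_times = np.empty(n_trials)
    end_times = np.empty(n_trials)
    for k in range(n_trials):
        angle = config.conditions[cond_idx[k]]
        T = durations[k]
        i0 = int(round(onset_times[k] * fs))
        i1 = int(round((onset_times[k] + T) * fs))
        i2 = int(round((onset_times[k] + T + config.hold_time) * fs))
        i3 = int(round((onset_times[k] + T + config.hold_time + T) * fs))
        tt = time[i0:i1] - onset_times[k]
        trace[i0:i1] = minimum_jerk(tt, angle, T)
        trace[i1:i2] = angle
        tt = time[i2:i3] - time[i2]
        trace[i2:i3] = angle - minimum_jerk(tt, angle, T)
        peak_velocities[k] = minimum_jerk_peak_velocity(angle, T)
        peak_times[k] = onset_times[k] + 0.5 * T
        end_times[k] = onset_times[k] + T
    trace = trace + rng.normal(0.0, config.trace_noise_sd, n_samples)

    # --- channel metadata ---------------------------------------------------
    pairs = ("01", "12", "23")
    rows = []
    for el in config.electrodes:
        hemi = "right" if el == "contra" else "left"
        for p in pairs:
            rows.append({"name": f"{el}-{p}", "electrode": el,
                         "hemisphere": hemi, "role": el})
    channel_table = pd.DataFrame(rows)
    n_channels = len(channel_table)

    # --- per-trial burst-rate modulation ------------------------------------
    b = config.bursts
    state_scale = config.off_rate_scaling if config.state == "OFF" else 1.0
    base_rate_hz = b.baseline_rate_per_halfs / 0.5
    # standardised velocity residual (log speed factor / sigma)
    z_v = (np.log(speed_factor) / config.velocity_variability
           if config.velocity_variability > 0 else np.zeros(n_trials))

    lfp = np.zeros((n_channels, n_samples), dtype=np.float64)
    burst_events: dict[str, pd.DataFrame] = {}
    gains_used: dict[str, list] = {}

    if include_lfp:
        mov_win = 0.5  # s of elevated rate after movement onset
        # ERD/ERS modulation windows are shared across channels
        w_erd = np.zeros(n_samples)
        w_ers = np.zeros(n_samples)
        if config.beta.amplitude > 0:
            ramp = int(0.15 * fs)
            for k in range(n_trials):
                i0 = int((onset_times[k] + config.beta.window_s[0]) * fs)
                i1 = int((onset_times[k] + config.beta.window_s[1]) * fs)
                w_erd = np.maximum(w_erd, _smooth_window(n_samples, i0, i1, ramp))
        if config.theta.ers_amplitude > 0:
            ramp = int(0.25 * fs)
            for k in range(n_trials):
                i0 = int((onset_times[k] + config.theta.window_s[0]) * fs)
                i1 = int((onset_times[k] + config.theta.window_s[1]) * fs)
                w_ers = np.maximum(w_ers, _smooth_window(n_samples, i0, i1, ramp))
        for ch, row in channel_table.iterrows():
            coupled = row["role"] == "contra"
            trial_gain = np.empty(n_trials)
            for k in range(n_trials):
                g = b.movement_gain_by_condition[cond_idx[k]] * state_scale
                if coupled and b.velocity_coupling > 0:
                    g = g * max(1.0 + b.velocity_coupling * z_v[k], 0.1)
                trial_gain[k] = g
            gains_used[row["name"]] = trial_gain.tolist()

            def rate_fn(t: float) -> float:
                k = np.searchsorted(onset_times, t) - 1
                if 0 <= k < n_trials and onset_times[k] <= t < onset_times[k] + mov_win:
                    return base_rate_hz * (1.0 + trial_gain[k])
                return base_rate_hz

            max_rate = base_rate_hz * (1.0 + max(trial_gain.max(), 0.0))
            events = _sample_bursts(rng, total_s, rate_fn, max_rate, config)

            sig = powerlaw_noise(n_samples, config.background_exponent, rng, fs)
            sig *= config.background_amplitude
            if config.line_noise_amplitude > 0:
                sig += config.line_noise_amplitude * np.sin(
                    2 * np.pi * 50.0 * time + rng.uniform(0, 2 * np.pi))
            # tonic beta with movement-related desynchronisation
            if config.beta.amplitude > 0:
                amp_beta = config.beta.amplitude * (1.0 - config.beta.erd_fraction * w_erd)
                sig += amp_beta * np.sin(2 * np.pi * config.beta.center_hz * time
                                         + rng.uniform(0, 2 * np.pi))
            # theta ERS
            if config.theta.ers_amplitude > 0:
                sig += (config.theta.ers_amplitude * w_ers
                        * np.sin(2 * np.pi * config.theta.center_hz * time
                                 + rng.uniform(0, 2 * np.pi)))
            # gamma bursts: Hann-windowed sinusoids
            for ev in events:
                i0 = int(round(ev["onset_s"] * fs))
                i1 = int(round(ev["offset_s"] * fs))
                if i1 <= i0 + 2:
                    continue
                tt = time[i0:i1] - ev["onset_s"]
                d = ev["offset_s"] - ev["onset_s"]
                win = 0.5 * (1 - np.cos(2 * np.pi * tt / d))
                sig[i0:i1] += ev["amplitude"] * win * np.sin(
                    2 * np.pi * ev["center_hz"] * tt + rng.uniform(0, 2 * np.pi))
            lfp[ch] = sig
            burst_events[row["name"]] = pd.DataFrame(
                events, columns=["onset_s", "offset_s", "center_hz", "amplitude"])
    else:
        for _, row in channel_table.iterrows():
            burst_events[row["name"]] = pd.DataFrame(
                columns=["onset_s", "offset_s", "center_hz", "amplitude"])

    recording = SessionRecording(
        lfp=lfp, channel_table=channel_table, movement_trace=trace,
        cue_times=cue_times,
        condition_labels=np.array([config.conditions[c] for c in cond_idx]),
        sampling_rate=fs, state=config.state)
    recording.validate()
    truth = GroundTruth(
        burst_events=burst_events,
        true_onset_times=onset_times,
        true_peak_velocities=peak_velocities,
        true_peak_times=peak_times,
        true_end_times=end_times,
        injected_effect_sizes={
            "movement_gain_by_condition": tuple(b.movement_gain_by_condition),
            "state_scale": state_scale,
            "velocity_coupling": b.velocity_coupling,
            "per_channel_trial_gains": gains_used,
        })
    return recording, truth


# ---------------------------------------------------------------------------
# Session container I/O: one directory with a raw numeric blob per array,
# TSV metadata/event tables and a YAML echo of the configuration.
# ---------------------------------------------------------------------------

def write_session(recording: SessionRecording, path: str | Path,
                  config: SimConfig | None = None) -> Path:
    recording.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.save(path / "lfp.npy", recording.lfp.astype(np.float32))
    np.save(path / "movement.npy", recording.movement_trace.astype(np.float32))
    recording.channel_table.to_csv(path / "channels.tsv", sep="\t", index=False)
    # %.17g keeps event times exact through the text round-trip
    recording.events_table().to_csv(path / "events.tsv", sep="\t", index=False,
                                    float_format="%.17g")
    meta = {"sampling_rate": float(recording.sampling_rate),
            "state": recording.state}
    if config is not None:
        meta["config"] = config.to_dict()
    with open(path / "config.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)
    return path


def read_session(path: str | Path) -> SessionRecording:
    path = Path(path)
    for fname in ("lfp.npy", "movement.npy", "channels.tsv", "events.tsv",
                  "config.yaml"):
        if not (path / fname).exists():
            raise ValueError(f"malformed session container: missing {fname}")
    lfp = np.load(path / "lfp.npy")
    movement = np.load(path / "movement.npy")
    channels = pd.read_csv(path / "channels.tsv", sep="\t")
    events = pd.read_csv(path / "events.tsv", sep="\t",
                         float_precision="round_trip")
    with open(path / "config.yaml") as fh:
        meta = yaml.safe_load(fh)
    fs = float(meta["sampling_rate"])
    if "config" in meta and float(meta["config"]["sampling_rate"]) != fs:
        raise ValueError("sampling-rate mismatch between metadata and config echo")
    rec = SessionRecording(
        lfp=np.asarray(lfp, dtype=np.float64),
        channel_table=channels,
        movement_trace=np.asarray(movement, dtype=np.float64),
        cue_times=events["cue_time_s"].to_numpy(dtype=float),
        condition_labels=events["condition"].to_numpy(),
        sampling_rate=fs,
        state=str(meta["state"]))
    rec.validate()
    return rec
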