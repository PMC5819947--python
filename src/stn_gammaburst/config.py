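"""Configuration of the synthetic task-session generator.

The generator emulates a cued forearm-pronation paradigm recorded from
bilateral subthalamic macroelectrodes: three target amplitudes (30, 60,
90 degrees) presented in randomised order with 4 s inter-trial periods,
local field potentials sampled at 1 kHz from three bipolar contact pairs
per electrode, and a potentiometer movement trace sampled in parallel.

All amplitudes are in arbitrary microvolt-like units; every detection
threshold downstream is data-relative (percentiles), so the absolute
scale is inert.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence


@dataclass(frozen=True)
class BetaParams:
    """Tonic beta oscillation that desynchronises around movement."""

    center_hz: float = 20.0
    amplitude: float = 0.45
    erd_fraction: float = 0.25         # fractional amplitude drop during ERD
    window_s: tuple[float, float] = (-0.4, 1.7)  # relative to movement onset


@dataclass(frozen=True)
class ThetaParams:
    """Theta event-related synchronisation around movement."""

    center_hz: float = 5.0
    ers_amplitude: float = 0.6
    window_s: tuple[float, float] = (-1.2, 2.7)


@dataclass(frozen=True)
class BurstParams:
    """Transient gamma bursts whose *rate* carries the movement effect.

    Rates are expressed per 0.5 s window (the unit used for burst-rate
    statistics throughout).  ``movement_gain_by_condition`` is the
    fractional rate increase in the 0.5 s following movement onset for
    the small/medium/large conditions.  ``velocity_coupling`` scales the
    per-trial movement gain with the standardised trial peak-velocity
    residual; it is applied on the contralateral electrode only.
    """

    center_hz: float = 70.0
    amplitude_mean: float = 1.2        # peak amplitude of the windowed sinusoid
    amplitude_sigma: float = 0.25      # lognormal sigma of burst amplitude
    duration_cycles_mean: float = 1.9
    duration_cycles_sd: float = 0.45
    duration_cycles_range: tuple[float, float] = (1.0, 3.0)
    baseline_rate_per_halfs: float = 1.6
    movement_gain_by_condition: tuple[float, ...] = (0.293, 0.367, 0.482)
    velocity_coupling: float = 1.2


@dataclass(frozen=True)
class SimConfig:
    """Full parameterisation of one synthetic session (one hand, one state)."""

    sampling_rate: float = 1000.0
    n_trials_per_condition: int = 15
    conditions: tuple[float, ...] = (30.0, 60.0, 90.0)   # target angles, degrees
    inter_trial_interval: float = 4.0                    # s between return and next cue
    reaction_time_mean: float = 0.65
    reaction_time_sd: float = 0.10
    movement_duration_by_condition: tuple[float, ...] = (0.45, 0.52, 0.58)
    hold_time: float = 3.0
    velocity_variability: float = 0.12   # lognormal sigma of per-trial speed factor
    trace_noise_sd: float = 0.15         # degrees, potentiometer noise

    background_exponent: float = 2.0     # 1/f^alpha power slope
    background_amplitude: float = 1.0    # broadband SD, a.u.
    line_noise_amplitude: float = 0.25   # 50 Hz component amplitude, a.u.

    beta: BetaParams = field(default_factory=BetaParams)
    theta: ThetaParams = field(default_factory=ThetaParams)
    bursts: BurstParams = field(default_factory=BurstParams)

    electrodes: tuple[str, ...] = ("contra", "ipsi")
    state: str = "ON"
    off_rate_scaling: float = 0.5        # multiplies the movement rate gain OFF
    edge_padding: float = 3.0            # s of signal before first cue / after last trial
    seed: int = 0

    def validate(self) -> None:
        c = self
        if c.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if c.n_trials_per_condition < 1:
            raise ValueError("need at least one trial per condition")
        if len(c.conditions) != len(c.movement_duration_by_condition):
            raise ValueError("one movement duration per condition required")
        if any(b <= a for a, b in zip(c.conditions, c.conditions[1:])):
            raise ValueError("conditions must be strictly increasing")
        if any(v <= 0 for v in c.conditions):
            raise ValueError("target angles must be positive")
        if any(v <= 0 for v in c.movement_duration_by_condition):
            raise ValueError("movement durations must be positive")
        if c.state not in ("ON", "OFF"):
            raise ValueError("state must be 'ON' or 'OFF'")
        if not (0.0 < c.off_rate_scaling <= 1.0):
            raise ValueError("off_rate_scaling must lie in (0, 1]")
        b = c.bursts
        if not (62.0 <= b.center_hz <= 81.0):
            raise ValueError("burst center frequency must lie within 62-81 Hz")
        if b.amplitude_mean <= 0 or b.baseline_rate_per_halfs <= 0:
            raise ValueError("burst amplitude and baseline rate must be positive")
        if any(g < 0 for g in b.movement_gain_by_condition):
            raise ValueError("movement rate gains must be non-negative")
        if len(b.movement_gain_by_condition) != len(c.conditions):
            raise ValueError("one movement rate gain per condition required")
        lo, hi = b.duration_cycles_range
        if not (0 < lo <= hi):
            raise ValueError("burst duration range must be positive and ordered")
        if c.beta.amplitude < 0 or c.theta.ers_amplitude < 0:
            raise ValueError("oscillation amplitudes must be non-negative")
        if not (0.0 <= c.beta.erd_fraction <= 1.0):
            raise ValueError("beta ERD fraction must lie in [0, 1]")
        # Trial slots must leave room for the -2/+3 s analysis epoch around
        # movement onset; an inter-trial interval that packs cues closer than
        # that makes epochs overlap and is rejected outright.
        slot = (c.inter_trial_interval + c.reaction_time_mean
                + max(c.movement_duration_by_condition) * 2 + c.hold_time)
        if slot < 5.5:
            raise ValueError(
                "inter_trial_interval too short: trial epochs (-2 to +3 s) overlap")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key, sub in (("beta", BetaParams), ("theta", ThetaParams),
                         ("bursts", BurstParams)):
            if key in d and isinstance(d[key], dict):
                sub_d = {k: tuple(v) if isinstance(v, list) else v
                         for k, v in d[key].items()}
                d[key] = sub(**sub_d)
        for key in ("conditions", "movement_duration_by_condition", "electrodes"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def _as_tuple(x: Sequence[float]) -> tuple[float, ...]:
    return tuple(float(v) for v in x)
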