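"""Bipolar referencing, filtering, epoching and artifact rejection.

Filters are fifth-order Butterworth designs applied forward-backward
(zero phase) so that the timing of event-related power changes and
burst onsets is preserved; the effective order consequently doubles.
Epochs span the closed interval [-2 s, +3 s] around the alignment
event, i.e. 5001 samples at 1 kHz with the event sample at t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

EPOCH_WINDOW = (-2.0, 3.0)
ARTIFACT_MAD_MULT = 6.0       # amplitude threshold: 6 x MAD-based SD
SATURATION_RUN = 10           # consecutive identical samples => rail saturation


def bipolar_montage(contacts: np.ndarray) -> np.ndarray:
    """Adjacent-pair differences of one electrode's monopolar contacts.

    A 4 x n array of monopolar contacts yields the 3 bipolar channels
    01, 12, 23 (contact k minus contact k+1).  A 3 x n array is assumed
    to already be bipolar and passes through unchanged.
    """
    contacts = np.asarray(contacts)
    if contacts.ndim != 2:
        raise ValueError("expected a contacts x samples array")
    if contacts.shape[0] == 3:
        return contacts
    if contacts.shape[0] != 4:
        raise ValueError("an electrode carries 4 monopolar contacts")
    return contacts[:-1] - contacts[1:]


def filter_lfp(data: np.ndarray, sampling_rate: float,
               highpass_hz: float = 1.0,
               notch_band: tuple[float, float] = (48.0, 52.0),
               order: int = 5) -> np.ndarray:
    """High-pass (>1 Hz) plus band-stop (48-52 Hz) Butterworth filtering,
    zero-phase, along the last axis."""
    if sampling_rate < 200.0:
        raise ValueError("sampling rate too low for the 48-52 Hz notch band")
    data = np.asarray(data, dtype=float)
    sos_hp = signal.butter(order, highpass_hz, btype="highpass",
                           fs=sampling_rate, output="sos")
    sos_bs = signal.butter(order, notch_band, btype="bandstop",
                           fs=sampling_rate, output="sos")
    out = signal.sosfiltfilt(sos_hp, data, axis=-1)
    out = signal.sosfiltfilt(sos_bs, out, axis=-1)
    return out


@dataclass
class EpochedLFP:
    """Trials x channels x samples around an alignment event."""

    data: np.ndarray
    times: np.ndarray             # s relative to the alignment event
    alignment: str
    sampling_rate: float
    trial_ids: np.ndarray         # indices into the session's trial list
    kept: np.ndarray              # bool per epoch
    reject_reason: dict = field(default_factory=dict)   # trial_id -> reason
    dropped: dict = field(default_factory=dict)         # trial_id -> reason (no epoch)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def kept_data(self) -> np.ndarray:
        return self.data[self.kept]


def epoch(data: np.ndarray, event_times: np.ndarray, sampling_rate: float,
          alignment: str = "movement_onset",
          window: tuple[float, float] = EPOCH_WINDOW,
          trial_ids: np.ndarray | None = None) -> EpochedLFP:
    """Cut epochs around `event_times` from a channels x samples array.

    Events whose window exceeds the recording bounds are dropped with
    reason ``"edge"``.  The window is a closed interval, so a (-2, +3) s
    window at 1 kHz yields 5001 samples with the event at t = 0.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n = data.shape[1]
    fs = sampling_rate
    pre = int(round(-window[0] * fs))
    post = int(round(window[1] * fs))
    n_samp = pre + post + 1
    event_times = np.asarray(event_times, dtype=float)
    if trial_ids is None:
        trial_ids = np.arange(len(event_times))

    epochs, kept_ids, dropped = [], [], {}
    for tid, t in zip(trial_ids, event_times):
        if not np.isfinite(t):
            dropped[int(tid)] = "no_event"
            continue
        i_ev = int(round(t * fs))
        i0, i1 = i_ev - pre, i_ev + post + 1
        if i0 < 0 or i1 > n:
            dropped[int(tid)] = "edge"
            continue
        epochs.append(data[:, i0:i1])
        kept_ids.append(int(tid))
    if not epochs:
        raise ValueError("no valid trials: every epoch exceeds recording bounds")
    arr = np.stack(epochs)
    times = (np.arange(n_samp) - pre) / fs
    return EpochedLFP(data=arr, times=times, alignment=alignment,
                      sampling_rate=fs, trial_ids=np.array(kept_ids),
                      kept=np.ones(len(kept_ids), dtype=bool),
                      dropped=dropped)


def _has_constant_run(x: np.ndarray, run: int) -> bool:
    """True if any row of x holds >= `run` consecutive identical samples."""
    same = np.diff(x, axis=-1) == 0
    if run <= 1:
        return True
    window = run - 1
    # rolling sum of the boolean diff mask
    cs = np.cumsum(same, axis=-1, dtype=int)
    cs = np.concatenate([np.zeros(same.shape[:-1] + (1,), dtype=int), cs], axis=-1)
    runs = cs[..., window:] - cs[..., :-window]
    return bool(np.any(runs == window))


def reject_artifacts(epochs: EpochedLFP,
                     valid_trials: np.ndarray | None = None,
                     mad_mult: float = ARTIFACT_MAD_MULT,
                     saturation_run: int = SATURATION_RUN) -> EpochedLFP:
    """Flag epochs containing amplitude artifacts, rail saturation, or an
    invalid behavioural trial.  Flags only; nothing is deleted.

    Thresholds are data-relative: the amplitude bound is `mad_mult` times
    the per-channel median-absolute-deviation-based SD over all epochs.
    """
    data = epochs.data
    med = np.median(data, axis=(0, 2), keepdims=True)
    mad_sd = 1.4826 * np.median(np.abs(data - med), axis=(0, 2), keepdims=True)
    amp_bad = np.any(np.abs(data - med) > mad_mult * mad_sd, axis=(1, 2))
    for i, tid in enumerate(epochs.trial_ids):
        reason = None
        if amp_bad[i]:
            reason = "amplitude"
        elif _has_constant_run(data[i], saturation_run):
            reason = "saturation"
        elif valid_trials is not None and int(tid) < len(valid_trials) \
                and not valid_trials[int(tid)]:
            reason = "invalid_trial"
        if reason is not None:
            epochs.kept[i] = False
            epochs.reject_reason[int(tid)] = reason
    return epochs
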