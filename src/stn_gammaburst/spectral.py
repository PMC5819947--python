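"""Morlet time-frequency decomposition and event-related power maps.

Power is computed with complex Morlet wavelets of seven cycles on the
integer frequencies 1..100 Hz, normalised in percent relative to a
pre-movement baseline, optionally smoothed with a separable Gaussian
kernel (FWHM 6 Hz x 200 ms, the SPM convention for "smoothed over"),
and averaged across trials with a bisquare iteratively-reweighted
robust mean.

Samples within one temporal SD of an epoch edge are flagged invalid at
each frequency rather than silently zero-padded.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import fft as sp_fft
from scipy import ndimage

GAMMA_BAND = (40.0, 90.0)
BETA_BAND = (13.0, 30.0)
THETA_BAND = (2.0, 8.0)
BANDS = {"theta": THETA_BAND, "beta": BETA_BAND, "gamma": GAMMA_BAND}
DEFAULT_FREQS = np.arange(1.0, 101.0)
MOVEMENT_WINDOW = (0.0, 0.5)


@dataclass
class TFRMap:
    """Trials x channels x frequencies x times power representation."""

    power: np.ndarray             # float32, trials x channels x freqs x times
    freqs: np.ndarray             # Hz
    times: np.ndarray             # s relative to the alignment event
    sampling_rate: float          # of the time axis (after decimation)
    units: str = "power"          # "power" (a.u.^2) or "percent"
    alignment: str = "movement_onset"
    valid: np.ndarray | None = None   # freqs x times bool, wavelet-edge mask
    baseline: tuple | None = None     # (window, statistic) once normalised

    def copy_with(self, **kw) -> "TFRMap":
        return replace(self, **kw)


def morlet_kernel(freq: float, sampling_rate: float, n_cycles: float = 7.0,
                  n_sd: float = 5.0) -> np.ndarray:
    """Complex Morlet wavelet, unit response to a unit-amplitude tone.

    The Gaussian envelope has SD ``n_cycles / (2*pi*f)`` s; support is
    truncated at +-`n_sd` SD.  The kernel is scaled so that convolution
    with ``A*sin(2*pi*f*t)`` yields magnitude ~= A at the tone frequency.
    """
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(n_sd * sigma_t * sampling_rate))
    t = np.arange(-half, half + 1) / sampling_rate
    env = np.exp(-(t ** 2) / (2.0 * sigma_t ** 2))
    kern = env * np.exp(2j * np.pi * freq * t)
    return kern / (0.5 * env.sum())


def morlet_tfr(data: np.ndarray, sampling_rate: float,
               freqs: np.ndarray = DEFAULT_FREQS, n_cycles: float = 7.0,
               decim: int = 1, alignment: str = "movement_onset",
               times: np.ndarray | None = None) -> TFRMap:
    """Morlet wavelet power of epoched data (trials x channels x samples).

    FFT-based convolution batched over trials and channels; `decim`
    subsamples the time axis of the output (power varies slowly after
    the implicit wavelet smoothing).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[np.newaxis]
    n_tr, n_ch, n = data.shape
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs >= sampling_rate / 2.0):
        raise ValueError("requested frequencies reach or exceed Nyquist")
    if np.any(freqs <= 0):
        raise ValueError("frequencies must be positive")

    kernels = [morlet_kernel(f, sampling_rate, n_cycles).astype(np.complex64)
               for f in freqs]
    max_len = max(len(k) for k in kernels)
    nfft = sp_fft.next_fast_len(n + max_len - 1, real=False)
    flat = data.reshape(n_tr * n_ch, n).astype(np.float32)
    Xf = sp_fft.fft(flat, nfft, axis=-1, workers=-1)

    out_idx = np.arange(0, n, decim)
    power = np.empty((n_tr, n_ch, len(freqs), len(out_idx)), dtype=np.float32)
    valid = np.ones((len(freqs), len(out_idx)), dtype=bool)
    for i, (f, kern) in enumerate(zip(freqs, kernels)):
        Kf = sp_fft.fft(kern, nfft)
        conv = sp_fft.ifft(Xf * Kf, axis=-1, workers=-1)
        start = (len(kern) - 1) // 2          # 'same' alignment
        seg = conv[:, start:start + n][:, out_idx]
        power[:, :, i, :] = (seg.real ** 2 + seg.imag ** 2).reshape(
            n_tr, n_ch, -1)
        sigma_t = n_cycles / (2.0 * np.pi * f)
        edge = int(np.ceil(sigma_t * sampling_rate))
        valid[i] = (out_idx >= edge) & (out_idx < n - edge)

    if times is None:
        times = np.arange(n) / sampling_rate
    times = np.asarray(times, dtype=float)[out_idx]
    return TFRMap(power=power, freqs=freqs, times=times,
                  sampling_rate=sampling_rate / decim, units="power",
                  alignment=alignment, valid=valid)


def baseline_normalize(tfr: TFRMap, baseline: tuple[float, float] = (-2.0, -0.5),
                       statistic: str = "mean", per_trial: bool = False) -> TFRMap:
    """Percent change relative to the baseline window.

    The baseline power B_f is, per channel and frequency, the within-
    window time average, combined across trials with the arithmetic mean
    (default) or the bisquare robust mean.  ``per_trial=True`` keeps a
    separate baseline per trial instead.  Values become
    ``100 * (P - B_f) / B_f``.
    """
    if tfr.units != "power":
        raise ValueError("baseline_normalize expects a raw power map")
    sel = (tfr.times >= baseline[0]) & (tfr.times <= baseline[1])
    if not np.any(sel):
        raise ValueError("baseline window outside epoch support")
    base_t = tfr.power[..., sel].mean(axis=-1)          # trials x ch x freqs
    if not per_trial:
        if statistic == "robust":
            base = robust_average(base_t.astype(float), axis=0)
        elif statistic == "mean":
            base = base_t.mean(axis=0)
        else:
            raise ValueError(f"unknown baseline statistic {statistic!r}")
        base = base[np.newaxis]
    else:
        base = base_t
    if np.any(base <= 0):
        raise ValueError("non-positive baseline power; cannot normalise")
    pct = 100.0 * (tfr.power - base[..., np.newaxis]) / base[..., np.newaxis]
    return tfr.copy_with(power=pct.astype(tfr.power.dtype), units="percent",
                         baseline=(tuple(baseline), statistic))


def smooth_tfr(tfr: TFRMap, fwhm_freq: float = 6.0,
               fwhm_time: float = 0.2) -> TFRMap:
    """Separable 2-D Gaussian smoothing over frequency and time.

    Full widths at half maximum are given in Hz and seconds; the kernel
    has unit mass and edges are handled by renormalised truncation, so a
    constant map passes through unchanged.
    """
    df = np.median(np.diff(tfr.freqs))
    dt = np.median(np.diff(tfr.times))
    to_sd = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    sigma = (fwhm_freq * to_sd / df, fwhm_time * to_sd / dt)
    sm = np.empty_like(tfr.power)
    norm = ndimage.gaussian_filter(np.ones(tfr.power.shape[-2:]), sigma,
                                   mode="constant")
    for i in range(tfr.power.shape[0]):
        for j in range(tfr.power.shape[1]):
            sm[i, j] = ndimage.gaussian_filter(
                tfr.power[i, j].astype(float), sigma, mode="constant") / norm
    return tfr.copy_with(power=sm)


def robust_average(values: np.ndarray, axis: int = 0, c: float = 4.685,
                   max_iter: int = 20, tol: float = 1e-6) -> np.ndarray:
    """Bisquare iteratively-reweighted mean along `axis`.

    Residual scale is the median absolute deviation (x 1.4826); elements
    whose scale is zero fall back to the arithmetic mean.  Down-weights
    outlier trials instead of letting them dominate the average.
    """
    x = np.moveaxis(np.asarray(values, dtype=float), axis, 0)
    mu = np.median(x, axis=0)
    resid0 = np.abs(x - mu)
    scale = 1.4826 * np.median(resid0, axis=0)
    # MAD degenerates when >50% of trials are identical; fall back to the
    # residual SD there (exact mean only when every residual is zero)
    sd = resid0.std(axis=0)
    scale = np.where(scale <= 0, sd, scale)
    degenerate = scale <= 0
    scale = np.where(degenerate, 1.0, scale)
    for _ in range(max_iter):
        r = (x - mu) / (c * scale)
        w = np.where(np.abs(r) < 1, (1 - r ** 2) ** 2, 0.0)
        wsum = w.sum(axis=0)
        new = np.where(wsum > 0, (w * x).sum(axis=0) / np.where(wsum > 0, wsum, 1.0),
                       mu)
        if np.max(np.abs(new - mu)) <= tol * (1.0 + np.max(np.abs(mu))):
            mu = new
            break
        mu = new
    return np.where(degenerate, x.mean(axis=0), mu)


def realign(tfr: TFRMap, from_times: np.ndarray, to_times: np.ndarray,
            alignment: str = "max_velocity") -> TFRMap:
    """Shift each trial's time axis so t=0 is a new per-trial landmark.

    `from_times` / `to_times` are the absolute times (s) of the current
    and requested landmarks per trial.  Trials with a missing landmark
    are dropped; the output is cropped to the common valid support.
    """
    shifts = np.asarray(to_times, dtype=float) - np.asarray(from_times, dtype=float)
    keep = np.isfinite(shifts)
    power = tfr.power[keep]
    shifts = shifts[keep]
    dt = 1.0 / tfr.sampling_rate
    shift_bins = np.round(shifts / dt).astype(int)
    n_t = power.shape[-1]
    lo = int(shift_bins.max())
    hi = int(shift_bins.min())
    new_len = n_t - (lo - hi)
    if new_len <= 0:
        raise ValueError("no common time support after realignment")
    out = np.empty(power.shape[:-1] + (new_len,), dtype=power.dtype)
    for k, s in enumerate(shift_bins):
        start = s - hi
        out[k] = power[k, ..., start:start + new_len]
    # trial k's sample j sits at original index j + s_k - hi, i.e. at time
    # times[0] + (j + s_k - hi)*dt - s_k*dt relative to the new landmark
    new_times = tfr.times[0] - hi * dt + np.arange(new_len) * dt
    return tfr.copy_with(power=out, times=new_times, alignment=alignment,
                         valid=None)


def band_power(tfr: TFRMap, band: tuple[float, float] = GAMMA_BAND,
               window: tuple[float, float] = MOVEMENT_WINDOW) -> np.ndarray:
    """Mean percent change over a band x window box, per trial and channel."""
    fsel = (tfr.freqs >= band[0]) & (tfr.freqs <= band[1])
    tsel = (tfr.times >= window[0]) & (tfr.times <= window[1])
    if not np.any(fsel) or not np.any(tsel):
        raise ValueError("band/window box outside map support")
    box = tfr.power[:, :, fsel][..., tsel]
    return box.mean(axis=(-2, -1))


def hierarchical_average(values: np.ndarray, channel_groups: np.ndarray) -> float:
    """Average contact pairs -> electrode/hemisphere -> subject, in that
    order (unequal group sizes make the order matter)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(channel_groups)
    per_group = [values[groups == g].mean() for g in np.unique(groups)]
    return float(np.mean(per_group))
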