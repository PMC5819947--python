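"""End-to-end study orchestration on synthetic sessions.

`run_study` composes the full analysis for a group of simulated
subjects: simulate -> kinematic landmarks -> preprocess -> time-
frequency band summaries -> gamma-burst statistics, for both medication
states and all three movement conditions, following the averaging
hierarchy contact pairs -> electrode/hemisphere -> subject.  The report
is a set of tidy tables plus a manifest (config hash, seeds) so every
number is traceable to a stage output and a seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from scipy import signal as sp_signal

from . import bursts as bm
from . import spectral as sp
from .config import SimConfig
from .fixtures import EXCLUSION_REASONS, load_table1, load_localization
from .kinematics import extract_trials
from .preprocess import epoch, filter_lfp, reject_artifacts
from .simulate import SessionRecording, generate_session

CONDITION_NAMES = {30.0: "small", 60.0: "medium", 90.0: "large"}


def config_hash(config: SimConfig) -> str:
    payload = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# per-session analyses
# ---------------------------------------------------------------------------

def relative_movement_spectrum(data: np.ndarray, sampling_rate: float,
                               onsets: np.ndarray,
                               movement: tuple[float, float] = (0.0, 0.5),
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Movement-window power spectrum as percent change over the 1/f
    background, averaged over trials and channels.

    The aperiodic background is a log-log linear fit to the movement
    spectrum outside the gamma band and the notch region; normalising by
    it isolates the narrowband gamma bump whose maximum defines the
    subject-level gamma peak frequency.  (Normalising by the pre-movement
    baseline spectrum instead would divide out most of the bump, because
    gamma bursts occur during baseline as well -- only their rate
    changes with movement.)
    """
    data = np.atleast_2d(data)
    fs = sampling_rate
    nseg = int(round((movement[1] - movement[0]) * fs))
    segs = []
    for t in onsets:
        if not np.isfinite(t):
            continue
        i0 = int(round((t + movement[0]) * fs))
        if i0 < 0 or i0 + nseg > data.shape[1]:
            continue
        segs.append(data[:, i0:i0 + nseg])
    if not segs:
        raise ValueError("no usable windows for spectrum")
    arr = np.stack(segs)                      # trials x ch x nseg
    freqs, p = sp_signal.periodogram(arr, fs=fs, axis=-1,
                                     window="hann", detrend="constant")
    p_mov = p.mean(axis=(0, 1))
    # aperiodic slope fitted above the gamma bump and extrapolated down;
    # the low-frequency side is avoided because theta/beta peaks sit there
    fit_mask = (((freqs >= 24) & (freqs <= 38)) |
                ((freqs >= 110) & (freqs <= 240)))
    coef = np.polyfit(np.log10(freqs[fit_mask]), np.log10(p_mov[fit_mask]), 1)
    background = 10 ** np.polyval(coef, np.log10(np.maximum(freqs, freqs[1])))
    # background-subtracted bump in percent of the band-centre background:
    # subtracting (rather than dividing by) the sloped background keeps the
    # bump's maximum at its true centre frequency
    centre = background[np.argmin(np.abs(freqs - 65.0))]
    rel = 100.0 * (p_mov - background) / centre
    return freqs, rel


def analyze_session_bursts(recording: SessionRecording,
                           trials: pd.DataFrame | None = None,
                           thresholds: dict | None = None,
                           percentile: float = bm.THRESHOLD_PERCENTILE) -> dict:
    """Gamma-burst detection and statistics per electrode.

    `thresholds` maps electrode id -> threshold; when given (the
    matched ON-state thresholds) they are applied instead of computing
    OFF-derived ones.
    """
    fs = recording.sampling_rate
    if trials is None:
        trials = extract_trials(recording)
    onsets = trials.loc[trials["valid"], "movement_onset"].to_numpy()
    conds = trials.loc[trials["valid"], "condition"].to_numpy()

    # line-noise removal before the gamma band-pass: 50 Hz sits inside
    # the 40-90 Hz band and would otherwise inflate every envelope
    filtered = filter_lfp(recording.lfp, fs)
    env = bm.gamma_envelope(filtered, fs)
    out = {}
    for el, grp in recording.channel_table.groupby("electrode", sort=False):
        idx = grp.index.to_numpy()
        names = grp["name"].tolist()
        thr = (thresholds[el] if thresholds is not None
               else bm.electrode_threshold(env[idx], percentile))
        freqs, rel = relative_movement_spectrum(filtered[idx], fs, onsets)
        # light spectral smoothing stabilises the peak against
        # single-periodogram noise (3 Hz Gaussian on the 2 Hz grid)
        rel_smooth = ndimage.gaussian_filter1d(rel, 1.5)
        peak_hz, has_peak = bm.gamma_peak_frequency(rel_smooth, freqs)
        burst_set = bm.detect_bursts(env[idx], thr, peak_hz, fs,
                                     channel_names=names)
        stats_all = bm.burst_stats(burst_set, onsets)
        stats_by_cond = {}
        for c in np.unique(conds):
            # pooled session-wide baseline: pre-cue activity carries no
            # condition effect, so the shared baseline cancels in contrasts
            stats_by_cond[float(c)] = bm.burst_stats(
                burst_set, onsets[conds == c], baseline_onset_times=onsets)
        out[el] = {"threshold": thr, "peak_frequency": peak_hz,
                   "has_peak": has_peak, "burst_set": burst_set,
                   "stats": stats_all, "stats_by_condition": stats_by_cond,
                   "hemisphere": grp["hemisphere"].iloc[0]}
    return out


def session_tfr(recording: SessionRecording, trials: pd.DataFrame,
                align: str = "movement_onset", decim: int = 10,
                baseline: tuple[float, float] = (-2.0, -1.0),
                smooth: bool = True) -> tuple[sp.TFRMap, pd.DataFrame]:
    """Filtered, epoched, baselined (and optionally smoothed) percent-change
    TFR of the kept trials, plus the matching trial rows."""
    fs = recording.sampling_rate
    col = {"movement_onset": "movement_onset",
           "max_velocity": "max_velocity_time",
           "max_amplitude": "max_amplitude_time"}[align]
    data = filter_lfp(recording.lfp, fs)
    ep = epoch(data, trials[col].to_numpy(), fs, alignment=align,
               trial_ids=trials["trial_id"].to_numpy())
    ep = reject_artifacts(ep, trials["valid"].to_numpy())
    kept_ids = ep.trial_ids[ep.kept]
    tfr = sp.morlet_tfr(ep.data[ep.kept], fs, decim=decim, alignment=align,
                        times=ep.times)
    tfr = sp.baseline_normalize(tfr, baseline=baseline)
    if smooth:
        tfr = sp.smooth_tfr(tfr)
    kept_trials = trials.set_index("trial_id").loc[kept_ids].reset_index()
    return tfr, kept_trials


def band_summaries(tfr: sp.TFRMap, trials: pd.DataFrame,
                   channel_table: pd.DataFrame,
                   window: tuple[float, float] = sp.MOVEMENT_WINDOW
                   ) -> pd.DataFrame:
    """Mean percent change per condition, electrode role and band, robust-
    averaged across trials and averaged across a role's contact pairs."""
    rows = []
    for band_name, band in sp.BANDS.items():
        bp = sp.band_power(tfr, band=band, window=window)   # trials x channels
        for cond in np.unique(trials["condition"]):
            sel = (trials["condition"] == cond).to_numpy()
            per_ch = sp.robust_average(bp[sel], axis=0)
            for el, grp in channel_table.groupby("electrode", sort=False):
                rows.append({
                    "condition": float(cond),
                    "condition_name": CONDITION_NAMES.get(float(cond), str(cond)),
                    "role": el, "band": band_name,
                    "percent_change": float(per_ch[grp.index.to_numpy()].mean()),
                })
    return pd.DataFrame(rows)


def velocity_maps(recording: SessionRecording, trials: pd.DataFrame,
                  decim: int = 10, role: str = "contra",
                  align: str = "max_velocity",
                  smooth: bool = True) -> tuple[np.ndarray, np.ndarray, sp.TFRMap]:
    """Single-trial percent-change maps around a movement landmark,
    averaged over one electrode's contact pairs, with the matching trial
    peak velocities -- the input to the power-velocity correlation map.

    Smoothing matters here: it roughly triples the per-bin single-trial
    correlation by averaging out background power fluctuations."""
    tfr, kept = session_tfr(recording, trials, align=align,
                            decim=decim, smooth=smooth)
    idx = recording.channel_table.index[
        recording.channel_table["role"] == role].to_numpy()
    maps = tfr.power[:, idx].mean(axis=1)       # trials x F x T
    velocities = kept["max_velocity"].to_numpy()
    return maps, velocities, tfr


# ---------------------------------------------------------------------------
# study orchestration
# ---------------------------------------------------------------------------

@dataclass
class StudyReport:
    band_table: pd.DataFrame
    burst_table: pd.DataFrame
    kinematics_table: pd.DataFrame
    clinical_summary: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def run_study(config: SimConfig, seeds: list[int], states: tuple[str, ...] = ("ON", "OFF"),
              include_tfr: bool = True, decim: int = 10) -> StudyReport:
    """Run the full study analogue for one simulated subject per seed."""
    if not seeds:
        raise ValueError("need at least one seed")
    seeds = sorted(int(s) for s in seeds)
    band_rows, burst_rows, kin_rows = [], [], []
    for seed in seeds:
        on_thresholds = None
        for state in states:
            cfg = replace(config, state=state, seed=seed)
            rec, _ = generate_session(cfg)
            trials = extract_trials(rec)
            for _, tr in trials.iterrows():
                kin_rows.append({"patient": seed, "state": state, **{
                    k: tr[k] for k in ("trial_id", "condition", "reaction_time",
                                       "max_velocity", "max_amplitude",
                                       "accuracy", "valid")}})
            res = analyze_session_bursts(
                rec, trials, thresholds=on_thresholds if state == "OFF" else None)
            if state == "ON":
                on_thresholds = {el: r["threshold"] for el, r in res.items()}
            for el, r in res.items():
                for cond, st in r["stats_by_condition"].items():
                    burst_rows.append({
                        "patient": seed, "state": state, "role": el,
                        "condition": cond,
                        "condition_name": CONDITION_NAMES.get(cond, str(cond)),
                        "rate_baseline": st.rate.get("baseline"),
                        "rate_movement": st.rate.get("movement"),
                        "rate_change_pct": st.relative_change["rate"],
                        "amplitude_change_pct": st.relative_change["amplitude"],
                        "duration_change_pct": st.relative_change["duration"],
                        "peak_frequency": r["peak_frequency"],
                    })
            if include_tfr:
                tfr, kept = session_tfr(rec, trials, decim=decim)
                bt = band_summaries(tfr, kept, rec.channel_table)
                bt.insert(0, "patient", seed)
                bt.insert(1, "state", state)
                band_rows.append(bt)
    band_table = (pd.concat(band_rows, ignore_index=True)
                  if band_rows else pd.DataFrame())
    report = StudyReport(
        band_table=band_table,
        burst_table=pd.DataFrame(burst_rows),
        kinematics_table=pd.DataFrame(kin_rows),
        clinical_summary=summarize_clinical(load_table1()),
        manifest={"config_hash": config_hash(config), "seeds": seeds,
                  "states": list(states)},
    )
    return report


def filter_contact_pairs(localization: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Drop contact pairs flagged as outside the subthalamic nucleus."""
    loc = localization.copy()
    bad_reason = ~loc["exclusion_reason"].isin(("",) + EXCLUSION_REASONS)
    if bad_reason.any():
        raise ValueError(
            f"unknown exclusion reason(s): {loc.loc[bad_reason, 'exclusion_reason'].unique()}")
    if ((loc["in_stn"] == 0) != (loc["exclusion_reason"] != "")).any():
        raise ValueError("every excluded pair needs exactly one reason")
    kept = loc[loc["in_stn"] == 1].reset_index(drop=True)
    counts = {
        "total": int(len(loc)),
        "kept": int(len(kept)),
        "excluded": int((loc["in_stn"] == 0).sum()),
        "kept_pct": 100.0 * len(kept) / len(loc),
        "by_reason": loc.loc[loc["in_stn"] == 0, "exclusion_reason"]
                        .value_counts().to_dict(),
    }
    return kept, counts


def summarize_clinical(table: pd.DataFrame) -> pd.DataFrame:
    """Column means over available entries, with n reported per column.
    Missing entries stay missing; nothing is imputed."""
    rows = []
    for col in table.columns:
        if not pd.api.types.is_numeric_dtype(table[col]) or col == "case":
            continue
        vals = table[col].dropna()
        rows.append({"column": col, "mean": float(vals.mean()),
                     "n": int(len(vals)), "n_missing": int(table[col].isna().sum())})
    return pd.DataFrame(rows)


def write_report(report: StudyReport, out_dir) -> None:
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.band_table.to_csv(out / "bands.tsv", sep="\t", index=False)
    report.burst_table.to_csv(out / "burst_stats.tsv", sep="\t", index=False)
    report.kinematics_table.to_csv(out / "trials.tsv", sep="\t", index=False)
    report.clinical_summary.to_csv(out / "clinical_summary.tsv", sep="\t", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(report.manifest, fh, indent=2, sort_keys=True)
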