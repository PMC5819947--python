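"""Extract kinematic landmarks from the simulated sessions.

Reads the containers written by 01_simulate_sessions.py (regenerating
them if absent), writes one row per trial to results/02_trials.tsv and
prints the behavioural summary: reaction times and the stepwise increase
of peak velocity across the three movement amplitudes.
"""

import argparse
from dataclasses import replace
from pathlib import Path

import pandas as pd

from stn_gammaburst import SimConfig, generate_session, read_session
from stn_gammaburst.kinematics import extract_trials

ROOT = Path(__file__).resolve().parents[1]


def load_or_simulate(seed: int, state: str):
    dest = ROOT / "scratch" / "sessions" / f"sub{seed}_{state}"
    if dest.exists():
        return read_session(dest)
    cfg = replace(SimConfig(), state=state, seed=seed)
    return generate_session(cfg)[0]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    frames = []
    for state in ("ON", "OFF"):
        rec = load_or_simulate(args.seed, state)
        trials = extract_trials(rec)
        trials.insert(0, "state", state)
        frames.append(trials)
        summary = trials.groupby("condition").agg(
            rt=("reaction_time", "mean"), vmax=("max_velocity", "mean"),
            acc=("accuracy", "mean"), valid=("valid", "sum"))
        print(f"[02] {state}: {trials['valid'].sum()}/{len(trials)} valid trials")
        for cond, row in summary.iterrows():
            print(f"     {cond:5.0f} deg: RT {row['rt']*1000:.0f} ms, "
                  f"peak velocity {row['vmax']:.0f} deg/s, accuracy dev {row['acc']:.1f}%")
    args.out.mkdir(parents=True, exist_ok=True)
    pd.concat(frames, ignore_index=True).to_csv(
        args.out / "02_trials.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
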