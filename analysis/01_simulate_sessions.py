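"""Generate one simulated subject's ON and OFF sessions and persist them.

Writes the two session containers under scratch/sessions/ and a summary
row per session to results/01_sessions.tsv.
"""

import argparse
from dataclasses import replace
from pathlib import Path

import pandas as pd

from stn_gammaburst import SimConfig, generate_session, write_session

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    rows = []
    for state in ("ON", "OFF"):
        cfg = replace(SimConfig(), state=state, seed=args.seed)
        rec, truth = generate_session(cfg)
        dest = ROOT / "scratch" / "sessions" / f"sub{args.seed}_{state}"
        write_session(rec, dest, config=cfg)
        n_bursts = sum(len(df) for df in truth.burst_events.values())
        rows.append({
            "seed": args.seed, "state": state, "duration_s": rec.duration,
            "n_channels": rec.n_channels, "n_trials": len(rec.cue_times),
            "injected_bursts": n_bursts,
            "mean_true_peak_velocity": truth.true_peak_velocities.mean(),
            "container": str(dest.relative_to(ROOT)),
        })
        print(f"[01] {state}: {rec.duration:.0f} s, {len(rec.cue_times)} trials, "
              f"{n_bursts} injected bursts -> {dest}")
    args.out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(args.out / "01_sessions.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
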