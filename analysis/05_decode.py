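"""Single-trial decoding of reach direction, low vs high uncertainty.

Decodes every uncertainty trial from PD-binned baseline-subtracted activity
in four 200 ms windows spanning target appearance to movement, scores each
session/window/condition by one minus the circular variance of the decode
errors, and runs the paired low-vs-high comparison across sessions.  Writes
results/decode_results.csv and results/decode_comparisons.csv.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from reachunc.pipeline import run_study_decoding
from reachunc.session_io import read_session, write_results

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--sessions", type=Path, default=Path("results/sessions"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

sessions = [
    read_session(d / "trials.csv", d / "spikes.csv", d / "neurons.csv")
    for d in sorted(p for p in args.sessions.iterdir() if p.is_dir())
]

results, comparisons = run_study_decoding(sessions, n_boot_tuning=150, seed=args.seed)
rows = [
    dict(session_id=r.session_id, window=r.window.name, condition=r.condition,
         n_trials=r.n_trials, performance=r.performance, included=r.included)
    for r in results
]
write_results(pd.DataFrame(rows), args.out / "decode_results.csv", {"seed": args.seed})

comp_rows = []
for wname in sorted(comparisons):
    comp = comparisons[wname]
    if comp is None:
        continue
    comp_rows.append(dict(window=wname, mean_low_minus_high=comp[0],
                          p=comp[1], n_sessions=comp[2]))
    print(f"{wname}: low-high performance {comp[0]:+.3f} (p={comp[1]:.3g}, "
          f"n={comp[2]} sessions)")
write_results(pd.DataFrame(comp_rows), args.out / "decode_comparisons.csv",
              {"seed": args.seed})
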