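#!/usr/bin/env python
"""Single-trial EEG analysis: epochs, robust first-level maps, group maps.

For every cohort subject, generates feedback-locked epochs (planted FRN/P3
modulations from the cohort provenance, fitted trial-wise RPEs from
02_fit_models), runs the preprocessing chain (fast-response filter, adaptive
artifact rejection, baseline correction) and the Huber single-trial
regression, both with the full transition x RPE design and within each
transition type.  Writes group t/p/FDR maps at FCz and Cz, the FRN/P3
component windows found on the grand average, and per-subject window-mean
RPE b values for the second level.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from twostep_eeg import cohort as ch
from twostep_eeg import firstlevel as fl
from twostep_eeg.experiments import simulate_cohort_behavior
from twostep_eeg.task import TaskConfig, read_behavior_csv


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=3)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    coh = pd.read_csv(args.out / "cohort.csv")
    behaviors = {b.subject_id: b for b in read_behavior_csv(args.out / "behavior.csv")}
    rpe = pd.read_csv(args.out / "rpe.csv")
    spec = ch.CohortSpec(n_subjects=len(coh))
    rng = np.random.default_rng(args.seed)

    full_maps, maps = [], {"common": [], "rare": []}
    ga_sum = None
    log = []
    for _, row in coh.iterrows():
        b = behaviors[row["subject_id"]]
        r = rpe.loc[rpe.subject_id == row["subject_id"], "rpe"].to_numpy()
        ep = ch.generate_eeg_epochs(b.trials, r, row, spec, rng)
        ep, n_fast = fl.drop_fast_response_trials(ep)
        ep, removed, th = fl.adaptive_artifact_rejection(ep)
        ep = fl.baseline_correct(ep)
        log.append({"subject_id": row["subject_id"], "n_fast_removed": n_fast,
                    "n_artifacts_removed": len(removed), "final_threshold": th})
        ga_sum = ep.data.mean(0) if ga_sum is None else ga_sum + ep.data.mean(0)
        full_maps.append(fl.robust_regress_trials(ep))
        for s in maps:
            maps[s].append(fl.robust_regress_trials(ep, subset=s))
    pd.DataFrame(log).to_csv(args.out / "eeg_processing_log.csv", index=False)

    ga = ga_sum / len(coh)
    windows = fl.find_component_windows(ga, list(spec.channels), full_maps[0].times)
    (args.out / "component_windows.json").write_text(json.dumps(
        {k: {"channel": w.channel, "peak_ms": w.peak_ms, "window": w.window}
         for k, w in windows.items()}, indent=2))

    rows = []
    for reg in ("transition", "rpe", "transition_x_rpe"):
        gm = fl.group_tmap(full_maps, reg)
        for ci, chan in enumerate(gm.channels):
            rows.append(pd.DataFrame({"regressor": reg, "channel": chan,
                                      "time_ms": gm.times, "t": gm.t[ci],
                                      "p_fdr": gm.p_fdr[ci], "sig": gm.mask[ci]}))
    pd.concat(rows).to_csv(args.out / "group_tmaps.csv", index=False)

    wb = []
    for comp, win in windows.items():
        for s in maps:
            for bm in maps[s]:
                wb.append({"subject_id": bm.subject_id, "component": comp,
                           "transition": s,
                           "mean_b_rpe": fl.mean_b_in_window(bm, win, "rpe")})
    pd.DataFrame(wb).to_csv(args.out / "windowed_b.csv", index=False)

    print(f"processed {len(coh)} subjects "
          f"(mean artifacts removed: {np.mean([l['n_artifacts_removed'] for l in log]):.1f})")
    for k, w in windows.items():
        print(f"  {k}: peak {w.peak_ms:.0f} ms at {w.channel}, window {w.window}")
    tm = pd.concat(rows)
    for reg in ("transition", "rpe"):
        sig = tm[(tm.regressor == reg) & tm.sig]
        print(f"  {reg}: {len(sig)} FDR-significant (channel, time) points")
    print(f"wrote {args.out}/group_tmaps.csv, component_windows.json, windowed_b.csv")


if __name__ == "__main__":
    main()
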