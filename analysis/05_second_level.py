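#!/usr/bin/env python
"""Trait moderation of RPE-related EEG effects (second-level regressions).

Regresses each subject's window-mean RPE b value (FRN at FCz, P3 at Cz;
common and rare trials separately) on z-scored BIS-11, OCI-R and the fitted
model-based weight w with all interactions (robust regression), follows up
BIS x w interactions with median-split fits, and compares coefficient pairs
with z-tests.  Writes a Table-2-shaped CSV plus follow-up and z-test CSVs.
"""

import argparse
from pathlib import Path

import pandas as pd

from twostep_eeg import secondlevel as sl


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    wb = pd.read_csv(args.out / "windowed_b.csv")
    coh = pd.read_csv(args.out / "cohort.csv").set_index("subject_id")
    fits = pd.read_csv(args.out / "fits.csv").set_index("subject_id")

    results = []
    for (comp, trans), g in wb.groupby(["component", "transition"]):
        g = g.set_index("subject_id")
        ids = g.index
        res = sl.second_level_regression(
            g["mean_b_rpe"], coh.loc[ids, "bis_z"], coh.loc[ids, "oci_z"],
            fits.loc[ids, "w"], component=comp, transition_type=trans,
            min_subjects=min(20, len(ids)))
        results.append(res)
    table = sl.second_level_table(results)
    table.to_csv(args.out / "second_level.csv", index=False)

    print("second-level robust regressions (fitted w as model-basedness):")
    for res in results:
        for term in ("w", "oci"):
            c = res.coef(term)
            star = "*" if c["p"] < 0.05 else " "
            print(f"  {res.component:3s} {res.transition_type:6s} {term:3s} "
                  f"b={c['beta']:6.3f} se={c['se']:.3f} p={c['p']:.3f}{star}")

    # median-split follow-ups of the BIS x w interaction, FRN common trials
    frn = wb.query("component=='FRN' and transition=='common'").set_index("subject_id")
    ids = frn.index
    split = sl.median_split_followup(frn["mean_b_rpe"], coh.loc[ids, "bis_z"],
                                     fits.loc[ids, "w"],
                                     split_on="bis", predictor="w", min_group=5)
    split.to_csv(args.out / "median_split_followup.csv", index=False)
    lo, hi = split.iloc[0], split.iloc[1]
    z, p = sl.compare_coefficients_z(lo["beta"], lo["se"], hi["beta"], hi["se"])
    pd.DataFrame([{"comparison": "w slope, low vs high BIS (FRN common)",
                   "z": z, "p": p}]).to_csv(args.out / "coefficient_ztests.csv",
                                            index=False)
    print(f"w slope on FRN (common): low-BIS {lo['beta']:.2f} vs "
          f"high-BIS {hi['beta']:.2f} (z={z:.2f}, p={p:.3f})")
    print(f"wrote {args.out}/second_level.csv, median_split_followup.csv, "
          "coefficient_ztests.csv")


if __name__ == "__main__":
    main()
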