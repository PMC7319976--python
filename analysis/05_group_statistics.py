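"""Compare the simulated young and old groups, metric by metric.

Technical replicates (images) are averaged to one value per mouse; groups
are compared with two-tailed pooled-variance t-tests; percent changes are
reported as reductions relative to the young group.  Also recomputes the
published worked examples directly from the printed group means.  Writes
results/comparisons.csv and results/worked_examples.csv.

Usage: python analysis/05_group_statistics.py
"""

from pathlib import Path

import pandas as pd

from lungmorph.stats import compare_groups, percent_change, round_percent

ROOT = Path(__file__).resolve().parents[1]

PRINTED_MEANS = [
    ("bronchiole_whole_area_um2", 33096.0, 25308.0),
    ("type1_density_per_mm2", 9453.0, 6279.0),
    ("bronchiole_diameter_um", 243.0, 217.0),
    ("club_edu_pct", 17.7, 10.7),
    ("ciliated_edu_pct", 13.5, 8.6),
    ("lumen_area_um2", 20207.0, 15587.0),
]


def _long_frames():
    res = ROOT / "results"
    frames = []

    par = pd.read_csv(res / "parenchyma.csv")
    for metric in ("lm_um", "tissue_density", "airspace_area_fraction"):
        frames.append(par[["group", "mouse_id", metric]].rename(columns={metric: "value"})
                      .assign(metric=metric))

    bro = pd.read_csv(res / "bronchioles.csv")
    for metric in ("whole_area_um2", "lumen_area_um2", "wall_area_um2",
                   "whole_feret_um", "lumen_feret_um", "wall_thickness_um",
                   "circ_whole", "circ_lumen"):
        frames.append(bro[["group", "mouse_id", metric]].rename(columns={metric: "value"})
                      .assign(metric="bronchiole_" + metric))

    cells = pd.read_csv(res / "cells_fields.csv")
    for ctype, sub in cells.groupby("cell_type"):
        frames.append(sub[["group", "mouse_id", "density"]].rename(columns={"density": "value"})
                      .assign(metric=f"{ctype}_density"))
        edu = sub.dropna(subset=["edu_pct"])
        frames.append(edu[["group", "mouse_id", "edu_pct"]].rename(columns={"edu_pct": "value"})
                      .assign(metric=f"{ctype}_edu_pct"))
    return pd.concat(frames, ignore_index=True)


def main():
    df = _long_frames()
    comparisons = compare_groups(df, variant="pooled")
    out = ROOT / "results" / "comparisons.csv"
    comparisons.to_csv(out, index=False)
    print(f"compared {len(comparisons)} metrics -> {out}\n")
    show = comparisons[["metric", "mean_young", "mean_old",
                        "percent_change_rounded", "p_two_tailed"]]
    print(show.round(3).to_string(index=False))

    worked = pd.DataFrame(
        [dict(metric=m, mean_young=y, mean_old=o,
              percent_change=percent_change(y, o),
              reported_pct=round_percent(percent_change(y, o)))
         for m, y, o in PRINTED_MEANS]
    )
    worked.to_csv(ROOT / "results" / "worked_examples.csv", index=False)
    print("\npublished worked examples (reduction %, from printed group means):")
    print(worked[["metric", "reported_pct"]].to_string(index=False))


if __name__ == "__main__":
    main()
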