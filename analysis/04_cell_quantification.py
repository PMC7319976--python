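"""Classify and quantify IF cells in the simulated study fields.

Alveolar fields: Type II (peri-nuclear Lamp3) and Type I (nuclear Hopx)
cells, normalised to the same mouse's mean alveolar tissue density from
the parenchyma measurements.  Bronchiolar fields: club (CC10) and ciliated
(acetylated tubulin) cells per mm of basement membrane.  EdU status per
nucleus throughout.  Writes results/cells_fields.csv (one row per field
and cell type).

Usage: python analysis/04_cell_quantification.py
"""

from pathlib import Path

import pandas as pd

from lungmorph import classify_cells, quantify_field
from lungmorph import io as lio

ROOT = Path(__file__).resolve().parents[1]


def main():
    res = ROOT / "results"
    manifest = pd.read_csv(res / "study" / "manifest.csv")
    parenchyma = pd.read_csv(res / "parenchyma.csv")
    mouse_density = parenchyma.groupby("mouse_id").tissue_density.mean()

    rows = []
    for rec in manifest[manifest.kind.str.startswith("if_")].itertuples():
        field = lio.read_if_field(ROOT / "scratch" / "study" / rec.file)
        records = classify_cells(field)
        if field.compartment == "alveolar":
            q = quantify_field(records, field, tissue_density=mouse_density[rec.mouse_id])
        else:
            q = quantify_field(records, field)
        for ctype in q.counts:
            rows.append(dict(
                group=rec.group, mouse_id=rec.mouse_id, image_id=field.image_id,
                compartment=field.compartment, cell_type=ctype,
                count=q.counts[ctype], edu_count=q.edu_counts[ctype],
                density=q.densities[ctype], edu_pct=q.edu_fractions[ctype],
                tissue_density=q.tissue_density, bm_length_mm=q.bm_length_mm,
            ))
    df = pd.DataFrame(rows)
    out = res / "cells_fields.csv"
    df.to_csv(out, index=False)

    print(f"quantified {df.image_id.nunique()} fields -> {out}")
    print(df.groupby(["group", "cell_type"])[["density", "edu_pct"]].mean().round(1).to_string())


if __name__ == "__main__":
    main()
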