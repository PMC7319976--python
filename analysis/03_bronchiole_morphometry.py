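"""Measure bronchiole morphometry on every simulated cross-section.

Detects bronchioles in the 100-500 µm Feret window, delineates the inner
and outer epithelial limits, and reports whole/lumen/wall areas, Feret
diameters, circularities and mean wall thickness.  Writes
results/bronchioles.csv (one row per bronchiole).

Usage: python analysis/03_bronchiole_morphometry.py
"""

from pathlib import Path

import pandas as pd

from lungmorph import io as lio
from lungmorph import segment_tissue
from lungmorph.bronchioles import analyze_bronchioles

ROOT = Path(__file__).resolve().parents[1]


def main():
    manifest = pd.read_csv(ROOT / "results" / "study" / "manifest.csv")
    sections = manifest[manifest.kind == "bronchiole"]
    frames = []
    for rec in sections.itertuples():
        img = lio.read_image(ROOT / "scratch" / "study" / rec.file, rec.pixel_size)
        df = analyze_bronchioles(segment_tissue(img), image_id=img.source_id)
        df.insert(0, "group", rec.group)
        df.insert(1, "mouse_id", rec.mouse_id)
        frames.append(df)
    df = pd.concat(frames, ignore_index=True)
    out = ROOT / "results" / "bronchioles.csv"
    df.to_csv(out, index=False)

    cols = ["whole_area_um2", "lumen_area_um2", "wall_area_um2",
            "whole_feret_um", "wall_thickness_um"]
    print(f"measured {len(df)} bronchioles -> {out}")
    print(df.groupby("group")[cols].mean().round(1).to_string())


if __name__ == "__main__":
    main()
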