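"""Simulate the two-group aging study on synthetic histology.

Builds a young (3-month) and an old (22-month) group of 4 mice each.  Every
mouse gets mouse-level metric values drawn from the published group means
and between-mouse SDs, and those values parameterise its synthetic images:

* 2 parenchyma sections (closed elliptical airspaces at the mouse's mean
  airspace Feret and tissue density),
* 1 bronchiole cross-section (annulus at the mouse's diameter and wall),
* 1 alveolar IF field (Type II/I densities and EdU fractions),
* 1 bronchiolar IF field (club/ciliated densities and EdU fractions).

Images go to scratch/study/ (regenerable); the ground-truth tables and the
image manifest go to results/study/.

Usage: python analysis/01_simulate_study.py [--seed 1]
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from lungmorph import io as lio
from lungmorph.synth import (
    BronchioleSpec,
    IFFieldSpec,
    ParenchymaSpec,
    generate_bronchiole,
    generate_if_field,
    generate_parenchyma,
)

ROOT = Path(__file__).resolve().parents[1]

# published group means and between-mouse SDs (young, old)
GROUP_PARAMS = {
    "lm_um": ((44.0, 0.4), (46.0, 3.0)),
    "tissue_density": ((0.63, 0.12), (0.56, 0.06)),
    "bronchiole_feret_um": ((243.0, 14.0), (217.0, 10.0)),
    "wall_thickness_um": ((20.4, 2.3), (17.1, 3.1)),
    "type2_per_mm2": ((14490.0, 3519.0), (14559.0, 6279.0)),
    "type1_per_mm2": ((9453.0, 1863.0), (6279.0, 1173.0)),
    "type2_edu_pct": ((17.0, 3.8), (18.4, 7.1)),
    "type1_edu_pct": ((11.8, 4.6), (5.8, 1.6)),
    "club_per_mm": ((149.0, 13.0), (153.0, 12.0)),
    "ciliated_per_mm": ((96.0, 26.0), (91.0, 12.0)),
    "club_edu_pct": ((17.7, 4.3), (10.7, 3.7)),
    "ciliated_edu_pct": ((13.5, 3.5), (8.6, 2.0)),
}

# generator feasibility bounds (documented in docs/methods.md)
CLIP = {"tissue_density": (0.57, 0.88), "wall_thickness_um": (8.0, 40.0)}
# 2-D packing ceilings of the IF generator: cells per mm² of field for
# alveolar nuclei at the 6 µm spacing floor, cells per mm of membrane for
# the bronchiolar band
MAX_ALVEOLAR_FIELD_DENSITY = 15500.0
MAX_BRONCHIOLAR_DENSITY = 260.0


def draw_mouse(seed, group_idx, mouse_idx):
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(group_idx, mouse_idx)))
    vals = {}
    for name, params in GROUP_PARAMS.items():
        mean, sd = params[group_idx]
        v = float(rng.normal(mean, sd))
        lo, hi = CLIP.get(name, (1e-6, np.inf))
        vals[name] = float(np.clip(v, lo, hi))
    # rescale cell densities that a 2-D section could not physically hold
    alv_total = (vals["type2_per_mm2"] + vals["type1_per_mm2"]) * vals["tissue_density"]
    if alv_total > MAX_ALVEOLAR_FIELD_DENSITY:
        f = MAX_ALVEOLAR_FIELD_DENSITY / alv_total
        vals["type2_per_mm2"] *= f
        vals["type1_per_mm2"] *= f
    bro_total = vals["club_per_mm"] + vals["ciliated_per_mm"]
    if bro_total > MAX_BRONCHIOLAR_DENSITY:
        f = MAX_BRONCHIOLAR_DENSITY / bro_total
        vals["club_per_mm"] *= f
        vals["ciliated_per_mm"] *= f
    return vals


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-mice", type=int, default=4)
    args = ap.parse_args()

    img_dir = ROOT / "scratch" / "study"
    out_dir = ROOT / "results" / "study"
    for sub in ("parenchyma", "bronchioles", "if_alveolar", "if_bronchiolar"):
        (img_dir / sub).mkdir(parents=True, exist_ok=True)
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest, truth_rows = [], []
    for g, group in enumerate(("young", "old")):
        for j in range(args.n_mice):
            mouse = f"{group}-{j + 1}"
            vals = draw_mouse(args.seed, g, j)
            for k, v in vals.items():
                truth_rows.append(dict(group=group, mouse_id=mouse, metric=k, value=v))
            base = (args.seed * 7919 + g * 1000 + j * 10) % (2**31 - 1)

            for rep in range(2):
                spec = ParenchymaSpec(
                    field_size=650, pixel_size=1.0,
                    airspace_feret_mean=vals["lm_um"],
                    target_tissue_density=vals["tissue_density"],
                    seed=base + rep,
                )
                img, truth = generate_parenchyma(spec)
                name = f"{mouse}_s{rep + 1}.png"
                lio.write_mask(img_dir / "parenchyma" / name, img.pixels.astype(bool))
                manifest.append(dict(group=group, mouse_id=mouse, kind="parenchyma",
                                     file=f"parenchyma/{name}", pixel_size=1.0))

            spec = BronchioleSpec(
                outer_feret=vals["bronchiole_feret_um"],
                wall_thickness=vals["wall_thickness_um"],
                boundary_wobble_amp=min(2.0, vals["wall_thickness_um"] / 3),
                seed=base + 5,
            )
            img, truth = generate_bronchiole(spec)
            name = f"{mouse}_b1.png"
            lio.write_mask(img_dir / "bronchioles" / name, img.pixels.astype(bool))
            manifest.append(dict(group=group, mouse_id=mouse, kind="bronchiole",
                                 file=f"bronchioles/{name}", pixel_size=spec.pixel_size))

            alv = IFFieldSpec(
                field_size=450,
                densities={"typeII": vals["type2_per_mm2"], "typeI": vals["type1_per_mm2"]},
                edu_fractions={"typeII": vals["type2_edu_pct"], "typeI": vals["type1_edu_pct"]},
                tissue_density=vals["tissue_density"],
                seed=base + 6,
            )
            field, truth = generate_if_field(alv)
            field.mouse_id, field.image_id = mouse, f"{mouse}_a1"
            lio.write_if_field(img_dir / "if_alveolar" / f"{mouse}_a1.tif", field)
            manifest.append(dict(group=group, mouse_id=mouse, kind="if_alveolar",
                                 file=f"if_alveolar/{mouse}_a1.tif", pixel_size=alv.pixel_size))

            bro = IFFieldSpec(
                compartment="bronchiolar",
                densities={"club": vals["club_per_mm"], "ciliated": vals["ciliated_per_mm"]},
                edu_fractions={"club": vals["club_edu_pct"], "ciliated": vals["ciliated_edu_pct"]},
                bm_length_mm=1.0, geometry="ring", seed=base + 7,
            )
            field, truth = generate_if_field(bro)
            field.mouse_id, field.image_id = mouse, f"{mouse}_c1"
            lio.write_if_field(img_dir / "if_bronchiolar" / f"{mouse}_c1.tif", field)
            manifest.append(dict(group=group, mouse_id=mouse, kind="if_bronchiolar",
                                 file=f"if_bronchiolar/{mouse}_c1.tif", pixel_size=bro.pixel_size))
            print(f"simulated {mouse}: Lm {vals['lm_um']:.1f} µm, "
                  f"density {vals['tissue_density']:.2f}, "
                  f"bronchiole {vals['bronchiole_feret_um']:.0f} µm")

    pd.DataFrame(manifest).to_csv(out_dir / "manifest.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(out_dir / "mouse_truth.csv", index=False)
    print(f"\nwrote {len(manifest)} images under {img_dir}")
    print(f"manifest and mouse-level truth under {out_dir}")


if __name__ == "__main__":
    main()
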