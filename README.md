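# lungmorph

Automated lung histomorphometry and epithelial progenitor-turnover
quantification for 2-D histology of the aging mouse lung — the kind of
study that asks whether airspaces enlarge, bronchioles narrow, and
progenitor cells (alveolar Type II, bronchiolar club) keep proliferating
and differentiating between 3 and 22 months of age.

Because studies of this design rarely deposit their slides, every analysis
stage here is exercised end-to-end on **synthetic histology with exact
ground truth**: the package contains generators for alveolar parenchyma,
bronchiole cross-sections, multichannel immunofluorescence (IF) fields and
hierarchical two-group cohorts, and the test suite demands that each
measurement recovers what was planted.

## What it computes

**Parenchyma** (per H&E section, large bronchi/vessels removed):

- airspace area fraction = airspace area / lung-section area,
- alveolar tissue density = tissue area / section area (the two sum to 1
  exactly),
- **Lm**, the mean linear intercept, computed as the *mean maximum Feret
  diameter of all closed airspaces* in the section — not by grid-line
  intercept counting.  The Feret diameter of a region is its largest
  caliper width, max<sub>p,q∈hull</sub>‖p−q‖.

**Bronchioles** (cross-sections whose whole-region Feret diameter lies in
100–500 µm): whole/lumen/wall areas (additive by construction), whole and
lumen Feret diameters, circularity 4πA/P², and mean wall thickness — for
every point of the outer epithelial limit, the shortest distance to the
inner limit, averaged over thousands of boundary points.

**Cells** (multichannel IF): Type II (peri-nuclear Lamp3) and Type I
(nuclear Hopx) cells per mm² of alveolar tissue (counts normalised by
field area × tissue density); club (CC10) and ciliated (acetylated
tubulin) cells per mm of basement membrane, individual cells delineated by
lateral E-cadherin borders; per-type EdU+ fractions (EdU over the
nucleus) as the readout of proliferation during the labelling window.

**Statistics**: technical replicates (images) are averaged to one value
per mouse; groups are compared with two-tailed pooled-variance t-tests
(Welch optional); percent change is 100·(young − old)/young, rounded
half-away-from-zero; a Monte-Carlo harness estimates the pipeline's null
type-I error and power.

## Worked example

```python
from lungmorph import analyze_parenchyma, segment_tissue, detect_bronchioles, measure_bronchiole
from lungmorph.synth import ParenchymaSpec, BronchioleSpec, generate_parenchyma, generate_bronchiole

img, truth = generate_parenchyma(ParenchymaSpec(
    field_size=700, pixel_size=1.0, airspace_feret_mean=44.0,
    target_tissue_density=0.63, seed=100))
m = analyze_parenchyma(img)
print(f"Lm {m.lm:.1f} um over {m.n_airspaces} closed airspaces; "
      f"tissue density {m.tissue_density:.3f} "
      f"(truth {truth.airspace_ferets.mean():.1f} um, {truth.tissue_density:.3f})")

bimg, btruth = generate_bronchiole(BronchioleSpec(
    outer_feret=243.0, wall_thickness=20.4, seed=2))
whole, lumen = detect_bronchioles(segment_tissue(bimg))[0]
b = measure_bronchiole(whole, lumen)
print(f"bronchiole {b.whole_feret:.1f} um, lumen {b.lumen_feret:.1f} um, "
      f"wall {b.wall_thickness_mean:.2f} um over {b.n_thickness_samples} samples")
```

prints

```
Lm 43.8 um over 146 closed airspaces; tissue density 0.634 (truth 43.8 um, 0.634)
bronchiole 243.2 um, lumen 202.4 um, wall 20.36 um over 2149 samples
```

The first line says a 700×700 µm synthetic section built from airspaces of
mean Feret 44 µm at 63 % tissue density was measured back to within a
fraction of a pixel on both numbers.  The second line measures a synthetic
bronchiole of diameter 243 µm and wall 20.4 µm: the lumen diameter is the
outer diameter minus two wall thicknesses, and the wall estimate averages
2 149 boundary-point distance measurements.

## Analysis scripts

`analysis/` contains numbered drivers that rebuild a complete two-group
study (4 mice per group at the published group means and SDs) and push it
through the whole pipeline:

```sh
python analysis/01_simulate_study.py --seed 1   # images -> scratch/, truth -> results/
python analysis/02_parenchyma_morphometry.py    # -> results/parenchyma.csv
python analysis/03_bronchiole_morphometry.py    # -> results/bronchioles.csv
python analysis/04_cell_quantification.py       # -> results/cells_fields.csv
python analysis/05_group_statistics.py          # -> results/comparisons.csv
```

There is also a small CLI (`lungmorph parenchyma|bronchioles|stats|simulate`)
for running the same steps on arbitrary image directories.

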