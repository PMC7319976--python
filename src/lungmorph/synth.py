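"""Synthetic histology with exact ground truth.

Every analysis stage in this package is validated against images generated
here, for which the truth (airspace Feret diameters, tissue density,
bronchiole geometry, cell tables, basement-membrane polylines) is known by
construction rather than re-measured.

Rasterisation convention
------------------------
Analytic boundaries are drawn half a pixel *inside* the nominal radius in
pixel-centre coordinates.  A pixel belongs to a disc of diameter D when its
centre lies within D/2 − px/2 of the centre; the footprint of the selected
pixel squares then spans D, so the corner-hull Feret diameter of the
rasterised shape matches the specified one to sub-pixel accuracy instead of
carrying a systematic +1 px bias.

Randomness
----------
One root seed per spec; substreams are split with ``numpy``'s
``SeedSequence.spawn`` so that, in cohorts, adding a mouse does not perturb
the fields of earlier mice.  Identical spec + seed reproduces bit-identical
images and truth tables.

Default output is noiseless label masks — the analysis contract, not image
restoration, is under test.  An optional pseudo-H&E rendering
(:func:`render_he`) adds colour, blur and noise for segmentation tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.signal import fftconvolve
from scipy.spatial import ConvexHull, cKDTree

from .cells import IFField
from .config import PAPER_PIXEL_SIZE_UM
from .segmentation import HistologyImage

MAX_PLACEMENT_ATTEMPTS = 10_000


class SynthesisError(ValueError):
    pass


# --------------------------------------------------------------------------
# parenchyma
# --------------------------------------------------------------------------


@dataclass
class ParenchymaSpec:
    """Alveolar parenchyma: elliptical closed airspaces in a tissue sheet.

    Airspace Feret diameters (ellipse major axes) are drawn from a normal
    distribution with mean ``airspace_feret_mean`` µm and coefficient of
    variation ``airspace_feret_cv``.  Placement is by dart throwing with a
    minimum septal wall of ``septum_um`` between airspaces.  Either a
    target tissue density or an exact airspace count may be requested;
    ``feret_values`` overrides the size distribution with an explicit list.
    """

    field_size: int = 1500
    pixel_size: float = PAPER_PIXEL_SIZE_UM
    airspace_feret_mean: float = 44.0
    airspace_feret_cv: float = 0.25
    target_tissue_density: float | None = 0.63
    n_airspaces: int | None = None
    feret_values: list | None = None
    septum_um: float = 2.0
    seed: int = 0


@dataclass
class ParenchymaTruth:
    airspace_ferets: np.ndarray  # µm, one per placed airspace
    airspace_areas: np.ndarray  # µm², analytic π·a·b
    tissue_density: float  # realised, from the pixel counts
    pixel_size: float
    seed: int


def _draw_ellipse_px(shape, center, a_px, b_px, theta):
    """Pixel (row, col) indices of a rotated ellipse, footprint convention."""
    a_eff, b_eff = max(a_px - 0.5, 0.5), max(b_px - 0.5, 0.5)
    rad = int(np.ceil(max(a_eff, b_eff))) + 1
    cy, cx = center
    r0, r1 = max(0, cy - rad), min(shape[0], cy + rad + 1)
    c0, c1 = max(0, cx - rad), min(shape[1], cx + rad + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    inside = (u / a_eff) ** 2 + (v / b_eff) ** 2 <= 1.0
    return yy[inside], xx[inside]


def generate_parenchyma(spec: ParenchymaSpec):
    """Generate a binary parenchyma field (tissue = 1) with ground truth.

    Returns ``(HistologyImage, ParenchymaTruth)``.  Raises when the
    requested density is infeasible at the requested airspace size (dart
    throwing exhausts its attempt budget) or when the realised tissue
    density misses the target by more than 0.01.
    """
    ps = spec.pixel_size
    n = spec.field_size
    if spec.target_tissue_density is not None and not 0 < spec.target_tissue_density <= 1:
        raise SynthesisError("target_tissue_density must be in (0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    tissue = np.ones((n, n), dtype=bool)
    occupied = np.zeros((n, n), dtype=bool)  # airspaces + septal margin
    sep_px = spec.septum_um / ps

    explicit = list(spec.feret_values) if spec.feret_values is not None else None
    want_n = spec.n_airspaces if spec.n_airspaces is not None else (
        len(explicit) if explicit is not None else None
    )
    target_air = (
        None if spec.target_tissue_density is None else 1.0 - spec.target_tissue_density
    )
    if want_n is None and target_air is None:
        raise SynthesisError("specify target_tissue_density, n_airspaces or feret_values")

    ferets, areas = [], []
    total_px = n * n
    air_px = 0
    k = 0
    redraws = 0
    while True:
        if want_n is not None and k >= want_n:
            break
        if want_n is None and target_air is not None and air_px / total_px >= target_air - 0.005:
            break
        if explicit is not None:
            feret = float(explicit[k])
        else:
            feret = float(
                rng.normal(spec.airspace_feret_mean, spec.airspace_feret_cv * spec.airspace_feret_mean)
            )
            feret = max(feret, 4 * ps)
        aspect = float(rng.uniform(0.65, 0.95))
        a_px = feret / (2 * ps)
        b_px = a_px * aspect
        theta = float(rng.uniform(0, np.pi))
        margin = int(np.ceil(a_px + sep_px)) + 2
        if 2 * margin >= n:
            raise SynthesisError("airspace too large for field")
        centre = None
        for _ in range(500):  # fast path: rejection sampling
            cy = int(rng.integers(margin, n - margin))
            cx = int(rng.integers(margin, n - margin))
            gy, gx = _draw_ellipse_px((n, n), (cy, cx), a_px + sep_px, b_px + sep_px, theta)
            if not occupied[gy, gx].any():
                centre = (cy, cx)
                break
        if centre is None:
            # exact path: enumerate every admissible centre by convolving the
            # occupancy mask with the candidate footprint
            rad = int(np.ceil(a_px + sep_px)) + 1
            side = 2 * rad + 1
            ky, kx = _draw_ellipse_px((side, side), (rad, rad), a_px + sep_px, b_px + sep_px, theta)
            kernel = np.zeros((side, side), dtype=np.float32)
            kernel[ky, kx] = 1.0
            conv = fftconvolve(occupied.astype(np.float32), kernel, mode="same")
            allowed = conv < 0.5
            allowed[:margin, :] = allowed[-margin:, :] = False
            allowed[:, :margin] = allowed[:, -margin:] = False
            idx = np.flatnonzero(allowed)
            if idx.size == 0:
                # in density mode a smaller draw may still fit: re-draw the
                # size; the realised list stays the ground truth
                if explicit is None and want_n is None and redraws < 200:
                    redraws += 1
                    continue
                raise SynthesisError(f"infeasible spec: no room for airspace {k}")
            pick = int(idx[rng.integers(0, idx.size)])
            centre = (pick // n, pick % n)
        cy, cx = centre
        yy, xx = _draw_ellipse_px((n, n), (cy, cx), a_px, b_px, theta)
        occupied[yy, xx] = True  # candidates carry the septal margin themselves
        tissue[yy, xx] = False
        air_px += len(yy)
        ferets.append(feret)
        areas.append(np.pi * (feret / 2) * (feret / 2 * aspect))
        k += 1

    realised_density = tissue.sum() / total_px
    if want_n is None and abs(realised_density - spec.target_tissue_density) > 0.01:
        raise SynthesisError(
            f"realised tissue density {realised_density:.3f} misses target "
            f"{spec.target_tissue_density:.3f} by more than 0.01"
        )
    image = HistologyImage(tissue.astype(np.uint8), ps, source_id=f"parenchyma-seed{spec.seed}")
    truth = ParenchymaTruth(
        np.asarray(ferets), np.asarray(areas), float(realised_density), ps, spec.seed
    )
    return image, truth


# --------------------------------------------------------------------------
# bronchioles
# --------------------------------------------------------------------------


@dataclass
class BronchioleSpec:
    """An annular epithelium ring with optional boundary wobble/eccentricity.

    ``outer_feret`` is the whole-bronchiole diameter (µm); the lumen is the
    outer boundary offset inward by ``wall_thickness`` (same sinusoidal
    wobble phase, so the radial gap stays equal to the wall thickness), its
    centre optionally displaced by ``eccentricity`` µm.
    """

    outer_feret: float = 243.0
    wall_thickness: float = 20.4
    boundary_wobble_amp: float = 0.0
    wobble_waves: int = 5
    eccentricity: float = 0.0
    pixel_size: float = PAPER_PIXEL_SIZE_UM
    margin_um: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if not self.wall_thickness < self.outer_feret / 2:
            raise SynthesisError("wall_thickness must be < outer_feret / 2")
        if not self.boundary_wobble_amp < max(self.wall_thickness / 2, 1e-9):
            if self.boundary_wobble_amp > 0:
                raise SynthesisError("wobble amplitude must be < wall_thickness / 2")
        if self.eccentricity >= self.wall_thickness:
            raise SynthesisError("eccentricity must be < wall_thickness")


@dataclass
class BronchioleTruth:
    outer_polygon: np.ndarray  # (m, 2) µm, image coordinates (x, y)
    inner_polygon: np.ndarray
    whole_area: float  # analytic, µm²
    lumen_area: float
    wall_area: float
    outer_feret: float
    lumen_feret: float
    wall_thickness_mean: float  # mean nearest-distance over analytic polygons
    wall_gap_min: float
    wall_gap_max: float
    pixel_size: float
    seed: int


def _polygon_feret(poly: np.ndarray) -> float:
    hull = ConvexHull(poly)
    v = poly[hull.vertices]
    d2 = ((v[:, None, :] - v[None, :, :]) ** 2).sum(axis=-1)
    return float(np.sqrt(d2.max()))


def generate_bronchiole(spec: BronchioleSpec):
    """Generate a bronchiole ring mask (tissue = 1) with analytic truth.

    Returns ``(HistologyImage, BronchioleTruth)``.
    """
    ps = spec.pixel_size
    R0 = spec.outer_feret / 2.0
    amp, k = spec.boundary_wobble_amp, spec.wobble_waves
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    phase = float(rng.uniform(0, 2 * np.pi))
    ecc_dir = float(rng.uniform(0, 2 * np.pi))
    e = spec.eccentricity
    half = int(np.ceil((R0 + amp + spec.margin_um) / ps))
    n = 2 * half + 1
    c = half  # centre pixel index

    yy, xx = np.mgrid[0:n, 0:n]
    dy, dx = (yy - c).astype(float), (xx - c).astype(float)
    th = np.arctan2(dy, dx)
    rr = np.hypot(dy, dx)
    r_out = (R0 + amp * np.sin(k * th + phase)) / ps - 0.5
    outer_disc = rr <= r_out

    iy, ix = e * np.sin(ecc_dir) / ps, e * np.cos(ecc_dir) / ps
    dyi, dxi = dy - iy, dx - ix
    thi = np.arctan2(dyi, dxi)
    rri = np.hypot(dyi, dxi)
    r_in = (R0 - spec.wall_thickness + amp * np.sin(k * thi + phase)) / ps - 0.5
    lumen = rri <= r_in

    tissue = outer_disc & ~lumen
    if not lumen.any() or not tissue.any():
        raise SynthesisError("degenerate bronchiole spec")

    t = np.linspace(0, 2 * np.pi, 2048, endpoint=False)
    ro = R0 + amp * np.sin(k * t + phase)
    outer_poly = np.stack([ro * np.cos(t), ro * np.sin(t)], axis=1)
    ri = (R0 - spec.wall_thickness) + amp * np.sin(k * t + phase)
    inner_poly = np.stack(
        [ri * np.cos(t) + e * np.cos(ecc_dir), ri * np.sin(t) + e * np.sin(ecc_dir)], axis=1
    )
    centre_um = (c + 0.5) * ps
    outer_poly_img = outer_poly + centre_um
    inner_poly_img = inner_poly + centre_um

    gaps, _ = cKDTree(inner_poly_img).query(outer_poly_img, k=1)
    whole_area = np.pi * (R0**2 + amp**2 / 2)
    lumen_area = np.pi * ((R0 - spec.wall_thickness) ** 2 + amp**2 / 2)
    truth = BronchioleTruth(
        outer_polygon=outer_poly_img,
        inner_polygon=inner_poly_img,
        whole_area=whole_area,
        lumen_area=lumen_area,
        wall_area=whole_area - lumen_area,
        outer_feret=_polygon_feret(outer_poly_img),
        lumen_feret=_polygon_feret(inner_poly_img),
        wall_thickness_mean=float(gaps.mean()),
        wall_gap_min=float(gaps.min()),
        wall_gap_max=float(gaps.max()),
        pixel_size=ps,
        seed=spec.seed,
    )
    image = HistologyImage(
        tissue.astype(np.uint8), ps, source_id=f"bronchiole-seed{spec.seed}"
    )
    return image, truth


# --------------------------------------------------------------------------
# immunofluorescence fields
# --------------------------------------------------------------------------


@dataclass
class IFFieldSpec:
    """A multichannel IF field with planted cells.

    Alveolar: per-type densities are cells per mm² of alveolar tissue; the
    expected in-field count is density × field area × tissue density.
    Bronchiolar: densities are cells per mm of basement membrane, the cells
    tiling an epithelial band along a straight ('strip') or circular
    ('ring') membrane.  EdU flags are independent Bernoulli draws at the
    per-type fraction.  ``count_model`` 'poisson' draws the per-type counts
    from a Poisson at the expectation; 'expected' rounds them.  Likewise
    ``edu_model`` 'bernoulli' draws per-cell flags while 'expected' plants
    the rounded count of EdU+ cells exactly (random positions), removing
    binomial noise when the measurement chain itself is under test.
    """

    compartment: str = "alveolar"
    densities: dict = dc_field(default_factory=lambda: {"typeII": 14490.0, "typeI": 9453.0})
    edu_fractions: dict = dc_field(default_factory=lambda: {"typeII": 17.0, "typeI": 11.8})
    tissue_density: float = 0.63
    bm_length_mm: float = 0.628
    geometry: str = "ring"  # bronchiolar only: 'strip' or 'ring'
    field_size: int = 570
    pixel_size: float = PAPER_PIXEL_SIZE_UM
    count_model: str = "poisson"
    edu_model: str = "bernoulli"
    nucleus_radius_um: float = 1.5
    vesicle_width_um: float = 1.1  # radial extent of the Lamp3 annulus
    min_separation_um: float = 6.0  # centre-to-centre floor, alveolar
    band_height_um: float = 12.0
    seed: int = 0

    def __post_init__(self):
        if any(v < 0 for v in self.densities.values()):
            raise SynthesisError("densities must be >= 0")
        if any(not 0 <= v <= 100 for v in self.edu_fractions.values()):
            raise SynthesisError("EdU fractions must be in [0, 100]")
        if self.count_model not in ("poisson", "expected"):
            raise SynthesisError("count_model must be 'poisson' or 'expected'")
        if self.edu_model not in ("bernoulli", "expected"):
            raise SynthesisError("edu_model must be 'bernoulli' or 'expected'")


@dataclass
class IFTruth:
    cells: pd.DataFrame  # cell_type, edu_positive, x_um, y_um
    densities: dict  # realised, same units as the spec
    edu_fractions: dict  # realised, %
    tissue_density: float | None
    bm_length_mm: float | None
    bm_polyline: np.ndarray | None  # (m, 2) µm (x, y)
    seed: int


def _disc_idx(shape, cy, cx, r_px):
    r_eff = max(r_px - 0.5, 0.5)
    rad = int(np.ceil(r_eff)) + 1
    r0, r1 = max(0, cy - rad), min(shape[0], cy + rad + 1)
    c0, c1 = max(0, cx - rad), min(shape[1], cx + rad + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_eff**2
    return yy[inside], xx[inside]


def _planted_counts(spec, expected: dict, rng) -> dict:
    if spec.count_model == "poisson":
        return {t: int(rng.poisson(mu)) for t, mu in expected.items()}
    return {t: int(round(mu)) for t, mu in expected.items()}


def _edu_flags(spec, types, rng):
    """Per-cell EdU flags aligned with the ``types`` list."""
    if spec.edu_model == "bernoulli":
        return [bool(rng.random() < spec.edu_fractions.get(t, 0.0) / 100.0) for t in types]
    flags = [False] * len(types)
    arr = np.asarray(types, dtype=object)
    for t in spec.edu_fractions:
        idx = np.flatnonzero(arr == t)
        k = int(round(len(idx) * spec.edu_fractions[t] / 100.0))
        for j in rng.permutation(idx)[:k]:
            flags[int(j)] = True
    return flags


def _generate_alveolar(spec: IFFieldSpec, rng):
    ps = spec.pixel_size
    n = spec.field_size
    area_mm2 = n * n * ps**2 / 1e6
    expected = {t: d * area_mm2 * spec.tissue_density for t, d in spec.densities.items()}
    counts = _planted_counts(spec, expected, rng)

    r_nuc = spec.nucleus_radius_um / ps
    min_sep_px = int(np.ceil(spec.min_separation_um / ps))
    shape = (n, n)
    channels = {name: np.zeros(shape, dtype=bool) for name in ("nuclei", "lamp3", "hopx", "edu")}
    forbidden = np.zeros(shape, dtype=bool)
    margin = int(np.ceil(r_nuc + (spec.vesicle_width_um + 1.0) / ps)) + 2

    order = []
    for t in counts:
        order += [t] * counts[t]
    order = list(np.asarray(order, dtype=object)[rng.permutation(len(order))])
    flags = _edu_flags(spec, order, rng)

    rows = []
    for ctype, edu in zip(order, flags):
        for _ in range(200):  # fast path
            cy = int(rng.integers(margin, n - margin))
            cx = int(rng.integers(margin, n - margin))
            if not forbidden[cy, cx]:
                break
        else:
            # exact path: the forbidden mask already encodes every
            # disallowed centre, so sample from its complement
            allowed = ~forbidden
            allowed[:margin, :] = allowed[-margin:, :] = False
            allowed[:, :margin] = allowed[:, -margin:] = False
            idx = np.flatnonzero(allowed)
            if idx.size == 0:
                raise SynthesisError("overcrowded spec: cells cannot fit")
            pick = int(idx[rng.integers(0, idx.size)])
            cy, cx = pick // n, pick % n
        fy, fx = _disc_idx(shape, cy, cx, min_sep_px)
        forbidden[fy, fx] = True
        ny, nx = _disc_idx(shape, cy, cx, r_nuc)
        channels["nuclei"][ny, nx] = True
        if ctype == "typeII":
            oy, ox = _disc_idx(shape, cy, cx, r_nuc + spec.vesicle_width_um / ps)
            ring = np.zeros(shape, dtype=bool)
            ring[oy, ox] = True
            ring[ny, nx] = False
            channels["lamp3"] |= ring
        else:
            channels["hopx"][ny, nx] = True
        if edu:
            channels["edu"][ny, nx] = True
        rows.append(dict(cell_type=ctype, edu_positive=edu,
                         x_um=(cx + 0.5) * ps, y_um=(cy + 0.5) * ps))

    cells = pd.DataFrame(rows, columns=["cell_type", "edu_positive", "x_um", "y_um"])
    realised_dens = {
        t: counts[t] / (area_mm2 * spec.tissue_density) for t in spec.densities
    }
    realised_edu = {
        t: (100.0 * cells[(cells.cell_type == t) & cells.edu_positive].shape[0] / counts[t])
        if counts[t] else None
        for t in spec.densities
    }
    field = IFField(channels, ps, "alveolar", image_id=f"alv-seed{spec.seed}")
    truth = IFTruth(cells, realised_dens, realised_edu, spec.tissue_density, None, None, spec.seed)
    return field, truth


def _generate_bronchiolar(spec: IFFieldSpec, rng):
    ps = spec.pixel_size
    bm_um = spec.bm_length_mm * 1000.0
    band_px = max(4, int(round(spec.band_height_um / ps)))
    expected = {t: d * spec.bm_length_mm for t, d in spec.densities.items()}
    counts = _planted_counts(spec, expected, rng)
    n_cells = sum(counts.values())
    if n_cells < 2:
        raise SynthesisError("need at least 2 cells in the band")
    # columnar epithelium: the nucleus narrows with the cell pitch
    pitch_um = bm_um / n_cells
    r_nuc_um = min(spec.nucleus_radius_um, pitch_um / 2 - 2 * ps)
    if r_nuc_um < 0.7:
        raise SynthesisError("overcrowded spec: cells cannot fit along the membrane")
    r_nuc = r_nuc_um / ps

    types = []
    for t, c in counts.items():
        types += [t] * c
    types = list(np.asarray(types, dtype=object)[rng.permutation(n_cells)])
    edu_flags = _edu_flags(spec, types, rng)

    apical_px = max(2, int(round(2.0 / ps)))

    if spec.geometry == "strip":
        L_px = int(round(bm_um / ps))
        margin = 10
        h = band_px + 2 * margin
        w = L_px + 2 * margin + 1
        shape = (h, w)
        channels = {k: np.zeros(shape, dtype=bool)
                    for k in ("nuclei", "ecad", "cc10", "actub", "edu")}
        top, bottom = margin, margin + band_px - 1  # apical row, basal row
        bounds = np.round(np.linspace(0, L_px, n_cells + 1)).astype(int) + margin
        for xb in bounds:
            channels["ecad"][top:bottom + 1, xb] = True
        rows = []
        nuc_cy = int(round(bottom - r_nuc - 1))
        for i, (ctype, edu) in enumerate(zip(types, edu_flags)):
            x0, x1 = bounds[i] + 1, bounds[i + 1] - 1
            if x1 < x0:
                raise SynthesisError("overcrowded spec: cells cannot fit")
            cx = (x0 + x1) // 2
            ny, nx = _disc_idx(shape, nuc_cy, cx, r_nuc)
            channels["nuclei"][ny, nx] = True
            if ctype == "ciliated":
                channels["actub"][top:top + apical_px, x0:x1 + 1] = True
            else:
                mid0 = top + apical_px + 1
                mid1 = int(nuc_cy - r_nuc) - 1
                channels["cc10"][mid0:max(mid0 + 2, mid1), x0:x1 + 1] = True
            if edu:
                channels["edu"][ny, nx] = True
            rows.append(dict(cell_type=ctype, edu_positive=edu,
                             x_um=(cx + 0.5) * ps, y_um=(nuc_cy + 0.5) * ps))
        bm_poly = np.stack(
            [np.array([bounds[0], bounds[-1]], float) + 0.5,
             np.array([bottom, bottom], float) + 1.0], axis=1
        ) * ps
        realised_bm = (bounds[-1] - bounds[0]) * ps / 1000.0
    elif spec.geometry == "ring":
        rb = bm_um / (2 * np.pi)  # basal (membrane) radius, µm
        half = int(np.ceil((rb + 10) / ps))
        npix = 2 * half + 1
        shape = (npix, npix)
        c = half
        channels = {k: np.zeros(shape, dtype=bool)
                    for k in ("nuclei", "ecad", "cc10", "actub", "edu")}
        yy, xx = np.mgrid[0:npix, 0:npix]
        rr_px = np.hypot(yy - c, xx - c)
        th_px = np.arctan2(yy - c, xx - c) % (2 * np.pi)
        rb_px = rb / ps
        ra_px = rb_px - band_px  # apical (luminal) radius
        band = (rr_px <= rb_px - 0.5) & (rr_px > ra_px - 0.5)
        bound_angles = np.linspace(0, 2 * np.pi, n_cells + 1)[:-1]
        dth = 2 * np.pi / n_cells
        ang_w = 1.2 / np.maximum(rr_px, 1.0)  # ~1.2 px wide radial border
        for a in bound_angles:
            diff = np.abs((th_px - a + np.pi) % (2 * np.pi) - np.pi)
            channels["ecad"] |= band & (diff <= ang_w)
        rows = []
        for i, (ctype, edu) in enumerate(zip(types, edu_flags)):
            a_mid = bound_angles[i] + dth / 2
            nr = rb_px - r_nuc - 1.5
            cy = int(round(c + nr * np.sin(a_mid)))
            cx = int(round(c + nr * np.cos(a_mid)))
            ny, nx = _disc_idx(shape, cy, cx, r_nuc)
            channels["nuclei"][ny, nx] = True
            diff = np.abs((th_px - a_mid + np.pi) % (2 * np.pi) - np.pi)
            sector = band & (diff <= dth / 2 - ang_w * 1.5)
            if ctype == "ciliated":
                channels["actub"] |= sector & (rr_px <= ra_px - 0.5 + apical_px)
            else:
                channels["cc10"] |= (
                    sector
                    & (rr_px > ra_px - 0.5 + apical_px + 1)
                    & (rr_px <= nr - r_nuc - 1)
                )
            if edu:
                channels["edu"][ny, nx] = True
            rows.append(dict(cell_type=ctype, edu_positive=edu,
                             x_um=(cx + 0.5) * ps, y_um=(cy + 0.5) * ps))
        tt = np.linspace(0, 2 * np.pi, 1024, endpoint=False)
        bm_poly = np.stack(
            [(c + 0.5 + rb_px * np.cos(tt)) * ps, (c + 0.5 + rb_px * np.sin(tt)) * ps], axis=1
        )
        realised_bm = spec.bm_length_mm
    else:
        raise SynthesisError(f"unknown geometry {spec.geometry!r}")

    cells = pd.DataFrame(rows, columns=["cell_type", "edu_positive", "x_um", "y_um"])
    realised_dens = {t: counts[t] / realised_bm for t in spec.densities}
    realised_edu = {
        t: (100.0 * cells[(cells.cell_type == t) & cells.edu_positive].shape[0] / counts[t])
        if counts[t] else None
        for t in spec.densities
    }
    field = IFField(channels, ps, "bronchiolar", image_id=f"bro-seed{spec.seed}")
    truth = IFTruth(cells, realised_dens, realised_edu, None, realised_bm, bm_poly, spec.seed)
    return field, truth


def generate_if_field(spec: IFFieldSpec):
    """Generate a multichannel IF field with an exact cell table.

    Returns ``(IFField, IFTruth)``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    if spec.compartment == "alveolar":
        return _generate_alveolar(spec, rng)
    if spec.compartment == "bronchiolar":
        return _generate_bronchiolar(spec, rng)
    raise SynthesisError(f"unknown compartment {spec.compartment!r}")


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------


@dataclass
class MetricGroupSpec:
    """Group-level parameters for one metric in a two-group cohort."""

    young_mean: float
    young_between_sd: float
    old_mean: float
    old_between_sd: float
    within_sd: float  # between-field SD within a mouse

    def __post_init__(self):
        if min(self.young_between_sd, self.old_between_sd, self.within_sd) < 0:
            raise SynthesisError("SDs must be >= 0")


@dataclass
class CohortSpec:
    """A two-group (young/old) hierarchical study design."""

    metrics: dict  # name -> MetricGroupSpec
    n_mice: int = 4
    fields_per_mouse: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_mice < 2:
            raise SynthesisError("n_mice must be >= 2")
        if self.fields_per_mouse < 1:
            raise SynthesisError("fields_per_mouse must be >= 1")


@dataclass
class CohortDataset:
    values: pd.DataFrame  # group, mouse_id, field_id, metric, value
    mouse_truth: pd.DataFrame  # group, mouse_id, metric, value
    seed: int


def generate_cohort(spec: CohortSpec) -> CohortDataset:
    """Sample a hierarchical two-group dataset.

    Mouse-level metric values are drawn from the group normal
    (mean, between-mouse SD); field-level values from the mouse normal
    (mouse value, within-mouse SD).  Each mouse owns a spawned substream,
    so extending the cohort does not perturb earlier mice.  Field rows can
    be routed to the field generators by using the per-field values as
    generator parameters (see the analysis drivers).
    """
    rows, truth_rows = [], []
    for g, group in enumerate(("young", "old")):
        for j in range(spec.n_mice):
            # key the stream by (group, mouse) so that growing the cohort
            # leaves earlier mice untouched
            rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(g, j)))
            mouse_id = f"{group}-{j + 1}"
            for name, m in spec.metrics.items():
                mean = m.young_mean if group == "young" else m.old_mean
                bsd = m.young_between_sd if group == "young" else m.old_between_sd
                mouse_val = float(rng.normal(mean, bsd))
                truth_rows.append(
                    dict(group=group, mouse_id=mouse_id, metric=name, value=mouse_val)
                )
                for f in range(spec.fields_per_mouse):
                    rows.append(
                        dict(
                            group=group,
                            mouse_id=mouse_id,
                            field_id=f"{mouse_id}-f{f + 1}",
                            metric=name,
                            value=float(rng.normal(mouse_val, m.within_sd)),
                        )
                    )
    return CohortDataset(pd.DataFrame(rows), pd.DataFrame(truth_rows), spec.seed)


# --------------------------------------------------------------------------
# pseudo-H&E rendering
# --------------------------------------------------------------------------


def render_he(mask: np.ndarray, seed: int = 0, blur_sigma: float = 0.6,
              noise_sd: float = 0.015) -> np.ndarray:
    """Render a binary tissue mask as a pseudo-H&E RGB image (uint8).

    Tissue takes an eosin-like pink with mild intensity texture; background
    is slide-white.  A slight Gaussian blur and sensor noise are added so
    that stain-density thresholding is exercised realistically.  For
    robustness testing only — quantitative tests run on the label masks.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    m = np.asarray(mask, dtype=float)
    texture = rng.normal(1.0, 0.05, m.shape)
    density = ndi.gaussian_filter(m * texture, blur_sigma)
    tissue_rgb = np.array([0.72, 0.35, 0.55])  # eosin/hematoxylin mix
    white = np.ones(3)
    img = white[None, None, :] * (1 - density[..., None]) + tissue_rgb[None, None, :] * density[..., None]
    img = img + rng.normal(0.0, noise_sd, img.shape)
    return (np.clip(img, 0, 1) * 255).astype(np.uint8)
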