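"""IF cell classification, basement-membrane length, and field quantification.

Marker rules
------------
Alveolar fields: a cell is Type II when Lamp3+ vesicles occupy its
peri-nuclear cytoplasm, Type I when Hopx overlaps its nucleus.  Cells
positive for both are ambiguous (the markers are lineage-specific), so they
are dropped and counted.  Bronchiolar fields: individual epithelial cells
are delimited by lateral E-cadherin borders; within its E-cadherin
compartment a cell is ciliated when apical acetylated tubulin is present
and club when cytoplasmic CC10 is present.  Any cell is EdU+ when the EdU
channel covers at least ``edu_overlap_frac`` of its nucleus.

Normalisation
-------------
Alveolar densities are reported per mm² of *alveolar tissue* — raw field
counts divided by (field area × tissue density) — so that a change in
septal density does not masquerade as a change in cell number.  Bronchiolar
densities are reported per mm of basement membrane, the polyline through
the basalmost points of the lateral E-cadherin borders.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk
from skimage.segmentation import watershed

from .config import CellConfig

_EIGHT = np.ones((3, 3), dtype=int)

ALVEOLAR_TYPES = ("typeII", "typeI")
BRONCHIOLAR_TYPES = ("club", "ciliated")

_REQUIRED = {
    "alveolar": ("nuclei", "lamp3", "hopx", "edu"),
    "bronchiolar": ("nuclei", "ecad", "cc10", "actub", "edu"),
}


class CellQuantError(ValueError):
    pass


@dataclass
class IFField:
    """A multichannel immunofluorescence field as named binary masks."""

    channels: dict
    pixel_size: float
    compartment: str
    image_id: str = ""
    mouse_id: str = ""

    def __post_init__(self):
        if self.compartment not in _REQUIRED:
            raise CellQuantError(f"unknown compartment {self.compartment!r}")
        self.channels = {k: np.asarray(v, dtype=bool) for k, v in self.channels.items()}
        shapes = {v.shape for v in self.channels.values()}
        if len(shapes) > 1:
            raise CellQuantError("channel shapes differ")
        if not self.pixel_size > 0:
            raise CellQuantError("pixel_size must be > 0")

    @property
    def shape(self):
        return next(iter(self.channels.values())).shape

    @property
    def field_area_mm2(self) -> float:
        h, w = self.shape
        return h * w * self.pixel_size**2 / 1e6

    def require(self, *names):
        for n in names:
            if n not in self.channels:
                raise CellQuantError(f"missing required channel {n!r}")


@dataclass
class CellRecord:
    cell_type: str
    edu_positive: bool
    centroid: tuple  # (x, y) µm


@dataclass
class ClassificationResult:
    records: list
    n_unclassified: int = 0
    n_ambiguous: int = 0

    @property
    def n_nuclei(self) -> int:
        return len(self.records) + self.n_unclassified + self.n_ambiguous


@dataclass
class FieldQuantification:
    """Per-field counts, denominators, densities and EdU fractions."""

    counts: dict
    edu_counts: dict
    densities: dict
    edu_fractions: dict
    tissue_density: float | None = None
    bm_length_mm: float | None = None
    image_id: str = ""
    mouse_id: str = ""


def _labelled_nuclei(field: IFField):
    lab, n = ndi.label(field.channels["nuclei"], structure=_EIGHT)
    objs = ndi.find_objects(lab)
    return lab, n, objs


def _frac_overlap(marker: np.ndarray, probe: np.ndarray) -> float:
    denom = int(probe.sum())
    return (marker & probe).sum() / denom if denom else 0.0


def classify_cells(
    field: IFField, config: CellConfig | None = None, detailed: bool = False
):
    """One :class:`CellRecord` per nucleus satisfying a marker rule.

    With ``detailed=True`` returns a :class:`ClassificationResult` that also
    carries the dropped (unclassified / ambiguous) counts, used for count-
    conservation checks.
    """
    config = config or CellConfig()
    field.require(*_REQUIRED[field.compartment])
    ps = field.pixel_size
    lab, n, objs = _labelled_nuclei(field)
    edu = field.channels["edu"]

    if field.compartment == "alveolar":
        lamp3, hopx = field.channels["lamp3"], field.channels["hopx"]
        peri_px = max(1, int(round(config.perinuclear_radius_um / ps)))
    else:
        ecad = field.channels["ecad"]
        cc10, actub = field.channels["cc10"], field.channels["actub"]
        # one territory per cell: flood the epithelial band from each
        # nucleus, with the lateral E-cadherin borders as watershed barriers
        band = field.channels["nuclei"] | ecad | cc10 | actub
        r_close = max(2, int(round(config.band_closing_um / ps)))
        pad = r_close + 1
        band_mask = np.pad(band, pad)
        band_mask = ndi.binary_closing(band_mask, structure=disk(r_close).astype(bool))
        band_mask = band_mask[pad:-pad, pad:-pad]
        cell_lab = watershed(ecad.astype(np.uint8), markers=lab, mask=band_mask)
        territory_slices = ndi.find_objects(cell_lab, max_label=n)

    records, n_unclassified, n_ambiguous = [], 0, 0
    h, w = field.shape
    for i in range(1, n + 1):
        sl = objs[i - 1]
        pad = peri_px + 1 if field.compartment == "alveolar" else 1
        r0, r1 = max(0, sl[0].start - pad), min(h, sl[0].stop + pad)
        c0, c1 = max(0, sl[1].start - pad), min(w, sl[1].stop + pad)
        nuc = lab[r0:r1, c0:c1] == i
        rr, cc = np.nonzero(nuc)
        cy, cx = rr.mean() + r0, cc.mean() + c0
        centroid = (float(cx + 0.5) * ps, float(cy + 0.5) * ps)

        if field.compartment == "alveolar":
            ring = ndi.binary_dilation(nuc, iterations=peri_px) & ~nuc
            is_t2 = _frac_overlap(lamp3[r0:r1, c0:c1], ring) >= config.marker_overlap_frac
            is_t1 = _frac_overlap(hopx[r0:r1, c0:c1], nuc) >= config.nuclear_overlap_frac
            if is_t2 and is_t1:
                n_ambiguous += 1
                continue
            if not (is_t2 or is_t1):
                n_unclassified += 1
                continue
            ctype = "typeII" if is_t2 else "typeI"
        else:
            tsl = territory_slices[i - 1]
            if tsl is None:
                n_unclassified += 1
                continue
            cell = cell_lab[tsl] == i
            has_cil = int((actub[tsl] & cell).sum()) >= 2
            has_club = int((cc10[tsl] & cell).sum()) >= 2
            if has_cil and has_club:
                n_ambiguous += 1
                continue
            if not (has_cil or has_club):
                n_unclassified += 1
                continue
            ctype = "ciliated" if has_cil else "club"

        edu_pos = _frac_overlap(edu[r0:r1, c0:c1], nuc) >= config.edu_overlap_frac
        records.append(CellRecord(ctype, edu_pos, centroid))

    result = ClassificationResult(records, n_unclassified, n_ambiguous)
    return result if detailed else result.records


def basement_membrane_length(field: IFField, config: CellConfig | None = None) -> float:
    """Length (mm) of the polyline through the basalmost points of the
    lateral E-cadherin borders.

    Each E-cadherin component is one lateral border; its basal endpoint is
    the end nearer the nuclear layer (nuclei sit basally in this columnar
    epithelium).  For an annular band (a hole in the filled band) the
    points are ordered by angle and the polyline closed; for a flat strip
    they are ordered along the band's principal axis.
    """
    if field.compartment != "bronchiolar":
        raise CellQuantError("basement membrane is defined for bronchiolar fields")
    field.require("ecad", "nuclei")
    ps = field.pixel_size
    ecad = field.channels["ecad"]
    nuclei = field.channels["nuclei"]
    lab, n = ndi.label(ecad, structure=_EIGHT)
    if n < 2:
        raise CellQuantError("fewer than 2 basal points")

    # distance to the nearest nucleus pixel decides which end is basal
    dist_nuc = ndi.distance_transform_edt(~nuclei)
    basal = np.zeros((n, 2), dtype=float)
    for i, sl in enumerate(ndi.find_objects(lab), start=1):
        pts = np.argwhere(lab[sl] == i) + [sl[0].start, sl[1].start]
        # endpoints: extremes along the segment's principal axis
        centred = pts - pts.mean(axis=0)
        if len(pts) > 1:
            _, _, vt = np.linalg.svd(centred, full_matrices=False)
            proj = centred @ vt[0]
            ends = pts[[proj.argmin(), proj.argmax()]]
        else:
            ends = pts[[0, 0]]
        d = dist_nuc[ends[:, 0], ends[:, 1]]
        basal[i - 1] = ends[int(np.argmin(d))]

    band = nuclei | ecad
    for ch in ("cc10", "actub"):
        if ch in field.channels:
            band = band | field.channels[ch]
    band = ndi.binary_closing(band, structure=np.ones((3, 3), bool))
    holes = ndi.binary_fill_holes(band) & ~band
    hole_lab, n_holes = ndi.label(holes, structure=_EIGHT)
    ring = False
    if n_holes:
        sizes = np.bincount(hole_lab.ravel())[1:]
        ring = sizes.max() * ps**2 > 100.0  # a real lumen, not a pore

    if ring:
        centre = np.argwhere(band).mean(axis=0)
        ang = np.arctan2(basal[:, 0] - centre[0], basal[:, 1] - centre[1])
        order = np.argsort(ang)
        pts = basal[order]
        closed = True
    else:
        centred = basal - basal.mean(axis=0)
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        order = np.argsort(centred @ vt[0])
        pts = basal[order]
        closed = False

    seg = np.sqrt(((pts[1:] - pts[:-1]) ** 2).sum(axis=1)).sum()
    if closed:
        seg += float(np.sqrt(((pts[0] - pts[-1]) ** 2).sum()))
    return float(seg) * ps / 1000.0


def quantify_field(
    records: list,
    field: IFField,
    tissue_density: float | None = None,
    bm_length_mm: float | None = None,
    config: CellConfig | None = None,
) -> FieldQuantification:
    """Counts, densities and EdU fractions for one field.

    Alveolar: density = count / (field area × tissue density), per mm² of
    alveolar tissue.  Bronchiolar: density = count / basement-membrane
    length, per mm.  EdU fractions are percentages; a type with zero cells
    reports a missing (None) fraction.
    """
    types = ALVEOLAR_TYPES if field.compartment == "alveolar" else BRONCHIOLAR_TYPES
    counts = {t: 0 for t in types}
    edu_counts = {t: 0 for t in types}
    for r in records:
        if r.cell_type not in counts:
            raise CellQuantError(
                f"cell type {r.cell_type!r} inconsistent with {field.compartment} compartment"
            )
        counts[r.cell_type] += 1
        if r.edu_positive:
            edu_counts[r.cell_type] += 1

    if field.compartment == "alveolar":
        if tissue_density is None or not 0 < tissue_density <= 1:
            raise CellQuantError("alveolar fields need tissue_density in (0, 1]")
        denom = field.field_area_mm2 * tissue_density
        if denom <= 0:
            raise CellQuantError("zero normalising area")
        densities = {t: counts[t] / denom for t in types}
        bm = None
    else:
        bm = bm_length_mm if bm_length_mm is not None else basement_membrane_length(field, config)
        if not bm > 0:
            raise CellQuantError("zero basement-membrane length")
        densities = {t: counts[t] / bm for t in types}

    edu_fractions = {
        t: (100.0 * edu_counts[t] / counts[t]) if counts[t] else None for t in types
    }
    return FieldQuantification(
        counts=counts,
        edu_counts=edu_counts,
        densities=densities,
        edu_fractions=edu_fractions,
        tissue_density=tissue_density,
        bm_length_mm=bm,
        image_id=field.image_id,
        mouse_id=field.mouse_id,
    )
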