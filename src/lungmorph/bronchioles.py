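"""Bronchiole cross-section morphometry.

A bronchiole cross-section is modelled as a lumen (closed non-tissue
component) enclosed by an epithelial ring (the surrounding tissue annulus).
Detection keeps candidates whose whole-region (lumen ∪ ring) Feret diameter
falls in the 100–500 µm window; everything smaller is alveolar, everything
larger a main bronchus.

Wall thickness follows the shortest-distance definition: for every point on
the outer epithelial limit, the distance to the nearest point of the inner
limit; the reported value is the mean over all outer boundary points, which
amounts to thousands of measurements per bronchiole at sub-micron pixel
sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .config import SegmentationConfig
from .geometry import (
    Contour,
    Region,
    circularity,
    feret_diameter,
    mask_contours,
    min_distance_contour_to_contour,
    region_area,
)
from .segmentation import SectionMasks

_EIGHT = np.ones((3, 3), dtype=int)


class BronchioleError(ValueError):
    pass


@dataclass
class BronchioleMeasurement:
    whole_area: float
    lumen_area: float
    wall_area: float
    whole_feret: float
    lumen_feret: float
    wall_thickness_mean: float
    circ_whole: float
    circ_lumen: float
    n_thickness_samples: int
    bronchiole_id: str = ""

    def as_dict(self):
        return dict(
            bronchiole_id=self.bronchiole_id,
            whole_area_um2=self.whole_area,
            lumen_area_um2=self.lumen_area,
            wall_area_um2=self.wall_area,
            whole_feret_um=self.whole_feret,
            lumen_feret_um=self.lumen_feret,
            wall_thickness_um=self.wall_thickness_mean,
            circ_whole=self.circ_whole,
            circ_lumen=self.circ_lumen,
            n_thickness_samples=self.n_thickness_samples,
        )


def detect_bronchioles(
    masks: SectionMasks, config: SegmentationConfig | None = None
) -> list[tuple[Region, Region]]:
    """Find (whole, lumen) region pairs for bronchiole candidates.

    A candidate lumen is a closed non-tissue component; its ring is the
    adjacent tissue component, trimmed to ``ring_thickness_cap_um`` around
    the lumen so that attached alveolar walls are not annexed.  Candidates
    touching the image border are rejected (truncated geometry), as are
    those outside the whole-Feret window.  Ordering is deterministic
    (row-major by lumen position).
    """
    config = config or SegmentationConfig()
    ps = masks.pixel_size
    lo, hi = config.bronchiole_feret_range_um
    cap_px = config.ring_thickness_cap_um / ps

    air = masks.section_mask & ~masks.tissue_mask
    air_lab, n_air = ndi.label(air, structure=_EIGHT)
    tis_lab, _ = ndi.label(masks.tissue_mask, structure=_EIGHT)

    h, w = air.shape
    out = []
    for sl_idx, sl in enumerate(ndi.find_objects(air_lab), start=1):
        if sl is None:
            continue
        # quick size gate on the lumen bounding box: the lumen of an in-window
        # bronchiole cannot be larger than the window upper bound
        bb_diag = np.hypot(sl[0].stop - sl[0].start, sl[1].stop - sl[1].start) * ps
        if bb_diag > hi * 1.5:
            continue
        # expand bbox by the ring cap
        pad = int(np.ceil(cap_px)) + 2
        r0, r1 = max(0, sl[0].start - pad), min(h, sl[0].stop + pad)
        c0, c1 = max(0, sl[1].start - pad), min(w, sl[1].stop + pad)
        lumen_local = air_lab[r0:r1, c0:c1] == sl_idx

        # closed lumen only: must not touch image border or leave the section
        touches_border = (
            sl[0].start == 0 or sl[1].start == 0 or sl[0].stop == h or sl[1].stop == w
        )
        if touches_border:
            continue
        dil = ndi.binary_dilation(lumen_local, structure=_EIGHT.astype(bool))
        shell = dil & ~lumen_local
        if np.any(shell & ~masks.tissue_mask[r0:r1, c0:c1]):
            continue  # lumen not fully enclosed by tissue

        ring_labels = np.unique(tis_lab[r0:r1, c0:c1][shell])
        ring_labels = ring_labels[ring_labels > 0]
        if ring_labels.size == 0:
            continue
        ring_local = np.isin(tis_lab[r0:r1, c0:c1], ring_labels)
        # trim the ring to the thickness cap around the lumen
        dist = ndi.distance_transform_edt(~lumen_local)
        ring_local &= dist <= cap_px
        # keep only ring parts connected to the lumen shell
        ring_cc, n_cc = ndi.label(ring_local, structure=_EIGHT)
        keep = np.unique(ring_cc[shell])
        keep = keep[keep > 0]
        ring_local = np.isin(ring_cc, keep)

        whole_local = lumen_local | ring_local
        # reject if the whole region is cut by the image border
        rr, cc = np.nonzero(whole_local)
        if (
            rr.min() + r0 == 0
            or cc.min() + c0 == 0
            or rr.max() + r0 == h - 1
            or cc.max() + c0 == w - 1
        ):
            continue

        whole = Region(np.stack([rr + r0, cc + c0], axis=1), ps, validate=False)
        if not (lo <= feret_diameter(whole) <= hi):
            continue
        lr, lc = np.nonzero(lumen_local)
        lumen = Region(np.stack([lr + r0, lc + c0], axis=1), ps, validate=False)
        out.append((whole, lumen))
    return out


def _largest_closed(contours: list[Contour]) -> Contour:
    closed = [c for c in contours if c.closed]
    if not closed:
        raise BronchioleError("no closed boundary contour")
    return max(closed, key=lambda c: c.length)


def delineate_epithelium(outer: Region, lumen: Region) -> tuple[Contour, Contour]:
    """Sub-pixel closed contours of the outer epithelial limit and the lumen.

    Raises ``degenerate bronchiole`` when the lumen is not strictly inside
    the outer region (a one-pixel tissue rim must separate them from the
    outside).
    """
    if outer.pixel_size != lumen.pixel_size:
        raise BronchioleError("pixel sizes differ")
    om, origin = outer.to_mask()
    lm_mask = np.zeros_like(om)
    lp = lumen.pixels - origin
    if lp.min() < 0 or (lp[:, 0] >= om.shape[0]).any() or (lp[:, 1] >= om.shape[1]).any():
        raise BronchioleError("degenerate bronchiole: lumen not inside outer region")
    lm_mask[lp[:, 0], lp[:, 1]] = True
    if not (om[lp[:, 0], lp[:, 1]]).all():
        raise BronchioleError("degenerate bronchiole: lumen not inside outer region")
    ring = om & ~lm_mask
    dil = ndi.binary_dilation(lm_mask, structure=_EIGHT.astype(bool)) & ~lm_mask
    if np.any(dil & ~ring):
        raise BronchioleError("degenerate bronchiole: lumen touches outer boundary")

    ps = outer.pixel_size
    outer_contour = _largest_closed(mask_contours(om, ps))
    inner_contour = _largest_closed(mask_contours(lm_mask, ps))
    # shift into absolute image coordinates
    shift = np.array([origin[1], origin[0]], dtype=float) * ps
    outer_contour = Contour(outer_contour.points + shift, closed=True)
    inner_contour = Contour(inner_contour.points + shift, closed=True)
    return outer_contour, inner_contour


def measure_bronchiole(
    outer: Region, lumen: Region, bronchiole_id: str = ""
) -> BronchioleMeasurement:
    """All reported quantities for one bronchiole.

    Areas satisfy whole = lumen + wall exactly (pixel-count arithmetic).
    """
    outer_contour, inner_contour = delineate_epithelium(outer, lumen)
    whole_area = region_area(outer)
    lumen_area = region_area(lumen)
    thick = min_distance_contour_to_contour(outer_contour, inner_contour)
    return BronchioleMeasurement(
        whole_area=whole_area,
        lumen_area=lumen_area,
        wall_area=whole_area - lumen_area,
        whole_feret=feret_diameter(outer),
        lumen_feret=feret_diameter(lumen),
        wall_thickness_mean=float(np.mean(thick)),
        circ_whole=circularity(outer),
        circ_lumen=circularity(lumen),
        n_thickness_samples=len(thick),
        bronchiole_id=bronchiole_id,
    )


def analyze_bronchioles(
    masks: SectionMasks, config: SegmentationConfig | None = None, image_id: str = ""
) -> pd.DataFrame:
    """Detect and measure every bronchiole in one image."""
    rows = []
    for k, (whole, lumen) in enumerate(detect_bronchioles(masks, config)):
        m = measure_bronchiole(whole, lumen, bronchiole_id=f"{image_id or 'img'}:{k}")
        rows.append(m.as_dict())
    cols = [
        "bronchiole_id",
        "whole_area_um2",
        "lumen_area_um2",
        "wall_area_um2",
        "whole_feret_um",
        "lumen_feret_um",
        "wall_thickness_um",
        "circ_whole",
        "circ_lumen",
        "n_thickness_samples",
    ]
    return pd.DataFrame(rows, columns=cols)
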