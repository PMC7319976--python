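"""Parenchymal morphometry: airspace fraction, tissue density, and Lm.

The mean linear intercept (Lm) is computed here as the unweighted mean
Feret diameter of all closed airspaces in the section — not by counting
grid-line intersections.  Every closed airspace in the image contributes,
which removes region-of-interest selection from the measurement.

Area fractions are computed over the section with large bronchus/vessel
lumina removed from both numerator and denominator, so that

    airspace_area_fraction + tissue_density == 1

holds exactly (pixel-count arithmetic) on every image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SegmentationConfig
from .geometry import feret_diameter
from .segmentation import (
    AirspaceSet,
    HistologyImage,
    SectionMasks,
    exclude_large_structures,
    identify_closed_airspaces,
    segment_tissue,
)


class ParenchymaError(ValueError):
    pass


@dataclass
class ParenchymaMetrics:
    """Per-image parenchymal statistics."""

    airspace_area_fraction: float
    tissue_density: float
    lm: float
    n_airspaces: int
    image_id: str = ""


def _pixel_counts(masks: SectionMasks, airspaces: AirspaceSet, config: SegmentationConfig):
    removed = airspaces.excluded_large.copy()
    if config.exclude_border_airspaces_from_fraction:
        removed |= airspaces.border_touching
    removed_px = sum(airspaces.airspaces[i].n_pixels for i in np.flatnonzero(removed))
    section_px = int(masks.section_mask.sum())
    tissue_px = int(masks.tissue_mask.sum())
    air_px = section_px - tissue_px
    denom = section_px - removed_px
    if denom <= 0:
        raise ParenchymaError("zero section area after exclusions")
    return air_px - removed_px, tissue_px, denom


def airspace_area_fraction(
    masks: SectionMasks, airspaces: AirspaceSet, config: SegmentationConfig | None = None
) -> float:
    """Airspace area / section area, large structures removed from both."""
    num, _, denom = _pixel_counts(masks, airspaces, config or SegmentationConfig())
    return num / denom


def tissue_density(
    masks: SectionMasks, airspaces: AirspaceSet, config: SegmentationConfig | None = None
) -> float:
    """Alveolar tissue area / section area; equals 1 − airspace fraction."""
    _, tis, denom = _pixel_counts(masks, airspaces, config or SegmentationConfig())
    return tis / denom


def compute_lm(airspaces: AirspaceSet) -> tuple[float, int]:
    """Mean Feret diameter (µm) of closed, non-excluded airspaces.

    Unweighted mean across airspaces; raises if none qualify.
    """
    idx = np.flatnonzero(airspaces.closed)
    if idx.size == 0:
        raise ParenchymaError("no closed airspaces")
    ferets = [feret_diameter(airspaces.airspaces[i]) for i in idx]
    return float(np.mean(ferets)), int(idx.size)


def analyze_parenchyma(
    image: HistologyImage | SectionMasks,
    config: SegmentationConfig | None = None,
    image_id: str = "",
) -> ParenchymaMetrics:
    """Full per-image pipeline: segment → label airspaces → flag → metrics."""
    config = config or SegmentationConfig()
    masks = image if isinstance(image, SectionMasks) else segment_tissue(image, config)
    airspaces = exclude_large_structures(identify_closed_airspaces(masks, config), config)
    frac = airspace_area_fraction(masks, airspaces, config)
    dens = tissue_density(masks, airspaces, config)
    try:
        lm, n = compute_lm(airspaces)
    except ParenchymaError:
        lm, n = float("nan"), 0
    return ParenchymaMetrics(frac, dens, lm, n, image_id=image_id or masks.source_id)
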