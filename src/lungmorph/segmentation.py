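"""Lung-section and airspace segmentation.

From a pseudo-H&E image (or a binary tissue mask) this module derives:

* the *section mask* — the extent of the lung section on the slide,
* the *tissue mask* — stain-positive (septal) tissue within the section,
* the labelled set of *closed airspaces*: connected non-tissue components
  inside the section, flagged when they touch a border (not measurable) or
  when they are large bronchus/vessel lumina (excluded from parenchyma
  metrics).

Stain separation for RGB input uses fixed published H&E stain vectors
(skimage's H&E deconvolution) with a single global Otsu threshold on the
combined stain optical density, clamped by config bounds; there is no
training step and the output is deterministic for a fixed config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import color, filters, morphology

from .config import SegmentationConfig
from .geometry import Region, circularity, feret_diameter, region_area

_EIGHT = np.ones((3, 3), dtype=int)


class SegmentationError(ValueError):
    pass


@dataclass
class HistologyImage:
    """A 2-D histology image with physical pixel size (µm, isotropic)."""

    pixels: np.ndarray
    pixel_size: float
    source_id: str = ""

    def __post_init__(self):
        arr = np.asarray(self.pixels)
        if arr.ndim not in (2, 3):
            raise SegmentationError("image must be 2-D (grayscale/binary) or RGB")
        if min(arr.shape[:2]) < 64:
            raise SegmentationError("image smaller than 64 px")
        if not self.pixel_size > 0:
            raise SegmentationError("pixel_size must be > 0")
        self.pixels = arr


@dataclass
class SectionMasks:
    """Section and tissue masks of one image; tissue ⊆ section."""

    section_mask: np.ndarray
    tissue_mask: np.ndarray
    pixel_size: float
    source_id: str = ""

    def __post_init__(self):
        self.section_mask = np.asarray(self.section_mask, dtype=bool)
        self.tissue_mask = np.asarray(self.tissue_mask, dtype=bool)
        if self.section_mask.shape != self.tissue_mask.shape:
            raise SegmentationError("mask shapes differ")
        if np.any(self.tissue_mask & ~self.section_mask):
            raise SegmentationError("tissue mask extends outside section mask")


@dataclass
class AirspaceSet:
    """Labelled closed airspaces of a section with exclusion flags."""

    airspaces: list
    border_touching: np.ndarray
    excluded_large: np.ndarray
    pixel_size: float = field(default=0.0)

    def __post_init__(self):
        self.border_touching = np.asarray(self.border_touching, dtype=bool)
        self.excluded_large = np.asarray(self.excluded_large, dtype=bool)
        n = len(self.airspaces)
        if len(self.border_touching) != n or len(self.excluded_large) != n:
            raise SegmentationError("flag arrays must match airspace count")
        if n and self.pixel_size == 0.0:
            self.pixel_size = self.airspaces[0].pixel_size

    def __len__(self):
        return len(self.airspaces)

    @property
    def closed(self) -> np.ndarray:
        """Measurable airspaces: not border-touching, not excluded as large."""
        return ~self.border_touching & ~self.excluded_large

    def to_table(self) -> pd.DataFrame:
        rows = []
        for i, region in enumerate(self.airspaces):
            rows.append(
                dict(
                    airspace_id=i,
                    area_um2=region_area(region),
                    feret_um=feret_diameter(region),
                    border_touching=bool(self.border_touching[i]),
                    excluded_large=bool(self.excluded_large[i]),
                )
            )
        return pd.DataFrame(
            rows,
            columns=["airspace_id", "area_um2", "feret_um", "border_touching", "excluded_large"],
        )


def _stain_density(rgb: np.ndarray) -> np.ndarray:
    """Combined hematoxylin + eosin optical density of an RGB image."""
    arr = rgb.astype(float)
    if arr.max() > 1.0:
        arr = arr / 255.0
    hed = color.rgb2hed(arr)
    return hed[..., 0] + hed[..., 1]


def segment_tissue(image: HistologyImage, config: SegmentationConfig | None = None) -> SectionMasks:
    """Derive section and tissue masks from an image.

    Binary input passes through as the tissue mask.  Grayscale input is
    thresholded directly (Otsu); RGB input is thresholded on the combined
    H&E stain optical density.  The section mask is the hole-filled
    morphological closing of the tissue mask, so enclosed airspaces belong
    to the section.
    """
    config = config or SegmentationConfig()
    arr = image.pixels
    if arr.ndim == 3:
        density = _stain_density(arr)
        thr = config.stain_threshold
        if thr is None:
            lo, hi = config.stain_threshold_bounds
            thr = float(np.clip(filters.threshold_otsu(density), lo, hi))
        tissue = density > thr
    elif arr.dtype == bool or set(np.unique(arr)).issubset({0, 1}):
        tissue = arr.astype(bool)
    else:
        thr = config.stain_threshold
        if thr is None:
            thr = float(filters.threshold_otsu(arr.astype(float)))
        tissue = arr.astype(float) > thr

    if not tissue.any():
        raise SegmentationError("no tissue detected")

    radius = max(1, int(round(config.section_closing_um / image.pixel_size)))
    # pad with edge values so closing does not erode tissue touching the frame
    padded = np.pad(tissue, radius, mode="edge")
    closed = ndi.binary_closing(padded, structure=morphology.disk(radius).astype(bool))
    section = ndi.binary_fill_holes(closed[radius:-radius, radius:-radius])
    tissue = tissue & section
    return SectionMasks(section, tissue, image.pixel_size, source_id=image.source_id)


def identify_closed_airspaces(
    masks: SectionMasks, config: SegmentationConfig | None = None
) -> AirspaceSet:
    """Label airspaces (section ∧ ¬tissue) and flag border-touching ones.

    Components smaller than ``min_airspace_area_um2`` are dropped as noise.
    Ordering is deterministic: row-major by first pixel (top-left).
    """
    config = config or SegmentationConfig()
    air = masks.section_mask & ~masks.tissue_mask
    lab, n = ndi.label(air, structure=_EIGHT)
    if n == 0:
        return AirspaceSet([], np.zeros(0, bool), np.zeros(0, bool), masks.pixel_size)

    min_px = config.min_airspace_area_um2 / masks.pixel_size**2
    counts = np.bincount(lab.ravel(), minlength=n + 1)

    # labels adjacent to outside-section background or to the image border are open
    outside = ~masks.section_mask
    near_outside = ndi.binary_dilation(outside, structure=_EIGHT.astype(bool))
    open_labels = set(np.unique(lab[near_outside & air]))
    border = np.zeros_like(air)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    open_labels |= set(np.unique(lab[border & air]))
    open_labels.discard(0)

    regions, flags = [], []
    slices = ndi.find_objects(lab)
    for i in range(1, n + 1):
        if counts[i] < min_px:
            continue
        sl = slices[i - 1]
        local = np.argwhere(lab[sl] == i)
        local += [sl[0].start, sl[1].start]
        regions.append(Region(local, masks.pixel_size, validate=False))
        flags.append(i in open_labels)
    return AirspaceSet(
        regions, np.array(flags, bool), np.zeros(len(regions), bool), masks.pixel_size
    )


def exclude_large_structures(
    airspaces: AirspaceSet, config: SegmentationConfig | None = None
) -> AirspaceSet:
    """Flag bronchus/vessel lumina so parenchyma metrics skip them.

    Primary rule: Feret diameter ≥ ``large_structure_feret_um`` (default
    100 µm, the lower bound of the bronchiole size window, keeping the
    bronchiole and parenchyma analyses disjoint).  Secondary rule: very
    round components (circularity ≥ ``vessel_circ_min``) with area ≥
    ``vessel_area_min_um2`` are flagged as vessel lumina.  Flagged
    airspaces stay in the set but are excluded downstream.
    """
    config = config or SegmentationConfig()
    flags = np.zeros(len(airspaces), dtype=bool)
    for i, region in enumerate(airspaces.airspaces):
        f = feret_diameter(region)
        if f >= config.large_structure_feret_um:
            flags[i] = True
        elif (
            config.vessel_circ_min is not None
            and region_area(region) >= config.vessel_area_min_um2
        ):
            if circularity(region) >= config.vessel_circ_min:
                flags[i] = True
    return AirspaceSet(
        airspaces.airspaces, airspaces.border_touching.copy(), flags, airspaces.pixel_size
    )
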