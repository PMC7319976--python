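"""Tunable parameters for segmentation and quantification.

Defaults are chosen for 20x slide scans at 0.452 µm/px and are documented
in docs/methods.md.  Every threshold that stands in for an unstated rule of
the original analysis (large-structure removal, EdU positivity) is exposed
here rather than hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import yaml

PAPER_PIXEL_SIZE_UM = 0.452  # 20x slide-scanner resolution


@dataclass
class SegmentationConfig:
    """Parameters for tissue segmentation and airspace analysis.

    Attributes
    ----------
    min_airspace_area_um2
        Components below this area are treated as staining noise, far below
        any alveolar cross-section.
    large_structure_feret_um
        Non-tissue components at least this wide are flagged as large
        bronchi/vessel lumina and excluded from parenchyma metrics; the
        default matches the lower bound of the bronchiole detection window
        so the two analyses stay disjoint.
    vessel_circ_min, vessel_area_min_um2
        Secondary rule: very round, large airspaces are flagged as vessel
        lumina even below the Feret cutoff.  Disabled by default
        (``vessel_circ_min = None``): on real H&E the smoothness of a
        vessel lumen separates it from crinkly alveoli, but no circularity
        threshold can make that distinction for smooth synthetic shapes,
        so the rule is opt-in.
    section_closing_um
        Radius of the morphological closing used to bridge the tissue mask
        before hole filling when building the section mask.
    stain_threshold
        Optical-density threshold on the combined H&E stain density; None
        selects Otsu's threshold clamped to ``stain_threshold_bounds``.
    exclude_border_airspaces_from_fraction
        If True, border-touching airspaces are also dropped from the
        area-fraction numerator (they are always dropped from Lm).
    bronchiole_feret_range_um
        Whole-bronchiole Feret window for detection.
    ring_thickness_cap_um
        Maximum epithelium thickness annexed around a lumen when the
        surrounding tissue component is larger than the true ring.
    """

    min_airspace_area_um2: float = 20.0
    large_structure_feret_um: float = 100.0
    vessel_circ_min: float | None = None
    vessel_area_min_um2: float = 2000.0
    section_closing_um: float = 10.0
    stain_threshold: float | None = None
    stain_threshold_bounds: tuple = (0.01, 0.6)
    exclude_border_airspaces_from_fraction: bool = False
    bronchiole_feret_range_um: tuple = (100.0, 500.0)
    ring_thickness_cap_um: float = 60.0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "SegmentationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("stain_threshold_bounds", "bronchiole_feret_range_um"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class CellConfig:
    """Parameters for IF cell classification.

    ``edu_overlap_frac``: a nucleus is EdU+ when at least this fraction of
    its pixels overlap the EdU channel ("EdU+ nuclei").
    ``perinuclear_radius_um``: width of the peri-nuclear ring probed for
    Lamp3 vesicles around each nucleus.
    ``marker_overlap_frac``: minimum fraction of the probe area a marker
    must cover to call the cell positive.
    ``band_closing_um``: closing radius used to knit the bronchiolar
    epithelial band together before watershed territory assignment.
    """

    edu_overlap_frac: float = 0.3
    perinuclear_radius_um: float = 1.2
    marker_overlap_frac: float = 0.1
    nuclear_overlap_frac: float = 0.3
    band_closing_um: float = 6.0
    count_edge_cells_by_centroid: bool = True
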