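"""Synthetic-histology generators: determinism, feasibility guards, and
agreement between analytic truth and geometric re-measurement."""

import numpy as np
import pytest

from lungmorph.geometry import feret_diameter, region_area
from lungmorph.segmentation import identify_closed_airspaces, segment_tissue
from lungmorph.synth import (
    BronchioleSpec,
    CohortSpec,
    IFFieldSpec,
    MetricGroupSpec,
    ParenchymaSpec,
    SynthesisError,
    generate_bronchiole,
    generate_cohort,
    generate_if_field,
    generate_parenchyma,
)


class TestParenchymaGenerator:
    def test_determinism(self):
        spec = ParenchymaSpec(field_size=400, pixel_size=1.0,
                              target_tissue_density=0.75, seed=42)
        a, ta = generate_parenchyma(spec)
        b, tb = generate_parenchyma(spec)
        assert np.array_equal(a.pixels, b.pixels)
        assert np.array_equal(ta.airspace_ferets, tb.airspace_ferets)

    def test_density_guard(self):
        img, truth = generate_parenchyma(
            ParenchymaSpec(field_size=500, pixel_size=1.0,
                           target_tissue_density=0.7, seed=1)
        )
        assert abs(truth.tissue_density - 0.7) <= 0.01

    def test_infeasible_spec_raises(self):
        with pytest.raises(SynthesisError):
            generate_parenchyma(
                ParenchymaSpec(field_size=120, pixel_size=1.0,
                               airspace_feret_mean=44.0, n_airspaces=30, seed=0)
            )

    def test_truth_ferets_match_remeasurement(self):
        """Analytic truth vs geometry re-measurement: max(2 %, 1 px)."""
        spec = ParenchymaSpec(field_size=500, pixel_size=1.0, n_airspaces=40,
                              target_tissue_density=None, seed=8)
        img, truth = generate_parenchyma(spec)
        aset = identify_closed_airspaces(segment_tissue(img))
        assert len(aset) == 40
        measured = sorted(feret_diameter(r) for r in aset.airspaces)
        for m, t in zip(measured, sorted(truth.airspace_ferets)):
            assert abs(m - t) <= max(0.02 * t, 1.0)


class TestBronchioleGenerator:
    def test_lumen_feret_truth_geometry(self):
        _, truth = generate_bronchiole(BronchioleSpec(outer_feret=243.0,
                                                      wall_thickness=20.4, seed=0))
        assert truth.lumen_feret == pytest.approx(243.0 - 2 * 20.4, abs=1e-6)
        assert truth.wall_thickness_mean == pytest.approx(20.4, abs=0.05)

    def test_out_of_window_spec_still_generates(self):
        img, truth = generate_bronchiole(
            BronchioleSpec(outer_feret=600.0, wall_thickness=25.0, pixel_size=1.0, seed=1)
        )
        assert truth.outer_feret == pytest.approx(600.0, abs=0.5)

    def test_eccentric_gap_range(self):
        _, truth = generate_bronchiole(
            BronchioleSpec(outer_feret=240.0, wall_thickness=20.0, eccentricity=5.0, seed=2)
        )
        assert truth.wall_gap_min == pytest.approx(15.0, abs=0.3)
        assert truth.wall_gap_max == pytest.approx(25.0, abs=0.3)

    def test_invalid_specs_rejected(self):
        with pytest.raises(SynthesisError):
            BronchioleSpec(outer_feret=100.0, wall_thickness=60.0)
        with pytest.raises(SynthesisError):
            BronchioleSpec(wall_thickness=20.0, boundary_wobble_amp=15.0)
        with pytest.raises(SynthesisError):
            BronchioleSpec(wall_thickness=20.0, eccentricity=25.0)

    def test_areas_match_pixel_measurement(self):
        img, truth = generate_bronchiole(BronchioleSpec(seed=3))
        ps = truth.pixel_size
        tissue_px = int(img.pixels.astype(bool).sum())
        assert tissue_px * ps**2 == pytest.approx(truth.wall_area, rel=0.02)


class TestIFGenerator:
    def test_determinism(self):
        spec = IFFieldSpec(field_size=300, seed=9)
        a, ta = generate_if_field(spec)
        b, tb = generate_if_field(spec)
        for ch in a.channels:
            assert np.array_equal(a.channels[ch], b.channels[ch])
        assert ta.cells.equals(tb.cells)

    def test_zero_edu_spec(self):
        spec = IFFieldSpec(
            field_size=300,
            densities={"typeII": 8000.0, "typeI": 5000.0},
            edu_fractions={"typeII": 0.0, "typeI": 0.0},
            seed=2,
        )
        field, truth = generate_if_field(spec)
        assert not truth.cells.edu_positive.any()
        assert not field.channels["edu"].any()

    def test_exact_edu_planting(self):
        """edu_model='expected' realises round(N·p)/N exactly."""
        spec = IFFieldSpec(field_size=400, count_model="expected",
                           edu_model="expected", seed=3)
        _, truth = generate_if_field(spec)
        for t, pct in spec.edu_fractions.items():
            sub = truth.cells[truth.cells.cell_type == t]
            expected_k = round(len(sub) * pct / 100.0)
            assert sub.edu_positive.sum() == expected_k

    def test_counts_near_expectation(self):
        spec = IFFieldSpec(seed=7)
        field, truth = generate_if_field(spec)
        area = field.field_area_mm2
        for t, d in spec.densities.items():
            expected = d * area * spec.tissue_density
            n = (truth.cells.cell_type == t).sum()
            assert abs(n - expected) <= 4 * np.sqrt(expected)  # Poisson noise

    def test_overcrowded_alveolar_spec_raises(self):
        with pytest.raises(SynthesisError, match="overcrowded|cannot fit"):
            generate_if_field(
                IFFieldSpec(field_size=200,
                            densities={"typeII": 60000.0, "typeI": 40000.0}, seed=0)
            )

    def test_bronchiolar_club_ciliated_counts(self):
        spec = IFFieldSpec(
            compartment="bronchiolar",
            densities={"club": 149.0, "ciliated": 96.0},
            edu_fractions={"club": 17.7, "ciliated": 13.5},
            bm_length_mm=1.0,
            geometry="ring",
            count_model="expected",
            seed=5,
        )
        _, truth = generate_if_field(spec)
        counts = truth.cells.cell_type.value_counts()
        assert counts["club"] == 149 and counts["ciliated"] == 96


class TestCohortGenerator:
    def test_determinism(self):
        spec = CohortSpec(metrics={"m": MetricGroupSpec(1, 0.1, 0.9, 0.1, 0.05)}, seed=3)
        assert generate_cohort(spec).values.equals(generate_cohort(spec).values)

    def test_structure(self):
        spec = CohortSpec(metrics={"a": MetricGroupSpec(1, 0, 1, 0, 0)},
                          n_mice=3, fields_per_mouse=2, seed=0)
        ds = generate_cohort(spec)
        assert len(ds.values) == 2 * 3 * 2
        assert set(ds.values.group) == {"young", "old"}

    def test_invalid_spec_rejected(self):
        with pytest.raises(SynthesisError):
            CohortSpec(metrics={}, n_mice=1)
        with pytest.raises(SynthesisError):
            MetricGroupSpec(1, -0.1, 1, 0.1, 0.1)
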