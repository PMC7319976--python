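"""IF cell classification, basement-membrane length and normalised densities."""

import collections

import numpy as np
import pytest

from lungmorph import basement_membrane_length, classify_cells, quantify_field
from lungmorph.cells import CellQuantError, IFField
from lungmorph.synth import IFFieldSpec, generate_if_field


@pytest.fixture(scope="module")
def alveolar():
    return generate_if_field(IFFieldSpec(seed=7))


@pytest.fixture(scope="module")
def bronchiolar_ring():
    spec = IFFieldSpec(
        compartment="bronchiolar",
        densities={"club": 149.0, "ciliated": 96.0},
        edu_fractions={"club": 17.7, "ciliated": 13.5},
        bm_length_mm=0.628,
        geometry="ring",
        seed=3,
    )
    return generate_if_field(spec)


class TestClassification:
    def test_alveolar_counts_exact(self, alveolar):
        field, truth = alveolar
        res = classify_cells(field, detailed=True)
        got = collections.Counter(r.cell_type for r in res.records)
        want = truth.cells.cell_type.value_counts().to_dict()
        assert dict(got) == want
        assert res.n_unclassified == 0 and res.n_ambiguous == 0

    def test_count_conservation(self, alveolar):
        field, truth = alveolar
        res = classify_cells(field, detailed=True)
        assert res.n_nuclei == len(truth.cells)

    def test_edu_flags_exact(self, alveolar):
        field, truth = alveolar
        records = classify_cells(field)
        got = collections.Counter(
            (r.cell_type, r.edu_positive) for r in records
        )
        want = collections.Counter(
            (t, bool(e)) for t, e in zip(truth.cells.cell_type, truth.cells.edu_positive)
        )
        assert got == want

    def test_bronchiolar_counts_exact(self, bronchiolar_ring):
        field, truth = bronchiolar_ring
        res = classify_cells(field, detailed=True)
        got = collections.Counter(r.cell_type for r in res.records)
        assert dict(got) == truth.cells.cell_type.value_counts().to_dict()

    def test_channel_order_irrelevant(self, alveolar):
        field, _ = alveolar
        reordered = IFField(
            dict(reversed(list(field.channels.items()))),
            field.pixel_size,
            field.compartment,
        )
        a = [(r.cell_type, r.edu_positive, r.centroid) for r in classify_cells(field)]
        b = [(r.cell_type, r.edu_positive, r.centroid) for r in classify_cells(reordered)]
        assert a == b

    def test_empty_markers_give_no_records(self):
        blank = np.zeros((128, 128), dtype=bool)
        field = IFField(
            {k: blank.copy() for k in ("nuclei", "lamp3", "hopx", "edu")}, 0.5, "alveolar"
        )
        assert classify_cells(field) == []

    def test_missing_channel_rejected(self):
        blank = np.zeros((128, 128), dtype=bool)
        field = IFField({"nuclei": blank, "edu": blank}, 0.5, "alveolar")
        with pytest.raises(CellQuantError, match="missing required channel"):
            classify_cells(field)


class TestBasementMembrane:
    def test_straight_strip(self):
        spec = IFFieldSpec(
            compartment="bronchiolar",
            densities={"club": 149.0, "ciliated": 96.0},
            edu_fractions={"club": 0.0, "ciliated": 0.0},
            bm_length_mm=1.0,
            geometry="strip",
            count_model="expected",
            seed=4,
        )
        field, truth = generate_if_field(spec)
        assert basement_membrane_length(field) == pytest.approx(1.0, rel=0.01)

    def test_circular_membrane(self, bronchiolar_ring):
        field, truth = bronchiolar_ring
        assert basement_membrane_length(field) == pytest.approx(0.628, rel=0.02)

    def test_two_borders(self):
        # two lateral borders 50 µm apart; nuclei mark the basal ends
        shape = (60, 140)
        ecad = np.zeros(shape, bool)
        nuclei = np.zeros(shape, bool)
        ecad[20:41, 20] = True
        ecad[20:41, 120] = True  # 100 px = 50 µm at 0.5 µm/px
        nuclei[36:40, 23:27] = True
        nuclei[36:40, 115:119] = True
        field = IFField(
            dict(nuclei=nuclei, ecad=ecad, cc10=np.zeros(shape, bool),
                 actub=np.zeros(shape, bool), edu=np.zeros(shape, bool)),
            0.5, "bronchiolar",
        )
        assert basement_membrane_length(field) == pytest.approx(0.05, rel=0.02)

    def test_single_border_rejected(self):
        shape = (60, 60)
        ecad = np.zeros(shape, bool)
        ecad[10:40, 30] = True
        field = IFField(
            dict(nuclei=np.zeros(shape, bool), ecad=ecad, cc10=np.zeros(shape, bool),
                 actub=np.zeros(shape, bool), edu=np.zeros(shape, bool)),
            0.5, "bronchiolar",
        )
        with pytest.raises(CellQuantError, match="basal points"):
            basement_membrane_length(field)


class TestQuantifyField:
    def test_alveolar_densities_match_truth(self, alveolar):
        field, truth = alveolar
        q = quantify_field(classify_cells(field), field, tissue_density=0.63)
        for t in ("typeII", "typeI"):
            assert q.densities[t] == pytest.approx(truth.densities[t], rel=1e-6)

    def test_normalisation_arithmetic(self):
        """131 cells in 0.0143 mm² at density 0.63 → ≈ 14,540 per mm²."""
        from lungmorph.cells import CellRecord

        side = int(round(np.sqrt(0.0143) * 1000 / 0.452))
        blank = np.zeros((side, side), bool)
        field = IFField(
            {k: blank for k in ("nuclei", "lamp3", "hopx", "edu")}, 0.452, "alveolar"
        )
        records = [CellRecord("typeII", False, (0.0, 0.0))] * 131
        q = quantify_field(records, field, tissue_density=0.63)
        assert q.densities["typeII"] == pytest.approx(131 / (field.field_area_mm2 * 0.63))
        assert q.densities["typeII"] == pytest.approx(14540, rel=0.01)

    def test_bronchiolar_density_per_mm(self, bronchiolar_ring):
        field, truth = bronchiolar_ring
        q = quantify_field(classify_cells(field), field)
        for t in ("club", "ciliated"):
            assert q.densities[t] == pytest.approx(truth.densities[t], rel=0.02)

    def test_zero_edu_fraction(self):
        from lungmorph.cells import CellRecord

        blank = np.zeros((128, 128), bool)
        field = IFField(
            {k: blank for k in ("nuclei", "lamp3", "hopx", "edu")}, 0.5, "alveolar"
        )
        records = [CellRecord("typeII", False, (0.0, 0.0))] * 50
        q = quantify_field(records, field, tissue_density=0.5)
        assert q.edu_fractions["typeII"] == 0.0
        assert q.edu_fractions["typeI"] is None  # no cells: fraction missing

    def test_zero_denominator_rejected(self, alveolar):
        field, _ = alveolar
        with pytest.raises(CellQuantError):
            quantify_field([], field, tissue_density=0.0)

    def test_wrong_compartment_type_rejected(self, alveolar):
        from lungmorph.cells import CellRecord

        field, _ = alveolar
        with pytest.raises(CellQuantError, match="inconsistent"):
            quantify_field(
                [CellRecord("club", False, (0.0, 0.0))], field, tissue_density=0.5
            )
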