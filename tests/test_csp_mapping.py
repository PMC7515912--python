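"""Δδ/ΔINT map construction, SD classification and structure export."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nmrbind import (
    Peak,
    PeakList,
    TitrationSeries,
    average_shift,
    classify_residues,
    combined_shift,
    export_structure_annotation,
    fraction_bound,
    generate_titration,
    intensity_change,
    perturbation_map,
)
from conftest import make_series


class TestCombinedShift:
    @pytest.mark.parametrize(
        "dh,dn,expected",
        [
            (0.0, 0.0, 0.0),
            (0.1, 0.0, 0.1),
            (0.03, 0.2, 0.05830952),  # sqrt(0.0009 + 0.0025)
        ],
    )
    def test_hand_computed_values(self, dh, dn, expected):
        assert combined_shift(dh, dn) == pytest.approx(expected, abs=1e-7)

    _ppm = lambda hi: st.one_of(
        st.just(0.0), st.floats(1e-6, hi), st.floats(-hi, -1e-6))

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(dh=_ppm(2.0), dn=_ppm(10.0))
    def test_is_a_norm(self, dh, dn):
        v = combined_shift(dh, dn)
        assert v >= 0
        assert combined_shift(-dh, dn) == v
        assert combined_shift(dh, -dn) == v
        assert (v == 0) == (dh == 0 and dn == 0)

    def test_n_weight_configurable(self):
        assert combined_shift(0.0, 1.0, n_weight=0.14) == pytest.approx(0.14)


class TestIntensityChange:
    @pytest.mark.parametrize(
        "int_o,int_i,expected",
        [(5.0, 5.0, 0.0), (5.0, 0.0, 1.0), (5.0, 6.0, -0.2)],
    )
    def test_sign_convention(self, int_o, int_i, expected):
        assert intensity_change(int_o, int_i) == pytest.approx(expected)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            intensity_change(0.0, 1.0)


class TestPerturbationMap:
    def test_identity_point_gives_zero_maps(self, small_peaklist):
        series = TitrationSeries(
            20.0, small_peaklist,
            [(100.0, PeakList(list(small_peaklist), ligand_concentration=100.0))],
        )
        pmap = perturbation_map(series, 0)
        assert np.allclose(pmap.table["delta_delta"], 0.0)
        assert np.allclose(pmap.table["delta_int"], 0.0)
        assert pmap.n_broadened == 0

    def test_removed_residue_flagged_broadened_with_dint_1(self, small_peaklist):
        point = PeakList([p for p in small_peaklist if p.residue_number != 160],
                         ligand_concentration=50.0)
        series = TitrationSeries(20.0, small_peaklist, [(50.0, point)])
        pmap = perturbation_map(series, 0)
        row = pmap.table.loc[160]
        assert row["status"] == "broadened_out"
        assert row["delta_int"] == 1.0
        assert math.isnan(row["delta_delta"])
        # statistics exclude the vanished residue
        assert pmap.mean_dd == pytest.approx(0.0)

    def test_fast_exchange_dd_equals_fb_times_offset(self, crd_protein, fast_design):
        """At zero noise in the fast limit, each residue's Δδ is the bound
        fraction times the combined bound-state offset."""
        series = generate_titration(crd_protein, fast_design)
        i = 2
        fb = fraction_bound(fast_design.protein_concentration,
                            series.concentrations[i], fast_design.kd)
        pmap = perturbation_map(series, i)
        for r in crd_protein.binding_site:
            expected = fb * combined_shift(crd_protein.offset_h[r], crd_protein.offset_n[r])
            assert pmap.table.loc[r, "delta_delta"] == pytest.approx(expected, rel=1e-3)

    def test_empty_overlap_errors(self, small_peaklist):
        point = PeakList([Peak(999, 8.0, 120.0, 1.0)], ligand_concentration=10.0)
        series = TitrationSeries(20.0, small_peaklist, [(10.0, point)])
        with pytest.raises(ValueError):
            pmap = perturbation_map(series, 0)
            classify_residues(pmap)  # all broadened: nothing observable


class TestAverageShift:
    def _map(self, values):
        apo = {r: (8.0, 120.0, 1e6) for r in range(1, len(values) + 1)}
        pt = {r: (8.0 + values[r - 1], 120.0, 1e6) for r in apo}
        return perturbation_map(make_series(apo, pt), 0)

    def test_single_residue_mean_is_value(self):
        pmap = self._map([0.25, 0.1])
        assert average_shift(pmap, subset=[1]) == pytest.approx(0.25)

    def test_two_residue_mean(self):
        pmap = self._map([0.1, 0.3])
        assert average_shift(pmap) == pytest.approx(0.2)

    def test_broadened_residues_do_not_shift_the_mean(self, small_peaklist):
        point = PeakList(
            [Peak(124, small_peaklist[124].shift_h + 0.1,
                  small_peaklist[124].shift_n, 1e6, "G"),
             Peak(146, small_peaklist[146].shift_h + 0.3,
                  small_peaklist[146].shift_n, 1e6, "A")],
            ligand_concentration=10.0)  # residue 160 vanished
        series = TitrationSeries(20.0, small_peaklist, [(10.0, point)])
        pmap = perturbation_map(series, 0)
        assert average_shift(pmap) == pytest.approx(0.2)

    def test_empty_subset_errors(self):
        pmap = self._map([0.1, 0.3])
        with pytest.raises(ValueError):
            average_shift(pmap, subset=[99])


class TestClassifyResidues:
    def _map_from_values(self, values):
        apo = {r: (8.0, 120.0, 1e6) for r in range(1, len(values) + 1)}
        pt = {r: (8.0 + values[r - 1], 120.0, 1e6) for r in apo}
        return perturbation_map(make_series(apo, pt), 0)

    def test_uniform_map_has_no_outliers(self, caplog):
        pmap = self._map_from_values([0.05] * 6)
        with caplog.at_level("WARNING"):
            cls = classify_residues(pmap)
        assert cls.residues("above_1sd") == []
        assert cls.residues("above_2sd") == []
        assert "zero SD" in caplog.text

    def test_hand_computed_sd_classification(self):
        # values {0.01 x9, 0.10}: mean 0.019, sample SD 0.0285
        pmap = self._map_from_values([0.01] * 9 + [0.10])
        assert pmap.mean_dd == pytest.approx(0.019, abs=1e-12)
        assert pmap.sd_dd == pytest.approx(0.02846, abs=1e-4)
        cls = classify_residues(pmap)
        assert cls.residues("above_2sd") == [10]
        assert cls.residues("above_1sd") == []

    def test_missing_residue_propagates(self, small_peaklist):
        point = PeakList([p for p in small_peaklist if p.residue_number != 160],
                         ligand_concentration=10.0)
        series = TitrationSeries(20.0, small_peaklist, [(10.0, point)])
        cls = classify_residues(perturbation_map(series, 0))
        assert 160 in cls.residues("missing")

    def test_categories_partition_and_nest(self, crd_protein):
        """Every residue gets exactly one category and the 2SD set never
        outgrows the union of flagged sets."""
        from nmrbind import SyntheticDesign

        design = SyntheticDesign(
            ligand_concentrations=(100.0, 400.0), kd=190.0, seed=5)
        series = generate_titration(crd_protein, design)
        pmap = perturbation_map(series, 1)
        cls = classify_residues(pmap)
        n = sum(len(cls.residues(c)) for c in
                ("above_2sd", "above_1sd", "below", "missing"))
        assert n == len(cls.table)
        assert len(cls.residues("above_2sd")) <= n


class TestFalsePositiveRate:
    def test_null_residues_rarely_cross_2sd(self, crd_protein):
        """Background (non-binding-site) residues should exceed the 2SD
        threshold in at most ~5% of calls under measurement noise alone."""
        from nmrbind import SyntheticDesign

        null = set(crd_protein.residues) - set(crd_protein.binding_site)
        false_calls = total = 0
        for seed in range(200):
            design = SyntheticDesign(
                ligand_concentrations=(200.0,), kd=190.0, seed=seed)
            series = generate_titration(crd_protein, design)
            cls = classify_residues(perturbation_map(series, 0))
            hits = set(cls.residues("above_2sd")) & null
            false_calls += len(hits)
            total += len(null)
        assert false_calls / total <= 0.05


class TestStructureExport:
    @pytest.fixture
    def tiny_pdb(self, tmp_path):
        from Bio.PDB import PDBIO
        from Bio.PDB.StructureBuilder import StructureBuilder

        sb = StructureBuilder()
        sb.init_structure("tiny")
        sb.init_model(0)
        sb.init_chain("A")
        sb.init_seg("    ")
        serial = 1
        for resseq, resname in [(1, "ALA"), (2, "GLY"), (3, "SER")]:
            sb.init_residue(resname, " ", resseq, " ")
            for name in ("N", "CA", "C"):
                sb.init_atom(name, np.array([1.0 * serial, 2.0, 3.0]), 25.0, 1.0,
                             " ", name.ljust(3), serial, element=name[0])
                serial += 1
        io = PDBIO()
        io.set_structure(sb.get_structure())
        path = tmp_path / "tiny.pdb"
        io.save(str(path))
        return path

    def _classified(self, values):
        apo = {r: (8.0, 120.0, 1e6) for r in range(1, len(values) + 1)}
        pt = {r: (8.0 + values[r - 1], 120.0, 1e6) for r in apo}
        return classify_residues(perturbation_map(make_series(apo, pt), 0))

    def test_bfactor_mode_writes_delta_delta(self, tiny_pdb, tmp_path):
        from Bio.PDB import PDBParser

        cls = self._classified([0.0, 0.0, 0.3])
        out = tmp_path / "annotated.pdb"
        export_structure_annotation(cls, tiny_pdb, out, mode="bfactor")
        structure = PDBParser(QUIET=True).get_structure("x", str(out))
        bfs = {res.id[1]: next(iter(res)).get_bfactor()
               for res in structure.get_residues()}
        assert bfs[3] == pytest.approx(0.3, abs=1e-2)
        assert bfs[1] == pytest.approx(0.0, abs=1e-6)

    def test_zero_map_gives_all_zero_bfactors(self, tiny_pdb, tmp_path):
        from Bio.PDB import PDBParser

        cls = self._classified([0.0, 0.0, 0.0])
        out = tmp_path / "zero.pdb"
        export_structure_annotation(cls, tiny_pdb, out, mode="bfactor")
        structure = PDBParser(QUIET=True).get_structure("x", str(out))
        for atom in structure.get_atoms():
            assert atom.get_bfactor() == 0.0

    def test_attribute_file_one_line_per_residue(self, tiny_pdb, tmp_path):
        cls = self._classified([0.01, 0.02, 0.3])
        out = tmp_path / "cat.defattr"
        export_structure_annotation(cls, tiny_pdb, out, mode="attribute")
        data_lines = [l for l in out.read_text().splitlines() if l.startswith("\t")]
        assert len(data_lines) == len(cls.table)

    def test_map_residue_absent_from_pdb_skipped(self, tiny_pdb, tmp_path, caplog):
        cls = self._classified([0.01, 0.02, 0.3, 0.05])  # residue 4 not in PDB
        with caplog.at_level("WARNING"):
            export_structure_annotation(cls, tiny_pdb, tmp_path / "o.pdb", "bfactor")
        assert "skipped" in caplog.text
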