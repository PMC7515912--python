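"""Determinism and physical fidelity of the synthetic-data generator."""

import json

import numpy as np
import pytest

from nmrbind import (
    SyntheticDesign,
    SyntheticProtein,
    average_shift,
    combined_shift,
    dominant_peak,
    fraction_bound,
    generate_pfg_series,
    generate_titration,
    perturbation_map,
    st_factor,
    write_fixture_bundle,
)
from nmrbind.exchange import ExchangeParams, is_broadened_out, n15_larmor


class TestGenerateTitration:
    def test_same_seed_reproduces_every_value(self, crd_protein):
        design = SyntheticDesign(ligand_concentrations=(50.0, 200.0), kd=190.0, seed=42)
        a = generate_titration(crd_protein, design)
        b = generate_titration(crd_protein, design)
        for (ca, pa), (cb, pb) in zip(a.points, b.points):
            assert ca == cb
            assert pa.to_frame().equals(pb.to_frame())
        assert a.apo.to_frame().equals(b.apo.to_frame())

    def test_different_seed_differs(self, crd_protein):
        d1 = SyntheticDesign(ligand_concentrations=(50.0,), kd=190.0, seed=1)
        d2 = SyntheticDesign(ligand_concentrations=(50.0,), kd=190.0, seed=2)
        a = generate_titration(crd_protein, d1)
        b = generate_titration(crd_protein, d2)
        assert not a.apo.to_frame().equals(b.apo.to_frame())

    def test_fast_exchange_noise_free_matches_closed_form(self, crd_protein, fast_design):
        """k_off huge, noise 0: per-residue Δδ = fraction_bound × combined
        bound-state offset, at every titration point."""
        series = generate_titration(crd_protein, fast_design)
        for i, conc in enumerate(series.concentrations):
            fb = fraction_bound(fast_design.protein_concentration, conc, fast_design.kd)
            pmap = perturbation_map(series, i)
            for r in list(crd_protein.binding_site)[:5]:
                expected = fb * combined_shift(
                    crd_protein.offset_h[r], crd_protein.offset_n[r])
                assert pmap.table.loc[r, "delta_delta"] == pytest.approx(
                    expected, rel=2e-3, abs=1e-6)

    def test_avg_shift_nondecreasing_at_zero_noise(self, crd_protein, fast_design):
        series = generate_titration(crd_protein, fast_design)
        avgs = [
            average_shift(perturbation_map(series, i), crd_protein.binding_site)
            for i in range(len(series))
        ]
        assert all(b >= a for a, b in zip(avgs, avgs[1:]))

    def test_intermediate_exchange_broadens_site_residues(self, crd_protein):
        """Slow-ish kinetics at µM affinity must reproduce vanished
        binding-site resonances (ΔINT = 1) at mid-titration, and the
        dropped residues must be exactly those the exchange model predicts
        to exceed the linewidth cutoff."""
        design = SyntheticDesign(
            ligand_concentrations=(5.0, 10.0, 20.0),
            kd=5.0, k_off=300.0, noise_h=0.0, noise_n=0.0,
            noise_intensity=0.0, seed=3)
        series = generate_titration(crd_protein, design)
        broadened_any = False
        for i, conc in enumerate(series.concentrations):
            fb = fraction_bound(design.protein_concentration, conc, design.kd)
            pmap = perturbation_map(series, i)
            for r in crd_protein.binding_site:
                expect_gone = False
                for larmor, shift, off in (
                    (design.spectrometer_h_mhz, crd_protein.shift_h[r], crd_protein.offset_h[r]),
                    (n15_larmor(design.spectrometer_h_mhz), crd_protein.shift_n[r], crd_protein.offset_n[r]),
                ):
                    comp = dominant_peak(
                        ExchangeParams(shift, shift + off, crd_protein.r2_free,
                                       crd_protein.r2_bound, design.k_off, larmor), fb)
                    if is_broadened_out(comp, crd_protein.r2_free, design.broadening_factor):
                        expect_gone = True
                row = pmap.table.loc[r]
                if expect_gone:
                    broadened_any = True
                    assert row["status"] == "broadened_out"
                    assert row["delta_int"] == 1.0
                else:
                    assert row["status"] == "ok"
        assert broadened_any, "intermediate design should broaden out site residues"

    def test_fast_design_keeps_all_residues(self, crd_protein, fast_design):
        series = generate_titration(crd_protein, fast_design)
        for i in range(len(series)):
            assert perturbation_map(series, i).n_broadened == 0


class TestGeneratePFG:
    def test_zero_noise_round_trip(self):
        from nmrbind import fit_diffusion

        series = generate_pfg_series(0.92e-6, noise_sd=0.0)
        assert fit_diffusion(series).d_value == pytest.approx(0.92e-6, rel=1e-9)

    def test_zero_gradient_amplitude_is_one(self):
        series = generate_pfg_series(1e-6, gradients=[0.0, 10.0, 30.0, 60.0])
        assert series.amplitudes[0] == 1.0

    def test_default_design_decays_strongly(self):
        """With the 14-gradient design (1–75 G/cm, Δ=34.2 ms, δ=4 ms) a
        D = 0.92e-6 cm²/s species decays to ~exp(−b_max·D) ≈ 0.14."""
        series = generate_pfg_series(0.92e-6)
        b_max = st_factor(75.0, 0.004, 0.0342)
        assert series.amplitudes[-1] == pytest.approx(np.exp(-b_max * 0.92e-6), rel=1e-9)
        assert series.amplitudes[-1] < 0.15

    def test_seeded_noise_reproducible(self):
        a = generate_pfg_series(1e-6, noise_sd=0.02, seed=9)
        b = generate_pfg_series(1e-6, noise_sd=0.02, seed=9)
        assert np.array_equal(a.amplitudes, b.amplitudes)


class TestFixtureBundle:
    def test_bundle_reproducible_byte_for_byte(self, tmp_path, crd_protein):
        design = SyntheticDesign(ligand_concentrations=(50.0, 200.0), kd=190.0, seed=7)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_fixture_bundle(d1, crd_protein, design)
        write_fixture_bundle(d2, crd_protein, design)
        for f1 in sorted(d1.iterdir()):
            assert f1.read_bytes() == (d2 / f1.name).read_bytes()

    def test_manifest_carries_ground_truth(self, tmp_path, crd_protein):
        design = SyntheticDesign(ligand_concentrations=(50.0,), kd=190.0, seed=7)
        write_fixture_bundle(tmp_path, crd_protein, design)
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["kd"] == 190.0
        assert manifest["c50_isotherm"] == pytest.approx(200.0)
        assert manifest["binding_site"] == list(crd_protein.binding_site)


class TestProteinConstruction:
    def test_deterministic(self):
        a = SyntheticProtein.galectin_crd()
        b = SyntheticProtein.galectin_crd()
        assert a.shift_h == b.shift_h and a.binding_site == b.binding_site

    def test_site_offsets_dominate_background(self, crd_protein):
        site = np.array([abs(crd_protein.offset_n[r]) for r in crd_protein.binding_site])
        bg = np.array([abs(crd_protein.offset_n[r]) for r in crd_protein.residues
                       if r not in crd_protein.binding_site])
        assert site.min() > bg.mean()

    def test_empty_binding_site_rejected(self, crd_protein):
        with pytest.raises(ValueError):
            SyntheticProtein(
                crd_protein.residues, crd_protein.shift_h, crd_protein.shift_n,
                crd_protein.offset_h, crd_protein.offset_n,
                crd_protein.base_intensity, crd_protein.residue_type,
                binding_site=())
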