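import pytest

from nmrbind import Peak, PeakList, SyntheticDesign, SyntheticProtein, TitrationSeries


@pytest.fixture(scope="session")
def crd_protein() -> SyntheticProtein:
    """Default virtual galectin CRD (deterministic construction)."""
    return SyntheticProtein.galectin_crd()


@pytest.fixture
def small_peaklist() -> PeakList:
    return PeakList(
        [
            Peak(124, 8.21, 118.30, 1.0e6, "G"),
            Peak(146, 8.85, 125.30, 2.0e6, "A"),
            Peak(160, 7.95, 110.12, 0.5e6, "S"),
        ],
        label="apo",
    )


@pytest.fixture
def fast_design() -> SyntheticDesign:
    """Noise-free fast-exchange design for closed-form checks."""
    return SyntheticDesign(
        ligand_concentrations=(25.0, 50.0, 100.0, 200.0, 400.0, 800.0),
        kd=190.0,
        k_off=1.0e7,
        noise_h=0.0,
        noise_n=0.0,
        noise_intensity=0.0,
        seed=11,
    )


def make_series(apo_shifts, point_shifts, p_total=20.0, conc=100.0) -> TitrationSeries:
    """Tiny two-list titration from {residue: (h, n, intensity)} dicts."""
    apo = PeakList(
        [Peak(r, h, n, i) for r, (h, n, i) in apo_shifts.items()], label="apo")
    pt = PeakList(
        [Peak(r, h, n, i) for r, (h, n, i) in point_shifts.items()],
        label="pt", ligand_concentration=conc)
    return TitrationSeries(p_total, apo, [(conc, pt)])
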