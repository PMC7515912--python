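"""Pulsed-field-gradient (PFG) NMR diffusion analysis.

Signal attenuation in a PFG experiment follows the Stejskal–Tanner
relation

    A(g) / A(0) = exp(−b(g) · D),   b(g) = γ² g² δ² (Δ − δ/3)

with γ the gyromagnetic ratio (rad·s⁻¹·G⁻¹), g the gradient amplitude
(G/cm), δ the gradient-pulse duration (s) and Δ the diffusion delay
between gradient pulses (s); the diffusion coefficient D then comes from
a linear regression of ln A on b.  The expected D of a compact globular
particle of given mass follows from the Stokes–Einstein relation on a
hydrated sphere, providing the reference against which an extended or
self-associating chain shows up as anomalously slow.

A rigid titration readout: as protein is added to a polymeric ligand the
complex grows and D of the ligand drops; once every site on the chain is
occupied, D plateaus.  :func:`detect_plateau` locates that plateau, which
estimates the chain's binding stoichiometry directly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import constants, stats

logger = logging.getLogger(__name__)

#: ¹H gyromagnetic ratio in rad·s⁻¹·G⁻¹ (CODATA 2.675e8 rad/s/T ÷ 1e4 G/T)
GAMMA_H1 = 26752.218744

#: specific volume of water, cm³/g, for the hydration shell
V_WATER = 1.0


@dataclass
class PFGSeries:
    """One gradient-strength series of normalized PFG amplitudes.

    ``gradients`` in G/cm (non-negative, increasing), ``amplitudes``
    normalized to the zero-gradient signal, ``big_delta`` the diffusion
    delay Δ (s), ``grad_duration`` the gradient-pulse length δ (s).
    """

    gradients: np.ndarray
    amplitudes: np.ndarray
    big_delta: float
    grad_duration: float
    gamma: float = GAMMA_H1
    label: str = ""

    def __post_init__(self) -> None:
        self.gradients = np.asarray(self.gradients, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.gradients.shape != self.amplitudes.shape:
            raise ValueError("gradients and amplitudes must have equal length")
        if np.any(self.gradients < 0) or np.any(np.diff(self.gradients) <= 0):
            raise ValueError("gradients must be non-negative and increasing")
        if not self.big_delta > self.grad_duration > 0:
            raise ValueError("need big_delta > grad_duration > 0")
        if np.any(self.amplitudes <= 0) or np.any(self.amplitudes > 1.05):
            raise ValueError("amplitudes must lie in (0, 1.05]")

    def b_factors(self) -> np.ndarray:
        """Stejskal–Tanner factor b = γ²g²δ²(Δ − δ/3) per gradient, s/cm²."""
        return st_factor(self.gradients, self.grad_duration, self.big_delta, self.gamma)


def st_factor(g, grad_duration: float, big_delta: float, gamma: float = GAMMA_H1):
    """Stejskal–Tanner gradient factor (s·cm⁻² when g is in G/cm)."""
    g = np.asarray(g, dtype=float)
    out = gamma**2 * g**2 * grad_duration**2 * (big_delta - grad_duration / 3.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class DiffusionFit:
    """Fitted translational diffusion coefficient (cm²/s) with the standard
    error and R² of the underlying log-linear regression."""

    d_value: float
    stderr: float
    r_squared: float
    n_points: int

    def to_dict(self) -> dict:
        return {"d_value": self.d_value, "stderr": self.stderr,
                "r_squared": self.r_squared, "n_points": self.n_points}


def fit_diffusion(series: PFGSeries, noise_floor: float = 0.0) -> DiffusionFit:
    """Linear regression of ln A on b; the slope is −D.

    Points at or below ``noise_floor`` are dropped.  A decay that is
    non-monotone beyond ~5 % warns (convection or poor phasing in real
    data) but still fits.
    """
    mask = series.amplitudes > noise_floor
    b = series.b_factors()[mask]
    a = series.amplitudes[mask]
    if len(b) < 3:
        raise ValueError("need at least 3 usable points above the noise floor")
    if np.ptp(a) < 1e-12 or np.all(a > 0.999):
        raise ValueError("no measurable decay in the series")
    rises = np.diff(a) / a[:-1]
    if np.any(rises > 0.05):
        logger.warning("non-monotone PFG decay (max fractional rise %.1f%%)",
                       100 * rises.max())
    reg = stats.linregress(b, np.log(a))
    d = -float(reg.slope)
    if d <= 0:
        raise ValueError("fitted diffusion coefficient is non-positive")
    return DiffusionFit(d, float(reg.stderr), float(reg.rvalue**2), int(mask.sum()))


@dataclass(frozen=True)
class HydroParams:
    """Hydrodynamic inputs to the Stokes–Einstein estimate.

    Defaults describe aqueous solution at 30 °C with a polysaccharide-like
    partial specific volume and a conventional hydration shell.
    """

    temperature: float = 303.15            # K
    viscosity: float = 0.797e-3            # Pa·s, water at 30 °C
    partial_specific_volume: float = 0.60  # cm³/g
    hydration: float = 0.35                # g water / g solute

    def __post_init__(self) -> None:
        if min(self.temperature, self.viscosity,
               self.partial_specific_volume, self.hydration) <= 0:
            raise ValueError("all hydrodynamic parameters must be > 0")


def stokes_einstein_d(mass: float, hydro: HydroParams = HydroParams()) -> float:
    """Globular-limit diffusion coefficient (cm²/s) of a hydrated sphere.

    R = (3·M·(v̄ + h·v_w) / (4π·N_A))^(1/3), D = k_B·T / (6π·η·R).
    """
    if mass <= 0:
        raise ValueError("mass must be > 0")
    vol_cm3 = mass * (hydro.partial_specific_volume + hydro.hydration * V_WATER) \
        / constants.Avogadro
    r_cm = (3.0 * vol_cm3 / (4.0 * math.pi)) ** (1.0 / 3.0)
    r_m = r_cm * 1e-2
    d_m2s = constants.k * hydro.temperature / (6.0 * math.pi * hydro.viscosity * r_m)
    return d_m2s * 1e4  # m²/s → cm²/s


def complex_d_curve(
    d_free: float,
    mass_poly: float,
    mass_protein: float,
    ratios,
    n_max: int,
    exponent: float = 1.0 / 3.0,
) -> np.ndarray:
    """Predicted ligand D along a protein titration, from mass scaling.

    At protein/chain molar ratio r the chain carries b = min(r, n_max)
    proteins and D = D_free · ((m_chain + b·m_prot)/m_chain)^(−exponent);
    exponent 1/3 is the compact-particle limit, ~0.588 a swollen coil.
    The curve plateaus exactly at r ≥ n_max.
    """
    if not 0 < exponent <= 1:
        raise ValueError("exponent must lie in (0, 1]")
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    ratios = np.asarray(ratios, dtype=float)
    bound = np.minimum(ratios, float(n_max))
    return d_free * ((mass_poly + bound * mass_protein) / mass_poly) ** (-exponent)


@dataclass
class PlateauResult:
    """Outcome of plateau detection on a D-vs-ratio titration."""

    n_max: float | None
    found: bool
    upturn: bool = False


def detect_plateau(ratios, d_values, tol: float = 0.03) -> PlateauResult:
    """Locate the molar ratio at which the D decline levels off.

    Returns the smallest ratio from which every successive relative
    decrease stays below ``tol``.  Late upturns (D rising again at high
    protein excess, where unbound protein contaminates the readout) set the
    ``upturn`` flag without disqualifying the plateau.  If no point
    satisfies the criterion the result is flagged not-found.
    """
    ratios = np.asarray(ratios, dtype=float)
    d_values = np.asarray(d_values, dtype=float)
    if len(ratios) < 4:
        raise ValueError("need at least 4 points")
    if np.any(np.diff(ratios) <= 0):
        raise ValueError("ratios must be strictly increasing")
    drops = -np.diff(d_values) / d_values[:-1]  # relative decrease per step
    upturn = bool(np.any(drops < -tol))
    # plateau start: first index i such that every later step drops < tol
    flat = drops < tol
    for i in range(len(flat)):
        if flat[i:].all():
            # plateau begins at the first point from which the curve stays flat
            return PlateauResult(float(ratios[i]), True, upturn)
    return PlateauResult(None, False, upturn)


def read_pfg_tsv(path: str | Path, big_delta: float, grad_duration: float,
                 gamma: float = GAMMA_H1) -> PFGSeries:
    """Load a two-column (gradient G/cm, normalized amplitude) TSV."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (gradient, amplitude)")
    return PFGSeries(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float),
                     big_delta, grad_duration, gamma, label=Path(path).stem)
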