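"""Two-site chemical exchange and 1:1 binding mass balance.

The central physical picture: a ligand-binding residue's amide resonance
interconverts between a free state (shift δ_f, transverse relaxation R2_f)
and a bound state (δ_b, R2_b) at rates set by k_off and the bound
population.  The observable spectrum follows from the 2×2 complex
evolution (Bloch–McConnell) matrix; its eigencomponents give the apparent
peak positions (imaginary parts), linewidths (real parts) and amplitudes
(projection of the equilibrium populations).

Exchange regimes on the chemical-shift timescale:

* fast (k_ex >> Δω): a single peak at the population-weighted shift,
  with excess broadening R_ex = p_f·p_b·Δω²/k_ex;
* slow (k_ex << Δω): two peaks at the free and bound positions with
  amplitudes tracking the populations;
* intermediate: a minimally shifted, strongly broadened — often
  undetectable — resonance.

In titration practice the regime correlates with affinity, and the common
heuristic classifies by K_D alone (fast above ~100 µM, slow below ~1 µM);
:func:`classify_exchange_regime` implements that heuristic and
:func:`classify_exchange_by_rate` the physically correct k_ex/Δω criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

#: γ(¹⁵N)/γ(¹H); converts a ¹H spectrometer frequency to the ¹⁵N one
N15_OVER_H1 = 0.10136767


def n15_larmor(spectrometer_h_mhz: float) -> float:
    """¹⁵N Larmor frequency (MHz, magnitude) on a given ¹H-frequency magnet."""
    return spectrometer_h_mhz * N15_OVER_H1


@dataclass(frozen=True)
class ExchangeParams:
    """Two-site exchange parameters for a single resonance.

    ``larmor_mhz`` is the Larmor frequency of the observed nucleus (use
    :func:`n15_larmor` for the ¹⁵N dimension); it converts ppm to rad/s as
    Δω = Δδ · larmor_mhz · 2π.
    """

    shift_free: float      # ppm
    shift_bound: float     # ppm
    r2_free: float         # 1/s
    r2_bound: float        # 1/s
    k_off: float           # 1/s
    larmor_mhz: float      # MHz of the observed nucleus

    def __post_init__(self) -> None:
        if min(self.r2_free, self.r2_bound, self.k_off) < 0:
            raise ValueError("rates must be >= 0")
        if self.larmor_mhz <= 0:
            raise ValueError("larmor_mhz must be > 0")

    def omega(self, shift_ppm: float) -> float:
        """ppm → angular frequency in rad/s."""
        return shift_ppm * self.larmor_mhz * 2.0 * math.pi

    @property
    def delta_omega(self) -> float:
        """Free–bound frequency separation |Δω| in rad/s."""
        return abs(self.omega(self.shift_bound) - self.omega(self.shift_free))


class PeakComponent(NamedTuple):
    """One spectral eigencomponent: position (ppm), decay rate (s⁻¹, the
    Lorentzian half-width at half-height in rad/s), amplitude (unitless)."""

    position: float
    linewidth: float
    amplitude: float


def fraction_bound(p_total: float, l_total: float, kd: float):
    """Bound fraction of the protein under 1:1 binding with ligand depletion.

    Solves the mass-balance quadratic P·fb² − (P+L+K)·fb + L = 0 and returns
    its physical root

        fb = ((P+L+K) − sqrt((P+L+K)² − 4·P·L)) / (2·P)

    with all concentrations in the same unit (µM throughout this package).
    ``l_total`` may be a numpy array.
    """
    l_total = np.asarray(l_total, dtype=float)
    if p_total <= 0:
        raise ValueError("p_total must be > 0")
    if np.any(l_total < 0) or kd < 0:
        raise ValueError("l_total and kd must be >= 0")
    s = p_total + l_total + kd
    disc = s * s - 4.0 * p_total * l_total
    fb = (s - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * p_total)
    fb = np.clip(fb, 0.0, 1.0)
    return float(fb) if fb.ndim == 0 else fb


def two_site_peak(params: ExchangeParams, p_bound: float) -> list[PeakComponent]:
    """Spectral components of a two-site exchanging resonance.

    Builds the complex evolution matrix with the detailed-balance
    pseudo-first-order on-rate k_on' = k_off·p_b/p_f, diagonalizes it, and
    returns both eigencomponents sorted by decreasing amplitude.  The summed
    amplitude is 1 (population conservation); the caller usually keeps the
    dominant component as "the peak".

    Degenerate limits are handled explicitly: p_bound ∈ {0, 1} returns the
    single pure-state peak, and k_off = 0 returns the two non-exchanging
    peaks with amplitudes equal to the populations.
    """
    if not 0.0 <= p_bound <= 1.0:
        raise ValueError("p_bound must lie in [0, 1]")
    free = PeakComponent(params.shift_free, params.r2_free, 1.0 - p_bound)
    bound = PeakComponent(params.shift_bound, params.r2_bound, p_bound)
    if p_bound == 0.0:
        return [free._replace(amplitude=1.0)]
    if p_bound == 1.0:
        return [bound._replace(amplitude=1.0)]
    if params.k_off == 0.0:
        return sorted([free, bound], key=lambda c: -c.amplitude)

    p_f, p_b = 1.0 - p_bound, p_bound
    k_on = params.k_off * p_b / p_f  # detailed balance: p_f·k_on' = p_b·k_off
    w_f, w_b = params.omega(params.shift_free), params.omega(params.shift_bound)
    a = np.array(
        [
            [1j * w_f - params.r2_free - k_on, params.k_off],
            [k_on, 1j * w_b - params.r2_bound - params.k_off],
        ],
        dtype=complex,
    )
    evals, vecs = np.linalg.eig(a)
    # magnetization starts at the equilibrium populations and is detected
    # uniformly: FID s(t) = 1ᵀ·exp(A t)·p = Σ_j a_j exp(λ_j t)
    pops = np.array([p_f, p_b])
    amps = (np.ones(2) @ vecs) * np.linalg.solve(vecs, pops)
    comps = [
        PeakComponent(
            position=float(ev.imag / (2.0 * math.pi * params.larmor_mhz)),
            linewidth=float(-ev.real),
            amplitude=float(am.real),
        )
        for ev, am in zip(evals, amps)
    ]
    return sorted(comps, key=lambda c: -c.amplitude)


def dominant_peak(params: ExchangeParams, p_bound: float) -> PeakComponent:
    """The largest-amplitude component of :func:`two_site_peak`."""
    return two_site_peak(params, p_bound)[0]


def exchange_broadening_fast(p_bound: float, delta_omega: float, k_ex: float) -> float:
    """Fast-limit exchange contribution to the linewidth,
    R_ex = p_f·p_b·Δω²/k_ex (s⁻¹)."""
    if k_ex <= 0:
        raise ValueError("k_ex must be > 0")
    p_f = 1.0 - p_bound
    return p_f * p_bound * delta_omega**2 / k_ex


def classify_exchange_regime(kd: float) -> str:
    """Heuristic titration-regime call from affinity alone.

    Weak binders (K_D > 100 µM) typically show fast exchange (smoothly
    shifting peaks), tight binders (K_D < 1 µM) slow exchange (coexisting
    free/bound peaks), and the µM range in between intermediate exchange
    (broadening).  Boundaries are inclusive to ``intermediate``.  This is a
    rule of thumb — the rigorous criterion compares k_ex with Δω, see
    :func:`classify_exchange_by_rate`.
    """
    if kd < 0:
        raise ValueError("kd must be >= 0")
    if kd > 100.0:
        return "fast"
    if kd < 1.0:
        return "slow"
    return "intermediate"


def classify_exchange_by_rate(
    k_ex: float, delta_omega: float, fast_ratio: float = 3.0
) -> str:
    """Physically grounded regime call: fast when k_ex/|Δω| > ``fast_ratio``,
    slow when below 1/``fast_ratio``, intermediate in between."""
    if delta_omega <= 0:
        raise ValueError("delta_omega must be > 0")
    ratio = k_ex / delta_omega
    if ratio > fast_ratio:
        return "fast"
    if ratio < 1.0 / fast_ratio:
        return "slow"
    return "intermediate"


def k_ex_from_koff(k_off: float, p_bound: float) -> float:
    """Total exchange rate k_ex = k_on' + k_off = k_off/(1 − p_b)."""
    if p_bound >= 1.0:
        raise ValueError("p_bound must be < 1")
    return k_off / (1.0 - p_bound)


@dataclass(frozen=True)
class BindingState:
    """Solved 1:1 binding state at one titration point (concentrations µM)."""

    p_total: float
    l_total: float
    kd: float
    fraction_bound: float

    @classmethod
    def solve(cls, p_total: float, l_total: float, kd: float) -> "BindingState":
        return cls(p_total, l_total, kd, fraction_bound(p_total, l_total, kd))


def is_broadened_out(
    component: PeakComponent, r2_free: float, factor: float = 5.0
) -> bool:
    """Detectability criterion for a simulated peak: a component whose
    linewidth exceeds ``factor`` × the free-state linewidth is treated as
    broadened beyond observation (the titration-spectra phenomenon of
    resonances 'no longer observed'), without modelling a noise floor."""
    return component.linewidth > factor * r2_free


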