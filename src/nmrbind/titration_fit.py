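"""Titration-curve fitting and multivalent stoichiometry estimators.

Two curve models are fitted to average-Δδ vs. ligand concentration data:

``saturation_exponential``
    Δδ(L) = Δδ_max · (1 − exp(−L/λ)), the empirical saturating form used
    to trace titration curves of polymeric ligands; the 50 %-bound mark is
    C50 = λ·ln 2.

``isotherm_1to1``
    Δδ(L) = Δδ_max · fb(P₀, L, K_D) with fb the depletion-corrected 1:1
    bound fraction — the mechanistic model, valid for fast exchange, whose
    C50 has the closed form K_D + P₀/2.

For a multivalent chain carrying n equivalent sites, the chain saturates
the protein at a much lower concentration than the monovalent sugar does:
n ≈ K_D(mono) / C50(chain), and the per-site (microscopic) dissociation
constant is K_D(micro) ≈ C50(chain) · n.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from lmfit import Model

from .exchange import fraction_bound

logger = logging.getLogger(__name__)


@dataclass
class BindingFit:
    """Result of a titration-curve fit (concentrations in µM, shifts ppm)."""

    model: str                       # saturation_exponential | isotherm_1to1
    dd_max: float
    dd_max_stderr: float | None
    c50: float
    c50_stderr: float | None
    lam: float | None = None         # exponential decay constant λ (µM)
    kd: float | None = None          # isotherm model only (µM)
    kd_stderr: float | None = None
    p_total: float | None = None
    residual_norm: float = 0.0
    n_points: int = 0
    at_bounds: bool = False

    def predict(self, lig) -> np.ndarray:
        lig = np.asarray(lig, dtype=float)
        if self.model == "saturation_exponential":
            return self.dd_max * (1.0 - np.exp(-lig / self.lam))
        return self.dd_max * np.asarray(fraction_bound(self.p_total, lig, self.kd))

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


@dataclass
class StoichiometryEstimate:
    """Binding-site count of a polymeric ligand from the ratio of the
    monovalent K_D to the chain's 50 %-bound concentration."""

    kd_mono: float
    c50_poly: float
    n_sites_raw: float
    n_sites: int

    @property
    def microscopic_kd(self) -> float:
        """Site-average microscopic K_D implied by this estimate (µM)."""
        return microscopic_kd(self.c50_poly, self.n_sites)


def _validate_series(lig, dd, min_points: int = 3):
    lig = np.asarray(lig, dtype=float)
    dd = np.asarray(dd, dtype=float)
    if lig.shape != dd.shape or lig.ndim != 1:
        raise ValueError("ligand and response series must be 1-D and equal length")
    if len(lig) < min_points:
        raise ValueError(f"need at least {min_points} titration points, got {len(lig)}")
    if np.any(lig < 0):
        raise ValueError("concentrations must be non-negative")
    if np.any(np.diff(lig) <= 0):
        raise ValueError("concentrations must be strictly increasing")
    if np.ptp(dd) <= 0 or np.allclose(dd, dd[0]):
        raise ValueError("flat response data: nothing to fit")
    return lig, dd


def _init_scale(lig, dd) -> float:
    """Concentration nearest the half-maximal response — a deterministic,
    derivative-free starting point for λ or K_D."""
    half = dd[-1] / 2.0
    idx = int(np.argmin(np.abs(dd - half)))
    return float(lig[idx]) if lig[idx] > 0 else float(lig[lig > 0][0])


def fit_saturation(lig, avg_dd, fix_dd_max: float | None = None) -> BindingFit:
    """Least-squares fit of the saturating exponential Δδ_max·(1−e^{−L/λ}).

    ``fix_dd_max`` pins the plateau (fixed-plateau mode); otherwise it
    floats.  Returns the fitted Δδ_max, λ and C50 = λ·ln2 with standard
    errors from the covariance matrix.
    """
    lig, dd = _validate_series(lig, avg_dd)

    def f(L, dd_max, lam):
        return dd_max * (1.0 - np.exp(-L / lam))

    model = Model(f)
    params = model.make_params(
        dd_max=fix_dd_max if fix_dd_max is not None else float(dd[-1]),
        lam=_init_scale(lig, dd) / math.log(2.0),
    )
    params["lam"].set(min=1e-12)
    params["dd_max"].set(min=1e-12, vary=fix_dd_max is None)
    result = model.fit(dd, params, L=lig)
    if not result.success:
        raise RuntimeError(f"saturation fit failed: {result.message}")
    lam = result.params["lam"]
    dd_max = result.params["dd_max"]
    return BindingFit(
        model="saturation_exponential",
        dd_max=float(dd_max.value),
        dd_max_stderr=float(dd_max.stderr) if dd_max.stderr is not None else None,
        c50=float(lam.value) * math.log(2.0),
        c50_stderr=float(lam.stderr) * math.log(2.0) if lam.stderr is not None else None,
        lam=float(lam.value),
        residual_norm=float(np.linalg.norm(result.residual)),
        n_points=len(lig),
    )


def fit_isotherm_kd(lig, dd, p_total: float, fix_dd_max: float | None = None) -> BindingFit:
    """Fit the 1:1 depletion-corrected isotherm Δδ_max·fb(P₀, L, K_D).

    Meaningful only in fast exchange, where the observed shift tracks the
    population-weighted average; the caller is responsible for checking the
    regime.  A K_D that ends on an optimizer bound is flagged, not raised.
    """
    if p_total <= 0:
        raise ValueError("p_total must be > 0")
    lig, dd = _validate_series(lig, dd)

    def f(L, dd_max, kd):
        return dd_max * np.asarray(fraction_bound(p_total, L, kd))

    kd0 = max(_init_scale(lig, dd) - p_total / 2.0, 1e-3)
    dd_max0 = fix_dd_max if fix_dd_max is not None else float(
        dd[-1] / max(fraction_bound(p_total, lig[-1], kd0), 1e-9)
    )
    model = Model(f)
    params = model.make_params(dd_max=dd_max0, kd=kd0)
    params["kd"].set(min=1e-9, max=1e9)
    params["dd_max"].set(min=1e-12, vary=fix_dd_max is None)
    result = model.fit(dd, params, L=lig)
    if not result.success:
        raise RuntimeError(f"isotherm fit failed: {result.message}")
    kd = result.params["kd"]
    dd_max = result.params["dd_max"]
    at_bounds = bool(
        kd.value <= kd.min * (1 + 1e-6) or kd.value >= kd.max * (1 - 1e-6)
    )
    if at_bounds:
        logger.warning("fitted K_D %.3g µM sits at an optimizer bound", kd.value)
    fit = BindingFit(
        model="isotherm_1to1",
        dd_max=float(dd_max.value),
        dd_max_stderr=float(dd_max.stderr) if dd_max.stderr is not None else None,
        c50=float(kd.value) + p_total / 2.0,
        c50_stderr=float(kd.stderr) if kd.stderr is not None else None,
        kd=float(kd.value),
        kd_stderr=float(kd.stderr) if kd.stderr is not None else None,
        p_total=p_total,
        residual_norm=float(np.linalg.norm(result.residual)),
        n_points=len(lig),
        at_bounds=at_bounds,
    )
    return fit


def c50_from_fit(fit: BindingFit) -> float:
    """Ligand concentration at half-maximal fitted response.

    λ·ln2 for the exponential model.  For the 1:1 isotherm the 50 %-bound
    condition has the exact solution L = K_D + P₀/2: at fb = 1/2 the free
    protein is P₀/2 and the free ligand L − P₀/2, so K_D = L − P₀/2.
    """
    if fit.model == "saturation_exponential":
        return fit.lam * math.log(2.0)
    if fit.model == "isotherm_1to1":
        return fit.kd + fit.p_total / 2.0
    raise ValueError(f"unknown model {fit.model!r}")


def estimate_stoichiometry(kd_mono: float, c50_poly: float) -> StoichiometryEstimate:
    """Number of protein-binding sites on a polymeric ligand,
    n = K_D(monovalent) / C50(polymer), raw and rounded to nearest integer."""
    if kd_mono <= 0 or c50_poly <= 0:
        raise ValueError("kd_mono and c50_poly must be > 0")
    raw = kd_mono / c50_poly
    return StoichiometryEstimate(kd_mono, c50_poly, raw, int(round(raw)))


def microscopic_kd(c50_poly: float, n_sites: float) -> float:
    """Site-average microscopic K_D of a multivalent chain,
    C50(polymer) × n_sites (µM)."""
    if c50_poly <= 0 or n_sites <= 0:
        raise ValueError("c50_poly and n_sites must be > 0")
    return c50_poly * n_sites


def read_titration_tsv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a two-column (concentration, Δδ) TSV with a header line."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (concentration, delta_delta)")
    return df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)
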