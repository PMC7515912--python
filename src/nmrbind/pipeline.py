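"""End-to-end titration and diffusion analysis runs driven by one config.

A run takes a flat YAML config naming the apo and per-point peak lists
(with ligand concentrations), executes load → map → classify → fit →
stoichiometry, and leaves behind a self-documenting bundle: per-point
perturbation maps (TSV), the SD classification (TSV, optionally a
B-factor-annotated PDB), the average-Δδ titration curve with its fits,
a versioned JSON summary, and a log echoing every parameter that applied.
A separate entry point covers PFG diffusion series (per-ratio D fits,
plateau stoichiometry, Stokes–Einstein reference).

Failures carry the stage name; partial outputs written before the failure
are retained.  Fit-stage failures on degenerate data (e.g. a titration
with no response) are recorded in the summary rather than raised, so a
null run exits cleanly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .csp_mapping import (
    average_shift,
    classify_residues,
    export_structure_annotation,
    perturbation_map,
)
from .diffusion import (
    GAMMA_H1,
    HydroParams,
    detect_plateau,
    fit_diffusion,
    read_pfg_tsv,
    stokes_einstein_d,
)
from .exchange import classify_exchange_regime
from .glycan_mass import GlycanRepeatSpec, desulfated_mass, repeat_count, repeat_mass
from .peaklist_io import TitrationSeries, read_peak_list
from .titration_fit import (
    estimate_stoichiometry,
    fit_isotherm_kd,
    fit_saturation,
    microscopic_kd,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Malformed or incomplete analysis configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class AnalysisConfig:
    """Validated analysis configuration (paths resolved against base_dir)."""

    base_dir: Path
    output_dir: Path
    protein_concentration: float | None = None
    dialect: str = "sparky"
    apo: Path | None = None
    points: list[tuple[float, Path]] = field(default_factory=list)
    ligand_label: str = "ligand"
    binding_site: list[int] | None = None
    excluded: list[int] = field(default_factory=list)
    fit_model: str = "both"           # saturation | isotherm | both
    fix_dd_max: float | None = None
    kd_mono: float | None = None
    pdb: Path | None = None
    chain: str | None = None
    pfg: dict[str, Any] | None = None
    glycan: dict[str, Any] | None = None
    seed: int = 0
    plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, output_dir: str | Path | None = None) -> "AnalysisConfig":
        path = Path(path)
        try:
            raw = yaml.safe_load(path.read_text()) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: not valid YAML ({exc})") from exc
        base = path.parent
        cfg = cls(
            base_dir=base,
            output_dir=Path(output_dir) if output_dir else base / "out",
        )
        if "protein_concentration" in raw:
            cfg.protein_concentration = float(raw["protein_concentration"])
            if cfg.protein_concentration <= 0:
                raise ConfigError("protein_concentration must be > 0")
        cfg.dialect = raw.get("dialect", "sparky")
        if raw.get("apo"):
            cfg.apo = base / raw["apo"]
        for entry in raw.get("points", []):
            try:
                conc = float(entry["concentration"])
            except (KeyError, TypeError, ValueError) as exc:
                raise ConfigError(f"bad titration point entry {entry!r}") from exc
            if conc < 0:
                raise ConfigError("ligand concentrations must be >= 0")
            cfg.points.append((conc, base / entry["path"]))
        cfg.ligand_label = raw.get("ligand_label", cfg.ligand_label)
        if raw.get("binding_site"):
            cfg.binding_site = [int(r) for r in raw["binding_site"]]
        cfg.excluded = [int(r) for r in raw.get("excluded", [])]
        fit = raw.get("fit", {})
        cfg.fit_model = fit.get("model", "both")
        if cfg.fit_model not in ("saturation", "isotherm", "both"):
            raise ConfigError(f"unknown fit model {cfg.fit_model!r}")
        if fit.get("fix_dd_max") is not None:
            cfg.fix_dd_max = float(fit["fix_dd_max"])
        if raw.get("kd_mono") is not None:
            cfg.kd_mono = float(raw["kd_mono"])
        if raw.get("pdb"):
            cfg.pdb = base / raw["pdb"]
        cfg.chain = raw.get("chain")
        cfg.pfg = raw.get("pfg")
        cfg.glycan = raw.get("glycan")
        cfg.seed = int(raw.get("seed", 0))
        cfg.plots = bool(raw.get("plots", False))
        for p in [cfg.apo, *(pp for _, pp in cfg.points)]:
            if p is not None and not p.exists():
                raise ConfigError(f"input file not found: {p}")
        return cfg


def _setup_run(cfg: AnalysisConfig) -> logging.Logger:
    cfg.output_dir.mkdir(parents=True, exist_ok=True)
    run_logger = logging.getLogger("nmrbind.run")
    run_logger.setLevel(logging.INFO)
    for h in list(run_logger.handlers):
        run_logger.removeHandler(h)
    handler = logging.FileHandler(cfg.output_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    run_logger.addHandler(handler)
    echo = {k: str(v) for k, v in dataclasses.asdict(cfg).items()}
    run_logger.info("nmrbind %s configuration: %s", __version__, json.dumps(echo, indent=2))
    return run_logger


def load_series(cfg: AnalysisConfig) -> TitrationSeries:
    if cfg.apo is None or not cfg.points or cfg.protein_concentration is None:
        raise ConfigError("titration analysis needs apo, points and protein_concentration")
    try:
        apo = read_peak_list(cfg.apo, cfg.dialect, label="apo")
        points = [
            (conc, read_peak_list(p, cfg.dialect, ligand_concentration=conc))
            for conc, p in cfg.points
        ]
        return TitrationSeries(cfg.protein_concentration, apo, points, cfg.ligand_label)
    except (OSError, ValueError) as exc:
        raise StageError("load", str(exc)) from exc


def run_titration_analysis(cfg: AnalysisConfig) -> dict[str, Any]:
    """Full titration analysis; returns (and writes) the summary dict."""
    run_logger = _setup_run(cfg)
    summary: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "tool": f"nmrbind {__version__}",
        "analysis": "titration",
        "ligand": cfg.ligand_label,
        "protein_concentration_uM": cfg.protein_concentration,
        "seed": cfg.seed,
    }
    series = load_series(cfg)

    # --- map stage -------------------------------------------------------
    maps = []
    try:
        for i in range(len(series)):
            pmap = perturbation_map(series, i)
            if cfg.excluded:
                pmap.table = pmap.table.drop(index=cfg.excluded, errors="ignore")
                ok = pmap.table.loc[pmap.table["status"] == "ok", "delta_delta"]
                pmap.mean_dd = float(ok.mean())
                pmap.sd_dd = float(ok.std(ddof=1)) if len(ok) > 1 else 0.0
            pmap.to_tsv(cfg.output_dir / f"map_point_{i:02d}.tsv")
            maps.append(pmap)
    except ValueError as exc:
        raise StageError("map", str(exc)) from exc
    summary["points"] = [
        {
            "ligand_concentration_uM": m.ligand_concentration,
            "mean_dd_ppm": m.mean_dd,
            "sd_dd_ppm": m.sd_dd,
            "n_broadened_out": m.n_broadened,
        }
        for m in maps
    ]

    # --- classify stage (final point: spectral effects largest) ----------
    try:
        cls = classify_residues(maps[-1])
        cls.to_tsv(cfg.output_dir / "classification.tsv")
        summary["classification"] = {
            "point": len(maps) - 1,
            "above_2sd": cls.residues("above_2sd"),
            "above_1sd": cls.residues("above_1sd"),
            "n_missing": len(cls.residues("missing")),
        }
        if cfg.pdb is not None:
            export_structure_annotation(
                cls, cfg.pdb, cfg.output_dir / "annotated.pdb", "bfactor", cfg.chain)
            export_structure_annotation(
                cls, cfg.pdb, cfg.output_dir / "classification.defattr", "attribute")
    except ValueError as exc:
        raise StageError("classify", str(exc)) from exc

    # --- curve + fit stage ------------------------------------------------
    subset = cfg.binding_site
    concs = np.array(series.concentrations, dtype=float)
    avg = np.array([average_shift(m, subset) for m in maps])
    curve = np.column_stack([concs, avg])
    np.savetxt(
        cfg.output_dir / "titration_curve.tsv", curve, delimiter="\t",
        header="ligand_concentration_uM\tavg_delta_delta_ppm", comments="",
        fmt="%.6g",
    )
    summary["curve"] = {"subset": subset, "n_points": len(concs)}

    fits: dict[str, Any] = {}
    c50_for_stoichiometry: float | None = None
    want = ("saturation", "isotherm") if cfg.fit_model == "both" else (cfg.fit_model,)
    for name in want:
        try:
            if name == "saturation":
                fit = fit_saturation(concs, avg, fix_dd_max=cfg.fix_dd_max)
            else:
                fit = fit_isotherm_kd(concs, avg, cfg.protein_concentration,
                                      fix_dd_max=cfg.fix_dd_max)
            fit.to_json(cfg.output_dir / f"fit_{name}.json")
            fits[name] = json.loads(fit.to_json())
            if c50_for_stoichiometry is None:
                c50_for_stoichiometry = fit.c50
            if name == "isotherm":
                fits[name]["exchange_regime"] = classify_exchange_regime(fit.kd)
        except (ValueError, RuntimeError) as exc:
            run_logger.warning("fit stage (%s) failed: %s", name, exc)
            fits[name] = {"error": str(exc)}
    summary["fits"] = fits

    # --- stoichiometry stage ---------------------------------------------
    if cfg.kd_mono is not None and c50_for_stoichiometry is not None:
        est = estimate_stoichiometry(cfg.kd_mono, c50_for_stoichiometry)
        summary["stoichiometry"] = {
            "kd_mono_uM": est.kd_mono,
            "c50_poly_uM": est.c50_poly,
            "n_sites_raw": est.n_sites_raw,
            "n_sites": est.n_sites,
            "microscopic_kd_uM": est.microscopic_kd,
        }

    if cfg.glycan:
        summary["glycan"] = _glycan_summary(cfg.glycan)

    if cfg.plots:
        _plot_titration(cfg, maps[-1], concs, avg, fits)

    _write_summary(cfg, summary)
    run_logger.info("titration analysis complete")
    return summary


def run_diffusion_analysis(cfg: AnalysisConfig) -> dict[str, Any]:
    """PFG diffusion analysis: per-ratio D fits, plateau, globular reference."""
    if not cfg.pfg:
        raise ConfigError("diffusion analysis needs a 'pfg' config block")
    run_logger = _setup_run(cfg)
    pfg = cfg.pfg
    try:
        big_delta = float(pfg["big_delta"])
        grad_duration = float(pfg["grad_duration"])
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError("pfg block needs numeric big_delta and grad_duration") from exc
    gamma = float(pfg.get("gamma", GAMMA_H1))
    noise_floor = float(pfg.get("noise_floor", 0.0))
    entries = pfg.get("series", [])
    if not entries:
        raise ConfigError("pfg block lists no series")

    summary: dict[str, Any] = {
        "schema_version": SCHEMA_VERSION,
        "tool": f"nmrbind {__version__}",
        "analysis": "diffusion",
        "seed": cfg.seed,
    }
    ratios, d_fits = [], []
    for entry in entries:
        path = cfg.base_dir / entry["path"]
        try:
            series = read_pfg_tsv(path, big_delta, grad_duration, gamma)
            fit = fit_diffusion(series, noise_floor)
        except (OSError, ValueError) as exc:
            raise StageError("diffusion_fit", f"{path}: {exc}") from exc
        ratios.append(float(entry.get("ratio", 0.0)))
        d_fits.append(fit)
    summary["series"] = [
        {"ratio": r, **f.to_dict()} for r, f in zip(ratios, d_fits)
    ]

    if len(ratios) >= 4:
        order = np.argsort(ratios)
        res = detect_plateau(np.array(ratios)[order],
                             np.array([f.d_value for f in d_fits])[order],
                             tol=float(pfg.get("plateau_tol", 0.03)))
        summary["plateau"] = {"n_max": res.n_max, "found": res.found,
                              "upturn": res.upturn}
    if pfg.get("stokes_einstein"):
        se = pfg["stokes_einstein"]
        hydro = HydroParams(
            temperature=float(se.get("temperature", HydroParams.temperature)),
            viscosity=float(se.get("viscosity", HydroParams.viscosity)),
            partial_specific_volume=float(
                se.get("partial_specific_volume", HydroParams.partial_specific_volume)),
            hydration=float(se.get("hydration", HydroParams.hydration)),
        )
        summary["stokes_einstein"] = {
            "mass_da": float(se["mass"]),
            "d_globular_cm2_s": stokes_einstein_d(float(se["mass"]), hydro),
        }
    if cfg.glycan:
        summary["glycan"] = _glycan_summary(cfg.glycan)
    _write_summary(cfg, summary)
    run_logger.info("diffusion analysis complete")
    return summary


def _glycan_summary(block: dict[str, Any]) -> dict[str, Any]:
    spec = GlycanRepeatSpec(
        residue_masses=tuple(block.get("residue_masses", GlycanRepeatSpec.residue_masses)),
        sulfates_per_repeat=float(block.get("sulfates_per_repeat", 2.0)),
        sulfate_mass=float(block.get("sulfate_mass", GlycanRepeatSpec.sulfate_mass)),
    )
    chain_mass = float(block["chain_mass"])
    return {
        "chain_mass_da": chain_mass,
        "repeat_mass_da": repeat_mass(spec),
        "repeat_count": repeat_count(chain_mass, spec),
        "desulfated_mass_da": desulfated_mass(chain_mass, spec),
    }


def _write_summary(cfg: AnalysisConfig, summary: dict[str, Any]) -> None:
    (cfg.output_dir / "summary.json").write_text(
        json.dumps(summary, indent=2, default=float) + "\n")


def _plot_titration(cfg, last_map, concs, avg, fits) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(8, 6))
    tbl = last_map.table
    ax1.bar(tbl.index, tbl["delta_delta"].fillna(0.0), color="steelblue")
    ax1.axhline(last_map.mean_dd + last_map.sd_dd, color="orange", lw=0.8)
    ax1.axhline(last_map.mean_dd + 2 * last_map.sd_dd, color="red", lw=0.8)
    ax1.set_xlabel("residue")
    ax1.set_ylabel(r"$\Delta\delta$ (ppm)")
    ax2.plot(concs, avg, "ko", label="average $\\Delta\\delta$")
    grid = np.linspace(0, concs.max(), 200)
    for name, fit in fits.items():
        if "error" in fit:
            continue
        if name == "saturation":
            y = fit["dd_max"] * (1 - np.exp(-grid / fit["lam"]))
        else:
            from .exchange import fraction_bound
            y = fit["dd_max"] * np.asarray(
                fraction_bound(fit["p_total"], grid, fit["kd"]))
        ax2.plot(grid, y, label=name)
    ax2.set_xlabel(f"[{cfg.ligand_label}] (µM)")
    ax2.set_ylabel(r"avg $\Delta\delta$ (ppm)")
    ax2.legend()
    fig.tight_layout()
    fig.savefig(cfg.output_dir / "titration.png", dpi=120)
    plt.close(fig)
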