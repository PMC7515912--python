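"""Per-residue chemical-shift-perturbation (Δδ) and broadening (ΔINT) maps.

The combined amide shift change between an apo and a ligand-loaded
spectrum is

    Δδ = sqrt((Δδ_H)² + (0.25·Δδ_N)²)            [ppm]

with the ¹⁵N change down-weighted by 0.25 to account for its wider ppm
dispersion, and the fractional intensity loss is

    ΔINT = 1 − Int_i / Int_o

so that 1 marks a resonance broadened beyond detection, 0 no change, and
negative values a genuinely intensified peak.  Residues whose cross-peak
has vanished from a titration point carry ΔINT = 1 and no Δδ.

Perturbed residues are flagged relative to the map's own statistics:
``above_2sd`` when Δδ > mean + 2·SD, ``above_1sd`` when Δδ > mean + 1·SD,
mirroring the red/orange/cyan colour convention of structure figures.
The mean and SD are computed over observable residues only — a vanished
peak contributes to the broadening map, not to the shift statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .peaklist_io import TitrationSeries, match_peaks

logger = logging.getLogger(__name__)

#: default ¹⁵N down-weighting in the combined shift
N_WEIGHT = 0.25

CATEGORIES = ("above_2sd", "above_1sd", "below", "missing")


def combined_shift(dh, dn, n_weight: float = N_WEIGHT):
    """Combined ¹H/¹⁵N chemical shift change, sqrt(dH² + (w·dN)²) in ppm.

    A norm: non-negative, zero only when both inputs are zero, and even in
    the sign of either argument.  Accepts scalars or arrays.
    """
    dh = np.asarray(dh, dtype=float)
    dn = np.asarray(dn, dtype=float)
    out = np.sqrt(dh**2 + (n_weight * dn) ** 2)
    return float(out) if out.ndim == 0 else out


def intensity_change(int_o: float, int_i: float) -> float:
    """Fractional intensity change 1 − int_i/int_o.

    1 means the resonance vanished, 0 no change, negative an intensified
    resonance (retained, not clipped).
    """
    if int_o <= 0:
        raise ValueError("reference intensity must be > 0")
    return 1.0 - int_i / int_o


@dataclass
class PerturbationMap:
    """Per-residue Δδ/ΔINT table for one titration point.

    ``table`` is indexed by residue number with columns ``delta_delta``
    (NaN where unmeasurable), ``delta_int`` and ``status``
    ({ok, broadened_out, missing}).  ``mean_dd``/``sd_dd`` are the Δδ
    statistics over ``ok`` residues (sample SD, ddof=1).
    """

    table: pd.DataFrame
    ligand_concentration: float
    mean_dd: float
    sd_dd: float
    label: str = ""

    def ok(self) -> pd.DataFrame:
        return self.table[self.table["status"] == "ok"]

    @property
    def n_broadened(self) -> int:
        return int((self.table["status"] == "broadened_out").sum())

    def to_tsv(self, path: str | Path) -> None:
        df = self.table.copy()
        df.insert(0, "residue", df.index)
        df.to_csv(path, sep="\t", index=False, float_format="%.5f")


@dataclass
class ClassifiedMap:
    """SD-threshold classification of a perturbation map.

    ``table``: residue-indexed frame with ``delta_delta`` and ``category``
    in {above_2sd, above_1sd, below, missing}; the categories are mutually
    exclusive and ``above_1sd`` excludes residues already above 2 SD.
    """

    table: pd.DataFrame
    mean_dd: float
    sd_dd: float

    def residues(self, category: str) -> list[int]:
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        return list(self.table.index[self.table["category"] == category])

    def to_tsv(self, path: str | Path) -> None:
        df = self.table.copy()
        df.insert(0, "residue", df.index)
        df.to_csv(path, sep="\t", index=False, float_format="%.5f")


def perturbation_map(
    series: TitrationSeries,
    point_index: int,
    n_weight: float = N_WEIGHT,
) -> PerturbationMap:
    """Δδ and ΔINT of every apo backbone residue at one titration point.

    Residues absent from the point's list are ``broadened_out`` with
    ΔINT = 1 and no Δδ; residues without a usable apo intensity still get a
    Δδ but a missing ΔINT.
    """
    conc, point = series.points[point_index]
    matched = match_peaks(series.apo.backbone(), point.backbone())
    if not len(matched):
        raise ValueError("no residues shared between apo and titration point")
    rows = []
    for rnum, row in matched.iterrows():
        if row["status"] == "broadened_out":
            rows.append({"residue_number": rnum, "delta_delta": np.nan,
                         "delta_int": 1.0, "status": "broadened_out"})
            continue
        dd = combined_shift(row["shift_h"] - row["shift_h_apo"],
                            row["shift_n"] - row["shift_n_apo"], n_weight)
        if row["intensity_apo"] is not None and row["intensity_apo"] > 0 \
                and row["intensity"] is not None:
            dint = intensity_change(row["intensity_apo"], row["intensity"])
        else:
            dint = np.nan
        rows.append({"residue_number": rnum, "delta_delta": dd,
                     "delta_int": dint, "status": "ok"})
    table = pd.DataFrame(rows).set_index("residue_number")
    ok_dd = table.loc[table["status"] == "ok", "delta_delta"]
    mean_dd = float(ok_dd.mean())
    sd_dd = float(ok_dd.std(ddof=1)) if len(ok_dd) > 1 else 0.0
    return PerturbationMap(table, conc, mean_dd, sd_dd, label=point.label)


def average_shift(pmap: PerturbationMap, subset=None) -> float:
    """Arithmetic mean Δδ over observable residues, optionally restricted to
    a residue subset (e.g. the binding-site strands); broadened-out residues
    never contribute."""
    ok = pmap.ok()
    if subset is not None:
        ok = ok.loc[ok.index.intersection(list(subset))]
    if not len(ok):
        raise ValueError("no observable residues in requested subset")
    return float(ok["delta_delta"].mean())


def classify_residues(pmap: PerturbationMap) -> ClassifiedMap:
    """Partition residues by Δδ against mean + 1·SD and mean + 2·SD.

    With a degenerate map (SD = 0, e.g. all values identical) every
    observable residue is ``below`` and a warning is logged.  Broadened-out
    and otherwise unmeasured residues propagate as ``missing``.
    """
    ok = pmap.ok()
    if len(ok) < 2:
        raise ValueError("need at least 2 observable residues to classify")
    if pmap.sd_dd == 0.0:
        logger.warning("zero SD in perturbation map; no residue classified above threshold")
    thr1 = pmap.mean_dd + pmap.sd_dd
    thr2 = pmap.mean_dd + 2.0 * pmap.sd_dd
    cats = []
    for rnum, row in pmap.table.iterrows():
        if row["status"] != "ok" or math.isnan(row["delta_delta"]):
            cats.append("missing")
        elif pmap.sd_dd > 0 and row["delta_delta"] > thr2:
            cats.append("above_2sd")
        elif pmap.sd_dd > 0 and row["delta_delta"] > thr1:
            cats.append("above_1sd")
        else:
            cats.append("below")
    table = pmap.table[["delta_delta"]].copy()
    table["category"] = cats
    return ClassifiedMap(table, pmap.mean_dd, pmap.sd_dd)


def export_structure_annotation(
    cls: ClassifiedMap,
    pdb_path: str | Path,
    out_path: str | Path,
    mode: str = "bfactor",
    chain: str | None = None,
) -> None:
    """Project a classification onto a structure for molecular viewers.

    ``bfactor`` mode writes a copy of the PDB with every atom's B-factor
    replaced by the residue's Δδ (0.0 for residues missing from the map),
    ready for putty/colour-by-B rendering; ``attribute`` mode writes a
    UCSF-Chimera ``defattr``-style per-residue category file.  Map residues
    absent from the structure are logged and skipped; insertion codes are
    not supported.
    """
    from Bio.PDB import PDBParser, PDBIO

    pdb_path, out_path = Path(pdb_path), Path(out_path)
    if mode == "attribute":
        lines = ["attribute: cspCategory", "match mode: 1-to-1", "recolor: false"]
        for rnum, row in cls.table.iterrows():
            lines.append(f"\t:{rnum}\t{row['category']}")
        out_path.write_text("\n".join(lines) + "\n")
        return
    if mode != "bfactor":
        raise ValueError(f"unsupported mode {mode!r}")

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("annotated", str(pdb_path))
    dd = cls.table["delta_delta"].to_dict()
    annotated: set[int] = set()
    for model in structure:
        for ch in model:
            if chain is not None and ch.id != chain:
                continue
            for residue in ch:
                het, resseq, icode = residue.id
                if icode.strip():
                    raise ValueError(
                        f"insertion code {icode!r} at residue {resseq} not supported"
                    )
                value = dd.get(resseq, np.nan)
                value = 0.0 if (value is None or (isinstance(value, float) and math.isnan(value))) else float(value)
                if resseq in dd:
                    annotated.add(resseq)
                for atom in residue:
                    atom.set_bfactor(value)
    skipped = set(dd) - annotated
    if skipped:
        logger.warning("map residues absent from structure, skipped: %s", sorted(skipped))
    io = PDBIO()
    io.set_structure(structure)
    io.save(str(out_path))
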