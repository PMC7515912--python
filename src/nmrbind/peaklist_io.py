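"""Reading, writing and matching assigned ¹H–¹⁵N HSQC peak lists.

A peak list holds one cross-peak per assigned amide (residue number,
residue type, ¹⁵N and ¹H chemical shifts in ppm, peak height).  Two text
dialects are supported:

``sparky``
    Whitespace-separated ``Assignment  w1(15N)  w2(1H)  Height`` rows, the
    de-facto interchange format of assignment software.  Assignment strings
    look like ``A146N-H`` (backbone) or ``N115ND2-HD21`` (Asn/Gln side-chain
    amide).

``tsv``
    A trivially scriptable five-column table with a header:
    ``residue_number  residue_type  shift_n  shift_h  intensity``.

Matching across a titration is assignment-driven: peaks are paired by
residue number, never by proximity in ppm space, because the analysis
assumes fully assigned spectra.  A residue present in the reference (apo)
list but absent from a titration point is classified ``broadened_out`` —
its resonance has decayed below detectability through exchange broadening.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

logger = logging.getLogger(__name__)

#: plausible backbone-amide shift windows (ppm); violations warn, never fail
H_RANGE = (0.0, 14.0)
N_RANGE = (90.0, 140.0)

BACKBONE_ATOM = "N-H"

# e.g. "A146N-H", "G124N-H", "N115ND2-HD21", "Q201NE2-HE22", "R144NE-HE"
_ASSIGNMENT_RE = re.compile(
    r"^(?P<type>[A-Za-z])?(?P<num>\d+)(?P<natom>N(?:D2|E2|E)?)-?(?P<hatom>H(?:[DE]2\d?)?)$"
)


@dataclass
class Peak:
    """One assigned HSQC cross-peak."""

    residue_number: int
    shift_h: float
    shift_n: float
    intensity: float | None = None
    residue_type: str = "X"
    atom: str = BACKBONE_ATOM

    def __post_init__(self) -> None:
        if self.atom == BACKBONE_ATOM:
            if not (H_RANGE[0] <= self.shift_h <= H_RANGE[1]):
                logger.warning(
                    "residue %d: 1H shift %.4f ppm outside %s",
                    self.residue_number, self.shift_h, H_RANGE,
                )
            if not (N_RANGE[0] <= self.shift_n <= N_RANGE[1]):
                logger.warning(
                    "residue %d: 15N shift %.4f ppm outside %s",
                    self.residue_number, self.shift_n, N_RANGE,
                )
        if self.intensity is not None and self.intensity < 0:
            logger.warning(
                "residue %d: negative intensity %.3g", self.residue_number, self.intensity
            )

    @property
    def is_backbone(self) -> bool:
        return self.atom == BACKBONE_ATOM

    @property
    def assignment(self) -> str:
        """Sparky-style assignment string, e.g. ``A146N-H``."""
        natom, hatom = self.atom.split("-")
        return f"{self.residue_type}{self.residue_number}{natom}-{hatom}"


class PeakList:
    """A collection of peaks from one spectrum, keyed by residue number.

    Backbone residue numbers must be unique; side-chain NH2 peaks (Asn/Gln)
    coexist with the backbone peak of the same residue and are kept apart
    through their ``atom`` label.
    """

    def __init__(
        self,
        peaks: Iterable[Peak] = (),
        label: str = "",
        ligand_concentration: float | None = None,
    ):
        if ligand_concentration is not None and ligand_concentration < 0:
            raise ValueError("ligand_concentration must be >= 0")
        self.label = label
        self.ligand_concentration = ligand_concentration
        self._peaks: dict[tuple[int, str], Peak] = {}
        for p in peaks:
            self.add(p)

    def add(self, peak: Peak) -> None:
        key = (peak.residue_number, peak.atom)
        if key in self._peaks:
            raise ValueError(
                f"duplicate peak for residue {peak.residue_number} ({peak.atom})"
            )
        self._peaks[key] = peak

    def __len__(self) -> int:
        return len(self._peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(sorted(self._peaks.values(), key=lambda p: (p.residue_number, p.atom)))

    def __contains__(self, residue_number: int) -> bool:
        return (residue_number, BACKBONE_ATOM) in self._peaks

    def __getitem__(self, residue_number: int) -> Peak:
        """Backbone peak of a residue."""
        return self._peaks[(residue_number, BACKBONE_ATOM)]

    def backbone(self) -> "PeakList":
        """A view restricted to backbone amide peaks."""
        return PeakList(
            (p for p in self if p.is_backbone),
            label=self.label,
            ligand_concentration=self.ligand_concentration,
        )

    def residues(self) -> list[int]:
        """Sorted backbone residue numbers."""
        return sorted(n for (n, atom) in self._peaks if atom == BACKBONE_ATOM)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "residue_number": p.residue_number,
                "residue_type": p.residue_type,
                "atom": p.atom,
                "shift_n": p.shift_n,
                "shift_h": p.shift_h,
                "intensity": p.intensity,
            }
            for p in self
        ]
        return pd.DataFrame(
            rows,
            columns=["residue_number", "residue_type", "atom", "shift_n", "shift_h", "intensity"],
        )

    def __eq__(self, other: object) -> bool:
        """Equality to the serialized precision: ppm to 4 decimals,
        intensity to 6 significant figures."""
        if not isinstance(other, PeakList):
            return NotImplemented
        import numpy as np

        a, b = self.to_frame(), other.to_frame()
        if len(a) != len(b):
            return False
        if not (a[["residue_number", "residue_type", "atom"]]
                .equals(b[["residue_number", "residue_type", "atom"]])):
            return False
        for col, kw in (("shift_n", {"atol": 5e-5}), ("shift_h", {"atol": 5e-5}),
                        ("intensity", {"rtol": 1e-5})):
            x, y = a[col].to_numpy(float), b[col].to_numpy(float)
            both_nan = np.isnan(x) & np.isnan(y)
            if not np.all(both_nan | np.isclose(x, y, equal_nan=False, **kw)):
                return False
        return True


@dataclass
class TitrationSeries:
    """An apo reference plus peak lists at increasing ligand concentrations.

    Parameters
    ----------
    protein_concentration
        Total protein concentration in µM, constant across the titration.
    apo
        Reference peak list in the absence of ligand.
    points
        Ordered ``(ligand_concentration_uM, PeakList)`` pairs; the
        concentrations must be strictly increasing.
    ligand_label
        Free-text name of the titrant (e.g. ``"KS"``).
    """

    protein_concentration: float
    apo: PeakList
    points: list[tuple[float, PeakList]] = field(default_factory=list)
    ligand_label: str = ""

    def __post_init__(self) -> None:
        if self.protein_concentration <= 0:
            raise ValueError("protein_concentration must be > 0")
        concs = [c for c, _ in self.points]
        if any(b <= a for a, b in zip(concs, concs[1:])):
            raise ValueError("ligand concentrations must be strictly increasing")
        for c, _ in self.points:
            if c < 0:
                raise ValueError("ligand concentrations must be >= 0")

    @property
    def concentrations(self) -> list[float]:
        return [c for c, _ in self.points]

    def __len__(self) -> int:
        return len(self.points)


def parse_assignment(text: str) -> tuple[str, int, str] | None:
    """Split a Sparky assignment string into (residue_type, number, atom).

    Returns None for strings that do not look like an amide assignment.
    Arginine side-chain Nε–Hε pairs are rejected deliberately: their shifts
    fold ambiguously in standard HSQC acquisition and are not interpretable
    alongside backbone amides.
    """
    m = _ASSIGNMENT_RE.match(text.strip())
    if m is None:
        return None
    natom, hatom = m.group("natom"), m.group("hatom")
    if natom == "NE":
        logger.warning("skipping arginine side-chain assignment %r", text)
        return None
    rtype = (m.group("type") or "X").upper()
    return rtype, int(m.group("num")), f"{natom}-{hatom}"


def read_peak_list(
    path: str | Path,
    dialect: str = "sparky",
    label: str | None = None,
    ligand_concentration: float | None = None,
) -> PeakList:
    """Read a peak list from ``path`` in the given dialect.

    Unparsable rows are skipped with a logged warning; a duplicate residue
    raises an error naming the residue.
    """
    path = Path(path)
    if dialect == "sparky":
        return _read_sparky(path, label or path.stem, ligand_concentration)
    if dialect == "tsv":
        return _read_tsv(path, label or path.stem, ligand_concentration)
    raise ValueError(f"unsupported dialect {dialect!r}")


def _read_sparky(path: Path, label: str, conc: float | None) -> PeakList:
    pl = PeakList(label=label, ligand_concentration=conc)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields or fields[0].lower() == "assignment":
                continue
            if len(fields) < 3:
                logger.warning("%s:%d: too few columns, skipped", path, lineno)
                continue
            parsed = parse_assignment(fields[0])
            if parsed is None:
                logger.warning("%s:%d: unparsable assignment %r, skipped", path, lineno, fields[0])
                continue
            rtype, rnum, atom = parsed
            try:
                shift_n, shift_h = float(fields[1]), float(fields[2])
                intensity = float(fields[3]) if len(fields) > 3 else None
            except ValueError:
                logger.warning("%s:%d: non-numeric shift columns, skipped", path, lineno)
                continue
            pl.add(Peak(rnum, shift_h, shift_n, intensity, rtype, atom))
    return pl


def _read_tsv(path: Path, label: str, conc: float | None) -> PeakList:
    df = pd.read_csv(path, sep="\t")
    expected = {"residue_number", "residue_type", "shift_n", "shift_h", "intensity"}
    missing = expected - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing TSV columns {sorted(missing)}")
    pl = PeakList(label=label, ligand_concentration=conc)
    for _, row in df.iterrows():
        atom = str(row["atom"]) if "atom" in df.columns else BACKBONE_ATOM
        intensity = None if pd.isna(row["intensity"]) else float(row["intensity"])
        pl.add(
            Peak(
                int(row["residue_number"]),
                float(row["shift_h"]),
                float(row["shift_n"]),
                intensity,
                str(row["residue_type"]),
                atom,
            )
        )
    return pl


def write_peak_list(pl: PeakList, path: str | Path, dialect: str = "sparky") -> None:
    """Write ``pl`` to ``path``; ppm values carry 4 decimals and the output
    round-trips through :func:`read_peak_list`."""
    path = Path(path)
    if dialect == "sparky":
        lines = [f"{'Assignment':>12} {'w1':>9} {'w2':>9} {'Height':>13}"]
        for p in pl:
            height = f"{p.intensity:14.6e}" if p.intensity is not None else ""
            lines.append(f"{p.assignment:>12} {p.shift_n:9.4f} {p.shift_h:9.4f} {height}")
        path.write_text("\n".join(lines) + "\n")
    elif dialect == "tsv":
        df = pl.to_frame()
        df["shift_n"] = df["shift_n"].map(lambda v: f"{v:.4f}")
        df["shift_h"] = df["shift_h"].map(lambda v: f"{v:.4f}")
        df.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unsupported dialect {dialect!r}")


def match_peaks(
    apo: PeakList,
    point: PeakList,
    tol_h: float = 0.5,
    tol_n: float = 2.5,
) -> pd.DataFrame:
    """Pair backbone peaks of a titration point against the apo reference.

    Returns a table indexed exactly by the apo backbone residue set with
    columns ``status`` ({matched, broadened_out}), the apo and point shifts,
    and intensities.  Pairing is by residue number; the ppm tolerances only
    trigger warnings for implausibly large single-step shift changes.
    Residues present in the point but not in apo are logged and ignored.
    """
    if tol_h <= 0 or tol_n <= 0:
        raise ValueError("tolerances must be > 0")
    apo_res = set(apo.residues())
    extra = set(point.residues()) - apo_res
    if extra:
        logger.warning("point %r has residues absent from apo, ignored: %s",
                       point.label, sorted(extra))
    rows = []
    for rnum in sorted(apo_res):
        ref = apo[rnum]
        row = {
            "residue_number": rnum,
            "residue_type": ref.residue_type,
            "shift_h_apo": ref.shift_h,
            "shift_n_apo": ref.shift_n,
            "intensity_apo": ref.intensity,
        }
        if rnum in point:
            p = point[rnum]
            dh, dn = p.shift_h - ref.shift_h, p.shift_n - ref.shift_n
            if abs(dh) > tol_h or abs(dn) > tol_n:
                logger.warning(
                    "residue %d: shift change (%.3f ppm 1H, %.3f ppm 15N) exceeds "
                    "tolerance (%.3f, %.3f) — check assignment tracking",
                    rnum, dh, dn, tol_h, tol_n,
                )
            row.update(
                status="matched",
                shift_h=p.shift_h,
                shift_n=p.shift_n,
                intensity=p.intensity,
            )
        else:
            row.update(status="broadened_out", shift_h=None, shift_n=None, intensity=None)
        rows.append(row)
    df = pd.DataFrame(
        rows,
        columns=["residue_number", "residue_type", "status", "shift_h_apo", "shift_n_apo",
                 "intensity_apo", "shift_h", "shift_n", "intensity"],
    )
    return df.set_index("residue_number")
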