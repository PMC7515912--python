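"""Average-mass accounting for sulfated polysaccharide chains.

A glycosaminoglycan like keratan sulfate is a run of disaccharide repeats
(hexose + N-acetylhexosamine) carrying 0–2 sulfate esters each.  With
average residue masses that already absorb the glycosidic water loss
(hexose 162.14 Da, HexNAc 203.19 Da, SO₃ 80.06 Da) and end groups
ignored, the chain mass is simply (repeat mass) × (repeat count) — which
makes desulfation arithmetic: divide the chain mass by the sulfated
repeat, multiply by the bare repeat.

Sulfation is modelled as a per-repeat average (non-integer values are
allowed) because real keratan chains mix mono- and disulfated repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

#: average residue masses, Da, glycosidic water loss included
HEXOSE = 162.14
HEXNAC = 203.19
SULFATE = 80.06  # SO3 adduct


@dataclass(frozen=True)
class GlycanRepeatSpec:
    """Composition of one repeat unit of a sulfated polysaccharide."""

    residue_masses: tuple[float, ...] = (HEXOSE, HEXNAC)
    sulfates_per_repeat: float = 2.0
    sulfate_mass: float = SULFATE

    def __post_init__(self) -> None:
        if not self.residue_masses or any(m <= 0 for m in self.residue_masses):
            raise ValueError("residue_masses must be non-empty and positive")
        if self.sulfates_per_repeat < 0 or self.sulfate_mass <= 0:
            raise ValueError("invalid sulfation parameters")

    def desulfated(self) -> "GlycanRepeatSpec":
        return replace(self, sulfates_per_repeat=0.0)


def lacnac_repeat(sulfates: float = 0.0) -> GlycanRepeatSpec:
    """An N-acetyllactosamine (Gal–HexNAc) repeat with the given average
    sulfation; ``sulfates=2`` is the fully 6,6'-disulfated keratan repeat."""
    return GlycanRepeatSpec(sulfates_per_repeat=float(sulfates))


def repeat_mass(spec: GlycanRepeatSpec) -> float:
    """Average mass of one repeat unit (Da)."""
    return sum(spec.residue_masses) + spec.sulfates_per_repeat * spec.sulfate_mass


def repeat_count(chain_mass: float, spec: GlycanRepeatSpec) -> float:
    """Fractional number of repeats in a chain of the given average mass;
    end-group corrections are deliberately ignored."""
    if chain_mass <= 0:
        raise ValueError("chain_mass must be > 0")
    return chain_mass / repeat_mass(spec)


def desulfated_mass(chain_mass: float, spec: GlycanRepeatSpec) -> float:
    """Chain mass after removal of every sulfate ester (Da): the repeat
    count is preserved, each repeat loses its sulfates."""
    return repeat_count(chain_mass, spec) * repeat_mass(spec.desulfated())
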