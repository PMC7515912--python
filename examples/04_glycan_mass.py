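"""Keratan-sulfate chain mass accounting.

From a 14,300 Da sulfated chain built of disulfated N-acetyllactosamine
repeats (Gal 162.14 + HexNAc 203.19 + 2 x SO3 80.06 Da), computes the
repeat count and the chain mass after chemical desulfation.
"""

from nmrbind import desulfated_mass, lacnac_repeat, repeat_count, repeat_mass

spec = lacnac_repeat(2)
chain = 14300.0
print(f"disulfated LacNAc repeat mass: {repeat_mass(spec):.2f} Da")
print(f"repeats in a {chain:.0f} Da chain: {repeat_count(chain, spec):.1f}")
print(f"mass after desulfation: {desulfated_mass(chain, spec):.0f} Da "
      "(every repeat loses two 80.06 Da sulfates)")
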