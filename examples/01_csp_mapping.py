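"""Chemical-shift-perturbation mapping on a simulated HSQC titration.

Builds a virtual ¹⁵N-labelled carbohydrate-recognition domain, titrates it
with a fast-exchanging ligand (K_D 190 µM), computes the per-residue Δδ
map at the highest ligand point, and classifies perturbed residues by the
mean + 1·SD / mean + 2·SD thresholds used to colour binding footprints on
structures.
"""

from nmrbind import (
    SyntheticDesign,
    SyntheticProtein,
    average_shift,
    classify_residues,
    generate_titration,
    perturbation_map,
)

protein = SyntheticProtein.galectin_crd()
design = SyntheticDesign(
    ligand_concentrations=(25.0, 50.0, 100.0, 200.0, 400.0, 800.0),
    kd=190.0,
    seed=1,
)
series = generate_titration(protein, design)

pmap = perturbation_map(series, len(series) - 1)
cls = classify_residues(pmap)

print(f"titration point: {pmap.ligand_concentration:g} uM ligand")
print(f"mean Delta-delta = {pmap.mean_dd:.4f} ppm, SD = {pmap.sd_dd:.4f} ppm")
print(f"residues > 2 SD above the mean: {cls.residues('above_2sd')}")
print(f"residues > 1 SD above the mean: {cls.residues('above_1sd')}")
print(f"average Delta-delta over the true binding site: "
      f"{average_shift(pmap, protein.binding_site):.4f} ppm")
overlap = set(cls.residues("above_2sd")) & set(protein.binding_site)
print(f"{len(overlap)}/{len(cls.residues('above_2sd'))} of the 2SD residues "
      "lie in the generator's binding site — the SD map recovers the footprint.")
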