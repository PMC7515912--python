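# nmrbind

Quantitative NMR analysis of protein–glycan binding, built around the
workflow used to characterise galectin binding to keratan sulfate and
related saccharides:

* **Chemical-shift-perturbation (CSP) mapping** — per-residue combined
  amide shift changes Δδ = [(Δδ_H)² + (0.25·Δδ_N)²]^½ and fractional
  intensity losses ΔINT = 1 − Int_i/Int_o from assigned ¹H–¹⁵N HSQC peak
  lists across a titration, with mean + 1·SD / mean + 2·SD outlier
  classification and export onto PDB structures (B-factor or attribute
  files) for binding-footprint figures.
* **Two-site exchange simulation** — peak positions, linewidths and
  amplitudes from the 2×2 complex evolution (Bloch–McConnell) matrix,
  covering the fast / intermediate / slow regimes, including the
  broadening-out of resonances characteristic of µM-affinity binding.
* **Titration fitting** — the empirical saturating exponential
  Δδ_max(1 − e^{−L/λ}) with C50 = λ·ln2, and the mechanistic
  depletion-corrected 1:1 isotherm Δδ_max·fb(P₀, L, K_D) whose 50 %-bound
  point is K_D + P₀/2; plus the multivalency estimators
  n = K_D(mono)/C50(chain) and microscopic K_D = C50(chain)·n.
* **PFG-NMR diffusion** — Stejskal–Tanner fitting
  (ln A = −γ²g²δ²(Δ−δ/3)·D), Stokes–Einstein globular references on a
  hydrated sphere, mass-scaled complex-growth curves and plateau
  detection for diffusion-based stoichiometry.
* **Glycan mass accounting** — repeat-unit arithmetic for sulfated
  polysaccharides (repeat counts, desulfated chain masses).
* **Synthetic data** — a seeded generator that renders full titration
  peak-list series *through the exchange model itself* and noisy PFG
  decays, so every stage has an exact generating truth.

The package is aimed at structural-biology groups running HSQC titration
and PFG experiments on lectin–glycosaminoglycan (or any protein–ligand)
systems who want the downstream arithmetic scripted, tested, and
reproducible.

## Worked example

`examples/02_affinity_and_stoichiometry.py` simulates a fast-exchange
titration of a carbohydrate-recognition domain (20 µM) with a K_D 190 µM
ligand, maps it, and fits the isotherm:

```
fitted K_D = 184 uM (truth 190), Delta-delta_max = 0.2528 ppm
C50 = 193.9 uM (= K_D + P/2 under ligand depletion at 20 uM protein)
monovalent K_D 190 uM / chain C50 11 uM -> n = 17.3 ~ 17 binding sites per chain
site-average microscopic K_D at chain C50 2 uM: 34 uM
```

The fitted K_D lands within noise of the generating value; the last two
lines are the multivalency arithmetic — a polymeric chain that
half-saturates the protein at 11 µM, against a monovalent K_D of 190 µM,
carries ≈17 equivalent sites, each with a per-site (microscopic) K_D of
C50 × n. The other examples cover CSP mapping/classification
(`01_csp_mapping.py`), diffusion analysis with plateau stoichiometry
(`03_diffusion.py`), and keratan desulfation mass accounting
(`04_glycan_mass.py`); each prints the numbers it computes with a line on
what they mean.

A thin CLI mirrors the pipeline for shell use:

```bash
nmrbind simulate --out fixture --kd 190 --seed 1
nmrbind run-all fixture/config.yaml --out results
nmrbind stoichiometry --kd-mono 190 --c50 11
```

## Layout

```
src/nmrbind/        peaklist_io, csp_mapping, exchange, titration_fit,
                    diffusion, glycan_mass, synthetic, pipeline, cli
examples/           narrative scripts, one per capability
tests/              pytest suite (unit, property and end-to-end checks)
docs/methods.md     models, assumptions, parameter choices, limitations
```
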