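# Methods

This note documents the models implemented in `nmrbind`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter for reproducing results.

## Chemical-shift-perturbation maps

For each assigned backbone amide the combined shift change between the
apo and ligand-loaded spectra is

Δδ = [(Δδ_H)² + (w·Δδ_N)²]^½,  w = 0.25 by default,

with the ¹⁵N change down-weighted for its wider ppm dispersion. The
weight is configurable (0.14–0.17 variants circulate in the literature)
but 0.25 is the package default. Intensity changes are
ΔINT = 1 − Int_i/Int_o: 1 for a vanished resonance, 0 for no change,
negative for a genuinely intensified peak (retained, never clipped).

Peak matching across a titration is assignment-driven — by residue
number, never nearest-neighbour in ppm — because the workflow assumes
fully assigned spectra. A residue present in the apo list but absent from
a titration point is classified `broadened_out` and assigned ΔINT = 1
with no Δδ; there is no intensity threshold beyond absence from the list.
Mean and SD of Δδ are computed over observable residues only (sample SD,
ddof = 1): a vanished peak has no measurable shift and contaminating the
shift statistics with it would bias the thresholds. Outliers are
classified `above_2sd` (Δδ > mean + 2·SD) and `above_1sd`
(mean + 1·SD < Δδ ≤ mean + 2·SD); the categories are mutually exclusive
and a zero-SD (degenerate) map classifies nothing. Asn/Gln side-chain
NH₂ peaks are parsed and carried separately from backbone maps; Arg
Nε–Hε assignments are rejected at parse time as uninterpretable in
standard HSQC acquisition. PDB insertion codes are unsupported (error).

Whether the plotted "average Δδ" should include residues that later
broaden out is genuinely open; the package excludes them and exposes a
residue-subset argument so either convention is one call away.

## Two-site exchange

A binding residue interconverts between free (δ_f, R2_f) and bound
(δ_b, R2_b) states. With bound population p_b and dissociation rate
k_off, detailed balance fixes the pseudo-first-order on-rate
k_on' = k_off·p_b/(1 − p_b), and the transverse magnetization evolves
under

A = [[iω_f − R2_f − k_on', k_off], [k_on', iω_b − R2_b − k_off]].

Peak observables are the eigencomponents of A: apparent frequency from
the imaginary part, decay rate (Lorentzian half-width, s⁻¹) from the real
part, and amplitude from projecting the equilibrium populations onto the
detection vector (s(t) = 1ᵀ·e^{At}·p). Amplitudes always sum to 1. The
parameterisation is (p_bound, k_off) with per-nucleus Larmor frequencies,
so users reason in K_D space via the mass balance and convert ppm → rad/s
per dimension (`n15_larmor` supplies the ¹⁵N frequency from the ¹H
field). Degenerate limits (p_b ∈ {0,1}, k_off = 0) are returned
explicitly rather than diagonalized.

Two regime classifiers are provided: the titration heuristic by K_D
alone (fast > 100 µM, slow < 1 µM, intermediate between, boundaries
inclusive to intermediate) and the physically correct k_ex/|Δω| ratio
criterion (default threshold 3). The heuristic is what titration
practice quotes; the ratio test is what the simulator obeys.

Simulated "detectability": a component whose linewidth exceeds 5× the
free-state linewidth (configurable) is treated as broadened beyond
observation. This reproduces intermediate-exchange peak disappearance
without modelling receiver noise floors.

The tests cross-check the eigendecomposition against an independent
numerical route: the FID is step-propagated with a matrix exponential,
Fourier transformed, and peak-picked; position and width agree within 1%
across fast, intermediate and slow parameter grids.

## Binding mass balance and titration fits

fraction bound fb(P, L, K) = ((P+L+K) − √((P+L+K)² − 4PL))/(2P), the
physical root of the 1:1 mass-balance quadratic with ligand depletion.

Two curve models are fitted to average-Δδ vs. concentration data
(least squares via lmfit, plateau floating by default with a
fixed-plateau option, since either convention is defensible for
saturation plots):

* saturation exponential Δδ_max(1 − e^{−L/λ}), C50 = λ·ln2 — the
  empirical form for polymeric ligands where a mechanistic site model is
  not justified;
* 1:1 isotherm Δδ_max·fb(P₀, L, K_D) — valid in fast exchange only
  (caller-checked); its 50%-bound point has the closed form
  C50 = K_D + P₀/2 (at fb = ½ the free ligand is L − P₀/2, hence
  K_D = L − P₀/2). With 20 µM protein and K_D = 1 µM this gives 11 µM;
  in the dilute-protein limit C50 → K_D.

Initialisation is deterministic and derivative-free: Δδ_max from the
final titration point, λ or K_D from the concentration nearest the
half-maximal response. K_D is bounded in [10⁻⁹, 10⁹] µM and a fit ending
on a bound is flagged, not raised.

Multivalency: a chain with n equivalent, independent sites saturates the
protein at roughly K_D(mono)/n, so n ≈ K_D(mono)/C50(chain) (reported raw
and rounded to the nearest integer) and the site-average microscopic
K_D ≈ C50(chain)·n. These are order-of-magnitude estimators, not a
partition-function fit; cooperative/Hill models are out of scope.

## PFG diffusion

Signal attenuation follows ln A = −b·D with the Stejskal–Tanner factor
b = γ²g²δ²(Δ − δ/3); D comes from linear regression of ln A on b
(free intercept, so a zero-gradient point is harmless), with the standard
error and R² reported. Gradients are in G/cm (¹H γ = 26 752.2
rad·s⁻¹·G⁻¹); the gradient-pulse duration δ is a required parameter with
a 4 ms fixture default, Δ defaults to 34.2 ms, and the default design
uses 14 gradients over 1–75 G/cm. Points at or below a configurable
noise floor are excluded; a decay rising by more than 5% between
consecutive points warns (convection/phasing symptoms) but still fits.

Stokes–Einstein reference: R = (3M(v̄ + h·v_w)/(4πN_A))^⅓,
D = k_BT/(6πηR). Defaults describe water at 30 °C (η = 0.797 mPa·s) with
v̄ = 0.60 cm³/g (polysaccharide-like) and hydration h = 0.35 g/g. For a
14,300 Da chain this gives ≈1.6×10⁻⁶ cm²/s; the choice of hydrated vs.
anhydrous radius moves the number by ~10–20%, which is why comparisons
against it should carry a ±20% band. A measured D well below the
globular value indicates an extended/dynamic chain.

Complex growth: at protein/chain molar ratio r the chain carries
b = min(r, n_max) proteins and D = D_free·((m_c + b·m_p)/m_c)^(−x),
x = ⅓ by default (compact growth; 0.588 offered for a swollen coil).
The mass→D mapping is deliberately simple — shape changes on binding are
not modelled — so the curve is used for plateau logic, not absolute D
prediction. Plateau detection returns the first ratio from which every
successive relative decrease stays below a tolerance (default 3%); late
upturns (free protein contaminating the readout at high excess) are
flagged but do not disqualify the plateau.

## Glycan mass accounting

Average residue masses with the glycosidic water loss baked in (hexose
162.14 Da, HexNAc 203.19 Da, SO₃ 80.06 Da), end groups ignored: chain
mass = repeat mass × repeat count, so desulfation is
count × unsulfated-repeat mass. A 14,300 Da chain of disulfated LacNAc
repeats (525.45 Da) holds 27.2 repeats and desulfates to 9,942 Da.
Sulfation is a per-repeat average (non-integer allowed) because real
keratan mixes mono- and disulfated repeats. Monoisotopic masses and
sequence-resolved sulfation patterns are out of scope.

## Synthetic data: what it does and does not emulate

The generator titrates a virtual assigned protein (default: a
carbohydrate-recognition-domain-like construct numbered 108–250 with a
20-residue high-offset subset standing in for the sugar-binding β-sheet
face, a few percent of positions as amide-less prolines, and 20 µM
protein, matching common HSQC practice). Per titration point the bound
population comes from the 1:1 mass balance; each residue's peak position
in each dimension is the dominant two-site eigencomponent, and its height
is the base intensity scaled per dimension by
amplitude × (free linewidth / observed linewidth) — a Lorentzian-height
proxy that couples exchange broadening to ΔINT without full lineshape
synthesis. Residues exceeding the 5× linewidth cutoff are dropped from
the list. Noise: additive Gaussian on ppm (0.002 ppm ¹H, 0.02 ppm ¹⁵N)
and 2% multiplicative on heights — typical HSQC reproducibility. k_off
defaults to 2×10⁴ s⁻¹ (fast exchange for sub-ppm offsets at 600 MHz);
a few hundred s⁻¹ reaches the broadening regime. No published k_off
exists for these systems, so kinetic values are fixture choices.

Not emulated: spectral overlap and peak-picking errors, assignment
mistakes, multi-step or cooperative binding, temperature/pH drift, raw
FID/spectrum synthesis. Passing recovery tests therefore demonstrates
the estimators are correct *under the stated exchange model and noise*,
not robustness to pathologies of real spectra.

Everything is driven by one `numpy` Generator seed; a fixed seed
reproduces every emitted byte, including on-disk fixture bundles.

## Problem sizes and numerical choices

Stochastic checks use 50 seeded replicates (100 for the bias test) at the
noise levels above — enough for stable medians/modes while keeping the
full suite under half a minute. Fits are bounded least squares; SD
thresholds use strict inequalities; regression-based D must be positive;
ties in plateau detection resolve to the earliest qualifying ratio.
Degenerate inputs (flat titrations, no-decay PFG series, zero-SD maps,
empty residue overlap) raise or warn explicitly rather than returning
silent numbers.

## Known limitations

* The K_D-based exchange-regime classifier is a heuristic; it is provided
  because titration practice quotes it, with the k_ex/Δω classifier as
  the physically grounded alternative.
* The multivalent stoichiometry estimators assume equivalent independent
  sites; affinity gradients along a chain require calorimetric or
  partition-function treatment.
* Diffusion analysis is single-component; polydisperse mixtures
  (CONTIN-style inversion) and convection compensation are not modelled.
* Structure annotation writes plain PDB only (no mmCIF), and skips
  residues absent from the structure.
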