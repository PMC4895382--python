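# efcalc

Analysis toolkit for EF-hand calcium-binding studies: sequence-level
motif classification, NMR chemical-shift-perturbation (CSP) titration
analysis with exact 1:1 isotherm K_d fitting, structure-ensemble
statistics (backbone RMSD and interhelical θ/φ angles of EF hands), and
single-site ITC thermodynamics. The worked case throughout is the
calmodulin-like domain (CaMD) of human non-muscle α-actinin-1, which
binds a single Ca²⁺ ion in its first EF hand.

It is written for structural biologists and biophysicists who have a
titration peak list, an NMR ensemble, or an ITC injection table and want
the standard quantitative chain behind such a study in one place —
reproducible, seeded, and testable offline through a first-class
synthetic-data module.

## The models

**EF-hand classification.** A canonical EF loop coordinates Ca²⁺ in a
pentagonal bipyramid through positions X(1), Y(3), Z(5), −Y(7, backbone
CO), −X(9, water-mediated) and −Z(12, bidentate Glu/Asp). Sequences are
scanned window-by-window against per-position allowed-residue rules.

**CSP titration.** Per residue, Δδ(H,N) = sqrt(Δδ_H² + (w·Δδ_N)²) with
nitrogen weight w = 0.2; residues above 0.3 ppm at saturation map the
binding site, and the exact 1:1 isotherm

Δδ_obs = Δδ_max·[(P₀+L₀+K_d) − sqrt((P₀+L₀+K_d)² − 4P₀L₀)]/(2P₀)

is fitted (globally shared K_d or per residue) by bounded trust-region
least squares.

**Ensemble geometry.** Kabsch superposition, ensemble RMSD under both
the to-mean and average-pairwise conventions, principal-axis helix fits,
and interhelical angles θ = arccos(e·z), φ = atan2(e·y, e·x) in a
loop-anchored frame, with circular statistics and wrap-safe holo − apo
differences.

**ITC.** Single-site (Wiseman-type) injection-heat model with perfusion
dilution, fitted over (n, K_d, ΔH, offset), and thermodynamic linkage
ΔG = RT ln K_d, TΔS = ΔH − ΔG.

## Worked example

```sh
efcalc demo --out demo_out --seed 1
```

runs the whole chain on synthetic inputs and prints

```json
{
  "kd_uM": 170.13428063518836,
  "count_canonical": 3,
  "delta_theta": 15.654964525977483,
  "rmsd_to_mean": 0.8538284016968397,
  "itc_kd_uM": 112.75761895898174
}
```

Reading: the global CSP fit recovered K_d = 170 μM from a titration
generated at 170 μM (15 points, 0–20 eq Ca²⁺ at 0.312 mM protein,
0.005 ppm shift noise); 3 of 8 generated EF loops classified canonical,
matching the generator's ground truth; the apo→holo interhelical opening
Δθ came back +15.7° for a constructed +15.1° under 2° ensemble jitter;
the 20-model ensemble's backbone RMSD to the mean was 0.85 Å for 0.5 Å
isotropic coordinate jitter (expectation σ√3 ≈ 0.87 Å); and the ITC fit
recovered K_d = 113 μM from a thermogram generated at 104.2 μM with 2%
heat noise. Full numbers land in `demo_out/report.json`.

The same steps are available as narrative drivers:

```sh
python analysis/01_scan_ef_hands.py --seed 1
python analysis/02_titration_csp_kd.py --seed 1
python analysis/03_ensemble_geometry.py --seed 1
python analysis/04_itc_thermodynamics.py --seed 1
```

each writing its tables under `results/`. Individual subcommands
(`efcalc scan|csp|vgm|rmsd|itc|simulate`) operate on standard formats:
FASTA, CSV peak lists with a series manifest, multi-model PDB/mmCIF, and
injection-table CSV.

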