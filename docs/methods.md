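# Methods

This package implements the quantitative analysis chain used to
characterise calcium binding by an EF-hand pair domain (the
calmodulin-like domain, CaMD, of human non-muscle α-actinin-1 is the
worked case throughout): sequence-level motif classification, NMR
chemical-shift-perturbation (CSP) titration analysis with 1:1 isotherm
fitting, structure-ensemble statistics (backbone RMSD and interhelical
θ/φ angles), and single-site ITC thermodynamics. Every analysis is
exercised on synthetic data whose statistical structure matches the
assumptions of the corresponding model, so the whole chain is testable
without any downloads.

## EF-hand loop classification (`efcalc.seqscan`)

A canonical EF hand coordinates one Ca²⁺ ion in a pentagonal bipyramid
through a 12-residue loop. Loop positions 1, 3, 5, 7, 9 and 12 supply the
ligands and are labelled by coordination axis: X, Y, Z, −Y, −X, −Z.
Position 7 coordinates through its backbone carbonyl and position 9
through a hydrogen-bonded water, so neither constrains the side chain
strongly; position 12 contributes the invariant bidentate Glu/Asp.

The default per-position allowed-residue sets are

| position | label | default residues | rationale |
|---|---|---|---|
| 1 | X | D | near-invariant Asp |
| 3 | Y | D, N, S | oxygen-bearing short side chains |
| 5 | Z | D, N, S, T | as Y, plus Thr |
| 7 | −Y | any (permissive) | backbone CO coordinates |
| 9 | −X | S, T, D, N, E, G, Q | water-mediated, weakly constrained |
| 12 | −Z | E, D | invariant bidentate ligand |

These sets are a design choice consistent with published EF-loop sequence
preferences and with every residue of the experimentally characterised
EF1 loop (D759, D761, S763, T765, G767, E770); they are overridable from
a plain-text config, and a strict profile restricting position 7 to small
residues is provided. A permissive position is encoded as `None`, which
is distinct from an empty set (nothing allowed); this keeps rule
tightening monotone: removing a residue from any set can never create a
new canonical call.

One consequence of the backbone-permissive position 7 is that a loop
degenerate *only* at −Y cannot be recognised as such from sequence — the
classification of the second EF hand in this domain therefore reports
failures at Z and −Z but not −Y, which matches what sequence information
alone can support. Window mode evaluates every 12-residue frame whose
first residue passes the X rule (a length-12 input is treated as a single
window regardless), reports all overlapping hits without suppression, and
is checked against a brute-force per-position enumeration in the tests.

The shipped α-actinin-1 record is a synthetic stand-in: the documented
coordinating residues sit at their author numbers (numbering offset 743),
the flanks are filler, and the record is labelled synthetic.

## CSP titration analysis (`efcalc.titration`)

Combined amide perturbation per residue:

    Δδ(H,N) = sqrt(Δδ_H² + (w·Δδ_N)²)

with nitrogen weight `w = 0.2` by default (the conventional amide
scaling that compensates the larger ¹⁵N shift range). The weight is
recorded in every output. Residues missing in either state are reported
as NaN, never as zero, and excluded from fits.

Binding-site mapping selects residues with Δδ(H,N) above a threshold
(default 0.3 ppm) at the saturating end point.

Kd estimation fits the exact 1:1 isotherm

    Δδ_obs = Δδ_max · [(P₀+L₀+Kd) − sqrt((P₀+L₀+Kd)² − 4P₀L₀)] / (2P₀)

by trust-region least squares (scipy `least_squares`), with Kd on a log
scale bounded in [1 nM, 1 M], Δδ_max in (0, 10] ppm, and three log-spaced
Kd starts to escape local minima. The implementation evaluates the
algebraically equivalent conjugate form 2L₀/(s + sqrt(s² − 4P₀L₀)), which
is numerically stable when the bound fraction is small; the tests verify
agreement with a brentq root of the mass-balance equation to 1e-10
relative. Global mode shares one Kd across residues with residue-specific
Δδ_max; per-residue mode reports the median. Standard errors come from
the Jacobian at the solution (delta method for the log-Kd
transformation). Both modes are exposed because a titration analysis may
reasonably do either; on the synthetic study conditions they agree, and
the global fit is at least as precise (asserted in the tests).

Peak tracking for unassigned lists uses greedy nearest-neighbour linking
in weighted (δH, w·δN) space with a maximum step; unmatched peaks keep
their gap (marked absent) and may re-link when they reappear within
range, mimicking exchange-broadened cross-peaks that vanish early in a
titration and return near saturation.

## Ensemble statistics (`efcalc.structure`)

Ensembles are read with gemmi (PDB or mmCIF), keeping author numbering,
dropping heteroatoms and non-'A' alternate locations, rejecting insertion
codes, and requiring one atom inventory across models. Superposition is
Kabsch SVD with a proper-rotation guard and a degeneracy check for
collinear selections; the default reference is the iteratively refined
mean structure (two refinement passes).

Ensemble spread is reported under both conventions:

- **to-mean**: deviations of all models' selected atoms from the mean
  structure with the sample (n−1) normalisation over models;
- **pairwise**: average RMSD over all model pairs.

With the (n−1) normalisation the two are related exactly by
pairwise = √2 · to-mean for two models, and isotropic Gaussian jitter of
per-coordinate σ gives an unbiased to-mean value of σ√3 — both asserted
in the tests. Both values are always emitted with the convention named,
since reported ensemble RMSDs in the literature rarely state which
convention was used; backbone means N, CA, C, O.

Helix axes are principal components (largest-variance eigenvector) of the
selected atom coordinates, sign-oriented from the N-terminal half
centroid to the C-terminal half centroid, so the orientation is set by
the termini and not by the arbitrary eigenvector sign; the RMS distance
of atoms to the axis is reported as a fit-quality measure. Ranges shorter
than 5 residues are rejected.

## Interhelical angles (`efcalc.vgm`)

Classical vector-geometry treatments of EF hands express the exiting
helix in the frame of a reference EF hand superposed on the z-axis. To
avoid a dependence on an external, unpinned reference structure, each
hand here carries its own loop-anchored right-handed frame:

- z = entering-helix axis (N→C),
- x = unit component of (first-loop-residue CA − entering centroid)
  perpendicular to z,
- y = z × x.

θ = arccos(e·z) ∈ [0°, 180°] is the opening angle and
φ = atan2(e·y, e·x) ∈ (−180°, 180°] the azimuth of the exiting-helix
axis e, measured counterclockwise from +x viewed from +z. The
construction is invariant under rigid transforms (verified to 1e-9°) and
exactly invertible: the synthetic generator poses helix pairs so the
fitted axes land on prescribed (θ, φ), and a 1000-point random grid round
trips to better than 1e-6°. Because the frame differs from any specific
external-reference convention, absolute θ/φ values are comparable across
states analysed with this package but may be offset from values computed
against a particular reference EF hand; state *differences* (holo −
apo on ensemble means, with φ wrapped circularly into (−180°, 180°]) are
the robust quantity. A parallel exiting axis makes φ undefined; it is
reported as 0 with a degeneracy flag. Ensemble summaries use the
arithmetic mean for θ and the circular mean/SD for φ; models with
degenerate frames are excluded and counted. Default helix boundaries for
the α-actinin-1 hands ship as an editable table, with the fourth hand
excluded from state comparisons by default because its exiting helix is
poorly defined in the ensembles.

## Single-site ITC (`efcalc.thermo`)

The bound concentration after each injection solves the same quadratic
mass balance as the NMR isotherm, with n·[P] as the site concentration.
Dilution follows the perfusion convention of overfilled-cell instruments:
cell volume constant, each injection displacing liquid of pre-injection
composition. The heat of injection i is

    q_i = ΔH · V₀ · ([PL]_i − [PL]_{i−1}·(1 − v_i/V₀)) + offset

in μcal for ΔH in kcal/mol. Under this dilution model the total heat
equals ΔH·V₀·[PL]_final *plus* the enthalpy carried out with displaced
complex; the conservation test asserts that full budget against an
independent brentq equilibrium solver. Positive heat means heat absorbed
(endothermic), matching the wild-type profile.

Fitting minimises squared heat residuals over (n, Kd, ΔH, offset), n
optionally fixed, Kd on a log scale with three starts. The c-value
(n·P₀/Kd) is reported and a value outside [0.01, 1000] triggers a
weak-information warning; all-zero heats are flagged unidentifiable
rather than fitted. Linkage uses R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹ and
T = 298.15 K by default, with ΔG = RT ln Kd (association, 1 M standard
state, negative favourable) and TΔS = ΔH − ΔG; ΔG = ΔH − TΔS holds by
construction on every emitted parameter set.

## Synthetic data (`efcalc.synthetic`)

The generators define the conditions every stochastic check runs under:

- **Titration**: 56 residues with 6 binders, 15 points from 0 to 20
  equivalents (denser below 1 eq), P₀ = 0.312 mM, residue Δδ_max uniform
  in [0.35, 1.24] ppm, Gaussian shift noise 0.005 ppm on both δH and δN,
  optional peak dropout over 0.25–1.0 eq mimicking exchange broadening of
  loop residues. Binder trajectories follow the exact isotherm; the
  random Δδ split between ¹H and ¹⁵N keeps the combined CSP exactly
  Δδ_max × bound-fraction.
- **Helix pairs**: idealised α-helices (rise 1.5 Å/residue, CA radius
  2.3 Å, 100° twist; full N/CA/C/O backbone on helix residues, CA-only
  loop), posed so the *fitted* principal axes — not the nominal
  construction axes — realise the requested (θ, φ) exactly, which is what
  makes the 1e-6° round trip meaningful. Per-model angular jitter applies
  a small random rotation to the exiting helix.
- **Ensembles**: isotropic Gaussian per-atom displacement of a base
  model.
- **EF-loop sequences**: canonical loops drawn from the active rule sets,
  degenerate loops violating named non-permissive positions, embedded in
  flanks rejection-sampled against a per-window check so no accidental
  canonical windows exist.
- **ITC**: the single-site simulator plus proportional Gaussian heat
  noise; default design 25 × 2 μL injections of 10 mM ligand into 0.40 mM
  protein in a 200 μL cell (molar-ratio span past 2).

All generators are deterministic in their seed (one numpy Generator per
call), write byte-identical files across runs, and emit machine-readable
ground-truth sidecars.

What the synthetic data does **not** emulate: real chemical-shift
directions predicted from structure, line-shape/intermediate-exchange
effects, peak overlap, realistic helix irregularity, baseline drift or
injection-spacing artefacts in ITC. Passing tests therefore demonstrate
correctness of the estimators under their own model assumptions — exact
isotherm saturation, isotropic coordinate noise, ideal helices — not
robustness to the systematic effects of real spectra and thermograms.

## Problem sizes and numerical choices

Stochastic checks use 200 titration replicates, 100 ITC replicates,
1000-draw isotherm and angle grids, and 20-model ensembles — sizes chosen
so each Monte-Carlo estimate is stable at the tolerance it is compared
against while the whole suite stays interactive. Fit tolerances are set
to machine-level (`xtol = ftol = gtol = 1e-15`) because the round-trip
contracts are asserted at 1e-6 relative. Ties and degenerate inputs are
errors, not silent defaults: empty selections, collinear superpositions,
anchors on the helix axis, non-positive concentrations and zero-ligand
titrations all raise.

## Known limitations

- Absolute θ/φ values depend on the loop-anchored frame convention (see
  above); comparisons against tables computed with an external reference
  EF hand should use the state differences, or supply the same reference.
- The scanner has no gap handling: EF loops shortened by deletions
  simply yield no passing frame in window mode.
- The CSP fitter assumes fast exchange (shift tracks population); no
  line-shape model is provided.
- The ITC model is strictly single-site; no competitive or sequential
  schemes.
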