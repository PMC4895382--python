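"""Synthetic fixtures with the statistical structure the analyses assume.

Every generator is deterministic in its seed (one ``numpy`` Generator per
call, never wall-clock seeded), returns in-memory objects together with a
machine-readable ground-truth record, and has a matching writer that emits
the same standard formats the analysis modules read (FASTA, CSV peak lists
with a manifest, multi-model PDB, injection-table CSV, JSON sidecars).

The default titration scenario reproduces the study conditions the
analyses target: 15 titration points from 0 to 20 molar equivalents at a
fixed 0.312 mM protein concentration, binder saturation following the
exact 1:1 isotherm, Gaussian shift noise, and optional peak disappearance
over an early-equivalents window (exchange broadening of loop residues).
"""

from __future__ import annotations

import json
import math
import pathlib
from dataclasses import dataclass, field

import numpy as np

from . import seqscan, thermo, titration
from .structure import StructureEnsemble
from .titration import (PeakAssignment, TitrationPoint, TitrationSeries,
                        isotherm_1to1)
from .vgm import HandDefinition

#: 15-point equivalents schedule, 0 to 20 eq, denser before 1 eq so the
#: early broadening window (0.25-1.0 eq) and the >3 eq reappearance are
#: both sampled.
DEFAULT_EQUIVALENTS = (0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0,
                       6.0, 8.0, 10.0, 15.0, 20.0)
DEFAULT_P0 = 0.312e-3  # molar
DEFAULT_DROPOUT_WINDOW = (0.25, 1.0)  # equivalents

AA20 = "ACDEFGHIKLMNPQRSTVWY"


# --------------------------------------------------------------------------
# titration fixtures
# --------------------------------------------------------------------------

def gen_titration(residues: int = 56, binding_subset: int = 6,
                  kd: float = 170e-6,
                  delta_max_range: tuple[float, float] = (0.35, 1.24),
                  p0: float = DEFAULT_P0,
                  equivalents: tuple[float, ...] = DEFAULT_EQUIVALENTS,
                  noise_sd: float = 0.005,
                  dropout: tuple[float, float] | None = None,
                  dropout_count: int = 2,
                  seed: int = 0) -> tuple[TitrationSeries, dict]:
    """Synthetic amide titration with a known binding subset.

    Binder residues follow the 1:1 isotherm with residue-specific Δδ_max
    drawn uniformly from ``delta_max_range``; the rest carry pure noise.
    ``dropout`` marks ``dropout_count`` binder peaks absent while the
    equivalents lie inside the window (exchange broadening). Returns the
    series plus the ground truth (Kd, binders, per-residue Δδ_max).
    """
    if binding_subset > residues:
        raise ValueError("binding_subset exceeds residue count")
    if list(equivalents) != sorted(equivalents) or equivalents[0] != 0:
        raise ValueError("equivalents schedule must start at 0 and be sorted")
    rng = np.random.default_rng(seed)
    resnums = np.arange(743, 743 + residues)
    binders = np.sort(rng.choice(resnums, size=binding_subset, replace=False))
    dmax = {int(r): float(rng.uniform(*delta_max_range)) for r in binders}
    # random split of the combined shift into H and N components
    split = {int(r): float(rng.uniform(0.3, 0.95)) for r in binders}
    ref_h = {int(r): float(rng.uniform(7.0, 9.5)) for r in resnums}
    ref_n = {int(r): float(rng.uniform(105.0, 130.0)) for r in resnums}
    dropped = [int(r) for r in binders[:dropout_count]] if dropout else []

    w = titration.DEFAULT_NITROGEN_WEIGHT
    points = []
    for eq in equivalents:
        l0 = eq * p0
        peaks = []
        for r in resnums:
            r = int(r)
            if r in dmax:
                dd = isotherm_1to1(p0, l0, kd, dmax[r]) if l0 else 0.0
                u = split[r]
                d_h = dd * u
                d_n = dd * math.sqrt(1.0 - u * u) / w
            else:
                d_h = d_n = 0.0
            present = True
            if dropout and r in dropped and dropout[0] <= eq <= dropout[1]:
                present = False
            peaks.append(PeakAssignment(
                residue_number=r,
                delta_H=ref_h[r] + d_h + rng.normal(0.0, noise_sd),
                delta_N=ref_n[r] + d_n + rng.normal(0.0, noise_sd),
                present=present))
        points.append(TitrationPoint(ligand_total=l0, protein_total=p0,
                                     peaks=peaks))
    truth = {
        "kd": kd,
        "p0": p0,
        "equivalents": list(equivalents),
        "binders": [int(b) for b in binders],
        "delta_max": {str(k): v for k, v in dmax.items()},
        "noise_sd": noise_sd,
        "dropped_residues": dropped,
        "dropout_window_eq": list(dropout) if dropout else None,
        "nitrogen_weight": w,
        "seed": seed,
    }
    return TitrationSeries(points=points), truth


def write_titration(series: TitrationSeries, truth: dict, outdir) -> pathlib.Path:
    """Write per-point peak CSVs, a series manifest, and the truth sidecar."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, pt in enumerate(series.points):
        name = f"point_{i:02d}.csv"
        with open(outdir / name, "w") as fh:
            fh.write("residue,dH_ppm,dN_ppm\n")
            for p in pt.peaks:
                if p.present:
                    fh.write(f"{p.residue_number},{p.delta_H:.6f},{p.delta_N:.6f}\n")
        rows.append((name, pt.ligand_total, pt.protein_total))
    with open(outdir / "manifest.csv", "w") as fh:
        fh.write("file,ligand_total_M,protein_total_M\n")
        for name, l0, p0 in rows:
            fh.write(f"{name},{l0:.9e},{p0:.9e}\n")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir / "manifest.csv"


# --------------------------------------------------------------------------
# idealised helix-pair ensembles
# --------------------------------------------------------------------------

#: per-atom (radius Å, phase offset deg, z offset Å) of the idealised
#: α-helix: 1.5 Å rise/residue, 100° twist, CA radius 2.3 Å
HELIX_ATOM_GEOMETRY = {
    "N": (1.55, -28.0, -0.70),
    "CA": (2.30, 0.0, 0.00),
    "C": (1.65, 27.0, 0.55),
    "O": (2.00, 40.0, 1.40),
}


def _helix_template(length: int, rise: float, radius: float,
                    twist_deg: float = 100.0):
    """Idealised helix backbone; returns (atom names, residue index, xyz)."""
    names, resi, xyz = [], [], []
    scale = radius / HELIX_ATOM_GEOMETRY["CA"][0]
    for i in range(length):
        for name, (r, phase, dz) in HELIX_ATOM_GEOMETRY.items():
            ang = math.radians(twist_deg * i + phase)
            xyz.append([scale * r * math.cos(ang), scale * r * math.sin(ang),
                        rise * i + dz])
            names.append(name)
            resi.append(i)
    return names, np.array(resi), np.array(xyz)


def _principal_axis(points: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Largest-variance eigenvector oriented from low-order to high-order
    centroid (same convention as the helix-axis fit)."""
    centered = points - points.mean(axis=0)
    w, v = np.linalg.eigh(centered.T @ centered)
    axis = v[:, -1]
    mid = (order.min() + order.max()) / 2.0
    if axis @ (points[order > mid].mean(axis=0) - points[order <= mid].mean(axis=0)) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector a to unit vector b (Rodrigues)."""
    c = float(a @ b)
    axis = np.cross(a, b)
    n = np.linalg.norm(axis)
    if n < 1e-15:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate 180° about any perpendicular
        perp = np.eye(3)[np.argmin(np.abs(a))]
        axis = np.cross(a, perp)
        axis /= np.linalg.norm(axis)
        return _rodrigues(axis, math.pi)
    return _rodrigues(axis / n, math.atan2(n, c))


def _rodrigues(axis: np.ndarray, angle: float) -> np.ndarray:
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(angle) * k + (1 - math.cos(angle)) * (k @ k)


def gen_helix_pair_ensemble(theta: float, phi: float, models: int = 1,
                            jitter_sd: float = 0.0, helix_length: int = 18,
                            rise: float = 1.5, radius: float = 2.3,
                            seed: int = 0
                            ) -> tuple[StructureEnsemble, HandDefinition, dict]:
    """Entering/exiting helix pair posed at exact (θ, φ) in the loop frame.

    The entering helix is posed so its fitted principal axis is exactly +z
    and the first loop residue CA lies on the +x side, making the
    loop-anchored frame the identity; the exiting helix's fitted axis is
    posed along (sinθcosφ, sinθsinφ, cosθ). Angular jitter rotates the
    exiting helix per model by a random small rotation about its centroid.
    Helix residues carry a full N/CA/C/O backbone; the three connecting
    loop residues carry CA only.
    """
    if not 0.0 < theta < 180.0:
        raise ValueError("theta must be in (0, 180) degrees")
    rng = np.random.default_rng(seed)
    names, resi, pts = _helix_template(helix_length, rise, radius)
    ca = pts[np.array(names) == "CA"]
    ca_resi = resi[np.array(names) == "CA"]
    axis_t = _principal_axis(ca, ca_resi)
    center_t = ca.mean(axis=0)

    # entering helix: fitted CA axis exactly +z, CA centroid at origin
    r_enter = _rotation_between(axis_t, np.array([0.0, 0.0, 1.0]))
    entering = (pts - center_t) @ r_enter.T

    th, ph = math.radians(theta), math.radians(phi)
    e_axis = np.array([math.sin(th) * math.cos(ph),
                       math.sin(th) * math.sin(ph), math.cos(th)])
    half = rise * helix_length / 2.0
    anchor = np.array([4.0, 0.0, half + 2.0])  # +x offset fixes the frame
    exit_center = anchor + e_axis * (half + 3.0)
    r_exit = _rotation_between(np.array([0.0, 0.0, 1.0]), e_axis)
    exiting0 = (entering @ r_exit.T) + exit_center

    loop_ca = np.array([anchor,
                        anchor + (exit_center - anchor) / 3.0,
                        anchor + 2.0 * (exit_center - anchor) / 3.0])

    atoms: list[tuple[str, int, str, str]] = []
    for i in range(helix_length):
        for name in HELIX_ATOM_GEOMETRY:
            atoms.append(("A", i + 1, "ALA", name))
    for j in range(3):
        atoms.append(("A", helix_length + 1 + j, "GLY", "CA"))
    for i in range(helix_length):
        for name in HELIX_ATOM_GEOMETRY:
            atoms.append(("A", helix_length + 4 + i, "ALA", name))

    model_coords = []
    for _ in range(models):
        if jitter_sd > 0:
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            rot = _rodrigues(axis, math.radians(rng.normal(0.0, jitter_sd)))
            ex_center_now = exiting0.mean(axis=0)
            exiting = (exiting0 - ex_center_now) @ rot.T + ex_center_now
        else:
            exiting = exiting0
        model_coords.append(np.vstack([entering, loop_ca, exiting]))
    ensemble = StructureEnsemble(atoms=atoms, coords=np.stack(model_coords),
                                 source_id="synthetic-helix-pair")
    hand = HandDefinition(
        name="SYN", entering=(1, helix_length),
        exiting=(helix_length + 4, 2 * helix_length + 3),
        loop_anchor=helix_length + 1)
    truth = {"theta": theta, "phi": phi, "models": models,
             "jitter_sd": jitter_sd, "helix_length": helix_length,
             "rise": rise, "radius": radius, "seed": seed}
    return ensemble, hand, truth


def gen_ensemble_jitter(base: StructureEnsemble, models: int,
                        coordinate_sd: float, seed: int = 0) -> StructureEnsemble:
    """Replicate a base model with isotropic Gaussian displacement per atom."""
    if coordinate_sd < 0:
        raise ValueError("coordinate_sd must be non-negative")
    rng = np.random.default_rng(seed)
    base_xyz = base.coords[0]
    coords = np.stack([
        base_xyz + rng.normal(0.0, coordinate_sd, size=base_xyz.shape)
        if coordinate_sd > 0 else base_xyz.copy()
        for _ in range(models)
    ])
    return StructureEnsemble(atoms=list(base.atoms), coords=coords,
                             source_id=f"{base.source_id}-jitter")


# --------------------------------------------------------------------------
# EF-loop sequence fixtures
# --------------------------------------------------------------------------

def _random_loop(rng, rules: seqscan.CoordinationRuleSet,
                 violate: list[str] | None = None) -> str:
    """A 12-mer satisfying every rule position, except the listed positions
    which are forced to fail (only non-permissive positions can fail)."""
    violate = violate or []
    loop = []
    for pos in range(1, 13):
        label = next((lb for lb, p in seqscan.POSITION_LABELS.items() if p == pos),
                     None)
        if label is None:
            loop.append(rng.choice(list("AGLKIVSTEQ")))
        else:
            allowed = rules.allowed[label]
            if label in violate:
                if allowed is None:
                    raise ValueError(f"position {label} is permissive; "
                                     "cannot be violated from sequence")
                pool = sorted(set(AA20) - set(allowed))
            else:
                pool = sorted(allowed) if allowed is not None else list("AGLKIVSTEQ")
            loop.append(rng.choice(pool))
    return "".join(loop)


def gen_ef_sequences(canonical: int, degenerate: int,
                     rules: seqscan.CoordinationRuleSet | None = None,
                     flank_length: int = 10, seed: int = 0
                     ) -> tuple[list[seqscan.SequenceRecord], list[dict]]:
    """EF-loop fixtures embedded in flanks free of accidental canonical windows.

    Canonical loops satisfy every rule position; each degenerate loop
    violates at least one named non-permissive position. Flanks are
    rejection-sampled against a per-window position check so the intended
    loop is the only canonical window in a canonical record and degenerate
    records contain none.
    """
    rules = rules or seqscan.CoordinationRuleSet()
    rng = np.random.default_rng(seed)
    violable = sorted(lb for lb, s in rules.allowed.items() if s is not None)
    records, truths = [], []

    def window_canonical(seq: str, start: int) -> bool:
        return all(rules.passes(lb, seq[start + p - 1])
                   for lb, p in seqscan.POSITION_LABELS.items())

    def build(index: int, make_canonical: bool):
        if make_canonical:
            violated: list[str] = []
        else:
            k = int(rng.integers(1, min(3, len(violable)) + 1))
            violated = sorted(rng.choice(violable, size=k, replace=False).tolist())
        loop = _random_loop(rng, rules, violate=violated or None)
        for _ in range(1000):
            left = "".join(rng.choice(list(AA20), size=flank_length))
            right = "".join(rng.choice(list(AA20), size=flank_length))
            seq = left + loop + right
            hits = [s for s in range(len(seq) - 11) if window_canonical(seq, s)]
            want = [flank_length] if make_canonical else []
            if hits == want:
                kind = "canonical" if make_canonical else "degenerate"
                rec = seqscan.SequenceRecord(
                    id=f"{kind}_{index:02d}", residues=seq, numbering_offset=1)
                records.append(rec)
                truths.append({
                    "id": rec.id,
                    "loop_start": flank_length + 1,
                    "canonical": make_canonical,
                    "violated_positions": violated,
                })
                return
        raise RuntimeError("flank rejection sampling failed")

    for i in range(canonical):
        build(i, True)
    for i in range(degenerate):
        build(i, False)
    return records, truths


def write_fasta(records: list[seqscan.SequenceRecord], truths: list[dict],
                outdir) -> pathlib.Path:
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "sequences.fasta"
    with open(fasta, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.residues}\n")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truths, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return fasta


def actn1_camd_fixture() -> seqscan.SequenceRecord:
    """Synthetic stand-in for the alpha-actinin-1 CaMD sequence region.

    The EF1 loop carries the experimentally documented coordinating
    residues at their author numbers (D759 at X, D761 at Y, S763 at Z,
    T765 at −Y, G767 near −X, E770 at −Z; construct numbering offset 743);
    the flanking sequence is synthetic filler, not the deposited sequence.
    """
    # offset 743 -> index of residue 759 is 16
    flank_n = "MTQIEDLSAQKAEMNR"  # residues 743-758 (synthetic filler)
    loop = "DADGSGTLGAHE"  # 759-770: D759 D761 S763 T765 G767 E770
    flank_c = "ALDFIAWRSVENMQKHA"  # 771-787 (synthetic filler)
    return seqscan.SequenceRecord(id="ACTN1_CaMD_synthetic",
                                  residues=flank_n + loop + flank_c,
                                  numbering_offset=743)


# --------------------------------------------------------------------------
# ITC fixtures
# --------------------------------------------------------------------------

def default_itc_design(cell_concentration: float = 0.40e-3,
                       syringe_concentration: float = 10e-3,
                       cell_volume: float = 200e-6,
                       injection_volume: float = 2e-6,
                       n_injections: int = 25,
                       temperature: float = thermo.T_STANDARD
                       ) -> thermo.ITCExperiment:
    """Experiment design mirroring the study: 0.26-0.72 mM protein in a
    200 μL cell, 5-20 mM Ca2+ in the syringe, 2 μL injections; the molar
    ratio axis spans past 2 by the final injection."""
    return thermo.ITCExperiment(
        cell_concentration=cell_concentration,
        syringe_concentration=syringe_concentration,
        cell_volume=cell_volume,
        injection_volumes=np.full(n_injections, injection_volume),
        temperature=temperature)


def gen_itc(params: thermo.ThermoParams,
            design: thermo.ITCExperiment | None = None,
            noise_fraction: float = 0.0, seed: int = 0
            ) -> tuple[thermo.ITCExperiment, dict]:
    """Simulated thermogram plus Gaussian heat noise and truth record."""
    design = design or default_itc_design(temperature=params.temperature)
    exp = thermo.simulate_itc(params, design)
    rng = np.random.default_rng(seed)
    if noise_fraction > 0:
        sd = noise_fraction * float(np.max(np.abs(exp.heats)))
        exp.heats = exp.heats + rng.normal(0.0, sd, size=exp.heats.shape)
    truth = {"n": params.n, "kd": params.kd, "dh": params.dh,
             "offset": params.offset, "temperature": params.temperature,
             "noise_fraction": noise_fraction, "seed": seed}
    return exp, truth


def write_itc(exp: thermo.ITCExperiment, truth: dict, outdir) -> pathlib.Path:
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = outdir / "injections.csv"
    with open(table, "w") as fh:
        fh.write("volume_uL,heat_ucal\n")
        for v, q in zip(exp.injection_volumes, exp.heats):
            fh.write(f"{v * 1e6:.3f},{q:.9f}\n")
    meta = {
        "cell_concentration_M": exp.cell_concentration,
        "syringe_concentration_M": exp.syringe_concentration,
        "cell_volume_L": exp.cell_volume,
        "temperature_K": exp.temperature,
    }
    with open(outdir / "experiment.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return table
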