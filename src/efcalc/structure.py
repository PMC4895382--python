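"""Multi-model structure ensembles: superposition, RMSD statistics, helix axes.

NMR structures are deposited as ensembles of models sharing one atom
inventory. The operations here work on a light array-backed container read
through gemmi: rigid-body (Kabsch) superposition over a residue selection,
ensemble precision as backbone RMSD (both to-the-mean-structure and
average-pairwise conventions), and least-squares helix axis fitting used by
the interhelical-angle analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class ResidueSelection:
    """Residue ranges (author numbering, inclusive) plus an atom class."""

    chain: str = "A"
    ranges: tuple[tuple[int, int], ...] = ()
    atoms: str = "backbone"  # backbone | CA | all

    def __post_init__(self) -> None:
        if self.atoms not in ("backbone", "CA", "all"):
            raise ValueError(f"unknown atom class {self.atoms!r}")
        for lo, hi in self.ranges:
            if hi < lo:
                raise ValueError(f"empty residue range {lo}-{hi}")

    def contains(self, chain: str, residue_number: int) -> bool:
        if chain != self.chain:
            return False
        if not self.ranges:
            return True
        return any(lo <= residue_number <= hi for lo, hi in self.ranges)

    def wants_atom(self, atom_name: str) -> bool:
        if self.atoms == "all":
            return True
        if self.atoms == "CA":
            return atom_name == "CA"
        return atom_name in BACKBONE_ATOMS


@dataclass
class StructureEnsemble:
    """Ordered models over a shared atom inventory.

    ``atoms`` is a record array of (chain, residue_number, residue_name,
    atom_name); ``coords`` has shape (n_models, n_atoms, 3) in Å.
    """

    atoms: list[tuple[str, int, str, str]]
    coords: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.coords.ndim != 3 or self.coords.shape[1] != len(self.atoms):
            raise ValueError("coords shape inconsistent with atom inventory")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    def selection_index(self, selection: ResidueSelection) -> np.ndarray:
        idx = [
            i for i, (ch, rn, _, an) in enumerate(self.atoms)
            if selection.contains(ch, rn) and selection.wants_atom(an)
        ]
        if not idx:
            raise ValueError("selection matches no atoms")
        if selection.atoms == "backbone":
            # selection-aware completeness check: every residue needs N,CA,C,O
            seen: dict[tuple[str, int], set[str]] = {}
            for i in idx:
                ch, rn, _, an = self.atoms[i]
                seen.setdefault((ch, rn), set()).add(an)
            for (ch, rn), names in seen.items():
                missing = set(BACKBONE_ATOMS) - names
                if missing:
                    raise ValueError(
                        f"chain {ch} residue {rn}: missing backbone atoms {sorted(missing)}")
        return np.array(idx, dtype=int)

    def subset_coords(self, selection: ResidueSelection) -> np.ndarray:
        return self.coords[:, self.selection_index(selection), :]


def read_ensemble(path, fmt: str | None = None) -> StructureEnsemble:
    """Read a multi-model PDB or mmCIF file.

    Heteroatoms and waters are excluded; of alternate locations only 'A'
    (or blank) is kept; insertion codes are rejected. Author residue
    numbering is preserved. All models must share one atom inventory.
    """
    path = str(path)
    if fmt == "pdb":
        st = gemmi.read_pdb(path)
    elif fmt in ("mmcif", "cif"):
        st = gemmi.make_structure_from_block(gemmi.cif.read(path)[0])
    else:
        st = gemmi.read_structure(path)
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"no models in {path}")

    def model_atoms(model):
        inv, xyz = [], []
        for chain in model:
            for res in chain:
                if res.het_flag == "H" or res.name == "HOH":
                    continue
                if res.seqid.icode not in (" ", "", "\x00"):
                    raise ValueError(
                        f"insertion code at {chain.name} {res.seqid.num}{res.seqid.icode}")
                for atom in res:
                    if atom.altloc not in ("", "\x00", "A"):
                        continue
                    inv.append((chain.name, res.seqid.num, res.name, atom.name))
                    xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
        return inv, np.array(xyz)

    inv0, xyz0 = model_atoms(st[0])
    coords = [xyz0]
    for k in range(1, len(st)):
        inv, xyz = model_atoms(st[k])
        if inv != inv0:
            extra = set(inv) ^ set(inv0)
            raise ValueError(
                f"model {k + 1} atom inventory differs from model 1: "
                f"{sorted(extra)[:5]}{'...' if len(extra) > 5 else ''}")
        coords.append(xyz)
    return StructureEnsemble(atoms=inv0, coords=np.stack(coords),
                             source_id=st.name or path)


def write_ensemble_pdb(ensemble: StructureEnsemble, path) -> None:
    with open(path, "w") as fh:
        for m in range(ensemble.n_models):
            fh.write(f"MODEL     {m + 1:4d}\n")
            for i, (ch, rn, resname, an) in enumerate(ensemble.atoms):
                x, y, z = ensemble.coords[m, i]
                name = an if len(an) == 4 else f" {an:<3s}"
                elem = an.strip()[0]
                fh.write(
                    f"ATOM  {i + 1:5d} {name}{'':1s}{resname:>3s} {ch:1s}"
                    f"{rn:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {elem:>2s}\n")
            fh.write("ENDMDL\n")
        fh.write("END\n")


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Proper rotation R and translation t minimising |R·mobile + t − target|.

    Returns (R, t) with det(R) = +1. Raises on degenerate (collinear) point
    sets where the rotation is not unique.
    """
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) selection: superposition not unique")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    r = vt.T @ diag @ u.T
    t = tc - r @ mc
    return r, t


def superpose(ensemble: StructureEnsemble, selection: ResidueSelection,
              reference: int | str = "mean",
              iterations: int = 2) -> StructureEnsemble:
    """Rigidly superpose every model onto a reference over the selection.

    ``reference`` is a model index, or ``"mean"`` for iterative superposition
    onto the mean structure (mean recomputed ``iterations`` times).
    """
    idx = ensemble.selection_index(selection)
    coords = ensemble.coords.copy()

    def apply_all(target_sel: np.ndarray) -> None:
        for m in range(coords.shape[0]):
            r, t = kabsch(coords[m, idx], target_sel)
            coords[m] = coords[m] @ r.T + t

    if reference == "mean":
        apply_all(coords[0, idx])
        for _ in range(iterations):
            apply_all(coords[:, idx].mean(axis=0))
    else:
        apply_all(ensemble.coords[int(reference), idx])
    return StructureEnsemble(atoms=ensemble.atoms, coords=coords,
                             source_id=ensemble.source_id)


def ensemble_rmsd(ensemble: StructureEnsemble, selection: ResidueSelection,
                  superposed: bool = False) -> dict:
    """Ensemble spread over a selection, under both conventions.

    ``to_mean``: RMS deviation of the models' selected atoms from the mean
    structure, with the sample (n−1) normalisation over models so the
    statistic is an unbiased spread estimate. ``pairwise``: average over
    all model pairs of the pairwise RMSD. For two models
    pairwise = sqrt(2)·to_mean exactly. Models are superposed over the same
    selection first unless ``superposed`` is set.
    """
    work = ensemble if superposed else superpose(ensemble, selection)
    sel = work.subset_coords(selection)
    n_models = sel.shape[0]
    mean = sel.mean(axis=0)
    per_model = np.sqrt(((sel - mean) ** 2).sum(axis=2).mean(axis=1))
    if n_models == 1:
        to_mean = 0.0
    else:
        to_mean = float(np.sqrt((per_model ** 2).mean() * n_models / (n_models - 1)))
    if n_models == 1:
        pairwise = 0.0
    else:
        acc = [
            math.sqrt(((sel[i] - sel[j]) ** 2).sum(axis=1).mean())
            for i in range(n_models) for j in range(i + 1, n_models)
        ]
        pairwise = float(np.mean(acc))
    return {
        "to_mean": to_mean,
        "pairwise": pairwise,
        "per_model": per_model.tolist(),
        "n_models": n_models,
        "n_atoms": sel.shape[1],
        "convention_default": "to_mean",
    }


@dataclass(frozen=True)
class HelixSegment:
    """A fitted helix: unit axis oriented N→C, centroid, and fit quality."""

    residue_range: tuple[int, int]
    axis: np.ndarray
    centroid: np.ndarray
    rmsd_to_axis: float

    def __post_init__(self) -> None:
        if not math.isclose(float(np.linalg.norm(self.axis)), 1.0, rel_tol=1e-9):
            raise ValueError("axis must be a unit vector")


def fit_helix_axis(ensemble: StructureEnsemble, model: int,
                   residue_range: tuple[int, int], chain: str = "A",
                   atoms: str = "CA") -> HelixSegment:
    """Principal-axis fit of a helix segment in one model.

    The axis is the largest-variance eigenvector of the selected atom
    coordinates, sign-oriented from the N-terminal half centroid toward the
    C-terminal half centroid (stable under atom-order reversal).
    """
    lo, hi = residue_range
    if hi - lo + 1 < 5:
        raise ValueError("helix range must span at least 5 residues")
    sel = ResidueSelection(chain=chain, ranges=((lo, hi),), atoms=atoms)
    idx = ensemble.selection_index(sel)
    pts = ensemble.coords[model, idx]
    resnums = np.array([ensemble.atoms[i][1] for i in idx])
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    axis = v[:, -1]
    mid = (lo + hi) / 2.0
    n_half = pts[resnums <= mid].mean(axis=0)
    c_half = pts[resnums > mid].mean(axis=0)
    if float(axis @ (c_half - n_half)) < 0:
        axis = -axis
    axis = axis / np.linalg.norm(axis)
    perp = centered - np.outer(centered @ axis, axis)
    rmsd_to_axis = float(np.sqrt((perp ** 2).sum(axis=1).mean()))
    return HelixSegment(residue_range=(lo, hi), axis=axis, centroid=centroid,
                        rmsd_to_axis=rmsd_to_axis)
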