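"""Ensemble I/O, Kabsch superposition, RMSD conventions, helix-axis fits."""

import math

import numpy as np
import pytest

from efcalc import synthetic
from efcalc.structure import (ResidueSelection, StructureEnsemble,
                              ensemble_rmsd, fit_helix_axis, kabsch,
                              read_ensemble, superpose, write_ensemble_pdb)
from efcalc.synthetic import _rodrigues, gen_ensemble_jitter


@pytest.fixture(scope="module")
def helix_pair():
    ens, hand, _ = synthetic.gen_helix_pair_ensemble(80.0, 30.0, models=1, seed=0)
    return ens, hand


def rigid(coords, rot, shift):
    return coords @ rot.T + shift


class TestReadWrite:
    def test_pdb_roundtrip_preserves_models_and_numbering(self, tmp_path, helix_pair):
        base, _ = helix_pair
        ens = gen_ensemble_jitter(base, models=20, coordinate_sd=0.3, seed=1)
        path = tmp_path / "ens.pdb"
        write_ensemble_pdb(ens, path)
        loaded = read_ensemble(path, fmt="pdb")
        assert loaded.n_models == 20
        assert len(loaded.atoms) == len(ens.atoms)
        assert [a[1] for a in loaded.atoms] == [a[1] for a in ens.atoms]
        np.testing.assert_allclose(loaded.coords, ens.coords, atol=2e-3)

    def test_single_model_file_gives_zero_rmsd(self, tmp_path, helix_pair):
        base, hand = helix_pair
        path = tmp_path / "one.pdb"
        write_ensemble_pdb(base, path)
        loaded = read_ensemble(path)
        sel = ResidueSelection(ranges=((1, hand.entering[1]),), atoms="backbone")
        stats = ensemble_rmsd(loaded, sel)
        assert stats["to_mean"] == 0.0
        assert stats["pairwise"] == 0.0

    def test_inconsistent_inventory_reported(self, tmp_path, helix_pair):
        base, _ = helix_pair
        ens = gen_ensemble_jitter(base, models=3, coordinate_sd=0.1, seed=2)
        path = tmp_path / "bad.pdb"
        write_ensemble_pdb(ens, path)
        lines = path.read_text().splitlines(keepends=True)
        # drop the first backbone O record of model 3
        model_starts = [i for i, l in enumerate(lines) if l.startswith("MODEL")]
        drop = next(i for i in range(model_starts[2], len(lines))
                    if lines[i][12:16].strip() == "O")
        path.write_text("".join(lines[:drop] + lines[drop + 1:]))
        with pytest.raises(ValueError, match="model 3"):
            read_ensemble(path)

    def test_missing_backbone_atom_in_selection_named(self, helix_pair):
        base, hand = helix_pair
        # loop residues carry CA only; a backbone selection over them must
        # fail naming the residue
        loop_res = hand.loop_anchor
        sel = ResidueSelection(ranges=((loop_res, loop_res),), atoms="backbone")
        with pytest.raises(ValueError, match=str(loop_res)):
            base.selection_index(sel)


class TestSuperpose:
    def test_pure_translation_removed(self, helix_pair):
        base, hand = helix_pair
        coords = np.stack([base.coords[0], base.coords[0] + [5.0, -3.0, 2.0]])
        ens = StructureEnsemble(atoms=list(base.atoms), coords=coords)
        sel = ResidueSelection(ranges=(), atoms="CA")
        out = superpose(ens, sel, reference=0)
        np.testing.assert_allclose(out.coords[1], out.coords[0], atol=1e-9)

    def test_known_rotation_recovered(self, helix_pair):
        base, _ = helix_pair
        rot = _rodrigues(np.array([1.0, 2.0, 2.0]) / 3.0, 0.7)
        moved = rigid(base.coords[0], rot, np.array([1.0, 0.0, -4.0]))
        r_rec, _ = kabsch(moved, base.coords[0])
        np.testing.assert_allclose(r_rec, rot.T, atol=1e-9)
        assert np.linalg.det(r_rec) == pytest.approx(1.0, abs=1e-12)

    def test_self_superposition_is_identity(self, helix_pair):
        base, _ = helix_pair
        r, t = kabsch(base.coords[0], base.coords[0])
        np.testing.assert_allclose(r, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(t, 0.0, atol=1e-9)

    def test_collinear_selection_rejected(self):
        pts = np.outer(np.arange(10.0), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="degenerate"):
            kabsch(pts, pts)


class TestEnsembleRMSD:
    def test_identical_models_zero_under_both_conventions(self, helix_pair):
        base, hand = helix_pair
        ens = gen_ensemble_jitter(base, models=5, coordinate_sd=0.0, seed=0)
        sel = ResidueSelection(ranges=((1, hand.entering[1]),), atoms="backbone")
        stats = ensemble_rmsd(ens, sel)
        assert stats["to_mean"] == pytest.approx(0.0, abs=1e-12)
        assert stats["pairwise"] == pytest.approx(0.0, abs=1e-12)

    def test_two_model_toy_matches_direct_arithmetic(self):
        """3-atom toy, one atom displaced by d in one model: the to-mean
        value follows from the (n-1)-normalised deviation formula."""
        d = 0.6
        a = np.array([[0.0, 0, 0], [3.0, 0, 0], [0, 3.0, 0]])
        b = a.copy()
        b[0, 2] += d
        ens = StructureEnsemble(
            atoms=[("A", i + 1, "GLY", "CA") for i in range(3)],
            coords=np.stack([a, b]))
        sel = ResidueSelection(ranges=(), atoms="CA")
        stats = ensemble_rmsd(ens, sel, superposed=True)  # no refitting
        # each model's one displaced atom deviates d/2 from the mean, so the
        # per-model msd is (d/2)^2/K; the n/(n-1) factor gives the spread
        expected = math.sqrt((d / 2) ** 2 / 3 * 2 / 1)
        assert stats["to_mean"] == pytest.approx(expected, abs=1e-12)
        assert stats["pairwise"] == pytest.approx(
            math.sqrt(2) * stats["to_mean"], abs=1e-12)

    def test_pairwise_is_sqrt2_times_to_mean_for_two_models(self, helix_pair):
        base, hand = helix_pair
        ens = gen_ensemble_jitter(base, models=2, coordinate_sd=0.4, seed=3)
        sel = ResidueSelection(ranges=((1, hand.entering[1]),), atoms="backbone")
        stats = ensemble_rmsd(ens, sel)
        assert stats["pairwise"] == pytest.approx(
            math.sqrt(2) * stats["to_mean"], rel=1e-9)

    def test_gaussian_jitter_matches_sigma_sqrt3(self, helix_pair):
        base, _ = helix_pair
        sigma = 0.5
        ens = gen_ensemble_jitter(base, models=20, coordinate_sd=sigma, seed=4)
        sel = ResidueSelection(ranges=(), atoms="all")  # 150 atoms
        stats = ensemble_rmsd(ens, sel)
        assert stats["to_mean"] == pytest.approx(sigma * math.sqrt(3), rel=0.10)

    def test_invariant_under_global_rigid_transform(self, helix_pair):
        base, hand = helix_pair
        ens = gen_ensemble_jitter(base, models=8, coordinate_sd=0.3, seed=5)
        rot = _rodrigues(np.array([0.0, 1.0, 0.0]), 1.1)
        moved = StructureEnsemble(
            atoms=list(ens.atoms),
            coords=np.stack([rigid(c, rot, np.array([10.0, -2.0, 7.0]))
                             for c in ens.coords]))
        sel = ResidueSelection(ranges=((1, hand.entering[1]),), atoms="backbone")
        a = ensemble_rmsd(ens, sel)
        b = ensemble_rmsd(moved, sel)
        assert b["to_mean"] == pytest.approx(a["to_mean"], abs=1e-9)
        assert b["pairwise"] == pytest.approx(a["pairwise"], abs=1e-9)

    def test_empty_selection_rejected(self, helix_pair):
        base, _ = helix_pair
        sel = ResidueSelection(chain="Z", ranges=(), atoms="CA")
        with pytest.raises(ValueError, match="no atoms"):
            ensemble_rmsd(base, sel)


class TestHelixAxis:
    def test_ideal_helix_axis_along_z(self, helix_pair):
        base, hand = helix_pair
        seg = fit_helix_axis(base, 0, hand.entering, atoms="CA")
        np.testing.assert_allclose(seg.axis, [0.0, 0.0, 1.0], atol=1e-6)

    def test_rotated_helix_axis_follows_rotation(self, helix_pair):
        base, hand = helix_pair
        rot = _rodrigues(np.array([1.0, 0.0, 0.0]), 0.9)
        moved = StructureEnsemble(atoms=list(base.atoms),
                                  coords=np.stack([base.coords[0] @ rot.T]))
        seg = fit_helix_axis(moved, 0, hand.entering, atoms="CA")
        np.testing.assert_allclose(seg.axis, rot @ [0.0, 0.0, 1.0], atol=1e-6)

    def test_atoms_on_a_line(self):
        n = 8
        atoms = [("A", i + 1, "GLY", "CA") for i in range(n)]
        direction = np.array([1.0, 1.0, 0.0]) / math.sqrt(2)
        coords = np.outer(np.arange(n, dtype=float), direction)[None]
        ens = StructureEnsemble(atoms=atoms, coords=coords)
        seg = fit_helix_axis(ens, 0, (1, n), atoms="CA")
        np.testing.assert_allclose(seg.axis, direction, atol=1e-12)
        assert seg.rmsd_to_axis == pytest.approx(0.0, abs=1e-12)

    def test_orientation_from_termini_not_eigen_sign(self, helix_pair):
        """Reversing atom storage order leaves the N->C orientation fixed."""
        base, hand = helix_pair
        fwd = fit_helix_axis(base, 0, hand.entering, atoms="CA")
        rev = StructureEnsemble(atoms=list(reversed(base.atoms)),
                                coords=base.coords[:, ::-1, :].copy())
        bwd = fit_helix_axis(rev, 0, hand.entering, atoms="CA")
        np.testing.assert_allclose(bwd.axis, fwd.axis, atol=1e-9)

    def test_too_short_range_rejected(self, helix_pair):
        base, _ = helix_pair
        with pytest.raises(ValueError, match="at least 5"):
            fit_helix_axis(base, 0, (1, 4))
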