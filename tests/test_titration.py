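"""CSP combination, binding-site mapping, 1:1 isotherm, and Kd fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from efcalc import synthetic, titration
from efcalc.titration import (CSPProfile, PeakAssignment, TitrationPoint,
                              TitrationSeries, compute_csp, fit_kd,
                              isotherm_1to1, map_binding_site, track_peaks)


def peaks(shifts):
    return [PeakAssignment(r, h, n) for r, h, n in shifts]


class TestComputeCSP:
    def test_identity_gives_zero(self):
        ref = peaks([(1, 8.0, 120.0), (2, 7.5, 110.0)])
        prof = compute_csp(ref, ref, nitrogen_weight=0.2)
        assert np.allclose(prof.table["d_HN"], 0.0)

    def test_single_component_and_weighted_combination(self):
        ref = peaks([(1, 8.0, 120.0), (2, 8.0, 120.0)])
        state = peaks([(1, 8.3, 120.0), (2, 8.06, 120.4)])
        prof = compute_csp(ref, state, nitrogen_weight=0.2)
        # pure-1H case: any weight leaves |d_H|
        assert prof.combined(1) == pytest.approx(0.3, abs=1e-12)
        # sqrt(0.06^2 + (0.2*0.4)^2) = 0.1
        assert prof.combined(2) == pytest.approx(0.1, abs=1e-12)

    def test_weight_reduces_to_components(self):
        ref = peaks([(1, 8.0, 120.0)])
        only_n = compute_csp(ref, peaks([(1, 8.0, 121.3)]), 0.15)
        assert only_n.combined(1) == pytest.approx(0.15 * 1.3, abs=1e-12)

    def test_missing_residue_is_nan_not_zero(self):
        ref = peaks([(1, 8.0, 120.0), (2, 7.0, 112.0)])
        state = [PeakAssignment(1, 8.1, 120.5),
                 PeakAssignment(2, math.nan, math.nan, present=False)]
        prof = compute_csp(ref, state, 0.2)
        assert math.isnan(prof.combined(2))
        assert prof.combined(1) > 0

    def test_no_common_residues_is_an_error(self):
        with pytest.raises(ValueError):
            compute_csp(peaks([(1, 8.0, 120.0)]), peaks([(9, 8.0, 120.0)]), 0.2)
        with pytest.raises(ValueError):
            compute_csp(peaks([(1, 8.0, 120.0)]), peaks([(1, 8.0, 120.0)]), 0.0)


class TestMapBindingSite:
    def test_threshold_selects_constructed_residues(self):
        import pandas as pd
        rng = np.random.default_rng(0)
        above = list(range(1, 7))
        below = list(range(7, 57))
        rows = [(r, 0.0, 0.0, rng.uniform(0.35, 1.2)) for r in above]
        rows += [(r, 0.0, 0.0, rng.uniform(0.0, 0.25)) for r in below]
        prof = CSPProfile(pd.DataFrame(
            rows, columns=["residue", "d_H", "d_N", "d_HN"]), 0.2)
        assert map_binding_site(prof, 0.3) == above
        # degenerate threshold returns every perturbed residue
        assert map_binding_site(prof, 0.0) == sorted(above + below)

    def test_all_zero_profile_is_empty(self):
        ref = peaks([(1, 8.0, 120.0)])
        prof = compute_csp(ref, ref, 0.2)
        assert map_binding_site(prof, 0.3) == []


class TestIsotherm:
    def test_free_state_and_closed_form(self):
        assert isotherm_1to1(1e-3, 0.0, 1e-4, 1.0) == 0.0
        # P0 = L0 = Kd = 1, dmax = 1 -> (3 - sqrt(5))/2
        assert isotherm_1to1(1.0, 1.0, 1.0, 1.0) == pytest.approx(
            (3.0 - math.sqrt(5.0)) / 2.0, abs=1e-12)

    def test_saturation_limit(self):
        kd = 1e-4
        assert isotherm_1to1(1e-6, 1e6 * kd, kd, 1.0) > 0.999

    def test_negative_concentrations_rejected(self):
        with pytest.raises(ValueError):
            isotherm_1to1(-1e-3, 1e-3, 1e-4, 1.0)
        with pytest.raises(ValueError):
            isotherm_1to1(1e-3, -1e-3, 1e-4, 1.0)
        with pytest.raises(ValueError):
            isotherm_1to1(1e-3, 1e-3, 0.0, 1.0)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.floats(1e-6, 1e-2), st.floats(1e-9, 1e-1), st.floats(1e-8, 1e-2))
    def test_mass_balance_oracle(self, p0, l0, kd):
        """The bound fraction implied by the quadratic root satisfies the
        equilibrium definition Kd = (P0-[PL])(L0-[PL])/[PL]."""
        bound = isotherm_1to1(p0, l0, kd, 1.0) * p0  # [PL]
        if bound / min(p0, max(l0, 1e-300)) < 1e-8:
            return  # numerically negligible complex: ratio test unstable
        kd_implied = (p0 - bound) * (l0 - bound) / bound
        assert kd_implied == pytest.approx(kd, rel=1e-9)

    def test_monotone_in_l0_and_kd(self):
        p0 = 0.312e-3
        l0 = np.linspace(0.0, 20 * p0, 200)
        vals = isotherm_1to1(p0, l0, 1.7e-4, 1.0)
        assert np.all(np.diff(vals) > 0)
        kds = np.logspace(-7, -2, 50)
        at_fixed_l0 = [isotherm_1to1(p0, 5 * p0, kd, 1.0) for kd in kds]
        assert np.all(np.diff(at_fixed_l0) < 0)


class TestFitKd:
    def test_noise_free_roundtrip_global_and_per_residue(self):
        series, truth = synthetic.gen_titration(noise_sd=0.0, seed=21)
        for mode in ("global", "per_residue"):
            fit = fit_kd(series, mode=mode)
            assert fit.converged
            assert fit.kd == pytest.approx(truth["kd"], rel=1e-6)
            for f in fit.per_residue:
                assert f.delta_max == pytest.approx(
                    truth["delta_max"][str(f.residue)], rel=1e-5)

    def test_zero_ligand_series_rejected(self):
        pt = TitrationPoint(0.0, 1e-3, peaks([(1, 8.0, 120.0)]))
        series = TitrationSeries(points=[pt, pt, pt, pt, pt])
        with pytest.raises(ValueError, match="no binding information"):
            fit_kd(series, residues=[1])

    def test_too_few_points_rejected(self):
        series, _ = synthetic.gen_titration(
            equivalents=(0.0, 1.0, 5.0), noise_sd=0.0, seed=2)
        with pytest.raises(ValueError, match="fewer than"):
            fit_kd(series)

    def test_global_fit_at_least_as_precise_as_per_residue_median(self):
        series, _ = synthetic.gen_titration(noise_sd=0.01, seed=31)
        g = fit_kd(series, mode="global")
        p = fit_kd(series, mode="per_residue")
        assert g.kd_stderr <= p.kd_stderr

    def test_dropout_points_are_excluded_not_imputed(self):
        series, truth = synthetic.gen_titration(
            noise_sd=0.0, dropout=(0.25, 1.0), dropout_count=2, seed=41)
        fit = fit_kd(series, mode="global")
        assert fit.kd == pytest.approx(truth["kd"], rel=1e-6)


class TestSeriesValidation:
    def test_first_point_must_be_ligand_free(self):
        pt = TitrationPoint(1e-3, 1e-3, peaks([(1, 8.0, 120.0)]))
        with pytest.raises(ValueError):
            TitrationSeries(points=[pt])

    def test_ligand_must_be_non_decreasing(self):
        p = peaks([(1, 8.0, 120.0)])
        pts = [TitrationPoint(0.0, 1e-3, p), TitrationPoint(2e-3, 1e-3, p),
               TitrationPoint(1e-3, 1e-3, p)]
        with pytest.raises(ValueError):
            TitrationSeries(points=pts)


class TestTrackPeaks:
    def test_preassigned_series_unchanged(self):
        series, _ = synthetic.gen_titration(seed=5)
        assert track_peaks(series, max_step=0.5) is series

    @staticmethod
    def _unassigned(trajectories, p0, equivalents):
        """Series whose non-reference points carry scrambled residue ids."""
        points = []
        for k, eq in enumerate(equivalents):
            pk = []
            for r, path in trajectories.items():
                h, n = path[k]
                rid = r if k == 0 else 900 + r  # unassigned label downstream
                if h is not None:
                    pk.append(PeakAssignment(rid, h, n))
            points.append(TitrationPoint(eq * p0, p0, pk))
        return TitrationSeries(points=points)

    def test_non_crossing_paths_linked_correctly(self):
        eqs = (0.0, 1.0, 2.0, 3.0)
        traj = {
            1: [(8.00 + 0.05 * k, 120.0 + 0.10 * k) for k in range(4)],
            2: [(7.00 - 0.04 * k, 112.0 - 0.08 * k) for k in range(4)],
        }
        series = self._unassigned(traj, 1e-3, eqs)
        linked = track_peaks(series, max_step=0.2)
        for k in range(4):
            p1 = linked.points[k].peak_for(1)
            assert p1.delta_H == pytest.approx(traj[1][k][0])
            p2 = linked.points[k].peak_for(2)
            assert p2.delta_N == pytest.approx(traj[2][k][1])

    def test_broadened_peak_relinks_on_reappearance(self):
        eqs = (0.0, 0.5, 1.0, 3.0)
        traj = {
            1: [(8.00, 120.0), (None, None), (None, None), (8.06, 120.10)],
            2: [(7.00, 112.0), (7.02, 112.02), (7.04, 112.04), (7.06, 112.06)],
        }
        series = self._unassigned(traj, 1e-3, eqs)
        linked = track_peaks(series, max_step=0.2)
        assert linked.points[1].peak_for(1) is None  # gap kept, marked absent
        assert linked.points[2].peak_for(1) is None
        reappeared = linked.points[3].peak_for(1)
        assert reappeared is not None
        assert reappeared.delta_H == pytest.approx(8.06)


class TestIO:
    def test_manifest_roundtrip(self, tmp_path):
        series, truth = synthetic.gen_titration(seed=17)
        manifest = synthetic.write_titration(series, truth, tmp_path)
        loaded = titration.read_series_manifest(manifest)
        assert len(loaded.points) == len(series.points)
        assert loaded.points[3].ligand_total == pytest.approx(
            series.points[3].ligand_total, rel=1e-8)
        fit = fit_kd(loaded, mode="global")
        assert fit.kd == pytest.approx(truth["kd"], rel=0.2)
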