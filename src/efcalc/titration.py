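"""NMR chemical-shift-perturbation titration analysis and 1:1 Kd fitting.

A ligand titration followed by 2D amide spectra yields, per residue, a
trajectory of (δH, δN) chemical shifts versus total ligand concentration.
Under fast exchange the observed perturbation is the population-weighted
average of the free and bound shifts, so the combined perturbation

    Δδ(H,N) = sqrt(Δδ_H² + (w · Δδ_N)²)

traces the bound fraction, and the exact 1:1 binding isotherm

    Δδ_obs = Δδ_max · ( (P0 + L0 + Kd) − sqrt((P0 + L0 + Kd)² − 4 P0 L0) )
             / (2 P0)

(the physical root of the quadratic mass balance) links it to the
dissociation constant Kd. The nitrogen weight ``w`` compensates for the
larger 15N shift range; 0.2 is the conventional amide scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

DEFAULT_NITROGEN_WEIGHT = 0.2

KD_BOUNDS = (1e-9, 1.0)  # molar
DELTA_MAX_BOUNDS = (1e-6, 10.0)  # ppm


@dataclass(frozen=True)
class PeakAssignment:
    residue_number: int
    delta_H: float  # ppm
    delta_N: float  # ppm
    present: bool = True

    def __post_init__(self) -> None:
        if self.present and not (math.isfinite(self.delta_H) and math.isfinite(self.delta_N)):
            raise ValueError(f"non-finite shift for residue {self.residue_number}")


@dataclass(frozen=True)
class TitrationPoint:
    ligand_total: float  # molar
    protein_total: float  # molar
    peaks: list[PeakAssignment]

    def __post_init__(self) -> None:
        if self.ligand_total < 0 or self.protein_total < 0:
            raise ValueError("concentrations must be non-negative")

    @property
    def equivalents(self) -> float:
        return self.ligand_total / self.protein_total if self.protein_total else math.inf

    def peak_for(self, residue_number: int) -> PeakAssignment | None:
        for p in self.peaks:
            if p.residue_number == residue_number and p.present:
                return p
        return None


@dataclass(frozen=True)
class TitrationSeries:
    """Ordered titration points; the first point is the ligand-free reference."""

    points: list[TitrationPoint]
    dilution_model: str = "none"

    def __post_init__(self) -> None:
        if not self.points:
            raise ValueError("empty titration series")
        if self.points[0].ligand_total != 0:
            raise ValueError("first titration point must be ligand-free")
        ltot = [p.ligand_total for p in self.points]
        if any(b < a for a, b in zip(ltot, ltot[1:])):
            raise ValueError("ligand_total must be non-decreasing")

    @property
    def reference(self) -> TitrationPoint:
        return self.points[0]

    def residues(self) -> list[int]:
        common = None
        for pt in self.points:
            ids = {p.residue_number for p in pt.peaks}
            common = ids if common is None else common | ids
        return sorted(common or [])


@dataclass
class CSPProfile:
    """Per-residue Δδ components and combined Δδ(H,N), one row per residue."""

    table: pd.DataFrame  # columns: residue, d_H, d_N, d_HN; NaN = missing peak
    nitrogen_weight: float

    def combined(self, residue: int) -> float:
        row = self.table.loc[self.table["residue"] == residue, "d_HN"]
        return float(row.iloc[0]) if len(row) else math.nan


@dataclass
class ResidueFit:
    residue: int
    kd: float
    kd_stderr: float
    delta_max: float
    delta_max_stderr: float
    converged: bool


@dataclass
class BindingFitResult:
    """Kd fit over selected residues; per-residue or shared (global) Kd."""

    mode: str
    kd: float  # molar (global mode: shared; per-residue: median)
    kd_stderr: float
    per_residue: list[ResidueFit]
    residuals: np.ndarray
    converged: bool

    @property
    def delta_max(self) -> dict[int, float]:
        return {f.residue: f.delta_max for f in self.per_residue}


def combine_shifts(d_h: float, d_n: float, nitrogen_weight: float) -> float:
    return math.sqrt(d_h * d_h + (nitrogen_weight * d_n) ** 2)


def compute_csp(reference: list[PeakAssignment], state: list[PeakAssignment],
                nitrogen_weight: float = DEFAULT_NITROGEN_WEIGHT) -> CSPProfile:
    """Combined amide CSP between a reference and a perturbed state.

    Residues missing (absent or broadened beyond detection) in either state
    are reported with NaN, never as zero.
    """
    if nitrogen_weight <= 0:
        raise ValueError("nitrogen_weight must be positive")
    ref = {p.residue_number: p for p in reference if p.present}
    st = {p.residue_number: p for p in state if p.present}
    residues = sorted(set(ref) | set(st))
    if not set(ref) & set(st):
        raise ValueError("no common residues between reference and state")
    rows = []
    for r in residues:
        if r in ref and r in st:
            d_h = st[r].delta_H - ref[r].delta_H
            d_n = st[r].delta_N - ref[r].delta_N
            rows.append((r, d_h, d_n, combine_shifts(d_h, d_n, nitrogen_weight)))
        else:
            rows.append((r, math.nan, math.nan, math.nan))
    table = pd.DataFrame(rows, columns=["residue", "d_H", "d_N", "d_HN"])
    return CSPProfile(table=table, nitrogen_weight=nitrogen_weight)


def map_binding_site(profile: CSPProfile, threshold: float = 0.3) -> list[int]:
    """Residues whose combined CSP exceeds ``threshold`` ppm, sorted."""
    t = profile.table
    hit = t.loc[t["d_HN"] > threshold, "residue"]
    return sorted(int(r) for r in hit)


def isotherm_1to1(P0, L0, Kd, delta_max):
    """Observed shift change for 1:1 binding (exact quadratic mass balance).

    Vectorised over ``L0``. Monotone increasing in L0, decreasing in Kd;
    approaches ``delta_max`` as L0 → ∞.
    """
    P0 = np.asarray(P0, dtype=float)
    L0 = np.asarray(L0, dtype=float)
    if np.any(P0 <= 0) or np.any(L0 < 0):
        raise ValueError("require P0 > 0 and L0 >= 0")
    if np.any(np.asarray(Kd) <= 0):
        raise ValueError("Kd must be positive")
    s = P0 + L0 + Kd
    disc = s * s - 4.0 * P0 * L0
    # conjugate form of the quadratic root: stable when [PL] << P0 + L0 + Kd
    bound = 2.0 * L0 / (s + np.sqrt(np.maximum(disc, 0.0)))
    out = delta_max * bound
    return float(out) if out.ndim == 0 else out


def _series_arrays(series: TitrationSeries, profiles: list[CSPProfile],
                   residues: list[int]):
    """Per-residue (L0, P0, Δδ) arrays over points with an observed peak."""
    data = {}
    for r in residues:
        l0, p0, dd = [], [], []
        for pt, prof in zip(series.points, profiles):
            v = prof.combined(r)
            if math.isfinite(v):
                l0.append(pt.ligand_total)
                p0.append(pt.protein_total)
                dd.append(v)
        data[r] = (np.array(l0), np.array(p0), np.array(dd))
    return data


def series_csp(series: TitrationSeries,
               nitrogen_weight: float = DEFAULT_NITROGEN_WEIGHT) -> list[CSPProfile]:
    """CSP profile of every titration point relative to the first (free) point."""
    ref = series.reference.peaks
    return [compute_csp(ref, pt.peaks, nitrogen_weight) for pt in series.points]


def _kd_starts() -> np.ndarray:
    # three log-spaced Kd initialisations to escape local minima
    return np.array([1e-6, 1e-4, 1e-2])


def fit_kd(series: TitrationSeries, profiles: list[CSPProfile] | None = None,
           residues: list[int] | None = None, mode: str = "global",
           nitrogen_weight: float = DEFAULT_NITROGEN_WEIGHT,
           min_points: int = 4) -> BindingFitResult:
    """Fit the 1:1 isotherm to per-residue CSP trajectories.

    ``global`` mode shares one Kd across residues with residue-specific
    Δδ_max; ``per_residue`` fits each residue independently (the headline
    Kd is then the median). Missing peaks are excluded from the residual.
    """
    if mode not in ("global", "per_residue"):
        raise ValueError(f"unknown fit mode {mode!r}")
    if profiles is None:
        profiles = series_csp(series, nitrogen_weight)
    if residues is None:
        residues = map_binding_site(profiles[-1])
    if not residues:
        raise ValueError("no residues selected for fitting")
    if all(pt.ligand_total == 0 for pt in series.points):
        raise ValueError("series has zero ligand at all points: no binding information")

    data = _series_arrays(series, profiles, residues)
    for r, (l0, _, _) in data.items():
        if len(l0) < min_points:
            raise ValueError(f"residue {r}: fewer than {min_points} observed points")

    if mode == "per_residue":
        fits = [_fit_single(r, *data[r]) for r in residues]
        kds = np.array([f.kd for f in fits if f.converged])
        if not len(kds):
            return BindingFitResult(mode, math.nan, math.nan, fits,
                                    np.array([]), converged=False)
        med = float(np.median(kds))
        resid = np.concatenate([
            data[f.residue][2] - isotherm_1to1(data[f.residue][1], data[f.residue][0],
                                               f.kd, f.delta_max)
            for f in fits if f.converged
        ])
        stderr = float(np.median([f.kd_stderr for f in fits if f.converged]))
        return BindingFitResult(mode, med, stderr, fits, resid,
                                converged=all(f.converged for f in fits))
    return _fit_global(residues, data)


def _fit_single(residue: int, l0, p0, dd) -> ResidueFit:
    n_par = 2
    if len(l0) <= n_par:
        raise ValueError(f"residue {residue}: fewer points than parameters")

    def resid(theta):
        log_kd, dmax = theta
        return dd - isotherm_1to1(p0, l0, 10.0 ** log_kd, dmax)

    best = None
    for kd0 in _kd_starts():
        sol = least_squares(
            resid, x0=[math.log10(kd0), float(np.clip(dd.max(), 1e-3, 10.0))],
            bounds=([math.log10(KD_BOUNDS[0]), DELTA_MAX_BOUNDS[0]],
                    [math.log10(KD_BOUNDS[1]), DELTA_MAX_BOUNDS[1]]),
            method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15)
        if best is None or sol.cost < best.cost:
            best = sol
    kd = 10.0 ** best.x[0]
    kd_err, dmax_err = _stderr(best, scale=np.array([kd * math.log(10.0), 1.0]))
    return ResidueFit(residue, kd, kd_err, best.x[1], dmax_err,
                      converged=bool(best.success))


def _fit_global(residues, data) -> BindingFitResult:
    n_res = len(residues)

    def resid(theta):
        log_kd = theta[0]
        out = []
        for i, r in enumerate(residues):
            l0, p0, dd = data[r]
            out.append(dd - isotherm_1to1(p0, l0, 10.0 ** log_kd, theta[1 + i]))
        return np.concatenate(out)

    dmax0 = [float(np.clip(data[r][2].max(), 1e-3, 10.0)) for r in residues]
    lb = [math.log10(KD_BOUNDS[0])] + [DELTA_MAX_BOUNDS[0]] * n_res
    ub = [math.log10(KD_BOUNDS[1])] + [DELTA_MAX_BOUNDS[1]] * n_res
    best = None
    for kd0 in _kd_starts():
        sol = least_squares(resid, x0=[math.log10(kd0)] + dmax0,
                            bounds=(lb, ub), method="trf",
                            xtol=1e-15, ftol=1e-15, gtol=1e-15)
        if best is None or sol.cost < best.cost:
            best = sol
    kd = 10.0 ** best.x[0]
    scale = np.ones(1 + n_res)
    scale[0] = kd * math.log(10.0)
    errs = _stderr(best, scale)
    fits = [
        ResidueFit(r, kd, errs[0], best.x[1 + i], errs[1 + i],
                   converged=bool(best.success))
        for i, r in enumerate(residues)
    ]
    return BindingFitResult("global", kd, errs[0], fits, best.fun,
                            converged=bool(best.success))


def _stderr(sol, scale) -> np.ndarray:
    """Standard errors from the Jacobian at the solution (delta method for
    parameters fitted on a transformed scale)."""
    m, n = sol.jac.shape
    dof = max(m - n, 1)
    s2 = 2.0 * sol.cost / dof
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * s2
        return np.sqrt(np.maximum(np.diag(cov), 0.0)) * scale
    except np.linalg.LinAlgError:
        return np.full(n, np.nan)


def track_peaks(series: TitrationSeries, max_step: float,
                nitrogen_weight: float = DEFAULT_NITROGEN_WEIGHT) -> TitrationSeries:
    """Resolve residue correspondence across points by greedy nearest-neighbour
    linking in weighted (δH, w·δN) shift space.

    A series whose peaks already carry consistent residue numbers is
    returned unchanged. A peak with no candidate within ``max_step`` of the
    last known position keeps its gap (marked absent at that point); it may
    re-link later when it reappears within range.
    """
    if max_step <= 0:
        raise ValueError("max_step must be positive")
    ref_ids = {p.residue_number for p in series.reference.peaks}
    if all({p.residue_number for p in pt.peaks} <= ref_ids for pt in series.points):
        return series

    def coords(p: PeakAssignment):
        return np.array([p.delta_H, nitrogen_weight * p.delta_N])

    last_pos = {p.residue_number: coords(p) for p in series.reference.peaks}
    new_points = [series.reference]
    for pt in series.points[1:]:
        unmatched = [p for p in pt.peaks if p.present]
        links: dict[int, PeakAssignment] = {}
        # greedy: repeatedly take the globally closest (residue, peak) pair
        pairs = sorted(
            ((float(np.linalg.norm(coords(p) - pos)), r, p)
             for r, pos in last_pos.items() for p in unmatched),
            key=lambda t: t[0])
        used_peaks: set[int] = set()
        for dist, r, p in pairs:
            if dist > max_step or r in links or id(p) in used_peaks:
                continue
            links[r] = p
            used_peaks.add(id(p))
        new_peaks = []
        for r in last_pos:
            if r in links:
                p = links[r]
                new_peaks.append(PeakAssignment(r, p.delta_H, p.delta_N, True))
                last_pos[r] = coords(p)
            else:
                new_peaks.append(PeakAssignment(r, math.nan, math.nan, present=False))
        new_points.append(TitrationPoint(pt.ligand_total, pt.protein_total, new_peaks))
    return TitrationSeries(points=new_points, dilution_model=series.dilution_model)


def read_peak_list(path) -> list[PeakAssignment]:
    """CSV/TSV peak list with columns residue, dH_ppm, dN_ppm."""
    df = pd.read_csv(path, sep=None, engine="python")
    return [
        PeakAssignment(int(r.residue), float(r.dH_ppm), float(r.dN_ppm))
        for r in df.itertuples()
    ]


def read_series_manifest(path) -> TitrationSeries:
    """Series manifest CSV: columns file, protein_total_M, and either
    ligand_total_M or equivalents. Paths are relative to the manifest."""
    import pathlib

    base = pathlib.Path(path).parent
    df = pd.read_csv(path)
    points = []
    for r in df.itertuples():
        p0 = float(r.protein_total_M)
        l0 = float(r.ligand_total_M) if hasattr(r, "ligand_total_M") \
            else float(r.equivalents) * p0
        points.append(TitrationPoint(l0, p0, read_peak_list(base / r.file)))
    return TitrationSeries(points=points)
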