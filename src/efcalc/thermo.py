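"""Single-site ITC thermodynamics: simulation, fitting, and linkage.

An isothermal titration calorimetry experiment injects ligand into a cell
of protein and measures the heat of each injection. For a single class of
n independent sites the bound concentration follows the same quadratic 1:1
mass balance as the NMR isotherm (with n·[P] as the site concentration),
and each injection's heat is ΔH times the newly formed complex in the cell
plus a constant per-injection dilution offset. Thermodynamic linkage then
gives ΔG = R·T·ln(Kd) (association free energy, negative = favourable,
standard state 1 M) and TΔS = ΔH − ΔG.

Dilution uses the perfusion convention of overfilled-cell instruments: the
cell volume is constant, and each injection displaces liquid of
pre-injection composition out of the sensed volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

R_KCAL = 1.9872e-3  # kcal / (mol K)
T_STANDARD = 298.15  # K ("at 25 °C")


@dataclass
class ITCExperiment:
    """Cell/syringe design plus per-injection volumes and measured heats."""

    cell_concentration: float  # protein in cell, molar
    syringe_concentration: float  # ligand in syringe, molar
    cell_volume: float  # litres
    injection_volumes: np.ndarray  # litres, per injection
    heats: np.ndarray | None = None  # μcal, per injection
    temperature: float = T_STANDARD  # K

    def __post_init__(self) -> None:
        self.injection_volumes = np.asarray(self.injection_volumes, dtype=float)
        if self.heats is not None:
            self.heats = np.asarray(self.heats, dtype=float)
            if self.heats.shape != self.injection_volumes.shape:
                raise ValueError("heats and injection volumes differ in length")
        if self.cell_concentration <= 0 or self.syringe_concentration <= 0:
            raise ValueError("concentrations must be positive")
        if self.cell_volume <= 0 or np.any(self.injection_volumes <= 0):
            raise ValueError("volumes must be positive")

    @property
    def n_injections(self) -> int:
        return len(self.injection_volumes)

    def molar_ratios(self) -> np.ndarray:
        """Cumulative ligand/protein molar ratio in the cell after each injection."""
        p, l = self.totals_after_injections()
        return l / p

    def totals_after_injections(self) -> tuple[np.ndarray, np.ndarray]:
        """Total cell concentrations (protein, ligand) after each injection
        under the perfusion dilution model."""
        p = self.cell_concentration
        l = 0.0
        ps, ls = [], []
        for v in self.injection_volumes:
            f = v / self.cell_volume
            p *= (1.0 - f)
            l = l * (1.0 - f) + self.syringe_concentration * f
            ps.append(p)
            ls.append(l)
        return np.array(ps), np.array(ls)


@dataclass
class ThermoParams:
    """Single-site thermodynamic parameters; ΔG and TΔS derived from Kd, ΔH."""

    n: float  # stoichiometry
    kd: float  # molar
    dh: float  # kcal/mol
    temperature: float = T_STANDARD  # K
    offset: float = 0.0  # μcal per injection (dilution heat)
    dg: float = field(init=False)
    tds: float = field(init=False)
    stderr: dict = field(default_factory=dict)
    converged: bool = True
    c_value: float | None = None

    def __post_init__(self) -> None:
        self.dg = delta_g(self.kd, self.temperature)
        self.tds = t_delta_s(self.dh, self.dg)
        assert abs(self.dg - (self.dh - self.tds)) < 1e-9


def delta_g(kd: float, temperature: float = T_STANDARD) -> float:
    """Association free energy R·T·ln(Kd) in kcal/mol (Kd molar, 1 M standard
    state); negative for sub-molar Kd, i.e. favourable binding."""
    if kd <= 0 or temperature <= 0:
        raise ValueError("Kd and temperature must be positive")
    return R_KCAL * temperature * math.log(kd)


def t_delta_s(dh: float, dg: float) -> float:
    """Entropic term TΔS = ΔH − ΔG (kcal/mol)."""
    return dh - dg


def bound_concentration(p_sites: float, l_total: float, kd: float) -> float:
    """Physical root of [PL]·Kd = (sites − [PL])(L − [PL])."""
    s = p_sites + l_total + kd
    disc = s * s - 4.0 * p_sites * l_total
    # conjugate root form: numerically stable for small bound fractions
    denom = s + math.sqrt(max(disc, 0.0))
    return 2.0 * p_sites * l_total / denom if denom > 0 else 0.0


def simulate_itc(params: ThermoParams, design: ITCExperiment) -> ITCExperiment:
    """Simulated injection heats for a single-site experiment.

    Per injection: displaced volume leaves at pre-injection composition,
    totals update, the cell re-equilibrates, and the measured heat is
    ΔH·V0·([PL]_after − [PL]_carryover) + offset, in μcal for ΔH in
    kcal/mol. Saturation past the syringe's capacity to move the bound
    fraction simply yields offset-sized heats.
    """
    v0 = design.cell_volume
    p_tot, l_tot = design.totals_after_injections()
    heats = np.empty(design.n_injections)
    pl_prev = 0.0
    for i, v in enumerate(design.injection_volumes):
        f = v / v0
        pl_carry = pl_prev * (1.0 - f)  # complex surviving displacement
        pl_new = bound_concentration(params.n * p_tot[i], l_tot[i], params.kd)
        heats[i] = params.dh * v0 * (pl_new - pl_carry) * 1e9 + params.offset
        pl_prev = pl_new
    return ITCExperiment(
        cell_concentration=design.cell_concentration,
        syringe_concentration=design.syringe_concentration,
        cell_volume=v0,
        injection_volumes=design.injection_volumes,
        heats=heats,
        temperature=design.temperature,
    )


def fit_itc(exp: ITCExperiment, fix_n: float | None = None,
            min_injections: int = 8) -> ThermoParams:
    """Least-squares fit of the single-site model to measured heats.

    Free parameters (n, Kd, ΔH, offset), with n optionally fixed; Kd is
    fitted on a log scale with multi-start initialisation. A c-value
    (n·P0/Kd) outside [0.01, 1000] is flagged as a weak-information regime,
    and a heat profile indistinguishable from the offset leaves Kd
    unidentifiable (converged=False).
    """
    if exp.heats is None:
        raise ValueError("experiment carries no measured heats")
    if exp.n_injections < min_injections:
        raise ValueError(f"need at least {min_injections} injections")

    heats = exp.heats
    scale = float(np.max(np.abs(heats)))
    design = ITCExperiment(exp.cell_concentration, exp.syringe_concentration,
                           exp.cell_volume, exp.injection_volumes,
                           temperature=exp.temperature)

    def model(n, kd, dh, offset):
        return simulate_itc(
            ThermoParams(n=n, kd=kd, dh=dh, temperature=exp.temperature,
                         offset=offset),
            design).heats

    if scale <= 0:
        flat = ThermoParams(n=fix_n or 1.0, kd=1.0, dh=0.0,
                            temperature=exp.temperature, converged=False)
        flat.stderr = {"note": "all-zero heats: Kd unidentifiable"}
        return flat

    dh0 = float(np.sum(heats - np.median(heats[-3:]))) \
        / (exp.cell_concentration * exp.cell_volume * 1e9)
    dh0 = dh0 if abs(dh0) > 1e-6 else math.copysign(1e-3, np.sum(heats) or 1.0)

    if fix_n is None:
        def resid(theta):
            n, log_kd, dh, off = theta
            return (heats - model(n, 10.0 ** log_kd, dh, off)) / scale
        x0_tail = [0.9]
        lb, ub = [0.05], [10.0]
    else:
        def resid(theta):
            log_kd, dh, off = theta
            return (heats - model(fix_n, 10.0 ** log_kd, dh, off)) / scale
        x0_tail, lb, ub = [], [], []

    best = None
    for kd0 in (1e-6, 1e-4, 1e-2):
        x0 = x0_tail + [math.log10(kd0), dh0, float(np.median(heats[-3:]))]
        sol = least_squares(
            resid, x0=x0,
            bounds=(lb + [-9.0, -1e3, -1e6], ub + [0.0, 1e3, 1e6]),
            method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15)
        if best is None or sol.cost < best.cost:
            best = sol

    if fix_n is None:
        n, log_kd, dh, off = best.x
    else:
        n = fix_n
        log_kd, dh, off = best.x
    kd = 10.0 ** log_kd

    m, npar = best.jac.shape
    dof = max(m - npar, 1)
    s2 = 2.0 * best.cost / dof * scale ** 2
    try:
        cov = np.linalg.inv(best.jac.T @ best.jac) * s2 / scale ** 2
        errs = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        errs = np.full(npar, np.nan)
    names = (["n"] if fix_n is None else []) + ["log10_kd", "dh", "offset"]
    stderr = dict(zip(names, errs.tolist()))
    stderr["kd"] = stderr.pop("log10_kd") * kd * math.log(10.0)

    c_value = n * exp.cell_concentration / kd
    params = ThermoParams(n=float(n), kd=float(kd), dh=float(dh),
                          temperature=exp.temperature, offset=float(off),
                          converged=bool(best.success), c_value=float(c_value))
    params.stderr = stderr
    if not (0.01 <= c_value <= 1000.0):
        params.stderr["warning"] = (
            f"c-value {c_value:.3g} outside [0.01, 1000]: "
            "weak-information regime")
    return params


def read_injection_table(path) -> tuple[np.ndarray, np.ndarray]:
    """CSV with columns volume_uL, heat_ucal -> (volumes in L, heats in μcal)."""
    df = pd.read_csv(path)
    return df["volume_uL"].to_numpy() * 1e-6, df["heat_ucal"].to_numpy()
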