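#!/usr/bin/env python
"""Single-site ITC fitting and thermodynamic linkage.

Simulates a wild-type-like endothermic titration (n = 0.75, Kd = 104.2 uM,
dH = +2.10 kcal/mol, 2% heat noise, 25 x 2 uL injections of 10 mM Ca2+
into 0.40 mM protein in a 200 uL cell), fits the single-site model with
free stoichiometry, and derives dG = RT ln Kd and TdS = dH - dG. The same
linkage is applied to the measured (Kd, dH) of both well-binding
constructs.

Finding: the fit recovers the generating parameters within the noise, the
c-value sits in the informative range, and the linkage reproduces the
printed calorimetric dG/TdS to within rounding of the reported Kd.
"""

import argparse
import json
import pathlib

from efcalc import synthetic, thermo

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out", type=pathlib.Path,
                    default=pathlib.Path(__file__).parent.parent / "results")
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

truth = thermo.ThermoParams(n=0.75, kd=104.2e-6, dh=2.10, offset=0.1)
exp, truth_rec = synthetic.gen_itc(truth, noise_fraction=0.02, seed=args.seed)
synthetic.write_itc(exp, truth_rec, args.out / "itc_fixture")
fit = thermo.fit_itc(exp)

linkage = {}
for tag, kd_uM, dh in (("wt", 104.2, 2.10), ("d800a", 82.2, 2.05)):
    dg = thermo.delta_g(kd_uM * 1e-6)
    linkage[tag] = {"kd_uM": kd_uM, "dh_kcal_mol": dh,
                    "dg_kcal_mol": round(dg, 2),
                    "tds_kcal_mol": round(thermo.t_delta_s(dh, dg), 2)}

payload = {
    "simulated_truth": truth_rec,
    "fit": {"n": fit.n, "kd_uM": fit.kd * 1e6, "dh_kcal_mol": fit.dh,
            "dg_kcal_mol": fit.dg, "tds_kcal_mol": fit.tds,
            "offset_ucal": fit.offset, "c_value": fit.c_value,
            "converged": fit.converged, "stderr": fit.stderr},
    "linkage_from_measured_parameters": linkage,
}
(args.out / "itc_thermodynamics.json").write_text(
    json.dumps(payload, indent=2, sort_keys=True) + "\n")

print(f"fit: n = {fit.n:.2f}, Kd = {fit.kd * 1e6:.1f} uM, "
      f"dH = {fit.dh:.2f} kcal/mol (c = {fit.c_value:.1f})")
print(f"     dG = {fit.dg:.2f}, TdS = {fit.tds:.2f} kcal/mol")
for tag, row in linkage.items():
    print(f"linkage {tag:6s}: Kd {row['kd_uM']:6.1f} uM, dH {row['dh_kcal_mol']:+.2f} "
          f"-> dG {row['dg_kcal_mol']:+.2f}, TdS {row['tds_kcal_mol']:+.2f} kcal/mol")
print(f"wrote {args.out / 'itc_thermodynamics.json'}")
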