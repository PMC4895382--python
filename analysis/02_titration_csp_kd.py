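#!/usr/bin/env python
"""Chemical-shift-perturbation titration analysis and Kd estimation.

Generates the study-condition titration (15 points, 0-20 equivalents of
Ca2+ at 0.312 mM protein, 0.005 ppm shift noise, exchange broadening of
two loop residues between 0.25 and 1.0 eq), computes combined CSPs with
nitrogen weight 0.2, maps the binding site at the 0.3 ppm threshold, and
fits the exact 1:1 isotherm globally and per residue.

Finding: the mapped site equals the generator's binder set and the global
fit recovers the generating Kd (170 uM regime) to within the shift-noise
limit; the global Kd standard error is below the per-residue median.
"""

import argparse
import json
import pathlib

from efcalc import synthetic, titration

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--kd-uM", type=float, default=170.0)
parser.add_argument("--out", type=pathlib.Path,
                    default=pathlib.Path(__file__).parent.parent / "results")
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

series, truth = synthetic.gen_titration(
    kd=args.kd_uM * 1e-6, seed=args.seed,
    dropout=synthetic.DEFAULT_DROPOUT_WINDOW)
profiles = titration.series_csp(series)
site = titration.map_binding_site(profiles[-1], threshold=0.3)

fits = {mode: titration.fit_kd(series, profiles, residues=site, mode=mode)
        for mode in ("global", "per_residue")}

profiles[-1].table.to_csv(args.out / "csp_endpoint.tsv", sep="\t", index=False)
payload = {
    "conditions": {"p0_mM": truth["p0"] * 1e3, "points": len(series.points),
                   "max_equivalents": series.points[-1].equivalents,
                   "noise_sd_ppm": truth["noise_sd"],
                   "nitrogen_weight": truth["nitrogen_weight"],
                   "dropout_window_eq": truth["dropout_window_eq"]},
    "true_kd_uM": truth["kd"] * 1e6,
    "binding_site_residues": site,
    "true_binders": truth["binders"],
    "fits": {mode: {"kd_uM": f.kd * 1e6, "kd_stderr_uM": f.kd_stderr * 1e6,
                    "converged": f.converged}
             for mode, f in fits.items()},
}
(args.out / "kd_fit.json").write_text(
    json.dumps(payload, indent=2, sort_keys=True) + "\n")

g = fits["global"]
print(f"binding site at 0.3 ppm: residues {site} "
      f"(true binders {truth['binders']})")
print(f"global fit:      Kd = {g.kd * 1e6:7.1f} +/- {g.kd_stderr * 1e6:.1f} uM")
p = fits["per_residue"]
print(f"per-residue med: Kd = {p.kd * 1e6:7.1f} +/- {p.kd_stderr * 1e6:.1f} uM")
print(f"generating Kd  = {truth['kd'] * 1e6:7.1f} uM")
print(f"wrote {args.out / 'kd_fit.json'}")
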