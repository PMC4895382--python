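#!/usr/bin/env python
"""Ensemble geometry: interhelical angles and backbone RMSD.

Builds 20-model apo-like and holo-like helix-pair ensembles posed at known
(theta, phi) with 2 deg angular jitter, measures per-model angles in the
loop-anchored frame, and reports the holo - apo angle changes. Also
quantifies ensemble precision as backbone RMSD (to-mean and pairwise) on a
Gaussian-jittered ensemble with known coordinate spread.

Finding: ensemble means recover the constructed angles to well under a
degree, the wrap-safe angle difference matches the constructed change, and
the to-mean RMSD matches the sigma*sqrt(3) expectation of isotropic jitter.
"""

import argparse
import json
import math
import pathlib

from efcalc import synthetic, vgm
from efcalc.structure import ResidueSelection, ensemble_rmsd

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out", type=pathlib.Path,
                    default=pathlib.Path(__file__).parent.parent / "results")
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

# apo/holo poses: a moderate opening (delta-theta +15.1) with a clockwise
# swing (delta-phi -27.6), the EF1-like change regime
poses = {"apo": (41.2, 10.0), "holo": (56.3, -17.6)}
results = {}
for state, (theta, phi) in poses.items():
    ens, hand, _ = synthetic.gen_helix_pair_ensemble(
        theta, phi, models=20, jitter_sd=2.0,
        seed=args.seed + (0 if state == "apo" else 1))
    results[state] = {hand.name: vgm.ensemble_vgm(ens, hand)}

comparison = vgm.compare_states(results["apo"], results["holo"])
hand_name = next(iter(comparison))

base, hand, _ = synthetic.gen_helix_pair_ensemble(90.0, 0.0, models=1,
                                                  seed=args.seed)
sigma = 0.5
jittered = synthetic.gen_ensemble_jitter(base, models=20, coordinate_sd=sigma,
                                         seed=args.seed)
sel = ResidueSelection(ranges=((1, hand.entering[1]),), atoms="backbone")
rmsd = ensemble_rmsd(jittered, sel)

payload = {
    "constructed": poses,
    "measured": comparison[hand_name],
    "circular_sd_deg": {s: results[s][hand_name].sd_phi for s in poses},
    "rmsd": {"to_mean_A": rmsd["to_mean"], "pairwise_A": rmsd["pairwise"],
             "n_models": rmsd["n_models"], "n_atoms": rmsd["n_atoms"],
             "coordinate_sd_A": sigma,
             "expected_to_mean_A": sigma * math.sqrt(3.0)},
}
(args.out / "ensemble_geometry.json").write_text(
    json.dumps(payload, indent=2, sort_keys=True) + "\n")

m = comparison[hand_name]
print(f"theta: apo {m['theta_apo']:.1f} deg, holo {m['theta_holo']:.1f} deg, "
      f"delta {m['delta_theta']:+.1f} (constructed "
      f"{poses['holo'][0] - poses['apo'][0]:+.1f})")
print(f"phi:   apo {m['phi_apo']:.1f} deg, holo {m['phi_holo']:.1f} deg, "
      f"delta {m['delta_phi']:+.1f} (constructed "
      f"{poses['holo'][1] - poses['apo'][1]:+.1f})")
print(f"RMSD to mean {rmsd['to_mean']:.3f} A, pairwise {rmsd['pairwise']:.3f} A "
      f"(expected to-mean {sigma * math.sqrt(3.0):.3f} A)")
print(f"wrote {args.out / 'ensemble_geometry.json'}")
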