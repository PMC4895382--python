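"""Interhelical-angle analysis of EF hands (vector geometry mapping style).

An EF hand is an entering helix, a 12-residue Ca2+-binding loop, and an
exiting helix. The exiting helix's orientation relative to the entering
helix is summarised by two angles: the polar angle θ (degree of opening,
measured from the entering-helix axis) and the azimuth φ (horizontal swing
around it). Rather than superposing on an external reference EF hand, each
hand carries its own loop-anchored right-handed frame:

    z = entering-helix axis (N→C)
    x = unit component of (first-loop-residue CA − entering centroid) ⊥ z
    y = z × x

θ = arccos(e·z) and φ = atan2(e·y, e·x) for the exiting-helix axis e.
φ is measured counterclockwise from +x viewed from +z (right-handed) and
wrapped to (−180°, 180°]. The construction is invariant under any rigid
transform of the model. State differences are holo − apo on ensemble
means, with φ differences wrapped circularly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structure import HelixSegment, StructureEnsemble, fit_helix_axis

PHI_CONVENTION = "right-handed, counterclockwise from +x viewed from +z"


@dataclass(frozen=True)
class HandDefinition:
    """Residue ranges defining one EF hand in a structure."""

    name: str
    entering: tuple[int, int]
    exiting: tuple[int, int]
    loop_anchor: int  # author residue number of the first loop residue
    chain: str = "A"

    def __post_init__(self) -> None:
        if self.entering[1] >= self.exiting[0]:
            raise ValueError("entering helix must precede exiting helix")


@dataclass(frozen=True)
class EFHandGeometry:
    entering_helix: HelixSegment
    exiting_helix: HelixSegment
    loop_anchor: np.ndarray  # CA coordinate of first loop residue


@dataclass
class VGMResult:
    """Per-model θ/φ plus circular summary statistics for one EF hand."""

    hand: str
    theta: np.ndarray  # degrees, per model
    phi: np.ndarray  # degrees, per model
    mean_theta: float
    mean_phi: float  # circular mean
    sd_theta: float
    sd_phi: float  # circular SD
    excluded_models: list[int]
    degenerate: bool = False


def wrap_angle(deg: float) -> float:
    """Wrap an angle in degrees to (−180, 180]."""
    wrapped = math.fmod(deg + 180.0, 360.0)
    if wrapped <= 0:
        wrapped += 360.0
    return wrapped - 180.0


def local_frame(geometry: EFHandGeometry, tol: float = 1e-8) -> np.ndarray:
    """Loop-anchored orthonormal frame, columns (x, y, z), right-handed."""
    z = geometry.entering_helix.axis
    z = z / np.linalg.norm(z)
    rel = geometry.loop_anchor - geometry.entering_helix.centroid
    x = rel - (rel @ z) * z
    nx = np.linalg.norm(x)
    if nx < tol * max(np.linalg.norm(rel), 1.0):
        raise ValueError("loop anchor collinear with the entering-helix axis: "
                         "frame is degenerate")
    x = x / nx
    y = np.cross(z, x)
    frame = np.column_stack([x, y, z])
    # right-handed orthonormal by construction; guard against numerics
    assert abs(np.linalg.det(frame) - 1.0) < 1e-9
    return frame


def vgm_angles(geometry: EFHandGeometry) -> tuple[float, float, bool]:
    """(θ, φ) in degrees for one EF-hand geometry.

    Returns (theta, phi, degenerate); φ is reported as 0 with the
    degeneracy flag set when the exiting axis is (anti)parallel to the
    entering axis, where the azimuth is undefined.
    """
    frame = local_frame(geometry)
    e = geometry.exiting_helix.axis
    e = e / np.linalg.norm(e)
    local = frame.T @ e
    theta = math.degrees(math.acos(float(np.clip(local[2], -1.0, 1.0))))
    planar = math.hypot(float(local[0]), float(local[1]))
    if planar < 1e-12:
        return theta, 0.0, True
    phi = math.degrees(math.atan2(float(local[1]), float(local[0])))
    return theta, wrap_angle(phi), False


def hand_geometry(ensemble: StructureEnsemble, model: int,
                  hand: HandDefinition) -> EFHandGeometry:
    entering = fit_helix_axis(ensemble, model, hand.entering, chain=hand.chain)
    exiting = fit_helix_axis(ensemble, model, hand.exiting, chain=hand.chain)
    anchor = None
    for i, (ch, rn, _, an) in enumerate(ensemble.atoms):
        if ch == hand.chain and rn == hand.loop_anchor and an == "CA":
            anchor = ensemble.coords[model, i]
            break
    if anchor is None:
        raise ValueError(f"loop anchor CA {hand.loop_anchor} not found "
                         f"in chain {hand.chain}")
    return EFHandGeometry(entering_helix=entering, exiting_helix=exiting,
                          loop_anchor=anchor)


def circular_mean_sd(deg: np.ndarray) -> tuple[float, float]:
    rad = np.radians(deg)
    c, s = np.cos(rad).mean(), np.sin(rad).mean()
    mean = math.degrees(math.atan2(s, c))
    r = min(math.hypot(c, s), 1.0)
    if 1.0 - r < 1e-12:  # constant sample up to float rounding
        sd = 0.0
    elif r > 0:
        sd = math.degrees(math.sqrt(-2.0 * math.log(r)))
    else:
        sd = math.inf
    return wrap_angle(mean), sd


def ensemble_vgm(ensemble: StructureEnsemble, hand: HandDefinition) -> VGMResult:
    """Per-model (θ, φ) over an ensemble with circular summary statistics.

    Models whose frame construction fails (degenerate geometry) are
    excluded from the summary and reported by index.
    """
    thetas, phis, excluded = [], [], []
    any_degenerate = False
    for m in range(ensemble.n_models):
        try:
            geom = hand_geometry(ensemble, m, hand)
            th, ph, degen = vgm_angles(geom)
        except ValueError:
            excluded.append(m)
            continue
        any_degenerate = any_degenerate or degen
        thetas.append(th)
        phis.append(ph)
    if not thetas:
        raise ValueError(f"no usable models for hand {hand.name}")
    theta = np.array(thetas)
    phi = np.array(phis)
    mean_phi, sd_phi = circular_mean_sd(phi)
    return VGMResult(
        hand=hand.name,
        theta=theta, phi=phi,
        mean_theta=float(theta.mean()),
        mean_phi=mean_phi,
        sd_theta=float(theta.std(ddof=1)) if len(theta) > 1 else 0.0,
        sd_phi=sd_phi if len(phi) > 1 else 0.0,
        excluded_models=excluded,
        degenerate=any_degenerate,
    )


def compare_states(apo: dict[str, VGMResult],
                   holo: dict[str, VGMResult]) -> dict[str, dict[str, float]]:
    """Angle changes holo − apo per EF hand (Δφ wrapped to (−180°, 180°])."""
    if set(apo) != set(holo):
        raise ValueError(f"mismatched hand sets: {sorted(apo)} vs {sorted(holo)}")
    out = {}
    for name in sorted(apo):
        out[name] = {
            "delta_theta": holo[name].mean_theta - apo[name].mean_theta,
            "delta_phi": wrap_angle(holo[name].mean_phi - apo[name].mean_phi),
            "theta_apo": apo[name].mean_theta,
            "theta_holo": holo[name].mean_theta,
            "phi_apo": apo[name].mean_phi,
            "phi_holo": holo[name].mean_phi,
        }
    return out


#: Editable default EF-hand helix boundaries for the alpha-actinin-1
#: calmodulin-like domain (author numbering; the deposited files' HELIX
#: records are the better source when available). EF4 is excluded from
#: state comparisons by default: its exiting helix is poorly defined.
ACTN1_HAND_DEFAULTS = {
    "EF1": HandDefinition("EF1", entering=(747, 758), exiting=(769, 780),
                          loop_anchor=759),
    "EF2": HandDefinition("EF2", entering=(788, 799), exiting=(810, 819),
                          loop_anchor=800),
    "EF3": HandDefinition("EF3", entering=(826, 837), exiting=(848, 857),
                          loop_anchor=838),
}
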