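"""Forward FvCB C3 photosynthesis model with mesophyll-conductance coupling.

Net assimilation is the minimum of three limitation-specific rates
(Rubisco carboxylation, RuBP regeneration, triose-phosphate use), each
evaluated at the chloroplastic CO2 partial pressure Cc = Ci - An/gm.
The carboxylation and regeneration cases reduce to a quadratic in An;
the lower root is the physical solution.

All CO2 amounts here are partial pressures (Pa); gm is in
umol m-2 s-1 Pa-1; temperatures in K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidInputError, InvalidParameterError, NumericalSolutionError
from .kinetics import KineticConfig

LIMITATIONS = ("carboxylation", "regeneration", "tpu")


@dataclass(frozen=True)
class PhotoCapacity:
    """FvCB capacity parameters at one evaluation temperature.

    Vcmax: maximum Rubisco carboxylation rate (umol m-2 s-1);
    J: electron transport rate at the measurement irradiance of
    1500 umol photons m-2 s-1 (umol electrons m-2 s-1);
    TPU: triose-phosphate utilization rate (umol m-2 s-1);
    Rd: non-photorespiratory day respiration (umol m-2 s-1).
    """

    Vcmax: float
    J: float
    TPU: float
    Rd: float = 0.0

    def __post_init__(self):
        for name in ("Vcmax", "J", "TPU"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise InvalidParameterError(f"{name} must be finite and > 0")
        if not (math.isfinite(self.Rd) and self.Rd >= 0):
            raise InvalidParameterError("Rd must be finite and >= 0")

    def scaled(self, factors: dict) -> "PhotoCapacity":
        """Return a copy with per-trait multiplicative factors applied."""
        return PhotoCapacity(
            Vcmax=self.Vcmax * factors.get("Vcmax", 1.0),
            J=self.J * factors.get("J", 1.0),
            TPU=self.TPU * factors.get("TPU", 1.0),
            Rd=self.Rd * factors.get("Rd", 1.0),
        )


def limiting_rates(Cc: float, cap: PhotoCapacity, gammastar: float, Kair: float):
    """The three limitation-specific net rates at chloroplastic CO2 Cc (Pa).

    Ac = Vcmax * (Cc - G*) / (Cc + Kair) - Rd
    Aj = J     * (Cc - G*) / (4*Cc + 8*G*) - Rd
    Ap = 3 * TPU - Rd

    Returns (Ac, Aj, Ap) in umol m-2 s-1.
    """
    if not (math.isfinite(Cc) and Cc > 0):
        raise InvalidInputError("Cc must be finite and > 0 Pa")
    if gammastar <= 0 or Kair <= 0:
        raise InvalidParameterError("gammastar and Kair must be > 0 Pa")
    ac = cap.Vcmax * (Cc - gammastar) / (Cc + Kair) - cap.Rd
    aj = cap.J * (Cc - gammastar) / (4.0 * Cc + 8.0 * gammastar) - cap.Rd
    ap = 3.0 * cap.TPU - cap.Rd
    return ac, aj, ap


def _solve_hyperbolic(Ci, gm, p, q, gammastar, Rd, label):
    """Lower root of the gm-coupled limitation An = p*(Cc-G*)/(Cc+q) - Rd.

    Substituting Cc = Ci - An/gm gives
    An^2 - An*(gm*(Ci+q) + p - Rd) + gm*(p*(Ci-G*) - Rd*(Ci+q)) = 0.
    """
    b = gm * (Ci + q) + p - Rd
    c = gm * (p * (Ci - gammastar) - Rd * (Ci + q))
    disc = b * b - 4.0 * c
    if disc < 0:
        raise NumericalSolutionError(
            f"no real root for the {label}-limited solution (disc={disc:.3g})"
        )
    return (b - math.sqrt(disc)) / 2.0


def net_assimilation(Ci: float, T_leaf: float, cfg: KineticConfig, cap: PhotoCapacity):
    """Net assimilation at intercellular CO2 Ci (Pa) and leaf temperature T (K).

    Solves each limitation jointly with the conductance equation
    Cc = Ci - An/gm(T) and takes the minimum. Returns
    (An umol m-2 s-1, limitation label, Cc Pa). Ties are labelled by the
    fixed priority carboxylation < regeneration < tpu. Negative An at low
    Ci is a valid (respiration-dominated) output.
    """
    if not (math.isfinite(Ci) and Ci > 0):
        raise InvalidInputError("Ci must be finite and > 0 Pa")
    gm = cfg.gm_at(T_leaf)
    gammastar = cfg.gammastar_pa_at(T_leaf)
    kair = cfg.kair_pa_at(T_leaf)

    a_c = _solve_hyperbolic(Ci, gm, cap.Vcmax, kair, gammastar, cap.Rd, "carboxylation")
    a_j = _solve_hyperbolic(
        Ci, gm, cap.J / 4.0, 2.0 * gammastar, gammastar, cap.Rd, "regeneration"
    )
    a_p = 3.0 * cap.TPU - cap.Rd

    candidates = {"carboxylation": a_c, "regeneration": a_j, "tpu": a_p}
    label = min(LIMITATIONS, key=lambda k: candidates[k])
    an = candidates[label]
    cc = Ci - an / gm
    return an, label, cc


def aci_response(ci_pa, T_leaf: float, cfg: KineticConfig, cap: PhotoCapacity):
    """Vectorized A-Ci sweep: returns (An array, label list, Cc array)."""
    import numpy as np

    ans, labels, ccs = [], [], []
    for ci in np.asarray(ci_pa, dtype=float):
        an, lab, cc = net_assimilation(float(ci), T_leaf, cfg, cap)
        ans.append(an)
        labels.append(lab)
        ccs.append(cc)
    return np.array(ans), labels, np.array(ccs)
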