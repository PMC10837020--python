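"""Enzyme-kinetic constants and temperature-scaling functions.

Houses the wheat FvCB kinetic parameterization (mesophyll conductance,
apparent carboxylation constant, photorespiratory compensation point,
each with an activation energy) and the temperature-response primitives:
the simple Arrhenius scaling, the peaked (deactivation-moderated)
Arrhenius form normalized at the reference temperature, and the closed
form of the peaked optimum.

Units policy: temperatures are Kelvin inside this module; energies enter
in kJ mol-1 and are converted to J mol-1 once, internally. CO2 amounts
cross module boundaries as mole fractions (umol mol-1) and are carried
as partial pressures (Pa) by downstream consumers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .errors import InvalidParameterError

#: Universal gas constant, J mol-1 K-1.
R_GAS = 8.314

#: Reference temperature, K (25 degC).
T_REF = 298.15

#: Celsius offset.
KELVIN = 273.15


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + KELVIN


def kelvin_to_celsius(t_k: float) -> float:
    return t_k - KELVIN


@dataclass(frozen=True)
class KineticConfig:
    """Species-level FvCB kinetic constants and temperature sensitivities.

    Reference values are at ``T_ref`` (K). Activation energies are in
    kJ mol-1. ``pressure`` is the chamber atmospheric pressure in kPa,
    used to convert mole fractions to partial pressures.
    """

    gm_ref: float  # mesophyll conductance at T_ref, umol m-2 s-1 Pa-1
    Ea_gm: float  # kJ mol-1
    Kair_ref: float  # apparent carboxylation constant (21% O2), umol mol-1
    Ea_Kair: float  # kJ mol-1
    gammastar_ref: float  # photorespiratory compensation point, umol mol-1
    Ea_gammastar: float  # kJ mol-1
    pressure: float = 96.0  # kPa
    T_ref: float = T_REF  # K
    R: float = field(default=R_GAS)

    def __post_init__(self):
        for name in ("gm_ref", "Kair_ref", "gammastar_ref"):
            if not math.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be finite and > 0")
        for name in ("Ea_gm", "Ea_Kair", "Ea_gammastar"):
            if not math.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be finite and > 0")
        if not 50.0 <= self.pressure <= 110.0:
            raise InvalidParameterError("pressure must be within [50, 110] kPa")
        if self.T_ref <= 0:
            raise InvalidParameterError("T_ref must be > 0 K")

    # -- temperature-scaled constants, Kelvin in -----------------------------

    def gm_at(self, T: float) -> float:
        """Mesophyll conductance at leaf temperature T (K)."""
        return arrhenius_scale(self.gm_ref, self.Ea_gm, T, self.T_ref, self.R)

    def kair_at(self, T: float) -> float:
        """Apparent carboxylation constant at T (K), umol mol-1."""
        return arrhenius_scale(self.Kair_ref, self.Ea_Kair, T, self.T_ref, self.R)

    def gammastar_at(self, T: float) -> float:
        """Photorespiratory compensation point at T (K), umol mol-1."""
        return arrhenius_scale(
            self.gammastar_ref, self.Ea_gammastar, T, self.T_ref, self.R
        )

    def kair_pa_at(self, T: float) -> float:
        return to_partial_pressure(self.kair_at(T), self.pressure)

    def gammastar_pa_at(self, T: float) -> float:
        return to_partial_pressure(self.gammastar_at(T), self.pressure)

    def to_dict(self) -> dict:
        return {
            "gm_ref": self.gm_ref,
            "Ea_gm": self.Ea_gm,
            "Kair_ref": self.Kair_ref,
            "Ea_Kair": self.Ea_Kair,
            "gammastar_ref": self.gammastar_ref,
            "Ea_gammastar": self.Ea_gammastar,
            "pressure": self.pressure,
            "T_ref": self.T_ref,
            "R": self.R,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KineticConfig":
        known = {
            "gm_ref", "Ea_gm", "Kair_ref", "Ea_Kair",
            "gammastar_ref", "Ea_gammastar", "pressure", "T_ref", "R",
        }
        return cls(**{k: float(v) for k, v in d.items() if k in known})

    @classmethod
    def from_file(cls, path) -> "KineticConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def load_default_config(name: str = "wheat_default") -> KineticConfig:
    """Load a packaged kinetic configuration by name."""
    ref = resources.files("photothermal.data").joinpath(f"{name}.yaml")
    return KineticConfig.from_dict(yaml.safe_load(ref.read_text()))


@dataclass(frozen=True)
class PeakedParams:
    """Parameters of the peaked Arrhenius response, normalized at T_ref.

    ``k_ref`` is the trait value at ``T_ref``; Ea/Ed in kJ mol-1; dS in
    kJ mol-1 K-1. The deactivation energy Ed defaults to 200 kJ mol-1 and
    is conventionally held fixed during fitting.
    """

    k_ref: float
    Ea: float
    dS: float
    Ed: float = 200.0
    T_ref: float = T_REF

    def __post_init__(self):
        if not (math.isfinite(self.k_ref) and self.k_ref > 0):
            raise InvalidParameterError("k_ref must be finite and > 0")
        if not (math.isfinite(self.Ea) and self.Ea > 0):
            raise InvalidParameterError("Ea must be finite and > 0")
        if not (math.isfinite(self.Ed) and self.Ed > self.Ea):
            raise InvalidParameterError(
                f"Ed must exceed Ea (got Ed={self.Ed}, Ea={self.Ea})"
            )
        if not (math.isfinite(self.dS) and self.dS > 0):
            raise InvalidParameterError("dS must be finite and > 0")


def arrhenius_scale(
    k_ref: float, Ea: float, T: float, T_ref: float = T_REF, R: float = R_GAS
) -> float:
    """Scale a trait value from T_ref to T with activation energy Ea.

    k(T) = k_ref * exp(Ea * (T - T_ref) / (T_ref * R * T)), Ea in
    kJ mol-1 (converted to J mol-1 internally), temperatures in K.
    Vectorizes over T via numpy broadcasting.
    """
    import numpy as np

    T = np.asarray(T, dtype=float)
    if not (math.isfinite(k_ref) and k_ref > 0):
        raise InvalidParameterError("k_ref must be finite and > 0")
    if not math.isfinite(Ea) or Ea < 0:
        raise InvalidParameterError("Ea must be finite and >= 0")
    if np.any(~np.isfinite(T)) or np.any(T <= 0) or T_ref <= 0:
        raise InvalidParameterError("temperatures must be finite and > 0 K")
    out = k_ref * np.exp(Ea * 1e3 * (T - T_ref) / (T_ref * R * T))
    return float(out) if out.ndim == 0 else out


def peaked_arrhenius(p: PeakedParams, T) -> float:
    """Peaked Arrhenius response at T (K), normalized so k(T_ref) = k_ref.

    k(T) = arrhenius(k_ref, Ea, T)
           * [1 + exp((T_ref*dS - Ed) / (T_ref*R))]
           / [1 + exp((T*dS - Ed) / (T*R))]
    """
    import numpy as np

    T = np.asarray(T, dtype=float)
    if np.any(~np.isfinite(T)) or np.any(T <= 0):
        raise InvalidParameterError("T must be finite and > 0 K")
    Ed_j, dS_j = p.Ed * 1e3, p.dS * 1e3
    rise = arrhenius_scale(p.k_ref, p.Ea, T, p.T_ref)
    num = 1.0 + math.exp((p.T_ref * dS_j - Ed_j) / (p.T_ref * R_GAS))
    den = 1.0 + np.exp((T * dS_j - Ed_j) / (T * R_GAS))
    out = rise * num / den
    return float(out) if out.ndim == 0 else out


def topt_from_peaked(p: PeakedParams) -> float:
    """Closed-form interior maximizer (K) of the peaked Arrhenius curve.

    T_opt = Ed / (dS - R * ln(Ea / (Ed - Ea))), all energies in J mol-1.
    """
    Ea_j, Ed_j, dS_j = p.Ea * 1e3, p.Ed * 1e3, p.dS * 1e3
    denom = dS_j - R_GAS * math.log(Ea_j / (Ed_j - Ea_j))
    if denom <= 0:
        raise InvalidParameterError(
            f"dS - R*ln(Ea/(Ed-Ea)) must be > 0 (got {denom:.6g} J mol-1 K-1)"
        )
    return Ed_j / denom


def to_partial_pressure(x, pressure: float):
    """Convert a mole fraction (umol mol-1) to partial pressure (Pa).

    x * 1e-6 * pressure(kPa) * 1e3; linear in both arguments.
    """
    import numpy as np

    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise InvalidParameterError("mole fraction must be >= 0")
    if not pressure > 0:
        raise InvalidParameterError("pressure must be > 0 kPa")
    out = x * 1e-6 * pressure * 1e3
    return float(out) if out.ndim == 0 else out


def from_partial_pressure(pa, pressure: float):
    """Inverse of :func:`to_partial_pressure` (Pa -> umol mol-1)."""
    import numpy as np

    pa = np.asarray(pa, dtype=float)
    if not pressure > 0:
        raise InvalidParameterError("pressure must be > 0 kPa")
    out = pa / (pressure * 1e3) * 1e6
    return float(out) if out.ndim == 0 else out
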