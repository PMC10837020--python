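"""Estimation of FvCB capacities (Vcmax, J1500, TPU, Rd) from A-Ci curves.

One curve = one leaf at one measurement temperature, assimilation
measured over a staircase of chamber CO2 mole fractions. The fit
minimizes squared residuals of the full min-rule forward model over the
capacity parameters, so limitation transitions are assigned by the model
itself rather than chosen by the operator. Mesophyll conductance is
fixed from the kinetic configuration (temperature-scaled), never fitted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    AggregationError,
    ConfigurationError,
    InsufficientDataError,
    InvalidInputError,
)
from .fvcb import PhotoCapacity, net_assimilation
from .kinetics import (
    KineticConfig,
    PeakedParams,
    arrhenius_scale,
    celsius_to_kelvin,
    peaked_arrhenius,
    to_partial_pressure,
)

#: The 13-step chamber CO2 sequence (umol mol-1) used throughout.
CI_SEQUENCE = (30, 50, 100, 150, 250, 400, 400, 600, 800, 1000, 1200, 1400, 400)

#: Physiological bounds for the fitted parameters (umol m-2 s-1).
PARAM_BOUNDS = {
    "Vcmax": (1e-3, 1500.0),
    "J": (1e-3, 800.0),
    "TPU": (1e-3, 60.0),
    "Rd": (0.0, 10.0),
}

DEFAULT_MULTISTART_SEED = 1704


@dataclass
class AciCurve:
    """One CO2-response curve: arrays of equal length plus metadata.

    Ci in umol mol-1, An in umol m-2 s-1, T_leaf in degC, irradiance in
    umol photons m-2 s-1, pressure in kPa.
    """

    ci: np.ndarray
    an: np.ndarray
    t_leaf: np.ndarray
    irradiance: np.ndarray
    pressure: np.ndarray
    genotype: str = ""
    night_temp: float = float("nan")
    leaf_class: str = "newly developed"
    replicate: str = ""

    def __post_init__(self):
        self.ci = np.asarray(self.ci, dtype=float)
        self.an = np.asarray(self.an, dtype=float)
        self.t_leaf = np.atleast_1d(np.asarray(self.t_leaf, dtype=float))
        if self.t_leaf.size == 1:
            self.t_leaf = np.full_like(self.ci, float(self.t_leaf[0]))
        self.irradiance = np.atleast_1d(np.asarray(self.irradiance, dtype=float))
        if self.irradiance.size == 1:
            self.irradiance = np.full_like(self.ci, float(self.irradiance[0]))
        self.pressure = np.atleast_1d(np.asarray(self.pressure, dtype=float))
        if self.pressure.size == 1:
            self.pressure = np.full_like(self.ci, float(self.pressure[0]))
        n = self.ci.size
        if not (self.an.size == self.t_leaf.size == self.irradiance.size == n):
            raise InvalidInputError("curve arrays must share one length")
        if n < 6:
            raise InsufficientDataError(f"A-Ci curve needs >=6 observations, got {n}")
        if np.any(self.ci <= 0):
            raise InvalidInputError("all Ci must be > 0")
        if self.t_leaf.max() - self.t_leaf.min() >= 1.5:
            raise InvalidInputError(
                "leaf temperatures within one curve must differ by < 1.5 degC"
            )

    @property
    def n_obs(self) -> int:
        return int(self.ci.size)

    @property
    def mean_t_leaf(self) -> float:
        return float(self.t_leaf.mean())

    @property
    def mean_pressure(self) -> float:
        return float(self.pressure.mean())


@dataclass
class AciFitResult:
    """Fitted capacities for one curve, with diagnostics."""

    cap: PhotoCapacity
    t_leaf: float  # degC at which cap applies
    rss: float
    limitation_labels: list
    se: dict
    converged: bool
    n_used: int
    tpu_identifiable: bool = True
    vcmax_identifiable: bool = True
    j_identifiable: bool = True
    cap_std: PhotoCapacity | None = None
    std_temp: float | None = None
    qc_warnings: list = field(default_factory=list)
    genotype: str = ""
    night_temp: float = float("nan")
    leaf_class: str = "newly developed"
    replicate: str = ""


def _model_an_vec(ci_pa, gm, gammastar, kair, vcmax, j, tpu, rd):
    """Vectorized min-rule An over Ci (Pa); same quadratic as fvcb module."""

    def lower_root(p, q):
        b = gm * (ci_pa + q) + p - rd
        c = gm * (p * (ci_pa - gammastar) - rd * (ci_pa + q))
        disc = np.maximum(b * b - 4.0 * c, 0.0)
        return (b - np.sqrt(disc)) / 2.0

    a_c = lower_root(vcmax, kair)
    a_j = lower_root(j / 4.0, 2.0 * gammastar)
    a_p = np.full_like(ci_pa, 3.0 * tpu - rd)
    return np.minimum(np.minimum(a_c, a_j), a_p)


def _initializations(curve: AciCurve, fit_rd: bool, rng: np.random.Generator):
    """7 deterministic starts (grid + data-driven) + 3 seeded random starts."""
    an_max = max(float(curve.an.max()), 1.0)
    rd0 = 1.0
    j0 = 4.0 * (an_max + rd0)
    tpu0 = (an_max + rd0) / 3.0
    vc0 = 2.0 * (an_max + rd0)

    # data-driven guesses ignoring gm drawdown (Cc ~ Ci): Vcmax from a
    # low-Ci point, J from a mid-Ci point, with nominal wheat constants
    press = curve.mean_pressure
    gammastar = to_partial_pressure(37.74, press)
    kair = to_partial_pressure(772.0, press)

    def vc_est(ci_target):
        i = int(np.argmin(np.abs(curve.ci - ci_target)))
        cc = to_partial_pressure(curve.ci[i], press)
        if cc <= gammastar * 1.2:
            return vc0
        return max((curve.an[i] + rd0) * (cc + kair) / (cc - gammastar), 1.0)

    def j_est(ci_target):
        i = int(np.argmin(np.abs(curve.ci - ci_target)))
        cc = to_partial_pressure(curve.ci[i], press)
        return max((curve.an[i] + rd0) * (4 * cc + 8 * gammastar) / (cc - gammastar), 1.0)

    vslope, jmid = vc_est(150.0), j_est(600.0)
    grid = [
        (vslope, jmid, tpu0, rd0),
        (vc0, j0, tpu0, rd0),
        (vslope * 0.5, jmid * 0.75, tpu0 * 1.5, 0.25),
        (vslope * 2.0, jmid * 1.25, tpu0 * 0.9, 2.0),
        (vc0 * 4.0, j0, tpu0, rd0),
        (vc0 * 0.5, j0 * 0.5, tpu0 * 2.0, 0.5),
        (vslope, jmid * 2.0, tpu0, rd0),
    ]

    lo = np.array([PARAM_BOUNDS[k][0] for k in ("Vcmax", "J", "TPU")])
    hi = np.array([PARAM_BOUNDS[k][1] for k in ("Vcmax", "J", "TPU")])
    for _ in range(3):
        u = rng.uniform(size=3)
        vjt = np.exp(np.log(np.maximum(lo, 1.0)) + u * (np.log(hi) - np.log(np.maximum(lo, 1.0))))
        grid.append((vjt[0], vjt[1], vjt[2], rng.uniform(0.0, 3.0)))

    starts = []
    for v, j, t, r in grid:
        theta = [v, j, t] + ([r] if fit_rd else [])
        starts.append(np.array(theta))
    return starts


def fit_aci(
    curve: AciCurve,
    cfg: KineticConfig,
    fit_rd: bool = True,
    rd_fixed: float = 0.0,
    multistart_seed: int = DEFAULT_MULTISTART_SEED,
    drift_tolerance: float = 0.15,
) -> AciFitResult:
    """Fit (Vcmax, J, TPU[, Rd]) to one A-Ci curve by multistart least squares.

    Limitations are assigned by the fitted min-rule model at each point.
    If no point is TPU-limited at the optimum, TPU is reported as a lower
    bound with ``tpu_identifiable=False`` rather than fabricated.
    """
    t_k = celsius_to_kelvin(curve.mean_t_leaf)
    press = curve.mean_pressure
    gm = cfg.gm_at(t_k)
    gammastar = to_partial_pressure(cfg.gammastar_at(t_k), press)
    kair = to_partial_pressure(cfg.kair_at(t_k), press)
    ci_pa = to_partial_pressure(curve.ci, press)
    an_obs = curve.an

    qc = _drift_check(curve, drift_tolerance)

    def residuals(theta):
        v, j, t = theta[0], theta[1], theta[2]
        r = theta[3] if fit_rd else rd_fixed
        return _model_an_vec(ci_pa, gm, gammastar, kair, v, j, t, r) - an_obs

    names = ["Vcmax", "J", "TPU"] + (["Rd"] if fit_rd else [])
    lo = np.array([PARAM_BOUNDS[n][0] for n in names])
    hi = np.array([PARAM_BOUNDS[n][1] for n in names])

    rng = np.random.default_rng(multistart_seed)
    best = None
    for x0 in _initializations(curve, fit_rd, rng):
        x0 = np.clip(x0, lo, hi)
        try:
            sol = least_squares(
                residuals, x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12, gtol=1e-12
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise InsufficientDataError("all initializations failed")

    # J-profile refinement: the min-rule objective has narrow basins in J
    # (J only acts in the transition region), so scan J on a grid with the
    # other parameters re-optimized, then polish the winner in full space.
    prof = _profile_j_refinement(residuals, curve, fit_rd, rd_fixed, lo, hi)
    if prof is not None and prof.cost < best.cost:
        best = prof

    theta = best.x
    rd = theta[3] if fit_rd else rd_fixed
    cap = PhotoCapacity(Vcmax=theta[0], J=theta[1], TPU=theta[2], Rd=rd)
    rss = float(2.0 * best.cost)

    labels = [
        net_assimilation(float(cp), t_k, cfg, cap)[1] for cp in ci_pa
    ]
    se = _approx_se(best, names, curve.n_obs)
    converged = bool(best.success)

    return AciFitResult(
        cap=cap,
        t_leaf=curve.mean_t_leaf,
        rss=rss,
        limitation_labels=labels,
        se=se,
        converged=converged,
        n_used=curve.n_obs,
        tpu_identifiable="tpu" in labels,
        vcmax_identifiable="carboxylation" in labels,
        j_identifiable="regeneration" in labels,
        qc_warnings=qc,
        genotype=curve.genotype,
        night_temp=curve.night_temp,
        leaf_class=curve.leaf_class,
        replicate=curve.replicate,
    )


def _profile_j_refinement(residuals, curve, fit_rd, rd_fixed, lo, hi, n_grid=25):
    """Scan J over a physiological grid, refitting the rest, then polish."""
    an_max = max(float(curve.an.max()), 1.0)
    j_grid = np.linspace(3.5 * an_max, 9.0 * an_max, n_grid)
    j_grid = np.clip(j_grid, PARAM_BOUNDS["J"][0], PARAM_BOUNDS["J"][1])
    lo_r = np.delete(lo, 1)
    hi_r = np.delete(hi, 1)
    x0_r = np.clip(
        np.array([2.0 * an_max, an_max / 3.0] + ([1.0] if fit_rd else [])), lo_r, hi_r
    )
    best = None
    for j_fix in j_grid:
        def sub(theta_r):
            theta = np.insert(theta_r, 1, j_fix)
            return residuals(theta)

        try:
            sol = least_squares(sub, x0_r, bounds=(lo_r, hi_r), xtol=1e-10, ftol=1e-10)
        except Exception:
            continue
        if best is None or sol.cost < best[0]:
            best = (sol.cost, j_fix, sol.x)
    if best is None:
        return None
    x0 = np.clip(np.insert(best[2], 1, best[1]), lo, hi)
    try:
        return least_squares(
            residuals, x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12, gtol=1e-12
        )
    except Exception:
        return None


def _drift_check(curve: AciCurve, tol: float) -> list:
    """Flag drift if the final 400-recovery point deviates from mid-sequence 400s."""
    qc = []
    idx400 = np.where(np.isclose(curve.ci, 400.0, atol=5.0))[0]
    if idx400.size >= 2:
        final = idx400[-1]
        mids = idx400[:-1]
        # only treat the last point as a recovery check when it ends the curve
        if final == curve.n_obs - 1 and mids.size:
            ref = float(curve.an[mids].mean())
            if abs(ref) > 1e-9 and abs(curve.an[final] - ref) / abs(ref) > tol:
                msg = (
                    f"recovery 400-point An deviates {abs(curve.an[final]-ref)/abs(ref):.0%} "
                    f"from mid-sequence mean (drift check)"
                )
                warnings.warn(msg)
                qc.append(msg)
    return qc


def _approx_se(sol, names, n_obs):
    """Gauss-Newton standard errors from the solution jacobian."""
    se = {}
    dof = max(n_obs - len(names), 1)
    s2 = 2.0 * sol.cost / dof
    try:
        jtj = sol.jac.T @ sol.jac
        cov = s2 * np.linalg.pinv(jtj)
        for i, n in enumerate(names):
            se[n] = float(np.sqrt(max(cov[i, i], 0.0)))
    except Exception:
        se = {n: float("nan") for n in names}
    return se


def standardize_capacity(fit, t_from: float, t_to: float, scaling: dict) -> PhotoCapacity:
    """Rescale capacities from t_from to t_to (degC) by each trait's response.

    ``scaling`` maps trait name -> either a plain activation energy
    (kJ mol-1, simple Arrhenius) or a :class:`PeakedParams`. Traits
    missing from the map raise a configuration error. Rd, if present in
    the map, is scaled too; otherwise carried unchanged.
    """
    if not (0.0 < t_from < 60.0 and 0.0 < t_to < 60.0):
        raise ConfigurationError("standardization temperatures must be in (0, 60) degC")
    cap = fit.cap if isinstance(fit, AciFitResult) else fit
    tk_from, tk_to = celsius_to_kelvin(t_from), celsius_to_kelvin(t_to)

    def ratio(spec):
        if isinstance(spec, PeakedParams):
            return peaked_arrhenius(spec, tk_to) / peaked_arrhenius(spec, tk_from)
        return arrhenius_scale(1.0, float(spec), tk_to) / arrhenius_scale(
            1.0, float(spec), tk_from
        )

    factors = {}
    for trait in ("Vcmax", "J", "TPU"):
        if trait not in scaling:
            raise ConfigurationError(f"no temperature scaling provided for {trait}")
        factors[trait] = ratio(scaling[trait])
    if "Rd" in scaling:
        factors["Rd"] = ratio(scaling["Rd"])
    return cap.scaled(factors)


def pool_fits(fits, by=("genotype", "night_temp", "t_leaf"), use_standardized=False):
    """Aggregate fit results into per-cell mean/SD/n of each capacity.

    Returns a tidy :class:`pandas.DataFrame` with one row per cell x trait.
    Cells with no fits are simply absent. SD is NaN for n = 1.
    """
    import pandas as pd

    if not fits:
        raise AggregationError("no fits to pool")
    if use_standardized:
        temps = {f.std_temp for f in fits}
        if len(temps) > 1:
            raise AggregationError(
                f"inconsistent standardization temperatures across fits: {sorted(temps)}"
            )
        if temps == {None}:
            raise AggregationError("fits carry no standardized capacities")

    rows = []
    for f in fits:
        cap = f.cap_std if use_standardized else f.cap
        if cap is None:
            raise AggregationError("fit missing standardized capacity")
        for trait in ("Vcmax", "J", "TPU", "Rd"):
            rows.append(
                {
                    "genotype": f.genotype,
                    "night_temp": f.night_temp,
                    "leaf_class": f.leaf_class,
                    "t_leaf": f.t_leaf,
                    "replicate": f.replicate,
                    "trait": trait,
                    "value": getattr(cap, trait),
                }
            )
    df = pd.DataFrame(rows)
    keys = [k for k in by if k in df.columns] + ["trait"]
    out = (
        df.groupby(keys, dropna=False)["value"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    return out


def series_from_fits(fits, trait: str, use_standardized=False):
    """Build ThermalSeries per (genotype, night_temp, leaf_class) cell."""
    from .thermal import ThermalSeries

    cells = {}
    for f in fits:
        cap = f.cap_std if use_standardized else f.cap
        key = (f.genotype, f.night_temp, f.leaf_class)
        cells.setdefault(key, []).append(
            (f.t_leaf, getattr(cap, trait), f.replicate)
        )
    out = {}
    for key, pts in cells.items():
        t, v, r = zip(*pts)
        out[key] = ThermalSeries(
            trait=trait,
            temps=np.array(t),
            values=np.array(v),
            replicates=list(r),
            grouping={"genotype": key[0], "night_temp": key[1], "leaf_class": key[2]},
        )
    return out
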