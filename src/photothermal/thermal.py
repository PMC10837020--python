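"""Temperature-response fitting and the comparative statistics layer.

Capacity- or assimilation-vs-leaf-temperature series are fitted either
with the peaked Arrhenius form (deactivation energy held fixed, default
200 kJ mol-1) or with a second-order polynomial; the optimum temperature
and the value at the optimum are derived quantities. Nested-regression
model selection (common line vs separate lines, extra-sum-of-squares
F-tests) and fixed-effects ANOVA with LSD/HSD post-hoc letters live here
too.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .errors import InsufficientDataError, InvalidInputError, InvalidParameterError
from .kinetics import (
    PeakedParams,
    celsius_to_kelvin,
    kelvin_to_celsius,
    peaked_arrhenius,
    topt_from_peaked,
)

DEFAULT_ED = 200.0  # kJ mol-1, held fixed in peaked fits
ALPHA = 0.05

#: Default trait -> response-model mapping.
TRAIT_MODELS = {
    "Vcmax": "peaked",
    "J1500": "quadratic",
    "TPU": "quadratic",
    "An": "quadratic",
    "gs": "quadratic",
}


@dataclass
class ThermalSeries:
    """A trait measured (or fitted) across leaf temperatures.

    temps in degC; values in trait units; one entry per replicate point.
    """

    trait: str
    temps: np.ndarray
    values: np.ndarray
    replicates: list = field(default_factory=list)
    grouping: dict = field(default_factory=dict)

    def __post_init__(self):
        self.temps = np.asarray(self.temps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.temps.size != self.values.size:
            raise InvalidInputError("temps and values must have equal length")
        if not self.replicates:
            self.replicates = [str(i) for i in range(self.temps.size)]

    @property
    def n_distinct_temps(self) -> int:
        return int(np.unique(np.round(self.temps, 6)).size)


@dataclass
class PeakedFit:
    params: PeakedParams
    t_opt: float  # degC
    value_at_topt: float
    rss: float
    converged: bool
    se: dict
    flag: str = ""


@dataclass
class QuadFit:
    a: float
    b: float
    c: float
    rss: float
    t_opt: float | None
    value_at_topt: float | None
    has_optimum: bool
    flag: str = ""

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        return self.a * t**2 + self.b * t + self.c


def fit_peaked(
    series: ThermalSeries,
    Ed_fixed: float = DEFAULT_ED,
    n_multistart: int = 5,
    seed: int = 0,
) -> PeakedFit:
    """Fit (k_ref, Ea, dS) of the peaked Arrhenius response, Ed fixed.

    A series whose fitted optimum lies at or beyond the warmest observed
    temperature carries ``converged=False`` and the flag
    ``"no optimum resolvable"`` — the data show no detectable deactivation.
    """
    if series.n_distinct_temps < 4:
        raise InsufficientDataError("peaked fit needs >=4 distinct temperatures")
    span = series.temps.max() - series.temps.min()
    if span < 15.0:
        raise InsufficientDataError(
            f"peaked fit needs a temperature span >= 15 degC (got {span:.1f})"
        )
    t_k = celsius_to_kelvin(series.temps)
    y = series.values
    if np.any(y <= 0):
        raise InvalidInputError("peaked fit requires positive trait values")

    def residuals(theta):
        k_ref, ea, ds = theta
        p = PeakedParams(k_ref=k_ref, Ea=ea, dS=ds, Ed=Ed_fixed)
        return peaked_arrhenius(p, t_k) - y

    lo = np.array([1e-6, 1.0, 0.2])
    hi = np.array([1e4, Ed_fixed - 1.0, 1.5])
    k0 = float(np.interp(25.0, series.temps, y)) if span > 0 else float(y.mean())
    k0 = max(k0, 1e-3)
    rng = np.random.default_rng(seed)
    starts = [np.array([k0, 60.0, 0.65]), np.array([k0, 40.0, 0.65]),
              np.array([k0 * 1.5, 80.0, 0.63])]
    while len(starts) < n_multistart:
        starts.append(
            np.array([k0 * rng.uniform(0.5, 2.0), rng.uniform(20, 150), rng.uniform(0.4, 1.0)])
        )

    best = None
    for x0 in starts:
        x0 = np.clip(x0, lo, hi)
        try:
            sol = least_squares(residuals, x0, bounds=(lo, hi), xtol=1e-13, ftol=1e-13)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise InsufficientDataError("all peaked-fit initializations failed")

    k_ref, ea, ds = best.x
    params = PeakedParams(k_ref=float(k_ref), Ea=float(ea), dS=float(ds), Ed=Ed_fixed)
    try:
        topt_k = topt_from_peaked(params)
    except InvalidParameterError:
        topt_k = float("inf")
    t_opt = kelvin_to_celsius(topt_k)
    rss = float(2.0 * best.cost)
    se = {}
    dof = max(y.size - 3, 1)
    try:
        cov = (2.0 * best.cost / dof) * np.linalg.pinv(best.jac.T @ best.jac)
        for i, n in enumerate(("k_ref", "Ea", "dS")):
            se[n] = float(np.sqrt(max(cov[i, i], 0.0)))
    except Exception:
        se = {n: float("nan") for n in ("k_ref", "Ea", "dS")}

    flag = ""
    converged = bool(best.success)
    if not math.isfinite(t_opt) or t_opt >= series.temps.max():
        flag = "no optimum resolvable"
        converged = False
        value_at = float("nan")
    else:
        value_at = peaked_arrhenius(params, topt_k)
    return PeakedFit(
        params=params, t_opt=t_opt, value_at_topt=value_at, rss=rss,
        converged=converged, se=se, flag=flag,
    )


def fit_quadratic(series: ThermalSeries) -> QuadFit:
    """OLS second-order polynomial in leaf temperature (degC).

    The optimum is the vertex -b/(2a), reported only for downward
    curvature (a < 0); otherwise the fit is flagged "no optimum in range".
    """
    if series.n_distinct_temps < 3:
        raise InsufficientDataError("quadratic fit needs >=3 distinct temperatures")
    t, y = series.temps, series.values
    X = np.column_stack([t**2, t, np.ones_like(t)])
    if np.linalg.matrix_rank(X) < 3:
        raise InvalidInputError("degenerate (collinear) temperature design")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    a, b, c = (float(v) for v in coef)
    resid = y - X @ coef
    rss = float(resid @ resid)
    if a < 0:
        t_opt = -b / (2.0 * a)
        value = a * t_opt**2 + b * t_opt + c
        return QuadFit(a, b, c, rss, t_opt, value, True)
    return QuadFit(a, b, c, rss, None, None, False, flag="no optimum in range")


def _stack_groups(series_by_group):
    groups, t, y = [], [], []
    for g, s in series_by_group.items():
        if s.n_distinct_temps < 3:
            raise InsufficientDataError(f"group {g!r} has <3 distinct temperatures")
        groups.extend([g] * s.temps.size)
        t.append(s.temps)
        y.append(s.values)
    return groups, np.concatenate(t), np.concatenate(y)


def _ols_rss(X, y):
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ coef
    return float(r @ r), coef


def compare_regressions(series_by_group, alpha: float = ALPHA) -> dict:
    """Nested quadratic-regression comparison across groups.

    M0: one common quadratic. M1: separate intercepts, common slope and
    curvature. M2: fully separate quadratics. Extra-sum-of-squares
    F-tests select the model: M2 if it beats M1 at ``alpha``, else M1 if
    it beats M0, else M0.
    """
    if len(series_by_group) < 2:
        raise InvalidInputError("need >=2 groups to compare regressions")
    groups, t, y = _stack_groups(series_by_group)
    labels = sorted(set(groups), key=str)
    n = y.size
    g = len(labels)
    D = np.zeros((n, g))
    for i, lab in enumerate(labels):
        D[:, i] = [1.0 if gr == lab else 0.0 for gr in groups]

    X0 = np.column_stack([np.ones(n), t, t**2])
    X1 = np.column_stack([D, t, t**2])
    X2 = np.hstack([D, D * t[:, None], D * t[:, None] ** 2])
    p0, p1, p2 = 3, g + 2, 3 * g

    rss0, c0 = _ols_rss(X0, y)
    rss1, c1 = _ols_rss(X1, y)
    rss2, c2 = _ols_rss(X2, y)
    # numerical floor: nested rss can exceed by rounding only
    rss1 = min(rss1, rss0)
    rss2 = min(rss2, rss1)

    def ftest(rss_r, rss_f, p_r, p_f):
        df1, df2 = p_f - p_r, n - p_f
        if df2 <= 0:
            return float("nan"), df1, df2, float("nan")
        drop = max(rss_r - rss_f, 0.0)
        scale = max(rss_r, 1.0)
        if drop / scale < 1e-12:  # no real improvement (incl. both ~0)
            return 0.0, df1, df2, 1.0
        if rss_f <= 1e-300:
            return float("inf"), df1, df2, 0.0
        f = (drop / df1) / (rss_f / df2)
        return f, df1, df2, float(stats.f.sf(f, df1, df2))

    f10 = ftest(rss0, rss1, p0, p1)
    f21 = ftest(rss1, rss2, p1, p2)
    f20 = ftest(rss0, rss2, p0, p2)

    if f21[3] < alpha:
        selected = "M2"
    elif f10[3] < alpha:
        selected = "M1"
    else:
        selected = "M0"

    return {
        "groups": labels,
        "n": n,
        "rss": {"M0": rss0, "M1": rss1, "M2": rss2},
        "params": {"M0": c0, "M1": c1, "M2": c2},
        "n_params": {"M0": p0, "M1": p1, "M2": p2},
        "tests": {
            "M1_vs_M0": dict(zip(("F", "df1", "df2", "p"), f10)),
            "M2_vs_M1": dict(zip(("F", "df1", "df2", "p"), f21)),
            "M2_vs_M0": dict(zip(("F", "df1", "df2", "p"), f20)),
        },
        "selected": selected,
        "alpha": alpha,
    }


# --------------------------------------------------------------------------
# ANOVA with post-hoc letters


def _one_way_ss(values_by_group):
    all_vals = np.concatenate([np.asarray(v, float) for v in values_by_group.values()])
    grand = all_vals.mean()
    ss_total = float(((all_vals - grand) ** 2).sum())
    ss_between = 0.0
    for v in values_by_group.values():
        v = np.asarray(v, float)
        ss_between += v.size * (v.mean() - grand) ** 2
    ss_within = ss_total - ss_between
    return ss_total, float(ss_between), float(ss_within)


def anova_posthoc(values_by_group, method: str = "HSD", alpha: float = ALPHA) -> dict:
    """Fixed-effects ANOVA with pairwise letters (Fisher LSD or Tukey HSD).

    ``values_by_group`` maps group label -> replicate values. Tuple keys
    (A, B) trigger a two-way (A x B + interaction) decomposition on a
    balanced layout; plain keys give a one-way table. The post-hoc letter
    display always compares the full cell means against the error MS.
    """
    method = method.upper()
    if method not in ("LSD", "HSD"):
        raise InvalidParameterError("method must be LSD or HSD")
    if len(values_by_group) < 2:
        raise InsufficientDataError("need >=2 groups")
    counts = {g: len(v) for g, v in values_by_group.items()}
    n_total = sum(counts.values())
    k = len(values_by_group)
    df_error = n_total - k
    if df_error <= 0:
        raise InsufficientDataError("zero error degrees of freedom: add replicates")

    two_way = all(isinstance(g, tuple) and len(g) == 2 for g in values_by_group)

    ss_total, ss_between, ss_within = _one_way_ss(values_by_group)
    ms_error = ss_within / df_error

    table = []
    if two_way:
        a_levels = sorted({g[0] for g in values_by_group}, key=str)
        b_levels = sorted({g[1] for g in values_by_group}, key=str)
        all_vals = np.concatenate([np.asarray(v, float) for v in values_by_group.values()])
        grand = all_vals.mean()

        def margin_ss(levels, pos):
            ss = 0.0
            for lev in levels:
                vals = np.concatenate(
                    [np.asarray(v, float) for g, v in values_by_group.items() if g[pos] == lev]
                )
                ss += vals.size * (vals.mean() - grand) ** 2
            return float(ss)

        ss_a = margin_ss(a_levels, 0)
        ss_b = margin_ss(b_levels, 1)
        ss_ab = ss_between - ss_a - ss_b
        df_a, df_b = len(a_levels) - 1, len(b_levels) - 1
        df_ab = (len(a_levels) - 1) * (len(b_levels) - 1)
        for name, ss, df in (
            ("factor_a", ss_a, df_a),
            ("factor_b", ss_b, df_b),
            ("interaction", max(ss_ab, 0.0), df_ab),
        ):
            ms = ss / df if df > 0 else float("nan")
            f = ms / ms_error if ms_error > 0 else (0.0 if ss == 0 else float("inf"))
            p = float(stats.f.sf(f, df, df_error)) if df > 0 and math.isfinite(f) else 1.0
            table.append({"source": name, "SS": ss, "df": df, "MS": ms, "F": f, "p": p})
    else:
        df_b = k - 1
        ms_b = ss_between / df_b
        if ms_error > 0:
            f = ms_b / ms_error
            p = float(stats.f.sf(f, df_b, df_error))
        else:
            f, p = (0.0, 1.0) if ss_between <= 1e-300 else (float("inf"), 0.0)
        table.append({"source": "group", "SS": ss_between, "df": df_b, "MS": ms_b, "F": f, "p": p})
    table.append(
        {"source": "error", "SS": ss_within, "df": df_error,
         "MS": ms_error, "F": float("nan"), "p": float("nan")}
    )

    means = {g: float(np.mean(v)) for g, v in values_by_group.items()}
    pairs = {}
    for g1, g2 in itertools.combinations(values_by_group, 2):
        n1, n2 = counts[g1], counts[g2]
        diff = abs(means[g1] - means[g2])
        if ms_error <= 0:
            p_pair = 1.0 if diff <= 1e-300 else 0.0
        elif method == "LSD":
            t_stat = diff / math.sqrt(ms_error * (1.0 / n1 + 1.0 / n2))
            p_pair = 2.0 * float(stats.t.sf(t_stat, df_error))
        else:
            nh = 2.0 / (1.0 / n1 + 1.0 / n2)  # harmonic mean for unbalanced cells
            q = diff / math.sqrt(ms_error / nh)
            p_pair = float(stats.studentized_range.sf(q, k, df_error))
        pairs[(g1, g2)] = p_pair

    letters = _letter_display(means, pairs, alpha)
    return {
        "table": table,
        "means": means,
        "pairwise_p": pairs,
        "letters": letters,
        "method": method,
        "alpha": alpha,
    }


def _letter_display(means, pairwise_p, alpha):
    """Greedy compact letter display: same letter = not significantly different."""

    def differ(g1, g2):
        p = pairwise_p.get((g1, g2), pairwise_p.get((g2, g1), 1.0))
        return p < alpha

    order = sorted(means, key=lambda g: -means[g])
    letter_sets: list[list] = []
    for g in order:
        placed = False
        for s in letter_sets:
            if all(not differ(g, other) for other in s):
                s.append(g)
                placed = True
        if not placed:
            letter_sets.append([g])
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in means}
    for i, s in enumerate(letter_sets):
        for g in s:
            out[g] += alphabet[i % len(alphabet)]
    return out
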