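"""Critical temperature of PSII from minimum-fluorescence temperature ramps.

A leaf disc's F0 trace is flat while PSII is intact and rises steeply
once thermal damage begins. T_crit is the intersection of two straight
lines fitted to the flat and steep portions. The boundary between
portions is chosen by exhaustive search: every admissible split is
scored by the combined two-segment residual sum of squares and the
global minimum wins — no operator-chosen windows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, InvalidParameterError, NoBreakpointError

#: Steep slope must exceed FLAT_FACTOR*|flat| + SIGMA_FACTOR*resid SD per degC.
FLAT_FACTOR = 5.0
SIGMA_FACTOR = 3.0
DEFAULT_SMOOTH_WINDOW = 0.5  # degC


@dataclass
class FluorescenceRamp:
    """F0 vs temperature trace from a constant-rate ramp."""

    temperature: np.ndarray  # degC, strictly increasing
    f0: np.ndarray  # arbitrary fluorescence units, > 0
    ramp_rate: float = 1.0  # degC min-1 (nominal)
    genotype: str = ""
    night_temp: float = float("nan")
    leaf_class: str = "newly developed"
    replicate: str = ""

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.f0 = np.asarray(self.f0, dtype=float)
        if self.temperature.size != self.f0.size:
            raise InvalidInputError("temperature and F0 arrays must match in length")
        if self.temperature.size < 50:
            raise InvalidInputError("ramp needs >=50 samples")
        if np.any(np.diff(self.temperature) <= 0):
            raise InvalidInputError("temperatures must be strictly increasing")
        if self.temperature[-1] - self.temperature[0] < 30.0:
            raise InvalidInputError("ramp must span >=30 degC")
        if np.any(self.f0 <= 0):
            raise InvalidInputError("F0 must be > 0")

    @property
    def span(self) -> float:
        return float(self.temperature[-1] - self.temperature[0])


@dataclass
class TcritResult:
    tcrit: float  # degC
    flat_slope: float
    flat_intercept: float
    steep_slope: float
    steep_intercept: float
    breakpoint: float  # temperature of the segment boundary used
    rss_total: float
    r2_flat: float
    r2_steep: float
    n_flat: int
    n_steep: int
    in_range: bool = True
    genotype: str = ""
    night_temp: float = float("nan")
    leaf_class: str = "newly developed"
    replicate: str = ""


def smooth_ramp(ramp: FluorescenceRamp, window: float) -> FluorescenceRamp:
    """Centered moving average over a temperature window (degC).

    window = 0 returns the input unchanged; endpoints average over the
    shrunken part of the window that falls inside the trace.
    """
    if window < 0:
        raise InvalidParameterError("window must be >= 0")
    if window == 0:
        return ramp
    if window > ramp.span / 2.0:
        raise InvalidParameterError("window exceeds half the ramp span")
    t, y = ramp.temperature, ramp.f0
    half = window / 2.0
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right")
    csum = np.concatenate([[0.0], np.cumsum(y)])
    sm = (csum[hi] - csum[lo]) / (hi - lo)
    return FluorescenceRamp(
        temperature=t.copy(), f0=sm, ramp_rate=ramp.ramp_rate,
        genotype=ramp.genotype, night_temp=ramp.night_temp,
        leaf_class=ramp.leaf_class, replicate=ramp.replicate,
    )


def _segment_stats(x, y):
    """Prefix/suffix least-squares line stats for every split, O(n).

    Returns (rss_prefix[k], rss_suffix[k]) where prefix = points [0, k)
    and suffix = points [k, n), plus slope/intercept closures.
    """
    n = x.size
    cx = np.concatenate([[0.0], np.cumsum(x)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cxx = np.concatenate([[0.0], np.cumsum(x * x)])
    cxy = np.concatenate([[0.0], np.cumsum(x * y)])
    cyy = np.concatenate([[0.0], np.cumsum(y * y)])

    def line(i, j):
        """LS line over points [i, j); returns slope, intercept, rss, tss."""
        m = j - i
        sx, sy = cx[j] - cx[i], cy[j] - cy[i]
        sxx, sxy, syy = cxx[j] - cxx[i], cxy[j] - cxy[i], cyy[j] - cyy[i]
        sxx_c = sxx - sx * sx / m
        sxy_c = sxy - sx * sy / m
        syy_c = syy - sy * sy / m
        slope = sxy_c / sxx_c if sxx_c > 0 else 0.0
        intercept = (sy - slope * sx) / m
        rss = max(syy_c - slope * sxy_c, 0.0)
        return slope, intercept, rss, max(syy_c, 0.0)

    return line


def estimate_tcrit(
    ramp: FluorescenceRamp,
    smooth_window: float = DEFAULT_SMOOTH_WINDOW,
    min_segment_frac: float = 0.10,
    min_segment_points: int = 5,
    flat_factor: float = FLAT_FACTOR,
    sigma_factor: float = SIGMA_FACTOR,
    min_rise_sigma: float = 10.0,
    truncate_after_peak: bool = True,
) -> TcritResult:
    """Two-line intersection estimate of T_crit.

    Samples above the F0 maximum are dropped first (the method targets
    the initial rise, not the post-peak decline), the trace is optionally
    smoothed, then every admissible flat/steep boundary is scored by
    total two-segment RSS. The winning pair of lines must show a steep
    slope exceeding ``flat_factor * |flat slope| + sigma_factor * residual
    SD per degC``, otherwise no breakpoint is declared.
    """
    work = smooth_ramp(ramp, smooth_window) if smooth_window > 0 else ramp
    t, y = work.temperature, work.f0
    if truncate_after_peak:
        peak = int(np.argmax(y))
        if peak >= 49:  # keep the ramp-validity minimum
            t, y = t[: peak + 1], y[: peak + 1]
    n = t.size
    m = max(min_segment_points, int(math.ceil(min_segment_frac * n)))
    if n < 2 * m:
        raise InvalidInputError("too few samples for two segments")

    line = _segment_stats(t, y)
    best = None
    for k in range(m, n - m + 1):
        _, _, rss1, _ = line(0, k)
        _, _, rss2, _ = line(k, n)
        tot = rss1 + rss2
        if best is None or tot < best[0]:
            best = (tot, k)
    rss_total, k = best
    s1, b1, rss1, tss1 = line(0, k)
    s2, b2, rss2, tss2 = line(k, n)

    sigma = math.sqrt(rss_total / max(n - 4, 1))
    threshold = flat_factor * abs(s1) + sigma_factor * sigma  # slopes are per degC
    if not (s2 > s1 and s2 > threshold):
        raise NoBreakpointError(
            f"steep slope {s2:.4g} does not exceed flat/noise threshold {threshold:.4g}"
        )
    # guard against noise-born "steep" tails: the total rise over the steep
    # segment must dwarf the residual scatter
    rise = s2 * (t[-1] - t[k])
    if rise < min_rise_sigma * sigma:
        raise NoBreakpointError(
            f"steep-segment rise {rise:.4g} below {min_rise_sigma:g} x residual SD "
            f"({sigma:.4g}); no credible breakpoint"
        )

    tcrit = (b1 - b2) / (s2 - s1)
    in_range = bool(t[0] <= tcrit <= t[-1])
    r2_flat = 1.0 - rss1 / tss1 if tss1 > 0 else 1.0
    r2_steep = 1.0 - rss2 / tss2 if tss2 > 0 else 1.0
    return TcritResult(
        tcrit=float(tcrit),
        flat_slope=float(s1), flat_intercept=float(b1),
        steep_slope=float(s2), steep_intercept=float(b2),
        breakpoint=float(t[k]),
        rss_total=float(rss_total),
        r2_flat=float(r2_flat), r2_steep=float(r2_steep),
        n_flat=int(k), n_steep=int(n - k),
        in_range=in_range,
        genotype=ramp.genotype, night_temp=ramp.night_temp,
        leaf_class=ramp.leaf_class, replicate=ramp.replicate,
    )


def summarize_tcrit(results, by=("genotype", "night_temp", "leaf_class")):
    """Per-cell mean, SD and n of T_crit as a tidy DataFrame."""
    import pandas as pd

    if not results:
        raise InvalidInputError("no T_crit results to summarize")
    rows = [
        {
            "genotype": r.genotype,
            "night_temp": r.night_temp,
            "leaf_class": r.leaf_class,
            "replicate": r.replicate,
            "tcrit": r.tcrit,
        }
        for r in results
    ]
    df = pd.DataFrame(rows)
    keys = [k for k in by if k in df.columns]
    out = (
        df.groupby(keys, dropna=False)["tcrit"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    return out


def tcrit_anova_input(results, by=("genotype", "night_temp")):
    """Group T_crit values for anova_posthoc: {(A, B): values} mapping."""
    groups = {}
    for r in results:
        key = tuple(getattr(r, k) for k in by)
        if len(key) == 1:
            key = key[0]
        groups.setdefault(key, []).append(r.tcrit)
    return groups
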