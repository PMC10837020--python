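"""Ground-truth synthetic data for every pipeline stage.

Generates A-Ci curve sets (forward FvCB model + Gaussian noise),
F0 temperature ramps (flat baseline, linear rise past the true T_crit,
optional post-peak decline), and metabolite tables with class-structured
treatment effects. Every generator takes explicit truth parameters and a
seed, returns the data together with its TruthBook, and is bit-identical
on regeneration with the same seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aci import CI_SEQUENCE, AciCurve
from .errors import InvalidInputError, InvalidParameterError
from .fvcb import PhotoCapacity
from .kinetics import KineticConfig, PeakedParams, celsius_to_kelvin, peaked_arrhenius
from .tcrit import FluorescenceRamp

DEFAULT_GENOTYPES = {
    "1704": "susceptible",
    "1898": "susceptible",
    "2254": "tolerant",
    "Mace": "tolerant",
}

METABOLITE_CLASSES = (
    "monosaccharide",
    "disaccharide",
    "fatty_acid_saturated",
    "fatty_acid_unsaturated",
    "amino_acid",
    "organic_acid",
    "polyol",
    "other",
)


@dataclass
class StudyDesign:
    """Experimental layout shared by all generators."""

    genotypes: dict = field(default_factory=lambda: dict(DEFAULT_GENOTYPES))
    night_temps: tuple = (15.0, 20.0, 25.0)
    leaf_classes: tuple = ("newly developed",)
    replicates_gas: int = 4
    replicates_tcrit: int = 6
    replicates_metab: int = 4
    measurement_temps: tuple = (20.0, 25.0, 30.0, 35.0, 40.0, 50.0)
    ci_sequence: tuple = CI_SEQUENCE
    irradiance: float = 1500.0
    pressure: float = 96.0
    seed: int = 42

    def __post_init__(self):
        for name in ("replicates_gas", "replicates_tcrit", "replicates_metab"):
            if getattr(self, name) < 1:
                raise InvalidParameterError(f"{name} must be >= 1")
        if any(c <= 0 for c in self.ci_sequence):
            raise InvalidParameterError("Ci sequence must be positive")

    def cells(self):
        for g in self.genotypes:
            for nt in self.night_temps:
                for lc in self.leaf_classes:
                    yield g, nt, lc


@dataclass
class CellTruth:
    """True generating parameters for one genotype x night-temp x leaf cell."""

    vcmax: PeakedParams
    j_quad: tuple  # (a, b, c), value = a*T^2 + b*T + c on degC
    tpu_quad: tuple
    rd: float
    tcrit: float  # degC


@dataclass
class TruthBook:
    """Ground truth per design cell plus noise levels and metabolite effects."""

    cells: dict  # (genotype, night_temp, leaf_class) -> CellTruth
    an_sd: float = 0.5  # umol m-2 s-1
    f0_rel_sd: float = 0.01  # fraction of baseline
    metab_log_sd: float = 0.3
    class_effects: dict = field(default_factory=dict)  # class -> fold change at 25C nights
    responsive_genotypes: tuple = ()

    def cell(self, key) -> CellTruth:
        if key not in self.cells:
            raise InvalidInputError(f"truth book has no cell {key!r}")
        return self.cells[key]


def _quad_from_vertex(t_opt, peak, curvature):
    """(a, b, c) of a downward parabola with vertex (t_opt, peak)."""
    a = -abs(curvature)
    b = -2.0 * a * t_opt
    c = peak + a * t_opt**2
    return (a, b, c)


def default_truthbook(
    design: StudyDesign,
    night_effect_ratio: float = 1.3,
    pre_existing_null: bool = True,
) -> TruthBook:
    """Archetype-structured truth for the default four-genotype design.

    Tolerant genotypes raise Vcmax (and J) with warmer nights by
    ``night_effect_ratio`` per 10 degC of night warming; susceptible
    genotypes lower J. Pre-existing leaves carry no night-temperature
    effect when ``pre_existing_null``.
    """
    cells = {}
    base_tcrit = {"tolerant": 43.8, "susceptible": 45.7}
    for g, nt, lc in design.cells():
        arch = design.genotypes[g]
        frac = (nt - min(design.night_temps)) / 10.0
        if lc != "newly developed" and pre_existing_null:
            frac = 0.0
        if arch == "tolerant":
            v_scale = night_effect_ratio**frac
            j_scale = night_effect_ratio ** (0.7 * frac)
        else:
            v_scale = 1.0
            j_scale = (1.0 / night_effect_ratio) ** (0.5 * frac)
        vcmax = PeakedParams(k_ref=150.0 * v_scale, Ea=65.0, dS=0.65, Ed=200.0)
        j_quad = _quad_from_vertex(t_opt=30.0, peak=170.0 * j_scale, curvature=0.12)
        tpu_quad = _quad_from_vertex(t_opt=30.0, peak=12.0, curvature=0.008)
        cells[(g, nt, lc)] = CellTruth(
            vcmax=vcmax, j_quad=j_quad, tpu_quad=tpu_quad, rd=1.0,
            tcrit=base_tcrit[arch],
        )
    return TruthBook(
        cells=cells,
        class_effects={"monosaccharide": 2.0, "fatty_acid_saturated": 1.6},
        responsive_genotypes=tuple(
            g for g, a in design.genotypes.items() if a == "tolerant"
        ),
    )


def capacity_at(truth: CellTruth, t_leaf_c: float) -> PhotoCapacity:
    """Evaluate a cell's true capacity functions at a leaf temperature (degC)."""
    t_k = celsius_to_kelvin(t_leaf_c)
    vc = peaked_arrhenius(truth.vcmax, t_k)
    a, b, c = truth.j_quad
    j = a * t_leaf_c**2 + b * t_leaf_c + c
    a, b, c = truth.tpu_quad
    tpu = a * t_leaf_c**2 + b * t_leaf_c + c
    if j <= 0 or tpu <= 0:
        raise InvalidParameterError(
            f"truth quadratics non-positive at {t_leaf_c} degC (J={j:.3g}, TPU={tpu:.3g})"
        )
    return PhotoCapacity(Vcmax=vc, J=j, TPU=tpu, Rd=truth.rd)


def simulate_aci_dataset(
    design: StudyDesign, truth: TruthBook, cfg: KineticConfig, seed: int | None = None
):
    """One AciCurve per cell x replicate x measurement temperature.

    An = forward FvCB model at the truth capacities + N(0, an_sd).
    Returns (list of AciCurve, TruthBook).
    """
    from .fvcb import net_assimilation
    from .kinetics import to_partial_pressure

    rng = np.random.default_rng(design.seed if seed is None else seed)
    curves = []
    ci = np.array(design.ci_sequence, dtype=float)
    for g, nt, lc in design.cells():
        ct = truth.cell((g, nt, lc))
        for rep in range(1, design.replicates_gas + 1):
            for t_meas in design.measurement_temps:
                cap = capacity_at(ct, t_meas)
                t_k = celsius_to_kelvin(t_meas)
                ci_pa = to_partial_pressure(ci, design.pressure)
                an = np.array(
                    [net_assimilation(float(cp), t_k, cfg, cap)[0] for cp in ci_pa]
                )
                if truth.an_sd > 0:
                    an = an + rng.normal(0.0, truth.an_sd, size=an.size)
                curves.append(
                    AciCurve(
                        ci=ci.copy(), an=an, t_leaf=t_meas,
                        irradiance=design.irradiance, pressure=design.pressure,
                        genotype=g, night_temp=nt, leaf_class=lc,
                        replicate=f"r{rep}",
                    )
                )
    return curves, truth


def simulate_f0_ramps(
    design: StudyDesign,
    truth: TruthBook,
    seed: int | None = None,
    t_start: float = 20.0,
    t_end: float = 65.0,
    samples_per_deg: int = 10,
    baseline: float = 500.0,
    baseline_drift: float = 0.2,  # F0 units per degC on the flat portion
    steep_slope: float = 100.0,  # F0 units per degC past T_crit
    peak_width: float = 10.0,  # degC of rise before the post-peak decline
    decline_slope: float = 30.0,
):
    """F0 ramps: drifting flat baseline, linear rise at the true T_crit.

    Returns (list of FluorescenceRamp, TruthBook). Noise sd is
    ``truth.f0_rel_sd * baseline``; zero gives exactly piecewise-linear
    traces whose two-line intersection is the true T_crit.
    """
    if truth.f0_rel_sd < 0:
        raise InvalidParameterError("noise sd must be >= 0")
    if peak_width <= 0:
        raise InvalidParameterError("steep segment must have positive width")
    rng = np.random.default_rng(design.seed + 1 if seed is None else seed)
    n = int(round((t_end - t_start) * samples_per_deg)) + 1
    t = np.linspace(t_start, t_end, n)
    ramps = []
    for g, nt, lc in design.cells():
        ct = truth.cell((g, nt, lc))
        if not 30.0 < ct.tcrit < 60.0:
            raise InvalidParameterError(f"true T_crit {ct.tcrit} outside (30, 60) degC")
        for rep in range(1, design.replicates_tcrit + 1):
            flat = baseline + baseline_drift * (t - t_start)
            f_at_tc = baseline + baseline_drift * (ct.tcrit - t_start)
            rise = f_at_tc + steep_slope * (t - ct.tcrit)
            t_peak = ct.tcrit + peak_width
            f_peak = f_at_tc + steep_slope * peak_width
            post = f_peak - decline_slope * (t - t_peak)
            f0 = np.where(t <= ct.tcrit, flat, np.where(t <= t_peak, rise, post))
            if truth.f0_rel_sd > 0:
                f0 = f0 + rng.normal(0.0, truth.f0_rel_sd * baseline, size=n)
            f0 = np.maximum(f0, 1e-6)
            ramps.append(
                FluorescenceRamp(
                    temperature=t.copy(), f0=f0, ramp_rate=1.0,
                    genotype=g, night_temp=nt, leaf_class=lc, replicate=f"r{rep}",
                )
            )
    return ramps, truth


def simulate_metabolite_table(
    design: StudyDesign,
    truth: TruthBook,
    n_compounds: int = 162,
    seed: int | None = None,
    leaf_class: str = "newly developed",
    effect_night: float = 25.0,
):
    """Samples x compounds table with planted class-level effects.

    Compound base abundances are log-normal; the classes named in
    ``truth.class_effects`` are multiplied by their fold change in
    ``responsive_genotypes`` at the ``effect_night`` treatment. Nuisance
    internal-standard and fresh-mass variation is layered on so that
    :func:`normalize_abundance` inverts it. Returns
    (MetaboliteTable, TruthBook).
    """
    from .metabolomics import MetaboliteTable

    for cls in truth.class_effects:
        if cls not in METABOLITE_CLASSES:
            raise InvalidInputError(f"effect specified for unknown class {cls!r}")
    rng = np.random.default_rng(design.seed + 2 if seed is None else seed)

    # deterministic class assignment: cycle through classes
    classes = [METABOLITE_CLASSES[i % len(METABOLITE_CLASSES)] for i in range(n_compounds)]
    compounds = [f"m{i+1:03d}" for i in range(n_compounds)]
    base = rng.lognormal(mean=8.0, sigma=1.0, size=n_compounds)

    rows, meta_rows, istd, mass = [], [], [], []
    sample_ids = []
    for g in design.genotypes:
        for nt in design.night_temps:
            for rep in range(1, design.replicates_metab + 1):
                sid = f"{g}_n{int(nt)}_r{rep}"
                sample_ids.append(sid)
                effect = np.ones(n_compounds)
                if g in truth.responsive_genotypes and nt == effect_night:
                    for i, cls in enumerate(classes):
                        if cls in truth.class_effects:
                            effect[i] = truth.class_effects[cls]
                signal = base * effect * rng.lognormal(
                    mean=0.0, sigma=truth.metab_log_sd, size=n_compounds
                )
                s_istd = rng.lognormal(mean=0.0, sigma=0.1)
                s_mass = rng.uniform(0.08, 0.12)
                # nuisance layered multiplicatively; normalize_abundance divides it out
                raw = signal * s_istd * s_mass
                rows.append(raw)
                istd.append(s_istd)
                mass.append(s_mass)
                meta_rows.append(
                    {"genotype": g, "night_temp": nt, "leaf_class": leaf_class,
                     "replicate": f"r{rep}"}
                )

    ab = pd.DataFrame(rows, index=sample_ids, columns=compounds)
    # istd nuisance enters relative to its batch mean, matching the chain
    istd_s = pd.Series(istd, index=sample_ids, name="istd_signal")
    istd_s = istd_s / istd_s.mean()
    mass_s = pd.Series(mass, index=sample_ids, name="fresh_mass")
    cls_s = pd.Series(classes, index=compounds, name="compound_class")
    meta = pd.DataFrame(meta_rows, index=sample_ids)
    table = MetaboliteTable(
        abundances=ab, istd_signal=istd_s, fresh_mass=mass_s,
        compound_class=cls_s, sample_meta=meta,
    )
    return table, truth


def null_truthbook(design: StudyDesign, **kwargs) -> TruthBook:
    """Truth with zero planted effects everywhere (type-I calibration input)."""
    tb = default_truthbook(design)
    tb = copy.deepcopy(tb)
    tb.class_effects = {}
    tb.responsive_genotypes = ()
    for k, v in kwargs.items():
        setattr(tb, k, v)
    return tb
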