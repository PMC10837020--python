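"""CSV readers/writers and the end-to-end pipeline runner.

All tabular I/O is plain CSV (comma, UTF-8, '.' decimal). Units at file
boundaries follow instrument conventions: Ci in umol mol-1, An in
umol m-2 s-1, temperatures in degC, pressure in kPa.
"""

from __future__ import annotations

import json
import logging
import os
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from . import __version__
from .aci import AciCurve, AciFitResult, fit_aci, pool_fits, series_from_fits, standardize_capacity
from .errors import ConfigurationError, SchemaError
from .kinetics import KineticConfig, load_default_config
from .tcrit import FluorescenceRamp, TcritResult, estimate_tcrit, summarize_tcrit

log = logging.getLogger("photothermal")

#: Column aliases for LI-6400-style gas-exchange exports (case-insensitive).
GAS_EXCHANGE_ALIASES = {
    "ci": ["ci"],
    "an": ["an", "photo", "a"],
    "t_leaf": ["t_leaf", "tleaf", "tl"],
    "irradiance": ["irradiance", "pari", "qin", "par"],
    "pressure": ["pressure", "press", "patm"],
}

META_COLUMNS = ["genotype", "night_temp", "leaf_class", "replicate", "curve_id"]


def _resolve_columns(columns, column_map=None):
    """Map canonical names to actual CSV headers, honoring user overrides."""
    lower = {c.lower(): c for c in columns}
    resolved = {}
    custom = {k.lower(): v for k, v in (column_map or {}).items()}
    for canon, aliases in GAS_EXCHANGE_ALIASES.items():
        if canon in custom:
            cand = custom[canon]
            if cand not in columns:
                raise SchemaError(f"mapped column {cand!r} for {canon!r} absent", columns)
            resolved[canon] = cand
            continue
        for a in aliases:
            if a in lower:
                resolved[canon] = lower[a]
                break
        else:
            raise SchemaError(f"cannot resolve required column {canon!r}", columns)
    return resolved


def read_gas_exchange(path, column_map=None):
    """Read a gas-exchange CSV into a list of AciCurve.

    Rows are grouped by curve: an explicit ``curve_id`` column if present,
    otherwise (genotype, night_temp, leaf_class, replicate, rounded
    T_leaf). Non-numeric or out-of-range rows are excluded and counted in
    the log.
    """
    df = pd.read_csv(path)
    resolved = _resolve_columns(df.columns, column_map)
    n_before = len(df)
    for canon, col in resolved.items():
        df[canon] = pd.to_numeric(df[col], errors="coerce")
    df = df.dropna(subset=list(resolved))
    # unit sanity: Ci in umol mol-1, An plausible leaf rates
    df = df[(df["ci"] > 0) & (df["ci"] < 5000) & (df["an"].abs() < 150)]
    n_excluded = n_before - len(df)
    if n_excluded:
        log.warning("excluded %d unusable row(s) from %s", n_excluded, path)

    if "curve_id" in df.columns:
        keys = ["curve_id"]
    else:
        df["_tround"] = df["t_leaf"].round(0)
        keys = [c for c in ("genotype", "night_temp", "leaf_class", "replicate") if c in df.columns]
        keys.append("_tround")

    curves = []
    for _, sub in df.groupby(keys, dropna=False, sort=False):
        curves.append(
            AciCurve(
                ci=sub["ci"].to_numpy(),
                an=sub["an"].to_numpy(),
                t_leaf=sub["t_leaf"].to_numpy(),
                irradiance=sub["irradiance"].to_numpy(),
                pressure=sub["pressure"].to_numpy(),
                genotype=str(sub["genotype"].iloc[0]) if "genotype" in sub else "",
                night_temp=float(sub["night_temp"].iloc[0]) if "night_temp" in sub else float("nan"),
                leaf_class=str(sub["leaf_class"].iloc[0]) if "leaf_class" in sub else "newly developed",
                replicate=str(sub["replicate"].iloc[0]) if "replicate" in sub else "",
            )
        )
    return curves


def write_gas_exchange(curves, path):
    """Write AciCurves as one long CSV (round-trips through read_gas_exchange)."""
    rows = []
    for i, c in enumerate(curves):
        cid = f"c{i:05d}"
        for j in range(c.n_obs):
            rows.append(
                {
                    "curve_id": cid,
                    "genotype": c.genotype,
                    "night_temp": c.night_temp,
                    "leaf_class": c.leaf_class,
                    "replicate": c.replicate,
                    "Ci": repr(float(c.ci[j])),
                    "An": repr(float(c.an[j])),
                    "Tleaf": repr(float(c.t_leaf[j])),
                    "PARi": repr(float(c.irradiance[j])),
                    "Press": repr(float(c.pressure[j])),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_fits(fits, path):
    """Tidy CSV: one row per curve x parameter with estimate, se, flags."""
    rows = []
    for i, f in enumerate(fits):
        for trait in ("Vcmax", "J", "TPU", "Rd"):
            rows.append(
                {
                    "fit_id": f"f{i:05d}",
                    "genotype": f.genotype,
                    "night_temp": f.night_temp,
                    "leaf_class": f.leaf_class,
                    "replicate": f.replicate,
                    "t_leaf": f.t_leaf,
                    "parameter": trait,
                    "estimate": getattr(f.cap, trait),
                    "se": f.se.get(trait, float("nan")),
                    "estimate_std": getattr(f.cap_std, trait) if f.cap_std else float("nan"),
                    "std_temp": f.std_temp if f.std_temp is not None else float("nan"),
                    "rss": f.rss,
                    "converged": f.converged,
                    "tpu_identifiable": f.tpu_identifiable,
                    "n_used": f.n_used,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_ramps(path):
    """Read long-format ramp CSV (temperature, F0, replicate metadata)."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    for req in ("temperature", "f0"):
        if req not in cols:
            raise SchemaError(f"ramp CSV needs a {req!r} column", df.columns)
    keys = [c for c in ("genotype", "night_temp", "leaf_class", "replicate", "ramp_id")
            if c in df.columns]
    ramps = []
    grouped = df.groupby(keys, dropna=False, sort=False) if keys else [((), df)]
    for _, sub in grouped:
        sub = sub.sort_values(cols["temperature"])
        ramps.append(
            FluorescenceRamp(
                temperature=sub[cols["temperature"]].to_numpy(dtype=float),
                f0=sub[cols["f0"]].to_numpy(dtype=float),
                genotype=str(sub["genotype"].iloc[0]) if "genotype" in sub else "",
                night_temp=float(sub["night_temp"].iloc[0]) if "night_temp" in sub else float("nan"),
                leaf_class=str(sub["leaf_class"].iloc[0]) if "leaf_class" in sub else "newly developed",
                replicate=str(sub["replicate"].iloc[0]) if "replicate" in sub else "",
            )
        )
    return ramps


def write_ramps(ramps, path):
    rows = []
    for i, r in enumerate(ramps):
        for j in range(r.temperature.size):
            rows.append(
                {
                    "ramp_id": f"t{i:05d}",
                    "genotype": r.genotype,
                    "night_temp": r.night_temp,
                    "leaf_class": r.leaf_class,
                    "replicate": r.replicate,
                    "temperature": repr(float(r.temperature[j])),
                    "F0": repr(float(r.f0[j])),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_metabolites(path, classes_path=None):
    """Read a wide metabolite CSV: sample rows, compound columns.

    Reserved columns: sample_id, genotype, night_temp, leaf_class,
    replicate, istd_signal, fresh_mass. ``classes_path`` is a two-column
    compound,class CSV.
    """
    from .metabolomics import MetaboliteTable

    df = pd.read_csv(path)
    if "sample_id" in df.columns:
        df = df.set_index("sample_id")
    reserved = ["genotype", "night_temp", "leaf_class", "replicate", "istd_signal", "fresh_mass"]
    for req in ("istd_signal", "fresh_mass"):
        if req not in df.columns:
            raise SchemaError(f"metabolite CSV needs {req!r}", df.columns)
    meta_cols = [c for c in reserved if c in df.columns]
    compounds = [c for c in df.columns if c not in reserved]
    if classes_path is not None:
        cmap = pd.read_csv(classes_path)
        cls = pd.Series(cmap.iloc[:, 1].to_numpy(), index=cmap.iloc[:, 0].to_numpy())
    else:
        cls = pd.Series("unknown", index=compounds)
    return MetaboliteTable(
        abundances=df[compounds].astype(float),
        istd_signal=df["istd_signal"].astype(float),
        fresh_mass=df["fresh_mass"].astype(float),
        compound_class=cls,
        sample_meta=df[[c for c in meta_cols if c not in ("istd_signal", "fresh_mass")]],
    )


def write_metabolites(table, path, classes_path=None):
    df = table.sample_meta.copy()
    df["istd_signal"] = table.istd_signal
    df["fresh_mass"] = table.fresh_mass
    out = pd.concat([df, table.abundances], axis=1)
    out.index.name = "sample_id"
    out.to_csv(path, float_format="%.12g")
    if classes_path is not None:
        pd.DataFrame(
            {"compound": table.compound_class.index, "class": table.compound_class.to_numpy()}
        ).to_csv(classes_path, index=False)


# --------------------------------------------------------------------------
# Pipeline


@dataclass
class PipelineConfig:
    """Configuration of the end-to-end run."""

    out_dir: str
    gas_exchange_path: str | None = None
    ramps_path: str | None = None
    metabolites_path: str | None = None
    classes_path: str | None = None
    kinetic_config: str = "wheat_default"
    std_temp: float = 28.0
    alpha: float = 0.05
    seed: int = 42
    n_perm: int = 999
    run_aci: bool = True
    run_tcrit: bool = True
    run_metabolomics: bool = True
    simulate_missing: bool = True
    design_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 < self.std_temp < 60.0:
            raise ConfigurationError("std_temp must be in (0, 60) degC")


def _load_kcfg(name_or_path) -> KineticConfig:
    if os.path.exists(str(name_or_path)):
        return KineticConfig.from_file(name_or_path)
    return load_default_config(str(name_or_path))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages and write a manifest beside outputs.

    Missing inputs are synthesized from the default study design when
    ``simulate_missing`` (so a bare `photothermal run` demonstrates the
    whole chain). Returns the manifest dict.
    """
    from .metabolomics import normalize_abundance, pca_decompose, permanova
    from .simulate import StudyDesign, default_truthbook, simulate_aci_dataset, \
        simulate_f0_ramps, simulate_metabolite_table
    from .thermal import anova_posthoc, compare_regressions, fit_peaked, fit_quadratic, \
        TRAIT_MODELS
    from .tcrit import tcrit_anova_input

    os.makedirs(cfg.out_dir, exist_ok=True)
    kcfg = _load_kcfg(cfg.kinetic_config)
    manifest = {
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": cfg.seed,
        "alpha": cfg.alpha,
        "std_temp": cfg.std_temp,
        "n_perm": cfg.n_perm,
        "Ed_fixed_kJ_mol": 200.0,
        "kinetics": kcfg.to_dict(),
        "stages": {},
    }
    design = StudyDesign(**{"seed": cfg.seed, **cfg.design_overrides})
    truth = default_truthbook(design)

    try:
        if cfg.run_aci:
            if cfg.gas_exchange_path:
                curves = read_gas_exchange(cfg.gas_exchange_path)
            elif cfg.simulate_missing:
                curves, _ = simulate_aci_dataset(design, truth, kcfg)
            else:
                raise ConfigurationError("no gas-exchange input and simulation disabled")
            fits = []
            scaling = {"Vcmax": 65.0, "J": 30.0, "TPU": 30.0}
            for c in curves:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    f = fit_aci(c, kcfg)
                f.cap_std = standardize_capacity(f, f.t_leaf, cfg.std_temp, scaling)
                f.std_temp = cfg.std_temp
                fits.append(f)
            write_fits(fits, os.path.join(cfg.out_dir, "aci_fits.csv"))
            pooled = pool_fits(fits)
            pooled.to_csv(os.path.join(cfg.out_dir, "capacity_by_cell.csv"), index=False)

            # thermal responses per genotype x treatment
            t2_rows = []
            for trait in ("Vcmax", "J", "TPU"):
                series = series_from_fits(fits, trait)
                for key, s in series.items():
                    model = TRAIT_MODELS.get("J1500" if trait == "J" else trait, "quadratic")
                    try:
                        if model == "peaked":
                            pf = fit_peaked(s)
                            row = {"t_opt": pf.t_opt, "value_at_topt": pf.value_at_topt,
                                   "model": "peaked", "converged": pf.converged, "flag": pf.flag}
                        else:
                            qf = fit_quadratic(s)
                            row = {"t_opt": qf.t_opt, "value_at_topt": qf.value_at_topt,
                                   "model": "quadratic", "converged": True, "flag": qf.flag}
                    except Exception as e:  # noqa: BLE001 - report, don't halt
                        row = {"t_opt": float("nan"), "value_at_topt": float("nan"),
                               "model": model, "converged": False, "flag": str(e)}
                    row.update(
                        trait=trait, genotype=key[0], night_temp=key[1], leaf_class=key[2]
                    )
                    t2_rows.append(row)
            pd.DataFrame(t2_rows).to_csv(
                os.path.join(cfg.out_dir, "thermal_optima.csv"), index=False
            )

            # comparative regression of Vcmax series across night temps, per genotype
            sel_rows = []
            series = series_from_fits(fits, "Vcmax")
            for g in {k[0] for k in series}:
                per_nt = {k[1]: s for k, s in series.items() if k[0] == g}
                if len(per_nt) >= 2:
                    rep = compare_regressions(per_nt, alpha=cfg.alpha)
                    sel_rows.append(
                        {"genotype": g, "selected": rep["selected"],
                         "F_M1_vs_M0": rep["tests"]["M1_vs_M0"]["F"],
                         "p_M1_vs_M0": rep["tests"]["M1_vs_M0"]["p"],
                         "F_M2_vs_M1": rep["tests"]["M2_vs_M1"]["F"],
                         "p_M2_vs_M1": rep["tests"]["M2_vs_M1"]["p"]}
                    )
            pd.DataFrame(sel_rows).to_csv(
                os.path.join(cfg.out_dir, "regression_selection.csv"), index=False
            )
            manifest["stages"]["aci"] = {"status": "complete", "n_curves": len(curves)}
        else:
            manifest["stages"]["aci"] = {"status": "skipped"}

        if cfg.run_tcrit:
            if cfg.ramps_path:
                ramps = read_ramps(cfg.ramps_path)
            elif cfg.simulate_missing:
                ramps, _ = simulate_f0_ramps(design, truth)
            else:
                raise ConfigurationError("no ramp input and simulation disabled")
            results = [estimate_tcrit(r) for r in ramps]
            summary = summarize_tcrit(results)
            summary.to_csv(os.path.join(cfg.out_dir, "tcrit_summary.csv"), index=False)
            groups = tcrit_anova_input(results)
            if len(groups) >= 2 and min(len(v) for v in groups.values()) >= 2:
                aov = anova_posthoc(groups, method="HSD", alpha=cfg.alpha)
                pd.DataFrame(aov["table"]).to_csv(
                    os.path.join(cfg.out_dir, "tcrit_anova.csv"), index=False
                )
            manifest["stages"]["tcrit"] = {"status": "complete", "n_ramps": len(ramps)}
        else:
            manifest["stages"]["tcrit"] = {"status": "skipped"}

        if cfg.run_metabolomics:
            if cfg.metabolites_path:
                table = read_metabolites(cfg.metabolites_path, cfg.classes_path)
            elif cfg.simulate_missing:
                table, _ = simulate_metabolite_table(design, truth)
            else:
                raise ConfigurationError("no metabolite input and simulation disabled")
            norm = normalize_abundance(table)
            norm.abundances.to_csv(os.path.join(cfg.out_dir, "metabolites_normalized.csv"))
            scores, loadings, ev = pca_decompose(norm, n_components=min(5, norm.n_samples - 1))
            scores.to_csv(os.path.join(cfg.out_dir, "pca_scores.csv"))
            loadings.to_csv(os.path.join(cfg.out_dir, "pca_loadings.csv"))
            perm = permanova(
                norm, ["genotype", "night_temp"], n_perm=cfg.n_perm, seed=cfg.seed
            )
            perm.to_csv(os.path.join(cfg.out_dir, "permanova.csv"), index=False)
            manifest["stages"]["metabolomics"] = {
                "status": "complete",
                "n_samples": norm.n_samples,
                "n_compounds": norm.n_compounds,
                "pc1_explained": float(ev[0]) if len(ev) else float("nan"),
            }
        else:
            manifest["stages"]["metabolomics"] = {"status": "skipped"}
    finally:
        with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return manifest
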