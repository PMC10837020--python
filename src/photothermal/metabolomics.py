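"""Metabolite-table normalization, PCA, and permutation MANOVA.

Normalization chain: divide each sample's signals by its internal-standard
signal relative to the batch mean, divide by the sample's fresh mass,
then weight each compound by its across-sample average so every compound
has mean 1 — the scale on which PCA and group statistics run.

The permutational multivariate ANOVA partitions squared Euclidean
distances on the (optionally per-compound autoscaled) matrix; the
pseudo-F reduces exactly to the classic one-way ANOVA F for a univariate
response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidInputError, InvalidParameterError

DEFAULT_N_PERM = 999
DEFAULT_SEED = 2254


@dataclass
class MetaboliteTable:
    """Samples x compounds abundance matrix with nuisance metadata.

    ``abundances``: DataFrame indexed by sample id, columns = compounds.
    ``istd_signal`` and ``fresh_mass``: per-sample Series aligned to the
    abundance index. ``compound_class``: compound -> class label Series.
    ``sample_meta``: per-sample DataFrame (genotype, night_temp, ...).
    """

    abundances: pd.DataFrame
    istd_signal: pd.Series
    fresh_mass: pd.Series
    compound_class: pd.Series
    sample_meta: pd.DataFrame
    normalized: bool = False
    n_imputed: int = 0
    dropped_compounds: list = field(default_factory=list)

    def __post_init__(self):
        idx = self.abundances.index
        for name, s in (("istd_signal", self.istd_signal), ("fresh_mass", self.fresh_mass)):
            s = s.reindex(idx)
            if s.isna().any():
                raise InvalidInputError(f"{name} missing for some samples")
            if (s <= 0).any():
                raise InvalidInputError(f"{name} must be > 0")
            setattr(self, name, s.astype(float))
        self.sample_meta = self.sample_meta.reindex(idx)
        missing = set(self.abundances.columns) - set(self.compound_class.index)
        if missing:
            # permit unannotated compounds but give them an explicit class
            extra = pd.Series("unknown", index=sorted(missing))
            self.compound_class = pd.concat([self.compound_class, extra])
        vals = self.abundances.to_numpy(dtype=float)
        if np.nanmin(vals) < 0:
            raise InvalidInputError("abundances must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(self.abundances.shape[0])

    @property
    def n_compounds(self) -> int:
        return int(self.abundances.shape[1])


def normalize_abundance(raw: MetaboliteTable) -> MetaboliteTable:
    """Apply the istd -> fresh-mass -> average-signal normalization chain.

    Missing values are imputed as half the compound's minimum observed
    abundance first (count reported on the result). All-zero compounds
    are dropped with a warning rather than dividing by zero. After the
    final weighting every retained compound has across-sample mean 1.
    """
    ab = raw.abundances.astype(float).copy()

    n_imputed = int(ab.isna().to_numpy().sum())
    if n_imputed:
        half_min = ab.min(axis=0, skipna=True) / 2.0
        ab = ab.fillna(half_min)

    istd_rel = raw.istd_signal / raw.istd_signal.mean()
    ab = ab.div(istd_rel, axis=0).div(raw.fresh_mass, axis=0)

    col_means = ab.mean(axis=0)
    dead = list(col_means.index[col_means <= 0])
    if dead:
        warnings.warn(f"dropping {len(dead)} all-zero compound(s): {dead[:5]}...")
        ab = ab.drop(columns=dead)
        col_means = col_means.drop(dead)
    ab = ab.div(col_means, axis=1)

    return MetaboliteTable(
        abundances=ab,
        istd_signal=raw.istd_signal.copy(),
        fresh_mass=raw.fresh_mass.copy(),
        compound_class=raw.compound_class.copy(),
        sample_meta=raw.sample_meta.copy(),
        normalized=True,
        n_imputed=n_imputed,
        dropped_compounds=dead,
    )


def pca_decompose(table: MetaboliteTable, n_components: int | None = None, scale: bool = False):
    """Centered (optionally unit-variance) PCA by singular value decomposition.

    Returns (scores DataFrame, loadings DataFrame, explained-variance
    fractions). Loadings are orthonormal columns.
    """
    X = table.abundances.to_numpy(dtype=float)
    n, p = X.shape
    if n < 3 or p < 2:
        raise InsufficientDataError("PCA needs >=3 samples and >=2 compounds")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    rank = int(np.linalg.matrix_rank(Xc))
    if n_components is None:
        n_components = rank
    elif n_components > rank:
        warnings.warn(f"requested {n_components} components; rank is {rank} — truncating")
        n_components = rank
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = float((S**2).sum())
    k = n_components
    scores = U[:, :k] * S[:k]
    explained = (S[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    cols = [f"PC{i+1}" for i in range(k)]
    scores_df = pd.DataFrame(scores, index=table.abundances.index, columns=cols)
    loadings_df = pd.DataFrame(Vt[:k].T, index=table.abundances.columns, columns=cols)
    return scores_df, loadings_df, explained


def _projection(X):
    """Hat-matrix projector onto the column space of X (rank-safe)."""
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    tol = max(X.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    U = U[:, s > tol]
    return U @ U.T


def _dummies(labels):
    labels = np.asarray(labels)
    levels = sorted(set(labels.tolist()), key=str)
    D = np.zeros((labels.size, len(levels)))
    for j, lev in enumerate(levels):
        D[:, j] = labels == lev
    return D, levels


def permanova(
    table: MetaboliteTable,
    factors,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = DEFAULT_SEED,
    autoscale: bool = True,
    interaction: bool = True,
) -> pd.DataFrame:
    """Permutation multivariate ANOVA on squared Euclidean distances.

    ``factors`` is a list of 1 or 2 column names in ``sample_meta``.
    Sums of squares are sequential (order as given; orthogonal and hence
    order-free for balanced designs). Main-effect p-values come from free
    permutation of sample rows; the interaction p-value from permutation
    of residuals under the main-effects model (an approximation, flagged
    in the output). p = (#{F_perm >= F_obs} + 1) / (n_perm + 1).
    """
    if n_perm < 99:
        raise InvalidParameterError("n_perm must be >= 99")
    factors = list(factors)
    if not 1 <= len(factors) <= 2:
        raise InvalidParameterError("permanova supports 1 or 2 factors")
    meta = table.sample_meta
    for f in factors:
        if f not in meta.columns:
            raise InvalidInputError(f"factor {f!r} not in sample metadata")
        counts = meta[f].value_counts()
        if (counts < 2).any():
            warnings.warn(
                f"factor {f!r} has singleton level(s); interaction testing disabled"
            )
            interaction = False
        if counts.size < 2:
            raise InsufficientDataError(f"factor {f!r} needs >=2 levels")

    Y = table.abundances.to_numpy(dtype=float)
    Y = Y - Y.mean(axis=0)
    if autoscale:
        sd = Y.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Y = Y / sd
    n = Y.shape[0]

    terms = []  # (name, projector-increment pair)
    ones = np.ones((n, 1))
    Xs = [ones]
    for f in factors:
        D, _ = _dummies(meta[f].to_numpy())
        Xs.append(D)
        terms.append(("x".join([f]), len(Xs) - 1))
    do_inter = interaction and len(factors) == 2
    if do_inter:
        D1, _ = _dummies(meta[factors[0]].to_numpy())
        D2, _ = _dummies(meta[factors[1]].to_numpy())
        inter = np.einsum("ij,ik->ijk", D1, D2).reshape(n, -1)
        Xs.append(inter)
        terms.append((f"{factors[0]}:{factors[1]}", len(Xs) - 1))

    # cumulative projectors P_0 (mean), P_1, ..., P_full
    projs = []
    for j in range(1, len(Xs) + 1):
        projs.append(_projection(np.hstack(Xs[:j])))

    def term_stats(Ymat):
        tot = float((Ymat * Ymat).sum())
        fitted_ss = [float(np.sum((P @ Ymat) * Ymat)) for P in projs]
        ss_terms = [fitted_ss[i + 1] - fitted_ss[i] for i in range(len(projs) - 1)]
        ss_resid = tot - fitted_ss[-1]
        return ss_terms, ss_resid, tot

    dfs = []
    for j in range(1, len(Xs)):
        r_full = np.linalg.matrix_rank(np.hstack(Xs[: j + 1]))
        r_red = np.linalg.matrix_rank(np.hstack(Xs[:j]))
        dfs.append(int(r_full - r_red))
    df_resid = n - int(np.linalg.matrix_rank(np.hstack(Xs)))
    if df_resid <= 0:
        raise InsufficientDataError("no residual degrees of freedom")

    ss_terms, ss_resid, ss_total = term_stats(Y)
    ms_resid = ss_resid / df_resid

    def pseudo_f(ss, df):
        if df == 0:
            return float("nan")
        if ms_resid <= 1e-300:
            return 0.0 if ss <= 1e-300 else float("inf")
        return (ss / df) / ms_resid

    f_obs = [pseudo_f(ss, df) for ss, df in zip(ss_terms, dfs)]

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    n_main = len(factors)
    P_main = projs[n_main]  # projector of the main-effects (reduced) model
    resid_red = Y - P_main @ Y
    fitted_red = P_main @ Y
    for _ in range(n_perm):
        perm = rng.permutation(n)
        ssp, ssr, _ = term_stats(Y[perm])
        msr = ssr / df_resid
        for i in range(n_main):
            fp = (ssp[i] / dfs[i]) / msr if msr > 1e-300 else (
                0.0 if ssp[i] <= 1e-300 else float("inf")
            )
            if fp >= f_obs[i] - 1e-12:
                exceed[i] += 1
        if do_inter:
            Yr = fitted_red + resid_red[rng.permutation(n)]
            ssp2, ssr2, _ = term_stats(Yr)
            msr2 = ssr2 / df_resid
            i = n_main
            fp = (ssp2[i] / dfs[i]) / msr2 if msr2 > 1e-300 else (
                0.0 if ssp2[i] <= 1e-300 else float("inf")
            )
            if fp >= f_obs[i] - 1e-12:
                exceed[i] += 1

    pvals = (exceed + 1.0) / (n_perm + 1.0)
    rows = []
    for (name, _), ss, df, f, p in zip(terms, ss_terms, dfs, f_obs, pvals):
        rows.append(
            {"term": name, "SS": ss, "df": df, "pseudo_F": f, "p_perm": float(p),
             "note": "residual-permutation approximation" if ":" in name else ""}
        )
    rows.append(
        {"term": "residual", "SS": ss_resid, "df": df_resid,
         "pseudo_F": float("nan"), "p_perm": float("nan"), "note": ""}
    )
    rows.append(
        {"term": "total", "SS": ss_total, "df": n - 1,
         "pseudo_F": float("nan"), "p_perm": float("nan"), "note": ""}
    )
    return pd.DataFrame(rows)


def responsive_metabolites(
    table: MetaboliteTable,
    factor: str = "night_temp",
    level_hi=25,
    level_lo=15,
    genotype_col: str = "genotype",
    genotypes=None,
) -> pd.DataFrame:
    """Rank compounds by log2 fold-change between two treatment levels.

    Per genotype, lfc = log2(mean at ``level_hi`` / mean at ``level_lo``).
    A compound is flagged consistent when its lfc has the same sign (and
    is nonzero) across all included genotypes. Genotypes missing either
    level are excluded with a warning. Class labels are carried through.
    """
    meta = table.sample_meta
    if genotypes is None:
        genotypes = sorted(meta[genotype_col].dropna().unique().tolist(), key=str)
    usable = []
    for g in genotypes:
        sub = meta[meta[genotype_col] == g]
        levels = set(sub[factor].tolist())
        if level_hi in levels and level_lo in levels:
            usable.append(g)
        else:
            warnings.warn(f"genotype {g!r} lacks one contrast level; excluded")
    if not usable:
        raise InsufficientDataError("no genotype has both contrast levels")

    eps = 1e-12
    lfc = {}
    for g in usable:
        hi_idx = meta.index[(meta[genotype_col] == g) & (meta[factor] == level_hi)]
        lo_idx = meta.index[(meta[genotype_col] == g) & (meta[factor] == level_lo)]
        mu_hi = table.abundances.loc[hi_idx].mean(axis=0)
        mu_lo = table.abundances.loc[lo_idx].mean(axis=0)
        lfc[g] = np.log2((mu_hi + eps) / (mu_lo + eps))
    lfc_df = pd.DataFrame(lfc)
    mean_lfc = lfc_df.mean(axis=1)
    arr = lfc_df.to_numpy()
    signs = np.sign(np.where(np.abs(arr) <= 1e-9, 0.0, arr))  # exact-zero lfc: no sign
    consistent = (np.abs(signs).min(axis=1) > 0) & (np.ptp(signs, axis=1) == 0)

    out = pd.DataFrame(
        {
            "compound": lfc_df.index,
            "class": table.compound_class.reindex(lfc_df.index).to_numpy(),
            "mean_log2fc": mean_lfc.to_numpy(),
            "consistent": consistent,
            "direction": np.where(mean_lfc > 0, "up", np.where(mean_lfc < 0, "down", "none")),
        }
    )
    for g in usable:
        out[f"log2fc_{g}"] = lfc_df[g].to_numpy()
    out = out.sort_values("mean_log2fc", key=np.abs, ascending=False).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
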