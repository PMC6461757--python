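"""Abundance–environment association statistics for clade count matrices.

Counts are first scaled by library size with the median-of-ratios method,
then each clade is regressed on each metadata variable *separately* with a
negative-binomial (NB) log-link GLM. The NB dispersion ``alpha``
(Var = mu + alpha mu^2) is chosen per fit by minimising the AIC
(2k − 2·log-likelihood, alpha counted as one parameter) over log-alpha; for
categorical variables the reference (treatment coding) or omitted level
(sum-to-zero coding) is likewise chosen by AIC. Significance is assessed by
Wald tests — a block test for the variable, z-tests per coefficient — with
Benjamini–Hochberg correction across clades, accepting variables at
adjusted p < 0.1 and coefficients at adjusted p < 0.05. Seasonal
time-series are modelled with an NB GAM: an unpenalised cubic regression
spline of time whose degrees of freedom (3–9) are selected jointly with
alpha by AIC.

Model fitting itself is delegated to statsmodels; design-matrix coding,
the AIC searches, the screening logic and the spline basis are local.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.interpolate import BSpline
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

ALPHA_BOUNDS = (1e-6, 1e3)
BH_VARIABLE_THRESHOLD = 0.1
BH_COEFFICIENT_THRESHOLD = 0.05
GAM_DF_RANGE = (3, 9)

#: the five single-copy ribosomal genes used for copy-number normalisation
SINGLE_COPY_RIBOSOMAL_GENES = ("S4", "S15", "S24e", "S27ae", "L21")


@dataclass
class AbundanceDataset:
    """Clade × sample counts with per-sample metadata and size factors."""

    counts: pd.DataFrame  # clades as rows, samples as columns
    metadata: pd.DataFrame  # samples as rows
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        missing = [s for s in self.counts.columns if s not in self.metadata.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing[:5]}")

    @property
    def scaled_counts(self) -> pd.DataFrame:
        if self.size_factors is None:
            return self.counts.astype(float)
        return self.counts / self.size_factors


@dataclass
class GLMFit:
    """One NB GLM of a clade's scaled counts on one metadata variable."""

    clade: str
    variable: str
    coding: str  # numeric | treatment | sum_to_zero
    reference_level: str | None
    params: pd.Series
    bse: pd.Series
    wald_p: pd.Series  # per-coefficient (non-intercept)
    block_p: float  # Wald test of the whole variable
    alpha: float
    aic: float
    converged: bool = True


@dataclass
class GAMFit:
    """An NB cubic-regression-spline fit of one clade's time series."""

    clade: str
    spline_df: int
    alpha: float
    aic: float
    time: np.ndarray
    fitted: np.ndarray  # expected counts
    lower: np.ndarray  # pointwise Wald band, response scale
    upper: np.ndarray
    significant_vs_baseline: bool
    converged: bool = True


def scale_by_library_size(
    counts: pd.DataFrame, reference: pd.Series | None = None
) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors and scaled counts.

    The reference pseudo-sample is the per-clade geometric mean across
    samples (or a fixed ``reference`` series); each sample's factor is the
    median over clades of count/reference, using only clades nonzero in
    every sample. Raises if no clade is nonzero everywhere (add a
    pseudo-count or drop sparse clades first).
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples to scale")
    mat = counts.to_numpy(dtype=float)
    if reference is None:
        with np.errstate(divide="ignore"):
            log_ref = np.mean(np.log(mat), axis=1)
        ref = np.exp(log_ref)
    else:
        ref = reference.reindex(counts.index).to_numpy(dtype=float)
    usable = np.isfinite(ref) & (ref > 0) & (mat > 0).all(axis=1)
    if not usable.any():
        raise ValueError(
            "no clade is nonzero in every sample; add a pseudo-count or "
            "restrict to prevalent clades before scaling"
        )
    ratios = mat[usable] / ref[usable, None]
    factors = pd.Series(np.median(ratios, axis=0), index=counts.columns, name="size_factor")
    return factors, counts / factors


def exclude_sparse_samples(
    counts: pd.DataFrame, min_fraction: float = 0.05
) -> pd.DataFrame:
    """Drop samples whose share of mapped reads is far below uniform.

    A sample is kept when its share of the total mapped reads is at least
    ``min_fraction`` of the uniform per-sample expectation (1/n samples) —
    i.e. at 5% a sample carrying under one-twentieth of its fair share of
    the data is excluded.
    """
    if not 0.0 < min_fraction < 1.0:
        raise ValueError("min_fraction must lie in (0, 1)")
    totals = counts.sum(axis=0).astype(float)
    grand = totals.sum()
    if grand <= 0:
        raise ValueError("count matrix is empty")
    share = totals / grand
    cutoff = min_fraction / counts.shape[1]
    kept = share[share >= cutoff].index
    if len(kept) == 0:
        raise ValueError("all samples fall below the sparsity cutoff")
    return counts[kept]


# ---------------------------------------------------------------------------
# design matrices


def _design_matrix(
    values: pd.Series, coding: str, reference: str | None
) -> tuple[pd.DataFrame, str]:
    """Build [intercept | variable columns] for one variable.

    Numeric variables enter as-is. Categorical variables use treatment
    coding (dummies against a reference level) or sum-to-zero deviation
    coding (omitted level coded −1 in every column).
    """
    n = len(values)
    intercept = pd.Series(np.ones(n), index=values.index, name="Intercept")
    if coding == "numeric":
        x = pd.to_numeric(values)
        if x.nunique() < 2:
            raise ValueError(f"variable {values.name!r} is constant")
        return pd.concat([intercept, x.rename(str(values.name))], axis=1), "numeric"
    levels = sorted(values.astype(str).unique())
    if len(levels) < 2:
        raise ValueError(f"variable {values.name!r} has fewer than 2 levels")
    if reference is None:
        reference = levels[0]
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} not observed")
    cols = {}
    for level in levels:
        if level == reference:
            continue
        if coding == "treatment":
            col = (values.astype(str) == level).astype(float)
            cols[f"{values.name}[T.{level}]"] = col
        elif coding == "sum_to_zero":
            col = (values.astype(str) == level).astype(float)
            col[values.astype(str) == reference] = -1.0
            cols[f"{values.name}[S.{level}]"] = col
        else:
            raise ValueError(f"unknown coding {coding!r}")
    X = pd.concat([intercept, pd.DataFrame(cols, index=values.index)], axis=1)
    return X, reference


def _nb_fit(y: np.ndarray, X: np.ndarray, alpha: float):
    family = sm.families.NegativeBinomial(alpha=alpha)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=family)
        return model.fit(maxiter=100)


def _aic(res, n_params: int) -> float:
    # alpha counts as one extra parameter beyond the regression coefficients
    return 2.0 * (n_params + 1) - 2.0 * res.llf


def _fit_nb_best_alpha(y: np.ndarray, X: np.ndarray):
    """NB GLM with dispersion chosen by bounded AIC search on log-alpha."""
    lo, hi = np.log(ALPHA_BOUNDS[0]), np.log(ALPHA_BOUNDS[1])
    k = X.shape[1]

    def objective(log_alpha: float) -> float:
        try:
            res = _nb_fit(y, X, float(np.exp(log_alpha)))
        except Exception:
            return np.inf
        if not np.isfinite(res.llf):
            return np.inf
        return _aic(res, k)

    opt = optimize.minimize_scalar(
        objective, bounds=(lo, hi), method="bounded", options={"xatol": 0.05}
    )
    alpha = float(np.exp(opt.x))
    res = _nb_fit(y, X, alpha)
    return res, alpha, _aic(res, k)


def fit_nb_glm(
    dataset: AbundanceDataset,
    clade: str,
    variable: str,
    coding: str | None = None,
    reference: str | None = None,
) -> GLMFit:
    """Fit one clade's scaled counts on one metadata variable.

    Rows with missing metadata are dropped before the fit. ``coding``
    defaults to ``numeric`` for numeric variables and ``treatment``
    otherwise. Non-convergence is flagged on the returned fit rather than
    raised, so screening can exclude it downstream.
    """
    y_all = dataset.scaled_counts.loc[clade]
    meta = dataset.metadata[variable].reindex(y_all.index)
    keep = meta.notna()
    y = y_all[keep].to_numpy(dtype=float)
    values = meta[keep]
    if coding is None:
        coding = "numeric" if pd.api.types.is_numeric_dtype(values) else "treatment"
    X, ref = _design_matrix(values, coding, reference)
    res, alpha, aic = _fit_nb_best_alpha(y, X.to_numpy())
    params = pd.Series(res.params, index=X.columns)
    bse = pd.Series(res.bse, index=X.columns)
    zcols = [c for c in X.columns if c != "Intercept"]
    z = params[zcols] / bse[zcols]
    wald_p = pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=zcols)
    # block Wald test on all non-intercept coefficients of the variable
    R = np.zeros((len(zcols), len(X.columns)))
    for i, c in enumerate(zcols):
        R[i, X.columns.get_loc(c)] = 1.0
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            block_p = float(res.wald_test(R, scalar=True).pvalue)
    except Exception:
        block_p = float("nan")
    converged = bool(getattr(res, "converged", True)) and np.isfinite(aic)
    return GLMFit(
        clade=clade,
        variable=variable,
        coding=coding,
        reference_level=None if coding == "numeric" else ref,
        params=params,
        bse=bse,
        wald_p=wald_p,
        block_p=block_p,
        alpha=alpha,
        aic=aic,
        converged=converged,
    )


def select_reference_level(
    dataset: AbundanceDataset,
    clade: str,
    variable: str,
    coding: str = "treatment",
) -> tuple[str, GLMFit]:
    """Choose the reference (or omitted) level of a categorical variable.

    Fits one model per candidate level and returns the AIC-minimising one;
    ties resolve to the first level in sorted order. Candidates whose fit
    fails are skipped with a warning; if all fail, raises.
    """
    values = dataset.metadata[variable].dropna().astype(str)
    levels = sorted(values.unique())
    if len(levels) < 2:
        raise ValueError(f"variable {variable!r} has fewer than 2 levels")
    best: tuple[float, str, GLMFit] | None = None
    for level in levels:
        try:
            fit = fit_nb_glm(dataset, clade, variable, coding=coding, reference=level)
        except Exception as exc:  # noqa: BLE001 - candidate skipped, not fatal
            logger.warning("reference candidate %r failed: %s", level, exc)
            continue
        if not np.isfinite(fit.aic):
            continue
        if best is None or fit.aic < best[0] - 1e-9:
            best = (fit.aic, level, fit)
    if best is None:
        raise RuntimeError(f"all reference-level fits failed for {variable!r}")
    return best[1], best[2]


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, ≥ raw)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def significance_screen(
    fits: Iterable[GLMFit],
    variable_threshold: float = BH_VARIABLE_THRESHOLD,
    coefficient_threshold: float = BH_COEFFICIENT_THRESHOLD,
    family: str = "variable",
) -> pd.DataFrame:
    """BH-corrected significance table of (clade, variable, coefficient).

    Variable-level (block Wald) p-values are BH-adjusted across clades
    within each variable (``family="variable"``) or across everything
    (``family="global"``); variables passing adjusted p < 0.1 are kept, and
    within them coefficients passing adjusted p < 0.05, with the sign of
    the association taken from the coefficient. Non-converged fits are
    excluded up front.
    """
    fits = [f for f in fits if f.converged and np.isfinite(f.block_p)]
    if not fits:
        raise ValueError("no converged fits to screen")
    frame = pd.DataFrame(
        {
            "clade": [f.clade for f in fits],
            "variable": [f.variable for f in fits],
            "block_p": [f.block_p for f in fits],
        }
    )
    if family == "variable":
        frame["block_p_adj"] = np.nan
        for _, idx in frame.groupby("variable").groups.items():
            frame.loc[idx, "block_p_adj"] = benjamini_hochberg(frame.loc[idx, "block_p"])
    elif family == "global":
        frame["block_p_adj"] = benjamini_hochberg(frame["block_p"])
    else:
        raise ValueError(f"unknown BH family {family!r}")
    rows = []
    for fit, (_, meta) in zip(fits, frame.iterrows()):
        if meta["block_p_adj"] >= variable_threshold:
            continue
        for coef, p in fit.wald_p.items():
            rows.append(
                {
                    "clade": fit.clade,
                    "variable": fit.variable,
                    "level": coef,
                    "estimate": fit.params[coef],
                    "se": fit.bse[coef],
                    "p": p,
                    "variable_p_adj": meta["block_p_adj"],
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=["clade", "variable", "level", "estimate", "se", "p", "p_adj", "sign"]
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    for _, idx in out.groupby("variable").groups.items():
        out.loc[idx, "p_adj"] = benjamini_hochberg(out.loc[idx, "p"])
    out = out[out["p_adj"] < coefficient_threshold].copy()
    out["sign"] = np.sign(out["estimate"]).astype(int)
    return out.reset_index(drop=True)[
        ["clade", "variable", "level", "estimate", "se", "p", "p_adj", "sign"]
    ]


# ---------------------------------------------------------------------------
# GAM


def cubic_spline_basis(x: np.ndarray, df: int) -> np.ndarray:
    """Unpenalised cubic B-spline basis with ``df`` columns (no intercept).

    Interior knots sit at quantiles of ``x``; df = 3 gives a plain cubic
    polynomial basis.
    """
    if df < 3:
        raise ValueError("cubic spline needs df >= 3")
    x = np.asarray(x, dtype=float)
    k = 3
    n_interior = df - k
    lo, hi = x.min(), x.max()
    if n_interior > 0:
        probs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(x, probs)
    else:
        interior = np.array([])
    t = np.r_[[lo] * (k + 1), interior, [hi] * (k + 1)]
    basis = BSpline.design_matrix(x, t, k, extrapolate=True).toarray()
    return basis[:, 1:]  # drop one column: the intercept is separate


def fit_nb_gam(
    counts: pd.Series,
    time: pd.Series | np.ndarray,
    df_range: tuple[int, int] = GAM_DF_RANGE,
    conf_level: float = 0.95,
    clade: str | None = None,
) -> GAMFit:
    """NB GAM of a clade time series with AIC-selected spline df and alpha.

    Fits an NB log-link GLM on a cubic spline basis of time for each df in
    ``df_range``, optimising alpha within each, and keeps the AIC minimum.
    The pointwise confidence band is Wald-type on the linear predictor,
    transformed through the log link. Requires at least 10 time points; the
    df range is truncated (with a warning) when points are scarce.
    """
    y = counts.to_numpy(dtype=float)
    t = np.asarray(time, dtype=float)
    if y.size != t.size:
        raise ValueError("counts and time must align")
    if y.size < 10:
        raise ValueError("need at least 10 time points for a seasonal smooth")
    lo_df, hi_df = df_range
    max_df = min(hi_df, y.size - 2)
    if max_df < hi_df:
        logger.warning("df range truncated to [%d, %d] for %d points", lo_df, max_df, y.size)
    best = None
    for df in range(lo_df, max_df + 1):
        X = np.column_stack([np.ones_like(t), cubic_spline_basis(t, df)])
        try:
            res, alpha, aic = _fit_nb_best_alpha(y, X)
        except Exception:
            continue
        if best is None or aic < best[0] - 1e-9:
            best = (aic, df, alpha, res, X)
    if best is None:
        raise RuntimeError("no spline fit converged")
    aic, df, alpha, res, X = best
    eta = X @ res.params
    cov = res.cov_params()
    se_eta = np.sqrt(np.einsum("ij,jk,ik->i", X, cov, X))
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    fitted = np.exp(eta)
    lower = np.exp(eta - z * se_eta)
    upper = np.exp(eta + z * se_eta)
    baseline = float(np.mean(fitted))
    significant = bool(np.any((lower > baseline) | (upper < baseline)))
    return GAMFit(
        clade=clade or str(counts.name),
        spline_df=df,
        alpha=alpha,
        aic=aic,
        time=t,
        fitted=fitted,
        lower=lower,
        upper=upper,
        significant_vs_baseline=significant,
        converged=bool(getattr(res, "converged", True)),
    )


def baseline_contrast(
    group_stats: pd.DataFrame, conf_level: float = 0.95
) -> pd.DataFrame:
    """Flag groups whose confidence interval excludes the grand mean.

    ``group_stats`` is indexed by group with columns ``estimate`` and
    ``se``. The grand mean is the mean of the group estimates (mean of
    means). The flags are invariant under relabelling of the groups.
    """
    if group_stats.shape[0] < 2:
        raise ValueError("baseline contrast needs at least 2 groups")
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    grand = group_stats["estimate"].mean()
    lower = group_stats["estimate"] - z * group_stats["se"]
    upper = group_stats["estimate"] + z * group_stats["se"]
    out = group_stats.copy()
    out["grand_mean"] = grand
    out["differs_from_baseline"] = (lower > grand) | (upper < grand)
    return out


def normalize_by_single_copy(
    gene_count: float, ribosomal_counts: Mapping[str, float] | Sequence[float]
) -> float:
    """Normalise a gene's abundance by the mean of five single-copy
    ribosomal genes; returns NaN (with a warning) if all five are zero."""
    if isinstance(ribosomal_counts, Mapping):
        values = [float(ribosomal_counts[g]) for g in SINGLE_COPY_RIBOSOMAL_GENES]
    else:
        values = [float(v) for v in ribosomal_counts]
    if len(values) != 5:
        raise ValueError("expected counts for exactly five ribosomal genes")
    mean = float(np.mean(values))
    if mean == 0.0:
        logger.warning("all ribosomal counts are zero; ratio undefined")
        return float("nan")
    return float(gene_count) / mean
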