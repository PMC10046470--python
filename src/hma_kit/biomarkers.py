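"""Responder-stratified biomarker screens and the permutation-validated
region-set methylation score.

All screens model a feature against a responder/nonresponder group
indicator (NR = 1) with a binary lineage covariate; the reported
coefficient is the adjusted NR − R difference, so negative coefficients
mark sensitivity-associated (responder-skewed) features. Multiple testing
uses Benjamini–Hochberg throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.api import Logit
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .dose_response import NONRESPONDER, RESPONDER
from .errors import InputError, UndefinedCorrelationError

logger = logging.getLogger(__name__)

SENSITIVITY = "sensitivity_associated"
RESISTANCE = "resistance_associated"


def _direction(coef: np.ndarray) -> np.ndarray:
    out = np.where(np.asarray(coef) < 0, SENSITIVITY, RESISTANCE).astype(object)
    out[np.asarray(coef) == 0] = "none"
    return out


def _design_matrix(classes: pd.Series, lineage: pd.Series):
    """Used lines (R/NR only) and their [1, group(NR=1), lineage] design."""
    used = classes.index[classes.isin([RESPONDER, NONRESPONDER])]
    if (classes[used] == RESPONDER).sum() < 3 or (classes[used] == NONRESPONDER).sum() < 3:
        raise InputError("need >=3 cell lines per response class")
    group = (classes[used] == NONRESPONDER).astype(float).to_numpy()
    lin = lineage.reindex(used).astype(float).to_numpy()
    X = np.column_stack([np.ones(len(used)), group, lin])
    return list(used), X


def _ols_screen(values: pd.DataFrame, classes: pd.Series,
                lineage: pd.Series) -> pd.DataFrame:
    """Vectorized per-feature OLS of value ~ group + lineage.

    ``values`` is feature x cell-line. Returns feature_id, coefficient
    (group effect, NR−R), p_value (two-sided t on the group coefficient),
    p_adjusted (BH), direction, and a ``constant`` flag (p forced to 1).
    """
    used, X = _design_matrix(classes, lineage)
    Y = values[used].to_numpy(dtype=float)
    n, k = X.shape
    if n <= k:
        raise InputError("more covariates than cell lines")

    XtX_inv = np.linalg.pinv(X.T @ X)
    beta = Y @ X @ XtX_inv  # features x k
    resid = Y - beta @ X.T
    df_resid = n - np.linalg.matrix_rank(X)
    sigma2 = (resid ** 2).sum(axis=1) / df_resid
    var_group = sigma2 * XtX_inv[1, 1]

    coef = beta[:, 1]
    constant = np.ptp(Y, axis=1) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = coef / np.sqrt(var_group)
    p = 2 * stats.t.sf(np.abs(tstat), df_resid)
    p = np.where(np.isnan(p) | constant, 1.0, p)
    coef = np.where(constant, 0.0, coef)

    p_adj = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame({
        "feature_id": values.index,
        "coefficient": coef,
        "p_value": p,
        "p_adjusted": p_adj,
        "direction": _direction(coef),
        "constant": constant,
    })
    return out


def differential_expression(expr: pd.DataFrame, classes: pd.Series,
                            lineage: pd.Series) -> pd.DataFrame:
    """Covariate-adjusted differential-expression screen.

    ``expr`` is gene x cell-line on the log2 scale; the coefficient is the
    adjusted log2 fold-change NR − R.
    """
    return _ols_screen(expr, classes, lineage)


def differential_methylation_regions(region_meth: pd.DataFrame,
                                     classes: pd.Series,
                                     lineage: pd.Series) -> pd.DataFrame:
    """Covariate-adjusted screen on region-mean methylation (region x line).

    Coefficient is the adjusted Δmethylation NR − R, so regions
    hypermethylated in responders come out negative / sensitivity-associated.
    """
    return _ols_screen(region_meth, classes, lineage)


def significant_regions(screen: pd.DataFrame, fdr: float = 0.05,
                        direction: str | None = SENSITIVITY) -> list:
    """Feature ids passing the BH threshold, optionally direction-filtered."""
    mask = screen["p_adjusted"] < fdr
    if direction is not None:
        mask &= screen["direction"] == direction
    return screen.loc[mask, "feature_id"].tolist()


def filter_mutations(mutations: pd.DataFrame,
                     whitelist: set | None = None) -> pd.DataFrame:
    """Restrict a gene x cell-line mutation matrix to whitelisted genes.

    With no whitelist the matrix passes through unchanged (with a logged
    warning); an empty post-filter matrix is an error.
    """
    if whitelist is None:
        logger.warning("no driver whitelist supplied; mutation matrix unfiltered")
        return mutations
    kept = [g for g in mutations.index if g in whitelist]
    if not kept:
        raise InputError("whitelist filtering removed every gene")
    return mutations.loc[kept]


def _haldane_or(mut_used: np.ndarray, group: np.ndarray):
    """Pooled 2x2 odds ratio with +0.5 correction and Fisher p."""
    a = int(((mut_used == 1) & (group == 1)).sum())  # mutated NR
    b = int(((mut_used == 0) & (group == 1)).sum())
    c = int(((mut_used == 1) & (group == 0)).sum())  # mutated R
    d = int(((mut_used == 0) & (group == 0)).sum())
    corrected = min(a, b, c, d) == 0
    aa, bb, cc, dd = (v + 0.5 for v in (a, b, c, d)) if corrected else (a, b, c, d)
    or_ = (aa * dd) / (bb * cc)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(or_), float(p)


def mutation_association(mutations: pd.DataFrame, classes: pd.Series,
                         lineage: pd.Series) -> pd.DataFrame:
    """Per-gene logistic model of mutation status on group + lineage.

    Positive coefficients (OR > 1) mean the mutation skews toward
    nonresponders; negative means responder-skewed (sensitivity-associated).
    On separation or non-convergence the gene falls back to a
    Haldane-corrected pooled 2x2 OR with Fisher p (``fallback`` flag set).
    Genes mutated in fewer than 2 used lines are skipped with a flag.
    """
    used, X = _design_matrix(classes, lineage)
    group = X[:, 1]
    rows = []
    for gene in mutations.index:
        mut = mutations.loc[gene, used].to_numpy(dtype=float)
        n_mut = int(mut.sum())
        if n_mut < 2:
            rows.append({"feature_id": gene, "coefficient": np.nan,
                         "p_value": np.nan, "odds_ratio": np.nan,
                         "fallback": False, "skipped": True})
            continue
        coef = p = None
        if 0 < n_mut < len(used):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = Logit(mut, X).fit(disp=0, maxiter=200)
                if res.mle_retvals.get("converged", False) and abs(res.params[1]) < 10:
                    coef = float(res.params[1])
                    p = float(res.pvalues[1])
            except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
                pass
        fallback = coef is None
        if fallback:
            or_, p = _haldane_or(mut, group)
            coef = float(np.log(or_))
        rows.append({"feature_id": gene, "coefficient": coef, "p_value": p,
                     "odds_ratio": float(np.exp(coef)), "fallback": fallback,
                     "skipped": False})
    out = pd.DataFrame(rows)
    tested = ~out["skipped"]
    p_adj = np.full(len(out), np.nan)
    if tested.any():
        p_adj[tested.to_numpy()] = multipletests(
            out.loc[tested, "p_value"].to_numpy(), method="fdr_bh")[1]
    out["p_adjusted"] = p_adj
    out["direction"] = _direction(out["coefficient"].fillna(0).to_numpy())
    out.loc[out["skipped"], "direction"] = "none"
    return out


def mutation_burden(mutations: pd.DataFrame, log2: bool = False) -> pd.Series:
    """Mutation count per cell line; ``log2`` gives log2(count + 1)."""
    burden = mutations.sum(axis=0).astype(float)
    burden.name = "mutation_burden"
    return np.log2(burden + 1) if log2 else burden


def aggregate_regions(beta: pd.DataFrame, region_map: pd.Series) -> pd.DataFrame:
    """Region x sample mean beta from a probe x sample matrix.

    ``region_map`` maps probe_id -> region_id; probes without a region are
    excluded.
    """
    regions = region_map.reindex(beta.index).dropna()
    return beta.loc[regions.index].groupby(regions).mean()


@dataclass(frozen=True)
class RegionSetScore:
    """Correlation of a region set's mean methylation with log2 IC50."""

    region_ids: tuple
    mean_methylation: pd.Series = field(repr=False)
    r_observed: float
    p_parametric: float
    n_lines: int
    n_excluded_censored: int


def _mean_meth_and_ic50(region_set, region_meth: pd.DataFrame,
                        ic50: pd.Series, censored: pd.Series | None):
    region_set = list(region_set)
    if not region_set:
        raise InputError("region set is empty")
    missing = set(region_set) - set(region_meth.index)
    if missing:
        raise InputError(f"regions not in matrix: {sorted(missing)[:5]}")
    ic = pd.to_numeric(ic50, errors="coerce")
    n_censored = 0
    if censored is not None:
        cen = censored.reindex(ic.index).fillna(False).astype(bool)
        n_censored = int((cen & np.isfinite(ic)).sum())
        ic = ic.where(~cen)
    lines = [l for l in region_meth.columns
             if l in ic.index and np.isfinite(ic[l]) and ic[l] > 0]
    if len(lines) < 3:
        raise InputError("need >=3 cell lines with finite IC50")
    mean_meth = region_meth.loc[region_set, lines].mean(axis=0)
    return mean_meth, np.log2(ic[lines].to_numpy(dtype=float)), n_censored


def region_set_score(region_set, region_meth: pd.DataFrame, ic50: pd.Series,
                     censored: pd.Series | None = None) -> RegionSetScore:
    """Mean methylation of a region set per line, correlated with log2(IC50).

    Censored IC50 lines are excluded (count logged). Higher methylation in
    sensitive (low-IC50) lines gives a negative r.
    """
    mean_meth, log2_ic50, n_cen = _mean_meth_and_ic50(
        region_set, region_meth, ic50, censored)
    if n_cen:
        logger.info("region_set_score: excluded %d censored-IC50 lines", n_cen)
    if np.ptp(mean_meth.to_numpy()) == 0 or np.ptp(log2_ic50) == 0:
        raise UndefinedCorrelationError("constant mean methylation or IC50")
    res = stats.pearsonr(mean_meth.to_numpy(), log2_ic50)
    return RegionSetScore(region_ids=tuple(region_set),
                          mean_methylation=mean_meth,
                          r_observed=float(res.statistic),
                          p_parametric=float(res.pvalue),
                          n_lines=len(mean_meth),
                          n_excluded_censored=n_cen)


@dataclass(frozen=True)
class PermutationResult:
    """Empirical significance of an observed region-set correlation."""

    r_observed: float
    empirical_p: float
    n_iterations: int
    universe_size: int
    set_size: int
    null_mean: float
    null_sd: float
    null_abs_q95: float


def permutation_null(
    region_set_size: int,
    universe,
    region_meth: pd.DataFrame,
    ic50: pd.Series,
    n_iterations: int,
    seed: int,
    r_observed: float,
    censored: pd.Series | None = None,
    batch_size: int = 500,
) -> PermutationResult:
    """Null distribution of |r| from random same-size region sets.

    Draws ``n_iterations`` uniform subsets of ``universe`` (without
    replacement within a draw), computes the mean-methylation correlation
    with log2(IC50) for each, and reports the add-one two-sided empirical p:
    (1 + #{|r_null| >= |r_observed|}) / (1 + n_iterations). Never zero.
    """
    universe = list(universe)
    if region_set_size > len(universe):
        raise InputError("region set size exceeds universe")
    if n_iterations < 1:
        raise InputError("n_iterations must be >= 1")

    mean_meth, y, _ = _mean_meth_and_ic50(universe, region_meth, ic50, censored)
    lines = mean_meth.index
    M = region_meth.loc[universe, lines].to_numpy(dtype=float)
    y = y - y.mean()
    y_ss = float(y @ y)
    if y_ss == 0:
        raise UndefinedCorrelationError("constant IC50 vector")

    rng = np.random.default_rng(seed)
    null_r = np.empty(n_iterations)
    pos = 0
    while pos < n_iterations:
        b = min(batch_size, n_iterations - pos)
        idx = np.empty((b, region_set_size), dtype=np.intp)
        for i in range(b):
            idx[i] = rng.choice(len(universe), size=region_set_size,
                                replace=False)
        means = M[idx].mean(axis=1)  # b x lines
        means = means - means.mean(axis=1, keepdims=True)
        num = means @ y
        denom = np.sqrt((means ** 2).sum(axis=1) * y_ss)
        with np.errstate(invalid="ignore", divide="ignore"):
            null_r[pos:pos + b] = np.where(denom > 0, num / denom, 0.0)
        pos += b

    exceed = int((np.abs(null_r) >= abs(r_observed)).sum())
    empirical_p = (1 + exceed) / (1 + n_iterations)
    return PermutationResult(
        r_observed=float(r_observed), empirical_p=float(empirical_p),
        n_iterations=n_iterations, universe_size=len(universe),
        set_size=region_set_size, null_mean=float(null_r.mean()),
        null_sd=float(null_r.std()),
        null_abs_q95=float(np.quantile(np.abs(null_r), 0.95)),
    )
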