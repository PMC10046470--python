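"""Per-cell-line sensitivity metrics and panel-level tissue enrichment.

AUC here is the normalized trapezoidal integral of mean viability over
log10(dose), clipped to [0, 1]: 0 means fully killed at every dose, 1 means
unaffected. Lower AUC = more sensitive, so the "sensitive" flag marks the
lowest-50%-AUC lines and the responder/nonresponder split takes the bottom
and top AUC thirds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import FitError, InputError, UndefinedCorrelationError

RESPONDER = "responder"
NONRESPONDER = "nonresponder"
INTERMEDIATE = "intermediate"
UNCLASSIFIED = "unclassified"

#: canonical column names of a sensitivity-record table
RECORD_COLUMNS = [
    "cell_line",
    "tissue",
    "hematopoietic",
    "auc",
    "ic50",
    "ic50_censored",
    "response_class",
]


@dataclass(frozen=True)
class DoseResponseCurve:
    """One cell line x drug dilution series with replicate viabilities.

    Parameters
    ----------
    cell_line, drug:
        Identifiers.
    doses:
        Strictly increasing positive concentrations (nM), >= 4 points.
    viabilities:
        Array of shape ``(n_doses,)`` or ``(n_doses, n_replicates)`` of
        viability fractions relative to vehicle (>= 0).
    """

    cell_line: str
    drug: str
    doses: np.ndarray
    viabilities: np.ndarray

    def __post_init__(self):
        doses = np.asarray(self.doses, dtype=float)
        viab = np.asarray(self.viabilities, dtype=float)
        if doses.ndim != 1 or len(np.unique(doses)) < 4:
            raise InputError("dose-response curve needs >=4 distinct doses")
        if not np.all(np.isfinite(doses)) or np.any(doses <= 0):
            raise InputError("doses must be finite and > 0")
        if np.any(np.diff(doses) <= 0):
            raise InputError("doses must be strictly increasing")
        if viab.shape[0] != doses.shape[0]:
            raise InputError("viability rows must match dose count")
        if not np.all(np.isfinite(viab)) or np.any(viab < 0):
            raise InputError("viabilities must be finite and >= 0")
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "viabilities", viab)

    def mean_viability(self) -> np.ndarray:
        """Replicate-averaged viability per dose."""
        viab = self.viabilities
        return viab if viab.ndim == 1 else viab.mean(axis=1)


@dataclass(frozen=True)
class IC50Fit:
    """Result of a four-parameter logistic fit.

    ``ic50`` is the concentration at which the fitted curve reaches 50% of
    the fitted top; ``censored`` is True when the fit never crosses that
    level within the tested dose range (ic50 is then the maximum dose).
    """

    ic50: float
    censored: bool
    top: float
    bottom: float
    hill: float
    ec50: float
    rss: float


@dataclass(frozen=True)
class TissueEnrichment:
    """Odds ratio of sensitivity for one tissue vs the rest of the panel."""

    tissue: str
    odds_ratio: float
    ci95_low: float
    ci95_high: float
    p_value: float  # Fisher exact, two-sided
    p_chi2: float  # auxiliary chi-square p (paper does not name its test)
    counts: tuple  # (a, b, c, d) = (sens&tissue, insens&tissue, sens&other, insens&other)
    haldane_corrected: bool


def compute_auc(curve: DoseResponseCurve) -> float:
    """Normalized trapezoidal AUC of mean viability over log10(dose).

    Returns the integral divided by the log-dose range, clipped to [0, 1].
    """
    x = np.log10(curve.doses)
    y = curve.mean_viability()
    auc = np.trapezoid(y, x) / (x[-1] - x[0])
    return float(np.clip(auc, 0.0, 1.0))


def four_pl(dose, top, bottom, ec50, hill):
    """4PL decreasing viability curve: bottom + (top-bottom)/(1+(d/ec50)^hill)."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / ec50) ** hill)


def _ic50_from_params(top, bottom, ec50, hill, dmax):
    """Dose at 50% of fitted top; censored at dmax when never crossed."""
    half = 0.5 * top
    if half <= bottom:  # curve plateaus above 50% of top
        return float(dmax), True
    ratio = (top - bottom) / (half - bottom) - 1.0
    if ratio <= 0:
        return float(dmax), True
    ic50 = ec50 * ratio ** (1.0 / hill)
    if ic50 > dmax:
        return float(dmax), True
    return float(ic50), False


def fit_ic50(curve: DoseResponseCurve) -> IC50Fit:
    """Fit a 4PL (bottom bounded at 0, top free) and report the IC50.

    Falls back to a coarse grid search for starting values when the direct
    fit fails; raises :class:`FitError` with diagnostics if both fail.
    """
    doses = curve.doses
    y = curve.mean_viability()
    dmin, dmax = doses[0], doses[-1]
    logd = np.log10(doses)

    bounds = ([0.2, 0.0, dmin / 1e3, 0.05], [2.0, 1.5, dmax * 1e3, 10.0])

    def _clip_p0(p0):
        return [float(np.clip(v, lo + 1e-12, hi - 1e-12))
                for v, lo, hi in zip(p0, bounds[0], bounds[1])]

    p0 = _clip_p0([max(y.max(), 0.5), max(y.min(), 0.0),
                   10 ** np.median(logd), 1.0])

    def _try(p0):
        popt, _ = optimize.curve_fit(
            lambda d, top, bottom, ec50, hill: four_pl(d, top, bottom, ec50, hill),
            doses, y, p0=p0, bounds=bounds, maxfev=20000,
        )
        return popt

    popt = None
    try:
        popt = _try(p0)
    except (RuntimeError, ValueError):
        pass
    if popt is None:
        # grid-search starting values, then one more refinement attempt
        best, best_rss = None, np.inf
        for lec in np.linspace(np.log10(dmin) - 2, np.log10(dmax) + 2, 25):
            for hill in (0.5, 1.0, 2.0, 4.0):
                for bottom in (0.0, float(max(y.min(), 0.0))):
                    top = float(max(y.max(), 0.3))
                    pred = four_pl(doses, top, bottom, 10 ** lec, hill)
                    rss = float(np.sum((pred - y) ** 2))
                    if rss < best_rss:
                        best, best_rss = [top, bottom, 10 ** lec, hill], rss
        try:
            popt = _try(_clip_p0(best))
        except (RuntimeError, ValueError):
            popt = np.asarray(_clip_p0(best))
        if popt is None:
            raise FitError(
                "4PL fit failed to converge",
                diagnostics={"grid_rss": best_rss, "grid_params": best},
            )

    top, bottom, ec50, hill = (float(v) for v in popt)
    rss = float(np.sum((four_pl(doses, top, bottom, ec50, hill) - y) ** 2))
    ic50, censored = _ic50_from_params(top, bottom, ec50, hill, dmax)
    return IC50Fit(ic50=ic50, censored=censored, top=top, bottom=bottom,
                   hill=hill, ec50=ec50, rss=rss)


def flag_sensitive(records: pd.DataFrame) -> pd.DataFrame:
    """Mark the lowest-50%-AUC lines sensitive (ties at the median included).

    Returns a copy with a boolean ``sensitive`` column; lines with missing
    AUC are not sensitive.
    """
    auc = pd.to_numeric(records["auc"], errors="coerce")
    finite = auc[np.isfinite(auc)]
    if len(finite) < 2:
        raise InputError("flag_sensitive needs >=2 records with finite AUC")
    out = records.copy()
    out["sensitive"] = (auc <= finite.median()) & np.isfinite(auc)
    return out


def tissue_odds_ratio(records: pd.DataFrame, tissue: str) -> TissueEnrichment:
    """2x2 odds ratio of the sensitive flag for one tissue vs the rest.

    Applies the Haldane–Anscombe +0.5 correction when any cell is zero;
    Wald 95% CI on the log odds ratio; two-sided Fisher exact p (plus an
    auxiliary chi-square p).
    """
    if "sensitive" not in records.columns:
        raise InputError("run flag_sensitive first")
    in_tissue = records["tissue"] == tissue
    if not in_tissue.any():
        raise InputError(f"tissue {tissue!r} absent from table")
    sens = records["sensitive"].astype(bool)
    a = int((sens & in_tissue).sum())
    b = int((~sens & in_tissue).sum())
    c = int((sens & ~in_tissue).sum())
    d = int((~sens & ~in_tissue).sum())

    corrected = min(a, b, c, d) == 0
    aa, bb, cc, dd = (v + 0.5 for v in (a, b, c, d)) if corrected else (a, b, c, d)
    odds_ratio = (aa * dd) / (bb * cc)
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    log_or = np.log(odds_ratio)
    ci_low = float(np.exp(log_or - 1.959963984540054 * se))
    ci_high = float(np.exp(log_or + 1.959963984540054 * se))

    _, p_fisher = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    try:
        chi2_res = stats.chi2_contingency([[a, b], [c, d]], correction=True)
        p_chi2 = float(chi2_res.pvalue)
    except ValueError:
        p_chi2 = float("nan")

    return TissueEnrichment(
        tissue=tissue, odds_ratio=float(odds_ratio),
        ci95_low=ci_low, ci95_high=ci_high,
        p_value=float(p_fisher), p_chi2=p_chi2,
        counts=(a, b, c, d), haldane_corrected=corrected,
    )


def all_tissue_odds_ratios(records: pd.DataFrame) -> pd.DataFrame:
    """Tissue enrichment table for every tissue present in the panel."""
    rows = []
    for tissue in sorted(records["tissue"].unique()):
        e = tissue_odds_ratio(records, tissue)
        rows.append({
            "tissue": e.tissue, "odds_ratio": e.odds_ratio,
            "ci95_low": e.ci95_low, "ci95_high": e.ci95_high,
            "p_value": e.p_value, "p_chi2": e.p_chi2,
            "a": e.counts[0], "b": e.counts[1],
            "c": e.counts[2], "d": e.counts[3],
            "haldane_corrected": e.haldane_corrected,
        })
    return pd.DataFrame(rows)


def classify_responders(records: pd.DataFrame) -> pd.DataFrame:
    """Tertile split on AUC: bottom third responders, top third nonresponders.

    Group size is floor(n/3) for each extreme; the remainder is
    intermediate. Ties are broken by stable cell-line-identifier order.
    Lines without finite AUC are left unclassified.
    """
    auc = pd.to_numeric(records["auc"], errors="coerce")
    finite_idx = records.index[np.isfinite(auc)]
    n = len(finite_idx)
    if n < 3:
        raise InputError("classify_responders needs >=3 records with finite AUC")
    sub = records.loc[finite_idx, ["cell_line"]].copy()
    sub["auc"] = auc.loc[finite_idx]
    if sub["auc"].nunique() == 1:
        warnings.warn("all AUC values equal; tertile split determined by "
                      "cell-line identifier order", stacklevel=2)
    order = sub.sort_values(["auc", "cell_line"], kind="stable").index
    k = n // 3
    out = records.copy()
    out["response_class"] = UNCLASSIFIED
    out.loc[finite_idx, "response_class"] = INTERMEDIATE
    out.loc[order[:k], "response_class"] = RESPONDER
    out.loc[order[n - k:], "response_class"] = NONRESPONDER
    return out


def correlate_feature(
    records: pd.DataFrame,
    feature: pd.Series,
    metric: str = "auc",
    transform: str = "identity",
) -> tuple[float, float, int]:
    """Pearson correlation of a per-cell-line feature with a sensitivity metric.

    Parameters
    ----------
    records:
        Sensitivity table with ``cell_line`` plus ``auc``/``ic50`` columns.
    feature:
        Numeric series indexed by cell line.
    metric:
        ``"auc"`` or ``"log2_ic50"`` (censored IC50s excluded).
    transform:
        ``"identity"``, ``"log2"`` (log2 of the feature), or ``"log2p1"``
        (log2(feature+1), the mutation-count convention).

    Returns ``(r, p, n_pairs)``.
    """
    rec = records.set_index("cell_line") if "cell_line" in records.columns else records
    if metric == "auc":
        y = pd.to_numeric(rec["auc"], errors="coerce")
    elif metric == "log2_ic50":
        ic50 = pd.to_numeric(rec["ic50"], errors="coerce")
        if "ic50_censored" in rec.columns:
            ic50 = ic50.where(~rec["ic50_censored"].astype(bool))
        y = np.log2(ic50.where(ic50 > 0))
    else:
        raise InputError(f"unknown metric {metric!r}")

    x = pd.to_numeric(feature, errors="coerce").reindex(y.index)
    if transform == "log2":
        x = np.log2(x.where(x > 0))
    elif transform == "log2p1":
        x = np.log2(x + 1)
    elif transform != "identity":
        raise InputError(f"unknown transform {transform!r}")

    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < 3:
        raise InputError("correlate_feature needs >=3 complete pairs")
    xv, yv = x[mask].to_numpy(), y[mask].to_numpy()
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise UndefinedCorrelationError("zero variance in feature or metric")
    res = stats.pearsonr(xv, yv)
    return float(res.statistic), float(res.pvalue), int(mask.sum())


def curves_from_long(df: pd.DataFrame) -> list[DoseResponseCurve]:
    """Build curves from a long table (cell_line, drug, dose, replicate, viability)."""
    curves = []
    for (cell_line, drug), grp in df.groupby(["cell_line", "drug"], sort=True):
        wide = grp.pivot_table(index="dose", columns="replicate",
                               values="viability")
        curves.append(DoseResponseCurve(
            cell_line=str(cell_line), drug=str(drug),
            doses=wide.index.to_numpy(dtype=float),
            viabilities=wide.to_numpy(dtype=float),
        ))
    return curves


def sensitivity_table(curves: list[DoseResponseCurve],
                      metadata: pd.DataFrame | None = None) -> pd.DataFrame:
    """AUC + IC50 per curve, joined with optional per-line metadata."""
    rows = []
    for c in curves:
        fit = fit_ic50(c)
        rows.append({"cell_line": c.cell_line, "drug": c.drug,
                     "auc": compute_auc(c), "ic50": fit.ic50,
                     "ic50_censored": fit.censored})
    out = pd.DataFrame(rows)
    if metadata is not None:
        out = out.merge(metadata, on="cell_line", how="left")
    return out
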