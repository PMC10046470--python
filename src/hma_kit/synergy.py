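"""Median-effect fits and Chou–Talalay combination indices.

The median-effect line regresses log10(fa/(1-fa)) on log10(dose); its slope
is m and its intercept is -m*log10(Dm). The combination index uses the
mutually exclusive two-term form: CI = d_a/Dx_a + d_b/Dx_b where
Dx = Dm*(fa/(1-fa))^(1/m) is each drug's single-agent dose producing the
combination's fraction affected. CI < 1 synergy, = 1 additivity, > 1
antagonism. fa is 1 - relative viability; cells with fa outside (0,1) are
unscorable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import FitError, InputError


@dataclass(frozen=True)
class MedianEffectFit:
    drug: str
    m: float  # slope of the median-effect line
    Dm: float  # median-effect dose (fa = 0.5)
    r2: float
    n_points: int

    def dose_for_fa(self, fa: float) -> float:
        """Single-agent dose producing fraction affected ``fa``."""
        if not 0 < fa < 1:
            raise InputError("fa must be strictly inside (0, 1)")
        return self.Dm * (fa / (1 - fa)) ** (1 / self.m)

    def fa_at_dose(self, dose) -> np.ndarray:
        """Median-effect prediction of fa at the given dose(s)."""
        dose = np.asarray(dose, dtype=float)
        ratio = (dose / self.Dm) ** self.m
        return ratio / (1 + ratio)


def fit_median_effect(doses, fa, drug: str = "") -> MedianEffectFit:
    """Least-squares median-effect fit on points with fa strictly in (0, 1).

    Raises :class:`InputError` for fa outside [0, 1] and :class:`FitError`
    when fewer than 2 usable points remain.
    """
    doses = np.asarray(doses, dtype=float)
    fa = np.asarray(fa, dtype=float)
    if doses.shape != fa.shape:
        raise InputError("doses and fa must have the same shape")
    if np.any(~np.isfinite(doses)) or np.any(doses <= 0):
        raise InputError("doses must be finite and > 0")
    if np.any((fa < 0) | (fa > 1) | ~np.isfinite(fa)):
        raise InputError("fa must lie in [0, 1]")

    usable = (fa > 0) & (fa < 1)
    if usable.sum() < 2:
        raise FitError("need >=2 points with fa strictly inside (0, 1)",
                       diagnostics={"n_usable": int(usable.sum())})
    x = np.log10(doses[usable])
    y = np.log10(fa[usable] / (1 - fa[usable]))
    if np.ptp(x) == 0:
        raise FitError("all usable points at the same dose")
    res = stats.linregress(x, y)
    m = float(res.slope)
    if m <= 0:
        raise FitError("non-positive median-effect slope",
                       diagnostics={"slope": m})
    Dm = float(10 ** (-res.intercept / m))
    return MedianEffectFit(drug=drug, m=m, Dm=Dm,
                           r2=float(res.rvalue ** 2),
                           n_points=int(usable.sum()))


def combination_index(fit_a: MedianEffectFit, fit_b: MedianEffectFit,
                      dose_a: float, dose_b: float,
                      fa_combo: float) -> float:
    """Two-term Chou–Talalay CI for one combination cell.

    Returns NaN (unscored) when fa_combo is not strictly inside (0, 1);
    both doses zero gives the degenerate CI = 0.
    """
    if not np.isfinite(fa_combo) or not 0 < fa_combo < 1:
        return float("nan")
    if dose_a < 0 or dose_b < 0:
        raise InputError("doses must be >= 0")
    if dose_a == 0 and dose_b == 0:
        return 0.0  # degenerate: no drug
    ci = 0.0
    if dose_a > 0:
        ci += dose_a / fit_a.dose_for_fa(fa_combo)
    if dose_b > 0:
        ci += dose_b / fit_b.dose_for_fa(fa_combo)
    return float(ci)


@dataclass
class CombinationMatrix:
    """Dose grid of two drugs with observed fa and (after scoring) CI.

    ``fa`` has shape (len(doses_a), len(doses_b)); ``ci`` is NaN for
    unscored cells.
    """

    doses_a: np.ndarray
    doses_b: np.ndarray
    fa: np.ndarray
    ci: np.ndarray | None = None
    drug_a: str = "A"
    drug_b: str = "B"

    def __post_init__(self):
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        self.fa = np.asarray(self.fa, dtype=float)
        if self.fa.shape != (len(self.doses_a), len(self.doses_b)):
            raise InputError("fa grid shape must match dose grids")

    @classmethod
    def from_viability(cls, doses_a, doses_b, viability, **kw):
        """Build from relative viability; fa = 1 - viability, cells with
        viability >= 1 (fa <= 0) become unscorable NaN-fa cells."""
        viability = np.asarray(viability, dtype=float)
        fa = 1.0 - viability
        fa = np.where((fa > 0) & (fa < 1), fa, np.nan)
        return cls(doses_a=doses_a, doses_b=doses_b, fa=fa, **kw)


@dataclass(frozen=True)
class SynergySummary:
    n_scored: int
    n_unscored: int
    fraction_synergistic: float  # CI < 1 among scored cells
    median_ci: float


def score_matrix(matrix: CombinationMatrix, fit_a: MedianEffectFit,
                 fit_b: MedianEffectFit) -> SynergySummary:
    """Fill per-cell CI values in place and summarize the scored cells."""
    ci = np.full(matrix.fa.shape, np.nan)
    for i, da in enumerate(matrix.doses_a):
        for j, db in enumerate(matrix.doses_b):
            fa = matrix.fa[i, j]
            if np.isfinite(fa):
                ci[i, j] = combination_index(fit_a, fit_b, da, db, fa)
    matrix.ci = ci
    scored = np.isfinite(ci)
    n_scored = int(scored.sum())
    return SynergySummary(
        n_scored=n_scored,
        n_unscored=int(ci.size - n_scored),
        fraction_synergistic=float((ci[scored] < 1).mean()) if n_scored else float("nan"),
        median_ci=float(np.median(ci[scored])) if n_scored else float("nan"),
    )
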