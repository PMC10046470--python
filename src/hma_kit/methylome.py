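"""Beta-value computation, differential-methylation calling, and drug-vs-drug
normalized demethylation ratios.

Beta for a probe is max(M, 0) / (|U| + |M| + 100) where M and U are
background-subtracted methylated/unmethylated fluorescence signals (the +100
offset is on the same arbitrary intensity scale). Demethylated CpGs (DMCs)
are flagged at nested Δβ cutoffs {0, −0.05, −0.1, −0.2}, each requiring a
two-tailed unpaired t-test p < 0.05 between treated and control replicates.
"""

from __future__ import annotations

import warnings
from collections import namedtuple
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError, InputError

#: Δβ cutoffs at which DMC flags are reported, loosest first.
DMC_CUTOFFS = (0.0, -0.05, -0.1, -0.2)

#: default p-value threshold required by every DMC flag
DMC_P_THRESHOLD = 0.05

CONTROL_CONDITION = "DMSO"


def flag_column(cutoff: float) -> str:
    """Column name holding the DMC flag at a Δβ cutoff (e.g. ``dmc_lt_-0.05``)."""
    return f"dmc_lt_{cutoff:g}"


def compute_beta(M, U):
    """Methylation beta value: max(M, 0) / (|U| + |M| + 100).

    Accepts scalars or arrays; background-subtracted signals may be
    negative. Output is in [0, 1) for all finite inputs.
    """
    M = np.asarray(M, dtype=float)
    U = np.asarray(U, dtype=float)
    if not (np.all(np.isfinite(M)) and np.all(np.isfinite(U))):
        raise InputError("non-finite intensity values")
    beta = np.maximum(M, 0.0) / (np.abs(U) + np.abs(M) + 100.0)
    return float(beta) if beta.ndim == 0 else beta


@dataclass
class MethylationExperiment:
    """Probe x sample beta matrix with a condition/replicate design.

    ``beta`` is indexed by probe_id with one column per sample; ``design``
    is indexed by sample name with ``condition`` and ``replicate`` columns.
    Every condition must have at least 2 replicates.
    """

    beta: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self):
        missing = set(self.beta.columns) - set(self.design.index)
        if missing:
            raise DesignError(f"samples missing from design: {sorted(missing)}")
        counts = self.design.loc[list(self.beta.columns), "condition"].value_counts()
        if (counts < 2).any():
            bad = counts[counts < 2].index.tolist()
            raise DesignError(f"conditions with <2 replicates: {bad}")
        vals = self.beta.to_numpy()
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() >= 1):
            raise InputError("beta values must lie in [0, 1)")

    @property
    def probe_count(self) -> int:
        return len(self.beta)

    def conditions(self) -> list[str]:
        return sorted(self.design["condition"].unique())

    def samples_for(self, condition: str) -> list[str]:
        sel = self.design.index[self.design["condition"] == condition]
        return [s for s in self.beta.columns if s in set(sel)]

    @classmethod
    def from_intensities(cls, M: pd.DataFrame, U: pd.DataFrame,
                         design: pd.DataFrame) -> "MethylationExperiment":
        """Build an experiment by applying the beta formula to M/U matrices."""
        if not M.index.equals(U.index) or not M.columns.equals(U.columns):
            raise InputError("M and U matrices must share index and columns")
        beta = pd.DataFrame(compute_beta(M.to_numpy(), U.to_numpy()),
                            index=M.index, columns=M.columns)
        return cls(beta=beta, design=design)


def call_dmcs(experiment: MethylationExperiment, drug: str,
              control: str = CONTROL_CONDITION,
              equal_var: bool = True,
              p_threshold: float = DMC_P_THRESHOLD) -> pd.DataFrame:
    """Per-probe Δβ and t-test p between a drug condition and the control.

    Returns a DataFrame indexed by probe_id with ``delta_beta``, ``p_value``
    and one nested boolean flag column per Δβ cutoff (flag requires
    p < ``p_threshold`` and Δβ strictly below the cutoff). Probes with any
    missing replicate are dropped; the dropped count is in
    ``result.attrs["n_dropped"]``. Default t-test is Student's equal-variance
    per the unpaired-t-test convention; pass ``equal_var=False`` for Welch.
    """
    for cond in (drug, control):
        if cond not in set(experiment.design["condition"]):
            raise DesignError(f"condition {cond!r} missing from design")
    treated = experiment.beta[experiment.samples_for(drug)].to_numpy()
    ctrl = experiment.beta[experiment.samples_for(control)].to_numpy()

    complete = np.isfinite(treated).all(axis=1) & np.isfinite(ctrl).all(axis=1)
    n_dropped = int((~complete).sum())
    probes = experiment.beta.index[complete]
    treated, ctrl = treated[complete], ctrl[complete]

    delta = treated.mean(axis=1) - ctrl.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(treated, ctrl, axis=1, equal_var=equal_var)
    p = np.asarray(res.pvalue, dtype=float)
    # zero-variance-in-both, identical-mean probes: t = 0/0; not a DMC
    p = np.where(np.isnan(p), 1.0, p)

    out = pd.DataFrame({"delta_beta": delta, "p_value": p}, index=probes)
    out.index.name = "probe_id"
    sig = p < p_threshold
    for cutoff in DMC_CUTOFFS:
        out[flag_column(cutoff)] = sig & (delta < cutoff)
    out.attrs["n_dropped"] = n_dropped
    out.attrs["drug"] = drug
    out.attrs["control"] = control
    out.attrs["equal_var"] = equal_var
    return out


SharedCounts = namedtuple("SharedCounts", ["a_only", "b_only", "shared"])


def _flagged(dmcs: pd.DataFrame, cutoff: float) -> set:
    col = flag_column(cutoff)
    if col not in dmcs.columns:
        raise InputError(f"no DMC flag column for cutoff {cutoff}")
    return set(dmcs.index[dmcs[col].astype(bool)])


def shared_dmcs(dmcs_a: pd.DataFrame, dmcs_b: pd.DataFrame,
                cutoff: float = 0.0) -> SharedCounts:
    """Counts of probes demethylated only by A, only by B, or by both."""
    if set(dmcs_a.index) != set(dmcs_b.index):
        raise InputError("DMC tables cover different probe universes")
    fa, fb = _flagged(dmcs_a, cutoff), _flagged(dmcs_b, cutoff)
    return SharedCounts(a_only=len(fa - fb), b_only=len(fb - fa),
                        shared=len(fa & fb))


def normalized_demethylation_ratio(
    dmcs_a: pd.DataFrame,
    dmcs_b: pd.DataFrame,
    feature_assignment: pd.Series,
    cutoff: float = 0.0,
) -> pd.DataFrame:
    """Per-feature ratio of drug-A DMC counts to drug-B DMC counts.

    ``feature_assignment`` maps probe_id -> genomic feature; probes absent
    from the mapping fall into ``"unannotated"``. A feature where drug B
    demethylated no CpGs gets a missing ratio and a warning, never infinity.
    """
    if set(dmcs_a.index) != set(dmcs_b.index):
        raise InputError("DMC tables cover different probe universes")
    features = feature_assignment.reindex(dmcs_a.index).fillna("unannotated")
    fa, fb = _flagged(dmcs_a, cutoff), _flagged(dmcs_b, cutoff)

    rows = []
    for feat in sorted(features.unique()):
        probes = set(features.index[features == feat])
        count_a = len(fa & probes)
        count_b = len(fb & probes)
        if count_b == 0:
            warnings.warn(f"feature {feat!r}: no drug-B DMCs, ratio undefined",
                          stacklevel=2)
            ratio = np.nan
        else:
            ratio = count_a / count_b
        rows.append({"feature": feat, "count_a": count_a,
                     "count_b": count_b, "ratio": ratio})
    return pd.DataFrame(rows)
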