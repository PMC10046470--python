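"""Probe annotation against chromatin-mark and replication-timing tracks.

All coordinates are BED-style: 0-based, half-open intervals [start, end).
Probe positions are single-base points; a probe at ``pos`` is covered by
[start, end) iff start <= pos < end. Replication-timing values are signed
reals classified as late (< 0), mid-early ([0, 1)), or early (>= 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FormatError, InputError
from .methylome import flag_column

LATE = "late"
MID_EARLY = "mid_early"
EARLY = "early"
TIMING_CLASSES = (LATE, MID_EARLY, EARLY)

CHROMATIN_MARKS = ("H3K27ac", "H3K36me3", "H3K9me3", "H3K27me3")

GENOMIC_FEATURES = ("CGI", "TSS1500", "gene_body", "noncoding", "unannotated")


def classify_timing(value: float) -> str:
    """Three-way replication-timing class for a signed Repli-seq score.

    value < 0 -> late; 0 <= value < 1 -> mid_early; value >= 1 -> early.
    """
    if not np.isfinite(value):
        raise InputError("replication-timing value must be finite")
    if value < 0:
        return LATE
    if value < 1:
        return MID_EARLY
    return EARLY


def classify_timing_array(values) -> np.ndarray:
    """Vectorized :func:`classify_timing`; NaN maps to missing (None)."""
    values = np.asarray(values, dtype=float)
    out = np.where(values < 0, LATE, np.where(values < 1, MID_EARLY, EARLY))
    out = out.astype(object)
    out[~np.isfinite(values)] = None
    return out


@dataclass
class IntervalTrack:
    """A named set of genomic intervals, chromatin mark or timing values.

    ``intervals`` columns: chrom, start, end, value (str label for marks,
    float for timing). Intervals are 0-based half-open and must satisfy
    start < end.
    """

    name: str
    kind: str  # "chromatin_mark" | "replication_timing"
    intervals: pd.DataFrame

    def __post_init__(self):
        if self.kind not in ("chromatin_mark", "replication_timing"):
            raise InputError(f"unknown track kind {self.kind!r}")
        bad = self.intervals["start"] >= self.intervals["end"]
        if bad.any():
            first = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError("interval with start >= end", line=first + 1)


def read_bed(path, name: str, kind: str) -> IntervalTrack:
    """Read a 4-column BED file (chrom, start, end, label-or-value)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError("BED line needs 4 columns", line=lineno)
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError("non-integer BED coordinates", line=lineno)
            if start >= end:
                raise FormatError("interval with start >= end", line=lineno)
            value = float(parts[3]) if kind == "replication_timing" else parts[3]
            rows.append((parts[0], start, end, value))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    return IntervalTrack(name=name, kind=kind, intervals=df)


def write_bed(track: IntervalTrack, path) -> None:
    track.intervals.to_csv(path, sep="\t", header=False, index=False)


class _ChromIndex:
    """Sorted-interval index supporting point-overlap queries.

    Intervals are sorted by start with a running maximum of ends, so a
    backward scan from the insertion point finds every covering interval
    without missing long intervals that start early.
    """

    def __init__(self, starts, ends, values):
        order = np.argsort(starts, kind="stable")
        self.starts = np.asarray(starts)[order]
        self.ends = np.asarray(ends)[order]
        self.values = np.asarray(values, dtype=object)[order]
        self.cummax_end = np.maximum.accumulate(self.ends)

    def covering(self, pos: int):
        """Indices of intervals with start <= pos < end."""
        hi = int(np.searchsorted(self.starts, pos, side="right"))
        hits = []
        j = hi - 1
        while j >= 0 and self.cummax_end[j] > pos:
            if self.ends[j] > pos:
                hits.append(j)
            j -= 1
        return hits


def _build_index(track: IntervalTrack) -> dict:
    out = {}
    for chrom, grp in track.intervals.groupby("chrom"):
        out[chrom] = _ChromIndex(grp["start"].to_numpy(),
                                 grp["end"].to_numpy(),
                                 grp["value"].to_numpy())
    return out


def annotate_probes(
    manifest: pd.DataFrame,
    mark_tracks: list[IntervalTrack] = (),
    timing_track: IntervalTrack | None = None,
) -> pd.DataFrame:
    """Annotate each probe with chromatin-mark booleans and a timing value.

    A probe carries a mark iff its position lies in any interval of that
    mark's track. The timing value comes from the covering timing interval;
    when several overlap, the interval whose midpoint is nearest the probe
    wins. Probes on chromosomes absent from a track are uncovered (False /
    NaN), not errors. Adds a ``timing_class`` column from the fixed
    thresholds.
    """
    out = manifest.copy()
    chroms = manifest["chrom"].to_numpy()
    positions = manifest["pos"].to_numpy()

    for track in mark_tracks:
        if track.kind != "chromatin_mark":
            raise InputError(f"track {track.name!r} is not a chromatin mark")
        index = _build_index(track)
        flags = np.zeros(len(manifest), dtype=bool)
        for i, (chrom, pos) in enumerate(zip(chroms, positions)):
            ci = index.get(chrom)
            if ci is not None and ci.covering(int(pos)):
                flags[i] = True
        out[track.name] = flags

    if timing_track is not None:
        if timing_track.kind != "replication_timing":
            raise InputError("timing track has wrong kind")
        index = _build_index(timing_track)
        timing = np.full(len(manifest), np.nan)
        for i, (chrom, pos) in enumerate(zip(chroms, positions)):
            ci = index.get(chrom)
            if ci is None:
                continue
            hits = ci.covering(int(pos))
            if not hits:
                continue
            if len(hits) == 1:
                timing[i] = float(ci.values[hits[0]])
            else:
                hits = np.asarray(hits)
                mids = (ci.starts[hits] + ci.ends[hits]) / 2.0
                # ties in midpoint distance broken by (start, end)
                order = np.lexsort((ci.ends[hits], ci.starts[hits],
                                    np.abs(mids - pos)))
                timing[i] = float(ci.values[hits[order[0]]])
        out["timing"] = timing
        out["timing_class"] = classify_timing_array(timing)
    return out


@dataclass(frozen=True)
class TimingProfile:
    """Per-timing-class DMC fractions and the Δβ–timing correlation."""

    fractions: dict  # class -> fraction of the drug's covered DMCs
    r: float
    p_value: float
    n_dmcs: int  # flagged probes with timing coverage
    n_uncovered: int  # flagged probes without timing coverage


def timing_demethylation_profile(
    dmcs: pd.DataFrame,
    annotated: pd.DataFrame,
    cutoff: float = 0.0,
) -> TimingProfile:
    """Distribution of a drug's DMCs over timing classes, plus Pearson r of
    Δβ against the timing value over those DMCs.

    ``annotated`` must be a probe manifest with ``timing``/``timing_class``
    columns (see :func:`annotate_probes`), indexed or keyed by probe_id.
    Fractions are over flagged probes with timing coverage and sum to 1.
    """
    ann = annotated.set_index("probe_id") if "probe_id" in annotated.columns else annotated
    if "timing" not in ann.columns:
        raise InputError("manifest lacks timing annotation")
    col = flag_column(cutoff)
    if col not in dmcs.columns:
        raise InputError(f"no DMC flag column for cutoff {cutoff}")

    flagged = dmcs.index[dmcs[col].astype(bool)]
    timing = ann["timing"].reindex(flagged)
    covered = timing[np.isfinite(timing)]
    if len(covered) < 3:
        raise InputError("need >=3 demethylated probes with timing coverage")

    classes = pd.Series(classify_timing_array(covered.to_numpy()),
                        index=covered.index)
    fractions = {c: float((classes == c).mean()) for c in TIMING_CLASSES}

    delta = dmcs.loc[covered.index, "delta_beta"].to_numpy()
    tvals = covered.to_numpy()
    if np.ptp(delta) == 0 or np.ptp(tvals) == 0:
        r, p = float("nan"), float("nan")  # degenerate, correlation undefined
    else:
        res = stats.pearsonr(delta, tvals)
        r, p = float(res.statistic), float(res.pvalue)
    return TimingProfile(fractions=fractions, r=r, p_value=p,
                         n_dmcs=len(covered),
                         n_uncovered=int(len(flagged) - len(covered)))
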