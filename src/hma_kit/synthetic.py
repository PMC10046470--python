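"""Seeded synthetic panels, methylomes, and omics matrices.

Every generator is deterministic given its spec (seeds are explicit fields;
no global random state). Beta values are produced on the intensity scale —
methylated/unmethylated signals drawn from gamma-distributed totals and
passed through the beta formula — so the formula path is exercised end to
end. Response classes are never planted directly: the panel generator runs
the real AUC computation and tertile split on its generated curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dose_response as dr
from .annotation import CHROMATIN_MARKS, IntervalTrack
from .errors import ConfigurationError
from .methylome import MethylationExperiment, compute_beta

DEFAULT_TISSUES = {
    "blood": 0.2, "lung": 0.2, "breast": 0.15, "colon": 0.15,
    "skin": 0.1, "cns": 0.1, "ovary": 0.1,
}
DEFAULT_HEMATOPOIETIC = frozenset({"blood"})

#: 10-point 3-fold dilution series, nM (top dose 10 uM)
DEFAULT_DOSES = 10000.0 / 3.0 ** np.arange(9, -1, -1)


def _validate_proportions(proportions: dict):
    total = sum(proportions.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(f"tissue proportions sum to {total}, not 1")
    if any(p < 0 for p in proportions.values()):
        raise ConfigurationError("tissue proportions must be >= 0")


@dataclass(frozen=True)
class PanelSpec:
    """Configuration of a synthetic cell-line sensitivity panel.

    ``base_auc`` is the mean AUC of non-hematopoietic lines — the paper
    does not state the panel's AUC distribution, so this is an explicit
    modeling choice.
    """

    n_cell_lines: int = 199
    tissue_proportions: dict = field(default_factory=lambda: dict(DEFAULT_TISSUES))
    hematopoietic_tissues: frozenset = DEFAULT_HEMATOPOIETIC
    auc_shift_hematopoietic: float = -0.15
    noise_sd: float = 0.08
    seed: int = 0
    base_auc: float = 0.65
    n_replicates: int = 3
    viability_sd: float = 0.03
    hill: float = 1.5

    def __post_init__(self):
        if self.n_cell_lines < 6:
            raise ConfigurationError("n_cell_lines must be >= 6")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        _validate_proportions(self.tissue_proportions)


@dataclass(frozen=True)
class MethylomeSpec:
    """Configuration of synthetic panel + treatment methylomes."""

    n_probes: int = 2500
    n_regions: int = 500
    probes_per_region: int = 4
    planted_dmr_count: int = 50
    planted_effect: float = 0.3
    replicate_sd: float = 0.05
    timing_coupling: float = -0.05
    seed: int = 0
    line_effect_sd: float = 0.1  # per-(region, line) biological variability
    base_delta_a: float = -0.05  # mean treatment Δβ for drug A (before coupling)
    base_delta_b: float = -0.12  # drug B demethylates uniformly (no coupling)

    def __post_init__(self):
        if self.planted_dmr_count > self.n_regions:
            raise ConfigurationError("planted_dmr_count exceeds n_regions")
        if not 0 <= self.planted_effect < 1:
            raise ConfigurationError("planted_effect must be in [0, 1)")
        if self.replicate_sd <= 0:
            raise ConfigurationError("replicate_sd must be > 0")
        if self.n_probes < self.n_regions * self.probes_per_region:
            raise ConfigurationError(
                "n_probes must cover n_regions * probes_per_region")


@dataclass(frozen=True)
class OmicsSpec:
    """Configuration of synthetic expression/mutation/protein matrices."""

    n_genes: int = 1000
    planted_marker_count: int = 20
    planted_log2fc: float = 1.5
    confounded_gene_count: int = 30
    mutation_rate_background: float = 0.05
    planted_mutation_or: float = 6.0
    seed: int = 0
    n_proteins: int = 30

    def __post_init__(self):
        for name in ("n_genes", "planted_marker_count",
                     "confounded_gene_count", "n_proteins"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0 <= self.mutation_rate_background <= 1:
            raise ConfigurationError("mutation_rate_background must be in [0, 1]")
        if self.planted_mutation_or <= 0:
            raise ConfigurationError("planted_mutation_or must be > 0")
        if self.planted_marker_count + self.confounded_gene_count > self.n_genes:
            raise ConfigurationError("planted + confounded genes exceed n_genes")


# ---------------------------------------------------------------------------
# panel


def _auc_for_ec50(log_ec50: float, doses: np.ndarray, hill: float) -> float:
    viab = dr.four_pl(doses, 1.0, 0.0, 10 ** log_ec50, hill)
    x = np.log10(doses)
    return float(np.trapezoid(viab, x) / (x[-1] - x[0]))


def _ec50_for_target_auc(target: float, doses: np.ndarray, hill: float) -> float:
    """Bisect the 4PL midpoint whose noiseless curve has the target AUC."""
    lo, hi = np.log10(doses[0]) - 4, np.log10(doses[-1]) + 4
    a_lo, a_hi = _auc_for_ec50(lo, doses, hill), _auc_for_ec50(hi, doses, hill)
    target = float(np.clip(target, a_lo + 1e-6, a_hi - 1e-6))
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _auc_for_ec50(mid, doses, hill) < target:
            lo = mid
        else:
            hi = mid
    return 10 ** (0.5 * (lo + hi))


@dataclass
class PanelData:
    """Generated sensitivity panel: per-line records plus raw curves."""

    records: pd.DataFrame  # cell_line, tissue, hematopoietic, doubling_time,
    #                        auc, ic50, ic50_censored, sensitive, response_class
    curves: pd.DataFrame  # long: cell_line, drug, dose, replicate, viability
    target_auc: pd.Series  # planted AUC per line (ground truth)
    spec: PanelSpec


def generate_panel(spec: PanelSpec, drug: str = "drugA") -> PanelData:
    """Generate a seeded panel of dose–response curves and sensitivity records.

    Planted per-line AUC = base_auc + shift (hematopoietic lines) + noise;
    each line's 10-dose curve is a 4PL whose noiseless AUC equals the
    planted value. Recorded AUC/IC50, the sensitive flag, and the
    responder split are then *computed* from the generated curves.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cell_lines
    tissues = sorted(spec.tissue_proportions)
    probs = np.array([spec.tissue_proportions[t] for t in tissues])
    tissue = rng.choice(tissues, size=n, p=probs / probs.sum())
    heme = np.array([t in spec.hematopoietic_tissues for t in tissue])

    target = (spec.base_auc
              + spec.auc_shift_hematopoietic * heme
              + rng.normal(0.0, spec.noise_sd, n))
    target = np.clip(target, 0.02, 0.98)
    # responders proliferate faster: doubling time tracks planted AUC
    doubling = 18.0 + 50.0 * target + rng.normal(0.0, 4.0, n)

    cell_lines = [f"CL{i:04d}" for i in range(n)]
    doses = DEFAULT_DOSES
    curve_rows = []
    curves = []
    for i, cl in enumerate(cell_lines):
        ec50 = _ec50_for_target_auc(target[i], doses, spec.hill)
        true_v = dr.four_pl(doses, 1.0, 0.0, ec50, spec.hill)
        viab = np.clip(
            true_v[:, None] + rng.normal(0, spec.viability_sd,
                                         (len(doses), spec.n_replicates)),
            0.0, None)
        curves.append(dr.DoseResponseCurve(cell_line=cl, drug=drug,
                                           doses=doses, viabilities=viab))
        for j, d in enumerate(doses):
            for r in range(spec.n_replicates):
                curve_rows.append((cl, drug, d, r, viab[j, r]))

    curves_df = pd.DataFrame(
        curve_rows, columns=["cell_line", "drug", "dose", "replicate", "viability"])
    metadata = pd.DataFrame({
        "cell_line": cell_lines, "tissue": tissue,
        "hematopoietic": heme, "doubling_time": doubling,
    })
    records = dr.sensitivity_table(curves, metadata=metadata)
    records = dr.flag_sensitive(records)
    records = dr.classify_responders(records)
    return PanelData(records=records, curves=curves_df,
                     target_auc=pd.Series(target, index=cell_lines),
                     spec=spec)


# ---------------------------------------------------------------------------
# methylome


def _beta_from_target(target_p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Generate beta values with the given targets via the intensity path."""
    p = np.clip(target_p, 0.001, 0.98)
    total = rng.gamma(shape=20.0, scale=500.0, size=p.shape)
    M = p * total
    U = (1.0 - p) * total
    return compute_beta(M, U)


@dataclass
class MethylomeData:
    """Panel + treatment methylomes sharing one probe manifest."""

    panel_beta: pd.DataFrame  # probe x cell line
    region_map: pd.Series  # probe_id -> region_id (region probes only)
    manifest: pd.DataFrame  # probe_id, chrom, pos, genomic_feature
    timing_track: IntervalTrack
    mark_tracks: list
    planted_regions: list  # region ids hypermethylated in responders
    experiment: MethylationExperiment  # triplicate DMSO/drugA/drugB design
    true_delta: dict  # drug -> planted Δβ per probe (Series)
    probe_timing: pd.Series  # ground-truth timing value per probe
    spec: MethylomeSpec


def generate_methylome(spec: MethylomeSpec, panel: PanelData) -> MethylomeData:
    """Generate a promoter methylome for the panel plus a triplicate
    treatment experiment, on one pseudo-chromosome.

    Planted DMRs are hypermethylated by ``planted_effect`` in responder
    lines. Treatment Δβ for drug A is base_delta_a + timing_coupling *
    timing; drug B demethylates uniformly. Identical spec + panel ->
    identical output.
    """
    if panel.records.empty:
        raise ConfigurationError("panel is empty")
    rng = np.random.default_rng(spec.seed)
    chrom = "chr1"
    region_span = 2000
    n_region_probes = spec.n_regions * spec.probes_per_region

    probe_ids, positions, region_of, features = [], [], [], []
    feature_cycle = ("CGI", "TSS1500", "gene_body")
    for r in range(spec.n_regions):
        feat = feature_cycle[r % len(feature_cycle)]
        for j in range(spec.probes_per_region):
            probe_ids.append(f"cg{len(probe_ids):07d}")
            positions.append(r * region_span + 100 + j * 50)
            region_of.append(f"R{r:05d}")
            features.append(feat)
    intergenic_start = spec.n_regions * region_span
    for j in range(spec.n_probes - n_region_probes):
        probe_ids.append(f"cg{len(probe_ids):07d}")
        positions.append(intergenic_start + 100 + j * 50)
        region_of.append(None)
        features.append("noncoding" if j % 2 == 0 else "unannotated")

    manifest = pd.DataFrame({
        "probe_id": probe_ids, "chrom": chrom, "pos": positions,
        "genomic_feature": features,
    })
    region_map = pd.Series(region_of, index=probe_ids, name="region_id").dropna()
    genome_len = max(positions) + 200

    # replication-timing track: contiguous windows, values spanning all classes
    win = 200
    starts = np.arange(0, genome_len, win)
    timing_vals = rng.uniform(-2.0, 2.0, len(starts))
    timing_track = IntervalTrack(
        name="timing", kind="replication_timing",
        intervals=pd.DataFrame({"chrom": chrom, "start": starts,
                                "end": starts + win, "value": timing_vals}))
    probe_timing = pd.Series(
        timing_vals[np.asarray(positions) // win], index=probe_ids,
        name="timing")

    mark_tracks = []
    for mark in CHROMATIN_MARKS:
        n_iv = max(genome_len // 2000, 4)
        s = np.sort(rng.integers(0, genome_len - 1000, n_iv))
        lengths = rng.integers(200, 1000, n_iv)
        mark_tracks.append(IntervalTrack(
            name=mark, kind="chromatin_mark",
            intervals=pd.DataFrame({"chrom": chrom, "start": s,
                                    "end": s + lengths, "value": mark})))

    # --- panel methylome: responder-hypermethylated planted regions
    records = panel.records.set_index("cell_line")
    lines = list(records.index)
    responder = (records["response_class"] == dr.RESPONDER).to_numpy()

    region_ids = sorted(region_map.unique())
    planted = list(rng.choice(region_ids, size=spec.planted_dmr_count,
                              replace=False))
    planted_set = set(planted)

    region_base = pd.Series(rng.uniform(0.15, 0.55, len(region_ids)),
                            index=region_ids)
    probe_base = np.where(
        region_map.reindex(probe_ids).notna(),
        region_base.reindex(region_map.reindex(probe_ids)).to_numpy(),
        rng.uniform(0.15, 0.55, len(probe_ids)))
    probe_base = probe_base + rng.normal(0, 0.02, len(probe_ids))
    in_planted = region_map.reindex(probe_ids).isin(planted_set).to_numpy()

    # biological per-(region, line) variability, shared by a region's probes
    region_pos = {rid: i for i, rid in enumerate(region_ids)}
    region_line = rng.normal(0, spec.line_effect_sd,
                             (len(region_ids), len(lines)))
    probe_region_idx = np.array(
        [region_pos.get(r, -1) for r in region_map.reindex(probe_ids)])
    line_noise = np.where((probe_region_idx >= 0)[:, None],
                          region_line[probe_region_idx, :], 0.0)

    target = (probe_base[:, None]
              + spec.planted_effect * np.outer(in_planted, responder)
              + line_noise
              + rng.normal(0, spec.replicate_sd, (len(probe_ids), len(lines))))
    panel_beta = pd.DataFrame(_beta_from_target(target, rng),
                              index=probe_ids, columns=lines)
    panel_beta.index.name = "probe_id"

    # --- treatment experiment: triplicate DMSO / drugA / drugB
    timing = probe_timing.to_numpy()
    base0 = rng.uniform(0.3, 0.8, len(probe_ids))
    delta_a = np.clip(spec.base_delta_a + spec.timing_coupling * timing
                      + rng.normal(0, 0.005, len(probe_ids)),
                      -base0 + 0.005, 0.95 - base0)
    delta_b = np.clip(spec.base_delta_b
                      + rng.normal(0, 0.005, len(probe_ids)),
                      -base0 + 0.005, 0.95 - base0)

    samples, conditions, cols = [], [], {}
    for cond, delta in (("DMSO", np.zeros_like(base0)),
                        ("drugA", delta_a), ("drugB", delta_b)):
        for rep in range(3):
            name = f"{cond}_{rep + 1}"
            tgt = base0 + delta + rng.normal(0, spec.replicate_sd, len(base0))
            cols[name] = _beta_from_target(tgt, rng)
            samples.append(name)
            conditions.append(cond)
    exp_beta = pd.DataFrame(cols, index=probe_ids)
    exp_beta.index.name = "probe_id"
    design = pd.DataFrame({
        "condition": conditions,
        "replicate": [int(s.split("_")[1]) for s in samples],
    }, index=pd.Index(samples, name="sample"))
    experiment = MethylationExperiment(beta=exp_beta, design=design)

    return MethylomeData(
        panel_beta=panel_beta, region_map=region_map, manifest=manifest,
        timing_track=timing_track, mark_tracks=mark_tracks,
        planted_regions=planted, experiment=experiment,
        true_delta={"drugA": pd.Series(delta_a, index=probe_ids),
                    "drugB": pd.Series(delta_b, index=probe_ids)},
        probe_timing=probe_timing, spec=spec)


# ---------------------------------------------------------------------------
# omics


@dataclass
class OmicsData:
    """Expression, mutation, and protein matrices for a panel."""

    expression: pd.DataFrame  # gene x cell line, log2 scale
    mutations: pd.DataFrame  # gene x cell line, binary
    protein: pd.DataFrame  # protein x cell line
    planted_expression_genes: list
    confounded_genes: list
    planted_mutation_genes: list
    planted_proteins: list
    spec: OmicsSpec


def generate_omics(spec: OmicsSpec, panel: PanelData) -> OmicsData:
    """Generate omics matrices with planted response-class effects.

    Planted expression markers differ NR − R by ``planted_log2fc``;
    confounded genes differ only by lineage (balanced with respect to
    class once lineage is adjusted for); planted mutations are enriched in
    nonresponders at odds ratio ``planted_mutation_or``; planted proteins
    track sensitivity (anti-correlated with AUC).
    """
    if panel.records.empty:
        raise ConfigurationError("panel is empty")
    rng = np.random.default_rng(spec.seed)
    records = panel.records.set_index("cell_line")
    lines = list(records.index)
    n = len(lines)
    nr = (records["response_class"] == dr.NONRESPONDER).to_numpy(dtype=float)
    heme = records["hematopoietic"].to_numpy(dtype=float)

    genes = [f"G{i:05d}" for i in range(spec.n_genes)]
    base = rng.normal(8.0, 1.0, spec.n_genes)
    expr = base[:, None] + rng.normal(0.0, 1.0, (spec.n_genes, n))
    planted_genes = genes[:spec.planted_marker_count]
    confounded = genes[spec.planted_marker_count:
                       spec.planted_marker_count + spec.confounded_gene_count]
    expr[:spec.planted_marker_count] += spec.planted_log2fc * nr
    expr[spec.planted_marker_count:
         spec.planted_marker_count + spec.confounded_gene_count] += 1.5 * heme
    expression = pd.DataFrame(expr, index=genes, columns=lines)

    mut_genes = [f"M{i:05d}" for i in range(spec.n_genes)]
    prob = np.full((spec.n_genes, n), spec.mutation_rate_background)
    planted_mut = mut_genes[:spec.planted_marker_count]
    if spec.planted_marker_count:
        p0 = max(spec.mutation_rate_background, 0.12)
        odds_nr = spec.planted_mutation_or * p0 / (1 - p0)
        p_nr = odds_nr / (1 + odds_nr)
        prob[:spec.planted_marker_count] = np.where(nr > 0, p_nr, p0)
    mutations = pd.DataFrame(
        (rng.random((spec.n_genes, n)) < prob).astype(int),
        index=mut_genes, columns=lines)

    proteins = [f"P{i:04d}" for i in range(spec.n_proteins)]
    n_planted_prot = min(spec.planted_marker_count, spec.n_proteins)
    auc = records["auc"].to_numpy(dtype=float)
    auc_z = (auc - auc.mean()) / (auc.std() or 1.0)
    prot = rng.normal(0.0, 1.0, (spec.n_proteins, n))
    prot[:n_planted_prot] += -1.0 * auc_z  # high protein -> sensitive
    protein = pd.DataFrame(prot, index=proteins, columns=lines)

    return OmicsData(
        expression=expression, mutations=mutations, protein=protein,
        planted_expression_genes=planted_genes, confounded_genes=confounded,
        planted_mutation_genes=planted_mut,
        planted_proteins=proteins[:n_planted_prot], spec=spec)


# ---------------------------------------------------------------------------
# combination (synergy) data


def generate_combination(
    fit_a, fit_b, doses_a, doses_b,
    synergy_boost: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Dose-grid fa values under Loewe additivity of two median-effect drugs.

    For each cell, fa solves d_a/Dx_a(fa) + d_b/Dx_b(fa) = 1 (so the
    two-term CI is exactly 1); ``synergy_boost`` shifts fa upward toward 1
    (planting synergy, CI < 1) and ``noise_sd`` adds seeded noise.
    Returns an fa grid aligned to the dose grids.
    """
    from scipy.optimize import brentq

    rng = np.random.default_rng(seed)
    doses_a = np.asarray(doses_a, dtype=float)
    doses_b = np.asarray(doses_b, dtype=float)
    fa = np.zeros((len(doses_a), len(doses_b)))
    for i, da in enumerate(doses_a):
        for j, db in enumerate(doses_b):
            if da == 0 and db == 0:
                fa[i, j] = 0.0
                continue

            def ci_minus_one(f, da=da, db=db):
                total = 0.0
                if da > 0:
                    total += da / fit_a.dose_for_fa(f)
                if db > 0:
                    total += db / fit_b.dose_for_fa(f)
                return total - 1.0

            f = brentq(ci_minus_one, 1e-9, 1 - 1e-9)
            if synergy_boost:
                f = f + synergy_boost * f * (1 - f)
            if noise_sd:
                f = f + rng.normal(0, noise_sd)
            fa[i, j] = float(np.clip(f, 1e-6, 1 - 1e-6))
    return fa
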