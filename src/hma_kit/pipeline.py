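"""End-to-end pipeline: generate -> sensitivity -> annotate -> dmc ->
biomarkers -> synergy, driven by one YAML config, with a JSON run manifest
and hash-based stage caching."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation, biomarkers, dose_response as dr, methylome, synergy, synthetic
from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

STAGES = ("generate", "sensitivity", "annotate", "dmc", "biomarkers", "synergy")

DEFAULTS = {
    "seed": 0,
    "stages": list(STAGES),
    "fdr": 0.05,
    "dmc_cutoff": 0.0,
    "dmc_p_threshold": 0.05,
    "n_iterations": 1000,
    "panel": {},
    "methylome": {},
    "omics": {},
}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    outdir: Path
    seed: int = 0
    stages: tuple = STAGES
    fdr: float = 0.05
    dmc_cutoff: float = 0.0
    dmc_p_threshold: float = 0.05
    n_iterations: int = 1000
    panel: dict = field(default_factory=dict)
    methylome: dict = field(default_factory=dict)
    omics: dict = field(default_factory=dict)
    whitelist: list | None = None

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        if not 0 < self.fdr < 1:
            raise ConfigurationError("fdr must be in (0, 1)")
        if self.dmc_cutoff not in set(methylome.DMC_CUTOFFS):
            raise ConfigurationError(
                f"dmc_cutoff must be one of {methylome.DMC_CUTOFFS}")
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be >= 1")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path, outdir=None) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = {**DEFAULTS, **raw}
        if outdir is not None:
            cfg["outdir"] = outdir
        if "outdir" not in cfg:
            raise ConfigurationError("config must set outdir")
        return cls(**cfg)

    def to_dict(self) -> dict:
        return {
            "outdir": str(self.outdir), "seed": self.seed,
            "stages": list(self.stages), "fdr": self.fdr,
            "dmc_cutoff": self.dmc_cutoff,
            "dmc_p_threshold": self.dmc_p_threshold,
            "n_iterations": self.n_iterations, "panel": self.panel,
            "methylome": self.methylome, "omics": self.omics,
            "whitelist": self.whitelist,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _params_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False):
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


class PipelineRunner:
    """Executes stages in dependency order with manifest-based caching.

    A stage is skipped when the manifest from a previous run records the
    same config hash and identical sha256 digests for all its input and
    output files; any tampered file invalidates the stage.
    """

    # per-stage input dependencies (files produced by earlier stages)
    STAGE_INPUTS = {
        "generate": [],
        "sensitivity": ["curves.tsv", "panel_records.tsv"],
        "annotate": ["probe_manifest.tsv", "timing.bed"],
        "dmc": ["experiment_beta.tsv", "design.tsv", "annotated_manifest.tsv"],
        "biomarkers": ["sensitivity.tsv", "expression.tsv", "mutations.tsv",
                       "beta_panel.tsv", "region_map.tsv"],
        "synergy": [],
    }

    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = config.outdir
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.outdir / "manifest.json"
        self.manifest = {"config": config.to_dict(),
                         "config_hash": _params_hash(config.to_dict()),
                         "seed": config.seed, "stages": {}}
        self.previous = None
        if self.manifest_path.exists():
            try:
                self.previous = json.loads(self.manifest_path.read_text())
            except json.JSONDecodeError:
                self.previous = None

    # -- caching helpers ---------------------------------------------------

    def _hashes(self, names) -> dict:
        out = {}
        for name in names:
            p = self.outdir / name
            out[name] = _sha256(p) if p.exists() else None
        return out

    def _cached(self, stage: str, outputs: list) -> bool:
        if self.previous is None:
            return False
        prev = self.previous.get("stages", {}).get(stage)
        if not prev or prev.get("status") != "ok":
            return False
        if self.previous.get("config_hash") != self.manifest["config_hash"]:
            return False
        for name, digest in {**prev.get("inputs", {}),
                             **prev.get("outputs", {})}.items():
            p = self.outdir / name
            if digest is None or not p.exists() or _sha256(p) != digest:
                return False
        return set(prev.get("outputs", {})) >= set(outputs)

    def _record(self, stage: str, inputs: list, outputs: list,
                elapsed: float, cached: bool, counts: dict | None = None):
        self.manifest["stages"][stage] = {
            "status": "ok", "cached": cached,
            "elapsed_s": round(elapsed, 3),
            "inputs": self._hashes(inputs),
            "outputs": self._hashes(outputs),
            "counts": counts or {},
        }

    # -- stages ------------------------------------------------------------

    def run(self, stages=None) -> dict:
        stages = [s for s in STAGES if s in (stages or self.config.stages)]
        for stage in stages:
            method = getattr(self, f"_stage_{stage}")
            t0 = time.monotonic()
            try:
                method()
            except Exception as exc:
                self.manifest["stages"][stage] = {
                    "status": "failed", "error": f"{type(exc).__name__}: {exc}",
                }
                self._flush()
                raise
            logger.info("stage %s done in %.2fs", stage,
                        time.monotonic() - t0)
        self._flush()
        return self.manifest

    def _flush(self):
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2))

    def _run_stage(self, stage, outputs, fn):
        inputs = self.STAGE_INPUTS[stage]
        if self._cached(stage, outputs):
            prev = self.previous["stages"][stage]
            self._record(stage, inputs, outputs, 0.0, cached=True,
                         counts=prev.get("counts"))
            logger.info("stage %s: cache hit, skipped", stage)
            return
        t0 = time.monotonic()
        counts = fn() or {}
        self._record(stage, inputs, outputs, time.monotonic() - t0,
                     cached=False, counts=counts)

    def _stage_generate(self):
        cfg = self.config
        outputs = ["panel_records.tsv", "curves.tsv", "beta_panel.tsv",
                   "probe_manifest.tsv", "region_map.tsv", "timing.bed",
                   "experiment_beta.tsv", "design.tsv", "expression.tsv",
                   "mutations.tsv", "protein.tsv", "planted.json"]
        outputs += [f"{m}.bed" for m in annotation.CHROMATIN_MARKS]

        def fn():
            panel = synthetic.generate_panel(
                synthetic.PanelSpec(seed=cfg.seed, **cfg.panel))
            meth = synthetic.generate_methylome(
                synthetic.MethylomeSpec(seed=cfg.seed + 1, **cfg.methylome), panel)
            omics = synthetic.generate_omics(
                synthetic.OmicsSpec(seed=cfg.seed + 2, **cfg.omics), panel)
            d = self.outdir
            _write_tsv(panel.records, d / "panel_records.tsv")
            _write_tsv(panel.curves, d / "curves.tsv")
            _write_tsv(meth.panel_beta, d / "beta_panel.tsv", index=True)
            _write_tsv(meth.manifest, d / "probe_manifest.tsv")
            _write_tsv(meth.region_map.rename_axis("probe_id").reset_index(),
                       d / "region_map.tsv")
            annotation.write_bed(meth.timing_track, d / "timing.bed")
            for tr in meth.mark_tracks:
                annotation.write_bed(tr, d / f"{tr.name}.bed")
            _write_tsv(meth.experiment.beta, d / "experiment_beta.tsv", index=True)
            _write_tsv(meth.experiment.design, d / "design.tsv", index=True)
            _write_tsv(omics.expression, d / "expression.tsv", index=True)
            _write_tsv(omics.mutations, d / "mutations.tsv", index=True)
            _write_tsv(omics.protein, d / "protein.tsv", index=True)
            (d / "planted.json").write_text(json.dumps({
                "planted_regions": meth.planted_regions,
                "planted_expression_genes": omics.planted_expression_genes,
                "planted_mutation_genes": omics.planted_mutation_genes,
            }, indent=2))
            return {"n_cell_lines": len(panel.records),
                    "n_probes": len(meth.manifest),
                    "n_genes": len(omics.expression)}

        self._run_stage("generate", outputs, fn)

    def _stage_sensitivity(self):
        d = self.outdir
        outputs = ["sensitivity.tsv", "tissue_enrichment.tsv"]

        def fn():
            curves_df = pd.read_csv(d / "curves.tsv", sep="\t")
            meta = pd.read_csv(d / "panel_records.tsv", sep="\t")[
                ["cell_line", "tissue", "hematopoietic", "doubling_time"]]
            curves = dr.curves_from_long(curves_df)
            records = dr.sensitivity_table(curves, metadata=meta)
            records = dr.flag_sensitive(records)
            records = dr.classify_responders(records)
            _write_tsv(records, d / "sensitivity.tsv")
            _write_tsv(dr.all_tissue_odds_ratios(records),
                       d / "tissue_enrichment.tsv")
            return {"n_records": len(records)}

        self._run_stage("sensitivity", outputs, fn)

    def _stage_annotate(self):
        d = self.outdir
        outputs = ["annotated_manifest.tsv"]

        def fn():
            manifest = pd.read_csv(d / "probe_manifest.tsv", sep="\t")
            marks = [annotation.read_bed(d / f"{m}.bed", m, "chromatin_mark")
                     for m in annotation.CHROMATIN_MARKS
                     if (d / f"{m}.bed").exists()]
            timing = annotation.read_bed(d / "timing.bed", "timing",
                                         "replication_timing")
            ann = annotation.annotate_probes(manifest, marks, timing)
            _write_tsv(ann, d / "annotated_manifest.tsv")
            return {"n_probes": len(ann)}

        self._run_stage("annotate", outputs, fn)

    def _stage_dmc(self):
        d = self.outdir
        cfg = self.config
        outputs = ["dmc_drugA.tsv", "dmc_drugB.tsv", "dmc_summary.json",
                   "demeth_ratio.tsv"]

        def fn():
            beta = pd.read_csv(d / "experiment_beta.tsv", sep="\t",
                               index_col="probe_id")
            design = pd.read_csv(d / "design.tsv", sep="\t", index_col="sample")
            exp = methylome.MethylationExperiment(beta=beta, design=design)
            dmcs = {}
            for drug in ("drugA", "drugB"):
                t = methylome.call_dmcs(exp, drug,
                                        p_threshold=cfg.dmc_p_threshold)
                dmcs[drug] = t
                _write_tsv(t.reset_index(), d / f"dmc_{drug}.tsv")
            shared = methylome.shared_dmcs(dmcs["drugA"], dmcs["drugB"],
                                           cfg.dmc_cutoff)
            ann = pd.read_csv(d / "annotated_manifest.tsv", sep="\t")
            features = ann.set_index("probe_id")["genomic_feature"]
            ratio = methylome.normalized_demethylation_ratio(
                dmcs["drugA"], dmcs["drugB"], features, cfg.dmc_cutoff)
            _write_tsv(ratio, d / "demeth_ratio.tsv")
            profiles = {}
            for drug in ("drugA", "drugB"):
                try:
                    prof = annotation.timing_demethylation_profile(
                        dmcs[drug], ann, cfg.dmc_cutoff)
                    profiles[drug] = {"fractions": prof.fractions,
                                      "r": prof.r, "p": prof.p_value,
                                      "n_dmcs": prof.n_dmcs}
                except InputError:
                    profiles[drug] = None
            summary = {
                "cutoff": cfg.dmc_cutoff,
                "shared": shared._asdict(),
                "counts_by_cutoff": {
                    drug: {f"{c:g}": int(t[methylome.flag_column(c)].sum())
                           for c in methylome.DMC_CUTOFFS}
                    for drug, t in dmcs.items()},
                "timing_profiles": profiles,
            }
            (d / "dmc_summary.json").write_text(json.dumps(summary, indent=2))
            return {"shared": shared.shared}

        self._run_stage("dmc", outputs, fn)

    def _stage_biomarkers(self):
        d = self.outdir
        cfg = self.config
        outputs = ["de_results.tsv", "mutation_results.tsv", "dmr_results.tsv",
                   "dmr_score.json"]

        def fn():
            records = pd.read_csv(d / "sensitivity.tsv", sep="\t").set_index(
                "cell_line")
            classes = records["response_class"]
            lineage = records["hematopoietic"].astype(int)
            expr = pd.read_csv(d / "expression.tsv", sep="\t", index_col=0)
            de = biomarkers.differential_expression(expr, classes, lineage)
            _write_tsv(de, d / "de_results.tsv")

            mut = pd.read_csv(d / "mutations.tsv", sep="\t", index_col=0)
            whitelist = set(cfg.whitelist) if cfg.whitelist else None
            mut = biomarkers.filter_mutations(mut, whitelist)
            ma = biomarkers.mutation_association(mut, classes, lineage)
            _write_tsv(ma, d / "mutation_results.tsv")

            beta = pd.read_csv(d / "beta_panel.tsv", sep="\t",
                               index_col="probe_id")
            region_map = pd.read_csv(d / "region_map.tsv", sep="\t").set_index(
                "probe_id")["region_id"]
            region_meth = biomarkers.aggregate_regions(beta, region_map)
            dmr = biomarkers.differential_methylation_regions(
                region_meth, classes, lineage)
            _write_tsv(dmr, d / "dmr_results.tsv")

            sig = biomarkers.significant_regions(dmr, fdr=cfg.fdr)
            score_report = {"n_significant": len(sig), "fdr": cfg.fdr}
            if len(sig) >= 1:
                ic50 = records["ic50"]
                censored = records["ic50_censored"]
                score = biomarkers.region_set_score(sig, region_meth, ic50,
                                                    censored)
                perm = biomarkers.permutation_null(
                    len(sig), list(region_meth.index), region_meth, ic50,
                    n_iterations=cfg.n_iterations, seed=cfg.seed,
                    r_observed=score.r_observed, censored=censored)
                score_report.update({
                    "r_observed": score.r_observed,
                    "p_parametric": score.p_parametric,
                    "empirical_p": perm.empirical_p,
                    "n_iterations": perm.n_iterations,
                    "universe_size": perm.universe_size,
                    "n_lines": score.n_lines,
                })
            (d / "dmr_score.json").write_text(
                json.dumps(score_report, indent=2))
            return {"n_significant_regions": len(sig)}

        self._run_stage("biomarkers", outputs, fn)

    def _stage_synergy(self):
        d = self.outdir
        cfg = self.config
        outputs = ["ci_matrix.tsv", "synergy_summary.json"]

        def fn():
            fit_a = synergy.MedianEffectFit(drug="drugA", m=1.2, Dm=50.0,
                                            r2=1.0, n_points=8)
            fit_b = synergy.MedianEffectFit(drug="drugC", m=0.9, Dm=400.0,
                                            r2=1.0, n_points=8)
            doses_a = np.array([0.0, 12.5, 25, 50, 100, 200])
            doses_b = np.array([0.0, 100, 200, 400, 800, 1600])
            fa = synthetic.generate_combination(
                fit_a, fit_b, doses_a, doses_b, synergy_boost=0.4,
                noise_sd=0.01, seed=cfg.seed)
            matrix = synergy.CombinationMatrix(doses_a=doses_a,
                                               doses_b=doses_b, fa=fa,
                                               drug_a="drugA", drug_b="drugC")
            summary = synergy.score_matrix(matrix, fit_a, fit_b)
            ci_df = pd.DataFrame(matrix.ci, index=doses_a, columns=doses_b)
            ci_df.index.name = "dose_a\\dose_b"
            _write_tsv(ci_df, d / "ci_matrix.tsv", index=True)
            (d / "synergy_summary.json").write_text(json.dumps({
                "n_scored": summary.n_scored,
                "n_unscored": summary.n_unscored,
                "fraction_synergistic": summary.fraction_synergistic,
                "median_ci": summary.median_ci,
            }, indent=2))
            return {"n_scored": summary.n_scored}

        self._run_stage("synergy", outputs, fn)


def run_pipeline(config: RunConfig, stages=None) -> dict:
    """Run the pipeline; returns the manifest dict (also written to disk)."""
    return PipelineRunner(config).run(stages=stages)
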