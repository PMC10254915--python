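"""End-to-end orchestration: metabolomics -> expression -> flux -> linkage.

A :class:`RunConfig` names the inputs (model, count matrix, gene lengths,
metabolite table, sample-group map) and the thresholds; :func:`run_pipeline`
executes every stage, writes each stage's table to the run directory and a
machine-readable ``summary.json``, and is byte-reproducible for a fixed
config and seed.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import expression as ex
from . import flux as fx
from . import linkage as lk
from . import metabolomics as mb
from .model_io import MetabolicModel, load_model

log = logging.getLogger("omicsflux")


class ConfigError(ValueError):
    pass


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Paths, group labels and thresholds for one pipeline run."""

    model_path: str
    counts_path: str
    lengths_path: str
    metabolites_path: str
    groups_path: str
    control_group: str
    malignant_groups: list[str]
    out_dir: str
    model_format: str = "json"
    de_fdr: float = 0.01
    de_fc: float = 2.0
    flux_fdr: float = 0.05
    min_diff: float = 0.001
    metabo_fdr: float = 0.05
    k: float | str = "auto"
    normalization: str = "autoscale"
    n_metabolite_clusters: int = 4
    seed: int = 0

    def validate(self, check_paths: bool = True) -> None:
        for name in ("de_fdr", "flux_fdr", "metabo_fdr"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigError(f"{name} must lie in (0, 1], got {v}")
        if self.de_fc < 1:
            raise ConfigError(f"de_fc must be >= 1, got {self.de_fc}")
        if self.min_diff < 0:
            raise ConfigError("min_diff must be >= 0")
        if self.k != "auto" and (not isinstance(self.k, (int, float)) or self.k <= 0):
            raise ConfigError(f"k must be 'auto' or a positive number, got {self.k!r}")
        if self.normalization not in ("autoscale", "log_autoscale", "none"):
            raise ConfigError(f"unknown normalization {self.normalization!r}")
        if not self.malignant_groups:
            raise ConfigError("at least one malignant group is required")
        if check_paths:
            for name in ("model_path", "counts_path", "lengths_path",
                         "metabolites_path", "groups_path"):
                p = getattr(self, name)
                if not os.path.exists(p):
                    raise ConfigError(f"{name} does not exist: {p}")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")


def read_group_map(path) -> dict[str, str]:
    """Two-column TSV (sample <tab> group) -> mapping."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["sample", "group"], dtype=str)
    return dict(zip(df["sample"], df["group"]))


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t")


@dataclass
class PipelineResult:
    summary: dict
    out_dir: Path
    de_tables: dict[str, ex.DETable] = field(default_factory=dict)
    diff_flux: dict[str, fx.DiffFluxTable] = field(default_factory=dict)
    perturbed: mb.PerturbedMetaboliteSet | None = None
    report: pd.DataFrame | None = None


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every stage and write outputs plus ``summary.json``.

    On a stage failure the partial outputs are retained and ``MANIFEST``
    marks the run incomplete with the failing stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")
    manifest: dict = {"complete": False, "stages_done": []}
    summary: dict = {"seed": config.seed}
    result = PipelineResult(summary, out)

    def finish_stage(name: str) -> None:
        manifest["stages_done"].append(name)
        with open(out / "MANIFEST", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        log.info("[%s] done", name)

    def fail(name: str, exc: Exception) -> PipelineError:
        manifest["failed_stage"] = name
        with open(out / "MANIFEST", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return PipelineError(name, exc)

    # ---- load inputs ----
    stage = "load"
    try:
        model = load_model(config.model_path, format=config.model_format)
        counts = pd.read_csv(config.counts_path, sep="\t", index_col=0)
        lengths = pd.read_csv(config.lengths_path, sep="\t",
                              index_col=0).iloc[:, 0]
        groups = read_group_map(config.groups_path)
        met_table = mb.MetaboliteTable.from_csv(
            config.metabolites_path, groups, set(config.malignant_groups))
    except Exception as exc:
        raise fail(stage, exc)
    finish_stage(stage)

    # ---- metabolomics ----
    stage = "metabolomics"
    try:
        norm = mb.normalize_abundances(met_table, config.normalization)
        pres = mb.pca(norm)
        pres.scores.to_csv(out / "pca_scores.csv")
        pres.loadings.to_csv(out / "pca_loadings.csv")
        clus = mb.cluster_metabolites(norm, k=config.n_metabolite_clusters)
        clus.labels.to_frame().to_csv(out / "metabolite_clusters.tsv", sep="\t")
        perturbed = mb.call_perturbed_metabolites(
            met_table, fdr_cutoff=config.metabo_fdr,
            n_clusters=config.n_metabolite_clusters)
        _write_tsv(perturbed.table, out / "perturbed_metabolites.tsv")
        result.perturbed = perturbed
        summary["pca_variance_pct"] = [
            round(float(f) * 100, 4) for f in pres.variance_fraction]
        summary["n_perturbed_metabolites"] = len(perturbed.flagged)
        summary["perturbed_metabolites"] = dict(sorted(perturbed.flagged.items()))
    except Exception as exc:
        raise fail(stage, exc)
    finish_stage(stage)

    # ---- expression ----
    stage = "expression"
    try:
        expr = ex.compute_rpkm(counts, lengths, sample_groups=groups)
        _write_tsv(expr.values.round(6), out / "rpkm.tsv")
        de_tables: dict[str, ex.DETable] = {}
        summary["de"] = {}
        for case in config.malignant_groups:
            det = ex.differential_expression(
                expr, case, config.control_group,
                fdr_cutoff=config.de_fdr, fc_cutoff=config.de_fc)
            de_tables[case] = det
            _write_tsv(det.table, out / f"de_{case}_vs_{config.control_group}.tsv")
            summary["de"][case] = {"up": len(det.up), "down": len(det.down)}
        result.de_tables = de_tables
        if len(config.malignant_groups) >= 2:
            a, b = (de_tables[g] for g in config.malignant_groups[:2])
            summary["consensus_up"] = sorted(ex.consensus_genes(a, b, ex.UP))
            summary["consensus_down"] = sorted(ex.consensus_genes(a, b, ex.DOWN))
            summary["n_consensus_up"] = len(summary["consensus_up"])
            summary["n_consensus_down"] = len(summary["consensus_down"])
    except Exception as exc:
        raise fail(stage, exc)
    finish_stage(stage)

    # ---- flux ----
    stage = "flux"
    try:
        k = fx.auto_k(model, expr) if config.k == "auto" else float(config.k)
        summary["k"] = round(k, 10)
        all_groups = [config.control_group] + list(config.malignant_groups)
        fluxes = {g: fx.replicate_fluxes(model, expr, g, k) for g in all_groups}
        for g, dists in fluxes.items():
            mat = pd.concat([d.fluxes.rename(d.sample_id) for d in dists], axis=1)
            _write_tsv(mat.round(9), out / f"fluxes_{g}.tsv")
        diff_tables: dict[str, fx.DiffFluxTable] = {}
        summary["diff_flux"] = {}
        summary["flux_controlling"] = {}
        for case in config.malignant_groups:
            diff = fx.differential_flux(
                fluxes[case], fluxes[config.control_group],
                fdr=config.flux_fdr, min_diff=config.min_diff,
                case=case, control=config.control_group)
            diff_tables[case] = diff
            _write_tsv(diff.table.round(9),
                       out / f"diff_flux_{case}_vs_{config.control_group}.tsv")
            summary["diff_flux"][case] = sorted(diff.significant_reactions)
            pairs = fx.flux_controlling_genes(diff, result.de_tables[case], model)
            pd.DataFrame([vars(p) for p in pairs]).to_csv(
                out / f"flux_controlling_{case}.tsv", sep="\t", index=False)
            summary["flux_controlling"][case] = [
                [p.reaction_id, p.gene_id, p.gene_call] for p in pairs]
        result.diff_flux = diff_tables
    except Exception as exc:
        raise fail(stage, exc)
    finish_stage(stage)

    # ---- linkage ----
    stage = "linkage"
    try:
        first_case = config.malignant_groups[0]
        report = lk.integrate_report(result.perturbed, model,
                                     result.de_tables[first_case],
                                     result.diff_flux[first_case])
        report.to_csv(out / "integrated_report.tsv", sep="\t", index=False)
        result.report = report
        summary["n_report_rows"] = int(len(report))
    except Exception as exc:
        raise fail(stage, exc)
    finish_stage(stage)

    manifest["complete"] = True
    with open(out / "MANIFEST", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    result.summary = summary
    return result
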