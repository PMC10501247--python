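"""End-to-end orchestration: config, input loading, stages, reports.

A run is deterministic given (inputs, config, seed): every stage draws its
randomness from a dedicated child stream of the run seed, and no persisted
artifact contains timestamps. Cohorts whose normal arm is smaller than
``min_normal_samples`` are excluded from the differential, co-expression and
dysregulation stages (with a logged reason) but still contribute to the
alteration-frequency and survival stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import clinical, coexpression, differential, dysregulation, genomics, io
from ._version import __version__
from .errors import (DegenerateSplitError, FamnetError, InvalidInputError,
                     InvalidParameterError, UndefinedCorrelationError)

__all__ = ["Thresholds", "CohortDef", "PipelineConfig", "StageReport",
           "load_inputs", "run_pipeline", "write_reports", "STAGES"]

log = logging.getLogger(__name__)

STAGES = ("genomics", "differential", "coexpression", "dysregulation",
          "survival", "drugs")


@dataclass
class Thresholds:
    de_log2fc: float = 1.0
    de_alpha: float = 0.05
    methylation_alpha: float = 0.05
    coexpr_alpha: float = 0.01
    n_null_pairs: int = 10000
    n_perm: int = 1000
    target_min_score: float = 100.0
    dysregulation_alpha: float = 0.05
    drug_pcc: float = 0.2
    drug_alpha: float = 0.05
    survival_alpha: float = 0.05
    min_normal_samples: int = 10
    cnv_amp_ge: float = 1.0
    cnv_del_le: float = -1.0

    def validate(self) -> None:
        for name in ("de_alpha", "methylation_alpha", "coexpr_alpha",
                     "dysregulation_alpha", "drug_alpha", "survival_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise InvalidParameterError(f"{name} must be in (0, 1), got {v}")
        for name in ("de_log2fc", "n_null_pairs", "n_perm", "drug_pcc",
                     "min_normal_samples"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if not self.cnv_del_le < self.cnv_amp_ge:
            raise InvalidParameterError("cnv_del_le must be below cnv_amp_ge")


@dataclass
class CohortDef:
    name: str
    cancer_samples: Sequence[str] | None = None  # None = all matrix columns
    normal_samples: Sequence[str] | None = None


@dataclass
class PipelineConfig:
    inputs: dict[str, str]
    outdir: str
    seed: int = 0
    cohorts: list[CohortDef] = field(default_factory=list)
    thresholds: Thresholds = field(default_factory=Thresholds)

    REQUIRED_INPUTS = ("expression_cancer", "expression_normal", "family_genes")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        thresholds = Thresholds(**raw.get("thresholds", {}))
        cohorts = [CohortDef(**c) for c in raw.get("cohorts", [])]
        return cls(inputs=dict(raw["inputs"]), outdir=raw["outdir"],
                   seed=int(raw.get("seed", 0)), cohorts=cohorts,
                   thresholds=thresholds)

    def validate(self) -> None:
        self.thresholds.validate()
        for key in self.REQUIRED_INPUTS:
            if key not in self.inputs:
                raise InvalidParameterError(f"missing required input {key!r}")
        for key, path in self.inputs.items():
            if not Path(path).exists():
                raise InvalidInputError(f"input {key!r}: no such file {path}")

    def config_hash(self) -> str:
        # outdir is excluded: the destination does not influence results
        payload = {"inputs": self.inputs,
                   "seed": self.seed,
                   "cohorts": [asdict(c) for c in self.cohorts],
                   "thresholds": asdict(self.thresholds)}
        blob = json.dumps(payload, sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class StageReport:
    stage: str
    n_in: int = 0
    n_out: int = 0
    dropped: dict[str, int] = field(default_factory=dict)
    seed: int | None = None
    wall_time_s: float = 0.0  # logged only, never persisted

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())

    def reconciles(self) -> bool:
        return self.n_in == self.n_out + self.n_dropped

    def to_json(self) -> dict:
        return {"stage": self.stage, "n_in": self.n_in, "n_out": self.n_out,
                "n_dropped": self.n_dropped, "dropped": dict(self.dropped),
                "seed": self.seed}


# ----------------------------------------------------------------------
def load_inputs(config: PipelineConfig) -> dict:
    """Load and validate every configured input table.

    Returns the tables plus a sample-intersection report across omics;
    samples missing from a secondary omic are reported, not fatal.
    """
    config.validate()
    paths = config.inputs
    data: dict = {}
    data["expression_cancer"] = io.read_matrix(paths["expression_cancer"], "gene")
    data["expression_normal"] = io.read_matrix(paths["expression_normal"], "gene")
    data["family_genes"] = io.read_gene_list(paths["family_genes"])
    if "expression_cell_lines" in paths:
        data["expression_cell_lines"] = io.read_matrix(paths["expression_cell_lines"], "gene")
    if "cnv" in paths:
        data["cnv"] = io.read_matrix(paths["cnv"], "gene")
    if "methylation" in paths:
        data["methylation"] = io.read_matrix(paths["methylation"], "probe",
                                             value_range=(0.0, 1.0))
    if "probe_map" in paths:
        data["probe_map"] = io.read_probe_map(paths["probe_map"])
    if "mutations" in paths:
        data["mutations"] = io.read_mutations(paths["mutations"])
    if "targets" in paths:
        data["targets"] = io.read_targets(paths["targets"])
    if "survival" in paths:
        data["survival"] = io.read_survival(paths["survival"])
    if "drug_ic50" in paths:
        data["drug_ic50"] = io.read_table(paths["drug_ic50"],
                                          ["cell_line", "drug", "ic50"])
    if "drug_annotation" in paths:
        data["drug_annotation"] = io.read_table(paths["drug_annotation"],
                                                ["drug", "target_gene", "pathway"])

    cancer_cols = set(data["expression_cancer"].columns)
    intersections = {}
    for key in ("cnv", "methylation"):
        if key in data:
            shared = cancer_cols & set(data[key].columns)
            intersections[key] = {
                "n_shared_with_expression": len(shared),
                "missing_from_omic": sorted(cancer_cols - set(data[key].columns)),
            }
    data["sample_intersections"] = intersections

    if not config.cohorts:
        config.cohorts = [CohortDef(name="ALL")]
    resolved = []
    for c in config.cohorts:
        cancer = list(c.cancer_samples) if c.cancer_samples else list(data["expression_cancer"].columns)
        normal = list(c.normal_samples) if c.normal_samples else list(data["expression_normal"].columns)
        resolved.append(CohortDef(c.name, cancer, normal))
    data["cohorts"] = resolved
    return data


def _gated_cohorts(data, thresholds):
    passed, skipped = [], []
    for c in data["cohorts"]:
        if len(c.normal_samples) >= thresholds.min_normal_samples:
            passed.append(c)
        else:
            skipped.append(c.name)
            log.info("cohort %s skipped: %d normal samples < %d", c.name,
                     len(c.normal_samples), thresholds.min_normal_samples)
    return passed, skipped


def _child_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {name: np.random.default_rng(ss) for name, ss in zip(STAGES, children)}


# ----------------------------------------------------------------------
def _stage_genomics(data, th: Thresholds):
    report = StageReport("genomics")
    expr_c = data["expression_cancer"]
    family = data["family_genes"]
    freq_frames, alt_rows, corr_rows = [], [], []
    for cohort in data["cohorts"]:
        report.n_in += 1
        freq = None
        if "mutations" in data:
            freq = genomics.mutation_frequency(
                data["mutations"], cohort.cancer_samples, family, cohort.name)
        if "cnv" in data:
            cnv_cols = [s for s in cohort.cancer_samples if s in data["cnv"].columns]
            cf = genomics.cnv_frequency(data["cnv"][cnv_cols].loc[
                [g for g in family if g in data["cnv"].index]],
                cnv_cols, th.cnv_amp_ge, th.cnv_del_le, cohort.name)
            freq = cf if freq is None else freq.merge(
                cf.drop(columns="n_samples"), on=["gene", "cohort"], how="left")
        if freq is not None:
            freq_frames.append(freq)

        cohort_expr = expr_c[[s for s in cohort.cancer_samples if s in expr_c.columns]]
        if "mutations" in data:
            muts = data["mutations"]
            for gene in family:
                if gene not in cohort_expr.index:
                    continue
                carriers = set(muts.loc[muts["gene"] == gene, "sample"])
                status = np.array([s in carriers for s in cohort_expr.columns])
                try:
                    res = genomics.alteration_expression_test(
                        cohort_expr.loc[gene].to_numpy(), status)
                except InvalidInputError:
                    continue  # gene unmutated (or fully mutated) in cohort
                alt_rows.append((gene, cohort.name, "mutation", res.statistic,
                                 res.p, res.median_a, res.median_b))
        if "cnv" in data:
            for gene in family:
                if gene not in cohort_expr.index or gene not in data["cnv"].index:
                    continue
                shared = [s for s in cohort_expr.columns if s in data["cnv"].columns]
                try:
                    r, p = genomics.omic_expression_correlation(
                        cohort_expr.loc[gene, shared].to_numpy(),
                        data["cnv"].loc[gene, shared].to_numpy())
                except (InvalidInputError, UndefinedCorrelationError):
                    continue
                corr_rows.append((gene, cohort.name, "cnv", r, p))
        report.n_out += 1
    out = {
        "alteration_frequency": pd.concat(freq_frames, ignore_index=True)
        if freq_frames else pd.DataFrame(
            columns=["gene", "cohort", "mutation_freq", "n_samples"]),
        "alteration_expression": pd.DataFrame(alt_rows, columns=[
            "gene", "cohort", "alteration", "statistic", "p",
            "median_altered", "median_unaltered"]),
        "omic_expression_correlation": pd.DataFrame(corr_rows, columns=[
            "gene", "cohort", "omic", "r", "p"]),
    }
    return out, report


def _stage_differential(data, th: Thresholds):
    report = StageReport("differential")
    de_frames, meth_frames = [], []
    passed, skipped = _gated_cohorts(data, th)
    report.n_in = len(data["cohorts"])
    for name in skipped:
        report.dropped[f"cohort {name}: below min_normal_samples"] = 1
    family = data["family_genes"]
    for cohort in passed:
        expr_c = data["expression_cancer"]
        expr_n = data["expression_normal"]
        fam_c = expr_c.loc[[g for g in family if g in expr_c.index],
                           [s for s in cohort.cancer_samples if s in expr_c.columns]]
        fam_n = expr_n.loc[[g for g in family if g in expr_n.index],
                           [s for s in cohort.normal_samples if s in expr_n.columns]]
        de_frames.append(differential.de_test(fam_c, fam_n, cohort.name,
                                              th.de_log2fc, th.de_alpha))
        if "methylation" in data and "probe_map" in data:
            betas = differential.aggregate_promoter_probes(
                data["methylation"], data["probe_map"])
            bc = betas[[s for s in cohort.cancer_samples if s in betas.columns]]
            bn = betas[[s for s in cohort.normal_samples if s in betas.columns]]
            if bc.shape[1] and bn.shape[1]:
                meth_frames.append(differential.diff_methylation(
                    bc, bn, cohort.name, th.methylation_alpha))
        report.n_out += 1
    out = {
        "differential_expression": pd.concat(de_frames, ignore_index=True)
        if de_frames else pd.DataFrame(columns=["gene", "cohort", "log2fc",
                                                "p", "p_adj", "call"]),
        "differential_methylation": pd.concat(meth_frames, ignore_index=True)
        if meth_frames else pd.DataFrame(columns=[
            "gene", "cohort", "mean_beta_cancer", "mean_beta_normal",
            "delta_beta", "p", "call"]),
    }
    return out, report


def _stage_coexpression(data, th: Thresholds, rng):
    report = StageReport("coexpression")
    passed, skipped = _gated_cohorts(data, th)
    report.n_in = len(data["cohorts"])
    for name in skipped:
        report.dropped[f"cohort {name}: below min_normal_samples"] = 1
    family = set(data["family_genes"])
    edge_frames, comp_rows = [], []
    for cohort in passed:
        expr_c = data["expression_cancer"][[s for s in cohort.cancer_samples
                                            if s in data["expression_cancer"].columns]]
        expr_n = data["expression_normal"][[s for s in cohort.normal_samples
                                            if s in data["expression_normal"].columns]]
        background = [g for g in expr_c.index if g not in family]
        edges, comp = coexpression.coexpression_analysis(
            expr_c, expr_n, sorted(family), background,
            n_null_pairs=th.n_null_pairs, alpha=th.coexpr_alpha,
            seed=rng, cohort_id=cohort.name)
        edges.insert(2, "cohort", cohort.name)
        edge_frames.append(edges)
        comp_rows.append(asdict(comp))
        report.n_out += 1
    out = {
        "coexpression_edges": pd.concat(edge_frames, ignore_index=True)
        if edge_frames else pd.DataFrame(columns=[
            "gene_a", "gene_b", "cohort", "r_cancer", "r_normal",
            "p_cancer", "p_normal", "status"]),
        "network_comparison": pd.DataFrame(comp_rows) if comp_rows else
        pd.DataFrame(columns=["cohort_id", "n_cancer_edges", "n_normal_edges",
                              "n_shared", "n_cancer_only", "n_normal_only",
                              "p", "direction"]),
    }
    return out, report


def _stage_dysregulation(data, th: Thresholds, rng):
    report = StageReport("dysregulation")
    passed, skipped = _gated_cohorts(data, th)
    report.n_in = len(data["cohorts"])
    for name in skipped:
        report.dropped[f"cohort {name}: below min_normal_samples"] = 1
    frames = []
    if "targets" not in data:
        for cohort in passed:
            report.dropped[f"cohort {cohort.name}: no target table"] = 1
    else:
        for cohort in passed:
            expr_c = data["expression_cancer"][[s for s in cohort.cancer_samples
                                                if s in data["expression_cancer"].columns]]
            expr_n = data["expression_normal"][[s for s in cohort.normal_samples
                                                if s in data["expression_normal"].columns]]
            frames.append(dysregulation.analyze_target_dysregulation(
                expr_c, expr_n, data["targets"], cohort.name,
                n_perm=th.n_perm, alpha=th.dysregulation_alpha,
                min_score=th.target_min_score, seed=rng))
            report.n_out += 1
    out = {"dysregulation": pd.concat(frames, ignore_index=True) if frames else
           pd.DataFrame(columns=["tf", "target", "cohort", "r_cancer",
                                 "r_normal", "delta_r", "s_count", "n_perm",
                                 "p_perm", "fdr", "pattern"])}
    return out, report


def _stage_survival(data, th: Thresholds):
    report = StageReport("survival")
    cox_rows, km_frames = [], []
    if "survival" not in data:
        report.dropped["no survival table"] = len(data["cohorts"])
        report.n_in = len(data["cohorts"])
        out = {"survival_cox": pd.DataFrame(), "km_curves": pd.DataFrame()}
        return out, report
    surv = data["survival"].set_index("sample")
    family = data["family_genes"]
    expr_c = data["expression_cancer"]
    for cohort in data["cohorts"]:
        samples = [s for s in cohort.cancer_samples
                   if s in surv.index and s in expr_c.columns]
        for gene in family:
            if gene not in expr_c.index:
                continue
            report.n_in += 1
            values = expr_c.loc[gene, samples].to_numpy()
            times = surv.loc[samples, "time"].to_numpy()
            events = surv.loc[samples, "event"].to_numpy()
            try:
                groups = clinical.median_split(values)
                high = groups == "high"
                lr = clinical.logrank_test(times[high], events[high],
                                           times[~high], events[~high])
                cox = clinical.cox_univariate(high.astype(float), times, events,
                                              alpha=th.survival_alpha)
            except (DegenerateSplitError, InvalidInputError) as exc:
                key = f"{type(exc).__name__}"
                report.dropped[key] = report.dropped.get(key, 0) + 1
                continue
            cox_rows.append((gene, cohort.name, cox.log_hr, cox.hr, cox.ci_low,
                             cox.ci_high, cox.p, cox.direction, lr.chi_square,
                             lr.p, cox.n, cox.n_events))
            for label, mask in (("high", high), ("low", ~high)):
                km = clinical.km_estimate(times[mask], events[mask])
                km.insert(0, "group", label)
                km.insert(0, "cohort", cohort.name)
                km.insert(0, "gene", gene)
                km_frames.append(km)
            report.n_out += 1
    out = {
        "survival_cox": pd.DataFrame(cox_rows, columns=[
            "gene", "cohort", "log_hr", "hr", "ci_low", "ci_high", "cox_p",
            "direction", "logrank_chi_square", "logrank_p", "n", "n_events"]),
        "km_curves": pd.concat(km_frames, ignore_index=True) if km_frames else
        pd.DataFrame(columns=["gene", "cohort", "group", "time", "n_at_risk",
                              "n_events", "survival"]),
    }
    return out, report


def _stage_drugs(data, th: Thresholds):
    report = StageReport("drugs")
    needed = ("expression_cell_lines", "drug_ic50", "drug_annotation")
    if any(k not in data for k in needed):
        report.dropped["missing drug inputs"] = 1
        report.n_in = 1
        return {"drug_associations": pd.DataFrame(),
                "drug_axis": pd.DataFrame()}, report
    expr = data["expression_cell_lines"]
    ic50 = data["drug_ic50"]
    anno = data["drug_annotation"]
    family = [g for g in data["family_genes"] if g in expr.index]
    gd_rows = []
    for drug, sub in ic50.groupby("drug", sort=True):
        profile = sub.set_index("cell_line")["ic50"]
        for gene in family:
            report.n_in += 1
            try:
                assoc = clinical.drug_correlation(
                    expr.loc[gene], profile, gene, drug,
                    th.drug_pcc, th.drug_alpha)
            except (InvalidInputError, UndefinedCorrelationError) as exc:
                key = type(exc).__name__
                report.dropped[key] = report.dropped.get(key, 0) + 1
                continue
            gd_rows.append((gene, drug, assoc.pcc, assoc.p, assoc.retained, assoc.n))
            report.n_out += 1
    gene_drug = pd.DataFrame(gd_rows, columns=["gene", "drug", "pcc", "p",
                                               "retained", "n"])
    # gene <-> drug-target correlations for every annotated target
    gt_rows = []
    targets = sorted(set(anno["target_gene"]) & set(expr.index))
    for gene in family:
        for target in targets:
            try:
                res = clinical.drug_correlation(expr.loc[gene], expr.loc[target],
                                                gene, target,
                                                th.drug_pcc, th.drug_alpha)
            except (InvalidInputError, UndefinedCorrelationError):
                continue
            gt_rows.append((gene, target, res.pcc, res.p, res.retained))
    gene_target = pd.DataFrame(gt_rows, columns=["gene", "target", "pcc", "p",
                                                 "retained"])
    axis = clinical.build_drug_axis(gene_drug, gene_target, anno) \
        if not gene_drug.empty else pd.DataFrame(
            columns=["pathway", "drug", "gene", "drug_target"])
    return {"drug_associations": gene_drug, "drug_axis": axis}, report


# ----------------------------------------------------------------------
def run_pipeline(config: PipelineConfig, stages: Sequence[str] | None = None) -> dict:
    """Run the requested stages (default: all) and write result tables,
    a JSON summary, stage reports and a run manifest to ``config.outdir``."""
    selected = list(stages) if stages else list(STAGES)
    unknown = [s for s in selected if s not in STAGES]
    if unknown:
        raise InvalidParameterError(f"unknown stage(s): {unknown}")
    data = load_inputs(config)
    th = config.thresholds
    rngs = _child_rngs(config.seed)
    results: dict[str, pd.DataFrame] = {}
    reports: list[StageReport] = []
    for stage in STAGES:
        if stage not in selected:
            continue
        t0 = time.perf_counter()
        if stage == "genomics":
            out, rep = _stage_genomics(data, th)
        elif stage == "differential":
            out, rep = _stage_differential(data, th)
        elif stage == "coexpression":
            out, rep = _stage_coexpression(data, th, rngs[stage])
        elif stage == "dysregulation":
            out, rep = _stage_dysregulation(data, th, rngs[stage])
        elif stage == "survival":
            out, rep = _stage_survival(data, th)
        else:
            out, rep = _stage_drugs(data, th)
        rep.seed = config.seed
        rep.wall_time_s = time.perf_counter() - t0
        log.info("stage %s: %d in / %d out / %d dropped (%.2fs)", stage,
                 rep.n_in, rep.n_out, rep.n_dropped, rep.wall_time_s)
        if not rep.reconciles():
            raise FamnetError(f"stage {stage} report does not reconcile: {rep}")
        results.update(out)
        reports.append(rep)
    manifest = write_reports(results, reports, config)
    return manifest


def _summarize(results: dict[str, pd.DataFrame]) -> dict:
    summary: dict = {}
    de = results.get("differential_expression")
    if de is not None and len(de):
        summary["de_calls"] = de["call"].value_counts().to_dict()
    edges = results.get("coexpression_edges")
    if edges is not None and len(edges):
        summary["edges_by_status"] = edges["status"].value_counts().to_dict()
    dys = results.get("dysregulation")
    if dys is not None and len(dys):
        summary["dysregulation_patterns"] = dys["pattern"].value_counts().to_dict()
    cox = results.get("survival_cox")
    if cox is not None and len(cox):
        summary["significant_cox_genes"] = int((cox["direction"] != "ns").sum())
    drugs = results.get("drug_associations")
    if drugs is not None and len(drugs):
        summary["retained_drug_pairs"] = int(drugs["retained"].sum())
    for key, df in results.items():
        summary.setdefault("row_counts", {})[key] = int(len(df))
    return summary


def write_reports(results: dict[str, pd.DataFrame],
                  reports: list[StageReport],
                  config: PipelineConfig) -> dict:
    """Persist one TSV per result table plus summary, stage reports and
    manifest JSONs. Outputs carry no timestamps so reruns are byte-identical."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table_paths = {}
    for name, df in sorted(results.items()):
        table_paths[name] = io.write_table(df, outdir / f"{name}.tsv")
    summary = _summarize(results)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2,
                                                    sort_keys=True) + "\n")
    (outdir / "stage_reports.json").write_text(json.dumps(
        [r.to_json() for r in reports], indent=2) + "\n")
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": [r.stage for r in reports],
        "tables": {k: Path(v).name for k, v in table_paths.items()},
        "thresholds": asdict(config.thresholds),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True) + "\n")
    return manifest
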