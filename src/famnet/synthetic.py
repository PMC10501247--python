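"""Synthetic paired cancer/normal cohorts with known planted structure.

Every downstream stage of the pipeline is testable against ground truth: the
generator plants pair correlations that differ between conditions, additive
mutation/copy-number/methylation effects on expression, exponential
proportional-hazards survival coupled to one gene's median split, and linear
expression-to-IC50 couplings in a cell-line panel. All randomness derives
deterministically from a single integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "sample_correlated_pair",
    "generate_cohort",
    "generate_target_sets",
    "write_cohort",
]

VARIANT_CLASSES = ("missense", "nonsense", "frameshift", "splice_site")

_STREAMS = ("expression", "mutation", "cnv", "methylation", "targets",
            "survival", "drugs", "cell_lines")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    return math.log(p / (1.0 - p))


@dataclass
class CohortConfig:
    """Declarative description of one synthetic cohort.

    ``planted_pairs`` entries are ``(gene_a, gene_b, rho_cancer, rho_normal)``.
    Genes participating in a planted pair are exempt from mutation, CNV and
    methylation coupling so that their sample correlation is not attenuated by
    the extra additive variance.
    """

    n_family_genes: int = 20
    n_background_genes: int = 200
    n_cancer: int = 60
    n_normal: int = 40
    n_cell_lines: int = 60
    planted_pairs: Sequence[tuple] = field(default_factory=tuple)
    mutation_rate: float = 0.08
    mutation_effect: float = -1.0
    cnv_dosage_slope: float = 0.5
    methylation_slope: float = -2.0
    methylation_de_genes: Sequence[tuple] = field(default_factory=tuple)
    de_genes: Sequence[tuple] = field(default_factory=tuple)
    survival_gene: str | None = None
    survival_log_hr: float = 0.0
    drug_couplings: Sequence[tuple] = field(default_factory=tuple)
    noise_sd: float = 1.0
    baseline_hazard: float = 0.05
    censoring_horizon: float = 60.0
    seed: int = 0

    # ------------------------------------------------------------------
    def family_genes(self) -> list[str]:
        return [f"FAM{i + 1:03d}" for i in range(self.n_family_genes)]

    def background_genes(self) -> list[str]:
        return [f"BG{i + 1:04d}" for i in range(self.n_background_genes)]

    def all_genes(self) -> list[str]:
        return self.family_genes() + self.background_genes()

    def resolved_survival_gene(self) -> str:
        return self.survival_gene or self.family_genes()[0]

    def validate(self) -> None:
        for name in ("n_family_genes", "n_background_genes", "n_cancer",
                     "n_normal", "n_cell_lines"):
            if getattr(self, name) < 1:
                raise InvalidParameterError(f"{name} must be >= 1")
        if not self.noise_sd > 0:
            raise InvalidParameterError("noise_sd must be > 0")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise InvalidParameterError("mutation_rate must be in [0, 1]")
        known = set(self.all_genes())
        seen_in_pairs: set[str] = set()
        for entry in self.planted_pairs:
            a, b, rho_c, rho_n = entry
            if a == b:
                raise InvalidParameterError(f"planted pair ({a}, {b}) is a self-pair")
            for g in (a, b):
                if g not in known:
                    raise InvalidParameterError(f"planted-pair gene {g!r} unknown")
                if g in seen_in_pairs:
                    raise InvalidParameterError(
                        f"gene {g!r} appears in more than one planted pair")
                seen_in_pairs.add(g)
            for rho in (rho_c, rho_n):
                if not -1.0 <= rho <= 1.0:
                    raise InvalidParameterError(f"rho {rho} outside [-1, 1]")
        for gene, _ in self.de_genes:
            if gene not in known:
                raise InvalidParameterError(f"de gene {gene!r} unknown")
        for gene, _ in self.methylation_de_genes:
            if gene not in set(self.family_genes()):
                raise InvalidParameterError(
                    f"methylation de gene {gene!r} is not a family gene")
        if self.resolved_survival_gene() not in known:
            raise InvalidParameterError(
                f"survival gene {self.resolved_survival_gene()!r} unknown")
        for gene, _drug, _slope, nsd in self.drug_couplings:
            if gene not in known:
                raise InvalidParameterError(f"drug-coupled gene {gene!r} unknown")
            if not nsd > 0:
                raise InvalidParameterError("drug coupling noise_sd must be > 0")


@dataclass
class SyntheticCohort:
    """All tables of one generated cohort plus the planted-effect ledger."""

    config: CohortConfig
    expression_cancer: pd.DataFrame  # genes x cancer samples (log2 scale)
    expression_normal: pd.DataFrame  # genes x normal samples
    expression_cell_lines: pd.DataFrame  # genes x cell lines
    mutations: pd.DataFrame  # sample, gene, variant_class
    cnv: pd.DataFrame  # family genes x cancer samples, integer dosage
    methylation_beta: pd.DataFrame  # probes x (cancer+normal samples)
    probe_map: pd.DataFrame  # probe, gene, region
    target_scores: pd.DataFrame  # tf, target, score
    survival: pd.DataFrame  # sample, time, event
    drug_ic50: pd.DataFrame  # cell_line, drug, ic50
    drug_annotation: pd.DataFrame  # drug, target_gene, pathway
    truth: dict

    @property
    def cancer_samples(self) -> list[str]:
        return list(self.expression_cancer.columns)

    @property
    def normal_samples(self) -> list[str]:
        return list(self.expression_normal.columns)


# ----------------------------------------------------------------------
def sample_correlated_pair(rho: float, n: int, rng: np.random.Generator):
    """Draw two length-``n`` vectors from a bivariate Gaussian with
    population correlation ``rho`` (unit marginals)."""
    if not -1.0 <= rho <= 1.0:
        raise InvalidParameterError(f"rho must be in [-1, 1], got {rho}")
    if n < 2:
        raise InvalidParameterError(f"need n >= 2 samples, got {n}")
    x = rng.standard_normal(n)
    if abs(rho) == 1.0:
        return x, rho * x
    y = rho * x + math.sqrt(1.0 - rho * rho) * rng.standard_normal(n)
    return x, y


def generate_target_sets(tfs: Sequence[str], candidates: Sequence[str],
                         score_range: tuple[float, float],
                         sizes, rng: np.random.Generator) -> pd.DataFrame:
    """Random TF -> target tables with uniform significance scores.

    ``sizes`` is either one int applied to every TF or a per-TF sequence.
    Targets are sampled without replacement from ``candidates`` minus the TF
    itself, so no self-targets occur.
    """
    if len(candidates) == 0:
        raise InvalidParameterError("candidate pool must be non-empty")
    lo, hi = score_range
    if hi < lo:
        raise InvalidParameterError("score_range upper bound below lower bound")
    if np.isscalar(sizes):
        sizes = [int(sizes)] * len(tfs)
    if len(sizes) != len(tfs):
        raise InvalidParameterError("sizes must match the number of TFs")
    rows = []
    for tf, size in zip(tfs, sizes):
        if size < 0:
            raise InvalidParameterError("target set size must be >= 0")
        pool = [g for g in candidates if g != tf]
        if size > len(pool):
            raise InvalidParameterError(
                f"requested {size} targets for {tf} from a pool of {len(pool)}")
        chosen = rng.choice(pool, size=size, replace=False) if size else []
        for target in chosen:
            rows.append((tf, str(target), float(rng.uniform(lo, hi))))
    return pd.DataFrame(rows, columns=["tf", "target", "score"])


# ----------------------------------------------------------------------
def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate one complete cohort; a pure function of the config."""
    config.validate()
    rngs = _streams(config.seed)
    family = config.family_genes()
    background = config.background_genes()
    genes = family + background
    gi = {g: k for k, g in enumerate(genes)}
    cancer = [f"C{i + 1:04d}" for i in range(config.n_cancer)]
    normal = [f"N{i + 1:04d}" for i in range(config.n_normal)]
    cells = [f"CL{i + 1:03d}" for i in range(config.n_cell_lines)]
    planted_genes = {g for pair in config.planted_pairs for g in pair[:2]}
    # genes receiving mutation/CNV/methylation expression coupling
    coupled = [g for g in family if g not in planted_genes]

    # --- expression residuals --------------------------------------------
    rng = rngs["expression"]
    mu = rng.uniform(3.0, 9.0, len(genes))
    z_c = rng.standard_normal((len(genes), config.n_cancer))
    z_n = rng.standard_normal((len(genes), config.n_normal))
    for a, b, rho_c, rho_n in config.planted_pairs:
        xa, xb = sample_correlated_pair(rho_c, config.n_cancer, rng)
        z_c[gi[a]], z_c[gi[b]] = xa, xb
        xa, xb = sample_correlated_pair(rho_n, config.n_normal, rng)
        z_n[gi[a]], z_n[gi[b]] = xa, xb
    expr_c = mu[:, None] + config.noise_sd * z_c
    expr_n = mu[:, None] + config.noise_sd * z_n
    for gene, lfc in config.de_genes:
        expr_c[gi[gene]] += lfc

    # --- somatic mutations (cancer samples, family genes) ----------------
    rng = rngs["mutation"]
    mut_rows = []
    mutated: dict[str, list[str]] = {}
    for gene in family:
        flags = rng.random(config.n_cancer) < config.mutation_rate
        hit = [cancer[j] for j in np.flatnonzero(flags)]
        if hit:
            mutated[gene] = hit
        if gene in coupled:
            expr_c[gi[gene], flags] += config.mutation_effect
        for s in hit:
            mut_rows.append((s, gene, VARIANT_CLASSES[int(rng.integers(len(VARIANT_CLASSES)))]))
            if rng.random() < 0.1:  # second variant in the same gene/sample
                mut_rows.append((s, gene, VARIANT_CLASSES[int(rng.integers(len(VARIANT_CLASSES)))]))
    mutations = pd.DataFrame(mut_rows, columns=["sample", "gene", "variant_class"])

    # --- copy number (cancer samples, family genes) ----------------------
    rng = rngs["cnv"]
    dosage = rng.choice([-2, -1, 0, 1, 2], size=(len(family), config.n_cancer),
                        p=[0.05, 0.15, 0.60, 0.15, 0.05])
    for k, gene in enumerate(family):
        if gene in coupled:
            expr_c[gi[gene]] += config.cnv_dosage_slope * dosage[k]
    cnv = pd.DataFrame(dosage, index=family, columns=cancer)

    # --- promoter methylation --------------------------------------------
    rng = rngs["methylation"]
    meth_shift = dict(config.methylation_de_genes)
    probe_rows, beta_rows, probe_ids = [], [], []
    probe_counter = 0
    all_samples = cancer + normal
    for gene in family:
        n_probes = int(rng.integers(1, 4))
        base_logit = rng.uniform(_logit(0.2), _logit(0.7))
        latent_c = base_logit + meth_shift.get(gene, 0.0) + 0.6 * rng.standard_normal(config.n_cancer)
        latent_n = base_logit + 0.6 * rng.standard_normal(config.n_normal)
        latent = np.concatenate([latent_c, latent_n])
        gene_betas = np.zeros((n_probes, len(all_samples)))
        for p in range(n_probes):
            probe_counter += 1
            pid = f"cg{probe_counter:06d}"
            probe_ids.append(pid)
            probe_rows.append((pid, gene, "promoter"))
            offset = 0.3 * rng.standard_normal()
            noise = 0.2 * rng.standard_normal(len(all_samples))
            gene_betas[p] = np.clip(_sigmoid(latent + offset + noise), 1e-6, 1 - 1e-6)
            beta_rows.append(gene_betas[p])
        # occasional non-promoter probe, exercised by the promoter filter
        if rng.random() < 0.2:
            probe_counter += 1
            pid = f"cg{probe_counter:06d}"
            probe_ids.append(pid)
            probe_rows.append((pid, gene, "body"))
            beta_rows.append(np.clip(
                _sigmoid(base_logit + 0.8 * rng.standard_normal(len(all_samples))),
                1e-6, 1 - 1e-6))
        if gene in coupled:
            gene_mean = gene_betas.mean(axis=0) - _sigmoid(base_logit)
            expr_c[gi[gene]] += config.methylation_slope * gene_mean[:config.n_cancer]
            expr_n[gi[gene]] += config.methylation_slope * gene_mean[config.n_cancer:]
    methylation = pd.DataFrame(np.vstack(beta_rows), index=probe_ids, columns=all_samples)
    probe_map = pd.DataFrame(probe_rows, columns=["probe", "gene", "region"])

    # --- TF target score table -------------------------------------------
    rng = rngs["targets"]
    sizes = np.minimum(rng.integers(5, 15, size=len(family)), len(background))
    target_scores = generate_target_sets(family, background, (0.0, 300.0), list(sizes), rng)

    expression_cancer = pd.DataFrame(expr_c, index=genes, columns=cancer)
    expression_normal = pd.DataFrame(expr_n, index=genes, columns=normal)

    # --- survival (exponential PH on the survival gene's median split) ---
    rng = rngs["survival"]
    surv_gene = config.resolved_survival_gene()
    values = expression_cancer.loc[surv_gene].to_numpy()
    high = values > np.median(values)
    hazard = config.baseline_hazard * np.exp(config.survival_log_hr * high)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.uniform(0.0, config.censoring_horizon, size=config.n_cancer)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    time = np.maximum(time, 1e-9)
    survival = pd.DataFrame({"sample": cancer, "time": time, "event": event})

    # --- cell-line panel and drug response -------------------------------
    rng = rngs["cell_lines"]
    expr_cl = mu[:, None] + config.noise_sd * rng.standard_normal((len(genes), config.n_cell_lines))
    expression_cell_lines = pd.DataFrame(expr_cl, index=genes, columns=cells)

    rng = rngs["drugs"]
    ic50_rows, anno_rows = [], []
    for gene, drug, slope, nsd in config.drug_couplings:
        centred = expr_cl[gi[gene]] - expr_cl[gi[gene]].mean()
        ic50 = 3.0 + slope * centred + nsd * rng.standard_normal(config.n_cell_lines)
        ic50_rows.extend((c, drug, float(v)) for c, v in zip(cells, ic50))
        anno_rows.append((drug, gene, f"PW_{gene}"))
    for k in range(2):  # uncoupled negative-control drugs
        drug = f"drug_null_{k + 1}"
        ic50 = 3.0 + rng.standard_normal(config.n_cell_lines)
        ic50_rows.extend((c, drug, float(v)) for c, v in zip(cells, ic50))
        anno_rows.append((drug, background[k % len(background)], "PW_null"))
    drug_ic50 = pd.DataFrame(ic50_rows, columns=["cell_line", "drug", "ic50"])
    drug_annotation = pd.DataFrame(anno_rows, columns=["drug", "target_gene", "pathway"])

    truth = {
        "planted_pairs": [tuple(p) for p in config.planted_pairs],
        "de_genes": [tuple(d) for d in config.de_genes],
        "methylation_de_genes": [tuple(m) for m in config.methylation_de_genes],
        "mutated_samples": mutated,
        "mutation_rate": config.mutation_rate,
        "mutation_effect": config.mutation_effect,
        "cnv_dosage_slope": config.cnv_dosage_slope,
        "methylation_slope": config.methylation_slope,
        "coupled_genes": coupled,
        "survival": {"gene": surv_gene, "log_hr": config.survival_log_hr},
        "drug_couplings": [tuple(d) for d in config.drug_couplings],
    }

    return SyntheticCohort(
        config=config,
        expression_cancer=expression_cancer,
        expression_normal=expression_normal,
        expression_cell_lines=expression_cell_lines,
        mutations=mutations,
        cnv=cnv,
        methylation_beta=methylation,
        probe_map=probe_map,
        target_scores=target_scores,
        survival=survival,
        drug_ic50=drug_ic50,
        drug_annotation=drug_annotation,
        truth=truth,
    )


# ----------------------------------------------------------------------
def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, str]:
    """Write every cohort table in the pipeline's TSV dialects.

    Returns a mapping of logical input name -> written path, suitable for
    splicing into a pipeline configuration.
    """
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = "%.10g"

    def _matrix(df, name, index_label):
        path = out / name
        df.to_csv(path, sep="\t", float_format=fmt, index_label=index_label)
        return str(path)

    def _table(df, name):
        path = out / name
        df.to_csv(path, sep="\t", float_format=fmt, index=False)
        return str(path)

    paths = {
        "expression_cancer": _matrix(cohort.expression_cancer, "expression_cancer.tsv", "gene"),
        "expression_normal": _matrix(cohort.expression_normal, "expression_normal.tsv", "gene"),
        "expression_cell_lines": _matrix(cohort.expression_cell_lines, "expression_cell_lines.tsv", "gene"),
        "cnv": _matrix(cohort.cnv, "cnv.tsv", "gene"),
        "methylation": _matrix(cohort.methylation_beta, "methylation.tsv", "probe"),
        "mutations": _table(cohort.mutations, "mutations.tsv"),
        "probe_map": _table(cohort.probe_map, "probe_map.tsv"),
        "targets": _table(cohort.target_scores, "targets.tsv"),
        "survival": _table(cohort.survival, "survival.tsv"),
        "drug_ic50": _table(cohort.drug_ic50, "drug_ic50.tsv"),
        "drug_annotation": _table(cohort.drug_annotation, "drug_annotation.tsv"),
    }
    family_path = out / "family_genes.txt"
    family_path.write_text("\n".join(cohort.config.family_genes()) + "\n")
    paths["family_genes"] = str(family_path)
    return paths
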