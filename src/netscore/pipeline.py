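"""End-to-end orchestration: network construction, module screening and
validation, representative-gene selection, NetScore training, scoring,
and downstream survival analytics, with a reproducibility manifest.

Every stage writes its tables into the run directory as TSV; the
manifest records all seeds, parameters and SHA-256 checksums of the
text outputs so that a rerun with identical configuration is verifiably
bit-identical.  Figures are written for inspection but never
checksummed (image metadata is not reproducible across runs).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .model import TrainingConfig, fit_cv_model, predict_netscore
from .modules import (
    gene_significance,
    screen_modules,
    select_representative_genes,
    surviving_modules,
    validate_modules,
)
from .network import (
    DEFAULT_POWER,
    adjacency,
    gene_module_membership,
    hierarchical_cluster,
    module_eigengenes,
    pearson_correlation_matrix,
    pick_soft_threshold,
    top_variable_genes,
    topological_overlap,
)
from .simulate import Cohort, SimulationConfig, generate_multi_cohort
from .survival import (
    ConvergenceError,
    cox_fit,
    dichotomize_by_median,
    kaplan_meier,
    logrank_test,
)
from .treecut import dynamic_tree_cut

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "SubgroupSpec", "run_full_pipeline", "subgroup_analysis", "write_report"]


@dataclass
class SubgroupSpec:
    """A clinical subgroup: a covariate plus either a level (categorical)
    or a (op, cut) pair with op in {<=, >} (numeric)."""

    covariate: str
    level: str | None = None
    op: str | None = None
    cut: float | None = None

    @property
    def name(self) -> str:
        if self.level is not None:
            return f"{self.covariate}={self.level}"
        return f"{self.covariate}{self.op}{self.cut}"

    def mask(self, table: pd.DataFrame) -> pd.Series:
        if self.covariate not in table.columns:
            raise KeyError(f"unknown covariate {self.covariate!r}")
        col = table[self.covariate]
        if self.level is not None:
            return col.astype(str) == str(self.level)
        if self.op == "<=":
            return col.astype(float) <= float(self.cut)
        if self.op == ">":
            return col.astype(float) > float(self.cut)
        raise ValueError("subgroup needs a level or an (op, cut) pair")


@dataclass
class PipelineConfig:
    """Exactly one of ``simulation`` or ``cohort_paths`` must be set."""

    simulation: SimulationConfig | None = None
    cohort_paths: list[tuple[str, str, str]] | None = None  # (name, expr, surv)
    power: int | None = DEFAULT_POWER  # None = auto-select
    height_cutoff: float = 0.99
    deep_split: int = 2
    min_size: int = 30
    top_n_genes: int | None = None  # None = all genes
    alpha: float = 0.05
    genes_per_module: int = 10
    cv_folds: int = 5
    cv_grid: list | None = None  # None = model.DEFAULT_GRID
    covariates: list[str] = field(default_factory=list)
    subgroups: list[SubgroupSpec] = field(default_factory=list)
    seed: int = 0
    outdir: str = "netscore_run"

    def __post_init__(self):
        if (self.simulation is None) == (self.cohort_paths is None):
            raise ValueError("exactly one of simulation / cohort_paths must be given")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, **kwargs) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format="%.10g", **kwargs)


def _screen_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "module": r.module,
                "coef": r.coef,
                "hazard_ratio": r.hazard_ratio,
                "ci_lower": r.ci_lower,
                "ci_upper": r.ci_upper,
                "p": r.p,
                "significant": r.significant,
            }
            for r in results
        ]
    )


def run_full_pipeline(config: PipelineConfig) -> Path:
    """Execute the whole analysis; returns the run directory.

    If no module survives validation the pipeline stops after the
    validation stage and writes a structured report saying so (the run
    directory is still returned; ``manifest.json`` carries
    ``"status": "stopped_no_validated_modules"``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "parameters": {
            "power": config.power,
            "height_cutoff": config.height_cutoff,
            "deep_split": config.deep_split,
            "min_size": config.min_size,
            "top_n_genes": config.top_n_genes,
            "alpha": config.alpha,
            "genes_per_module": config.genes_per_module,
            "cv_folds": config.cv_folds,
        },
    }

    # stage 0: cohorts
    if config.simulation is not None:
        cohorts, truth = generate_multi_cohort(config.simulation)
        manifest["simulation"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config.simulation).items()
        }
        _write_tsv(truth.gene_to_module.to_frame(), outdir / "planted_truth.tsv",
                   index_label="gene")
    else:
        cohorts = [
            Cohort.read(name, expr, surv) for name, expr, surv in config.cohort_paths
        ]
    training, tests = cohorts[0], cohorts[1:]

    # stage 1: network on the training cohort
    expr = training.expression
    if config.top_n_genes is not None:
        expr = top_variable_genes(expr, config.top_n_genes)
    corr = pearson_correlation_matrix(expr)
    if config.power is None:
        sel = pick_soft_threshold(corr)
        power = sel.chosen
        _write_tsv(sel.table, outdir / "power_selection.tsv", index=False)
    else:
        power = config.power
    manifest["parameters"]["power_used"] = power
    adj = adjacency(corr, power)
    tom = topological_overlap(adj)
    dend = hierarchical_cluster(tom.dissimilarity, gene_ids=tom.gene_ids)
    assignment = dynamic_tree_cut(
        dend,
        tom.dissimilarity,
        height_cutoff=config.height_cutoff,
        deep_split=config.deep_split,
        min_size=config.min_size,
    )
    _write_tsv(assignment.to_frame(), outdir / "module_assignment.tsv", index_label="gene")

    # stage 2: screening in training
    mes = module_eigengenes(expr, assignment)
    screen = screen_modules(mes, training.survival)
    _write_tsv(_screen_frame(screen), outdir / "screen_training.tsv", index=False)

    # stage 3: validation in each test cohort
    validations = []
    for cohort in tests:
        val = validate_modules(assignment, cohort)
        validations.append(val)
        _write_tsv(_screen_frame(val), outdir / f"screen_{cohort.name}.tsv", index=False)

    # stage 4: modules significant everywhere advance
    advanced = surviving_modules(screen, validations)
    (outdir / "advanced_modules.json").write_text(
        json.dumps({"modules": advanced}, indent=1) + "\n"
    )
    if not advanced:
        manifest["status"] = "stopped_no_validated_modules"
        _finalize_manifest(outdir, manifest)
        write_report(outdir)
        return outdir

    # stage 5: representative genes by kME
    gmm = gene_module_membership(expr, mes)
    selected: dict[str, list[str]] = {}
    for mod in advanced:
        selected[mod] = select_representative_genes(
            gmm, assignment.module_genes(mod), k=config.genes_per_module, module=mod
        )
    sel_frame = pd.DataFrame(
        [
            {"module": mod, "rank": i + 1, "gene": g, "kME": gmm.loc[g, mod]}
            for mod, genes in selected.items()
            for i, g in enumerate(genes)
        ]
    )
    _write_tsv(sel_frame, outdir / "selected_genes.tsv", index=False)

    # stage 6: CV + training of the scoring network
    blocks = tuple((mod, tuple(genes)) for mod, genes in selected.items())
    model = fit_cv_model(
        training, blocks, grid=config.cv_grid, k=config.cv_folds, seed=config.seed
    )
    _write_tsv(model.cv_record.table, outdir / "cv_table.tsv", index=False)
    model.save(outdir / "model")

    # stages 7-8: scoring + survival analytics per cohort
    gene_sig = gene_significance(expr.loc[[g for gs in selected.values() for g in gs]],
                                 training.survival)
    _write_tsv(
        pd.DataFrame({"p": gene_sig.p, "score": gene_sig.score}),
        outdir / "gene_significance_selected.tsv",
        index_label="gene",
    )
    analytics_rows = []
    for cohort in cohorts:
        scores = predict_netscore(model, cohort)
        _write_tsv(scores.to_frame(), outdir / f"netscore_{cohort.name}.tsv",
                   index_label="sample")
        analytics_rows.append(_cohort_analytics(cohort, scores, config, outdir))
    _write_tsv(pd.DataFrame(analytics_rows), outdir / "cohort_analytics.tsv", index=False)

    manifest["status"] = "completed"
    manifest["advanced_modules"] = advanced
    _finalize_manifest(outdir, manifest)
    write_report(outdir)
    _finalize_manifest(outdir, manifest)  # report files join the checksums
    return outdir


def _cohort_analytics(cohort: Cohort, scores: pd.Series, config: PipelineConfig,
                      outdir: Path) -> dict:
    surv = cohort.survival
    row: dict = {"cohort": cohort.name, "n": len(surv), "events": int(surv["event"].sum())}
    try:
        cont = cox_fit(scores.to_frame("netscore"), surv)
        row["cont_hr"] = float(cont.hazard_ratio[0])
        row["cont_p"] = float(cont.p[0])
    except (ConvergenceError, ValueError) as exc:
        log.warning("%s: continuous Cox failed (%s)", cohort.name, exc)
        row["cont_hr"] = row["cont_p"] = np.nan
    try:
        groups = dichotomize_by_median(scores)
        chi2, df, p = logrank_test(groups.to_numpy(), surv)
        row["logrank_chi2"], row["logrank_p"] = chi2, p
        km_frames = []
        for level in ("low", "high"):
            km = kaplan_meier(surv[groups == level])
            f = km.to_frame()
            f.insert(0, "group", level)
            km_frames.append(f)
        _write_tsv(pd.concat(km_frames), outdir / f"km_{cohort.name}.tsv", index=False)
        _km_plot(surv, groups, outdir / "figures" / f"km_{cohort.name}.png")
        design = (groups == "high").astype(float).rename("risk_group_high").to_frame()
        for cov in config.covariates:
            if cov in surv.columns:
                design[cov] = surv[cov]
        multi = cox_fit(design, surv)
        summ = multi.summary()
        _write_tsv(summ, outdir / f"cox_multivariate_{cohort.name}.tsv",
                   index_label="covariate")
        row["group_hr"] = float(summ.loc["risk_group_high", "hazard_ratio"])
        row["group_p"] = float(summ.loc["risk_group_high", "p"])
        if config.subgroups:
            sub = subgroup_analysis(groups, surv, config.subgroups)
            _write_tsv(sub, outdir / f"subgroups_{cohort.name}.tsv", index=False)
    except (ConvergenceError, ValueError) as exc:
        log.warning("%s: dichotomized analytics failed (%s)", cohort.name, exc)
    return row


def _km_plot(surv: pd.DataFrame, groups: pd.Series, path: Path) -> None:
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:  # pragma: no cover
        return
    path.parent.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(5, 4))
    for level, color in (("low", "tab:blue"), ("high", "tab:red")):
        km = kaplan_meier(surv[groups == level])
        t = np.concatenate([[0.0], np.repeat(km.times, 2)])
        s = np.concatenate([[1.0, 1.0], np.repeat(km.survival, 2)[:-1]])
        ax.plot(t, s, color=color, label=f"{level} risk")
    ax.set_xlabel("time (months)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def subgroup_analysis(
    risk_groups: pd.Series, survival: pd.DataFrame, subgroups: list[SubgroupSpec]
) -> pd.DataFrame:
    """Univariate Cox of the dichotomized risk group within each clinical
    subgroup; rows with fewer than 10 samples or 3 events are emitted as
    "insufficient" with no fit attempted."""
    rows = []
    for spec in subgroups:
        mask = spec.mask(survival)
        sub = survival[mask]
        row = {"subgroup": spec.name, "n": int(mask.sum()),
               "events": int(sub["event"].sum()) if mask.any() else 0}
        if row["n"] < 10 or row["events"] < 3:
            row.update(status="insufficient", hr=np.nan, ci_lower=np.nan,
                       ci_upper=np.nan, p=np.nan)
            rows.append(row)
            continue
        design = (risk_groups[mask] == "high").astype(float).rename("risk_group_high").to_frame()
        try:
            fit = cox_fit(design, sub)
            summ = fit.summary().iloc[0]
            row.update(status="ok", hr=float(summ["hazard_ratio"]),
                       ci_lower=float(summ["ci_lower"]), ci_upper=float(summ["ci_upper"]),
                       p=float(summ["p"]))
        except (ConvergenceError, ValueError):
            row.update(status="failed", hr=np.nan, ci_lower=np.nan, ci_upper=np.nan,
                       p=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def _finalize_manifest(outdir: Path, manifest: dict) -> None:
    checksums = {}
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.suffix in {".tsv", ".md", ".json"} and path.name != "manifest.json":
            checksums[str(path.relative_to(outdir))] = _sha256(path)
    manifest["checksums"] = checksums
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")


def write_report(outdir: Path | str) -> Path:
    """Assemble a markdown report from whatever stage tables exist.

    Deterministic: regenerating from the same run directory is
    byte-identical.  Missing stages are marked "not run".
    """
    outdir = Path(outdir)
    lines = ["# Coexpression-network risk-stratification run report", ""]

    def section(title: str, fname: str, formatter=None):
        lines.append(f"## {title}")
        path = outdir / fname
        if not path.exists():
            lines.append("")
            lines.append("_not run_")
            lines.append("")
            return None
        df = pd.read_csv(path, sep="\t")
        lines.append("")
        lines.append((formatter or _md_table)(df))
        lines.append("")
        return df

    adv_path = outdir / "advanced_modules.json"
    section("Module screening (training cohort)", "screen_training.tsv")
    for val in sorted(outdir.glob("screen_cohort*.tsv")):
        section(f"Module validation ({val.stem.removeprefix('screen_')})", val.name)
    if adv_path.exists():
        advanced = json.loads(adv_path.read_text())["modules"]
        lines.append("## Modules advanced to model building")
        lines.append("")
        if advanced:
            lines.append(", ".join(advanced))
        else:
            lines.append("**No survival-related modules validated; pipeline stopped.**")
        lines.append("")
    section("Selected representative genes", "selected_genes.tsv")
    section("Cross-validation grid", "cv_table.tsv")
    section("Per-cohort survival analytics", "cohort_analytics.tsv")
    for sub in sorted(outdir.glob("subgroups_*.tsv")):
        section(f"Subgroup analysis ({sub.stem.removeprefix('subgroups_')})", sub.name)
    (outdir / "report.md").write_text("\n".join(lines))
    return outdir / "report.md"


def _md_table(df: pd.DataFrame) -> str:
    df = df.copy()
    for col in df.columns:
        if pd.api.types.is_float_dtype(df[col]):
            df[col] = df[col].map(lambda v: f"{v:.4g}")
    header = "| " + " | ".join(map(str, df.columns)) + " |"
    sep = "|" + "|".join(["---"] * len(df.columns)) + "|"
    rows = ["| " + " | ".join(map(str, row)) + " |" for row in df.itertuples(index=False)]
    return "\n".join([header, sep, *rows])
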