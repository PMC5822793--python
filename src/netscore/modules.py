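"""Survival-related module screening, validation, gene-level statistics,
representative-gene selection, and gene-set enrichment.

Screening fits one univariate Cox model per module eigengene and flags
modules at uncorrected p < 0.05.  Validation recomputes eigengenes from
each test cohort's own expression (no projection of training loadings)
and screens again; modules significant in the training cohort AND every
validation cohort advance to model building.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .network import ModuleEigengenes, gene_module_membership, module_eigengenes
from .simulate import Cohort
from .survival import ConvergenceError, cox_fit
from .treecut import ModuleAssignment

log = logging.getLogger(__name__)

__all__ = [
    "ModuleScreenResult",
    "GeneSignificance",
    "EnrichmentRow",
    "screen_modules",
    "validate_modules",
    "surviving_modules",
    "gene_significance",
    "gmm_significance_correlation",
    "select_representative_genes",
    "hypergeometric_enrichment",
    "read_gmt",
]

ALPHA = 0.05  # uncorrected module-screening threshold


@dataclass
class ModuleScreenResult:
    module: str
    coef: float
    hazard_ratio: float
    ci_lower: float
    ci_upper: float
    p: float
    converged: bool

    @property
    def significant(self) -> bool:
        return self.converged and not np.isnan(self.p) and self.p < ALPHA


def _screen_one(me: pd.Series, survival: pd.DataFrame, label: str) -> ModuleScreenResult:
    try:
        fit = cox_fit(me.to_frame(label), survival)
        return ModuleScreenResult(
            module=label,
            coef=float(fit.coef[0]),
            hazard_ratio=float(fit.hazard_ratio[0]),
            ci_lower=float(fit.ci_lower[0]),
            ci_upper=float(fit.ci_upper[0]),
            p=float(fit.p[0]),
            converged=True,
        )
    except (ConvergenceError, ValueError) as exc:
        log.warning("module %s: Cox fit failed (%s); excluded from significance", label, exc)
        return ModuleScreenResult(label, np.nan, np.nan, np.nan, np.nan, np.nan, False)


def screen_modules(mes: ModuleEigengenes, survival: pd.DataFrame) -> list[ModuleScreenResult]:
    """Univariate Cox on each module eigengene; uncorrected p < 0.05."""
    if int(survival["event"].sum()) < 10:
        raise ValueError("need at least 10 events for module screening")
    return [
        _screen_one(mes.values[label].loc[survival.index], survival, label)
        for label in mes.module_labels
    ]


def validate_modules(
    assignment: ModuleAssignment, test_cohort: Cohort, *, min_fraction_present: float = 0.5
) -> list[ModuleScreenResult]:
    """Recompute module eigengenes from the test cohort's own expression
    and screen them against the test cohort's survival.

    Modules with fewer than ``min_fraction_present`` of their genes
    present in the test cohort are skipped with a warning.
    """
    results = []
    present = set(test_cohort.expression.index)
    usable = {}
    for label in assignment.module_labels:
        genes = assignment.module_genes(label)
        found = [g for g in genes if g in present]
        if len(found) < max(2, int(np.ceil(min_fraction_present * len(genes)))):
            log.warning(
                "module %s: only %d/%d genes present in %s; skipped",
                label, len(found), len(genes), test_cohort.name,
            )
            continue
        if len(found) < len(genes):
            log.warning(
                "module %s: %d genes missing from %s", label, len(genes) - len(found),
                test_cohort.name,
            )
        usable[label] = found
    if not usable:
        return results
    labels = pd.Series(
        {g: lb for lb, genes in usable.items() for g in genes}, name="module"
    )
    mes = module_eigengenes(test_cohort.expression, labels)
    for label in usable:
        results.append(
            _screen_one(mes.values[label].loc[test_cohort.survival.index],
                        test_cohort.survival, label)
        )
    return results


def surviving_modules(
    training: list[ModuleScreenResult], validations: list[list[ModuleScreenResult]]
) -> list[str]:
    """Modules significant in training AND in every validation cohort."""
    keep = {r.module for r in training if r.significant}
    for val in validations:
        sig = {r.module for r in val if r.significant}
        keep &= sig
    order = [r.module for r in training]
    return [m for m in order if m in keep]


@dataclass
class GeneSignificance:
    """Per-gene univariate Cox Wald p and the score -log10(p)."""

    p: pd.Series
    score: pd.Series  # -log10(p), 0 where the fit failed

    def __post_init__(self):
        assert (self.score.dropna() >= 0).all()


def gene_significance(expression: pd.DataFrame, survival: pd.DataFrame) -> GeneSignificance:
    """Univariate Cox Wald p per gene, transformed to s_g = -log10(p)."""
    ps = {}
    surv = survival.loc[expression.columns]
    for gene in expression.index:
        try:
            fit = cox_fit(expression.loc[[gene]].T, surv)
            ps[gene] = float(fit.p[0])
        except (ConvergenceError, ValueError) as exc:
            warnings.warn(f"gene {gene}: Cox fit failed ({exc}); score set to 0")
            ps[gene] = 1.0
    p = pd.Series(ps, name="p")
    score = (-np.log10(p)).clip(lower=0.0).rename("score")
    return GeneSignificance(p=p, score=score)


def gmm_significance_correlation(
    gmm: pd.DataFrame, sig: GeneSignificance, module: str
) -> tuple[float, float]:
    """Pearson correlation between |kME| and -log10(p) over the module's
    member genes (membership = genes whose strongest |kME| is this module
    unless the caller pre-subsets gmm)."""
    if module not in gmm.columns:
        raise KeyError(f"unknown module {module!r}")
    genes = gmm.index.intersection(sig.score.index)
    if len(genes) < 10:
        raise ValueError("module has fewer than 10 genes with significance scores")
    x = gmm.loc[genes, module].abs()
    y = sig.score.loc[genes]
    if x.nunique() == 1 or y.nunique() == 1:
        raise ValueError("constant input to correlation")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def select_representative_genes(
    gmm: pd.DataFrame,
    module_genes: list[str],
    k: int = 10,
    *,
    module: str,
    signed: bool = False,
) -> list[str]:
    """Top-k module genes by decreasing |kME| (signed kME via flag).

    Ties break on gene id; if the module holds fewer than k genes the
    whole module is returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    kme = gmm.loc[[g for g in module_genes if g in gmm.index], module]
    key = kme if signed else kme.abs()
    ranked = sorted(key.index, key=lambda g: (-key[g], g))
    if len(ranked) < k:
        warnings.warn(
            f"module {module} has only {len(ranked)} genes (< k = {k}); returning all"
        )
        return ranked
    return ranked[:k]


@dataclass
class EnrichmentRow:
    set_name: str
    overlap: int
    set_size: int
    module_size: int
    universe_size: int
    p: float
    q: float | None = None


def hypergeometric_enrichment(
    module_genes: list[str],
    gene_sets: dict[str, list[str]],
    universe: list[str],
    *,
    bh_correct: bool = False,
) -> list[EnrichmentRow]:
    """Upper-tail hypergeometric test P(X >= overlap) per gene set.

    Sets are intersected with the universe; rows sorted by p.  An
    optional Benjamini-Hochberg q-value column is an extension beyond
    the uncorrected convention and is off by default.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    mod = set(module_genes) & uni
    if set(module_genes) - uni:
        warnings.warn("module genes outside the universe were dropped")
    rows = []
    for name, genes in gene_sets.items():
        gs = set(genes) & uni
        ov = len(gs & mod)
        # X ~ Hypergeom(M=universe, n=set, N=module); P(X >= ov)
        p = float(stats.hypergeom.sf(ov - 1, len(uni), len(gs), len(mod)))
        rows.append(
            EnrichmentRow(
                set_name=name, overlap=ov, set_size=len(gs),
                module_size=len(mod), universe_size=len(uni), p=min(p, 1.0),
            )
        )
    rows.sort(key=lambda r: (r.p, r.set_name))
    if bh_correct and rows:
        ps = np.array([r.p for r in rows])
        m = len(ps)
        order = np.argsort(ps)
        q = np.empty(m)
        prev = 1.0
        for rank_pos in range(m - 1, -1, -1):
            i = order[rank_pos]
            prev = min(prev, ps[i] * m / (rank_pos + 1))
            q[i] = prev
        for r, qq in zip(rows, q):
            r.q = float(qq)
    return rows


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> gene ids."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
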