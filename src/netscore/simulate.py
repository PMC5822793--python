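"""Synthetic multi-cohort expression + survival data with planted structure.

Each cohort draws one latent factor per module, f_k ~ N(0, 1) per sample.
A gene g in module m(g) has expression

    x_gs = lambda_m(g) * f_{m(g), s} + eps,   eps ~ N(0, noise_sd^2)

so with the default noise_sd = 0.6 and loading 0.8 the gene variance is 1,
the gene-factor correlation equals lambda / sqrt(lambda^2 + noise_sd^2),
and the expected within-module pairwise correlation is
lambda^2 / (lambda^2 + noise_sd^2).  Background genes are pure noise.

Survival follows an exponential proportional-hazards model whose linear
predictor is a weighted sum of the module factors (plus an optional
product interaction between the first two modules); censoring is
independent uniform(0, c_max) with c_max solved to hit a target
censoring fraction.  Expression is standardized per gene per cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["SimulationConfig", "PlantedTruth", "Cohort", "generate_cohort", "generate_multi_cohort"]


@dataclass
class Cohort:
    """Expression matrix (genes x samples) plus aligned survival table."""

    name: str
    expression: pd.DataFrame  # genes x samples, standardized per gene
    survival: pd.DataFrame  # index sample id; columns time, event (+ covariates)

    def __post_init__(self):
        if list(self.expression.columns) != list(self.survival.index):
            raise ValueError("expression columns and survival index must align")

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.expression.index)

    def write(self, expr_path, surv_path) -> None:
        self.expression.to_csv(expr_path, sep="\t", index_label="gene")
        self.survival.to_csv(surv_path, sep="\t", index_label="sample")

    @classmethod
    def read(cls, name, expr_path, surv_path) -> "Cohort":
        expr = pd.read_csv(expr_path, sep="\t", index_col=0)
        surv = pd.read_csv(surv_path, sep="\t", index_col=0)
        return cls(name=name, expression=expr, survival=surv.loc[expr.columns])


@dataclass
class SimulationConfig:
    """Generative conditions for the planted-module benchmark.

    module_loading is the factor loading lambda per module (target
    gene-factor correlation when lambda^2 + noise_sd^2 = 1);
    survival_effect is the log-hazard coefficient beta per module on the
    latent factor (0 = null module).  interaction_effect, if nonzero,
    adds gamma * f_1 * f_2 (the first two modules) to the linear
    predictor, giving a hazard no linear gene model can capture.
    """

    n_genes: int = 300
    n_samples_per_cohort: tuple[int, ...] = (300, 200)
    n_modules: int = 6
    module_sizes: tuple[int, ...] = (60, 50, 40, 30, 30, 30)
    module_loading: tuple[float, ...] = (0.8,) * 6
    survival_effect: tuple[float, ...] = (1.0, 1.0, 0.0, 0.0, 0.0, 0.0)
    interaction_effect: float = 0.0
    baseline_hazard: float = 0.05
    censoring_rate_target: float = 0.3
    noise_sd: float = 0.6
    seed: int = 0

    def __post_init__(self):
        for name in ("module_sizes", "module_loading", "survival_effect", "n_samples_per_cohort"):
            object.__setattr__(self, name, tuple(getattr(self, name)))
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes must have length n_modules")
        if len(self.module_loading) != self.n_modules:
            raise ValueError("module_loading must have length n_modules")
        if len(self.survival_effect) != self.n_modules:
            raise ValueError("survival_effect must have length n_modules")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("sum(module_sizes) exceeds n_genes")
        if any(not (0 < lam <= 1) for lam in self.module_loading):
            raise ValueError("module loadings must lie in (0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if not (0 <= self.censoring_rate_target < 1):
            raise ValueError("censoring_rate_target must lie in [0, 1)")


@dataclass
class PlantedTruth:
    """Ground truth for recovery tests."""

    gene_to_module: pd.Series  # gene id -> module index, -1 = background
    module_effects: tuple[float, ...]
    latent_factors: dict[str, pd.DataFrame] = field(default_factory=dict)  # cohort -> samples x modules

    def module_genes(self, k: int) -> list[str]:
        return list(self.gene_to_module.index[self.gene_to_module == k])


def _gene_ids(config: SimulationConfig) -> tuple[list[str], np.ndarray]:
    ids, membership = [], []
    g = 0
    for k, size in enumerate(config.module_sizes):
        for _ in range(size):
            ids.append(f"G{g:05d}")
            membership.append(k)
            g += 1
    while g < config.n_genes:
        ids.append(f"G{g:05d}")
        membership.append(-1)
        g += 1
    return ids, np.asarray(membership)


def _solve_cmax(times: np.ndarray, target: float) -> float:
    """c_max for uniform(0, c_max) censoring: expected censored fraction,
    given the drawn event times, is mean(min(T_i / c_max, 1)); bisect."""

    def frac(c):
        return float(np.mean(np.minimum(times / c, 1.0)))

    lo, hi = times.min() * 1e-6, times.max() * 1e6
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if frac(mid) > target:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def generate_cohort(
    config: SimulationConfig, cohort_index: int = 0
) -> tuple[Cohort, PlantedTruth]:
    """One cohort under the planted-module generative model.

    The random stream is fully determined by (config.seed, cohort_index).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, cohort_index]))
    n = config.n_samples_per_cohort[min(cohort_index, len(config.n_samples_per_cohort) - 1)]
    gene_ids, membership = _gene_ids(config)
    sample_ids = [f"C{cohort_index}_S{i:04d}" for i in range(n)]

    factors = rng.standard_normal((n, config.n_modules))
    X = rng.normal(0.0, 1.0, size=(config.n_genes, n))  # background: unit noise
    in_module = membership >= 0
    lam = np.asarray(config.module_loading)[membership[in_module]]
    X[in_module, :] = (
        lam[:, None] * factors[:, membership[in_module]].T
        + rng.normal(0.0, config.noise_sd, size=(int(in_module.sum()), n))
    )

    eta = factors @ np.asarray(config.survival_effect)
    if config.interaction_effect != 0.0 and config.n_modules >= 2:
        eta = eta + config.interaction_effect * factors[:, 0] * factors[:, 1]
    rate = config.baseline_hazard * np.exp(eta)
    T = rng.exponential(1.0 / rate)
    if config.censoring_rate_target > 0:
        cmax = _solve_cmax(T, config.censoring_rate_target)
        C = rng.uniform(0.0, cmax, size=n)
        time = np.minimum(T, C)
        event = (T <= C).astype(int)
    else:
        time, event = T, np.ones(n, dtype=int)

    # standardize per gene per cohort (ddof=0), the pipeline's input contract
    X = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)

    expr = pd.DataFrame(X, index=gene_ids, columns=sample_ids)
    surv = pd.DataFrame({"time": time, "event": event}, index=sample_ids)
    cohort = Cohort(name=f"cohort{cohort_index}", expression=expr, survival=surv)
    truth = PlantedTruth(
        gene_to_module=pd.Series(membership, index=gene_ids, name="module"),
        module_effects=config.survival_effect,
        latent_factors={
            cohort.name: pd.DataFrame(
                factors, index=sample_ids, columns=[f"M{k}" for k in range(config.n_modules)]
            )
        },
    )
    return cohort, truth


def generate_multi_cohort(config: SimulationConfig) -> tuple[list[Cohort], PlantedTruth]:
    """Training cohort plus >=1 test cohorts sharing gene ids, module
    membership and effects, with independent factors and noise."""
    n_cohorts = len(config.n_samples_per_cohort)
    if n_cohorts < 2:
        raise ValueError("need at least 2 cohorts (1 training + >=1 test)")
    cohorts: list[Cohort] = []
    truth: PlantedTruth | None = None
    for i in range(n_cohorts):
        cohort, t = generate_cohort(config, i)
        cohorts.append(cohort)
        if truth is None:
            truth = t
        else:
            truth.latent_factors.update(t.latent_factors)
    assert truth is not None
    return cohorts, truth


def null_config(config: SimulationConfig) -> SimulationConfig:
    """Same conditions with every survival effect zeroed."""
    return replace(
        config, survival_effect=(0.0,) * config.n_modules, interaction_effect=0.0
    )
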