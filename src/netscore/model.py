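"""The convolutional survival network producing the NetScore.

Architecture: the input is the expression of the representative genes,
laid out in module blocks (within a block, genes ordered by decreasing
|kME|).  For each module, one-dimensional convolutional filters of
kernel length equal to that module's gene count (stride = block length)
each summarize the module's gene vector into a single activation, so a
module with F filters contributes F features.  The concatenated
activations pass through three fully connected rectified layers and a
final linear unit that emits the scalar risk score.

Training minimizes the negative Cox log partial likelihood (Breslow
ties) over the full batch — the partial likelihood couples samples
through risk sets, so mini-batching would change the objective.  The
network is small enough that forward, backward and the Adam update are
written directly in numpy; gradients are validated against central
finite differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .simulate import Cohort
from .survival import concordance_index, cox_fit, ConvergenceError

__all__ = [
    "ArchitectureSpec",
    "TrainingConfig",
    "NetScoreModel",
    "CVRecord",
    "build_model",
    "cox_loss",
    "train_model",
    "cross_validate",
    "predict_netscore",
    "compare_with_cox_baseline",
    "DEFAULT_GRID",
]


@dataclass(frozen=True)
class ArchitectureSpec:
    """Input layout and layer sizes. Exactly three FC hidden layers."""

    modules: tuple[tuple[str, tuple[str, ...]], ...]  # (label, ordered genes)
    filters_per_module: int = 8
    fc_layer_sizes: tuple[int, int, int] = (16, 8, 4)
    activation: str = "relu"

    def __post_init__(self):
        object.__setattr__(
            self, "modules", tuple((lb, tuple(genes)) for lb, genes in self.modules)
        )
        object.__setattr__(self, "fc_layer_sizes", tuple(self.fc_layer_sizes))
        if len(self.modules) < 1:
            raise ValueError("need at least one module")
        if any(len(genes) < 1 for _, genes in self.modules):
            raise ValueError("empty gene list in a module block")
        if len(self.fc_layer_sizes) != 3:
            raise ValueError("exactly 3 fully connected hidden layers")
        all_genes = [g for _, genes in self.modules for g in genes]
        if len(all_genes) != len(set(all_genes)):
            raise ValueError("module gene lists overlap")
        if self.activation != "relu":
            raise ValueError("only the rectifier activation is supported")

    @property
    def input_genes(self) -> list[str]:
        return [g for _, genes in self.modules for g in genes]

    @property
    def input_width(self) -> int:
        return len(self.input_genes)


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 1e-2
    epochs: int = 200
    seed: int = 0
    optimizer: str = "adam"
    full_batch: bool = True
    weight_decay: float = 1e-4  # decoupled; keeps the unbounded partial
    # likelihood from driving weights to infinity under perfect separation

    def __post_init__(self):
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight decay must be >= 0")


@dataclass
class CVRecord:
    fold_assignments: np.ndarray  # fold index per training sample
    table: pd.DataFrame  # one row per config: mean_c, sd_c
    chosen_index: int

    @property
    def chosen(self):
        return self.table.iloc[self.chosen_index]


@dataclass
class NetScoreModel:
    spec: ArchitectureSpec
    weights: dict[str, np.ndarray]
    training_config: TrainingConfig | None = None
    cv_record: CVRecord | None = None
    init_seed: int = 0
    loss_trace: list[float] = field(default_factory=list)

    def copy_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.weights.items()}

    def save(self, prefix) -> None:
        """Persist as JSON (architecture, provenance) + npz weights."""
        meta = {
            "modules": [[lb, list(genes)] for lb, genes in self.spec.modules],
            "filters_per_module": self.spec.filters_per_module,
            "fc_layer_sizes": list(self.spec.fc_layer_sizes),
            "activation": self.spec.activation,
            "init_seed": self.init_seed,
            "training_config": None
            if self.training_config is None
            else {
                "learning_rate": self.training_config.learning_rate,
                "epochs": self.training_config.epochs,
                "seed": self.training_config.seed,
                "optimizer": self.training_config.optimizer,
            },
        }
        with open(f"{prefix}.json", "w") as fh:
            json.dump(meta, fh, indent=1)
        np.savez_compressed(f"{prefix}.weights.npz", **self.weights)

    @classmethod
    def load(cls, prefix) -> "NetScoreModel":
        with open(f"{prefix}.json") as fh:
            meta = json.load(fh)
        spec = ArchitectureSpec(
            modules=tuple((lb, tuple(genes)) for lb, genes in meta["modules"]),
            filters_per_module=meta["filters_per_module"],
            fc_layer_sizes=tuple(meta["fc_layer_sizes"]),
            activation=meta["activation"],
        )
        with np.load(f"{prefix}.weights.npz") as npz:
            weights = {k: npz[k] for k in npz.files}
        tc = meta.get("training_config")
        return cls(
            spec=spec,
            weights=weights,
            training_config=None if tc is None else TrainingConfig(**tc),
            init_seed=meta.get("init_seed", 0),
        )


def build_model(spec: ArchitectureSpec, seed: int = 0) -> NetScoreModel:
    """Initialize weights from a seeded small-variance normal scheme."""
    rng = np.random.default_rng(seed)
    w: dict[str, np.ndarray] = {}
    for i, (_, genes) in enumerate(spec.modules):
        w[f"conv{i}_W"] = rng.normal(0.0, 0.1, size=(spec.filters_per_module, len(genes)))
        w[f"conv{i}_b"] = np.zeros(spec.filters_per_module)
    width = spec.filters_per_module * len(spec.modules)
    sizes = [width, *spec.fc_layer_sizes]
    for li in range(3):
        w[f"fc{li}_W"] = rng.normal(0.0, 0.1, size=(sizes[li + 1], sizes[li]))
        w[f"fc{li}_b"] = np.zeros(sizes[li + 1])
    w["out_W"] = rng.normal(0.0, 0.1, size=(sizes[-1],))
    w["out_b"] = np.zeros(1)
    return NetScoreModel(spec=spec, weights=w, init_seed=seed)


def _forward(spec: ArchitectureSpec, w: dict, X: np.ndarray, cache: bool = False):
    """X: samples x input_width (module blocks concatenated)."""
    acts = []
    offset = 0
    convs = []
    for i, (_, genes) in enumerate(spec.modules):
        block = X[:, offset : offset + len(genes)]
        z = block @ w[f"conv{i}_W"].T + w[f"conv{i}_b"]
        convs.append((block, z))
        acts.append(np.maximum(z, 0.0))
        offset += len(genes)
    h = np.concatenate(acts, axis=1)
    caches = [h]
    zs = []
    for li in range(3):
        z = h @ w[f"fc{li}_W"].T + w[f"fc{li}_b"]
        zs.append(z)
        h = np.maximum(z, 0.0)
        caches.append(h)
    eta = h @ w["out_W"] + w["out_b"][0]
    if cache:
        return eta, (convs, caches, zs)
    return eta


def _backward(spec: ArchitectureSpec, w: dict, cache, d_eta: np.ndarray) -> dict:
    convs, caches, zs = cache
    grads: dict[str, np.ndarray] = {}
    h3 = caches[3]
    grads["out_W"] = h3.T @ d_eta
    grads["out_b"] = np.array([d_eta.sum()])
    dh = np.outer(d_eta, w["out_W"])
    for li in (2, 1, 0):
        dz = dh * (zs[li] > 0)
        grads[f"fc{li}_W"] = dz.T @ caches[li]
        grads[f"fc{li}_b"] = dz.sum(axis=0)
        dh = dz @ w[f"fc{li}_W"]
    F = spec.filters_per_module
    for i, (_, _genes) in enumerate(spec.modules):
        dact = dh[:, i * F : (i + 1) * F]
        block, z = convs[i]
        dz = dact * (z > 0)
        grads[f"conv{i}_W"] = dz.T @ block
        grads[f"conv{i}_b"] = dz.sum(axis=0)
    return grads


def cox_loss(
    scores: np.ndarray, survival: pd.DataFrame
) -> tuple[float, np.ndarray]:
    """Negative Cox log partial likelihood (Breslow) and its gradient
    in the scores.

    loss = -sum_{i: event} [eta_i - log sum_{j: t_j >= t_i} exp(eta_j)]
    """
    eta = np.asarray(scores, dtype=float)
    time = np.asarray(survival["time"], dtype=float)
    event = np.asarray(survival["event"], dtype=float)
    if event.sum() < 1:
        raise ValueError("Cox loss undefined with zero events")
    n = len(eta)
    order = np.argsort(-time, kind="stable")
    ts, es = time[order], event[order]
    eta_s = eta[order]
    # log-space risk sets: logS0_i = log sum_{j: t_j >= t_i} exp(eta_j),
    # computed by a running log-add-exp so arbitrary score spreads are safe
    logS0 = np.logaddexp.accumulate(eta_s)
    last = np.searchsorted(-ts, -ts, side="right") - 1
    ev = es == 1.0
    ev_logS0 = logS0[last[ev]]
    loss = -float(np.sum(eta_s[ev] - ev_logS0))

    # dL/deta_j = -e_j + sum over events i with j in risk set of
    # exp(eta_j - logS0_i); each term is <= 1 by construction
    ev_last = last[ev]  # risk set of event i = sorted positions 0..ev_last[i]
    with np.errstate(over="ignore"):
        E = np.exp(eta_s[:, None] - ev_logS0[None, :])
    E[np.arange(n)[:, None] > ev_last[None, :]] = 0.0
    grad_s = -es + E.sum(axis=1)
    grad = np.empty(n)
    grad[order] = grad_s
    return loss, grad


def train_model(
    model: NetScoreModel, cohort: Cohort, config: TrainingConfig
) -> NetScoreModel:
    """Full-batch Adam on the Cox partial-likelihood loss.

    Deterministic under a fixed (init, config) seed pair; raises if the
    loss becomes non-finite.
    """
    X = _input_matrix(model.spec, cohort)
    surv = cohort.survival
    if len(surv) < 20 or surv["event"].sum() < 5:
        raise ValueError("need >= 20 samples with >= 5 events to train")
    w = model.copy_weights()
    m = {k: np.zeros_like(v) for k, v in w.items()}
    v = {k: np.zeros_like(vv) for k, vv in w.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    trace: list[float] = []
    eta, cache = _forward(model.spec, w, X, cache=True)
    loss, _ = cox_loss(eta, surv)
    trace.append(loss)
    for t in range(1, config.epochs + 1):
        eta, cache = _forward(model.spec, w, X, cache=True)
        loss, d_eta = cox_loss(eta, surv)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"training diverged (non-finite loss) at learning rate {config.learning_rate}"
            )
        grads = _backward(model.spec, w, cache, d_eta)
        for k in w:
            m[k] = b1 * m[k] + (1 - b1) * grads[k]
            v[k] = b2 * v[k] + (1 - b2) * grads[k] ** 2
            mhat = m[k] / (1 - b1**t)
            vhat = v[k] / (1 - b2**t)
            w[k] = w[k] - config.learning_rate * (
                mhat / (np.sqrt(vhat) + eps) + config.weight_decay * w[k]
            )
        trace.append(loss)
    return NetScoreModel(
        spec=model.spec,
        weights=w,
        training_config=config,
        cv_record=model.cv_record,
        init_seed=model.init_seed,
        loss_trace=trace,
    )


def _input_matrix(spec: ArchitectureSpec, cohort: Cohort) -> np.ndarray:
    """Samples x genes in the spec's block order, standardized per gene
    within the cohort being scored."""
    missing = [g for g in spec.input_genes if g not in cohort.expression.index]
    if missing:
        raise KeyError(f"cohort {cohort.name} missing input genes: {missing[:10]}")
    X = cohort.expression.loc[spec.input_genes].to_numpy(dtype=float).T
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - X.mean(axis=0)) / sd


def predict_netscore(model: NetScoreModel, cohort: Cohort) -> pd.Series:
    """Deterministic forward pass; genes standardized within the cohort."""
    X = _input_matrix(model.spec, cohort)
    eta = _forward(model.spec, model.weights, X)
    return pd.Series(eta, index=cohort.expression.columns, name="netscore")


#: default cross-validation grid (architecture x training settings)
DEFAULT_GRID: list[tuple[dict, TrainingConfig]] = [
    ({"filters_per_module": f, "fc_layer_sizes": fc}, TrainingConfig(learning_rate=lr, epochs=ep))
    for f in (4, 8)
    for fc in ((32, 16, 8), (16, 8, 4))
    for lr in (1e-2, 1e-3)
    for ep in (200, 500)
]


def _subset_cohort(cohort: Cohort, idx: np.ndarray) -> Cohort:
    cols = cohort.expression.columns[idx]
    return Cohort(
        name=cohort.name,
        expression=cohort.expression[cols],
        survival=cohort.survival.loc[cols],
    )


def cross_validate(
    cohort: Cohort,
    modules: tuple[tuple[str, tuple[str, ...]], ...],
    grid: list[tuple[dict, TrainingConfig]] | None = None,
    k: int = 5,
    seed: int = 0,
) -> CVRecord:
    """Seeded k-fold CV over an (architecture, training) grid; the chosen
    configuration maximizes the mean held-out C-index."""
    if k < 2:
        raise ValueError("k must be >= 2")
    grid = DEFAULT_GRID if grid is None else grid
    if not grid:
        raise ValueError("empty grid")
    n = cohort.n_samples
    events = cohort.survival["event"].to_numpy()

    rng = np.random.default_rng(seed)
    folds = _make_folds(rng, n, k)
    if any(events[folds == f].sum() == 0 for f in range(k)):
        folds = _make_folds(rng, n, k)  # re-randomize once
        if any(events[folds == f].sum() == 0 for f in range(k)):
            raise ValueError("a CV fold has zero events even after re-randomization")

    rows = []
    for ci, (arch_kwargs, tconf) in enumerate(grid):
        spec = ArchitectureSpec(modules=modules, **arch_kwargs)
        cs = []
        for f in range(k):
            train = _subset_cohort(cohort, folds != f)
            test = _subset_cohort(cohort, folds == f)
            model = build_model(spec, seed=seed + ci)
            fitted = train_model(model, train, tconf) if tconf.epochs > 0 else model
            scores = predict_netscore(fitted, test)
            try:
                c = concordance_index(scores, test.survival, n_bootstrap=0).c_index
            except ValueError:
                c = np.nan
            cs.append(c)
        cs = np.asarray(cs)
        rows.append(
            {
                "config": ci,
                "filters_per_module": spec.filters_per_module,
                "fc_layer_sizes": str(spec.fc_layer_sizes),
                "learning_rate": tconf.learning_rate,
                "epochs": tconf.epochs,
                "mean_c": float(np.nanmean(cs)),
                "sd_c": float(np.nanstd(cs, ddof=1)),
            }
        )
    table = pd.DataFrame(rows)
    chosen = int(table["mean_c"].idxmax())
    return CVRecord(fold_assignments=folds, table=table, chosen_index=chosen)


def _make_folds(rng, n: int, k: int) -> np.ndarray:
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    for f, part in enumerate(np.array_split(perm, k)):
        folds[part] = f
    return folds


def fit_cv_model(
    cohort: Cohort,
    modules: tuple[tuple[str, tuple[str, ...]], ...],
    grid: list[tuple[dict, TrainingConfig]] | None = None,
    k: int = 5,
    seed: int = 0,
) -> NetScoreModel:
    """Cross-validate, then retrain the chosen configuration on the full
    training cohort."""
    record = cross_validate(cohort, modules, grid=grid, k=k, seed=seed)
    grid = DEFAULT_GRID if grid is None else grid
    arch_kwargs, tconf = grid[record.chosen_index]
    spec = ArchitectureSpec(modules=modules, **arch_kwargs)
    model = build_model(spec, seed=seed + record.chosen_index)
    fitted = train_model(model, cohort, tconf) if tconf.epochs > 0 else model
    fitted.cv_record = record
    return fitted


def compare_with_cox_baseline(
    cohorts: list[Cohort],
    gene_list: list[str],
    modules: tuple[tuple[str, tuple[str, ...]], ...],
    seed: int = 0,
    training_config: TrainingConfig | None = None,
    arch_kwargs: dict | None = None,
) -> pd.DataFrame:
    """NetScore versus a conventional multivariate Cox model on the same
    gene panel: both fit on the first (training) cohort, C-index +/- SE
    reported on every cohort."""
    training = cohorts[0]
    tconf = training_config or TrainingConfig(learning_rate=1e-2, epochs=300, seed=seed)
    spec = ArchitectureSpec(modules=modules, **(arch_kwargs or {}))
    model = build_model(spec, seed=seed)
    model = train_model(model, training, tconf)

    Xtr = training.expression.loc[gene_list].T
    cox_ok = True
    try:
        cox = cox_fit(Xtr, training.survival)
    except (ConvergenceError, ValueError):
        cox_ok = False
        cox = None

    rows = []
    for cohort in cohorts:
        ns = predict_netscore(model, cohort)
        cns = concordance_index(ns, cohort.survival, seed=seed)
        row = {
            "cohort": cohort.name,
            "netscore_c": cns.c_index,
            "netscore_se": cns.se,
            "cox_c": np.nan,
            "cox_se": np.nan,
            "cox_converged": cox_ok,
        }
        if cox_ok:
            Xc = cohort.expression.loc[gene_list].T.to_numpy(dtype=float)
            lin = Xc @ cox.coef
            cc = concordance_index(lin, cohort.survival, seed=seed)
            row["cox_c"], row["cox_se"] = cc.c_index, cc.se
        rows.append(row)
    return pd.DataFrame(rows)
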