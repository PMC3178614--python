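"""L1-regularized maximum-entropy niche models from presence-only records.

The model estimates a probability distribution q over background cells
that has maximum entropy subject to (soft) constraints that feature
expectations under q match their empirical means over presence cells.
Equivalently, with linear predictor eta(x) = sum_j lambda_j f_j(x) and
q(x) = exp(eta(x)) / Z, the weights minimize the convex objective

    J(lambda) = -mean_presence eta(x)  +  log Z(lambda)
                + sum_j beta_j |lambda_j|

where the per-feature L1 budgets beta_j shrink with presence sample size.
The raw output q sums to one over the background; the logistic output
L(x) = c q(x) / (1 + c q(x)) with c = exp(H(q)) rescales it to [0, 1]
under an assumed prevalence of 0.5 for a cell with "typical" suitability.

Optimization is proximal gradient descent (soft-thresholding) with
backtracking line search, which is monotone in the objective and handles
the non-smooth L1 term exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from . import validation
from .features import FeatureMatrix, expand_features, auto_classes
from .layers import LayerStack
from .occurrence import CellOccurrences, MIN_UNIQUE_CELLS

__all__ = [
    "MaxentModel",
    "SuitabilitySurface",
    "ReplicateResult",
    "ReplicateEnsemble",
    "regularization",
    "fit_maxent",
    "predict",
    "run_replicates",
]

#: Default cap on background size; larger backgrounds are sampled.
DEFAULT_BACKGROUND_SIZE = 10_000

#: Logistic-output prevalence assumption.
DEFAULT_TAU = 0.5

# Per-class base regularization, interpolated against presence sample size.
# Classes not listed fall back to "linear".
_BETA_TABLES: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    "linear": ((0, 10, 30, 100), (1.0, 1.0, 0.2, 0.05)),
    "quadratic": ((0, 10, 30, 100), (1.0, 1.0, 0.2, 0.05)),
    "product": ((0, 10, 30, 100), (1.0, 1.0, 0.2, 0.05)),
    "category": ((0, 10, 17), (0.65, 0.5, 0.25)),
    "threshold": ((0, 100), (2.0, 1.0)),
    "hinge": ((0, 100), (0.5, 0.5)),
}

#: Floor on the presence-sample standard deviation used in beta_j, so
#: features constant over presences still carry a positive budget.
_STD_FLOOR = 0.05


def regularization(features: FeatureMatrix, presence_rows: np.ndarray,
                   reg_multiplier: float = 1.0) -> np.ndarray:
    """Per-feature L1 budgets beta_j.

    beta_j = multiplier * base(class, m) * max(sd_j, floor) / sqrt(m),
    where sd_j is the feature's standard deviation over the m presences.
    """
    m = len(presence_rows)
    if m < 1:
        raise ValueError("need at least one presence")
    fp = features.values[presence_rows]
    sd = np.maximum(fp.std(axis=0, ddof=0), _STD_FLOOR)
    base = np.empty(features.n_features)
    for j, d in enumerate(features.descriptors):
        xs, ys = _BETA_TABLES.get(d.klass, _BETA_TABLES["linear"])
        base[j] = np.interp(m, xs, ys)
    return reg_multiplier * base * sd / np.sqrt(m)


@dataclass
class MaxentModel:
    """Fitted weights and the raw distribution they induce on the background."""

    lambdas: np.ndarray
    betas: np.ndarray
    descriptors: list
    background_rows: np.ndarray
    q_background: np.ndarray       # sums to 1 over background_rows
    log_z: float                   # log partition over background
    entropy: float                 # H(q), nats
    tau: float = DEFAULT_TAU
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = True

    @property
    def n_features(self) -> int:
        return len(self.lambdas)

    def dump(self) -> str:
        lines = [f"entropy {self.entropy:.6f}", f"log_z {self.log_z:.6f}",
                 f"tau {self.tau}", "feature\tlambda\tbeta"]
        for d, lam, b in zip(self.descriptors, self.lambdas, self.betas):
            lines.append(f"{d.label()}\t{lam:.6g}\t{b:.6g}")
        return "\n".join(lines)


@dataclass
class SuitabilitySurface:
    """Raw and logistic suitability on the analysis grid.

    ``raw`` sums to 1 over the background cells; ``logistic`` is the
    monotone [0, 1] transform anchored at prevalence tau.  Cells outside
    the valid extent are NaN.
    """

    raw: np.ndarray
    logistic: np.ndarray
    provenance: dict = field(default_factory=dict)

    def values_at(self, cell_ids: Sequence[int], which: str = "logistic") -> np.ndarray:
        arr = self.logistic if which == "logistic" else self.raw
        return arr.ravel()[np.asarray(cell_ids)]


def _objective_smooth(lam, F_bg, fbar_p):
    eta = F_bg @ lam
    return float(-(fbar_p @ lam) + logsumexp(eta)), eta


def fit_maxent(
    presence_rows: np.ndarray,
    background_rows: np.ndarray,
    features: FeatureMatrix,
    reg_multiplier: float = 1.0,
    tol: float = 1e-5,
    max_iter: int = 500,
    betas: np.ndarray | None = None,
) -> MaxentModel:
    """Fit weights by proximal gradient descent on the regularized objective.

    Deterministic given inputs.  The objective trace is non-increasing
    across accepted iterations; convergence is declared when the relative
    objective change drops below ``tol``.  ``betas`` overrides the
    sample-size-derived budgets (used by oracle tests).
    """
    presence_rows = np.asarray(presence_rows, dtype=np.intp)
    background_rows = np.asarray(background_rows, dtype=np.intp)
    if presence_rows.size == 0:
        raise ValueError("no presence cells")
    if not np.isfinite(features.values).all():
        raise ValueError("non-finite feature values")

    F_bg = features.values[background_rows]
    fbar_p = features.values[presence_rows].mean(axis=0)
    n_feat = features.n_features
    if betas is None:
        betas = regularization(features, presence_rows, reg_multiplier)
    betas = np.broadcast_to(np.asarray(betas, dtype=float), (n_feat,)).copy()

    lam = np.zeros(n_feat)
    j_smooth, eta = _objective_smooth(lam, F_bg, fbar_p)
    j_total = j_smooth  # beta term is zero at lambda = 0
    trace = [j_total]
    step = 1.0
    converged = False
    for _ in range(max_iter):
        if n_feat == 0:
            converged = True
            break
        w = np.exp(eta - logsumexp(eta))
        grad = F_bg.T @ w - fbar_p
        # backtracking proximal step
        for _bt in range(60):
            z = lam - step * grad
            lam_new = np.sign(z) * np.maximum(np.abs(z) - step * betas, 0.0)
            d = lam_new - lam
            js_new, eta_new = _objective_smooth(lam_new, F_bg, fbar_p)
            if js_new <= j_smooth + grad @ d + (d @ d) / (2 * step) + 1e-12:
                break
            step *= 0.5
        j_new = js_new + betas @ np.abs(lam_new)
        rel = (j_total - j_new) / max(1.0, abs(j_total))
        lam, eta, j_smooth, j_total = lam_new, eta_new, js_new, j_new
        trace.append(j_total)
        if 0 <= rel < tol:
            converged = True
            break
        step *= 1.25  # cautiously re-grow the step after success

    log_z = float(logsumexp(eta))
    q = np.exp(eta - log_z)
    q /= q.sum()  # enforce exact normalization against float round-off
    entropy = float(-(q * np.log(np.maximum(q, 1e-300))).sum())
    return MaxentModel(
        lambdas=lam, betas=betas, descriptors=features.descriptors,
        background_rows=background_rows, q_background=q, log_z=log_z,
        entropy=entropy, objective_trace=np.asarray(trace), converged=converged,
    )


def predict(model: MaxentModel, features: FeatureMatrix) -> SuitabilitySurface:
    """Project a fitted model onto the full valid extent of a stack.

    Raw values are normalized by the partition function of the model's
    background, so they sum to 1 over the background cells.  The logistic
    transform is L = c q / (1 + c q) with c = exp(H).
    """
    if [d.label() for d in features.descriptors] != [d.label() for d in model.descriptors]:
        raise ValueError("feature descriptors do not match the fitted model")
    eta = features.values @ model.lambdas
    log_z = logsumexp(eta[model.background_rows])
    raw_valid = np.exp(eta - log_z)
    c = np.exp(model.entropy)
    logi_valid = c * raw_valid / (1.0 + c * raw_valid)

    n_cells = features.grid_shape[0] * features.grid_shape[1]
    raw = np.full(n_cells, np.nan)
    logi = np.full(n_cells, np.nan)
    raw[features.cell_ids] = raw_valid
    logi[features.cell_ids] = logi_valid
    return SuitabilitySurface(
        raw=raw.reshape(features.grid_shape),
        logistic=logi.reshape(features.grid_shape),
    )


@dataclass
class ReplicateResult:
    """One train/test replicate: the fitted model, surface, and scores."""

    replicate: int
    train_cells: np.ndarray
    test_cells: np.ndarray
    model: MaxentModel
    surface: SuitabilitySurface
    auc_train: float
    auc_test: float
    omission_tests: list


@dataclass
class ReplicateEnsemble:
    """The replicated-model unit that the acceptance rule judges."""

    species_id: str
    replicates: list[ReplicateResult]
    seed: int
    test_frac: float
    variable_set_id: str | None = None
    n_records: int = 0

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    def mean_logistic_surface(self) -> np.ndarray:
        """Cell-wise mean of the replicate logistic surfaces."""
        return np.mean([r.surface.logistic for r in self.replicates], axis=0)

    def validation_report(self) -> "validation.ValidationReport":
        return validation.ValidationReport(
            mean_train_auc=float(np.mean([r.auc_train for r in self.replicates])),
            mean_test_auc=float(np.mean([r.auc_test for r in self.replicates])),
            omission_tests=[t for r in self.replicates for t in r.omission_tests],
            n_replicates=self.n_replicates,
        )

    def summary_rows(self) -> list[dict]:
        return [{"replicate": r.replicate, "train_auc": r.auc_train,
                 "test_auc": r.auc_test} for r in self.replicates]


def run_replicates(
    cells: CellOccurrences,
    stack: LayerStack,
    n_rep: int = 100,
    test_frac: float = 0.4,
    seed: int = 0,
    reg_multiplier: float = 1.0,
    background_size: int = DEFAULT_BACKGROUND_SIZE,
    classes: str | Sequence[str] = "auto",
    tol: float = 1e-5,
    max_iter: int = 500,
    min_cells: int = MIN_UNIQUE_CELLS,
) -> ReplicateEnsemble:
    """Fit the replicated train/test ensemble for one species.

    Each replicate withholds ``round(test_frac * n)`` presence cells
    (at least one) as test records, fits on the remainder, and scores
    both partitions with rank-based AUC and the eleven binomial omission
    tests.  Fully reproducible given ``seed``.
    """
    if not 0 < test_frac < 1:
        raise ValueError("test_frac must be in (0, 1)")
    n = cells.n_cells
    if n < min_cells:
        raise ValueError(
            f"species {cells.species_id!r} occupies {n} unique cells; "
            f"modelling requires at least {min_cells}"
        )
    n_test = max(1, int(round(test_frac * n)))
    n_train = n - n_test
    if n_train < 1:
        raise ValueError("test fraction leaves no training cells")

    features = expand_features(stack, n_presence=n_train, classes=classes)
    presence_cells = np.array(sorted(cells.cell_ids))
    presence_rows = features.rows_for_cells(presence_cells)

    rng = np.random.default_rng(seed)
    all_rows = np.arange(features.n_cells)
    if features.n_cells > background_size:
        bg = rng.choice(all_rows, size=background_size, replace=False)
        background_rows = np.union1d(bg, presence_rows)
    else:
        background_rows = all_rows

    replicates: list[ReplicateResult] = []
    for r in range(n_rep):
        perm = rng.permutation(n)
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        train_rows = presence_rows[train_idx]
        test_rows = presence_rows[test_idx]
        model = fit_maxent(train_rows, background_rows, features,
                           reg_multiplier=reg_multiplier, tol=tol, max_iter=max_iter)
        surface = predict(model, features)
        surface.provenance = {"species": cells.species_id, "replicate": r}
        flat_logi = surface.logistic.ravel()
        bg_scores = flat_logi[features.cell_ids[background_rows]]
        train_scores = flat_logi[presence_cells[train_idx]]
        test_scores = flat_logi[presence_cells[test_idx]]
        auc_tr = validation.compute_auc(train_scores, bg_scores)
        auc_te = validation.compute_auc(test_scores, bg_scores)
        raw_bg = surface.raw.ravel()[features.cell_ids[background_rows]]
        tests = validation.binomial_omission_tests(
            bg_logistic=bg_scores, raw_bg=raw_bg, entropy=model.entropy,
            train_scores=train_scores, test_scores=test_scores,
        )
        replicates.append(ReplicateResult(
            replicate=r, train_cells=presence_cells[train_idx],
            test_cells=presence_cells[test_idx], model=model, surface=surface,
            auc_train=auc_tr, auc_test=auc_te, omission_tests=tests,
        ))
    return ReplicateEnsemble(
        species_id=cells.species_id, replicates=replicates, seed=seed,
        test_frac=test_frac, variable_set_id=stack.set_id,
        n_records=cells.n_records_raw,
    )
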