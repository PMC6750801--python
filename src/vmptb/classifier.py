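"""Two-step preterm-birth risk model and its evaluation.

Step 1 screens features (soft-threshold-log taxon abundances, or min-max
normalized clinical variables) with a two-sided Mann-Whitney U test at
p <= 0.05.  Step 2 fits L1-regularized logistic regression on the survivors,
minimizing

    sum_i ln(1 + exp(-y_i (w . x_i + b))) + C * ||w||_1

with labels y in {-1 (term), +1 (preterm)} and an unpenalized intercept.
Note the convention: C multiplies the *penalty*, so larger C means more
shrinkage (the reverse of scikit-learn's ``C``).  C is chosen by inner
stratified k-fold grid search maximizing AUROC, using training samples only.

Generalization is assessed by leave-one-out: for each held-out subject the
entire two-step procedure (filter + grid search + fit) reruns on the rest.
Significance comes from a permutation test that re-trains the full pipeline
on label-shuffled data and compares AUROCs, with the add-one estimator
p = (1 + #{null >= observed}) / (1 + n_perm).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy import stats

from .differential import mann_whitney
from .profiles import soft_threshold_log

logger = logging.getLogger(__name__)

#: coefficients of the published 4-taxon PTB predictive score, applied to
#: soft-threshold-log10 transformed proportions
PTB_SCORE_COEFFICIENTS = {
    "Sneathia_amnii": 0.775,
    "Lachnospiraceae_BVAB1": 0.751,
    "TM7_H1": 0.116,
    "Prevotella_cluster2": 0.011,
}

DEFAULT_C_GRID = tuple(np.logspace(-3, 3, 13))

#: the 11 clinical variables of the comparator model
CLINICAL_VARIABLES = (
    "short_cervix",
    "cerclage",
    "vaginal_ph",
    "bmi",
    "progesterone",
    "gravidity",
    "parity",
    "gravidity_minus_parity",
    "history_miscarriage_stillbirth",
    "history_ptb",
    "antibiotics_6mo",
)


class ConvergenceError(RuntimeError):
    """Solver failed to reach the objective tolerance."""


@dataclass
class TrainingSet:
    """Feature matrix, +/-1 labels and feature names for model training."""

    x: np.ndarray
    y: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y)
        if set(np.unique(self.y)) - {-1, 1}:
            raise ValueError("labels must be -1 (TB) or +1 (PTB)")
        if len({-1, 1} & set(np.unique(self.y))) < 2:
            raise ValueError("both classes must be present")


@dataclass
class PtbModel:
    """Fitted two-step model: surviving features, weights, intercept, C."""

    selected_features: list[str]
    w: np.ndarray
    intercept: float
    C: float
    training_meta: dict = field(default_factory=dict)

    @property
    def intercept_only(self) -> bool:
        return len(self.selected_features) == 0

    def decision_values(self, x: pd.DataFrame | np.ndarray,
                        feature_names: list[str] | None = None) -> np.ndarray:
        """w . x + b restricted to the selected features."""
        if isinstance(x, pd.DataFrame):
            sub = x[self.selected_features].to_numpy(dtype=float)
        else:
            if self.intercept_only:
                return np.full(np.asarray(x).shape[0], self.intercept)
            idx = [feature_names.index(f) for f in self.selected_features]
            sub = np.asarray(x, dtype=float)[:, idx]
        if self.intercept_only:
            return np.full(sub.shape[0], self.intercept)
        return sub @ self.w + self.intercept


@dataclass
class EvaluationResult:
    """Held-out decision values and summary metrics."""

    loo_scores: pd.Series  # per-subject held-out decision value
    sensitivity: float
    specificity: float
    auroc: float
    permutation_p: float | None = None
    null_aurocs: np.ndarray | None = None


def auroc(scores, labels) -> float:
    """Area under the ROC curve by the tie-corrected rank statistic.

    Equals the probability that a random positive outscores a random
    negative, with ties counting one half.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = y == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("need both classes to compute AUROC")
    ranks = stats.rankdata(s)  # midranks for ties
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def fit_l1_logistic(
    data: TrainingSet,
    C: float,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> tuple[np.ndarray, float]:
    """Minimize the L1-penalized logistic objective; returns ``(w, intercept)``.

    The non-smooth L1 term is handled by the positive/negative split
    w = w+ - w-, giving a smooth bound-constrained problem solved with
    L-BFGS-B to objective (projected-gradient) tolerance ``tol``.  The
    intercept is unpenalized.  With separable data at C = 0 the objective
    has no finite minimizer; the solver then stops at the iteration cap with
    a warning rather than raising.
    """
    if C < 0:
        raise ValueError("C must be >= 0")
    X, y = data.x, data.y.astype(float)
    n, p = X.shape

    def objective(theta):
        wp, wm, b = theta[:p], theta[p:2 * p], theta[-1]
        w = wp - wm
        margins = y * (X @ w + b)
        # stable log(1 + exp(-m))
        loss = np.logaddexp(0.0, -margins).sum()
        grad_m = -y / (1.0 + np.exp(margins))  # d loss / d margin, stable
        gw = X.T @ grad_m
        grad = np.concatenate([gw + C, -gw + C, [grad_m.sum()]])
        return loss + C * (wp.sum() + wm.sum()), grad

    theta0 = np.zeros(2 * p + 1)
    bounds = [(0, None)] * (2 * p) + [(None, None)]
    res = minimize(objective, theta0, jac=True, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-8})
    if not np.all(np.isfinite(res.x)):
        raise ConvergenceError(
            f"L1-logistic solver diverged (C={C}): {res.message}")
    if not res.success:
        # iteration cap (expected on separable data at C ~ 0) or a line-search
        # stall at rounding level; the bounded iterate is still the best found
        logger.warning("fit_l1_logistic stopped early (C=%g, nit=%d): %s",
                       C, res.nit, res.message)
    wp, wm, b = res.x[:p], res.x[p:2 * p], res.x[-1]
    w = wp - wm
    w[np.abs(w) < 1e-8] = 0.0  # numerically-zero coordinates are exact zeros
    return w, float(b)


def two_step_train(
    data: TrainingSet,
    p_cut: float = 0.05,
    c_grid=DEFAULT_C_GRID,
    n_splits: int = 5,
    seed: int = 0,
) -> PtbModel:
    """Univariate Mann-Whitney filter then inner-CV-tuned L1 logistic fit.

    Step 1 keeps features whose two-sided Mann-Whitney p (PTB vs TB values)
    is at most ``p_cut``.  Step 2 picks C from ``c_grid`` by stratified
    ``n_splits``-fold cross-validation on the training set, maximizing mean
    held-out AUROC, then refits on all training samples.  If no feature
    survives step 1 a flagged intercept-only model is returned, its
    intercept the unpenalized log-odds log(n+/n-).
    """
    from sklearn.model_selection import StratifiedKFold

    X, y = data.x, data.y
    keep = []
    for j, name in enumerate(data.feature_names):
        xj = X[:, j]
        _, pval = mann_whitney(xj[y == 1], xj[y == -1], zero_floor=0.0)
        if pval <= p_cut:
            keep.append(j)

    n_pos, n_neg = int((y == 1).sum()), int((y == -1).sum())
    if not keep:
        logger.warning("two_step_train: no feature passed the univariate filter")
        return PtbModel(
            selected_features=[], w=np.zeros(0),
            intercept=float(np.log(n_pos / n_neg)), C=float("nan"),
            training_meta={"flag": "intercept-only", "p_cut": p_cut},
        )

    Xs = X[:, keep]
    names = [data.feature_names[j] for j in keep]
    sub = TrainingSet(x=Xs, y=y, feature_names=names)

    c_grid = list(c_grid)
    if len(c_grid) > 1:
        n_splits_eff = min(n_splits, n_pos, n_neg)
        skf = StratifiedKFold(n_splits=n_splits_eff, shuffle=True, random_state=seed)
        mean_auc = []
        folds = list(skf.split(Xs, y))
        for C in c_grid:
            aucs = []
            for tr, te in folds:
                try:
                    fold_data = TrainingSet(x=Xs[tr], y=y[tr], feature_names=names)
                except ValueError:
                    continue
                w, b = fit_l1_logistic(fold_data, C)
                aucs.append(auroc(Xs[te] @ w + b, y[te]))
            mean_auc.append(np.mean(aucs) if aucs else -np.inf)
        best_C = c_grid[int(np.argmax(mean_auc))]
    else:
        best_C = c_grid[0]

    w, b = fit_l1_logistic(sub, best_C)
    nz = np.flatnonzero(w)
    return PtbModel(
        selected_features=[names[j] for j in nz],
        w=w[nz],
        intercept=b,
        C=float(best_C),
        training_meta={
            "univariate_kept": names,
            "c_grid": c_grid,
            "n_splits": n_splits,
            "seed": seed,
            "p_cut": p_cut,
        },
    )


def _metrics(scores: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    pred_pos = scores > 0
    pos, neg = y == 1, y == -1
    sens = float(np.mean(pred_pos[pos]))
    spec = float(np.mean(~pred_pos[neg]))
    return sens, spec, auroc(scores, y)


def loo_evaluate(
    data: TrainingSet,
    subject_ids,
    p_cut: float = 0.05,
    c_grid=DEFAULT_C_GRID,
    n_splits: int = 5,
    seed: int = 0,
    whole_cohort_filter: bool = False,
) -> EvaluationResult:
    """Leave-one-subject-out evaluation of the full two-step pipeline.

    For each subject the entire procedure — univariate filter, C grid
    search, final fit — reruns on the remaining subjects (no leakage), and
    the held-out decision value is recorded.  Sensitivity and specificity
    use decision threshold 0; AUROC uses the tie-corrected rank statistic
    over the held-out scores.

    ``whole_cohort_filter=True`` runs the univariate filter once on the full
    cohort before the folds (a comparison mode that leaks the held-out
    subject into feature selection; the leakage-free in-fold filter is the
    default).
    """
    X, y = data.x, data.y
    subject_ids = list(subject_ids)
    if len(subject_ids) != X.shape[0]:
        raise ValueError("one subject id per sample required")
    if whole_cohort_filter:
        pre = two_step_train(data, p_cut=p_cut, c_grid=list(c_grid)[:1],
                             n_splits=n_splits, seed=seed)
        kept = pre.training_meta.get("univariate_kept", [])
        idx = [data.feature_names.index(f) for f in kept]
        X = X[:, idx] if idx else X[:, :0]
        names = kept
        fold_p_cut = 1.1  # filtering already done; keep everything in-fold
    else:
        names = data.feature_names
        fold_p_cut = p_cut
    scores = np.empty(X.shape[0])
    for i in range(X.shape[0]):
        mask = np.ones(X.shape[0], dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            raise ValueError("a LOO fold has only one class")
        if X.shape[1] == 0:
            n_pos, n_neg = (y[mask] == 1).sum(), (y[mask] == -1).sum()
            scores[i] = float(np.log(n_pos / n_neg))
            continue
        train = TrainingSet(x=X[mask], y=y[mask], feature_names=names)
        model = two_step_train(train, p_cut=fold_p_cut, c_grid=c_grid,
                               n_splits=n_splits, seed=seed)
        scores[i] = model.decision_values(X[i:i + 1], names)[0]
    sens, spec, auc = _metrics(scores, y)
    return EvaluationResult(
        loo_scores=pd.Series(scores, index=subject_ids),
        sensitivity=sens, specificity=spec, auroc=auc,
    )


def permutation_test(
    data: TrainingSet,
    n_perm: int = 10000,
    seed: int = 0,
    p_cut: float = 0.05,
    c_grid=DEFAULT_C_GRID,
    n_splits: int = 5,
    observed_auroc: float | None = None,
) -> tuple[float, np.ndarray, float]:
    """Permutation significance of the two-step model.

    Each permutation shuffles the class labels, reruns the full two-step
    training on the shuffled data, and records the refit model's AUROC on
    the (shuffled) training cohort; the observed AUROC is the same statistic
    on the unshuffled labels, so observed and null values are exchangeable
    under the no-association hypothesis.  Returns
    ``(p, null_aurocs, observed)`` with the add-one estimator
    ``p = (1 + #{null >= observed}) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)

    def train_auroc(y):
        d = TrainingSet(x=data.x, y=y, feature_names=data.feature_names)
        model = two_step_train(d, p_cut=p_cut, c_grid=c_grid, n_splits=n_splits,
                               seed=int(rng.integers(2**31)))
        return auroc(model.decision_values(data.x, data.feature_names), y)

    if observed_auroc is None:
        observed_auroc = train_auroc(data.y)
    null = np.empty(n_perm)
    for k in range(n_perm):
        null[k] = train_auroc(rng.permutation(data.y))
    p = (1 + int(np.sum(null >= observed_auroc))) / (1 + n_perm)
    return p, null, float(observed_auroc)


def ptb_score(abundances: dict) -> float:
    """The published 4-taxon PTB predictive score.

    ``0.775*L(Samn) + 0.751*L(BVAB1) + 0.116*L(TM7) + 0.011*L(Pcl2)`` where
    L is the soft-threshold log10 transform; each input is a proportion in
    [0, 1].  The score ranges over [0, 4.959].  Inputs may use either
    canonical taxon names or the field abbreviations.
    """
    from .io import canonical_taxon

    canon = {canonical_taxon(k): v for k, v in abundances.items()}
    total = 0.0
    for taxon, coef in PTB_SCORE_COEFFICIENTS.items():
        if taxon not in canon:
            raise KeyError(f"missing abundance for taxon {taxon}")
        total += coef * soft_threshold_log(canon[taxon])
    return total


def microbiome_training_set(table, outcomes: pd.Series, taxa=None) -> TrainingSet:
    """Soft-threshold-log features from an abundance table.

    ``outcomes`` maps sample_id -> "PTB"/"TB"; rows follow the table order.
    """
    frame = table if isinstance(table, pd.DataFrame) else table.to_frame()
    if taxa is not None:
        frame = frame[list(taxa)]
    x = soft_threshold_log(frame.to_numpy(dtype=float))
    y = np.where(outcomes.reindex(frame.index).to_numpy() == "PTB", 1, -1)
    return TrainingSet(x=x, y=y, feature_names=list(frame.columns))


def clinical_training_set(records: pd.DataFrame) -> tuple[TrainingSet, list[str]]:
    """Build the 11-variable clinical feature matrix (one row per subject).

    YES/NO flags map to 1/0; gravidity-minus-parity is derived; continuous
    variables are left on their native scale here — min-max normalization is
    learned *inside* each training fold by :func:`clinical_model` (see
    :class:`MinMaxWithinFold`).  Returns the TrainingSet plus subject ids.
    """
    frame = records.drop_duplicates("subject_id").reset_index(drop=True)
    feats = pd.DataFrame(index=frame.index)
    for var in CLINICAL_VARIABLES:
        if var == "gravidity_minus_parity":
            feats[var] = frame["gravidity"] - frame["parity"]
        else:
            feats[var] = frame[var]
    y = np.where(frame["outcome"] == "PTB", 1, -1)
    data = TrainingSet(x=feats.to_numpy(dtype=float), y=y,
                       feature_names=list(CLINICAL_VARIABLES))
    return data, list(frame["subject_id"])


def minmax_normalize(train_x: np.ndarray, apply_x: np.ndarray) -> np.ndarray:
    """Min-max normalization with parameters learned on the training rows.

    Constant columns (max equals min) map to 0 with a warning.
    """
    lo = train_x.min(axis=0)
    hi = train_x.max(axis=0)
    span = hi - lo
    const = span == 0
    if const.any():
        logger.warning("min-max normalization: %d constant feature(s) set to 0",
                       int(const.sum()))
    span = np.where(const, 1.0, span)
    out = (apply_x - lo) / span
    out[:, const] = 0.0
    return np.clip(out, 0.0, 1.0)


def clinical_model(
    records: pd.DataFrame,
    p_cut: float = 0.05,
    c_grid=DEFAULT_C_GRID,
    n_splits: int = 5,
    seed: int = 0,
) -> tuple[PtbModel, EvaluationResult]:
    """Two-step pipeline on the 11 clinical variables, with LOO evaluation.

    Min-max normalization parameters are learned inside each LOO fold (and
    on the full set for the final reported model), never from held-out rows.
    """
    data, subject_ids = clinical_training_set(records)
    X, y = data.x, data.y

    scores = np.empty(X.shape[0])
    for i in range(X.shape[0]):
        mask = np.ones(X.shape[0], dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            raise ValueError("a LOO fold has only one class")
        Xtr = minmax_normalize(X[mask], X[mask])
        Xte = minmax_normalize(X[mask], X[i:i + 1])
        train = TrainingSet(x=Xtr, y=y[mask], feature_names=data.feature_names)
        model = two_step_train(train, p_cut=p_cut, c_grid=c_grid,
                               n_splits=n_splits, seed=seed)
        scores[i] = model.decision_values(Xte, data.feature_names)[0]
    sens, spec, auc = _metrics(scores, y)
    evaluation = EvaluationResult(
        loo_scores=pd.Series(scores, index=subject_ids),
        sensitivity=sens, specificity=spec, auroc=auc,
    )

    Xn = minmax_normalize(X, X)
    final = two_step_train(TrainingSet(x=Xn, y=y, feature_names=data.feature_names),
                           p_cut=p_cut, c_grid=c_grid, n_splits=n_splits, seed=seed)
    return final, evaluation
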