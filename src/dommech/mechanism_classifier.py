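"""Polynomial-kernel SVM trio: split, resampling, Bayesian tuning, final fit.

Each binary task (DN vs LOF, GOF vs LOF, LOF vs non-LOF) gets a stratified
75/25 train/test split, 3x repeated 10-fold cross-validation on the training
portion, and Gaussian-process expected-improvement search over the SVM
hyperparameters (cost, degree, scale factor, margin), maximising mean
cross-resample AUROC.  Probability outputs come from Platt scaling fitted
within the training data.

The "margin" parameter is accepted, logged and carried in the artefact, but
has no effect on a classification SVM (it parametrises the epsilon-insensitive
band of the regression formulation); it participates in the search space for
protocol fidelity.

An alternative Monte-Carlo resampling mode (75/25 analysis/assessment splits
instead of k-fold partitions) is available via ``mode="mc"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import (
    RepeatedStratifiedKFold,
    StratifiedShuffleSplit,
    train_test_split,
)
from sklearn.svm import SVC

from . import preprocessing
from .feature_engineering import select_top_embeddings
from .preprocessing import BinaryTaskDataset, NormaliseImputeState

logger = logging.getLogger(__name__)

SPLIT_PROP = 0.75
CV_REPEATS = 3
CV_FOLDS = 10
INIT_GRID = 10
MAX_ITER = 20
PATIENCE = 10

#: search bounds: log10(cost), degree, log10(scale factor), margin
BOUNDS = {
    "log_cost": (-3.0, 2.0),
    "degree": (1, 5),
    "log_scale": (-3.0, 0.0),
    "margin": (0.0, 0.2),
}


@dataclass(frozen=True)
class SvmHyperparams:
    cost: float
    degree: int
    scale_factor: float
    margin: float = 0.0

    def __post_init__(self):
        if not (self.cost > 0 and self.scale_factor > 0):
            raise ValueError("cost and scale factor must be positive")
        if not (1 <= self.degree <= 5):
            raise ValueError("degree must be an integer in [1, 5]")


@dataclass
class TrainedMechanismModel:
    """A fitted binary mechanism classifier with its preprocessing state."""

    task: str
    svm: SVC
    params: SvmHyperparams
    state: NormaliseImputeState
    feature_names: list
    cv_auroc: list
    seed: int
    meta: dict = field(default_factory=dict)

    def predict_proba(self, rows: pd.DataFrame) -> pd.Series:
        """Probability of the primary outcome; applies the train-fitted
        normalisation/imputation, selects the model's features and permutes
        with rows."""
        transformed = preprocessing.apply_state(rows, self.state)
        x = transformed[self.feature_names].to_numpy()
        p = self.svm.predict_proba(x)[:, list(self.svm.classes_).index(1)]
        return pd.Series(p, index=rows.index, name=f"p_{self.task}")


def _make_svc(params: SvmHyperparams, seed: int) -> SVC:
    return SVC(
        kernel="poly",
        C=params.cost,
        degree=params.degree,
        gamma=params.scale_factor,
        coef0=1.0,
        random_state=seed,
    )


def _make_probability_svc(params: SvmHyperparams, seed: int) -> CalibratedClassifierCV:
    """Polynomial SVM with Platt-scaled probability outputs (sigmoid
    calibration fitted by internal cross-validation within the training data)."""
    return CalibratedClassifierCV(
        _make_svc(params, seed), method="sigmoid", cv=5, ensemble=False
    )


# ---------------------------------------------------------------------------
# Splitting and resampling
# ---------------------------------------------------------------------------

def split_data(
    dataset: BinaryTaskDataset, prop: float = SPLIT_PROP, seed: int = 0
) -> tuple:
    """Stratified train/test split of a task dataset (default 75/25)."""
    counts = dataset.outcomes.value_counts()
    if counts.min() < 4 or len(counts) < 2:
        raise ValueError(f"task {dataset.task}: each class needs >= 4 rows to split")
    idx_train, idx_test = train_test_split(
        dataset.outcomes.index,
        train_size=prop,
        stratify=dataset.outcomes,
        random_state=seed,
    )
    return list(idx_train), list(idx_test)


def make_resamples(
    outcomes: pd.Series,
    repeats: int = CV_REPEATS,
    folds: int = CV_FOLDS,
    seed: int = 0,
    mode: str = "kfold",
) -> list:
    """Stratified resamples of the training rows.

    ``mode="kfold"`` (default): ``repeats`` x ``folds`` repeated stratified
    k-fold; each resample is an (analysis, assessment) pair of positional
    indices and each repeat's assessment sets cover the rows exactly once.
    ``mode="mc"``: the same number of Monte-Carlo 75/25 splits.
    """
    y = outcomes.to_numpy()
    if mode == "kfold":
        splitter = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    elif mode == "mc":
        splitter = StratifiedShuffleSplit(
            n_splits=repeats * folds, train_size=0.75, random_state=seed
        )
    else:
        raise ValueError(f"unknown resampling mode {mode!r}")
    return [(a, b) for a, b in splitter.split(np.zeros(len(y)), y)]


# ---------------------------------------------------------------------------
# Objective: mean cross-resample AUROC
# ---------------------------------------------------------------------------

def _resample_auroc(X: np.ndarray, y: np.ndarray, resamples, params: SvmHyperparams,
                    seed: int) -> float:
    """Mean assessment-set AUROC of the SVM decision function across resamples.

    Uses the (monotone-equivalent) decision function rather than calibrated
    probabilities; AUROC is rank-based so calibration cannot change it.
    """
    scores = []
    for analysis, assessment in resamples:
        ya = y[analysis]
        if len(np.unique(ya)) < 2 or len(np.unique(y[assessment])) < 2:
            continue
        svc = _make_svc(params, seed)
        svc.fit(X[analysis], ya)
        s = svc.decision_function(X[assessment])
        scores.append(roc_auc_score(y[assessment], s))
    if not scores:
        raise ValueError("no valid resample had both classes")
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# Gaussian-process Bayesian tuning
# ---------------------------------------------------------------------------

def _sample_config(rng: np.random.Generator) -> np.ndarray:
    lo_c, hi_c = BOUNDS["log_cost"]
    lo_d, hi_d = BOUNDS["degree"]
    lo_s, hi_s = BOUNDS["log_scale"]
    lo_m, hi_m = BOUNDS["margin"]
    return np.array([
        rng.uniform(lo_c, hi_c),
        rng.integers(lo_d, hi_d + 1),
        rng.uniform(lo_s, hi_s),
        rng.uniform(lo_m, hi_m),
    ])


def _to_params(vec: np.ndarray) -> SvmHyperparams:
    return SvmHyperparams(
        cost=float(10.0 ** vec[0]),
        degree=int(round(vec[1])),
        scale_factor=float(10.0 ** vec[2]),
        margin=float(vec[3]),
    )


def _expected_improvement(mu, sigma, best, xi=0.01):
    from scipy.stats import norm

    sigma = np.maximum(sigma, 1e-12)
    imp = mu - best - xi
    z = imp / sigma
    return imp * norm.cdf(z) + sigma * norm.pdf(z)


def tune_bayes(
    X: np.ndarray,
    y: np.ndarray,
    resamples,
    init_grid: int = INIT_GRID,
    max_iter: int = MAX_ITER,
    patience: int = PATIENCE,
    seed: int = 0,
) -> tuple:
    """Gaussian-process expected-improvement search over SVM hyperparameters.

    Starts from a random grid of ``init_grid`` configurations, then performs
    up to ``max_iter`` iterations proposing the candidate maximising expected
    improvement of mean cross-resample AUROC, stopping early after
    ``patience`` iterations without improvement.  Deterministic under
    ``seed``.  Returns ``(best_params, trace)`` where trace is a DataFrame of
    every evaluated configuration.
    """
    rng = np.random.default_rng(seed)
    evaluated, objectives = [], []

    def evaluate(vec):
        params = _to_params(vec)
        auroc = _resample_auroc(X, y, resamples, params, seed)
        evaluated.append(vec)
        objectives.append(auroc)
        return auroc

    for _ in range(init_grid):
        evaluate(_sample_config(rng))

    lows = np.array([BOUNDS["log_cost"][0], BOUNDS["degree"][0],
                     BOUNDS["log_scale"][0], BOUNDS["margin"][0]], dtype=float)
    highs = np.array([BOUNDS["log_cost"][1], BOUNDS["degree"][1],
                      BOUNDS["log_scale"][1], BOUNDS["margin"][1]], dtype=float)

    stall = 0
    for _ in range(max_iter):
        best = max(objectives)
        Xe = (np.array(evaluated) - lows) / (highs - lows)
        gp = GaussianProcessRegressor(
            kernel=ConstantKernel(1.0) * Matern(nu=2.5) + WhiteKernel(1e-4),
            normalize_y=True,
            random_state=int(rng.integers(2**31)),
        )
        gp.fit(Xe, np.array(objectives))
        candidates = np.array([_sample_config(rng) for _ in range(500)])
        cn = (candidates - lows) / (highs - lows)
        mu, sigma = gp.predict(cn, return_std=True)
        ei = _expected_improvement(mu, sigma, best)
        new = evaluate(candidates[int(np.argmax(ei))])
        if new > best + 1e-9:
            stall = 0
        else:
            stall += 1
            if stall >= patience:
                logger.info("tune_bayes: early stop after %d stalled iterations", stall)
                break

    objectives = np.array(objectives)
    if np.allclose(objectives, 0.5, atol=1e-9):
        logger.warning("tune_bayes: degenerate objective (all AUROC = 0.5); "
                       "returning best-so-far")
    best_idx = int(np.argmax(objectives))
    trace = pd.DataFrame(
        np.array(evaluated), columns=["log_cost", "degree", "log_scale", "margin"]
    )
    trace["auroc"] = objectives
    best_params = _to_params(evaluated[best_idx])
    logger.info("tune_bayes: best %s (mean CV AUROC %.3f over %d evals)",
                best_params, objectives[best_idx], len(objectives))
    return best_params, trace


# ---------------------------------------------------------------------------
# Final fit
# ---------------------------------------------------------------------------

def fit_final(
    X: pd.DataFrame, y: pd.Series, params: SvmHyperparams, *,
    task: str, state: NormaliseImputeState, cv_auroc=None, seed: int = 0,
) -> TrainedMechanismModel:
    """Fit the final probability SVM on (already transformed) training rows."""
    svc = _make_probability_svc(params, seed)
    svc.fit(X.to_numpy(), y.to_numpy())
    return TrainedMechanismModel(
        task=task, svm=svc, params=params, state=state,
        feature_names=list(X.columns),
        cv_auroc=list(cv_auroc) if cv_auroc is not None else [],
        seed=seed,
    )


def train_task(
    dataset: BinaryTaskDataset,
    *,
    n_embeddings: int = 20,
    embedding_cols=None,
    seed: int = 0,
    tune: bool = True,
    params: SvmHyperparams | None = None,
    init_grid: int = INIT_GRID,
    max_iter: int = MAX_ITER,
    resample_mode: str = "kfold",
    folds: int = CV_FOLDS,
    repeats: int = CV_REPEATS,
) -> dict:
    """End-to-end training for one task: split, embedding selection,
    normalise/impute (train-fitted), tune (optional), final fit, test scores.

    Embedding selection and preprocessing are fitted on the training split
    only.  Returns a dict with the model, train/test indices, test
    probabilities and AUROC summaries.
    """
    from .thresholds_and_ranking import auroc

    idx_train, idx_test = split_data(dataset, seed=seed)
    y_train = dataset.outcomes.loc[idx_train]
    y_test = dataset.outcomes.loc[idx_test]

    feat_cols = list(dataset.X.columns)
    if embedding_cols:
        emb_present = [c for c in feat_cols if c in set(embedding_cols)]
        interp = [c for c in feat_cols if c not in set(embedding_cols)]
        if emb_present:
            from .data_io import GeneFeatureTable

            gft = GeneFeatureTable(dataset.X, emb_present)
            ranking = select_top_embeddings(gft, y_train, k=n_embeddings)
            feat_cols = interp + ranking.selected

    train_t, test_t, state = preprocessing.normalise_impute(
        dataset.X.loc[idx_train, feat_cols], dataset.X.loc[idx_test, feat_cols]
    )

    Xtr, ytr = train_t.to_numpy(), y_train.to_numpy()
    resamples = make_resamples(y_train, repeats=repeats, folds=folds,
                               seed=seed, mode=resample_mode)
    if tune and params is None:
        params, trace = tune_bayes(Xtr, ytr, resamples, seed=seed,
                                   init_grid=init_grid, max_iter=max_iter)
    else:
        params = params or SvmHyperparams(cost=1.0, degree=3, scale_factor=0.1)
        trace = None

    cv_scores = [
        _fold_auroc(Xtr, ytr, a, b, params, seed) for a, b in resamples
    ]
    cv_scores = [s for s in cv_scores if s is not None]
    model = fit_final(train_t, y_train, params, task=dataset.task,
                      state=state, cv_auroc=cv_scores, seed=seed)
    p_test = model.predict_proba(dataset.X.loc[idx_test])
    return {
        "model": model,
        "train_index": idx_train,
        "test_index": idx_test,
        "test_probabilities": p_test,
        "test_outcomes": y_test,
        "cv_auroc": float(np.mean(cv_scores)) if cv_scores else float("nan"),
        "test_auroc": auroc(p_test.to_numpy(), y_test.to_numpy()),
        "tuning_trace": trace,
    }


def _fold_auroc(X, y, analysis, assessment, params, seed):
    if len(np.unique(y[analysis])) < 2 or len(np.unique(y[assessment])) < 2:
        return None
    svc = _make_svc(params, seed)
    svc.fit(X[analysis], y[analysis])
    return roc_auc_score(y[assessment], svc.decision_function(X[assessment]))


def train_trio(datasets: dict, *, seed: int = 0, **kwargs) -> dict:
    """Train all three binary tasks; returns {task: train_task result}."""
    return {task: train_task(ds, seed=seed, **kwargs) for task, ds in datasets.items()}
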