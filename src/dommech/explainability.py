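"""Model explanation: global permutation importance and local Shapley values.

Global importance of a feature is the loss in AUROC when its column is
shuffled (default 10 permutations).  Local attributions use the sampling
Shapley estimator over random feature orderings (default 20 permutations),
marginalising absent features over a background sample of training rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .thresholds_and_ranking import auroc

logger = logging.getLogger(__name__)

N_PERM_IMPORTANCE = 10
N_PERM_SHAPLEY = 20
BACKGROUND_CAP = 200


@dataclass
class ImportanceReport:
    """Per-feature AUROC-loss vectors (one value per permutation)."""

    losses: pd.DataFrame  # columns = features, one row per permutation
    baseline_auroc: float
    split: str  # which rows the report was computed on ("train"/"test"/...)

    @property
    def median(self) -> pd.Series:
        return self.losses.median().sort_values(ascending=False)


@dataclass
class ShapleyReport:
    """Sampling-based Shapley attribution for one instance.

    Additivity holds by construction: the values sum to prediction - baseline,
    where the baseline is the mean model output over the sampled background
    rows.
    """

    protein: str
    values: pd.Series  # feature -> mean marginal contribution
    baseline: float
    prediction: float
    per_permutation: pd.DataFrame


def permutation_importance(
    predict_fn,
    X: pd.DataFrame,
    y: pd.Series,
    n_perm: int = N_PERM_IMPORTANCE,
    seed: int = 0,
    split: str = "train",
) -> ImportanceReport:
    """AUROC loss upon shuffling each feature column, ``n_perm`` times.

    ``predict_fn`` maps a DataFrame of rows to scores for the primary
    outcome.  Loss = AUROC(intact) - AUROC(shuffled); positive means the
    model relies on the feature.
    """
    if y.nunique() < 2:
        raise ValueError("need both outcome classes")
    rng = np.random.default_rng(seed)
    base = auroc(np.asarray(predict_fn(X)), y.to_numpy())
    losses = {}
    for col in X.columns:
        vals = []
        for _ in range(n_perm):
            Xp = X.copy()
            Xp[col] = rng.permutation(Xp[col].to_numpy())
            vals.append(base - auroc(np.asarray(predict_fn(Xp)), y.to_numpy()))
        losses[col] = vals
    return ImportanceReport(losses=pd.DataFrame(losses), baseline_auroc=base, split=split)


def shapley_local(
    predict_fn,
    instance: pd.Series,
    background: pd.DataFrame,
    n_perm: int = N_PERM_SHAPLEY,
    seed: int = 0,
    protein: str = "",
    background_cap: int = BACKGROUND_CAP,
) -> ShapleyReport:
    """Sampling Shapley values for one instance over ``n_perm`` orderings.

    For each random permutation of the features, one background row is drawn
    and features are switched from the background value to the instance value
    in permutation order; a feature's marginal contribution is the change in
    model output when it switches.  Averaged over permutations this converges
    to the Shapley value under the background distribution.
    """
    if len(background) == 0:
        raise ValueError("background sample is empty")
    rng = np.random.default_rng(seed)
    if len(background) > background_cap:
        keep = rng.choice(len(background), size=background_cap, replace=False)
        background = background.iloc[keep]
    features = list(instance.index)
    x = instance.to_numpy(dtype=float)
    bg = background[features].to_numpy(dtype=float)

    contribs = np.zeros((n_perm, len(features)))
    baselines = np.zeros(n_perm)
    for p in range(n_perm):
        order = rng.permutation(len(features))
        b = bg[rng.integers(len(bg))]
        # walk from all-background to all-instance, evaluating in one batch
        states = np.tile(b, (len(features) + 1, 1))
        current = b.copy()
        for step, j in enumerate(order, start=1):
            current[j] = x[j]
            states[step] = current
        outs = np.asarray(predict_fn(pd.DataFrame(states, columns=features)))
        baselines[p] = outs[0]
        for step, j in enumerate(order, start=1):
            contribs[p, j] = outs[step] - outs[step - 1]

    values = pd.Series(contribs.mean(axis=0), index=features)
    prediction = float(np.asarray(predict_fn(pd.DataFrame([x], columns=features)))[0])
    return ShapleyReport(
        protein=protein,
        values=values,
        baseline=float(baselines.mean()),
        prediction=prediction,
        per_permutation=pd.DataFrame(contribs, columns=features),
    )
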