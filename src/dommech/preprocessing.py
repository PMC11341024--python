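"""From labels + features to the three binary task datasets.

Pipeline order: class-priority task labelling -> Spearman correlation filter
-> homology deduplication -> train/test split (classifier module) ->
z-normalisation and k-NN imputation fitted on training rows only.

Class priority: in each binary task the primary class wins — a gene carrying
the primary class is a primary case even if it also carries other mechanism
classes.  Homology deduplication enforces <50% pairwise sequence identity
within each outcome group (not across groups, since contrasting homologues
assigned to different classes is informative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.impute import KNNImputer

from .data_io import MechanismLabelSet, validate_identity_matrix

logger = logging.getLogger(__name__)

IDENTITY_CUTOFF = 0.5
SPEARMAN_THRESHOLD = 0.9
KNN_K = 5

#: task name -> (primary class, secondary class spec)
TASKS = {
    "DN_vs_LOF": ("DN", ("LOF",)),
    "GOF_vs_LOF": ("GOF", ("LOF",)),
    "LOF_vs_nonLOF": ("LOF", ("DN", "GOF")),
}


@dataclass
class NormaliseImputeState:
    """Fitted preprocessing state: retained columns, train means/sds, imputer."""

    columns: list
    means: pd.Series
    sds: pd.Series
    imputer: KNNImputer
    k: int


@dataclass
class BinaryTaskDataset:
    """One binary classification task after labelling, filtering and dedup.

    ``outcomes`` is a Series over protein ids with values 1 (primary class)
    and 0 (secondary); ``X`` holds the feature matrix aligned to it.
    ``state`` is filled once normalisation/imputation has been fitted.
    """

    task: str
    X: pd.DataFrame
    outcomes: pd.Series
    retained_features: list
    state: NormaliseImputeState | None = None
    meta: dict = field(default_factory=dict)

    @property
    def class_balance(self) -> float:
        return float(self.outcomes.mean())


# ---------------------------------------------------------------------------
# Task labelling
# ---------------------------------------------------------------------------

def build_binary_task(labels: dict, task: str) -> pd.Series:
    """Assign binary outcomes for one task from pooled mechanism labels.

    Primary (1): genes carrying the primary class, regardless of other
    annotations.  Secondary (0): genes carrying a secondary class and not the
    primary.  Genes with neither are excluded.  For LOF_vs_nonLOF the
    secondary pool is (DN or GOF) minus LOF-labelled genes.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {sorted(TASKS)}")
    primary, secondary = TASKS[task]
    out = {}
    for gene, ls in labels.items():
        if not isinstance(ls, MechanismLabelSet):
            raise TypeError(f"{gene}: expected MechanismLabelSet")
        if primary in ls.classes:
            out[gene] = 1
        elif any(s in ls.classes for s in secondary):
            out[gene] = 0
    s = pd.Series(out, dtype=int).sort_index()
    if len(s) == 0 or s.nunique() < 2:
        raise ValueError(f"task {task}: an outcome class is empty after labelling")
    return s


# ---------------------------------------------------------------------------
# Correlation filter
# ---------------------------------------------------------------------------

def correlation_filter(
    features: pd.DataFrame, threshold: float = SPEARMAN_THRESHOLD
) -> list:
    """Greedy removal of redundant features by absolute Spearman correlation.

    While any pair exceeds |rho| > threshold, drop the member of the worst
    offending pair with the larger mean absolute correlation to all remaining
    features; ties go to the later column.  Interpretable features and
    embedding dimensions are treated alike.
    """
    cols = list(features.columns)
    if len(cols) < 2:
        return cols
    with np.errstate(invalid="ignore"):
        rho = spearmanr(features.to_numpy(dtype=float), nan_policy="omit")[0]
    rho = np.atleast_2d(np.abs(np.asarray(rho, dtype=float)))
    np.fill_diagonal(rho, 0.0)
    rho = np.nan_to_num(rho, nan=0.0)

    alive = list(range(len(cols)))
    while True:
        sub = rho[np.ix_(alive, alive)]
        mx = sub.max()
        if mx <= threshold:
            break
        i_loc, j_loc = np.unravel_index(np.argmax(sub), sub.shape)
        mean_i = sub[i_loc].sum() / (len(alive) - 1)
        mean_j = sub[j_loc].sum() / (len(alive) - 1)
        if mean_i > mean_j:
            drop_loc = i_loc
        elif mean_j > mean_i:
            drop_loc = j_loc
        else:  # tie: later column order
            drop_loc = max(i_loc, j_loc)
        dropped = alive.pop(drop_loc)
        logger.info("correlation filter: dropped %s (|rho|=%.3f)", cols[dropped], mx)
    return [cols[i] for i in alive]


# ---------------------------------------------------------------------------
# Normalisation + imputation
# ---------------------------------------------------------------------------

def normalise_impute(
    train: pd.DataFrame, apply: pd.DataFrame | None = None, k: int = KNN_K
) -> tuple:
    """Z-score normalise then k-NN impute, fitting on training rows only.

    Distances use mutually observed normalised features (nan-aware Euclidean);
    a missing entry becomes the mean of its k nearest training rows.  A row
    with no observed features falls back to training column means (all
    distances degenerate).  Zero-variance training features are dropped with a
    warning.  Returns ``(train_t, apply_t, state)``; ``apply_t`` is None when
    no apply rows were given.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(train) < k + 1:
        raise ValueError(f"need at least k+1={k + 1} training rows")
    sds = train.std(ddof=0)
    keep = sds[sds > 0].index.tolist()
    dropped = [c for c in train.columns if c not in keep]
    if dropped:
        logger.warning("normalise_impute: dropped zero-variance features %s", dropped)
    train = train[keep]
    means = train.mean()
    sds = train.std(ddof=0)

    z_train = (train - means) / sds
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    t = pd.DataFrame(imputer.fit_transform(z_train), index=train.index, columns=keep)
    state = NormaliseImputeState(columns=keep, means=means, sds=sds, imputer=imputer, k=k)
    a = apply_state(apply, state) if apply is not None else None
    return t, a, state


def apply_state(rows: pd.DataFrame, state: NormaliseImputeState) -> pd.DataFrame:
    """Transform new rows with train-fitted normalisation/imputation state."""
    missing = set(state.columns) - set(rows.columns)
    if missing:
        raise ValueError(f"rows missing features {sorted(missing)[:5]}")
    z = (rows[state.columns] - state.means) / state.sds
    out = state.imputer.transform(z)
    return pd.DataFrame(out, index=rows.index, columns=state.columns)


# ---------------------------------------------------------------------------
# Homology deduplication
# ---------------------------------------------------------------------------

def homology_dedup(
    matrix: pd.DataFrame,
    outcomes: pd.Series,
    labels: dict | None = None,
    cutoff: float = IDENTITY_CUTOFF,
) -> list:
    """Greedy within-outcome redundancy removal at a sequence-identity cutoff.

    Offending pairs (same outcome, identity >= cutoff) are resolved in order
    of descending identity.  Within a pair the removed member is, in order of
    preference: the one whose mechanism label set overlaps another class
    (signal-to-noise: keep the unambiguous gene); the one involved in more
    remaining conflicts; finally the lexicographically later id.  Cross-
    outcome pairs are never touched.  Returns retained protein ids in input
    order.
    """
    validate_identity_matrix(matrix)
    proteins = list(outcomes.index)
    absent = [p for p in proteins if p not in matrix.index]
    if absent:
        raise ValueError(f"identity matrix does not cover {absent[:5]}")

    def multiclass(p):
        if labels is None or p not in labels:
            return False
        return len(labels[p].classes) > 1

    # offending same-outcome pairs
    pairs = []
    for grp in (0, 1):
        members = [p for p in proteins if outcomes[p] == grp]
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                ident = float(matrix.at[a, b])
                if ident >= cutoff:
                    pairs.append((ident, a, b))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))

    removed = set()

    def n_conflicts(p):
        return sum(1 for ident, a, b in pairs
                   if p in (a, b) and a not in removed and b not in removed)

    for ident, a, b in pairs:
        if a in removed or b in removed:
            continue
        ma, mb = multiclass(a), multiclass(b)
        if ma != mb:
            victim = a if ma else b
        else:
            ca, cb = n_conflicts(a), n_conflicts(b)
            if ca != cb:
                victim = a if ca > cb else b
            else:
                victim = max(a, b)
        removed.add(victim)
        logger.debug("dedup: removed %s (pair with %s at %.0f%% identity)",
                     victim, a if victim == b else b, 100 * ident)
    return [p for p in proteins if p not in removed]


# ---------------------------------------------------------------------------
# Full task assembly
# ---------------------------------------------------------------------------

def assemble_task(
    labels: dict,
    features: pd.DataFrame,
    identity: pd.DataFrame,
    task: str,
    *,
    spearman_threshold: float = SPEARMAN_THRESHOLD,
    identity_cutoff: float = IDENTITY_CUTOFF,
) -> BinaryTaskDataset:
    """Label -> correlation-filter -> dedup for one task (split and
    normalisation happen at training time).

    ``features`` is indexed by protein id; genes without a feature row are
    dropped with a warning.
    """
    outcomes = build_binary_task(labels, task)
    have = [g for g in outcomes.index if g in features.index]
    lost = len(outcomes) - len(have)
    if lost:
        logger.warning("task %s: %d labelled gene(s) lack feature rows", task, lost)
    outcomes = outcomes.loc[have]

    retained = correlation_filter(features.loc[have], threshold=spearman_threshold)
    kept_ids = homology_dedup(identity, outcomes, labels, cutoff=identity_cutoff)
    outcomes = outcomes.loc[kept_ids]
    X = features.loc[kept_ids, retained]
    balance = float(outcomes.mean())
    logger.info("task %s: %d proteins, %.0f%% primary", task, len(outcomes), 100 * balance)
    return BinaryTaskDataset(
        task=task, X=X, outcomes=outcomes, retained_features=retained,
        meta={"class_balance": balance},
    )
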