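"""End-to-end orchestration: labels + features -> trio -> proteome table.

Glue over the task modules, used by the CLI and by reproduction scripts.
"""

from __future__ import annotations

import logging

import pandas as pd

from . import preprocessing, thresholds_and_ranking
from .data_io import GeneFeatureTable
from .mechanism_classifier import train_task

logger = logging.getLogger(__name__)

#: binary task -> probability column of its primary class
TASK_PROB = {"DN_vs_LOF": "pDN", "GOF_vs_LOF": "pGOF", "LOF_vs_nonLOF": "pLOF"}


def run_trio(
    labels: dict,
    features: GeneFeatureTable,
    identity: pd.DataFrame,
    *,
    seed: int = 0,
    tune: bool = True,
    n_embeddings: int = 20,
    **train_kwargs,
) -> dict:
    """Assemble, train and evaluate all three binary tasks.

    Returns {task: train_task result} with the assembled dataset attached
    under "dataset".
    """
    results = {}
    for task in TASK_PROB:
        ds = preprocessing.assemble_task(labels, features.table, identity, task)
        res = train_task(
            ds, embedding_cols=features.embedding_cols,
            n_embeddings=n_embeddings, seed=seed, tune=tune, **train_kwargs,
        )
        res["dataset"] = ds
        results[task] = res
    return results


def trio_t50s(results: dict) -> dict:
    """Derive per-model t50 thresholds from the held-out test sets."""
    t50s = {}
    for task, res in results.items():
        table = thresholds_and_ranking.threshold_table(
            res["test_probabilities"].to_numpy(), res["test_outcomes"].to_numpy()
        )
        cls = TASK_PROB[task][1:]  # pDN -> DN
        t50s[cls] = thresholds_and_ranking.derive_t50(table)
    return t50s


def proteome_predictions(
    results: dict, features: GeneFeatureTable, t50s: dict
) -> pd.DataFrame:
    """Score every protein with the three models and rank-classify.

    Proteins with any missing model feature are imputed through each model's
    train-fitted state, so the whole feature table gets scored.
    """
    trio = pd.DataFrame(index=features.table.index)
    for task, res in results.items():
        model = res["model"]
        trio[TASK_PROB[task]] = model.predict_proba(features.table)
    return thresholds_and_ranking.rank_classify(trio, t50s, use_cutoff=True)


def training_label_series(labels: dict) -> pd.Series:
    """Slash-joined class annotation per labelled gene (e.g. "DN/LOF")."""
    return pd.Series(
        {g: "/".join(sorted(ls.classes)) for g, ls in labels.items()}
    ).sort_index()
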