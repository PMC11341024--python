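"""Threshold-agnostic metrics, threshold tables, t50, and proteome ranking.

AUROC/AUPRC come with percentile-bootstrap confidence intervals (1,000
resamples, 90% by default).  Threshold tables report sensitivity,
specificity, accuracy, MCC, F1, NPV and PPV at every 0.01 step of class
probability; t50 is the largest grid threshold at which sensitivity still
reaches 50%.  Proteome-scale assignment is rank-based: each protein goes to
the mechanism whose class probability has the highest fractional rank across
the proteome, provided (when the cutoff is active) that the winning raw
probability exceeds its model's t50.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score, roc_auc_score

logger = logging.getLogger(__name__)

N_BOOT = 1000
CI_LEVEL = 0.90
THRESHOLD_GRID = np.round(np.arange(0, 101) / 100.0, 2)

#: tie-break priority for equal rank fractions (highest first)
CLASS_PRIORITY = ("DN", "GOF", "LOF")

UNCLASSIFIED = "unclassified"


def auroc(scores, labels) -> float:
    """Rank-statistic AUROC with tie correction (pair-ordering probability)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def auprc(scores, labels) -> float:
    """Area under the precision-recall curve (step interpolation)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUPRC needs both classes present")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def auroc_auprc_ci(
    scores, labels, n_boot: int = N_BOOT, level: float = CI_LEVEL, seed: int = 0
) -> dict:
    """Point estimates plus percentile-bootstrap CIs over row resamples.

    Bootstrap resamples that lose one class are redrawn implicitly by being
    skipped; ``n_boot`` successful resamples are accumulated.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    point_roc = auroc(scores, labels)
    point_prc = auprc(scores, labels)
    rng = np.random.default_rng(seed)
    n = len(scores)
    rocs, prcs = [], []
    attempts = 0
    while len(rocs) < n_boot and attempts < 20 * n_boot:
        attempts += 1
        idx = rng.integers(0, n, n)
        yb = labels[idx]
        if len(np.unique(yb)) < 2:
            continue
        rocs.append(roc_auc_score(yb, scores[idx]))
        prcs.append(average_precision_score(yb, scores[idx]))
    alpha = (1.0 - level) / 2.0
    qs = [100 * alpha, 100 * (1 - alpha)]
    return {
        "auroc": point_roc,
        "auroc_ci": tuple(np.percentile(rocs, qs)),
        "auprc": point_prc,
        "auprc_ci": tuple(np.percentile(prcs, qs)),
        "n_boot": len(rocs),
        "level": level,
    }


# ---------------------------------------------------------------------------
# Threshold tables and t50
# ---------------------------------------------------------------------------

def threshold_table(scores, labels) -> pd.DataFrame:
    """Confusion-matrix metrics at every 0.01 probability threshold.

    A prediction is positive iff score >= threshold.  MCC is 0 when its
    denominator vanishes; F1 = 2TP / (2TP + FP + FN); NPV/PPV are NaN when
    undefined (no predicted negatives/positives).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    rows = []
    for theta in THRESHOLD_GRID:
        pred = scores >= theta
        tp = int(np.sum(pred & y))
        fp = int(np.sum(pred & ~y))
        fn = n_pos - tp
        tn = n_neg - fp
        sens = tp / n_pos if n_pos else np.nan
        spec = tn / n_neg if n_neg else np.nan
        acc = (tp + tn) / (n_pos + n_neg)
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom > 0 else 0.0
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
        ppv = tp / (tp + fp) if (tp + fp) > 0 else np.nan
        npv = tn / (tn + fn) if (tn + fn) > 0 else np.nan
        rows.append({
            "threshold": theta, "sensitivity": sens, "specificity": spec,
            "accuracy": acc, "mcc": mcc, "f1": f1, "npv": npv, "ppv": ppv,
            "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        })
    return pd.DataFrame(rows)


def derive_t50(table: pd.DataFrame) -> float:
    """Largest grid threshold at which sensitivity is still >= 50%.

    At this threshold the observed sensitivity is the smallest value at or
    above 0.5 that the score vector can realise on the grid.
    """
    ok = table[table["sensitivity"] >= 0.5]
    if ok.empty:
        raise ValueError("sensitivity never reaches 50%")
    return float(ok["threshold"].max())


# ---------------------------------------------------------------------------
# Proteome rank-based assignment
# ---------------------------------------------------------------------------

@dataclass
class TrioPredictions:
    """Per-protein trio probabilities, proteome rank fractions and the
    rank-based mechanism assignment with/without the t50 cutoff."""

    table: pd.DataFrame  # protein-indexed
    t50s: dict

    def to_frame(self) -> pd.DataFrame:
        df = self.table.reset_index().rename(columns={"index": "protein"})
        if "protein" not in df.columns:
            df = df.rename(columns={df.columns[0]: "protein"})
        return df


_PROB_COLS = {"DN": "pDN", "GOF": "pGOF", "LOF": "pLOF"}


def rank_classify(
    trio: pd.DataFrame,
    t50s: dict,
    use_cutoff: bool = True,
) -> pd.DataFrame:
    """Assign each protein to the mechanism with the highest proteome rank.

    ``trio`` is protein-indexed with columns pDN, pGOF, pLOF.  Per model, the
    fractional rank of every probability is computed across all scored
    proteins (ties get their average rank); the winner is the class with the
    highest rank fraction, ties broken DN > GOF > LOF.  With the cutoff
    active, a winner is assigned only when its raw probability is strictly
    above its model's t50, otherwise the protein is unclassified.  Proteins
    with a missing probability are unclassified with a warning.
    Rank-based by design, the assignment (without cutoff) is invariant under
    any strictly increasing transform of one model's probabilities.
    """
    missing_cols = [c for c in _PROB_COLS.values() if c not in trio.columns]
    if missing_cols:
        raise ValueError(f"trio table missing {missing_cols}")
    n = len(trio)
    probs = trio[list(_PROB_COLS.values())].to_numpy(dtype=float)
    incomplete = np.isnan(probs).any(axis=1)
    if incomplete.any():
        logger.warning("%d protein(s) with missing probabilities left unclassified",
                       int(incomplete.sum()))

    rank_frac = np.full_like(probs, np.nan)
    for j in range(probs.shape[1]):
        col = probs[:, j]
        ok = ~np.isnan(col)
        rank_frac[ok, j] = rankdata(col[ok]) / ok.sum()

    classes = list(_PROB_COLS)  # DN, GOF, LOF — also the tie-break priority
    out = pd.DataFrame(index=trio.index)
    for cls, col in _PROB_COLS.items():
        out[col] = trio[col]
        out[f"rank_{cls}"] = rank_frac[:, classes.index(cls)]

    winners, with_cut, without_cut = [], [], []
    thresholds = np.array([t50s[c] for c in classes], dtype=float)
    for i in range(n):
        if incomplete[i]:
            winners.append(UNCLASSIFIED)
            with_cut.append(UNCLASSIFIED)
            without_cut.append(UNCLASSIFIED)
            continue
        rf = rank_frac[i]
        best = rf.max()
        # first index at the max follows DN > GOF > LOF priority
        w = int(np.flatnonzero(rf == best)[0])
        winner = classes[w]
        winners.append(winner)
        without_cut.append(winner)
        with_cut.append(winner if probs[i, w] > thresholds[w] else UNCLASSIFIED)
    out["winner"] = winners
    out["rank_class_no_cutoff"] = without_cut
    out["rank_class"] = with_cut if use_cutoff else without_cut
    return out


def build_prediction_table(
    assignments: pd.DataFrame, training_labels: pd.Series | None = None
) -> pd.DataFrame:
    """Assemble the proteome prediction table in the release column layout."""
    df = assignments.copy()
    df["training_label"] = ""
    if training_labels is not None:
        common = df.index.intersection(training_labels.index)
        df.loc[common, "training_label"] = training_labels.loc[common]
    df = df.reset_index().rename(columns={df.index.name or "index": "protein"})
    return df[["protein", "pDN", "pGOF", "pLOF",
               "rank_class", "rank_class_no_cutoff", "training_label"]]
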