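"""Model-independent validation metrics.

Covers: spatial clustering of pathogenic missense variants in predicted
structures (EDC, with low-confidence residues excluded), class-wise
comparison of mutation stability effects (ddG, one-sided rank-sum with
Holm-Bonferroni correction), per-protein variant-effect-predictor AUROC
aggregation, and a generic Fisher overrepresentation test with FDR, sample
size and fold-enrichment filters plus redundancy collapse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import fisher_exact, mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .data_io import StructureRecord, VariantScoreTable

logger = logging.getLogger(__name__)

PLDDT_MIN = 70.0
MIN_PATHOGENIC = 5
FDR_MAX = 0.01
MIN_SAMPLE = 50
MIN_FOLD = 1.5
JACCARD_COLLAPSE = 0.5


@dataclass
class EdcResult:
    protein: str
    edc: float
    n_variants_used: int
    n_residues_used: int


@dataclass
class EnrichmentRow:
    term: str
    sample_size: int  # foreground proteins carrying the term
    expected: float
    fold: float
    p: float
    fdr: float


# ---------------------------------------------------------------------------
# Extent of disease clustering
# ---------------------------------------------------------------------------

def edc(
    structure: StructureRecord,
    pathogenic_positions,
    plddt_min: float = PLDDT_MIN,
    min_variants: int = MIN_PATHOGENIC,
) -> EdcResult | None:
    """Extent of disease clustering of pathogenic variants on a structure.

    Residues with pLDDT below ``plddt_min`` are excluded (AlphaFold models
    with high disorder would otherwise show pseudo-clustering); variants
    falling on excluded residues are dropped.  If fewer than ``min_variants``
    variant positions survive, returns None.  Otherwise

        EDC = ln( mean over non-variant residues of the distance to the
                  nearest variant C-alpha
                  / mean over variant residues of the distance to the nearest
                  other variant C-alpha )

    so larger values mean stronger spatial clustering.  The metric only uses
    pairwise distances, hence is invariant under rigid-body motion.
    """
    positions = np.unique(np.asarray(list(pathogenic_positions), dtype=int))
    known = set(structure.positions.tolist())
    outside = [int(p) for p in positions if p not in known]
    if outside:
        raise ValueError(f"{structure.protein}: variant positions not in structure: {outside[:5]}")

    ok = structure.plddt >= plddt_min
    if not ok.any():
        return None
    coords = structure.coords[ok]
    kept_pos = structure.positions[ok]
    is_var = np.isin(kept_pos, positions)
    n_var = int(is_var.sum())
    if n_var < min_variants:
        return None
    var_xyz = coords[is_var]
    non_xyz = coords[~is_var]
    if len(non_xyz) == 0 or n_var < 2:
        return None

    d_non = cdist(non_xyz, var_xyz).min(axis=1)
    dvv = cdist(var_xyz, var_xyz)
    np.fill_diagonal(dvv, np.inf)
    d_var = dvv.min(axis=1)
    value = float(np.log(d_non.mean() / d_var.mean()))
    return EdcResult(
        protein=structure.protein, edc=value,
        n_variants_used=n_var, n_residues_used=int(ok.sum()),
    )


# ---------------------------------------------------------------------------
# ddG class comparison
# ---------------------------------------------------------------------------

def ddg_class_compare(ddg_by_class: dict) -> pd.DataFrame:
    """One-sided rank-sum tests of mutation ddG: DN < LOF and GOF < LOF,
    Holm-Bonferroni corrected over the two tests.

    Callers must pre-exclude variants at residues with pLDDT < 70, where the
    stability change is not interpretable.  Location-shift invariance: adding
    a constant to every group leaves the p-values unchanged.
    """
    for cls in ("DN", "GOF", "LOF"):
        if cls not in ddg_by_class or len(ddg_by_class[cls]) == 0:
            raise ValueError(f"class {cls} empty or absent")
    lof = np.asarray(ddg_by_class["LOF"], dtype=float)
    raw = {}
    for cls in ("DN", "GOF"):
        vals = np.asarray(ddg_by_class[cls], dtype=float)
        raw[cls] = mannwhitneyu(vals, lof, alternative="less").pvalue
    corrected = multipletests(list(raw.values()), method="holm")[1]
    return pd.DataFrame({
        "comparison": [f"{c} < LOF" for c in raw],
        "p_raw": list(raw.values()),
        "p_holm": corrected,
        "n": [len(ddg_by_class[c]) for c in raw],
        "n_lof": len(lof),
    })


# ---------------------------------------------------------------------------
# Per-protein VEP AUROC
# ---------------------------------------------------------------------------

def per_protein_vep_auroc(
    variants: VariantScoreTable,
    min_pathogenic: int = 5,
    min_benign: int = 5,
) -> pd.DataFrame:
    """Per-protein, per-scorer AUROC of pathogenic vs benign variants.

    Only variants scored by every scorer are used ("mutually shared"), and
    only proteins with at least ``min_pathogenic`` pathogenic and
    ``min_benign`` benign such variants are reported.
    """
    from sklearn.metrics import roc_auc_score

    if not variants.scorers:
        raise ValueError("need at least one scorer")
    df = variants.df
    df = df[df["label"].isin(["pathogenic", "benign"])]
    shared = df.dropna(subset=variants.scorers)
    rows = []
    for protein, grp in shared.groupby("protein", sort=True):
        y = (grp["label"] == "pathogenic").to_numpy()
        if y.sum() < min_pathogenic or (~y).sum() < min_benign:
            continue
        row = {"protein": protein, "n_pathogenic": int(y.sum()), "n_benign": int((~y).sum())}
        for scorer in variants.scorers:
            row[scorer] = float(roc_auc_score(y, grp[scorer].to_numpy(dtype=float)))
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_vep_auroc(per_protein: pd.DataFrame, classes: pd.Series, scorers) -> pd.DataFrame:
    """Attach predicted mechanism classes and melt to long form for
    class-wise AUROC distribution comparison."""
    df = per_protein.merge(
        classes.rename("mechanism"), left_on="protein", right_index=True, how="inner"
    )
    return df.melt(
        id_vars=["protein", "mechanism"], value_vars=list(scorers),
        var_name="scorer", value_name="auroc",
    )


# ---------------------------------------------------------------------------
# Fisher overrepresentation
# ---------------------------------------------------------------------------

def overrepresentation(
    foreground: set,
    background: set,
    annotation: dict,
    fdr_max: float = FDR_MAX,
    min_sample: int = MIN_SAMPLE,
    min_fold: float = MIN_FOLD,
    jaccard_collapse: float = JACCARD_COLLAPSE,
) -> list:
    """One-sided Fisher overrepresentation of annotation terms in a
    foreground protein set against a background.

    Per term the 2x2 table is (in/out foreground) x (in/out term), tested for
    enrichment; Benjamini-Hochberg FDR across all tested terms.  Reported
    rows must pass FDR < ``fdr_max``, sample size (foreground proteins with
    the term) > ``min_sample`` and fold enrichment > ``min_fold``.  Groups of
    similar surviving terms (Jaccard similarity of foreground membership
    above ``jaccard_collapse``) are collapsed to the single term with the
    largest sample size.
    """
    foreground = set(foreground)
    background = set(background)
    if not foreground <= background:
        raise ValueError("foreground must be a subset of background")
    n_fg, n_bg = len(foreground), len(background)
    tested, pvals = [], []
    fg_members = {}
    for term, proteins in annotation.items():
        members = set(proteins) & background
        if not members:
            logger.debug("term %s has no background members; skipped", term)
            continue
        k = len(members & foreground)
        table = [
            [k, len(members) - k],
            [n_fg - k, (n_bg - len(members)) - (n_fg - k)],
        ]
        p = fisher_exact(table, alternative="greater")[1]
        expected = n_fg * len(members) / n_bg
        fold = k / expected if expected > 0 else np.inf
        tested.append((term, k, expected, fold))
        pvals.append(p)
        fg_members[term] = members & foreground
    if not tested:
        return []
    fdr = multipletests(pvals, method="fdr_bh")[1]
    surviving = [
        EnrichmentRow(term=t, sample_size=k, expected=e, fold=f, p=p, fdr=q)
        for (t, k, e, f), p, q in zip(tested, pvals, fdr)
        if q < fdr_max and k > min_sample and f > min_fold
    ]
    return _collapse_similar(surviving, fg_members, jaccard_collapse)


def _collapse_similar(rows, fg_members, threshold):
    """Keep the largest-sample term of each group of overlapping terms."""
    rows = sorted(rows, key=lambda r: (-r.sample_size, r.term))
    kept = []
    for row in rows:
        a = fg_members[row.term]
        redundant = False
        for other in kept:
            b = fg_members[other.term]
            union = len(a | b)
            if union and len(a & b) / union > threshold:
                redundant = True
                break
        if not redundant:
            kept.append(row)
    return kept
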