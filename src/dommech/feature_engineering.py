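"""Surrogate feature computation.

Features engineered here replace structural/functional annotations that are
incomplete for the proteome: relative solvent accessibility (RSA) against
theoretical Gly-X-Gly maxima, a surface-interaction summary (median predicted
protein-binding propensity over surface residues), a pair of mutational
ESM/ddG ratio features, and effect-size-ranked selection of protein-language-
model embedding dimensions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, tiecorrect

from .data_io import GeneFeatureTable, StructureRecord, VariantScoreTable

logger = logging.getLogger(__name__)

# Defaults (configurable per call)
RSA_THRESHOLD = 0.05  # surface residue: RSA > 5%
N_EMBEDDINGS = 20     # embedding dims kept per binary task
DDG_EPSILON = 0.01    # kcal/mol; |ddG| clamp before division

#: Theoretical maximum solvent-accessible surface area (A^2) of residue X in
#: a Gly-X-Gly tripeptide (Tien et al. 2013, "theoretical" column).
MAX_ASA_GXG = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}


@dataclass
class EffectSizeRanking:
    """Embedding dimensions ranked by Wilcoxon effect size r (descending)."""

    effect_sizes: pd.Series  # feature name -> r, all candidate dims
    selected: list           # top-k feature names

    @property
    def ranks(self) -> pd.Series:
        order = np.lexsort((np.arange(len(self.effect_sizes)), -self.effect_sizes.to_numpy()))
        r = pd.Series(index=self.effect_sizes.index[order], data=np.arange(1, len(order) + 1))
        return r.reindex(self.effect_sizes.index)


def compute_rsa(asa: float, aa: str, table: dict = MAX_ASA_GXG) -> float:
    """Relative solvent accessibility: ASA / max-ASA(Gly-X-Gly).

    Values above 1 are preserved (not clamped).  Nonstandard residues yield
    NaN with a log message.
    """
    if asa < 0:
        raise ValueError(f"negative ASA {asa}")
    if aa not in table:
        logger.info("nonstandard residue %r: RSA set to missing", aa)
        return float("nan")
    return asa / table[aa]


def structure_rsa(structure: StructureRecord, table: dict = MAX_ASA_GXG) -> np.ndarray:
    """Per-residue RSA over a structure; requires attached ASA."""
    if structure.asa is None:
        raise ValueError(f"{structure.protein}: no ASA attached")
    maxes = np.array([table.get(a, np.nan) for a in structure.aa])
    return structure.asa / maxes


def surface_interaction_summary(
    structure: StructureRecord, rsa_threshold: float = RSA_THRESHOLD
) -> float:
    """Median SCRIBER score over surface residues (RSA > ``rsa_threshold``).

    Returns NaN when no residue qualifies.  A structure without ASA is an
    error; residues without a SCRIBER score are ignored.
    """
    rsa = structure_rsa(structure)
    if structure.scriber is None:
        raise ValueError(f"{structure.protein}: no SCRIBER scores attached")
    mask = (rsa > rsa_threshold) & ~np.isnan(structure.scriber)
    if not mask.any():
        return float("nan")
    return float(np.median(structure.scriber[mask]))


def _clamp(x: np.ndarray, eps: float) -> np.ndarray:
    """Clamp |x| below eps to eps, preserving sign (sign(0) treated as +)."""
    sign = np.where(x < 0, -1.0, 1.0)
    return sign * np.maximum(np.abs(x), eps)


def mutational_ratio_features(
    variants: VariantScoreTable | pd.DataFrame,
    esm_col: str = "ESM-1v",
    eps: float = DDG_EPSILON,
) -> tuple:
    """Median ESM-1v/ddG ratio over all missense substitutions of one protein.

    Returns ``(median_ratio_raw, median_ratio_abs)`` where the first uses the
    signed ddG and the second its absolute value.  Denominators with
    |ddG| < ``eps`` kcal/mol are clamped to eps with sign preserved, keeping
    the ratios bounded near-zero stability changes.  An empty variant set
    yields (NaN, NaN).
    """
    df = variants.df if isinstance(variants, VariantScoreTable) else variants
    if len(df) == 0:
        return (float("nan"), float("nan"))
    esm = df[esm_col].to_numpy(dtype=float)
    ddg = df["ddg"].to_numpy(dtype=float)
    raw = esm / _clamp(ddg, eps)
    absd = esm / np.maximum(np.abs(ddg), eps)
    return (float(np.median(raw)), float(np.median(absd)))


def wilcoxon_effect_size(x, y) -> float:
    """Rank-sum (Mann-Whitney) effect size r = |Z| / sqrt(n1 + n2).

    Z is the tie-corrected normal approximation of the rank-sum statistic
    without continuity correction.  When every value is tied across both
    groups the statistic is degenerate and r is 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    tie = tiecorrect(ranks)
    if tie == 0:  # all values identical
        return 0.0
    sigma = np.sqrt(tie * n1 * n2 * (n1 + n2 + 1) / 12.0)
    if sigma == 0:
        return 0.0
    z = (u - mu) / sigma
    return float(abs(z) / np.sqrt(n1 + n2))


def select_top_embeddings(
    table: GeneFeatureTable,
    labels: pd.Series,
    k: int = N_EMBEDDINGS,
) -> EffectSizeRanking:
    """Rank embedding dimensions by Wilcoxon effect size against a binary
    outcome and keep the top ``k``.

    ``labels`` is a boolean/0-1 Series indexed by protein covering the
    training rows only; the selection must be refit inside each resample to
    avoid information leakage.  Ties in r are broken by ascending dimension
    (column) index.
    """
    emb = table.table.loc[labels.index, table.embedding_cols]
    y = labels.astype(bool).to_numpy()
    if y.all() or (~y).all():
        raise ValueError("labels must contain both outcomes")
    rs = {}
    for col in table.embedding_cols:
        v = emb[col].to_numpy(dtype=float)
        ok = ~np.isnan(v)
        pos, neg = v[ok & y], v[ok & ~y]
        rs[col] = wilcoxon_effect_size(pos, neg) if len(pos) and len(neg) else 0.0
    r = pd.Series(rs)
    if k > len(r):
        logger.warning("k=%d > %d embedding dims; returning all", k, len(r))
        k = len(r)
    # stable sort on -r keeps original (ascending dimension) order among ties
    order = np.argsort(-r.to_numpy(), kind="stable")
    selected = list(r.index[order[:k]])
    return EffectSizeRanking(effect_sizes=r, selected=selected)
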