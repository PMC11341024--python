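"""Seeded generators for every input class the framework consumes.

The generators emulate the statistical structure the pipeline assumes — a
curated mechanism label collection with the observed unique/double/triple
class mixture, class-conditional gene-level features with configurable effect
sizes, a block-structured sequence-identity matrix with homolog families,
jittered self-avoiding-walk backbones with low-confidence segments, and
variant tables in which non-LOF proteins carry spatially clustered, mildly
destabilising pathogenic variants while LOF proteins carry scattered, more
destabilising ones that are easier for variant effect predictors to call.

Everything is bit-reproducible under a fixed seed; each generator draws from
its own stream derived from (seed, stage tag) so outputs do not depend on
call order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import (
    GeneFeatureTable,
    MechanismLabelSet,
    StructureRecord,
    VariantScoreTable,
)
from .feature_engineering import MAX_ASA_GXG

_CLASSES = ("DN", "GOF", "LOF")
_PAIRS = (("DN", "GOF"), ("DN", "LOF"), ("GOF", "LOF"))

# stage tags for independent random streams
_TAG_LABELS, _TAG_FEATURES, _TAG_IDENTITY, _TAG_STRUCT = 1, 2, 3, 4

#: interpretable feature names; the first block mirrors the constraint and
#: surrogate metrics used by the classifiers.
INTERPRETABLE_FEATURES = [
    "s_het", "pLI", "pRec", "oe_lof", "n_paralogues", "cotranslational_assembly",
    "surface_interaction", "esm_ddg_ratio_raw", "esm_ddg_ratio_abs",
]


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic cohort.

    Defaults emulate the curated collection: 1,270 genes of which 874 carry a
    unique mechanism class, 318 two classes and 78 all three; 21 interpretable
    features of which a handful separate the classes with moderate effect;
    1,024 embedding dimensions with a small informative subset; homolog
    families straddling the 50% identity cutoff; structures of 100-300
    residues with a low-pLDDT segment.
    """

    seed: int
    n_genes: int = 1270
    mixture: tuple = (874, 318, 78)  # unique / double / triple class counts shape
    deterministic_mixture: bool = True
    n_interpretable: int = 21
    effect_size: float = 0.8          # standardised mean shift of informative features
    n_informative: int = 6            # informative interpretable features
    #: class contrast each informative feature separates ("DN", "GOF", "LOF"
    #: or "nonLOF" = DN-or-GOF genes); None = realistic defaults where the
    #: constraint-like metrics load on the LOF / non-LOF contrast
    informative_axes: tuple | None = None
    oe_lof_coupling: bool = True      # generate oe_lof as a near-duplicate of s_het
    n_embedding_dims: int = 1024
    n_informative_embeddings: int = 5
    embedding_effect: float = 0.5
    missing_rate: float = 0.05
    n_families: int = 40
    family_size: int = 3
    family_identity: float = 0.6
    background_identity: tuple = (0.05, 0.35)
    length_range: tuple = (100, 300)
    disorder_fraction: float = 0.2
    n_pathogenic: int = 10
    n_benign: int = 10
    ddg_offset: float = 1.0           # how much milder non-LOF pathogenic ddG is
    scorers: tuple = ("ESM-1v", "EVE", "MetaRNN", "VARITY_R")
    gene_prefix: str = "G"

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not (0 <= self.missing_rate <= 1 and 0 <= self.disorder_fraction <= 1):
            raise ValueError("rates must be in [0, 1]")

    def rng(self, tag: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), tag])

    def gene_ids(self):
        width = len(str(self.n_genes))
        return [f"{self.gene_prefix}{i + 1:0{width}d}" for i in range(self.n_genes)]


# ---------------------------------------------------------------------------
# Labels
# ---------------------------------------------------------------------------

def gen_labels(spec: SyntheticSpec) -> dict:
    """Draw per-gene mechanism class sets with the configured
    unique/double/triple mixture."""
    rng = spec.rng(_TAG_LABELS)
    props = np.asarray(spec.mixture, dtype=float)
    props = props / props.sum()
    if spec.deterministic_mixture:
        counts = np.floor(props * spec.n_genes).astype(int)
        # largest-remainder rounding to hit n_genes exactly
        rem = props * spec.n_genes - counts
        for i in np.argsort(-rem)[: spec.n_genes - counts.sum()]:
            counts[i] += 1
    else:
        counts = rng.multinomial(spec.n_genes, props)
    multiplicity = np.repeat([1, 2, 3], counts)
    rng.shuffle(multiplicity)

    genes = spec.gene_ids()
    out = {}
    for gene, m in zip(genes, multiplicity):
        if m == 1:
            classes = ( _CLASSES[rng.integers(3)], )
        elif m == 2:
            classes = _PAIRS[rng.integers(3)]
        else:
            classes = _CLASSES
        evidence = tuple(
            (f"{rng.integers(10**7, 10**8)}", f"synthetic evidence for {cls} in {gene}")
            for cls in classes
        )
        out[gene] = MechanismLabelSet(gene, frozenset(classes), evidence)
    return out


def class_multiplicity_counts(labels: dict) -> tuple:
    """(n_genes, n_unique, n_double, n_triple) of a label collection."""
    sizes = np.array([len(ls.classes) for ls in labels.values()])
    return (len(sizes), int((sizes == 1).sum()), int((sizes == 2).sum()),
            int((sizes == 3).sum()))


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------

def _feature_names(spec: SyntheticSpec):
    names = list(INTERPRETABLE_FEATURES[: spec.n_interpretable])
    while len(names) < spec.n_interpretable:
        names.append(f"feat_{len(names) + 1:02d}")
    return names


#: realistic default contrasts for the first informative features: mutational
#: constraint loads on the LOF axis, "recessive-likeness" and paralogy on the
#: non-LOF axis.
_DEFAULT_AXES = ("LOF", "LOF", "nonLOF", "nonLOF", "LOF", "nonLOF")


def informative_features(spec: SyntheticSpec) -> list:
    """Names of the interpretable features carrying a class effect."""
    names = _feature_names(spec)
    return [nm for nm in names if nm != "oe_lof"][: spec.n_informative]


def gen_features(spec: SyntheticSpec, labels: dict) -> GeneFeatureTable:
    """Class-conditional Gaussian features plus embeddings.

    Each informative interpretable feature separates one class contrast
    (``informative_axes``): genes on that axis get a mean shift of
    ``effect_size`` standard deviations.  Informative embedding dims cycle
    the DN/GOF/LOF axes with ``embedding_effect``.  ``oe_lof`` is generated
    as a strongly anticorrelated transform of ``s_het`` so the redundancy
    filter has a realistic target (switchable via ``oe_lof_coupling``).
    Missingness is MCAR over interpretable features only (embedding stores
    are complete in practice).
    """
    rng = spec.rng(_TAG_FEATURES)
    genes = list(labels)
    n = len(genes)
    names = _feature_names(spec)

    member = {cls: np.array([cls in labels[g].classes for g in genes]) for cls in _CLASSES}
    member["nonLOF"] = member["DN"] | member["GOF"]

    axes = spec.informative_axes
    if axes is None:
        axes = _DEFAULT_AXES + tuple(
            _CLASSES[i % 3] for i in range(max(0, spec.n_informative - len(_DEFAULT_AXES)))
        )

    X = rng.normal(size=(n, spec.n_interpretable))
    informative = informative_features(spec)
    for j, nm in enumerate(informative):
        axis = axes[j % len(axes)]
        X[member[axis], names.index(nm)] += spec.effect_size
    if spec.oe_lof_coupling and "oe_lof" in names and "s_het" in names:
        i_oe, i_sh = names.index("oe_lof"), names.index("s_het")
        X[:, i_oe] = -0.97 * X[:, i_sh] + 0.15 * rng.normal(size=n)
    if "cotranslational_assembly" in names:
        i_ca = names.index("cotranslational_assembly")
        X[:, i_ca] = (X[:, i_ca] > 0.5).astype(float)  # indicator-like

    emb = rng.normal(size=(n, spec.n_embedding_dims))
    for j in range(min(spec.n_informative_embeddings, spec.n_embedding_dims)):
        axis = _CLASSES[j % 3]
        emb[member[axis], j] += spec.embedding_effect

    if spec.missing_rate > 0:
        mask = rng.random(size=X.shape) < spec.missing_rate
        X = np.where(mask, np.nan, X)

    emb_cols = [f"emb_{i + 1:04d}" for i in range(spec.n_embedding_dims)]
    table = pd.DataFrame(
        np.hstack([X, emb]), index=pd.Index(genes, name="protein"),
        columns=names + emb_cols,
    )
    return GeneFeatureTable(table, emb_cols)


# ---------------------------------------------------------------------------
# Identity matrix
# ---------------------------------------------------------------------------

def gen_identity_matrix(spec: SyntheticSpec, labels: dict) -> pd.DataFrame:
    """Block-structured pairwise identity: homolog families at or above the
    configured within-family identity on a low-identity background."""
    rng = spec.rng(_TAG_IDENTITY)
    genes = list(labels)
    n = len(genes)
    lo, hi = spec.background_identity
    a = rng.uniform(lo, hi, size=(n, n))
    a = (a + a.T) / 2.0

    order = rng.permutation(n)
    fam_members = []
    pos = 0
    for _ in range(spec.n_families):
        if pos + spec.family_size > n:
            break
        fam = order[pos: pos + spec.family_size]
        fam_members.append(fam)
        pos += spec.family_size
        for i in fam:
            for j in fam:
                if i != j:
                    ident = min(spec.family_identity + rng.uniform(0, 0.1), 0.98)
                    a[i, j] = a[j, i] = ident
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=pd.Index(genes, name="protein"), columns=genes)


# ---------------------------------------------------------------------------
# Structures and variants
# ---------------------------------------------------------------------------

_AA = np.array(list(MAX_ASA_GXG))


def _backbone(rng: np.random.Generator, length: int, spacing: float = 3.8,
              min_clash: float = 3.0) -> np.ndarray:
    """Jittered self-avoiding walk with ~3.8 A C-alpha spacing."""
    coords = np.zeros((length, 3))
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    for i in range(1, length):
        for _ in range(30):
            step = direction + 0.8 * rng.normal(size=3)
            step = spacing * step / np.linalg.norm(step)
            candidate = coords[i - 1] + step
            if i < 2 or np.min(np.linalg.norm(coords[: i - 1] - candidate, axis=1)) > min_clash:
                break
        coords[i] = candidate
        direction = step / np.linalg.norm(step)
    return coords


def gen_structure(spec: SyntheticSpec, rng: np.random.Generator, protein: str) -> StructureRecord:
    length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
    coords = _backbone(rng, length)
    aa = _AA[rng.integers(0, len(_AA), size=length)]
    plddt = rng.uniform(80, 98, size=length)
    n_dis = int(round(spec.disorder_fraction * length))
    if n_dis > 0:
        start = int(rng.integers(0, length - n_dis + 1))
        plddt[start: start + n_dis] = rng.uniform(35, 65, size=n_dis)
    maxes = np.array([MAX_ASA_GXG[a] for a in aa])
    asa = rng.uniform(0, 1, size=length) * maxes
    rsa = asa / maxes
    scriber = np.clip(rng.beta(2, 5, size=length) + 0.3 * (rsa > 0.25), 0, 1)
    return StructureRecord(
        protein=protein, positions=np.arange(1, length + 1), aa=aa,
        coords=coords, plddt=plddt, asa=asa, scriber=scriber,
    )


def _variant_positions(rng, structure: StructureRecord, n: int, clustered: bool):
    """Pick n distinct positions among confidently folded residues; clustered
    picks the 3-D neighbourhood of a random centre, scattered picks uniformly."""
    ok = np.flatnonzero(structure.plddt >= 70)
    if len(ok) == 0:
        ok = np.arange(len(structure))
    n = min(n, len(ok))
    if clustered:
        centre = rng.choice(ok)
        d = np.linalg.norm(structure.coords[ok] - structure.coords[centre], axis=1)
        chosen = ok[np.argsort(d)[:n]]
    else:
        chosen = rng.choice(ok, size=n, replace=False)
    return structure.positions[chosen]


def gen_structures_variants(
    spec: SyntheticSpec, labels: dict, proteins=None
) -> tuple:
    """Generate per-protein structures and a pooled variant score table.

    Non-LOF proteins (label set containing DN or GOF) receive spatially
    clustered pathogenic variants with milder ddG and weaker VEP separation;
    LOF-only proteins receive scattered, more destabilising and more
    predictable pathogenic variants.  Returns ``({protein: StructureRecord},
    VariantScoreTable)``.
    """
    rng = spec.rng(_TAG_STRUCT)
    if proteins is None:
        proteins = list(labels)
    structures, rows = {}, []
    for protein in proteins:
        structures[protein] = st = gen_structure(spec, rng, protein)
        classes = labels[protein].classes if protein in labels else frozenset({"LOF"})
        non_lof = bool(classes & {"DN", "GOF"})
        quality = 0.6 if non_lof else 1.6  # VEP separation strength
        path_pos = _variant_positions(rng, st, spec.n_pathogenic, clustered=non_lof)
        benign_pos = _variant_positions(rng, st, spec.n_benign, clustered=False)

        used = set()
        for label, positions in (("pathogenic", path_pos), ("benign", benign_pos)):
            for pos in positions:
                idx = int(np.flatnonzero(st.positions == pos)[0])
                wt = st.aa[idx]
                mut = str(rng.choice(_AA[_AA != wt]))
                if (pos, mut) in used:
                    continue
                used.add((pos, mut))
                is_path = label == "pathogenic"
                if is_path:
                    ddg = rng.normal(2.5 - (spec.ddg_offset if non_lof else 0.0), 1.0)
                    esm = rng.normal(-4.5 - 2.5 * quality, 1.5)
                else:
                    ddg = rng.normal(0.3, 0.5)
                    esm = rng.normal(-2.0, 1.5)
                row = {
                    "protein": protein, "position": int(pos), "wt": wt, "mut": mut,
                    "label": label, "ddg": float(ddg), "ESM-1v": float(esm),
                }
                signal = quality * (1.0 if is_path else -1.0)
                for scorer in spec.scorers:
                    if scorer == "ESM-1v":
                        continue
                    z = rng.normal(signal, 1.0)
                    row[scorer] = float(1.0 / (1.0 + np.exp(-z)))
                rows.append(row)
    table = VariantScoreTable(pd.DataFrame(rows), list(spec.scorers))
    return structures, table


# ---------------------------------------------------------------------------
# Whole-cohort convenience
# ---------------------------------------------------------------------------

def gen_all(spec: SyntheticSpec, with_structures: bool = True) -> dict:
    """Generate the complete input bundle for an end-to-end run."""
    labels = gen_labels(spec)
    out = {
        "spec": spec,
        "labels": labels,
        "features": gen_features(spec, labels),
        "identity": gen_identity_matrix(spec, labels),
        "gene_map": pd.DataFrame({"gene": list(labels), "protein": list(labels)}),
    }
    if with_structures:
        out["structures"], out["variants"] = gen_structures_variants(spec, labels)
    return out


def write_dataset(spec: SyntheticSpec, outdir, with_structures: bool = True) -> dict:
    """Materialise a synthetic cohort to disk in the formats data_io reads."""
    from pathlib import Path

    from . import data_io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = gen_all(spec, with_structures=with_structures)
    data_io.write_mechanism_labels(bundle["labels"], outdir / "labels.csv")
    gft = bundle["features"]
    interp = gft.table[gft.interpretable_cols]
    data_io.write_feature_table(GeneFeatureTable(interp, []), outdir / "features.csv")
    data_io.write_embeddings_h5(gft.table[gft.embedding_cols], outdir / "embeddings.h5")
    data_io.write_identity_matrix(bundle["identity"], outdir / "identity.csv")
    bundle["gene_map"].to_csv(outdir / "gene_protein_map.csv", index=False)
    if with_structures:
        data_io.write_variant_table(bundle["variants"], outdir / "variants.csv")
    return bundle
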