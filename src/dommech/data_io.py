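"""Readers and writers for the tables and structures the framework consumes.

All tabular formats are plain CSV/TSV (XLSX supplementary exports are accepted
too, sniffed by extension); structures are PDB or mmCIF with AlphaFold's
convention of per-residue pLDDT stored in the B-factor column; per-protein
embedding vectors live in an HDF5 store keyed by accession.

Protein-level keys are accession strings throughout.  The gene-to-protein
mapping is always supplied as an explicit two-column table, never inferred.
Residues are numbered by 1-based sequence position, matching variant positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MECHANISM_CLASSES = ("DN", "GOF", "LOF")

#: Tokens accepted in label files, mapped to canonical class names.
_CLASS_TOKENS = {"dn": "DN", "gof": "GOF", "lof": "LOF"}

PREDICTION_COLUMNS = [
    "protein",
    "pDN",
    "pGOF",
    "pLOF",
    "rank_class",
    "rank_class_no_cutoff",
    "training_label",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MechanismLabelSet:
    """Evidence-backed molecular mechanism classes assigned to one gene.

    ``classes`` is the pooled, non-empty subset of {DN, GOF, LOF} supported by
    at least one evidence line; ``evidence`` keeps (pmid, statement) pairs for
    provenance.
    """

    gene: str
    classes: frozenset
    evidence: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if not self.classes:
            raise ValueError(f"gene {self.gene!r}: empty class set")
        unknown = set(self.classes) - set(MECHANISM_CLASSES)
        if unknown:
            raise ValueError(f"gene {self.gene!r}: unknown classes {unknown}")


@dataclass
class GeneFeatureTable:
    """Per-protein feature matrix: interpretable features plus embeddings.

    ``table`` is indexed by protein accession; embedding columns are named in
    ``embedding_cols`` and must all be present.  Missing values are NaN.
    """

    table: pd.DataFrame
    embedding_cols: list

    def __post_init__(self):
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].tolist()
            raise ValueError(f"duplicate protein ids: {dups[:5]}")
        if self.table.columns.has_duplicates:
            raise ValueError("feature names must be unique")
        missing = set(self.embedding_cols) - set(self.table.columns)
        if missing:
            raise ValueError(f"embedding columns absent from table: {sorted(missing)[:5]}")

    @property
    def interpretable_cols(self):
        emb = set(self.embedding_cols)
        return [c for c in self.table.columns if c not in emb]

    @property
    def n_embedding_dims(self):
        return len(self.embedding_cols)


@dataclass
class StructureRecord:
    """Per-residue view of a (predicted) protein structure.

    One entry per residue with a resolved C-alpha atom: 1-based sequence
    position, amino-acid one-letter code, C-alpha coordinate in Angstrom,
    pLDDT confidence (0-100, from the B-factor column for AlphaFold models),
    and optionally solvent-accessible surface area (A^2) and a per-residue
    protein-binding propensity (SCRIBER) score.
    """

    protein: str
    positions: np.ndarray  # int, strictly increasing, 1-based
    aa: np.ndarray  # one-letter codes
    coords: np.ndarray  # (n, 3) float, Angstrom
    plddt: np.ndarray  # float, 0-100
    asa: np.ndarray | None = None  # float, >= 0
    scriber: np.ndarray | None = None  # float, 0-1

    def __post_init__(self):
        n = len(self.positions)
        if n == 0:
            raise ValueError(f"{self.protein}: structure has no residues")
        if not np.all(np.diff(self.positions) > 0):
            raise ValueError(f"{self.protein}: residue positions not strictly increasing")
        if self.coords.shape != (n, 3):
            raise ValueError(f"{self.protein}: coords shape {self.coords.shape} != ({n}, 3)")
        if np.any((self.plddt < 0) | (self.plddt > 100)):
            raise ValueError(f"{self.protein}: pLDDT outside [0, 100]")
        if self.asa is not None and np.any(self.asa < 0):
            raise ValueError(f"{self.protein}: negative ASA")

    def __len__(self):
        return len(self.positions)


@dataclass
class VariantScoreTable:
    """Per-variant pathogenicity labels, VEP scores and FoldX ddG values.

    ``df`` columns: protein, position (1-based), wt, mut, label (pathogenic /
    benign / unlabelled), one column per scorer, and ``ddg`` (kcal/mol, FoldX
    sign convention: positive = destabilising).
    """

    df: pd.DataFrame
    scorers: list

    REQUIRED = ("protein", "position", "wt", "mut", "label")
    LABELS = ("pathogenic", "benign", "unlabelled")

    def __post_init__(self):
        missing = set(self.REQUIRED) - set(self.df.columns)
        if missing:
            raise ValueError(f"variant table missing columns {sorted(missing)}")
        bad = set(self.df["label"].unique()) - set(self.LABELS)
        if bad:
            raise ValueError(f"unknown variant labels {sorted(bad)}")
        key = self.df[["protein", "position", "wt", "mut"]]
        if key.duplicated().any():
            raise ValueError("duplicate (protein, position, wt, mut) rows")
        absent = [s for s in self.scorers if s not in self.df.columns]
        if absent:
            raise ValueError(f"scorer columns absent: {absent}")

    def for_protein(self, protein):
        return self.df[self.df["protein"] == protein]


def validate_identity_matrix(m: pd.DataFrame, atol: float = 1e-6) -> pd.DataFrame:
    """Check a pairwise sequence-identity matrix: square, symmetric,
    unit diagonal, values in [0, 1]."""
    if list(m.index) != list(m.columns):
        raise ValueError("identity matrix index and columns differ")
    a = m.to_numpy(dtype=float)
    if not np.allclose(a, a.T, atol=atol):
        raise ValueError("identity matrix not symmetric")
    if not np.allclose(np.diag(a), 1.0, atol=atol):
        raise ValueError("identity matrix diagonal != 1")
    if a.min() < -atol or a.max() > 1 + atol:
        raise ValueError("identity values outside [0, 1]")
    return m


# ---------------------------------------------------------------------------
# Tabular IO helpers
# ---------------------------------------------------------------------------

def _read_table(path) -> pd.DataFrame:
    """Read CSV/TSV/XLSX by extension."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".xlsx", ".xls"):
        return pd.read_excel(path)
    sep = "\t" if suffix in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep)


def read_mechanism_labels(path) -> dict:
    """Read a curated label table into {gene: MechanismLabelSet}.

    Expected columns: gene, class (dn/gof/lof), pmid, evidence_line.  Rows
    are pooled by gene; any unrecognised class token is a hard error naming
    the offending row.
    """
    df = _read_table(path)
    required = {"gene", "class", "pmid", "evidence_line"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"label table missing columns {sorted(missing)}")
    out: dict[str, dict] = {}
    cols = df[["gene", "class", "pmid", "evidence_line"]]
    for i, (gene, token, pmid, line) in enumerate(cols.itertuples(index=False, name=None)):
        token = str(token).strip().lower()
        if token not in _CLASS_TOKENS:
            raise ValueError(f"row {i}: unknown mechanism class {token!r} for gene {gene!r}")
        rec = out.setdefault(str(gene), {"classes": set(), "evidence": []})
        rec["classes"].add(_CLASS_TOKENS[token])
        rec["evidence"].append((str(pmid), str(line)))
    return {
        g: MechanismLabelSet(g, frozenset(r["classes"]), tuple(r["evidence"]))
        for g, r in out.items()
    }


def write_mechanism_labels(labels: dict, path) -> None:
    rows = []
    for gene in sorted(labels):
        ls = labels[gene]
        ev = list(ls.evidence)
        # one row per class; reuse evidence lines round-robin so every class
        # keeps at least one provenance entry
        for j, cls in enumerate(sorted(ls.classes)):
            pmid, line = ev[j % len(ev)] if ev else ("NA", "NA")
            rows.append({"gene": gene, "class": cls.lower(), "pmid": pmid, "evidence_line": line})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_feature_table(path, embedding_prefix: str = "emb_") -> GeneFeatureTable:
    """Read a per-protein feature table; columns starting with
    ``embedding_prefix`` are treated as embedding dimensions."""
    df = _read_table(path)
    if "protein" not in df.columns:
        raise ValueError("feature table needs a 'protein' column")
    df = df.set_index("protein")
    emb = [c for c in df.columns if c.startswith(embedding_prefix)]
    return GeneFeatureTable(df, emb)


def write_feature_table(table: GeneFeatureTable, path) -> None:
    table.table.rename_axis("protein").reset_index().to_csv(path, index=False)


def read_embeddings_h5(path) -> pd.DataFrame:
    """Read an HDF5 per-protein embedding store (one dataset per accession)
    into a DataFrame with columns emb_0001..emb_NNNN."""
    with h5py.File(path, "r") as f:
        keys = sorted(f.keys())
        if not keys:
            raise ValueError("embedding store is empty")
        vecs = {k: np.asarray(f[k], dtype=float) for k in keys}
    lengths = {v.shape for v in vecs.values()}
    if len(lengths) != 1:
        raise ValueError(f"inconsistent embedding lengths: {lengths}")
    dim = next(iter(lengths))[0]
    cols = [f"emb_{i + 1:04d}" for i in range(dim)]
    return pd.DataFrame.from_dict(vecs, orient="index", columns=cols).rename_axis("protein")


def write_embeddings_h5(embeddings: pd.DataFrame, path) -> None:
    with h5py.File(path, "w") as f:
        for protein, row in embeddings.iterrows():
            f.create_dataset(str(protein), data=row.to_numpy(dtype=np.float32))


def read_identity_matrix(path) -> pd.DataFrame:
    df = _read_table(path)
    df = df.set_index(df.columns[0])
    df.index.name = "protein"
    df.columns = df.columns.astype(str)
    df.index = df.index.astype(str)
    return validate_identity_matrix(df)


def write_identity_matrix(m: pd.DataFrame, path) -> None:
    validate_identity_matrix(m).rename_axis("protein").to_csv(path)


def read_variant_table(path, scorers=None) -> VariantScoreTable:
    df = _read_table(path)
    if scorers is None:
        reserved = set(VariantScoreTable.REQUIRED) | {"ddg"}
        scorers = [c for c in df.columns if c not in reserved]
    return VariantScoreTable(df, list(scorers))


def write_variant_table(table: VariantScoreTable, path) -> None:
    table.df.to_csv(path, index=False)


def read_gene_protein_map(path) -> pd.DataFrame:
    """Two-column gene <-> protein accession mapping."""
    df = _read_table(path)
    if not {"gene", "protein"} <= set(df.columns):
        raise ValueError("mapping needs 'gene' and 'protein' columns")
    return df[["gene", "protein"]]


# ---------------------------------------------------------------------------
# Predictions round-trip
# ---------------------------------------------------------------------------

def write_predictions(predictions: pd.DataFrame, path) -> None:
    """Write the proteome prediction table (class probabilities, rank-based
    assignment with and without the t50 cutoff, training label if any)."""
    missing = set(PREDICTION_COLUMNS) - set(predictions.columns)
    if missing:
        raise ValueError(f"prediction table missing columns {sorted(missing)}")
    if predictions["protein"].duplicated().any():
        raise ValueError("duplicate protein ids in prediction table")
    predictions[PREDICTION_COLUMNS].to_csv(path, index=False)


def read_predictions(path) -> pd.DataFrame:
    df = _read_table(path)
    missing = set(PREDICTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"prediction table missing columns {sorted(missing)}")
    if df["protein"].duplicated().any():
        raise ValueError("duplicate protein ids in prediction table")
    df["training_label"] = df["training_label"].fillna("").astype(str)
    return df


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

_AA_3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def read_structure(path, protein: str | None = None) -> StructureRecord:
    """Read a PDB or mmCIF structure into a per-residue record.

    The B-factor column is copied to pLDDT (AlphaFold convention).  Residues
    without a C-alpha atom are skipped with a warning; an atom-less file is an
    error.  mmCIF and PDB encodings of the same model yield identical records.
    """
    import biotite.structure.io.pdb as bpdb
    import biotite.structure.io.pdbx as bpdbx

    path = Path(path)
    if path.suffix.lower() in (".cif", ".mmcif", ".pdbx"):
        cif = bpdbx.CIFFile.read(str(path))
        atoms = bpdbx.get_structure(cif, model=1, extra_fields=["b_factor"])
    else:
        pdbf = bpdb.PDBFile.read(str(path))
        atoms = pdbf.get_structure(model=1, extra_fields=["b_factor"])
    if atoms.array_length() == 0:
        raise ValueError(f"{path}: no atoms in structure")

    ca = atoms[atoms.atom_name == "CA"]
    if ca.array_length() == 0:
        raise ValueError(f"{path}: no C-alpha atoms")
    res_ids = np.unique(atoms.res_id)
    ca_ids = set(ca.res_id.tolist())
    skipped = [int(r) for r in res_ids if r not in ca_ids]
    if skipped:
        logger.warning("%s: %d residue(s) without C-alpha skipped: %s",
                       path.name, len(skipped), skipped[:10])

    order = np.argsort(ca.res_id, kind="stable")
    ca = ca[order]
    # keep the first C-alpha per residue (altlocs are already filtered by biotite)
    _, first = np.unique(ca.res_id, return_index=True)
    ca = ca[first]
    aa = np.array([_AA_3TO1.get(str(r).upper(), "X") for r in ca.res_name])
    return StructureRecord(
        protein=protein or path.stem,
        positions=ca.res_id.astype(int),
        aa=aa,
        coords=ca.coord.astype(float),
        plddt=ca.b_factor.astype(float),
    )


def attach_residue_scores(structure: StructureRecord, scores: pd.DataFrame) -> StructureRecord:
    """Attach per-residue ASA (and optional SCRIBER) values to a structure.

    ``scores`` has columns position, asa [, scriber]; positions absent from
    the table get NaN.
    """
    if "position" not in scores.columns or "asa" not in scores.columns:
        raise ValueError("residue score table needs 'position' and 'asa' columns")
    by_pos = scores.set_index("position")
    asa = np.full(len(structure), np.nan)
    scriber = np.full(len(structure), np.nan)
    for i, pos in enumerate(structure.positions):
        if pos in by_pos.index:
            asa[i] = by_pos.at[pos, "asa"]
            if "scriber" in by_pos.columns:
                scriber[i] = by_pos.at[pos, "scriber"]
    structure.asa = asa
    structure.scriber = scriber if "scriber" in by_pos.columns else None
    return structure
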