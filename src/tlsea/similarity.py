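"""Circular fingerprints, Tanimoto similarity, and the three similarity
matrix flavours.

M is the full target-library (rows) x phenotype-actives (columns) Tanimoto
matrix; M_t is the row slice belonging to one protein's ligand set; M_r is a
random background matrix drawn from property-matched background compounds.
Fingerprints are extended-connectivity (Morgan) with circular-neighborhood
diameter 4 (radius 2), hashed to 2048 bits by default. Hashed-bit layouts
differ between toolkits, so similarity values are formula-faithful rather
than identical to any other platform's ECFP_4 output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .filtering import LigandSet, PropertyWindow, property_filter
from .io import CompoundRecord


@dataclass(frozen=True)
class Fingerprint:
    """Sparse on-bit representation of one molecule's circular fingerprint."""

    compound_id: str
    bits: frozenset[int]
    nbits: int
    diameter: int = 4

    def __post_init__(self):
        if any(b < 0 or b >= self.nbits for b in self.bits):
            raise ValueError("bit index out of range")


@dataclass
class SimilarityMatrix:
    """Dense similarity matrix with identifier-labelled rows and columns.

    Rows are target-library compounds, columns phenotype actives; every
    entry lies in [0, 1]. Stored in double precision; nothing is rounded
    before thresholding.
    """

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.row_ids)} rows x {len(self.col_ids)} cols"
            )
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("similarity entries must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row_index(self, compound_id: str) -> int:
        try:
            return self._row_lookup[compound_id]
        except AttributeError:
            self._row_lookup = {cid: i for i, cid in enumerate(self.row_ids)}
            return self.row_index(compound_id)


def compute_fingerprint(
    compound: CompoundRecord, diameter: int = 4, nbits: int = 2048
) -> Fingerprint:
    """Hashed Morgan (extended-connectivity) fingerprint of one compound.

    Deterministic: the same structure always yields the same bit set,
    regardless of SMILES canonicalization.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    if diameter % 2:
        raise ValueError("circular-neighborhood diameter must be even")
    mol = Chem.MolFromSmiles(compound.structure)
    if mol is None:
        raise ValueError(f"unparseable structure for {compound.compound_id}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=diameter // 2, fpSize=nbits)
    bv = gen.GetFingerprint(mol)
    return Fingerprint(compound.compound_id, frozenset(bv.GetOnBits()), nbits, diameter)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient S_t = C / (A + B - C) over on-bit counts, where
    A and B are the two molecules' on-bit counts and C the shared count."""
    if a.nbits != b.nbits or a.diameter != b.diameter:
        raise ValueError("fingerprints computed with different parameters")
    c = len(a.bits & b.bits)
    denom = len(a.bits) + len(b.bits) - c
    return c / denom if denom else 0.0


def _bit_matrix(fps: list[Fingerprint]) -> np.ndarray:
    nbits = fps[0].nbits
    mat = np.zeros((len(fps), nbits), dtype=np.float64)
    for i, fp in enumerate(fps):
        mat[i, list(fp.bits)] = 1.0
    return mat


def build_similarity_matrix(
    rows: list[Fingerprint], cols: list[Fingerprint]
) -> SimilarityMatrix:
    """All-pairs Tanimoto matrix; entry [j, i] = tanimoto(rows[j], cols[i])."""
    if not rows or not cols:
        raise ValueError("row and column fingerprint lists must be nonempty")
    params = {(fp.nbits, fp.diameter) for fp in rows} | {(fp.nbits, fp.diameter) for fp in cols}
    if len(params) != 1:
        raise ValueError("inconsistent fingerprint parameters")
    ra, ca = _bit_matrix(rows), _bit_matrix(cols)
    inter = ra @ ca.T
    denom = ra.sum(axis=1)[:, None] + ca.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore"):
        values = np.where(denom > 0, inter / np.where(denom > 0, denom, 1.0), 0.0)
    return SimilarityMatrix(
        [fp.compound_id for fp in rows], [fp.compound_id for fp in cols], values
    )


def slice_target_matrix(M: SimilarityMatrix, ligands: LigandSet) -> SimilarityMatrix:
    """M_t: the rows of M belonging to one protein's ligand set, all columns,
    in ligand-set order."""
    lookup = {cid: i for i, cid in enumerate(M.row_ids)}
    missing = [cid for cid in ligands.compound_ids if cid not in lookup]
    if missing:
        raise KeyError(
            f"ligand(s) of {ligands.protein_id} absent from similarity matrix rows: "
            f"{missing[:5]}"
        )
    idx = [lookup[cid] for cid in ligands.compound_ids]
    return SimilarityMatrix(list(ligands.compound_ids), list(M.col_ids), M.values[idx])


def build_random_matrix(
    background: list[CompoundRecord],
    cols: list[Fingerprint],
    window: PropertyWindow,
    n_rows: int,
    seed: int | np.random.Generator = 0,
    nbits: int = 2048,
    diameter: int = 4,
) -> SimilarityMatrix:
    """M_r: Tanimoto matrix of a random, property-filtered background sample
    against the phenotype actives. Row selection is reproducible under the
    given seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    filtered = property_filter(background, window)
    if len(filtered) < n_rows:
        raise ValueError(
            f"background holds {len(filtered)} property-filtered compounds, "
            f"fewer than the requested {n_rows}"
        )
    pick = rng.choice(len(filtered), size=n_rows, replace=False)
    chosen = [filtered[i] for i in pick]
    fps = [compute_fingerprint(rec, diameter=diameter, nbits=nbits) for rec in chosen]
    return build_similarity_matrix(fps, cols)
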