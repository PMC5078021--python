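"""Input/output for compound structures, activity tables, similarity matrices
and result tables.

All activities are ingested in mol/L; pGI50 is computed internally and never
read from input, so a single unit convention holds throughout. Compound
identifiers are namespaced by library: the same structure may legitimately
occur in both the phenotype and the target library (self-similarity pairs are
real signal for a ligand-set ensemble statistic, not duplication artifacts).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

LIBRARIES = ("phenotype", "target", "random_background")
PHENOTYPE_ENDPOINTS = ("GI50",)
PROTEIN_ENDPOINTS = ("Ki", "IC50", "Kd", "EC50")
ENDPOINTS = PHENOTYPE_ENDPOINTS + PROTEIN_ENDPOINTS


@dataclass(frozen=True)
class CompoundRecord:
    """A single small molecule in one of the three libraries."""

    compound_id: str
    structure: str  # SMILES
    library: str
    mol_weight: float | None = None  # daltons
    alogp: float | None = None  # unitless octanol-water partition estimate

    def __post_init__(self):
        if self.library not in LIBRARIES:
            raise ValueError(f"unknown library {self.library!r}")


@dataclass(frozen=True)
class ActivityRecord:
    """One activity measurement, value in mol/L.

    GI50 endpoints belong to phenotype (cell line) targets; Ki/IC50/Kd/EC50
    to protein targets.
    """

    compound_id: str
    target_id: str
    endpoint: str
    value_mol_per_l: float

    def __post_init__(self):
        if self.endpoint not in ENDPOINTS:
            raise ValueError(f"unknown endpoint {self.endpoint!r}")
        if not (self.value_mol_per_l > 0):
            raise ValueError("activity value must be positive (mol/L)")

    @property
    def p_value(self) -> float:
        """-log10 of the molar value (pGI50 for GI50 endpoints)."""
        return -np.log10(self.value_mol_per_l)


@dataclass
class RunConfig:
    """Configuration of one full association run.

    Desk-scale sampling defaults (200 lengths x 500 repeats, a 1e5 null pool)
    keep runs tractable on a single core; :meth:`full_scale` switches to the
    2000 x 5000 sampling that yields ten-million-member pools. The empirical
    p-value resolution is ``1 / (n_lengths * reps_per_length)`` and is
    reported alongside every score.
    """

    sim_threshold: float = 0.15
    alpha_z: float = 0.01
    network_pz_cutoff: float = 1e-4
    n_lengths: int = 200
    reps_per_length: int = 500
    length_range: tuple[int, int] = (1, 10_000)
    o_length_range: tuple[int, int] | None = None  # None: reuse length_range
    min_ligands: int = 10
    seed: int = 0
    pgi50_min: float = 6.0
    target_activity_threshold: float = 1e-6  # mol/L
    property_windows: dict = field(default_factory=dict)  # library -> window kwargs
    fp_nbits: int = 2048
    fp_diameter: int = 4
    gi50_aggregation: str = "most_potent"  # or "mean"
    column_mode: str = "redraw"  # or "cycle"
    reuse_fit_pool: bool = True

    def __post_init__(self):
        if not 0 < self.sim_threshold < 1:
            raise ValueError("sim_threshold must lie in (0, 1)")
        if not 0 < self.alpha_z < 1:
            raise ValueError("alpha_z must lie in (0, 1)")
        self.length_range = tuple(self.length_range)
        if self.o_length_range is not None:
            self.o_length_range = tuple(self.o_length_range)
        if self.length_range[0] < 1 or self.length_range[0] > self.length_range[1]:
            raise ValueError("length_range must satisfy 1 <= min <= max")

    @property
    def pool_size(self) -> int:
        return self.n_lengths * self.reps_per_length

    @classmethod
    def full_scale(cls, **overrides) -> "RunConfig":
        """The ten-million-sample configuration (2000 lengths x 5000 reps)."""
        overrides.setdefault("n_lengths", 2000)
        overrides.setdefault("reps_per_length", 5000)
        return cls(**overrides)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def with_(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# compound structures


def _rdkit_props(smiles: str):
    """Parse SMILES; return (mol_weight, alogp) or None if unparseable."""
    from rdkit import Chem
    from rdkit.Chem import Crippen, Descriptors
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.error")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Descriptors.MolWt(mol), Crippen.MolLogP(mol)


def read_compounds(path: str | Path, format: str, library: str) -> list[CompoundRecord]:
    """Read a compound library from a whitespace-delimited SMILES table or an
    SDF (V2000) file.

    Unparseable structures and duplicate identifiers are rejected with a
    logged reason; zero parseable structures is a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "smiles_table":
        entries = _iter_smiles_table(path)
    elif format == "sdf":
        entries = _iter_sdf(path)
    else:
        raise ValueError(f"unknown compound format {format!r}")

    records: list[CompoundRecord] = []
    seen: set[str] = set()
    n_rejected = 0
    for compound_id, smiles in entries:
        if compound_id in seen:
            n_rejected += 1
            logger.warning("rejecting %s: duplicate compound_id", compound_id)
            continue
        props = _rdkit_props(smiles)
        if props is None:
            n_rejected += 1
            logger.warning("rejecting %s: unparseable structure %r", compound_id, smiles)
            continue
        mw, alogp = props
        seen.add(compound_id)
        records.append(CompoundRecord(compound_id, smiles, library, mw, alogp))
    if not records:
        raise ValueError(f"zero parseable structures in {path}")
    if n_rejected:
        logger.info("%s: %d records, %d rejected", path.name, len(records), n_rejected)
    return records


def _iter_smiles_table(path: Path):
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            smiles = parts[0]
            compound_id = parts[1] if len(parts) > 1 else smiles
            yield compound_id, smiles


def _iter_sdf(path: Path):
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.error")
    supplier = Chem.SDMolSupplier(str(path), sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            yield f"__unparseable_{i}", ""
            continue
        cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol_{i}"
        yield cid, Chem.MolToSmiles(mol)


def write_smiles_table(records: Iterable[CompoundRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"{rec.structure}\t{rec.compound_id}\n")


# ---------------------------------------------------------------------------
# activity tables

ACTIVITY_COLUMNS = ["compound_id", "target_id", "endpoint", "value_mol_per_L"]


def read_activities(path: str | Path) -> list[ActivityRecord]:
    """Read a CSV/TSV activity table.

    Rows with unknown endpoint labels or nonpositive/nonnumeric values are
    rejected with a logged reason; an all-rejected table is a hard error.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in ACTIVITY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"activity table missing columns: {missing}")

    records: list[ActivityRecord] = []
    n_rejected = 0
    for row in df.itertuples(index=False):
        try:
            value = float(getattr(row, "value_mol_per_L"))
        except (TypeError, ValueError):
            value = float("nan")
        try:
            records.append(
                ActivityRecord(str(row.compound_id), str(row.target_id), str(row.endpoint), value)
            )
        except ValueError as exc:
            n_rejected += 1
            logger.warning("rejecting activity row %s: %s", tuple(row), exc)
    if not records:
        raise ValueError(f"no valid activity rows in {path}")
    if n_rejected:
        logger.info("%s: %d records, %d rejected", path.name, len(records), n_rejected)
    return records


def write_activities(records: Iterable[ActivityRecord], path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.DataFrame(
        [(r.compound_id, r.target_id, r.endpoint, np.format_float_scientific(r.value_mol_per_l))
         for r in records],
        columns=ACTIVITY_COLUMNS,
    )
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# similarity matrices (dense TSV with row/column identifier headers)


def write_similarity_tsv(matrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.row_ids, columns=matrix.col_ids)
    df.to_csv(path, sep="\t", index_label="compound_id", float_format="%.12g")


def read_similarity_tsv(path: str | Path):
    from .similarity import SimilarityMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    return SimilarityMatrix(
        row_ids=[str(i) for i in df.index],
        col_ids=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# result tables


def association_table(result) -> pd.DataFrame:
    """Per-protein table: protein_id, O, P_O, rank.

    Ordering is P_O ascending with ties broken by lexicographic protein_id;
    rank 1 is the smallest P_O.
    """
    rows = sorted(
        ((p.protein_id, p.o_score, p.p_o) for p in result.proteins),
        key=lambda r: (r[2], r[0]),
    )
    df = pd.DataFrame(rows, columns=["protein_id", "O", "P_O"])
    df["rank"] = range(1, len(df) + 1)
    return df


def write_association_table(result, path: str | Path) -> None:
    """Write the per-protein association (AS score) table as TSV.

    Ordering is deterministic: P_O ascending with ties broken by
    lexicographic protein_id; rank 1 is the smallest P_O.
    """
    df = association_table(result)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def write_pz_table(result, path: str | Path) -> None:
    """Long-format per (compound, protein) score table."""
    rows = []
    for p in result.proteins:
        for cid, i_val, z_val, pz in zip(result.col_ids, p.initial_scores, p.z_scores, p.p_z):
            rows.append((cid, p.protein_id, i_val, z_val, pz))
    df = pd.DataFrame(rows, columns=["compound_id", "protein_id", "I", "Z", "P_Z"])
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
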