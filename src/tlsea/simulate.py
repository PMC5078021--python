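"""Self-contained synthetic test universes with known ground truth.

Two generation paths cover the pipeline at different depths:

* the **matrix path** draws similarity matrices directly from a null model
  (a mixture of a low-similarity bulk centred near 0.2 and a thin
  high-similarity tail) with optional planted protein blocks whose entries
  are shifted toward high similarity — it exercises the statistics quickly
  and with exact control over the similarity distribution;
* the **structure path** assembles valid SMILES from a small fragment
  grammar, with activity tables planted so that stated fractions pass each
  filter — it exercises parsing, fingerprints, and the filter chain.

Chemistry-level generation cannot precisely control similarity
distributions, which is why the two paths are separate. Both are fully
reproducible from (spec, seed) and record a ground-truth manifest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .filtering import LigandSet
from .io import ActivityRecord, CompoundRecord
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BaselineSimilarityModel:
    """Null distribution of pairwise similarities: a Beta bulk (mean
    low_alpha/(low_alpha+low_beta), default 0.2) mixed with a small-weight
    high Beta tail emulating the rare near-duplicate pair."""

    low_alpha: float = 2.5
    low_beta: float = 10.0
    high_alpha: float = 8.0
    high_beta: float = 2.0
    high_weight: float = 0.01

    def draw(self, rng: np.random.Generator, size, elevated_weight: float | None = None):
        """Draw similarities; ``elevated_weight`` overrides the high-tail
        mixture weight (used for planted blocks)."""
        w = self.high_weight if elevated_weight is None else elevated_weight
        low = rng.beta(self.low_alpha, self.low_beta, size=size)
        high = rng.beta(self.high_alpha, self.high_beta, size=size)
        mask = rng.random(size=size) < w
        return np.where(mask, high, low)


@dataclass
class FixtureSpec:
    """Everything needed to generate one reproducible test universe."""

    n_phenotype_actives: int = 30
    n_phenotype_inactives: int = 20
    n_target_compounds: int = 400
    n_background_compounds: int = 400
    n_proteins: int = 20
    ligand_set_size_range: tuple[int, int] = (10, 30)
    planted_proteins: list[tuple[str, float]] = field(default_factory=list)
    baseline: BaselineSimilarityModel = field(default_factory=BaselineSimilarityModel)
    n_malformed_activity_rows: int = 0
    seed: int = 0

    def __post_init__(self):
        for pid, frac in self.planted_proteins:
            if not 0 <= frac <= 1:
                raise ValueError(f"planted overlap fraction for {pid} must lie in [0,1]")
        if min(
            self.n_phenotype_actives, self.n_target_compounds, self.n_proteins
        ) < 1:
            raise ValueError("universe sizes must be >= 1")
        lo, hi = self.ligand_set_size_range
        if not 1 <= lo <= hi:
            raise ValueError("ligand_set_size_range must satisfy 1 <= min <= max")


# ---------------------------------------------------------------------------
# matrix path


def generate_similarity_matrix_direct(
    spec: FixtureSpec, rng: np.random.Generator | None = None
) -> tuple[SimilarityMatrix, dict]:
    """Target x phenotype similarity matrix drawn i.i.d. from the baseline
    model, with planted (protein rows x all columns) blocks redrawn with an
    elevated high-tail weight equal to the planted overlap fraction.

    The manifest records the protein -> row assignment, the planted blocks,
    and the generator settings.
    """
    rng = rng or np.random.default_rng(spec.seed)
    n_rows, n_cols = spec.n_target_compounds, spec.n_phenotype_actives
    row_ids = [f"T{i:05d}" for i in range(n_rows)]
    col_ids = [f"P{i:05d}" for i in range(n_cols)]
    values = spec.baseline.draw(rng, (n_rows, n_cols))

    sizes = rng.integers(
        spec.ligand_set_size_range[0], spec.ligand_set_size_range[1] + 1, spec.n_proteins
    )
    if sizes.sum() > n_rows:
        raise ValueError(
            f"ligand sets need {sizes.sum()} rows but only {n_rows} target "
            "compounds are available"
        )
    perm = rng.permutation(n_rows)
    assignments: dict[str, list[int]] = {}
    cursor = 0
    planted = dict(spec.planted_proteins)
    protein_ids = sorted(
        set(planted) | {f"PR{i:03d}" for i in range(spec.n_proteins - len(planted))}
    )
    if len(protein_ids) != spec.n_proteins:
        raise ValueError("planted protein ids collide with generated ids")
    for pid, m in zip(protein_ids, sizes):
        rows = sorted(int(r) for r in perm[cursor : cursor + int(m)])
        cursor += int(m)
        assignments[pid] = rows
        if pid in planted:
            values[rows, :] = spec.baseline.draw(rng, (len(rows), n_cols), planted[pid])

    manifest = {
        "kind": "matrix_universe",
        "seed": spec.seed,
        "baseline": asdict(spec.baseline),
        "planted_proteins": {pid: float(f) for pid, f in spec.planted_proteins},
        "ligand_sets": {
            pid: [row_ids[r] for r in rows] for pid, rows in assignments.items()
        },
    }
    return SimilarityMatrix(row_ids, col_ids, values), manifest


def null_similarity_matrix(
    n_rows: int,
    n_cols: int,
    model: BaselineSimilarityModel,
    rng: np.random.Generator | int | None = None,
    row_prefix: str = "R",
) -> SimilarityMatrix:
    """A pure-null similarity matrix (no planted structure), e.g. M_r."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    return SimilarityMatrix(
        [f"{row_prefix}{i:05d}" for i in range(n_rows)],
        [f"P{i:05d}" for i in range(n_cols)],
        model.draw(rng, (n_rows, n_cols)),
    )


def generate_matrix_universe(spec: FixtureSpec) -> dict:
    """Full matrix-level universe: M with ligand-set row assignments, a
    null M_r over the same columns, the LigandSet list, and the manifest."""
    rng = np.random.default_rng(spec.seed)
    M, manifest = generate_similarity_matrix_direct(spec, rng)
    M_r = SimilarityMatrix(
        [f"B{i:05d}" for i in range(spec.n_background_compounds)],
        list(M.col_ids),
        spec.baseline.draw(rng, (spec.n_background_compounds, spec.n_phenotype_actives)),
    )
    ligand_sets = [
        LigandSet(pid, tuple(cids)) for pid, cids in sorted(manifest["ligand_sets"].items())
    ]
    return {"M": M, "M_r": M_r, "ligand_sets": ligand_sets, "manifest": manifest}


# ---------------------------------------------------------------------------
# structure path

_SCAFFOLDS = [
    "c1ccccc1",
    "c1ccncc1",
    "c1ccc2ccccc2c1",
    "C1CCCCC1",
    "C1CCNCC1",
    "c1ccsc1",
    "c1ccoc1",
    "c1cnc2ccccc2c1",
]
_LINKERS = [
    "C",
    "CC",
    "CCC",
    "CCO",
    "CN",
    "CCN",
    "OC",
    "C(=O)",
    "C(=O)N",
    "C(=O)O",
    "S",
    "OCC",
    "C(C)",
    "C#C",
]
_TERMINALS = ["C", "CC", "O", "N", "Cl", "F", "Br", "C#N", "C(F)(F)F", "OC", "C(C)C"]


def _random_smiles(rng: np.random.Generator) -> str:
    """One valid molecule from the fragment grammar (validated with RDKit;
    redrawn on the rare invalid concatenation)."""
    from rdkit import Chem
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.error")
    while True:
        parts = []
        for _ in range(int(rng.integers(0, 3))):
            parts.append(_LINKERS[rng.integers(len(_LINKERS))])
        parts.append(_SCAFFOLDS[rng.integers(len(_SCAFFOLDS))])
        if rng.random() < 0.7:
            parts.append(_LINKERS[rng.integers(len(_LINKERS))])
            parts.append(_SCAFFOLDS[rng.integers(len(_SCAFFOLDS))])
        parts.append(_TERMINALS[rng.integers(len(_TERMINALS))])
        smiles = "".join(parts)
        if Chem.MolFromSmiles(smiles) is not None:
            return smiles


def _make_compounds(
    n: int, prefix: str, library: str, rng: np.random.Generator,
    structures: list[str] | None = None,
) -> list[CompoundRecord]:
    from .io import _rdkit_props

    records = []
    for i in range(n):
        smiles = structures[i] if structures else _random_smiles(rng)
        mw, alogp = _rdkit_props(smiles)
        records.append(CompoundRecord(f"{prefix}{i:05d}", smiles, library, mw, alogp))
    return records


def generate_structure_universe(spec: FixtureSpec) -> dict:
    """Structure-level universe: SMILES libraries, activity tables, and a
    ground-truth manifest.

    Phenotype actives receive GI50 values with pGI50 in (6.05, 9); inactives
    in (4, 5.95), so the activity filter recovers exactly the planted actives.
    Each protein's ligands are active at Ki < 1e-6 mol/L; planted proteins
    draw the planted fraction of their ligand structures verbatim from the
    phenotype actives (re-identified in the target namespace), giving those
    pairs self-similarity 1.
    """
    rng = np.random.default_rng(spec.seed)
    n_pheno = spec.n_phenotype_actives + spec.n_phenotype_inactives
    phenotype = _make_compounds(n_pheno, "NCI", "phenotype", rng)
    active_ids = sorted(
        str(cid)
        for cid in rng.choice(
            [c.compound_id for c in phenotype], spec.n_phenotype_actives, replace=False
        )
    )
    active_set = set(active_ids)
    active_structures = {c.compound_id: c.structure for c in phenotype if c.compound_id in active_set}

    pheno_activities = []
    for c in phenotype:
        if c.compound_id in active_set:
            pgi50 = rng.uniform(6.05, 9.0)
        else:
            pgi50 = rng.uniform(4.0, 5.95)
        pheno_activities.append(ActivityRecord(c.compound_id, "CELL1", "GI50", 10.0 ** -pgi50))

    # target library: planted ligands copy phenotype-active structures
    planted = dict(spec.planted_proteins)
    sizes = rng.integers(
        spec.ligand_set_size_range[0], spec.ligand_set_size_range[1] + 1, spec.n_proteins
    )
    protein_ids = sorted(
        set(planted) | {f"PR{i:03d}" for i in range(spec.n_proteins - len(planted))}
    )
    target_structures: list[str] = []
    ligand_rows: dict[str, list[int]] = {}
    for pid, m in zip(protein_ids, sizes):
        m = int(m)
        rows = []
        n_overlap = int(round(planted.get(pid, 0.0) * m))
        overlap_src = rng.choice(active_ids, size=min(n_overlap, len(active_ids)), replace=False)
        for src in overlap_src:
            rows.append(len(target_structures))
            target_structures.append(active_structures[src])
        for _ in range(m - len(overlap_src)):
            rows.append(len(target_structures))
            target_structures.append(_random_smiles(rng))
        ligand_rows[pid] = rows
    while len(target_structures) < spec.n_target_compounds:
        target_structures.append(_random_smiles(rng))
    target = _make_compounds(
        len(target_structures), "BDB", "target", rng, structures=target_structures
    )

    endpoints = np.array(["Ki", "IC50", "Kd", "EC50"])
    target_activities = []
    for pid, rows in ligand_rows.items():
        for r in rows:
            cid = target[r].compound_id
            ep = endpoints[rng.integers(4)]
            target_activities.append(
                ActivityRecord(cid, pid, ep, 10.0 ** rng.uniform(-9.0, -6.05))
            )
    # a sprinkle of inactive pairs so the activity filter has work to do
    for _ in range(spec.n_proteins * 2):
        cid = target[rng.integers(len(target))].compound_id
        pid = protein_ids[rng.integers(len(protein_ids))]
        ep = endpoints[rng.integers(4)]
        target_activities.append(ActivityRecord(cid, pid, ep, 10.0 ** rng.uniform(-5.95, -4.0)))

    background = _make_compounds(
        spec.n_background_compounds, "RND", "random_background", rng
    )

    manifest = {
        "kind": "structure_universe",
        "seed": spec.seed,
        "phenotype_actives": list(active_ids),
        "planted_proteins": {pid: float(f) for pid, f in spec.planted_proteins},
        "ligand_sets": {
            pid: [target[r].compound_id for r in rows] for pid, rows in ligand_rows.items()
        },
        "n_malformed_activity_rows": spec.n_malformed_activity_rows,
    }
    return {
        "phenotype": phenotype,
        "target": target,
        "background": background,
        "phenotype_activities": pheno_activities,
        "target_activities": target_activities,
        "manifest": manifest,
    }


def write_malformed_activity_table(
    records, n_malformed: int, path, rng: np.random.Generator | int | None = None
) -> None:
    """Write an activity table with ``n_malformed`` corrupted rows
    interleaved (nonpositive values or unknown endpoints), for reader tests."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    rows = [
        (r.compound_id, r.target_id, r.endpoint, np.format_float_scientific(r.value_mol_per_l))
        for r in records
    ]
    bad_templates = [
        ("badc", "CELL1", "GI50", "-1"),
        ("badc", "CELL1", "GI50", "not_a_number"),
        ("badc", "CELL1", "LD50", "1e-7"),
        ("badc", "CELL1", "GI50", "0"),
    ]
    for i in range(n_malformed):
        t = bad_templates[int(rng.integers(len(bad_templates)))]
        rows.insert(int(rng.integers(len(rows) + 1)), (f"{t[0]}{i}",) + t[1:])
    import pandas as pd

    pd.DataFrame(rows, columns=["compound_id", "target_id", "endpoint", "value_mol_per_L"]).to_csv(
        path, sep="\t" if str(path).endswith((".tsv", ".tab")) else ",", index=False
    )
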