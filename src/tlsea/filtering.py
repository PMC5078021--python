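"""Activity and physicochemical filters, and protein ligand-set assembly.

Boundary conventions follow the wording of the thresholds literally:
"over 6" and "smaller than 1e-6 mol/L" are strict inequalities, while
molecular-weight and AlogP windows written as [lo, hi] are closed intervals.
All boundaries are configurable. AlogP is the Crippen estimate computed by
RDKit; exact membership at window edges under other descriptor
implementations is not claimed.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import (
    ActivityRecord,
    CompoundRecord,
    PHENOTYPE_ENDPOINTS,
    PROTEIN_ENDPOINTS,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PropertyWindow:
    """Closed MW/AlogP acceptance window."""

    mw_min: float = 150.0
    mw_max: float = 750.0
    alogp_min: float = 2.0
    alogp_max: float = 7.0

    def __post_init__(self):
        if not (self.mw_min < self.mw_max and self.alogp_min < self.alogp_max):
            raise ValueError("window bounds must satisfy min < max")

    def contains(self, mol_weight: float, alogp: float) -> bool:
        return (self.mw_min <= mol_weight <= self.mw_max
                and self.alogp_min <= alogp <= self.alogp_max)


@dataclass(frozen=True)
class LigandSet:
    """The filtered active compounds of one protein."""

    protein_id: str
    compound_ids: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.compound_ids)) != len(self.compound_ids):
            raise ValueError(f"duplicate compound_ids in ligand set {self.protein_id}")

    def __len__(self) -> int:
        return len(self.compound_ids)


def phenotype_active_filter(
    records: Sequence[ActivityRecord],
    pgi50_min: float = 6.0,
    aggregation: str = "most_potent",
) -> set[str]:
    """Compounds whose pGI50 (= -log10 GI50 in mol/L) strictly exceeds
    ``pgi50_min``.

    Repeated measurements of one compound are aggregated before thresholding:
    ``most_potent`` (default) takes the smallest GI50, ``mean`` the arithmetic
    mean of the molar values.
    """
    for rec in records:
        if rec.endpoint not in PHENOTYPE_ENDPOINTS:
            raise ValueError(
                f"phenotype filter requires GI50 endpoints, got {rec.endpoint} "
                f"for {rec.compound_id}"
            )
    by_compound: dict[str, list[float]] = defaultdict(list)
    for rec in records:
        by_compound[rec.compound_id].append(rec.value_mol_per_l)

    active: set[str] = set()
    for cid, values in by_compound.items():
        if aggregation == "most_potent":
            gi50 = min(values)
        elif aggregation == "mean":
            gi50 = sum(values) / len(values)
        else:
            raise ValueError(f"unknown aggregation {aggregation!r}")
        if -math.log10(gi50) > pgi50_min:
            active.add(cid)
    return active


def target_active_filter(
    records: Sequence[ActivityRecord],
    threshold_mol_per_l: float = 1e-6,
) -> set[tuple[str, str]]:
    """(compound, protein) pairs active under the any-endpoint rule: a pair is
    active if ANY of its Ki/IC50/Kd/EC50 values is strictly below the
    threshold."""
    for rec in records:
        if rec.endpoint not in PROTEIN_ENDPOINTS:
            raise ValueError(
                f"target filter requires Ki/IC50/Kd/EC50 endpoints, got "
                f"{rec.endpoint} for {rec.compound_id}"
            )
    return {
        (rec.compound_id, rec.target_id)
        for rec in records
        if rec.value_mol_per_l < threshold_mol_per_l
    }


def property_filter(
    compounds: Sequence[CompoundRecord],
    window: PropertyWindow,
) -> list[CompoundRecord]:
    """Keep compounds inside the closed MW and AlogP windows.

    Compounds with missing/uncomputable properties are rejected with a log.
    """
    kept: list[CompoundRecord] = []
    for rec in compounds:
        if rec.mol_weight is None or rec.alogp is None:
            logger.warning("rejecting %s: MW/AlogP not available", rec.compound_id)
            continue
        if window.contains(rec.mol_weight, rec.alogp):
            kept.append(rec)
    return kept


def build_ligand_sets(
    active_pairs: Iterable[tuple[str, str]],
    min_ligands: int = 10,
) -> list[LigandSet]:
    """Group active (compound, protein) pairs into per-protein ligand sets,
    discarding proteins with fewer than ``min_ligands`` active compounds."""
    by_protein: dict[str, list[str]] = defaultdict(list)
    for cid, pid in sorted(set(active_pairs)):
        by_protein[pid].append(cid)
    sets: list[LigandSet] = []
    for pid in sorted(by_protein):
        ligands = by_protein[pid]
        if len(ligands) < min_ligands:
            logger.info("dropping protein %s: %d ligands < %d", pid, len(ligands), min_ligands)
            continue
        sets.append(LigandSet(pid, tuple(ligands)))
    return sets
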