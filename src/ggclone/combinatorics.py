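"""Combinatorial library design and strain-improvement bookkeeping.

Promoter/terminator shuffling enumerates the Cartesian product of
candidate parts over a backbone's slots; the round planner splits a
multi-gene pathway into successive Golden Gate assemblies, each mapped
to the smallest backbone that fits (a marker plus k transcription units
needs 1 + 3k fragments); and the strain ledger turns measured titers
into the standard improvement metrics (fold change, percent increase,
volumetric productivity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product as iproduct
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .assemble import AssemblyDesign
from .errors import CapacityError, ValidationError
from .registry import RegistryCatalog, Slot, backbone_for_tu_count, slot_layout


@dataclass
class ShuffleSpec:
    """Per-slot candidate part lists over one backbone."""

    backbone_id: str
    slot_candidates: list[list[str]]  # part ids per slot, in slot order

    def validate(self, registry: RegistryCatalog) -> list[Slot]:
        slots = slot_layout(self.backbone_id)
        if len(self.slot_candidates) != len(slots):
            raise ValidationError(
                f"{self.backbone_id} has {len(slots)} slots, "
                f"{len(self.slot_candidates)} candidate lists given"
            )
        for slot, cands in zip(slots, self.slot_candidates):
            if not cands:
                raise ValidationError(f"empty candidate list for slot {slot.role!r}")
            for pid in cands:
                part = registry.part(pid)
                if part.role != slot.role:
                    raise ValidationError(
                        f"candidate {pid!r} has role {part.role!r}, "
                        f"slot needs {slot.role!r}"
                    )
        return slots


def enumerate_designs(spec: ShuffleSpec, registry: RegistryCatalog) -> list[AssemblyDesign]:
    """Full Cartesian product over candidate lists, lexicographic order.

    The count equals the product of the candidate-list sizes.
    """
    spec.validate(registry)
    return [
        AssemblyDesign(spec.backbone_id, list(combo))
        for combo in iproduct(*spec.slot_candidates)
    ]


# ---------------------------------------------------------------------------
# Round planning


@dataclass
class PathwaySet:
    """Genes co-assembled in one round, with that round's marker."""

    genes: list[str]
    marker: str
    promoters: Optional[list[str]] = None  # one per gene; None = pick later
    terminators: Optional[list[str]] = None


@dataclass
class RoundPlan:
    rounds: list[AssemblyDesign]

    @property
    def backbones(self) -> list[str]:
        return [d.backbone_id for d in self.rounds]


def plan_rounds(
    pathway_sets: Sequence[PathwaySet],
    registry: RegistryCatalog,
    default_promoter: Optional[str] = None,
    default_terminator: Optional[str] = None,
) -> RoundPlan:
    """Map each gene set to the smallest backbone that fits it.

    k genes (transcription units) plus a marker means 1 + 3k fragments:
    one gene fits pGGYL1 (4), two pGGYL2 (7), three pGGYL3 (10); more
    than three exceeds toolkit capacity.  Promoters/terminators are
    assigned slot-positionally, cycling through the registry's
    inventory when the set does not pin them.
    """
    designs = []
    for rnd, pset in enumerate(pathway_sets):
        k = len(pset.genes)
        backbone = backbone_for_tu_count(k)  # raises CapacityError on k>3
        for g in pset.genes:
            registry.part(g)
        registry.part(pset.marker)
        promoters = pset.promoters or _cycle_role(registry, "promoter", k, rnd)
        terminators = pset.terminators or _cycle_role(registry, "terminator", k, rnd)
        if len(promoters) != k or len(terminators) != k:
            raise ValidationError("need one promoter and one terminator per gene")
        slot_parts = [pset.marker]
        for g, p, t in zip(pset.genes, promoters, terminators):
            slot_parts += [p, g, t]
        designs.append(AssemblyDesign(backbone, slot_parts))
    return RoundPlan(designs)


def _cycle_role(registry: RegistryCatalog, role: str, k: int, offset: int) -> list[str]:
    pool = sorted(p.id for p in registry.parts_by_role(role))
    if not pool:
        raise ValidationError(f"registry has no {role} parts")
    return [pool[(offset * k + i) % len(pool)] for i in range(k)]


# ---------------------------------------------------------------------------
# Improvement metrics


@dataclass(frozen=True)
class StrainRecord:
    strain: str
    round: int
    titer: float  # mg/L
    yield_mg_per_gdcw: Optional[float] = None
    time_h: Optional[float] = None

    def __post_init__(self) -> None:
        if self.titer <= 0:
            raise ValidationError(f"{self.strain}: titer must be positive")
        if self.time_h is not None and self.time_h <= 0:
            raise ValidationError(f"{self.strain}: time must be positive")


def fold_change(baseline: float, value: float) -> float:
    """value / baseline (dimensionless)."""
    if baseline <= 0:
        raise ValidationError("baseline must be positive")
    return value / baseline


def percent_increase(a: float, b: float) -> float:
    """(b/a - 1) x 100."""
    if a <= 0:
        raise ValidationError("reference value must be positive")
    return (b / a - 1.0) * 100.0


def productivity(titer_mg_per_l: float, time_h: float) -> float:
    """Volumetric productivity in mg L^-1 h^-1."""
    if time_h <= 0:
        raise ValidationError("time must be positive")
    return titer_mg_per_l / time_h


def round_fold(x: float) -> float:
    """Fold value at reporting precision: 1 decimal, integer when within
    0.05 of one."""
    r = round(x, 1)
    return float(round(r)) if abs(r - round(r)) < 0.05 else r


@dataclass(frozen=True)
class LadderRow:
    round: int
    best_strain: str
    titer: float
    fold_vs_previous: float
    cumulative_fold: float


def ladder_report(records: Sequence[StrainRecord]) -> list[LadderRow]:
    """Best strain per round, fold over the previous round's best, and
    cumulative fold over the first round's best.

    Rounds are ordered ascending; within a round the best is the highest
    titer, ties broken by strain id.  The report is invariant to the
    input order of records.
    """
    if not records:
        raise ValidationError("empty ledger")
    by_round: dict[int, list[StrainRecord]] = {}
    for r in records:
        by_round.setdefault(r.round, []).append(r)
    rows: list[LadderRow] = []
    prev_titer: Optional[float] = None
    baseline: Optional[float] = None
    for rnd in sorted(by_round):
        grp = by_round[rnd]
        if not grp:
            raise ValidationError(f"empty round {rnd}")
        # best = highest titer; among ties, the smallest strain id
        top = max(r.titer for r in grp)
        best = sorted((r for r in grp if r.titer == top), key=lambda r: r.strain)[0]
        if baseline is None:
            baseline = best.titer
        fold_prev = fold_change(prev_titer, best.titer) if prev_titer else 1.0
        rows.append(
            LadderRow(rnd, best.strain, best.titer, fold_prev, fold_change(baseline, best.titer))
        )
        prev_titer = best.titer
    return rows


def read_ledger(path: str | Path) -> list[StrainRecord]:
    """TSV columns: strain, round, titer_mg_per_L[, yield_mg_per_gDCW, time_h]."""
    df = pd.read_csv(path, sep="\t")
    records = []
    for _, row in df.iterrows():
        records.append(
            StrainRecord(
                strain=str(row["strain"]),
                round=int(row["round"]),
                titer=float(row["titer_mg_per_L"]),
                yield_mg_per_gdcw=_opt(row, "yield_mg_per_gDCW"),
                time_h=_opt(row, "time_h"),
            )
        )
    return records


def _opt(row, col) -> Optional[float]:
    if col in row and pd.notna(row[col]):
        return float(row[col])
    return None
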