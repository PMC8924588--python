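"""The modular-cloning grammar: overhang table, typed parts, backbones.

The toolkit's junction grammar assigns each fusion site a label from 1 to
11.  The three destination backbones (pGGYL1/2/3) accept 4, 7 and 10
fragments respectively — one selection marker plus 1, 2 or 3
promoter-gene-terminator transcription units — and share one numbering:
junctions are counted left to right around the largest design, so a
building block cloned for a given slot is reusable in every backbone that
has that slot.  The backbone's own two junctions are label 1 (marker
side) and the label one past the last slot (5, 8 or 11).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import dna
from .dna import BSAI, SWAI, Annotation, NucleotideSequence, revcomp
from .errors import RegistryError, ValidationError

#: Default faithful fusion-site table, labels 1..11.  The eleven 4-mers
#: are mutually distinct, non-palindromic, free of reverse-complement
#: pairs and of Hamming-distance-1 near-misses, and none occurs inside
#: the BsaI or SwaI recognition sequences on either strand — so junction
#: regions can never complete a new enzyme site across two parts.
DEFAULT_OVERHANGS: dict[int, str] = {
    1: "AAAC",
    2: "AACA",
    3: "AAGG",
    4: "ACAA",
    5: "ACCC",
    6: "ACTG",
    7: "AGAG",
    8: "AGGA",
    9: "AGTC",
    10: "ATCG",
    11: "ATGC",
}

ROLES = ("marker", "promoter", "cds", "terminator", "stuffer")

#: Marker recycling mechanisms: Cre/loxP excision or hisG-repeat pop-out.
RECYCLING_MODES = ("loxP", "hisG")


@dataclass(frozen=True)
class Overhang:
    label: int
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != 4:
            raise ValidationError(f"overhang {self.label}: sequence must be 4 nt")


@dataclass(frozen=True)
class Slot:
    """One position in a backbone: a role and its two junction labels."""

    role: str
    left_label: int
    right_label: int


def _tu(first_label: int) -> list[Slot]:
    return [
        Slot("promoter", first_label, first_label + 1),
        Slot("cds", first_label + 1, first_label + 2),
        Slot("terminator", first_label + 2, first_label + 3),
    ]


SLOT_LAYOUTS: dict[str, list[Slot]] = {
    "pGGYL1": [Slot("marker", 1, 2)] + _tu(2),
    "pGGYL2": [Slot("marker", 1, 2)] + _tu(2) + _tu(5),
    "pGGYL3": [Slot("marker", 1, 2)] + _tu(2) + _tu(5) + _tu(8),
}


def slot_layout(backbone_id: str) -> list[Slot]:
    """Ordered slot list for a backbone (4, 7 or 10 slots)."""
    try:
        return list(SLOT_LAYOUTS[backbone_id])
    except KeyError:
        raise RegistryError(f"unknown backbone {backbone_id!r}") from None


def backbone_junction_labels(backbone_id: str) -> tuple[int, int]:
    """(right-end label, closing label) of the backbone vector body."""
    slots = slot_layout(backbone_id)
    return slots[0].left_label, slots[-1].right_label


def backbone_for_tu_count(k: int) -> str:
    """Smallest backbone holding a marker plus k transcription units."""
    from .errors import CapacityError

    if k not in (1, 2, 3):
        raise CapacityError(f"{k} transcription units exceeds toolkit capacity (1-3)")
    return {1: "pGGYL1", 2: "pGGYL2", 3: "pGGYL3"}[k]


# ---------------------------------------------------------------------------
# Parts and plasmids


@dataclass
class Part:
    """A typed DNA building block with its two fusion-site labels."""

    id: str
    role: str
    insert: NucleotideSequence
    left_label: int
    right_label: int
    recycling: Optional[str] = None  # "loxP" | "hisG" | None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"part {self.id}: unknown role {self.role!r}")
        # equal labels are not rejected here: validate_part reports them
        # as a self-circularizing pair (report-style check)
        if self.recycling is not None and self.recycling not in RECYCLING_MODES:
            raise ValidationError(f"part {self.id}: unknown recycling {self.recycling!r}")

    def with_labels(self, left: int, right: int) -> "Part":
        """The same insert re-cloned under a different fusion-site pair."""
        return Part(self.id, self.role, self.insert, left, right, self.recycling)


@dataclass
class BuildingBlockPlasmid:
    """Donor plasmid: part insert between two inward-pointing BsaI sites."""

    part: Part
    vector: NucleotideSequence  # the full circular plasmid


@dataclass
class BackbonePlasmid:
    """Destination vector with a lacZ stuffer between outward BsaI sites.

    The circular sequence carries, in order around the assembly region:
    vector body (ori and kanR placeholders, the two verification-primer
    landing sites), a SwaI site, the junction-1 fusion window, the
    stuffer flanked by its two BsaI recognitions, the closing fusion
    window, and the second SwaI site.
    """

    id: str
    sequence: NucleotideSequence
    slots: list[Slot] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.slots:
            self.slots = slot_layout(self.id)


# ---------------------------------------------------------------------------
# Validation

FORBIDDEN_ENZYMES = (BSAI, SWAI)


@dataclass
class OverhangFidelityReport:
    duplicates: list[tuple[int, int]]
    rc_collisions: list[tuple[int, int]]
    palindromes: list[int]
    near_misses: list[tuple[int, int]]  # Hamming distance 1 (warning tier)

    @property
    def faithful(self) -> bool:
        return not (self.duplicates or self.rc_collisions or self.palindromes)


def check_overhang_set(overhangs: list[str]) -> OverhangFidelityReport:
    """Pairwise ligation-fidelity check of a 4-mer fusion-site set.

    A set is *faithful* when no two entries are identical, none is the
    reverse complement of another, and none is self-palindromic — i.e.
    every sticky end anneals only with its own junction partner.  Pairs
    at Hamming distance 1 are reported as warnings (one-mismatch
    ligation is the dominant in vitro infidelity mode) but do not fail
    the set.
    """
    for ov in overhangs:
        if len(ov) != 4:
            raise ValidationError(f"overhang {ov!r} is not 4 nt")
    dup, rcc, pal, near = [], [], [], []
    for i, a in enumerate(overhangs):
        if revcomp(a) == a:
            pal.append(i)
        for j in range(i + 1, len(overhangs)):
            b = overhangs[j]
            if a == b:
                dup.append((i, j))
            if revcomp(a) == b:
                rcc.append((i, j))
            if sum(x != y for x, y in zip(a, b)) == 1 or sum(
                x != y for x, y in zip(a, revcomp(b))
            ) == 1:
                near.append((i, j))
    return OverhangFidelityReport(dup, rcc, pal, near)


@dataclass
class PartValidationReport:
    part_id: str
    internal_sites: list[tuple[str, int, int]]  # (enzyme, position, strand)
    unknown_labels: list[int]
    degenerate_pair: bool

    @property
    def ok(self) -> bool:
        return not (self.internal_sites or self.unknown_labels or self.degenerate_pair)

    @property
    def violations(self) -> list[str]:
        out = [
            f"internal {e} site at {p} (strand {s:+d})"
            for e, p, s in self.internal_sites
        ]
        out += [f"unknown overhang label {l}" for l in self.unknown_labels]
        if self.degenerate_pair:
            out.append("self-circularizing part: left and right labels equal")
        return out


def validate_part(part: Part, overhang_table: dict[int, str] | None = None) -> PartValidationReport:
    """Report internal BsaI/SwaI sites, unknown labels, degenerate pairs.

    The insert is scanned together with its two flanking fusion sites so
    that a motif completed by insert + fusion-site bases is caught too.
    """
    table = overhang_table or DEFAULT_OVERHANGS
    unknown = [l for l in (part.left_label, part.right_label) if l not in table]
    flank_l = table.get(part.left_label, "")
    flank_r = table.get(part.right_label, "")
    scanned = NucleotideSequence(flank_l + part.insert.bases + flank_r, "linear")
    sites = []
    for enz in FORBIDDEN_ENZYMES:
        for s in dna.scan_sites(scanned, enz):
            sites.append((enz.name, s.position - len(flank_l), s.strand))
    return PartValidationReport(
        part_id=part.id,
        internal_sites=sites,
        unknown_labels=unknown,
        degenerate_pair=(part.left_label == part.right_label),
    )


# ---------------------------------------------------------------------------
# Building-block minting

#: Single-nt spacer between a BsaI recognition and its cut window.
_SPACER = "A"


def mint_building_block(
    part: Part,
    donor_body: NucleotideSequence,
    overhang_table: dict[int, str] | None = None,
) -> BuildingBlockPlasmid:
    """Clone a part into a donor vector between inward-pointing BsaI sites.

    BsaI digestion of the result releases exactly the insert flanked by
    its two labelled fusion windows; both recognition sequences stay on
    the vector fragment, so the insert carries none.
    """
    table = overhang_table or DEFAULT_OVERHANGS
    w_l, w_r = table[part.left_label], table[part.right_label]
    rec, rec_rc = BSAI.recognition, revcomp(BSAI.recognition)
    left_arm = rec + _SPACER + w_l
    right_arm = w_r + _SPACER + rec_rc
    body = donor_body.bases
    offset = len(body) + len(left_arm)
    bases = body + left_arm + part.insert.bases + right_arm
    anns = [Annotation("donor_body", 0, len(body))]
    anns += [
        Annotation(a.label, a.start + offset, a.end + offset, a.strand)
        for a in part.insert.annotations
    ]
    anns.append(Annotation(part.role, offset, offset + len(part.insert)))
    seq = NucleotideSequence(bases, "circular", anns, id=f"pBB-{part.id}")
    return BuildingBlockPlasmid(part=part, vector=seq)


# ---------------------------------------------------------------------------
# Catalog


@dataclass
class RegistryCatalog:
    """Overhang table, parts indexed by id, and the three backbones."""

    overhang_table: dict[int, str]
    parts: dict[str, Part]
    backbones: dict[str, BackbonePlasmid]
    donor_body: NucleotideSequence

    def parts_by_role(self, role: str) -> list[Part]:
        return [p for p in self.parts.values() if p.role == role]

    def role_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for p in self.parts.values():
            counts[p.role] = counts.get(p.role, 0) + 1
        return counts

    def part(self, part_id: str) -> Part:
        try:
            return self.parts[part_id]
        except KeyError:
            raise RegistryError(f"unknown part {part_id!r}") from None

    def building_block(self, part_id: str, slot: Slot | None = None) -> BuildingBlockPlasmid:
        """Donor plasmid for a part, relabelled for ``slot`` if given.

        The physical library stores a part under every fusion-site pair
        it is used with; minting on demand models that without
        duplicating catalog rows.
        """
        part = self.part(part_id)
        if slot is not None:
            if part.role != slot.role:
                raise RegistryError(
                    f"part {part_id!r} has role {part.role!r}, slot needs {slot.role!r}"
                )
            part = part.with_labels(slot.left_label, slot.right_label)
        return mint_building_block(part, self.donor_body, self.overhang_table)

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        def seq_obj(s: NucleotideSequence) -> dict:
            return {
                "bases": s.bases,
                "topology": s.topology,
                "id": s.id,
                "annotations": [asdict(a) for a in s.annotations],
            }

        obj = {
            "overhang_table": {str(k): v for k, v in self.overhang_table.items()},
            "donor_body": seq_obj(self.donor_body),
            "parts": [
                {
                    "id": p.id,
                    "role": p.role,
                    "left_label": p.left_label,
                    "right_label": p.right_label,
                    "recycling": p.recycling,
                    "insert": seq_obj(p.insert),
                }
                for p in self.parts.values()
            ],
            "backbones": [
                {"id": b.id, "sequence": seq_obj(b.sequence)} for b in self.backbones.values()
            ],
        }
        return json.dumps(obj, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RegistryCatalog":
        obj = json.loads(text)

        def seq_of(d: dict) -> NucleotideSequence:
            anns = [Annotation(**a) for a in d["annotations"]]
            return NucleotideSequence(d["bases"], d["topology"], anns, d["id"])

        parts = {
            p["id"]: Part(
                p["id"], p["role"], seq_of(p["insert"]), p["left_label"],
                p["right_label"], p["recycling"],
            )
            for p in obj["parts"]
        }
        backbones = {
            b["id"]: BackbonePlasmid(b["id"], seq_of(b["sequence"]))
            for b in obj["backbones"]
        }
        return cls(
            overhang_table={int(k): v for k, v in obj["overhang_table"].items()},
            parts=parts,
            backbones=backbones,
            donor_body=seq_of(obj["donor_body"]),
        )


def load_registry(
    catalog_table: str | Path | pd.DataFrame,
    sequences: dict[str, NucleotideSequence],
    overhang_table: dict[int, str] | None = None,
    donor_body: NucleotideSequence | None = None,
    backbones: dict[str, BackbonePlasmid] | None = None,
) -> RegistryCatalog:
    """Build a catalog from a part table plus named sequence records.

    ``catalog_table`` is a TSV path or DataFrame with columns
    id, role, left_label, right_label, recycling, sequence_ref.
    Loading fails atomically: every violation across all rows is listed.
    """
    if isinstance(catalog_table, pd.DataFrame):
        df = catalog_table
    else:
        df = pd.read_csv(catalog_table, sep="\t", dtype=str, keep_default_na=False)
    table = overhang_table or DEFAULT_OVERHANGS

    problems: list[str] = []
    parts: dict[str, Part] = {}
    for _, row in df.iterrows():
        pid = row["id"]
        if pid in parts:
            problems.append(f"{pid}: duplicate part id")
            continue
        role = row["role"]
        if role not in ROLES:
            problems.append(f"{pid}: role {role!r} outside vocabulary")
            continue
        ref = row.get("sequence_ref", pid) or pid
        if ref not in sequences:
            problems.append(f"{pid}: missing sequence record {ref!r}")
            continue
        recycling = row.get("recycling", "") or None
        try:
            part = Part(
                pid, role, sequences[ref],
                int(row["left_label"]), int(row["right_label"]), recycling,
            )
        except (ValidationError, ValueError) as e:
            problems.append(f"{pid}: {e}")
            continue
        report = validate_part(part, table)
        if not report.ok:
            problems.extend(f"{pid}: {v}" for v in report.violations)
            continue
        parts[pid] = part

    if problems:
        raise RegistryError("catalog rejected:\n  " + "\n  ".join(problems))

    if donor_body is None:
        donor_body = NucleotideSequence("", "linear") if False else _minimal_donor_body()
    return RegistryCatalog(
        overhang_table=dict(table),
        parts=parts,
        backbones=dict(backbones or {}),
        donor_body=donor_body,
    )


def _minimal_donor_body() -> NucleotideSequence:
    # Small fixed ampR/ori stand-in, free of BsaI/SwaI sites; real donor
    # bodies come from the fixtures generator.
    bases = "ATGCCTGCAGGTCGACTCTAGAGGATCCCCGGGTACCGAGCTCGAATTCACTGGCCGTCGTTTTACAACGTCGTGA"
    return NucleotideSequence(bases, "linear", [Annotation("donor_ori", 0, len(bases))], "donor-body")
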