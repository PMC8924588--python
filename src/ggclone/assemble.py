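"""One-pot Golden Gate assembly simulation.

BsaI digestion of the destination backbone and every donor plasmid
yields a pool of sticky fragments.  Because correct products lose all
recognition sites while every misassembly that regenerates a site is
re-cut, the reaction funnels toward circles over the fusion-site
grammar; the simulator models the end state of that funnel as the set of
circular closures over the fragment pool in which each physical
fragment is used at most once and every junction joins equal normalized
4-nt overhangs.

The closure search walks a directed graph whose nodes are overhang
4-mers and whose edges are fragments in either orientation; an
independent permutation brute force (:func:`enumerate_products_bruteforce`)
serves as its oracle for small pools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from . import dna
from .dna import BSAI, NucleotideSequence, StickyFragment
from .errors import AssemblyFailure, ValidationError
from .registry import RegistryCatalog, Slot, backbone_junction_labels, slot_layout

#: An oriented fragment inside a circle: (pool index, flipped?).
OrientedFragment = tuple[int, bool]


@dataclass
class AssemblyDesign:
    """A backbone plus one part assigned to each of its slots."""

    backbone_id: str
    slot_parts: list[str]  # part ids, in slot order

    def validate(self, registry: RegistryCatalog) -> list[Slot]:
        slots = slot_layout(self.backbone_id)
        if len(self.slot_parts) != len(slots):
            raise ValidationError(
                f"{self.backbone_id} has {len(slots)} slots, "
                f"{len(self.slot_parts)} parts assigned"
            )
        for slot, pid in zip(slots, self.slot_parts):
            if pid is None:
                continue  # explicitly unfilled slot (assembly will fail to close)
            part = registry.part(pid)
            if part.role != slot.role:
                raise ValidationError(
                    f"slot {slot.role!r} cannot take part {pid!r} of role {part.role!r}"
                )
        return slots


@dataclass
class Circle:
    """A circular closure: oriented pool fragments in ligation order."""

    members: tuple[OrientedFragment, ...]
    fragments: list[StickyFragment]  # oriented, ready to ligate

    def sequence(self, id: str = "") -> NucleotideSequence:
        return dna.ligate(self.fragments, circular=True, id=id)

    def junction_overhangs(self) -> list[str]:
        return [f.right_overhang for f in self.fragments]


@dataclass
class AssemblyProduct:
    sequence: NucleotideSequence
    junctions: list[tuple[Optional[int], str]]  # (label or None, 4-mer)
    colony_color: str  # "white" | "blue"
    misjoin_flags: list[str] = field(default_factory=list)
    circle: Optional[Circle] = None


@dataclass
class SideProduct:
    sequence: NucleotideSequence
    composition: list[str]  # provenance of each member fragment
    classification: str  # backbone-religation | donor-religation | misjoin-circle | dead-end-linear


# ---------------------------------------------------------------------------
# Closure search


def _oriented(frag: StickyFragment, flip: bool) -> StickyFragment:
    return frag.flipped() if flip else frag


def find_closures(
    fragments: list[StickyFragment], max_pieces: int = 12
) -> list[list[OrientedFragment]]:
    """All distinct sticky circular closures of at most ``max_pieces``.

    Each physical fragment is used at most once; junctions require equal
    non-empty normalized overhangs.  Circles are canonicalized by
    anchoring each at its lowest-index fragment in forward orientation,
    which fixes both rotation and reflection.
    """
    ends = [
        (f.left_overhang, f.right_overhang) if f.is_sticky else None for f in fragments
    ]
    circles: list[list[OrientedFragment]] = []
    n = len(fragments)

    def extend(anchor: int, path: list[OrientedFragment], used: set[int], open_end: str, target: str):
        if len(path) > max_pieces:
            return
        if open_end == target and path:
            circles.append(list(path))
            # a longer circle may still pass through; keep extending
        for j in range(anchor + 1, n):
            if j in used or ends[j] is None:
                continue
            l, r = ends[j]
            if l == open_end:
                used.add(j)
                path.append((j, False))
                extend(anchor, path, used, r, target)
                path.pop()
                used.remove(j)
            if r and l and dna.revcomp(r) == open_end:
                used.add(j)
                path.append((j, True))
                extend(anchor, path, used, dna.revcomp(l), target)
                path.pop()
                used.remove(j)

    for s in range(n):
        if ends[s] is None:
            continue
        l, r = ends[s]
        if not (l and r):
            continue  # a blunt end can never close a sticky circle
        extend(s, [(s, False)], {s}, r, l)

    # Deduplicate: a circle may be emitted once per closing revisit.
    uniq = {}
    for c in circles:
        uniq.setdefault(tuple(c), c)
    return list(uniq.values())


def realize_circle(pool: list[StickyFragment], members: Iterable[OrientedFragment]) -> Circle:
    members = tuple(members)
    frags = [_oriented(pool[i], flip) for i, flip in members]
    return Circle(members, frags)


def enumerate_products_bruteforce(
    fragments: list[StickyFragment], max_pieces: int = 6
) -> list[list[OrientedFragment]]:
    """Exhaustive closure enumeration over subsets x permutations x
    orientations; canonicalized like :func:`find_closures`.

    Independent of the graph walk by construction; quadratic-factorial,
    so capped at 6 fragments.
    """
    from itertools import permutations, product as iproduct

    if len(fragments) > 6:
        raise ValidationError("brute force capped at 6 fragments")
    n = len(fragments)
    found: dict[tuple, list[OrientedFragment]] = {}
    indices = list(range(n))
    for size in range(1, min(n, max_pieces) + 1):
        from itertools import combinations

        for subset in combinations(indices, size):
            for perm in permutations(subset):
                if perm[0] != min(subset):
                    continue  # fix rotation: anchor at smallest index
                for orients in iproduct((False, True), repeat=size):
                    if orients[0]:
                        continue  # fix reflection: anchor forward
                    frags = [_oriented(fragments[i], o) for i, o in zip(perm, orients)]
                    if any(not f.left_overhang or not f.right_overhang for f in frags):
                        continue
                    ok = all(
                        frags[k].right_overhang == frags[(k + 1) % size].left_overhang
                        for k in range(size)
                    )
                    if ok:
                        key = tuple(zip(perm, orients))
                        found.setdefault(key, list(key))
    return list(found.values())


# ---------------------------------------------------------------------------
# Product interpretation


def predict_colony_color(sequence: NucleotideSequence) -> str:
    """Blue iff the lacZ stuffer is intact; requires the resistance
    placeholder for platability."""
    if not sequence.has_feature("kanR"):
        raise ValidationError("not platable: product lacks the resistance placeholder")
    return "blue" if sequence.has_feature("lacZ_stuffer") else "white"


def junction_report(product: AssemblyProduct) -> list[tuple[Optional[int], str]]:
    """Ordered (label, 4-mer) list of the product's junctions."""
    return list(product.junctions)


def classify_side_product(sequence: NucleotideSequence) -> str:
    if sequence.has_feature("lacZ_stuffer") and sequence.has_feature("kanR"):
        return "backbone-religation"
    if sequence.has_feature("donor_body") and not sequence.has_feature("lacZ_stuffer"):
        return "donor-religation"
    return "misjoin-circle"


def simulate_assembly(
    design: AssemblyDesign,
    registry: RegistryCatalog,
    max_side_pieces: int = 12,
    include_donor_backbones: bool = True,
) -> tuple[AssemblyProduct, list[SideProduct]]:
    """Digest backbone + building blocks with BsaI and search closures.

    Returns the intended product — the unique circle containing the
    backbone vector body under a faithful fusion-site table — plus every
    alternative circle as a classified side product.  If several circles
    contain the vector body, the intended one is returned with
    ``misjoin_flags`` naming the alternatives; if none exists an
    :class:`AssemblyFailure` carries the longest linear extension as a
    diagnostic.
    """
    slots = design.validate(registry)
    backbone = registry.backbones[design.backbone_id]
    label_of = {v: k for k, v in registry.overhang_table.items()}

    pool: list[StickyFragment] = list(dna.digest(backbone.sequence, BSAI))
    for slot, pid in zip(slots, design.slot_parts):
        if pid is None:
            continue  # deliberately unfilled slot
        block = registry.building_block(pid, slot)
        frags = dna.digest(block.vector, BSAI)
        if include_donor_backbones:
            pool.extend(frags)
        else:
            pool.extend(f for f in frags if not f.core.has_feature("donor_body"))

    pool = [f for f in pool if not f.uncut and f.is_sticky]

    vector_idx = [
        i for i, f in enumerate(pool)
        if f.core.has_feature("kanR") and not f.core.has_feature("lacZ_stuffer")
    ]
    if len(vector_idx) != 1:
        raise AssemblyFailure(
            f"expected exactly one backbone vector-body fragment, found {len(vector_idx)}"
        )
    v = vector_idx[0]

    closures = find_closures(pool, max_pieces=max_side_pieces)
    realized = [(c, realize_circle(pool, c)) for c in closures]

    # Circles that retain a BsaI recognition site are transient: the
    # cyclic digestion-ligation re-cuts them.  Only site-free circles
    # are stable end products; under a faithful fusion-site table the
    # intended one is the unique stable closure with the vector body.
    def recuttable(circle: Circle) -> bool:
        # scan the ligated circle, not the pieces: a site could in
        # principle span a junction
        return bool(dna.scan_sites(circle.sequence(), BSAI))

    stable_with_backbone = [
        (c, rc) for c, rc in realized
        if any(i == v for i, _ in c) and not recuttable(rc)
    ]
    if not stable_with_backbone:
        failure = AssemblyFailure(
            "assembly failure: no stable circular closure contains the backbone",
            longest_linear=_longest_linear(pool, v),
        )
        failure.side_products = _side_products(realized, exclude=None)
        raise failure

    intended, intended_circle = stable_with_backbone[0]
    for c, rc in stable_with_backbone:
        if len(c) == len(slots) + 1:
            intended, intended_circle = c, rc
            break
    misjoin_flags: list[str] = []
    for c, _ in stable_with_backbone:
        if c is not intended:
            misjoin_flags.append(
                "ambiguous closure: alternative stable circle of "
                f"{len(c)} pieces: {[pool[i].provenance for i, _ in c]}"
            )

    # Rotate so the vector-body fragment comes first.
    k = next(j for j, (i, _) in enumerate(intended) if i == v)
    members = tuple(intended[k:] + intended[:k])
    circle = realize_circle(pool, members)

    seq = circle.sequence(id=f"{design.backbone_id}-assembly")
    junctions = [(label_of.get(ov), ov) for ov in circle.junction_overhangs()]

    expected = [registry.overhang_table[s.left_label] for s in slots]
    expected.append(registry.overhang_table[slots[-1].right_label])
    if [ov for _, ov in junctions] != expected:
        misjoin_flags.append("junction order differs from the designed slot order")

    color = predict_colony_color(seq)
    product = AssemblyProduct(seq, junctions, color, misjoin_flags, circle)
    side = _side_products(realized, exclude=intended)
    return product, side


def _side_products(realized, exclude) -> list[SideProduct]:
    out: list[SideProduct] = []
    for c, rc in realized:
        if exclude is not None and c is exclude:
            continue
        s_seq = rc.sequence(id="side-product")
        out.append(
            SideProduct(
                sequence=s_seq,
                composition=[f.provenance for f in rc.fragments],
                classification=classify_side_product(s_seq),
            )
        )
    return out


def _longest_linear(pool: list[StickyFragment], start: int) -> list[str]:
    """Greedy longest chain from the backbone fragment (diagnostic only)."""
    best: list[int] = []

    def walk(path: list[int], used: set[int], open_end: str):
        nonlocal best
        if len(path) > len(best):
            best = list(path)
        if len(path) > len(pool):
            return
        for j, f in enumerate(pool):
            if j in used or not f.is_sticky:
                continue
            if f.left_overhang == open_end:
                used.add(j)
                walk(path + [j], used, f.right_overhang)
                used.remove(j)

    walk([start], {start}, pool[start].right_overhang)
    return [pool[i].provenance for i in best]


# ---------------------------------------------------------------------------
# Protocol recommendation

#: Thermal program shared by all piece counts: cycled digestion/ligation
#: then ligase heat-kill and enzyme denaturation.
THERMAL_PROGRAM = (
    "(37C 3 min / 16C 4 min) x cycles, then 50C 5 min, 80C 5 min"
)


@dataclass(frozen=True)
class ProtocolRecommendation:
    ligase_units: int
    cycles: int
    thermal_program: str = THERMAL_PROGRAM


def recommend_protocol(n_fragments: int) -> ProtocolRecommendation:
    """Ligase amount and cycle count by piece number.

    Four-piece reactions assemble efficiently with 600 U of T4 ligase
    and 60 cycles; from five pieces up the optimized conditions are
    1,400 U and 120 cycles.
    """
    if not 2 <= n_fragments <= 10:
        raise ValidationError(f"fragment count {n_fragments} outside supported range 2-10")
    if n_fragments <= 4:
        return ProtocolRecommendation(600, 60)
    return ProtocolRecommendation(1400, 120)
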