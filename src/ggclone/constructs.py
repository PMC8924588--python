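"""Post-assembly operations on constructed plasmids.

An assembled plasmid is linearized with blunt-cutting SwaI to release
the integration cassette (selection marker plus transcription units) for
chromosomal transformation; colony PCR with a fixed verification primer
pair spans the assembled region; and used selection markers are recycled
either by Cre/loxP excision (leaving one loxP scar) or by 5-FOA-selected
recombination between the hisG repeats of a hisG-URA3-hisG marker.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from . import dna
from .dna import SWAI, Annotation, NucleotideSequence, StickyFragment, revcomp
from .errors import ExcisionError, GGCloneError, ValidationError

#: Verification primers targeting the vector body just outside the two
#: SwaI sites, 5'->3'.
DEFAULT_PRIMER_F = "TCTCCCCGCGCGTTGGCCGATT"
DEFAULT_PRIMER_R = "GTCTCGCGCGTTTCGGTGATG"

#: Canonical 34-nt loxP site (13-nt arm / 8-nt asymmetric spacer / arm).
LOXP = "ATAACTTCGTATAATGTATGCTATACGAAGTTAT"


@dataclass(frozen=True)
class PrimerPair:
    forward: str = DEFAULT_PRIMER_F
    reverse: str = DEFAULT_PRIMER_R

    def __post_init__(self) -> None:
        if not self.forward or not self.reverse:
            raise ValidationError("primers must be non-empty")


@dataclass
class Cassette:
    """SwaI-released blunt linear fragment: marker + transcription units."""

    sequence: NucleotideSequence

    def feature_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for a in self.sequence.annotations:
            counts[a.label] = counts.get(a.label, 0) + 1
        return counts


def extract_cassette(product_seq: NucleotideSequence) -> tuple[Cassette, StickyFragment]:
    """SwaI-digest an assembled plasmid into cassette + vector fragment.

    Requires exactly two SwaI sites; the fragment carrying the marker
    feature is the cassette, the other retains the resistance and origin
    placeholders.  Base content is conserved across the two fragments.
    """
    sites = dna.scan_sites(product_seq, SWAI)
    if len(sites) != 2:
        raise GGCloneError(
            f"cassette not excisable: {len(sites)} SwaI sites (need exactly 2)"
        )
    fragments = dna.digest(product_seq, SWAI)
    with_marker = [f for f in fragments if f.core.has_feature("marker")]
    if len(with_marker) != 1:
        raise GGCloneError(
            f"cassette not excisable: marker feature on {len(with_marker)} fragments"
        )
    cassette = with_marker[0]
    vector = next(f for f in fragments if f is not cassette)
    return Cassette(cassette.core), vector


@dataclass(frozen=True)
class Amplicon:
    start: int  # forward-primer 5' position on the template top strand
    end: int  # one past the reverse-primer 5' position (may wrap: end<=start on circles)
    length: int
    sequence: str


def in_silico_pcr(
    template: NucleotideSequence, primers: PrimerPair | None = None
) -> Optional[Amplicon]:
    """Exact-match PCR: shortest product with convergent primer 3' ends.

    The forward primer must match one strand and the reverse primer the
    other, 3' ends facing each other.  Circular templates are measured
    both ways around; both strand assignments of the pair are tried.
    Returns ``None`` when no such product exists.
    """
    primers = primers or PrimerPair()
    n = len(template.bases)
    if n == 0:
        return None
    top = template.bases + (template.bases if template.is_circular else "")

    def occurrences(motif: str) -> list[int]:
        out = []
        i = top.find(motif)
        while i != -1:
            if i < n:
                out.append(i)
            i = top.find(motif, i + 1)
        return out

    best: Optional[Amplicon] = None
    for fwd, rev in ((primers.forward, primers.reverse), (primers.reverse, primers.forward)):
        f_hits = occurrences(fwd)  # primer along the top strand, extends rightwards
        r_hits = occurrences(revcomp(rev))  # reverse primer site on top strand
        for f in f_hits:
            for r in r_hits:
                prod_end = r + len(rev)
                if template.is_circular:
                    length = (prod_end - f) % n or n
                else:
                    if prod_end <= f or r < f:
                        continue
                    length = prod_end - f
                if length < len(fwd) + len(rev):
                    continue  # primers overlap; no room for convergent 3' ends
                seq = top[f : f + length] if f + length <= len(top) else ""
                amp = Amplicon(f, (f + length) % n if template.is_circular else prod_end, length, seq)
                if best is None or amp.length < best.length:
                    best = amp
    return best


# ---------------------------------------------------------------------------
# Marker recycling


def _motif_hits(bases: str, motif: str) -> list[tuple[int, int]]:
    """(position, strand) of motif on either strand of a linear string."""
    hits = [(p, 1) for p in _all(bases, motif)]
    rc = revcomp(motif)
    if rc != motif:
        hits += [(p, -1) for p in _all(bases, rc)]
    return sorted(hits)


def _all(s: str, m: str) -> list[int]:
    out, i = [], s.find(m)
    while i != -1:
        out.append(i)
        i = s.find(m, i + 1)
    return out


def cre_excise(seq: NucleotideSequence, loxp: str = LOXP) -> NucleotideSequence:
    """Cre recombination between the first direct-orientation loxP pair.

    The region between the pair is removed together with one loxP copy,
    so exactly one loxP scar remains; the output length is shorter by
    (inter-loxP distance + one loxP length).  Inverted pairs are not
    modelled and raise.
    """
    hits = _motif_hits(seq.bases, loxp)
    pair = None
    for i, (p1, s1) in enumerate(hits):
        for p2, s2 in hits[i + 1 :]:
            if s1 == s2:
                pair = ((p1, s1), (p2, s2))
                break
        if pair:
            break
    if pair is None:
        if len(hits) >= 2:
            raise ExcisionError("nothing to excise: loxP sites are inverted, not direct")
        raise ExcisionError("nothing to excise: fewer than 2 direct loxP sites")
    (p1, _), (p2, _) = pair
    cut1, cut2 = p1 + len(loxp), p2 + len(loxp)
    bases = seq.bases[:cut1] + seq.bases[cut2:]
    anns = _shift_annotations(seq.annotations, cut1, cut2)
    return NucleotideSequence(bases, seq.topology, anns, seq.id)


def hisG_popout(seq: NucleotideSequence) -> NucleotideSequence:
    """Collapse a hisG-URA3-hisG locus to a single hisG copy.

    Homologous recombination between the two identical direct hisG
    repeats (selected on 5-FOA) deletes URA3 and one repeat.  Repeats
    and the URA3 feature are located via annotations; the two repeat
    sequences must be identical.
    """
    hisg = sorted(seq.features("hisG"), key=lambda a: a.start)
    ura3 = seq.features("URA3")
    if len(hisg) < 2:
        raise ExcisionError("nothing to excise: fewer than two hisG repeats")
    a, b = hisg[0], hisg[1]
    if seq.fetch(a.start, a.end) != seq.fetch(b.start, b.end) or a.strand != b.strand:
        raise ExcisionError("hisG repeats are not identical direct repeats")
    flanked = [u for u in ura3 if a.end <= u.start and u.end <= b.start]
    if not flanked:
        raise ExcisionError("no URA3 feature between the hisG repeats")
    bases = seq.bases[: a.end] + seq.bases[b.end :]
    anns = _shift_annotations(seq.annotations, a.end, b.end)
    return NucleotideSequence(bases, seq.topology, anns, seq.id)


def _shift_annotations(anns: list[Annotation], cut1: int, cut2: int) -> list[Annotation]:
    """Drop features overlapping the deleted [cut1, cut2); shift the rest."""
    removed = cut2 - cut1
    out = []
    for a in anns:
        if a.end <= cut1:
            out.append(a)
        elif a.start >= cut2:
            out.append(Annotation(a.label, a.start - removed, a.end - removed, a.strand))
    return out
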