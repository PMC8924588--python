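"""Double-stranded DNA model with exact type IIS restriction geometry.

Sequences are stored as their top strand, 5'->3', over the unambiguous
alphabet {A, C, G, T}.  Coordinates are 0-based half-open on the top
strand; on circular molecules positions are reduced modulo the length, so
features and cut windows may wrap the origin.

The cut geometry implemented here is the standard one for BsaI-class
enzymes: the recognition sequence is asymmetric, the enzyme cuts outside
it after a spacer, and the staggered cut leaves a 4-nt 5' overhang.  For
a site on the plus strand at recognition start ``p``::

    top_cut    = p + len(recognition) + spacer
    bottom_cut = top_cut + overhang_len

and mirrored for minus-strand sites.  Sticky ends are normalized to the
top-strand reading of the 4-nt window between the two cuts, so two ends
are ligation-compatible exactly when their normalized strings are equal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from Bio.Seq import Seq

from .errors import EntangledCutError, FrameError, ValidationError

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID_BASES = frozenset("ACGT")


def _check_bases(bases: str) -> None:
    for i, b in enumerate(bases):
        if b not in _VALID_BASES:
            raise ValidationError(
                f"invalid base {b!r} at position {i}; only A/C/G/T accepted"
            )


def revcomp(bases: str) -> str:
    """Reverse complement of a bare top-strand string."""
    _check_bases(bases)
    return bases.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Annotation:
    """A labelled feature on the top strand, 0-based half-open.

    On circular molecules ``end`` may exceed the sequence length to
    denote an origin-spanning feature; it is interpreted modulo length.
    """

    label: str
    start: int
    end: int
    strand: int = 1

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class NucleotideSequence:
    """A linear or circular double-stranded DNA molecule."""

    bases: str
    topology: str = "linear"
    annotations: list[Annotation] = field(default_factory=list)
    id: str = ""

    def __post_init__(self) -> None:
        _check_bases(self.bases)
        if self.topology not in ("linear", "circular"):
            raise ValidationError(f"unknown topology {self.topology!r}")
        n = len(self.bases)
        for a in self.annotations:
            if n == 0 or a.start < 0 or a.start >= n or a.end <= a.start:
                raise ValidationError(f"annotation {a.label!r} out of range")
            if a.end > n and self.topology != "circular":
                raise ValidationError(
                    f"annotation {a.label!r} wraps a linear sequence"
                )

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def fetch(self, start: int, end: int) -> str:
        """Top-strand slice [start, end); on circles wraps the origin."""
        n = len(self.bases)
        if end < start:
            raise ValidationError("fetch end before start")
        if not self.is_circular:
            if start < 0 or end > n:
                raise ValidationError("slice outside linear sequence")
            return self.bases[start:end]
        if end - start > n:
            raise ValidationError("slice longer than the circle")
        start %= n
        doubled = self.bases + self.bases
        return doubled[start : start + (end - start)] if n else ""

    def rotated(self, offset: int) -> "NucleotideSequence":
        """Circular rotation placing old position ``offset`` at index 0."""
        if not self.is_circular:
            raise ValidationError("only circular sequences can be rotated")
        n = len(self.bases)
        offset %= n
        bases = self.bases[offset:] + self.bases[:offset]
        anns = [
            replace(a, start=(a.start - offset) % n, end=(a.start - offset) % n + a.length)
            for a in self.annotations
        ]
        return NucleotideSequence(bases, "circular", anns, self.id)

    def features(self, label: str) -> list[Annotation]:
        return [a for a in self.annotations if a.label == label]

    def has_feature(self, label: str) -> bool:
        return any(a.label == label for a in self.annotations)


def reverse_complement(seq: NucleotideSequence) -> NucleotideSequence:
    """Watson-Crick reverse complement; topology preserved.

    Annotations are carried over to their mirrored coordinates with
    strand flipped (wrap-around features are dropped: their mirrored
    coordinates are ambiguous without a chosen origin).
    """
    n = len(seq.bases)
    bases = str(Seq(seq.bases).reverse_complement())
    anns = [
        Annotation(a.label, n - a.end, n - a.start, -a.strand)
        for a in seq.annotations
        if a.end <= n
    ]
    return NucleotideSequence(bases, seq.topology, anns, seq.id)


# ---------------------------------------------------------------------------
# Enzymes and cut sites


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction enzyme: type IIS (offset sticky cutter) or blunt.

    ``spacer``/``overhang_len`` apply to type IIS enzymes; ``cut_offset``
    (cut position relative to recognition start, both strands) applies to
    blunt enzymes, whose recognition must be palindromic.
    """

    name: str
    recognition: str
    kind: str  # "typeIIS" | "blunt"
    spacer: int = 0
    overhang_len: int = 0
    cut_offset: int = 0

    def __post_init__(self) -> None:
        _check_bases(self.recognition)
        if self.kind not in ("typeIIS", "blunt"):
            raise ValidationError(f"unknown enzyme kind {self.kind!r}")
        if self.kind == "blunt" and revcomp(self.recognition) != self.recognition:
            raise ValidationError(
                f"{self.name}: blunt symmetric cutter must have palindromic recognition"
            )

    @property
    def is_palindromic(self) -> bool:
        return revcomp(self.recognition) == self.recognition


BSAI = EnzymeSpec("BsaI", "GGTCTC", "typeIIS", spacer=1, overhang_len=4)
SWAI = EnzymeSpec("SwaI", "ATTTAAAT", "blunt", cut_offset=4)


@dataclass(frozen=True)
class CutSite:
    """One enzyme binding event with its absolute cut coordinates.

    ``top_cut``/``bottom_cut`` bracket the overhang window
    ``[top_cut, bottom_cut)``; for blunt cuts the window is empty.
    Coordinates on circular molecules are reduced modulo length and may
    therefore wrap (``top_cut`` close to the end, ``bottom_cut`` small).
    """

    enzyme: str
    position: int
    strand: int
    top_cut: int
    bottom_cut: int


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    i = haystack.find(needle)
    while i != -1:
        yield i
        i = haystack.find(needle, i + 1)


def scan_sites(seq: NucleotideSequence, enzyme: EnzymeSpec) -> list[CutSite]:
    """All recognition-site occurrences on either strand, sorted by position.

    Minus-strand occurrences are located by searching the reverse
    complement of the recognition on the top strand.  On circular
    molecules, occurrences spanning the origin are found by scanning the
    doubled sequence and reducing positions modulo length.
    """
    n = len(seq.bases)
    k = len(enzyme.recognition)
    if n == 0 or k == 0 or (not seq.is_circular and n < k):
        return []

    if seq.is_circular:
        search = seq.bases + seq.bases[: k - 1]
    else:
        search = seq.bases

    sites: list[CutSite] = []
    motifs = [(enzyme.recognition, 1)]
    if not enzyme.is_palindromic:
        motifs.append((revcomp(enzyme.recognition), -1))

    for motif, strand in motifs:
        for pos in _find_all(search, motif):
            p = pos % n if seq.is_circular else pos
            if enzyme.kind == "typeIIS":
                if strand == 1:
                    top = p + k + enzyme.spacer
                    bottom = top + enzyme.overhang_len
                else:
                    top = p - enzyme.spacer - enzyme.overhang_len
                    bottom = p - enzyme.spacer
            else:
                top = bottom = p + enzyme.cut_offset
            if seq.is_circular:
                shift = top - (top % n)
                top, bottom = top - shift, bottom - shift
            sites.append(CutSite(enzyme.name, p, strand, top, bottom))

    sites.sort(key=lambda s: (s.position, -s.strand))
    return sites


# ---------------------------------------------------------------------------
# Sticky fragments and digestion


@dataclass
class StickyFragment:
    """A linear dsDNA fragment with normalized 5' sticky (or blunt) ends.

    ``core`` is the top strand from the start of the left overhang window
    to the end of the right one, so each overhang string is also the
    first/last 4 nt of ``core``.  Overhangs are normalized to the
    top-strand 5'->3' reading of the cut window; two ends ligate exactly
    when their normalized strings are equal.  Empty string means blunt.
    """

    core: NucleotideSequence
    left_overhang: str = ""
    right_overhang: str = ""
    provenance: str = ""
    uncut: bool = False

    def __post_init__(self) -> None:
        for ov, side in ((self.left_overhang, "left"), (self.right_overhang, "right")):
            if ov:
                _check_bases(ov)
        if self.left_overhang and not self.core.bases.startswith(self.left_overhang):
            raise ValidationError("left overhang is not a prefix of the core")
        if self.right_overhang and not self.core.bases.endswith(self.right_overhang):
            raise ValidationError("right overhang is not a suffix of the core")

    def __len__(self) -> int:
        return len(self.core)

    @property
    def is_sticky(self) -> bool:
        return bool(self.left_overhang or self.right_overhang)

    def flipped(self) -> "StickyFragment":
        """The same physical molecule read from the other strand."""
        return StickyFragment(
            core=reverse_complement(self.core),
            left_overhang=revcomp(self.right_overhang) if self.right_overhang else "",
            right_overhang=revcomp(self.left_overhang) if self.left_overhang else "",
            provenance=self.provenance,
            uncut=self.uncut,
        )


def _extract_fragment(
    seq: NucleotideSequence,
    start: int,
    end: int,
    left_ov: str,
    right_ov: str,
    idx: int,
) -> StickyFragment:
    """Fragment spanning top-strand [start, end); end may wrap on circles."""
    n = len(seq.bases)
    if seq.is_circular:
        span = end - start if end > start else end + n - start
        doubled = seq.bases + seq.bases
        bases = doubled[start : start + span]
    else:
        span = end - start
        bases = seq.bases[start:end]
    anns = []
    for a in seq.annotations:
        a_start = a.start
        if seq.is_circular:
            rel = (a_start - start) % n
        else:
            rel = a_start - start
        if 0 <= rel and rel + a.length <= span:
            anns.append(Annotation(a.label, rel, rel + a.length, a.strand))
    frag_id = f"{seq.id}/frag{idx}" if seq.id else f"frag{idx}"
    core = NucleotideSequence(bases, "linear", anns, frag_id)
    return StickyFragment(core, left_ov, right_ov, provenance=seq.id or frag_id)


def digest(seq: NucleotideSequence, enzyme: EnzymeSpec) -> list[StickyFragment]:
    """Cut at every site; fragments carry normalized sticky ends.

    A circular parent with n sites yields n fragments, a linear parent
    n+1.  Base content is conserved: concatenating fragments in order,
    counting each shared overhang window once, reproduces the parent.  A
    circular parent with zero sites is returned intact, flagged
    ``uncut``.  Overlapping cut windows raise :class:`EntangledCutError`.
    """
    n = len(seq.bases)
    sites = scan_sites(seq, enzyme)

    if not seq.is_circular:
        # Sites whose cut window leaves the molecule cannot be cleaved.
        sites = [s for s in sites if 0 <= s.top_cut and s.bottom_cut <= n]

    if not sites:
        whole = NucleotideSequence(seq.bases, seq.topology, list(seq.annotations), seq.id)
        return [StickyFragment(whole, "", "", provenance=seq.id, uncut=True)]

    windows = sorted((s.top_cut, s.bottom_cut) for s in sites)
    # Wrapping windows (bottom < top) are split for the overlap check.
    flat: list[tuple[int, int]] = []
    for t, b in windows:
        if b >= t:
            flat.append((t, b))
        else:
            flat.append((t, n))
            flat.append((0, b))
    flat.sort()
    for (t1, b1), (t2, b2) in zip(flat, flat[1:]):
        if t2 < b1:
            raise EntangledCutError(
                f"entangled cut: windows [{t1},{b1}) and [{t2},{b2}) overlap"
            )
    if seq.is_circular and len(flat) > 1 and flat[0][0] < (flat[-1][1] % n) and flat[-1][1] > n:
        raise EntangledCutError("entangled cut: windows overlap across the origin")

    def window_seq(t: int, b: int) -> str:
        if b >= t:
            return seq.fetch(t, b) if b > t else ""
        return seq.bases[t:] + seq.bases[:b]

    frags: list[StickyFragment] = []
    if seq.is_circular:
        # Fragment i runs from the start of window i to the end of
        # window i+1 (so both cut windows are included once each).
        for i, (t, b) in enumerate(windows):
            t2, b2 = windows[(i + 1) % len(windows)]
            left = window_seq(t, b)
            right = window_seq(t2, b2)
            end_abs = t2 + (b2 - t2 if b2 >= t2 else b2 + n - t2)
            if end_abs <= t:
                end_abs += n
            frags.append(_extract_fragment(seq, t, end_abs, left, right, i))
    else:
        bounds = [(0, 0)] + windows + [(n, n)]
        for i in range(len(bounds) - 1):
            t, b = bounds[i]
            t2, b2 = bounds[i + 1]
            left = seq.bases[t:b]
            right = seq.bases[t2:b2]
            frags.append(_extract_fragment(seq, t, b2, left, right, i))
    return frags


def ligate(fragments: list[StickyFragment], circular: bool = True, id: str = "") -> NucleotideSequence:
    """Join fragments in order, merging each shared overhang window once.

    Adjacent ends (and, for a circle, the last/first pair) must carry
    equal normalized overhangs; blunt-blunt junctions are also accepted.
    """
    if not fragments:
        raise ValidationError("nothing to ligate")
    parts: list[str] = []
    anns: list[Annotation] = []
    offset = 0
    for i, frag in enumerate(fragments):
        if i == 0:
            chunk = frag.core.bases
            skip = 0
        else:
            prev = fragments[i - 1]
            if prev.right_overhang != frag.left_overhang:
                raise ValidationError(
                    f"incompatible junction at fragment {i}: "
                    f"{prev.right_overhang!r} vs {frag.left_overhang!r}"
                )
            skip = len(frag.left_overhang)
            chunk = frag.core.bases[skip:]
        for a in frag.core.annotations:
            anns.append(Annotation(a.label, a.start + offset - skip, a.end + offset - skip, a.strand))
        parts.append(chunk)
        offset += len(chunk)
    if circular:
        last, first = fragments[-1], fragments[0]
        if last.right_overhang != first.left_overhang:
            raise ValidationError("ends do not close: incompatible terminal overhangs")
        trim = len(last.right_overhang)
        seq_str = "".join(parts)
        if trim:
            seq_str = seq_str[:-trim]
        n = len(seq_str)
        wrapped = [
            Annotation(a.label, a.start % n, a.start % n + a.length, a.strand)
            for a in anns
        ]
        return NucleotideSequence(seq_str, "circular", wrapped, id)
    return NucleotideSequence("".join(parts), "linear", anns, id)


# ---------------------------------------------------------------------------
# Translation

_STANDARD_TABLE: dict[str, str] = {}


def _codon_table() -> dict[str, str]:
    if not _STANDARD_TABLE:
        from Bio.Data import CodonTable

        std = CodonTable.unambiguous_dna_by_id[1]
        _STANDARD_TABLE.update(std.forward_table)
        for stop in std.stop_codons:
            _STANDARD_TABLE[stop] = "*"
    return _STANDARD_TABLE


def translate(cds: NucleotideSequence | str) -> str:
    """Standard-code translation; stops rendered as '*'."""
    bases = cds.bases if isinstance(cds, NucleotideSequence) else cds
    _check_bases(bases)
    if len(bases) % 3 != 0:
        raise FrameError(f"CDS length {len(bases)} is not a multiple of 3")
    table = _codon_table()
    return "".join(table[bases[i : i + 3]] for i in range(0, len(bases), 3))
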