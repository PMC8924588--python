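"""Codon-preserving removal of internal assembly-enzyme sites.

Internal BsaI or SwaI recognition sites inside a coding building block
would be cut during assembly, so they are *domesticated*: a synonymous
codon substitution destroys the motif without changing the protein.
Non-coding parts (promoters, terminators, vector backbones) are only
flagged — an automatic edit could silently change their function.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from . import dna
from .dna import BSAI, SWAI, EnzymeSpec, NucleotideSequence, revcomp, translate
from .errors import FrameError, UndomesticatableSite

DEFAULT_FORBIDDEN: tuple[str, ...] = (
    BSAI.recognition,
    revcomp(BSAI.recognition),
    SWAI.recognition,  # palindromic; one strand suffices
)


@dataclass(frozen=True)
class DomesticationEdit:
    codon_index: int
    old_codon: str
    new_codon: str
    motif_removed: str
    position: int  # motif start in the unedited-at-that-step sequence


@dataclass
class DomesticationResult:
    sequence: NucleotideSequence
    edits: list[DomesticationEdit] = field(default_factory=list)
    residual_flags: list[int] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not self.residual_flags


def _synonyms() -> dict[str, list[str]]:
    table = dna._codon_table()
    by_aa: dict[str, list[str]] = {}
    for codon, aa in table.items():
        by_aa.setdefault(aa, []).append(codon)
    return {codon: sorted(by_aa[aa]) for codon, aa in table.items()}


_SYNONYMS: dict[str, list[str]] = {}


def _find_motifs(bases: str, motifs: Sequence[str]) -> list[tuple[int, str]]:
    hits = []
    for m in motifs:
        start = bases.find(m)
        while start != -1:
            hits.append((start, m))
            start = bases.find(m, start + 1)
    return sorted(hits)


def flag_noncoding_sites(
    seq: NucleotideSequence, forbidden_motifs: Sequence[str] = DEFAULT_FORBIDDEN
) -> list[int]:
    """Positions of forbidden motifs; no edits are applied.

    On circular sequences origin-spanning occurrences are reported with
    their start reduced modulo length.
    """
    n = len(seq.bases)
    if n == 0:
        return []
    search = seq.bases
    if seq.is_circular:
        k = max((len(m) for m in forbidden_motifs), default=1)
        search = seq.bases + seq.bases[: k - 1]
    positions = sorted({p % n if seq.is_circular else p for p, _ in _find_motifs(search, forbidden_motifs)})
    return positions


def domesticate_cds(
    cds: NucleotideSequence | str,
    forbidden_motifs: Sequence[str] = DEFAULT_FORBIDDEN,
    rescan_window: int = 10,
) -> DomesticationResult:
    """Destroy every forbidden motif by minimal synonymous codon edits.

    For each motif occurrence, every codon it overlaps is tried with
    every synonymous replacement; among replacements that (1) destroy
    the motif and (2) create no new forbidden motif within +-``rescan_window``
    nt of the edit, the one changing the fewest bases wins, ties broken
    by lexicographically smallest new codon.  The loop repeats until a
    full-sequence scan is clean; the result is a fixed point of this
    procedure.  Raises :class:`UndomesticatableSite` if some occurrence
    admits no valid substitution.
    """
    if isinstance(cds, NucleotideSequence):
        bases, seq_id = cds.bases, cds.id
    else:
        bases, seq_id = cds, ""
    if len(bases) % 3 != 0:
        raise FrameError(f"CDS length {len(bases)} is not a multiple of 3")
    global _SYNONYMS
    if not _SYNONYMS:
        _SYNONYMS = _synonyms()

    edits: list[DomesticationEdit] = []
    guard = 0
    while True:
        hits = _find_motifs(bases, forbidden_motifs)
        if not hits:
            break
        guard += 1
        if guard > len(bases):
            raise UndomesticatableSite("domestication did not converge", hits[0][0])
        pos, motif = hits[0]
        bases, edit = _fix_one(bases, pos, motif, forbidden_motifs, rescan_window)
        edits.append(edit)

    out = NucleotideSequence(bases, "linear", id=seq_id)
    return DomesticationResult(out, edits, residual_flags=[])


def _fix_one(
    bases: str,
    pos: int,
    motif: str,
    forbidden: Sequence[str],
    window: int,
) -> tuple[str, DomesticationEdit]:
    first_codon = pos // 3
    last_codon = (pos + len(motif) - 1) // 3
    candidates: list[tuple[int, str, int, str]] = []  # (n_changes, new_codon, codon_idx, edited)
    for ci in range(first_codon, last_codon + 1):
        old = bases[ci * 3 : ci * 3 + 3]
        for new in _SYNONYMS[old]:
            if new == old:
                continue
            edited = bases[: ci * 3] + new + bases[ci * 3 + 3 :]
            if edited[pos : pos + len(motif)] == motif:
                continue  # motif survives
            lo = max(0, ci * 3 - window)
            hi = min(len(edited), ci * 3 + 3 + window)
            before = {(lo + p, m) for p, m in _find_motifs(bases[lo:hi], forbidden)}
            after = {(lo + p, m) for p, m in _find_motifs(edited[lo:hi], forbidden)}
            if (pos, motif) in after or not after <= before:
                continue  # target survives shifted, or a new motif appeared
            n_changes = sum(a != b for a, b in zip(old, new))
            candidates.append((n_changes, new, ci, edited))
    if not candidates:
        raise UndomesticatableSite(
            f"undomesticatable site: no synonymous edit removes {motif} at {pos}", pos
        )
    n_changes, new, ci, edited = min(candidates, key=lambda c: (c[0], c[1]))
    old = bases[ci * 3 : ci * 3 + 3]
    return edited, DomesticationEdit(ci, old, new, motif, pos)
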