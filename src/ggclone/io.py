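"""FASTA / GenBank round-tripping for annotated sequences.

GenBank is the canonical annotated output (features carry part and
junction labels; circular topology is recorded in the locus line);
FASTA is used for bare sequences.  File dates are pinned to a sentinel
so outputs are byte-reproducible.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .dna import Annotation, NucleotideSequence

_SENTINEL_DATE = "01-JAN-2000"


def to_seqrecord(seq: NucleotideSequence, description: str = "") -> SeqRecord:
    rec = SeqRecord(Seq(seq.bases), id=seq.id or "sequence", description=description)
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if seq.is_circular else "linear"
    rec.annotations["date"] = _SENTINEL_DATE
    n = len(seq.bases)
    for a in seq.annotations:
        if a.end <= n:
            loc = FeatureLocation(a.start, a.end, strand=a.strand)
        else:  # origin-spanning feature on a circle
            loc = FeatureLocation(a.start, n, strand=a.strand) + FeatureLocation(
                0, a.end - n, strand=a.strand
            )
        rec.features.append(
            SeqFeature(loc, type="misc_feature", qualifiers={"label": [a.label]})
        )
    return rec


def from_seqrecord(rec: SeqRecord) -> NucleotideSequence:
    topology = rec.annotations.get("topology", "linear")
    anns = []
    for f in rec.features:
        label = f.qualifiers.get("label", [f.type])[0]
        parts = f.location.parts if hasattr(f.location, "parts") else [f.location]
        start = int(parts[0].start)
        length = sum(int(p.end) - int(p.start) for p in parts)
        anns.append(Annotation(label, start, start + length, f.location.strand or 1))
    return NucleotideSequence(str(rec.seq).upper(), topology, anns, rec.id)


def write_genbank(seqs: NucleotideSequence | Iterable[NucleotideSequence], path: str | Path) -> None:
    if isinstance(seqs, NucleotideSequence):
        seqs = [seqs]
    SeqIO.write([to_seqrecord(s) for s in seqs], str(path), "genbank")


def read_genbank(path: str | Path) -> dict[str, NucleotideSequence]:
    return {r.id: from_seqrecord(r) for r in SeqIO.parse(str(path), "genbank")}


def write_fasta(seqs: NucleotideSequence | Iterable[NucleotideSequence], path: str | Path) -> None:
    if isinstance(seqs, NucleotideSequence):
        seqs = [seqs]
    SeqIO.write([to_seqrecord(s) for s in seqs], str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, NucleotideSequence]:
    out = {}
    for r in SeqIO.parse(str(path), "fasta"):
        out[r.id] = NucleotideSequence(str(r.seq).upper(), "linear", [], r.id)
    return out
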