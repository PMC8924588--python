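"""Seeded synthetic toolkit generation.

The wet-lab toolkit's part and backbone sequences are not bundled with
the package, so the simulator ships a generator that builds a fully
synthetic but structurally faithful toolkit from a seed: 8 promoters, 9
terminators, 9 coding genes (the 8 mevalonate-pathway genes plus the
bisabolol synthase stand-in MrBBS), 6 selection markers (five
loxP-flanked, one hisG-URA3-hisG), and the three destination backbones
with lacZ stuffer, kanamycin-resistance and origin placeholders and two
SwaI sites flanking the assembly region.  Placeholder features carry
real feature labels but random sequence content — only their positions
and freedom from assembly-enzyme sites matter to the simulation.

Every generated sequence is a pure function of the seed.  Parts are
guaranteed free of BsaI/SwaI sites even when read together with any
fusion window of the default table, so assembled products can never
contain a recognition site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import dna
from .constructs import DEFAULT_PRIMER_F, DEFAULT_PRIMER_R, LOXP
from .dna import BSAI, SWAI, Annotation, NucleotideSequence, revcomp
from .domesticate import DEFAULT_FORBIDDEN, domesticate_cds
from .errors import GGCloneError, ValidationError
from .registry import (
    DEFAULT_OVERHANGS,
    BackbonePlasmid,
    Part,
    RegistryCatalog,
    validate_part,
)

PROMOTERS = ("P_GPD", "P_GPDin", "P_EXP", "P_TEF", "P_TEFin", "P_ILV5", "P_FBAin", "P_YAT")
TERMINATORS = (
    "T_Mig1", "T_Lip1", "T_Lip2", "T_ScCYC1", "T_YlCYC1", "T_TEF", "T_POT1", "T_Aco3", "T_XPR2",
)
MVA_GENES = ("tHMG1", "IDI", "ERG8", "ERG10", "ERG12", "ERG13", "ERG19", "ERG20")
EXTRA_GENES = ("MrBBS",)  # terpene synthase stand-in
LOXP_MARKERS = ("LEU2", "HPH", "NEO", "URA3", "DsdA")
HISG_MARKER = "HUH"


@dataclass
class FixtureConfig:
    """Seed plus length/composition bounds for generated parts (nt)."""

    seed: int = 0
    promoter_len: tuple[int, int] = (300, 800)
    cds_len: tuple[int, int] = (600, 1800)
    terminator_len: tuple[int, int] = (100, 300)
    marker_len: tuple[int, int] = (1000, 2000)
    stuffer_len: int = 500
    gc_bounds: tuple[float, float] = (0.30, 0.70)
    overhang_table: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_OVERHANGS))
    max_retries: int = 200


_BASES = np.array(list("ACGT"))


def _rng(config: FixtureConfig, stream: str) -> np.random.Generator:
    # independent deterministic substream per component; crc32 keeps the
    # stream label -> seed mapping stable across processes
    import zlib

    h = zlib.crc32(stream.encode()) % (2**31)
    return np.random.default_rng([config.seed % (2**31), h])


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _gc(s: str) -> float:
    return (s.count("G") + s.count("C")) / len(s) if s else 0.0


def _scan_clean(bases: str) -> bool:
    return not any(m in bases for m in DEFAULT_FORBIDDEN)


def _ends_clean(insert: str, table: dict[int, str]) -> bool:
    """No forbidden motif can be completed by any fusion window abutting
    either end of the insert (checked for every table entry, so the part
    stays valid under slot relabelling)."""
    head, tail = insert[:10], insert[-10:]
    for w in table.values():
        if not _scan_clean(w + head) or not _scan_clean(tail + w):
            return False
    return True


def _clean_random(
    rng: np.random.Generator,
    n: int,
    config: FixtureConfig,
    check_ends: bool = True,
) -> str:
    """Random sequence free of forbidden motifs, GC within bounds."""
    lo, hi = config.gc_bounds
    for _ in range(config.max_retries):
        s = _random_bases(rng, n)
        if not lo <= _gc(s) <= hi:
            continue
        if not _scan_clean(s):
            continue
        if check_ends and not _ends_clean(s, config.overhang_table):
            continue
        return s
    raise GGCloneError(f"could not generate a clean {n}-nt sequence within retry limit")


def _random_cds(rng: np.random.Generator, n_codons: int, config: FixtureConfig) -> str:
    """Random CDS: ATG start, random internal codons, one stop; any
    leftover forbidden motif is removed by synonymous domestication."""
    from .dna import _codon_table

    table = _codon_table()
    internal = [c for c, aa in table.items() if aa != "*" and c != "ATG"]
    stops = sorted(c for c, aa in table.items() if aa == "*")
    for _ in range(config.max_retries):
        body = "".join(
            internal[i] for i in rng.integers(0, len(internal), size=n_codons - 2)
        )
        cds = "ATG" + body + stops[int(rng.integers(0, len(stops)))]
        try:
            cds = domesticate_cds(cds).sequence.bases
        except GGCloneError:
            continue
        if _ends_clean(cds, config.overhang_table) and _scan_clean(cds):
            return cds
    raise GGCloneError("could not generate a clean CDS within retry limit")


def gen_random_part(
    role: str,
    labels: tuple[int, int],
    config: FixtureConfig,
    name: Optional[str] = None,
    recycling: Optional[str] = None,
) -> Part:
    """One seeded synthetic part of the given role and fusion labels.

    The same (config.seed, role, name) always yields the same sequence.
    The result is guaranteed to pass :func:`~ggclone.registry.validate_part`.
    """
    name = name or f"{role}-part"
    rng = _rng(config, f"part/{role}/{name}")
    if role == "promoter":
        lo, hi = config.promoter_len
        insert = _make_plain(rng, int(rng.integers(lo, hi + 1)), config, name)
    elif role == "terminator":
        lo, hi = config.terminator_len
        insert = _make_plain(rng, int(rng.integers(lo, hi + 1)), config, name)
    elif role == "cds":
        lo, hi = config.cds_len
        n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
        bases = _random_cds(rng, n_codons, config)
        insert = NucleotideSequence(bases, "linear", [Annotation(name, 0, len(bases))], name)
    elif role == "marker":
        insert = _make_marker(rng, config, name, recycling)
    elif role == "stuffer":
        insert = _make_plain(rng, config.stuffer_len, config, name)
    else:
        raise ValidationError(f"unknown role {role!r}")

    part = Part(name, role, insert, labels[0], labels[1], recycling=recycling)
    report = validate_part(part, config.overhang_table)
    if not report.ok:
        raise GGCloneError(f"generated part failed validation: {report.violations}")
    return part


def _make_plain(rng, n: int, config: FixtureConfig, name: str) -> NucleotideSequence:
    bases = _clean_random(rng, n, config)
    return NucleotideSequence(bases, "linear", [Annotation(name, 0, n)], name)


def _make_marker(rng, config: FixtureConfig, name: str, recycling: Optional[str]) -> NucleotideSequence:
    lo, hi = config.marker_len
    total = int(rng.integers(lo, hi + 1))
    if recycling == "hisG":
        # hisG-URA3-hisG: two identical direct repeats around URA3
        hisg_len = 300
        ura_len = max(60, total - 2 * hisg_len)
        for _ in range(config.max_retries):
            hisg = _clean_random(rng, hisg_len, config, check_ends=False)
            ura = _clean_random(rng, ura_len, config, check_ends=False)
            bases = hisg + ura + hisg
            if _scan_clean(bases) and _ends_clean(bases, config.overhang_table):
                break
        else:
            raise GGCloneError("could not build a clean hisG-URA3-hisG marker")
        anns = [
            Annotation("hisG", 0, hisg_len),
            Annotation("URA3", hisg_len, hisg_len + ura_len),
            Annotation("hisG", hisg_len + ura_len, len(bases)),
            Annotation(name, 0, len(bases)),
        ]
        return NucleotideSequence(bases, "linear", anns, name)
    if recycling == "loxP":
        core_len = max(60, total - 2 * len(LOXP))
        for _ in range(config.max_retries):
            core = _clean_random(rng, core_len, config, check_ends=False)
            bases = LOXP + core + LOXP
            if _scan_clean(bases) and _ends_clean(bases, config.overhang_table):
                break
        else:
            raise GGCloneError("could not build a clean loxP-flanked marker")
        anns = [
            Annotation("loxP", 0, len(LOXP)),
            Annotation(name, len(LOXP), len(LOXP) + core_len),
            Annotation("loxP", len(LOXP) + core_len, len(bases)),
        ]
        return NucleotideSequence(bases, "linear", anns, name)
    bases = _clean_random(rng, total, config)
    return NucleotideSequence(bases, "linear", [Annotation(name, 0, total)], name)


# ---------------------------------------------------------------------------
# Backbones


def gen_backbone(backbone_id: str, config: FixtureConfig) -> BackbonePlasmid:
    """Destination vector for one of pGGYL1/2/3.

    Circular layout from the origin: SwaI site, reverse-primer landing
    site, ori and kanR placeholders, forward-primer landing site, SwaI
    site, junction-1 fusion window, lacZ stuffer between two
    inward-facing BsaI recognitions, closing fusion window.
    """
    from .registry import backbone_junction_labels

    table = config.overhang_table
    j_open, j_close = backbone_junction_labels(backbone_id)
    w1, wc = table[j_open], table[j_close]
    rng = _rng(config, f"backbone/{backbone_id}")

    swa = SWAI.recognition
    rc_r = revcomp(DEFAULT_PRIMER_R)
    rec, rec_rc = BSAI.recognition, revcomp(BSAI.recognition)

    for _ in range(config.max_retries):
        pad1 = _clean_random(rng, 40, config, check_ends=False)
        ori = _clean_random(rng, 400, config, check_ends=False)
        kanr = _clean_random(rng, 800, config, check_ends=False)
        pad2 = _clean_random(rng, 40, config, check_ends=False)
        stuffer = _clean_random(rng, config.stuffer_len, config, check_ends=False)

        pieces = [
            ("swa_b", swa),
            ("primer_R_site", rc_r + "T"),  # pad keeps GAGAC from extending
            ("pad1", pad1),
            ("ori", ori),
            ("kanR", kanr),
            ("pad2", pad2),
            ("primer_F_site", DEFAULT_PRIMER_F),
            ("swa_a", swa),
            ("w1", w1),
            ("spacer_a", "A"),
            ("bsa_minus", rec_rc),
            ("lacZ_stuffer", stuffer),
            ("bsa_plus", rec),
            ("spacer_b", "A"),
            ("wclose", wc),
        ]
        bases = "".join(p for _, p in pieces)
        seq = NucleotideSequence(bases, "circular", [], backbone_id)
        n_bsa = len(dna.scan_sites(seq, BSAI))
        n_swa = len(dna.scan_sites(seq, SWAI))
        if n_bsa == 2 and n_swa == 2:
            break
    else:
        raise GGCloneError(f"could not generate a clean backbone {backbone_id}")

    anns, off = [], 0
    label_map = {
        "swa_b": "SwaI_site", "swa_a": "SwaI_site", "primer_R_site": "primer_R",
        "primer_F_site": "primer_F", "ori": "ori", "kanR": "kanR",
        "lacZ_stuffer": "lacZ_stuffer",
    }
    for name, p in pieces:
        if name in label_map:
            anns.append(Annotation(label_map[name], off, off + len(p)))
        off += len(p)
    seq = NucleotideSequence(bases, "circular", anns, backbone_id)
    return BackbonePlasmid(backbone_id, seq)


def gen_donor_body(config: FixtureConfig) -> NucleotideSequence:
    """Donor-vector body placeholder (ampicillin-resistance/ori stand-in).

    Checked in the junction context it will occupy in a minted donor
    plasmid (between the outward recognition arms)."""
    rng = _rng(config, "donor-body")
    for _ in range(config.max_retries):
        body = _clean_random(rng, 600, config, check_ends=False)
        ctx = revcomp(BSAI.recognition) + body + BSAI.recognition
        if _scan_clean(ctx[1:-1]) and len(dna.scan_sites(NucleotideSequence(ctx, "linear"), BSAI)) == 2:
            if len(dna.scan_sites(NucleotideSequence(ctx, "linear"), SWAI)) == 0:
                return NucleotideSequence(
                    body, "linear", [Annotation("donor_body", 0, len(body))], "donor-body"
                )
    raise GGCloneError("could not generate a clean donor body")


def gen_genome_stub(config: FixtureConfig, length: int = 5000) -> NucleotideSequence:
    """A small random chromosome stand-in for integration demos."""
    rng = _rng(config, "genome")
    bases = _clean_random(rng, length, config, check_ends=False)
    return NucleotideSequence(bases, "linear", [Annotation("chromosome_stub", 0, length)], "genome-stub")


# ---------------------------------------------------------------------------
# Full toolkit


def gen_demo_toolkit(config: FixtureConfig | None = None) -> RegistryCatalog:
    """The complete seeded toolkit: parts, backbones, donor body.

    Counts mirror the physical library: 8 promoters, 9 terminators, 9
    coding genes (8 mevalonate-pathway + MrBBS), 6 markers.  All parts
    carry first-transcription-unit labels; slot-specific building
    blocks are minted on demand by the catalog.
    """
    config = config or FixtureConfig()
    parts: dict[str, Part] = {}

    for name in PROMOTERS:
        parts[name] = gen_random_part("promoter", (2, 3), config, name)
    for name in TERMINATORS:
        parts[name] = gen_random_part("terminator", (4, 5), config, name)
    for name in MVA_GENES + EXTRA_GENES:
        parts[name] = gen_random_part("cds", (3, 4), config, name)
    parts[HISG_MARKER] = gen_random_part("marker", (1, 2), config, HISG_MARKER, recycling="hisG")
    for name in LOXP_MARKERS:
        parts[name] = gen_random_part("marker", (1, 2), config, name, recycling="loxP")

    backbones = {bid: gen_backbone(bid, config) for bid in ("pGGYL1", "pGGYL2", "pGGYL3")}
    return RegistryCatalog(
        overhang_table=dict(config.overhang_table),
        parts=parts,
        backbones=backbones,
        donor_body=gen_donor_body(config),
    )
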