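"""Grammar: overhang table fidelity, slots, parts, catalog loading."""

import pandas as pd
import pytest

import ggclone as gg
from ggclone.dna import BSAI, SWAI, NucleotideSequence, scan_sites
from ggclone.errors import RegistryError
from ggclone.registry import (
    DEFAULT_OVERHANGS,
    Part,
    RegistryCatalog,
    backbone_junction_labels,
    check_overhang_set,
    load_registry,
    mint_building_block,
    slot_layout,
    validate_part,
)


class TestOverhangSet:
    def test_default_table_is_faithful_with_no_near_misses(self):
        rep = check_overhang_set(list(DEFAULT_OVERHANGS.values()))
        assert rep.faithful
        assert rep.near_misses == []

    def test_example_faithful_set(self):
        assert check_overhang_set(["AATG", "AGGT", "GCTT", "CCAG"]).faithful

    def test_palindrome_flagged(self):
        rep = check_overhang_set(["AATG", "ACGT"])
        assert rep.palindromes == [1] and not rep.faithful

    def test_rc_collision_flagged(self):
        rep = check_overhang_set(["GGAC", "GTCC"])
        assert rep.rc_collisions == [(0, 1)] and not rep.faithful

    def test_duplicate_flagged(self):
        rep = check_overhang_set(["AATG", "AATG"])
        assert rep.duplicates == [(0, 1)]

    def test_wrong_length_rejected(self):
        with pytest.raises(Exception):
            check_overhang_set(["AAT"])


class TestSlotLayout:
    @pytest.mark.parametrize(
        "backbone, n_slots, n_tus",
        [("pGGYL1", 4, 1), ("pGGYL2", 7, 2), ("pGGYL3", 10, 3)],
    )
    def test_capacities(self, backbone, n_slots, n_tus):
        slots = slot_layout(backbone)
        assert len(slots) == n_slots
        assert sum(1 for s in slots if s.role == "cds") == n_tus
        assert slots[0].role == "marker"

    def test_adjacent_slots_share_a_junction_label(self):
        for bid in ("pGGYL1", "pGGYL2", "pGGYL3"):
            slots = slot_layout(bid)
            for a, b in zip(slots, slots[1:]):
                assert a.right_label == b.left_label

    def test_labels_drawn_from_table_without_repetition(self):
        for bid in ("pGGYL1", "pGGYL2", "pGGYL3"):
            slots = slot_layout(bid)
            labels = [slots[0].left_label] + [s.right_label for s in slots]
            assert len(labels) == len(set(labels))
            assert set(labels) <= set(DEFAULT_OVERHANGS)

    def test_part_labels_shared_across_backbones(self):
        # the first transcription unit uses the same labels everywhere
        for bid in ("pGGYL2", "pGGYL3"):
            assert slot_layout(bid)[:4] == slot_layout("pGGYL1")[:4]

    def test_unknown_backbone(self):
        with pytest.raises(RegistryError, match="pGGYL9"):
            slot_layout("pGGYL9")

    def test_junction_labels(self):
        assert backbone_junction_labels("pGGYL1") == (1, 5)
        assert backbone_junction_labels("pGGYL3") == (1, 11)


class TestValidatePart:
    def test_clean_part_passes(self, registry):
        part = registry.part("P_GPD")
        report = validate_part(part, registry.overhang_table)
        assert report.ok and report.violations == []

    def test_internal_bsai_site_reported_with_position(self):
        insert = NucleotideSequence("AAA" + "GGTCTC" + "TTT")
        part = Part("bad", "promoter", insert, 2, 3)
        report = validate_part(part)
        assert not report.ok
        assert ("BsaI", 3, 1) in report.internal_sites

    def test_self_circularizing_pair_reported(self, registry):
        part = registry.part("P_GPD").with_labels(2, 2)
        report = validate_part(part, registry.overhang_table)
        assert report.degenerate_pair and not report.ok

    def test_self_circularizing_part_actually_self_ligates(self, registry):
        # brute-force confirmation: equal labels close a one-piece circle
        from ggclone.assemble import enumerate_products_bruteforce
        from ggclone.dna import digest

        part = registry.part("P_GPD").with_labels(2, 2)
        block = mint_building_block(part, registry.donor_body, registry.overhang_table)
        frags = [f for f in digest(block.vector, BSAI) if f.is_sticky]
        circles = enumerate_products_bruteforce(frags)
        assert any(len(c) == 1 for c in circles)

    def test_unknown_label_reported(self, registry):
        part = registry.part("P_GPD").with_labels(2, 99)
        report = validate_part(part, registry.overhang_table)
        assert report.unknown_labels == [99]


class TestBuildingBlocks:
    def test_digestion_releases_part_between_labelled_overhangs(self, registry):
        part = registry.part("tHMG1")
        block = registry.building_block("tHMG1")
        frags = gg.digest(block.vector, BSAI)
        assert len(frags) == 2
        insert_frags = [f for f in frags if not scan_sites(f.core, BSAI)]
        assert len(insert_frags) == 1
        (pf,) = insert_frags
        table = registry.overhang_table
        assert pf.left_overhang == table[part.left_label]
        assert pf.right_overhang == table[part.right_label]
        assert part.insert.bases in pf.core.bases

    def test_slot_relabelling_keeps_insert(self, registry):
        slots = slot_layout("pGGYL3")
        block = registry.building_block("P_GPD", slots[4])  # second-TU promoter
        assert block.part.left_label == 5 and block.part.right_label == 6
        assert block.part.insert.bases == registry.part("P_GPD").insert.bases

    def test_role_mismatch_rejected(self, registry):
        with pytest.raises(RegistryError, match="role"):
            registry.building_block("P_GPD", slot_layout("pGGYL1")[0])


class TestBackbones:
    def test_backbone_has_two_bsai_and_two_swai_sites(self, registry):
        for bb in registry.backbones.values():
            assert len(scan_sites(bb.sequence, BSAI)) == 2
            assert len(scan_sites(bb.sequence, SWAI)) == 2

    def test_swai_sites_bracket_assembly_region_not_vector_features(self, registry):
        bb = registry.backbones["pGGYL1"].sequence
        swa = sorted(a.start for a in bb.features("SwaI_site"))
        stuffer = bb.features("lacZ_stuffer")[0]
        kanr = bb.features("kanR")[0]
        ori = bb.features("ori")[0]
        # cassette side runs from the second SwaI site through the origin
        assert swa[1] < stuffer.start
        assert swa[0] < kanr.start < swa[1] and swa[0] < ori.start < swa[1]


class TestCatalog:
    def test_default_catalog_role_counts(self, registry):
        counts = registry.role_counts()
        assert counts["promoter"] == 8
        assert counts["terminator"] == 9
        assert counts["marker"] == 6
        assert counts["cds"] == 9  # 8 MVA-pathway genes + the synthase

    def test_mva_genes_present(self, registry):
        from ggclone.fixtures import MVA_GENES

        assert len(MVA_GENES) == 8
        assert all(g in registry.parts for g in MVA_GENES)

    def test_empty_table_gives_empty_catalog(self, registry):
        df = pd.DataFrame(columns=["id", "role", "left_label", "right_label", "recycling", "sequence_ref"])
        cat = load_registry(df, {})
        assert cat.role_counts() == {}

    def test_missing_sequence_record_listed(self):
        df = pd.DataFrame(
            [{"id": "pX", "role": "promoter", "left_label": 2, "right_label": 3,
              "recycling": "", "sequence_ref": "pX"}]
        )
        with pytest.raises(RegistryError, match="pX"):
            load_registry(df, {})

    def test_duplicate_id_listed(self, registry):
        row = {"id": "pX", "role": "promoter", "left_label": 2, "right_label": 3,
               "recycling": "", "sequence_ref": "pX"}
        df = pd.DataFrame([row, row])
        seqs = {"pX": registry.part("P_GPD").insert}
        with pytest.raises(RegistryError, match="duplicate"):
            load_registry(df, seqs)

    def test_json_roundtrip_is_idempotent(self, registry):
        text = registry.to_json()
        again = RegistryCatalog.from_json(text)
        assert again.to_json() == text
        assert again.role_counts() == registry.role_counts()
        assert again.backbones["pGGYL3"].sequence.bases == registry.backbones["pGGYL3"].sequence.bases
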