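"""Shuffle enumeration, round planning, and improvement metrics."""

import numpy as np
import pytest

import ggclone as gg
from ggclone.combinatorics import (
    PathwaySet,
    ShuffleSpec,
    StrainRecord,
    enumerate_designs,
    fold_change,
    ladder_report,
    percent_increase,
    plan_rounds,
    productivity,
    round_fold,
)
from ggclone.errors import CapacityError, ValidationError
from ggclone.fixtures import MVA_GENES, PROMOTERS, TERMINATORS

#: Best-of-round titers (mg/L) along the published strain-improvement
#: ladder: synthase only, then three pathway-integration rounds, then
#: the two copy-number rounds.
LADDER_TITERS = [2.5, 70.6, 135.3, 242.6, 275.3, 573.7]


class TestEnumerateDesigns:
    def test_promoter_by_terminator_shuffle_gives_72(self, registry):
        spec = ShuffleSpec(
            "pGGYL1",
            [["LEU2"], list(PROMOTERS), ["MrBBS"], list(TERMINATORS)],
        )
        designs = enumerate_designs(spec, registry)
        assert len(designs) == 8 * 9 == 72
        # deterministic lexicographic order, no duplicates
        keys = [tuple(d.slot_parts) for d in designs]
        assert keys == sorted(set(keys), key=keys.index) and len(set(keys)) == 72

    def test_all_fixed_gives_one(self, registry):
        spec = ShuffleSpec("pGGYL1", [["LEU2"], ["P_GPD"], ["MrBBS"], ["T_Mig1"]])
        assert len(enumerate_designs(spec, registry)) == 1

    def test_three_tus_two_promoters_each_gives_eight(self, registry):
        two_p = ["P_GPD", "P_TEF"]
        spec = ShuffleSpec(
            "pGGYL3",
            [["HUH"],
             two_p, ["tHMG1"], ["T_Mig1"],
             two_p, ["ERG12"], ["T_Lip1"],
             two_p, ["ERG19"], ["T_Lip2"]],
        )
        assert len(enumerate_designs(spec, registry)) == 2 ** 3

    def test_count_matches_nested_loop_oracle(self, registry):
        rng = np.random.default_rng(8)
        proms, terms = list(PROMOTERS), list(TERMINATORS)
        for _ in range(10):
            np_, nt = int(rng.integers(1, 8)), int(rng.integers(1, 9))
            spec = ShuffleSpec(
                "pGGYL1", [["LEU2"], proms[:np_], ["ERG10"], terms[:nt]]
            )
            count = 0
            for _p in proms[:np_]:
                for _t in terms[:nt]:
                    count += 1
            assert len(enumerate_designs(spec, registry)) == count

    def test_role_mismatch_rejected(self, registry):
        spec = ShuffleSpec("pGGYL1", [["LEU2"], ["T_Mig1"], ["MrBBS"], ["T_Mig1"]])
        with pytest.raises(ValidationError, match="role"):
            enumerate_designs(spec, registry)

    def test_empty_candidate_list_rejected(self, registry):
        spec = ShuffleSpec("pGGYL1", [["LEU2"], [], ["MrBBS"], ["T_Mig1"]])
        with pytest.raises(ValidationError, match="empty"):
            enumerate_designs(spec, registry)


class TestPlanRounds:
    def test_pathway_split_maps_to_smallest_backbones(self, registry):
        sets = [
            PathwaySet(["tHMG1", "ERG12", "ERG19"], "URA3"),
            PathwaySet(["ERG10", "ERG13", "IDI"], "LEU2"),
            PathwaySet(["ERG8", "ERG20"], "HPH"),
        ]
        plan = plan_rounds(sets, registry)
        assert plan.backbones == ["pGGYL3", "pGGYL3", "pGGYL2"]

    def test_single_gene_set_takes_smallest_backbone(self, registry):
        plan = plan_rounds([PathwaySet(["MrBBS"], "HUH")], registry)
        assert plan.backbones == ["pGGYL1"]
        assert plan.rounds[0].slot_parts[0] == "HUH"

    def test_four_gene_set_exceeds_capacity(self, registry):
        sets = [PathwaySet(["tHMG1", "ERG12", "ERG19", "ERG8"], "URA3")]
        with pytest.raises(CapacityError, match="capacity"):
            plan_rounds(sets, registry)

    def test_planned_rounds_assemble_with_expected_tu_counts(self, registry):
        sets = [
            PathwaySet(["tHMG1", "ERG12", "ERG19"], "URA3"),
            PathwaySet(["ERG10", "ERG13", "IDI"], "LEU2"),
            PathwaySet(["ERG8", "ERG20"], "HPH"),
        ]
        plan = plan_rounds(sets, registry)
        tu_counts = []
        for design in plan.rounds:
            product, _ = gg.simulate_assembly(design, registry)
            cassette, _ = gg.extract_cassette(product.sequence)
            tu_counts.append(cassette.feature_counts()["cds"])
        assert tu_counts == [3, 3, 2]


class TestMetrics:
    def test_fold_change_examples(self):
        assert round_fold(fold_change(2.5, 70.6)) == pytest.approx(28.2)
        assert fold_change(3.0, 3.0) == 1.0
        assert round_fold(fold_change(2.5, 242.6)) == pytest.approx(97.0)

    def test_fold_change_scale_invariance(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            a, b, k = rng.uniform(0.1, 100, size=3)
            assert fold_change(k * a, k * b) == pytest.approx(fold_change(a, b))

    def test_percent_increase_examples(self):
        assert percent_increase(70.6, 135.3) == pytest.approx(91.6, abs=0.05)
        assert percent_increase(135.3, 242.6) == pytest.approx(79.3, abs=0.05)
        assert percent_increase(242.6, 275.3) == pytest.approx(13.48, abs=0.005)
        assert percent_increase(275.3, 573.7) == pytest.approx(108.4, abs=0.05)

    def test_productivity(self):
        assert productivity(4400, 168) == pytest.approx(26.2, abs=0.05)
        assert productivity(0.0001, 5) == pytest.approx(0, abs=1e-4)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValidationError):
            fold_change(0, 5)
        with pytest.raises(ValidationError):
            percent_increase(-1, 5)
        with pytest.raises(ValidationError):
            productivity(5, 0)


class TestLadderReport:
    def records(self):
        return [
            StrainRecord(f"LYW{i+1}-best", i + 1, t) for i, t in enumerate(LADDER_TITERS)
        ] + [
            StrainRecord("LYW2-low", 2, 30.0),
            StrainRecord("LYW5-low", 5, 200.0),
        ]

    def test_cumulative_folds_match_division_of_titers(self):
        rows = ladder_report(self.records())
        folds = [round_fold(r.cumulative_fold) for r in rows]
        assert folds == [1.0, 28.2, 54.1, 97.0, 110.1, 229.5]

    def test_best_strains_selected(self):
        rows = ladder_report(self.records())
        assert [r.titer for r in rows] == LADDER_TITERS

    def test_single_round_cumulative_equals_per_round(self):
        rows = ladder_report([StrainRecord("s", 1, 5.0)])
        assert rows[0].fold_vs_previous == rows[0].cumulative_fold == 1.0

    def test_order_invariance(self):
        recs = self.records()
        shuffled = list(reversed(recs))
        assert ladder_report(recs) == ladder_report(shuffled)

    def test_tie_broken_by_strain_id(self):
        recs = [StrainRecord("b", 1, 5.0), StrainRecord("a", 1, 5.0)]
        assert ladder_report(recs)[0].best_strain == "a"

    def test_empty_ledger_rejected(self):
        with pytest.raises(ValidationError):
            ladder_report([])
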