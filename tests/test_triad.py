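"""Pattern classifier: enumeration, symmetry, and planted-class recovery."""

import itertools

import numpy as np
import pandas as pd
import pytest

from triadex import SimConfig, classify_gene, classify_triad, simulate_counts
from triadex.triad import ROLLUP_OF_GROUP, enumerate_groups, swap_roles

# Hand-derived truth table for all 27 (state_FH, state_MH, state_FM)
# combinations, written out case by case from the group geometries
# (F = female, M = male, H = hybrid; FH/MH = sign of H - parent, FM = sign
# of M - F). Kept independent of the implementation's lookup table.
HAND_TABLE = {
    ("ns", "ns", "ns"): 0,
    # H strictly between differing parents
    ("down", "up", "down"): 1,   # F > H > M
    ("up", "down", "up"): 2,     # M > H > F
    # H ~ M, both differ from F
    ("up", "ns", "up"): 3,       # M high
    ("down", "ns", "down"): 4,   # M low
    # H ~ F, both differ from M
    ("ns", "up", "down"): 5,     # F high
    ("ns", "down", "up"): 6,     # F low
    # H below both parents
    ("down", "down", "down"): 7,
    ("down", "down", "ns"): 8,
    ("down", "down", "up"): 9,
    # H above both parents
    ("up", "up", "down"): 10,
    ("up", "up", "ns"): 11,
    ("up", "up", "up"): 12,
    # everything else is ambiguous
    ("up", "ns", "ns"): 13, ("down", "ns", "ns"): 13,
    ("ns", "up", "ns"): 13, ("ns", "down", "ns"): 13,
    ("ns", "ns", "up"): 13, ("ns", "ns", "down"): 13,
    ("up", "ns", "down"): 13, ("down", "ns", "up"): 13,
    ("ns", "up", "up"): 13, ("ns", "down", "down"): 13,
    ("up", "down", "down"): 13, ("up", "down", "ns"): 13,
    ("down", "up", "up"): 13, ("down", "up", "ns"): 13,
}


class TestEnumeration:
    def test_exhaustive_and_matches_hand_table(self):
        table = enumerate_groups()
        assert len(table) == 27
        assert table == HAND_TABLE

    def test_twelve_informative_groups(self):
        groups = set(enumerate_groups().values())
        assert {g for g in groups if 1 <= g <= 12} == set(range(1, 13))

    def test_conserved_reached_by_single_combination(self):
        table = enumerate_groups()
        assert [c for c, g in table.items() if g == 0] == [("ns", "ns", "ns")]

    def test_every_combination_gets_one_group(self):
        table = enumerate_groups()
        assert set(table) == set(itertools.product(("up", "down", "ns"), repeat=3))
        assert all(g in ROLLUP_OF_GROUP for g in table.values())


class TestClassifyGene:
    def test_all_ns_conserved(self):
        call = classify_gene("ns", "ns", "ns")
        assert call.group == 0 and call.rollup == "conserved"

    def test_hybrid_above_both_parents_od_up(self):
        assert classify_gene("up", "up", "ns").rollup == "OD-up"

    def test_hybrid_matches_male_below_female_meld(self):
        # H ~ M, H below F, M below F
        call = classify_gene("down", "ns", "down")
        assert call.rollup == "M-ELD" and call.group == 4

    def test_hybrid_between_parents_additive(self):
        # H below F, above M, M below F
        call = classify_gene("down", "up", "down")
        assert call.rollup == "additive" and call.group == 1

    def test_single_contrast_significant_ambiguous(self):
        call = classify_gene("up", "ns", "ns")
        assert call.group == 13 and call.rollup == "ambiguous"

    def test_invalid_token(self):
        with pytest.raises(ValueError):
            classify_gene("UP", "ns", "ns")


class TestRoleSwapSymmetry:
    SWAP_GROUP = {0: 0, 1: 2, 2: 1, 3: 5, 4: 6, 5: 3, 6: 4,
                  7: 9, 8: 8, 9: 7, 10: 12, 11: 11, 12: 10, 13: 13}

    def test_swap_maps_groups(self):
        for combo, group in enumerate_groups().items():
            swapped = classify_gene(*swap_roles(combo))
            assert swapped.group == self.SWAP_GROUP[group], combo

    def test_swap_exchanges_eld_rollups(self):
        for combo, group in enumerate_groups().items():
            r = ROLLUP_OF_GROUP[group]
            rs = classify_gene(*swap_roles(combo)).rollup
            expected = {"M-ELD": "F-ELD", "F-ELD": "M-ELD"}.get(r, r)
            assert rs == expected


class TestClassifyTriad:
    def test_identical_genotypes_all_conserved(self):
        rng = np.random.default_rng(1)
        base = rng.negative_binomial(20, 20 / 120, size=100)
        cols = {}
        rows = []
        for geno, role in (("A", "female"), ("B", "male"), ("H", "hybrid")):
            for rep in (1, 2, 3):
                cols[f"{geno}_root_{rep}"] = base
                rows.append({"sample_id": f"{geno}_root_{rep}", "genotype": geno,
                             "role": role, "triad_id": "H", "tissue": "root",
                             "replicate": rep})
        from triadex.io import CountMatrix, SampleSheet
        cm = CountMatrix(pd.DataFrame(cols, index=[f"g{i}" for i in range(100)]))
        sheet = SampleSheet(pd.DataFrame(rows))
        calls, hist = classify_triad(cm, sheet, "H", "root")
        assert hist[0] == 100

    def test_planted_od_up_recovery(self):
        cfg = SimConfig(
            seed=9, n_genes=1000, tissues=("root",),
            class_proportions={"conserved": 0.5, "OD-up": 0.5},
            dispersion_a1=0.0,
        )
        cm, sheet, truth = simulate_counts(cfg)
        calls, _ = classify_triad(cm, sheet, "H", "root", fc_threshold=0.5)
        planted = truth[(truth["tissue"] == "root") & (truth["class"] == "OD-up")]
        groups = calls.loc[planted["gene"], "group"]
        assert (groups.isin([10, 11, 12])).mean() >= 0.9

    def test_pure_additive_majority_groups_1_2(self):
        cfg = SimConfig(
            seed=10, n_genes=800, tissues=("root",),
            class_proportions={"additive": 1.0},
            dispersion_a1=0.0,
        )
        cm, sheet, truth = simulate_counts(cfg)
        calls, hist = classify_triad(cm, sheet, "H", "root", fc_threshold=0.5)
        frac_additive = (hist[1] + hist[2]) / hist.sum()
        frac_od = hist.loc[7:12].sum() / hist.sum()
        assert frac_additive > 0.5
        assert frac_od <= 0.01

    def test_missing_role_is_design_error(self, sim_data):
        from triadex.io import DesignError
        cm, sheet, _ = sim_data
        with pytest.raises((DesignError, KeyError)):
            classify_triad(cm, sheet, "X", "root")

    def test_low_expression_flagged_as_conserved(self, sim_data):
        cm, sheet, _ = sim_data
        counts = cm.counts.copy()
        counts.iloc[0] = 0  # first gene silent everywhere
        from triadex.io import CountMatrix
        calls, _ = classify_triad(CountMatrix(counts), sheet, "H", "root")
        first = calls.iloc[0]
        assert first["group"] == 0 and first["low_expression"]
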