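"""Fold-change table, activated/inhibited calls, DBZ refinement, Venn, top-k."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from archncc import (
    ClassifierThresholds,
    ExpressionMatrix,
    GeneClassification,
    classify_pathway,
    compute_fold_changes,
    intersect_lists,
    refine_notch_with_dbz,
    top_k_regulated,
)
from archncc.io import ConfigurationError, ContrastSpec


def _fc_table(rows: dict[str, dict[str, float]]) -> pd.DataFrame:
    """rows: gene -> {contrast: fold-change}."""
    return pd.DataFrame.from_dict(rows, orient="index")


class TestComputeFoldChanges:
    @pytest.mark.parametrize(
        "perturbed,control,expected",
        [(10.0, 5.0, 2.0), (5.0, 0.0, 500.0), (0.0, 0.0, 1.0)],
    )
    def test_zero_replacement_rule(self, perturbed, control, expected):
        matrix = ExpressionMatrix(
            pd.DataFrame({"p": [perturbed], "c": [control]}, index=["g"])
        )
        fc = compute_fold_changes(matrix, [ContrastSpec("edn1_mut", "p", "c")])
        assert fc.at["g", "edn1_mut"] == pytest.approx(expected)

    def test_common_scaling_of_a_contrast_leaves_fc_unchanged(self):
        rng = np.random.default_rng(5)
        base = pd.DataFrame(
            rng.uniform(0.5, 50.0, size=(20, 2)),
            index=[f"g{i}" for i in range(20)],
            columns=["p", "c"],
        )
        scaled = base * 7.3
        spec = [ContrastSpec("dbz", "p", "c")]
        fc1 = compute_fold_changes(ExpressionMatrix(base), spec)
        fc2 = compute_fold_changes(ExpressionMatrix(scaled), spec)
        assert np.allclose(fc1["dbz"], fc2["dbz"])


class TestClassifyPathway:
    @pytest.mark.parametrize(
        "fc_oe,fc_mut,expect_act,expect_inh",
        [
            (3.0, 2.0, True, False),    # ratio exactly 1.5, guard 3 >= 1
            (0.5, 0.75, False, False),  # ratio 0.667 but mutant guard 0.75 < 1
            (0.667, 1.0, False, True),  # ratio exactly 0.667, guard 1 >= 1
            (1.2, 1.0, False, False),   # between thresholds
            (0.8, 0.4, False, False),   # ratio 2 but OE guard fails (0.8 < 1)
            (2.0, 0.5, True, False),    # ratio 4, OE guard 2 >= 1
        ],
    )
    def test_threshold_and_guard_semantics(self, fc_oe, fc_mut, expect_act, expect_inh):
        table = _fc_table({"g": {"nicd_oe": fc_oe, "jag1b_mut": fc_mut}})
        act, inh = classify_pathway(table, "notch")
        assert ("g" in act) is expect_act
        assert ("g" in inh) is expect_inh

    def test_inhibited_boundary_is_inclusive(self):
        # 0.5 / 0.75 is not exactly 0.667 in floats; use an exact-ratio case
        table = _fc_table({"g": {"edn1_oe": 0.667, "edn1_mut": 1.0}})
        act, inh = classify_pathway(table, "edn1")
        assert "g" in inh and "g" not in act

    def test_universe_restriction(self):
        table = _fc_table(
            {
                "in": {"nicd_oe": 4.0, "jag1b_mut": 1.0},
                "out": {"nicd_oe": 4.0, "jag1b_mut": 1.0},
            }
        )
        act, _ = classify_pathway(table, "notch", universe={"in"})
        assert act == {"in"}

    def test_missing_contrast_is_configuration_error(self):
        table = _fc_table({"g": {"nicd_oe": 2.0}})
        with pytest.raises(ConfigurationError, match="jag1b_mut"):
            classify_pathway(table, "notch")

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.floats(0.01, 100.0, allow_nan=False),
                st.floats(0.01, 100.0, allow_nan=False),
            ),
            min_size=1,
            max_size=30,
        )
    )
    def test_activated_and_inhibited_are_disjoint(self, pairs):
        table = _fc_table(
            {f"g{i}": {"edn1_oe": oe, "edn1_mut": mut}
             for i, (oe, mut) in enumerate(pairs)}
        )
        act, inh = classify_pathway(table, "edn1")
        assert act & inh == set()


class TestDbzRefinement:
    @pytest.mark.parametrize(
        "fc_nicd,fc_dbz,in_act,in_inh,keep_act,keep_inh",
        [
            (2.5, 2.0, True, False, True, False),   # ratio exactly 1.25: retained
            (3.0, 2.5, True, False, False, False),  # ratio 1.2 < 1.25: removed
            (0.4, 0.5, False, True, False, True),   # ratio exactly 0.8: retained
            (0.85, 1.0, False, True, False, False),  # ratio 0.85 > 0.8: removed
        ],
    )
    def test_refinement_boundaries(
        self, fc_nicd, fc_dbz, in_act, in_inh, keep_act, keep_inh
    ):
        table = _fc_table({"g": {"nicd_oe": fc_nicd, "dbz": fc_dbz}})
        refined = refine_notch_with_dbz(
            {"g"} if in_act else set(), {"g"} if in_inh else set(), table
        )
        assert ("g" in refined.activated) is keep_act
        assert ("g" in refined.inhibited) is keep_inh
        removed = refined.removed_activated | refined.removed_inhibited
        assert ("g" in removed) is (in_act and not keep_act or in_inh and not keep_inh)

    def test_refinement_is_a_contraction(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(50)]
        table = pd.DataFrame(
            {
                "nicd_oe": rng.uniform(0.1, 5.0, 50),
                "dbz": rng.uniform(0.1, 5.0, 50),
            },
            index=genes,
        )
        act = set(genes[:30])
        inh = set(genes[30:])
        refined = refine_notch_with_dbz(act, inh, table)
        assert refined.activated <= act
        assert refined.inhibited <= inh
        assert refined.removed_activated == act - refined.activated
        assert refined.removed_inhibited == inh - refined.inhibited


class TestVennAndTopK:
    def test_intersection_counts(self):
        cls = GeneClassification(
            universe=set("abcdefg"),
            notch_activated=set(),
            notch_inhibited={"a", "b", "c", "d", "e"},
            edn1_activated={"c", "d", "e", "f", "g"},
            edn1_inhibited=set(),
        )
        venn = intersect_lists(cls)
        pair = venn["notch_inhibited__edn1_activated"]
        assert pair == {"A": 5, "B": 5, "A_and_B": 3, "A_not_B": 2, "B_not_A": 2}

    def test_venn_identity_holds_for_every_pair(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(40)]
        pick = lambda: set(rng.choice(genes, size=rng.integers(0, 25), replace=False))
        cls = GeneClassification(
            universe=set(genes),
            notch_activated=pick(),
            notch_inhibited=pick(),
            edn1_activated=pick(),
            edn1_inhibited=pick(),
        )
        for counts in intersect_lists(cls).values():
            assert counts["A_not_B"] + counts["A_and_B"] == counts["A"]
            assert counts["B_not_A"] + counts["A_and_B"] == counts["B"]

    def test_top_k_ordering_and_ties(self):
        table = _fc_table(
            {
                "g1": {"dbz": 4.0},
                "g2": {"dbz": 3.0},
                "g3": {"dbz": 2.0},
                "g10": {"dbz": 3.0},
            }
        )
        assert top_k_regulated(table, "dbz", 2, "up") == ["g1", "g10"]
        assert top_k_regulated(table, "dbz", 10, "down") == ["g3", "g10", "g2", "g1"]

    def test_top_k_rejects_nonpositive_k(self):
        table = _fc_table({"g": {"dbz": 1.0}})
        with pytest.raises(ValueError):
            top_k_regulated(table, "dbz", 0, "up")
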