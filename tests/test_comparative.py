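"""Orthogroup assignment, Venn partitioning, and GO Slim chi-square."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from interphyte.comparative import (
    REGIONS,
    assign_orthogroups,
    goslim_chi_square,
    interface_fractions,
    unigene_region_table,
    venn_partition,
)
from interphyte.similarity import MappingPolicy
from interphyte.simulate import mutate

OG_SET = st.sets(st.integers(0, 40), max_size=25)


def paper_style_partition():
    """Region sets sized like a two-host interface comparison: 5947 shared by
    all, 1124 interface-shared, 677/361 interface-unique, 1066/314 shared
    with above-ground growth."""
    sizes = {
        "shared_all": 5947,
        "interface_shared": 1124,
        "A_interface_unique": 677,
        "B_interface_unique": 361,
        "A_above_shared": 1066,
        "B_above_shared": 314,
        "above_unique": 1606,
    }
    ids = {}
    counter = 0
    for region, n in sizes.items():
        ids[region] = {f"OG{counter + i:05d}" for i in range(n)}
        counter += n
    set_a = ids["shared_all"] | ids["interface_shared"] | ids["A_interface_unique"] | ids["A_above_shared"]
    set_b = ids["shared_all"] | ids["interface_shared"] | ids["B_interface_unique"] | ids["B_above_shared"]
    set_ref = ids["shared_all"] | ids["A_above_shared"] | ids["B_above_shared"] | ids["above_unique"]
    return set_a, set_b, set_ref, sizes


class TestVennPartition:
    def test_two_host_fixture_counts(self):
        set_a, set_b, set_ref, sizes = paper_style_partition()
        part = venn_partition(set_a, set_b, set_ref)
        for region, n in sizes.items():
            assert part.counts[region] == n
        assert part.interface_only_total == 1124 + 677 + 361 == 2162

    def test_disjoint_sets_populate_only_unique_regions(self):
        part = venn_partition({"a"}, {"b"}, {"c"})
        assert part.counts["A_interface_unique"] == 1
        assert part.counts["B_interface_unique"] == 1
        assert part.counts["above_unique"] == 1
        assert sum(part.counts.values()) == 3

    def test_identical_sets_populate_only_shared_all(self):
        s = {"x", "y", "z"}
        part = venn_partition(s, s, s)
        assert part.counts["shared_all"] == 3
        assert sum(part.counts.values()) == 3

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(a=OG_SET, b=OG_SET, r=OG_SET)
    def test_regions_disjoint_and_complete(self, a, b, r):
        part = venn_partition(a, b, r)
        union = set()
        total = 0
        for region in REGIONS:
            s = part.regions[region]
            assert not (union & s)
            union |= s
            total += len(s)
        assert union == a | b | r
        assert total == len(a | b | r)


class TestInterfaceFractions:
    def test_two_host_fixture_fractions(self):
        set_a, set_b, set_ref, _ = paper_style_partition()
        fr = interface_fractions(venn_partition(set_a, set_b, set_ref))
        assert fr == {
            "interface_shared": 52,
            "A_interface_unique": 31,
            "B_interface_unique": 17,
        }

    def test_equal_thirds(self):
        part = venn_partition(set(range(10)), set(range(10, 20)), set())
        part.regions["interface_shared"] = frozenset(range(100, 110))
        fr = interface_fractions(part)
        assert fr == {"interface_shared": 33, "A_interface_unique": 33, "B_interface_unique": 33}

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(a=st.integers(0, 500), b=st.integers(0, 500), c=st.integers(0, 500))
    def test_matches_rational_arithmetic(self, a, b, c):
        if a + b + c == 0:
            return
        part = venn_partition(
            {f"s{i}" for i in range(a)} | {f"x{i}" for i in range(b)},
            {f"s{i}" for i in range(a)} | {f"y{i}" for i in range(c)},
            set(),
        )
        fr = interface_fractions(part)
        total = a + b + c
        assert fr["interface_shared"] == round(100 * a / total)
        assert 99 <= sum(fr.values()) <= 101

    def test_empty_interface_rejected(self):
        with pytest.raises(ValueError):
            interface_fractions(venn_partition(set(), set(), {"og1"}))


class TestGoslimChiSquare:
    def test_proportional_table_gives_zero_statistic(self):
        t = pd.DataFrame({"r1": [10, 20], "r2": [20, 40]}, index=["c1", "c2"])
        res = goslim_chi_square(t)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert (res.flags.values == 0).all()

    def test_2x2_closed_form(self):
        """[[10, 20], [20, 10]]: all expected cells are 15, so
        chi2 = 4 * 25/15 = 20/3."""
        t = pd.DataFrame([[10, 20], [20, 10]], index=["a", "b"], columns=["x", "y"])
        res = goslim_chi_square(t)
        assert res.chi2 == pytest.approx(20 / 3)
        assert res.dof == 1
        assert res.residuals.loc["a", "x"] == pytest.approx((10 - 15) / np.sqrt(15))

    def test_statistic_invariant_under_permutation(self, rng):
        t = pd.DataFrame(
            rng.integers(5, 60, size=(4, 3)),
            index=list("abcd"),
            columns=["x", "y", "z"],
        )
        r1 = goslim_chi_square(t)
        r2 = goslim_chi_square(t.iloc[::-1, ::-1])
        assert r1.chi2 == pytest.approx(r2.chi2)
        assert r1.dof == r2.dof

    def test_zero_margin_dropped_with_note(self):
        t = pd.DataFrame(
            [[5, 10, 0], [10, 5, 0], [0, 0, 0]],
            index=["a", "b", "c"],
            columns=["x", "y", "z"],
        )
        res = goslim_chi_square(t)
        assert ("row", "c") in res.dropped and ("col", "z") in res.dropped
        assert res.table.shape == (2, 2)

    def test_low_expected_cells_reported(self):
        t = pd.DataFrame([[1, 50], [2, 60]], index=["a", "b"], columns=["x", "y"])
        res = goslim_chi_square(t)
        assert ("a", "x") in res.low_expected_cells

    def test_too_small_table_rejected(self):
        with pytest.raises(ValueError):
            goslim_chi_square(pd.DataFrame([[1], [2]], index=["a", "b"], columns=["x"]))


class TestAssignOrthogroups:
    def _labels(self, refs):
        return pd.DataFrame(
            [{"subject_id": sid, "orthogroup": f"OG_{sid}"} for sid in refs]
        )

    def test_identical_unigene_inherits_orthogroup(self, rng):
        refs = {f"r{i}": "".join(rng.choice(list("ACGT"), size=300)) for i in range(5)}
        out = assign_orthogroups({"u": refs["r2"]}, refs, self._labels(refs))
        assert out[0].orthogroup == "OG_r2"

    def test_no_significant_hit_unassigned(self, rng):
        refs = {"r0": "".join(rng.choice(list("ACGT"), size=300))}
        out = assign_orthogroups(
            {"u": "".join(rng.choice(list("ACGT"), size=200))},
            refs,
            self._labels(refs),
            MappingPolicy(min_score=40),
        )
        assert out[0].orthogroup is None

    def test_accuracy_degrades_gracefully_with_divergence(self, rng):
        nprng = np.random.default_rng(4)
        refs = {f"r{i:02d}": "".join(nprng.choice(list("ACGT"), size=400)) for i in range(30)}
        labels = self._labels(refs)
        for d, floor in ((0.0, 0.99), (0.05, 0.9)):
            queries = {f"q_{k}": mutate(v, d, nprng) for k, v in refs.items()}
            out = assign_orthogroups(queries, refs, labels)
            correct = sum(
                1 for a in out if a.orthogroup == f"OG_{a.unigene_id[2:]}"
            )
            assert correct >= floor * len(refs), d

    def test_unlabeled_reference_rejected(self, rng):
        refs = {"r0": "ACGT" * 50}
        with pytest.raises(ValueError, match="r0"):
            assign_orthogroups({"u": refs["r0"]}, refs, pd.DataFrame(columns=["subject_id", "orthogroup"]))


def test_unigene_region_table_counts_none_category():
    part = venn_partition({"OG1", "OG2"}, {"OG1"}, set())
    from interphyte.comparative import OrthogroupAssignment

    assignments = [
        OrthogroupAssignment("u1", "OG1"),
        OrthogroupAssignment("u2", "OG2"),
        OrthogroupAssignment("u3", "OG2"),
        OrthogroupAssignment("u4", None),
    ]
    table = unigene_region_table(assignments, {"u1": "transport"}, part)
    assert table.loc["transport", "interface_shared"] == 1
    assert table.loc["none", "A_interface_unique"] == 2
    assert int(table.values.sum()) == 3
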