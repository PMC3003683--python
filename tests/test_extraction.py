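"""Fold computation, condition evaluation and the set-algebra miner."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from sagemine import (
    Condition,
    ConfigurationError,
    DomainError,
    Op,
    SageLibrary,
    ValidationError,
    build_fold_matrix,
    build_matrix,
    evaluate_condition,
    extract,
    fold,
    read_condition_pool,
    scale_transform,
    score_tags,
    write_condition_pool,
)

from conftest import (
    T1, T2, T3,
    libs_to_count_dicts,
    make_matrix_from_tpm,
    random_instance,
)
from _oracle import oracle_extract, oracle_fold


class TestFold:
    def test_plain_division(self):
        m = make_matrix_from_tpm({"A": {T1: 100.0}, "B": {T1: 50.0}})
        assert fold(m, T1, "A", "B") == (2.0, "normal")

    def test_zero_numerator_stays_zero(self):
        m = make_matrix_from_tpm({"A": {T1: 0.0, T2: 1.0}, "B": {T1: 5.0, T2: 1.0}})
        assert fold(m, T1, "A", "B") == (0.0, "zero_numerator")

    def test_both_zero(self):
        m = make_matrix_from_tpm({"A": {T1: 0.0, T2: 1.0}, "B": {T1: 0.0, T2: 1.0}})
        assert fold(m, T1, "A", "B") == (0.0, "both_zero")

    def test_zero_denominator_adjusted_to_min_positive(self):
        # denominator column {T1: 0, T2: 40, T3: 960}: min positive TPM is 40
        m = make_matrix_from_tpm(
            {"A": {T1: 100.0, T2: 1.0, T3: 1.0},
             "B": {T1: 0.0, T2: 40.0, T3: 960.0}}
        )
        value, flag = fold(m, T1, "A", "B")
        assert (value, flag) == (2.5, "adjusted_denominator")

    def test_empty_denominator_library_is_domain_error(self):
        m = make_matrix_from_tpm({"A": {T1: 10.0}, "B": {T1: 0.0}})
        with pytest.raises(DomainError):
            fold(m, T1, "A", "B")

    def test_unknown_tag_rejected(self):
        m = make_matrix_from_tpm({"A": {T1: 1.0}, "B": {T1: 1.0}})
        with pytest.raises(ValidationError):
            fold(m, T2, "A", "B")


class TestEvaluateCondition:
    def test_gt_threshold(self, gt_lt_matrix):
        ts = evaluate_condition(gt_lt_matrix, Condition("A", Op.GT, 2.0, "B"))
        assert ts.members == {T1}

    def test_lt_threshold_with_adjusted_denominator(self, gt_lt_matrix):
        # T2: fold(B/A) = 1 >= 1 -> in; T3: 5 / min-positive(A)=50 -> 0.1 -> out
        ts = evaluate_condition(gt_lt_matrix, Condition("A", Op.LT, 1.0, "B"))
        assert ts.members == {T2}

    def test_not_in_presence_absence(self):
        libs = [
            SageLibrary("A", {T1: 3, T2: 1}),
            SageLibrary("B", {T2: 2, T3: 4}),
        ]
        m = build_matrix(libs)
        ts = evaluate_condition(m, Condition("A", Op.NOT_IN, 1.0, "B"))
        assert ts.members == {T1}

    def test_unknown_library_rejected(self, gt_lt_matrix):
        with pytest.raises(ValidationError):
            evaluate_condition(gt_lt_matrix, Condition("A", Op.GT, 2.0, "Z"))

    @pytest.mark.parametrize("op", [Op.GT, Op.LT])
    def test_members_shrink_as_factor_grows(self, op):
        """Factor monotonicity: members(f2) is a subset of members(f1) for f2 >= f1."""
        rng = np.random.default_rng(7)
        libs = [
            SageLibrary("A", {t: int(c) for t, c in zip(_tags(rng, 30), rng.integers(0, 40, 30)) if c}),
            SageLibrary("B", {t: int(c) for t, c in zip(_tags(rng, 30), rng.integers(0, 40, 30)) if c}),
        ]
        # overlap the tag sets so all branches appear
        libs[1].counts.update({t: 3 for t in list(libs[0].counts)[:10]})
        m = build_matrix(libs)
        previous = None
        for factor in [1.0, 1.5, 2.0, 4.0, 8.0]:
            members = evaluate_condition(m, Condition("A", op, factor, "B")).members
            if previous is not None:
                assert members <= previous
            previous = members


def _tags(rng, n):
    bases = np.array(list("ACGT"))
    out = set()
    while len(out) < n:
        out.add("".join(bases[rng.integers(0, 4, 10)]))
    return sorted(out)


class TestConditionValidation:
    def test_self_comparison_rejected(self):
        with pytest.raises(ValidationError):
            Condition("A", Op.GT, 2.0, "A")

    def test_factor_below_one_rejected_for_fold_ops(self):
        with pytest.raises(ValidationError):
            Condition("A", Op.GT, 0.5, "B")
        Condition("A", Op.NOT_IN, 0.0, "B")  # factor ignored for NOT_IN


class TestExtract:
    def test_intersection_of_included(self, gt_lt_matrix):
        pool = [
            Condition("A", Op.GT, 1.0, "B"),   # {T1, T2}
            Condition("B", Op.GT, 1.0, "A"),   # {T2, T3}
        ]
        res = extract(gt_lt_matrix, pool)
        assert res.mined == [T2]

    def test_excluded_conditions_subtract(self, gt_lt_matrix):
        pool = [
            Condition("A", Op.GT, 1.0, "B", inclusion=True),
            Condition("B", Op.GT, 1.0, "A", inclusion=False),
        ]
        res = extract(gt_lt_matrix, pool)
        assert res.mined == [T1]
        # mined is disjoint from every excluded condition's tag set
        assert not set(res.mined) & res.per_condition_sets[1].members

    def test_no_included_condition_rejected(self, gt_lt_matrix):
        with pytest.raises(ConfigurationError):
            extract(gt_lt_matrix, [Condition("A", Op.GT, 1.0, "B", inclusion=False)])

    @pytest.mark.parametrize("top_n", [0, 101, -5])
    def test_top_n_bounds(self, gt_lt_matrix, top_n):
        with pytest.raises(ValidationError):
            extract(gt_lt_matrix, [Condition("A", Op.GT, 1.0, "B")], top_n=top_n)

    def test_top_n_truncates(self):
        rng = np.random.default_rng(3)
        tags = _tags(rng, 40)
        filler = "A" * 10
        # filler mass in B makes every other tag TPM-enriched in A
        a = SageLibrary("A", {t: 10 for t in tags if t != filler} | {filler: 10})
        b = SageLibrary("B", {t: 1 for t in tags if t != filler} | {filler: 400})
        m = build_matrix([a, b])
        pool = [Condition("A", Op.GT, 2.0, "B")]
        assert len(extract(m, pool).mined) == 10  # default
        assert len(extract(m, pool, top_n=25).mined) == 25

    def test_all_included_result_is_subset_of_every_tm(self):
        from sagemine import set_inclusion

        rng = np.random.default_rng(11)
        libs, raw_pool = random_instance(rng)
        m = build_matrix(libs)
        pool = set_inclusion([_to_condition(c) for c in raw_pool])
        res = extract(m, pool, top_n=100)
        for ts in res.per_condition_sets:
            assert set(res.mined) <= ts.members


def _to_condition(tup):
    lib_a, op, factor, lib_b, incl = tup
    return Condition(lib_a, Op(op), factor, lib_b, inclusion=incl)


class TestTissueSpecificMining:
    def test_breast_specific_set_recovered_exactly(self):
        """Four-tissue design with exact planted counts: markers up 4-fold in
        breast cases only are mined by breast-included / others-excluded
        screening at factor 2, and nothing else is."""
        rng = np.random.default_rng(17)
        background = _tags(rng, 20)
        markers = _tags(np.random.default_rng(18), 4)
        markers = [t for t in markers if t not in background][:3]
        tissues = ["colon", "ovary", "pancreas", "breast"]
        libs = []
        for ts in tissues:
            for role in ("case", "ctrl"):
                counts = {t: 10 for t in background}
                counts.update(
                    {t: 40 if (ts == "breast" and role == "case") else 10
                     for t in markers}
                )
                libs.append(SageLibrary(f"{ts.upper()}_{role.upper()}", counts, tissue=ts))
        m = build_matrix(libs)
        pool = [
            Condition(f"{ts.upper()}_CASE", Op.GT, 2.0, f"{ts.upper()}_CTRL",
                      inclusion=(ts == "breast"), label=ts)
            for ts in tissues
        ]
        res = extract(m, pool, top_n=100)
        assert set(res.mined) == set(markers)
        # cross-checked against the per-tag brute-force enumeration
        counts_dict = libs_to_count_dicts(libs)
        raw_pool = [(c.lib_a, c.op.value, c.factor, c.lib_b, c.inclusion) for c in pool]
        expected, _ = oracle_extract(counts_dict, sorted(m.tags), raw_pool, top_n=100)
        assert res.mined == expected


class TestScoring:
    def test_score_is_sum_of_folds_over_included(self):
        fold_df = pd.DataFrame(
            {"0:A>B": {T1: 10.0, T2: 1.0}, "1:C>D": {T1: 2.0, T2: 1.0}}
        )
        from sagemine import FoldMatrix
        fm = FoldMatrix(fold=fold_df, flags=fold_df * 0, conditions=[])
        scores = score_tags(fm, {0, 1})
        assert scores == {T1: 12.0, T2: 2.0}

    def test_tie_broken_lexicographically(self):
        m = make_matrix_from_tpm(
            {"A": {T1: 100.0, T2: 100.0}, "B": {T1: 10.0, T2: 10.0}}
        )
        res = extract(m, [Condition("A", Op.GT, 2.0, "B")])
        assert res.mined == sorted([T1, T2])

    def test_single_condition_order_is_descending_fold(self, gt_lt_matrix):
        res = extract(gt_lt_matrix, [Condition("A", Op.GT, 1.0, "B")])
        folds = [res.scores[t] for t in res.mined]
        assert folds == sorted(folds, reverse=True)


class TestScaleTransform:
    def test_linear_is_identity(self):
        x = np.array([0.0, 1.0, 7.0])
        np.testing.assert_array_equal(scale_transform(x, "linear"), x)

    def test_log2_shifts_by_one(self):
        assert scale_transform(np.array([7.0]), "log2")[0] == 3.0

    def test_sqrt_of_zero(self):
        assert scale_transform(np.array([0.0]), "sqrt")[0] == 0.0

    def test_unknown_scale_rejected(self):
        with pytest.raises(ValidationError):
            scale_transform(np.array([1.0]), "cubic")

    def test_negative_values_rejected(self):
        with pytest.raises(ValidationError):
            scale_transform(np.array([-1.0]), "log2")

    @pytest.mark.parametrize("scale", ["linear", "log2", "log10", "sqrt"])
    @given(xs=st.lists(st.floats(min_value=0, max_value=1e6), min_size=2, max_size=20))
    def test_rank_preserving(self, scale, xs):
        x = np.array(xs)
        y = np.asarray(scale_transform(x, scale))
        assert (np.argsort(y, kind="stable") == np.argsort(x, kind="stable")).all()


class TestOracleEquivalence:
    def test_extract_matches_brute_force_on_random_instances(self):
        """Vectorized miner == per-tag brute-force enumeration, exact equality."""
        rng = np.random.default_rng(20260929)
        for _ in range(100):
            libs, raw_pool = random_instance(rng)
            m = build_matrix(libs)
            pool = [_to_condition(c) for c in raw_pool]
            res = extract(m, pool, top_n=100)
            counts = libs_to_count_dicts(libs)
            expected_order, expected_sets = oracle_extract(
                counts, sorted(m.tags), raw_pool, top_n=100
            )
            assert res.mined == expected_order
            for ts, exp in zip(res.per_condition_sets, expected_sets):
                assert ts.members == exp

    def test_fold_matches_scalar_oracle(self):
        rng = np.random.default_rng(5)
        libs, _ = random_instance(rng)
        m = build_matrix(libs)
        counts = libs_to_count_dicts(libs)
        for tag in m.tags:
            for num in m.libraries:
                for den in m.libraries:
                    if num == den:
                        continue
                    got, _flag = fold(m, tag, num, den)
                    assert got == pytest.approx(oracle_fold(counts, tag, num, den))


class TestConditionPoolFile:
    def test_round_trip(self, tmp_path):
        pool = [
            Condition("GSM670", Op.GT, 2.0, "GSM677", inclusion=True, label="breast"),
            Condition("GSM755", Op.LT, 4.0, "GSM728", inclusion=False, label="colon"),
            Condition("GSM735", Op.NOT_IN, 1.0, "GSM719", inclusion=True, label="ovary"),
        ]
        p = tmp_path / "pool.tsv"
        write_condition_pool(pool, p)
        assert read_condition_pool(p) == pool

    def test_bad_operator_rejected(self, tmp_path):
        p = tmp_path / "pool.tsv"
        p.write_text("A\t>=\t2\tB\tY\tx\n")
        from sagemine import ParseError
        with pytest.raises(ParseError, match="operator"):
            read_condition_pool(p)


def test_fold_matrix_columns_follow_condition_direction(gt_lt_matrix):
    pool = [Condition("A", Op.GT, 2.0, "B"), Condition("A", Op.LT, 1.0, "B")]
    fm = build_fold_matrix(gt_lt_matrix, pool)
    # GT column is A/B, LT column is B/A: for T1 these are 10 and 0.1
    assert fm.fold.iloc[:, 0][T1] == pytest.approx(10.0)
    assert fm.fold.iloc[:, 1][T1] == pytest.approx(0.1)
    assert set(np.unique(fm.flags.to_numpy())) <= {
        "normal", "zero_numerator", "adjusted_denominator", "both_zero"
    }
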