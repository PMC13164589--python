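"""Karyomorphometry: per-chromosome metrics, classification, formulas, indices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from karyodelim import datasets, karyomorph
from karyodelim.io_tables import ChromosomeRecord, ValidationError
from karyodelim.karyomorph import (
    CategoryAssignment,
    ClassificationThresholds,
    aggregate_indices,
    chromosome_metrics,
    classify_chromosome,
    classify_r_values,
    karyotype_formula,
    relative_lengths,
)

arm_pairs = st.tuples(
    st.floats(0.5, 50.0, allow_nan=False), st.floats(0.5, 50.0, allow_nan=False)
).map(lambda t: (max(t), min(t)))


class TestChromosomeMetrics:
    @pytest.mark.parametrize(
        "l, s, total, r, ci, adr",
        [
            (10.02, 3.89, 13.91, None, None, None),  # largest T. scardica pair
            (5.0, 5.0, 10.0, 1.0, 0.5, 0.0),  # perfectly metacentric
            (7.5, 2.5, 10.0, 3.0, 0.75, 0.5),  # hand arithmetic
        ],
    )
    def test_examples(self, l, s, total, r, ci, adr):
        m = chromosome_metrics((l, s))
        assert m.total_length == pytest.approx(total)
        if r is not None:
            assert m.r_index == pytest.approx(r)
            assert m.centromeric_index == pytest.approx(ci)
            assert m.arm_difference_ratio == pytest.approx(adr)

    def test_unordered_and_degenerate_arms_rejected(self):
        with pytest.raises(ValidationError):
            chromosome_metrics((3.0, 5.0))
        with pytest.raises(ValidationError):
            chromosome_metrics((3.0, 0.0))

    @given(arm_pairs)
    @settings(deadline=None)
    def test_exact_identities_per_chromosome(self, pair):
        m = chromosome_metrics(pair)
        assert m.arm_difference_ratio == pytest.approx(
            2 * m.centromeric_index - 1, abs=1e-12
        )
        assert m.r_index == pytest.approx(
            m.centromeric_index / (1 - m.centromeric_index), rel=1e-12
        )

    @given(st.lists(arm_pairs, min_size=3, max_size=12))
    @settings(deadline=None)
    def test_adr_identity_survives_averaging_but_r_identity_does_not(self, pairs):
        """adr = 2*ci - 1 is linear, so it holds for averages of chromosomes;
        r = ci/(1 - ci) is nonlinear and in general fails after averaging."""
        ms = [chromosome_metrics(p) for p in pairs]
        mean_ci = np.mean([m.centromeric_index for m in ms])
        mean_adr = np.mean([m.arm_difference_ratio for m in ms])
        assert mean_adr == pytest.approx(2 * mean_ci - 1, abs=1e-12)
        mean_r = np.mean([m.r_index for m in ms])
        # nonlinear identity: only guaranteed when all ci are equal
        if np.ptp([m.centromeric_index for m in ms]) > 1e-3:
            assert mean_r > mean_ci / (1 - mean_ci) - 1e-12  # Jensen: mean of convex


class TestRelativeLengths:
    def test_largest_scardica_pair_printed_value(self, scardica_pairs):
        rel = relative_lengths(scardica_pairs)
        assert round(rel[1], 3) == 0.052

    def test_identical_pairs_give_uniform_relative_length(self):
        pairs = [ChromosomeRecord("sp", "p", i, 6.0, 4.0) for i in range(1, 13)]
        rel = relative_lengths(pairs)
        assert all(v == pytest.approx(1 / 24) for v in rel.values())

    def test_sum_over_pairs_is_half(self, rng):
        longs = rng.uniform(5, 12, 12)
        shorts = longs * rng.uniform(0.2, 0.9, 12)
        pairs = [
            ChromosomeRecord("sp", "p", i + 1, l, s)
            for i, (l, s) in enumerate(zip(longs, shorts))
        ]
        assert sum(relative_lengths(pairs).values()) == pytest.approx(0.5)

    def test_incomplete_complement_names_missing_pairs(self, scardica_pairs):
        with pytest.raises(ValidationError, match=r"\[12\]"):
            relative_lengths(scardica_pairs[:-1])


class TestClassification:
    @pytest.mark.parametrize(
        "r, expected",
        [(1.0, "m"), (1.69, "m"), (1.7, "sm"), (2.86, "sm"), (3.27, "st"),
         (3.02, "sm/st"), (2.96, "sm/st"), (7.5, "t")],
    )
    def test_default_thresholds(self, r, expected):
        assert classify_chromosome(r) == expected

    def test_band_zero_removes_mixed_class(self):
        t = ClassificationThresholds(borderline_band=0.0)
        assert classify_chromosome(3.02, t) == "st"
        assert classify_chromosome(3.0, t) == "sm/st"  # exact cutoff stays mixed

    def test_r_below_one_rejected(self):
        with pytest.raises(ValidationError):
            classify_chromosome(0.9)

    def test_published_scardica_formula_from_printed_ratios(self):
        r_values = {i: r for i, r, *_ in datasets.CHROMOSOME_RATIOS[datasets.SCARDICA]}
        formula = karyotype_formula(
            classify_r_values(r_values, datasets.SAT_PAIRS[datasets.SCARDICA])
        )
        assert formula == "8 sm + 4 sm-SAT + 2 sm/st-SAT + 10 st"


class TestKaryotypeFormula:
    def test_all_metacentric_no_sat(self):
        asg = [CategoryAssignment(i, "m", False) for i in range(1, 13)]
        assert karyotype_formula(asg) == "24 m"

    def test_counts_are_chromosomes_not_pairs(self):
        asg = (
            [CategoryAssignment(i, "sm", False) for i in range(1, 5)]
            + [CategoryAssignment(i, "sm", True) for i in range(5, 7)]
            + [CategoryAssignment(7, "sm/st", True)]
            + [CategoryAssignment(i, "st", False) for i in range(8, 13)]
        )
        assert karyotype_formula(asg) == "8 sm + 4 sm-SAT + 2 sm/st-SAT + 10 st"

    @given(
        st.lists(
            st.tuples(st.sampled_from(["m", "sm", "sm/st", "st", "t"]), st.booleans()),
            min_size=12,
            max_size=12,
        )
    )
    def test_term_counts_always_sum_to_2n(self, cats):
        asg = [CategoryAssignment(i + 1, c, s) for i, (c, s) in enumerate(cats)]
        formula = karyotype_formula(asg)
        assert sum(int(term.split()[0]) for term in formula.split(" + ")) == 24

    def test_wrong_pair_count_rejected(self):
        with pytest.raises(ValidationError):
            karyotype_formula([CategoryAssignment(1, "m", False)])


class TestAggregateIndices:
    def test_brute_force_agreement_on_reference_complements(
        self, scardica_pairs, undulatifolia_pairs
    ):
        """Direct formula evaluation (independent of the implementation's
        internals) must agree to machine precision."""
        for pairs in (scardica_pairs, undulatifolia_pairs):
            idx = aggregate_indices(pairs)
            lengths = np.array([p.long_arm + p.short_arm for p in pairs])
            ci = np.array([p.long_arm / (p.long_arm + p.short_arm) for p in pairs])
            adr = np.array(
                [(p.long_arm - p.short_arm) / (p.long_arm + p.short_arm) for p in pairs]
            )
            assert idx.tcl == pytest.approx(2 * lengths.sum(), abs=1e-12)
            assert idx.thl == pytest.approx(lengths.sum(), abs=1e-12)
            assert idx.acl == pytest.approx(lengths.sum() / 12, abs=1e-12)
            assert idx.cv_cl == pytest.approx(
                100 * lengths.std(ddof=1) / lengths.mean(), abs=1e-12
            )
            assert idx.m_ca == pytest.approx(100 * adr.mean(), abs=1e-12)
            assert idx.cv_ci == pytest.approx(100 * ci.std(ddof=1) / ci.mean(), abs=1e-12)

    def test_identical_chromosomes_degenerate_case(self):
        pairs = [ChromosomeRecord("sp", "p", i, 6.0, 4.0) for i in range(1, 13)]
        idx = aggregate_indices(pairs)
        assert idx.cv_cl == 0.0
        assert idx.cv_ci == pytest.approx(0.0, abs=1e-12)
        assert idx.m_ca == pytest.approx(20.0)

    @given(st.floats(0.1, 10.0), st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_scale_invariance(self, k, seed):
        rng = np.random.default_rng(seed)
        longs = rng.uniform(5, 12, 12)
        shorts = longs * rng.uniform(0.2, 0.9, 12)
        base = [
            ChromosomeRecord("sp", "p", i + 1, l, s)
            for i, (l, s) in enumerate(zip(longs, shorts))
        ]
        scaled = [
            ChromosomeRecord("sp", "p", p.pair_index, k * p.long_arm, k * p.short_arm)
            for p in base
        ]
        a, b = aggregate_indices(base), aggregate_indices(scaled)
        for fname in ("cv_cl", "m_ca", "cv_ci"):
            assert getattr(b, fname) == pytest.approx(getattr(a, fname), rel=1e-9)
        for fname in ("min_length", "max_length", "tcl", "acl", "thl"):
            assert getattr(b, fname) == pytest.approx(k * getattr(a, fname), rel=1e-9)
        assert relative_lengths(scaled) == pytest.approx(relative_lengths(base))


class TestComplementTable:
    def test_report_rounding_conventions(self, scardica_pairs):
        table = karyomorph.complement_table(scardica_pairs)
        assert len(table) == 12
        row1 = table.iloc[0]
        assert row1["total_length"] == 13.91
        assert row1["relative_length"] == 0.052
        assert table["relative_length"].sum() == pytest.approx(0.5, abs=0.01)
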