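"""Rates, background subtraction, logit/BH helpers, specificity ratios."""

import math

import pandas as pd
import pytest
from hypothesis import given, strategies as st

from dualcut.quantification import (
    CLASS_SCHEMA,
    LESION_CLASSES,
    LesionCountTable,
    bh_adjust,
    compute_rates,
    fold_improvement,
    logit_transform,
    precise_deletion_fraction,
    specificity_ratio,
    subtract_background,
    subtract_background_catalog,
    summarize_specificity,
)


def _table(sample_id="s", unclassified=0, **counts):
    full = {cls: counts.get(cls, 0) for cls in CLASS_SCHEMA}
    return LesionCountTable(sample_id, full, unclassified)


class TestComputeRates:
    def test_percentages(self):
        rates = compute_rates(_table(UNEDITED=90, PRECISE_DELETION=10))
        assert rates.rate("PRECISE_DELETION") == pytest.approx(10.0)
        assert rates.total_lesion_rate == pytest.approx(10.0)

    def test_all_unedited_has_zero_lesion_rate(self):
        rates = compute_rates(_table(UNEDITED=50))
        assert rates.total_lesion_rate == 0.0

    def test_round_trip_to_counts(self):
        counts = dict(UNEDITED=37, PRECISE_DELETION=11, SP_INDEL=2)
        table = _table(**counts)
        rates = compute_rates(table)
        for cls, n in counts.items():
            assert rates.rate(cls) * table.total / 100 == pytest.approx(n)

    def test_empty_sample_is_an_error_not_nan(self):
        with pytest.raises(ValueError):
            compute_rates(_table())

    def test_unclassified_kept_in_denominator(self):
        rates = compute_rates(_table(UNEDITED=90, unclassified=10))
        assert rates.unclassified_rate == pytest.approx(10.0)
        assert rates.rate("UNEDITED") == pytest.approx(90.0)


class TestBackgroundSubtraction:
    def test_mean_of_controls_subtracted(self):
        treated = compute_rates(_table(UNEDITED=90, PRECISE_DELETION=10))
        controls = [compute_rates(_table(UNEDITED=100 - n, PRECISE_DELETION=n))
                    for n in (1, 1, 1)]
        corrected = subtract_background(treated, controls)
        assert corrected.rate("PRECISE_DELETION") == pytest.approx(9.0)
        assert corrected.corrected

    def test_floors_at_zero(self):
        treated = compute_rates(_table(UNEDITED=199, PRECISE_DELETION=1))  # 0.5%
        controls = [compute_rates(_table(UNEDITED=99, PRECISE_DELETION=1))] * 3
        corrected = subtract_background(treated, controls)
        assert corrected.rate("PRECISE_DELETION") == 0.0

    def test_self_subtraction_is_identically_zero(self):
        treated = compute_rates(_table(UNEDITED=70, PRECISE_DELETION=20,
                                       SP_INDEL=6, INVERSION=4))
        corrected = subtract_background(treated, [treated, treated, treated])
        assert all(corrected.rate(c) == 0.0 for c in CLASS_SCHEMA)

    def test_corrected_never_exceeds_raw(self):
        treated = compute_rates(_table(UNEDITED=60, PRECISE_DELETION=30,
                                       BOTH_INDEL=10))
        controls = [compute_rates(_table(UNEDITED=95, PRECISE_DELETION=5))] * 3
        corrected = subtract_background(treated, controls)
        for cls in CLASS_SCHEMA:
            assert 0.0 <= corrected.rate(cls) <= treated.rate(cls)

    def test_no_controls_is_an_error(self):
        with pytest.raises(ValueError):
            subtract_background(compute_rates(_table(UNEDITED=1)), [])

    def test_positional_catalog_matched_exactly(self):
        treated = pd.DataFrame({
            "frame": ["WT", "WT"], "kind": ["deletion", "insertion"],
            "position": [60, 110], "length": [2, 3],
            "count": [10, 5], "frequency": [0.10, 0.05]})
        control = pd.DataFrame({
            "frame": ["WT"], "kind": ["deletion"], "position": [60],
            "length": [2], "count": [2], "frequency": [0.02]})
        out = subtract_background_catalog(treated, [control, control, control])
        by_kind = out.set_index("kind")["frequency_corrected"]
        assert by_kind["deletion"] == pytest.approx(0.08)
        assert by_kind["insertion"] == pytest.approx(0.05)  # unmatched: untouched


class TestPreciseDeletionFraction:
    def test_ratio_of_precise_to_all_lesions(self):
        rates = compute_rates(_table(UNEDITED=90, PRECISE_DELETION=9, SP_INDEL=1))
        assert precise_deletion_fraction(rates) == pytest.approx(0.9)

    def test_only_precise_lesions_gives_one(self):
        rates = compute_rates(_table(UNEDITED=50, PRECISE_DELETION=50))
        assert precise_deletion_fraction(rates) == pytest.approx(1.0)

    def test_no_lesions_is_undefined(self):
        rates = compute_rates(_table(UNEDITED=100))
        assert math.isnan(precise_deletion_fraction(rates))

    def test_recovered_within_binomial_noise_of_simulation(self):
        from dualcut.lesion_classifier import classify_sample
        from dualcut.synthetic_data import SimulationConfig, simulate_molecules
        config = SimulationConfig(n_molecules=2000, substitution_rate=0.0)
        mols, truth, ref = simulate_molecules(config, seed=61)
        rates = compute_rates(classify_sample(mols, ref).table)
        truth_frac = ((truth.true_class == "PRECISE_DELETION").sum()
                      / truth.true_class.isin(LESION_CLASSES).sum())
        assert precise_deletion_fraction(rates) == pytest.approx(truth_frac, abs=0.02)


class TestLogit:
    def test_half_maps_to_zero(self):
        assert logit_transform(0.5) == pytest.approx(0.0)

    def test_point_nine_closed_form(self):
        assert logit_transform(0.9) == pytest.approx(math.log(9.0))

    @given(st.floats(0.01, 0.99))
    def test_antisymmetry(self, p):
        assert logit_transform(p) == pytest.approx(-logit_transform(1.0 - p))

    def test_boundary_clamped_by_half_molecule(self):
        assert logit_transform(0.0, n_total=100) == pytest.approx(
            math.log((1 / 200) / (1 - 1 / 200)))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            logit_transform(1.5)


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    def test_adjusted_at_least_raw_and_monotone(self, pvals):
        adjusted = bh_adjust(pvals)
        assert all(a >= p - 1e-12 for a, p in zip(adjusted, pvals))
        order = sorted(range(len(pvals)), key=lambda i: pvals[i])
        assert all(adjusted[order[i]] <= adjusted[order[i + 1]] + 1e-12
                   for i in range(len(order) - 1))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.2])


class TestSpecificity:
    def test_ratio(self):
        assert specificity_ratio(100, [20, 30]) == pytest.approx(2.0)

    def test_no_off_targets_is_infinite(self):
        assert math.isinf(specificity_ratio(50, []))

    def test_zero_on_target(self):
        assert specificity_ratio(0, [10]) == 0.0

    def test_both_zero_is_undefined(self):
        assert math.isnan(specificity_ratio(0, []))

    @pytest.mark.parametrize("variant,reference,expected", [
        (8.0, 2.0, 4.0), (3.0, 3.0, 1.0)])
    def test_fold_improvement(self, variant, reference, expected):
        assert fold_improvement(variant, reference) == pytest.approx(expected)

    def test_fold_improvement_propagates_infinity(self):
        assert math.isinf(fold_improvement(math.inf, 2.0))

    def test_fold_improvement_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            fold_improvement(2.0, 0.0)

    def test_table_summary_with_reference(self):
        table = pd.DataFrame({
            "nuclease": ["WT", "WT", "WT", "fusion", "fusion"],
            "site_id": ["on", "ot1", "ot2", "on", "ot1"],
            "is_on_target": [True, False, False, True, False],
            "unique_reads": [100, 20, 30, 80, 10],
        })
        summaries = {s.nuclease_id: s
                     for s in summarize_specificity(table, "WT")}
        assert summaries["WT"].specificity_ratio == pytest.approx(2.0)
        assert summaries["fusion"].specificity_ratio == pytest.approx(8.0)
        assert summaries["fusion"].fold_improvement == pytest.approx(4.0)
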