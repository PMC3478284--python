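"""Histogram peaks, doubling-series classes, cytotype inference."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cytoploid import (
    AmbiguityError,
    PloidyAnalyzer,
    PloidySeriesModel,
    SyntheticSpec,
    UnresolvedCytotypeError,
    ValidationError,
    assign_classes,
    build_histogram,
    class_boundaries,
    estimate_unit,
    find_g1_peak,
    infer_cytotype,
    sample_nuclei,
    split_overlap,
)


class TestHistogram:
    def test_small_example(self):
        hist = build_histogram([0.5, 0.5, 1.0], bin_width=0.1)
        at = lambda x: hist.counts[np.searchsorted(hist.edges, x, "right") - 1]
        assert at(0.5) == 2
        assert at(1.0) == 1
        assert hist.counts.sum() == 3

    def test_rejects_empty_and_bad_width(self):
        with pytest.raises(ValidationError):
            build_histogram([])
        with pytest.raises(ValidationError):
            build_histogram([1.0], bin_width=0.0)

    @given(st.lists(st.floats(0.05, 20.0), min_size=1, max_size=300),
           st.floats(0.01, 1.0))
    @settings(max_examples=60, deadline=None)
    def test_counts_conserve_n(self, areas, width):
        hist = build_histogram(areas, width)
        assert hist.counts.sum() == len(areas)


class TestG1Peak:
    def test_single_class_peak_within_one_bin(self):
        rng = np.random.default_rng(0)
        areas = rng.normal(1.3, 0.1, 500)
        peak = find_g1_peak(build_histogram(areas, 0.1))
        assert abs(peak - 1.3) <= 0.1

    def test_dominant_gamete_mode_near_half_micron(self, gamete_sample):
        peak = find_g1_peak(build_histogram(gamete_sample["area_um2"], 0.1))
        assert abs(peak - 0.5) <= 0.1

    def test_flat_histogram_is_ambiguous(self):
        areas = [0.05 + 0.1 * i for i in range(10)]  # one nucleus per bin
        with pytest.raises(AmbiguityError):
            find_g1_peak(build_histogram(areas, 0.1), smooth_window=1)

    def test_equal_modes_warn_and_resolve_low(self):
        areas = [0.5] * 5 + [1.0] * 5
        with pytest.warns(UserWarning, match="equal histogram modes"):
            peak = find_g1_peak(build_histogram(areas, 0.1))
        assert abs(peak - 0.5) <= 0.1


class TestEstimateUnit:
    def test_idealized_gametes(self):
        areas = np.concatenate([np.full(50, 0.5), np.full(20, 1.0)])
        assert estimate_unit(areas) == pytest.approx(0.25, abs=1e-9)

    def test_synthetic_gametes_recover_quarter_micron(self, gamete_sample):
        unit = estimate_unit(gamete_sample["area_um2"])
        assert unit == pytest.approx(0.25, abs=0.01)

    def test_requires_gametes(self):
        with pytest.raises(ValidationError):
            estimate_unit([])


class TestClassBoundaries:
    def test_geometric_means(self):
        assert class_boundaries([0.5, 1.0])[1] == pytest.approx(0.70711, abs=1e-4)
        b = class_boundaries([1.0, 2.0, 4.0])
        assert b[1:3] == pytest.approx([1.41421, 2.82843], abs=1e-4)

    def test_single_center_covers_all_positive_areas(self):
        b = class_boundaries([0.8])
        assert b[0] == 0.0 and np.isinf(b[1])

    def test_rejects_non_increasing(self):
        with pytest.raises(ValidationError):
            class_boundaries([1.0, 0.5])


class TestSeriesModel:
    def test_header_series_from_gamete_unit(self):
        """unit 0.25 reproduces the published size approximations per level."""
        model = PloidySeriesModel(unit=0.25)
        printed = {2: 0.5, 3: 0.7, 4: 1.0, 6: 1.5, 8: 2.0, 12: 3.0,
                   16: 4.0, 32: 8.0}
        for m, c in zip(model.multipliers, model.centers):
            # 3Cx prints 0.7 vs arithmetic 0.75; everything else exact
            assert abs(c - printed[m]) <= 0.05 + 1e-12
        assert model.centers[-1] == pytest.approx(8.0)

    def test_invariants_enforced(self):
        with pytest.raises(ValidationError):
            PloidySeriesModel(unit=-1.0)
        with pytest.raises(ValidationError):
            PloidySeriesModel(unit=0.25, multipliers=(4, 2))
        with pytest.raises(ValidationError):
            PloidySeriesModel(unit=0.25, multipliers=(2, 4),
                              centers=(0.5, 1.0), boundaries=(0.0, 1.1, 2.0))


class TestAssignClasses:
    def test_boundary_arithmetic_example(self):
        model = PloidySeriesModel(unit=0.25, multipliers=(2, 4))
        pop = assign_classes(pd.DataFrame({"area_um2": [0.5, 0.72, 1.0]}), model)
        assert list(pop.records["cx"]) == [2, 4, 4]

    def test_single_center_takes_everything(self):
        model = PloidySeriesModel(unit=0.25, multipliers=(4,))
        pop = assign_classes([1.0] * 7, model)
        assert pop.counts == {4: 7}

    @given(st.lists(st.floats(0.1, 10.0), min_size=1, max_size=200),
           st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_counts_conserved_and_oracle_equivalent(self, areas, seed):
        """Boundary assignment == brute-force nearest center in log space."""
        model = PloidySeriesModel(unit=0.25)
        pop = assign_classes(areas, model)
        assert sum(pop.counts.values()) == len(areas)
        log_c = np.log(model.centers)
        oracle = [model.multipliers[int(np.argmin(np.abs(np.log(a) - log_c)))]
                  for a in areas]
        assert list(pop.records["cx"]) == oracle

    def test_out_of_series_records_flagged_not_lost(self):
        model = PloidySeriesModel(unit=0.25, multipliers=(2, 4))
        pop = assign_classes([0.01, 0.5, 40.0], model)
        flags = list(pop.records["flag"])
        assert flags.count("out_of_series") == 2
        assert sum(pop.counts.values()) == 3


class TestSplitOverlap:
    def _pop(self, areas):
        model = PloidySeriesModel(unit=0.25, multipliers=(2, 4))
        return assign_classes(areas, model), model

    def test_even_band_halved(self):
        # boundary at 0.7071; band ±10 percent
        areas = [0.66, 0.68, 0.73, 0.75]
        pop, _ = self._pop(areas)
        pop = split_overlap(pop, 2, 4)
        assert pop.counts == {2: 2, 4: 2}

    def test_odd_band_gives_extra_to_upper(self):
        areas = [0.65, 0.67, 0.70, 0.73, 0.76]
        pop, _ = self._pop(areas)
        pop = split_overlap(pop, 2, 4)
        assert pop.counts == {2: 2, 4: 3}

    def test_conserves_n_and_flags(self):
        areas = [0.3, 0.66, 0.68, 0.73, 0.75, 1.1]
        pop, _ = self._pop(areas)
        out = split_overlap(pop, 2, 4)
        assert sum(out.counts.values()) == len(areas)
        assert set(out.records["flag"]).issuperset(
            {"overlap_split_lower", "overlap_split_upper"})

    def test_non_adjacent_classes_rejected(self):
        model = PloidySeriesModel(unit=0.25, multipliers=(2, 4, 8))
        pop = assign_classes([0.5, 1.0, 2.0], model)
        with pytest.raises(ValidationError):
            split_overlap(pop, 2, 8)


class TestInferCytotype:
    def test_triploid_from_racemosa_like_g1(self):
        model = PloidySeriesModel(unit=0.25, multipliers=(3, 6))
        pop = assign_classes([0.7] * 50 + [1.4] * 10, model)
        prof = infer_cytotype(pop, unit=0.25)
        assert prof.base_multiplier == 3

    def test_unresolved_ratio_raises(self):
        model = PloidySeriesModel(unit=0.25, multipliers=(2, 4))
        pop = assign_classes([0.38] * 30, model)  # ratio 1.52: below 2Cx band
        with pytest.raises(UnresolvedCytotypeError):
            infer_cytotype(pop, unit=0.25)

    def test_phase_roles_pair_g2_with_g1(self):
        model = PloidySeriesModel(unit=0.25, multipliers=(4, 8, 16, 32))
        pop = assign_classes([1.0] * 50 + [2.0] * 20 + [4.0] * 5 + [8.0] * 2,
                             model)
        prof = infer_cytotype(pop, unit=0.25)
        present = {m for m, _ in prof.phases}
        for m, role in prof.phases:
            if role == "G2":
                assert m // 2 in present
        assert prof.endopolyploid  # four somatic classes


class TestPloidyAnalyzer:
    def test_diploid_no_endopolyploidy(self):
        spec = SyntheticSpec(class_centers=(0.55, 1.12),
                             class_weights=(123 / 152, 29 / 152),
                             cv=(0.2, 0.125), n=152, seed=5,
                             class_counts=(123, 29))
        fit = PloidyAnalyzer(unit=0.25, sample_id="taxifolia").fit(
            sample_nuclei(spec))
        assert fit.base_multiplier_ == 2
        assert tuple(fit.classes_) == (2, 4)
        assert not fit.endopolyploid_

    def test_tetraploid_endoreduplicating_frond(self, sterile_frond_sample):
        fit = PloidyAnalyzer(unit=0.245).fit(sterile_frond_sample)
        assert fit.base_multiplier_ == 4
        assert tuple(fit.classes_) == (4, 8, 16, 32)
        assert fit.endopolyploid_

    def test_conservation_through_fit(self, sterile_frond_sample):
        fit = PloidyAnalyzer(unit=0.245).fit(sterile_frond_sample)
        assert len(fit.classified_) == len(sterile_frond_sample)
        assert sum(c.count for c in fit.size_classes_) == len(
            sterile_frond_sample)

    def test_scale_equivariance(self, gamete_sample):
        """Multiplying all areas and the unit by k changes nothing."""
        k = 3.7
        base = PloidyAnalyzer(unit=0.25).fit(gamete_sample["area_um2"])
        scaled = PloidyAnalyzer(unit=0.25 * k).fit(
            gamete_sample["area_um2"] * k)
        assert base.base_multiplier_ == scaled.base_multiplier_
        assert tuple(base.classes_) == tuple(scaled.classes_)
        assert list(base.classified_["cx"]) == list(scaled.classified_["cx"])

    def test_predict_uses_fitted_boundaries(self, gamete_sample):
        fit = PloidyAnalyzer(unit=0.25).fit(gamete_sample)
        pred = fit.predict([0.5, 0.72, 1.0])
        assert list(pred) == [2, 4, 4]

    def test_sklearn_param_interface(self):
        est = PloidyAnalyzer(unit=0.25)
        params = est.get_params()
        assert params["unit"] == 0.25
        est.set_params(bin_width=0.2)
        assert est.bin_width == 0.2

    def test_unit_required(self, gamete_sample):
        with pytest.raises(ValidationError):
            PloidyAnalyzer().fit(gamete_sample)

    def test_gamete_portion_not_somatic(self, gamete_sample):
        fit = PloidyAnalyzer(unit=0.25).fit(gamete_sample)
        assert not fit.endopolyploid_
        assert set(fit.classified_["phase"]) == {"G1", "G2"}
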