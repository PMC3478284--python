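"""Generator contracts: mixture sampling, presets, field rendering."""

import math

import numpy as np
import pandas as pd
import pytest

from cytoploid import (
    FieldSpec,
    ResolutionError,
    SyntheticSpec,
    UnknownPresetError,
    ValidationError,
    preset_cytotype,
    preset_names,
    render_field,
    sample_nuclei,
)
from cytoploid.synthetic import _PRESET_TABLE


class TestSyntheticSpec:
    def test_degenerate_dispersion_gives_constant_areas(self):
        spec = SyntheticSpec(class_centers=(0.5,), class_weights=(1.0,),
                             cv=1e-12, n=5, seed=0)
        df = sample_nuclei(spec)
        assert len(df) == 5
        assert df["area_um2"].to_numpy() == pytest.approx([0.5] * 5)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(class_centers=(1.0, 0.5), class_weights=(0.5, 0.5), cv=0.1, n=5),
            dict(class_centers=(0.5, 1.0), class_weights=(0.6, 0.6), cv=0.1, n=5),
            dict(class_centers=(-0.5,), class_weights=(1.0,), cv=0.1, n=5),
            dict(class_centers=(0.5,), class_weights=(1.0,), cv=1.5, n=5),
            dict(class_centers=(0.5,), class_weights=(1.0,), cv=0.1, n=0),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            SyntheticSpec(seed=0, **kwargs)

    def test_mixture_weights_respected(self):
        # two classes 0.9/0.1: the lower-class fraction must fall in the
        # analytic 99% binomial interval around 0.9
        spec = SyntheticSpec(class_centers=(0.5, 1.0),
                             class_weights=(0.9, 0.1), cv=0.05,
                             n=10_000, seed=7)
        df = sample_nuclei(spec)
        frac = (df["true_class"] == 0).mean()
        half = 2.576 * math.sqrt(0.9 * 0.1 / 10_000)
        assert 0.9 - half <= frac <= 0.9 + half

    def test_reproducible_and_seed_sensitive(self):
        spec = lambda s: SyntheticSpec(class_centers=(0.5,),
                                       class_weights=(1.0,), cv=0.2,
                                       n=50, seed=s)
        a = sample_nuclei(spec(3))["area_um2"]
        b = sample_nuclei(spec(3))["area_um2"]
        c = sample_nuclei(spec(4))["area_um2"]
        assert (a == b).all()
        assert not (a == c).all()

    def test_empirical_moments_converge(self):
        spec = SyntheticSpec(class_centers=(1.0,), class_weights=(1.0,),
                             cv=0.2, n=10_000, seed=5)
        areas = sample_nuclei(spec)["area_um2"]
        se = 0.2 / math.sqrt(10_000)
        assert abs(areas.mean() - 1.0) < 3 * se
        assert abs(areas.std(ddof=1) - 0.2) < 0.01


class TestPresets:
    def test_all_presets_valid_and_sampled_at_published_n(self):
        for name in preset_names():
            spec = preset_cytotype(name)  # construction validates invariants
            df = sample_nuclei(spec)
            assert len(df) == spec.n
            assert (df["area_um2"] > 0).all()

    def test_unknown_preset(self):
        with pytest.raises(UnknownPresetError):
            preset_cytotype("prolifera_blade")

    def test_taxifolia_frond_row(self):
        spec = preset_cytotype("taxifolia_frond")
        assert spec.class_centers == (0.55, 1.12)
        assert spec.class_counts == (123, 29)
        assert spec.n == 152

    def test_gamete_row(self):
        spec = preset_cytotype("prolifera_gametes")
        assert spec.class_centers == (0.49, 0.88)
        assert spec.class_counts == (18, 8)
        assert spec.n == 26

    def test_sterile_frond_class_means_within_3_se(self):
        spec = preset_cytotype("prolifera_sterile_frond", seed=2)
        assert spec.class_centers == (1.07, 2.29, 3.67, 7.54)
        df = sample_nuclei(spec)
        for k, (center, cv, count) in enumerate(
            zip(spec.class_centers, spec.cv, spec.class_counts)
        ):
            members = df.loc[df["true_class"] == k, "area_um2"]
            assert len(members) == count
            se = cv * center / math.sqrt(count)
            assert abs(members.mean() - center) < 3 * se + 1e-9


class TestRenderField:
    def test_single_nucleus_ground_truth(self):
        records = pd.DataFrame({"area_um2": [1.5]})
        fspec = FieldSpec(shape=(128, 128), n_chloroplasts=0, n_bacteria=0,
                          seed=0)
        image, truth = render_field(records, fspec)
        assert list(truth["category"]) == ["nucleus"]
        assert truth["area_um2"].iloc[0] == 1.5
        assert image.dtype == np.uint16

    def test_rendering_is_bit_deterministic(self):
        records = sample_nuclei(preset_cytotype("taxifolia_frond", seed=1)).head(6)
        fspec = FieldSpec(seed=9)
        img1, _ = render_field(records, fspec)
        img2, _ = render_field(records, fspec)
        assert np.array_equal(img1, img2)

    def test_nuclear_diameters_in_morphological_range(self):
        records = sample_nuclei(
            preset_cytotype("prolifera_reproductive_frond", seed=3)).head(15)
        _, truth = render_field(records, FieldSpec(seed=3))
        nuc = truth[truth["category"] == "nucleus"]
        diam = 2 * np.sqrt(nuc["area_um2"] / np.pi)
        assert ((diam >= 0.6) & (diam <= 4.0)).all()

    def test_subpixel_area_rejected(self):
        records = pd.DataFrame({"area_um2": [0.5]})
        with pytest.raises(ResolutionError):
            render_field(records, FieldSpec(pixel_scale=1.0, seed=0))

    def test_confounder_counts_rendered(self):
        records = pd.DataFrame({"area_um2": [0.8, 1.2]})
        fspec = FieldSpec(n_chloroplasts=3, n_bacteria=4, seed=5)
        _, truth = render_field(records, fspec)
        assert truth["category"].value_counts().to_dict() == {
            "bacterium": 4, "chloroplast": 3, "nucleus": 2}


def test_preset_table_counts_are_self_consistent():
    # row totals printed alongside per-class counts must agree
    for name, row in _PRESET_TABLE.items():
        assert sum(row["counts"]) == preset_cytotype(name).n
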