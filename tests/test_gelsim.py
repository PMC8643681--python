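"""Virtual gel simulator: sampling, effective writhe, mobility, rendering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from plectoneme.gelsim import (
    GelConditions,
    TopoisomerDistribution,
    calibrate_chloroquine_coefficient,
    dim2_saturation,
    effective_writhe,
    migrate,
    render_gel,
    sample_topoisomers,
)
from plectoneme.topology import CorrectionParameters, PlasmidSpec


class TestSampleTopoisomers:
    def test_degenerate_spread_collapses_to_one_band(self, ptptk2):
        dist = sample_topoisomers(ptptk2, -17.0, 0.01, 1000, seed=1)
        assert dist.entries == ((-17, 1000.0),)

    def test_empirical_mean_matches_center(self, ptptk2):
        n = 100_000
        dist = sample_topoisomers(ptptk2, 0.0, 1.5, n, seed=2)
        # multinomial sampling: mean within 3 standard errors of the center
        se = 1.5 / np.sqrt(n)
        assert abs(dist.mean_writhe()) < 3 * se

    def test_same_seed_is_bit_identical(self, ptptk2):
        a = sample_topoisomers(ptptk2, 3.0, 1.2, 5000, seed=7)
        b = sample_topoisomers(ptptk2, 3.0, 1.2, 5000, seed=7)
        assert a.entries == b.entries

    def test_rejects_bad_inputs(self, ptptk2):
        with pytest.raises(ValueError):
            sample_topoisomers(ptptk2, 0.0, 1.0, 0, seed=0)
        with pytest.raises(ValueError):
            sample_topoisomers(ptptk2, 0.0, -1.0, 10, seed=0)


class TestEffectiveWrithe:
    def test_reproduces_worked_example_forward(self, ptptk2, counting_gel, params):
        # native +5 grown at 85 C appears as +14 on the 1.5 ug/ml gel at 24 C
        assert effective_writhe(5, ptptk2, counting_gel, 85.0, params, 1) == 14.0
        assert effective_writhe(-17, ptptk2, counting_gel, 85.0, params, 1) == -8.0

    def test_no_chloroquine_equal_temperature_is_identity(self, ptptk2, params):
        gel = GelConditions(
            temperature_C=85.0, chloroquine_dim1_ug_ml=0.0, chloroquine_dim2_ug_ml=0.0
        )
        assert effective_writhe(-3, ptptk2, gel, 85.0, params, 1) == -3.0

    def test_affine_in_native_writhe(self, ptptk2, counting_gel, params):
        vals = [
            effective_writhe(w, ptptk2, counting_gel, 85.0, params, 1)
            for w in (-2, 0, 2)
        ]
        assert vals[2] - vals[1] == vals[1] - vals[0] == 2.0


class TestCalibration:
    def test_from_paired_measurement(self, ptptk2):
        u = calibrate_chloroquine_coefficient(19.0, 1.5, ptptk2)
        assert u == pytest.approx(2.322e-3, rel=1e-3)

    def test_zero_supercoils_zero_coefficient(self, ptptk2):
        assert calibrate_chloroquine_coefficient(0.0, 1.5, ptptk2) == 0.0

    def test_round_trip_adds_back_19_supercoils(self, ptptk2, counting_gel):
        u = calibrate_chloroquine_coefficient(19.0, 1.5, ptptk2)
        params = CorrectionParameters(chloroquine_unwinding_per_ug_ml_per_bp=u)
        same_temp = GelConditions(
            temperature_C=85.0, chloroquine_dim1_ug_ml=1.5, chloroquine_dim2_ug_ml=7.5
        )
        assert effective_writhe(0, ptptk2, same_temp, 85.0, params, 1) == 19.0

    def test_zero_concentration_rejected(self, ptptk2):
        with pytest.raises(ValueError):
            calibrate_chloroquine_coefficient(19.0, 0.0, ptptk2)


class TestMigrate:
    def test_relaxed_comigrates_with_nicked_at_origin(self):
        assert migrate(0.0, GelConditions()) == 0.0

    def test_front_band_saturation(self):
        gel = GelConditions()
        S = gel.mobility_saturation_wr
        assert migrate(S, gel) == gel.migration_max
        assert migrate(-(S + 15), gel) == gel.migration_max

    @given(
        a=st.floats(-19.9, 19.9),
        b=st.floats(-19.9, 19.9),
    )
    def test_strictly_monotone_in_magnitude_below_saturation(self, a, b):
        gel = GelConditions()
        if abs(a) < abs(b):
            assert migrate(a, gel) < migrate(b, gel)
        elif abs(a) == abs(b):
            assert migrate(a, gel) == migrate(b, gel)


class TestRenderGel:
    def test_single_topoisomer_gives_single_band_at_its_position(
        self, ptptk2, counting_gel, params
    ):
        dist = TopoisomerDistribution(ptptk2, ((5, 1000.0),))
        profile = render_gel(dist, counting_gel, 85.0, params, mode="1D")
        peak_pos = profile.loc[profile["intensity"].idxmax(), "position"]
        expected = migrate(
            effective_writhe(5, ptptk2, counting_gel, 85.0, params, 1), counting_gel
        )
        assert peak_pos == pytest.approx(expected, abs=0.2)

    def test_total_area_conserves_total_abundance(self, ptptk2, counting_gel, params):
        dist = sample_topoisomers(ptptk2, 5.0, 1.5, 10_000, seed=3, nicked_fraction=0.1)
        profile = render_gel(dist, counting_gel, 85.0, params, mode="1D")
        area = np.trapezoid(profile["intensity"], profile["position"])
        total = dist.total_closed + dist.nicked_abundance
        assert area == pytest.approx(total, rel=1e-6)

    def test_noise_free_render_is_deterministic(self, ptptk2, counting_gel, params):
        dist = sample_topoisomers(ptptk2, 5.0, 1.5, 10_000, seed=3)
        a = render_gel(dist, counting_gel, 85.0, params, mode="1D")
        b = render_gel(dist, counting_gel, 85.0, params, mode="1D")
        pd.testing.assert_frame_equal(a, b)

    def test_seeded_noise_is_reproducible(self, ptptk2, params):
        gel = GelConditions(
            chloroquine_dim1_ug_ml=1.5, noise_sd=0.5, seed=9
        )
        dist = sample_topoisomers(ptptk2, 5.0, 1.5, 10_000, seed=3)
        a = render_gel(dist, gel, 85.0, params, mode="1D")
        b = render_gel(dist, gel, 85.0, params, mode="1D")
        pd.testing.assert_frame_equal(a, b)

    def test_2d_arcs_mirror_symmetric_for_symmetric_distribution(
        self, ptptk2, params
    ):
        # chloroquine only in dimension 2, equal temperatures: species +w and
        # -w share x and sit symmetrically about the relaxed ordinate in y
        gel = GelConditions(
            temperature_C=85.0,
            chloroquine_dim1_ug_ml=0.0,
            chloroquine_dim2_ug_ml=7.5,
        )
        entries = tuple((w, 100.0) for w in range(-5, 6))
        dist = TopoisomerDistribution(ptptk2, entries)
        spots = render_gel(dist, gel, 85.0, params, mode="2D")
        spots = spots.set_index("true_writhe")
        y0 = spots.loc[0, "dimension2_position"]
        for w in range(1, 6):
            assert spots.loc[w, "dimension1_position"] == pytest.approx(
                spots.loc[-w, "dimension1_position"]
            )
            up = spots.loc[w, "dimension2_position"] - y0
            down = y0 - spots.loc[-w, "dimension2_position"]
            assert up == pytest.approx(down, rel=1e-9)
            assert up > 0

    def test_opposite_signs_separate_in_dimension_2(
        self, ptptk2, reference_gel, params
    ):
        dist = TopoisomerDistribution(ptptk2, ((6, 10.0), (-6, 10.0)))
        spots = render_gel(dist, reference_gel, 85.0, params, mode="2D")
        x = spots["dimension1_position"]
        y = spots["dimension2_position"]
        assert x.iloc[0] != pytest.approx(x.iloc[1])  # temp shift breaks |.| tie
        assert abs(y.iloc[0] - y.iloc[1]) > 1.0


def test_dim2_saturation_covers_arc_range(ptptk2, counting_gel, params):
    s2 = dim2_saturation(ptptk2, counting_gel, params)
    assert s2 > counting_gel.mobility_saturation_wr
    # a topoisomer countable in dim 1 stays in the linear dim-2 regime
    e2 = effective_writhe(5, ptptk2, counting_gel, 85.0, params, 2)
    assert abs(e2) < s2
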