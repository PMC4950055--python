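"""BCCG distribution math: centiles, z-scores, density, tabulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

import lmsgrowth as lg
from lmsgrowth.bccg import (
    DEFAULT_CENTILES,
    CentileSpec,
    DomainError,
    InvalidParameterError,
    LMSTable,
    LMSTriple,
    round_half_away,
)

BOYS_38 = LMSTriple(L=0.69, M=3019.0, S=0.162)
BOYS_40 = LMSTriple(L=0.83, M=3251.0, S=0.150)


def valid_triples():
    return st.builds(
        LMSTriple,
        L=st.floats(-0.5, 1.5),
        M=st.floats(500.0, 5000.0),
        S=st.floats(0.05, 0.3),
    )


class TestCentileValue:
    def test_median_identity(self):
        assert lg.centile_value(BOYS_38, 0.0) == BOYS_38.M

    def test_lognormal_limit_closed_form(self):
        got = lg.centile_value(LMSTriple(0.0, 1000.0, 0.1), 1.0)
        assert got == pytest.approx(1000.0 * np.exp(0.1), rel=1e-12)

    def test_normal_case_is_linear_in_z(self):
        lms = LMSTriple(1.0, 3000.0, 0.15)
        assert lg.centile_value(lms, 2.0) == pytest.approx(3900.0)
        assert lg.centile_value(lms, -2.0) == pytest.approx(2100.0)

    def test_published_cell_boys_40w_2nd(self):
        # 2nd centile (z = -2) at 40 weeks for boys; printed chart shows 2302 g
        assert round_half_away(lg.centile_value(BOYS_40, -2.0)) == pytest.approx(2302, abs=3)

    def test_domain_error_when_transform_leaves_support(self):
        with pytest.raises(DomainError):
            lg.centile_value(LMSTriple(1.0, 3000.0, 0.3), -4.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            LMSTriple(0.5, -1.0, 0.1)
        with pytest.raises(InvalidParameterError):
            LMSTriple(0.5, 3000.0, 0.0)


class TestZScore:
    def test_median_maps_to_zero(self):
        assert lg.zscore_value(BOYS_38.M, BOYS_38) == 0.0

    def test_inverse_of_centile_at_minus_two(self):
        # oracle: the full-precision 2nd-centile weight maps back to z = -2
        x = lg.centile_value(BOYS_40, -2.0)
        assert lg.zscore_value(x, BOYS_40) == pytest.approx(-2.0, abs=1e-12)
        # the chart-rounded weight 2302.4 g still scores -2.000 to 3 decimals
        assert round(lg.zscore_value(2302.4, BOYS_40), 3) == -2.0

    def test_rejects_nonpositive_weight(self):
        with pytest.raises(InvalidParameterError):
            lg.zscore_value(0.0, BOYS_38)

    @settings(derandomize=True, max_examples=200)
    @given(lms=valid_triples(), z=st.floats(-3.0, 3.0))
    def test_round_trip_property(self, lms, z):
        if abs(lms.L) >= 1e-8 and 1.0 + lms.L * lms.S * z <= 1e-6:
            return  # outside the BCCG support
        x = lg.centile_value(lms, z)
        assert lg.zscore_value(x, lms) == pytest.approx(z, abs=1e-9)

    @settings(derandomize=True, max_examples=100)
    @given(lms=valid_triples(), z=st.floats(-2.5, 2.4))
    def test_centile_strictly_increasing_in_z(self, lms, z):
        dz = 0.1
        if abs(lms.L) >= 1e-8 and 1.0 + lms.L * lms.S * min(z, z + dz) <= 1e-6:
            return
        assert lg.centile_value(lms, z + dz) > lg.centile_value(lms, z)

    @settings(derandomize=True, max_examples=100)
    @given(m=st.floats(500, 5000), s=st.floats(0.05, 0.3), z=st.floats(-3, 3))
    def test_small_L_matches_lognormal_limit(self, m, s, z):
        near_zero = lg.centile_value(LMSTriple(1e-8, m, s), z)
        assert abs(near_zero - m * np.exp(s * z)) < 1e-6 * m


class TestDistribution:
    def test_cdf_at_median_is_half(self):
        assert lg.bccg_cdf(BOYS_38.M, BOYS_38) == pytest.approx(0.5)

    def test_quantile_at_half_is_median(self):
        assert lg.bccg_quantile(0.5, BOYS_38) == pytest.approx(BOYS_38.M)

    @pytest.mark.parametrize("p", [0.1, 0.25, 0.5, 0.9, 0.98])
    def test_quantile_cdf_mutual_inverses(self, p):
        assert lg.bccg_cdf(lg.bccg_quantile(p, BOYS_38), BOYS_38) == pytest.approx(p, abs=1e-9)

    @pytest.mark.parametrize("p", [0.1, 0.5, 0.9])
    def test_cdf_matches_numeric_integration_of_density(self, p):
        # independent oracle: integrate exp(logdensity) from near zero
        x = lg.bccg_quantile(p, BOYS_38)
        val, err = quad(lambda u: np.exp(lg.bccg_logdensity(u, BOYS_38)), 1.0, x, limit=200)
        assert val == pytest.approx(lg.bccg_cdf(x, BOYS_38), abs=1e-6)

    def test_quantile_rejects_bad_probability(self):
        with pytest.raises(InvalidParameterError):
            lg.bccg_quantile(1.0, BOYS_38)


class TestCentileSpec:
    def test_default_is_two_thirds_sd_spaced(self):
        assert DEFAULT_CENTILES.labels == ("2nd", "9th", "25th", "50th", "75th", "91st", "98th")
        assert DEFAULT_CENTILES.z == pytest.approx((-2, -4 / 3, -2 / 3, 0, 2 / 3, 4 / 3, 2))

    def test_rejects_non_increasing_z(self):
        with pytest.raises(ValueError):
            CentileSpec(labels=("a", "b"), z=(1.0, 1.0))

    def test_rejects_duplicate_labels(self):
        with pytest.raises(ValueError):
            CentileSpec(labels=("a", "a"), z=(0.0, 1.0))


class TestLMSTable:
    def test_gap_detection(self):
        frame = lg.reference_lms_table().to_frame()
        frame = frame[~((frame.sex == "F") & (frame.week == 35))]
        with pytest.raises(ValueError, match=r"\('F', 35\)"):
            LMSTable(frame)

    def test_interpolation_exact_at_knots(self, reference_lms):
        trip = lg.interpolate_lms(reference_lms, "M", 38.0)
        assert trip == reference_lms.triple("M", 38)

    def test_interpolation_log_median_midpoint(self, reference_lms):
        # oracle: geometric mean of the printed 38- and 39-week boys' medians
        trip = lg.interpolate_lms(reference_lms, "M", 38.5)
        assert trip.M == pytest.approx(np.sqrt(3019.0 * 3164.0), rel=1e-12)
        assert trip.M == pytest.approx(3090.6, abs=0.1)

    def test_interpolation_range_error(self, reference_lms):
        with pytest.raises(ValueError):
            lg.interpolate_lms(reference_lms, "M", 27.9)


class TestCentileTable:
    def test_rows_strictly_increasing_across_labels(self, reference_lms):
        ct = lg.make_centile_table(reference_lms)
        for sex in ("M", "F"):
            values = ct.frame(sex).to_numpy()
            assert (np.diff(values, axis=1) > 0).all()

    def test_median_only_spec_gives_M_column(self, reference_lms):
        ct = lg.make_centile_table(reference_lms, CentileSpec(("50th",), (0.0,)))
        for sex in ("M", "F"):
            for week in reference_lms.weeks:
                assert ct.frame(sex).loc[week, "50th"] == round(reference_lms.triple(sex, week).M)

    def test_domain_error_names_offending_cell(self):
        table = LMSTable.from_dict({("M", 30): LMSTriple(1.0, 3000.0, 0.3)})
        spec = CentileSpec(("lo", "hi"), (-4.0, 4.0))
        with pytest.raises(DomainError, match="sex=M, week=30, label='lo'"):
            lg.make_centile_table(table, spec)


def test_round_half_away_from_zero():
    assert round_half_away(2302.5) == 2303
    assert round_half_away(-2.5) == -3
    assert round_half_away(2.49) == 2
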