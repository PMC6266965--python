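import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eistrack import (
    ArrayType,
    CohortDataset,
    FormatError,
    FrequencyGrid,
    ImpedanceSpectrum,
    SessionMeta,
    SessionTime,
    default_grid,
    from_complex,
    make_frequency_grid,
    read_cohort,
    read_instrument_dta,
    read_spectrum_csv,
    to_complex,
    write_cohort,
    write_instrument_dta,
    write_spectrum_csv,
)


class TestFrequencyGrid:
    def test_default_grid_is_31_points_with_exact_1khz(self):
        g = make_frequency_grid(5, 1, 1e6)
        assert len(g) == 31
        assert g.values[15] == 1000.0  # exact, not approximate
        assert g.values[0] == 1.0 and g.values[-1] == 1e6

    def test_log_spacing_closed_form(self):
        g = make_frequency_grid(5, 1, 1e6)
        assert g.values[7] == pytest.approx(10 ** (7 / 5), rel=1e-15)

    def test_single_point_per_decade(self):
        g = make_frequency_grid(1, 1, 10)
        np.testing.assert_allclose(g.values, [1.0, 10.0])

    def test_constant_ratio(self):
        g = default_grid()
        ratios = g.values[1:] / g.values[:-1]
        np.testing.assert_allclose(ratios, 10 ** 0.2, rtol=1e-12)

    @pytest.mark.parametrize(
        "args", [(5, -1, 1e6), (5, 0, 1e6), (5, 1e6, 1), (5, 1, 1), (0, 1, 1e6)]
    )
    def test_invalid_bounds_raise(self, args):
        with pytest.raises(ValueError):
            make_frequency_grid(*args)

    def test_grid_rejects_unsorted(self):
        with pytest.raises(ValueError):
            FrequencyGrid(np.array([1.0, 3.0, 2.0]))


class TestSessionTime:
    def test_ordering(self):
        order = [
            SessionTime.in_vitro(),
            SessionTime.post_op(),
            SessionTime.week_(2),
            SessionTime.week_(3),
            SessionTime.week_(12),
        ]
        assert order == sorted(reversed(order))

    def test_weekly_sessions_start_at_two(self):
        with pytest.raises(ValueError):
            SessionTime.week_(1)

    def test_label_round_trip(self):
        for s in (SessionTime.in_vitro(), SessionTime.post_op(), SessionTime.week_(7)):
            assert SessionTime.from_label(s.label()) == s

    def test_channel_range_enforced(self):
        with pytest.raises(ValueError):
            SessionMeta("a", 17, ArrayType.IROX, SessionTime.in_vitro())


class TestComplexConversion:
    def test_zero_phase_is_real(self, irox_meta):
        g = FrequencyGrid(np.array([1000.0]))
        s = ImpedanceSpectrum(g, np.array([100.0]), np.array([0.0]), irox_meta)
        assert to_complex(s)[0] == pytest.approx(100 + 0j)

    def test_minus_ninety_is_negative_imaginary(self, irox_meta):
        g = FrequencyGrid(np.array([1000.0]))
        s = ImpedanceSpectrum(g, np.array([100.0]), np.array([-90.0]), irox_meta)
        z = to_complex(s)[0]
        assert z.real == pytest.approx(0.0, abs=1e-10)
        assert z.imag == pytest.approx(-100.0, rel=1e-10)

    @settings(max_examples=50, derandomize=True)
    @given(
        zmag=st.lists(st.floats(1e-3, 1e9), min_size=3, max_size=8),
        phase=st.lists(st.floats(-179.0, 179.0), min_size=8, max_size=8),
    )
    def test_polar_round_trip(self, zmag, phase):
        meta = SessionMeta("a", 1, ArrayType.IROX, SessionTime.in_vitro())
        n = len(zmag)
        g = FrequencyGrid(np.logspace(0, 3, n))
        s = ImpedanceSpectrum(g, np.array(zmag), np.array(phase[:n]), meta)
        back = from_complex(g, to_complex(s), meta)
        np.testing.assert_allclose(back.zmag, s.zmag, rtol=1e-12)
        np.testing.assert_allclose(back.phase, s.phase, rtol=1e-12, atol=1e-12)


CSV_OK = "frequency_hz,zmag_ohm,zphz_deg\n10,1000,-30\n100,500,-20\n1000,200,-10\n"


class TestCsvIO:
    def test_well_formed(self, irox_meta):
        s = read_spectrum_csv(io.StringIO(CSV_OK), irox_meta)
        assert len(s) == 3
        np.testing.assert_allclose(s.frequencies, [10, 100, 1000])

    def test_rows_sorted_on_read(self, irox_meta):
        shuffled = "frequency_hz,zmag_ohm,zphz_deg\n1000,200,-10\n10,1000,-30\n100,500,-20\n"
        a = read_spectrum_csv(io.StringIO(CSV_OK), irox_meta)
        b = read_spectrum_csv(io.StringIO(shuffled), irox_meta)
        np.testing.assert_array_equal(a.zmag, b.zmag)
        np.testing.assert_array_equal(a.phase, b.phase)

    @pytest.mark.parametrize(
        "bad",
        [
            "frequency_hz,zmag_ohm\n10,1000\n",  # missing column
            "frequency_hz,zmag_ohm,zphz_deg\n10,zero,-30\n",  # non-numeric
            "frequency_hz,zmag_ohm,zphz_deg\n10,1,0\n10,2,0\n",  # duplicate freq
            "frequency_hz,zmag_ohm,zphz_deg\n10,0,-30\n100,1,0\n",  # |Z| = 0
            "frequency_hz,zmag_ohm,zphz_deg\n",  # no rows
        ],
    )
    def test_malformed_raises(self, bad, irox_meta):
        with pytest.raises(FormatError):
            read_spectrum_csv(io.StringIO(bad), irox_meta)

    def test_round_trip_full_precision(self, randles_spectrum):
        buf = io.StringIO()
        write_spectrum_csv(randles_spectrum, buf)
        back = read_spectrum_csv(io.StringIO(buf.getvalue()), randles_spectrum.meta)
        np.testing.assert_array_equal(back.zmag, randles_spectrum.zmag)
        np.testing.assert_array_equal(back.phase, randles_spectrum.phase)
        np.testing.assert_array_equal(back.frequencies, randles_spectrum.frequencies)


DTA_RECT_ONLY = (
    "EXPLAIN\nTAG\tEISPOT\nZCURVE\tTABLE\t1\n"
    "\tPt\tFreq\tZreal\tZimag\n\t#\tHz\tohm\tohm\n\t0\t1000\t3\t-4\n"
)


class TestInstrumentIO:
    def test_magnitude_from_rectangular(self, irox_meta):
        s = read_instrument_dta(io.StringIO(DTA_RECT_ONLY), irox_meta)
        assert s.zmag[0] == pytest.approx(5.0)
        assert s.phase[0] == pytest.approx(-53.130, abs=1e-3)

    def test_empty_table_raises(self, irox_meta):
        text = "EXPLAIN\nZCURVE\tTABLE\t0\n\tPt\tFreq\tZreal\tZimag\n\t#\tHz\tohm\tohm\n"
        with pytest.raises(FormatError):
            read_instrument_dta(io.StringIO(text), irox_meta)

    def test_no_zcurve_raises(self, irox_meta):
        with pytest.raises(FormatError):
            read_instrument_dta(io.StringIO("EXPLAIN\nOCVCURVE\tTABLE\n"), irox_meta)

    def test_inconsistent_zmod_recomputed_with_warning(self, irox_meta):
        text = (
            "ZCURVE\tTABLE\t1\n\tPt\tFreq\tZreal\tZimag\tZmod\tZphz\n"
            "\t#\tHz\tohm\tohm\tohm\t°\n\t0\t1000\t3\t-4\t7.5\t-53.13\n"
        )
        with pytest.warns(UserWarning, match="inconsistent"):
            s = read_instrument_dta(io.StringIO(text), irox_meta)
        assert s.zmag[0] == pytest.approx(5.0)

    def test_write_read_write_is_bit_identical(self, randles_spectrum):
        buf1 = io.StringIO()
        write_instrument_dta(randles_spectrum, buf1)
        back = read_instrument_dta(io.StringIO(buf1.getvalue()), randles_spectrum.meta)
        buf2 = io.StringIO()
        write_instrument_dta(back, buf2)
        assert buf1.getvalue() == buf2.getvalue()
        np.testing.assert_array_equal(back.zmag, randles_spectrum.zmag)
        np.testing.assert_array_equal(back.phase, randles_spectrum.phase)


class TestCohortContainer:
    @pytest.mark.parametrize("file_format", ["csv", "dta"])
    def test_directory_round_trip(self, tmp_path, randles_spectrum, file_format):
        cohort = CohortDataset()
        cohort.add(randles_spectrum, truth="hockey-stick")
        write_cohort(cohort, tmp_path / "cohort", file_format=file_format)
        back = read_cohort(tmp_path / "cohort")
        assert len(back) == 1
        key = randles_spectrum.meta.key
        assert back.truth_labels[key] == "hockey-stick"
        np.testing.assert_array_equal(back.spectra[key].zmag, randles_spectrum.zmag)

    def test_duplicate_key_rejected(self, randles_spectrum):
        cohort = CohortDataset()
        cohort.add(randles_spectrum)
        with pytest.raises(ValueError):
            cohort.add(randles_spectrum)
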