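import math

import numpy as np
import pandas as pd
import pytest

from eistrack import (
    ArrayType,
    Category,
    CategoryLabel,
    CohortDataset,
    ExtendedParams,
    FrequencyGrid,
    ImpedanceSpectrum,
    RandlesParams,
    SessionMeta,
    SessionTime,
    aggregate_metric,
    channel_trajectories,
    convert_q_units,
    f_peak,
    impedance_at_1khz,
    population_table,
    scale_access_resistance,
    scale_areal_admittance,
    simulate_spectrum,
)
from eistrack.circuit import TWO_PI, z_extended
from eistrack.longitudinal import UNMEASURED


def spectrum_on(freqs, zmag, phase, meta):
    return ImpedanceSpectrum(
        FrequencyGrid(np.asarray(freqs, float)),
        np.asarray(zmag, float),
        np.asarray(phase, float),
        meta,
    )


class TestImpedanceAt1kHz:
    def test_exact_grid_sample(self, grid, irox_meta):
        zmag = np.linspace(1e6, 1e3, 31)
        s = ImpedanceSpectrum(grid, zmag, np.full(31, -45.0), irox_meta)
        assert impedance_at_1khz(s) == zmag[15]

    def test_log_log_interpolation(self, irox_meta):
        s = spectrum_on([500.0, 2000.0], [2000.0, 500.0], [-45.0, -45.0], irox_meta)
        # closed form: log-log line through (500, 2000) and (2000, 500)
        slope = (math.log10(500) - math.log10(2000)) / (math.log10(2000) - math.log10(500))
        expected = 10 ** (math.log10(2000) + slope * (3 - math.log10(500)))
        assert impedance_at_1khz(s) == pytest.approx(expected, rel=1e-12)
        assert impedance_at_1khz(s) == pytest.approx(1000.0, rel=1e-12)  # symmetry

    def test_unbracketed_grid_raises(self, irox_meta):
        s = spectrum_on([2000.0, 4000.0], [1e3, 1e3], [0.0, 0.0], irox_meta)
        with pytest.raises(ValueError):
            impedance_at_1khz(s)


class TestFPeak:
    def test_monotone_phase_peaks_at_top_frequency(self, grid, irox_meta):
        phase = np.linspace(-80, -5, 31)
        s = ImpedanceSpectrum(grid, np.full(31, 1e5), phase, irox_meta)
        assert f_peak(s) == grid.values[-1]

    def test_tie_breaks_to_lowest_frequency(self, irox_meta):
        s = spectrum_on([10, 100, 1000], [1e5] * 3, [-20.0, -50.0, -20.0], irox_meta)
        assert f_peak(s) == 10.0

    def test_aged_hockey_stick_peak_matches_dense_oracle(self, grid, irox_meta):
        p = ExtendedParams(
            base=RandlesParams(R_E=6.2e10, Q=30e-8 / TWO_PI**0.64, n=0.64, R_S=138e3),
            C_d=5e-11,
        )
        s = simulate_spectrum(p, grid, irox_meta)
        fp = f_peak(s)
        dense = np.logspace(0, 6, 5001)
        f_oracle = dense[np.argmax(np.rad2deg(np.angle(z_extended(TWO_PI * dense, p))))]
        # grid argmax within one 5-per-decade step of the continuous argmax
        assert abs(math.log10(fp) - math.log10(f_oracle)) <= 0.2 + 1e-9
        assert grid.values[0] < fp < grid.values[-1]


def wk(n):
    return SessionTime.week_(n)


class TestPopulationTable:
    def test_full_array_single_category(self):
        roster = [("a", ch) for ch in range(1, 17)]
        labels = {("a", ch, wk(2)): CategoryLabel(Category.MIXED) for ch in range(1, 17)}
        table = population_table(labels, roster, [wk(2)])
        assert table.loc["week02", "mixed"] == 16
        assert table.loc["week02", UNMEASURED] == 0

    def test_absent_array_counts_unmeasured(self):
        roster = [("a", ch) for ch in range(1, 17)]
        labels = {("a", ch, wk(2)): CategoryLabel(Category.MIXED) for ch in range(1, 17)}
        table = population_table(labels, roster, [wk(2), wk(9)])
        assert table.loc["week09", UNMEASURED] == 16
        assert (table.sum(axis=1) == 16).all()

    def test_empty_labels_all_unmeasured(self):
        roster = [("a", 1), ("a", 2)]
        table = population_table({}, roster, [wk(2)])
        assert table.loc["week02", UNMEASURED] == 2


class TestAggregation:
    def test_three_channels_report_count_only(self):
        df = pd.DataFrame(
            {"category": ["mixed"] * 3, "session": ["week02"] * 3, "value": [1.0, 2.0, 3.0]}
        )
        out = aggregate_metric(df)
        assert out.loc[0, "count"] == 3
        assert math.isnan(out.loc[0, "mean"]) and math.isnan(out.loc[0, "sem"])

    def test_four_identical_values(self):
        df = pd.DataFrame(
            {"category": ["mixed"] * 4, "session": ["week02"] * 4, "value": [7.0] * 4}
        )
        out = aggregate_metric(df)
        assert out.loc[0, "mean"] == 7.0 and out.loc[0, "sem"] == 0.0

    def test_hand_computed_sem(self):
        df = pd.DataFrame(
            {"category": ["mixed"] * 4, "session": ["week02"] * 4, "value": [1.0, 2.0, 3.0, 4.0]}
        )
        out = aggregate_metric(df)
        assert out.loc[0, "mean"] == pytest.approx(2.5)
        sd = math.sqrt(((1 - 2.5) ** 2 + (2 - 2.5) ** 2 + (3 - 2.5) ** 2 + (4 - 2.5) ** 2) / 3)
        assert out.loc[0, "sem"] == pytest.approx(sd / 2)


class TestUnitConversions:
    def test_areal_admittance_published_example(self):
        # 27e-6 S s^-n mm^-2 over a 4000 um^2 tip
        got = scale_areal_admittance(27e-6, 4000.0)
        assert got == pytest.approx(1.08e-7, rel=1e-12)
        assert float(f"{got:.1e}") == pytest.approx(1.1e-7)

    def test_areal_admittance_identity_area(self):
        assert scale_areal_admittance(3.3e-6, 1e6) == pytest.approx(3.3e-6)

    def test_areal_admittance_hand_value(self):
        assert scale_areal_admittance(1e-6, 500.0) == pytest.approx(5e-10)

    def test_access_resistance_published_example(self):
        # 7.38 kOhm at 900 um^2 rescaled to a 4000 um^2 electrode
        assert scale_access_resistance(7380.0, 900.0, 4000.0) == pytest.approx(1660.5)

    def test_access_resistance_identity(self):
        assert scale_access_resistance(1234.0, 4000.0, 4000.0) == 1234.0

    def test_access_resistance_hand_value(self):
        assert scale_access_resistance(1000.0, 100.0, 400.0) == pytest.approx(250.0)

    def test_q_unit_conversion_published_example(self):
        got = convert_q_units(0.89e-9, 0.86)
        assert float(f"{got:.1e}") == pytest.approx(1.6e-8)

    def test_q_unit_conversion_identity_exponent(self):
        assert convert_q_units(4.2e-9, 1.0) == pytest.approx(4.2e-9)

    def test_q_unit_conversion_hand_value(self):
        assert convert_q_units(1e-10, 0.5) == pytest.approx(1e-5)


class TestTrajectories:
    def test_points_ordered_and_fpeak_only_for_hockey_stick(self, grid):
        cohort = CohortDataset()
        labels = {}
        p = ExtendedParams.randles(RandlesParams(6.2e10, 9.25e-8, 0.64, 138e3))
        for session, cat in [
            (SessionTime.in_vitro(), Category.HOCKEY_STICK),
            (wk(2), Category.MIXED),
        ]:
            meta = SessionMeta("a", 1, ArrayType.IROX, session)
            cohort.add(simulate_spectrum(p, grid, meta))
            labels[meta.key] = CategoryLabel(cat)
        (traj,) = channel_trajectories(cohort, labels)
        assert [pt[0] for pt in traj.points] == [SessionTime.in_vitro(), wk(2)]
        assert traj.points[0][3] is not None  # hockey-stick carries f_peak
        assert traj.points[1][3] is None
        assert traj.points[0][2] > 0
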