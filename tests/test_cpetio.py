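"""I/O and preprocessing-chain tests, including brute-force oracles."""

import logging
import math

import numpy as np
import pandas as pd
import pytest

from cpetml import cpetio
from cpetml.cpetio import (BreathTable, REGRESSOR_CHANNELS, derive_ratios,
                           extract_windows, interpolate_to_seconds,
                           normalize_minmax, read_cpet_csv, read_labels,
                           window_tensor, write_cpet_csv, write_labels)
from cpetml.errors import (DegenerateValueError, FormatError,
                           InsufficientDataError, TooShortTestError,
                           ValidationError)
from conftest import random_breath_table


CSV_3ROW = """t,VO2,VCO2,VE,Rf,PetO2,PetCO2
0.0,300,250,10,15,110,32
2.5,400,330,12,16,109,33
5.0,500,430,14,17,108,34
"""


class TestReadWrite:
    def test_well_formed_csv_is_read_verbatim(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(CSV_3ROW)
        bt = read_cpet_csv(p)
        assert len(bt) == 3
        assert bt.channel("VO2").tolist() == [300, 400, 500]

    def test_missing_mandatory_column_names_it(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(CSV_3ROW.replace("VE,", "XX,"))
        with pytest.raises(FormatError, match="VE"):
            read_cpet_csv(p)

    def test_non_increasing_time_reports_row(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("t,VO2,VCO2,VE,Rf,PetO2,PetCO2\n"
                     "0,300,250,10,15,110,32\n"
                     "5,400,330,12,16,109,33\n"
                     "5,500,430,14,17,108,34\n")
        with pytest.raises(ValidationError, match="row 3"):
            read_cpet_csv(p)

    def test_write_read_round_trip(self, tmp_path, breath_table):
        p = tmp_path / "rt.csv"
        write_cpet_csv(breath_table, p)
        back = read_cpet_csv(p)
        for ch in ["t"] + breath_table.channels:
            np.testing.assert_allclose(back.data[ch], breath_table.data[ch],
                                       rtol=1e-9)

    def test_domain_comment_round_trip(self, tmp_path, tiny_breath_table):
        p = tmp_path / "d.csv"
        write_cpet_csv(tiny_breath_table, p, domain="second")
        assert read_cpet_csv(p).data.attrs["domain"] == "second"

    def test_label_json_round_trip(self, tmp_path):
        labels = {"VT1_s": 300.0, "VT2_s": None,
                  "VT1_VO2": 1500.0, "VT2_VO2": None}
        p = tmp_path / "l.json"
        write_labels(labels, p)
        assert read_labels(p) == labels

    def test_label_json_missing_key_rejected(self, tmp_path):
        p = tmp_path / "l.json"
        p.write_text('{"VT1_s": 1.0}')
        with pytest.raises(FormatError, match="VT2_s"):
            read_labels(p)


class TestInterpolation:
    def test_linear_midpoint(self, tiny_breath_table):
        st = interpolate_to_seconds(tiny_breath_table)
        assert st.channel("VO2")[st.t == 5.0][0] == pytest.approx(800.0)

    def test_constant_channel_stays_constant(self):
        df = pd.DataFrame({"t": [0.3, 4.1, 9.9],
                           "VO2": [700.0] * 3, "VCO2": [600.0] * 3,
                           "VE": [20.0] * 3, "Rf": [20.0] * 3,
                           "PetO2": [100.0] * 3, "PetCO2": [35.0] * 3})
        st = interpolate_to_seconds(BreathTable(df))
        assert np.all(st.channel("VO2") == 700.0)
        assert st.t[0] == 1.0 and st.t[-1] == 9.0

    def test_grid_is_one_hertz(self, breath_table):
        st = interpolate_to_seconds(breath_table)
        assert np.all(np.diff(st.t) == 1.0)

    def test_matches_bruteforce_two_point_oracle(self, rng):
        for _ in range(20):
            bt = random_breath_table(rng, n_breaths=50)
            st = interpolate_to_seconds(bt)
            t, grid = bt.t, st.t
            for ch in bt.channels:
                v = bt.channel(ch)
                expect = np.empty(len(grid))
                for i, g in enumerate(grid):  # naive bracketing per second
                    j = np.searchsorted(t, g, side="right")
                    j = min(max(j, 1), len(t) - 1)
                    frac = (g - t[j - 1]) / (t[j] - t[j - 1])
                    expect[i] = v[j - 1] + frac * (v[j] - v[j - 1])
                np.testing.assert_allclose(st.channel(ch), expect,
                                           rtol=1e-9, atol=1e-9)

    def test_single_breath_rejected(self, tiny_breath_table):
        one = BreathTable(tiny_breath_table.data.iloc[:1])
        with pytest.raises(InsufficientDataError):
            interpolate_to_seconds(one)


class TestDerivedRatios:
    def test_ventilatory_equivalent_definition(self):
        from conftest import constant_second_table
        st = constant_second_table(n=10, VE=60.0, VO2=2400.0, VCO2=1800.0)
        out = derive_ratios(st)
        assert out.channel("VEVO2")[0] == pytest.approx(25.0)

    def test_rer_definition(self):
        from conftest import constant_second_table
        st = constant_second_table(n=10, VCO2=1800.0, VO2=2000.0)
        assert derive_ratios(st).channel("RER")[0] == pytest.approx(0.9)

    def test_zero_vo2_rejected_with_time(self):
        from conftest import constant_second_table
        st = constant_second_table(n=10)
        st.data.loc[4, "VO2"] = 0.0
        with pytest.raises(DegenerateValueError, match="t=4"):
            derive_ratios(st)

    def test_idempotent(self, breath_table):
        st = derive_ratios(interpolate_to_seconds(breath_table))
        twice = derive_ratios(st)
        pd.testing.assert_frame_equal(st.data, twice.data)


class TestNormalization:
    def test_affine_map_midpoint_and_endpoints(self):
        from conftest import constant_second_table
        st = constant_second_table(n=3, VE=np.array([10.0, 15.0, 20.0]))
        nt = normalize_minmax(st, ("VE",))
        np.testing.assert_allclose(nt.channel("VE"), [0.0, 0.5, 1.0])
        assert nt.stats["VE"] == (10.0, 20.0)

    def test_round_trip_denormalization(self, rng, breath_table):
        st = derive_ratios(interpolate_to_seconds(breath_table))
        nt = normalize_minmax(st, REGRESSOR_CHANNELS)
        back = nt.denormalize()
        for ch in REGRESSOR_CHANNELS:
            np.testing.assert_allclose(back[ch], st.channel(ch), atol=1e-9)

    def test_each_channel_attains_bounds(self, breath_table):
        st = derive_ratios(interpolate_to_seconds(breath_table))
        nt = normalize_minmax(st, REGRESSOR_CHANNELS)
        for ch in REGRESSOR_CHANNELS:
            x = nt.channel(ch)
            assert x.min() == 0.0 and x.max() == 1.0

    def test_constant_channel_maps_to_half_with_warning(self, caplog):
        from conftest import constant_second_table
        st = constant_second_table(n=10)
        with caplog.at_level(logging.WARNING, logger="cpetml.cpetio"):
            nt = normalize_minmax(st, ("PetCO2",))
        assert np.all(nt.channel("PetCO2") == 0.5)
        assert any("constant" in r.message for r in caplog.records)


class TestWindows:
    @pytest.mark.parametrize("n_rows,expected", [(40, 1), (100, 61)])
    def test_window_count(self, n_rows, expected, breath_table):
        st = derive_ratios(interpolate_to_seconds(breath_table))
        nt = normalize_minmax(st, REGRESSOR_CHANNELS)
        nt.data = nt.data.iloc[:n_rows]
        assert len(extract_windows(nt)) == expected

    def test_too_short_test_rejected(self, breath_table):
        st = derive_ratios(interpolate_to_seconds(breath_table))
        nt = normalize_minmax(st, REGRESSOR_CHANNELS)
        nt.data = nt.data.iloc[:39]
        with pytest.raises(TooShortTestError):
            extract_windows(nt)

    def test_windows_are_consecutive_slices_in_unit_range(self, breath_table):
        st = derive_ratios(interpolate_to_seconds(breath_table))
        nt = normalize_minmax(st, REGRESSOR_CHANNELS)
        wins = extract_windows(nt)
        arr = nt.data[list(nt.channels)].to_numpy()
        t = nt.t
        for k in (0, len(wins) // 2, len(wins) - 1):
            w = wins[k]
            assert w.values.shape == (40, 6)
            assert np.all((w.values >= 0) & (w.values <= 1))
            i = np.searchsorted(t, w.start_s)
            np.testing.assert_array_equal(w.values, arr[i:i + 40])

    def test_stride_changes_count(self, breath_table):
        st = derive_ratios(interpolate_to_seconds(breath_table))
        nt = normalize_minmax(st, REGRESSOR_CHANNELS)
        tensor, starts = window_tensor(nt, width_s=40, stride_s=5)
        assert tensor.shape[0] == (len(nt) - 40) // 5 + 1
        assert np.all(np.diff(starts) == 5.0)
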