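"""FLUXNET-style reader and the quality/meteorological filters."""

import numpy as np
import pandas as pd
import pytest

from svadetect.ec_io import (
    ConfigurationError,
    DataError,
    FilterSettings,
    apply_filters,
    read_fluxnet_csv,
    select_night,
)
from svadetect.synthetic import SynthConfig, generate_site, write_fluxnet_csv

COLS = "TIMESTAMP_START,LE_F_MDS,LE_F_MDS_QC,VPD_F,TA_F,SWC_F_MDS_1,P_F,NIGHT"


def write_csv(tmp_path, rows, name="XX-Tst.csv", header=COLS):
    p = tmp_path / name
    p.write_text(header + "\n" + "\n".join(rows) + "\n")
    return p


def ts(day, halfhour):
    return f"201501{day:02d}{halfhour // 2:02d}{30 * (halfhour % 2):02d}"


class TestReader:
    def test_sentinel_becomes_missing_not_zero(self, tmp_path):
        p = write_csv(tmp_path, [f"{ts(1, 0)},-9999,0,0.5,15,12,0,1"])
        s = read_fluxnet_csv(p)
        assert s.records["le"].isna().all()

    def test_zero_vpd_gives_saturated_air(self, tmp_path):
        p = write_csv(tmp_path, [f"{ts(1, 0)},5,0,0,15,12,0,1"])
        s = read_fluxnet_csv(p)
        assert s.records["rha"].iloc[0] == 100.0

    def test_full_day_cadence(self, tmp_path):
        rows = [f"{ts(1, h)},5,0,0.5,15,12,0,0" for h in range(48)]
        s = read_fluxnet_csv(write_csv(tmp_path, rows))
        assert len(s) == 48

    def test_duplicate_timestamps_rejected(self, tmp_path):
        rows = [f"{ts(1, 0)},5,0,0.5,15,12,0,0"] * 2
        with pytest.raises(DataError):
            read_fluxnet_csv(write_csv(tmp_path, rows))

    def test_missing_mapped_column_named_in_error(self, tmp_path):
        p = write_csv(
            tmp_path,
            [f"{ts(1, 0)},5,0,0.5,15,0,1"],
            header="TIMESTAMP_START,LE_F_MDS,LE_F_MDS_QC,VPD_F,TA_F,P_F,NIGHT",
        )
        with pytest.raises(ConfigurationError, match="SWC_F_MDS_1"):
            read_fluxnet_csv(p)

    def test_column_map_override(self, tmp_path):
        p = write_csv(
            tmp_path,
            [f"{ts(1, 0)},5,0,0.5,15,12,0,1"],
            header=COLS.replace("SWC_F_MDS_1", "SWC_F_MDS_2"),
        )
        s = read_fluxnet_csv(p, column_map={"vwc": "SWC_F_MDS_2"})
        assert s.records["vwc"].iloc[0] == 12.0

    def test_fractional_vwc_normalized_to_percent(self, tmp_path):
        p = write_csv(tmp_path, [f"{ts(1, 0)},5,0,0.5,15,0.12,0,1"])
        s = read_fluxnet_csv(p)
        assert s.records["vwc"].iloc[0] == pytest.approx(12.0)

    def test_vpd_in_hpa_dialect(self, tmp_path):
        p = write_csv(tmp_path, [f"{ts(1, 0)},5,0,5.0,15,12,0,1"])
        s = read_fluxnet_csv(p, vpd_unit="hPa")
        assert s.records["vpd"].iloc[0] == pytest.approx(0.5)

    def test_roundtrip_through_writer(self, tmp_path):
        series, truth = generate_site(SynthConfig(seed=1, n_days=3))
        p = tmp_path / "syn.csv"
        write_fluxnet_csv(series, p, truth)
        back = read_fluxnet_csv(p, site_id=series.site_id)
        assert len(back) == len(series)
        assert np.allclose(
            back.records["le"].to_numpy(), series.records["le"].to_numpy(), atol=1e-4
        )
        assert (tmp_path / "syn_truth.csv").exists()


class TestFilters:
    def base_rows(self):
        # two full days, all good
        return [f"{ts(d, h)},5,0,0.5,15,12,0,{int(h < 14)}" for d in (1, 2) for h in range(48)]

    def test_rain_day_invalidates_all_48_records(self, tmp_path):
        rows = self.base_rows()
        rows[10] = f"{ts(1, 10)},5,0,0.5,15,12,0.2,0"  # 0.2 mm in one half hour
        s = read_fluxnet_csv(write_csv(tmp_path, rows))
        flagged, report = apply_filters(s)
        day1 = flagged.records["timestamp"].dt.day == 1
        assert (~flagged.records.loc[day1, "valid"]).all()
        assert flagged.records.loc[~day1, "valid"].all()
        assert report.set_index("rule").loc["rain_day", "records_removed"] == 48

    def test_cold_half_hour_invalidated(self, tmp_path):
        rows = self.base_rows()
        rows[5] = f"{ts(1, 5)},5,0,0.5,4.9,12,0,1"
        flagged, _ = apply_filters(read_fluxnet_csv(write_csv(tmp_path, rows)))
        assert not flagged.records["valid"].iloc[5]
        assert flagged.records["invalid_reason"].iloc[5] == "ta"

    def test_gap_filled_flux_invalidated(self, tmp_path):
        rows = self.base_rows()
        rows[7] = f"{ts(1, 7)},5,1,0.5,15,12,0,1"
        flagged, _ = apply_filters(read_fluxnet_csv(write_csv(tmp_path, rows)))
        assert flagged.records["invalid_reason"].iloc[7] == "qc"

    def test_nonpositive_vwc_invalidated(self, tmp_path):
        rows = self.base_rows()
        rows[9] = f"{ts(1, 9)},5,0,0.5,15,0,0,1"
        flagged, _ = apply_filters(read_fluxnet_csv(write_csv(tmp_path, rows)))
        assert flagged.records["invalid_reason"].iloc[9] == "vwc"

    def test_counts_conserved_and_report_sums(self, tmp_path):
        rows = self.base_rows()
        rows[3] = f"{ts(1, 3)},-9999,0,0.5,15,12,0,1"
        rows[5] = f"{ts(1, 5)},5,2,0.5,15,12,0,1"
        rows[50] = f"{ts(2, 2)},5,0,0.5,2,12,0,1"
        s = read_fluxnet_csv(write_csv(tmp_path, rows))
        flagged, report = apply_filters(s)
        assert len(flagged) == len(s)  # no rows dropped
        n_invalid = int((~flagged.records["valid"]).sum())
        assert report["records_removed"].sum() == n_invalid

    def test_filtering_does_not_touch_values(self, filtered_synthetic):
        flagged, truth, _ = filtered_synthetic
        # only flag columns may differ from a fresh generation
        from svadetect.synthetic import SynthConfig as SC, generate_site as gen

        fresh, _ = gen(SC(seed=42))
        for col in ("le", "vwc", "ta", "vpd", "precip"):
            assert np.array_equal(
                flagged.records[col].to_numpy(), fresh.records[col].to_numpy()
            )

    def test_configurable_thresholds(self, tmp_path):
        rows = self.base_rows()
        rows[5] = f"{ts(1, 5)},5,0,0.5,7.0,12,0,1"
        s = read_fluxnet_csv(write_csv(tmp_path, rows))
        flagged, _ = apply_filters(s, FilterSettings(ta_min_c=10.0))
        assert not flagged.records["valid"].iloc[5]


class TestNightSelection:
    def test_all_day_series_selects_nothing(self, tmp_path):
        rows = [f"{ts(1, h)},5,0,0.5,15,12,0,0" for h in range(48)]
        flagged, _ = apply_filters(read_fluxnet_csv(write_csv(tmp_path, rows)))
        assert len(select_night(flagged)) == 0

    def test_matches_brute_force_recount(self, filtered_synthetic):
        flagged, _, _ = filtered_synthetic
        night = select_night(flagged)
        df = flagged.records
        expected = int((df["valid"] & df["night"]).sum())
        assert len(night) == expected

    def test_missing_night_flag_is_configuration_error(self, tmp_path):
        p = write_csv(
            tmp_path,
            [f"{ts(1, 0)},5,0,0.5,15,12,0"],
            header=COLS.replace(",NIGHT", ""),
        )
        flagged, _ = apply_filters(read_fluxnet_csv(p))
        with pytest.raises(ConfigurationError):
            select_night(flagged)
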