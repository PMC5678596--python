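import datetime as dt

import numpy as np
import pandas as pd
import pytest

from phenodiel import (
    CalibrationSpec,
    Frame,
    Modality,
    PhotoperiodSchedule,
    build_session,
    load_session,
    read_traits,
    write_masks,
    write_session,
    write_traits,
)
from phenodiel.session import TRAIT_COLUMNS, read_mask


def _frames(start: dt.datetime, n: int, schedule, step_min: int = 20):
    out = []
    for k in range(n):
        ts = start + dt.timedelta(minutes=k * step_min)
        if schedule.is_light(ts):
            out.append(Frame(np.zeros((8, 10, 3), np.uint8), ts, Modality.VIS))
        else:
            out.append(Frame(np.zeros((8, 10), np.uint8), ts, Modality.NIR))
    return out


class TestFrameInvariants:
    def test_vis_needs_three_planes(self):
        with pytest.raises(ValueError):
            Frame(np.zeros((8, 10), np.uint8), dt.datetime(2024, 1, 1), Modality.VIS)

    def test_nir_needs_single_plane(self):
        with pytest.raises(ValueError):
            Frame(np.zeros((8, 10, 3), np.uint8), dt.datetime(2024, 1, 1), Modality.NIR)

    def test_non_uint8_rejected(self):
        with pytest.raises(ValueError):
            Frame(np.zeros((8, 10), np.int32), dt.datetime(2024, 1, 1), Modality.NIR)


class TestSchedule:
    def test_light_plus_dark_is_24h(self, schedule_12_12):
        assert schedule_12_12.light_hours + schedule_12_12.dark_hours == 24.0

    def test_half_open_boundaries(self, schedule_12_12):
        assert schedule_12_12.is_light(dt.datetime(2024, 1, 1, 8, 0))
        assert not schedule_12_12.is_light(dt.datetime(2024, 1, 1, 20, 0))

    def test_wrapping_photoperiod(self):
        night_grown = PhotoperiodSchedule(dt.time(22, 0), dt.time(6, 0))
        assert night_grown.is_light(dt.datetime(2024, 1, 1, 23, 0))
        assert night_grown.is_light(dt.datetime(2024, 1, 1, 2, 0))
        assert not night_grown.is_light(dt.datetime(2024, 1, 1, 12, 0))
        assert night_grown.light_hours == 8.0


class TestPartition:
    def test_single_light_period(self, schedule_12_12):
        frames = _frames(dt.datetime(2024, 3, 1, 8, 0), 36, schedule_12_12)
        s = build_session(frames, schedule_12_12)
        assert len(s.periods) == 1
        assert s.periods[0].kind == "light" and s.periods[0].n_frames == 36

    def test_frame_at_lights_off_is_first_dark(self, schedule_12_12):
        frames = _frames(dt.datetime(2024, 3, 1, 19, 40), 2, schedule_12_12)
        s = build_session(frames, schedule_12_12)
        assert [p.kind for p in s.periods] == ["light", "dark"]
        assert s.frames[1].timestamp.time() == dt.time(20, 0)
        assert s.frames[1].modality is Modality.NIR

    def test_partition_matches_enumeration_oracle(self, schedule_12_12):
        # 105 frames at 20-min spacing starting 20 min after lights-on
        start = dt.datetime(2024, 3, 1, 8, 20)
        frames = _frames(start, 105, schedule_12_12)
        s = build_session(frames, schedule_12_12)
        # oracle: brute-force enumeration of each timestamp against the clock
        kinds = [
            "light" if schedule_12_12.is_light(start + dt.timedelta(minutes=20 * k))
            else "dark"
            for k in range(105)
        ]
        runs = []
        for k in kinds:
            if runs and runs[-1][0] == k:
                runs[-1][1] += 1
            else:
                runs.append([k, 1])
        assert [(p.kind, p.n_frames) for p in s.periods] == [
            (k, n) for k, n in runs
        ]
        assert [p.n_frames for p in s.periods] == [35, 36, 34]

    def test_partition_exhaustive_and_disjoint(self, schedule_12_12):
        frames = _frames(dt.datetime(2024, 3, 1, 10, 0), 100, schedule_12_12)
        s = build_session(frames, schedule_12_12)
        covered = [i for p in s.periods for i in range(p.start, p.stop)]
        assert covered == list(range(len(s.frames)))

    def test_duplicate_timestamps_rejected(self, schedule_12_12):
        f = _frames(dt.datetime(2024, 3, 1, 9, 0), 1, schedule_12_12)
        with pytest.raises(ValueError, match="duplicate"):
            build_session(f + f, schedule_12_12)

    def test_mixed_dimensions_rejected(self, schedule_12_12):
        a = Frame(np.zeros((8, 10, 3), np.uint8),
                  dt.datetime(2024, 3, 1, 9, 0), Modality.VIS)
        b = Frame(np.zeros((9, 10, 3), np.uint8),
                  dt.datetime(2024, 3, 1, 9, 20), Modality.VIS)
        with pytest.raises(ValueError, match="dimensions"):
            build_session([a, b], schedule_12_12)


class TestSessionIO:
    def test_write_load_round_trip_idempotent(self, tmp_path, schedule_12_12):
        rng = np.random.default_rng(0)
        frames = []
        for k, f in enumerate(
            _frames(dt.datetime(2024, 3, 1, 19, 0), 6, schedule_12_12)
        ):
            px = rng.integers(0, 256, f.pixels.shape, dtype=np.uint8)
            frames.append(Frame(px, f.timestamp, f.modality))
        s = build_session(frames, schedule_12_12)
        write_session(s, tmp_path)
        s1 = load_session(tmp_path, schedule_12_12)
        s2 = load_session(tmp_path, schedule_12_12)
        assert len(s1.frames) == 6
        for a, b, orig in zip(s1.frames, s2.frames, s.frames):
            assert a.timestamp == b.timestamp == orig.timestamp
            assert a.modality is orig.modality
            np.testing.assert_array_equal(a.pixels, b.pixels)
            np.testing.assert_array_equal(a.pixels, orig.pixels)

    def test_empty_directory_errors(self, tmp_path, schedule_12_12):
        with pytest.raises(ValueError, match="no images"):
            load_session(tmp_path, schedule_12_12)

    def test_mtime_fallback_warns(self, tmp_path, schedule_12_12):
        import imageio.v3 as iio

        iio.imwrite(tmp_path / "plain.png", np.zeros((4, 4), np.uint8))
        with pytest.warns(UserWarning, match="modification"):
            load_session(tmp_path, schedule_12_12)

    def test_mask_round_trip_bit_exact(self, tmp_path, schedule_12_12):
        frames = _frames(dt.datetime(2024, 3, 1, 8, 0), 3, schedule_12_12)
        s = build_session(frames, schedule_12_12)
        rng = np.random.default_rng(1)
        masks = [rng.integers(0, 3, (8, 10)).astype(np.int64) for _ in range(3)]
        paths = write_masks(s, masks, tmp_path / "masks")
        assert len(paths) == 3
        for p, m in zip(paths, masks):
            np.testing.assert_array_equal(read_mask(p), m)

    def test_mask_dimension_mismatch_errors(self, tmp_path, schedule_12_12):
        frames = _frames(dt.datetime(2024, 3, 1, 8, 0), 1, schedule_12_12)
        s = build_session(frames, schedule_12_12)
        with pytest.raises(ValueError, match="shape"):
            write_masks(s, [np.zeros((4, 4), np.int64)], tmp_path)


class TestTraitTable:
    def _table(self):
        rows = []
        for pid in (1, 2):
            for fi in range(3):
                px = 400 + 10 * fi + pid
                rows.append(
                    dict(plant_id=pid,
                         timestamp=dt.datetime(2024, 3, 1, 8, 20 * fi),
                         frame_index=fi, period_index=0, period_kind="light",
                         pra_px=float(px), pra_mm2=px * 0.25,
                         missing=False)
                )
        return pd.DataFrame(rows, columns=TRAIT_COLUMNS)

    def test_round_trip_numerically_identical(self, tmp_path):
        table = self._table()
        write_traits(table, tmp_path / "traits.csv")
        back = read_traits(tmp_path / "traits.csv")
        assert len(back) == 6
        pd.testing.assert_frame_equal(
            back.reset_index(drop=True), table.reset_index(drop=True),
            check_dtype=False,
        )

    def test_area_unit_conversion(self):
        calib = CalibrationSpec(0.5)
        assert calib.px_to_mm2(400) == 100.0

    def test_empty_table_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="empty"):
            write_traits(pd.DataFrame(columns=TRAIT_COLUMNS), tmp_path / "t.csv")
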