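"""Recording I/O, windowing, channel selection and splitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from breathnet.nirs_io import (
    Condition,
    ExcludedChannelError,
    NirsRecording,
    SplitSpec,
    Window,
    crop_windows,
    load_recording,
    load_windows,
    normalize_windows,
    save_windows,
    select_channels,
    split_dataset,
    windows_to_arrays,
)

from conftest import write_recording_csv


def make_recording(n, condition=Condition.BASELINE, subject="s1",
                   channels=("O2Hb", "HHb"), seed=0):
    rng = np.random.default_rng(seed)
    return NirsRecording(
        subject_id=subject, condition=condition,
        channels={c: rng.normal(size=n) for c in channels})


def make_windows(counts_by_class, n_subjects=1, length=8):
    """Dummy windows: `counts_by_class` maps Condition -> count."""
    out = []
    i = 0
    for cond, count in counts_by_class.items():
        for _ in range(count):
            out.append(Window(
                values=np.zeros((1, length), dtype=np.float32),
                label=cond, subject_id=f"s{i % n_subjects}", source_offset=0,
                channel_names=("O2Hb",)))
            i += 1
    return out


class TestLoadRecording:
    def test_three_minute_file_at_10hz_has_1800_samples(self, tmp_path):
        path = write_recording_csv(tmp_path / "rec.csv", 1800)
        rec = load_recording(path, condition="baseline")
        assert rec.n_samples == 1800
        assert rec.duration_s == pytest.approx(180.0)
        assert rec.channel_names == ("O2Hb", "HHb")

    def test_single_row_file(self, tmp_path):
        path = write_recording_csv(tmp_path / "rec.csv", 1)
        rec = load_recording(path, condition="loaded")
        assert rec.n_samples == 1

    def test_non_numeric_cell_error_names_row_and_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("O2Hb,HHb\n0.1,0.2\nNA,0.4\n")
        with pytest.raises(ValueError, match=r"O2Hb.*row 1|row 1.*O2Hb"):
            load_recording(path, condition="baseline")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_recording(tmp_path / "absent.csv", condition="baseline")

    def test_unknown_channel_in_format_spec(self, tmp_path):
        path = write_recording_csv(tmp_path / "rec.csv", 10)
        with pytest.raises(ValueError, match="unknown channel"):
            load_recording(path, {"SpO2": "O2Hb"}, condition="baseline")

    def test_declared_column_absent(self, tmp_path):
        path = write_recording_csv(tmp_path / "rec.csv", 10)
        with pytest.raises(ValueError, match="not present"):
            load_recording(path, {"O2Hb": "oxy"}, condition="baseline")

    def test_column_mapping_and_extra_time_column(self, tmp_path):
        path = tmp_path / "rec.csv"
        path.write_text("t,oxy,deoxy\n0.0,1.0,2.0\n0.1,3.0,4.0\n")
        rec = load_recording(path, {"O2Hb": "oxy", "HHb": "deoxy"},
                             condition="baseline")
        np.testing.assert_allclose(rec.channels["O2Hb"], [1.0, 3.0])
        np.testing.assert_allclose(rec.channels["HHb"], [2.0, 4.0])

    def test_exclusion_mask_removes_ranges(self, tmp_path):
        path = write_recording_csv(tmp_path / "rec.csv", 100)
        mask = tmp_path / "rec.mask.json"
        mask.write_text('{"exclude": [[0, 10], [90, 100]]}')
        rec = load_recording(path, condition="baseline", exclusion_mask=mask)
        assert rec.n_samples == 80


class TestCropWindows:
    @pytest.mark.parametrize("n,expected", [(1800, 28), (64, 1), (63, 0),
                                            (3000, 46)])
    def test_nonoverlapping_window_counts(self, n, expected):
        rec = make_recording(n)
        assert len(crop_windows(rec)) == expected

    def test_windows_inherit_label_subject_and_offset(self):
        rec = make_recording(200, condition=Condition.LOADED, subject="p7")
        wins = crop_windows(rec)
        assert all(w.label is Condition.LOADED for w in wins)
        assert all(w.subject_id == "p7" for w in wins)
        assert [w.source_offset for w in wins] == [0, 64, 128]

    @given(n=st.integers(0, 400), w=st.integers(1, 70))
    @settings(max_examples=40, deadline=None)
    def test_concatenation_reproduces_prefix(self, n, w):
        rec = make_recording(max(n, 1), channels=("O2Hb",), seed=n)
        wins = crop_windows(rec, window_len=w, stride=w)
        assert len(wins) == rec.n_samples // w
        if wins:
            joined = np.concatenate([win.values[0] for win in wins])
            np.testing.assert_array_equal(
                joined, rec.channels["O2Hb"][: len(wins) * w].astype(np.float32))

    def test_overlapping_stride(self):
        rec = make_recording(128)
        assert len(crop_windows(rec, window_len=64, stride=32)) == 3

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            crop_windows(make_recording(64), window_len=0)


class TestSelectChannels:
    def test_single_channel_keeps_shape(self):
        wins = crop_windows(make_recording(64))
        out = select_channels(wins, {"O2Hb"})
        assert out[0].values.shape == (1, 64)
        assert out[0].channel_names == ("O2Hb",)

    def test_pair_is_ordered_o2hb_first(self):
        wins = crop_windows(make_recording(64))
        out = select_channels(wins, {"HHb", "O2Hb"})
        assert out[0].values.shape == (2, 64)
        assert out[0].channel_names == ("O2Hb", "HHb")
        np.testing.assert_array_equal(out[0].values, wins[0].values)

    @pytest.mark.parametrize("banned", ["THb", "TSI"])
    def test_excluded_by_design(self, banned):
        wins = crop_windows(make_recording(64))
        with pytest.raises(ExcludedChannelError, match="excluded by design"):
            select_channels(wins, {banned})

    def test_missing_channel(self):
        wins = crop_windows(make_recording(64, channels=("HHb",)))
        with pytest.raises(ValueError, match="lacks"):
            select_channels(wins, {"O2Hb"})


class TestSplitDataset:
    def test_published_per_class_counts(self):
        """Ceiling rounding at 0.8 reproduces 425/106, 624/156, 700/174."""
        wins = make_windows({Condition.BASELINE: 531, Condition.LOADED: 780,
                             Condition.RAPID_SHALLOW: 874})
        train, test = split_dataset(wins, SplitSpec(seed=3))
        counts = {c: (sum(w.label is c for w in train),
                      sum(w.label is c for w in test)) for c in Condition}
        assert counts[Condition.BASELINE] == (425, 106)
        assert counts[Condition.LOADED] == (624, 156)
        assert counts[Condition.RAPID_SHALLOW] == (700, 174)

    def test_small_class_eight_two(self):
        wins = make_windows({Condition.BASELINE: 10})
        train, test = split_dataset(wins, SplitSpec(seed=0))
        assert (len(train), len(test)) == (8, 2)

    # classes below 5 cannot populate both sides at 0.8 (ceiling rule)
    @given(n0=st.integers(5, 60), n1=st.integers(5, 60), seed=st.integers(0, 99))
    @settings(max_examples=40, deadline=None)
    def test_conservation_and_disjointness(self, n0, n1, seed):
        wins = make_windows({Condition.BASELINE: n0, Condition.LOADED: n1})
        for i, w in enumerate(wins):
            w.source_offset = i  # tag identity
        train, test = split_dataset(wins, SplitSpec(seed=seed))
        got = sorted(w.source_offset for w in train + test)
        assert got == list(range(n0 + n1))
        assert not ({w.source_offset for w in train}
                    & {w.source_offset for w in test})

    def test_seed_determinism(self):
        wins = make_windows({Condition.BASELINE: 40, Condition.LOADED: 40})
        for i, w in enumerate(wins):
            w.source_offset = i
        a = split_dataset(wins, SplitSpec(seed=11))
        b = split_dataset(wins, SplitSpec(seed=11))
        assert [w.source_offset for w in a[0]] == [w.source_offset for w in b[0]]
        c = split_dataset(wins, SplitSpec(seed=12))
        assert ([w.source_offset for w in a[0]]
                != [w.source_offset for w in c[0]])

    def test_subject_level_purity_and_17_4(self):
        wins = make_windows({c: 210 for c in Condition}, n_subjects=21)
        train, test = split_dataset(
            wins, SplitSpec(mode="subject_level", seed=5))
        train_subjects = {w.subject_id for w in train}
        test_subjects = {w.subject_id for w in test}
        assert not train_subjects & test_subjects
        assert (len(train_subjects), len(test_subjects)) == (17, 4)

    def test_class_too_small(self):
        wins = make_windows({Condition.BASELINE: 1})
        with pytest.raises(ValueError, match="too few"):
            split_dataset(wins, SplitSpec(seed=0))


class TestContainerRoundTrip:
    def test_hdf5_round_trip_with_split(self, tmp_path):
        wins = crop_windows(make_recording(256, condition=Condition.LOADED))
        path = tmp_path / "w.h5"
        save_windows(path, wins, split={0: "train", 1: "train", 2: "test",
                                        3: "test"})
        loaded, membership = load_windows(path)
        assert len(loaded) == len(wins)
        assert membership == {0: "train", 1: "train", 2: "test", 3: "test"}
        np.testing.assert_array_equal(loaded[2].values, wins[2].values)
        assert loaded[0].label is Condition.LOADED
        assert loaded[0].channel_names == ("O2Hb", "HHb")


def test_normalization_zero_mean_preserves_amplitude():
    x = np.random.default_rng(0).normal(5.0, 2.0, size=(4, 2, 64)).astype(np.float32)
    z = normalize_windows(x)
    np.testing.assert_allclose(z.mean(axis=-1), 0.0, atol=1e-5)
    np.testing.assert_allclose(np.ptp(z, axis=-1), np.ptp(x, axis=-1),
                               rtol=1e-5)


def test_windows_to_arrays_labels_in_class_order(small_dataset):
    x, y = windows_to_arrays(small_dataset)
    assert x.shape[1:] == (1, 64)
    assert set(y.tolist()) == {0, 1, 2}
    assert y[0] == small_dataset[0].label.index
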