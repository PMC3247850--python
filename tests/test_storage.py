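"""Container round trips, schema guards, model serialization fidelity, EDF."""

import json
import struct

import h5py
import numpy as np
import pytest

from bcifes.decode import posterior
from bcifes.exceptions import DataError
from bcifes.selection import Thresholds
from bcifes.storage import (
    load_model,
    load_thresholds,
    read_recording,
    save_model,
    save_thresholds,
    write_recording,
)
from bcifes.synth import generate_recording

from conftest import small_config


@pytest.fixture(scope="module")
def tiny_recording():
    return generate_recording(small_config(n_epochs_per_class=2, fs_gonio=256.0))


class TestRecordingRoundTrip:
    def test_container_bit_identical(self, tiny_recording, tmp_path):
        path = tmp_path / "rec.h5"
        write_recording(tiny_recording, path)
        back = read_recording(path)
        np.testing.assert_array_equal(back.eeg, tiny_recording.eeg)
        np.testing.assert_array_equal(back.goniometer, tiny_recording.goniometer)
        assert back.cue_schedule == tiny_recording.cue_schedule
        assert back.channel_labels == tiny_recording.channel_labels

    def test_delimited_round_trip(self, tiny_recording, tmp_path):
        path = tmp_path / "rec_txt"
        write_recording(tiny_recording, path, fmt="delimited")
        back = read_recording(path, fmt="delimited")
        np.testing.assert_allclose(back.eeg, tiny_recording.eeg, rtol=1e-10)

    def test_truncated_container_is_an_error(self, tiny_recording, tmp_path):
        path = tmp_path / "rec.h5"
        write_recording(tiny_recording, path)
        raw = path.read_bytes()
        path.write_bytes(raw[: len(raw) // 3])
        with pytest.raises(DataError):
            read_recording(path)

    def test_missing_file_is_an_error(self, tmp_path):
        with pytest.raises(DataError):
            read_recording(tmp_path / "nope.h5")


def write_minimal_edf(path, signals, fs, labels):
    """Synthetic EDF writer oracle: fixed ASCII header + int16 data records.

    Implements just enough of the European Data Format (one data record per
    second, physical range scaled to the data) to exercise the reader.
    """
    n_sig = len(labels)
    n_rec = signals.shape[1] // int(fs)
    spr = int(fs)
    header = bytearray()
    header += b"0".ljust(8)
    header += b"local patient".ljust(80)
    header += b"local recording".ljust(80)
    header += b"01.01.20".ljust(8) + b"00.00.00".ljust(8)
    header += str(256 * (n_sig + 1)).encode().ljust(8)
    header += b"".ljust(44)
    header += str(n_rec).encode().ljust(8)
    header += b"1".ljust(8)
    header += str(n_sig).encode().ljust(4)
    pmax = float(np.abs(signals).max()) * 1.1 + 1e-6
    for lab in labels:
        header += lab.encode().ljust(16)
    header += b"".ljust(80 * n_sig)  # transducer
    header += (b"uV".ljust(8)) * n_sig
    header += (f"{-pmax:.3f}".encode()[:8].ljust(8)) * n_sig
    header += (f"{pmax:.3f}".encode()[:8].ljust(8)) * n_sig
    header += (b"-32768".ljust(8)) * n_sig
    header += (b"32767".ljust(8)) * n_sig
    header += (b"".ljust(80)) * n_sig  # prefiltering
    header += (str(spr).encode().ljust(8)) * n_sig
    header += (b"".ljust(32)) * n_sig
    scale = 32767 / pmax
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_rec):
            for s in range(n_sig):
                chunk = signals[s, r * spr : (r + 1) * spr]
                ints = np.clip(np.round(chunk * scale), -32768, 32767).astype("<i2")
                fh.write(struct.pack(f"<{spr}h", *ints))


class TestEdfImport:
    def test_64_signal_edf_imports_with_normalized_labels(self, tmp_path):
        from bcifes.synth import montage_labels

        labels = montage_labels()
        rng = np.random.default_rng(0)
        fs = 256.0
        sig = rng.normal(0, 20, size=(64, int(2 * fs)))
        path = tmp_path / "rec.edf"
        write_minimal_edf(path, sig, fs, [f"EEG {c}" for c in labels])
        rec = read_recording(path, fmt="edf")
        assert rec.eeg.shape[0] == 64
        assert rec.channel_labels == labels
        assert rec.fs_eeg == fs
        # amplitudes survive the int16 quantization
        np.testing.assert_allclose(rec.eeg, sig, atol=0.01 * np.abs(sig).max())

    def test_unknown_labels_rejected(self, tmp_path):
        path = tmp_path / "bad.edf"
        write_minimal_edf(path, np.zeros((2, 256)), 256.0, ["Cz", "Bogus99"])
        with pytest.raises(DataError, match="Bogus99"):
            read_recording(path, fmt="edf")


class TestModelRoundTrip:
    def test_posteriors_identical_after_reload(self, small_model, tmp_path):
        path = tmp_path / "model.h5"
        save_model(small_model, path)
        back = load_model(path)
        rng = np.random.default_rng(0)
        f = rng.normal(size=(100, 2))
        p1 = posterior(small_model.classifier, f)
        p2 = posterior(back.classifier, f)
        np.testing.assert_allclose(p1[1], p2[1], atol=1e-12)
        assert back.band == small_model.band
        assert back.channel_labels == small_model.channel_labels
        assert back.train_seg_len_s == small_model.train_seg_len_s

    def test_extractor_maps_identical_after_reload(self, small_model, tmp_path):
        from bcifes.decode import extract_feature

        path = tmp_path / "model.h5"
        save_model(small_model, path)
        back = load_model(path)
        rng = np.random.default_rng(1)
        d = rng.normal(size=(20, small_model.extractor.n_features))
        np.testing.assert_allclose(
            extract_feature(small_model.extractor, d), extract_feature(back.extractor, d),
            atol=1e-12,
        )

    def test_legacy_schema_refused_with_hint(self, small_model, tmp_path):
        path = tmp_path / "model.h5"
        save_model(small_model, path)
        with h5py.File(path, "a") as f:
            f.attrs["schema_version"] = 0
        with pytest.raises(DataError, match="schema version"):
            load_model(path)


class TestThresholds:
    def test_round_trip(self, tmp_path):
        thr = Thresholds(T1=0.8, T2=0.2, quartiles={"D": (0.7, 0.8, 0.9)})
        path = tmp_path / "thr.json"
        save_thresholds(thr, path)
        back = load_thresholds(path)
        assert (back.T1, back.T2) == (0.8, 0.2)
        assert back.quartiles["D"] == (0.7, 0.8, 0.9)
        assert json.loads(path.read_text())["T1"] == 0.8

    def test_malformed_file_rejected(self, tmp_path):
        path = tmp_path / "thr.json"
        path.write_text("{}")
        with pytest.raises(DataError):
            load_thresholds(path)
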