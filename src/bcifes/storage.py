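"""Container formats, model/threshold serialization, and provenance.

Array-valued artifacts (recordings, epoch sets, spectra, prediction models,
online runs) live in self-describing HDF5 containers with a ``schema_version``
attribute and provenance metadata (tool version, config hash, input hashes);
scalar artifacts (thresholds, performance reports) are JSON.  A delimited-text
fallback exists for recordings, and real EEG can be imported from EDF
(European Data Format) through mne.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np

from . import __version__
from .decode import CLASSES, FeatureExtractor, GaussianPieceModel
from .exceptions import ConfigError, DataError
from .preprocess import EpochSet
from .selection import PredictionModel, Thresholds
from .spectral import SpectralTrials
from .synth import Recording

__all__ = [
    "SCHEMA_VERSION",
    "read_recording",
    "write_recording",
    "read_epochs",
    "write_epochs",
    "save_model",
    "load_model",
    "save_thresholds",
    "load_thresholds",
    "config_hash",
    "file_hash",
]

SCHEMA_VERSION = 1


def config_hash(obj) -> str:
    """SHA-256 of the canonical JSON encoding of a configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()


def file_hash(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _provenance(extra: dict | None = None) -> dict:
    prov = {"tool": "bcifes", "version": __version__}
    if extra:
        prov.update(extra)
    return prov


def _check_schema(attrs, path):
    v = int(attrs.get("schema_version", -1))
    if v != SCHEMA_VERSION:
        raise DataError(
            f"{path}: schema version {v} != supported {SCHEMA_VERSION}; "
            "re-export the artifact with this version of the tool"
        )


# ---------------------------------------------------------------- recordings


def write_recording(
    rec: Recording, path: str | Path, fmt: str = "container", provenance: dict | None = None
) -> None:
    """Serialize a Recording (HDF5 container or delimited text + JSON sidecar)."""
    rec.validate()
    path = Path(path)
    if fmt == "container":
        with h5py.File(path, "w") as f:
            f.create_dataset("eeg", data=rec.eeg)
            f.create_dataset("goniometer", data=rec.goniometer)
            f.attrs["fs_eeg"] = rec.fs_eeg
            f.attrs["fs_gonio"] = rec.fs_gonio
            f.attrs["channel_labels"] = json.dumps(rec.channel_labels)
            f.attrs["cue_schedule"] = json.dumps(rec.cue_schedule)
            f.attrs["schema_version"] = SCHEMA_VERSION
            f.attrs["provenance"] = json.dumps(_provenance(provenance))
    elif fmt == "delimited":
        path.mkdir(parents=True, exist_ok=True)
        np.savetxt(path / "eeg.tsv", rec.eeg, delimiter="\t")
        np.savetxt(path / "goniometer.tsv", rec.goniometer, delimiter="\t")
        meta = {
            "fs_eeg": rec.fs_eeg,
            "fs_gonio": rec.fs_gonio,
            "channel_labels": rec.channel_labels,
            "cue_schedule": rec.cue_schedule,
            "schema_version": SCHEMA_VERSION,
            "provenance": _provenance(provenance),
        }
        (path / "meta.json").write_text(json.dumps(meta, indent=1))
    else:
        raise ConfigError(f"unknown recording format {fmt!r}")


def _normalize_edf_label(name: str) -> str:
    name = name.strip()
    for prefix in ("EEG ", "eeg "):
        if name.startswith(prefix):
            name = name[len(prefix) :]
    return name.split("-")[0].strip()


def read_recording(path: str | Path, fmt: str = "container") -> Recording:
    """Read a Recording from a container, delimited directory, or EDF file."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"{path}: no such file or directory")
    if fmt == "container":
        try:
            with h5py.File(path, "r") as f:
                _check_schema(f.attrs, path)
                rec = Recording(
                    eeg=f["eeg"][()],
                    fs_eeg=float(f.attrs["fs_eeg"]),
                    channel_labels=json.loads(f.attrs["channel_labels"]),
                    goniometer=f["goniometer"][()],
                    fs_gonio=float(f.attrs["fs_gonio"]),
                    cue_schedule=[tuple(c) for c in json.loads(f.attrs["cue_schedule"])],
                )
        except (OSError, KeyError) as e:
            raise DataError(f"{path}: malformed recording container ({e})") from e
    elif fmt == "delimited":
        try:
            meta = json.loads((path / "meta.json").read_text())
            _check_schema(meta, path)
            rec = Recording(
                eeg=np.atleast_2d(np.loadtxt(path / "eeg.tsv", delimiter="\t")),
                fs_eeg=float(meta["fs_eeg"]),
                channel_labels=list(meta["channel_labels"]),
                goniometer=np.atleast_2d(np.loadtxt(path / "goniometer.tsv", delimiter="\t")),
                fs_gonio=float(meta["fs_gonio"]),
                cue_schedule=[tuple(c) for c in meta["cue_schedule"]],
            )
        except (OSError, KeyError, ValueError) as e:
            if isinstance(e, DataError):
                raise
            raise DataError(f"{path}: malformed delimited recording ({e})") from e
    elif fmt == "edf":
        rec = _read_edf(path)
    else:
        raise ConfigError(f"unknown recording format {fmt!r}")
    rec.validate()
    return rec


def _read_edf(path: Path) -> Recording:
    from mne.io import read_raw_edf

    from .synth import montage_labels

    raw = read_raw_edf(path, preload=True, verbose="error")
    labels = [_normalize_edf_label(c) for c in raw.ch_names]
    known = {c.lower(): c for c in montage_labels()}
    normalized, unknown = [], []
    for c in labels:
        if c.lower() in known:
            normalized.append(known[c.lower()])
        else:
            unknown.append(c)
    if unknown:
        raise DataError(f"{path}: unknown channel labels {unknown}")
    fs = float(raw.info["sfreq"])
    eeg = raw.get_data() * 1e6  # mne returns volts
    n = eeg.shape[1]
    return Recording(
        eeg=eeg,
        fs_eeg=fs,
        channel_labels=normalized,
        goniometer=np.zeros((2, n)),
        fs_gonio=fs,
        cue_schedule=[],
    )


# ---------------------------------------------------------------- epoch sets


def write_epochs(epochs: EpochSet, path: str | Path, provenance: dict | None = None) -> None:
    epochs.validate()
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("retained_mask", data=epochs.retained_mask)
        f.attrs["labels"] = json.dumps(list(map(str, epochs.labels)))
        f.attrs["channel_labels"] = json.dumps(epochs.channel_labels)
        f.attrs["fs"] = epochs.fs
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["provenance"] = json.dumps(_provenance(provenance))


def read_epochs(path: str | Path) -> EpochSet:
    try:
        with h5py.File(path, "r") as f:
            _check_schema(f.attrs, path)
            epochs = EpochSet(
                data=f["data"][()],
                labels=np.asarray(json.loads(f.attrs["labels"])),
                channel_labels=json.loads(f.attrs["channel_labels"]),
                fs=float(f.attrs["fs"]),
                retained_mask=f["retained_mask"][()].astype(bool),
            )
    except OSError as e:
        raise DataError(f"{path}: malformed epochs container ({e})") from e
    epochs.validate()
    return epochs


def write_spectra(st: SpectralTrials, path: str | Path, provenance: dict | None = None) -> None:
    st.validate()
    with h5py.File(path, "w") as f:
        f.create_dataset("power", data=st.power)
        f.create_dataset("bin_centers", data=st.bin_centers)
        f.attrs["labels"] = json.dumps(list(map(str, st.labels)))
        f.attrs["channel_labels"] = json.dumps(st.channel_labels)
        f.attrs["band"] = json.dumps(list(st.band))
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["provenance"] = json.dumps(_provenance(provenance))


def read_spectra(path: str | Path) -> SpectralTrials:
    try:
        with h5py.File(path, "r") as f:
            _check_schema(f.attrs, path)
            st = SpectralTrials(
                power=f["power"][()],
                bin_centers=f["bin_centers"][()],
                channel_labels=json.loads(f.attrs["channel_labels"]),
                band=tuple(json.loads(f.attrs["band"])),
                labels=np.asarray(json.loads(f.attrs["labels"])),
            )
    except OSError as e:
        raise DataError(f"{path}: malformed spectra container ({e})") from e
    st.validate()
    return st


# ----------------------------------------------------------- prediction model


def save_model(model: PredictionModel, path: str | Path, provenance: dict | None = None) -> None:
    """Serialize a PredictionModel; rejects models that retain no channels."""
    model.validate()
    with h5py.File(path, "w") as f:
        for c in CLASSES:
            g = f.create_group(f"piece_{c}")
            g.create_dataset("center", data=model.extractor.centers[c])
            g.create_dataset("basis", data=model.extractor.bases[c])
            g.create_dataset("discriminant", data=model.extractor.discriminants[c])
        f.attrs["header"] = json.dumps(
            {
                "channel_labels": model.channel_labels,
                "band": list(model.band),
                "fs": model.fs,
                "cv_accuracy": model.cv_accuracy,
                "variance_kept": model.variance_kept,
                "method": model.method,
                "n_features": model.extractor.n_features,
                "priors": model.classifier.priors,
                "means": model.classifier.means,
                "variances": model.classifier.variances,
                "covariances": model.classifier.covariances,
                "train_seg_len_s": model.train_seg_len_s,
            }
        )
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["provenance"] = json.dumps(_provenance(provenance))


def load_model(path: str | Path) -> PredictionModel:
    try:
        with h5py.File(path, "r") as f:
            _check_schema(f.attrs, path)
            hdr = json.loads(f.attrs["header"])
            centers, bases, discs = {}, {}, {}
            for c in CLASSES:
                g = f[f"piece_{c}"]
                centers[c] = g["center"][()]
                bases[c] = g["basis"][()]
                discs[c] = g["discriminant"][()]
    except OSError as e:
        raise DataError(f"{path}: malformed model container ({e})") from e
    ext = FeatureExtractor(
        centers=centers, bases=bases, discriminants=discs, n_features=int(hdr["n_features"])
    )
    clf = GaussianPieceModel(
        means=hdr["means"],
        variances=hdr["variances"],
        covariances=hdr.get("covariances", {}),
        priors=hdr["priors"],
    )
    model = PredictionModel(
        channel_labels=list(hdr["channel_labels"]),
        band=tuple(hdr["band"]),
        extractor=ext,
        classifier=clf,
        cv_accuracy=float(hdr["cv_accuracy"]),
        fs=float(hdr["fs"]),
        variance_kept=float(hdr["variance_kept"]),
        method=str(hdr["method"]),
        train_seg_len_s=float(hdr.get("train_seg_len_s", 6.0)),
    )
    model.validate()
    ext.validate()
    clf.validate()
    return model


# ---------------------------------------------------------------- online runs


def write_run(result, path: str | Path, provenance: dict | None = None) -> None:
    """Serialize an OnlineRunResult (per-step trajectory + virtual response)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("times", data=result.times)
        f.create_dataset("p_d", data=result.p_d)
        f.create_dataset("p_bar", data=result.p_bar)
        f.create_dataset("response_gonio", data=result.response_gonio)
        f.create_dataset("command_active", data=np.asarray([c.active for c in result.commands]))
        f.create_dataset("command_amplitude", data=np.asarray([c.amplitude for c in result.commands]))
        f.create_dataset("command_timestamp", data=np.asarray([c.timestamp for c in result.commands]))
        f.attrs["states"] = json.dumps(list(map(str, result.states)))
        f.attrs["response_fs"] = result.response_fs
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["provenance"] = json.dumps(_provenance(provenance))


def read_run(path: str | Path):
    from .online import OnlineRunResult, StimCommand

    try:
        with h5py.File(path, "r") as f:
            _check_schema(f.attrs, path)
            commands = [
                StimCommand(active=bool(a), amplitude=float(m), timestamp=float(t))
                for a, m, t in zip(
                    f["command_active"][()], f["command_amplitude"][()], f["command_timestamp"][()]
                )
            ]
            return OnlineRunResult(
                times=f["times"][()],
                p_d=f["p_d"][()],
                p_bar=f["p_bar"][()],
                states=np.asarray(json.loads(f.attrs["states"])),
                commands=commands,
                response_gonio=f["response_gonio"][()],
                response_fs=float(f.attrs["response_fs"]),
            )
    except OSError as e:
        raise DataError(f"{path}: malformed run container ({e})") from e


# ----------------------------------------------------------------- thresholds


def save_thresholds(thr: Thresholds, path: str | Path) -> None:
    thr.validate()
    payload = {"T1": thr.T1, "T2": thr.T2, "quartiles": thr.quartiles}
    Path(path).write_text(json.dumps(payload, indent=1))


def load_thresholds(path: str | Path) -> Thresholds:
    try:
        payload = json.loads(Path(path).read_text())
        thr = Thresholds(
            T1=float(payload["T1"]),
            T2=float(payload["T2"]),
            quartiles={k: tuple(v) for k, v in payload.get("quartiles", {}).items()},
        )
    except (OSError, KeyError, ValueError) as e:
        raise DataError(f"{path}: malformed thresholds file ({e})") from e
    thr.validate()
    return thr
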