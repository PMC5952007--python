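"""Epoch container serialization.

Native format: a single zip archive holding one ``data.npy`` tensor
(trials x channels x samples, float64) and a ``meta.json`` sidecar with the
sampling rate, channel labels and per-trial metadata — language-neutral and
bit-exact on round trip.  Delimited export: one tab-separated matrix file
per trial plus the same JSON sidecar.  EDF files are read through ``mne``
when it is installed (``pip install pacbci[edf]``).
"""

from __future__ import annotations

import io as _io
import json
import zipfile
from pathlib import Path

import numpy as np

from .core import EpochSet, FormatError, ValidationError

__all__ = ["read_epochs", "write_epochs"]

_META_FIELDS = ("fs", "channels", "class_label", "session_id", "attend", "t0")


def _meta_dict(epochs: EpochSet) -> dict:
    return {
        "fs": epochs.fs,
        "channels": list(epochs.channels),
        "class_label": epochs.class_label.tolist(),
        "session_id": epochs.session_id.tolist(),
        "attend": epochs.attend.tolist(),
        "t0": epochs.t0,
        "shape": list(epochs.data.shape),
    }


def _epochs_from_meta(data: np.ndarray, meta: dict) -> EpochSet:
    missing = [f for f in _META_FIELDS if f not in meta]
    if missing:
        raise FormatError(f"metadata sidecar missing fields: {missing}")
    if meta["fs"] <= 0:
        raise ValidationError(f"fs must be > 0, got {meta['fs']}")
    return EpochSet(
        data=data,
        fs=float(meta["fs"]),
        channels=list(meta["channels"]),
        class_label=np.asarray(meta["class_label"], dtype=np.int64),
        session_id=np.asarray(meta["session_id"], dtype=np.int64),
        attend=np.asarray(meta["attend"], dtype=bool),
        t0=float(meta["t0"]),
    )


def write_epochs(epochs: EpochSet, path, format: str = "native") -> None:
    """Write an epoch set; 'native' (zip archive) round-trips bit-for-bit."""
    path = Path(path)
    if not np.all(np.isfinite(epochs.data)):
        raise ValidationError("refusing to write non-finite sample values")
    meta = _meta_dict(epochs)
    if format == "native":
        buf = _io.BytesIO()
        np.save(buf, epochs.data)
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            zf.writestr("data.npy", buf.getvalue())
            zf.writestr("meta.json", json.dumps(meta, indent=1))
    elif format == "delimited":
        path.mkdir(parents=True, exist_ok=True)
        (path / "meta.json").write_text(json.dumps(meta, indent=1))
        for i, trial in enumerate(epochs.data):
            np.savetxt(path / f"trial_{i:05d}.tsv", trial,
                       delimiter="\t", fmt="%.17g")
    else:
        raise ValidationError(f"unsupported write format {format!r}")


def read_epochs(path, format: str = "native") -> EpochSet:
    """Read an epoch set from native archive, delimited directory or EDF."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "native":
        with zipfile.ZipFile(path) as zf:
            names = set(zf.namelist())
            if "meta.json" not in names:
                raise FormatError("native archive missing meta.json")
            if "data.npy" not in names:
                raise FormatError("native archive missing data.npy")
            meta = json.loads(zf.read("meta.json"))
            data = np.load(_io.BytesIO(zf.read("data.npy")))
        return _epochs_from_meta(data, meta)
    if format == "delimited":
        sidecar = path / "meta.json"
        if not sidecar.exists():
            raise FormatError(f"missing metadata sidecar {sidecar}")
        meta = json.loads(sidecar.read_text())
        missing = [f for f in _META_FIELDS if f not in meta]
        if missing:
            raise FormatError(f"metadata sidecar missing fields: {missing}")
        n_trials, n_channels, n_samples = meta.get(
            "shape", (len(meta["class_label"]), len(meta["channels"]), -1))
        trials = []
        for i in range(n_trials):
            f = path / f"trial_{i:05d}.tsv"
            if not f.exists():
                raise FormatError(f"missing trial file {f}")
            trials.append(np.loadtxt(f, delimiter="\t", ndmin=2))
        data = (np.stack(trials) if trials
                else np.zeros((0, n_channels, max(n_samples, 0))))
        return _epochs_from_meta(data, meta)
    if format == "edf":
        return _read_edf(path)
    raise ValidationError(f"unsupported read format {format!r}")


def _read_edf(path: Path) -> EpochSet:
    try:
        import mne
    except ImportError as e:  # pragma: no cover
        raise ImportError(
            "EDF support needs the optional 'mne' dependency "
            "(pip install pacbci[edf])"
        ) from e
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data(units="uV")[None, :, :]  # one continuous 'trial'
    return EpochSet(
        data=data,
        fs=float(raw.info["sfreq"]),
        channels=list(raw.ch_names),
        class_label=np.array([1]),
        session_id=np.array([1]),
        attend=np.array([True]),
        t0=0.0,
    )
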