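"""Readers and writers: EDF and delimited-text recordings with a manifest.

A dataset on disk is a tab-delimited manifest (one row per
subject x condition recording: subject, condition, path, fs, channels)
next to the recordings themselves, which are either EDF files (read via
mne, optional dependency) or plain-text channels x samples matrices in
microvolts. Truth tables for synthetic studies are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .records import EEGRecord

__all__ = [
    "read_text_matrix",
    "write_text_matrix",
    "read_edf",
    "read_manifest",
    "write_manifest",
    "load_dataset",
    "write_study",
]


def write_text_matrix(record: EEGRecord, path: str | Path) -> Path:
    """Write channels x samples microvolt values, channel labels as header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# fs=%g\n" % record.fs)
        fh.write("\t".join(record.channel_labels) + "\n")
        np.savetxt(fh, record.samples.T, fmt="%.6f", delimiter="\t")
    return path


def read_text_matrix(path: str | Path, subject_id: str = "",
                     condition: str = "") -> EEGRecord:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# fs="):
            raise ValueError(f"{path}: missing '# fs=' header line")
        fs = float(first.split("=", 1)[1])
        labels = fh.readline().strip().split("\t")
        samples = np.loadtxt(fh, delimiter="\t", ndmin=2).T
    return EEGRecord(samples, fs, labels, subject_id, condition)


def read_edf(path: str | Path, channels: list[str] | None = None,
             subject_id: str = "", condition: str = "") -> EEGRecord:
    """Read a continuous EDF/EDF+ recording (requires mne), in microvolts."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if channels:
        raw.pick(channels)
    return EEGRecord(raw.get_data() * 1e6, float(raw.info["sfreq"]),
                     list(raw.ch_names), subject_id, condition)


def read_record(path: str | Path, **kw) -> EEGRecord:
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_edf(path, **kw)
    return read_text_matrix(path, **kw)


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    manifest.to_csv(path, sep="\t", index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_dataset(manifest_path: str | Path) -> list[EEGRecord]:
    """Load every recording listed in a manifest (paths relative to it)."""
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    records = []
    for _, row in manifest.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = manifest_path.parent / p
        records.append(read_record(p, subject_id=str(row["subject"]),
                                   condition=str(row["condition"])))
    return records


def write_study(dataset, manifest: pd.DataFrame, truth: dict,
                out_dir: str | Path) -> Path:
    """Write a synthetic study: text matrices, manifest.tsv, truth.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for (record, _labels), (_, mrow) in zip(dataset, manifest.iterrows()):
        fname = f"{mrow['subject']}_{mrow['condition']}.tsv"
        write_text_matrix(record, out_dir / fname)
        row = dict(mrow)
        row["path"] = fname
        rows.append(row)
    write_manifest(pd.DataFrame(rows), out_dir / "manifest.tsv")
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return out_dir
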