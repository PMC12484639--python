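"""Reading and writing the package's plain-text interchange formats.

* Feature tables: CSV, one row per ECG, columns ``ecg_id, patient_id,
  <lead>_<feature> x 276, lvmi, age, sex, label_basal, label_mid,
  label_apical`` (covariates/labels optional at prediction time).
* Waveforms: CSV with one column per lead, values in mV.
* Fiducial annotations: JSON ``{"sampling_rate_hz": ..., "leads": {"V1":
  {"samples": [...] | "samples_file": "wave.csv", "beats": [{"qrs_onset": ...,
  "q_peak": ... | null, ...}, ...]}, ...}}``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .features import FiducialBeat
from .registry import LEADS, VECTOR_COLUMNS

_BEAT_FIELDS = (
    "qrs_onset", "q_peak", "r_peak", "s_peak", "qrs_offset",
    "t_onset", "t_peak", "t_offset", "next_p_onset",
)


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in VECTOR_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(
            f"feature table is missing {len(missing)} feature columns "
            f"(first: {missing[:3]})"
        )
    return table


def write_waveforms_csv(signals: dict[str, np.ndarray], path: str | Path) -> None:
    pd.DataFrame({lead: signals[lead] for lead in LEADS}).to_csv(path, index=False)


def read_waveforms_csv(path: str | Path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path)
    return {lead: df[lead].to_numpy(float) for lead in df.columns}


def write_annotations(
    beats: dict[str, Sequence[FiducialBeat]],
    path: str | Path,
    sampling_rate: float,
    samples_file: str | None = None,
    signals: dict[str, np.ndarray] | None = None,
) -> None:
    """Write the fiducial JSON; samples either inline or by file reference."""
    doc: dict = {"sampling_rate_hz": sampling_rate, "leads": {}}
    for lead, lead_beats in beats.items():
        entry: dict = {
            "beats": [
                {f: getattr(b, f) for f in _BEAT_FIELDS} for b in lead_beats
            ]
        }
        if samples_file is not None:
            entry["samples_file"] = samples_file
        elif signals is not None:
            entry["samples"] = np.asarray(signals[lead], float).tolist()
        doc["leads"][lead] = entry
    Path(path).write_text(json.dumps(doc))


def read_annotations(
    path: str | Path,
) -> tuple[dict[str, np.ndarray], dict[str, list[FiducialBeat]]]:
    """Read fiducial JSON; resolves ``samples_file`` relative to the JSON."""
    path = Path(path)
    doc = json.loads(path.read_text())
    fs = float(doc["sampling_rate_hz"])
    signals: dict[str, np.ndarray] = {}
    beats: dict[str, list[FiducialBeat]] = {}
    file_cache: dict[str, dict[str, np.ndarray]] = {}
    for lead, entry in doc["leads"].items():
        if "samples" in entry:
            signals[lead] = np.asarray(entry["samples"], float)
        elif "samples_file" in entry:
            ref = entry["samples_file"]
            if ref not in file_cache:
                file_cache[ref] = read_waveforms_csv(path.parent / ref)
            signals[lead] = file_cache[ref][lead]
        else:
            raise ValueError(f"lead {lead}: neither 'samples' nor 'samples_file'")
        beats[lead] = [
            FiducialBeat(sampling_rate=fs, **{f: b.get(f) for f in _BEAT_FIELDS})
            for b in entry["beats"]
        ]
    return signals, beats
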