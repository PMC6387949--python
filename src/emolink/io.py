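"""Readers and writers for the cohort directory layout.

Everything is plain text: EEG as CSV sample-rows with a YAML sidecar
(sampling rate), events as TSV (onset_s, condition, trial_id), RR series
as one-interval-per-line millisecond text, behavior tables as CSV, and
the generating ground truth as YAML. EDF reading is available through
the optional ``mne`` dependency.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import EegRecording
from .synthetic import CohortBundle, GroundTruthSpec, PlantedEdge

__all__ = [
    "write_recording",
    "read_recording",
    "write_events",
    "read_events",
    "write_rr",
    "read_rr",
    "write_cohort",
    "read_cohort_participant_ids",
    "read_participant_recording",
    "read_ground_truth",
]

_FLOAT_FMT = "%.8e"


def write_recording(rec: EegRecording, path: Path) -> None:
    """Write continuous EEG as CSV (rows = samples, header = channels)
    plus a ``<stem>_meta.yaml`` sidecar with the sampling rate."""
    path = Path(path)
    header = ",".join(rec.ch_names)
    np.savetxt(path, rec.data.T, delimiter=",", fmt=_FLOAT_FMT,
               header=header, comments="")
    meta = {"fs": float(rec.fs), "channels": list(rec.ch_names)}
    path.with_name(path.stem + "_meta.yaml").write_text(
        yaml.safe_dump(meta, sort_keys=True)
    )


def read_recording(path: Path, events: pd.DataFrame | None = None) -> EegRecording:
    """Read a continuous recording from CSV (+ sidecar) or EDF.

    EDF files are read through :mod:`mne` (optional dependency).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording file not found: {path}")
    if path.suffix.lower() == ".edf":
        try:
            import mne
        except ImportError as exc:  # pragma: no cover - optional extra
            raise ImportError("reading EDF requires the 'mne' package") from exc
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # volts -> microvolts
        fs = float(raw.info["sfreq"])
        ch_names = tuple(raw.ch_names)
    else:
        frame = pd.read_csv(path)
        data = frame.to_numpy(dtype=float).T
        ch_names = tuple(frame.columns)
        meta_path = path.with_name(path.stem + "_meta.yaml")
        if not meta_path.exists():
            raise FileNotFoundError(f"sidecar metadata not found: {meta_path}")
        meta = yaml.safe_load(meta_path.read_text())
        fs = float(meta["fs"])
    if events is None:
        events = pd.DataFrame(columns=["onset_sample", "condition", "trial_id"])
    return EegRecording(data=data, fs=fs, ch_names=ch_names, events=events)


def write_events(events_s: pd.DataFrame, path: Path) -> None:
    """Events TSV with columns onset_s, condition, trial_id."""
    events_s.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_events(path: Path, fs: float) -> pd.DataFrame:
    """Read the events TSV and attach integer onset samples at ``fs``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"event file not found: {path}")
    ev = pd.read_csv(path, sep="\t")
    ev["onset_sample"] = np.rint(ev["onset_s"].to_numpy(dtype=float) * fs).astype(int)
    return ev[["onset_sample", "condition", "trial_id"]]


def write_rr(intervals_ms: np.ndarray, path: Path) -> None:
    np.savetxt(path, np.asarray(intervals_ms, dtype=float), fmt="%.4f")


def read_rr(path: Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"RR file not found: {path}")
    return np.loadtxt(path, ndmin=1)


def _spec_to_dict(spec: GroundTruthSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["planted_edges"] = [dataclasses.asdict(e) for e in spec.planted_edges]
    d["channels"] = list(spec.channels)
    d["epoch_window_s"] = list(spec.epoch_window_s)
    return d


def spec_from_dict(d: dict) -> GroundTruthSpec:
    d = dict(d)
    d["planted_edges"] = [PlantedEdge(**e) for e in d.get("planted_edges", [])]
    d["channels"] = tuple(d["channels"])
    d["epoch_window_s"] = tuple(d["epoch_window_s"])
    return GroundTruthSpec(**d)


def write_cohort(bundle: CohortBundle, out_dir: Path) -> Path:
    """Write the cohort directory (continuous EEG + events per participant,
    RR text files, behavior CSVs, ground truth YAML).

    Epochs are concatenated into one continuous stream per participant;
    event onsets mark the second-presentation onset inside each segment.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = bundle.spec
    fs = spec.fs
    t0 = spec.epoch_window_s[0]
    truth = {"spec": _spec_to_dict(spec), "participants": {}}
    for p in bundle.participants:
        pdir = out_dir / "participants" / f"p{p.participant:03d}"
        pdir.mkdir(parents=True, exist_ok=True)
        n_ch, n_samp, n_trials = p.epochs.shape
        cont = np.ascontiguousarray(
            p.epochs.transpose(0, 2, 1).reshape(n_ch, n_trials * n_samp)
        )
        rec = EegRecording(data=cont, fs=fs, ch_names=spec.channels)
        write_recording(rec, pdir / "eeg.csv")
        # onset pinned to an integer sample inside each segment so epoch
        # re-extraction tiles the stored stream exactly
        onsets = (np.arange(n_trials) * n_samp + int(np.floor(-t0 * fs))) / fs
        ev = pd.DataFrame({
            "onset_s": onsets,
            "condition": p.epoch_conditions,
            "trial_id": np.arange(n_trials),
        })
        write_events(ev, pdir / "events.tsv")
        for cond, arr in p.rr_raw.items():
            write_rr(arr, pdir / f"rr_{cond}.txt")
        p.ratings.to_csv(pdir / "ratings.csv", index=False)
        p.outcomes.to_csv(pdir / "outcomes.csv", index=False)
        pd.DataFrame([p.anxiety]).to_csv(pdir / "anxiety.csv", index=False)
        truth["participants"][p.participant] = {
            k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
            for k, v in p.truth.items()
        }
    (out_dir / "ground_truth.yaml").write_text(
        yaml.safe_dump(truth, sort_keys=True)
    )
    return out_dir


def read_cohort_participant_ids(cohort_dir: Path) -> list[str]:
    pdir = Path(cohort_dir) / "participants"
    if not pdir.exists():
        raise FileNotFoundError(f"cohort participants directory not found: {pdir}")
    return sorted(d.name for d in pdir.iterdir() if d.is_dir())


def read_participant_recording(cohort_dir: Path, pid: str) -> EegRecording:
    pdir = Path(cohort_dir) / "participants" / pid
    meta = yaml.safe_load((pdir / "eeg_meta.yaml").read_text()) \
        if (pdir / "eeg_meta.yaml").exists() else None
    fs = float(meta["fs"]) if meta else 250.0
    events = read_events(pdir / "events.tsv", fs)
    return read_recording(pdir / "eeg.csv", events=events)


def read_ground_truth(cohort_dir: Path) -> dict:
    path = Path(cohort_dir) / "ground_truth.yaml"
    if not path.exists():
        raise FileNotFoundError(f"ground truth file not found: {path}")
    return yaml.safe_load(path.read_text())
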