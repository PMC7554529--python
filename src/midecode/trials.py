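"""Trial/session data model, fixture I/O, and train/test split assembly.

A *trial* is one cued motor-imagery attempt: 8 s of 3-channel bipolar EEG
(C3, Cz, C4) sampled at 250 Hz, with the cue at 3 s and the imagery period
spanning 3-7 s.  Trials are grouped into numbered sessions (1-5) per
subject; sessions 1-3 are the calibration ("training") recordings and
sessions 4-5 the evaluation ("feedback") recordings.

Two split protocols are provided:

* intra-subject  — train on sessions 1-3, test on sessions 4-5 of the same
  subject;
* inter-subject  — leave-one-subject-out: train on all five sessions of
  every *other* subject, test on the held-out subject's sessions 4-5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

CHANNELS: tuple[str, ...] = ("C3", "Cz", "C4")
LABELS: tuple[str, ...] = ("left", "right")

#: cue onset within a trial, seconds from trial start
CUE_ONSET_S = 3.0
#: epoch window relative to trial start, seconds (half-open)
EPOCH_WINDOW_S = (0.0, 8.0)

TRAIN_SESSIONS = (1, 2, 3)
TEST_SESSIONS = (4, 5)

FIXTURE_VERSION = 1

# BCI-competition IV-2b GDF annotation codes
_GDF_EVENT_TRIAL_START = "768"
_GDF_EVENT_LEFT = "769"
_GDF_EVENT_RIGHT = "770"


class DialectError(ValueError):
    """Unknown or unreadable trial-file dialect."""


@dataclass
class Trial:
    """One labeled MI trial: ``data`` is channels x samples in microvolts."""

    data: np.ndarray
    label: str
    sampling_rate: float = 250.0
    trial_start: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2 or self.data.shape[0] != len(CHANNELS):
            raise ValueError(
                f"trial data must be {len(CHANNELS)} channels x samples, "
                f"got shape {self.data.shape}"
            )
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class SessionSet:
    """All trials of one recording session for one subject."""

    subject_id: int
    session_id: int
    trials: list[Trial] = field(default_factory=list)
    #: free-form provenance (e.g. the generator's per-subject ERD depth)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1 <= int(self.session_id) <= 5:
            raise ValueError(f"session_id must be in 1..5, got {self.session_id}")
        rates = {t.sampling_rate for t in self.trials}
        if len(rates) > 1:
            raise ValueError(f"mixed sampling rates within session: {rates}")

    def __len__(self) -> int:
        return len(self.trials)


# ---------------------------------------------------------------------------
# fixture format: per subject one .npz (arrays) + .json manifest
# ---------------------------------------------------------------------------

def write_fixture(sessions: Iterable[SessionSet], outdir: str | Path) -> list[Path]:
    """Write sessions to the internal fixture format.

    One ``subject_<id>.npz`` per subject holding the stacked trial array
    plus a human-readable ``subject_<id>.json`` manifest (subject, session
    ids, labels, sampling rate, format version).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_subject: dict[int, list[SessionSet]] = {}
    for s in sessions:
        by_subject.setdefault(s.subject_id, []).append(s)
    written = []
    for sid, sess_list in sorted(by_subject.items()):
        sess_list = sorted(sess_list, key=lambda s: s.session_id)
        data = np.stack([t.data for s in sess_list for t in s.trials])
        labels = [t.label for s in sess_list for t in s.trials]
        session_ids = [s.session_id for s in sess_list for _ in s.trials]
        fs = sess_list[0].trials[0].sampling_rate if sess_list[0].trials else 250.0
        npz_path = outdir / f"subject_{sid:02d}.npz"
        np.savez(npz_path, data=data)
        manifest = {
            "version": FIXTURE_VERSION,
            "subject_id": sid,
            "sampling_rate": fs,
            "channels": list(CHANNELS),
            "session_ids": session_ids,
            "labels": labels,
        }
        (outdir / f"subject_{sid:02d}.json").write_text(json.dumps(manifest, indent=1))
        written.append(npz_path)
    return written


def _read_fixture(path: Path) -> list[SessionSet]:
    manifests = sorted(path.glob("subject_*.json"))
    if not manifests:
        raise FileNotFoundError(f"no fixture manifests under {path}")
    out: list[SessionSet] = []
    for mpath in manifests:
        manifest = json.loads(mpath.read_text())
        if manifest.get("version") != FIXTURE_VERSION:
            raise DialectError(
                f"{mpath}: fixture version {manifest.get('version')} unsupported"
            )
        arrays = np.load(mpath.with_suffix(".npz"))
        data = arrays["data"]
        if data.ndim != 3 or data.shape[1] != len(CHANNELS):
            raise DialectError(f"{mpath}: expected trials x 3 x samples array")
        fs = float(manifest["sampling_rate"])
        sid = int(manifest["subject_id"])
        sessions: dict[int, SessionSet] = {}
        for row, label, sess in zip(
            data, manifest["labels"], manifest["session_ids"]
        ):
            sessions.setdefault(
                sess, SessionSet(subject_id=sid, session_id=sess)
            ).trials.append(Trial(row, label, sampling_rate=fs))
        out.extend(sessions[k] for k in sorted(sessions))
    return out


def _read_gdf(path: Path) -> list[SessionSet]:
    """Read BCI-competition IV-2b GDF recordings via MNE.

    Each GDF file is one session; the subject/session ids are parsed from
    the competition file naming (``B0102T`` -> subject 1, session 2).
    Trials are epoched to [0, 8) s from trial start (code 768) with the cue
    (769 left / 770 right) at 3 s.  Trials carrying competition rejection
    markers are kept.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise DialectError("reading GDF requires the optional 'mne' package") from exc

    files = sorted(path.glob("*.gdf")) if path.is_dir() else [path]
    if not files:
        raise FileNotFoundError(f"no .gdf files under {path}")
    out = []
    for f in files:
        raw = mne.io.read_raw_gdf(f, preload=True, verbose="error")
        fs = float(raw.info["sfreq"])
        picks = [
            i for i, name in enumerate(raw.ch_names)
            if not name.upper().startswith("EOG")
        ][: len(CHANNELS)]
        if len(picks) != len(CHANNELS):
            raise DialectError(f"{f}: expected {len(CHANNELS)} EEG channels")
        sig = raw.get_data(picks=picks) * 1e6  # volts -> microvolts
        onsets = {}
        ann = raw.annotations
        n_epoch = int(round((EPOCH_WINDOW_S[1] - EPOCH_WINDOW_S[0]) * fs))
        stem = f.stem  # e.g. B0102T
        subject = int(stem[1:3]) if stem[1:3].isdigit() else 0
        session = int(stem[3:5]) if stem[3:5].isdigit() else 1
        trials = []
        cue_shift = int(round(CUE_ONSET_S * fs))
        for onset, desc in zip(ann.onset, ann.description):
            if desc not in (_GDF_EVENT_LEFT, _GDF_EVENT_RIGHT):
                continue
            label = "left" if desc == _GDF_EVENT_LEFT else "right"
            start = int(round(onset * fs)) - cue_shift
            if start < 0 or start + n_epoch > sig.shape[1]:
                continue
            trials.append(Trial(sig[:, start:start + n_epoch], label, fs))
        if not trials:
            raise DialectError(f"{f}: no cue events found")
        out.append(SessionSet(subject_id=subject, session_id=session, trials=trials))
    return out


def read_trials(path: str | Path, dialect: str = "fixture") -> list[SessionSet]:
    """Read a directory (or file) of trials in the given dialect."""
    path = Path(path)
    if dialect == "fixture":
        return _read_fixture(path)
    if dialect == "gdf":
        return _read_gdf(path)
    raise DialectError(f"unknown dialect {dialect!r}; expected 'fixture' or 'gdf'")


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def _sessions_of(sessions: Iterable[SessionSet], subject_id) -> dict[int, SessionSet]:
    found = {}
    for s in sessions:
        if s.subject_id == subject_id:
            if s.session_id in found:
                raise ValueError(
                    f"duplicate session {s.session_id} for subject {subject_id}"
                )
            found[s.session_id] = s
    return found


def split_intra_subject(
    sessions: Iterable[SessionSet], subject_id
) -> tuple[list[Trial], list[Trial]]:
    """Sessions 1-3 -> train, sessions 4-5 -> test, for one subject."""
    found = _sessions_of(sessions, subject_id)
    for sid in TRAIN_SESSIONS + TEST_SESSIONS:
        if sid not in found:
            raise ValueError(f"subject {subject_id}: missing session {sid}")
    train = [t for sid in TRAIN_SESSIONS for t in found[sid].trials]
    test = [t for sid in TEST_SESSIONS for t in found[sid].trials]
    return train, test


def assemble_inter_subject(
    all_subjects: Iterable[SessionSet], held_out_subject
) -> tuple[list[Trial], list[Trial]]:
    """Leave-one-subject-out: all 5 sessions of the others -> train;
    held-out subject's sessions 4-5 -> test."""
    all_subjects = list(all_subjects)
    subject_ids = {s.subject_id for s in all_subjects}
    if held_out_subject not in subject_ids:
        raise ValueError(f"held-out subject {held_out_subject!r} not in dataset")
    if len(subject_ids) < 2:
        raise ValueError("inter-subject split needs at least 2 subjects")
    train = [
        t
        for s in all_subjects
        if s.subject_id != held_out_subject
        for t in s.trials
    ]
    held = _sessions_of(all_subjects, held_out_subject)
    test = [t for sid in TEST_SESSIONS if sid in held for t in held[sid].trials]
    return train, test
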