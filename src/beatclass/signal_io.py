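"""Record I/O, preprocessing and annotation handling for two-lead ECG.

Records are stored in the WFDB header+signal convention (``.hea`` plus a
16-bit little-endian interleaved ``.dat``, format 16) with beat annotations
in a plain-text TSV sidecar (``<record>.tsv``: sample_index, source_label).
Preprocessing brings every record to 250 Hz, band-limits it to 0.05--75 Hz
and derives the two composite leads (magnitude and velocity) that all
downstream template matching and feature measurement run on.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps

TARGET_FS = 250.0
#: pairing window between a detection and an annotation fiducial
PAIR_WINDOW_MS = 150.0

# AAMI EC57 beat-class groups, keyed by the MIT-BIH/EDB annotation symbols.
# N: sinus node beats incl. left/right bundle branch block
# S: supraventricular ectopy (atrial/nodal premature or escape, aberrated)
# V: ventricular ectopy (premature, R-on-T, escape)
# F: fusion of ventricular and normal
# Q: unclassified (unknown, paced, fusion of paced and normal)
AAMI_MAP = {
    "N": "N", "L": "N", "R": "N", "e": "N", "j": "N", ".": "N",
    "A": "S", "a": "S", "J": "S", "S": "S",
    "V": "V", "E": "V", "r": "V",
    "F": "F",
    "Q": "Q", "/": "Q", "f": "Q", "?": "Q", "P": "Q",
}

#: binary class per AAMI group; Q beats never enter Se/Sp/PPV accounting
BINARY_MAP = {"N": "SVB", "S": "SVB", "V": "VB", "F": "VB", "Q": "EXCLUDED"}


@dataclass(frozen=True)
class BeatAnnotation:
    """A single annotated beat: fiducial sample, source symbol, class labels."""

    fiducial: int
    source_label: str
    aami: str
    binary: str

    @classmethod
    def from_label(cls, fiducial: int, source_label: str) -> "BeatAnnotation":
        aami, binary = map_annotation(source_label)
        return cls(int(fiducial), source_label, aami, binary)


@dataclass
class EcgRecord:
    """Two equal-length leads plus beat annotations."""

    lead1: np.ndarray
    lead2: np.ndarray
    fs: float
    annotations: list[BeatAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.lead1 = np.asarray(self.lead1, dtype=float)
        self.lead2 = np.asarray(self.lead2, dtype=float)
        if self.lead1.shape != self.lead2.shape or self.lead1.ndim != 1:
            raise ValueError("lead1 and lead2 must be 1-D and equal length")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        n = len(self.lead1)
        for a in self.annotations:
            if not 0 <= a.fiducial < n:
                raise ValueError(f"annotation fiducial {a.fiducial} outside [0, {n})")

    def __len__(self) -> int:
        return len(self.lead1)


@dataclass(frozen=True)
class CompositeLeads:
    """Composite magnitude and velocity leads (both nonnegative)."""

    mag: np.ndarray
    vel: np.ndarray


class FormatError(ValueError):
    """Raised for records that violate the two-signal WFDB layout."""


def map_annotation(source_label: str) -> tuple[str, str]:
    """Map a database beat symbol to its (AAMI class, binary class).

    Unknown symbols map to Q/EXCLUDED with a warning so that a stray label
    never silently enters the scored beat population.
    """
    aami = AAMI_MAP.get(source_label)
    if aami is None:
        warnings.warn(f"unknown beat label {source_label!r} mapped to Q", stacklevel=2)
        aami = "Q"
    return aami, BINARY_MAP[aami]


# ---------------------------------------------------------------------------
# WFDB-style record I/O (format 16, two signals) + TSV annotation dialect


def save_record(path: str | Path, record: EcgRecord, adc_gain: float = 1000.0) -> None:
    """Write ``<path>.hea`` / ``<path>.dat`` (format 16) and ``<path>.tsv``."""
    path = Path(path)
    n = len(record)
    counts = np.round(np.stack([record.lead1, record.lead2], axis=1) * adc_gain)
    counts = np.clip(counts, -32768, 32767).astype("<i2")
    path.with_suffix(".dat").write_bytes(counts.tobytes())
    name = path.name
    lines = [f"{name} 2 {record.fs:g} {n}"]
    for i in (1, 2):
        lines.append(f"{name}.dat 16 {adc_gain:g}(0)/mV 12 0 0 0 0 lead{i}")
    path.with_suffix(".hea").write_text("\n".join(lines) + "\n")
    ann_lines = ["sample_index\tsource_label"]
    ann_lines += [f"{a.fiducial}\t{a.source_label}" for a in record.annotations]
    path.with_suffix(".tsv").write_text("\n".join(ann_lines) + "\n")


def load_record(path: str | Path) -> EcgRecord:
    """Read a WFDB-style record (format 16) with its TSV annotations.

    The record is returned at its native sampling rate; lead order follows
    the header. Raises ``FileNotFoundError`` on missing files and
    ``FormatError`` for records with fewer than two signals or an
    unsupported sample format.
    """
    path = Path(path)
    hea = path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(hea)
    header_lines = [
        ln for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    rec_fields = header_lines[0].split()
    n_sig = int(rec_fields[1])
    fs = float(rec_fields[2]) if len(rec_fields) > 2 else 250.0
    if n_sig < 2:
        raise FormatError(f"record {path.name} has {n_sig} signal(s); need >= 2")
    sig_specs = [ln.split() for ln in header_lines[1 : 1 + n_sig]]
    gains = []
    for spec in sig_specs[:2]:
        if len(spec) > 1 and spec[1].split("x")[0] != "16":
            raise FormatError(f"unsupported sample format {spec[1]!r} (only 16)")
        gain_field = spec[2] if len(spec) > 2 else "200"
        gain = float(gain_field.split("(")[0].split("/")[0]) or 200.0
        gains.append(gain)
    dat = path.with_suffix(".dat")
    if not dat.exists():
        raise FileNotFoundError(dat)
    raw = np.frombuffer(dat.read_bytes(), dtype="<i2")
    raw = raw[: (len(raw) // n_sig) * n_sig].reshape(-1, n_sig)
    lead1 = raw[:, 0] / gains[0]
    lead2 = raw[:, 1] / gains[1]
    annotations = []
    tsv = path.with_suffix(".tsv")
    if tsv.exists():
        for ln in tsv.read_text().splitlines()[1:]:
            if not ln.strip():
                continue
            idx, label = ln.split("\t")[:2]
            annotations.append(BeatAnnotation.from_label(int(idx), label))
    return EcgRecord(lead1, lead2, fs, annotations)


# ---------------------------------------------------------------------------
# Preprocessing


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def resample_linear(record: EcgRecord, target_fs: float = TARGET_FS) -> EcgRecord:
    """Piecewise-linear resampling to ``target_fs`` with fiducial rescaling."""
    if record.fs == target_fs:
        return record
    n_in = len(record)
    ratio = target_fs / record.fs
    n_out = int(round(n_in * ratio))
    t_out = np.arange(n_out) / ratio
    src = np.arange(n_in, dtype=float)
    lead1 = np.interp(t_out, src, record.lead1)
    lead2 = np.interp(t_out, src, record.lead2)
    anns = []
    for a in record.annotations:
        fid = int(_round_half_away(np.array(a.fiducial * ratio)))
        fid = min(max(fid, 0), n_out - 1)
        anns.append(replace(a, fiducial=fid))
    return EcgRecord(lead1, lead2, target_fs, anns)


def bandpass(record: EcgRecord, low: float = 0.05, high: float = 75.0) -> EcgRecord:
    """Zero-phase 0.05--75 Hz band limiting, applied per lead.

    Realized as a 2nd-order Butterworth high-pass at ``low`` cascaded with a
    4th-order Butterworth low-pass at ``high``, run forward-backward.
    """
    if not 0 < low < high < record.fs / 2:
        raise ValueError(f"invalid band edges ({low}, {high}) at fs={record.fs}")
    sos_hp = sps.butter(2, low, btype="highpass", fs=record.fs, output="sos")
    sos_lp = sps.butter(4, high, btype="lowpass", fs=record.fs, output="sos")
    sos = np.vstack([sos_hp, sos_lp])
    lead1 = sps.sosfiltfilt(sos, record.lead1)
    lead2 = sps.sosfiltfilt(sos, record.lead2)
    return EcgRecord(lead1, lead2, record.fs, list(record.annotations))


def composite_leads(record: EcgRecord) -> CompositeLeads:
    """Magnitude and velocity composite leads.

    mag[i] = sqrt(lead1[i]^2 + lead2[i]^2);
    vel[i] = sqrt(d_lead1[i]^2 + d_lead2[i]^2) with the first-order
    difference of adjacent samples and vel[0] = 0 by convention.
    """
    mag = np.hypot(record.lead1, record.lead2)
    d1 = np.diff(record.lead1)
    d2 = np.diff(record.lead2)
    vel = np.concatenate([[0.0], np.hypot(d1, d2)])
    return CompositeLeads(mag=mag, vel=vel)


def preprocess(record: EcgRecord) -> EcgRecord:
    """Resample to 250 Hz then band-limit to 0.05--75 Hz."""
    return bandpass(resample_linear(record, TARGET_FS))


# ---------------------------------------------------------------------------
# Detection/annotation pairing


def pair_detections(
    detections: list[int],
    annotations: list[BeatAnnotation],
    fs: float = TARGET_FS,
    window_ms: float = PAIR_WINDOW_MS,
) -> tuple[list[tuple[int, BeatAnnotation]], list[int], list[BeatAnnotation]]:
    """Greedy one-to-one nearest pairing within ``window_ms``.

    Candidate (detection, annotation) pairs inside the window are taken in
    order of increasing time difference; each detection and each annotation
    is used at most once. Returns (pairs, unpaired_detections,
    unpaired_annotations); unpaired items are excluded from scoring.
    """
    max_delta = window_ms * fs / 1000.0
    candidates = []
    for di, d in enumerate(detections):
        for ai, a in enumerate(annotations):
            delta = abs(d - a.fiducial)
            if delta <= max_delta:
                candidates.append((delta, di, ai))
    candidates.sort()
    used_d: set[int] = set()
    used_a: set[int] = set()
    pairs = []
    for _, di, ai in candidates:
        if di in used_d or ai in used_a:
            continue
        used_d.add(di)
        used_a.add(ai)
        pairs.append((detections[di], annotations[ai]))
    pairs.sort(key=lambda p: p[0])
    unpaired_d = [d for i, d in enumerate(detections) if i not in used_d]
    unpaired_a = [a for i, a in enumerate(annotations) if i not in used_a]
    return pairs, unpaired_d, unpaired_a
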