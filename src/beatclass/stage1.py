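"""Stage 1: beat-template learning and matching with an adaptive threshold.

The first 10 s of a recording (the learning period) define the predominant
normal (reference) beat template: beats are greedily grouped by waveform
similarity and the largest/shortest-QRS subgroup is averaged.  Every later
beat is correlated against the reference template on the composite velocity
lead inside a 180 ms window from QRS onset; a correlation at or above the
adaptive correlation threshold (ACT) fast-tracks the beat to the SVB class.
ACT tracks the per-10-s optimal correlation threshold (OCT)

    ACT(i) = 0.75*ACT(i-1) + 0.25*OCT(i-1),   80 <= ACT <= 98

so that matching stays permissive under noise and strict on clean signal.
Non-matching beats may match, or found, one of up to 8 secondary templates
(repetitive non-reference morphologies); either way they proceed to the
feature extractor and Stage 2.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from beatclass.signal_io import CompositeLeads, EcgRecord, TARGET_FS, composite_leads

#: analysis window after QRS onset: 180 ms = 45 samples at 250 Hz
WINDOW_MS = 180.0
WINDOW_SAMPLES = 45
LEARNING_PERIOD_S = 10.0
SEGMENT_S = 10.0
ACT_MIN, ACT_MAX = 80.0, 98.0
ACT_DEFAULT = 90.0
OCT_STEP = 0.5
MAX_TEMPLATES = 8
#: exponential running-average weight of a newly matched beat
TEMPLATE_UPDATE_WEIGHT = 1.0 / 8.0
#: subgroup score weights: size must dominate over QRS shortness
SUBGROUP_SIZE_WEIGHT = 0.7
SUBGROUP_DUR_WEIGHT = 0.3


class MatchOutcome(Enum):
    MATCHED_REFERENCE = "matched_reference"
    MATCHED_OTHER = "matched_other"
    NONE = "none"


@dataclass
class BeatContext:
    """Everything Stage 1 and the feature extractor need about one beat."""

    fiducial: int
    qrs_on: int
    qrs_off: int
    vel_window: np.ndarray
    mag_window: np.ndarray
    p_wave: bool
    rr_prev: float = float("nan")
    rr_cur: float = float("nan")
    rr_next: float = float("nan")

    @property
    def qrs_dur_ms(self) -> float:
        return (self.qrs_off - self.qrs_on) * 1000.0 / TARGET_FS


@dataclass
class BeatTemplate:
    vel_avg: np.ndarray
    mag_avg: np.ndarray
    members: int
    qrs_dur: float
    qrs_act: float
    qrs_mob: float
    p_wave: bool
    is_reference: bool = False
    last_hit: int = -1

    @classmethod
    def from_beat(cls, beat: BeatContext, is_reference: bool = False) -> "BeatTemplate":
        from beatclass.features import qrs_activity, qrs_mobility

        return cls(
            vel_avg=beat.vel_window.astype(float).copy(),
            mag_avg=beat.mag_window.astype(float).copy(),
            members=1,
            qrs_dur=beat.qrs_dur_ms,
            qrs_act=qrs_activity(beat.mag_window),
            qrs_mob=qrs_mobility(beat.vel_window, beat.mag_window),
            p_wave=beat.p_wave,
            is_reference=is_reference,
        )

    def update(self, beat: BeatContext, beat_index: int,
               weight: float = TEMPLATE_UPDATE_WEIGHT) -> None:
        """Exponential running average with the new beat at ``weight``."""
        w = weight
        self.vel_avg = (1 - w) * self.vel_avg + w * beat.vel_window
        self.mag_avg = (1 - w) * self.mag_avg + w * beat.mag_window
        self.qrs_dur = (1 - w) * self.qrs_dur + w * beat.qrs_dur_ms
        from beatclass.features import qrs_activity, qrs_mobility

        self.qrs_act = (1 - w) * self.qrs_act + w * qrs_activity(beat.mag_window)
        self.qrs_mob = (1 - w) * self.qrs_mob + w * qrs_mobility(
            beat.vel_window, beat.mag_window
        )
        self.members += 1
        self.last_hit = beat_index


@dataclass
class TemplateBank:
    templates: list[BeatTemplate] = field(default_factory=list)
    act: float = ACT_DEFAULT
    oct_history: list[float] = field(default_factory=list)
    segment_index: int = 0

    @property
    def reference(self) -> BeatTemplate | None:
        for t in self.templates:
            if t.is_reference:
                return t
        return None

    def to_json(self) -> str:
        doc = {
            "version": 1,
            "act": self.act,
            "oct_history": self.oct_history,
            "segment_index": self.segment_index,
            "templates": [
                {
                    "vel_avg": t.vel_avg.tolist(),
                    "mag_avg": t.mag_avg.tolist(),
                    "members": t.members,
                    "qrs_dur": t.qrs_dur,
                    "qrs_act": t.qrs_act,
                    "qrs_mob": t.qrs_mob,
                    "p_wave": t.p_wave,
                    "is_reference": t.is_reference,
                    "last_hit": t.last_hit,
                }
                for t in self.templates
            ],
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "TemplateBank":
        doc = json.loads(text)
        bank = cls(act=doc["act"], oct_history=list(doc["oct_history"]),
                   segment_index=doc["segment_index"])
        for t in doc["templates"]:
            bank.templates.append(BeatTemplate(
                vel_avg=np.asarray(t["vel_avg"], dtype=float),
                mag_avg=np.asarray(t["mag_avg"], dtype=float),
                members=t["members"], qrs_dur=t["qrs_dur"],
                qrs_act=t["qrs_act"], qrs_mob=t["qrs_mob"],
                p_wave=t["p_wave"], is_reference=t["is_reference"],
                last_hit=t["last_hit"],
            ))
        return bank


# ---------------------------------------------------------------------------
# Delineation and P-wave detection (plumbing around the template matcher)


def _smooth(x: np.ndarray, n: int = 5) -> np.ndarray:
    if len(x) < n:
        return x.astype(float)
    kernel = np.ones(n) / n
    return np.convolve(x, kernel, mode="same")


def delineate_qrs(
    vel: np.ndarray, mag: np.ndarray, fiducial: int, fs: float = TARGET_FS
) -> tuple[int, int]:
    """Locate QRS onset/offset around a fiducial from the velocity lead.

    Onset is the last sample before the fiducial where the smoothed velocity
    stays below 10% of the beat's peak velocity for at least 20 ms (searched
    up to 150 ms back); offset is the symmetric forward search (up to
    300 ms). A flat or too-short beat degenerates to fiducial +/- 1 sample.
    """
    s = _smooth(np.asarray(vel, dtype=float))
    run = max(int(round(0.020 * fs)), 1)          # 20 ms of quiet signal
    back = int(round(0.150 * fs))
    fwd = int(round(0.300 * fs))
    lo = max(fiducial - back, 0)
    hi = min(fiducial + fwd, len(s) - 1)
    peak = float(np.max(s[max(fiducial - back, 0): min(fiducial + back, len(s)) + 1]))
    if peak <= 0:
        return fiducial - 1, fiducial + 1
    # 10% of the beat's peak velocity, floored above the local noise level
    # (median of the search neighbourhood) so noisy baselines still delineate
    noise_floor = float(np.median(s[lo: hi + 1]))
    thr = max(0.10 * peak, 1.4 * noise_floor)
    below = s < thr

    qrs_on = -1
    # last i <= fiducial with `run` consecutive below-threshold samples ending at i
    for i in range(fiducial, lo - 1, -1):
        j = max(i - run + 1, 0)
        if np.all(below[j: i + 1]):
            qrs_on = i
            break
    if qrs_on < 0:  # no quiet run: take the quietest pre-beat sample
        seg = s[lo: fiducial + 1]
        qrs_on = lo + int(np.argmin(seg)) if len(seg) else lo
    qrs_off = -1
    for i in range(fiducial, hi + 1):
        j = min(i + run, len(s))
        if np.all(below[i:j]):
            qrs_off = i
            break
    if qrs_off < 0:
        seg = s[fiducial: hi + 1]
        qrs_off = fiducial + int(np.argmin(seg)) if len(seg) else hi
    if qrs_off <= qrs_on:
        return fiducial - 1, fiducial + 1
    return qrs_on, qrs_off


def detect_p_wave(
    mag: np.ndarray, qrs_on: int, fs: float = TARGET_FS
) -> bool:
    """Heuristic P-wave presence from the magnitude lead before QRS onset.

    True iff the maximum in [qrs_on - 200 ms, qrs_on - 40 ms] exceeds both
    5% of the beat's peak magnitude and twice the window's median. With
    less than 200 ms of pre-QRS signal the learning-period default (True)
    is returned.
    """
    pre = int(round(0.200 * fs))
    gap = int(round(0.040 * fs))
    if qrs_on - pre < 0:
        return True
    lo, hi = qrs_on - pre, qrs_on - gap
    window = np.asarray(mag[lo:hi], dtype=float)
    if window.size < 3:
        return True
    beat_peak = float(np.max(mag[qrs_on: qrs_on + WINDOW_SAMPLES])) if qrs_on + 1 < len(mag) else 0.0
    # true interior local maxima only: a monotone tail of a peak outside the
    # window (e.g. the previous beat's T wave) must not count as a P wave
    interior = (window[1:-1] >= window[:-2]) & (window[1:-1] >= window[2:])
    if not np.any(interior):
        return False
    m = float(np.max(window[1:-1][interior]))
    return m > 0.05 * beat_peak and m > 2.0 * float(np.median(window))


def extract_beat_contexts(record: EcgRecord, leads: CompositeLeads | None = None) -> list[BeatContext]:
    """Build a BeatContext per non-excluded-margin annotated beat.

    Beats closer than 300 ms to either record edge are skipped with a
    warning (insufficient delineation margin). RR intervals are attached in
    ms from the surviving fiducial sequence.
    """
    if leads is None:
        leads = composite_leads(record)
    margin = int(round(0.300 * record.fs))
    contexts: list[BeatContext] = []
    n = len(record)
    for ann in record.annotations:
        fid = ann.fiducial
        if fid < margin or fid > n - margin:
            warnings.warn(f"beat at {fid} skipped: insufficient margin", stacklevel=2)
            continue
        qrs_on, qrs_off = delineate_qrs(leads.vel, leads.mag, fid, record.fs)
        vel_w = leads.vel[qrs_on: qrs_on + WINDOW_SAMPLES].astype(float)
        mag_w = leads.mag[qrs_on: qrs_on + WINDOW_SAMPLES].astype(float)
        if len(vel_w) < WINDOW_SAMPLES:
            pad = WINDOW_SAMPLES - len(vel_w)
            vel_w = np.pad(vel_w, (0, pad))
            mag_w = np.pad(mag_w, (0, pad))
        contexts.append(BeatContext(
            fiducial=fid, qrs_on=qrs_on, qrs_off=qrs_off,
            vel_window=vel_w, mag_window=mag_w,
            p_wave=detect_p_wave(leads.mag, qrs_on, record.fs),
        ))
    ms_per_sample = 1000.0 / record.fs
    for i, ctx in enumerate(contexts):
        if i > 0:
            ctx.rr_cur = (ctx.fiducial - contexts[i - 1].fiducial) * ms_per_sample
        if i > 1:
            ctx.rr_prev = (contexts[i - 1].fiducial - contexts[i - 2].fiducial) * ms_per_sample
        if i < len(contexts) - 1:
            ctx.rr_next = (contexts[i + 1].fiducial - ctx.fiducial) * ms_per_sample
    return contexts


# ---------------------------------------------------------------------------
# Correlation and the adaptive threshold


def correlation(beat_vel: np.ndarray, template_vel: np.ndarray) -> float:
    """Normalized inner product of two velocity windows, in percent.

    corr = 100 * sum(B*T) / sqrt(sum(B^2) * sum(T^2)); for nonnegative
    velocity windows the range is [0, 100]. A zero-energy beat window
    yields 0 with a warning; a zero-energy template violates the contract.
    """
    b = np.asarray(beat_vel, dtype=float)
    t = np.asarray(template_vel, dtype=float)
    if b.shape != t.shape:
        raise ValueError("beat and template windows must have equal length")
    te = float(np.dot(t, t))
    if te == 0.0:
        raise ValueError("template window has zero energy")
    be = float(np.dot(b, b))
    if be == 0.0:
        warnings.warn("zero-energy beat window; correlation set to 0", stacklevel=2)
        return 0.0
    return 100.0 * float(np.dot(b, t)) / np.sqrt(be * te)


def _oct_grid() -> np.ndarray:
    # 98, 97.5, ..., 80 : 37 thresholds
    return np.round(np.arange(ACT_MAX, ACT_MIN - OCT_STEP / 2, -OCT_STEP), 1)


def find_oct(
    segment_beats: list[np.ndarray], prev_oct: float | None = None
) -> float:
    """Optimal correlation threshold of a 10 s segment.

    Scans 98% downwards in 0.5% steps for the highest threshold at which at
    least 75% of the segment's beats correlate at/above the threshold with
    at least 25% of the other beats; 80 if none qualifies. Segments with
    fewer than 2 beats return the previous OCT (default 90).
    """
    n = len(segment_beats)
    if n < 2:
        return prev_oct if prev_oct is not None else ACT_DEFAULT
    windows = np.stack([np.asarray(b, dtype=float) for b in segment_beats])
    energies = np.einsum("ij,ij->i", windows, windows)
    cross = windows @ windows.T
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(np.outer(energies, energies))
        corr = np.where(denom > 0, 100.0 * cross / denom, 0.0)
    np.fill_diagonal(corr, -np.inf)
    for thr in _oct_grid():
        per_beat = np.sum(corr >= thr, axis=1)
        qualifying = np.sum(per_beat >= 0.25 * (n - 1))
        if qualifying >= 0.75 * n:
            return float(thr)
    return ACT_MIN


def update_act(act_prev: float, oct_prev: float) -> float:
    """ACT(i) = 0.75*ACT(i-1) + 0.25*OCT(i-1), clipped to [80, 98]."""
    return float(np.clip(0.75 * act_prev + 0.25 * oct_prev, ACT_MIN, ACT_MAX))


# ---------------------------------------------------------------------------
# Reference learning and matching


def learn_reference(beats_10s: list[BeatContext]) -> TemplateBank:
    """Learn the predominant (reference) template from the learning period.

    Beats are greedily grouped: a beat joins the first subgroup whose
    average it correlates with at/above the learning segment's OCT, else it
    founds a new subgroup. Subgroups score
    0.7*(members/max_members) + 0.3*(1 - qrs_dur/max_qrs_dur); the top
    scorer's average becomes the reference. ACT is initialized to the
    learning segment's OCT.
    """
    if not beats_10s:
        raise ValueError("learning period contains no beats; defer to next window")
    init_thr = find_oct([b.vel_window for b in beats_10s], prev_oct=ACT_DEFAULT)
    groups: list[list[BeatContext]] = []
    averages: list[np.ndarray] = []
    for beat in beats_10s:
        placed = False
        for gi, avg in enumerate(averages):
            if correlation(beat.vel_window, avg) >= init_thr:
                groups[gi].append(beat)
                k = len(groups[gi])
                averages[gi] = avg * (k - 1) / k + beat.vel_window / k
                placed = True
                break
        if not placed:
            groups.append([beat])
            averages.append(beat.vel_window.astype(float).copy())
    max_members = max(len(g) for g in groups)
    durations = [float(np.mean([b.qrs_dur_ms for b in g])) for g in groups]
    max_dur = max(durations) if max(durations) > 0 else 1.0
    scores = [
        SUBGROUP_SIZE_WEIGHT * len(g) / max_members
        + SUBGROUP_DUR_WEIGHT * (1.0 - d / max_dur)
        for g, d in zip(groups, durations)
    ]
    best = int(np.argmax(scores))
    ref = _average_template(groups[best], is_reference=True)
    bank = TemplateBank(templates=[ref], act=init_thr)
    bank.oct_history.append(init_thr)
    return bank


def _average_template(beats: list[BeatContext], is_reference: bool) -> BeatTemplate:
    from beatclass.features import qrs_activity, qrs_mobility

    vel = np.mean([b.vel_window for b in beats], axis=0)
    mag = np.mean([b.mag_window for b in beats], axis=0)
    p_frac = np.mean([b.p_wave for b in beats])
    return BeatTemplate(
        vel_avg=vel, mag_avg=mag, members=len(beats),
        qrs_dur=float(np.mean([b.qrs_dur_ms for b in beats])),
        qrs_act=qrs_activity(mag), qrs_mob=qrs_mobility(vel, mag),
        p_wave=bool(p_frac >= 0.5), is_reference=is_reference,
    )


def match_and_update(
    beat: BeatContext, bank: TemplateBank, beat_index: int = 0
) -> MatchOutcome:
    """Match one beat against the bank and update/extend it.

    Reference first: corr >= ACT fast-tracks the beat (SVB by Stage 1) and
    updates the reference by running average. Otherwise the secondary
    templates are tried in insertion order; the first at/above ACT is
    updated. A fully non-matching beat founds a new single-member template
    only while the bank holds fewer than 8 (no replacement).
    """
    ref = bank.reference
    if ref is None:
        raise ValueError("bank has no reference template")
    if correlation(beat.vel_window, ref.vel_avg) >= bank.act:
        ref.update(beat, beat_index)
        return MatchOutcome.MATCHED_REFERENCE
    for template in bank.templates:
        if template.is_reference:
            continue
        if correlation(beat.vel_window, template.vel_avg) >= bank.act:
            template.update(beat, beat_index)
            return MatchOutcome.MATCHED_OTHER
    if len(bank.templates) < MAX_TEMPLATES:
        bank.templates.append(BeatTemplate.from_beat(beat))
        bank.templates[-1].last_hit = beat_index
    return MatchOutcome.NONE
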