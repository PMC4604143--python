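"""The 20 basic time-domain beat features and their second-order expansion.

Features F1-F20 describe a beat relative to the reference template and the
ongoing rhythm: template-match codes of the current/previous/next beat
(F1-F3), P-wave presence of the beat and the reference (F4-F5),
beat/previous/next correlation with the reference (F6-F8), QRS duration,
activity and mobility of the beat, the reference, and their difference
(F9-F17), and the normalized current/next RR interval plus the relative RR
variability of the trailing 10 s (F18-F20).  The expansion appends the 190
pairwise products Fi*Fj (i<j) for a 210-element vector capturing
second-order interactions.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd

from beatclass.stage1 import BeatContext, MatchOutcome, TemplateBank
from beatclass.signal_io import TARGET_FS

N_BASIC = 20
N_EXPANDED = N_BASIC + N_BASIC * (N_BASIC - 1) // 2  # 210

# Defaults substituted while no reference template exists (learning period)
# and for missing neighbours at record edges.
DEFAULT_REF_P_WAVE = 1.0
DEFAULT_CORR = 80.0
DEFAULT_REF_QRS_DUR = 100.0   # ms
DEFAULT_REF_QRS_ACT = 100.0   # %
DEFAULT_REF_QRS_MOB = 100.0   # %
DEFAULT_MATCH_CODE = 0.0      # treat a missing neighbour as reference-matched

_MATCH_CODE = {
    MatchOutcome.MATCHED_REFERENCE: 0.0,
    MatchOutcome.MATCHED_OTHER: 1.0,
    MatchOutcome.NONE: -1.0,
}


def qrs_duration(qrs_on: int, qrs_off: int, fs: float = TARGET_FS) -> float:
    """QRS width between the delineated boundaries, in ms."""
    if qrs_off < qrs_on:
        raise ValueError("qrs_off must be >= qrs_on")
    return (qrs_off - qrs_on) * 1000.0 / fs


def qrs_activity(mag_window: np.ndarray) -> float:
    """100 * mean(mag) / max(mag) over the 180 ms window; 0 for a flat window.

    Large values indicate extended-area QRS morphologies (ventricular).
    """
    w = np.asarray(mag_window, dtype=float)
    if w.size == 0:
        raise ValueError("empty magnitude window")
    peak = float(np.max(w))
    if peak == 0.0:
        warnings.warn("all-zero magnitude window; QRSact set to 0", stacklevel=2)
        return 0.0
    # mean <= max holds mathematically; guard the float round-off at equality
    return min(100.0 * float(np.mean(w)) / peak, 100.0)


def qrs_mobility(vel_window: np.ndarray, mag_window: np.ndarray) -> float:
    """100 * sum(vel) / sum(mag): velocity area over magnitude area.

    A time-domain proxy for the higher/lower frequency content ratio; low
    for slow-edge/large-area (ventricular) morphologies.
    """
    v = np.asarray(vel_window, dtype=float)
    m = np.asarray(mag_window, dtype=float)
    if v.shape != m.shape:
        raise ValueError("velocity and magnitude windows must have equal length")
    denom = float(np.sum(m))
    if denom == 0.0:
        warnings.warn("zero magnitude area; QRSmob set to 0", stacklevel=2)
        return 0.0
    return 100.0 * float(np.sum(v)) / denom


def rr_features(
    rr_last4: list[float], rr_cur: float, rr_next: float, rr_10s: list[float]
) -> tuple[float, float, float]:
    """(curRR, nextRR, relRRv) in percent.

    curRR/nextRR normalize the current/next interval to the mean of the
    last (up to) four intervals; relRRv is the mean absolute successive
    difference over the trailing 10 s, normalized to its mean interval.
    """
    if len(rr_last4) == 0 or len(rr_10s) == 0:
        raise ValueError("at least one RR interval required")
    mean4 = float(np.mean(rr_last4[-4:]))
    if mean4 == 0.0:
        raise ValueError("mean of last four RR intervals is zero")
    cur = 100.0 * rr_cur / mean4
    nxt = 100.0 * rr_next / mean4
    rr10 = np.asarray(rr_10s, dtype=float)
    mean10 = float(np.mean(rr10))
    if len(rr10) < 2 or mean10 == 0.0:
        rel = 0.0
    else:
        rel = 100.0 * float(np.mean(np.abs(np.diff(rr10)))) / mean10
    return cur, nxt, rel


def assemble_basic(
    beat: BeatContext,
    prev: BeatContext | None,
    next: BeatContext | None,
    bank: TemplateBank | None,
    outcome: MatchOutcome = MatchOutcome.NONE,
    prev_outcome: MatchOutcome | None = None,
    next_outcome: MatchOutcome | None = None,
    rr_last4: list[float] | None = None,
    rr_10s: list[float] | None = None,
) -> np.ndarray:
    """Assemble F1-F20 for one beat.

    ``bank`` may be None (learning period): the reference-template features
    then take their documented defaults (reference P-wave present,
    corr = 80%, QRSdur = 100 ms, QRSact = 100%, QRSmob = 100%). Missing
    neighbours (record edges) likewise take defaults. Correlations F6-F8
    are always measured against the reference template at beat-arrival
    state.
    """
    from beatclass.stage1 import correlation

    ref = bank.reference if bank is not None else None

    def code(oc: MatchOutcome | None) -> float:
        return _MATCH_CODE[oc] if oc is not None else DEFAULT_MATCH_CODE

    def ref_corr(ctx: BeatContext | None) -> float:
        if ref is None or ctx is None:
            return DEFAULT_CORR
        return correlation(ctx.vel_window, ref.vel_avg)

    f = np.empty(N_BASIC)
    f[0] = code(outcome)                                   # F1
    f[1] = code(prev_outcome if prev is not None else None)  # F2
    f[2] = code(next_outcome if next is not None else None)  # F3
    f[3] = 1.0 if beat.p_wave else 0.0                     # F4
    f[4] = (1.0 if ref.p_wave else 0.0) if ref is not None else DEFAULT_REF_P_WAVE
    f[5] = ref_corr(beat)                                  # F6
    f[6] = ref_corr(prev)                                  # F7
    f[7] = ref_corr(next)                                  # F8
    f[8] = beat.qrs_dur_ms                                 # F9
    f[9] = ref.qrs_dur if ref is not None else DEFAULT_REF_QRS_DUR
    f[10] = f[8] - f[9]                                    # F11
    f[11] = qrs_activity(beat.mag_window)                  # F12
    f[12] = ref.qrs_act if ref is not None else DEFAULT_REF_QRS_ACT
    f[13] = f[11] - f[12]                                  # F14
    f[14] = qrs_mobility(beat.vel_window, beat.mag_window)  # F15
    f[15] = ref.qrs_mob if ref is not None else DEFAULT_REF_QRS_MOB
    f[16] = f[14] - f[15]                                  # F17

    rr_cur = beat.rr_cur if np.isfinite(beat.rr_cur) else float("nan")
    rr_next = beat.rr_next if np.isfinite(beat.rr_next) else float("nan")
    last4 = [r for r in (rr_last4 or []) if np.isfinite(r)]
    rr10 = [r for r in (rr_10s or []) if np.isfinite(r)]
    if not last4 and np.isfinite(rr_cur):
        last4 = [rr_cur]
    if not rr10 and np.isfinite(rr_cur):
        rr10 = [rr_cur]
    if last4 and rr10 and np.isfinite(rr_cur):
        nxt = rr_next if np.isfinite(rr_next) else float(np.mean(last4[-4:]))
        cur, nxt, rel = rr_features(last4, rr_cur, nxt, rr10)
    else:  # record edge without any usable interval
        cur, nxt, rel = 100.0, 100.0, 0.0
    f[17], f[18], f[19] = cur, nxt, rel
    return f


_PAIRS = list(itertools.combinations(range(N_BASIC), 2))


def expand(basic: np.ndarray) -> np.ndarray:
    """Second-order expansion: the n basic features followed by the
    n(n-1)/2 pairwise products fi*fj (i<j) in lexicographic pair order.

    Accepts a single vector or a 2-D table (rows expanded independently).
    No squared terms, so n = 20 expands to exactly 210 values.
    """
    x = np.asarray(basic, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("basic features must be finite")
    single = x.ndim == 1
    if single:
        x = x[None, :]
    n = x.shape[1]
    pairs = list(itertools.combinations(range(n), 2))
    out = np.empty((x.shape[0], n + len(pairs)))
    out[:, :n] = x
    for k, (i, j) in enumerate(pairs):
        out[:, n + k] = x[:, i] * x[:, j]
    return out[0] if single else out


def expanded_feature_names(n: int = N_BASIC) -> list[str]:
    """Stable column names of the expanded vector: F1..Fn then Fi*Fj."""
    names = [f"F{i + 1}" for i in range(n)]
    names += [f"F{i + 1}*F{j + 1}" for i, j in itertools.combinations(range(n), 2)]
    return names


# ---------------------------------------------------------------------------
# TSV interchange: beat id + 20 basic + 210 expanded = 231 columns


def write_feature_table(
    path, basic: np.ndarray, labels: np.ndarray, beat_ids=None
) -> None:
    basic = np.atleast_2d(np.asarray(basic, dtype=float))
    expanded = expand(basic)
    if beat_ids is None:
        beat_ids = np.arange(len(basic))
    cols = {"beat_id": beat_ids}
    for i in range(N_BASIC):
        cols[f"basic_F{i + 1}"] = basic[:, i]
    for k, name in enumerate(expanded_feature_names()):
        cols[name] = expanded[:, k]
    df = pd.DataFrame(cols)
    df["label"] = labels
    df.to_csv(path, sep="\t", index=False)


def read_feature_table(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Returns (expanded 210-column matrix, labels, beat ids)."""
    df = pd.read_csv(path, sep="\t")
    X = df[expanded_feature_names()].to_numpy(dtype=float)
    return X, df["label"].to_numpy(), df["beat_id"].to_numpy()
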