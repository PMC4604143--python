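"""Synthetic fixtures: annotated two-lead ECG streams and feature tables.

``gen_ecg_stream`` builds a two-lead record at 250 Hz as sums of Gaussian
bumps (P, QRS with Q/S lobes, T) per beat: normal beats are narrow
(~90 ms QRS) with a P wave; premature ventricular contractions (PVCs) are
wide (~160 ms), bifid, without a P wave, arrive early by a prematurity
fraction of the RR interval and are followed by a compensatory pause.
Additive white Gaussian noise models electrode noise.  This exercises
delineation, template matching and feature extraction; it does not emulate
respiration, baseline wander or electrode motion artefacts.

``gen_feature_table`` draws the 20 basic features directly from the
class-conditional distributions observed on large ambulatory training data
(discrete frequencies for F1-F5, Gaussian mean/std for F6-F20, correlation
features clipped to [0, 100]) and applies the 210-element expansion — the
canonical workload for the Stage-2 classifiers and the stepwise trainer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from beatclass.signal_io import BeatAnnotation, EcgRecord, TARGET_FS
from beatclass.features import expand

# Class-conditional distribution of the basic features on the beats that
# reach Stage 2 (SVB, VB). Continuous features: (mean, std); discrete
# F1-F3: frequencies for match codes (reference=0, other=1, none=-1);
# F4-F5: probability of a present P-wave.
FEATURE_DISTRIBUTIONS = {
    "F1": {"SVB": (0.0, 0.686, 0.314), "VB": (0.0, 0.713, 0.287)},
    "F2": {"SVB": (0.480, 0.311, 0.209), "VB": (0.823, 0.109, 0.068)},
    "F3": {"SVB": (0.489, 0.311, 0.200), "VB": (0.814, 0.108, 0.078)},
    "F4": {"SVB": 0.874, "VB": 0.620},
    "F5": {"SVB": 0.902, "VB": 0.949},
    "F6": {"SVB": (89.4, 12.0), "VB": (60.6, 24.9)},
    "F7": {"SVB": (91.6, 12.5), "VB": (93.3, 15.8)},
    "F8": {"SVB": (91.8, 12.2), "VB": (93.5, 14.5)},
    "F9": {"SVB": (138.6, 50.0), "VB": (184.1, 38.4)},
    "F10": {"SVB": (122.7, 32.2), "VB": (126.4, 29.3)},
    "F11": {"SVB": (15.9, 44.7), "VB": (57.7, 39.4)},
    "F12": {"SVB": (124.8, 35.9), "VB": (172.0, 34.7)},
    "F13": {"SVB": (113.9, 32.9), "VB": (109.9, 29.2)},
    "F14": {"SVB": (10.9, 33.7), "VB": (62.1, 38.4)},
    "F15": {"SVB": (90.8, 22.4), "VB": (60.0, 19.0)},
    "F16": {"SVB": (93.4, 19.6), "VB": (92.5, 18.6)},
    "F17": {"SVB": (-2.6, 18.4), "VB": (-32.5, 22.3)},
    "F18": {"SVB": (100.1, 12.8), "VB": (73.1, 16.4)},
    "F19": {"SVB": (100.0, 12.0), "VB": (121.5, 23.1)},
    "F20": {"SVB": (4.7, 5.6), "VB": (5.7, 7.7)},
}

#: correlation-type features are percentages in [0, 100]
_CLIPPED_FEATURES = {"F6", "F7", "F8"}
_MATCH_CODES = np.array([0.0, 1.0, -1.0])  # reference / other / none


@dataclass
class SyntheticSpec:
    """Conditions of a synthetic two-lead beat stream."""

    duration: float = 120.0        # s
    heart_rate: float = 75.0       # bpm
    pvc_rate: float = 0.1          # fraction of beats replaced by PVCs
    prematurity: float = 0.7       # PVC RR as a fraction of the base RR
    noise_rms: float = 0.02        # mV additive white noise
    p_wave_amp: float = 0.15       # mV
    qrs_widths: dict = field(default_factory=lambda: {"N": 90.0, "V": 160.0})
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.pvc_rate < 1:
            raise ValueError("pvc_rate must be in [0, 1)")
        if self.duration < 30:
            raise ValueError("duration must cover learning period + test beats (>= 30 s)")
        if self.heart_rate <= 0:
            raise ValueError("heart rate must be positive")


def _gauss(t: np.ndarray, center: float, sigma: float, amp: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((t - center) / sigma) ** 2)


def _beat_waveforms(t: np.ndarray, center: float, kind: str, spec: SyntheticSpec):
    """Additive contribution of one beat to (lead1, lead2)."""
    w1 = np.zeros_like(t)
    w2 = np.zeros_like(t)
    if kind == "N":
        qrs_s = spec.qrs_widths["N"] / 1000.0 / 6.0  # ~90 ms base width
        # P wave 160 ms before R
        w1 += _gauss(t, center - 0.160, 0.022, spec.p_wave_amp)
        w2 += _gauss(t, center - 0.160, 0.022, 0.6 * spec.p_wave_amp)
        # Q, R, S
        w1 += _gauss(t, center - 0.025, 0.008, -0.1)
        w1 += _gauss(t, center, qrs_s, 1.0)
        w1 += _gauss(t, center + 0.025, 0.008, -0.15)
        w2 += _gauss(t, center, qrs_s, 0.7)
        # T wave
        w1 += _gauss(t, center + 0.26, 0.05, 0.25)
        w2 += _gauss(t, center + 0.26, 0.05, 0.15)
    else:  # wide, bifid, no P wave, discordant T
        qrs_s = spec.qrs_widths["V"] / 1000.0 / 6.0
        w1 += _gauss(t, center - 0.02, qrs_s, 1.1)
        w1 += _gauss(t, center + 0.045, 0.6 * qrs_s, 0.55)
        w2 += _gauss(t, center, qrs_s, -0.9)
        w2 += _gauss(t, center + 0.05, 0.6 * qrs_s, -0.4)
        w1 += _gauss(t, center + 0.32, 0.07, -0.3)
        w2 += _gauss(t, center + 0.32, 0.07, 0.25)
    return w1, w2


def gen_ecg_stream(spec: SyntheticSpec) -> EcgRecord:
    """Generate an annotated two-lead 250 Hz record from ``spec``.

    PVCs are planted independently at ``pvc_rate`` (never the first two
    beats, never back-to-back), arrive at ``prematurity`` of the base RR
    and are followed by a compensatory pause so that the next normal beat
    falls back on the underlying sinus grid. Annotations mark each R peak
    with N or V. Output is byte-identical for a fixed spec + seed.
    """
    rng = np.random.default_rng(spec.seed)
    base_rr = 60.0 / spec.heart_rate
    fs = TARGET_FS

    beat_times: list[float] = []
    beat_kinds: list[str] = []
    t = 0.5
    grid = t  # underlying sinus grid
    while grid < spec.duration - 1.0:
        is_pvc = (
            len(beat_kinds) >= 2
            and beat_kinds[-1] != "V"
            and rng.random() < spec.pvc_rate
        )
        if is_pvc:
            # premature beat, then a compensatory pause back to the grid
            pvc_time = beat_times[-1] + spec.prematurity * base_rr
            if pvc_time < spec.duration - 1.2:
                beat_times.append(pvc_time)
                beat_kinds.append("V")
            grid += base_rr  # the skipped sinus beat
        else:
            beat_times.append(grid)
            beat_kinds.append("N")
        grid += base_rr

    n = int(round(spec.duration * fs))
    tt = np.arange(n) / fs
    lead1 = np.zeros(n)
    lead2 = np.zeros(n)
    for center, kind in zip(beat_times, beat_kinds):
        lo = max(int((center - 0.5) * fs), 0)
        hi = min(int((center + 0.6) * fs), n)
        w1, w2 = _beat_waveforms(tt[lo:hi], center, kind, spec)
        lead1[lo:hi] += w1
        lead2[lo:hi] += w2
    if spec.noise_rms > 0:
        lead1 = lead1 + rng.normal(0.0, spec.noise_rms, n)
        lead2 = lead2 + rng.normal(0.0, spec.noise_rms, n)

    annotations = [
        BeatAnnotation.from_label(int(round(c * fs)), k)
        for c, k in zip(beat_times, beat_kinds)
    ]
    return EcgRecord(lead1, lead2, fs, annotations)


@dataclass
class FeatureTableSpec:
    """Conditions of a synthetic Stage-2 feature table."""

    n_per_class: int = 5000
    distributions: dict = field(default_factory=lambda: FEATURE_DISTRIBUTIONS)
    #: correlation between F6 and F18 draws (their product ranks first in
    #: every trained model, so joint structure is worth emulating)
    corr_f6_f18: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("need at least one beat per class")
        if not -1.0 <= self.corr_f6_f18 <= 1.0:
            raise ValueError("correlation must lie in [-1, 1]")


def gen_feature_table(spec: FeatureTableSpec):
    """Draw a labeled feature table and expand it.

    Returns (expanded 210-column matrix, labels, basic 20-column matrix).
    Continuous features are Gaussian per class (independent apart from the
    optional F6-F18 correlation knob); discrete features are categorical at
    the observed frequencies; correlation-type features are clipped to
    [0, 100] after the draw.
    """
    rng = np.random.default_rng(spec.seed)
    dists = spec.distributions
    blocks = []
    labels = []
    for cls in ("SVB", "VB"):
        n = spec.n_per_class
        basic = np.empty((n, 20))
        for j in range(20):
            name = f"F{j + 1}"
            d = dists[name][cls]
            if name in ("F1", "F2", "F3"):
                basic[:, j] = _MATCH_CODES[rng.choice(3, size=n, p=np.asarray(d) / np.sum(d))]
            elif name in ("F4", "F5"):
                basic[:, j] = (rng.random(n) < d).astype(float)
            else:
                mean, std = d
                basic[:, j] = rng.normal(mean, std, n) if std > 0 else mean
        if spec.corr_f6_f18 != 0.0:
            # redraw F6/F18 jointly with the requested correlation
            rho = spec.corr_f6_f18
            z = rng.standard_normal((n, 2))
            z[:, 1] = rho * z[:, 0] + np.sqrt(1 - rho**2) * z[:, 1]
            m6, s6 = dists["F6"][cls]
            m18, s18 = dists["F18"][cls]
            basic[:, 5] = m6 + s6 * z[:, 0]
            basic[:, 17] = m18 + s18 * z[:, 1]
        for j, name in enumerate(f"F{i + 1}" for i in range(20)):
            if name in _CLIPPED_FEATURES:
                basic[:, j] = np.clip(basic[:, j], 0.0, 100.0)
        blocks.append(basic)
        labels.append(np.full(n, cls))
    basic_all = np.vstack(blocks)
    y = np.concatenate(labels)
    return expand(basic_all), y, basic_all
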